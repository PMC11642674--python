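"""REML repeatability model: oracles, ratios, DRPs, bivariate fits."""

import numpy as np
import pandas as pd
import pytest

from pathblup.repeatability import (
    RepeatabilityModel,
    VarianceComponents,
    deregress_ebv,
    derive_ratios,
    genetic_correlation_bivariate,
)
from pathblup.simulate import SimulationScenario, TraitSpec, simulate_dataset
from pathblup.tables import Pedigree


def balanced_unrelated(n_boars=40, reps=6, s_between=2.0, s_within=1.0, seed=0):
    """Balanced one-way design on unrelated boars: intercept-only fixed part."""
    rng = np.random.default_rng(seed)
    rows = []
    effects = rng.normal(0, np.sqrt(s_between), n_boars)
    for b in range(n_boars):
        for _ in range(reps):
            rows.append(
                {"boar_id": f"b{b}", "hys": "h0", "age_months": 20.0,
                 "interval_days": 5.0,
                 "y": 10.0 + effects[b] + rng.normal(0, np.sqrt(s_within))}
            )
    pheno = pd.DataFrame(rows)
    ped = Pedigree(pd.DataFrame(
        {"id": [f"b{b}" for b in range(n_boars)], "sire": "0", "dam": "0"}
    ))
    return pheno, ped


class TestUnivariateREML:
    def test_matches_anova_intraclass_oracle(self):
        """On a balanced unrelated design the REML solution must match the
        one-way ANOVA estimator: between-boar variance (here the sum of the
        confounded additive and permanent-environment parts, since A = I)
        and the within-boar residual."""
        pheno, ped = balanced_unrelated()
        reps = 6
        res = RepeatabilityModel(pheno, ped, "y", fixed=()).fit(
            tol=1e-12, max_iter=500
        )
        wide = pheno.pivot_table(index="boar_id", values="y", aggfunc=["mean", "var"])
        grand = pheno["y"].mean()
        msb = reps * ((wide["mean"]["y"] - grand) ** 2).sum() / (len(wide) - 1)
        msw = wide["var"]["y"].mean()
        np.testing.assert_allclose(res.vc.sigma_e2, msw, rtol=1e-5)
        np.testing.assert_allclose(
            res.vc.sigma_u2 + res.vc.sigma_pe2, (msb - msw) / reps, rtol=1e-5
        )

    def test_mme_likelihood_equals_dense_oracle(self):
        """The MME determinant-identity likelihood must agree with the
        direct dense-V restricted likelihood at arbitrary parameter values."""
        sc = SimulationScenario(
            n_founders=20, n_generations=1, m_snps=80, n_chrom=2, n_genes=8,
            n_pathways=2, genes_per_pathway=4,
            traits=(TraitSpec("t", 0.3, 0.2, 1.0, 10.0),),
            n_records_mean=4, n_hys=3, seed=3,
        )
        ds = simulate_dataset(sc)
        m = RepeatabilityModel(ds.phenotypes, ds.pedigree, "t")
        Z, E, X, y = m.Zu.toarray(), m.Ep.toarray(), m.X, m.y

        def dense(su2, sp2, se2):
            V = su2 * Z @ m.A @ Z.T + sp2 * E @ E.T + se2 * np.eye(m.n)
            Vi = np.linalg.inv(V)
            XVX = X.T @ Vi @ X
            P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
            return (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XVX)[1]
                    + y @ P @ y)

        for theta in [(1, 1, 1), (2.0, 0.5, 3.0), (0.3, 0.2, 0.5)]:
            np.testing.assert_allclose(
                m.minus2_reml(*theta), dense(*theta), rtol=1e-9
            )

    def test_optimum_beats_dense_grid(self):
        """REML optimum attains a restricted likelihood at least as high as
        every point of a 20^3 grid evaluated by the dense oracle."""
        sc = SimulationScenario(
            n_founders=14, n_generations=1, m_snps=60, n_chrom=2, n_genes=6,
            n_pathways=2, genes_per_pathway=3,
            traits=(TraitSpec("t", 0.3, 0.2, 1.0, 10.0),),
            n_records_mean=3, n_hys=2, seed=5,
        )
        ds = simulate_dataset(sc)
        m = RepeatabilityModel(ds.phenotypes, ds.pedigree, "t")
        res = m.fit()
        vy = np.var(m.y)
        grid = np.linspace(0.05, 2.0, 20) * vy
        best_grid = min(
            m.minus2_reml(a, b, c) for a in grid for b in grid for c in grid
        )
        assert -2 * res.vc.loglik <= best_grid + 1e-8

    def test_null_additive_variance_recovery(self):
        """Data simulated without additive variance must yield small h2."""
        h2s = []
        for seed in range(5):
            sc = SimulationScenario(
                n_founders=100, n_generations=2, offspring_per_mating=4,
                m_snps=200, n_chrom=2, n_genes=8, n_pathways=2,
                genes_per_pathway=4,
                traits=(TraitSpec("t", 1e-4, 0.3, 1.0, 10.0),),
                n_records_mean=8, n_hys=8, seed=100 + seed,
            )
            ds = simulate_dataset(sc)
            res = RepeatabilityModel(ds.phenotypes, ds.pedigree, "t").fit()
            h2s.append(res.h2)
        assert np.mean(h2s) < 0.05

    def test_ebv_shrinkage_and_reliabilities(self):
        sc = SimulationScenario(
            n_founders=60, n_generations=2, offspring_per_mating=3,
            m_snps=200, n_chrom=2, n_genes=8, n_pathways=2, genes_per_pathway=4,
            traits=(TraitSpec("t", 0.3, 0.15, 1.0, 10.0),),
            n_records_mean=6, n_hys=6, seed=9,
        )
        ds = simulate_dataset(sc)
        res = RepeatabilityModel(ds.phenotypes, ds.pedigree, "t").fit()
        ebv = res.ebv_table()
        assert ebv["ebv"].var() <= res.vc.sigma_u2
        assert ebv["reliability"].between(0, 1).all()
        phenotyped = ebv[ebv["record_count"] > 0]
        assert (phenotyped["reliability"] > 0).all()

    def test_summary_mentions_ratios(self):
        pheno, ped = balanced_unrelated(n_boars=20, reps=4)
        res = RepeatabilityModel(pheno, ped, "y", fixed=()).fit()
        assert "h2=" in res.summary() and "repeatability=" in res.summary()


class TestDeriveRatios:
    @pytest.mark.parametrize(
        "comps, expected",
        [
            ((8.496, 7.744, 22.269), (0.221, 0.422)),  # semen volume row
            ((1.217, 0.732, 3.422), (0.227, 0.363)),   # sperm concentration row
            ((2.5, 0.0, 0.0), (1.0, 1.0)),
        ],
    )
    def test_published_component_arithmetic(self, comps, expected):
        vc = VarianceComponents("t", *comps)
        assert derive_ratios(vc) == expected

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            derive_ratios(VarianceComponents("t", 0.0, 0.0, 0.0))


class TestDeregression:
    def ebv_frame(self, rel, ebv=2.0):
        return pd.DataFrame(
            {"id": ["x"], "ebv": [ebv], "reliability": [rel], "record_count": [30]}
        )

    def test_full_reliability_no_shrinkage_to_undo(self):
        out = deregress_ebv(self.ebv_frame(1.0, ebv=1.7), h2=0.25)
        assert out.loc[0, "drp"] == pytest.approx(1.7)
        assert out.loc[0, "weight"] == pytest.approx((1 - 0.25) / (0.5 * 0.25))

    def test_half_reliability_doubles(self):
        out = deregress_ebv(self.ebv_frame(0.5, ebv=2.0), h2=0.25)
        assert out.loc[0, "drp"] == pytest.approx(4.0)

    def test_weight_formula_worked_example(self):
        # h2=0.25, rel=0.5, c=0.5: w = 0.75 / ((0.5 + 1) * 0.25) = 2
        out = deregress_ebv(self.ebv_frame(0.5), h2=0.25, c=0.5)
        assert out.loc[0, "weight"] == pytest.approx(2.0)

    def test_low_reliability_dropped(self):
        df = pd.concat([self.ebv_frame(0.05), self.ebv_frame(0.8)], ignore_index=True)
        out = deregress_ebv(df, h2=0.3)
        assert len(out) == 1
        assert out.loc[0, "reliability_drp"] == 0.8

    def test_invalid_h2_raises(self):
        with pytest.raises(ValueError):
            deregress_ebv(self.ebv_frame(0.9), h2=1.2)


class TestBivariate:
    def test_trait_with_itself_is_unity(self):
        r = genetic_correlation_bivariate(None, None, "vol", "vol")
        assert (r.r_g, r.r_p) == (1.0, 1.0)
        rg, rp = r  # tuple-unpackable contract
        assert (rg, rp) == (1.0, 1.0)

    def test_independent_traits_near_zero(self):
        sc = SimulationScenario(
            n_founders=80, n_generations=2, offspring_per_mating=4,
            m_snps=300, n_chrom=3, n_genes=9, n_pathways=2, genes_per_pathway=4,
            causal_fraction=1.0,
            traits=(TraitSpec("a", 0.3, 0.15, 1.0, 10.0),
                    TraitSpec("b", 0.3, 0.15, 1.0, 20.0)),
            genetic_corr=np.eye(2),
            n_records_mean=6, n_hys=6, seed=31,
        )
        ds = simulate_dataset(sc)
        r = genetic_correlation_bivariate(
            ds.phenotypes, ds.pedigree, "a", "b", max_iter=80, tol=1e-4
        )
        assert abs(r.r_g) < 0.15

    def test_em_increases_restricted_likelihood(self):
        """Positive-correlation data: the fitted genetic covariance must be
        positive and all component matrices PSD."""
        sc = SimulationScenario(
            n_founders=80, n_generations=2, offspring_per_mating=4,
            m_snps=300, n_chrom=3, n_genes=9, n_pathways=2, genes_per_pathway=4,
            causal_fraction=1.0,
            traits=(TraitSpec("a", 0.3, 0.15, 1.0, 10.0),
                    TraitSpec("b", 0.3, 0.15, 1.0, 20.0)),
            genetic_corr=np.array([[1.0, 0.6], [0.6, 1.0]]),
            n_records_mean=6, n_hys=6, seed=32,
        )
        ds = simulate_dataset(sc)
        r = genetic_correlation_bivariate(
            ds.phenotypes, ds.pedigree, "a", "b", max_iter=80, tol=1e-4
        )
        assert r.r_g > 0.2
        for S in (r.sigma_u, r.sigma_pe, r.sigma_e):
            assert np.linalg.eigvalsh(S)[0] > 0
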