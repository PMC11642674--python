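"""Kernel mixed models: ridge equivalence, grid oracles, predictions."""

import numpy as np
import pandas as pd
import pytest

from pathblup.kernel_models import (
    GPModelSpec,
    KernelBLUP,
    fit_gp_model,
    predict_genetic_values,
    reml_kernel_model,
)
from pathblup.kinship import RelationshipMatrix, vanraden_grm
from pathblup.pathways import build_pathway_snp_sets, extend_gene_intervals
from tests.conftest import make_genotypes


def hwe_genotypes(n, m, seed=0):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.5, m)
    return make_genotypes(rng.binomial(2, p, size=(n, m)).astype(float))


class TestOneKernel:
    def test_gblup_equals_snp_blup_ridge(self):
        """GBLUP BLUP values must equal ridge regression on centered
        dosages with penalty sigma_e2/sigma_alpha2 (marker-effect
        equivalence), to 1e-8 on a 50 x 200 panel."""
        rng = np.random.default_rng(1)
        gm = hwe_genotypes(50, 200, seed=1)
        M = gm.centered()
        p = gm.allele_freq()
        denom = 2 * np.sum(p * (1 - p))
        y = 1.0 + M @ rng.normal(0, 0.05, 200) + rng.normal(0, 1.0, 50)
        fit = KernelBLUP(y, [vanraden_grm(gm)], gm.ids).fit()
        sg2, se2 = fit.components
        # independent ridge oracle built directly from the marker matrix
        sa2 = sg2 / denom
        V = sa2 * M @ M.T + se2 * np.eye(50)
        Vi = np.linalg.inv(V)
        ones = np.ones(50)
        mu = (ones @ Vi @ y) / (ones @ Vi @ ones)
        alpha = np.linalg.solve(M.T @ M + (se2 / sa2) * np.eye(200), M.T @ (y - mu))
        np.testing.assert_allclose(
            fit.predictions()["ghat"].to_numpy(), M @ alpha, atol=1e-8
        )
        assert fit.mu == pytest.approx(mu, abs=1e-8)

    def test_profiled_and_ai_paths_agree(self):
        """The 1-D profiled solver and the generic AI-REML solver must find
        the same optimum when the second kernel is forced to nothing."""
        rng = np.random.default_rng(2)
        gm = hwe_genotypes(60, 150, seed=2)
        G = vanraden_grm(gm).ensure_psd()
        y = rng.normal(0, 1, 60) + np.linalg.cholesky(
            G.values + 1e-6 * np.eye(60)
        ) @ rng.normal(0, 0.8, 60)
        one = KernelBLUP(y, [G], gm.ids).fit(method="profiled")
        two = KernelBLUP(y, [G], gm.ids).fit(method="ai")
        np.testing.assert_allclose(one.components, two.components, rtol=1e-4)
        assert one.loglik == pytest.approx(two.loglik, abs=1e-6)

    def test_pure_noise_gives_null_heritability(self):
        ratios = []
        for seed in range(5):
            rng = np.random.default_rng(40 + seed)
            gm = hwe_genotypes(300, 300, seed=50 + seed)
            y = rng.normal(0, 1, 300)
            fit = KernelBLUP(y, [vanraden_grm(gm)], gm.ids).fit()
            sg2, se2 = fit.components
            ratios.append(sg2 / (sg2 + se2))
        assert np.mean(ratios) < 0.05


class TestTwoKernel:
    def test_optimum_beats_grid_oracle(self):
        """Two-kernel AI-REML optimum must beat a 15^3 brute-force grid."""
        rng = np.random.default_rng(3)
        gm = hwe_genotypes(25, 120, seed=3)
        G = vanraden_grm(gm).ensure_psd()
        Gp = vanraden_grm(gm, np.arange(40)).ensure_psd()
        L = np.linalg.cholesky(G.values + 1e-6 * np.eye(25))
        y = L @ rng.normal(0, 1, 25) + rng.normal(0, 0.7, 25)
        fit = KernelBLUP(y, [G, Gp], gm.ids).fit()
        vy = y.var()
        grid = np.linspace(0.05, 2.0, 15) * vy
        d = np.ones(25)
        best = min(
            KernelBLUP._minus2_reml_dense(y, [G.values, Gp.values], d,
                                          np.array([a, b, c]))
            for a in grid for b in grid for c in grid
        )
        assert fit.minus2_reml <= best + 1e-8

    def test_weights_scale_residual_variance(self):
        rng = np.random.default_rng(4)
        gm = hwe_genotypes(40, 100, seed=4)
        G = vanraden_grm(gm).ensure_psd()
        y = rng.normal(0, 1, 40)
        w = np.full(40, 2.0)
        plain = KernelBLUP(y, [G], gm.ids).fit()
        weighted = KernelBLUP(y, [G], gm.ids, weights=w).fit()
        # constant weights w: residual variance rescales by w, the kernel
        # variance and the likelihood-implied fit stay the same
        assert weighted.components[-1] == pytest.approx(
            2 * plain.components[-1], rel=1e-4
        )
        assert weighted.components[0] == pytest.approx(
            plain.components[0], rel=1e-4
        )


class TestPrediction:
    def test_duplicate_masked_individual_gets_identical_prediction(self):
        rng = np.random.default_rng(5)
        gm = hwe_genotypes(30, 80, seed=5)
        calls = gm.calls.copy()
        calls[-1] = calls[0]  # masked duplicate of training individual 0
        gm2 = make_genotypes(calls)
        y = rng.normal(0, 1, 30)
        G = vanraden_grm(gm2).ensure_psd()
        fit = KernelBLUP(y, [G], gm2.ids, masked_ids=[gm2.ids[-1]]).fit()
        preds = fit.predictions().set_index("id")
        assert preds.loc[gm2.ids[-1], "total"] == pytest.approx(
            preds.loc[gm2.ids[0], "total"], abs=1e-10
        )

    def test_fixed_zero_genetic_variance_predicts_zero(self):
        rng = np.random.default_rng(6)
        gm = hwe_genotypes(25, 60, seed=6)
        G = vanraden_grm(gm).ensure_psd()
        y = rng.normal(0, 1, 25)
        fit = KernelBLUP(y, [G], gm.ids).fit(fixed_components=(1e-12, 1.0))
        assert np.abs(fit.predictions()["total"]).max() < 1e-6

    def test_three_individual_hand_mme(self):
        """Two training individuals, one masked: prediction equals the
        closed-form BLUP K_vt (K_tt sigma_g2 + I sigma_e2)^-1 (y - mu)."""
        K = np.array([[1.0, 0.2, 0.5], [0.2, 1.0, 0.3], [0.5, 0.3, 1.0]])
        rm = RelationshipMatrix(["a", "b", "c"], K, "grm_vanraden")
        y = np.array([1.0, -1.0, 0.0])
        sg2, se2 = 0.8, 0.4
        # build below the n >= 20 production floor for this desk-size check
        fit = object.__new__(KernelBLUP)
        fit.ids = ["a", "b", "c"]
        fit.y = y
        fit.kernels = [rm]
        fit.train = np.array([True, True, False])
        fit.weights = None
        res = fit.fit(fixed_components=(sg2, se2))
        Ktt = K[:2, :2]
        V = sg2 * Ktt + se2 * np.eye(2)
        Vi = np.linalg.inv(V)
        ones = np.ones(2)
        mu = (ones @ Vi @ y[:2]) / (ones @ Vi @ ones)
        ghat_c = sg2 * K[2, :2] @ Vi @ (y[:2] - mu)
        table = predict_genetic_values(res, ["c"])
        assert table.loc[0, "total"] == pytest.approx(ghat_c, abs=1e-10)

    def test_masked_id_must_exist(self):
        gm = hwe_genotypes(25, 40, seed=7)
        G = vanraden_grm(gm).ensure_psd()
        with pytest.raises(KeyError):
            KernelBLUP(np.zeros(25), [G], gm.ids, masked_ids=["ghost"])


class TestModelSuite:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            GPModelSpec("GFBLUP")  # pathway models need a pathway
        with pytest.raises(ValueError):
            GPModelSpec("superBLUP")

    def test_biblup_on_all_snp_pathway_additive_data(self, small_epistatic_dataset):
        """With an additive-only response, the pathway interaction variance
        must stay small relative to the genome-wide additive variance."""
        ds = small_epistatic_dataset
        rng = np.random.default_rng(8)
        boars = ds.boars
        tv = ds.truth.values.set_index("id").loc[boars]
        drp = pd.DataFrame(
            {"id": boars, "drp": tv["abn_u"] + rng.normal(0, 0.3, len(boars)),
             "weight": 1.0}
        )
        sets = build_pathway_snp_sets(
            ds.genotypes.snps, extend_gene_intervals(ds.annotation), ds.pathway_map
        )
        idx = [ds.genotypes.ids.index(b) for b in boars]
        gmb = ds.genotypes.subset(individuals=idx)
        res = fit_gp_model(
            GPModelSpec("GFBLUP", pathway_id="path001"), drp, gmb, sets
        )
        assert res.sigma_i2 < 0.5 * res.sigma_g2 + 0.05

    def test_divisor_selection_member_of_family(self, small_epistatic_dataset):
        ds = small_epistatic_dataset
        rng = np.random.default_rng(9)
        boars = ds.boars
        tv = ds.truth.values.set_index("id").loc[boars]
        drp = pd.DataFrame(
            {"id": boars,
             "drp": tv["abn_u"] + tv["abn_epi"] + rng.normal(0, 0.2, len(boars)),
             "weight": 1.0}
        )
        sets = build_pathway_snp_sets(
            ds.genotypes.snps, extend_gene_intervals(ds.annotation), ds.pathway_map
        )
        idx = [ds.genotypes.ids.index(b) for b in boars]
        gmb = ds.genotypes.subset(individuals=idx)
        res = fit_gp_model(
            GPModelSpec("biBLUP", pathway_id="path000"), drp, gmb, sets
        )
        # the selected kernel bandwidth must come from the divisor family
        div = res.model.kernels[1].meta["bandwidth"]
        from pathblup.kinship import bandwidth_candidates

        fam = bandwidth_candidates(gmb.mean_impute(), sets.sets["path000"])
        assert any(abs(div - h) / h < 1e-9 for h in fam.candidates)
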