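"""Relationship matrices: VanRaden G, Gaussian kernels, pedigree A,
bandwidth family and reference-panel selection."""

import numpy as np
import pandas as pd
import pytest

from pathblup.kinship import (
    RelationshipMatrix,
    bandwidth_candidates,
    gaussian_kernel,
    pedigree_numerator_matrix,
    select_reference_panel,
    vanraden_grm,
)
from pathblup.tables import Pedigree
from tests.conftest import make_genotypes


class TestVanRadenGRM:
    def test_two_by_two_hand_example(self):
        # dosages [(0,2),(2,0)], p=(0.5,0.5): denominator 1, G = [[2,-2],[-2,2]]
        gm = make_genotypes([[0, 2], [2, 0]])
        G = vanraden_grm(gm)
        np.testing.assert_allclose(G.values, [[2, -2], [-2, 2]], atol=1e-12)

    def test_identical_individuals(self):
        gm = make_genotypes([[0, 1, 2], [0, 1, 2], [2, 1, 0]])
        G = vanraden_grm(gm).values
        assert G[0, 0] == pytest.approx(G[0, 1])
        np.testing.assert_allclose(G[0], G[1])

    def test_mean_diagonal_near_one_under_hwe(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.5, 2000)
        calls = rng.binomial(2, p, size=(400, 2000)).astype(float)
        G = vanraden_grm(make_genotypes(calls))
        assert np.diag(G.values).mean() == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_dropped_and_all_mono_raises(self):
        gm = make_genotypes([[0, 2, 1], [0, 0, 1], [0, 1, 2]])
        G = vanraden_grm(gm)
        assert G.meta["n_snps"] == 2  # the all-zero column contributes nothing
        mono = make_genotypes([[2, 2], [2, 2]])
        with pytest.raises(ValueError, match="monomorphic"):
            vanraden_grm(mono)

    def test_partition_additivity(self):
        """G over all SNPs equals the denominator-weighted sum of the
        per-subset numerators over a partition of the SNPs."""
        rng = np.random.default_rng(8)
        calls = rng.binomial(2, rng.uniform(0.1, 0.5, 60), size=(30, 60)).astype(float)
        gm = make_genotypes(calls)
        G = vanraden_grm(gm)
        parts = [np.arange(0, 20), np.arange(20, 45), np.arange(45, 60)]
        num = sum(
            vanraden_grm(gm, pt).values * vanraden_grm(gm, pt).meta["denominator"]
            for pt in parts
        )
        np.testing.assert_allclose(
            G.values, num / G.meta["denominator"], atol=1e-10
        )

    def test_psd_validation(self):
        rng = np.random.default_rng(9)
        gm = make_genotypes(rng.binomial(2, 0.3, size=(20, 100)).astype(float))
        vanraden_grm(gm).validate()


class TestGaussianKernel:
    def test_unit_diagonal(self):
        rng = np.random.default_rng(10)
        gm = make_genotypes(rng.integers(0, 3, size=(8, 40)).astype(float))
        K = gaussian_kernel(gm, bandwidth=3.0)
        assert (np.diag(K.values) == 1.0).all()
        K.validate()

    def test_known_offdiagonal_value(self):
        # two individuals, centered squared distance d, h = d -> K12 = e^-1
        gm = make_genotypes([[0, 0], [2, 2]])
        d = float(((gm.centered()[0] - gm.centered()[1]) ** 2).sum())
        K = gaussian_kernel(gm, bandwidth=d)
        assert K.values[0, 1] == pytest.approx(np.exp(-1), abs=1e-12)

    def test_limits(self):
        rng = np.random.default_rng(11)
        gm = make_genotypes(rng.integers(0, 3, size=(6, 30)).astype(float))
        med = bandwidth_candidates(gm).median_sq_dist
        wide = gaussian_kernel(gm, bandwidth=1e9 * med)
        np.testing.assert_allclose(wide.values, 1.0, atol=1e-6)
        narrow = gaussian_kernel(gm, bandwidth=med / 1e6)
        off = narrow.values[~np.eye(6, dtype=bool)]
        assert (off < 1e-12).all()

    def test_rejects_nonpositive_bandwidth(self):
        gm = make_genotypes([[0, 1], [1, 2]])
        with pytest.raises(ValueError):
            gaussian_kernel(gm, bandwidth=0.0)


class TestBandwidthFamily:
    def test_median_and_divisor_arithmetic(self):
        # three individuals with pairwise squared distances {1, 4, 9}
        gm = make_genotypes([[0, 0], [2, 0], [0, 2]])
        M = gm.centered()
        from scipy.spatial.distance import pdist

        d2 = sorted(pdist(M, "sqeuclidean"))
        fam = bandwidth_candidates(gm)
        assert fam.median_sq_dist == pytest.approx(d2[1])
        np.testing.assert_allclose(
            fam.candidates, [fam.median_sq_dist / d for d in fam.divisors]
        )
        assert list(fam.candidates) == sorted(fam.candidates, reverse=True)

    def test_two_individuals_single_distance(self):
        gm = make_genotypes([[0, 1], [2, 1]])
        from scipy.spatial.distance import pdist

        fam = bandwidth_candidates(gm)
        assert fam.median_sq_dist == pytest.approx(
            float(pdist(gm.centered(), "sqeuclidean")[0])
        )

    def test_identical_individuals_raise(self):
        gm = make_genotypes([[1, 1], [1, 1], [0, 2]])
        # distances all zero after centering only if ALL are identical
        gm2 = make_genotypes([[1, 2], [1, 2]])
        with pytest.raises(ValueError, match="median"):
            bandwidth_candidates(gm2)


class TestPedigreeA:
    def test_unrelated_founders_identity(self):
        ped = Pedigree(pd.DataFrame(
            {"id": list("abc"), "sire": ["0"] * 3, "dam": ["0"] * 3}
        ))
        A = pedigree_numerator_matrix(ped)
        np.testing.assert_array_equal(A.values, np.eye(3))

    def test_parent_offspring_and_full_sibs(self):
        ped = Pedigree(pd.DataFrame(
            {
                "id": ["S", "D", "O1", "O2"],
                "sire": ["0", "0", "S", "S"],
                "dam": ["0", "0", "D", "D"],
            }
        ))
        A = pedigree_numerator_matrix(ped, subset_ids=["S", "D", "O1", "O2"])
        idx = {i: k for k, i in enumerate(A.ids)}
        assert A.values[idx["O1"], idx["S"]] == pytest.approx(0.5)
        assert A.values[idx["O1"], idx["O2"]] == pytest.approx(0.5)

    def test_inbred_offspring_of_full_sibs(self):
        ped = Pedigree(pd.DataFrame(
            {
                "id": ["S", "D", "O1", "O2", "X"],
                "sire": ["0", "0", "S", "S", "O1"],
                "dam": ["0", "0", "D", "D", "O2"],
            }
        ))
        A = pedigree_numerator_matrix(ped)
        x = A.ids.index("X")
        assert A.values[x, x] == pytest.approx(1.25)

    def test_subset_extraction(self):
        ped = Pedigree(pd.DataFrame(
            {"id": ["S", "D", "O"], "sire": ["0", "0", "S"], "dam": ["0", "0", "D"]}
        ))
        A = pedigree_numerator_matrix(ped, subset_ids=["O"])
        assert A.ids == ["O"] and A.values.shape == (1, 1)


class TestReferencePanel:
    def grm_from(self, values, ids):
        return RelationshipMatrix(ids=ids, values=np.asarray(values, float),
                                  flavor="grm_vanraden")

    def test_first_pick_is_highest_row_mean(self):
        G = [[1.0, 0.1, 0.1], [0.1, 1.0, 0.6], [0.1, 0.6, 1.0]]
        sel = select_reference_panel(self.grm_from(G, list("abc")), 0.99)
        assert sel[0] in ("b", "c")  # tie between b and c -> id order
        assert sel[0] == "b"

    def test_full_target_selects_everyone_unrelated(self):
        sel = select_reference_panel(self.grm_from(np.eye(3), list("abc")), 1.0)
        assert sorted(sel) == list("abc")

    def test_duplicate_individual_never_selected_second(self):
        # c duplicates b; once b is in, c is fully covered (rep contribution 1)
        G = np.array(
            [
                [1.0, 0.05, 0.05, 0.3],
                [0.05, 1.0, 1.0, 0.4],
                [0.05, 1.0, 1.0, 0.4],
                [0.3, 0.4, 0.4, 1.0],
            ]
        )
        sel = select_reference_panel(self.grm_from(G, list("abcd")), 0.999)
        assert "c" not in sel[:3]  # a and d add coverage before the duplicate

    def test_rejects_wrong_flavor(self):
        rm = RelationshipMatrix(list("ab"), np.eye(2), "gaussian_kernel")
        with pytest.raises(ValueError):
            select_reference_panel(rm)
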