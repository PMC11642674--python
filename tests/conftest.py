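import numpy as np
import pandas as pd
import pytest

from pathblup.genotypes import GenotypeMatrix
from pathblup.tables import Pedigree


def make_genotypes(calls, chrom=None, pos=None, ids=None):
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else (np.arange(m) + 1) * 100,
            "ref": "A",
            "alt": "B",
        }
    )
    return GenotypeMatrix(
        ids=ids if ids is not None else [f"i{k}" for k in range(n)],
        snps=snps,
        calls=calls,
    )


@pytest.fixture
def trio_pedigree():
    return Pedigree(
        pd.DataFrame(
            {"id": ["O", "S", "D"], "sire": ["S", "0", "0"], "dam": ["D", "0", "0"]}
        )
    )


@pytest.fixture
def small_epistatic_dataset():
    """Sib-structured population with one epistatic trait (cached per session)."""
    from pathblup.simulate import SimulationScenario, TraitSpec, simulate_dataset

    sc = SimulationScenario(
        n_founders=40, n_generations=2, offspring_per_mating=4,
        m_snps=600, n_chrom=3, n_genes=40, n_pathways=3, genes_per_pathway=8,
        n_epi_pairs=80,
        traits=(TraitSpec("abn", 0.2, 0.0, 1.0, 0.0, h2_epi=0.4,
                          causal_pathway_id="path000"),),
        n_records_mean=1, n_hys=2, seed=424242,
    )
    return simulate_dataset(sc)
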