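"""Synthetic pedigree / genotype / phenotype generator.

Emulates the statistical structure of a boar-station dataset: a
pedigreed population genotyped at biallelic SNPs, four correlated
semen traits (VOL, DEN, MOT, ABN) measured repeatedly per boar under
a repeatability model

    y = HYS + age + interval + u + (epi) + pe + e,

with additive values built from a random causal SNP subset, optional
additive-by-additive epistasis confined to one annotated pathway, a
permanent-environment effect per boar, and i.i.d. residuals per
ejection record.  Every draw flows from a single scenario seed, so
datasets are reproducible bit for bit.

Defaults mirror the analysis regime this package targets: founder
allele frequencies U(0.05, 0.5), trait heritabilities/repeatabilities
and variance scales as estimated for Duroc boar semen traits, an
average of 111 ejection records per boar, and a default genetic
correlation matrix whose signs follow the reported trait correlations
(projected to the nearest PSD matrix; a fixture, not a claim).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .tables import Pedigree
from .pathways import build_pathway_snp_sets, extend_gene_intervals


# (h2_add, var_pe_frac, sigma_e) per trait: ratios and residual scales
# follow the repeatability-model estimates for Duroc semen traits.
DEFAULT_TRAITS = (
    ("vol", 0.221, 0.201, 4.719, 163.0),
    ("den", 0.227, 0.136, 1.850, 5.06),
    ("mot", 0.164, 0.158, 0.0548, 0.90),
    ("abn", 0.432, 0.155, 0.0548, 0.10),
)

# signs follow the reported genetic correlations among the four traits
DEFAULT_GENETIC_CORR = np.array(
    [
        [1.0, -0.736, -0.248, -0.20],
        [-0.736, 1.0, 0.552, 0.064],
        [-0.248, 0.552, 1.0, -0.837],
        [-0.20, 0.064, -0.837, 1.0],
    ]
)


def nearest_correlation_psd(R: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped PSD projection with unit diagonal restored."""
    w, V = np.linalg.eigh((R + R.T) / 2)
    R2 = (V * np.clip(w, eps, None)) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return R2


@dataclass
class TraitSpec:
    name: str
    h2_add: float
    var_pe_frac: float
    sigma_e: float
    mean: float = 0.0
    h2_epi: float = 0.0
    causal_pathway_id: str | None = None

    @property
    def total_variance(self) -> float:
        rest = 1.0 - self.h2_add - self.h2_epi - self.var_pe_frac
        if rest <= 0:
            raise ValueError(
                f"{self.name}: h2_add + h2_epi + var_pe_frac must be < 1"
            )
        return self.sigma_e**2 / rest

    @property
    def repeatability(self) -> float:
        return (self.h2_add + self.h2_epi + self.var_pe_frac)


@dataclass
class SimulationScenario:
    """All knobs of the generator; see module docstring for the model."""

    # population
    n_founders: int = 100
    n_generations: int = 3
    offspring_per_mating: int = 2
    # genome
    m_snps: int = 10_000
    n_chrom: int = 18
    maf_low: float = 0.05
    maf_high: float = 0.5
    snp_spacing_bp: int = 1000
    ld_block_snps: int = 1  # >1: founder haplotype blocks (LD for prune tests)
    ld_flip_prob: float = 0.05
    # annotation
    n_genes: int = 200
    gene_length_bp: int = 5000
    n_pathways: int = 10
    genes_per_pathway: int = 20
    # traits
    traits: tuple = tuple(
        TraitSpec(name, h2, pe, se, mu) for name, h2, pe, se, mu in DEFAULT_TRAITS
    )
    genetic_corr: np.ndarray | None = None
    causal_fraction: float = 0.2
    n_epi_pairs: int = 2000
    flank_bp: int = 5000
    # fixed effects and records
    n_hys: int = 20
    hys_sd_frac: float = 0.5  # HYS effect SD as fraction of trait SD
    age_slope_frac: float = 0.01  # per month, fraction of trait SD
    interval_slope_frac: float = 0.02  # per day, fraction of trait SD
    n_records_mean: float = 111.0
    seed: int = 20240101

    def __post_init__(self):
        if self.n_founders < 2 and self.n_generations > 0:
            raise ValueError("need at least 2 founders to breed generations")
        for v in (self.n_founders, self.m_snps, self.n_chrom, self.n_genes,
                  self.n_pathways, self.genes_per_pathway):
            if v <= 0:
                raise ValueError("all counts must be positive")
        for t in self.traits:
            t.total_variance  # raises if fractions exceed 1
        if self.genetic_corr is None:
            k = len(self.traits)
            base = DEFAULT_GENETIC_CORR[:k, :k] if k <= 4 else np.eye(k)
            self.genetic_corr = nearest_correlation_psd(np.array(base))
        else:
            self.genetic_corr = nearest_correlation_psd(
                np.asarray(self.genetic_corr, dtype=float)
            )

    def trait(self, name: str) -> TraitSpec:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(name)

    def with_trait(self, name: str, **kwargs) -> "SimulationScenario":
        traits = tuple(
            replace(t, **kwargs) if t.name == name else t for t in self.traits
        )
        return replace(self, traits=traits)


@dataclass
class TruthTables:
    """Per-individual true genetic/permanent values and realized fractions."""

    values: pd.DataFrame  # id x {trait}_u, {trait}_epi, {trait}_pe
    fractions: pd.DataFrame  # trait x realized h2_add, h2_epi, pe_frac
    causal_snps: np.ndarray


# ------------------------------------------------------------ population
def _founder_calls(sc: SimulationScenario, rng: np.random.Generator) -> tuple:
    m, n = sc.m_snps, sc.n_founders
    if sc.ld_block_snps <= 1:
        p = rng.uniform(sc.maf_low, sc.maf_high, size=m)
        calls = rng.binomial(2, p, size=(n, m)).astype(float)
        return calls, p
    # block-copy founders: two haplotypes per block, per-SNP flips
    n_blocks = int(np.ceil(m / sc.ld_block_snps))
    p_block = rng.uniform(sc.maf_low, sc.maf_high, size=n_blocks)
    haps = np.empty((2 * n, m), dtype=np.int8)
    for b in range(n_blocks):
        lo, hi = b * sc.ld_block_snps, min((b + 1) * sc.ld_block_snps, m)
        base = rng.binomial(1, p_block[b], size=2 * n)
        block = np.repeat(base[:, None], hi - lo, axis=1)
        flips = rng.random((2 * n, hi - lo)) < sc.ld_flip_prob
        haps[:, lo:hi] = np.where(flips, 1 - block, block)
    calls = (haps[0::2] + haps[1::2]).astype(float)
    return calls, calls.mean(axis=0) / 2.0


def simulate_population(
    sc: SimulationScenario,
) -> tuple[Pedigree, GenotypeMatrix]:
    """Pedigreed genotypes: binomial founders, gene-drop descendants.

    Each non-founder receives one allele per parent per SNP (a Bernoulli
    draw at half the parental dosage), SNPs transmitted independently.
    Individuals of the final generation are the phenotyping candidates.
    """
    rng = np.random.default_rng(sc.seed)
    founder_calls, _ = _founder_calls(sc, rng)

    ids = [f"F{i:05d}" for i in range(sc.n_founders)]
    sex = list(rng.integers(0, 2, size=sc.n_founders))  # 0 male, 1 female
    rows = [{"id": i, "sire": None, "dam": None} for i in ids]
    calls = [founder_calls]
    current = list(range(sc.n_founders))
    counter = sc.n_founders
    all_calls = founder_calls

    for gen in range(1, sc.n_generations + 1):
        males = [i for i in current if sex[i] == 0]
        females = [i for i in current if sex[i] == 1]
        if not males or not females:
            raise ValueError("a generation lacks one sex; increase n_founders")
        n_matings = max(1, len(current) // 2)
        sires = rng.choice(males, size=n_matings)
        dams = rng.choice(females, size=n_matings)
        new_idx = []
        kids = []
        for s_i, d_i in zip(sires, dams):
            for _ in range(sc.offspring_per_mating):
                a = rng.binomial(1, all_calls[s_i] / 2.0)
                b = rng.binomial(1, all_calls[d_i] / 2.0)
                kids.append((a + b).astype(float))
                iid = f"G{gen}_{counter:05d}"
                rows.append({"id": iid, "sire": ids[s_i], "dam": ids[d_i]})
                ids.append(iid)
                sex.append(int(rng.integers(0, 2)))
                new_idx.append(counter)
                counter += 1
        all_calls = np.vstack([all_calls, np.array(kids)])
        current = new_idx

    # SNP map: sorted positions over n_chrom chromosomes
    per_chrom = np.array_split(np.arange(sc.m_snps), sc.n_chrom)
    snp_rows = []
    for c, idx in enumerate(per_chrom, start=1):
        offs = np.sort(
            rng.choice(
                np.arange(1, (len(idx) + 1) * sc.snp_spacing_bp),
                size=len(idx), replace=False,
            )
        )
        for k, off in zip(idx, offs):
            snp_rows.append(
                {"snp_id": f"snp{k:06d}", "chrom": str(c), "pos": int(off),
                 "ref": "A", "alt": "B"}
            )
    gm = GenotypeMatrix(ids=ids, snps=pd.DataFrame(snp_rows), calls=all_calls)
    gm.meta["final_generation"] = [ids[i] for i in current] if sc.n_generations else list(ids)
    ped = Pedigree(pd.DataFrame(rows))
    return ped, gm


# ------------------------------------------------------------ annotation
def simulate_annotation(
    sc: SimulationScenario, snps: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Non-overlapping genes tiled over the simulated chromosomes plus a
    random pathway->gene map (sampling with replacement across pathways)."""
    rng = np.random.default_rng(sc.seed + 1)
    chroms = snps["chrom"].unique()
    lengths = {c: int(snps.loc[snps["chrom"] == c, "pos"].max()) for c in chroms}
    genes_per_chrom = int(np.ceil(sc.n_genes / len(chroms)))
    rows = []
    gid = 0
    for c in chroms:
        L = lengths[c]
        pitch = L / genes_per_chrom
        if sc.gene_length_bp >= pitch:
            raise ValueError(
                f"requested gene span exceeds genome length on chrom {c}"
            )
        for k in range(genes_per_chrom):
            if gid >= sc.n_genes:
                break
            start = int(k * pitch) + 1
            rows.append(
                {"gene_id": f"gene{gid:04d}", "chrom": str(c), "start": start,
                 "end": start + sc.gene_length_bp - 1, "strand": "+"}
            )
            gid += 1
    annotation = pd.DataFrame(rows)
    gene_ids = annotation["gene_id"].to_numpy()
    prows = []
    for p in range(sc.n_pathways):
        chosen = rng.choice(gene_ids, size=min(sc.genes_per_pathway, len(gene_ids)),
                            replace=False)
        for g in chosen:
            prows.append({"pathway_id": f"path{p:03d}", "gene_id": g,
                          "name": f"synthetic pathway {p}"})
    return annotation, pd.DataFrame(prows)


# ------------------------------------------------------------ phenotypes
def _rescale(x: np.ndarray, target_var: float, over: np.ndarray) -> np.ndarray:
    v = x[over].var()
    if v <= 0:
        raise ValueError("degenerate simulated component (zero variance)")
    return x * np.sqrt(target_var / v)


def simulate_phenotypes(
    sc: SimulationScenario,
    pedigree: Pedigree,
    gm: GenotypeMatrix,
    annotation: pd.DataFrame | None = None,
    pathway_map: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, TruthTables]:
    """Repeated ejection records for the final-generation boars.

    Additive values are built from a shared random causal SNP subset with
    per-trait effects drawn under the scenario's genetic correlation
    matrix and rescaled so the realized additive variance (over the
    phenotyped boars) hits each trait's target exactly.  Epistatic values
    (traits with ``h2_epi > 0``) are sums over centered-dosage products of
    SNP pairs sampled within the trait's causal pathway.
    """
    rng = np.random.default_rng(sc.seed + 2)
    boars = gm.meta.get("final_generation", gm.ids)
    boar_idx = np.array([gm.ids.index(b) for b in boars])
    n_all = gm.n_individuals
    Z = gm.mean_impute().centered()

    m_causal = max(1, int(round(sc.causal_fraction * sc.m_snps)))
    causal = np.sort(rng.choice(sc.m_snps, size=m_causal, replace=False))
    T = len(sc.traits)
    L = np.linalg.cholesky(sc.genetic_corr + 1e-10 * np.eye(T))
    alpha = rng.standard_normal((m_causal, T)) @ L.T

    # pathway SNP sets are needed for any epistatic trait
    pathway_sets = None
    if any(t.h2_epi > 0 for t in sc.traits):
        if annotation is None or pathway_map is None:
            raise ValueError("epistatic traits need annotation and pathway map")
        ext = extend_gene_intervals(annotation, flank=sc.flank_bp)
        pathway_sets = build_pathway_snp_sets(gm.snps, ext, pathway_map)

    truth_cols = {"id": list(gm.ids)}
    fractions = []
    u_all, epi_all, pe_all = {}, {}, {}
    for t_i, t in enumerate(sc.traits):
        V_T = t.total_variance
        u = Z[:, causal] @ alpha[:, t_i]
        u = _rescale(u, t.h2_add * V_T, boar_idx)
        epi = np.zeros(n_all)
        if t.h2_epi > 0:
            if t.causal_pathway_id is None:
                raise ValueError(f"{t.name}: h2_epi > 0 needs a causal pathway")
            snp_set = np.array(pathway_sets.sets[t.causal_pathway_id])
            if len(snp_set) < 2:
                raise ValueError(
                    f"causal pathway {t.causal_pathway_id} has <2 mapped SNPs"
                )
            n_pairs = min(sc.n_epi_pairs, len(snp_set) * (len(snp_set) - 1) // 2)
            a = rng.choice(snp_set, size=4 * n_pairs)
            b = rng.choice(snp_set, size=4 * n_pairs)
            ok = a != b
            pairs = np.unique(
                np.sort(np.stack([a[ok], b[ok]], axis=1), axis=1), axis=0
            )[:n_pairs]
            W = Z[:, pairs[:, 0]] * Z[:, pairs[:, 1]]
            beta = rng.standard_normal(len(pairs))
            epi = _rescale(W @ beta, t.h2_epi * V_T, boar_idx)
        pe = np.zeros(n_all)
        pe[boar_idx] = rng.normal(0, np.sqrt(t.var_pe_frac * V_T), size=len(boar_idx))
        u_all[t.name], epi_all[t.name], pe_all[t.name] = u, epi, pe
        truth_cols[f"{t.name}_u"] = u
        truth_cols[f"{t.name}_epi"] = epi
        truth_cols[f"{t.name}_pe"] = pe
        denom = u[boar_idx].var() + epi[boar_idx].var() + pe[boar_idx].var() + t.sigma_e**2
        fractions.append(
            {"trait": t.name,
             "h2_add": u[boar_idx].var() / denom,
             "h2_epi": epi[boar_idx].var() / denom,
             "pe_frac": pe[boar_idx].var() / denom}
        )

    # fixed-effect machinery shared across traits
    hys_levels = [f"hys{k:03d}" for k in range(sc.n_hys)]
    hys_effects = {
        t.name: rng.normal(0, sc.hys_sd_frac * np.sqrt(t.total_variance), sc.n_hys)
        for t in sc.traits
    }
    counts = 1 + rng.poisson(max(sc.n_records_mean - 1.0, 0.0), size=len(boars))
    records = []
    for b_k, (boar, b_i) in enumerate(zip(boars, boar_idx)):
        age = rng.uniform(12.0, 36.0)
        for r in range(counts[b_k]):
            interval = rng.uniform(3.0, 10.0)
            age += interval / 30.0
            h = int(rng.integers(0, sc.n_hys))
            rec = {"boar_id": boar, "hys": hys_levels[h],
                   "age_months": age, "interval_days": interval}
            for t in sc.traits:
                y = (
                    t.mean
                    + hys_effects[t.name][h]
                    + sc.age_slope_frac * np.sqrt(t.total_variance) * (age - 24.0)
                    + sc.interval_slope_frac * np.sqrt(t.total_variance) * (interval - 6.5)
                    + u_all[t.name][b_i]
                    + epi_all[t.name][b_i]
                    + pe_all[t.name][b_i]
                    + rng.normal(0, t.sigma_e)
                )
                rec[t.name] = y
            records.append(rec)
    pheno = pd.DataFrame(records)
    truth = TruthTables(
        values=pd.DataFrame(truth_cols),
        fractions=pd.DataFrame(fractions).set_index("trait"),
        causal_snps=causal,
    )
    return pheno, truth


@dataclass
class SimulatedDataset:
    scenario: SimulationScenario
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    annotation: pd.DataFrame
    pathway_map: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: TruthTables

    @property
    def boars(self) -> list:
        return self.genotypes.meta["final_generation"]


def simulate_dataset(sc: SimulationScenario) -> SimulatedDataset:
    """Run the three generator stages under one scenario seed."""
    ped, gm = simulate_population(sc)
    annotation, pathway_map = simulate_annotation(sc, gm.snps)
    pheno, truth = simulate_phenotypes(sc, ped, gm, annotation, pathway_map)
    return SimulatedDataset(sc, ped, gm, annotation, pathway_map, pheno, truth)
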