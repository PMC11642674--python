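"""Relationship and kernel matrices.

Implements the VanRaden genomic relationship matrix
``G = MM' / (2 * sum_j p_j (1 - p_j))`` with M the 2p-centered dosage
matrix, the Gaussian kernel ``K(i, i') = exp(-||M_i - M_i'||^2 / h)``
on the same centered coordinates, the bandwidth candidate family
``h = median ||M_i - M_i'||^2 / {0.05, 0.1, 0.5, 1, 2, 4}``, the
pedigree numerator relationship matrix A by the tabular recursion, and
greedy reference-panel selection by genome representativity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .genotypes import GenotypeMatrix
from .tables import Pedigree

log = logging.getLogger(__name__)

DEFAULT_DIVISORS = (0.05, 0.1, 0.5, 1.0, 2.0, 4.0)

FLAVORS = ("pedigree_A", "grm_vanraden", "gaussian_kernel")


@dataclass
class RelationshipMatrix:
    """Symmetric PSD kinship/kernel matrix with an id index."""

    ids: list
    values: np.ndarray
    flavor: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.flavor not in FLAVORS:
            raise ValueError(f"unknown flavor {self.flavor!r}")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")

    @property
    def n(self) -> int:
        return len(self.ids)

    def validate(self, atol_sym: float = 1e-12, eig_tol: float = 1e-8) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol_sym, rtol=0):
            raise ValueError("matrix is not symmetric")
        d = np.diag(v)
        if self.flavor == "gaussian_kernel":
            if not np.all(d == 1.0):
                raise ValueError("Gaussian kernel diagonal must be exactly 1")
        elif np.any(d < 0):
            raise ValueError("diagonal must be non-negative")
        w = np.linalg.eigvalsh((v + v.T) / 2)
        if w[0] < -eig_tol * max(w[-1], 1.0):
            raise ValueError(f"matrix is not PSD (min eigenvalue {w[0]:.3g})")

    def ensure_psd(self, rel_tol: float = 1e-8, jitter: float = 1e-6) -> "RelationshipMatrix":
        """Add diagonal jitter when the smallest eigenvalue dips below
        -rel_tol * largest; REML solvers need an invertible V."""
        w = np.linalg.eigvalsh((self.values + self.values.T) / 2)
        if w[0] < -rel_tol * max(w[-1], 1.0):
            log.info(
                "%s: min eigenvalue %.3g; adding %.1e diagonal jitter",
                self.flavor, w[0], jitter,
            )
            self.values = self.values + jitter * np.eye(self.n)
            self.meta["jitter"] = self.meta.get("jitter", 0.0) + jitter
        return self

    def index_of(self, ids: Sequence) -> np.ndarray:
        lookup = {i: k for k, i in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids])
        except KeyError as e:
            raise KeyError(f"id {e.args[0]!r} absent from relationship matrix")

    def align(self, ids: Sequence) -> "RelationshipMatrix":
        idx = self.index_of(ids)
        return RelationshipMatrix(
            ids=list(ids), values=self.values[np.ix_(idx, idx)],
            flavor=self.flavor, meta=dict(self.meta),
        )


def _prepare_centered(gm: GenotypeMatrix, snp_subset):
    """Centered dosages restricted to polymorphic SNPs of the subset."""
    gm = gm.mean_impute()
    idx = np.arange(gm.n_snps) if snp_subset is None else np.asarray(snp_subset, dtype=int)
    if idx.size == 0:
        raise ValueError("empty SNP subset")
    calls = gm.calls[:, idx]
    p = calls.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs in subset are monomorphic")
    n_mono = int((~poly).sum())
    if n_mono:
        log.info("dropping %d monomorphic SNPs from kernel construction", n_mono)
    calls, p = calls[:, poly], p[poly]
    return gm, calls - 2.0 * p, p


def vanraden_grm(
    gm: GenotypeMatrix, snp_subset: Sequence[int] | None = None
) -> RelationshipMatrix:
    """VanRaden (2008) genomic relationship matrix on a SNP subset."""
    gm, M, p = _prepare_centered(gm, snp_subset)
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (M @ M.T) / denom
    G = (G + G.T) / 2
    return RelationshipMatrix(
        ids=gm.ids, values=G, flavor="grm_vanraden",
        meta={"n_snps": M.shape[1], "denominator": denom,
              "snp_set": "all" if snp_subset is None else "subset"},
    )


def gaussian_kernel(
    gm: GenotypeMatrix,
    snp_subset: Sequence[int] | None = None,
    bandwidth: float = 1.0,
) -> RelationshipMatrix:
    """Gaussian kernel on 2p-centered dosages; unit diagonal exactly."""
    if bandwidth <= 0:
        raise ValueError("bandwidth h must be > 0")
    gm, M, _ = _prepare_centered(gm, snp_subset)
    D = squareform(pdist(M, metric="sqeuclidean"))
    K = np.exp(-D / bandwidth)
    np.fill_diagonal(K, 1.0)
    return RelationshipMatrix(
        ids=gm.ids, values=K, flavor="gaussian_kernel",
        meta={"n_snps": M.shape[1], "bandwidth": bandwidth,
              "snp_set": "all" if snp_subset is None else "subset"},
    )


@dataclass
class BandwidthFamily:
    """Bandwidth candidates h = median squared distance / divisor."""

    median_sq_dist: float
    divisors: tuple = DEFAULT_DIVISORS
    candidates: tuple = ()

    def __post_init__(self):
        self.divisors = tuple(sorted(self.divisors))
        self.candidates = tuple(self.median_sq_dist / d for d in self.divisors)
        if any(h <= 0 for h in self.candidates):
            raise ValueError("bandwidth candidates must be positive")


def bandwidth_candidates(
    gm: GenotypeMatrix,
    snp_subset: Sequence[int] | None = None,
    divisors: Sequence[float] = DEFAULT_DIVISORS,
    max_exact_n: int = 2000,
    n_sample_pairs: int = 1_000_000,
    seed: int = 0,
) -> BandwidthFamily:
    """Median pairwise squared distance and the divisor family.

    Exact over all n(n-1)/2 pairs up to ``max_exact_n`` individuals,
    otherwise estimated from sampled pairs with a fixed seed.
    """
    if gm.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    _, M, _ = _prepare_centered(gm, snp_subset)
    n = M.shape[0]
    if n <= max_exact_n:
        d2 = pdist(M, metric="sqeuclidean")
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, size=n_sample_pairs)
        j = rng.integers(0, n - 1, size=n_sample_pairs)
        j = np.where(j >= i, j + 1, j)
        d2 = ((M[i] - M[j]) ** 2).sum(axis=1)
    med = float(np.median(d2))
    if med == 0:
        raise ValueError("median pairwise distance is zero (identical individuals)")
    return BandwidthFamily(median_sq_dist=med, divisors=tuple(divisors))


def pedigree_numerator_matrix(
    pedigree: Pedigree, subset_ids: Sequence | None = None
) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular (recursive) method.

    A_ii = 1 + 0.5 * A(sire, dam); A_ij = 0.5 * (A(j, sire_i) + A(j, dam_i));
    unknown parents contribute 0.  The subset is extracted after the full
    matrix is built.
    """
    order = pedigree.order
    n = len(order)
    pos = {iid: k for k, iid in enumerate(order)}
    A = np.zeros((n, n))
    for k, iid in enumerate(order):
        sire, dam = pedigree.parents(iid)
        si = pos.get(sire, -1)
        di = pos.get(dam, -1)
        row = np.zeros(n)
        if si >= 0:
            row += 0.5 * A[si]
        if di >= 0:
            row += 0.5 * A[di]
        A[k, :k] = row[:k]
        A[:k, k] = row[:k]
        A[k, k] = 1.0 + (0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0)
    rm = RelationshipMatrix(ids=order, values=A, flavor="pedigree_A")
    if subset_ids is not None:
        rm = rm.align(list(subset_ids))
    return rm


def select_reference_panel(
    grm: RelationshipMatrix, target_representativity: float = 0.70
) -> list:
    """Greedy sequencing-panel choice maximizing genome representativity.

    The first pick is the individual with the highest average kinship
    with the rest; each next pick maximizes the gain of
    rep(S) = mean over unselected i of max_{s in S} G_is / sqrt(G_ii G_ss),
    clipped to [0, 1].  Stops at the target or when all are selected.
    Ties break by id order.
    """
    if grm.flavor != "grm_vanraden":
        raise ValueError("reference-panel selection expects a VanRaden GRM")
    n = grm.n
    if n < 2:
        raise ValueError("need at least 2 individuals")
    G = grm.values
    d = np.sqrt(np.clip(np.diag(G), 1e-12, None))
    N = np.clip(G / np.outer(d, d), 0.0, 1.0)
    row_mean = (G.sum(axis=1) - np.diag(G)) / (n - 1)
    first = int(np.argmax(row_mean))  # argmax returns the first (id-order) tie
    selected = [first]
    best_cover = N[:, first].copy()

    def rep(cover, sel):
        mask = np.ones(n, dtype=bool)
        mask[sel] = False
        if not mask.any():
            return 1.0
        return float(cover[mask].mean())

    while rep(best_cover, selected) < target_representativity and len(selected) < n:
        remaining = [i for i in range(n) if i not in selected]
        scores = [
            rep(np.maximum(best_cover, N[:, c]), selected + [c]) for c in remaining
        ]
        nxt = remaining[int(np.argmax(scores))]
        selected.append(nxt)
        best_cover = np.maximum(best_cover, N[:, nxt])
    return [grm.ids[i] for i in selected]
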