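"""Kernel mixed models on de-regressed proofs.

Four model flavors over a DRP vector y (one record per individual):

    GBLUP   y = mu + g + e,        g ~ N(0, G sigma_g^2)
    RKHS    y = mu + i + e,        i ~ N(0, K sigma_i^2)
    GFBLUP  y = mu + g + i + e,    i ~ N(0, G_p sigma_i^2)
    biBLUP  y = mu + g + i + e,    i ~ N(0, K_p sigma_i^2)

where G is the genome-wide VanRaden GRM, K a Gaussian kernel on all
SNPs, and G_p / K_p the corresponding matrices on the SNPs of one
pathway.  Validation individuals stay inside the kernels with their
DRPs masked out of y, so BLUP back-solving yields predictions for
everybody in one pass.

One kernel: profiled REML on the variance ratio via eigendecomposition
(1-D bounded search, tolerance 1e-8).  Two kernels: AI-REML over
(sigma_g^2, sigma_i^2, sigma_e^2) with an EM fallback, on the dense
training-subset covariance.  Optional per-id DRP weights scale the
residual variance as sigma_e^2 / w_i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize_scalar

from .genotypes import GenotypeMatrix
from .kinship import (
    DEFAULT_DIVISORS,
    RelationshipMatrix,
    bandwidth_candidates,
    gaussian_kernel,
    vanraden_grm,
)
from .repeatability import ConvergenceError

log = logging.getLogger(__name__)

MODEL_NAMES = ("GBLUP", "RKHS", "GFBLUP", "biBLUP")


@dataclass
class GPModelSpec:
    """Which kernels enter the mixed model (one row of the model table)."""

    name: str
    pathway_id: str | None = None
    bandwidth_divisor: float | None = None  # None = select by training REML

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"model must be one of {MODEL_NAMES}")
        if self.name in ("GFBLUP", "biBLUP") and self.pathway_id is None:
            raise ValueError(f"{self.name} needs a pathway_id")


class KernelBLUP:
    """Mixed model with 1 or 2 kernel random effects on masked records.

    Parameters
    ----------
    y : array of DRPs aligned with ``ids``; entries for masked ids are ignored.
    kernels : list of RelationshipMatrix (1 or 2), all indexed by ``ids``.
    ids : identifiers for the rows of y.
    masked_ids : ids whose records are excluded from fitting (validation set).
    weights : optional per-id DRP weights; residual variance becomes
        sigma_e^2 / w_i.
    """

    def __init__(self, y, kernels, ids, masked_ids=(), weights=None):
        self.ids = list(ids)
        self.y = np.asarray(y, dtype=float)
        if self.y.shape != (len(self.ids),):
            raise ValueError("y length must match ids")
        if not 1 <= len(kernels) <= 2:
            raise ValueError("KernelBLUP takes 1 or 2 kernels")
        self.kernels = [k.align(self.ids) for k in kernels]
        masked = set(masked_ids)
        unknown = masked - set(self.ids)
        if unknown:
            raise KeyError(f"masked ids absent from kernels: {sorted(unknown)[:5]}")
        self.train = np.array([i not in masked for i in self.ids])
        n_train = int(self.train.sum())
        if n_train < 20:
            raise ValueError(f"need >= 20 unmasked records, have {n_train}")
        if np.isnan(self.y[self.train]).any():
            raise ValueError("training DRPs contain NaN")
        self.weights = None
        if weights is not None:
            self.weights = np.asarray(weights, dtype=float)
            if self.weights.shape != (len(self.ids),) or (self.weights[self.train] <= 0).any():
                raise ValueError("weights must be positive and aligned with ids")

    # ---------------------------------------------------------- fitting
    def fit(self, fixed_components=None, max_iter=200, tol=1e-8,
        method: str = "profiled") -> "KernelBLUPResults":
        t = self.train
        y = self.y[t]
        Ks = [k.values[np.ix_(t, t)] for k in self.kernels]
        d = np.ones(len(y)) if self.weights is None else 1.0 / self.weights[t]
        if fixed_components is not None:
            comps = np.asarray(fixed_components, dtype=float)
            if len(comps) != len(Ks) + 1:
                raise ValueError("fixed_components must be (kernel vars ..., sigma_e2)")
            m2 = self._minus2_reml_dense(y, Ks, d, comps)
            return self._finish(comps, m2, it=0)
        if len(Ks) == 1 and method == "profiled":
            comps, m2, it = self._fit_one_kernel(y, Ks[0], d, tol)
        else:
            comps, m2, it = self._fit_ai(y, Ks, d, max_iter, tol)
        return self._finish(comps, m2, it)

    @staticmethod
    def _minus2_reml_dense(y, Ks, d, comps):
        """Direct dense evaluation of log|V| + log|X'V^-1X| + y'Py, X = 1."""
        V = comps[-1] * np.diag(d)
        for K, s in zip(Ks, comps[:-1]):
            V = V + s * K
        f = cho_factor(V, lower=True)
        logdetV = 2 * np.log(np.diag(f[0])).sum()
        ones = np.ones(len(y))
        Vi1 = cho_solve(f, ones)
        Viy = cho_solve(f, y)
        xvx = ones @ Vi1
        beta = (ones @ Viy) / xvx
        Py = Viy - Vi1 * beta
        return logdetV + np.log(xvx) + y @ Py

    def _fit_one_kernel(self, y, K, d, tol):
        """Profiled REML over the ratio lambda = sigma_k^2 / sigma_e^2.

        With V = sigma_e^2 (lambda K + D), sigma_e^2 profiles out in
        closed form; the 1-D search runs on log10(lambda).
        """
        di = 1.0 / np.sqrt(d)
        Kt = K * np.outer(di, di)  # D^-1/2 K D^-1/2
        w, U = eigh(Kt)
        yt = U.T @ (di * y)
        xt = U.T @ di  # rotated intercept
        n = len(y)

        def m2(log10_lam):
            lam = 10.0**log10_lam
            h = lam * w + 1.0
            xvx = np.sum(xt**2 / h)
            beta = np.sum(xt * yt / h) / xvx
            r = yt - beta * xt
            ypy = np.sum(r**2 / h)
            se2 = ypy / (n - 1)
            return (
                (n - 1) * np.log(se2)
                + np.sum(np.log(h))
                + np.log(xvx)
                + (n - 1)
            )

        res = minimize_scalar(m2, bounds=(-8, 8), method="bounded",
                              options={"xatol": 1e-10})
        lam = 10.0**res.x
        h = lam * w + 1.0
        xvx = np.sum(xt**2 / h)
        beta = np.sum(xt * yt / h) / xvx
        ypy = np.sum((yt - beta * xt) ** 2 / h)
        se2 = ypy / (n - 1)
        comps = np.array([lam * se2, se2])
        return comps, self._minus2_reml_dense(y, [K], d, comps), res.nfev

    def _fit_ai(self, y, Ks, d, max_iter, tol):
        """AI-REML over the kernel variances and sigma_e^2, EM fallback.

        A kernel variance driven to the boundary (negative gradient at a
        negligible value) is pinned there and the remaining one-kernel
        problem is solved exactly by the profiled path.
        """
        n = len(y)
        nk = len(Ks)
        nc = nk + 1
        vy = float(np.var(y))
        floor = 1e-10 * vy
        boundary = 1e-6 * vy
        Vs = Ks + [np.diag(d)]
        theta = np.full(nc, vy / nc)
        ones = np.ones(n)
        m2_prev = np.inf
        best = (np.inf, theta)
        stall = 0
        for it in range(1, max_iter + 1):
            V = sum(s * Vk for s, Vk in zip(theta, Vs))
            try:
                f = cho_factor(V, lower=True)
            except np.linalg.LinAlgError:
                V = V + 1e-8 * np.trace(V) / n * np.eye(n)
                f = cho_factor(V, lower=True)
            Vi = cho_solve(f, np.eye(n))
            Vi1 = Vi @ ones
            xvx = ones @ Vi1
            P = Vi - np.outer(Vi1, Vi1) / xvx
            Py = P @ y
            grad = np.empty(nc)
            PVs = [P @ Vk for Vk in Vs]
            for k in range(nc):
                grad[k] = -0.5 * (np.trace(PVs[k]) - Py @ (Vs[k] @ Py))
            AI = np.empty((nc, nc))
            VPy = [Vk @ Py for Vk in Vs]
            for a in range(nc):
                for b in range(a, nc):
                    AI[a, b] = AI[b, a] = 0.5 * (VPy[a] @ (P @ VPy[b]))
            m2 = self._minus2_reml_dense(y, Ks, d, theta)
            if nk == 2:  # a kernel variance collapsing to zero
                for k in range(2):
                    if theta[k] <= boundary and grad[k] < 0:
                        other = 1 - k
                        comps1, _, it1 = self._fit_one_kernel(y, Ks[other], d, tol)
                        cand = np.empty(3)
                        cand[k] = floor
                        cand[other] = comps1[0]
                        cand[2] = comps1[1]
                        m2_cand = self._minus2_reml_dense(y, Ks, d, cand)
                        if m2_cand <= m2 + 1e-6 * (1 + abs(m2)):
                            return cand, m2_cand, it + it1
            theta_new = None
            # active-set Newton step: components pinned at the floor with a
            # negative gradient are held there and excluded from the solve
            act = ~((theta <= 2 * floor) & (grad < 0))
            try:
                delta = np.zeros(nc)
                if act.any():
                    delta[act] = np.linalg.solve(AI[np.ix_(act, act)], grad[act])
                for frac in (1.0, 0.5, 0.25):  # step-halving near the boundary
                    cand = np.maximum(theta + frac * delta, floor)
                    m2_cand = self._minus2_reml_dense(y, Ks, d, cand)
                    if m2_cand <= m2 + 1e-10:
                        theta_new, m2_new = cand, m2_cand
                        break
            except np.linalg.LinAlgError:
                pass
            if theta_new is None:  # EM step
                theta_new = np.array(
                    [
                        max(s + (s**2 / n) * (Py @ VPy[k] - np.trace(PVs[k])), floor)
                        for k, s in enumerate(theta)
                    ]
                )
                m2_new = self._minus2_reml_dense(y, Ks, d, theta_new)
            free = theta > floor  # components pinned at the floor are settled
            rel = np.max(
                np.abs(theta_new - theta)[free] / np.maximum(theta[free], floor)
            ) if free.any() else 0.0
            dm2 = abs(m2_prev - m2_new)
            theta, m2_prev = theta_new, m2_new
            if m2_new < best[0] - 1e-7 * (1 + abs(m2_new)):
                best = (m2_new, theta.copy())
                stall = 0
            else:
                stall += 1
            if rel < tol or dm2 < max(tol, 1e-9) * (1 + abs(m2_new)):
                return theta, m2_new, it
            if stall >= 10:  # likelihood plateau (typically a boundary fit)
                log.info("AI-REML stopping on a likelihood plateau at iter %d", it)
                return best[1], best[0], it
        raise ConvergenceError(f"kernel AI-REML did not converge in {max_iter} iters")

    def _finish(self, comps, m2, it):
        t = self.train
        y = self.y[t]
        d = np.ones(t.sum()) if self.weights is None else 1.0 / self.weights[t]
        Ks = [k.values[np.ix_(t, t)] for k in self.kernels]
        V = comps[-1] * np.diag(d)
        for K, s in zip(Ks, comps[:-1]):
            V = V + s * K
        f = cho_factor(V, lower=True)
        ones = np.ones(len(y))
        Vi1 = cho_solve(f, ones)
        Viy = cho_solve(f, y)
        mu = (ones @ Viy) / (ones @ Vi1)
        Py = Viy - Vi1 * mu
        # BLUP back-solve for every id (training and masked alike)
        effects = []
        for K_full, s in zip(self.kernels, comps[:-1]):
            effects.append(s * (K_full.values[:, t] @ Py))
        return KernelBLUPResults(
            model=self, components=np.asarray(comps), mu=float(mu),
            minus2_reml=float(m2), iterations=it, effects=effects, Py=Py,
        )


@dataclass
class KernelBLUPResults:
    """Variance components, intercept and BLUP genetic values."""

    model: KernelBLUP
    components: np.ndarray  # kernel variances ..., sigma_e2
    mu: float
    minus2_reml: float
    iterations: int
    effects: list = field(repr=False, default_factory=list)
    Py: np.ndarray = field(repr=False, default=None)

    converged: bool = True

    @property
    def loglik(self) -> float:
        return -0.5 * self.minus2_reml

    @property
    def sigma_g2(self) -> float:
        return float(self.components[0])

    @property
    def sigma_i2(self) -> float | None:
        return float(self.components[1]) if len(self.components) == 3 else None

    @property
    def sigma_e2(self) -> float:
        return float(self.components[-1])

    def predictions(self) -> pd.DataFrame:
        ghat = self.effects[0]
        ihat = self.effects[1] if len(self.effects) > 1 else np.zeros_like(ghat)
        return pd.DataFrame(
            {
                "id": self.model.ids,
                "ghat": ghat,
                "ihat": ihat,
                "total": ghat + ihat,
                "masked": ~self.model.train,
            }
        )

    def summary(self) -> str:
        names = ["sigma_g2"] + (["sigma_i2"] if len(self.components) == 3 else [])
        comp_str = "  ".join(
            f"{n}={v:.6g}" for n, v in zip(names + ["sigma_e2"], self.components)
        )
        return (
            f"KernelBLUP: {len(self.model.kernels)} kernel(s), "
            f"n_train={int(self.model.train.sum())}, "
            f"n_masked={int((~self.model.train).sum())}\n"
            f"  {comp_str}\n  mu={self.mu:.6g}  logL={self.loglik:.4f}"
        )


def predict_genetic_values(fit: KernelBLUPResults, masked_ids: Sequence) -> pd.DataFrame:
    """Predicted total genetic values for the masked individuals."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    preds = fit.predictions().set_index("id")
    missing = [i for i in masked_ids if i not in preds.index]
    if missing:
        raise KeyError(f"masked ids absent from kernels: {missing[:5]}")
    return preds.loc[list(masked_ids)].reset_index()


# ----------------------------------------------------------- model suite
def reml_kernel_model(y, kernels, ids, masked_ids=(), weights=None,
                      **fit_kwargs) -> KernelBLUPResults:
    """Functional wrapper around KernelBLUP(...).fit(...)."""
    return KernelBLUP(y, kernels, ids, masked_ids, weights).fit(**fit_kwargs)


def _select_bandwidth(y, gm, snp_subset, ids, masked_ids, base_kernel,
                      divisors, weights, seed=0):
    """Pick the bandwidth divisor maximizing training restricted likelihood."""
    fam = bandwidth_candidates(gm, snp_subset, divisors=divisors, seed=seed)
    best = None
    for div, h in zip(fam.divisors, fam.candidates):
        K = gaussian_kernel(gm, snp_subset, bandwidth=h).ensure_psd()
        kernels = ([base_kernel] if base_kernel is not None else []) + [K]
        try:
            res = reml_kernel_model(y, kernels, ids, masked_ids, weights)
        except (ConvergenceError, np.linalg.LinAlgError):
            continue
        if best is None or res.loglik > best[0]:
            best = (res.loglik, div, h, res)
    if best is None:
        raise ConvergenceError("no bandwidth candidate produced a converged fit")
    log.info("selected bandwidth divisor %g (h=%.4g)", best[1], best[2])
    return best


def fit_gp_model(
    spec: GPModelSpec,
    drp: pd.DataFrame,
    genotypes: GenotypeMatrix,
    pathway_sets=None,
    masked_ids: Sequence = (),
    use_weights: bool = False,
    divisors: Sequence[float] = DEFAULT_DIVISORS,
    grm: RelationshipMatrix | None = None,
) -> KernelBLUPResults:
    """Assemble the kernels for one model row and fit it.

    ``drp`` needs columns id/drp (and weight when ``use_weights``).  The
    genotype matrix must cover every id in ``drp``; ``grm`` can carry a
    precomputed genome-wide G to avoid rebuilding it per fold.
    """
    ids = [i for i in genotypes.ids if i in set(drp["id"])]
    drp_s = drp.set_index("id").loc[ids]
    y = drp_s["drp"].to_numpy(dtype=float)
    weights = drp_s["weight"].to_numpy(dtype=float) if use_weights else None
    keep_idx = [genotypes.ids.index(i) for i in ids]
    gm = genotypes.subset(individuals=keep_idx).mean_impute()

    subset = None
    if spec.name in ("GFBLUP", "biBLUP"):
        if pathway_sets is None:
            raise ValueError("pathway models need pathway_sets")
        subset = np.asarray(pathway_sets.sets[spec.pathway_id], dtype=int)
        if subset.size == 0:
            raise ValueError(f"pathway {spec.pathway_id} has no SNPs after QC")

    if grm is None and spec.name != "RKHS":
        grm = vanraden_grm(gm).ensure_psd()
    elif grm is not None:
        grm = grm.align(ids).ensure_psd()

    if spec.name == "GBLUP":
        return reml_kernel_model(y, [grm], ids, masked_ids, weights)
    if spec.name == "RKHS":
        if spec.bandwidth_divisor is not None:
            fam = bandwidth_candidates(gm, None, divisors=divisors)
            h = fam.median_sq_dist / spec.bandwidth_divisor
            K = gaussian_kernel(gm, None, bandwidth=h).ensure_psd()
            return reml_kernel_model(y, [K], ids, masked_ids, weights)
        *_, res = _select_bandwidth(y, gm, None, ids, masked_ids, None,
                                    divisors, weights)
        return res
    if spec.name == "GFBLUP":
        gp = vanraden_grm(gm, subset).ensure_psd()
        return reml_kernel_model(y, [grm, gp], ids, masked_ids, weights)
    # biBLUP
    if spec.bandwidth_divisor is not None:
        fam = bandwidth_candidates(gm, subset, divisors=divisors)
        h = fam.median_sq_dist / spec.bandwidth_divisor
        Kp = gaussian_kernel(gm, subset, bandwidth=h).ensure_psd()
        return reml_kernel_model(y, [grm, Kp], ids, masked_ids, weights)
    *_, res = _select_bandwidth(y, gm, subset, ids, masked_ids, grm,
                                divisors, weights)
    return res
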