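"""Cross-validation harness, pathway screening and improvement arithmetic.

Predictive ability is the Pearson correlation between predicted total
genetic values and the DRPs of a validation fold; the protocol is
repeated k-fold random cross-validation (default 20 repetitions of
5 folds) with fold assignments shared across models and pathways so
comparisons are paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .kernel_models import GPModelSpec, fit_gp_model
from .kinship import vanraden_grm

log = logging.getLogger(__name__)


def make_cv_folds(ids, k: int = 5, reps: int = 20, seed: int = 0) -> list:
    """Random k-fold partitions, one per repetition.

    Returns a list of length ``reps``; each element is an int array
    aligned with ``ids`` giving the validation fold (0..k-1) of each id.
    Deterministic for a fixed seed.
    """
    ids = list(ids)
    n = len(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("need at least k individuals")
    rng = np.random.default_rng(seed)
    folds = []
    base = np.arange(n) % k  # sizes floor(n/k) or ceil(n/k)
    for _ in range(reps):
        perm = rng.permutation(n)
        assign = np.empty(n, dtype=int)
        assign[perm] = base
        folds.append(assign)
    return folds


@dataclass
class CVResult:
    """Fold-level predictive abilities with their mean and SE."""

    model: str
    fold_correlations: np.ndarray
    pathway_id: str | None = None
    seed: int | None = None
    n_skipped_folds: int = 0

    def __post_init__(self):
        self.fold_correlations = np.asarray(self.fold_correlations, dtype=float)
        if ((self.fold_correlations < -1) | (self.fold_correlations > 1)).any():
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def mean(self) -> float:
        return float(self.fold_correlations.mean())

    @property
    def se(self) -> float:
        n = len(self.fold_correlations)
        return float(self.fold_correlations.std(ddof=1) / np.sqrt(n))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"model": self.model, "pathway_id": self.pathway_id,
             "fold": np.arange(len(self.fold_correlations)),
             "correlation": self.fold_correlations}
        )

    def __repr__(self):
        tag = f", pathway={self.pathway_id}" if self.pathway_id else ""
        return (f"CVResult({self.model}{tag}: "
                f"{self.mean:.3f} +/- {self.se:.3f}, "
                f"{len(self.fold_correlations)} folds)")


def run_cross_validation(
    spec: GPModelSpec,
    drp: pd.DataFrame,
    genotypes,
    pathway_sets=None,
    folds=None,
    use_weights: bool = False,
    grm=None,
    seed: int | None = None,
) -> CVResult:
    """Fit the model per training fold and score the validation fold.

    Variance components (and any bandwidth choice) are re-estimated
    inside every training fold; validation individuals remain inside
    the kernels with their DRPs masked.
    """
    ids = [i for i in genotypes.ids if i in set(drp["id"])]
    if folds is None:
        folds = make_cv_folds(ids, seed=seed or 0)
    if grm is None and spec.name != "RKHS":
        keep = [genotypes.ids.index(i) for i in ids]
        grm = vanraden_grm(genotypes.subset(individuals=keep).mean_impute()).ensure_psd()
    cors = []
    n_skipped = 0
    id_arr = np.array(ids)
    for rep, assign in enumerate(folds):
        for fold in np.unique(assign):
            val_ids = id_arr[assign == fold]
            if len(val_ids) < 3:
                log.info("rep %d fold %d: %d validation ids, skipping",
                         rep, fold, len(val_ids))
                n_skipped += 1
                continue
            res = fit_gp_model(
                spec, drp, genotypes, pathway_sets,
                masked_ids=list(val_ids), use_weights=use_weights, grm=grm,
            )
            preds = res.predictions().set_index("id").loc[val_ids, "total"]
            obs = drp.set_index("id").loc[val_ids, "drp"]
            r = pearsonr(preds.to_numpy(), obs.to_numpy()).statistic
            cors.append(r)
    return CVResult(model=spec.name, fold_correlations=np.array(cors),
                    pathway_id=spec.pathway_id, seed=seed,
                    n_skipped_folds=n_skipped)


def pathway_screen(
    model: str,
    drp: pd.DataFrame,
    genotypes,
    pathway_sets,
    folds,
    top_n: int = 10,
    use_weights: bool = False,
) -> pd.DataFrame:
    """Rank pathways by cross-validated ability of the requested model.

    Runs GFBLUP and biBLUP with shared folds for every pathway and
    returns all pathways sorted descending by the requested model's
    mean ability (stable sort), with mean and SE columns for both.
    """
    if model not in ("gfblup", "biblup"):
        raise ValueError("model must be 'gfblup' or 'biblup'")
    if not pathway_sets.pathway_ids:
        raise ValueError("no pathways to screen")
    ids = [i for i in genotypes.ids if i in set(drp["id"])]
    keep = [genotypes.ids.index(i) for i in ids]
    grm = vanraden_grm(genotypes.subset(individuals=keep).mean_impute()).ensure_psd()
    rows = []
    for pid in pathway_sets.pathway_ids:
        res = {}
        for name in ("GFBLUP", "biBLUP"):
            spec = GPModelSpec(name=name, pathway_id=pid)
            res[name] = run_cross_validation(
                spec, drp, genotypes, pathway_sets, folds,
                use_weights=use_weights, grm=grm,
            )
        rows.append(
            {
                "pathway_id": pid,
                "gfblup_mean": res["GFBLUP"].mean, "gfblup_se": res["GFBLUP"].se,
                "biblup_mean": res["biBLUP"].mean, "biblup_se": res["biBLUP"].se,
                "function": pathway_sets.names.get(pid, ""),
            }
        )
    table = pd.DataFrame(rows)
    key = "biblup_mean" if model == "biblup" else "gfblup_mean"
    table = table.sort_values(key, ascending=False, kind="mergesort").reset_index(drop=True)
    table.attrs["top_n"] = top_n
    return table


def percent_improvement(a_mean: float, b_mean: float) -> float:
    """Relative improvement 100 * (a - b) / b, half-up rounded to 2 dp.

    Decimal arithmetic on the printed values avoids binary-float
    round-half artifacts (e.g. (0.370 - 0.320)/0.320 must give 15.63).
    """
    if b_mean == 0:
        raise ZeroDivisionError("baseline mean is zero")
    a, b = Decimal(str(a_mean)), Decimal(str(b_mean))
    pct = (a - b) / b * 100
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
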