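"""Record- and SNP-level quality control.

Boundary semantics follow the removal rules: SNPs are removed at
MAF <= maf_min or call rate <= call_rate_min (kept only at strict >),
records are removed at VOL < 20 mL, DEN > 20e9/mL, MOT < 0.5 or
ABN > 0.6 (kept at the complementary closed inequalities), and boars
with fewer than 10 surviving records are dropped afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


class QCError(ValueError):
    pass


@dataclass
class QCStage:
    name: str
    n_in: int
    n_removed: int
    n_out: int
    removed: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_in - self.n_removed != self.n_out:
            raise ValueError(f"stage {self.name}: in - removed != out")


@dataclass
class QCReport:
    stages: list = field(default_factory=list)
    max_listed: int = 1000

    def add(self, name, n_in, n_removed, n_out, removed=(), **params):
        self.stages.append(
            QCStage(name, n_in, n_removed, n_out,
                    list(removed)[: self.max_listed], params)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"stage": s.name, "n_in": s.n_in, "n_removed": s.n_removed,
                 "n_out": s.n_out, **s.params}
                for s in self.stages
            ]
        )


def filter_snps(
    gm: GenotypeMatrix, maf_min: float = 0.01, call_rate_min: float = 0.90
) -> tuple[GenotypeMatrix, QCReport]:
    """Keep SNPs with MAF > maf_min and call rate > call_rate_min."""
    if not (0 <= maf_min < 0.5):
        raise ValueError("maf_min must be in [0, 0.5)")
    if not (0 < call_rate_min <= 1):
        raise ValueError("call_rate_min must be in (0, 1]")
    maf = gm.maf()
    cr = gm.call_rate()
    keep = (maf > maf_min) & (cr > call_rate_min)
    report = QCReport()
    report.add(
        "snp_maf_callrate", gm.n_snps, int((~keep).sum()), int(keep.sum()),
        removed=gm.snps.loc[~keep, "snp_id"].tolist(),
        maf_min=maf_min, call_rate_min=call_rate_min,
    )
    if not keep.any():
        raise QCError("no SNPs survive MAF/call-rate filtering; review thresholds")
    return gm.subset(snps=np.where(keep)[0]), report


def _pairwise_r2(calls: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns (mean-filled)."""
    x = calls.copy()
    col_mean = np.nanmean(x, axis=0)
    nan_r, nan_c = np.where(np.isnan(x))
    x[nan_r, nan_c] = col_mean[nan_c]
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.nan
    c = (x.T @ x) / len(x)
    r = c / np.outer(sd, sd)
    return np.nan_to_num(r**2, nan=0.0)


def ld_prune(
    gm: GenotypeMatrix,
    r2_max: float = 0.9,
    window_snps: int = 50,
    step: int = 5,
) -> tuple[GenotypeMatrix, QCReport]:
    """Windowed greedy LD pruning within chromosomes.

    In each sliding window, for any SNP pair with r^2 >= r2_max the
    lower-MAF SNP is removed (ties: the later position).  Passes repeat
    until no window contains a violating pair.
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    maf = gm.maf()
    pos = gm.snps["pos"].to_numpy()
    keep = np.ones(gm.n_snps, dtype=bool)
    chroms = gm.snps["chrom"].to_numpy()
    changed = True
    while changed:
        changed = False
        for chrom in pd.unique(chroms):
            idx = np.where((chroms == chrom) & keep)[0]
            start = 0
            while start < len(idx):
                win = idx[start : start + window_snps]
                if len(win) >= 2:
                    r2 = _pairwise_r2(gm.calls[:, win])
                    for a in range(len(win)):
                        if not keep[win[a]]:
                            continue
                        for b in range(a + 1, len(win)):
                            if not keep[win[b]]:
                                continue
                            if r2[a, b] >= r2_max:
                                ia, ib = win[a], win[b]
                                if maf[ia] < maf[ib]:
                                    drop = ia
                                elif maf[ib] < maf[ia]:
                                    drop = ib
                                else:  # tie: later position goes
                                    drop = ia if pos[ia] > pos[ib] else ib
                                keep[drop] = False
                                changed = True
                if start + window_snps >= len(idx):
                    break
                start += step
    report = QCReport()
    report.add(
        "ld_prune", gm.n_snps, int((~keep).sum()), int(keep.sum()),
        removed=gm.snps.loc[~keep, "snp_id"].tolist(),
        r2_max=r2_max, window_snps=window_snps, step=step,
    )
    return gm.subset(snps=np.where(keep)[0]), report


def filter_records(
    phenotypes: pd.DataFrame,
    vol_min_ml: float = 20.0,
    den_max: float = 20.0,
    mot_min: float = 0.5,
    abn_max: float = 0.6,
    min_records: int = 10,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the ejection-record thresholds, then the per-boar count rule."""
    for v in (vol_min_ml, den_max, mot_min, abn_max):
        if v <= 0:
            raise ValueError("thresholds must be positive")
    df = phenotypes.reset_index(drop=True)
    keep = (
        (df["vol"] >= vol_min_ml)
        & (df["den"] <= den_max)
        & (df["mot"] >= mot_min)
        & (df["abn"] <= abn_max)
    )
    report = QCReport()
    report.add(
        "record_thresholds", len(df), int((~keep).sum()), int(keep.sum()),
        removed=df.index[~keep].tolist(),
        vol_min_ml=vol_min_ml, den_max=den_max, mot_min=mot_min, abn_max=abn_max,
    )
    surv = df[keep]
    counts = surv.groupby("boar_id").size()
    good_boars = set(counts.index[counts >= min_records])
    keep2 = surv["boar_id"].isin(good_boars)
    removed_boars = sorted(set(counts.index) - good_boars)
    out = surv[keep2].reset_index(drop=True)
    report.add(
        "boar_min_records", len(surv), int((~keep2).sum()), len(out),
        removed=removed_boars, min_records=min_records,
    )
    if out.empty:
        raise QCError("no records survive QC; review thresholds")
    return out, report
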