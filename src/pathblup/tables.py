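"""Tabular domain objects: phenotypes, pedigree, gene annotation, pathways.

Phenotype records are ejection-level repeated measures.  Canonical units:
VOL in mL, DEN in 1e9 cells/mL, MOT and ABN as proportions in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PHENO_COLUMNS = ["boar_id", "hys", "age_months", "interval_days", "vol", "den", "mot", "abn"]
TRAITS = ["vol", "den", "mot", "abn"]

UNKNOWN_PARENT = {"0", "NA", "na", "", ".", "nan", "None"}


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Pedigree as (id, sire, dam) rows; unknown parents are None.

    Construction validates acyclicity and stores a topological order
    (parents before offspring), which the tabular relationship-matrix
    recursion requires.
    """

    df: pd.DataFrame
    order: list = field(init=False)

    def __post_init__(self):
        df = self.df.copy()
        for col in ("id", "sire", "dam"):
            if col not in df.columns:
                raise PedigreeError(f"pedigree lacks column '{col}'")
            df[col] = df[col].astype(object).where(df[col].notna(), None)
        df["id"] = df["id"].astype(str)
        for col in ("sire", "dam"):
            df[col] = [
                None if v is None or str(v) in UNKNOWN_PARENT else str(v)
                for v in df[col]
            ]
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise PedigreeError(f"duplicated individual '{dup}' in pedigree")
        known = set(df["id"])
        # parents appearing only as parents become founders
        extra = sorted(
            {p for p in pd.concat([df["sire"], df["dam"]]) if p is not None} - known
        )
        if extra:
            log.info("adding %d parent-only individuals as founders", len(extra))
            df = pd.concat(
                [pd.DataFrame({"id": extra, "sire": None, "dam": None}), df],
                ignore_index=True,
            )
        g = nx.DiGraph()
        g.add_nodes_from(df["id"])
        for _, row in df.iterrows():
            for parent in (row["sire"], row["dam"]):
                if parent is not None:
                    g.add_edge(parent, row["id"])
        try:
            self.order = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(g)
            path = " -> ".join(e[0] for e in cycle) + " -> " + cycle[-1][1]
            raise PedigreeError(f"pedigree contains a cycle: {path}")
        self.df = df.set_index("id", drop=False)

    @property
    def ids(self) -> list:
        return list(self.df["id"])

    def __len__(self) -> int:
        return len(self.df)

    def parents(self, iid: str):
        row = self.df.loc[iid]
        return row["sire"], row["dam"]


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    out = df.copy()
    out["boar_id"] = out["boar_id"].astype(str)
    out["hys"] = out["hys"].astype(str)
    for c in ("age_months", "interval_days") + tuple(TRAITS):
        out[c] = pd.to_numeric(out[c], errors="coerce")
    return out.reset_index(drop=True)


def normalize_units(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce trait columns onto canonical units; idempotent.

    Heuristics (logged when applied): a `vol` column whose maximum is
    below 20 is taken to be liters and multiplied by 1000 (the volume
    filter threshold is 20 mL, so plausible mL data exceed it); `mot`
    or `abn` columns with values above 1.5 are taken to be percentages
    and divided by 100.
    """
    out = validate_phenotypes(df)
    vol = out["vol"].dropna()
    if len(vol) and vol.max() < 20.0:
        log.info("vol column looks like liters (max %.3f); converting to mL", vol.max())
        out["vol"] = out["vol"] * 1000.0
    for c in ("mot", "abn"):
        col = out[c].dropna()
        if len(col) and col.max() > 1.5:
            log.info("%s column looks like percentages; dividing by 100", c)
            out[c] = out[c] / 100.0
    return out


def validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    """Gene annotation: gene_id, chrom, start, end (1-based inclusive), strand."""
    need = ["gene_id", "chrom", "start", "end", "strand"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"annotation lacks columns {missing}")
    out = df.copy()
    out["gene_id"] = out["gene_id"].astype(str)
    out["chrom"] = out["chrom"].astype(str)
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    if (out["start"] > out["end"]).any():
        bad = out.loc[out["start"] > out["end"], "gene_id"].iloc[0]
        raise ValueError(f"gene '{bad}' has start > end")
    if out["gene_id"].duplicated().any():
        dup = out.loc[out["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicated gene_id '{dup}'")
    bad_strand = ~out["strand"].isin(["+", "-", "."])
    if bad_strand.any():
        raise ValueError(
            f"unknown strand symbol {out.loc[bad_strand, 'strand'].iloc[0]!r}"
        )
    return out.reset_index(drop=True)


def validate_pathway_map(df: pd.DataFrame) -> pd.DataFrame:
    need = ["pathway_id", "gene_id"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"pathway map lacks columns {missing}")
    out = df.copy()
    out["pathway_id"] = out["pathway_id"].astype(str)
    out["gene_id"] = out["gene_id"].astype(str)
    if "name" not in out.columns:
        out["name"] = ""
    out = out.drop_duplicates(subset=["pathway_id", "gene_id"])
    return out.reset_index(drop=True)
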