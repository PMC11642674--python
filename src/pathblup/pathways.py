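"""SNP-to-gene-to-pathway mapping.

Genes are extended 5 kb on both ends (strand-agnostic: 5 kb upstream of
the TSS and downstream of the TTS is a symmetric extension for either
strand) and a SNP maps to a gene when its position falls in the closed,
1-based extended interval.  A pathway's SNP set is the union over its
genes; pathways represented by fewer than ``min_represented_genes``
genes (a gene counts only if at least one SNP maps to it) are pruned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import validate_annotation, validate_pathway_map


def extend_gene_intervals(annotation: pd.DataFrame, flank: int = 5000) -> pd.DataFrame:
    """Extend each gene ``flank`` bp on both ends, clamped at position 1."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    ann = validate_annotation(annotation).copy()
    ann["start"] = np.maximum(1, ann["start"] - flank)
    ann["end"] = ann["end"] + flank
    return ann


@dataclass
class PathwaySNPSets:
    """Per-pathway SNP index lists with representation counts."""

    sets: dict  # pathway_id -> sorted unique snp index list
    represented_genes: dict  # pathway_id -> count of genes with >= 1 SNP
    n_genes: dict  # pathway_id -> genes annotated to the pathway
    names: dict = field(default_factory=dict)

    def snp_count(self, pathway_id) -> int:
        return len(self.sets[pathway_id])

    @property
    def pathway_ids(self) -> list:
        return list(self.sets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pathway_id": p,
                    "name": self.names.get(p, ""),
                    "n_genes": self.n_genes[p],
                    "n_represented_genes": self.represented_genes[p],
                    "n_snps": len(s),
                    "snp_indices": ",".join(map(str, s)),
                }
                for p, s in self.sets.items()
            ]
        )


def build_pathway_snp_sets(
    snps: pd.DataFrame,
    extended_annotation: pd.DataFrame,
    pathway_map: pd.DataFrame,
) -> PathwaySNPSets:
    """Map SNPs to genes (closed interval, chrom match) then to pathways.

    ``snps`` is the SNP metadata table of a GenotypeMatrix; returned
    indices are positions in that table.  A SNP may map to several
    genes and pathways; within a pathway it is counted once.
    """
    pathway_map = validate_pathway_map(pathway_map)
    if pathway_map.empty:
        raise ValueError("empty pathway map")
    ann = validate_annotation(extended_annotation)
    chrom = snps["chrom"].astype(str).to_numpy()
    pos = snps["pos"].to_numpy()
    gene_snps: dict[str, np.ndarray] = {}
    for _, g in ann.iterrows():
        mask = (chrom == g["chrom"]) & (pos >= g["start"]) & (pos <= g["end"])
        gene_snps[g["gene_id"]] = np.where(mask)[0]
    sets, represented, n_genes, names = {}, {}, {}, {}
    for pid, grp in pathway_map.groupby("pathway_id", sort=True):
        genes = grp["gene_id"].tolist()
        hit_genes = 0
        idx: set[int] = set()
        for gid in genes:
            snp_idx = gene_snps.get(gid, np.empty(0, dtype=int))
            if len(snp_idx):
                hit_genes += 1
                idx.update(snp_idx.tolist())
        sets[pid] = sorted(idx)
        represented[pid] = hit_genes
        n_genes[pid] = len(genes)
        name = grp["name"].iloc[0] if "name" in grp.columns else ""
        names[pid] = name
    return PathwaySNPSets(sets=sets, represented_genes=represented,
                          n_genes=n_genes, names=names)


def prune_pathways(
    sets: PathwaySNPSets, min_represented_genes: int = 10
) -> tuple[PathwaySNPSets, pd.DataFrame]:
    """Keep pathways with at least ``min_represented_genes`` represented genes."""
    if min_represented_genes < 1:
        raise ValueError("min_represented_genes must be >= 1")
    keep = [p for p in sets.pathway_ids
            if sets.represented_genes[p] >= min_represented_genes]
    removed = [p for p in sets.pathway_ids if p not in keep]
    if not keep:
        raise ValueError("all pathways pruned; lower min_represented_genes")
    pruned = PathwaySNPSets(
        sets={p: sets.sets[p] for p in keep},
        represented_genes={p: sets.represented_genes[p] for p in keep},
        n_genes={p: sets.n_genes[p] for p in keep},
        names={p: sets.names.get(p, "") for p in keep},
    )
    report = pd.DataFrame(
        {"pathway_id": removed,
         "n_represented_genes": [sets.represented_genes[p] for p in removed]}
    )
    return pruned, report
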