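"""Readers and writers for the standard formats the pipeline touches.

Genotypes come from PLINK bed/bim/fam or VCF (optionally gzipped, via
cyvcf2); phenotypes/pedigree/pathway maps are headered delimited text;
gene annotation is GFF3 (``type == gene``) or a BED-like TSV.
Relationship matrices round-trip through an ``.npy`` payload plus an id
sidecar so saved kernels reload bitwise-equal.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .tables import (
    Pedigree,
    normalize_units,
    validate_annotation,
    validate_pathway_map,
)

log = logging.getLogger(__name__)

_BED_MAGIC = b"\x6c\x1b\x01"
# PLINK 2-bit codes, SNP-major: 00=hom A1, 01=missing, 10=het, 11=hom A2.
# Dosage counts the A1 allele.
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


# ---------------------------------------------------------------- PLINK
def read_plink(prefix: str | Path) -> GenotypeMatrix:
    prefix = str(prefix)
    fam = pd.read_csv(
        prefix + ".fam", sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str,
    )
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "alt", "ref"], dtype=str,
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK bed file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise ValueError(
            f"{prefix}.bed: payload {body.size} bytes does not match "
            f"{n} samples x {m} SNPs"
        )
    body = body.reshape(m, bytes_per_snp)
    # expand the four 2-bit fields of each byte, low bits = first sample
    codes = np.stack(
        [(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1
    ).reshape(m, -1)[:, :n]
    calls = _BED_DECODE[codes].T.copy()
    snps = pd.DataFrame(
        {
            "snp_id": bim["snp_id"],
            "chrom": bim["chrom"].astype(str),
            "pos": bim["pos"].astype(int),
            "ref": bim["ref"],
            "alt": bim["alt"],
        }
    )
    return GenotypeMatrix(ids=list(fam["iid"]), snps=snps, calls=calls)


def write_plink(gm: GenotypeMatrix, prefix: str | Path) -> list[str]:
    prefix = str(prefix)
    n, m = gm.n_individuals, gm.n_snps
    fam = pd.DataFrame(
        {"fid": gm.ids, "iid": gm.ids, "father": "0", "mother": "0",
         "sex": "0", "pheno": "-9"}
    )
    fam.to_csv(prefix + ".fam", sep=" ", header=False, index=False)
    bim = pd.DataFrame(
        {"chrom": gm.snps["chrom"], "snp_id": gm.snps["snp_id"], "cm": 0,
         "pos": gm.snps["pos"], "a1": gm.snps["alt"], "a2": gm.snps["ref"]}
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    encode = {2.0: 0, 1.0: 2, 0.0: 3}
    codes = np.full((m, n), 1, dtype=np.uint8)  # 1 = missing
    for dosage, code in encode.items():
        codes[(gm.calls.T == dosage)] = code
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((m, pad), dtype=np.uint8)], axis=1
        )
    packed = (
        codes.reshape(m, -1, 4)
        * np.array([1, 4, 16, 64], dtype=np.uint8)
    ).sum(axis=2, dtype=np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    return [prefix + ext for ext in (".bed", ".bim", ".fam")]


# ------------------------------------------------------------------ VCF
def read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, cols = [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped += 1
            continue
        dosages = np.array(
            [a0 + a1 if (a0 >= 0 and a1 >= 0) else np.nan
             for a0, a1, *_ in v.genotypes],
            dtype=float,
        )
        cols.append(dosages)
        rows.append(
            {
                "snp_id": v.ID or f"{v.CHROM}:{v.POS}",
                "chrom": str(v.CHROM),
                "pos": int(v.POS),
                "ref": v.REF,
                "alt": v.ALT[0],
            }
        )
    vcf.close()
    if n_skipped:
        log.info("skipped %d non-biallelic VCF records", n_skipped)
    if not rows:
        raise ValueError(f"{path}: no biallelic records")
    gm = GenotypeMatrix(
        ids=ids, snps=pd.DataFrame(rows), calls=np.column_stack(cols)
    )
    gm.meta["n_skipped_non_biallelic"] = n_skipped
    return gm


def load_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Load genotypes from a PLINK prefix or a VCF file.

    ``format`` is 'plink' or 'vcf'; inferred from the path when omitted.
    """
    p = str(path)
    if format is None:
        if p.endswith((".vcf", ".vcf.gz")):
            format = "vcf"
        elif os.path.exists(p + ".bed") or p.endswith(".bed"):
            format = "plink"
        else:
            raise ValueError(f"cannot infer genotype format for {p!r}")
    if format == "plink":
        return read_plink(p[:-4] if p.endswith(".bed") else p)
    if format == "vcf":
        return read_vcf(p)
    raise ValueError(f"unknown genotype format {format!r}")


# --------------------------------------------------------------- tables
def load_phenotypes(path: str | Path) -> pd.DataFrame:
    return normalize_units(pd.read_csv(path))


def load_pedigree(path: str | Path) -> Pedigree:
    return Pedigree(pd.read_csv(path, dtype=str))


def _parse_gff3_attr(attrs: str, key: str) -> str | None:
    for field in attrs.strip().split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def load_annotation(path: str | Path) -> pd.DataFrame:
    """GFF3 (gene features) or TSV gene_id/chrom/start/end/strand."""
    path = str(path)
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("##gff") or path.endswith((".gff", ".gff3")):
        gff = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "source", "type", "start", "end", "score",
                   "strand", "phase", "attributes"],
            dtype={"chrom": str},
        )
        genes = gff[gff["type"] == "gene"].copy()
        genes["gene_id"] = [
            _parse_gff3_attr(a, "ID") or _parse_gff3_attr(a, "gene_id") or f"gene{i}"
            for i, a in enumerate(genes["attributes"])
        ]
        genes["gene_id"] = genes["gene_id"].str.removeprefix("gene:")
        df = genes[["gene_id", "chrom", "start", "end", "strand"]]
    else:
        df = pd.read_csv(path, sep="\t")
        if {"start", "end"} - set(df.columns):
            raise ValueError(f"{path}: not GFF3 and not a gene TSV")
    return validate_annotation(df)


def load_pathways(path: str | Path) -> pd.DataFrame:
    return validate_pathway_map(pd.read_csv(path, sep="\t"))


def load_tables(pheno_path, pedigree_path, annotation_path, pathway_path):
    """Load the four side tables in one call (spec convenience)."""
    return (
        load_phenotypes(pheno_path),
        load_pedigree(pedigree_path),
        load_annotation(annotation_path),
        load_pathways(pathway_path),
    )


# -------------------------------------------------------------- results
def save_results(tables: dict, out_dir: str | Path, overwrite: bool = False) -> dict:
    """Write each table (DataFrame) as headered TSV under ``out_dir``.

    Returns {name: path}.  Raises on collision unless ``overwrite``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists (pass overwrite=True)")
        pd.DataFrame(table).to_csv(path, sep="\t", index=False)
        paths[name] = str(path)
    return paths


def save_relationship_matrix(rm, prefix: str | Path, overwrite: bool = False) -> dict:
    prefix = str(prefix)
    paths = {
        "values": prefix + ".npy",
        "ids": prefix + ".ids.txt",
        "meta": prefix + ".meta.json",
    }
    for p in paths.values():
        if os.path.exists(p) and not overwrite:
            raise FileExistsError(f"{p} exists (pass overwrite=True)")
    np.save(paths["values"], rm.values)
    Path(paths["ids"]).write_text("\n".join(map(str, rm.ids)) + "\n")
    Path(paths["meta"]).write_text(
        json.dumps({"flavor": rm.flavor, **rm.meta}, default=str)
    )
    return paths


def load_relationship_matrix(prefix: str | Path):
    from .kinship import RelationshipMatrix

    prefix = str(prefix)
    values = np.load(prefix + ".npy")
    ids = Path(prefix + ".ids.txt").read_text().splitlines()
    meta = json.loads(Path(prefix + ".meta.json").read_text())
    flavor = meta.pop("flavor")
    return RelationshipMatrix(ids=ids, values=values, flavor=flavor, meta=meta)
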