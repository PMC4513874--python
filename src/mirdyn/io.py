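"""Readers/writers for the package's plain-text interchange formats.

Tab-delimited UTF-8 with '.' decimals throughout: fold-change matrices
(gene_id + one 't<hours>' column per timepoint), label and Ct tables,
gene-ID lists, GMT gene sets, FASTA sequence files with region-tagged ids
('<gene>|utr3', '<gene>|cds'), and CurveSet serialization (coefficient
TSV + JSON basis sidecar).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fda import BasisSpec, CurveSet

__all__ = [
    "read_fc_tsv", "write_fc_tsv",
    "read_gene_list", "write_gene_list",
    "read_labels_tsv", "write_labels_tsv",
    "read_ct_tsv", "write_ct_tsv",
    "read_gmt", "write_gmt",
    "read_region_fasta", "write_region_fasta",
    "read_curveset", "write_curveset",
]


def read_fc_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    bad = [c for c in df.columns if not str(c).startswith("t")]
    if bad:
        raise ValueError(f"expected 't<hours>' columns, got {bad[:3]}")
    return df


def write_fc_tsv(fc: pd.DataFrame, path) -> None:
    fc.rename_axis("gene_id").to_csv(path, sep="\t")


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines()
            if ln.strip()]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_labels_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(str)


def write_labels_tsv(labels: pd.Series, path) -> None:
    labels.rename("label").rename_axis("gene_id").to_csv(path, sep="\t")


def read_ct_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ct_tsv(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {ln[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict, path, description: str = "na") -> None:
    lines = [f"{name}\t{description}\t" + "\t".join(genes)
             for name, genes in gene_sets.items()]
    Path(path).write_text("".join(f"{ln}\n" for ln in lines))


def read_region_fasta(path) -> tuple[dict[str, str], dict[str, str]]:
    """Parse FASTA with ids '<gene>|utr3' / '<gene>|cds' into two dicts."""
    utr, cds = {}, {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"FASTA id {rec.id!r} lacks '|region' tag")
        gene, region = rec.id.rsplit("|", 1)
        if region == "utr3":
            utr[gene] = str(rec.seq)
        elif region == "cds":
            cds[gene] = str(rec.seq)
        else:
            raise ValueError(f"unknown region tag {region!r} in {rec.id!r}")
    return utr, cds


def write_region_fasta(utr_sequences: dict, cds_sequences: dict, path
                       ) -> None:
    recs = []
    for region, seqs in (("utr3", utr_sequences), ("cds", cds_sequences)):
        recs.extend(SeqRecord(Seq(s), id=f"{g}|{region}", description="")
                    for g, s in sorted(seqs.items()))
    SeqIO.write(recs, str(path), "fasta")


def write_curveset(curves: CurveSet, coef_path, basis_path) -> None:
    pd.DataFrame(curves.coefficients,
                 index=pd.Index(curves.gene_ids, name="gene_id")
                 ).to_csv(coef_path, sep="\t")
    Path(basis_path).write_text(json.dumps({
        "knots": list(curves.basis.knots),
        "order": curves.basis.order,
        "lambda": curves.basis.lam}, indent=2))


def read_curveset(coef_path, basis_path) -> CurveSet:
    meta = json.loads(Path(basis_path).read_text())
    basis = BasisSpec(knots=tuple(meta["knots"]), order=int(meta["order"]),
                      lam=float(meta["lambda"]))
    coef = pd.read_csv(coef_path, sep="\t", index_col=0)
    return CurveSet(list(coef.index.astype(str)),
                    coef.to_numpy(float), basis)
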