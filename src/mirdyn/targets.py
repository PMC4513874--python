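"""miRNA seed matching and direct/indirect/non-target training-set assembly.

A miRNA "seed match" is the reverse complement, on the mRNA sense strand,
of miRNA positions 2-8 (7-mer) or 2-9 (8-mer).  Training sets for the
functional classifier are built from an external direct-target prediction
list intersected with a non-specific fold-change response filter; indirect
and non-target sets are drawn from seed-free / non-responding genes and
subsampled to match the direct set size.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "SeedSpec",
    "SeedMatch",
    "GeneAnnotation",
    "TargetLabelSets",
    "MIR9_SEQUENCE",
    "find_seed_matches",
    "annotate_sequences",
    "nonspecific_filter",
    "build_training_sets",
]

#: hsa-miR-9-5p, 5'->3'.  Reverse complement of positions 2-9 is AACCAAAG,
#: the antimiR sequence used to block the seed region.
MIR9_SEQUENCE = "UCUUUGGUUAUCUAGCUGUAUGA"

_VALID_SEQ = re.compile(r"^[ACGTUN]*$")


@dataclass(frozen=True)
class SeedSpec:
    """Seed-match strings derived from a miRNA sequence.

    seed7 / seed8 are DNA reverse complements of miRNA positions 2-8 and
    2-9 (1-based); seed8 extends seed7 by the base pairing miRNA position
    9, so seed8 always ends with seed7.
    """

    mirna_sequence: str
    seed7: str = field(init=False)
    seed8: str = field(init=False)

    def __post_init__(self) -> None:
        seq = self.mirna_sequence.upper().replace("T", "U")
        if len(seq) < 9:
            raise ValueError("miRNA sequence must be at least 9 nt")
        if not _VALID_SEQ.match(seq.replace("U", "T")):
            raise ValueError(f"invalid miRNA sequence: {self.mirna_sequence}")
        object.__setattr__(self, "mirna_sequence", seq)
        dna = seq.replace("U", "T")
        object.__setattr__(
            self, "seed7", str(Seq(dna[1:8]).reverse_complement()))
        object.__setattr__(
            self, "seed8", str(Seq(dna[1:9]).reverse_complement()))
        assert self.seed8.endswith(self.seed7)


class SeedMatch(NamedTuple):
    position: int       # 0-based start on the given sequence
    site_type: str      # '7mer' | '8mer'
    region: str


def _normalize_sequence(sequence: str) -> str:
    seq = sequence.upper().replace("U", "T")
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"invalid sequence characters: {bad}")
    return seq


def find_seed_matches(seed: SeedSpec, sequence: str, region_label: str = ""
                      ) -> list[SeedMatch]:
    """All 7-mer and 8-mer seed-site occurrences on the sense strand.

    Overlapping occurrences are all reported; every 8-mer site contains a
    7-mer site (offset +1), which the 7-mer scan reports independently.
    N never matches.  Positions are 0-based half-open starts.
    """
    seq = _normalize_sequence(sequence)
    out: list[SeedMatch] = []
    for pattern, label in ((seed.seed7, "7mer"), (seed.seed8, "8mer")):
        start = seq.find(pattern)
        while start != -1:
            out.append(SeedMatch(start, label, region_label))
            start = seq.find(pattern, start + 1)
    out.sort(key=lambda m: (m.position, m.site_type))
    return out


@dataclass
class GeneAnnotation:
    """Per-gene UTR/CDS lengths and seed-match counts, plus raw sequences.

    `table` is indexed by gene id with columns utr3_len, cds_len,
    seed7_utr, seed8_utr, seed7_cds, seed8_cds.  Counts are NaN (unknown,
    not zero) when the region sequence is absent.
    """

    table: pd.DataFrame
    utr_sequences: dict[str, str] | None = None
    cds_sequences: dict[str, str] | None = None
    seed: SeedSpec | None = None

    def __post_init__(self) -> None:
        req = {"utr3_len", "cds_len", "seed7_utr", "seed8_utr",
               "seed7_cds", "seed8_cds"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns {missing}")
        counts = self.table[list(req - {"utr3_len", "cds_len"})]
        if (counts.fillna(0) < 0).any().any():
            raise ValueError("negative seed counts")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def carriers(self, regions: Iterable[str] = ("utr3", "cds")) -> pd.Series:
        """Boolean: gene has >=1 7-mer site (8-mers are included) in any
        of the regions.  NaN counts propagate as False with unknown flag
        available via .seed_known()."""
        cols = [f"seed7_{ 'utr' if r == 'utr3' else 'cds'}" for r in regions]
        return self.table[cols].fillna(0).sum(axis=1) > 0

    def seed_known(self, regions: Iterable[str] = ("utr3", "cds")) -> pd.Series:
        cols = [f"seed7_{ 'utr' if r == 'utr3' else 'cds'}" for r in regions]
        return self.table[cols].notna().all(axis=1)


def annotate_sequences(utr_sequences: Mapping[str, str],
                       cds_sequences: Mapping[str, str],
                       seed: SeedSpec) -> GeneAnnotation:
    """Count seed sites in per-gene UTR/CDS sequences."""
    genes = sorted(set(utr_sequences) | set(cds_sequences))
    rows = []
    for g in genes:
        row: dict[str, float] = {}
        for region, seqs in (("utr", utr_sequences), ("cds", cds_sequences)):
            s = seqs.get(g)
            if s is None:
                row[f"{'utr3' if region == 'utr' else 'cds'}_len"] = np.nan
                row[f"seed7_{region}"] = np.nan
                row[f"seed8_{region}"] = np.nan
            else:
                matches = find_seed_matches(seed, s, region)
                row[f"{'utr3' if region == 'utr' else 'cds'}_len"] = len(s)
                row[f"seed7_{region}"] = sum(
                    1 for m in matches if m.site_type == "7mer")
                row[f"seed8_{region}"] = sum(
                    1 for m in matches if m.site_type == "8mer")
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(genes, name="gene"))
    return GeneAnnotation(table, dict(utr_sequences), dict(cds_sequences),
                          seed)


def nonspecific_filter(fc: pd.DataFrame, threshold_linear: float
                       ) -> set[str]:
    """Genes whose |log2 FC| meets a linear-scale threshold at any time.

    The threshold is quoted on the linear scale (e.g. 1.5) and applied as
    |log2FC| >= log2(threshold), inclusive.
    """
    if threshold_linear <= 1:
        raise ValueError("threshold must be > 1 (linear scale)")
    cut = np.log2(threshold_linear)
    hit = (fc.abs().max(axis=1) >= cut)
    return set(map(str, fc.index[hit]))


@dataclass(frozen=True)
class TargetLabelSets:
    direct: frozenset[str]
    indirect: frozenset[str]
    nontarget: frozenset[str]
    filter_log: dict = field(compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if (self.direct & self.indirect or self.direct & self.nontarget
                or self.indirect & self.nontarget):
            raise ValueError("label sets must be pairwise disjoint")


def build_training_sets(predictions: Iterable[str],
                        annotations: GeneAnnotation,
                        fc: pd.DataFrame,
                        threshold: float = 1.5,
                        other_predictor_genes: Iterable[str] = (),
                        rng_seed: int = 0) -> TargetLabelSets:
    """Assemble direct / indirect / non-target training sets.

    direct    = externally predicted targets passing the non-specific
                fold-change filter;
    indirect  = responders with no 7/8-mer seed in UTR or CDS and not
                predicted by any supplied predictor, subsampled to |direct|;
    nontarget = non-responders not predicted, subsampled to |direct|.
    """
    predictions = set(map(str, predictions))
    all_genes = set(map(str, fc.index))
    unknown = predictions - set(annotations.gene_ids)
    if unknown:
        raise ValueError(f"predictions not annotated: {sorted(unknown)[:5]}")

    responders = nonspecific_filter(fc, threshold)
    direct = predictions & responders
    if not direct:
        raise ValueError("empty direct set: no predicted target passes the "
                         f"FC>= {threshold} filter")

    predicted_any = predictions | set(map(str, other_predictor_genes))
    known = annotations.seed_known()
    carrier = annotations.carriers()
    # seed status must be KNOWN zero, not merely unrecorded
    seed_free = set(annotations.table.index[known & ~carrier]) & all_genes

    indirect_pool = (seed_free & responders) - predicted_any - direct
    nontarget_pool = (all_genes - responders) - predicted_any

    n = len(direct)
    log = {
        "threshold_linear": threshold,
        "n_predictions": len(predictions),
        "n_responders": len(responders),
        "n_direct": n,
        "n_indirect_pool": len(indirect_pool),
        "n_nontarget_pool": len(nontarget_pool),
        "rng_seed": rng_seed,
    }
    for name, pool in (("indirect", indirect_pool),
                       ("nontarget", nontarget_pool)):
        if len(pool) < n:
            raise ValueError(
                f"{name} candidate pool ({len(pool)}) smaller than direct "
                f"set ({n}); counts: {log}")
    rng = np.random.default_rng(rng_seed)
    indirect = set(rng.choice(sorted(indirect_pool), size=n, replace=False))
    nontarget = set(rng.choice(sorted(nontarget_pool), size=n, replace=False))
    return TargetLabelSets(frozenset(direct), frozenset(indirect),
                           frozenset(nontarget), log)
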