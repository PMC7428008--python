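"""Sequential apportionment of reads to genomic feature classes.

Every read is assigned to the FIRST class, in the fixed genome-wide priority
order

    TSS_region > UTR5 > TTS_region > UTR3 > exonic > intronic > intergenic,

whose interval set (pooled over all genes) it overlaps by at least one base.
The unextended read interval is used — apportionment describes where reads
fall, not smoothed density. Read strand is ignored; feature strand is
already encoded in window construction.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _intervals as iv
from .annotation import GeneModel, derive_feature_windows

#: Priority order; 'intergenic' is the fall-through class.
CATEGORY_ORDER = ("TSS_region", "UTR5", "TTS_region", "UTR3",
                  "exonic", "intronic")
CATEGORIES = CATEGORY_ORDER + ("intergenic",)

_WINDOW_ATTR = {"TSS_region": "tss_region", "UTR5": "utr5",
                "TTS_region": "tts_region", "UTR3": "utr3",
                "exonic": "exonic", "intronic": "intronic"}


@dataclass
class FeatureIndex:
    """Merged per-category, per-chromosome interval arrays for fast overlap."""

    # category -> chrom -> (starts, ends) of merged, sorted intervals
    merged: Dict[str, Dict[str, Tuple[np.ndarray, np.ndarray]]]
    # category -> chrom -> list of (start, end, gene_id), start-sorted
    per_gene: Dict[str, Dict[str, List[Tuple[int, int, str]]]]

    @classmethod
    def from_genes(cls, genes: Iterable[GeneModel],
                   chrom_sizes: Mapping[str, int]) -> "FeatureIndex":
        raw: Dict[str, Dict[str, List[Tuple[int, int]]]] = {
            c: {} for c in CATEGORY_ORDER}
        per_gene: Dict[str, Dict[str, List[Tuple[int, int, str]]]] = {
            c: {} for c in CATEGORY_ORDER}
        for gene in genes:
            win = derive_feature_windows(gene, chrom_sizes[gene.chrom])
            for cat in CATEGORY_ORDER:
                for s, e in getattr(win, _WINDOW_ATTR[cat]):
                    raw[cat].setdefault(gene.chrom, []).append((s, e))
                    per_gene[cat].setdefault(gene.chrom, []).append(
                        (s, e, gene.gene_id))
        merged = {
            cat: {chrom: tuple(np.array(x, dtype=np.int64)
                               for x in zip(*iv.merge(ivs)))
                  for chrom, ivs in by_chrom.items()}
            for cat, by_chrom in raw.items()
        }
        for cat in per_gene:
            for chrom in per_gene[cat]:
                per_gene[cat][chrom].sort()
        return cls(merged=merged, per_gene=per_gene)

    def overlaps(self, category: str, chrom: str, start: int, end: int) -> bool:
        by_chrom = self.merged[category]
        if chrom not in by_chrom:
            return False
        starts, ends = by_chrom[chrom]
        j = bisect.bisect_left(starts.tolist(), end) - 1
        # intervals are merged and sorted: only the last one starting before
        # `end` can reach past `start`
        return j >= 0 and ends[j] > start


@dataclass
class FeatureCounts:
    """Read counts per feature class; categories partition the library."""

    counts: Dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CATEGORIES})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> Dict[str, float]:
        t = self.total
        return {c: (n / t if t else 0.0) for c, n in self.counts.items()}

    def as_frame(self) -> pd.DataFrame:
        fr = self.fractions
        return pd.DataFrame({"category": list(CATEGORIES),
                             "count": [self.counts[c] for c in CATEGORIES],
                             "fraction": [fr[c] for c in CATEGORIES]})


def classify_read(chrom: str, start: int, end: int,
                  index: FeatureIndex) -> str:
    """Assign one read to the first overlapping category in priority order."""
    for cat in CATEGORY_ORDER:
        if index.overlaps(cat, chrom, start, end):
            return cat
    return "intergenic"


def classify_reads(reads: pd.DataFrame, index: FeatureIndex) -> np.ndarray:
    """Vectorized :func:`classify_read` over a read table (row order kept)."""
    result = np.full(len(reads), "intergenic", dtype=object)
    chroms = reads["chrom"].to_numpy()
    all_start = reads["start"].to_numpy(np.int64)
    all_end = reads["end"].to_numpy(np.int64)
    for chrom in pd.unique(chroms):
        rows = np.flatnonzero(chroms == chrom)
        start, end = all_start[rows], all_end[rows]
        unassigned = np.ones(rows.size, dtype=bool)
        for cat in CATEGORY_ORDER:
            by_chrom = index.merged[cat]
            if chrom not in by_chrom or not unassigned.any():
                continue
            starts, ends = by_chrom[chrom]
            sub = np.flatnonzero(unassigned)
            j = np.searchsorted(starts, end[sub], side="left") - 1
            hit = (j >= 0) & (ends[np.maximum(j, 0)] > start[sub])
            result[rows[sub[hit]]] = cat
            unassigned[sub[hit]] = False
    return result


def apportion_library(
    reads: pd.DataFrame,
    index: FeatureIndex,
    per_gene: bool = False,
) -> Tuple[FeatureCounts, Optional[pd.DataFrame]]:
    """Apportion every read of a library; the categories partition the total.

    With ``per_gene=True`` additionally attributes each non-intergenic read
    to a gene (the lexicographically smallest gene whose window of the
    winning category overlaps the read) and returns a per-gene breakdown.
    """
    fc = FeatureCounts()
    cats = classify_reads(reads, index)
    for cat, n in zip(*np.unique(cats, return_counts=True)):
        fc.counts[str(cat)] = int(n)
    breakdown = None
    if per_gene:
        gene_rows: Dict[Tuple[str, str], int] = {}
        chroms = reads["chrom"].to_numpy()
        starts = reads["start"].to_numpy(np.int64)
        ends = reads["end"].to_numpy(np.int64)
        for chrom, s, e, cat in zip(chroms, starts, ends, cats):
            if cat == "intergenic":
                continue
            gid = _attribute_gene(index, cat, chrom, int(s), int(e))
            gene_rows[(gid, cat)] = gene_rows.get((gid, cat), 0) + 1
        breakdown = pd.DataFrame(
            [(g, c, n) for (g, c), n in sorted(gene_rows.items())],
            columns=["gene_id", "category", "count"])
    return fc, breakdown


def _attribute_gene(index: FeatureIndex, category: str, chrom: str,
                    start: int, end: int) -> str:
    entries = index.per_gene[category].get(chrom, [])
    hits = [gid for s, e, gid in entries if s < end and e > start]
    return min(hits)
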