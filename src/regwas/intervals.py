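"""Interval algebra for regulatory-element processing.

All coordinates in this package are 0-based half-open ``[start, end)``,
the BED convention.  Readers for 1-based inclusive dialects convert on
input (see :mod:`regwas.io_formats`).

The operations here implement the epigenomic pre-processing of the
pipeline: merging tissue H3K27ac peaks, restricting a regulatory-element
(RE) catalog to peak-supported elements, classifying REs into promoters
and candidate enhancers by transcription-start-site (TSS) windows, and
nearest-TSS assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: promoter window, bp upstream / downstream of the TSS (strand-aware)
PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 100


@dataclass(frozen=True)
class Interval:
    """A genomic interval on the internal 0-based half-open convention."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(start must be < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        """Strict half-open intersection of at least one base pair."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class RegulatoryElement:
    """A regulatory element with its candidate target-gene links.

    ``gene_links`` are ``(gene_id, link_score)`` pairs; an element may
    link several genes and a gene may be linked from several elements.
    ``re_class`` is set by :func:`classify_re` and ``tissue_supported``
    by :func:`filter_res_by_peaks`; both are ``None`` until then.
    """

    re_id: str
    chrom: str
    start: int
    end: int
    gene_links: list[tuple[str, float]] = field(default_factory=list)
    re_class: Optional[str] = None  # {"promoter", "enhancer"} once classified
    tissue_supported: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"RE {self.re_id}: start must be < end")

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or bookended intervals into a disjoint union.

    Matches the default semantics of standard BED merge tooling: two
    intervals merge iff they overlap or touch (``end_a == start_b``).
    Output is sorted by (chrom, start, end) and non-overlapping.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[Interval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = Interval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


class _ChromIndex:
    """Sorted start/end arrays per chromosome for overlap queries."""

    def __init__(self, intervals: Sequence[Interval]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        tmp: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, pairs in tmp.items():
            pairs.sort()
            starts = np.array([p[0] for p in pairs], dtype=np.int64)
            ends = np.array([p[1] for p in pairs], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends)

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) shares >= 1 bp with any indexed interval.

        Assumes the indexed intervals are disjoint and sorted (i.e. the
        output of :func:`merge_intervals`), so a single binary search
        suffices.
        """
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        i = int(np.searchsorted(starts, end, side="left")) - 1
        return i >= 0 and ends[i] > start


def filter_res_by_peaks(
    catalog: Sequence[RegulatoryElement],
    merged_peaks: Sequence[Interval],
) -> list[RegulatoryElement]:
    """Restrict an RE catalog to elements supported by tissue peaks.

    An element is retained iff it shares at least one base pair with at
    least one peak; retained elements are flagged ``tissue_supported``.
    ``merged_peaks`` must be pre-merged (disjoint, sorted).
    """
    if not merged_peaks:
        raise ValueError("empty peak set: tissue filtering would discard every RE")
    index = _ChromIndex(merged_peaks)
    kept: list[RegulatoryElement] = []
    for re_ in catalog:
        if index.any_overlap(re_.chrom, re_.start, re_.end):
            re_.tissue_supported = True
            kept.append(re_)
        else:
            re_.tissue_supported = False
    logger.info(
        "peak filter retained %d / %d REs", len(kept), len(catalog)
    )
    return kept


def promoter_window(tss: int, strand: str) -> tuple[int, int]:
    """Strand-aware promoter window around a TSS, internal coordinates.

    The window covers 1,000 bp upstream and 100 bp downstream of the TSS
    (1-based inclusive genomic span), mirrored for the minus strand, and
    is returned converted to the 0-based half-open convention, clipped
    at zero.
    """
    if strand == "-":
        lo, hi = tss - PROMOTER_DOWNSTREAM, tss + PROMOTER_UPSTREAM
    else:
        lo, hi = tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
    return max(lo - 1, 0), hi  # 1-based inclusive [lo, hi] -> [lo-1, hi)


def _promoter_index(gene_locations: Sequence) -> _ChromIndex:
    windows = []
    for g in gene_locations:
        strand = g.strand
        if strand not in ("+", "-"):
            logger.warning("gene %s: unknown strand %r treated as '+'", g.gene_id, strand)
            strand = "+"
        lo, hi = promoter_window(g.tss, strand)
        if lo < hi:
            windows.append(Interval(g.chrom, lo, hi))
    return _ChromIndex(merge_intervals(windows))


def classify_re(re_: RegulatoryElement, gene_locations: Sequence) -> str:
    """Classify one RE as ``"promoter"`` or ``"enhancer"``.

    Promoter iff the element overlaps (>= 1 bp) the promoter window of
    any gene's TSS; every other element is a candidate active enhancer.
    The window is evaluated against all genes, not only linked ones.
    """
    return classify_catalog([re_], gene_locations)[0]


def classify_catalog(
    catalog: Sequence[RegulatoryElement], gene_locations: Sequence
) -> list[str]:
    """Classify every RE in a catalog; sets ``re_class`` in place."""
    index = _promoter_index(gene_locations)
    classes = []
    for re_ in catalog:
        cls = (
            "promoter"
            if index.any_overlap(re_.chrom, re_.start, re_.end)
            else "enhancer"
        )
        re_.re_class = cls
        classes.append(cls)
    return classes


def enhancer_tss_distance(re_: RegulatoryElement, gene) -> int:
    """Distance in bp between the element's start coordinate and the TSS."""
    return abs(re_.start - gene.tss)


def nearest_tss(
    position: int, gene_locations: Sequence, chrom: str
) -> Optional[str]:
    """Gene with the TSS closest to ``position`` on ``chrom``.

    Ties are broken by lexicographically smallest gene id; returns
    ``None`` when the chromosome carries no gene.
    """
    best: Optional[tuple[int, str]] = None
    for g in gene_locations:
        if g.chrom != chrom:
            continue
        key = (abs(position - g.tss), g.gene_id)
        if best is None or key < best:
            best = key
    return None if best is None else best[1]
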