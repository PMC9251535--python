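"""Cross-method comparisons and secondary analyses.

* ``bootstrap_compare`` asks whether one method's P-value population is
  systematically lower than another's, via bootstrap resampling of the
  difference in mean -log10(P).
* ``spearman`` is the rank-correlation diagnostic used to compare
  pre/post-adjustment gene rankings.
* ``ld_bin_novel_genes`` partitions the genome into LD bins and reports
  genes significant in the RE-centric scan whose best element falls in
  a bin containing no gene-body-significant gene — candidates the
  conventional scan cannot readily nominate because the signal sits in
  a distinct LD block from any gene body.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

SENTINEL_BIN = -1  # positions falling outside every bin


@dataclass(frozen=True)
class LdBin:
    chrom: str
    start: int  # 0-based half-open
    end: int
    bin_id: int


def bootstrap_compare(
    pvals_a: Sequence[float],
    pvals_b: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
) -> float:
    """One-sided bootstrap test that list ``b`` has lower P-values.

    Statistic: ``mean(-log10 p_b) - mean(-log10 p_a)``.  Both lists are
    resampled independently with replacement ``n_boot`` times; the
    reported p is the smoothed proportion of resampled statistics <= 0,
    i.e. evidence against "b is more significant than a".
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    a = np.asarray(pvals_a, dtype=np.float64)
    b = np.asarray(pvals_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both P-value lists must be non-empty")
    tiny = np.nextafter(0.0, 1.0)
    n_clamped = int((a <= 0).sum() + (b <= 0).sum())
    if n_clamped:
        logger.warning("clamped %d non-positive P-values before log transform", n_clamped)
    la = -np.log10(np.clip(a, tiny, 1.0))
    lb = -np.log10(np.clip(b, tiny, 1.0))
    rng = np.random.default_rng(seed)
    count_le0 = 0
    chunk = max(1, min(n_boot, int(2e7 // max(a.size, b.size, 1)) or 1))
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        ma = la[rng.integers(0, la.size, size=(m, la.size))].mean(axis=1)
        mb = lb[rng.integers(0, lb.size, size=(m, lb.size))].mean(axis=1)
        count_le0 += int(((mb - ma) <= 0).sum())
        done += m
    return (count_le0 + 1) / (n_boot + 1)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties).

    Returns NaN for a constant vector, where the coefficient is
    undefined.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


# ---------------------------------------------------------------------------
# LD bins

def bins_from_intervals(intervals: Sequence) -> list[LdBin]:
    """Number a sorted, per-chromosome non-overlapping interval set."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start))
    bins = []
    prev: Optional[LdBin] = None
    for i, iv in enumerate(ivs):
        if prev is not None and prev.chrom == iv.chrom and iv.start < prev.end:
            raise ValueError(f"LD bins overlap at {iv.chrom}:{iv.start}")
        b = LdBin(iv.chrom, iv.start, iv.end, bin_id=i)
        bins.append(b)
        prev = b
    return bins


def assign_bin(chrom: str, position: int, bins: Sequence[LdBin]) -> int:
    """Bin id containing a 0-based position, or the sentinel."""
    for b in bins:
        if b.chrom == chrom and b.start <= position < b.end:
            return b.bin_id
    return SENTINEL_BIN


def build_ld_bins(
    panel,
    r2_threshold: float = 0.1,
    window: int = 200,
) -> list[LdBin]:
    """Greedy fallback LD-bin builder from a reference panel.

    Walks SNPs in position order per chromosome and opens a new bin
    whenever a SNP's maximum r-squared with the previous ``window``
    SNPs of the current bin falls below ``r2_threshold``.  Bin
    boundaries are placed midway between the flanking SNPs; terminal
    bins extend a flank beyond the outermost SNPs.
    """
    bins: list[LdBin] = []
    order = np.lexsort((panel.pos, np.array(panel.chroms, dtype=object)))
    bin_id = 0
    i = 0
    FLANK = 500_000
    while i < len(order):
        chrom = panel.chroms[order[i]]
        idxs = [j for j in order if panel.chroms[j] == chrom]
        cuts = [0]
        block_members: list[int] = [idxs[0]]
        for k in range(1, len(idxs)):
            g = panel.dosages[idxs[k]]
            recent = block_members[-window:]
            max_r2 = 0.0
            if np.std(g) > 0:
                for j in recent:
                    h = panel.dosages[j]
                    if np.std(h) > 0:
                        r = np.corrcoef(g, h)[0, 1]
                        max_r2 = max(max_r2, r * r)
            if max_r2 < r2_threshold:
                cuts.append(k)
                block_members = [idxs[k]]
            else:
                block_members.append(idxs[k])
        cuts.append(len(idxs))
        pos = [int(panel.pos[j]) for j in idxs]
        for c in range(len(cuts) - 1):
            lo_snp = pos[cuts[c]]
            hi_snp = pos[cuts[c + 1] - 1]
            start = max(0, lo_snp - FLANK) if c == 0 else (pos[cuts[c] - 1] + lo_snp) // 2
            end = hi_snp + FLANK if c == len(cuts) - 2 else (hi_snp + pos[cuts[c + 1]]) // 2
            bins.append(LdBin(chrom, start, end, bin_id))
            bin_id += 1
        i += len(idxs)
    return bins


@dataclass
class NovelGeneReport:
    gene_id: str
    best_re_id: str
    re_bin: int
    gene_body_bin: int
    re_outside_bins: bool


def ld_bin_novel_genes(
    chrom_sig: set[str],
    magma_sig: set[str],
    gene_assocs: Sequence,
    re_intervals: dict[str, tuple[str, int, int]],
    gene_locations: Sequence,
    bins: Sequence[LdBin],
) -> list[NovelGeneReport]:
    """Genes nominated by the RE-centric scan in LD bins the gene-body
    scan leaves silent.

    A gene significant in the RE-centric scan is *novel* iff the LD bin
    holding its best element's start contains no gene-body-significant
    gene (any overlap of the gene body with the bin counts).  Elements
    outside every bin get the sentinel bin and are flagged.
    """
    loc_by_id = {g.gene_id: g for g in gene_locations}
    # bins occupied by gene bodies of conventionally significant genes
    occupied: set[int] = set()
    for gid in magma_sig:
        g = loc_by_id.get(gid)
        if g is None:
            continue
        for b in bins:
            if b.chrom == g.chrom and b.start < g.end and (g.start - 1) < b.end:
                occupied.add(b.bin_id)
    assoc_by_gene = {a.gene_id: a for a in gene_assocs}
    out: list[NovelGeneReport] = []
    for gid in sorted(chrom_sig):
        a = assoc_by_gene.get(gid)
        if a is None:
            continue
        chrom, start, _end = re_intervals[a.best_re_id]
        re_bin = assign_bin(chrom, start, bins)
        g = loc_by_id.get(gid)
        body_bin = (
            assign_bin(g.chrom, g.start - 1, bins) if g is not None else SENTINEL_BIN
        )
        if re_bin == SENTINEL_BIN:
            logger.warning("best RE %s of %s falls outside all LD bins", a.best_re_id, gid)
        if re_bin not in occupied:
            out.append(
                NovelGeneReport(
                    gene_id=gid,
                    best_re_id=a.best_re_id,
                    re_bin=re_bin,
                    gene_body_bin=body_bin,
                    re_outside_bins=re_bin == SENTINEL_BIN,
                )
            )
    return out
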