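"""Gene-level collapse of feature associations and ranked-list building.

Several regulatory elements may regulate one gene, and one element may
regulate several genes; the gene-level P-value is the minimum over the
gene's tested elements (the element "represents" the gene).  A Sidak
min-P adjustment for the number of tested elements is computed and
reported alongside, but deliberately not substituted for the primary
P-value: aggressive correction trades type-I for type-II error, and the
feature test already accounts for the number of SNPs per element.

For downstream gene-set enrichment the genes are ranked by
-log10(P) descending, with ties broken by an expression-weighted score
(-log10(P) x mean tissue expression) and then gene id, after removing
an optional exclusion list (e.g. the HLA region, whose long-range LD
clusters many gene-level associations).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)


@dataclass
class GeneAssociation:
    """Gene-level result: the most significant linked element's P-value."""

    gene_id: str
    best_re_id: str
    pvalue: float
    n_res: int  # number of tested REs linked to this gene
    re_class: Optional[str] = None
    adjusted_pvalue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.adjusted_pvalue is not None and self.adjusted_pvalue < self.pvalue - 1e-15:
            raise ValueError(f"{self.gene_id}: adjusted P below raw P")


@dataclass
class RankedGeneList:
    """Deterministically ordered gene list for preranked enrichment."""

    genes: list[str]
    scores: list[float]  # -log10(P)
    weighted_scores: list[float]  # -log10(P) * expression
    excluded_genes: list[str]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")

    def as_pairs(self) -> list[tuple[str, float]]:
        return list(zip(self.genes, self.scores))


def gene_level(
    feature_assocs: Sequence,
    re_gene_links: dict[str, Iterable[str]],
    re_class: Optional[dict[str, str]] = None,
) -> list[GeneAssociation]:
    """Collapse tested feature associations to one record per gene.

    ``re_gene_links`` maps RE id -> linked gene ids.  Per gene the best
    (minimum-P) tested element is chosen, ties broken by the smaller RE
    id; ``n_res`` counts the gene's tested elements.  Genes whose
    elements were all untested are omitted (counted in the log).
    """
    tested = {f.feature_id: f for f in feature_assocs}
    per_gene: dict[str, list] = {}
    genes_seen: set[str] = set()
    for re_id, genes in re_gene_links.items():
        for gene in genes:
            genes_seen.add(gene)
            if re_id in tested:
                per_gene.setdefault(gene, []).append(tested[re_id])
    omitted = len(genes_seen) - len(per_gene)
    if omitted:
        logger.info("%d genes had no tested RE and were omitted", omitted)
    out = []
    for gene, feats in per_gene.items():
        best = min(feats, key=lambda f: (f.pvalue, f.feature_id))
        out.append(
            GeneAssociation(
                gene_id=gene,
                best_re_id=best.feature_id,
                pvalue=best.pvalue,
                n_res=len(feats),
                re_class=(re_class or {}).get(best.feature_id),
                adjusted_pvalue=sidak_adjust(best.pvalue, len(feats)),
            )
        )
    out.sort(key=lambda g: (g.pvalue, g.gene_id))
    return out


def sidak_adjust(p_min: float, k: int) -> float:
    """Sidak correction of a minimum P-value over k elements.

    ``1 - (1 - p)^k`` evaluated stably for small p via expm1/log1p;
    the identity at k=1 is exact.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0.0 < p_min <= 1.0):
        raise ValueError("p must be in (0, 1]")
    if p_min == 1.0:
        return 1.0
    return -math.expm1(k * math.log1p(-p_min))


def bonferroni_threshold(alpha: float, n_genes: int) -> float:
    """Family-wise significance threshold alpha / n_genes."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return alpha / n_genes


def call_significant(gene_assocs: Sequence[GeneAssociation], threshold: float) -> set[str]:
    """Genes with P strictly below the threshold."""
    sig = {g.gene_id for g in gene_assocs if g.pvalue < threshold}
    logger.info("%d / %d genes significant at %g", len(sig), len(gene_assocs), threshold)
    return sig


def build_ranked_list(
    gene_assocs: Sequence[GeneAssociation],
    expression_table: dict[str, float],
    hla_exclusion: Iterable[str] = (),
) -> RankedGeneList:
    """Expression-weighted ranked gene list for preranked enrichment.

    Excluded genes are removed first.  Primary key: -log10(P)
    descending; ties broken by -log10(P) x expression descending, then
    gene id ascending.  Genes missing from the expression table get
    expression 0 (logged).
    """
    excluded = set(hla_exclusion)
    rows = []
    n_noexpr = 0
    for g in gene_assocs:
        if g.gene_id in excluded:
            continue
        expr = expression_table.get(g.gene_id)
        if expr is None:
            expr = 0.0
            n_noexpr += 1
        elif expr < 0:
            raise ValueError(f"{g.gene_id}: negative expression")
        score = -math.log10(g.pvalue)
        rows.append((g.gene_id, score, score * expr))
    if n_noexpr:
        logger.warning("%d genes missing from expression table (expression=0)", n_noexpr)
    if not rows:
        raise ValueError("ranked list empty after exclusions")
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    applied = sorted(excluded & {g.gene_id for g in gene_assocs})
    return RankedGeneList(
        genes=[r[0] for r in rows],
        scores=[r[1] for r in rows],
        weighted_scores=[r[2] for r in rows],
        excluded_genes=applied,
    )
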