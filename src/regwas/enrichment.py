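"""Preranked gene-set enrichment with leading-edge and nexus-TF calls.

The engine implements the classic weighted Kolmogorov-Smirnov-like
running-sum statistic on a ranked gene list: walking down the list, the
sum rises by ``|score|^w / N_R`` at set members ("hits") and falls by
``1/(N-n)`` at non-members; the enrichment score (ES) is the maximum
deviation from zero.  Significance comes from a null of random same-size
gene sets (set permutation — the only permutation scheme available for
preranked input), the normalized enrichment score (NES) divides ES by
the mean magnitude of same-sign null scores, and FDR q-values follow the
standard NES-based two-tail procedure.  The leading edge of a
positive-ES set is the members at or before the running-sum maximum —
the genes driving the enrichment.

On top of the engine sit the transcription-factor analyses: building the
super-enhancer-associated TF gene set (TFs overlapping, nearest to, or
proximal to a super-enhancer), collapsing multiple target-gene sets per
TF to the most significant one, and calling "nexus" TFs — factors both
on the leading edge of the super-enhancer TF enrichment and with a
significantly enriched target-gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .intervals import Interval

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 3
DEFAULT_MAX_SIZE = 800
PATHWAY_MIN_SIZE = 25  # small sets make the NES size-normalization unstable


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: Optional[float]
    leading_edge: list[str]
    set_size_used: int
    p_is_bound: bool = False  # nominal_p reported at the 1/nperm resolution floor

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.es <= 1.0 + 1e-12):
            raise ValueError(f"{self.set_name}: |ES| > 1")


@dataclass
class NexusCall:
    tf_id: str
    in_se_leading_edge: bool
    tft_set_name: str
    tft_p: float
    tft_q: float
    is_nexus: bool = field(init=False)

    def __post_init__(self) -> None:
        self.is_nexus = bool(
            self.in_se_leading_edge and self.tft_p < 0.05 and self.tft_q < 0.25
        )


# ---------------------------------------------------------------------------
# running-sum core

def _running_sum(
    scores: np.ndarray, hit_mask: np.ndarray, weight: float
) -> np.ndarray:
    """Running deviation of the weighted KS statistic along the list."""
    N = scores.size
    n = int(hit_mask.sum())
    w = np.abs(scores) ** weight if weight != 0 else np.ones(N)
    nr = float(w[hit_mask].sum())
    steps = np.empty(N)
    if nr > 0:
        steps[hit_mask] = w[hit_mask] / nr
    else:  # all hit scores zero: fall back to unweighted increments
        steps[hit_mask] = 1.0 / n
    steps[~hit_mask] = -1.0 / (N - n)
    return np.cumsum(steps)


def _es_from_run(run: np.ndarray) -> tuple[float, int]:
    i = int(np.argmax(np.abs(run)))
    return float(run[i]), i


def _null_es(
    scores: np.ndarray,
    set_size: int,
    weight: float,
    nperm: int,
    rng: np.random.Generator,
    chunk: int = 512,
) -> np.ndarray:
    """ES of ``nperm`` random same-size gene sets (vectorized)."""
    N = scores.size
    w = np.abs(scores) ** weight if weight != 0 else np.ones(N)
    out = np.empty(nperm)
    done = 0
    while done < nperm:
        b = min(chunk, nperm - done)
        # b random subsets of size set_size, via partial argsort of noise
        idx = np.argpartition(rng.random((b, N)), set_size, axis=1)[:, :set_size]
        mask = np.zeros((b, N), dtype=bool)
        np.put_along_axis(mask, idx, True, axis=1)
        wm = np.where(mask, w, 0.0)
        nr = wm.sum(axis=1)
        zero_nr = nr == 0
        steps = wm / np.where(zero_nr, 1.0, nr)[:, None]
        if zero_nr.any():
            steps[zero_nr] = mask[zero_nr] / set_size
        steps[~mask] = 0.0
        steps = steps - (~mask) / (N - set_size)
        run = np.cumsum(steps, axis=1)
        flat = np.argmax(np.abs(run), axis=1)
        out[done : done + b] = run[np.arange(b), flat]
        done += b
    return out


def _nes(es: float, null_es: np.ndarray) -> float:
    pos = null_es[null_es >= 0]
    neg = null_es[null_es < 0]
    if es >= 0:
        denom = pos.mean() if pos.size else np.nan
    else:
        denom = np.abs(neg).mean() if neg.size else np.nan
    return float(es / denom) if denom and np.isfinite(denom) else 0.0


def _nominal_p(es: float, null_es: np.ndarray, nperm: int) -> tuple[float, bool]:
    if es >= 0:
        same = null_es[null_es >= 0]
        count = int((same >= es).sum())
    else:
        same = null_es[null_es < 0]
        count = int((same <= es).sum())
    if same.size == 0 or count == 0:
        return 1.0 / nperm, True  # resolution floor, reported as "< 1/nperm"
    return count / same.size, False


def gsea_preranked(
    ranked: Sequence[tuple[str, float]],
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
    nperm: int = 1000,
    seed: int = 0,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    set_name: str = "set",
) -> Optional[GseaResult]:
    """Enrichment of one gene set in a ranked (gene, score) list.

    Returns ``None`` (logged) when the set, intersected with the list,
    falls outside ``[min_size, max_size]`` or covers the entire list
    (no misses, ES undefined).  ``fdr_q`` is left ``None``; q-values are
    a collection-level quantity (see :func:`gsea_collection`).
    """
    if nperm < 100:
        logger.warning("nperm=%d is very low; P resolution will be poor", nperm)
    genes = [g for g, _ in ranked]
    scores = np.array([s for _, s in ranked], dtype=np.float64)
    members = set(gene_set)
    hit_mask = np.array([g in members for g in genes])
    n = int(hit_mask.sum())
    N = len(genes)
    if n < min_size or n > max_size:
        logger.info("set %s skipped: size %d outside [%d, %d]", set_name, n, min_size, max_size)
        return None
    if n == N:
        logger.info("set %s skipped: covers the whole list (no misses)", set_name)
        return None
    run = _running_sum(scores, hit_mask, weight_exponent)
    es, es_idx = _es_from_run(run)
    rng = np.random.default_rng(seed)
    null_es = _null_es(scores, n, weight_exponent, nperm, rng)
    nes = _nes(es, null_es)
    p, bound = _nominal_p(es, null_es, nperm)
    if es >= 0:
        le_idx = np.nonzero(hit_mask[: es_idx + 1])[0]
    else:
        le_idx = np.nonzero(hit_mask[es_idx:])[0] + es_idx
    leading = [genes[i] for i in le_idx]
    return GseaResult(
        set_name=set_name,
        es=es,
        nes=nes,
        nominal_p=p,
        fdr_q=None,
        leading_edge=leading,
        set_size_used=n,
        p_is_bound=bound,
    )


def gsea_collection(
    ranked: Sequence[tuple[str, float]],
    collection,
    weight_exponent: float = 1.0,
    nperm: int = 1000,
    seed: int = 0,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> tuple[list[GseaResult], dict[str, str]]:
    """Run every set of a collection and attach NES-based FDR q-values.

    Each set gets an independent, deterministic permutation stream
    derived from ``seed``; results are returned in set-name order so the
    outcome is invariant to evaluation order.
    """
    genes = [g for g, _ in ranked]
    scores = np.array([s for _, s in ranked], dtype=np.float64)
    results: list[GseaResult] = []
    null_nes_pool: list[np.ndarray] = []
    skipped: dict[str, str] = {}
    ss = np.random.SeedSequence(seed)
    names = sorted(collection.sets)
    child_seeds = dict(zip(names, ss.spawn(len(names))))
    for name in names:
        members = set(collection.sets[name])
        hit_mask = np.array([g in members for g in genes])
        n = int(hit_mask.sum())
        if n < min_size or n > max_size:
            skipped[name] = f"size_{n}_outside_bounds"
            continue
        if n == len(genes):
            skipped[name] = "covers_whole_list"
            continue
        rng = np.random.default_rng(child_seeds[name])
        run = _running_sum(scores, hit_mask, weight_exponent)
        es, es_idx = _es_from_run(run)
        null_es = _null_es(scores, n, weight_exponent, nperm, rng)
        nes = _nes(es, null_es)
        p, bound = _nominal_p(es, null_es, nperm)
        if es >= 0:
            le_idx = np.nonzero(hit_mask[: es_idx + 1])[0]
        else:
            le_idx = np.nonzero(hit_mask[es_idx:])[0] + es_idx
        results.append(
            GseaResult(
                set_name=name, es=es, nes=nes, nominal_p=p, fdr_q=None,
                leading_edge=[genes[i] for i in le_idx],
                set_size_used=n, p_is_bound=bound,
            )
        )
        # normalize this set's null the same way for the FDR pool
        pos = null_es[null_es >= 0]
        neg = null_es[null_es < 0]
        pool = np.concatenate([
            pos / pos.mean() if pos.size else pos,
            -(np.abs(neg) / np.abs(neg).mean()) if neg.size else neg,
        ])
        null_nes_pool.append(pool)
    if results:
        _attach_fdr(results, np.concatenate(null_nes_pool))
    return results, skipped


def _attach_fdr(results: list[GseaResult], null_nes: np.ndarray) -> None:
    """Standard two-tail NES-based FDR with monotonicity enforcement."""
    obs = np.array([r.nes for r in results])
    null_pos = null_nes[null_nes >= 0]
    null_neg = null_nes[null_nes < 0]
    obs_pos = obs[obs >= 0]
    obs_neg = obs[obs < 0]
    qs = np.empty(obs.size)
    for i, nes in enumerate(obs):
        if nes >= 0:
            num = (null_pos >= nes).mean() if null_pos.size else 1.0
            den = (obs_pos >= nes).mean() if obs_pos.size else 1.0
        else:
            num = (null_neg <= nes).mean() if null_neg.size else 1.0
            den = (obs_neg <= nes).mean() if obs_neg.size else 1.0
        qs[i] = min(1.0, num / den) if den > 0 else 1.0
    # monotone: a more extreme NES never has a larger q
    for sign, idxs in (
        (1, np.nonzero(obs >= 0)[0]),
        (-1, np.nonzero(obs < 0)[0]),
    ):
        order = idxs[np.argsort(-sign * obs[idxs])]  # most extreme first
        running = np.inf
        for j in order[::-1]:  # sweep from least extreme: q never rises
            running = min(running, qs[j])
            qs[j] = running
    for r, q in zip(results, qs):
        r.fdr_q = float(q)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# super-enhancer TF set construction

def _tss_to_interval_distance(tss: int, iv: Interval) -> int:
    t = tss - 1  # 0-based base under the TSS
    if iv.start <= t < iv.end:
        return 0
    return iv.start - t if t < iv.start else t - (iv.end - 1)


def build_se_tf_set(
    tf_list: Sequence[str],
    super_enhancers: Sequence[Interval],
    gene_locations: Sequence,
    proximity: int = 50_000,
) -> tuple[list[str], dict[str, list[str]]]:
    """TFs overlapping, nearest to, or proximal to a super-enhancer.

    A TF joins the set when (a) its gene body shares >= 1 bp with a
    super-enhancer, (b) it is the nearest-TSS gene to some
    super-enhancer, or (c) its TSS lies within ``proximity`` bp of one.
    Returns the member list (sorted) and per-TF provenance.  TFs with no
    known location are dropped with a warning.
    """
    loc_by_id = {g.gene_id: g for g in gene_locations}
    known_tfs = []
    for tf in tf_list:
        if tf in loc_by_id:
            known_tfs.append(tf)
        else:
            logger.warning("TF %s has no gene location; dropped", tf)
    provenance: dict[str, set[str]] = {}

    # nearest-TSS gene per SE, among *all* genes
    for se in super_enhancers:
        best: Optional[tuple[int, str]] = None
        for g in gene_locations:
            if g.chrom != se.chrom:
                continue
            key = (_tss_to_interval_distance(g.tss, se), g.gene_id)
            if best is None or key < best:
                best = key
        if best is not None and best[1] in set(known_tfs):
            provenance.setdefault(best[1], set()).add("nearest")

    for tf in known_tfs:
        g = loc_by_id[tf]
        body = Interval(g.chrom, g.start - 1, g.end)  # 1-based inclusive -> internal
        for se in super_enhancers:
            if se.chrom != g.chrom:
                continue
            if body.overlaps(se):
                provenance.setdefault(tf, set()).add("overlap")
            if _tss_to_interval_distance(g.tss, se) <= proximity:
                provenance.setdefault(tf, set()).add("proximal")
    members = sorted(provenance)
    return members, {tf: sorted(v) for tf, v in provenance.items()}


# ---------------------------------------------------------------------------
# TF-set collapsing and nexus calls

def collapse_tf_sets(
    gsea_results: Sequence[GseaResult], set_to_tf: dict[str, str]
) -> dict[str, GseaResult]:
    """Represent each TF by its most significant target-gene set.

    Minimum nominal P wins; ties broken by larger |NES|, then set name.
    """
    best: dict[str, GseaResult] = {}
    for r in gsea_results:
        tf = set_to_tf.get(r.set_name)
        if tf is None:
            continue
        key = (r.nominal_p, -abs(r.nes), r.set_name)
        cur = best.get(tf)
        if cur is None or key < (cur.nominal_p, -abs(cur.nes), cur.set_name):
            best[tf] = r
    return best


def nexus_tfs(
    se_leading_edge: Iterable[str],
    collapsed_tft_results: dict[str, GseaResult],
    p_cut: float = 0.05,
    q_cut: float = 0.25,
) -> list[NexusCall]:
    """Call nexus TFs: leading-edge membership plus enriched target set.

    A TF is a nexus iff it sits on the leading edge of the
    super-enhancer TF enrichment AND its best target-gene set has
    nominal P < ``p_cut`` and FDR q < ``q_cut`` (strict).
    """
    edge = set(se_leading_edge)
    if not edge:
        logger.warning("empty super-enhancer leading edge: no nexus TF can be called")
    calls = []
    for tf in sorted(collapsed_tft_results):
        r = collapsed_tft_results[tf]
        call = NexusCall(
            tf_id=tf,
            in_se_leading_edge=tf in edge,
            tft_set_name=r.set_name,
            tft_p=r.nominal_p,
            tft_q=r.fdr_q if r.fdr_q is not None else 1.0,
        )
        # apply the configured cuts (NexusCall freezes the default cuts)
        call.is_nexus = bool(
            call.in_se_leading_edge and call.tft_p < p_cut and call.tft_q < q_cut
        )
        calls.append(call)
    return calls


def negative_control_tfs(
    collapsed_tft_results: dict[str, GseaResult],
    se_leading_edge: Iterable[str],
    n: int = 16,
    order_by: str = "p",
) -> list[str]:
    """Bottom-ranked TFs not on the super-enhancer leading edge.

    ``order_by`` selects the bottom-ranking metric: ``"p"`` (largest
    nominal P first) or ``"nes"`` (smallest NES first); both orderings
    are exposed because the choice is a convention.
    """
    edge = set(se_leading_edge)
    candidates = [tf for tf in collapsed_tft_results if tf not in edge]
    if order_by == "p":
        candidates.sort(key=lambda tf: (-collapsed_tft_results[tf].nominal_p, tf))
    elif order_by == "nes":
        candidates.sort(key=lambda tf: (collapsed_tft_results[tf].nes, tf))
    else:
        raise ValueError("order_by must be 'p' or 'nes'")
    return candidates[:n]


def write_gsea_table(results: Sequence[GseaResult], path, set_to_tf=None) -> None:
    """Results TSV: set, TF, size, ES, NES, P, q, leading edge."""
    rows = sorted(results, key=lambda r: (r.nominal_p, r.set_name))
    with open(path, "w") as fh:
        fh.write("SET\tTF\tSIZE\tES\tNES\tP\tQ\tLEADING_EDGE\n")
        for r in rows:
            tf = (set_to_tf or {}).get(r.set_name, "NA")
            q = f"{r.fdr_q:.5e}" if r.fdr_q is not None else "NA"
            fh.write(
                f"{r.set_name}\t{tf}\t{r.set_size_used}\t{r.es:.6g}\t"
                f"{r.nes:.6g}\t{r.nominal_p:.5e}\t{q}\t"
                + ";".join(r.leading_edge)
                + "\n"
            )
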