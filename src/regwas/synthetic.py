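"""Synthetic-data generator for the full pipeline.

Produces every input the pipeline consumes — a reference LD panel, GWAS
summary statistics, an RE catalog with many-to-many RE-gene links, peak
and super-enhancer BED files, gene locations, an expression table and
GMT gene sets — with controllable LD structure and implanted causal
signals, so the whole analysis runs end to end without any download.

The genotype model is deliberately simple and fast: latent Gaussians
with block-AR(1) correlation are thresholded at Hardy-Weinberg
cutpoints determined by each SNP's minor-allele frequency, giving
dosages in {0, 1, 2}; the latent AR(1) parameter is calibrated so the
*realized* dosage correlation matches the requested rho (thresholding
would otherwise attenuate it).  One LD block corresponds to one
regulatory element.  GWAS z-scores are drawn from a multivariate normal
with the panel's realized per-block correlation; a causal element adds
a mean shift ``R @ delta`` with ``delta = ncp / sqrt(m)`` on each of
its m SNPs, so LD neighbours of causal SNPs inherit proportionally
attenuated signal, exactly as in real summary statistics.

All randomness flows from the single config seed through named
``numpy.random.SeedSequence`` children (panel, gwas, landscape), so a
seeded run is byte-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import io_formats
from .genescan import LdPanel
from .intervals import Interval, RegulatoryElement
from .io_formats import GeneLocation, GeneSetCollection, SnpRecord

logger = logging.getLogger(__name__)

CHROM = "1"
GENE_SPACING = 60_000
GENE_LENGTH = 15_000
GENE_BASE = 100_000
RE_LENGTH = 2_000
N_TFS = 30
N_SE_TFS = 10


@dataclass
class SimConfig:
    """Study conditions for a simulated workspace."""

    seed: int
    n_samples: int = 5_000
    snps_per_block: int = 10
    within_block_rho: float = 0.8
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_res: int = 300
    n_genes: int = 200
    links_per_re: int = 2
    fraction_unsupported: float = 0.2
    causal_spec: list[tuple[int, float]] = field(default_factory=list)
    n_blocks: Optional[int] = None  # defaults to one LD block per RE

    def __post_init__(self) -> None:
        if not (0.0 <= self.within_block_rho < 1.0):
            raise ValueError("within_block_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie inside (0, 0.5]")
        if self.n_res < 1 or self.n_genes < 1:
            raise ValueError("n_res and n_genes must be >= 1")
        if self.n_res < self.n_genes:
            raise ValueError("need at least one RE per gene (n_res >= n_genes)")

    def seeds(self) -> dict[str, np.random.SeedSequence]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        return dict(zip(("landscape", "panel", "gwas", "misc"), children))


def _gene_id(i: int) -> str:
    return f"G{i:04d}"


# ---------------------------------------------------------------------------
# landscape

@dataclass
class Landscape:
    """The simulated regulatory landscape and its companion tables."""

    re_catalog: list[RegulatoryElement]
    peaks: list[Interval]
    gene_locations: list[GeneLocation]
    expression: dict[str, float]
    gene_sets: GeneSetCollection
    super_enhancers: list[Interval]
    tf_list: list[str]
    ld_bins: list[Interval]
    hla_genes: list[str]
    supported_re_ids: list[str]


def simulate_landscape(config: SimConfig) -> Landscape:
    """Lay out genes, REs, peaks, super-enhancers and gene sets.

    Genes sit on one chromosome at a fixed spacing with alternating
    strands.  Each gene owns one "primary" RE — 40% placed inside the
    promoter window, 60% in the downstream intergenic space — and the
    remaining elements occupy intergenic slots while linking one or two
    random (possibly distant) genes, emulating many-to-many RE-gene
    maps.  A configured fraction of elements lacks peak support; peaks
    coincide with the supported elements.  All elements are >= 3 kb
    apart, so peak support is exact by construction.
    """
    rng = np.random.default_rng(config.seeds()["landscape"])
    n_genes, n_res = config.n_genes, config.n_res

    genes: list[GeneLocation] = []
    for i in range(n_genes):
        start = GENE_BASE + i * GENE_SPACING
        strand = "+" if i % 2 == 0 else "-"
        genes.append(
            GeneLocation(
                gene_id=_gene_id(i), chrom=CHROM,
                start=start, end=start + GENE_LENGTH, strand=strand,
            )
        )

    catalog: list[RegulatoryElement] = []
    # primary REs, one per gene
    for i, g in enumerate(genes):
        if i % 5 < 2:  # 40%: promoter-window RE
            if g.strand == "+":
                start = g.tss - 601  # internal; inside [tss-1000, tss+100]
            else:
                start = g.tss + 99
            end = start + 500
        else:  # 60%: distal intergenic RE
            start = g.start - 1 + GENE_LENGTH + 5_000
            end = start + RE_LENGTH
        links = [(g.gene_id, 10.0)]
        if rng.random() < 0.3 and i + 1 < n_genes:  # one RE, two genes
            links.append((genes[i + 1].gene_id, 5.0))
        catalog.append(
            RegulatoryElement(
                re_id=f"RE{i:04d}", chrom=CHROM, start=start, end=end,
                gene_links=links,
            )
        )

    # extra REs in intergenic slots; long-range links to random genes
    slot_offsets = [25_000, 30_000, 35_000, 40_000]
    extra = n_res - n_genes
    k = 0
    while k < extra:
        host = k % n_genes
        slot = slot_offsets[(k // n_genes) % len(slot_offsets)]
        start = GENE_BASE + host * GENE_SPACING + GENE_LENGTH + slot
        n_links = int(rng.integers(1, config.links_per_re + 1))
        targets = rng.choice(n_genes, size=n_links, replace=False)
        links = [(_gene_id(int(t)), float(rng.uniform(1, 10))) for t in targets]
        catalog.append(
            RegulatoryElement(
                re_id=f"RE{n_genes + k:04d}", chrom=CHROM,
                start=start, end=start + RE_LENGTH, gene_links=links,
            )
        )
        k += 1

    # peak support: an exact fraction of REs lacks any peak
    n_unsupported = int(round(config.fraction_unsupported * n_res))
    unsupported = set(
        rng.choice(n_res, size=n_unsupported, replace=False).tolist()
    )
    supported_ids = [
        re_.re_id for i, re_ in enumerate(catalog) if i not in unsupported
    ]
    peaks = [
        Interval(re_.chrom, re_.start, re_.end)
        for i, re_ in enumerate(catalog)
        if i not in unsupported
    ]

    expression = {
        g.gene_id: float(np.exp(rng.normal(2.0, 1.0))) for g in genes
    }

    tf_list = [_gene_id(i) for i in range(min(N_TFS, n_genes))]
    super_enhancers = [
        Interval(CHROM, genes[i].start - 1 - 2_000, genes[i].end + 2_000)
        for i in range(min(N_SE_TFS, n_genes))
    ]

    sets: dict[str, list[str]] = {}
    tf_of_set: dict[str, str] = {}
    sets["SE_TF_SET"] = tf_list[:N_SE_TFS]
    for j in range(min(15, len(tf_list))):
        tf = tf_list[j]
        for suffix in ("01", "B")[: 1 + int(rng.random() < 0.5)]:
            name = f"{tf}_{suffix}"
            size = min(int(rng.integers(25, 41)), max(n_genes - 2, 1))
            members = rng.choice(n_genes, size=size, replace=False)
            sets[name] = sorted(_gene_id(int(m)) for m in members)
            tf_of_set[name] = tf
    gene_sets = GeneSetCollection(sets=sets, tf_of_set=tf_of_set)

    genome_end = GENE_BASE + n_genes * GENE_SPACING + 1_100_000
    ld_bins = [
        Interval(CHROM, s, min(s + GENE_SPACING, genome_end))
        for s in range(0, genome_end, GENE_SPACING)
    ]

    hla_genes = [_gene_id(n_genes - 1), _gene_id(n_genes - 2)] if n_genes >= 3 else []

    return Landscape(
        re_catalog=catalog,
        peaks=peaks,
        gene_locations=genes,
        expression=expression,
        gene_sets=gene_sets,
        super_enhancers=super_enhancers,
        tf_list=tf_list,
        ld_bins=ld_bins,
        hla_genes=hla_genes,
        supported_re_ids=supported_ids,
    )


# ---------------------------------------------------------------------------
# genotype panel

def _block_ar1(rho: float, m: int) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _dosage_corr(latent_r: float, maf: float) -> float:
    """Correlation of two thresholded dosages given the latent correlation."""
    from scipy.stats import multivariate_normal, norm

    q = maf
    c1 = norm.ppf((1 - q) ** 2)
    c2 = norm.ppf(1 - q**2)
    p1, p2 = 1 - norm.cdf(c1), 1 - norm.cdf(c2)

    def upper2(a: float, b: float, r: float) -> float:
        bvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]])
        return 1.0 - norm.cdf(a) - norm.cdf(b) + float(bvn.cdf([a, b]))

    cov = 0.0
    for a, pa in ((c1, p1), (c2, p2)):
        for b, pb in ((c1, p1), (c2, p2)):
            cov += upper2(a, b, latent_r) - pa * pb
    var = p1 * (1 - p1) + p2 * (1 - p2) + 2 * (p2 - p1 * p2)
    return cov / var


def _latent_rho(target: float, maf: float) -> float:
    """Latent AR(1) parameter whose thresholded dosage correlation hits
    ``target`` (inverse of the tetrachoric-style attenuation)."""
    if target <= 0.0:
        return 0.0
    from scipy.optimize import brentq

    hi = 0.9999
    if _dosage_corr(hi, maf) < target:
        return hi
    return float(brentq(lambda r: _dosage_corr(r, maf) - target, target * 0.5, hi,
                        xtol=1e-4))


def simulate_panel(
    config: SimConfig,
    re_catalog: Sequence[RegulatoryElement],
    gene_locations: Sequence[GeneLocation] = (),
) -> tuple[LdPanel, dict[str, list[str]]]:
    """Draw a genotype dosage panel with one AR(1) LD block per region.

    Every RE gets a SNP block; when ``gene_locations`` are supplied each
    gene body gets one too, so a conventional gene-body scan sees SNPs
    as well.  Within a block, adjacent dosages correlate at
    ``within_block_rho`` (the latent correlation is inflated to
    compensate for threshold attenuation); blocks are mutually
    independent.  Returns the panel and the map region id -> SNP rsids
    (RE blocks first, in catalog order).
    """
    rng = np.random.default_rng(config.seeds()["panel"])
    m = config.snps_per_block
    regions: list[tuple[str, str, int, int]] = [
        (re_.re_id, re_.chrom, re_.start, re_.end) for re_ in re_catalog
    ] + [
        (g.gene_id, g.chrom, g.start - 1, g.end) for g in gene_locations
    ]
    rsids: list[str] = []
    chroms: list[str] = []
    pos: list[int] = []
    rows: list[np.ndarray] = []
    block_of: dict[str, list[str]] = {}
    counter = 0
    chol_cache: dict[float, np.ndarray] = {}
    for region_id, chrom, start, end in regions:
        # one MAF per block so the latent AR(1) parameter can be
        # calibrated to yield the *realized* dosage correlation rho
        maf = float(np.round(rng.uniform(*config.maf_range), 2))
        if maf not in chol_cache:
            latent_rho = _latent_rho(config.within_block_rho, maf)
            chol_cache[maf] = np.linalg.cholesky(_block_ar1(latent_rho, m))
        L = chol_cache[maf]
        latent = rng.standard_normal((config.n_samples, m)) @ L.T
        step = max(1, (end - start) // (m + 1))
        ids = []
        # Hardy-Weinberg cutpoints on the latent scale
        c1 = stats.norm.ppf((1 - maf) ** 2)
        c2 = stats.norm.ppf(1 - maf**2)
        for j in range(m):
            dos = np.digitize(latent[:, j], [c1, c2]).astype(np.float64)
            rsid = f"rs{counter}"
            counter += 1
            ids.append(rsid)
            rsids.append(rsid)
            chroms.append(chrom)
            pos.append(start + 1 + (j + 1) * step)
            rows.append(dos)
        block_of[region_id] = ids
    panel = LdPanel(
        rsids=rsids, chroms=chroms, pos=np.array(pos, dtype=np.int64),
        dosages=np.vstack(rows),
    )
    return panel, block_of


# ---------------------------------------------------------------------------
# GWAS summary statistics

def simulate_gwas(
    panel: LdPanel,
    blocks: dict[str, list[str]],
    delta: Optional[dict[str, float]] = None,
    seed: int | np.random.SeedSequence = 0,
) -> list[SnpRecord]:
    """Draw GWAS z-scores block-wise and convert to two-sided P-values.

    Null blocks receive ``z ~ N(0, R)`` with R the realized dosage
    correlation of the block; for causal SNPs with per-SNP effect
    ``delta`` the mean becomes ``R @ delta``, so an LD neighbour at
    correlation r inherits an ``r``-scaled mean shift.
    """
    rng = np.random.default_rng(seed)
    delta = delta or {}
    pmap: dict[str, tuple[str, int, float]] = {}
    for re_id, ids in blocks.items():
        G = panel.rows(ids)
        m = len(ids)
        if m == 1:
            R = np.ones((1, 1))
        else:
            sd = G.std(axis=1)
            R = np.corrcoef(G) if np.all(sd > 0) else np.eye(m)
            R = np.where(np.isfinite(R), R, 0.0)
            np.fill_diagonal(R, 1.0)
        d = np.array([delta.get(s, 0.0) for s in ids])
        mean = R @ d
        # nearest-PSD Cholesky with a small jitter for numerical safety
        jitter = 1e-10
        for _ in range(6):
            try:
                L = np.linalg.cholesky(R + jitter * np.eye(m))
                break
            except np.linalg.LinAlgError:
                jitter *= 100
        z = mean + L @ rng.standard_normal(m)
        for s, zj in zip(ids, z):
            pmap[s] = (re_id, 0, float(stats.chi2.sf(zj * zj, df=1)))
    records = []
    index = {r: i for i, r in enumerate(panel.rsids)}
    for rsid in panel.rsids:
        _, _, p = pmap[rsid]
        i = index[rsid]
        records.append(
            SnpRecord(
                rsid=rsid, chrom=panel.chroms[i], pos=int(panel.pos[i]),
                pvalue=max(p, io_formats.MIN_PVALUE), n=panel.n_samples,
            )
        )
    return records


def causal_deltas(
    config: SimConfig, blocks: dict[str, list[str]]
) -> tuple[dict[str, float], list[str]]:
    """Per-SNP mean shifts for the configured causal elements.

    The noncentrality of a causal element is spread over its m SNPs as
    ``ncp / sqrt(m)`` per SNP.  Returns the delta map and the causal RE
    ids.
    """
    delta: dict[str, float] = {}
    causal_ids: list[str] = []
    re_ids = list(blocks)
    for re_index, ncp in config.causal_spec:
        re_id = re_ids[re_index]
        causal_ids.append(re_id)
        ids = blocks[re_id]
        per_snp = ncp / np.sqrt(len(ids))
        for s in ids:
            delta[s] = per_snp
    return delta, causal_ids


# ---------------------------------------------------------------------------
# full workspace

def simulate_workspace(config: SimConfig, outdir) -> dict:
    """Materialize a complete input workspace on disk.

    Writes every file the pipeline reads and returns a manifest of
    paths plus ground truth (causal RE ids and their target genes).
    Causal elements are guaranteed peak support: losing the signal to
    the tissue filter would change the question, not answer it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    land = simulate_landscape(config)

    # ensure causal REs are peak-supported
    supported = set(land.supported_re_ids)
    for re_index, _ in config.causal_spec:
        re_ = land.re_catalog[re_index]
        if re_.re_id not in supported:
            supported.add(re_.re_id)
            land.peaks.append(Interval(re_.chrom, re_.start, re_.end))
    land.peaks.sort(key=lambda iv: (iv.chrom, iv.start))

    panel, blocks = simulate_panel(config, land.re_catalog, land.gene_locations)
    delta, causal_ids = causal_deltas(config, blocks)
    snps = simulate_gwas(panel, blocks, delta, seed=config.seeds()["gwas"])

    paths = {
        "gwas": outdir / "gwas.tsv",
        "panel": outdir / "panel.tsv",
        "re_catalog": outdir / "re_catalog.tsv",
        "peaks": outdir / "peaks.bed",
        "gene_locations": outdir / "gene_locations.tsv",
        "expression": outdir / "expression.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "super_enhancers": outdir / "super_enhancers.bed",
        "tf_list": outdir / "tf_list.txt",
        "hla": outdir / "hla_exclude.txt",
        "ld_bins": outdir / "ld_bins.bed",
    }
    with open(paths["gwas"], "w") as fh:
        fh.write("SNP\tCHR\tBP\tP\tN\n")
        for s in snps:
            fh.write(f"{s.rsid}\t{s.chrom}\t{s.pos}\t{s.pvalue:.6e}\t{s.n}\n")
    io_formats.write_panel(panel, paths["panel"])
    io_formats.write_re_catalog(land.re_catalog, paths["re_catalog"])
    io_formats.write_bed(land.peaks, paths["peaks"])
    io_formats.write_gene_locations(land.gene_locations, paths["gene_locations"])
    io_formats.write_expression_table(land.expression, paths["expression"])
    io_formats.write_gmt(land.gene_sets, paths["gene_sets"])
    io_formats.write_bed(land.super_enhancers, paths["super_enhancers"])
    with open(paths["tf_list"], "w") as fh:
        fh.write("\n".join(land.tf_list) + "\n")
    with open(paths["hla"], "w") as fh:
        fh.write("\n".join(land.hla_genes) + ("\n" if land.hla_genes else ""))
    io_formats.write_bed(land.ld_bins, paths["ld_bins"])

    causal_genes = sorted(
        {
            g
            for re_ in land.re_catalog
            if re_.re_id in causal_ids
            for g, _ in re_.gene_links
        }
    )
    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "causal_res": causal_ids,
        "causal_genes": causal_genes,
        "supported_res": sorted(supported),
        "n_snps": len(snps),
    }
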