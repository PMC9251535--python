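"""Readers and writers for every external file the pipeline touches.

Conventions
-----------
* Internal coordinates are 0-based half-open everywhere.  BED input is
  taken as-is; the RE catalog and gene-location tables (1-based
  inclusive dialects) are converted on read.
* Chromosome labels are normalized by stripping a leading ``chr`` and
  uppercasing X/Y/MT, so UCSC- and NCBI-style inputs mix freely.
* Output tables are deterministic: fixed column order, fixed numeric
  formatting (P-values in scientific notation with 6 significant
  digits), rows sorted by P ascending then identifier.  Reading a
  written table returns exactly the values printed in it.
"""

from __future__ import annotations

import logging
import math
import re as _re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import Interval, RegulatoryElement

logger = logging.getLogger(__name__)

#: smallest positive double; P-values of exactly 0 are clamped here
MIN_PVALUE = float(np.nextafter(0.0, 1.0))


class ConfigurationError(ValueError):
    """A mapped column or config key is missing or invalid."""


class EmptyInputError(ValueError):
    """An input file yields zero usable records."""


class FormatError(ValueError):
    """A file violates its format contract (with a line number)."""


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr`` prefix and uppercase X/Y/MT."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.lower() in ("x", "y", "mt", "m"):
        s = "MT" if s.lower() in ("mt", "m") else s.upper()
    return s


@dataclass(frozen=True)
class SnpRecord:
    """One GWAS summary-statistic row: a SNP with its two-sided P-value."""

    rsid: str
    chrom: str
    pos: int  # 1-based base-pair position
    pvalue: float  # in (0, 1]
    n: int  # GWAS sample size

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.rsid}: pvalue {self.pvalue} outside (0, 1]")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1")


@dataclass(frozen=True)
class GeneLocation:
    """A gene span with strand and derived transcription start site."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    tss: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.tss == 0:
            object.__setattr__(
                self, "tss", self.start if self.strand != "-" else self.end
            )
        if not (self.start <= self.tss <= self.end):
            raise ValueError(f"{self.gene_id}: TSS outside gene span")


@dataclass
class GeneSetCollection:
    """Named gene sets, optionally annotated with an owning TF label."""

    sets: dict[str, list[str]]
    tf_of_set: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")


# ---------------------------------------------------------------------------
# GWAS summary statistics

DEFAULT_GWAS_COLUMNS = {
    "rsid": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "pvalue": "P",
    "n": "N",
}


def read_gwas_summary(
    path, column_map: Optional[dict[str, str]] = None
) -> list[SnpRecord]:
    """Read a tab/whitespace-delimited GWAS summary-statistics file.

    Rows with missing or non-numeric P are dropped (count logged);
    duplicate rsIDs keep the first occurrence; P-values of exactly 0 are
    clamped to the smallest positive double with a warning.
    """
    colmap = dict(DEFAULT_GWAS_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: mapped column(s) {missing} not found in header "
            f"{list(df.columns)}"
        )
    pvals = pd.to_numeric(df[colmap["pvalue"]], errors="coerce")
    bad = pvals.isna()
    if bad.any():
        logger.warning("%s: dropped %d rows with missing/non-numeric P", path, int(bad.sum()))
    df = df.loc[~bad].copy()
    pvals = pvals.loc[~bad]

    dup = df[colmap["rsid"]].duplicated(keep="first")
    if dup.any():
        logger.warning("%s: %d duplicate rsIDs, keeping first occurrence", path, int(dup.sum()))
        df = df.loc[~dup]
        pvals = pvals.loc[~dup]

    records: list[SnpRecord] = []
    n_clamped = 0
    for (_, row), p in zip(df.iterrows(), pvals):
        p = float(p)
        if p == 0.0:
            p = MIN_PVALUE
            n_clamped += 1
        records.append(
            SnpRecord(
                rsid=str(row[colmap["rsid"]]),
                chrom=normalize_chrom(row[colmap["chrom"]]),
                pos=int(float(row[colmap["pos"]])),
                pvalue=p,
                n=int(float(row[colmap["n"]])),
            )
        )
    if n_clamped:
        logger.warning("%s: clamped %d zero P-values to %g", path, n_clamped, MIN_PVALUE)
    if not records:
        raise EmptyInputError(f"{path}: no usable SNP records")
    return records


# ---------------------------------------------------------------------------
# BED

def read_bed(path) -> list[Interval]:
    """Read a BED3+ file (0-based half-open), sorted by (chrom, start, end)."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has < 3 fields")
            chrom = normalize_chrom(fields[0])
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: malformed interval start={start} end={end}"
                )
            out.append(Interval(chrom, start, end))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_bed(intervals: Sequence[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# RE catalog (GeneHancer-style, 1-based inclusive, GFF attribute dialect)

_ATTR_GENE = _re.compile(r"connected_gene=([^;]+)")


def _parse_gene_links(attr: str) -> list[tuple[str, float]]:
    """Parse ``connected_gene=G;score=S;...`` attribute pairs."""
    links: list[tuple[str, float]] = []
    parts = [p for p in attr.strip().split(";") if p]
    i = 0
    while i < len(parts):
        key, _, value = parts[i].partition("=")
        if key != "connected_gene" or not value:
            raise ValueError(f"unexpected attribute token {parts[i]!r}")
        score = math.nan
        if i + 1 < len(parts):
            k2, _, v2 = parts[i + 1].partition("=")
            if k2 == "score":
                score = float(v2)
                i += 1
        links.append((value, score))
        i += 1
    return links


def read_re_catalog(path) -> list[RegulatoryElement]:
    """Read a tab-delimited RE catalog with per-link gene scores.

    Expected columns: RE id, chromosome, start, end (1-based inclusive)
    and an attribute field of ``connected_gene=G;score=S`` pairs.  Rows
    with an unparseable attribute field are skipped with a warning;
    duplicate RE ids are fatal.  Elements with no gene links are
    retained (and counted in the log).
    """
    elements: list[RegulatoryElement] = []
    seen: set[str] = set()
    n_unlinked = 0
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise EmptyInputError(f"{path}: empty catalog")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 tab-separated fields")
            re_id = fields[0]
            if re_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate RE id {re_id!r}")
            seen.add(re_id)
            chrom = normalize_chrom(fields[1])
            start1, end1 = int(fields[2]), int(fields[3])
            attr = fields[4] if len(fields) > 4 else ""
            try:
                links = _parse_gene_links(attr) if attr else []
            except ValueError as exc:
                logger.warning("%s:%d: skipping row (%s)", path, lineno, exc)
                seen.discard(re_id)
                continue
            if not links:
                n_unlinked += 1
            # 1-based inclusive [start1, end1] -> 0-based half-open
            elements.append(
                RegulatoryElement(
                    re_id=re_id, chrom=chrom, start=start1 - 1, end=end1,
                    gene_links=links,
                )
            )
    if n_unlinked:
        logger.info("%s: %d REs have no gene links", path, n_unlinked)
    return elements


def write_re_catalog(catalog: Sequence[RegulatoryElement], path) -> None:
    """Inverse of :func:`read_re_catalog` (coordinates back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("re_id\tchrom\tstart\tend\tattributes\n")
        for re_ in catalog:
            attr = ";".join(
                f"connected_gene={g};score={s:g}" for g, s in re_.gene_links
            )
            fh.write(f"{re_.re_id}\t{re_.chrom}\t{re_.start + 1}\t{re_.end}\t{attr}\n")


# ---------------------------------------------------------------------------
# Gene locations ("GENE CHR START STOP STRAND", 1-based inclusive)

def read_gene_locations(path) -> list[GeneLocation]:
    genes: list[GeneLocation] = []
    with open(path) as fh:
        header = fh.readline().split()
        has_header = header and not header[2].isdigit()
        if not has_header:
            fh.seek(0)
        for lineno, line in enumerate(fh, start=2 if has_header else 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 fields")
            genes.append(
                GeneLocation(
                    gene_id=fields[0],
                    chrom=normalize_chrom(fields[1]),
                    start=int(fields[2]),
                    end=int(fields[3]),
                    strand=fields[4],
                )
            )
    if not genes:
        raise EmptyInputError(f"{path}: no gene locations")
    return genes


def write_gene_locations(genes: Sequence[GeneLocation], path) -> None:
    with open(path, "w") as fh:
        fh.write("GENE\tCHR\tSTART\tSTOP\tSTRAND\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line.

    The description field doubles as an owning-TF label when it is
    non-empty and not ``"na"``.
    """
    sets: dict[str, list[str]] = {}
    tf_of_set: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has < 3 fields")
            name, desc, members = fields[0], fields[1], fields[2:]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set {name!r}")
            members = [m for m in members if m]
            # preserve order, drop duplicate members
            sets[name] = list(dict.fromkeys(members))
            if desc and desc.lower() != "na":
                tf_of_set[name] = desc
    return GeneSetCollection(sets=sets, tf_of_set=tf_of_set or None)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = (collection.tf_of_set or {}).get(name, "na")
            fh.write(name + "\t" + desc + "\t" + "\t".join(members) + "\n")


# ---------------------------------------------------------------------------
# Simple column files

def read_gene_list(path) -> list[str]:
    """One gene id per line (HLA exclusions, TF lists)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_expression_table(path) -> dict[str, float]:
    """Two-column TSV gene_id -> mean expression."""
    df = pd.read_csv(path, sep="\t")
    gene_col, expr_col = df.columns[0], df.columns[1]
    return dict(zip(df[gene_col].astype(str), df[expr_col].astype(float)))


def write_expression_table(expr: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\texpression\n")
        for gene, value in expr.items():
            fh.write(f"{gene}\t{value:.6g}\n")


def read_rnk(path) -> list[tuple[str, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            gene, score = line.split("\t")
            out.append((gene, float(score)))
    return out


def write_rnk(ranked: Sequence[tuple[str, float]], path) -> None:
    with open(path, "w") as fh:
        for gene, score in ranked:
            fh.write(f"{gene}\t{score:.6g}\n")


# ---------------------------------------------------------------------------
# Result tables (MAGMA-like feature table; gene table)

_FEATURE_COLUMNS = ["FEATURE", "CHR", "START", "STOP", "NSNPS", "NPARAM", "STAT", "P"]
_GENE_COLUMNS = ["GENE", "BEST_RE", "NRES", "RE_CLASS", "P", "ADJ_P"]


def _fmt_p(p: float) -> str:
    return f"{p:.5e}"  # scientific, 6 significant digits


def write_feature_table(results: Sequence, path) -> None:
    """Write per-feature association results.

    ``results`` are objects with feature_id / chrom / start / end /
    n_snps / n_params / stat / pvalue attributes (see
    :class:`regwas.genescan.FeatureAssociation`).  Rows are sorted by P
    ascending then feature id.
    """
    rows = sorted(results, key=lambda r: (r.pvalue, r.feature_id))
    with open(path, "w") as fh:
        fh.write("\t".join(_FEATURE_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.feature_id}\t{r.chrom}\t{r.start}\t{r.end}\t"
                f"{r.n_snps}\t{r.n_params}\t{r.stat:.6g}\t{_fmt_p(r.pvalue)}\n"
            )


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = [c for c in _FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def write_gene_table(results: Sequence, path) -> None:
    """Write gene-level results (see :class:`regwas.assignment.GeneAssociation`)."""
    rows = sorted(results, key=lambda r: (r.pvalue, r.gene_id))
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for r in rows:
            adj = _fmt_p(r.adjusted_pvalue) if r.adjusted_pvalue is not None else "NA"
            fh.write(
                f"{r.gene_id}\t{r.best_re_id}\t{r.n_res}\t"
                f"{r.re_class or 'NA'}\t{_fmt_p(r.pvalue)}\t{adj}\n"
            )


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# LD reference panel (TSV: rsid, chrom, pos, then per-sample dosages)

def read_panel(path):
    """Read a dosage-matrix reference panel into an LdPanel."""
    from .genescan import LdPanel

    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 4:
        raise FormatError(f"{path}: panel needs rsid, chrom, pos + >=1 sample column")
    rsids = df.iloc[:, 0].astype(str).tolist()
    chroms = [normalize_chrom(c) for c in df.iloc[:, 1]]
    pos = df.iloc[:, 2].astype(int).to_numpy()
    dosages = df.iloc[:, 3:].to_numpy(dtype=np.float64)
    return LdPanel(rsids=rsids, chroms=chroms, pos=pos, dosages=dosages)


def write_panel(panel, path) -> None:
    n = panel.dosages.shape[1]
    with open(path, "w") as fh:
        fh.write("rsid\tchrom\tpos\t" + "\t".join(f"S{i}" for i in range(n)) + "\n")
        for i, rsid in enumerate(panel.rsids):
            row = "\t".join(str(int(v)) if float(v).is_integer() else f"{v:g}"
                            for v in panel.dosages[i])
            fh.write(f"{rsid}\t{panel.chroms[i]}\t{panel.pos[i]}\t{row}\n")
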