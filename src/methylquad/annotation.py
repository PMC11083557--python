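"""Gene-anchored regions of interest (ROIs) and CpG-island context.

Every gene contributes two ROIs: a promoter window around the TSS
(oriented by strand) and the CDS span.  Each ROI is then classified as
CGI or nonCGI by overlap with a CpG-island interval track.  All
coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

PROMOTER = "promoter"
CDS = "CDS"
CGI = "CGI"
NONCGI = "nonCGI"


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: TSS plus CDS span on a stranded chromosome."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_start < self.cds_end:
            raise DataError(f"{self.gene_id}: cds_start must be < cds_end")


@dataclass(frozen=True)
class ROIRecord:
    """One promoter or CDS region tied to a gene, with CGI context."""

    gene_id: str
    chrom: str
    start: int
    end: int
    region_class: str  # PROMOTER or CDS
    cgi_class: str | None = None  # CGI or NONCGI once classified

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise DataError(f"{self.gene_id}/{self.region_class}: start must be < end")
        if self.region_class not in (PROMOTER, CDS):
            raise DataError(f"unknown region_class {self.region_class!r}")

    @property
    def key(self) -> str:
        """Row key used by the score matrices: ``gene|region_class``."""
        return f"{self.gene_id}|{self.region_class}"

    @property
    def length(self) -> int:
        return self.end - self.start


def build_rois(
    genes: Sequence[GeneModel],
    promoter_upstream: int = 2000,
    promoter_downstream: int = 500,
) -> list[ROIRecord]:
    """Build one promoter and one CDS ROI per gene.

    The promoter window is ``[tss - upstream, tss + downstream)`` on the
    plus strand and mirrored on the minus strand; coordinates are
    clipped at zero (with a warning when clipping occurs).
    """
    if promoter_upstream <= 0 or promoter_downstream <= 0:
        raise ConfigError("promoter window sizes must be positive")
    rois: list[ROIRecord] = []
    for g in genes:
        if g.strand == "+":
            p_start, p_end = g.tss - promoter_upstream, g.tss + promoter_downstream
        else:
            p_start, p_end = g.tss - promoter_downstream, g.tss + promoter_upstream
        if p_start < 0:
            logger.warning("%s: promoter window clipped at chromosome start", g.gene_id)
            p_start = 0
        rois.append(ROIRecord(g.gene_id, g.chrom, p_start, p_end, PROMOTER))
        rois.append(ROIRecord(g.gene_id, g.chrom, g.cds_start, g.cds_end, CDS))
    return rois


def classify_cgi(
    rois: Sequence[ROIRecord],
    cgis: Iterable[tuple[str, int, int]] | pd.DataFrame,
    min_overlap_bp: int = 1,
) -> list[ROIRecord]:
    """Assign CGI/nonCGI context to each ROI by interval overlap.

    An ROI is CGI when it overlaps any single CpG-island interval by at
    least ``min_overlap_bp`` bases.  Input order is preserved.
    """
    if min_overlap_bp < 1:
        raise ConfigError("min_overlap_bp must be >= 1")
    if isinstance(cgis, pd.DataFrame):
        cgis = list(cgis[["chrom", "start", "end"]].itertuples(index=False, name=None))
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in cgis:
        trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))

    missing_chroms = {r.chrom for r in rois} - set(trees)
    if missing_chroms:
        logger.warning(
            "chromosomes %s absent from CGI track; their ROIs set to nonCGI",
            sorted(missing_chroms),
        )

    out: list[ROIRecord] = []
    for r in rois:
        tree = trees.get(r.chrom)
        is_cgi = False
        if tree is not None:
            for iv in tree.overlap(r.start, r.end):
                if min(r.end, iv.end) - max(r.start, iv.begin) >= min_overlap_bp:
                    is_cgi = True
                    break
        out.append(replace(r, cgi_class=CGI if is_cgi else NONCGI))
    return out


def rois_to_frame(rois: Sequence[ROIRecord]) -> pd.DataFrame:
    """Tabulate ROIs, indexed by the ``gene|region_class`` key."""
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rois],
            "chrom": [r.chrom for r in rois],
            "start": [r.start for r in rois],
            "end": [r.end for r in rois],
            "region_class": [r.region_class for r in rois],
            "cgi_class": [r.cgi_class for r in rois],
            "length": [r.length for r in rois],
        },
        index=pd.Index([r.key for r in rois], name="roi"),
    )
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise DataError(f"duplicate (gene_id, region_class) ROIs: {dups}")
    return df


# ---------------------------------------------------------------------------
# file formats


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a header-bearing TSV.

    Required columns: gene_id, chrom, strand, tss, cds_start, cds_end
    (0-based; declare 1-based inputs upstream by shifting them).
    """
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chrom", "strand", "tss", "cds_start", "cds_end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"gene model table missing columns: {missing}")
    return [
        GeneModel(
            str(r.gene_id), str(r.chrom), str(r.strand), int(r.tss),
            int(r.cds_start), int(r.cds_end),
        )
        for r in df.itertuples(index=False)
    ]


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
            "cds_start": [g.cds_start for g in genes],
            "cds_end": [g.cds_end for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_cgi_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read CpG islands from 3-column BED (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    return list(df.itertuples(index=False, name=None))


def write_cgi_bed(cgis: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in cgis:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_rois_bed(rois: Sequence[ROIRecord], path: str | Path) -> None:
    """Write ROIs as BED6; name field encodes ``gene|region_class|cgi_class``."""
    with open(path, "w") as fh:
        for r in rois:
            name = f"{r.gene_id}|{r.region_class}|{r.cgi_class or 'NA'}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t+\n")
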