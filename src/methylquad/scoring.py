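"""Absolute methylation scores (ams) from MBD-seq ROI read counts.

The ams is a transparent CpG-density-corrected RPKM: reads per kilobase
of ROI per million mapped reads, divided by the ROI's CpG density
relative to the cohort median.  MBD pulldown enriches proportionally to
CpG content, so dividing by relative CpG density puts CpG-poor and
CpG-rich regions on a comparable methylation scale.  With the CpG
correction off the score reduces to plain RPKM.  Downstream differential
logic operates on per-sample 0-1 min-max scaled values, so it is
insensitive to any monotone per-sample rescaling of the raw score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"

SAMPLE_COLUMNS = ("subtype", "tumor_normal", "pair_id")


@dataclass
class MethylationMatrix:
    """ROI x sample methylation scores plus per-sample metadata.

    ``values`` is indexed by ROI key (``gene|region_class``) with sample
    IDs as columns; ``samples`` is indexed by sample ID and carries
    subtype, tumor/normal flag and pair ID.  ``scaled`` records whether
    each sample column has been min-max mapped to [0, 1].
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scaled: bool = False

    def __post_init__(self) -> None:
        missing_meta = [s for s in self.values.columns if s not in self.samples.index]
        if missing_meta:
            raise DataError(f"samples missing metadata: {missing_meta}")
        missing_cols = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise DataError(f"sample metadata missing columns: {missing_cols}")
        if (self.values.to_numpy() < 0).any():
            raise DataError("methylation scores must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_rois(self, keys) -> "MethylationMatrix":
        return MethylationMatrix(self.values.loc[keys], self.samples, self.scaled)

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        sample_ids = list(sample_ids)
        return MethylationMatrix(
            self.values[sample_ids], self.samples.loc[sample_ids], self.scaled
        )


def compute_ams(
    counts: pd.DataFrame,
    roi_lengths: pd.Series,
    library_sizes: pd.Series,
    samples: pd.DataFrame,
    cpg_counts: pd.Series | None = None,
    cpg_pseudocount: float = 1.0,
    cpg_correction: bool = True,
) -> MethylationMatrix:
    """Convert an ROI x sample count matrix to unscaled ams.

    ams[g, s] = (count / (library_size/1e6)) / (length/1e3) / cpg_factor
    where cpg_factor = (cpg_count + pseudocount) / median(cpg_count +
    pseudocount) across ROIs.  ``cpg_correction=False`` skips the last
    division (RPKM-like score).
    """
    roi_lengths = roi_lengths.reindex(counts.index)
    library_sizes = library_sizes.reindex(counts.columns)
    if roi_lengths.isna().any():
        raise DataError("roi_lengths missing entries for some ROIs")
    if library_sizes.isna().any():
        raise DataError("library_sizes missing entries for some samples")
    if (roi_lengths <= 0).any():
        raise DataError("zero or negative ROI length")
    if (library_sizes <= 0).any():
        raise DataError("zero or negative library size")
    if (counts.to_numpy() < 0).any():
        raise DataError("negative read counts")

    per_million = counts.to_numpy(dtype=float) / (library_sizes.to_numpy(dtype=float) / 1e6)
    per_kb = per_million / (roi_lengths.to_numpy(dtype=float)[:, None] / 1e3)
    if cpg_correction:
        if cpg_counts is None:
            raise DataError("cpg_counts required when cpg_correction is on")
        cpg = cpg_counts.reindex(counts.index).to_numpy(dtype=float) + cpg_pseudocount
        if (cpg <= 0).any():
            raise DataError("cpg_count + pseudocount must be positive")
        factor = cpg / np.median(cpg)
        per_kb = per_kb / factor[:, None]
    values = pd.DataFrame(per_kb, index=counts.index, columns=counts.columns)
    return MethylationMatrix(values, samples, scaled=False)


def minmax_scale(m: MethylationMatrix) -> MethylationMatrix:
    """Min-max scale each sample column to [0, 1].

    Constant columns map to all zeros with a warning, so degenerate
    inputs flow through rather than aborting the pipeline.
    """
    if m.scaled:
        raise DataError("matrix already scaled")
    x = m.values.to_numpy(dtype=float)
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    span = hi - lo
    const = span == 0
    if const.any():
        logger.warning(
            "constant sample columns mapped to 0: %s",
            list(np.asarray(m.values.columns)[const]),
        )
    span = np.where(const, 1.0, span)
    scaled = (x - lo) / span
    scaled[:, const] = 0.0
    values = pd.DataFrame(scaled, index=m.values.index, columns=m.values.columns)
    return MethylationMatrix(values, m.samples, scaled=True)


def scale_per_region_class(m: MethylationMatrix) -> MethylationMatrix:
    """Min-max scale each region-class submatrix (promoter, CDS) separately.

    Mirrors normalising "each ROI matrix" on its own: a sample's
    promoter scores and CDS scores are scaled independently to [0, 1].
    """
    if m.scaled:
        raise DataError("matrix already scaled")
    region = m.values.index.to_series().str.split("|").str[-1]
    parts = []
    for _, keys in region.groupby(region, sort=False):
        sub = MethylationMatrix(m.values.loc[keys.index], m.samples, scaled=False)
        parts.append(minmax_scale(sub).values)
    values = pd.concat(parts).reindex(m.values.index)
    return MethylationMatrix(values, m.samples, scaled=True)


def read_matrix_tsv(path, samples: pd.DataFrame, scaled: bool = False) -> MethylationMatrix:
    """Read a score matrix TSV (first column = ROI key, header = sample IDs)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    return MethylationMatrix(values, samples, scaled=scaled)


def write_matrix_tsv(m: MethylationMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", float_format="%.6g")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV (sample, subtype, tumor_normal, pair_id)."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise DataError("sample metadata must have a 'sample' column")
    df = df.set_index("sample")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"sample metadata missing columns: {missing}")
    return df
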