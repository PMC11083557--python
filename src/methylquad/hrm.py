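"""MS-HRM quantification: melting-peak AUC and linear calibration.

A bisulfite-PCR product from unmethylated template melts at a lower
temperature than one from methylated template, so the -dF/dT melting
profile of a mixed sample shows two peaks whose areas reflect the
template proportions.  The percent methylation of a sample is read off
a straight line fitted between an AUC-derived metric and known
methylation standards (0%, 50%, 100%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

# Default peak windows bracket the simulator's peak centers (78 / 85 C).
DEFAULT_UNMETH_WINDOW = (70.0, 81.5)
DEFAULT_METH_WINDOW = (81.5, 95.0)


@dataclass(frozen=True)
class MeltingCurve:
    """A -dF/dT melting profile on a strictly ascending temperature grid."""

    temperature: np.ndarray
    signal: np.ndarray
    sample_id: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or s.shape != t.shape:
            raise DataError("temperature and signal must be 1-D and equal length")
        if not (np.diff(t) > 0).all():
            raise DataError("temperature grid must be strictly ascending")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class CalibrationModel:
    """percent = slope * metric + intercept, fitted on known standards."""

    slope: float
    intercept: float
    r_squared: float
    residuals: tuple[float, ...]


def peak_auc(
    curve: MeltingCurve,
    window: tuple[float, float],
    baseline: str = "zero",
) -> float:
    """Trapezoidal area of (signal - baseline) over a temperature window.

    ``baseline="zero"`` integrates the raw signal; ``"linear"``
    subtracts the straight line between the window's endpoint signals.
    The resulting area is clipped at 0.
    """
    t0, t1 = window
    if not t0 < t1:
        raise DataError("empty or inverted window")
    t, s = curve.temperature, curve.signal
    if t0 < t[0] or t1 > t[-1]:
        raise DataError("window extends beyond the temperature grid")
    mask = (t >= t0) & (t <= t1)
    tw, sw = t[mask], s[mask]
    if tw.size < 2:
        raise DataError("window contains fewer than 2 grid points")
    if baseline == "zero":
        base = np.zeros_like(sw)
    elif baseline == "linear":
        base = np.interp(tw, [tw[0], tw[-1]], [sw[0], sw[-1]])
    else:
        raise ConfigError(f"unknown baseline method {baseline!r}")
    area = float(np.trapezoid(sw - base, tw))
    return max(area, 0.0)


def methylation_metric(
    curve: MeltingCurve,
    meth_window: tuple[float, float] = DEFAULT_METH_WINDOW,
    unmeth_window: tuple[float, float] = DEFAULT_UNMETH_WINDOW,
    baseline: str = "zero",
    normalize: bool = True,
) -> float:
    """Methylated-peak AUC, optionally normalised by total peak AUC.

    The calibration line absorbs any affine change of the metric, so
    the normalisation choice does not alter calibrated percents as long
    as it is applied consistently to standards and samples.
    """
    a_meth = peak_auc(curve, meth_window, baseline)
    if not normalize:
        return a_meth
    a_unmeth = peak_auc(curve, unmeth_window, baseline)
    total = a_meth + a_unmeth
    if total == 0:
        raise DataError("zero total peak area; cannot form normalised metric")
    return a_meth / total


def fit_calibration(standards: list[tuple[float, float]]) -> CalibrationModel:
    """OLS fit of known percent methylation on the AUC metric.

    ``standards`` is a list of (known_percent, metric) pairs, e.g. from
    the 0/50/100% controls.  Needs >= 2 distinct known percents and
    non-identical metrics.
    """
    if len(standards) < 2:
        raise DataError("need >= 2 standards")
    percent = np.asarray([s[0] for s in standards], dtype=float)
    metric = np.asarray([s[1] for s in standards], dtype=float)
    if np.unique(percent).size < 2:
        raise DataError("standards must cover >= 2 distinct percents")
    if np.unique(metric).size < 2:
        raise DataError("non-identifiable calibration: identical metric values")
    slope, intercept = np.polyfit(metric, percent, 1)
    fitted = slope * metric + intercept
    resid = percent - fitted
    ss_res = float((resid**2).sum())
    ss_tot = float(((percent - percent.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        residuals=tuple(float(r) for r in resid),
    )


def percent_methylation(metric: float, model: CalibrationModel) -> tuple[float, bool]:
    """Calibrated percent in [0, 100] plus an extrapolation flag.

    The raw prediction slope*metric + intercept is clipped to [0, 100];
    the flag is True when the raw value fell outside that range.
    """
    raw = model.slope * metric + model.intercept
    extrapolated = raw < 0.0 or raw > 100.0
    return float(np.clip(raw, 0.0, 100.0)), extrapolated


def read_curve_csv(path: str | Path, sample_id: str | None = None) -> MeltingCurve:
    """Read a melting curve CSV with columns temperature, signal."""
    df = pd.read_csv(path)
    if not {"temperature", "signal"} <= set(df.columns):
        raise DataError("curve CSV must have 'temperature' and 'signal' columns")
    return MeltingCurve(
        df["temperature"].to_numpy(float),
        df["signal"].to_numpy(float),
        sample_id=sample_id or Path(path).stem,
    )


def write_curve_csv(curve: MeltingCurve, path: str | Path) -> None:
    pd.DataFrame({"temperature": curve.temperature, "signal": curve.signal}).to_csv(
        path, index=False, float_format="%.6g"
    )


def quantify_samples(
    standards: list[tuple[float, MeltingCurve]],
    samples: list[MeltingCurve],
    **metric_kwargs,
) -> pd.DataFrame:
    """Calibrate on standard curves and quantify sample curves.

    Returns a report with one row per sample: metric, percent, and the
    extrapolation flag.
    """
    model = fit_calibration(
        [(pct, methylation_metric(c, **metric_kwargs)) for pct, c in standards]
    )
    rows = []
    for c in samples:
        metric = methylation_metric(c, **metric_kwargs)
        pct, flag = percent_methylation(metric, model)
        rows.append((c.sample_id, metric, pct, flag))
    report = pd.DataFrame(rows, columns=["sample", "metric", "percent", "extrapolated"])
    report.attrs["model"] = model
    return report
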