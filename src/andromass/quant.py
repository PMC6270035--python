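"""Calibration, LOD/LOQ, precision and recovery statistics.

The validation suite of a targeted LC-MS assay: ordinary least-squares
calibration of peak area on concentration (1/x weighting available for
two-decade ranges), back-calculation with range/LOQ flags, detection and
quantification limits from the signal-to-noise crossing of a dilution
series (S/N 3 and 10), relative standard deviation as the precision metric,
and spiked relative recovery as the matrix-effect metric.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

#: Signal-to-noise thresholds defining the limits of detection/quantification.
LOD_SNR = 3.0
LOQ_SNR = 10.0


@dataclass(frozen=True)
class CalibrationCurve:
    """response = slope * concentration + intercept over a validated range."""

    slope: float
    intercept: float
    r_squared: float
    range: tuple[float, float]
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a calibration curve needs at least 2 points")
        if not self.range[0] < self.range[1]:
            raise ValueError("calibration range must have min < max")


@dataclass(frozen=True)
class QuantResult:
    analyte: str
    concentration: float
    response: float
    flag: str  # below_LOQ | above_range | ok


def fit_calibration(
    points: Sequence[tuple[float, float]], weighting: Optional[str] = None
) -> CalibrationCurve:
    """Least-squares fit of response on concentration.

    ``weighting=None`` is unweighted OLS; ``weighting="1/x"`` weights each
    point by the inverse concentration, which equalises relative influence
    over calibration ranges spanning decades.
    """
    pts = [(float(c), float(r)) for c, r in points]
    if len(pts) < 2:
        raise ValueError("at least 2 calibration points are required")
    conc = np.array([c for c, _ in pts])
    resp = np.array([r for _, r in pts])
    if np.all(conc == conc[0]):
        raise ValueError("calibration requires at least 2 distinct concentrations")
    if weighting is None:
        w = np.ones_like(conc)
    elif weighting == "1/x":
        if np.any(conc <= 0):
            raise ValueError("1/x weighting requires positive concentrations")
        w = 1.0 / conc
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    sw = w.sum()
    xbar = (w * conc).sum() / sw
    ybar = (w * resp).sum() / sw
    sxx = (w * (conc - xbar) ** 2).sum()
    slope = (w * (conc - xbar) * (resp - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    pred = slope * conc + intercept
    ss_res = (w * (resp - pred) ** 2).sum()
    ss_tot = (w * (resp - ybar) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        range=(float(conc.min()), float(conc.max())),
        n_points=len(pts),
    )


def back_calculate(response: float, curve: CalibrationCurve) -> float:
    """Invert the calibration relation: (response - intercept)/slope."""
    if curve.slope == 0:
        raise ValueError("cannot back-calculate with zero slope")
    return (response - curve.intercept) / curve.slope


def quantify_response(
    analyte: str,
    response: float,
    curve: CalibrationCurve,
    loq: Optional[float] = None,
) -> QuantResult:
    conc = back_calculate(response, curve)
    if loq is not None and conc < loq:
        flag = "below_LOQ"
    elif conc > curve.range[1]:
        flag = "above_range"
    else:
        flag = "ok"
    return QuantResult(analyte, conc, response, flag)


def _snr_crossing(
    conc: np.ndarray, snr: np.ndarray, threshold: float, interpolate: bool
) -> Optional[float]:
    idx = np.flatnonzero(snr >= threshold)
    if idx.size == 0:
        return None
    i = int(idx[0])
    if interpolate and i > 0 and snr[i] > threshold:
        c0, c1 = conc[i - 1], conc[i]
        s0, s1 = snr[i - 1], snr[i]
        if s1 > s0:
            return float(c0 + (threshold - s0) / (s1 - s0) * (c1 - c0))
    return float(conc[i])


def lod_loq(
    dilution_series: Sequence[tuple[float, float]],
    interpolate: bool = False,
) -> tuple[Optional[float], Optional[float]]:
    """LOD (S/N >= 3) and LOQ (S/N >= 10) from a dilution series.

    The series is sorted by concentration; a non-monotone S/N profile
    triggers a warning and an isotonic (least-squares monotone) projection
    before the crossing search.  ``None`` marks a limit the series never
    reaches ("not determined").
    """
    pts = sorted((float(c), float(s)) for c, s in dilution_series)
    if not pts:
        return None, None
    conc = np.array([c for c, _ in pts])
    snr = np.array([s for _, s in pts])
    if np.any(np.diff(snr) < 0):
        warnings.warn(
            "S/N is not non-decreasing in concentration; applying isotonic "
            "projection",
            stacklevel=2,
        )
        snr = IsotonicRegression(increasing=True).fit_transform(conc, snr)
    lod = _snr_crossing(conc, snr, LOD_SNR, interpolate)
    loq = _snr_crossing(conc, snr, LOQ_SNR, interpolate)
    return lod, loq


def precision_rsd(replicates: Sequence[float]) -> float:
    """Relative standard deviation in percent (n-1 denominator)."""
    vals = np.asarray(list(replicates), dtype=float)
    if vals.size < 2:
        raise ValueError("precision needs at least 2 replicates")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    if np.all(vals == vals[0]):  # identical replicates: exactly zero
        return 0.0
    return float(vals.std(ddof=1) / mean * 100.0)


def relative_recovery(
    spiked_content: float, original_content: float, added_content: float
) -> float:
    """Matrix-effect relative recovery, (spiked - original)/added * 100%."""
    if added_content <= 0:
        raise ValueError("added content must be positive")
    return (spiked_content - original_content) / added_content * 100.0
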