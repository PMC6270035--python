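"""Lock-mass correction, narrow-window XICs and peak integration.

Operates on centroided MS1 scan series.  The extraction window is the
*full* width in mDa (the conventional way a "20 mDa window" is quoted), so
centroids within +-window/2 of the target are summed per scan.  Peak
detection is deliberately simple and robust for sparse TOF baselines:
baseline = a low quantile of the trace, noise = scaled median absolute
deviation of the trace outside the top-intensity region, peaks = contiguous
regions above baseline + min_snr * noise, integrated by the trapezoid rule
after baseline subtraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .masscalc import MassTolerance

LOCK_MASS_MZ = 556.2771  # [M+H]+ of leucine enkephalin, the Lock-Spray reference


@dataclass
class Scan:
    """One centroided MS1 scan."""

    retention_time: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must align")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class ScanSeries:
    """Time-ordered centroided MS1 run."""

    scans: list[Scan]

    def __post_init__(self) -> None:
        rts = [s.retention_time for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("retention times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.retention_time for s in self.scans])

    def __len__(self) -> int:
        return len(self.scans)


@dataclass
class XIC:
    """Narrow-window extracted ion chromatogram."""

    target_mz: float
    window_mda: float
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        if not self.window_mda > 0:
            raise ValueError("window must be positive")
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)


@dataclass(frozen=True)
class PeakResult:
    apex_rt: float
    height: float
    area: float
    snr: float
    rt_start: float
    rt_end: float


def lock_mass_correct(
    series: ScanSeries,
    reference_mz: float = LOCK_MASS_MZ,
    tol: MassTolerance = MassTolerance("mDa", 50.0),
) -> tuple[ScanSeries, np.ndarray]:
    """Rescale each scan's mass axis onto the lock-mass reference.

    Per scan the most intense centroid within ``tol`` of ``reference_mz``
    defines a multiplicative factor reference/observed applied to every m/z
    of that scan.  Scans without the reference borrow the factor of the
    nearest scan that has it; if fewer than half the scans contain the
    reference a warning is raised, and if none do it is an error.
    """
    n = len(series.scans)
    factors = np.full(n, np.nan)
    for i, scan in enumerate(series.scans):
        if scan.mz.size == 0:
            continue
        mask = np.abs(scan.mz - reference_mz) <= tol.window_da(reference_mz)
        if mask.any():
            idx = np.flatnonzero(mask)
            obs = scan.mz[idx[np.argmax(scan.intensity[idx])]]
            factors[i] = reference_mz / obs
    found = np.flatnonzero(~np.isnan(factors))
    if found.size == 0:
        raise ValueError(
            f"lock-mass reference {reference_mz} not found in any of {n} scans"
        )
    if found.size < 0.5 * n:
        warnings.warn(
            f"lock-mass reference found in only {found.size}/{n} scans; "
            "borrowing nearest-scan factors",
            stacklevel=2,
        )
    missing = np.flatnonzero(np.isnan(factors))
    if missing.size:
        nearest = found[np.argmin(np.abs(missing[:, None] - found[None, :]), axis=1)]
        factors[missing] = factors[nearest]
    corrected = ScanSeries(
        [
            Scan(s.retention_time, s.mz * f, s.intensity.copy())
            for s, f in zip(series.scans, factors)
        ]
    )
    return corrected, factors


def extract_nwxic(
    series: ScanSeries, target_mz: float, window_mda: float = 20.0
) -> XIC:
    """Sum centroid intensities within +-window/2 of the target, per scan."""
    if not window_mda > 0:
        raise ValueError("window must be positive")
    half = window_mda * 1e-3 / 2.0
    inten = np.array(
        [
            float(s.intensity[np.abs(s.mz - target_mz) <= half].sum())
            if s.mz.size
            else 0.0
            for s in series.scans
        ]
    )
    return XIC(target_mz, window_mda, series.times, inten)


def estimate_baseline_noise(
    trace: np.ndarray, baseline_quantile: float = 0.1
) -> tuple[float, float]:
    """(baseline level, robust noise sd) of a chromatographic trace.

    Baseline is the ``baseline_quantile`` quantile.  Noise is 1.4826x the
    median absolute deviation of the trace after discarding the top
    ``baseline_quantile`` fraction (the candidate peak region), which keeps
    the estimate robust when peaks occupy a minority of scans.
    """
    y = np.asarray(trace, dtype=float)
    baseline = float(np.quantile(y, baseline_quantile))
    low = y[y <= np.quantile(y, 1.0 - baseline_quantile)]
    if low.size == 0:
        return baseline, 0.0
    noise = 1.4826 * float(np.median(np.abs(low - np.median(low))))
    return baseline, noise


def detect_and_integrate(
    xic: XIC,
    min_snr: float = 3.0,
    baseline_quantile: float = 0.1,
    max_gap: int = 1,
) -> list[PeakResult]:
    """Threshold-crossing peak detection with trapezoidal integration.

    Contiguous regions above baseline + min_snr * noise become peaks; the
    integration bounds extend one sample beyond the region so the crossing
    flanks are included.  Sub-threshold gaps of up to ``max_gap`` scans are
    bridged, so a single centroid dropout cannot split a peak.  With zero
    estimated noise and nonzero signal the S/N is reported as +infinity.
    """
    y = xic.intensities
    t = xic.times
    if y.size == 0:
        raise ValueError("empty XIC trace")
    if not np.any(y > 0):
        return []
    baseline, noise = estimate_baseline_noise(y, baseline_quantile)
    threshold = baseline + min_snr * noise
    above = y > threshold
    if max_gap > 0:  # bridge short dropouts flanked by above-threshold scans
        idx = np.flatnonzero(above)
        for a, b in zip(idx, idx[1:]):
            if 1 < b - a <= max_gap + 1:
                above[a:b] = True
    peaks: list[PeakResult] = []
    i = 0
    n = y.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        lo = max(i - 1, 0)
        hi = min(j + 1, n - 1)
        seg_y = y[lo : hi + 1] - baseline
        seg_t = t[lo : hi + 1]
        area = float(np.trapezoid(seg_y, seg_t)) if seg_y.size > 1 else 0.0
        apex = i + int(np.argmax(y[i : j + 1]))
        height = float(y[apex])
        snr = (height - baseline) / noise if noise > 0 else math.inf
        if area > 0:
            peaks.append(
                PeakResult(
                    apex_rt=float(t[apex]),
                    height=height,
                    area=area,
                    snr=snr,
                    rt_start=float(t[lo]),
                    rt_end=float(t[hi]),
                )
            )
        i = j + 1
    return peaks


def window_snr(
    xic: XIC,
    expected_rt: float,
    rt_tol: float = 0.1,
    baseline_quantile: float = 0.1,
) -> float:
    """Signal-to-noise at a known elution window, detection-free.

    (max trace value within ``expected_rt +- rt_tol`` minus the median
    baseline) over the robust noise estimate — the quantity dilution series
    are scored on when determining detection and quantification limits,
    where the analyte may well sit below the peak-detection threshold.
    The median is the right baseline location here: a low quantile would
    credit every blank with ~1 sigma of spurious signal.
    """
    _, noise = estimate_baseline_noise(xic.intensities, baseline_quantile)
    baseline = float(np.median(xic.intensities))
    mask = np.abs(xic.times - expected_rt) <= rt_tol
    if not mask.any():
        raise ValueError("no scans inside the expected retention-time window")
    height = float(xic.intensities[mask].max())
    if noise <= 0:
        return math.inf if height > baseline else 0.0
    return (height - baseline) / noise


def quantifier_peak(
    peaks: Sequence[PeakResult],
    expected_rt: Optional[float] = None,
    rt_tol: float = 0.1,
) -> Optional[PeakResult]:
    """Pick the peak for quantitation: nearest the expected retention time
    (within ``rt_tol`` minutes) when one is given, else the largest area."""
    if not peaks:
        return None
    if expected_rt is None:
        return max(peaks, key=lambda p: p.area)
    near = [p for p in peaks if abs(p.apex_rt - expected_rt) <= rt_tol]
    if not near:
        return None
    return min(near, key=lambda p: abs(p.apex_rt - expected_rt))
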