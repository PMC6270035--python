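"""Lock-mass correction, narrow-window XIC extraction and peak integration."""

import math

import numpy as np
import pytest

from andromass import (
    LOCK_MASS_MZ,
    MassTolerance,
    Scan,
    ScanSeries,
    XIC,
    detect_and_integrate,
    extract_nwxic,
    lock_mass_correct,
)
from andromass.chrom import quantifier_peak
from andromass.simulate import RunSpec, default_templates


def _series_with_lock(bias_ppm=0.0, analyte_mz=351.2171, n=20):
    scale = 1.0 + bias_ppm * 1e-6
    scans = [
        Scan(
            0.1 * (i + 1),
            np.array([analyte_mz * scale, LOCK_MASS_MZ * scale]),
            np.array([100.0, 500.0]),
        )
        for i in range(n)
    ]
    return ScanSeries(scans)


class TestLockMassCorrect:
    def test_systematic_bias_is_removed(self):
        series = _series_with_lock(bias_ppm=5.0)
        corrected, factors = lock_mass_correct(series)
        for scan in corrected.scans:
            err_ppm = (scan.mz[0] - 351.2171) / 351.2171 * 1e6
            assert abs(err_ppm) < 0.1

    def test_exact_series_gives_unit_factors(self):
        _, factors = lock_mass_correct(_series_with_lock(0.0))
        assert np.allclose(factors, 1.0, atol=1e-12)

    def test_idempotent_within_tolerance(self):
        series = _series_with_lock(bias_ppm=8.0)
        once, _ = lock_mass_correct(series)
        _, factors2 = lock_mass_correct(once)
        assert np.all(np.abs(factors2 - 1.0) < 0.05e-6)

    def test_missing_reference_is_an_error(self):
        scans = [Scan(0.1, np.array([100.0]), np.array([1.0]))]
        with pytest.raises(ValueError, match="lock-mass"):
            lock_mass_correct(ScanSeries(scans))

    def test_sparse_reference_warns_and_interpolates(self):
        series = _series_with_lock(bias_ppm=5.0, n=10)
        for scan in series.scans[3:]:  # strip the lock ion from 70% of scans
            scan.mz = scan.mz[:1]
            scan.intensity = scan.intensity[:1]
        with pytest.warns(UserWarning, match="lock-mass"):
            corrected, factors = lock_mass_correct(series)
        assert np.all(np.isfinite(factors))
        assert np.allclose(factors, factors[0])


def _gaussian_series(h=1000.0, rt0=5.0, sigma=0.05, dt=0.005, mz=297.187,
                     t_max=10.0):
    times = np.arange(dt / 2, t_max, dt)
    scans = []
    for t in times:
        inten = h * math.exp(-0.5 * ((t - rt0) / sigma) ** 2)
        scans.append(Scan(t, np.array([mz]), np.array([inten])))
    return ScanSeries(scans)


class TestExtractNwxic:
    def test_ion_outside_window_gives_flat_zero(self):
        series = _gaussian_series(mz=297.187 + 0.05)
        xic = extract_nwxic(series, 297.187, window_mda=20.0)
        assert np.all(xic.intensities == 0.0)

    def test_one_trace_point_per_scan(self):
        series = _gaussian_series()
        xic = extract_nwxic(series, 297.187)
        assert xic.intensities.size == len(series.scans)

    def test_apex_at_generating_time(self):
        series = _gaussian_series(rt0=5.0, dt=0.01)
        xic = extract_nwxic(series, 297.187)
        apex = xic.times[np.argmax(xic.intensities)]
        assert abs(apex - 5.0) <= 0.01

    def test_window_monotonicity(self):
        """Widening the window never decreases any trace value."""
        rng = np.random.default_rng(3)
        scans = [
            Scan(
                0.1 * (i + 1),
                np.sort(297.187 + rng.normal(0.0, 0.02, size=8)),
                rng.uniform(0.0, 100.0, size=8),
            )
            for i in range(30)
        ]
        series = ScanSeries(scans)
        prev = None
        for window in (5.0, 10.0, 20.0, 40.0, 80.0):
            xic = extract_nwxic(series, 297.187, window)
            if prev is not None:
                assert np.all(xic.intensities >= prev - 1e-12)
            prev = xic.intensities

    def test_invalid_window_is_an_error(self):
        with pytest.raises(ValueError):
            extract_nwxic(_gaussian_series(), 297.187, window_mda=0.0)


class TestDetectAndIntegrate:
    def test_noiseless_gaussian_area_matches_closed_form(self):
        h, sigma = 1000.0, 0.05
        series = _gaussian_series(h=h, sigma=sigma, dt=0.002)
        xic = extract_nwxic(series, 297.187)
        peaks = detect_and_integrate(xic)
        assert len(peaks) == 1
        expected = h * sigma * math.sqrt(2 * math.pi)
        assert peaks[0].area == pytest.approx(expected, rel=0.01)
        assert peaks[0].snr == math.inf
        assert peaks[0].rt_start < peaks[0].apex_rt < peaks[0].rt_end

    def test_area_stable_under_doubled_sampling(self):
        areas = []
        for dt in (0.01, 0.005):
            xic = extract_nwxic(_gaussian_series(dt=dt), 297.187)
            areas.append(detect_and_integrate(xic)[0].area)
        assert abs(areas[1] - areas[0]) / areas[0] < 0.005

    def test_flat_zero_trace_yields_no_peaks(self):
        xic = XIC(297.187, 20.0, np.arange(100) * 0.01, np.zeros(100))
        assert detect_and_integrate(xic) == []

    def test_snr_tracks_generator_truth(self):
        """Estimated S/N within 30% of h/noise_sd on average over 100 seeds."""
        h, sd = 100.0, 5.0
        times = np.arange(0, 10, 0.01)
        shape = h * np.exp(-0.5 * ((times - 5.0) / 0.05) ** 2)
        snrs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            trace = shape + rng.normal(0.0, sd, size=times.size)
            peaks = detect_and_integrate(XIC(297.187, 20.0, times, trace))
            pk = quantifier_peak(peaks, expected_rt=5.0, rt_tol=0.1)
            assert pk is not None
            snrs.append(pk.snr)
        assert np.mean(snrs) == pytest.approx(h / sd, rel=0.30)


class TestWindowSnr:
    def test_blank_window_scores_below_detection(self):
        """Pure baseline noise must not read as a detectable analyte."""
        from andromass.chrom import window_snr

        rng = np.random.default_rng(0)
        times = np.arange(0, 10, 0.01)
        snrs = []
        for _ in range(20):
            trace = np.clip(20.0 + rng.normal(0.0, 15.0, times.size), 0, None)
            snrs.append(window_snr(XIC(297.18, 20.0, times, trace), 5.0))
        assert np.median(snrs) < 3.0

    def test_snr_grows_with_signal(self):
        from andromass.chrom import window_snr

        rng = np.random.default_rng(1)
        times = np.arange(0, 10, 0.01)
        noise = np.clip(20.0 + rng.normal(0.0, 15.0, times.size), 0, None)
        peak = 500.0 * np.exp(-0.5 * ((times - 5.0) / 0.05) ** 2)
        low = window_snr(XIC(297.18, 20.0, times, noise), 5.0)
        high = window_snr(XIC(297.18, 20.0, times, noise + peak), 5.0)
        assert high > 10.0 > low


class TestTwoCompoundResolution:
    def test_shared_channel_resolves_both_markers(self):
        """A run containing andrographolide and dehydroandrographolide shows
        two resolved peaks in the 297.187 narrow-window XIC at their
        published retention times."""
        tpl = {t.id: t for t in default_templates()}
        spec = RunSpec(
            templates=(tpl["andrographolide"], tpl["dehydroandrographolide"]),
            concentrations={"andrographolide": 20.0, "dehydroandrographolide": 20.0},
            seed=11,
        )
        from andromass.simulate import generate_run

        series, _ = generate_run(spec)
        xic = extract_nwxic(series, 297.187, 20.0)
        peaks = detect_and_integrate(xic)
        apexes = [p.apex_rt for p in peaks if p.snr > 50]
        assert len(apexes) == 2
        assert min(abs(a - 5.11) for a in apexes) <= 0.02
        assert min(abs(a - 7.57) for a in apexes) <= 0.02
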