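"""Generators: fixture integrity, noise calibration, determinism, I/O."""

import math

import numpy as np
import pytest

from andromass import (
    adduct_mz,
    generate_calibration_series,
    generate_run,
    generate_spectrum,
    ppm_error,
    table1_fixture,
)
from andromass.masscalc import ElementalFormula
from andromass.simulate import (
    TABLE1_COMPOUNDS,
    CompoundTemplate,
    RunSpec,
    default_templates,
    validate_template,
)
from andromass import msio


class TestTable1Fixture:
    def test_fifteen_compounds(self, fixture_spectra):
        assert len(fixture_spectra) == 15

    def test_verbatim_precursors(self, fixture_spectra):
        by_id = {s.compound_id: s for s in fixture_spectra}
        assert by_id["6"].precursor_mz == 351.2164
        assert by_id["12"].precursor_mz == 681.3962

    def test_constant_between_calls(self):
        a, b = table1_fixture(), table1_fixture()
        assert a == b

    def test_registry_covers_all_rows(self):
        assert set(TABLE1_COMPOUNDS) == {str(i) for i in range(1, 16)}
        named = [r for r in TABLE1_COMPOUNDS.values() if r["calc"] is not None]
        # every printed calculated value is consistent with its composition
        for row in named:
            assert abs(adduct_mz(row["formula"]) - row["calc"]) < 0.002


class TestGenerateSpectrum:
    def test_zero_noise_reproduces_exact_masses(self):
        for template in default_templates():
            sp = generate_spectrum(template, seed=0)
            exact = sorted(mz for _, mz, _ in template.ion_table())
            assert np.allclose(sorted(sp.mz), exact, atol=1e-12)

    def test_ppm_noise_is_calibrated(self):
        """Empirical mass-error spread within 10% of the requested 5 ppm."""
        template = default_templates()[0]
        true_mz = template.precursor_mz
        errors = [
            ppm_error(
                generate_spectrum(template, mass_noise_ppm=5.0, seed=s).precursor_mz,
                true_mz,
            )
            for s in range(1000)
        ]
        assert np.std(errors) == pytest.approx(5.0, rel=0.10)

    def test_inconsistent_template_is_rejected(self):
        bad = CompoundTemplate(
            id="bad", formula=ElementalFormula("C20H30O5"),
            class_label="diterpene_glucoside", retention_time=5.0,
            diagnostic_ions=(),
        )
        with pytest.raises(ValueError, match="inconsistent"):
            validate_template(bad)


class TestGenerateRun:
    def _spec(self, **kw):
        tpl = [t for t in default_templates() if t.id == "andrographolide"]
        base = dict(
            templates=tuple(tpl),
            concentrations={"andrographolide": 10.0},
            scan_interval=0.02,
            seed=5,
        )
        base.update(kw)
        return RunSpec(**base)

    def test_same_seed_is_identical(self):
        s1, t1 = generate_run(self._spec())
        s2, t2 = generate_run(self._spec())
        assert all(
            np.array_equal(a.mz, b.mz) and np.array_equal(a.intensity, b.intensity)
            for a, b in zip(s1.scans, s2.scans)
        )
        assert t1.equals(t2)

    def test_different_seed_differs(self):
        s1, _ = generate_run(self._spec())
        s2, _ = generate_run(self._spec(seed=6))
        assert any(
            not np.array_equal(a.intensity, b.intensity)
            for a, b in zip(s1.scans, s2.scans)
        )

    def test_noiseless_tic_conserves_gaussian_mass(self):
        spec = self._spec(
            mass_noise_ppm=0.0, intensity_noise_cv=0.0,
            baseline_level=0.0, baseline_noise_sd=0.0, lock_mass=False,
        )
        series, truth = generate_run(spec)
        tic = np.array([s.intensity.sum() for s in series.scans])
        t = series.times
        rel = np.zeros_like(t)
        for _, row in truth.iterrows():
            rel += row["amplitude"] * np.exp(
                -0.5 * ((t - row["apex_rt"]) / spec.peak_width_sd) ** 2
            )
        assert np.allclose(tic, rel, rtol=1e-6, atol=1e-6)

    def test_truth_area_matches_closed_form(self):
        _, truth = generate_run(self._spec())
        row = truth[truth["ion"] == "[M+H]+"].iloc[0]
        expected = row["amplitude"] * 0.05 * math.sqrt(2 * math.pi)
        assert row["true_area"] == pytest.approx(expected)

    def test_suppression_bounds_enforced(self):
        with pytest.raises(ValueError, match="suppression"):
            self._spec(matrix_suppression={"andrographolide": 1.5})


class TestCalibrationSeries:
    def test_noiseless_recovers_generating_slope(self):
        from andromass import fit_calibration

        table = generate_calibration_series(22.35, -9.56, [0.2, 1, 10, 100])
        curve = fit_calibration(list(zip(table["concentration"], table["response"])))
        assert curve.slope == pytest.approx(22.35, rel=1e-12)
        assert curve.intercept == pytest.approx(-9.56, rel=1e-12)

    def test_zero_cv_is_seed_independent(self):
        a = generate_calibration_series(22.35, -9.56, [1, 10], seed=1)
        b = generate_calibration_series(22.35, -9.56, [1, 10], seed=99)
        assert a.equals(b)

    def test_noisy_slope_is_unbiased(self):
        """Fitted slope distribution centred on truth, |bias| < 0.5%."""
        from andromass import fit_calibration

        slopes = []
        for seed in range(100):
            table = generate_calibration_series(
                22.35, -9.56, [0.2, 0.5, 2, 10, 50, 100],
                replicates=3, noise_cv=0.02, seed=seed,
            )
            slopes.append(
                fit_calibration(
                    list(zip(table["concentration"], table["response"]))
                ).slope
            )
        assert abs(np.mean(slopes) - 22.35) / 22.35 < 0.005

    def test_all_negative_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            generate_calibration_series(-5.0, -1.0, [1.0, 2.0])


class TestRoundTrips:
    def test_mzml(self, tmp_path):
        series, _ = generate_run(
            RunSpec(
                templates=tuple(default_templates()[:1]),
                concentrations={"andrographolide": 5.0},
                scan_interval=0.05, duration=2.0, seed=3,
            )
        )
        path = tmp_path / "run.mzml"
        msio.write_mzml(series, str(path))
        back = msio.read_mzml(str(path))
        assert len(back) == len(series)
        for a, b in zip(series.scans, back.scans):
            assert np.allclose(a.mz, b.mz, atol=0)
            assert np.allclose(a.intensity, b.intensity, atol=0)
            assert b.retention_time == pytest.approx(a.retention_time, abs=1e-9)

    def test_mgf(self, tmp_path, fixture_spectra):
        path = tmp_path / "spectra.mgf"
        msio.write_mgf(fixture_spectra, str(path))
        back = msio.read_mgf(str(path))
        assert [s.compound_id for s in back] == [s.compound_id for s in fixture_spectra]
        for a, b in zip(fixture_spectra, back):
            assert np.allclose(a.mz, b.mz)
            assert b.retention_time == pytest.approx(a.retention_time, abs=1e-6)

    def test_scan_table(self, tmp_path):
        series, _ = generate_run(
            RunSpec(
                templates=tuple(default_templates()[:1]),
                concentrations={"andrographolide": 5.0},
                scan_interval=0.1, duration=1.0, seed=4,
            )
        )
        path = tmp_path / "scans.tsv"
        msio.write_scan_table(series, str(path))
        back = msio.read_scan_table(str(path))
        assert len(back) == len(series)
        for a, b in zip(series.scans, back.scans):
            assert np.allclose(np.sort(a.mz), np.sort(b.mz))
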