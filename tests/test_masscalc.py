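"""Exact-mass arithmetic, adduct calculus and formula enumeration."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from andromass import (
    ElementalFormula,
    MassTolerance,
    adduct_mz,
    enumerate_formulas,
    get_adduct,
    monoisotopic_mass,
    ppm_error,
    rdbe,
)
from andromass.masscalc import ELEMENT_MASSES
from andromass.simulate import TABLE1_COMPOUNDS


class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "formula,expected",
        [("C20H30O5", 350.2093), ("H2O", 18.0106), ("C6H10O5", 162.0528)],
    )
    def test_reference_masses(self, formula, expected):
        assert monoisotopic_mass(formula) == pytest.approx(expected, abs=5e-4)

    def test_empty_formula_has_zero_mass(self):
        assert monoisotopic_mass(ElementalFormula()) == 0.0

    def test_unknown_element_is_named_in_error(self):
        with pytest.raises(ValueError, match="Xx"):
            ElementalFormula({"Xx": 1})

    def test_hill_notation_round_trip(self):
        f = ElementalFormula("C21H18O11")
        assert f.hill() == "C21H18O11"
        assert ElementalFormula(f.hill()) == f
        assert ElementalFormula("H2O").hill() == "H2O"
        assert ElementalFormula(C=1, H=4).hill() == "CH4"

    def test_subtraction_below_zero_is_an_error(self):
        with pytest.raises(ValueError, match="negative"):
            ElementalFormula("CH4") - ElementalFormula("C2")

    @settings(deadline=None, max_examples=100)
    @given(
        st.fixed_dictionaries(
            {s: st.integers(0, 40) for s in ("C", "H", "N", "O")}
        ),
        st.fixed_dictionaries(
            {s: st.integers(0, 40) for s in ("C", "H", "N", "O")}
        ),
    )
    def test_mass_additivity(self, a, b):
        fa, fb = ElementalFormula(a), ElementalFormula(b)
        assert (fa + fb).monoisotopic_mass == pytest.approx(
            fa.monoisotopic_mass + fb.monoisotopic_mass, abs=1e-9
        )


class TestAdductMz:
    @pytest.mark.parametrize(
        "cid",
        [c for c, row in TABLE1_COMPOUNDS.items() if row["calc"] is not None],
    )
    def test_printed_calculated_values_reproduce(self, cid):
        """Every printed calculated protonated-molecule m/z follows from the
        literature composition under the hydrogen-atom convention."""
        row = TABLE1_COMPOUNDS[cid]
        assert adduct_mz(row["formula"], "[M+H]+") == pytest.approx(
            row["calc"], abs=5e-4
        )

    def test_cross_check_against_pyteomics(self):
        """Independent oracle: pyteomics' elemental mass tables agree with
        the shipped registry to well below the reporting precision."""
        from pyteomics import mass as pt_mass

        for composition in ("C20H30O5", "C26H40O8", "C28H37N5O7", "C21H18O11"):
            ours = monoisotopic_mass(composition)
            theirs = pt_mass.calculate_mass(formula=composition)
            assert ours == pytest.approx(theirs, abs=1e-5)

    def test_lock_mass_reference(self):
        assert adduct_mz("C28H37N5O7", "[M+H]+") == pytest.approx(556.2771, abs=5e-4)

    def test_proton_bound_dimer(self):
        assert adduct_mz("C20H30O5", "[2M+H]+") == pytest.approx(701.4265, abs=5e-4)

    def test_electron_correction_shifts_down(self):
        plain = adduct_mz("C20H30O5")
        corrected = adduct_mz("C20H30O5", electron_correction=True)
        assert plain - corrected == pytest.approx(0.000549, abs=1e-5)

    def test_unknown_adduct_lists_registry(self):
        with pytest.raises(KeyError, match=r"\[M\+H\]\+"):
            get_adduct("[M-H]-")


class TestPpmError:
    @pytest.mark.parametrize(
        "obs,calc,expected",
        [(351.2164, 351.2171, -2.0), (447.0887, 447.0927, -8.9)],
    )
    def test_published_mass_errors(self, obs, calc, expected):
        assert ppm_error(obs, calc) == pytest.approx(expected, abs=0.05)

    def test_identity_is_zero(self):
        assert ppm_error(333.2075, 333.2075) == 0.0

    def test_nonpositive_reference_is_an_error(self):
        with pytest.raises(ValueError):
            ppm_error(100.0, 0.0)

    @settings(deadline=None, max_examples=100)
    @given(
        st.floats(10.0, 2000.0, allow_nan=False),
        st.floats(10.0, 2000.0, allow_nan=False),
    )
    def test_antisymmetry(self, a, b):
        # (a-b)/b = -[(b-a)/a] * a/b
        assert ppm_error(a, b) == pytest.approx(
            -ppm_error(b, a) * a / b, rel=1e-9, abs=1e-9
        )


class TestRdbe:
    @pytest.mark.parametrize(
        "formula,expected",
        [("C20H30O5", 6.0), ("CH4", 0.0), ("C17H14O6", 11.0), ("C28H37N5O7", 13.0)],
    )
    def test_values(self, formula, expected):
        assert rdbe(formula) == expected


def brute_force_enumeration(target, adduct_name, tol, bounds):
    """Independent oracle: exhaustive quadruple loop over the lattice."""
    adduct = get_adduct(adduct_name)
    hits = set()
    for c in range(bounds.get("C", (0, 0))[0], bounds.get("C", (0, 0))[1] + 1):
        for h in range(bounds.get("H", (0, 0))[0], bounds.get("H", (0, 0))[1] + 1):
            for n in range(bounds.get("N", (0, 0))[0], bounds.get("N", (0, 0))[1] + 1):
                for o in range(bounds.get("O", (0, 0))[0], bounds.get("O", (0, 0))[1] + 1):
                    mass = (
                        c * ELEMENT_MASSES["C"]
                        + h * ELEMENT_MASSES["H"]
                        + n * ELEMENT_MASSES["N"]
                        + o * ELEMENT_MASSES["O"]
                    )
                    if c + h + n + o == 0:
                        continue
                    mz = (
                        adduct.multiplicity * mass
                        + adduct.delta_formula.monoisotopic_mass
                    ) / adduct.charge
                    if abs(mz - target) > tol.window_da(target):
                        continue
                    r = (2 * c + 2 + n - h) / 2
                    if not (0 <= r <= 25) or r != int(r):
                        continue
                    hits.add(f"C{c}H{h}N{n}O{o}")
    return hits


class TestEnumerateFormulas:
    def test_andrographolide_is_found(self):
        cands = enumerate_formulas(
            351.2171, "[M+H]+", MassTolerance("ppm", 5.0),
            {"C": 30, "H": 60, "O": 12},
        )
        assert any(c.formula.hill() == "C20H30O5" for c in cands)

    def test_water_only_candidate(self):
        cands = enumerate_formulas(
            19.0184, "[M+H]+", MassTolerance("ppm", 10.0),
            {"C": 2, "H": 6, "O": 2},
        )
        assert [c.formula.hill() for c in cands] == ["H2O"]

    def test_below_minimum_mass_is_empty(self):
        assert enumerate_formulas(
            5.0, "[M+H]+", MassTolerance("ppm", 5.0), {"C": 5, "H": 10, "O": 3}
        ) == []

    def test_empty_bounds_yield_empty_list(self):
        assert enumerate_formulas(
            100.0, "[M+H]+", MassTolerance("ppm", 5.0), {}
        ) == []

    def test_invalid_tolerance_is_an_error(self):
        with pytest.raises(ValueError):
            MassTolerance("ppm", 0.0)

    def test_metal_bounds_are_rejected(self):
        with pytest.raises(ValueError, match="CHNO"):
            enumerate_formulas(
                100.0, "[M+H]+", MassTolerance("ppm", 5.0), {"Na": 2}
            )

    def test_ranking_is_by_abs_ppm(self):
        cands = enumerate_formulas(
            301.1414, "[M+H]+", MassTolerance("ppm", 200.0),
            {"C": 20, "H": 40, "N": 2, "O": 8},
        )
        errors = [abs(c.ppm) for c in cands]
        assert errors == sorted(errors)

    def test_matches_brute_force_oracle(self):
        """Exhaustiveness against an independent nested-loop search on >=100
        random bounded instances."""
        import random

        rng = random.Random(20130930)
        bounds = {"C": (0, 15), "H": (0, 30), "N": (0, 2), "O": (0, 10)}
        for _ in range(100):
            target = rng.uniform(60.0, 380.0)
            tol = MassTolerance("ppm", rng.choice([5.0, 10.0, 25.0]))
            got = {
                f"C{c.formula.get('C')}H{c.formula.get('H')}"
                f"N{c.formula.get('N')}O{c.formula.get('O')}"
                for c in enumerate_formulas(target, "[M+H]+", tol, bounds)
            }
            assert got == brute_force_enumeration(target, "[M+H]+", tol, bounds)
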