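"""Exact monoisotopic mass arithmetic, adduct m/z calculus and formula search.

All arithmetic is carried by :class:`ElementalFormula`, an immutable mapping of
element symbols to non-negative integer counts.  Masses are *monoisotopic*
(lightest isotope per element) and come from a plain-text registry shipped
with the package (``data/elements.tsv``), so the numeric convention is
auditable and editable.  Adduct m/z values follow the hydrogen-atom
convention used by TOF vendor software for "calculated" protonated molecules:
the ``[M+H]+`` delta is one hydrogen *atom* and no electron-mass correction is
applied.  An electron-corrected mode is available via
:func:`adduct_mz`'s ``electron_correction`` flag.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

ELECTRON_MASS = 0.00054857990907  # Da

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _load_kv_table(name: str) -> list[list[str]]:
    text = resources.files("andromass.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


ELEMENT_MASSES: dict[str, float] = {
    sym: float(mass) for sym, mass in _load_kv_table("elements.tsv")
}


class ElementalFormula(Mapping):
    """Immutable elemental composition with exact-mass arithmetic.

    Parameters
    ----------
    counts
        Mapping of element symbol to non-negative integer count, or a Hill
        string such as ``"C20H30O5"``.  Keyword arguments are merged in, e.g.
        ``ElementalFormula(C=20, H=30, O=5)``.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | str | None = None, **kw: int):
        merged: dict[str, int] = {}
        if isinstance(counts, str):
            merged.update(_parse_hill(counts))
        elif counts is not None:
            merged.update(counts)
        for sym, n in kw.items():
            merged[sym] = merged.get(sym, 0) + n
        for sym, n in merged.items():
            if sym not in ELEMENT_MASSES:
                raise ValueError(
                    f"unknown element symbol {sym!r}; known: "
                    + ", ".join(sorted(ELEMENT_MASSES))
                )
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {sym} must be a non-negative integer, got {n!r}")
        object.__setattr__(self, "_counts", {s: n for s, n in merged.items() if n > 0})

    @classmethod
    def from_string(cls, hill: str) -> "ElementalFormula":
        return cls(hill)

    # Mapping protocol ----------------------------------------------------
    def __getitem__(self, sym: str) -> int:
        return self._counts[sym]

    def get(self, sym: str, default: int = 0) -> int:
        return self._counts.get(sym, default)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    # arithmetic ----------------------------------------------------------
    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = dict(self._counts)
        for s, n in other.items():
            out[s] = out.get(s, 0) + n
        return ElementalFormula(out)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = dict(self._counts)
        for s, n in other.items():
            out[s] = out.get(s, 0) - n
            if out[s] < 0:
                raise ValueError(f"subtraction yields negative {s} count")
        return ElementalFormula(out)

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int) or k < 0:
            raise ValueError("formula multiplier must be a non-negative integer")
        return ElementalFormula({s: n * k for s, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalFormula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    @property
    def monoisotopic_mass(self) -> float:
        return sum(ELEMENT_MASSES[s] * n for s, n in self._counts.items())

    @property
    def atom_count(self) -> int:
        return sum(self._counts.values())

    def hill(self) -> str:
        """Hill notation: C first, H second, remaining symbols alphabetical."""
        parts = []
        for sym in ["C", "H"] + sorted(set(self._counts) - {"C", "H"}):
            n = self._counts.get(sym, 0)
            if n:
                parts.append(sym + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill()!r})"


def _parse_hill(s: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(s):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula string {s!r} at position {pos}")
        pos = m.end()
        sym, digits = m.group(1), m.group(2)
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
    if pos != len(s):
        raise ValueError(f"cannot parse formula string {s!r} at position {pos}")
    return counts


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic mass in Da; the empty formula has mass 0.0."""
    if isinstance(formula, str):
        formula = ElementalFormula(formula)
    return formula.monoisotopic_mass


@dataclass(frozen=True)
class MassTolerance:
    """Symmetric mass-match tolerance in ppm (relative) or mDa (absolute)."""

    mode: str
    value: float

    def __post_init__(self) -> None:
        if self.mode not in ("ppm", "mDa"):
            raise ValueError(f"tolerance mode must be 'ppm' or 'mDa', got {self.mode!r}")
        if not self.value > 0:
            raise ValueError("tolerance value must be positive")

    def window_da(self, reference: float) -> float:
        """Half-width of the acceptance window around ``reference``, in Da."""
        if self.mode == "ppm":
            return self.value * reference * 1e-6
        return self.value * 1e-3

    def matches(self, a: float, b: float) -> bool:
        """True when |a - b| is within the window anchored at ``a``."""
        return abs(a - b) <= self.window_da(a)


@dataclass(frozen=True)
class AdductSpec:
    """Electrospray adduct: m/z = (multiplicity * M + delta) / charge."""

    name: str
    multiplicity: int
    delta_formula: ElementalFormula
    charge: int = 1

    def __post_init__(self) -> None:
        if self.multiplicity < 1 or self.charge < 1:
            raise ValueError("multiplicity and charge must be positive integers")


def _load_adducts() -> dict[str, AdductSpec]:
    registry = {}
    for name, mult, delta, charge in _load_kv_table("adducts.tsv"):
        registry[name] = AdductSpec(
            name=name,
            multiplicity=int(mult),
            delta_formula=ElementalFormula(delta) if delta else ElementalFormula(),
            charge=int(charge),
        )
    return registry


ADDUCT_REGISTRY: dict[str, AdductSpec] = _load_adducts()


def get_adduct(name: str) -> AdductSpec:
    try:
        return ADDUCT_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown adduct {name!r}; registered adducts: "
            + ", ".join(sorted(ADDUCT_REGISTRY))
        ) from None


def adduct_mz(
    formula: ElementalFormula | str,
    adduct: AdductSpec | str = "[M+H]+",
    electron_correction: bool = False,
) -> float:
    """m/z of ``formula`` under ``adduct``.

    The default (``electron_correction=False``) is the hydrogen-atom
    convention that reproduces TOF vendor "calculated" values; setting the
    flag subtracts one electron mass per positive charge.
    """
    if isinstance(formula, str):
        formula = ElementalFormula(formula)
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    mz = (
        adduct.multiplicity * formula.monoisotopic_mass
        + adduct.delta_formula.monoisotopic_mass
    ) / adduct.charge
    if electron_correction:
        mz -= ELECTRON_MASS
    return mz


def ppm_error(observed: float, calculated: float) -> float:
    """Signed relative mass error, (observed - calculated)/calculated * 1e6."""
    if calculated <= 0:
        raise ValueError("calculated m/z must be positive")
    return (observed - calculated) / calculated * 1e6


def rdbe(formula: ElementalFormula | str) -> float:
    """Ring-plus-double-bond equivalents, (2C + 2 + N - H)/2; O/Na/K ignored."""
    if isinstance(formula, str):
        formula = ElementalFormula(formula)
    return (2 * formula.get("C") + 2 + formula.get("N") - formula.get("H")) / 2


@dataclass(frozen=True)
class FormulaCandidate:
    formula: ElementalFormula
    mz: float
    ppm: float
    rdbe: float


_SEARCH_ELEMENTS = ("C", "H", "N", "O")


def _normalize_bounds(bounds: Mapping[str, tuple[int, int] | int]) -> dict[str, tuple[int, int]]:
    norm: dict[str, tuple[int, int]] = {}
    for sym, b in bounds.items():
        if sym not in _SEARCH_ELEMENTS:
            raise ValueError(
                f"formula search is restricted to CHNO; {sym!r} is allowed only "
                "as an adduct delta"
            )
        lo, hi = (0, b) if isinstance(b, int) else b
        if hi < lo or lo < 0:
            raise ValueError(f"invalid bounds for {sym}: {(lo, hi)}")
        norm[sym] = (lo, hi)
    for sym in _SEARCH_ELEMENTS:
        norm.setdefault(sym, (0, 0))
    return norm


def enumerate_formulas(
    target: float,
    adduct: AdductSpec | str,
    tol: MassTolerance,
    bounds: Mapping[str, tuple[int, int] | int],
    rdbe_range: tuple[float, float] = (0.0, 25.0),
    require_integer_rdbe: bool = True,
) -> list[FormulaCandidate]:
    """All CHNO compositions whose adduct m/z matches ``target`` under ``tol``.

    Candidates are additionally filtered to a plausibility window on RDBE
    (integer-valued by default, as expected for even-electron protonated
    molecules) and ranked by |ppm error|, then total atom count, then Hill
    string.  The search is exhaustive over the bounded composition lattice:
    for each (C, N, O) cell the admissible H counts are solved directly from
    the mass window, so the result equals a brute-force nested loop.
    """
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    b = _normalize_bounds(bounds)
    w = tol.window_da(target)  # Da window on the adduct m/z
    delta = adduct.delta_formula.monoisotopic_mass
    # neutral-mass window implied by |adduct_mz - target| <= w
    lo = (target * adduct.charge - delta - w * adduct.charge) / adduct.multiplicity
    hi = (target * adduct.charge - delta + w * adduct.charge) / adduct.multiplicity
    if hi < 0:
        return []
    mC, mH, mN, mO = (ELEMENT_MASSES[s] for s in ("C", "H", "N", "O"))
    out = []
    for c in range(b["C"][0], b["C"][1] + 1):
        base_c = c * mC
        if base_c > hi:
            break
        for n in range(b["N"][0], b["N"][1] + 1):
            base_cn = base_c + n * mN
            if base_cn > hi:
                break
            for o in range(b["O"][0], b["O"][1] + 1):
                base = base_cn + o * mO
                if base > hi:
                    break
                h_lo = max(b["H"][0], int(-(-(lo - base) // mH)) if lo > base else 0)
                h_hi = int((hi - base) // mH)
                for h in range(h_lo, min(h_hi, b["H"][1]) + 1):
                    mass = base + h * mH
                    if mass < lo or mass > hi:
                        continue
                    r = (2 * c + 2 + n - h) / 2
                    if not (rdbe_range[0] <= r <= rdbe_range[1]):
                        continue
                    if require_integer_rdbe and r != int(r):
                        continue
                    f = ElementalFormula(C=c, H=h, N=n, O=o)
                    if f.atom_count == 0:
                        continue
                    mz = adduct_mz(f, adduct)
                    out.append(FormulaCandidate(f, mz, ppm_error(target, mz), r))
    out.sort(key=lambda fc: (abs(fc.ppm), fc.formula.atom_count, fc.formula.hill()))
    return out
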