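"""Neutral-loss annotation and fingerprint classification of composite spectra.

The spectra handled here are in-source-fragmentation TOF full scans acquired
at a hot cone voltage: the protonated molecule and its fragment/adduct ions
co-occur in one peak-apex spectrum, so annotation works on mass *differences*
(precursor-to-fragment and fragment-to-fragment) rather than on isolated
MS/MS scans.

Losses are explained by a small composite vocabulary — up to four waters plus
at most one of {CH2, CO, CH3, 2xCH3, glucosyl, glucuronyl, CH2O} — matched at
two tiers: an *exact* tier on the monoisotopic loss mass (default 15 mDa) and
a *nominal* fallback on the integer-rounded loss (default +-0.3 Da).  The
nominal tier exists because published ion tables are not always internally
consistent at exact-mass level; it lets the classifier reproduce row-level
annotations without silently editing printed data.

Class calls follow a fixed precedence of fingerprints (bis-diterpene >
diterpene glucoside > diterpene monomer > flavone aglycone > flavone
O-glycoside), each leaving an evidence trail of the matched edges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Optional, Sequence

import yaml

from .masscalc import MassTolerance

CLASS_LABELS = (
    "diterpene_monomer",
    "diterpene_glucoside",
    "bis_diterpene",
    "flavone_aglycone",
    "flavone_O_glycoside",
    "unknown",
)

#: Monoisotopic masses of the neutral-loss units (Da).
LOSS_MASSES = {
    "H2O": 18.010565,
    "CH2": 14.015650,
    "CO": 27.994915,
    "CH3": 15.023475,
    "Glc": 162.052824,
    "GlcA": 176.032088,
    "CH2O": 30.010565,
}

#: Nominal-tier tie-break order for the non-water unit (earlier wins).
#: CH2O last: a formaldehyde call is the least informative reading of a
#: nominal-30 loss, which more often is a double methyl loss.
_UNIT_PREFERENCE = ["Glc", "CO", "CH3", ("CH3", 2), "CH2", "GlcA", "CH2O"]


@dataclass(frozen=True)
class LossComposition:
    """Composite neutral loss as unit counts; mass is the weighted sum."""

    n_H2O: int = 0
    n_CH2: int = 0
    n_CO: int = 0
    n_CH3: int = 0
    n_Glc: int = 0
    n_GlcA: int = 0
    n_CH2O: int = 0

    def __post_init__(self) -> None:
        counts = self.counts()
        if any(n < 0 for n in counts.values()):
            raise ValueError("loss counts must be non-negative")
        if not any(counts.values()):
            raise ValueError("a loss composition must contain at least one unit")

    def counts(self) -> dict[str, int]:
        return {u: getattr(self, f"n_{u}") for u in LOSS_MASSES}

    @property
    def mass(self) -> float:
        return sum(LOSS_MASSES[u] * n for u, n in self.counts().items())

    @property
    def nominal_mass(self) -> int:
        return round(self.mass)

    @property
    def sugar_count(self) -> int:
        return self.n_Glc + self.n_GlcA

    def label(self) -> str:
        parts = []
        for u, n in self.counts().items():
            if n == 1:
                parts.append(u)
            elif n > 1:
                parts.append(f"{n}{u}")
        return "+".join(parts)

    def __str__(self) -> str:
        return self.label()


def default_loss_vocabulary(max_water: int = 4) -> list[LossComposition]:
    """0..max_water waters plus at most one non-water unit (2xCH3 allowed)."""
    vocab = []
    units: list[Optional[tuple[str, int]]] = [None] + [
        u if isinstance(u, tuple) else (u, 1) for u in _UNIT_PREFERENCE
    ]
    for w in range(max_water + 1):
        for unit in units:
            kw = {"n_H2O": w}
            if unit is not None:
                kw[f"n_{unit[0]}"] = unit[1]
            if w == 0 and unit is None:
                continue
            vocab.append(LossComposition(**kw))
    return vocab


@dataclass(frozen=True)
class FragmentSpectrum:
    """Composite full-scan spectrum of one chromatographic compound."""

    compound_id: str
    precursor_mz: float
    retention_time: float
    peaks: tuple[tuple[float, float], ...]
    ion_labels: Optional[tuple[Optional[str], ...]] = None

    def __init__(
        self,
        compound_id: str,
        precursor_mz: float,
        retention_time: float,
        peaks: Sequence[tuple[float, float]],
        ion_labels: Optional[Sequence[Optional[str]]] = None,
    ):
        if any(i < 0 for _, i in peaks):
            raise ValueError("peak intensities must be non-negative")
        order = sorted(range(len(peaks)), key=lambda k: peaks[k][0])
        object.__setattr__(
            self, "peaks", tuple((float(peaks[k][0]), float(peaks[k][1])) for k in order)
        )
        if ion_labels is not None:
            if len(ion_labels) != len(peaks):
                raise ValueError("ion_labels must align with peaks")
            object.__setattr__(self, "ion_labels", tuple(ion_labels[k] for k in order))
        else:
            object.__setattr__(self, "ion_labels", None)
        object.__setattr__(self, "compound_id", str(compound_id))
        object.__setattr__(self, "precursor_mz", float(precursor_mz))
        object.__setattr__(self, "retention_time", float(retention_time))

    @property
    def mz(self) -> tuple[float, ...]:
        return tuple(m for m, _ in self.peaks)


@dataclass(frozen=True)
class LossEdge:
    """One explained mass difference between two ions of a spectrum."""

    from_mz: float
    to_mz: float
    composition: LossComposition
    tier: str  # "exact" | "nominal"
    mass_error_mda: float  # observed delta minus monoisotopic loss mass, mDa

    def __post_init__(self) -> None:
        if self.from_mz <= self.to_mz:
            raise ValueError("a loss edge must run from the heavier to the lighter ion")
        if self.tier not in ("exact", "nominal"):
            raise ValueError(f"unknown tier {self.tier!r}")


@dataclass(frozen=True)
class ClassCall:
    compound_id: str
    class_label: str
    evidence: tuple[str, ...] = ()
    aglycone_mz: Optional[float] = None
    sugar_residue: str = "none"  # hexosyl | glucuronyl | none

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class {self.class_label!r}")
        if self.class_label != "unknown" and not self.evidence:
            raise ValueError("a non-unknown class call requires evidence")


def load_rules(path: Optional[str] = None) -> dict[str, Any]:
    """Load the rule configuration (packaged default when ``path`` is None)."""
    if path is None:
        text = resources.files("andromass.data").joinpath("rules.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rules = yaml.safe_load(text)
    _check_rules(rules)
    return rules


def _check_rules(rules: Any) -> None:
    if not isinstance(rules, dict):
        raise ValueError("rule configuration must be a mapping")
    for key in ("tolerances", "precedence", "flavone_O_glycoside", "residues"):
        if key not in rules:
            raise ValueError(f"rule configuration missing section {key!r}")
    unknown = set(rules["precedence"]) - set(CLASS_LABELS)
    if unknown:
        raise ValueError(f"precedence lists unknown classes: {sorted(unknown)}")


_DEFAULT_RULES: Optional[dict[str, Any]] = None


def default_rules() -> dict[str, Any]:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_rules()
    return _DEFAULT_RULES


def _best_composition(
    delta: float,
    vocab: Sequence[LossComposition],
    tol_exact: MassTolerance,
    tol_nominal: MassTolerance,
) -> Optional[tuple[LossComposition, str, float]]:
    """Best explanation of a mass difference, exact tier first."""
    w_exact = tol_exact.window_da(delta)
    w_nominal = tol_nominal.window_da(delta)
    exact = [
        (abs(delta - c.mass), i, c)
        for i, c in enumerate(vocab)
        if abs(delta - c.mass) <= w_exact
    ]
    if exact:
        err, _, comp = min(exact)
        return comp, "exact", (delta - comp.mass) * 1e3
    nominal = [
        (abs(delta - c.nominal_mass), i, c)
        for i, c in enumerate(vocab)
        if abs(delta - c.nominal_mass) <= w_nominal
    ]
    if nominal:
        _, _, comp = min(nominal)  # ties broken by vocabulary preference order
        return comp, "nominal", (delta - comp.mass) * 1e3
    return None


def annotate_losses(
    spec: FragmentSpectrum,
    tol_exact: MassTolerance = MassTolerance("mDa", 15.0),
    tol_nominal: MassTolerance = MassTolerance("mDa", 300.0),
    vocab: Optional[Sequence[LossComposition]] = None,
) -> list[LossEdge]:
    """Explain precursor->fragment and fragment->fragment mass differences.

    Ions above the precursor (sodiated/dimeric adducts) are not loss
    products and are excluded from the edge graph.  At most one edge — the
    best-matching composition, exact tier preferred — is emitted per ion
    pair; unexplained differences simply yield no edge.
    """
    if vocab is None:
        vocab = default_loss_vocabulary()
    max_loss = max(c.mass for c in vocab) + 0.5
    min_loss = min(c.mass for c in vocab) - 0.5
    products = [m for m in spec.mz if m < spec.precursor_mz - 0.5]
    edges = []
    pairs = [(spec.precursor_mz, f) for f in products]
    pairs += [(a, b) for a, b in itertools.combinations(sorted(products, reverse=True), 2)]
    for hi, lo in pairs:
        delta = hi - lo
        if not (min_loss <= delta <= max_loss):
            continue
        hit = _best_composition(delta, vocab, tol_exact, tol_nominal)
        if hit is not None:
            comp, tier, err = hit
            edges.append(LossEdge(hi, lo, comp, tier, err))
    return edges


def water_chain_length(
    edges: Sequence[LossEdge], precursor_mz: Optional[float] = None
) -> int:
    """Longest consecutive pure-water loss chain anchored at the precursor."""
    if not edges:
        return 0
    if precursor_mz is None:
        precursor_mz = max(e.from_mz for e in edges)
    waters = {
        e.composition.n_H2O
        for e in edges
        if e.from_mz == precursor_mz
        and e.composition.n_H2O > 0
        and sum(e.composition.counts().values()) == e.composition.n_H2O
    }
    n = 0
    while (n + 1) in waters:
        n += 1
    return n


def aglycone_residue(
    precursor_mz: float,
    aglycone_mz: float,
    tol: MassTolerance = MassTolerance("mDa", 15.0),
    residues: Optional[dict[str, float]] = None,
) -> str:
    """Sugar residue implied by the precursor-aglycone mass difference."""
    if precursor_mz <= aglycone_mz:
        raise ValueError("precursor m/z must exceed aglycone m/z")
    if residues is None:
        residues = {"hexosyl": LOSS_MASSES["Glc"], "glucuronyl": LOSS_MASSES["GlcA"]}
    delta = precursor_mz - aglycone_mz
    hits = [
        (abs(delta - mass), name)
        for name, mass in residues.items()
        if abs(delta - mass) <= tol.window_da(delta)
    ]
    return min(hits)[1] if hits else "none"


def _precursor_edges(edges: Sequence[LossEdge], precursor_mz: float) -> list[LossEdge]:
    return [e for e in edges if e.from_mz == precursor_mz]


def classify_compound(
    spec: FragmentSpectrum,
    edges: Sequence[LossEdge],
    rules: Optional[dict[str, Any]] = None,
) -> ClassCall:
    """Apply the class fingerprints in precedence order; first match wins."""
    if rules is None:
        rules = default_rules()
    else:
        _check_rules(rules)
    tol_exact = MassTolerance("mDa", float(rules["tolerances"]["exact_mda"]))
    residues = {k: float(v) for k, v in rules["residues"].items()}
    matchers = {
        "bis_diterpene": _match_bis,
        "diterpene_glucoside": _match_glucoside,
        "diterpene_monomer": _match_monomer,
        "flavone_aglycone": _match_flavone_aglycone,
        "flavone_O_glycoside": _match_flavone_glycoside,
    }
    for label in rules["precedence"]:
        hit = matchers[label](spec, edges, rules.get(label, {}))
        if hit is None:
            continue
        evidence, aglycone = hit
        residue = "none"
        if aglycone is not None and spec.precursor_mz > aglycone:
            residue = aglycone_residue(spec.precursor_mz, aglycone, tol_exact, residues)
        return ClassCall(spec.compound_id, label, tuple(evidence), aglycone, residue)
    return ClassCall(spec.compound_id, "unknown")


def _fmt_edge(e: LossEdge) -> str:
    return (
        f"{e.from_mz:.4f}->{e.to_mz:.4f} -{e.composition.label()} "
        f"[{e.tier}, {e.mass_error_mda:+.1f} mDa]"
    )


def _match_bis(spec, edges, cfg):
    """Dimer: heavy precursor, a >=3-water loss chain, a monomer fragment."""
    if spec.precursor_mz <= float(cfg.get("min_precursor_mz", 600.0)):
        return None
    min_w = int(cfg.get("min_water_count", 3))
    anchors = [float(x) for x in cfg.get("monomer_fragments", (297.18, 269.18))]
    a_tol = float(cfg.get("monomer_tol_da", 0.05))
    water_edges = [
        e for e in _precursor_edges(edges, spec.precursor_mz)
        if e.composition.n_H2O >= min_w and e.composition.sugar_count == 0
    ]
    monomer_hits = [
        m for m in spec.mz if any(abs(m - a) <= a_tol for a in anchors)
    ]
    if water_edges and monomer_hits:
        ev = [_fmt_edge(e) for e in water_edges]
        ev += [f"monomer fragment {m:.4f}" for m in monomer_hits]
        return ev, None
    return None


def _match_glucoside(spec, edges, cfg):
    """Exact glucosyl loss off the precursor, waters off the aglycone."""
    require_exact = bool(cfg.get("require_exact_glc", True))
    for e in _precursor_edges(edges, spec.precursor_mz):
        c = e.composition
        if c.n_Glc == 1 and c.n_H2O == 0 and sum(c.counts().values()) == 1:
            if require_exact and e.tier != "exact":
                continue
            aglycone = e.to_mz
            followups = [
                f for f in edges
                if (f.from_mz == aglycone and f.composition.n_H2O >= 1)
                or (f.from_mz == spec.precursor_mz
                    and f.composition.n_Glc == 1 and f.composition.n_H2O >= 1)
            ]
            if followups:
                return [_fmt_edge(e)] + [_fmt_edge(f) for f in followups], aglycone
    return None


def _match_monomer(spec, edges, cfg):
    """Polyhydroxylated monomer: any sugar-free edge carrying >=2 waters."""
    min_w = int(cfg.get("min_water_count", 2))
    hits = [
        e for e in edges
        if e.composition.n_H2O >= min_w and e.composition.sugar_count == 0
    ]
    if hits:
        return [_fmt_edge(e) for e in hits], None
    return None


def _match_flavone_aglycone(spec, edges, cfg):
    """Methyl (exact) or CO (either tier) loss from a light precursor."""
    if spec.precursor_mz >= float(cfg.get("max_precursor_mz", 400.0)):
        return None
    hits = []
    for e in edges:
        c = e.composition
        if c.n_H2O or c.sugar_count or c.n_CH2 or c.n_CH2O:
            continue
        if c.n_CH3 in (1, 2) and c.n_CO == 0 and e.tier == "exact":
            hits.append(e)
        elif c.n_CO == 1 and c.n_CH3 == 0:
            hits.append(e)
    if hits:
        return [_fmt_edge(e) for e in hits], None
    return None


def _match_flavone_glycoside(spec, edges, cfg):
    """A fragment in the flavone-aglycone window, tight tier then loose."""
    windows = [float(w) for w in cfg.get("aglycone_windows", ())]
    for tol, tag in (
        (float(cfg.get("window_tol_da", 0.010)), "tight"),
        (float(cfg.get("loose_tol_da", 0.1)), "loose"),
    ):
        for m in spec.mz:
            if m >= spec.precursor_mz - 0.5:
                continue
            for w in windows:
                if abs(m - w) <= tol:
                    ev = [f"aglycone-window fragment {m:.4f} ~ {w:.3f} ({tag} tier)"]
                    return ev, m
    return None
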