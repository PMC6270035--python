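"""Seeded generators for fixtures and full synthetic LC-TOF runs.

Two kinds of synthetic input are produced:

* :func:`table1_fixture` — the fifteen published composite ion tables for the
  *Andrographis paniculata* constituents, verbatim (printed m/z values,
  including their internal inconsistencies, with uniform nominal
  intensities).  These drive the annotation tests and the worked examples.

* :func:`generate_run` — full centroided MS1 runs with Gaussian
  chromatographic elution, in-source composite spectra (precursor plus
  diagnostic fragment/adduct ions at exact calculated masses), Gaussian
  ppm-scale mass noise, multiplicative intensity noise, a chemical baseline
  on every analyte ion channel, an optional systematic mass-axis bias
  (applied before noise so lock-mass correction is testable) and a
  continuously present lock-mass ion.  A ground-truth table accompanies
  every run.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .annotate import LOSS_MASSES, FragmentSpectrum, LossComposition
from .chrom import LOCK_MASS_MZ, Scan, ScanSeries
from .masscalc import ElementalFormula, adduct_mz

# --------------------------------------------------------------------------
# Published ion tables: 15 compounds, printed m/z values verbatim.
# Compositions are the named compounds' literature identities (the published
# table prints calculated m/z but not formulas); None marks unknowns.
# Compound 9's composition is tentative (hydroxylated congener of 13).
# --------------------------------------------------------------------------

_T1 = [
    dict(id="1", rt=2.33, type="Flavone", name="Unknown", formula=None, calc=None,
         ions=[("[M+H]+", 463.3319), ("[M+H-H2O]+", 445.3206),
               ("[Aglycone+H]+", 287.0592)]),
    dict(id="2", rt=3.28, type="Flavone", name="Apigenin-7-O-beta-D-glucuronide",
         formula="C21H18O11", calc=447.0927,
         ions=[("[M+H]+", 447.0887), ("[2M+H]+", 893.1624),
               ("[Aglycone+H]+", 271.0568)]),
    dict(id="3", rt=3.49, type="Flavone",
         name="5,4'-dihydroxy-7-methoxy-8-O-beta-D-glucopyranosyl-flavone",
         formula="C22H22O11", calc=463.1240,
         ions=[("[M+H]+", 463.1211), ("[M+H-H2O]+", 445.3185),
               ("[Aglycone+H]+", 301.0673)]),
    dict(id="4", rt=4.67, type="Flavone", name="5,4'-dihydroxy-7,8-dimethoxyflavone",
         formula="C17H14O6", calc=315.0869,
         ions=[("[M+H]+", 315.0859), ("[M+H-CO]+", 287.1990),
               ("[M+H-2CH3]+", 285.1879), ("[M+H-CH3]+", 300.0630),
               ("fragment", 287.2906), ("fragment", 197.0449),
               ("fragment", 153.0941)]),
    dict(id="5", rt=4.89, type="Diterpene", name="14-deoxyandrographiside",
         formula="C26H40O9", calc=497.2751,
         ions=[("[M+H]+", 497.2740), ("[M+H-Glc]+", 335.2223),
               ("[M+H-Glc-H2O]+", 317.2087), ("[M+H-Glc-2H2O]+", 299.1959),
               ("fragment", 287.1954), ("fragment", 259.1660),
               ("[M+Na]+", 519.2543), ("[2M+H]+", 993.5358)]),
    dict(id="6", rt=5.11, type="Diterpene", name="Andrographolide",
         formula="C20H30O5", calc=351.2171,
         ions=[("[M+H]+", 351.2164), ("[M+H-H2O]+", 333.2063),
               ("[M+H-2H2O]+", 315.1929), ("[M+H-3H2O]+", 297.1798),
               ("fragment", 285.1804), ("fragment", 257.1501),
               ("[2M+H]+", 701.4224)]),
    dict(id="7", rt=5.40, type="Diterpene", name="Isoandrographolide",
         formula="C20H30O5", calc=351.2171,
         ions=[("[M+H]+", 351.2173), ("[M+H-H2O]+", 333.2065),
               ("[M+H-2H2O]+", 315.1954), ("[M+H-3H2O]+", 297.1828),
               ("fragment", 285.1847), ("fragment", 257.1558),
               ("[2M+H]+", 701.4210)]),
    dict(id="8", rt=6.30, type="Diterpene", name="Neoandrographolide",
         formula="C26H40O8", calc=481.2801,
         ions=[("[M+H]+", 481.2825), ("[M+H-Glc]+", 319.2288),
               ("[M+H-Glc-H2O]+", 301.2125), ("fragment", 289.2166),
               ("fragment", 261.1866), ("[M+Na]+", 503.2672),
               ("[M+NH4]+", 498.3100), ("[2M+H]+", 961.5472)]),
    dict(id="9", rt=6.60, type="Diterpene", name="Unknown", formula="C21H30O6",
         calc=None,
         ions=[("[M+H]+", 379.2119), ("[M+Na]+", 401.1998), ("[M+K]+", 417.1768),
               ("[M+H-H2O]+", 361.2029), ("[M+H-2H2O]+", 343.1904),
               ("[M+H-2H2O-CH2]+", 329.1776), ("[M+H-3H2O-CH2]+", 311.1636),
               ("fragment", 283.1701), ("fragment", 257.1414),
               ("[2M+H]+", 757.4134)]),
    dict(id="10", rt=7.44, type="Diterpene", name="14-deoxyandrographolide",
         formula="C20H30O4", calc=335.2222,
         ions=[("[M+H]+", 335.2202), ("[M+Na]+", 357.2104),
               ("[M+H-H2O]+", 317.2092), ("[M+H-2H2O]+", 299.1965),
               ("fragment", 287.1896), ("fragment", 259.1652),
               ("[2M+H]+", 669.4372)]),
    dict(id="11", rt=7.57, type="Diterpene", name="Dehydroandrographolide",
         formula="C20H28O4", calc=333.2066,
         ions=[("[M+H]+", 333.2075), ("[M+H-H2O]+", 315.1942),
               ("[M+H-2H2O]+", 297.1787), ("fragment", 285.1805),
               ("fragment", 257.1506), ("[2M+H]+", 665.4048)]),
    dict(id="12", rt=7.83, type="Diterpene", name="Unknown (bis-diterpene)",
         formula=None, calc=None,
         ions=[("[M+H]+", 681.3962), ("[M+Na]+", 703.3758),
               ("[M+H-H2O]+", 663.3945), ("[M+H-2H2O]+", 645.3752),
               ("[M+H-3H2O]+", 627.3672), ("[M+H-4H2O]+", 609.3548),
               ("fragment", 297.1833), ("fragment", 269.1812)]),
    dict(id="13", rt=8.48, type="Diterpene",
         name="3,19-dihydroxy-15-methoxy-ent-labda-8(17),11,13-trien-16,15-olide",
         formula="C21H30O5", calc=363.2171,
         ions=[("[M+H]+", 363.2169), ("[M+Na]+", 385.1991),
               ("[M+H-H2O]+", 345.2104), ("[M+H-2H2O]+", 327.1988),
               ("[M+H-2H2O-CH2]+", 313.1779), ("[M+H-3H2O-CH2]+", 295.1685),
               ("fragment", 283.1694), ("fragment", 255.1414),
               ("[2M+H]+", 725.4254)]),
    dict(id="14", rt=8.80, type="Flavone", name="Dihydroxydimethoxyflavone",
         formula="C17H14O6", calc=315.0869,
         ions=[("[M+H]+", 315.0829), ("[M+H-CO]+", 287.1985),
               ("[M+H-CH3]+", 300.0635), ("fragment", 271.0628),
               ("fragment", 197.0524)]),
    dict(id="15", rt=8.98, type="Diterpene", name="Unknown (bis-diterpene)",
         formula=None, calc=None,
         ions=[("[M+H]+", 697.4302), ("[M+Na]+", 719.4150),
               ("[M+H-3H2O-CH2]+", 629.3845), ("[M+H-4H2O-CH2]+", 611.3734),
               ("[M+H-4H2O-CH2-C]+", 599.3704), ("fragment", 297.1829),
               ("fragment", 255.1491)]),
]

#: Per-compound registry: published retention time, family ("Diterpene" /
#: "Flavone"), identification, literature composition and printed calculated
#: protonated-molecule m/z (None where the table prints no value).
TABLE1_COMPOUNDS: dict[str, dict] = {row["id"]: row for row in _T1}

_FIXTURE_INTENSITY = 100.0


def table1_fixture() -> list[FragmentSpectrum]:
    """The 15 published composite spectra, verbatim, uniform intensities."""
    out = []
    for row in _T1:
        labels = [lab for lab, _ in row["ions"]]
        mzs = [mz for _, mz in row["ions"]]
        out.append(
            FragmentSpectrum(
                compound_id=row["id"],
                precursor_mz=mzs[labels.index("[M+H]+")],
                retention_time=row["rt"],
                peaks=[(m, _FIXTURE_INTENSITY) for m in mzs],
                ion_labels=labels,
            )
        )
    return out


# --------------------------------------------------------------------------
# Templates and run generation
# --------------------------------------------------------------------------

IonSpec = tuple[str, Union[LossComposition, str, float, None], float]


@dataclass(frozen=True)
class CompoundTemplate:
    """Recipe for one compound's composite in-source spectrum.

    ``diagnostic_ions`` entries are ``(kind, value, relative_intensity)``
    with kind one of ``"loss"`` (a :class:`LossComposition` below the
    protonated molecule), ``"adduct"`` (a registered adduct name) or
    ``"mz"`` (an absolute m/z, for fragments whose composition is not
    modelled).  The protonated molecule itself is always emitted at
    relative intensity 1.
    """

    id: str
    formula: ElementalFormula
    class_label: str
    retention_time: float
    diagnostic_ions: tuple[IonSpec, ...]
    base_intensity: float = 1000.0

    @property
    def precursor_mz(self) -> float:
        return adduct_mz(self.formula, "[M+H]+")

    def ion_table(self) -> list[tuple[str, float, float]]:
        """(label, exact m/z, relative intensity) for every emitted ion."""
        ions = [("[M+H]+", self.precursor_mz, 1.0)]
        for kind, value, rel in self.diagnostic_ions:
            if kind == "loss":
                ions.append((f"-{value.label()}", self.precursor_mz - value.mass, rel))
            elif kind == "adduct":
                ions.append((value, adduct_mz(self.formula, value), rel))
            elif kind == "mz":
                ions.append((f"m/z {value:.4f}", float(value), rel))
            else:
                raise ValueError(f"unknown ion kind {kind!r}")
        return ions


def validate_template(template: CompoundTemplate) -> None:
    """Check that a template's ions are consistent with its declared class."""
    losses = [v for k, v, _ in template.diagnostic_ions if k == "loss"]
    frag_mz = [v for k, v, _ in template.diagnostic_ions if k == "mz"]
    label = template.class_label
    ok = True
    if label == "diterpene_monomer":
        ok = any(c.n_H2O >= 2 and c.sugar_count == 0 for c in losses)
    elif label == "diterpene_glucoside":
        ok = any(c.n_Glc == 1 and c.n_H2O == 0 for c in losses) and any(
            c.n_Glc == 1 and c.n_H2O >= 1 for c in losses
        )
    elif label == "bis_diterpene":
        ok = template.precursor_mz > 600 and any(c.n_H2O >= 3 for c in losses) and any(
            abs(m - a) <= 0.05 for m in frag_mz for a in (297.18, 269.18)
        )
    elif label == "flavone_aglycone":
        ok = template.precursor_mz < 400 and any(
            (c.n_CH3 in (1, 2) or c.n_CO == 1) and c.n_H2O == 0 for c in losses
        )
    elif label == "flavone_O_glycoside":
        aglycones = [template.precursor_mz - c.mass for c in losses if c.sugar_count]
        ok = any(
            abs(m - w) <= 0.01
            for m in aglycones + frag_mz
            for w in (271.060, 287.055, 301.071, 315.087)
        )
    if not ok:
        raise ValueError(
            f"template {template.id!r} ions are inconsistent with class {label!r}"
        )


def default_templates() -> list[CompoundTemplate]:
    """One realistic template per compound class, built on the three marker
    substances plus a flavone aglycone, a flavone glucuronide and a
    bis-diterpene congener."""
    W = lambda n: LossComposition(n_H2O=n)  # noqa: E731
    return [
        CompoundTemplate(
            id="andrographolide", formula=ElementalFormula("C20H30O5"),
            class_label="diterpene_monomer", retention_time=5.11,
            diagnostic_ions=(
                ("loss", W(1), 0.35), ("loss", W(2), 0.45), ("loss", W(3), 0.85),
            ),
        ),
        CompoundTemplate(
            id="neoandrographolide", formula=ElementalFormula("C26H40O8"),
            class_label="diterpene_glucoside", retention_time=6.30,
            diagnostic_ions=(
                ("loss", LossComposition(n_Glc=1), 0.85),
                ("loss", LossComposition(n_Glc=1, n_H2O=1), 0.40),
            ),
        ),
        CompoundTemplate(
            id="dehydroandrographolide", formula=ElementalFormula("C20H28O4"),
            class_label="diterpene_monomer", retention_time=7.57,
            diagnostic_ions=(("loss", W(1), 0.40), ("loss", W(2), 0.90)),
        ),
        CompoundTemplate(
            id="bis-diterpene", formula=ElementalFormula("C40H56O9"),
            class_label="bis_diterpene", retention_time=7.83,
            diagnostic_ions=(
                ("loss", W(1), 0.50), ("loss", W(2), 0.45),
                ("loss", W(3), 0.40), ("loss", W(4), 0.35),
                ("mz", 297.1833, 0.60), ("mz", 269.1812, 0.30),
            ),
        ),
        CompoundTemplate(
            id="dihydroxydimethoxyflavone", formula=ElementalFormula("C17H14O6"),
            class_label="flavone_aglycone", retention_time=4.67,
            diagnostic_ions=(
                ("loss", LossComposition(n_CH3=1), 0.60),
                ("loss", LossComposition(n_CH3=2), 0.30),
                ("loss", LossComposition(n_CO=1), 0.45),
            ),
        ),
        CompoundTemplate(
            id="apigenin-glucuronide", formula=ElementalFormula("C21H18O11"),
            class_label="flavone_O_glycoside", retention_time=3.28,
            diagnostic_ions=(("loss", LossComposition(n_GlcA=1), 0.80),),
        ),
    ]


def marker_templates() -> list[CompoundTemplate]:
    """The three quantified marker substances only."""
    keep = {"andrographolide", "neoandrographolide", "dehydroandrographolide"}
    return [t for t in default_templates() if t.id in keep]


def generate_spectrum(
    template: CompoundTemplate,
    concentration: float = 1.0,
    mass_noise_ppm: float = 0.0,
    intensity_cv: float = 0.0,
    seed: int | None = 0,
    rng: Optional[np.random.Generator] = None,
) -> FragmentSpectrum:
    """One composite spectrum from a template, with seeded Gaussian ppm mass
    noise and multiplicative intensity noise.  Zero-noise output reproduces
    the exact-mass calculus values."""
    validate_template(template)
    if rng is None:
        rng = np.random.default_rng(seed)
    peaks, labels = [], []
    for label, mz, rel in template.ion_table():
        mz_obs = mz * (1.0 + rng.normal(0.0, mass_noise_ppm) * 1e-6)
        inten = template.base_intensity * concentration * rel
        inten = max(inten * (1.0 + rng.normal(0.0, intensity_cv)), 0.0)
        peaks.append((mz_obs, inten))
        labels.append(label)
    return FragmentSpectrum(
        compound_id=template.id,
        precursor_mz=peaks[0][0],
        retention_time=template.retention_time,
        peaks=peaks,
        ion_labels=labels,
    )


@dataclass(frozen=True)
class RunSpec:
    """Conditions for one synthetic centroided MS1 run.

    Defaults emulate the published acquisition: ~3 ppm mass accuracy, 2%
    detector CV, Gaussian elution with sigma 0.05 min over a 10-min
    gradient, a chemical baseline on every analyte ion channel scaled so
    S/N crosses 3 near 0.06 ug/mL and 10 near 0.2 ug/mL for a response of
    1000 area units per ug/mL, and a continuously infused lock-mass ion.
    """

    templates: tuple[CompoundTemplate, ...]
    concentrations: dict[str, float]
    mass_noise_ppm: float = 3.0
    intensity_noise_cv: float = 0.02
    baseline_level: float = 20.0
    baseline_noise_sd: float = 15.0
    peak_width_sd: float = 0.05  # minutes
    scan_interval: float = 0.01  # minutes
    duration: float = 10.0  # minutes
    mass_axis_bias_ppm: float = 0.0
    matrix_suppression: dict[str, float] = field(default_factory=dict)
    lock_mass: bool = True
    lock_mass_intensity: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_interval <= 0 or self.peak_width_sd < 0:
            raise ValueError("scan_interval must be > 0 and peak_width_sd >= 0")
        if self.mass_noise_ppm < 0 or self.intensity_noise_cv < 0:
            raise ValueError("noise parameters must be non-negative")
        missing = {t.id for t in self.templates} - set(self.concentrations)
        if missing:
            raise ValueError(f"concentrations missing for templates: {sorted(missing)}")
        for tid, f in self.matrix_suppression.items():
            if not 0 < f <= 1:
                raise ValueError(f"suppression factor for {tid!r} must be in (0, 1]")


def generate_run(spec: RunSpec) -> tuple[ScanSeries, pd.DataFrame]:
    """Synthesize a full run plus its ground truth.

    Returns ``(series, truth)`` where ``truth`` has one row per emitted ion:
    compound, ion label, exact m/z, true apex retention time, the noiseless
    Gaussian amplitude and the closed-form ion peak area
    (amplitude x sigma x sqrt(2 pi)).
    """
    rng = np.random.default_rng(spec.seed)
    bias = 1.0 + spec.mass_axis_bias_ppm * 1e-6
    times = np.arange(spec.scan_interval / 2, spec.duration, spec.scan_interval)
    sig = spec.peak_width_sd
    compounds = []
    for t in spec.templates:
        validate_template(t)
        suppr = spec.matrix_suppression.get(t.id, 1.0)
        amp = t.base_intensity * spec.concentrations[t.id] * suppr
        compounds.append((t, suppr, amp, t.ion_table()))
    truth_rows = []
    for t, suppr, amp, ions in compounds:
        for label, mz, rel in ions:
            truth_rows.append(
                dict(
                    compound_id=t.id,
                    ion=label,
                    mz=mz,
                    apex_rt=t.retention_time,
                    concentration=spec.concentrations[t.id],
                    suppression=suppr,
                    amplitude=amp * rel,
                    true_area=amp * rel * sig * math.sqrt(2 * math.pi),
                )
            )
    truth = pd.DataFrame(truth_rows)
    scans = []
    for rt in times:
        mzs, intens = [], []
        for t, suppr, amp, ions in compounds:
            z = (rt - t.retention_time) / sig if sig > 0 else math.inf
            elution = amp * math.exp(-0.5 * z * z) if abs(z) < 37 else 0.0
            for label, mz, rel in ions:
                # chemical baseline rides on every analyte ion channel
                base = spec.baseline_level + rng.normal(0.0, spec.baseline_noise_sd)
                signal = elution * rel * (1.0 + rng.normal(0.0, spec.intensity_noise_cv))
                inten = max(base, 0.0) + max(signal, 0.0)
                if inten <= 0:
                    continue
                mz_obs = mz * bias * (1.0 + rng.normal(0.0, spec.mass_noise_ppm) * 1e-6)
                mzs.append(mz_obs)
                intens.append(inten)
        if spec.lock_mass:
            mz_obs = LOCK_MASS_MZ * bias * (
                1.0 + rng.normal(0.0, spec.mass_noise_ppm) * 1e-6
            )
            mzs.append(mz_obs)
            intens.append(spec.lock_mass_intensity)
        order = np.argsort(mzs)
        scans.append(
            Scan(rt, np.asarray(mzs)[order], np.asarray(intens)[order])
        )
    return ScanSeries(scans), truth


def generate_calibration_series(
    slope: float,
    intercept: float,
    levels: Sequence[float],
    replicates: int = 3,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Calibration response table: response = (slope*c + intercept) * (1 + eps),
    eps ~ N(0, cv).  Noisy responses are truncated at zero (a detector reports
    no negative areas); with ``noise_cv=0`` the exact design values are kept,
    so noiseless tables reproduce the generating equation verbatim."""
    rng = np.random.default_rng(seed)
    rows = []
    raw = []
    for conc in levels:
        for rep in range(1, replicates + 1):
            y = slope * conc + intercept
            raw.append(y)
            if noise_cv > 0:
                y = max(y * (1.0 + rng.normal(0.0, noise_cv)), 0.0)
            rows.append(dict(concentration=float(conc), replicate=rep, response=y))
    if raw and max(raw) < 0:
        import warnings

        warnings.warn("all calibration responses are negative; truncated at zero",
                      stacklevel=2)
    return pd.DataFrame(rows)
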