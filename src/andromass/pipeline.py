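"""Workflow orchestration: annotate, quantify and validate whole runs.

Thin composition layer over the library modules; the CLI and the analysis
drivers both call these functions.  All tabular outputs are pandas frames
that serialise losslessly to TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import annotate as ann
from . import chrom, msio, quant
from .annotate import FragmentSpectrum
from .chrom import LOCK_MASS_MZ, ScanSeries, XIC
from .masscalc import MassTolerance, enumerate_formulas

log = logging.getLogger("andromass")

#: Published apex retention times (min) of the quantified marker substances.
MARKER_RT = {
    "andrographolide": 5.11,
    "neoandrographolide": 6.30,
    "dehydroandrographolide": 7.57,
}


@dataclass
class PipelineConfig:
    """Tunable knobs of the annotate/quantify workflows."""

    rules: dict = field(default_factory=ann.default_rules)
    xic_window_mda: float = 20.0
    min_snr: float = 3.0
    tic_min_snr: float = 10.0  # stiffer threshold for whole-run TIC peak picking
    rt_tol: float = 0.1  # standard-vs-sample identity window, minutes
    lock_mass: bool = True
    lock_mass_mz: float = LOCK_MASS_MZ
    formula_bounds: dict = field(
        default_factory=lambda: {"C": (0, 45), "H": (0, 80), "N": (0, 2), "O": (0, 15)}
    )
    formula_tol_ppm: float = 10.0
    expected_rt: dict = field(default_factory=lambda: dict(MARKER_RT))

    @property
    def quantifier_ions(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.rules["quantifier_ions"].items()}


def _load_spectra(path: str) -> list[FragmentSpectrum]:
    if str(path).lower().endswith(".mgf"):
        return msio.read_mgf(path)
    raise ValueError(f"cannot read spectra from {path!r} (expected .mgf)")


def _load_series(run: Union[str, ScanSeries]) -> ScanSeries:
    if isinstance(run, ScanSeries):
        return run
    p = str(run).lower()
    if p.endswith(".mzml"):
        return msio.read_mzml(run)
    if p.endswith((".tsv", ".txt")):
        return msio.read_scan_table(run)
    raise ValueError(f"cannot read run from {run!r} (expected .mzML or .tsv)")


def total_ion_current(series: ScanSeries) -> XIC:
    tic = np.array([float(s.intensity.sum()) for s in series.scans])
    return XIC(target_mz=0.0, window_mda=1e6, times=series.times, intensities=tic)


def apex_spectra(
    series: ScanSeries,
    min_snr: float = 10.0,
    lock_mass_mz: Optional[float] = LOCK_MASS_MZ,
    rel_area_min: float = 0.01,
    rel_intensity_min: float = 0.01,
) -> list[FragmentSpectrum]:
    """Composite apex spectra of the TIC peaks of a run.

    Each detected TIC peak contributes its apex scan as one composite
    in-source spectrum whose precursor is the most intense centroid (the
    lock-mass channel excluded).  TIC peaks below ``rel_area_min`` of the
    largest peak's area are treated as baseline excursions and skipped,
    and centroids below ``rel_intensity_min`` of the apex base peak are
    dropped so the chemical baseline of co-monitored channels does not
    masquerade as fragment ions."""
    peaks = chrom.detect_and_integrate(total_ion_current(series), min_snr=min_snr)
    if peaks:
        floor = rel_area_min * max(p.area for p in peaks)
        peaks = [p for p in peaks if p.area >= floor]
    times = series.times
    out = []
    for pk in peaks:
        scan = series.scans[int(np.argmin(np.abs(times - pk.apex_rt)))]
        mask = np.ones(scan.mz.size, dtype=bool)
        if lock_mass_mz is not None:
            mask &= np.abs(scan.mz - lock_mass_mz) > 0.05
        if not mask.any():
            continue
        mzs = scan.mz[mask]
        intens = scan.intensity[mask]
        keep = intens >= rel_intensity_min * intens.max()
        mzs, intens = mzs[keep], intens[keep]
        out.append(
            FragmentSpectrum(
                compound_id=f"rt{pk.apex_rt:.2f}",
                precursor_mz=float(mzs[np.argmax(intens)]),
                retention_time=pk.apex_rt,
                peaks=list(zip(mzs, intens)),
            )
        )
    return out


def annotate_spectra(
    spectra: Sequence[FragmentSpectrum], config: Optional[PipelineConfig] = None
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Loss edges, class call and formula candidates for each spectrum."""
    cfg = config or PipelineConfig()
    tol_exact = MassTolerance("mDa", float(cfg.rules["tolerances"]["exact_mda"]))
    tol_nominal = MassTolerance("mDa", float(cfg.rules["tolerances"]["nominal_da"]) * 1e3)
    rows = []
    for sp in spectra:
        edges = ann.annotate_losses(sp, tol_exact, tol_nominal)
        call = ann.classify_compound(sp, edges, cfg.rules)
        candidates = enumerate_formulas(
            sp.precursor_mz,
            "[M+H]+",
            MassTolerance("ppm", cfg.formula_tol_ppm),
            cfg.formula_bounds,
        )[:3]
        rows.append(
            dict(
                compound_id=sp.compound_id,
                retention_time=sp.retention_time,
                precursor_mz=sp.precursor_mz,
                class_label=call.class_label,
                n_edges=len(edges),
                water_chain=ann.water_chain_length(edges, sp.precursor_mz),
                aglycone_mz=call.aglycone_mz,
                sugar_residue=call.sugar_residue,
                evidence="; ".join(call.evidence),
                formula_candidates="; ".join(
                    f"{c.formula.hill()} ({c.ppm:+.1f} ppm)" for c in candidates
                ),
            )
        )
        log.info("annotated %s as %s", sp.compound_id, call.class_label)
    table = pd.DataFrame(rows)
    diterpene = {"diterpene_monomer", "diterpene_glucoside", "bis_diterpene"}
    flavone = {"flavone_aglycone", "flavone_O_glycoside"}
    summary = {
        "n_spectra": len(rows),
        "class_counts": table["class_label"].value_counts().to_dict() if len(rows) else {},
        "n_diterpene_family": int(table["class_label"].isin(diterpene).sum()) if len(rows) else 0,
        "n_flavone_family": int(table["class_label"].isin(flavone).sum()) if len(rows) else 0,
    }
    return table, summary


def annotate_run(
    run: Union[str, ScanSeries, Sequence[FragmentSpectrum]],
    config: Optional[PipelineConfig] = None,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Annotate an MGF spectrum collection or a full mzML/TSV run."""
    cfg = config or PipelineConfig()
    if isinstance(run, (list, tuple)) and all(
        isinstance(s, FragmentSpectrum) for s in run
    ):
        spectra = list(run)
    elif isinstance(run, str) and run.lower().endswith(".mgf"):
        spectra = _load_spectra(run)
    else:
        series = _load_series(run)
        if cfg.lock_mass:
            series, _ = chrom.lock_mass_correct(series, cfg.lock_mass_mz)
        spectra = apex_spectra(series, cfg.tic_min_snr, cfg.lock_mass_mz)
    return annotate_spectra(spectra, cfg)


def quantify_run(
    run: Union[str, ScanSeries],
    calibration: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Narrow-window XIC quantitation of the marker analytes in one run.

    ``calibration`` needs columns analyte/concentration/response.  Each
    analyte is extracted at its quantifier ion (20 mDa window by default),
    the peak nearest its expected retention time is integrated and the
    area back-calculated through that analyte's calibration curve.
    Analytes without a detectable peak are censored (``below_LOQ``);
    analytes without calibration produce an ``error`` row.
    """
    cfg = config or PipelineConfig()
    series = _load_series(run)
    if cfg.lock_mass:
        series, _ = chrom.lock_mass_correct(series, cfg.lock_mass_mz)
    rows = []
    for analyte, target_mz in cfg.quantifier_ions.items():
        row = dict(
            analyte=analyte,
            quantifier_mz=target_mz,
            expected_rt=cfg.expected_rt.get(analyte),
            apex_rt=np.nan,
            area=np.nan,
            snr=np.nan,
            concentration=np.nan,
            flag="",
            error="",
        )
        cal = calibration[calibration["analyte"] == analyte]
        if cal.empty:
            row.update(flag="error", error="analyte missing from calibration table")
            rows.append(row)
            log.error("no calibration for %s", analyte)
            continue
        curve = quant.fit_calibration(
            list(zip(cal["concentration"], cal["response"]))
        )
        xic = chrom.extract_nwxic(series, target_mz, cfg.xic_window_mda)
        peaks = chrom.detect_and_integrate(xic, min_snr=cfg.min_snr)
        pk = chrom.quantifier_peak(peaks, row["expected_rt"], cfg.rt_tol)
        if pk is None:
            row.update(flag="below_LOQ", error="no peak at expected retention time")
            rows.append(row)
            continue
        result = quant.quantify_response(analyte, pk.area, curve)
        row.update(
            apex_rt=pk.apex_rt,
            area=pk.area,
            snr=pk.snr,
            concentration=result.concentration,
            flag=result.flag,
        )
        rows.append(row)
    return pd.DataFrame(rows)


_ND = "not determined"


def validate(design: Mapping[str, Mapping[str, Any]]) -> pd.DataFrame:
    """Method-validation report: linearity, LOD/LOQ, precision, recovery.

    ``design`` maps analyte name to a dict with any of:

    * ``calibration`` — sequence of (concentration, response) pairs
    * ``dilution`` — sequence of (concentration, snr) pairs
    * ``intra_day`` / ``inter_day`` — replicate measurement sequences
    * ``spikes`` — sequence of (spiked, original, added) triples

    Missing or undersized components are reported as "not determined"
    (replicate sets need >= 3 values)."""
    import warnings

    rows = []
    for analyte, parts in design.items():
        row: dict[str, Any] = dict(analyte=analyte)
        cal = parts.get("calibration")
        if cal is not None and len(cal) >= 2:
            curve = quant.fit_calibration(cal)
            sign = "-" if curve.intercept < 0 else "+"
            row.update(
                equation=f"y = {curve.slope:.4g}x {sign} {abs(curve.intercept):.4g}",
                slope=curve.slope,
                intercept=curve.intercept,
                r_squared=curve.r_squared,
                range_min=curve.range[0],
                range_max=curve.range[1],
            )
        else:
            row.update(equation=_ND, slope=_ND, intercept=_ND, r_squared=_ND,
                       range_min=_ND, range_max=_ND)
        dil = parts.get("dilution")
        if dil:
            lod, loq = quant.lod_loq(dil)
            row.update(lod=lod if lod is not None else _ND,
                       loq=loq if loq is not None else _ND)
        else:
            row.update(lod=_ND, loq=_ND)
        for key, col in (("intra_day", "rsd_intra_pct"), ("inter_day", "rsd_inter_pct")):
            reps = parts.get(key)
            if reps is not None and len(reps) >= 3:
                row[col] = quant.precision_rsd(reps)
            else:
                if reps is not None:
                    warnings.warn(
                        f"{analyte}: fewer than 3 {key} replicates; precision "
                        "not determined",
                        stacklevel=2,
                    )
                row[col] = _ND
        spikes = parts.get("spikes")
        if spikes:
            recs = [quant.relative_recovery(s, o, a) for s, o, a in spikes]
            row["recovery_mean_pct"] = float(np.mean(recs))
            row["recovery_rsd_pct"] = (
                quant.precision_rsd(recs) if len(recs) >= 2 else _ND
            )
        else:
            row.update(recovery_mean_pct=_ND, recovery_rsd_pct=_ND)
        rows.append(row)
    return pd.DataFrame(rows)
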