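"""Standard-format I/O: centroid mzML, MGF, and TSV table dialects.

Reading of mzML and MGF goes through pyteomics.  Writing MGF also uses
pyteomics; mzML *writing* is a minimal self-contained centroid dialect
(uncompressed 64-bit float arrays, MS1 scans with start times in minutes)
sufficient for round-tripping synthetic runs through any mzML reader.
"""

from __future__ import annotations

import base64
import struct
import zlib
import xml.etree.ElementTree as ET
from typing import Iterable
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .annotate import FragmentSpectrum
from .chrom import Scan, ScanSeries

# ---------------------------------------------------------------- mzML ----

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _b64(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *map(float, values))
    return base64.b64encode(raw).decode("ascii")


def _binary_array(values: np.ndarray, accession: str, name: str) -> str:
    payload = _b64(values)
    return (
        f'          <binaryDataArray encodedLength="{len(payload)}">\n'
        '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
        f'            <cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>\n'
        f"            <binary>{payload}</binary>\n"
        "          </binaryDataArray>\n"
    )


def write_mzml(series: ScanSeries, path: str, run_id: str = "synthetic_run") -> None:
    """Write a centroided MS1 scan series as minimal uncompressed mzML."""
    with open(path, "w") as fh:
        fh.write(_MZML_HEADER.format(run_id=escape(run_id), count=len(series.scans)))
        for i, scan in enumerate(series.scans):
            fh.write(
                f'      <spectrum index="{i}" id="scan={i + 1}" '
                f'defaultArrayLength="{scan.mz.size}">\n'
                '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>\n'
                '        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>\n'
                '        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
                '        <scanList count="1">\n'
                '          <scan>\n'
                f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
                f'value="{float(scan.retention_time):.12g}" unitCvRef="UO" '
                'unitAccession="UO:0000031" unitName="minute"/>\n'
                "          </scan>\n"
                "        </scanList>\n"
                '        <binaryDataArrayList count="2">\n'
            )
            fh.write(_binary_array(scan.mz, "MS:1000514", "m/z array"))
            fh.write(_binary_array(scan.intensity, "MS:1000515", "intensity array"))
            fh.write("        </binaryDataArrayList>\n      </spectrum>\n")
        fh.write(_MZML_FOOTER)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda: ET.Element) -> np.ndarray:
    dtype, compressed = "d", False
    payload = ""
    for child in bda.iter():
        tag = _local(child.tag)
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":  # 32-bit float
                dtype = "f"
            elif acc == "MS:1000574":  # zlib compression
                compressed = True
        elif tag == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    width = struct.calcsize(dtype)
    return np.array(struct.unpack(f"<{len(raw) // width}{dtype}", raw), dtype=float)


def read_mzml(path: str) -> ScanSeries:
    """Read centroided MS1 scans into a :class:`ScanSeries`.

    Self-contained namespace-agnostic parser covering uncompressed and
    zlib-compressed 32/64-bit float arrays and scan start times quoted in
    minutes or seconds; MSn spectra are skipped.
    """
    scans = []
    for _, spectrum in ET.iterparse(path):
        if _local(spectrum.tag) != "spectrum":
            continue
        ms_level, rt, arrays = 1, None, {}
        for el in spectrum.iter():
            if _local(el.tag) == "cvParam":
                acc = el.get("accession", "")
                if acc == "MS:1000511":
                    ms_level = int(el.get("value", "1"))
                elif acc == "MS:1000016":
                    rt = float(el.get("value"))
                    if "second" in (el.get("unitName") or "minute"):
                        rt /= 60.0
            elif _local(el.tag) == "binaryDataArray":
                kinds = {
                    c.get("accession")
                    for c in el.iter()
                    if _local(c.tag) == "cvParam"
                }
                if "MS:1000514" in kinds:
                    arrays["mz"] = _decode_binary_array(el)
                elif "MS:1000515" in kinds:
                    arrays["intensity"] = _decode_binary_array(el)
        if ms_level == 1 and rt is not None and "mz" in arrays:
            scans.append(Scan(rt, arrays["mz"], arrays.get(
                "intensity", np.zeros_like(arrays["mz"]))))
        spectrum.clear()
    scans.sort(key=lambda s: s.retention_time)
    if not scans:
        raise ValueError(f"no MS1 scans found in {path!r}")
    return ScanSeries(scans)


# ----------------------------------------------------------------- MGF ----


def write_mgf(spectra: Iterable[FragmentSpectrum], path: str) -> None:
    entries = []
    for sp in spectra:
        entries.append(
            dict(
                params=dict(
                    title=sp.compound_id,
                    pepmass=sp.precursor_mz,
                    rtinseconds=sp.retention_time * 60.0,
                    charge="1+",
                ),
                **{
                    "m/z array": np.array([m for m, _ in sp.peaks]),
                    "intensity array": np.array([i for _, i in sp.peaks]),
                },
            )
        )
    _mgf.write(entries, path, file_mode="w")


def read_mgf(path: str) -> list[FragmentSpectrum]:
    out = []
    with _mgf.read(path) as reader:
        for entry in reader:
            params = entry["params"]
            pepmass = params["pepmass"]
            precursor = float(pepmass[0] if isinstance(pepmass, tuple) else pepmass)
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            mzs = entry["m/z array"]
            intens = entry["intensity array"]
            out.append(
                FragmentSpectrum(
                    compound_id=str(params.get("title", f"spectrum_{len(out) + 1}")),
                    precursor_mz=precursor,
                    retention_time=rt,
                    peaks=list(zip(map(float, mzs), map(float, intens))),
                )
            )
    if not out:
        raise ValueError(f"no spectra found in {path!r}")
    return out


# ----------------------------------------------------------------- TSV ----


def write_scan_table(series: ScanSeries, path: str) -> None:
    """Long-format TSV dialect: one centroid per row (rt, mz, intensity)."""
    rows = [
        (s.retention_time, m, i)
        for s in series.scans
        for m, i in zip(s.mz, s.intensity)
    ]
    pd.DataFrame(rows, columns=["rt", "mz", "intensity"]).to_csv(
        path, sep="\t", index=False
    )


def read_scan_table(path: str) -> ScanSeries:
    df = pd.read_csv(path, sep="\t")
    scans = [
        Scan(float(rt), g["mz"].to_numpy(), g["intensity"].to_numpy())
        for rt, g in df.groupby("rt", sort=True)
    ]
    return ScanSeries(scans)


def read_calibration_table(path: str) -> pd.DataFrame:
    """Calibration TSV: analyte, concentration, replicate, response."""
    df = pd.read_csv(path, sep="\t")
    required = {"analyte", "concentration", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration table missing columns: {sorted(missing)}")
    return df
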