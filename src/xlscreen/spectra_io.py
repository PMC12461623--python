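"""Reading and writing LC-MS/MS runs and tabular results.

MGF parsing is delegated to pyteomics; mzML is read with a lean
CV-accession-driven lxml stream parser. Everything downstream works on the
uniform in-memory :class:`SpectrumRecord` / :class:`Run` model. Retention
times are stored in minutes throughout (mzML second-valued scan times are
converted on read). Peaks are treated as centroids.

MGF files carry MS2 scans only; a Run read from MGF has an empty MS1 list,
which disables XIC-based quantification downstream.

A minimal mzML writer is included so synthetic runs can round-trip through
the standard format: spectra are serialized with base64-encoded 64-bit float
peak arrays, no compression, and the usual PSI-MS controlled-vocabulary
accessions, and round-trip losslessly through the reader.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree
from pyteomics import mgf as _mgf

__all__ = [
    "SpectrumRecord",
    "Run",
    "read_run",
    "write_run_mgf",
    "write_run_mzml",
    "write_table",
]


@dataclass
class SpectrumRecord:
    """One centroided spectrum: MS1 survey scan or MS2 fragment scan."""

    scan_id: str
    ms_level: int
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    precursor_z: int | None = None  # None = unknown, enumerate downstream
    precursor_intensity: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays must have equal length")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if self.mz.size and self.mz[0] <= 0:
            raise ValueError("m/z values must be positive")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError(f"MS2 scan {self.scan_id!r} lacks a precursor m/z")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class Run:
    """Time-ordered MS1 and MS2 spectra of one LC-MS/MS acquisition."""

    ms1: list[SpectrumRecord] = field(default_factory=list)
    ms2: list[SpectrumRecord] = field(default_factory=list)
    gradient_length: float = 120.0  # minutes

    def __post_init__(self) -> None:
        if self.gradient_length <= 0:
            raise ValueError("gradient_length must be positive")
        for level in (self.ms1, self.ms2):
            rts = [s.rt for s in level]
            if any(b < a for a, b in zip(rts, rts[1:])):
                level.sort(key=lambda s: s.rt)

    @property
    def has_ms1(self) -> bool:
        return bool(self.ms1)


# PSI-MS controlled-vocabulary accessions used when parsing mzML
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CHARGE_STATE = "MS:1000041"
_ACC_PEAK_INTENSITY = "MS:1000042"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _cv_params(element) -> dict[str, dict]:
    """accession -> {value, unit name} over all cvParam descendants."""
    params = {}
    for cv in element.iter("{*}cvParam"):
        params[cv.get("accession")] = {
            "value": cv.get("value"),
            "unit": cv.get("unitName") or "",
        }
    return params


def _decode_binary_array(array_element) -> tuple[str | None, np.ndarray]:
    params = _cv_params(array_element)
    binary = array_element.find("{*}binary")
    raw = base64.b64decode(binary.text or "")
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_32BIT in params else "<f8"
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    kind = ("mz" if _ACC_MZ_ARRAY in params
            else "intensity" if _ACC_INTENSITY_ARRAY in params else None)
    return kind, values


def _read_mzml(path: str) -> Run:
    """Stream spectra out of a (plain or indexed) mzML file."""
    ms1, ms2 = [], []
    for _event, elem in etree.iterparse(path, events=("end",),
                                        tag="{*}spectrum"):
        scan_id = elem.get("id", "")
        params = _cv_params(elem)
        level = int(params.get(_ACC_MS_LEVEL, {"value": "1"})["value"])
        rt = 0.0
        scan = elem.find("{*}scanList/{*}scan")
        if scan is not None:
            sp = _cv_params(scan)
            if _ACC_SCAN_START in sp:
                rt = float(sp[_ACC_SCAN_START]["value"])
                if "second" in sp[_ACC_SCAN_START]["unit"]:
                    rt /= 60.0
        mz = inten = np.array([])
        for arr in elem.iter("{*}binaryDataArray"):
            kind, values = _decode_binary_array(arr)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                inten = values
        prec_mz = prec_z = prec_i = None
        if level == 2:
            ion = elem.find("{*}precursorList/{*}precursor/"
                            "{*}selectedIonList/{*}selectedIon")
            if ion is None:
                raise ValueError(
                    f"MS2 scan {scan_id!r} lacks precursor information")
            ip = _cv_params(ion)
            if _ACC_SELECTED_MZ not in ip:
                raise ValueError(
                    f"MS2 scan {scan_id!r} lacks a selected ion m/z")
            prec_mz = float(ip[_ACC_SELECTED_MZ]["value"])
            if _ACC_CHARGE_STATE in ip:
                prec_z = int(ip[_ACC_CHARGE_STATE]["value"])
            if _ACC_PEAK_INTENSITY in ip:
                prec_i = float(ip[_ACC_PEAK_INTENSITY]["value"])
        rec = SpectrumRecord(scan_id, level, rt, mz, inten,
                             prec_mz, prec_z, prec_i)
        (ms1 if level == 1 else ms2).append(rec)
        elem.clear()
    return Run(ms1=ms1, ms2=ms2)


def _read_mgf(path: str) -> Run:
    ms2 = []
    with _mgf.MGF(path) as reader:
        for i, spec in enumerate(reader):
            params = spec["params"]
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise ValueError(
                    f"MGF spectrum {params.get('title', i)!r} lacks PEPMASS")
            prec_mz = float(pepmass[0] if isinstance(pepmass, (tuple, list))
                            else pepmass)
            prec_i = None
            if isinstance(pepmass, (tuple, list)) and len(pepmass) > 1 \
                    and pepmass[1] is not None:
                prec_i = float(pepmass[1])
            charge = params.get("charge")
            prec_z = int(charge[0]) if charge else None
            rt = params.get("rtinseconds")
            rt = float(rt) / 60.0 if rt is not None else 0.0
            ms2.append(SpectrumRecord(
                scan_id=str(params.get("title", f"index={i}")),
                ms_level=2, rt=rt,
                mz=spec["m/z array"], intensity=spec["intensity array"],
                precursor_mz=prec_mz, precursor_z=prec_z,
                precursor_intensity=prec_i))
    return Run(ms1=[], ms2=ms2)


def read_run(path, format: str | None = None,
             gradient_length: float = 120.0) -> Run:
    """Load an mzML or MGF file into a :class:`Run`.

    ``format`` is inferred from the suffix when omitted. MGF inputs yield an
    MS2-only run (no XIC quantification possible).
    """
    path = str(path)
    if format is None:
        suffix = Path(path).suffix.lower()
        format = {".mzml": "mzML", ".mgf": "MGF"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer run format from suffix {suffix!r}")
    if not Path(path).exists():
        raise FileNotFoundError(path)
    if format.lower() == "mzml":
        run = _read_mzml(path)
    elif format.lower() == "mgf":
        run = _read_mgf(path)
    else:
        raise ValueError(f"unknown run format {format!r}")
    run.gradient_length = gradient_length
    if not run.ms1 and not run.ms2:
        raise ValueError(f"no spectra found in {path}")
    return run


# ---------------------------------------------------------------------------
# writers


def write_run_mgf(run: Run, path) -> None:
    """Serialize the MS2 scans as MGF (MS1 scans are dropped by format)."""
    spectra = []
    for s in run.ms2:
        params = {
            "title": s.scan_id,
            "pepmass": (s.precursor_mz, s.precursor_intensity),
            "rtinseconds": s.rt * 60.0,
        }
        if s.precursor_z is not None:
            params["charge"] = [s.precursor_z]
        spectra.append({"m/z array": s.mz, "intensity array": s.intensity,
                        "params": params})
    _mgf.write(spectra, output=str(path), file_mode="w")


def _b64_floats(values: np.ndarray, compress: bool = False) -> str:
    raw = struct.pack(f"<{len(values)}d", *map(float, values))
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="xlscreen" version="0.1.0">
      <cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="xlscreen"/>
    </software>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1">
      <cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>
    </instrumentConfiguration>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="xlscreen">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="run" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{count}" defaultDataProcessingRef="DP1">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _mzml_spectrum_xml(s: SpectrumRecord, index: int) -> str:
    n = s.n_peaks
    mz_b64 = _b64_floats(s.mz)
    int_b64 = _b64_floats(s.intensity)
    level_param = (
        '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
        if s.ms_level == 1 else
        '<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>'
    )
    parts = [
        f'      <spectrum index="{index}" id="{s.scan_id}" '
        f'defaultArrayLength="{n}">',
        f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" '
        f'value="{s.ms_level}"/>',
        f"        {level_param}",
        '        <cvParam cvRef="MS" accession="MS:1000127" '
        'name="centroid spectrum" value=""/>',
        '        <scanList count="1">',
        '          <scan>',
        f'            <cvParam cvRef="MS" accession="MS:1000016" '
        f'name="scan start time" value="{s.rt!r}" unitCvRef="UO" '
        f'unitAccession="UO:0000031" unitName="minute"/>',
        '          </scan>',
        '        </scanList>',
    ]
    if s.ms_level == 2:
        ion = [
            f'              <cvParam cvRef="MS" accession="MS:1000744" '
            f'name="selected ion m/z" value="{s.precursor_mz!r}" '
            f'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
        ]
        if s.precursor_z is not None:
            ion.append(
                f'              <cvParam cvRef="MS" accession="MS:1000041" '
                f'name="charge state" value="{s.precursor_z}"/>')
        if s.precursor_intensity is not None:
            ion.append(
                f'              <cvParam cvRef="MS" accession="MS:1000042" '
                f'name="peak intensity" value="{s.precursor_intensity!r}" '
                f'unitCvRef="MS" unitAccession="MS:1000131" '
                f'unitName="number of detector counts"/>')
        parts += [
            '        <precursorList count="1">',
            '          <precursor>',
            '            <selectedIonList count="1">',
            '              <selectedIon>',
            *ion,
            '              </selectedIon>',
            '            </selectedIonList>',
            '            <activation>',
            '              <cvParam cvRef="MS" accession="MS:1000422" '
            'name="beam-type collision-induced dissociation" value=""/>',
            '            </activation>',
            '          </precursor>',
            '        </precursorList>',
        ]
    parts += [
        '        <binaryDataArrayList count="2">',
        f'          <binaryDataArray encodedLength="{len(mz_b64)}">',
        '            <cvParam cvRef="MS" accession="MS:1000523" '
        'name="64-bit float" value=""/>',
        '            <cvParam cvRef="MS" accession="MS:1000576" '
        'name="no compression" value=""/>',
        '            <cvParam cvRef="MS" accession="MS:1000514" '
        'name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" '
        'unitName="m/z"/>',
        f'            <binary>{mz_b64}</binary>',
        '          </binaryDataArray>',
        f'          <binaryDataArray encodedLength="{len(int_b64)}">',
        '            <cvParam cvRef="MS" accession="MS:1000523" '
        'name="64-bit float" value=""/>',
        '            <cvParam cvRef="MS" accession="MS:1000576" '
        'name="no compression" value=""/>',
        '            <cvParam cvRef="MS" accession="MS:1000515" '
        'name="intensity array" value="" unitCvRef="MS" '
        'unitAccession="MS:1000131" unitName="number of detector counts"/>',
        f'            <binary>{int_b64}</binary>',
        '          </binaryDataArray>',
        '        </binaryDataArrayList>',
        '      </spectrum>',
    ]
    return "\n".join(parts) + "\n"


def write_run_mzml(run: Run, path) -> None:
    """Serialize MS1 + MS2 scans as plain (non-indexed) mzML in time order."""
    spectra = sorted(run.ms1 + run.ms2, key=lambda s: (s.rt, s.ms_level))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_MZML_HEADER.format(count=len(spectra)))
        for i, s in enumerate(spectra):
            fh.write(_mzml_spectrum_xml(s, i))
        fh.write(_MZML_FOOTER)


# float formatting at report time: masses 4 dp, ppm 1 dp, RT 2 dp
_COLUMN_PRECISION = {
    "mass": 4, "mz": 4, "da": 4,
    "ppm": 1,
    "rt": 2, "min": 2,
    "fraction": 3, "similarity": 3, "percent": 2, "score": 3,
}


def _precision_for(column: str) -> int | None:
    low = column.lower()
    for key, digits in _COLUMN_PRECISION.items():
        if key in low:
            return digits
    return None


def write_table(records, path, columns: list[str] | None = None) -> None:
    """Write a list of dicts (or a DataFrame) as a deterministic TSV.

    Column order is taken from ``columns`` or from the first record; floats
    are fixed-precision by column kind (masses 4 dp, ppm 1 dp, RT 2 dp). An
    empty record list yields a header-only file (header requires
    ``columns``).
    """
    import pandas as pd

    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        records = list(records)
        if not records and columns is None:
            raise ValueError("columns required to write an empty table")
        df = pd.DataFrame(records, columns=columns or list(records[0].keys()))
    if columns is not None:
        df = df.reindex(columns=columns)
    for col in df.columns:
        digits = _precision_for(str(col))
        if digits is not None and df[col].dtype.kind == "f":
            df[col] = df[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.{digits}f}")
    df.to_csv(path, sep="\t", index=False)
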