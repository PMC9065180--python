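"""Tandem-spectrum I/O, HexNAc-oxonium detection and CID inclusion lists.

Implements the acquisition-side logic of an HCD-triggered-CID workflow
offline: HCD scans are screened for the HexNAc oxonium ion (m/z 204.087,
±0.01 Da by default) and the triggered precursors are emitted as a CID
inclusion list, merged at 5 ppm and ranked by evidence intensity.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple
from xml.etree import ElementTree
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .chem import IonSpecies, oxonium_series, oxonium_trigger_mz

__all__ = [
    "Spectrum",
    "InclusionEntry",
    "read_spectra",
    "write_mgf",
    "write_mzml",
    "detect_oxonium",
    "oxonium_trigger",
    "diagnostic_ratio",
    "build_inclusion_list",
    "inclusion_list_to_csv",
]


@dataclass
class Spectrum:
    """A centroided tandem spectrum with precursor metadata.

    ``precursor_charge`` is ``None`` when the instrument could not assign one;
    peaks are kept sorted by m/z.
    """

    scan_id: str
    precursor_mz: float
    precursor_charge: Optional[int]
    fragmentation: str  # "HCD" | "CID"
    mz: np.ndarray
    intensity: np.ndarray
    retention_time: float = 0.0

    def __post_init__(self) -> None:
        if self.fragmentation not in ("HCD", "CID"):
            raise ValueError(f"bad fragmentation type {self.fragmentation!r}")
        if self.precursor_charge is not None and not (1 <= self.precursor_charge <= 8):
            raise ValueError(f"precursor charge {self.precursor_charge} outside 1..8")
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in shape")
        if self.mz.size:
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            if self.mz[0] <= 0:
                raise ValueError("non-positive fragment m/z")

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class InclusionEntry:
    precursor_mz: float
    charge: Optional[int]
    evidence: List[Tuple[float, float]]  # (oxonium m/z, intensity) pairs
    rt_start: float = 0.0
    rt_end: float = 0.0
    scan_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("inclusion entry needs a positive precursor m/z")
        if not self.evidence:
            raise ValueError("inclusion entry needs non-empty oxonium evidence")

    @property
    def best_intensity(self) -> float:
        return max(i for _, i in self.evidence)


# ---------------------------------------------------------------------------
# I/O


def _spectrum_from_mgf(entry: dict) -> Spectrum:
    params = entry["params"]
    title = params.get("title", "")
    frag = "HCD"
    scan_id = title or "scan"
    for token in title.split():
        if token.lower().startswith("frag="):
            frag = token.split("=", 1)[1].upper()
        if token.lower().startswith("scan="):
            scan_id = token.split("=", 1)[1]
    charge = None
    if params.get("charge"):
        charge = int(params["charge"][0])
    rt = float(params.get("rtinseconds", 0.0))
    return Spectrum(
        scan_id=scan_id,
        precursor_mz=float(params["pepmass"][0]),
        precursor_charge=charge,
        fragmentation=frag,
        mz=entry["m/z array"],
        intensity=entry["intensity array"],
        retention_time=rt,
    )


# Minimal mzML parsing. The mzML standard is XML with base64-encoded binary
# peak arrays; the subset below (MS2 spectra, 32/64-bit float arrays, zlib or
# no compression, CV-param precursor/activation/scan metadata) covers files
# from the common converters. Element matching ignores the namespace.

_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _cv_params(elem) -> Dict[str, str]:
    return {
        cv.get("name"): cv.get("value", "")
        for cv in elem.iter(f"{_MZML_NS}cvParam")
    }


def _decode_binary_array(bda) -> Tuple[str, np.ndarray]:
    params = _cv_params(bda)
    binary = bda.find(f"{_MZML_NS}binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = np.float32 if "32-bit float" in params else np.float64
    values = np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<"))
    kind = "mz" if "m/z array" in params else (
        "intensity" if "intensity array" in params else "other"
    )
    return kind, values.astype(float)


def _spectrum_from_mzml_elem(elem) -> Optional[Spectrum]:
    params = _cv_params(elem)
    if params.get("ms level", "2") != "2":
        return None
    scan_id = _mzml_scan_id(elem.get("id", "scan"))
    frag = "HCD"
    precursor_mz = 0.0
    charge: Optional[int] = None
    precursor = elem.find(f"{_MZML_NS}precursorList/{_MZML_NS}precursor")
    if precursor is not None:
        ion = precursor.find(
            f"{_MZML_NS}selectedIonList/{_MZML_NS}selectedIon"
        )
        if ion is not None:
            ion_params = _cv_params(ion)
            precursor_mz = float(ion_params.get("selected ion m/z", 0.0))
            if "charge state" in ion_params:
                charge = int(float(ion_params["charge state"]))
        activation = precursor.find(f"{_MZML_NS}activation")
        if activation is not None:
            act_params = _cv_params(activation)
            if (
                "collision-induced dissociation" in act_params
                and "beam-type collision-induced dissociation" not in act_params
            ):
                frag = "CID"
    rt = 0.0
    scan = elem.find(f"{_MZML_NS}scanList/{_MZML_NS}scan")
    if scan is not None:
        for cv in scan.iter(f"{_MZML_NS}cvParam"):
            if cv.get("name") == "scan start time":
                rt = float(cv.get("value", 0.0))
                if cv.get("unitName", "minute") == "minute":
                    rt *= 60.0
    arrays: Dict[str, np.ndarray] = {}
    for bda in elem.iter(f"{_MZML_NS}binaryDataArray"):
        kind, values = _decode_binary_array(bda)
        arrays[kind] = values
    if "mz" not in arrays or "intensity" not in arrays:
        raise ValueError(f"spectrum {scan_id!r}: missing m/z or intensity array")
    return Spectrum(
        scan_id=scan_id,
        precursor_mz=precursor_mz,
        precursor_charge=charge,
        fragmentation=frag,
        mz=arrays["mz"],
        intensity=arrays["intensity"],
        retention_time=rt,
    )


def _iter_mzml(path: str) -> Iterator[Spectrum]:
    for _, elem in ElementTree.iterparse(path, events=("end",)):
        if elem.tag == f"{_MZML_NS}spectrum":
            s = _spectrum_from_mzml_elem(elem)
            if s is not None:
                yield s
            elem.clear()


def read_spectra(path, fmt: Optional[str] = None) -> Iterator[Spectrum]:
    """Stream spectra from an MGF or mzML file (format inferred from the
    extension unless given). Unknown precursor charges are preserved as None."""
    path = str(path)
    if fmt is None:
        fmt = "mzml" if path.lower().endswith((".mzml", ".mzml.gz")) else "mgf"
    fmt = fmt.lower()
    if fmt == "mgf":
        with _mgf.MGF(path) as reader:
            for entry in reader:
                yield _spectrum_from_mgf(entry)
    elif fmt == "mzml":
        yield from _iter_mzml(path)
    else:
        raise ValueError(f"unsupported spectrum format {fmt!r}")


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra to MGF; fragmentation type is encoded in the TITLE."""
    entries = []
    for s in spectra:
        params = {
            "title": f"scan={s.scan_id} frag={s.fragmentation}",
            "pepmass": (s.precursor_mz, None),
            "rtinseconds": s.retention_time,
        }
        if s.precursor_charge is not None:
            params["charge"] = [s.precursor_charge]
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    _mgf.write(entries, str(path), file_mode="w")


def _b64_doubles(values: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="run">
    <spectrumList count="{count}">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="{sid}" defaultArrayLength="{npeaks}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>
        <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt_min}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <precursorList count="1">
          <precursor>
            <selectedIonList count="1">
              <selectedIon>
                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{premz}"/>
{charge_param}              </selectedIon>
            </selectedIonList>
            <activation>
{activation_param}            </activation>
          </precursor>
        </precursorList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""

_CHARGE_PARAM = ('                <cvParam cvRef="MS" accession="MS:1000041" '
                 'name="charge state" value="{z}"/>\n')
_HCD_PARAM = ('              <cvParam cvRef="MS" accession="MS:1000422" '
              'name="beam-type collision-induced dissociation" value=""/>\n')
_CID_PARAM = ('              <cvParam cvRef="MS" accession="MS:1000133" '
              'name="collision-induced dissociation" value=""/>\n')


def write_mzml(spectra: Sequence[Spectrum], path) -> None:
    """Write a minimal standards-compliant mzML rendering of the spectra.

    Uncompressed 64-bit float binary arrays; MS2 only. Intended for
    interoperability checks and small fixture runs — MGF is the primary
    exchange format of this package.
    """
    with open(path, "w") as fh:
        fh.write(_MZML_HEADER.format(count=len(spectra)))
        for i, s in enumerate(spectra):
            mz_b64 = _b64_doubles(s.mz)
            int_b64 = _b64_doubles(s.intensity)
            charge = (
                _CHARGE_PARAM.format(z=s.precursor_charge)
                if s.precursor_charge is not None
                else ""
            )
            fh.write(
                _MZML_SPECTRUM.format(
                    index=i,
                    sid=escape(f"scan={s.scan_id}"),
                    npeaks=len(s),
                    rt_min=s.retention_time / 60.0,
                    premz=s.precursor_mz,
                    charge_param=charge,
                    activation_param=_HCD_PARAM if s.fragmentation == "HCD" else _CID_PARAM,
                    mz_len=len(mz_b64),
                    mz_b64=mz_b64,
                    int_len=len(int_b64),
                    int_b64=int_b64,
                )
            )
        fh.write(_MZML_FOOTER)


def _mzml_scan_id(raw: str) -> str:
    for token in raw.split():
        if token.startswith("scan="):
            return token.split("=", 1)[1]
    return raw


# ---------------------------------------------------------------------------
# oxonium diagnostics


def detect_oxonium(
    spectrum: Spectrum, window: float = 0.01
) -> List[Tuple[IonSpecies, float, float]]:
    """Diagnostic oxonium peaks found in an HCD spectrum.

    Returns (ion, observed m/z, intensity) for every peak within ±window Da of
    any ion in the HexNAc oxonium series. Widening the window can only add
    matches, never remove them.
    """
    if spectrum.fragmentation != "HCD":
        raise ValueError("oxonium screening is defined for HCD spectra")
    out = []
    for ion in oxonium_series("HexNAc"):
        lo = np.searchsorted(spectrum.mz, ion.mz - window, side="left")
        hi = np.searchsorted(spectrum.mz, ion.mz + window, side="right")
        for k in range(lo, hi):
            out.append((ion, float(spectrum.mz[k]), float(spectrum.intensity[k])))
    return out


def oxonium_trigger(
    spectrum: Spectrum,
    window: float = 0.01,
    min_relative_intensity: float = 0.0,
) -> bool:
    """CID trigger decision: HexNAc oxonium (m/z 204.087) present within
    ±window Da, optionally above a relative-intensity floor."""
    target = oxonium_trigger_mz()
    if len(spectrum) == 0:
        return False
    floor = min_relative_intensity * float(spectrum.intensity.max())
    lo = np.searchsorted(spectrum.mz, target - window, side="left")
    hi = np.searchsorted(spectrum.mz, target + window, side="right")
    return bool(np.any(spectrum.intensity[lo:hi] >= floor)) if hi > lo else False


def _summed_intensity(spectrum: Spectrum, center: float, window: float) -> float:
    lo = np.searchsorted(spectrum.mz, center - window, side="left")
    hi = np.searchsorted(spectrum.mz, center + window, side="right")
    return float(spectrum.intensity[lo:hi].sum())


def diagnostic_ratio(
    spectrum: Spectrum, window: float = 0.01
) -> Optional[float]:
    """Intensity ratio I(144.066)/I(138.055) of the GalNAc-discriminating
    oxonium fragment pair; ``None`` (flagged undefined) when the denominator
    peak is absent."""
    if spectrum.fragmentation != "HCD":
        raise ValueError("diagnostic ratio is defined for HCD spectra")
    ions = {ion.label: ion.mz for ion in oxonium_series("HexNAc")}
    num = _summed_intensity(spectrum, ions["HexNAc-C2H4O2"], window)   # 144.066
    den = _summed_intensity(spectrum, ions["HexNAc-CH6O3"], window)    # 138.055
    if den == 0.0:
        return None
    return num / den


# ---------------------------------------------------------------------------
# inclusion lists


def build_inclusion_list(
    spectra: Iterable[Spectrum],
    window: float = 0.01,
    merge_ppm: float = 5.0,
    min_relative_intensity: float = 0.0,
) -> List[InclusionEntry]:
    """CID inclusion list from a stream of HCD spectra.

    One entry per distinct triggered precursor: precursors within
    ``merge_ppm`` of each other with the same charge are merged (their
    evidence pooled, RT window extended). Entries are sorted by descending
    best oxonium-evidence intensity. Purely deterministic.
    """
    entries: List[InclusionEntry] = []
    for s in spectra:
        if s.fragmentation != "HCD":
            continue
        if not oxonium_trigger(s, window, min_relative_intensity):
            continue
        evidence = [(mz, inten) for _, mz, inten in detect_oxonium(s, window)]
        merged = False
        for e in entries:
            if e.charge == s.precursor_charge and abs(
                s.precursor_mz - e.precursor_mz
            ) / e.precursor_mz * 1e6 <= merge_ppm:
                e.evidence.extend(evidence)
                e.rt_start = min(e.rt_start, s.retention_time)
                e.rt_end = max(e.rt_end, s.retention_time)
                e.scan_ids.append(s.scan_id)
                merged = True
                break
        if not merged:
            entries.append(
                InclusionEntry(
                    precursor_mz=s.precursor_mz,
                    charge=s.precursor_charge,
                    evidence=evidence,
                    rt_start=s.retention_time,
                    rt_end=s.retention_time,
                    scan_ids=[s.scan_id],
                )
            )
    entries.sort(key=lambda e: (-e.best_intensity, e.precursor_mz))
    return entries


def inclusion_list_to_csv(entries: Sequence[InclusionEntry], path) -> None:
    """Vendor-style inclusion-list CSV: mz, z, rt_start, rt_end, evidence."""
    df = pd.DataFrame(
        [
            {
                "mz": e.precursor_mz,
                "z": e.charge if e.charge is not None else "",
                "rt_start": e.rt_start,
                "rt_end": e.rt_end,
                "evidence_intensity": e.best_intensity,
            }
            for e in entries
        ],
        columns=["mz", "z", "rt_start", "rt_end", "evidence_intensity"],
    )
    df.to_csv(path, index=False)
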