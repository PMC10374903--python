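"""Experimental MS/MS spectra: in-memory container plus MGF/mzML reading.

Retention times are normalised to minutes on input whatever the source units;
ion mobility (1/K0) is captured when the file carries it.  Peak lists are kept
sorted by m/z and support removal of individual peaks, which the multi-rank
DIA path uses to stop one experimental peak from serving several co-isolated
peptides across ranks.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Optional

import numpy as np
from pyteomics import mgf as _mgf


class SpectraFormatError(ValueError):
    """Unreadable or unsupported spectral file."""


@dataclass
class ExperimentalSpectrum:
    """One MS2 scan: sorted peak arrays plus scan metadata."""

    scan_nr: int
    mz: np.ndarray
    intensity: np.ndarray
    rt_minutes: Optional[float] = None
    im: Optional[float] = None
    precursor_charge: Optional[int] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)

    def copy(self) -> "ExperimentalSpectrum":
        return ExperimentalSpectrum(
            self.scan_nr,
            self.mz.copy(),
            self.intensity.copy(),
            self.rt_minutes,
            self.im,
            self.precursor_charge,
        )

    def remove_peaks(self, indices: Iterable[int]) -> None:
        """Delete peaks at the given positions (deduplicated)."""
        idx = sorted(set(int(i) for i in indices))
        if not idx:
            return
        keep = np.ones(len(self.mz), dtype=bool)
        keep[idx] = False
        self.mz = self.mz[keep]
        self.intensity = self.intensity[keep]


_SCAN_RE = re.compile(r"scan[=\s:]*(\d+)", re.IGNORECASE)


def _scan_from_params(params: dict) -> Optional[int]:
    if "scans" in params:
        m = re.search(r"\d+", str(params["scans"]))
        if m:
            return int(m.group(0))
    title = str(params.get("title", ""))
    m = _SCAN_RE.search(title)
    if m:
        return int(m.group(1))
    m = re.search(r"\.(\d+)\.\d+(?:\.\d+)?$", title.strip())
    if m:
        return int(m.group(1))
    return None


def _read_mgf(path: Path) -> Dict[int, ExperimentalSpectrum]:
    out: Dict[int, ExperimentalSpectrum] = {}
    fallback_scan = 0
    with _mgf.read(str(path), use_index=False) as reader:
        for entry in reader:
            params = entry.get("params", {})
            scan = _scan_from_params(params)
            if scan is None:
                fallback_scan += 1
                scan = fallback_scan
            rt = None
            if "rtinseconds" in params:
                rt = float(params["rtinseconds"]) / 60.0
            elif "rtinminutes" in params:
                rt = float(params["rtinminutes"])
            if rt is None:
                warnings.warn(f"{path.name}: scan {scan} has no retention time")
            im = None
            for key in ("ion_mobility", "1/k0", "inv_k0"):
                if key in params:
                    im = float(params[key])
                    break
            charge = None
            if params.get("charge"):
                charge = int(params["charge"][0])
            out[scan] = ExperimentalSpectrum(
                scan_nr=scan,
                mz=np.asarray(entry["m/z array"], dtype=float),
                intensity=np.asarray(entry["intensity array"], dtype=float),
                rt_minutes=rt,
                im=im,
                precursor_charge=charge,
            )
    return out


def _decode_binary_array(bda) -> np.ndarray:
    """Decode one <binaryDataArray>: base64, optional zlib, 32/64-bit floats."""
    import base64
    import zlib

    dtype = np.float64
    compressed = False
    for cv in bda.findall("{*}cvParam"):
        acc = cv.get("accession")
        if acc == "MS:1000521":
            dtype = np.float32
        elif acc == "MS:1000523":
            dtype = np.float64
        elif acc == "MS:1000574":
            compressed = True
    node = bda.find("{*}binary")
    raw = base64.b64decode(node.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> Dict[int, ExperimentalSpectrum]:
    """Minimal mzML reader: MS2 spectra with RT, IM, charge and peak arrays."""
    from lxml import etree

    out: Dict[int, ExperimentalSpectrum] = {}
    for _, elem in etree.iterparse(str(path), tag="{*}spectrum"):
        params = {
            cv.get("name"): cv
            for cv in elem.iterfind(".//{*}cvParam")
        }
        level = params.get("ms level")
        if level is not None and level.get("value") != "2":
            elem.clear()
            continue
        sid = elem.get("id", "")
        m = _SCAN_RE.search(sid)
        scan = int(m.group(1)) if m else int(elem.get("index", "0")) + 1
        rt = None
        if "scan start time" in params:
            cv = params["scan start time"]
            value = float(cv.get("value"))
            unit = (cv.get("unitName") or "minute").lower()
            rt = value / 60.0 if unit.startswith("second") else value
        else:
            warnings.warn(f"{path.name}: scan {scan} has no retention time")
        im = None
        if "inverse reduced ion mobility" in params:
            im = float(params["inverse reduced ion mobility"].get("value"))
        charge = None
        if "charge state" in params:
            charge = int(params["charge state"].get("value"))
        arrays = {}
        for bda in elem.iterfind(".//{*}binaryDataArray"):
            names = {cv.get("name") for cv in bda.findall("{*}cvParam")}
            if "m/z array" in names:
                arrays["mz"] = _decode_binary_array(bda)
            elif "intensity array" in names:
                arrays["intensity"] = _decode_binary_array(bda)
        if "mz" not in arrays or "intensity" not in arrays:
            raise SpectraFormatError(f"{path}: spectrum {sid!r} lacks peak arrays")
        out[scan] = ExperimentalSpectrum(
            scan_nr=scan,
            mz=arrays["mz"],
            intensity=arrays["intensity"],
            rt_minutes=rt,
            im=im,
            precursor_charge=charge,
        )
        elem.clear()
    return out


def read_spectra(path: str | Path) -> Dict[int, ExperimentalSpectrum]:
    """Read MGF or mzML into a scan-number -> spectrum map.

    The format is chosen by file extension (.mgf vs .mzml); RT is converted
    to minutes regardless of source units.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix == ".mgf":
            return _read_mgf(path)
        if suffix == ".mzml":
            return _read_mzml(path)
    except Exception as exc:  # noqa: BLE001 - re-raise as a format error
        raise SpectraFormatError(f"could not parse {path}: {exc}") from exc
    raise SpectraFormatError(f"unsupported spectral file extension {path.suffix!r}")
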