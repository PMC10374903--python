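"""Predicted-property libraries: fragment spectra, RT and ion mobility.

Two on-disk dialects carry the same information:

* **msp** -- NIST-style blocks::

      Name: PEPTIDEK/2
      Comment: RT=55.3 IM=0.85
      Num peaks: 4
      200.103	0.55	"b2"
      ...

  The name is a bracketed-delta modified peptide plus ``/charge``; fragment
  annotations are ``b3`` / ``y5^2`` (fragment charge after ``^``, default 1).

* **tsv** -- one entry per row with columns ``peptide``, ``mods``, ``charge``,
  ``rt``, ``im`` and ``fragments``, where ``mods`` is comma-separated
  ``position:delta`` pairs (empty for none, position 0 = N-terminus) and
  ``fragments`` is comma-separated ``mz;intensity;annotation`` triples.

Entries are keyed by (stripped sequence, modification set, precursor charge):
peptides with the same sequence but different PTMs or charges are distinct.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .peptides import ModifiedPeptide, fragment_covers

LibKey = Tuple[str, Tuple[Tuple[int, float], ...], int]

_ANNOT_RE = re.compile(r'^"?([by])(\d+)(?:\^(\d+))?"?$')


class LibraryFormatError(ValueError):
    """Malformed prediction-library file."""


@dataclass(frozen=True)
class Fragment:
    mz: float
    intensity: float
    ion_type: str  # 'b' or 'y'
    position: int
    frag_charge: int


@dataclass
class PredictedEntry:
    """Predicted fragments, RT and IM for one (peptide, mods, charge)."""

    peptide: ModifiedPeptide
    fragments: List[Fragment]
    rt_predicted: float
    im_predicted: Optional[float] = None

    @property
    def key(self) -> LibKey:
        return self.peptide.key

    def mz_array(self) -> np.ndarray:
        return np.array([f.mz for f in self.fragments], dtype=float)

    def intensity_array(self) -> np.ndarray:
        return np.array([f.intensity for f in self.fragments], dtype=float)


def parse_annotation(token: str) -> Optional[Tuple[str, int, int]]:
    """Parse ``b3`` / ``y5^2`` into (ion_type, position, frag_charge)."""
    m = _ANNOT_RE.match(token.strip())
    if not m:
        return None
    return m.group(1), int(m.group(2)), int(m.group(3) or 1)


def _register(entries: Dict[LibKey, PredictedEntry], entry: PredictedEntry, where: str) -> None:
    if entry.key in entries:
        raise LibraryFormatError(f"{where}: duplicate library key {entry.key}")
    entries[entry.key] = entry


def _parse_mods(text: str) -> Tuple[Tuple[int, float], ...]:
    text = text.strip()
    if not text:
        return ()
    out = []
    for token in text.split(","):
        pos, delta = token.split(":")
        out.append((int(pos), float(delta)))
    return tuple(out)


def _read_msp(path: Path) -> Dict[LibKey, PredictedEntry]:
    entries: Dict[LibKey, PredictedEntry] = {}
    name: Optional[str] = None
    comment: Dict[str, str] = {}
    peaks: List[Tuple[float, float, str]] = []

    def flush() -> None:
        nonlocal name, comment, peaks
        if name is None:
            return
        if "/" not in name:
            raise LibraryFormatError(f"{path}: msp Name lacks /charge: {name!r}")
        pep_str, charge_str = name.rsplit("/", 1)
        pep = ModifiedPeptide.parse(pep_str, int(charge_str))
        if "RT" not in comment:
            raise LibraryFormatError(f"{path}: entry {name!r} lacks RT")
        frags = []
        for mz, inten, annot in peaks:
            parsed = parse_annotation(annot)
            if parsed is None:
                warnings.warn(f"{path}: {name}: unparsable annotation {annot!r}, fragment dropped")
                continue
            ion, position, fz = parsed
            frags.append(Fragment(mz, inten, ion, position, fz))
        _register(
            entries,
            PredictedEntry(
                peptide=pep,
                fragments=frags,
                rt_predicted=float(comment["RT"]),
                im_predicted=float(comment["IM"]) if "IM" in comment else None,
            ),
            str(path),
        )
        name, comment, peaks = None, {}, []

    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                flush()
                continue
            if line.startswith("Name:"):
                flush()
                name = line[len("Name:"):].strip()
            elif line.startswith("Comment:"):
                for token in line[len("Comment:"):].split():
                    if "=" in token:
                        k, v = token.split("=", 1)
                        comment[k] = v
            elif line.startswith(("Num peaks:", "Num Peaks:", "MW:", "PrecursorMZ:")):
                continue
            elif name is not None:
                parts = line.split()
                if len(parts) < 3:
                    raise LibraryFormatError(f"{path}: bad peak line {line!r}")
                peaks.append((float(parts[0]), float(parts[1]), parts[2]))
    flush()
    return entries


def _read_tsv(path: Path) -> Dict[LibKey, PredictedEntry]:
    entries: Dict[LibKey, PredictedEntry] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"peptide", "mods", "charge", "rt", "im", "fragments"}
        if not required.issubset(header):
            raise LibraryFormatError(
                f"{path}: TSV library needs columns {sorted(required)}, got {header}"
            )
        idx = {name: i for i, name in enumerate(header)}
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            pep = ModifiedPeptide(
                fields[idx["peptide"]],
                _parse_mods(fields[idx["mods"]]),
                int(fields[idx["charge"]]),
            )
            im_text = fields[idx["im"]].strip()
            frags = []
            frag_field = fields[idx["fragments"]].strip()
            for triple in frag_field.split(",") if frag_field else []:
                mz_s, int_s, annot = triple.split(";")
                parsed = parse_annotation(annot)
                if parsed is None:
                    warnings.warn(f"{path}:{lineno}: unparsable annotation {annot!r}, dropped")
                    continue
                ion, position, fz = parsed
                frags.append(Fragment(float(mz_s), float(int_s), ion, position, fz))
            _register(
                entries,
                PredictedEntry(
                    peptide=pep,
                    fragments=frags,
                    rt_predicted=float(fields[idx["rt"]]),
                    im_predicted=float(im_text) if im_text else None,
                ),
                f"{path}:{lineno}",
            )
    return entries


def read_prediction_library(path: str | Path, dialect: str = "auto") -> Dict[LibKey, PredictedEntry]:
    """Read a predicted-property library in the msp or tsv dialect."""
    path = Path(path)
    if dialect == "auto":
        dialect = "msp" if path.suffix.lower() == ".msp" else "tsv"
    if dialect == "msp":
        return _read_msp(path)
    if dialect == "tsv":
        return _read_tsv(path)
    raise LibraryFormatError(f"unknown library dialect {dialect!r}")


# -- writers (used by the fixture simulator and for cross-dialect tests) ----

def _annot(f: Fragment) -> str:
    return f"{f.ion_type}{f.position}" + (f"^{f.frag_charge}" if f.frag_charge != 1 else "")


def write_library_tsv(entries: Sequence[PredictedEntry], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("peptide\tmods\tcharge\trt\tim\tfragments\n")
        for e in entries:
            mods = ",".join(f"{p}:{d:.5f}" for p, d in e.peptide.mods)
            im = "" if e.im_predicted is None else f"{e.im_predicted:.6f}"
            frags = ",".join(
                f"{f.mz:.5f};{f.intensity:.6g};{_annot(f)}" for f in e.fragments
            )
            fh.write(
                f"{e.peptide.sequence}\t{mods}\t{e.peptide.charge}\t"
                f"{e.rt_predicted:.6f}\t{im}\t{frags}\n"
            )
    return path


def write_library_msp(entries: Sequence[PredictedEntry], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for e in entries:
            fh.write(f"Name: {e.peptide.to_string()}/{e.peptide.charge}\n")
            comment = f"RT={e.rt_predicted:.6f}"
            if e.im_predicted is not None:
                comment += f" IM={e.im_predicted:.6f}"
            fh.write(f"Comment: {comment}\n")
            fh.write(f"Num peaks: {len(e.fragments)}\n")
            for f in e.fragments:
                fh.write(f'{f.mz:.5f}\t{f.intensity:.6g}\t"{_annot(f)}"\n')
            fh.write("\n")
    return path


def shift_predicted_fragments(
    entry: PredictedEntry, extra_mods: Sequence[Tuple[int, float]]
) -> PredictedEntry:
    """Shift fragment m/z to account for modifications absent from the library.

    Each fragment whose residue span covers a modified position moves by the
    summed delta mass divided by its fragment charge; predicted intensities,
    RT and IM are copied unchanged.  Used for PTMs the prediction model does
    not support: the library entry for the stripped counterpart is adjusted
    rather than re-predicted.
    """
    if not extra_mods:
        return entry
    n = len(entry.peptide.sequence)
    new_frags = []
    for f in entry.fragments:
        shift = sum(
            delta for pos, delta in extra_mods if fragment_covers(f.ion_type, f.position, pos, n)
        )
        new_frags.append(replace(f, mz=f.mz + shift / f.frag_charge) if shift else f)
    new_pep = ModifiedPeptide(
        entry.peptide.sequence,
        entry.peptide.mods + tuple(extra_mods),
        entry.peptide.charge,
    )
    return PredictedEntry(
        peptide=new_pep,
        fragments=new_frags,
        rt_predicted=entry.rt_predicted,
        im_predicted=entry.im_predicted,
    )
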