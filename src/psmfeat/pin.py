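"""Percolator pin (tab-separated PSM table) reading and writing.

Pin files start with identifier columns ``SpecId``, ``Label``, ``ScanNr``,
carry an arbitrary block of numeric feature columns, and end with ``Peptide``
and ``Proteins``.  The ``Proteins`` cell may itself contain tab characters in
some search-engine dialects; it is preserved verbatim so that a read->write
round trip is byte-identical.  New feature columns produced by this package
are inserted immediately before ``Peptide`` (the Percolator convention: every
column between ``ScanNr`` and ``Peptide`` is a rescoring feature).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence

REQUIRED_COLUMNS = ("SpecId", "Label", "ScanNr", "Peptide", "Proteins")

#: Transforms recovering an expectation value from a pin score column.
EVALUE_TRANSFORMS: Dict[str, Callable[[float], float]] = {
    "identity": lambda x: x,
    "pow10_of_negated": lambda x: 10.0 ** (-x),
    "exp_of_negated": lambda x: math.exp(-x),
}

_SPECID_RE = re.compile(r"\.(\d+)\.(\d+)\.(\d+)_(\d+)$")


class PinFormatError(ValueError):
    """Malformed pin file (missing column, ragged row, bad value)."""


@dataclass
class PsmRecord:
    """One parsed pin row."""

    spec_id: str
    label: int
    scan_nr: int
    rank: int
    peptide: str  # modified-peptide string, flanks stripped
    charge: int
    evalue: float
    feature_values: Dict[str, float] = field(default_factory=dict)

    @property
    def is_target(self) -> bool:
        return self.label == 1


@dataclass
class PinTable:
    """An ordered pin file: header, raw rows, and parsed records."""

    header: List[str]
    rows: List[List[str]]  # len(row) == len(header); Proteins may embed tabs
    source_path: str = ""
    records: List[PsmRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def column_index(self, name: str) -> int:
        try:
            return self.header.index(name)
        except ValueError:
            raise PinFormatError(f"pin file lacks required column {name!r}") from None


def _parse_spec_id(spec_id: str) -> tuple[Optional[int], Optional[int]]:
    """Extract (charge, rank) from MSFragger-style ``base.scan.scan.charge_rank``."""
    m = _SPECID_RE.search(spec_id)
    if m:
        return int(m.group(3)), int(m.group(4))
    return None, None


def _charge_from_onehot(header: Sequence[str], fields: Sequence[str]) -> Optional[int]:
    for i, name in enumerate(header):
        m = re.fullmatch(r"[Cc]harge(\d+)", name)
        if m and fields[i] not in ("0", "0.0", ""):
            return int(m.group(1))
    return None


def read_pin(
    path: str | Path,
    evalue_column: str = "log10_evalue",
    evalue_transform: str = "pow10_of_negated",
) -> PinTable:
    """Read a pin file, deriving each PSM's expectation value.

    ``evalue_column`` names the score column holding the (possibly
    transformed) expectation value; ``evalue_transform`` maps its numeric
    content back onto the e-value scale.  Pin files do not standardise this
    column, so both are configuration.
    """
    if evalue_transform not in EVALUE_TRANSFORMS:
        raise PinFormatError(f"unknown e-value transform {evalue_transform!r}")
    transform = EVALUE_TRANSFORMS[evalue_transform]
    path = Path(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        lines = fh.read().split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise PinFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    for col in REQUIRED_COLUMNS:
        if col not in header:
            raise PinFormatError(f"{path}: missing required column {col!r}")
    if evalue_column not in header:
        raise PinFormatError(f"{path}: missing e-value column {evalue_column!r}")
    if header.index("Proteins") != len(header) - 1 or header.index("Peptide") != len(header) - 2:
        raise PinFormatError(f"{path}: header must end with Peptide, Proteins")

    ncol = len(header)
    idx = {name: i for i, name in enumerate(header)}
    feat_lo, feat_hi = idx["ScanNr"] + 1, idx["Peptide"]
    rows: List[List[str]] = []
    records: List[PsmRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) < ncol:
            raise PinFormatError(f"{path}:{lineno}: expected >= {ncol} fields, got {len(parts)}")
        # extra tabs belong to the Proteins cell: rejoin them verbatim
        fields = parts[: ncol - 1] + ["\t".join(parts[ncol - 1 :])]
        rows.append(fields)

        label = int(fields[idx["Label"]])
        if label not in (1, -1):
            raise PinFormatError(f"{path}:{lineno}: Label must be +1 or -1, got {label}")
        feats: Dict[str, float] = {}
        for i in range(feat_lo, feat_hi):
            try:
                feats[header[i]] = float(fields[i])
            except ValueError:
                raise PinFormatError(
                    f"{path}:{lineno}: non-numeric value {fields[i]!r} "
                    f"in feature column {header[i]!r}"
                ) from None
        evalue = transform(feats[evalue_column])
        if not evalue > 0:
            raise PinFormatError(f"{path}:{lineno}: derived e-value {evalue} not positive")
        spec_id = fields[idx["SpecId"]]
        charge, rank = _parse_spec_id(spec_id)
        if rank is None:
            rank = int(float(feats["rank"])) if "rank" in feats else 1
        if charge is None:
            charge = _charge_from_onehot(header, fields)
        if charge is None:
            charge = int(float(feats["charge"])) if "charge" in feats else 1
        records.append(
            PsmRecord(
                spec_id=spec_id,
                label=label,
                scan_nr=int(fields[idx["ScanNr"]]),
                rank=rank,
                peptide=fields[idx["Peptide"]],
                charge=charge,
                evalue=evalue,
                feature_values=feats,
            )
        )
    return PinTable(header=header, rows=rows, source_path=str(path), records=records)


def write_pin(
    table: PinTable,
    new_features: Mapping[str, Mapping[str, float]],
    path: str | Path,
) -> Path:
    """Write *table* with ``new_features`` columns inserted before ``Peptide``.

    ``new_features`` maps feature name -> {spec_id -> value}; every PSM must
    have a value for every feature.  Values are serialised with ``%.6g`` so
    repeated runs are byte-identical.
    """
    path = Path(path)
    pep_idx = table.column_index("Peptide")
    spec_idx = table.column_index("SpecId")
    names = list(new_features)
    for name in names:
        have = new_features[name]
        missing = [row[spec_idx] for row in table.rows if row[spec_idx] not in have]
        if missing:
            raise PinFormatError(
                f"feature {name!r} missing values for spec_ids: {', '.join(missing[:5])}"
                + ("..." if len(missing) > 5 else "")
            )
    header = table.header[:pep_idx] + names + table.header[pep_idx:]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(header) + "\n")
        for row in table.rows:
            sid = row[spec_idx]
            extra = ["%.6g" % new_features[name][sid] for name in names]
            fh.write("\t".join(row[:pep_idx] + extra + row[pep_idx:]) + "\n")
    return path
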