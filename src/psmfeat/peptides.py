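"""Modified peptides and theoretical b/y fragment masses.

A peptide is represented by its stripped residue sequence plus a set of
``(position, delta_mass)`` modifications, where position 0 denotes the
N-terminus and positions ``1..len`` denote residues.  Fragment m/z values
are monoisotopic; only b and y ions at charge 1-2 are modelled, matching
the fragment dialect of the prediction libraries this package consumes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Tuple

from pyteomics import mass as _pmass

PROTON = 1.00727646688  # Da
WATER = 18.0105646863  # Da

#: Monoisotopic residue masses for the 20 standard amino acids.
RESIDUE_MASS: Mapping[str, float] = dict(_pmass.std_aa_mass)

#: Decimal places used when rounding modification deltas into dictionary keys,
#: so that e.g. "57.02146" in a pin file and "57.0215" in a library agree.
MOD_KEY_DECIMALS = 4

_MOD_RE = re.compile(r"\[([+-]?\d+(?:\.\d+)?)\]")


class PeptideParseError(ValueError):
    """Raised when a modified-peptide string cannot be interpreted."""


def _round_delta(delta: float) -> float:
    return round(float(delta), MOD_KEY_DECIMALS)


@dataclass(frozen=True)
class ModifiedPeptide:
    """A stripped sequence with aggregated position->delta-mass modifications.

    ``mods`` maps position (0 = N-terminus, 1..n = residues) to the summed
    delta mass at that position.  Multiple deltas reported at one position
    are aggregated by summation.
    """

    sequence: str
    mods: Tuple[Tuple[int, float], ...] = ()
    charge: int = 1

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n == 0:
            raise PeptideParseError("empty peptide sequence")
        for aa in self.sequence:
            if aa not in RESIDUE_MASS:
                raise PeptideParseError(f"unknown residue {aa!r} in {self.sequence}")
        agg: dict[int, float] = {}
        for pos, delta in self.mods:
            if not 0 <= pos <= n:
                raise PeptideParseError(
                    f"modification position {pos} outside 0..{n} for {self.sequence}"
                )
            agg[pos] = agg.get(pos, 0.0) + float(delta)
        object.__setattr__(self, "mods", tuple(sorted(agg.items())))
        if self.charge < 1:
            raise PeptideParseError("charge must be >= 1")

    # -- constructors ---------------------------------------------------
    @classmethod
    def parse(cls, peptide: str, charge: int = 1) -> "ModifiedPeptide":
        """Parse bracketed-delta notation, e.g. ``n[42.0106]PEPC[57.02146]K``.

        A leading ``n[delta]`` (or a bracket before the first residue) is the
        N-terminal modification (position 0); a bracket following residue *i*
        modifies residue *i*.  Percolator-style flanking residues
        (``K.PEPTIDE.R`` / ``-.PEPTIDE.-``) are stripped first.
        """
        pep = strip_flanks(peptide)
        if pep.startswith("n"):
            pep = pep[1:]
        seq_chars: list[str] = []
        mods: list[Tuple[int, float]] = []
        i = 0
        while i < len(pep):
            c = pep[i]
            if c == "[":
                m = _MOD_RE.match(pep, i)
                if not m:
                    raise PeptideParseError(f"unbalanced bracket in {peptide!r}")
                mods.append((len(seq_chars), float(m.group(1))))
                i = m.end()
            elif c.isalpha():
                seq_chars.append(c.upper())
                i += 1
            else:
                raise PeptideParseError(f"unexpected character {c!r} in {peptide!r}")
        return cls("".join(seq_chars), tuple(mods), charge)

    # -- properties -----------------------------------------------------
    @property
    def stripped(self) -> str:
        return self.sequence

    @property
    def key(self) -> Tuple[str, Tuple[Tuple[int, float], ...], int]:
        """Library key: peptides differing in PTMs or charge are distinct.

        Delta masses are rounded so pin files and libraries reporting the
        same modification at different precision agree on the key.
        """
        return (
            self.sequence,
            tuple((p, _round_delta(d)) for p, d in self.mods),
            self.charge,
        )

    def mod_dict(self) -> dict[int, float]:
        return dict(self.mods)

    def neutral_mass(self) -> float:
        return (
            sum(RESIDUE_MASS[aa] for aa in self.sequence)
            + WATER
            + sum(d for _, d in self.mods)
        )

    def mz(self) -> float:
        return (self.neutral_mass() + self.charge * PROTON) / self.charge

    def without_mods(self, deltas: Iterable[Tuple[int, float]]) -> "ModifiedPeptide":
        """Return a copy with the given (position, delta) mods removed.

        Deltas are compared after rounding, so callers may pass either the
        library's or the pin file's precision.
        """
        drop = {(p, _round_delta(d)) for p, d in deltas}
        kept = tuple(m for m in self.mods if (m[0], _round_delta(m[1])) not in drop)
        return ModifiedPeptide(self.sequence, kept, self.charge)

    def to_string(self) -> str:
        """Bracketed-delta rendering (inverse of :meth:`parse`)."""

        def fmt(d: float) -> str:
            return f"{d:.5f}".rstrip("0").rstrip(".")

        md = self.mod_dict()
        out = []
        if 0 in md:
            out.append(f"n[{fmt(md[0])}]")
        for i, aa in enumerate(self.sequence, start=1):
            out.append(aa)
            if i in md:
                out.append(f"[{fmt(md[i])}]")
        return "".join(out)


def strip_flanks(peptide: str) -> str:
    """Remove Percolator flanking residues: ``K.PEPTIDE.R`` -> ``PEPTIDE``."""
    if len(peptide) > 4 and peptide[1] == "." and peptide[-2] == ".":
        return peptide[2:-2]
    return peptide


def fragment_mz(
    peptide: ModifiedPeptide, ion_type: str, position: int, frag_charge: int = 1
) -> float:
    """Monoisotopic m/z of the b- or y-ion at *position* (1..n-1).

    b_i covers residues 1..i plus the N-terminal modification; y_i covers the
    i C-terminal residues, the C-terminal modification and the water of the
    peptide backbone.
    """
    n = len(peptide.sequence)
    if not 1 <= position <= n - 1:
        raise ValueError(f"fragment position {position} outside 1..{n - 1}")
    if frag_charge < 1:
        raise ValueError("fragment charge must be >= 1")
    md = peptide.mod_dict()
    if ion_type == "b":
        residues = range(1, position + 1)
        neutral = sum(RESIDUE_MASS[peptide.sequence[i - 1]] for i in residues)
        neutral += md.get(0, 0.0)  # N-terminal mod travels with b ions
        neutral += sum(md.get(i, 0.0) for i in residues)
    elif ion_type == "y":
        residues = range(n - position + 1, n + 1)
        neutral = sum(RESIDUE_MASS[peptide.sequence[i - 1]] for i in residues)
        neutral += WATER
        neutral += sum(md.get(i, 0.0) for i in residues)
    else:
        raise ValueError(f"unsupported ion type {ion_type!r}")
    return (neutral + frag_charge * PROTON) / frag_charge


def fragment_covers(
    ion_type: str, position: int, mod_position: int, seq_len: int
) -> bool:
    """Whether the fragment's residue span includes the modified position.

    Position 0 (N-terminus) belongs to b ions; position ``seq_len`` is the
    C-terminal residue and is covered by every y ion.
    """
    if ion_type == "b":
        return mod_position <= position
    if ion_type == "y":
        return mod_position >= seq_len - position + 1
    raise ValueError(f"unsupported ion type {ion_type!r}")
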