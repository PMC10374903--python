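"""Synthetic fixture generation: library, spectra, pin file and truth table.

The simulator emulates the tool's three inputs end to end.  Target PSMs pair
a scan with the peptide whose predicted fragments generated it (intensities
perturbed by multiplicative log-normal noise, per-fragment dropout, small
ppm m/z jitter, plus uniform background peaks); decoy PSMs pair a scan with
an unrelated peptide's prediction, so their matched vectors and RT/IM deltas
behave like random matches.  Experimental RT is drawn uniformly over the
gradient and mapped to the predicted scale through a configurable monotone
warp (identity, linear or sigmoid) plus Gaussian noise; ion mobility uses a
distinct linear map per precursor charge.  A subset of target peptides
carries a phospho-like +79.96633 Da modification that is deliberately absent
from the library entries, exercising the fragment m/z-shifting path.

Everything derives from a single seeded generator: identical seeds give
byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .library import Fragment, PredictedEntry, write_library_msp, write_library_tsv
from .peptides import ModifiedPeptide, fragment_mz
from .pipeline import split_supported_mods

_AA = "ACDEFGHIKLMNPQRSTVWY"
PHOSPHO = 79.96633
OXIDATION = 15.9949
CARBAMIDOMETHYL = 57.02146
ACETYL = 42.0106


def sigmoid_warp(rt_max: float, pred_max: float) -> Callable[[float], float]:
    """Monotone S-shaped experimental->predicted RT map over [0, rt_max]."""

    def warp(t: float) -> float:
        return pred_max / (1.0 + math.exp(-(t - rt_max / 2.0) / (rt_max / 10.0)))

    return warp


def linear_warp(rt_max: float, pred_max: float) -> Callable[[float], float]:
    return lambda t: pred_max * t / rt_max


@dataclass
class SimSpec:
    """Study conditions for one simulated experiment."""

    n_peptides: int = 300
    n_scans: int = 500
    decoy_fraction: float = 0.5
    peptide_length: Tuple[int, int] = (7, 15)
    charges: Tuple[int, ...] = (2, 3)
    charge_probs: Tuple[float, ...] = (0.7, 0.3)
    max_fragments: int = 12
    intensity_noise_sigma: float = 0.3  # multiplicative log-normal sigma
    dropout: float = 0.1  # per-fragment dropout probability
    mz_jitter_ppm: float = 3.0
    n_background_peaks: int = 10
    rt_max: float = 100.0  # gradient length, minutes
    pred_rt_max: float = 100.0  # predicted-scale span
    rt_warp: str = "sigmoid"  # identity | linear | sigmoid
    rt_noise_sigma: float = 1.0  # predicted-scale units
    with_im: bool = True
    im_noise_sigma: float = 0.01
    #: slope/intercept of the per-charge experimental->predicted IM map
    im_maps: Dict[int, Tuple[float, float]] = field(
        default_factory=lambda: {2: (1.02, 0.01), 3: (0.98, -0.02)}
    )
    #: fraction of target peptides carrying the unsupported +79.96633 mod
    unsupported_mod_fraction: float = 0.1
    #: mean/sigma of log10(e-value) for targets and decoys (overlapping)
    target_log10e: Tuple[float, float] = (-5.0, 1.2)
    decoy_log10e: Tuple[float, float] = (-1.5, 1.0)
    dia_rank2_fraction: float = 0.0  # fraction of scans with a rank-2 PSM
    seed: int = 0

    def warp_fn(self) -> Callable[[float], float]:
        if self.rt_warp == "identity":
            return lambda t: t
        if self.rt_warp == "linear":
            return linear_warp(self.rt_max, self.pred_rt_max)
        if self.rt_warp == "sigmoid":
            return sigmoid_warp(self.rt_max, self.pred_rt_max)
        raise ValueError(f"unknown rt_warp {self.rt_warp!r}")


@dataclass
class SimScan:
    scan_nr: int
    rt_exp: float
    im_exp: Optional[float]
    charge: int
    mz: np.ndarray
    intensity: np.ndarray


@dataclass
class SimResult:
    """In-memory simulation output (files are written by :func:`simulate`)."""

    library: List[PredictedEntry]
    scans: List[SimScan]
    pin_rows: List[dict]
    truth_rows: List[dict]


def _random_peptide(rng: np.random.Generator, spec: SimSpec) -> str:
    length = int(rng.integers(spec.peptide_length[0], spec.peptide_length[1] + 1))
    body = "".join(rng.choice(list(_AA), size=length - 1))
    return body + str(rng.choice(["K", "R"]))


def predicted_entry_for(
    pep: ModifiedPeptide, rng: np.random.Generator, spec: SimSpec,
    rt_predicted: float, im_predicted: Optional[float],
) -> PredictedEntry:
    """All b/y fragments at charge 1-2, random intensities, top ``max_fragments``."""
    n = len(pep.sequence)
    candidates = []
    for ion in ("b", "y"):
        for pos in range(1, n):
            for fz in (1, 2):
                if fz > 1 and pep.charge < 2:
                    continue
                candidates.append((ion, pos, fz))
    intensities = rng.exponential(1.0, size=len(candidates))
    order = np.argsort(-intensities, kind="stable")[: spec.max_fragments]
    frags = []
    for i in sorted(order):
        ion, pos, fz = candidates[i]
        frags.append(
            Fragment(
                mz=fragment_mz(pep, ion, pos, fz),
                intensity=float(intensities[i]),
                ion_type=ion,
                position=pos,
                frag_charge=fz,
            )
        )
    top = max(f.intensity for f in frags)
    frags = [Fragment(f.mz, f.intensity / top, f.ion_type, f.position, f.frag_charge) for f in frags]
    return PredictedEntry(pep, frags, rt_predicted, im_predicted)


def _spectrum_from_entry(
    entry: PredictedEntry, rng: np.random.Generator, spec: SimSpec
) -> Tuple[np.ndarray, np.ndarray]:
    mzs: List[float] = []
    ints: List[float] = []
    for f in entry.fragments:
        if rng.random() < spec.dropout:
            continue
        jitter = rng.normal(0.0, spec.mz_jitter_ppm) * 1e-6 * f.mz
        noise = math.exp(rng.normal(0.0, spec.intensity_noise_sigma))
        mzs.append(f.mz + jitter)
        ints.append(f.intensity * noise)
    for _ in range(spec.n_background_peaks):
        mzs.append(float(rng.uniform(150.0, 1500.0)))
        ints.append(float(rng.uniform(0.01, 0.2)))
    order = np.argsort(mzs)
    return np.asarray(mzs)[order], np.asarray(ints)[order]


def build_simulation(spec: SimSpec) -> SimResult:
    """Run the simulation in memory (no files)."""
    rng = np.random.default_rng(spec.seed)
    warp = spec.warp_fn()

    n_decoys = int(round(spec.n_scans * spec.decoy_fraction))
    n_targets = spec.n_scans - n_decoys

    # --- peptides and their predictions ---------------------------------
    sequences: set[str] = set()
    while len(sequences) < 2 * spec.n_peptides:
        sequences.add(_random_peptide(rng, spec))
    seqs = sorted(sequences)
    rng.shuffle(seqs)
    target_seqs, decoy_seqs = seqs[: spec.n_peptides], seqs[spec.n_peptides :]

    def make_peptide(seq: str, allow_unsupported: bool) -> Tuple[ModifiedPeptide, Tuple]:
        mods: List[Tuple[int, float]] = [
            (i + 1, CARBAMIDOMETHYL) for i, aa in enumerate(seq) if aa == "C"
        ]
        for i, aa in enumerate(seq):
            if aa == "M" and rng.random() < 0.3:
                mods.append((i + 1, OXIDATION))
        if rng.random() < 0.1:
            mods.append((0, ACETYL))
        extra: Tuple[Tuple[int, float], ...] = ()
        if allow_unsupported and rng.random() < spec.unsupported_mod_fraction:
            sty = [i + 1 for i, aa in enumerate(seq) if aa in "STY"]
            if sty:
                extra = ((int(rng.choice(sty)), PHOSPHO),)
        charge = int(rng.choice(spec.charges, p=spec.charge_probs))
        return ModifiedPeptide(seq, tuple(mods) + extra, charge), extra

    library: List[PredictedEntry] = []
    target_peps: List[ModifiedPeptide] = []
    target_extra: List[Tuple] = []
    decoy_peps: List[ModifiedPeptide] = []
    full_entries: Dict[Tuple, PredictedEntry] = {}  # incl. unsupported mods (truth)
    elution: Dict[Tuple, Tuple[float, Optional[float]]] = {}  # key -> (rt_exp, im_exp)

    def im_for(charge: int, im_exp: float) -> float:
        a, b = spec.im_maps.get(charge, (1.0, 0.0))
        return a * im_exp + b

    for seq_list, pep_list, extra_list, is_target_pool in (
        (target_seqs, target_peps, target_extra, True),
        (decoy_seqs, decoy_peps, None, False),
    ):
        for seq in seq_list:
            pep, extra = make_peptide(seq, is_target_pool)
            if is_target_pool:
                # target predictions follow the warp: the model "knows" where
                # the peptide elutes on the predicted scale
                rt_exp = float(rng.uniform(0.0, spec.rt_max))
                rt_pred = warp(rt_exp) + float(rng.normal(0.0, spec.rt_noise_sigma))
                im_exp = float(rng.uniform(0.7, 1.3)) if spec.with_im else None
                im_pred = (
                    im_for(pep.charge, im_exp) + float(rng.normal(0.0, spec.im_noise_sigma))
                    if im_exp is not None
                    else None
                )
                elution[pep.key] = (rt_exp, im_exp)
            else:
                # decoys: prediction unrelated to any scan
                rt_pred = float(rng.uniform(0.0, spec.pred_rt_max))
                im_pred = float(rng.uniform(0.7, 1.3)) if spec.with_im else None
            full = predicted_entry_for(pep, rng, spec, rt_pred, im_pred)
            full_entries[pep.key] = full
            pep_list.append(pep)
            if extra_list is not None:
                extra_list.append(extra)
            if extra:
                # library holds only the supported counterpart; the tool must
                # recover the full entry by m/z shifting
                base, _ = split_supported_mods(pep, (57.0215, 15.9949, 42.0106))
                base_frags = [
                    Fragment(
                        fragment_mz(base, f.ion_type, f.position, f.frag_charge),
                        f.intensity,
                        f.ion_type,
                        f.position,
                        f.frag_charge,
                    )
                    for f in full.fragments
                ]
                library.append(PredictedEntry(base, base_frags, rt_pred, im_pred))
            else:
                library.append(full)

    # --- scans and PSMs --------------------------------------------------
    scans: List[SimScan] = []
    pin_rows: List[dict] = []
    truth_rows: List[dict] = []

    def eval_draw(is_target: bool) -> float:
        mu, sd = spec.target_log10e if is_target else spec.decoy_log10e
        return float(10.0 ** min(rng.normal(mu, sd), 2.0))

    def add_psm(scan: SimScan, pep: ModifiedPeptide, rank: int, is_target: bool,
                generator_key: Tuple) -> None:
        ev = eval_draw(is_target)
        spec_id = f"sim.{scan.scan_nr}.{scan.scan_nr}.{pep.charge}_{rank}"
        pin_rows.append(
            {
                "SpecId": spec_id,
                "Label": 1 if is_target else -1,
                "ScanNr": scan.scan_nr,
                "log10_evalue": -math.log10(ev),
                "hyperscore": max(0.0, -10.0 * math.log10(ev) + rng.normal(0.0, 3.0)),
                "Peptide": f"-.{pep.to_string()}.-",
                "Proteins": ("sp|TGT|" if is_target else "rev_sp|DEC|") + pep.sequence,
            }
        )
        entry = full_entries[pep.key]
        truth_rows.append(
            {
                "spec_id": spec_id,
                "is_target": int(is_target),
                "peptide": pep.to_string(),
                "charge": pep.charge,
                "rank": rank,
                "scan_nr": scan.scan_nr,
                "rt_exp": scan.rt_exp,
                "rt_pred_true": warp(scan.rt_exp),
                "rt_pred_library": entry.rt_predicted,
                "im_exp": scan.im_exp if scan.im_exp is not None else "",
                "evalue": ev,
                "generator_peptide": "|".join(map(str, generator_key[:1])),
                "n_peaks": len(scan.mz),
            }
        )

    n_t = len(target_peps)
    gen_order = rng.permutation(n_t)
    for i in range(spec.n_scans):
        scan_nr = i + 1
        is_target_scan = i < n_targets
        gen_idx = int(gen_order[i % n_t])
        gen_pep = target_peps[gen_idx]
        gen_entry = full_entries[gen_pep.key]
        rt_exp, im_exp = elution[gen_pep.key]
        mz, inten = _spectrum_from_entry(gen_entry, rng, spec)

        rank2_pep: Optional[ModifiedPeptide] = None
        if spec.dia_rank2_fraction > 0 and rng.random() < spec.dia_rank2_fraction:
            j = int(rng.integers(0, n_t))
            if j != gen_idx:
                rank2_pep = target_peps[j]
                e2 = full_entries[rank2_pep.key]
                mz2, int2 = _spectrum_from_entry(e2, rng, spec)
                order = np.argsort(np.concatenate([mz, mz2]))
                mz = np.concatenate([mz, mz2])[order]
                inten = np.concatenate([inten, int2 * 0.5])[order]

        scan = SimScan(scan_nr, rt_exp, im_exp, gen_pep.charge, mz, inten)
        scans.append(scan)
        if is_target_scan:
            add_psm(scan, gen_pep, 1, True, gen_pep.key)
        else:
            dec_pep = decoy_peps[int(rng.integers(0, len(decoy_peps)))]
            add_psm(scan, dec_pep, 1, False, gen_pep.key)
        if rank2_pep is not None:
            add_psm(scan, rank2_pep, 2, True, gen_pep.key)

    library.sort(key=lambda e: e.key)
    return SimResult(library, scans, pin_rows, truth_rows)


# -- file writers ---------------------------------------------------------

def write_mgf(scans: Sequence[SimScan], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for s in scans:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE=sim.{s.scan_nr}.{s.scan_nr}.{s.charge}\n")
            fh.write(f"SCANS={s.scan_nr}\n")
            fh.write(f"RTINSECONDS={s.rt_exp * 60.0:.4f}\n")
            fh.write(f"CHARGE={s.charge}+\n")
            if s.im_exp is not None:
                fh.write(f"ION_MOBILITY={s.im_exp:.6f}\n")
            fh.write("PEPMASS=500.0\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.5f} {inten:.6g}\n")
            fh.write("END IONS\n")
    return path


def write_mzml(scans: Sequence[SimScan], path: str | Path) -> Path:
    """Minimal mzML writer (uncompressed 64-bit binary arrays) for fixtures."""
    import base64
    import struct

    def b64(values: Sequence[float]) -> str:
        raw = struct.pack(f"<{len(values)}d", *values)
        return base64.b64encode(raw).decode("ascii")

    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write('<?xml version="1.0" encoding="utf-8"?>\n')
        fh.write('<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n')
        fh.write(f'<run id="sim"><spectrumList count="{len(scans)}">\n')
        for i, s in enumerate(scans):
            fh.write(
                f'<spectrum index="{i}" id="scan={s.scan_nr}" '
                f'defaultArrayLength="{len(s.mz)}">\n'
            )
            fh.write('<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>\n')
            fh.write('<scanList count="1"><scan>\n')
            fh.write(
                '<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
                f'value="{s.rt_exp * 60.0:.4f}" unitName="second"/>\n'
            )
            if s.im_exp is not None:
                fh.write(
                    '<cvParam cvRef="MS" accession="MS:1002815" '
                    f'name="inverse reduced ion mobility" value="{s.im_exp:.6f}"/>\n'
                )
            fh.write("</scan></scanList>\n")
            fh.write(
                '<precursorList count="1"><precursor><selectedIonList count="1">'
                "<selectedIon>"
                '<cvParam cvRef="MS" accession="MS:1000041" name="charge state" '
                f'value="{s.charge}"/>'
                "</selectedIon></selectedIonList></precursor></precursorList>\n"
            )
            fh.write('<binaryDataArrayList count="2">\n')
            for accession, name, values in (
                ("MS:1000514", "m/z array", s.mz),
                ("MS:1000515", "intensity array", s.intensity),
            ):
                data = b64(list(values))
                fh.write(f'<binaryDataArray encodedLength="{len(data)}">\n')
                fh.write(
                    '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>\n'
                    '<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>\n'
                    f'<cvParam cvRef="MS" accession="{accession}" name="{name}"/>\n'
                )
                fh.write(f"<binary>{data}</binary>\n</binaryDataArray>\n")
            fh.write("</binaryDataArrayList>\n</spectrum>\n")
        fh.write("</spectrumList></run>\n</mzML>\n")
    return path


def write_pin_file(pin_rows: Sequence[dict], path: str | Path) -> Path:
    path = Path(path)
    cols = ["SpecId", "Label", "ScanNr", "log10_evalue", "hyperscore", "Peptide", "Proteins"]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in pin_rows:
            fh.write(
                "\t".join(
                    "%.6g" % row[c] if isinstance(row[c], float) else str(row[c])
                    for c in cols
                )
                + "\n"
            )
    return path


def write_truth(truth_rows: Sequence[dict], path: str | Path) -> Path:
    path = Path(path)
    if not truth_rows:
        raise ValueError("no truth rows")
    cols = list(truth_rows[0])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in truth_rows:
            fh.write(
                "\t".join(
                    "%.6g" % row[c] if isinstance(row[c], float) else str(row[c])
                    for c in cols
                )
                + "\n"
            )
    return path


def simulate(spec: SimSpec, outdir: str | Path, spectra_format: str = "mgf") -> Dict[str, Path]:
    """Generate library (tsv + msp), spectra, pin and truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = build_simulation(spec)
    paths = {
        "library_tsv": write_library_tsv(result.library, outdir / "library.tsv"),
        "library_msp": write_library_msp(result.library, outdir / "library.msp"),
        "pin": write_pin_file(result.pin_rows, outdir / "psms.pin"),
        "truth": write_truth(result.truth_rows, outdir / "truth.tsv"),
    }
    if spectra_format == "mgf":
        paths["spectra"] = write_mgf(result.scans, outdir / "spectra.mgf")
    elif spectra_format == "mzml":
        paths["spectra"] = write_mzml(result.scans, outdir / "spectra.mzML")
    else:
        raise ValueError(f"unknown spectra format {spectra_format!r}")
    return paths
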