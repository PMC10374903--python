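"""End-to-end orchestration: pin + spectra + predictions -> extended pin.

For each pin/spectral-file pair the pipeline (1) resolves every PSM to a
predicted entry, shifting fragment m/z for modifications the prediction
model does not support, (2) fits the RT calibration and per-charge IM
calibrations from that file's confident PSMs, (3) builds the per-bin KDE
distributions, (4) walks each scan's PSMs in ascending rank computing the
configured features — consuming matched experimental peaks between ranks in
DIA mode — and (5) writes the pin back out with the new feature columns
inserted before the Peptide column.  The whole path is deterministic: two
runs on identical inputs produce byte-identical output.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import calibration as cal
from . import kde as kdemod
from .config import RunConfig
from .library import LibKey, PredictedEntry, shift_predicted_fragments
from .peptides import ModifiedPeptide, PeptideParseError
from .pin import PinTable, PsmRecord, read_pin, write_pin
from .similarity import (
    auxiliary_similarities,
    consume_matched_peaks,
    match_fragments,
    unweighted_spectral_entropy,
)
from .spectra import ExperimentalSpectrum, read_spectra

logger = logging.getLogger("psmfeat")

_SIMILARITY_FEATURES = frozenset(
    {
        "unweighted_spectral_entropy",
        "cosine_similarity",
        "dot_product",
        "pearson_corr",
        "spearman_corr",
        "bray_curtis",
        "matched_count",
        "matched_fraction",
    }
)


def split_supported_mods(
    peptide: ModifiedPeptide, supported_deltas: Sequence[float]
) -> Tuple[ModifiedPeptide, Tuple[Tuple[int, float], ...]]:
    """Split a peptide into its library-supported part and the extra mods.

    Returns the peptide carrying only supported delta masses plus the tuple
    of (position, delta) modifications the prediction model cannot handle.
    """
    supported = {round(d, 4) for d in supported_deltas}
    extra = tuple(m for m in peptide.mods if round(m[1], 4) not in supported)
    if not extra:
        return peptide, ()
    return peptide.without_mods(extra), extra


def extract_prediction_targets(
    pins: Sequence[PinTable], supported_deltas: Sequence[float] = ()
) -> List[Tuple[ModifiedPeptide, Tuple[Tuple[int, float], ...]]]:
    """Deduplicated prediction requests over all pins (targets AND decoys).

    Each element is (peptide-to-predict, extra mods to re-apply by m/z
    shifting).  Peptides with unsupported PTMs are requested as their
    supported counterparts with a shift recipe.
    """
    seen: Dict[LibKey, Tuple[ModifiedPeptide, Tuple[Tuple[int, float], ...]]] = {}
    for table in pins:
        for rec in table.records:
            try:
                pep = ModifiedPeptide.parse(rec.peptide, rec.charge)
            except PeptideParseError as exc:
                raise PeptideParseError(f"{rec.spec_id}: {exc}") from exc
            base, extra = (
                split_supported_mods(pep, supported_deltas) if supported_deltas else (pep, ())
            )
            seen.setdefault(pep.key, (base, extra))
    return [seen[k] for k in sorted(seen)]


def write_prediction_request(
    targets: Sequence[Tuple[ModifiedPeptide, Tuple[Tuple[int, float], ...]]],
    path: str | Path,
) -> Path:
    """Write the prediction-request TSV consumed by an external predictor."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("peptide\tmods\tcharge\textra_mods\n")
        for pep, extra in targets:
            mods = ",".join(f"{p}:{d:.5f}" for p, d in pep.mods)
            extras = ",".join(f"{p}:{d:.5f}" for p, d in extra)
            fh.write(f"{pep.sequence}\t{mods}\t{pep.charge}\t{extras}\n")
    return path


def resolve_entry(
    record: PsmRecord,
    library: Dict[LibKey, PredictedEntry],
    config: RunConfig,
) -> Optional[PredictedEntry]:
    """Find (or synthesise by m/z shifting) the predicted entry for a PSM."""
    try:
        pep = ModifiedPeptide.parse(record.peptide, record.charge)
    except PeptideParseError:
        return None
    entry = library.get(pep.key)
    if entry is not None:
        return entry
    base, extra = split_supported_mods(pep, config.supported_mod_deltas)
    if not extra:
        return None
    base_entry = library.get(base.key)
    if base_entry is None:
        return None
    return shift_predicted_fragments(base_entry, extra)


class FilePairAnnotator:
    """Computes the configured features for one pin/spectra pair."""

    def __init__(
        self,
        pin_table: PinTable,
        spectra: Dict[int, ExperimentalSpectrum],
        library: Dict[LibKey, PredictedEntry],
        config: RunConfig,
    ) -> None:
        self.table = pin_table
        self.spectra = spectra
        self.config = config
        self.entries: Dict[str, Optional[PredictedEntry]] = {
            rec.spec_id: resolve_entry(rec, library, config) for rec in pin_table.records
        }
        self.rt_model: Optional[cal.CalibrationModel] = None
        self.im_models: Dict[object, cal.CalibrationModel] = {}
        self.rt_bins: Optional[kdemod.KdeBinSet] = None
        self.im_bins: Dict[object, kdemod.KdeBinSet] = {}
        self.missing_scans = 0
        self._fit_models()

    # -- model fitting ---------------------------------------------------
    def _confident_records(self) -> Tuple[List[PsmRecord], str]:
        usable = [
            r
            for r in self.table.records
            if self.entries[r.spec_id] is not None
            and r.scan_nr in self.spectra
            and self.spectra[r.scan_nr].rt_minutes is not None
        ]
        return cal.select_calibration_psms(
            usable,
            self.config.evalue_threshold,
            self.config.calibration_max_n,
            self.config.calibration_min_n,
        )

    def _fit_models(self) -> None:
        cfg = self.config
        try:
            confident, flag = self._confident_records()
        except cal.CalibrationError as exc:
            logger.warning("RT calibration skipped: %s", exc)
            return
        rt_pairs = [
            (self.spectra[r.scan_nr].rt_minutes, self.entries[r.spec_id].rt_predicted)
            for r in confident
        ]
        try:
            self.rt_model = cal.fit_calibration(rt_pairs, flag, cfg.rt_bandwidth)
        except cal.CalibrationError as exc:
            logger.warning("RT calibration failed: %s", exc)
        rt_triples = [
            (
                self.spectra[r.scan_nr].rt_minutes,
                self.entries[r.spec_id].rt_predicted,
                r.evalue,
            )
            for r in confident
        ]
        if rt_triples:
            self.rt_bins = kdemod.build_bins(rt_triples, cfg.rt_bin_width)

        im_items = [
            (r, self.spectra[r.scan_nr].im, self.entries[r.spec_id].im_predicted)
            for r in confident
            if self.spectra[r.scan_nr].im is not None
            and self.entries[r.spec_id].im_predicted is not None
        ]
        if im_items:
            try:
                self.im_models = cal.fit_im_models(
                    im_items,
                    cfg.evalue_threshold,
                    cfg.calibration_max_n,
                    cfg.calibration_min_n,
                    cfg.im_bandwidth,
                )
            except cal.CalibrationError as exc:
                logger.warning("IM calibration skipped: %s", exc)
            by_charge: Dict[int, list] = defaultdict(list)
            for r, ime, imp in im_items:
                by_charge[r.charge].append((ime, imp, r.evalue))
            for charge, triples in sorted(by_charge.items()):
                self.im_bins[charge] = kdemod.build_bins(
                    triples, cfg.im_bin_width, charge=charge
                )
            all_triples = [t for ts in by_charge.values() for t in ts]
            self.im_bins["all"] = kdemod.build_bins(all_triples, cfg.im_bin_width)

    # -- feature computation ---------------------------------------------
    def _sentinel(self, feature: str) -> float:
        if feature in _SIMILARITY_FEATURES:
            return 0.0
        if feature == "RT_probability_unif_prior":
            return self.rt_bins.p_u if self.rt_bins else 0.0
        if feature == "IM_probability_unif_prior":
            bins = self.im_bins.get("all")
            return bins.p_u if bins else 0.0
        return self.config.delta_sentinel

    def _psm_features(
        self, rec: PsmRecord, spectrum: Optional[ExperimentalSpectrum]
    ) -> Dict[str, float]:
        cfg = self.config
        entry = self.entries[rec.spec_id]
        out = {f: self._sentinel(f) for f in cfg.features}
        wanted = set(cfg.features)

        if entry is not None and spectrum is not None and len(spectrum) >= 0:
            if wanted & _SIMILARITY_FEATURES and entry.fragments:
                vectors = match_fragments(spectrum, entry, cfg.tol_ppm, cfg.tol_da)
                if "unweighted_spectral_entropy" in wanted:
                    out["unweighted_spectral_entropy"] = unweighted_spectral_entropy(vectors)
                aux_wanted = wanted & _SIMILARITY_FEATURES - {"unweighted_spectral_entropy"}
                if aux_wanted:
                    aux = auxiliary_similarities(vectors)
                    for name in aux_wanted:
                        out[name] = aux[name]

        rt_exp = spectrum.rt_minutes if spectrum is not None else None
        if entry is not None and rt_exp is not None:
            if self.rt_model is not None:
                if "delta_RT_loess" in wanted:
                    out["delta_RT_loess"] = cal.delta_rt_loess(
                        self.rt_model, rt_exp, entry.rt_predicted
                    )
                if "delta_RT_loess_normalized" in wanted:
                    out["delta_RT_loess_normalized"] = cal.delta_rt_loess_normalized(
                        self.rt_model, rt_exp, entry.rt_predicted
                    )
            if self.rt_bins is not None and "RT_probability_unif_prior" in wanted:
                out["RT_probability_unif_prior"] = kdemod.probability_with_uniform_prior(
                    self.rt_bins, rt_exp, entry.rt_predicted
                )

        im_exp = spectrum.im if spectrum is not None else None
        if entry is not None and im_exp is not None and entry.im_predicted is not None:
            model = self.im_models.get(rec.charge) or self.im_models.get("all")
            if model is not None and "delta_IM_loess" in wanted:
                out["delta_IM_loess"] = cal.delta_im(model, im_exp, entry.im_predicted)
            bins = self.im_bins.get(rec.charge) or self.im_bins.get("all")
            if bins is not None and "IM_probability_unif_prior" in wanted:
                out["IM_probability_unif_prior"] = kdemod.probability_with_uniform_prior(
                    bins, im_exp, entry.im_predicted
                )
        return out

    def annotate(self) -> Dict[str, Dict[str, float]]:
        """Compute every configured feature for every PSM.

        Returns {feature name -> {spec_id -> value}} in config feature order.
        """
        cfg = self.config
        features: Dict[str, Dict[str, float]] = {f: {} for f in cfg.features}
        by_scan: Dict[int, List[PsmRecord]] = defaultdict(list)
        for rec in self.table.records:
            by_scan[rec.scan_nr].append(rec)

        for scan_nr in sorted(by_scan):
            recs = sorted(by_scan[scan_nr], key=lambda r: (r.rank, r.spec_id))
            base = self.spectra.get(scan_nr)
            if base is None:
                self.missing_scans += len(recs)
            working = base.copy() if (base is not None and cfg.mode == "dia") else base
            for rec in recs:
                features_for_rec = self._psm_features(rec, working)
                for name, value in features_for_rec.items():
                    features[name][rec.spec_id] = value
                if (
                    cfg.mode == "dia"
                    and working is not None
                    and self.entries[rec.spec_id] is not None
                ):
                    consume_matched_peaks(
                        working, self.entries[rec.spec_id], cfg.tol_ppm, cfg.tol_da
                    )
        return features


def annotate_file_pair(
    pin_table: PinTable,
    spectra: Dict[int, ExperimentalSpectrum],
    library: Dict[LibKey, PredictedEntry],
    config: RunConfig,
) -> Dict[str, Dict[str, float]]:
    """Feature columns ({name -> {spec_id -> value}}) for one file pair."""
    return FilePairAnnotator(pin_table, spectra, library, config).annotate()


def run(
    pin_paths: Sequence[str | Path],
    spectra_paths: Sequence[str | Path],
    library_path: str | Path,
    out_dir: str | Path,
    config: Optional[RunConfig] = None,
) -> List[Path]:
    """Annotate each pin/spectra pair and write ``<name>.psmfeat.pin`` files.

    Calibration and KDE models are fitted per spectral file, so files with
    different chromatography do not share a mapping.  Logs per-file medians
    of each feature for targets vs decoys.
    """
    from .library import read_prediction_library

    config = config or RunConfig()
    if len(pin_paths) != len(spectra_paths):
        raise ValueError("need one spectra file per pin file")
    library = read_prediction_library(library_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    for pin_path, spec_path in zip(pin_paths, spectra_paths):
        table = read_pin(pin_path, config.evalue_column, config.evalue_transform)
        spectra = read_spectra(spec_path)
        annotator = FilePairAnnotator(table, spectra, library, config)
        features = annotator.annotate()
        if annotator.missing_scans:
            logger.warning(
                "%s: %d PSM(s) with no matching scan; sentinel features written",
                pin_path,
                annotator.missing_scans,
            )
        for name, values in features.items():
            tgt = [values[r.spec_id] for r in table.records if r.is_target]
            dec = [values[r.spec_id] for r in table.records if not r.is_target]
            logger.info(
                "%s %s: median target=%.4g decoy=%.4g",
                Path(pin_path).name,
                name,
                float(np.median(tgt)) if tgt else float("nan"),
                float(np.median(dec)) if dec else float("nan"),
            )
        out_path = out_dir / (Path(pin_path).stem + ".psmfeat.pin")
        write_pin(table, features, out_path)
        written.append(out_path)
    return written
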