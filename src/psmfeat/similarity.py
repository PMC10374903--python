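"""Fragment matching and spectral-similarity features.

For each predicted fragment the single highest-intensity experimental peak
within the m/z tolerance is taken, producing predicted and experimental
intensity vectors of identical length (unmatched positions are zero-filled).
The primary similarity is the unweighted spectral entropy score; a set of
auxiliary correlated metrics is available as an option.  In multi-rank DIA
mode the matched experimental peaks of a PSM are consumed (deleted) before
the next rank is matched, so one peak cannot support several co-isolated
peptides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy import stats as _stats

from .library import PredictedEntry
from .spectra import ExperimentalSpectrum

LN4 = float(np.log(4.0))


@dataclass
class MatchedVectors:
    """Same-length predicted/experimental intensity vectors for one PSM."""

    predicted: np.ndarray
    experimental: np.ndarray
    matched_mask: np.ndarray
    matched_peak_indices: np.ndarray  # index into the spectrum, -1 if unmatched
    tolerance_ppm: float

    def __post_init__(self) -> None:
        if not (len(self.predicted) == len(self.experimental) == len(self.matched_mask)):
            raise ValueError("matched vectors must share one length")


def _select_peak(
    spectrum: ExperimentalSpectrum, target_mz: float, tol_ppm: float, tol_da: Optional[float]
) -> int:
    """Index of the best in-tolerance peak, or -1.

    Best = highest intensity; ties broken by smaller |m/z - target|, then by
    lower m/z, so matching is deterministic.
    """
    half = tol_da if tol_da is not None else target_mz * tol_ppm * 1e-6
    lo = np.searchsorted(spectrum.mz, target_mz - half, side="left")
    hi = np.searchsorted(spectrum.mz, target_mz + half, side="right")
    if hi <= lo:
        return -1
    window_int = spectrum.intensity[lo:hi]
    window_mz = spectrum.mz[lo:hi]
    best = np.flatnonzero(window_int == window_int.max())
    if len(best) > 1:
        dist = np.abs(window_mz[best] - target_mz)
        best = best[dist == dist.min()]
    return int(lo + best[0])  # remaining ties: lowest m/z (arrays are sorted)


def match_fragments(
    spectrum: ExperimentalSpectrum,
    entry: PredictedEntry,
    tol_ppm: float = 20.0,
    tol_da: Optional[float] = None,
) -> MatchedVectors:
    """Build matched intensity vectors under a ppm (or absolute Da) tolerance.

    Selection is non-exclusive within one PSM: two predicted fragments may
    claim the same experimental peak.  Exclusivity across ranks is enforced
    separately by :func:`consume_matched_peaks`.
    """
    if not entry.fragments:
        raise ValueError("predicted fragment list is empty; similarity undefined")
    if tol_da is None and not tol_ppm > 0:
        raise ValueError("tolerance must be positive")
    n = len(entry.fragments)
    pred = entry.intensity_array()
    exp = np.zeros(n)
    mask = np.zeros(n, dtype=bool)
    peak_idx = np.full(n, -1, dtype=int)
    for i, frag in enumerate(entry.fragments):
        j = _select_peak(spectrum, frag.mz, tol_ppm, tol_da)
        if j >= 0:
            exp[i] = spectrum.intensity[j]
            mask[i] = True
            peak_idx[i] = j
    return MatchedVectors(pred, exp, mask, peak_idx, tol_ppm)


def shannon_entropy(p: np.ndarray) -> float:
    """S(p) = -sum p_i ln p_i with 0 ln 0 = 0 (p need not be normalised)."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def unweighted_spectral_entropy(v: MatchedVectors) -> float:
    """Entropy similarity in [0, 1] between the matched vectors.

    Both vectors are normalised to unit sum; the score is
    ``1 - (2 S(M) - S(P) - S(Q)) / ln 4`` with ``M = (P + Q) / 2``.
    An all-zero experimental vector scores 0 by convention so every PSM
    receives a numeric feature value.
    """
    p, q = v.predicted, v.experimental
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("negative intensities")
    ps, qs = p.sum(), q.sum()
    if not ps > 0:
        raise ValueError("predicted vector has zero total intensity")
    if not qs > 0:
        return 0.0
    pn, qn = p / ps, q / qs
    m = 0.5 * (pn + qn)
    sim = 1.0 - (2.0 * shannon_entropy(m) - shannon_entropy(pn) - shannon_entropy(qn)) / LN4
    # clip tiny numerical excursions outside [0, 1]
    return float(min(1.0, max(0.0, sim)))


def _safe_corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0  # constant vectors: correlation undefined, report 0
    if method == "pearson":
        r = _stats.pearsonr(x, y).statistic
    else:
        r = _stats.spearmanr(x, y).statistic
    return float(r) if np.isfinite(r) else 0.0


def auxiliary_similarities(v: MatchedVectors) -> Dict[str, float]:
    """Optional correlated similarity metrics for one matched-vector pair."""
    p, q = v.predicted.astype(float), v.experimental.astype(float)
    out: Dict[str, float] = {}
    np_norm, nq_norm = np.linalg.norm(p), np.linalg.norm(q)
    out["cosine_similarity"] = (
        float(np.dot(p, q) / (np_norm * nq_norm)) if np_norm > 0 and nq_norm > 0 else 0.0
    )
    ps, qs = p.sum(), q.sum()
    out["dot_product"] = float(np.dot(p / ps, q / qs)) if ps > 0 and qs > 0 else 0.0
    out["pearson_corr"] = _safe_corr(p, q, "pearson")
    out["spearman_corr"] = _safe_corr(p, q, "spearman")
    denom = np.sum(p + q)
    out["bray_curtis"] = (
        float(1.0 - np.sum(np.abs(p - q)) / denom) if denom > 0 else 0.0
    )
    out["matched_count"] = float(np.count_nonzero(v.matched_mask))
    out["matched_fraction"] = float(np.count_nonzero(v.matched_mask) / len(p))
    return out


def consume_matched_peaks(
    spectrum: ExperimentalSpectrum,
    entry: PredictedEntry,
    tol_ppm: float = 20.0,
    tol_da: Optional[float] = None,
) -> ExperimentalSpectrum:
    """Delete (in place) the selected experimental peak of every fragment.

    Two predicted fragments selecting the same peak cause exactly one
    deletion.  Returns the spectrum for chaining.
    """
    idx = set()
    for frag in entry.fragments:
        j = _select_peak(spectrum, frag.mz, tol_ppm, tol_da)
        if j >= 0:
            idx.add(j)
    spectrum.remove_peaks(idx)
    return spectrum
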