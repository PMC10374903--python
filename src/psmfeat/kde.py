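"""Per-experimental-bin KDE distributions of predicted RT/IM with a uniform prior.

The experimental axis (RT in minutes, IM in 1/K0) is divided into equal bins
(1 min / 0.01 1/K0 by default).  Each confident PSM contributes its
*predicted* value to the bin of its *experimental* value, with an integer
multiplicity derived from its expectation value (better e-value => more
copies).  Each bin's expanded sample is smoothed by a Gaussian KDE with
Silverman's rule-of-thumb bandwidth ``h = 1.06 sigma m^(-1/5)``.

A probability read straight off a sparse bin is unreliable — a single-PSM bin
would give its own PSM an artificially high probability — so the density is
shrunk toward a uniform prior over the predicted range.  With bin occupancy
``E``, prior pseudo-count ``U`` (the occupancy of the bin at a configured
percentile), uniform density ``P_U`` and KDE density ``P_E``, the feature is

    (P_U * U) / (U + E)  +  (P_E * E) / (U + E)

which tends to ``P_U`` for empty bins and to ``P_E`` for well-populated ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

DEFAULT_RT_BIN_WIDTH = 1.0  # minutes
DEFAULT_IM_BIN_WIDTH = 0.01  # 1/K0
DEFAULT_PERCENTILE = 0.10

_SQRT_2PI = math.sqrt(2.0 * math.pi)


def default_weight_rule(evalue: float) -> int:
    """Multiplicity of a PSM in its bin: clamp(floor(-log10 e), 1, 10)."""
    if not evalue > 0:
        raise ValueError("e-value must be positive")
    return int(min(10, max(1, math.floor(-math.log10(evalue)))))


@dataclass
class KdeBin:
    """Weighted expanded sample of predicted values for one experimental bin."""

    values: np.ndarray  # expanded sample (each PSM repeated by its weight)
    bandwidth: float

    @property
    def count(self) -> int:
        return len(self.values)

    def density(self, x: float) -> float:
        """Gaussian KDE density at *x* (mean of kernels over the sample)."""
        z = (x - self.values) / self.bandwidth
        return float(np.mean(np.exp(-0.5 * z * z)) / (self.bandwidth * _SQRT_2PI))


@dataclass
class KdeBinSet:
    """All bins along one experimental axis plus the uniform-prior parameters."""

    bin_width: float
    bins: Dict[int, KdeBin]
    p_u: float = 0.0  # uniform prior density over the predicted range
    u: float = 0.0  # pseudo-count from the occupancy percentile
    predicted_range: Tuple[float, float] = (0.0, 1.0)
    charge: object = "all"

    def bin_index(self, experimental_value: float) -> int:
        return int(math.floor(experimental_value / self.bin_width))


def silverman_bandwidth(sample: np.ndarray, floor: float) -> float:
    """h = 1.06 sigma m^(-1/5); degenerate samples get the floor bandwidth."""
    m = len(sample)
    sigma = float(np.std(sample))
    if m < 2 or sigma == 0.0:
        return floor
    return max(1.06 * sigma * m ** (-0.2), floor)


def build_bins(
    triples: Sequence[Tuple[float, float, float]],
    bin_width: float = DEFAULT_RT_BIN_WIDTH,
    weight_rule: Callable[[float], int] = default_weight_rule,
    bandwidth_floor: Optional[float] = None,
    charge: object = "all",
) -> KdeBinSet:
    """Build per-bin KDEs from (experimental, predicted, evalue) triples.

    ``bandwidth_floor`` defaults to ``0.1 * bin_width`` and guards bins whose
    expanded sample has zero variance.
    """
    if not len(triples):
        raise ValueError("no PSMs available to build KDE bins")
    if bandwidth_floor is None:
        bandwidth_floor = 0.1 * bin_width
    raw: Dict[int, List[float]] = {}
    for exp_val, pred_val, evalue in triples:
        idx = int(math.floor(exp_val / bin_width))
        raw.setdefault(idx, []).extend([float(pred_val)] * weight_rule(evalue))
    bins = {
        idx: KdeBin(
            values=np.asarray(vals, dtype=float),
            bandwidth=silverman_bandwidth(np.asarray(vals, dtype=float), bandwidth_floor),
        )
        for idx, vals in raw.items()
    }
    binset = KdeBinSet(bin_width=bin_width, bins=bins, charge=charge)
    preds = np.array([t[1] for t in triples], dtype=float)
    lo, hi = float(preds.min()), float(preds.max())
    pad = 0.01 * (hi - lo) if hi > lo else max(abs(hi), 1.0) * 0.01
    binset.p_u, binset.u = uniform_prior_params(
        binset, DEFAULT_PERCENTILE, (lo - pad, hi + pad)
    )
    binset.predicted_range = (lo - pad, hi + pad)
    return binset


def uniform_prior_params(
    binset: KdeBinSet,
    percentile: float = DEFAULT_PERCENTILE,
    predicted_range: Tuple[float, float] = (0.0, 1.0),
) -> Tuple[float, float]:
    """Compute (P_U, U): uniform density over the range and the pseudo-count.

    Bins are sorted ascending by occupancy; ``U`` is the occupancy of the bin
    at the nearest-rank percentile (ties toward the smaller bin); ``P_U`` is
    1 / (range width).
    """
    lo, hi = predicted_range
    if not hi > lo:
        raise ValueError("predicted range must have positive width")
    if not binset.bins:
        raise ValueError("no non-empty bins")
    counts = sorted(b.count for b in binset.bins.values())
    rank = max(1, math.ceil(percentile * len(counts)))  # nearest-rank
    u = float(counts[rank - 1])
    p_u = 1.0 / (hi - lo)
    return p_u, u


def probability_with_uniform_prior(
    binset: KdeBinSet, experimental_value: float, predicted_value: float
) -> float:
    """Uniform-prior-shrunk KDE probability of the predicted value.

    Returns ``(P_U U + P_E E) / (U + E)`` where ``E`` is the weighted
    occupancy of the experimental value's bin and ``P_E`` the bin's KDE
    density at the predicted value.  An empty bin gives exactly ``P_U``.
    """
    idx = binset.bin_index(experimental_value)
    kbin = binset.bins.get(idx)
    u, p_u = binset.u, binset.p_u
    if kbin is None or kbin.count == 0:
        return p_u
    e = float(kbin.count)
    p_e = kbin.density(predicted_value)
    return (p_u * u + p_e * e) / (u + e)


def dump_diagnostics(binset: KdeBinSet, path) -> None:
    """Write per-bin occupancy and bandwidth as TSV for inspection."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("bin_index\tcount\tbandwidth\n")
        for idx in sorted(binset.bins):
            b = binset.bins[idx]
            fh.write(f"{idx}\t{b.count}\t{b.bandwidth:.6g}\n")
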