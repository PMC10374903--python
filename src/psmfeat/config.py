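"""Run configuration for the feature pipeline."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import List, Optional, Tuple

#: Features the pipeline can compute, in output-column order.
KNOWN_FEATURES = (
    "unweighted_spectral_entropy",
    "delta_RT_loess",
    "delta_RT_loess_normalized",
    "RT_probability_unif_prior",
    "delta_IM_loess",
    "IM_probability_unif_prior",
    # auxiliary correlated similarity metrics (optional)
    "cosine_similarity",
    "dot_product",
    "pearson_corr",
    "spearman_corr",
    "bray_curtis",
    "matched_count",
    "matched_fraction",
)

DEFAULT_FEATURES = (
    "unweighted_spectral_entropy",
    "delta_RT_loess",
    "delta_RT_loess_normalized",
    "RT_probability_unif_prior",
)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All knobs of one annotation run.

    ``mode`` is ``"dda"`` (one PSM per scan) or ``"dia"`` (up to ``top_ranks``
    co-isolated PSMs per scan, with peak consumption between ranks).
    """

    mode: str = "dda"
    top_ranks: int = 1
    tol_ppm: float = 20.0
    tol_da: Optional[float] = None  # absolute-Da tolerance overrides ppm when set
    features: Tuple[str, ...] = DEFAULT_FEATURES
    evalue_column: str = "log10_evalue"
    evalue_transform: str = "pow10_of_negated"
    evalue_threshold: float = 10.0 ** -3.5
    calibration_max_n: int = 5000
    calibration_min_n: int = 50
    rt_bandwidth: float = 0.05
    im_bandwidth: float = 0.1
    rt_bin_width: float = 1.0
    im_bin_width: float = 0.01
    kde_percentile: float = 0.10
    #: delta-mass values (rounded to 4 decimals) the prediction model supports
    supported_mod_deltas: Tuple[float, ...] = (57.0215, 15.9949, 42.0106)
    #: sentinel for delta features when inputs are missing (worst case)
    delta_sentinel: float = 100.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("dda", "dia"):
            raise ConfigError(f"mode must be dda or dia, got {self.mode!r}")
        if self.mode == "dda":
            self.top_ranks = 1
        if self.top_ranks < 1:
            raise ConfigError("top_ranks must be >= 1")
        self.features = tuple(self.features)
        unknown = [f for f in self.features if f not in KNOWN_FEATURES]
        if unknown:
            raise ConfigError(f"unknown feature name(s): {', '.join(unknown)}")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        valid = {f.name for f in fields(cls)}
        bad = set(data) - valid
        if bad:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(bad))}")
        data.update(overrides)
        return cls(**data)
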