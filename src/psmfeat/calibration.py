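"""Monotone calibration of experimental RT / ion mobility onto the predicted scale.

Confident PSMs (rank-1 targets with expectation value below a threshold,
capped at ``max_n`` by ascending e-value) supply (experimental, predicted)
pairs.  A LOESS curve (local linear, tricube weights, span = fraction of
points, no robustness iterations) is fitted and then made monotone by
isotonic (pool-adjacent-violators) regression of the fitted values; queries
interpolate linearly between training abscissae and clamp outside the
training domain.  With fewer than ``min_n`` qualifying PSMs an ordinary
least-squares line is used instead.  Ion mobility uses the same machinery
per precursor charge, with a pooled fallback for sparse charges.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .pin import PsmRecord

#: Default e-value threshold for calibration PSMs: 1x10^-3.5.
DEFAULT_EVALUE_THRESHOLD = 10.0 ** -3.5
DEFAULT_MAX_N = 5000
DEFAULT_MIN_N = 50
DEFAULT_RT_BANDWIDTH = 0.05
DEFAULT_IM_BANDWIDTH = 0.1


class CalibrationError(ValueError):
    """Calibration cannot be fitted from the available PSMs."""


@dataclass
class CalibrationModel:
    """A monotone piecewise-linear map from the experimental to the predicted scale."""

    kind: str  # "loess_monotone" | "linear"
    x_knots: np.ndarray
    y_knots: np.ndarray
    domain: Tuple[float, float]
    n_train: int
    bandwidth: float
    charge: object = "all"  # int or "all"
    residual_iqr: float = 0.0
    slope: Optional[float] = None  # linear kind only
    intercept: Optional[float] = None

    def predict(self, x) -> np.ndarray:
        """Map experimental values to the predicted scale (clamped outside domain)."""
        x = np.asarray(x, dtype=float)
        return np.interp(x, self.x_knots, self.y_knots)

    def __call__(self, x):
        out = self.predict(x)
        return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out

    # -- persistence ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "x_knots": self.x_knots.tolist(),
            "y_knots": self.y_knots.tolist(),
            "domain": list(self.domain),
            "n_train": self.n_train,
            "bandwidth": self.bandwidth,
            "charge": self.charge,
            "residual_iqr": self.residual_iqr,
            "slope": self.slope,
            "intercept": self.intercept,
        }

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            kind=d["kind"],
            x_knots=np.asarray(d["x_knots"], dtype=float),
            y_knots=np.asarray(d["y_knots"], dtype=float),
            domain=tuple(d["domain"]),
            n_train=int(d["n_train"]),
            bandwidth=float(d["bandwidth"]),
            charge=d.get("charge", "all"),
            residual_iqr=float(d.get("residual_iqr", 0.0)),
            slope=d.get("slope"),
            intercept=d.get("intercept"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def select_calibration_psms(
    psms: Sequence[PsmRecord],
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    max_n: int = DEFAULT_MAX_N,
    min_n: int = DEFAULT_MIN_N,
) -> Tuple[List[PsmRecord], str]:
    """Pick confident rank-1 target PSMs for calibration.

    Returns the qualifying set (capped at ``max_n`` by ascending e-value)
    and the regression flag: ``"loess"`` normally, ``"linear"`` when fewer
    than ``min_n`` qualify.  Raises when none qualify.
    """
    qualifying = [
        p for p in psms if p.is_target and p.rank == 1 and p.evalue < evalue_threshold
    ]
    qualifying.sort(key=lambda p: (p.evalue, p.spec_id))
    if not qualifying:
        raise CalibrationError(
            "no rank-1 target PSMs below the e-value threshold; skip RT/IM features"
        )
    flag = "linear" if len(qualifying) < min_n else "loess"
    return qualifying[:max_n], flag


def _fit_linear(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def fit_calibration(
    pairs: Sequence[Tuple[float, float]],
    flag: str = "loess",
    bandwidth: float = DEFAULT_RT_BANDWIDTH,
    charge: object = "all",
) -> CalibrationModel:
    """Fit the monotone experimental->predicted mapping from training pairs."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise CalibrationError("need at least 2 training pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise CalibrationError("all experimental values identical; cannot calibrate")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    domain = (float(x[0]), float(x[-1]))

    if flag == "linear":
        slope, intercept = _fit_linear(x, y)
        xk = np.array(domain)
        yk = slope * xk + intercept
        model = CalibrationModel(
            kind="linear",
            x_knots=xk,
            y_knots=yk,
            domain=domain,
            n_train=len(x),
            bandwidth=bandwidth,
            charge=charge,
            slope=slope,
            intercept=intercept,
        )
    elif flag == "loess":
        # span = fraction of points per local window; at least 3 points
        frac = max(bandwidth, 3.0 / len(x))
        fitted = _lowess(
            y, x, frac=min(frac, 1.0), it=0, return_sorted=False
        )
        if np.any(~np.isfinite(fitted)):  # degenerate windows: fall back locally
            fitted = np.where(np.isfinite(fitted), fitted, y)
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        mono = iso.fit_transform(x, fitted)
        # collapse duplicate abscissae so interpolation knots are unique
        xk, first = np.unique(x, return_index=True)
        yk = mono[first]
        model = CalibrationModel(
            kind="loess_monotone",
            x_knots=xk,
            y_knots=yk,
            domain=domain,
            n_train=len(x),
            bandwidth=bandwidth,
            charge=charge,
        )
    else:
        raise CalibrationError(f"unknown calibration flag {flag!r}")

    residuals = np.abs(model.predict(x) - y)
    q75, q25 = np.percentile(residuals, [75, 25])
    iqr = float(q75 - q25)
    # a perfect training fit leaves only floating-point dust; treat as zero
    if iqr < 1e-10 * max(1.0, float(np.max(np.abs(y)))):
        iqr = 0.0
    model.residual_iqr = iqr
    return model


def fit_im_models(
    psms_with_pairs: Sequence[Tuple[PsmRecord, float, float]],
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    max_n: int = DEFAULT_MAX_N,
    min_n: int = DEFAULT_MIN_N,
    bandwidth: float = DEFAULT_IM_BANDWIDTH,
) -> Dict[object, CalibrationModel]:
    """Fit one ion-mobility model per precursor charge.

    ``psms_with_pairs`` holds (record, experimental IM, predicted IM).
    Charges with fewer than ``min_n`` qualifying PSMs share a pooled
    all-charge model (key ``"all"``); the pooled model is included whenever
    any charge needs the fallback.
    """
    confident = [
        (p, xe, yp)
        for p, xe, yp in psms_with_pairs
        if p.is_target and p.rank == 1 and p.evalue < evalue_threshold
    ]
    if not confident:
        raise CalibrationError("no confident PSMs with ion mobility; skip IM features")
    by_charge: Dict[int, List[Tuple[PsmRecord, float, float]]] = {}
    for item in confident:
        by_charge.setdefault(item[0].charge, []).append(item)

    models: Dict[object, CalibrationModel] = {}
    need_pooled = False
    for charge in sorted(by_charge):
        group = sorted(by_charge[charge], key=lambda t: (t[0].evalue, t[0].spec_id))[:max_n]
        if len(group) >= min_n:
            pairs = [(xe, yp) for _, xe, yp in group]
            models[charge] = fit_calibration(pairs, "loess", bandwidth, charge=charge)
        else:
            need_pooled = True
    if need_pooled or not models:
        pooled = sorted(confident, key=lambda t: (t[0].evalue, t[0].spec_id))[:max_n]
        pairs = [(xe, yp) for _, xe, yp in pooled]
        flag = "loess" if len(pairs) >= min_n else "linear"
        try:
            models["all"] = fit_calibration(pairs, flag, bandwidth, charge="all")
        except CalibrationError:
            if not models:
                raise
            warnings.warn("pooled IM fallback could not be fitted")
    return models


def delta_rt_loess(model: CalibrationModel, rt_exp: float, rt_pred: float) -> float:
    """|calibrated experimental RT - predicted RT| on the predicted scale."""
    return abs(model(rt_exp) - rt_pred)


def delta_rt_loess_normalized(
    model: CalibrationModel,
    rt_exp: float,
    rt_pred: float,
    residual_scale: Optional[float] = None,
) -> float:
    """Delta RT divided by the IQR of the calibration residuals.

    A zero residual scale (perfect training fit) falls back to the
    unnormalised delta with a warning.
    """
    scale = model.residual_iqr if residual_scale is None else residual_scale
    raw = delta_rt_loess(model, rt_exp, rt_pred)
    if not scale > 0:
        warnings.warn("residual IQR is zero; returning unnormalised delta")
        return raw
    return raw / scale


def delta_im(model: CalibrationModel, im_exp: float, im_pred: float) -> float:
    """|calibrated experimental IM - predicted IM| (per-charge model)."""
    return abs(model(im_exp) - im_pred)
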