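"""Rescaling of raw measurements into [0, 1] network targets.

Raw readouts (binding affinities, fluorescence intensities, ...) span
arbitrary ranges and are often heavily skewed.  Before training, each
cross-validation training set is rescaled to [0, 1]: optionally
log-transformed, outliers beyond three standard deviations from the mean
are clamped to exactly three standard deviations (they would otherwise
stretch the scale and leave sparse empty regions), and the clamped values
are mapped linearly onto [0, 1].  The parameters are fitted on training
folds only and then applied unchanged to the corresponding test folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: relative shift applied before the log transform when values are <= 0
LOG_SHIFT_EPS = 1e-6


@dataclass
class RescaleParams:
    """Fitted parameters of the target rescaling transform.

    ``mean``/``sd`` are computed on the (possibly log-transformed) training
    values; ``clamp_lo``/``clamp_hi`` are mean ± 3 sd; ``out_min``/
    ``out_max`` are the min/max of the clamped training values and define
    the linear map onto [0, 1].  ``log_shift`` is the additive shift used
    inside the log transform (0 when the raw values are all positive).
    """

    mode: str  # "linear" | "log"
    mean: float
    sd: float
    clamp_lo: float
    clamp_hi: float
    out_min: float
    out_max: float
    log_shift: float = 0.0

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "mean": self.mean,
            "sd": self.sd,
            "clamp_lo": self.clamp_lo,
            "clamp_hi": self.clamp_hi,
            "out_min": self.out_min,
            "out_max": self.out_max,
            "log_shift": self.log_shift,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RescaleParams":
        return cls(**d)


def _log_transform(values: np.ndarray, shift: float) -> np.ndarray:
    return np.log(values + shift)


def _fit_log_shift(values: np.ndarray) -> float:
    """Shift making all values strictly positive before taking logs.

    Plain ln(v) when every value is positive; otherwise values are shifted
    by -min(v) plus a small fraction of the dynamic range.
    """
    vmin = float(values.min())
    if vmin > 0:
        return 0.0
    rng = float(values.max() - vmin)
    if rng == 0:
        rng = 1.0
    return -vmin + LOG_SHIFT_EPS * rng


def fit_rescaler(values, mode: str = "linear") -> RescaleParams:
    """Fit rescaling parameters on a training set of raw measurements.

    The standard deviation is the population sd (ddof=0).  Raises on fewer
    than two values or zero dynamic range.
    """
    if mode not in ("linear", "log"):
        raise ValueError(f"unknown rescale mode {mode!r}")
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 values to fit a rescaler")
    if np.ptp(vals) == 0:
        raise ValueError("all values identical: zero dynamic range, cannot rescale")
    shift = 0.0
    if mode == "log":
        shift = _fit_log_shift(vals)
        vals = _log_transform(vals, shift)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    clamp_lo = mean - 3.0 * sd
    clamp_hi = mean + 3.0 * sd
    clamped = np.clip(vals, clamp_lo, clamp_hi)
    out_min = float(clamped.min())
    out_max = float(clamped.max())
    if not out_min < out_max:
        raise ValueError("zero dynamic range after clamping, cannot rescale")
    return RescaleParams(
        mode=mode,
        mean=mean,
        sd=sd,
        clamp_lo=clamp_lo,
        clamp_hi=clamp_hi,
        out_min=out_min,
        out_max=out_max,
        log_shift=shift,
    )


def apply_rescaler(params: RescaleParams, values) -> np.ndarray:
    """Map raw values onto [0, 1] with previously fitted parameters.

    Test values outside the training range are clamped, never rejected, so
    the mapping is total and monotone non-decreasing.
    """
    vals = np.asarray(list(values), dtype=float)
    if params.mode == "log":
        # keep the argument of log positive even for unseen smaller values
        vals = np.maximum(vals + params.log_shift, LOG_SHIFT_EPS * 1e-3)
        vals = np.log(vals)
    vals = np.clip(vals, params.clamp_lo, params.clamp_hi)
    scaled = (vals - params.out_min) / (params.out_max - params.out_min)
    return np.clip(scaled, 0.0, 1.0)
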