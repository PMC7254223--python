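"""Force-signal processing: preload offset, CoF, smoothing, endpoint statistic.

The friction sensor is preloaded, so the raw friction channel carries a
constant offset that is estimated from the pre-motion (static) segment and
subtracted.  The coefficient of friction is the rectified ratio
``|friction| / normal`` — rectified because the friction force flips sign
with each reciprocating stroke while the reported CoF is unsigned.  The
headline statistic compares the mean of the first and last 1000 CoF
samples and reports the change as a percentage of the initial mean.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io_formats import ForceRecord

__all__ = [
    "CoFTrace",
    "DeviationResult",
    "offset_friction",
    "compute_cof",
    "smooth_trace",
    "percent_change_endpoints",
    "FrictionProcessor",
]

MIN_STATIC_SAMPLES = 10


@dataclass
class CoFTrace:
    """Coefficient-of-friction time series (dimensionless, >= 0)."""

    time: np.ndarray
    cof: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.cof = np.asarray(self.cof, dtype=float)
        if len(self.time) != len(self.cof):
            raise ValueError("time and cof lengths differ")
        if not np.all(np.isfinite(self.cof)):
            raise ValueError("cof must be finite")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class DeviationResult:
    """Percentage change between the first and last averaging windows.

    ``percent`` is nonnegative; ``direction`` carries the sign
    ("increase" or "decrease"); ``window`` is the number of samples
    averaged at each end.
    """

    percent: float
    direction: str
    window: int

    def __str__(self) -> str:  # matches the reporting style "61.55%-Increase"
        return f"{self.percent:.2f}%-{self.direction.capitalize()}"


def offset_friction(record: ForceRecord) -> ForceRecord:
    """Remove the friction-sensor preload using the static segment mean.

    The static segment (``time <= static_segment_end``) precedes any
    motion, so its mean friction is pure sensor offset.  After the shift
    the static segment has zero mean; applying the correction twice is a
    no-op.
    """
    static = record.time <= record.static_segment_end
    n_static = int(np.count_nonzero(static))
    if n_static < MIN_STATIC_SAMPLES:
        raise ValueError(
            f"static segment has {n_static} samples; "
            f">= {MIN_STATIC_SAMPLES} required for offset calibration"
        )
    shift = float(record.friction_raw[static].mean())
    return replace(record, friction_raw=record.friction_raw - shift)


def compute_cof(record: ForceRecord, epsilon: float | None = None) -> CoFTrace:
    """Rectified CoF trace ``|friction| / normal`` over the motion span.

    Parameters
    ----------
    record : ForceRecord
        Offset-corrected record.
    epsilon : float, optional
        Minimum valid normal force; samples at or below it are trimmed.
        Defaults to 1% of the median normal force.

    The pre-motion static segment is excluded: the CoF trend is defined
    during sliding only.
    """
    motion = record.time > record.static_segment_end
    time = record.time[motion]
    normal = record.normal_raw[motion]
    friction = record.friction_raw[motion]
    if epsilon is None:
        epsilon = 0.01 * float(np.median(np.abs(record.normal_raw)))
    valid = normal > epsilon
    if not np.any(valid):
        raise ValueError("normal force never exceeds the validity threshold")
    return CoFTrace(time=time[valid], cof=np.abs(friction[valid]) / normal[valid])


def smooth_trace(trace: CoFTrace, window: int) -> CoFTrace:
    """Centered moving average; the window shrinks at the edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd number of samples")
    if window > len(trace):
        raise ValueError("window longer than the trace")
    smoothed = (
        pd.Series(trace.cof).rolling(window, center=True, min_periods=1).mean()
    )
    return CoFTrace(time=trace.time.copy(), cof=smoothed.to_numpy())


def percent_change_endpoints(values, window: int = 1000) -> DeviationResult:
    """Endpoint deviation: mean of the last ``window`` samples vs the first.

    ``percent = 100 |d| / mean(first window)`` with
    ``d = mean(last) - mean(first)``; the direction is "increase" for
    ``d > 0`` and "decrease" otherwise (a zero change reports
    0%-increase).  Accepts a CoFTrace, a trend series or a plain array.
    """
    arr = np.asarray(getattr(values, "cof", getattr(values, "value", values)),
                     dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(arr) < 2 * window:
        raise ValueError(
            f"need >= {2 * window} samples for two {window}-sample windows, "
            f"got {len(arr)}"
        )
    first = float(arr[:window].mean())
    last = float(arr[-window:].mean())
    if first == 0:
        raise ValueError("first-window mean is zero; percentage undefined")
    d = last - first
    return DeviationResult(
        percent=100.0 * abs(d) / abs(first),
        direction="increase" if d > 0 else "decrease" if d < 0 else "increase",
        window=window,
    )


class FrictionProcessor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: raw force record -> smoothed CoF trace.

    Parameters
    ----------
    smoothing_window : int
        Moving-average window in samples (odd); 1 disables smoothing.
    endpoint_window : int
        Samples averaged at each end for the deviation statistic.
    load : float or None
        Configured normal load in N; when given, the normal-force
        validity threshold is 1% of it.

    Fitted attributes: ``offset_`` (estimated preload in N),
    ``deviation_`` and ``deviation_raw_`` (endpoint statistics on the
    smoothed and unsmoothed trace) after :meth:`transform`.
    """

    def __init__(self, smoothing_window: int = 51, endpoint_window: int = 1000,
                 load: float | None = None):
        self.smoothing_window = smoothing_window
        self.endpoint_window = endpoint_window
        self.load = load

    def fit(self, X: ForceRecord, y=None) -> "FrictionProcessor":
        static = X.time <= X.static_segment_end
        if int(np.count_nonzero(static)) < MIN_STATIC_SAMPLES:
            raise ValueError("static segment too short for offset calibration")
        self.offset_ = float(X.friction_raw[static].mean())
        return self

    def transform(self, X: ForceRecord) -> CoFTrace:
        if not hasattr(self, "offset_"):
            self.fit(X)
        corrected = replace(X, friction_raw=X.friction_raw - self.offset_)
        eps = 0.01 * self.load if self.load is not None else None
        raw = compute_cof(corrected, epsilon=eps)
        trace = smooth_trace(raw, self.smoothing_window)
        self.deviation_raw_ = percent_change_endpoints(raw, self.endpoint_window)
        self.deviation_ = percent_change_endpoints(trace, self.endpoint_window)
        return trace
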