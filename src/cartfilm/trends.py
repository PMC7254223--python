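"""Trend analytics and parameter calibration.

The recording is segmented into reciprocating cycles; one sample per cycle
(the one nearest the cycle's temporal midpoint, avoiding turnaround
artifacts) feeds the six-cycle endpoint statistic.  Calibration sweeps a
grid of (TopHat width, Threshold) settings, eliminates settings whose
particle-count trend contradicts the independent fluorescence-intensity
trend ("knockout"), and picks the survivor whose baseline-normalized
linear slope is closest to the intensity slope — photobleaching makes
absolute intensity untrustworthy, but its *relative* decay rate is a
usable reference for the count decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .friction import DeviationResult, percent_change_endpoints
from .imaging import (
    ContactMask,
    PipelineSettings,
    disk_structuring_element,
    label_particles,
    threshold_binarize,
    white_tophat,
)
from .io_formats import ImageStack

__all__ = [
    "TrendSeries",
    "SweepEntry",
    "KnockoutChart",
    "CalibrationResult",
    "mean_mask_intensity",
    "segment_cycles",
    "percent_decrease_cycles",
    "linear_slope",
    "knockout_sweep",
    "eliminate_opposite",
    "select_setting",
    "analyze_static_loading",
    "SettingsCalibrator",
]


@dataclass
class TrendSeries:
    """Any per-frame scalar vs time (count, size, intensity, CoF)."""

    time: np.ndarray
    value: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if len(self.time) != len(self.value):
            raise ValueError("time and value lengths differ")
        if np.any(np.diff(self.time) < 0):
            raise ValueError("time must be nondecreasing")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class SweepEntry:
    """One grid point of the knockout chart."""

    settings: PipelineSettings
    percent: float | None = None
    direction: str | None = None
    counts: TrendSeries | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass
class KnockoutChart:
    """Percent count decrease per swept setting plus the reference direction."""

    entries: list
    flm_direction: str

    def __post_init__(self) -> None:
        keys = [(e.settings.tophat_width, e.settings.threshold)
                for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate sweep settings")

    def surviving(self) -> list:
        return [e for e in self.entries if e.ok]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tophat_width": [e.settings.tophat_width for e in self.entries],
                "threshold": [e.settings.threshold for e in self.entries],
                "percent": [e.percent for e in self.entries],
                "direction": [e.direction for e in self.entries],
                "error": [e.error for e in self.entries],
            }
        )


@dataclass
class CalibrationResult:
    """Chosen processing setting and the slope evidence behind it."""

    chosen: PipelineSettings
    chosen_slope: float
    flm_slope: float
    candidates: list = field(default_factory=list)  # (settings, slope) by rank


def mean_mask_intensity(stack: ImageStack, mask: ContactMask) -> TrendSeries:
    """Per-frame mean intensity over the contact disk.

    Recomputed from the frames; this stands in for the intensity trend the
    original camera software exported directly.
    """
    inside = mask.boolean(stack.frames.shape[1:])
    if not inside.any():
        raise ValueError("contact mask is disjoint from the frame")
    vals = stack.frames[:, inside].mean(axis=1)
    return TrendSeries(time=stack.timestamps.copy(), value=vals,
                       label="mean_mask_intensity")


def segment_cycles(times, cycle_period: float):
    """Assign samples to reciprocating cycles and pick mid-cycle samples.

    Sample ``i`` belongs to cycle ``floor(t_i / period)``.  Per cycle the
    sample whose time is nearest ``(k + 0.5) * period`` is the mid-cycle
    sample; ties break toward the earlier sample.

    Returns
    -------
    (ndarray, ndarray)
        Per-sample cycle index and the mid-cycle sample indices in cycle
        order.
    """
    times = np.asarray(times, dtype=float)
    if not cycle_period > 0:
        raise ValueError("cycle_period must be positive")
    if len(times) > 1 and cycle_period < np.min(np.diff(times)):
        raise ValueError("cycle period shorter than the sampling interval")
    cycle_idx = np.floor(times / cycle_period).astype(int)
    mids = []
    for k in np.unique(cycle_idx):
        members = np.flatnonzero(cycle_idx == k)
        target = (k + 0.5) * cycle_period
        # argmin returns the first minimum -> earlier sample on ties
        mids.append(members[np.argmin(np.abs(times[members] - target))])
    return cycle_idx, np.asarray(mids, dtype=int)


def percent_decrease_cycles(trend: TrendSeries, cycle_period: float,
                            n_cycles: int = 6) -> DeviationResult:
    """Six-cycle endpoint statistic on mid-cycle samples.

    Mean of the first ``n_cycles`` mid-cycle values minus the mean of the
    last ``n_cycles``, as a percentage of the first mean; the direction
    follows the sign of the change over time.
    """
    _, mids = segment_cycles(trend.time, cycle_period)
    if len(mids) < 2 * n_cycles:
        raise ValueError(
            f"need >= {2 * n_cycles} cycles, found {len(mids)}"
        )
    res = percent_change_endpoints(trend.value[mids], window=n_cycles)
    return res


def linear_slope(trend: TrendSeries, normalize: bool = False) -> float:
    """Ordinary least-squares slope of value vs time.

    With ``normalize=True`` the slope is divided by the fitted value at
    the first timestamp, giving fraction-of-baseline per second — the
    scale-free "tangent direction" that makes particle counts comparable
    with fluorescence intensity across different y axes.
    """
    if len(trend) < 2:
        raise ValueError("need at least two points")
    t = trend.time - trend.time[0]
    if np.ptp(t) == 0:
        raise ValueError("all timestamps equal")
    slope, intercept = np.polyfit(t, trend.value, 1)
    if not normalize:
        return float(slope)
    if intercept == 0:
        raise ValueError("fitted baseline is zero; normalized slope undefined")
    return float(slope / intercept)


def _count_trends_by_settings(stack: ImageStack, mask: ContactMask, grid):
    """Particle-count trend per setting, sharing top-hats across thresholds."""
    inside = mask.boolean(stack.frames.shape[1:])
    by_width: dict[int, list] = {}
    for s in grid:
        by_width.setdefault(s.tophat_width, []).append(s)
    counts = {(s.tophat_width, s.threshold): [] for s in grid}
    for frame in stack.frames:
        for width, settings in by_width.items():
            th = white_tophat(frame, disk_structuring_element(width))
            for s in settings:
                binary = threshold_binarize(th, s.threshold) & inside
                n = len(label_particles(binary, mask))
                counts[(s.tophat_width, s.threshold)].append(n)
    return {
        key: TrendSeries(time=stack.timestamps.copy(),
                         value=np.asarray(vals, dtype=float),
                         label=f"count_{key[0]}_{key[1]}")
        for key, vals in counts.items()
    }


def knockout_sweep(stack: ImageStack, mask: ContactMask, grid,
                   flm: TrendSeries, cycle_period: float,
                   n_cycles: int = 6) -> KnockoutChart:
    """Run the count pipeline for every grid setting and tag its direction.

    Failed settings are recorded as failed entries rather than aborting
    the sweep.  The reference direction comes from the sign of the
    fluorescence-intensity linear slope.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty sweep grid")
    flm_dir = "decrease" if linear_slope(flm) < 0 else "increase"
    trends = _count_trends_by_settings(stack, mask, grid)
    entries = []
    for s in grid:
        counts = trends[(s.tophat_width, s.threshold)]
        try:
            dev = percent_decrease_cycles(counts, cycle_period, n_cycles)
            entries.append(SweepEntry(settings=s, percent=dev.percent,
                                      direction=dev.direction, counts=counts))
        except ValueError as exc:
            entries.append(SweepEntry(settings=s, counts=counts, error=str(exc)))
    return KnockoutChart(entries=entries, flm_direction=flm_dir)


def eliminate_opposite(chart: KnockoutChart) -> KnockoutChart:
    """Knock out settings whose count trend contradicts the intensity trend."""
    keep = [e for e in chart.surviving() if e.direction == chart.flm_direction]
    if not keep:
        raise ValueError("all sweep entries eliminated; no candidate settings")
    return KnockoutChart(entries=keep, flm_direction=chart.flm_direction)


def select_setting(chart: KnockoutChart, stack: ImageStack, mask: ContactMask,
                   flm: TrendSeries, cycle_period: float) -> CalibrationResult:
    """Pick the survivor whose normalized count slope best matches intensity.

    Both slopes are baseline-normalized (fraction of initial value per
    second) so the comparison is meaningful across the two quantities.
    Ties break toward smaller TopHat width, then smaller threshold.
    """
    survivors = chart.surviving()
    if not survivors:
        raise ValueError("empty candidate chart")
    flm_slope = linear_slope(flm, normalize=True)
    ranked = []
    for e in survivors:
        counts = e.counts
        if counts is None:
            trends = _count_trends_by_settings(stack, mask, [e.settings])
            counts = trends[(e.settings.tophat_width, e.settings.threshold)]
        slope = linear_slope(counts, normalize=True)
        ranked.append((e.settings, slope))
    ranked.sort(
        key=lambda c: (abs(c[1] - flm_slope), c[0].tophat_width, c[0].threshold)
    )
    chosen, chosen_slope = ranked[0]
    return CalibrationResult(chosen=chosen, chosen_slope=chosen_slope,
                             flm_slope=flm_slope, candidates=ranked)


def analyze_static_loading(stack: ImageStack, mask: ContactMask,
                           settings: PipelineSettings,
                           load_trace: TrendSeries) -> pd.DataFrame:
    """Align count/size/intensity trends with a gradually rising load.

    The load trace is resampled to the frame timestamps (linear
    interpolation); returns one row per frame with columns
    ``timestamp, load, particle_count, mean_size_um, intensity``.
    """
    from .imaging import process_stack

    t0 = max(stack.timestamps[0], load_trace.time[0])
    t1 = min(stack.timestamps[-1], load_trace.time[-1])
    if t0 > t1:
        raise ValueError("stack and load trace do not overlap in time")
    counts, sizes = process_stack(stack, mask, settings)
    intensity = mean_mask_intensity(stack, mask)
    load = np.interp(stack.timestamps, load_trace.time, load_trace.value)
    return pd.DataFrame(
        {
            "timestamp": stack.timestamps,
            "load": load,
            "particle_count": counts.value,
            "mean_size_um": sizes.value,
            "intensity": intensity.value,
        }
    )


class SettingsCalibrator(BaseEstimator):
    """Sklearn-style estimator: fit the processing setting to a recording.

    ``fit`` runs the knockout sweep over ``grid``, eliminates settings
    contradicting the fluorescence-intensity direction, and selects the
    survivor with the closest baseline-normalized slope.

    Parameters
    ----------
    grid : sequence of PipelineSettings or None
        Candidate settings; the default brackets the published working
        points 15/4 and 13/4 (TopHat widths 9..19, thresholds 2..6).
    mask : ContactMask
        Contact region of the recording.
    cycle_period : float
        Reciprocating cycle duration in seconds.
    n_cycles : int
        Cycles averaged at each end of the percent-decrease statistic.

    Fitted attributes: ``settings_`` (chosen PipelineSettings),
    ``chart_`` (post-elimination knockout chart), ``result_``
    (full CalibrationResult), ``flm_`` (intensity trend used).
    """

    DEFAULT_WIDTHS = (9, 11, 13, 15, 17, 19)
    DEFAULT_THRESHOLDS = (2, 3, 4, 5, 6)

    def __init__(self, grid=None, mask: ContactMask | None = None,
                 cycle_period: float = 2.0, n_cycles: int = 6):
        self.grid = grid
        self.mask = mask
        self.cycle_period = cycle_period
        self.n_cycles = n_cycles

    def _grid(self):
        if self.grid is not None:
            return list(self.grid)
        return [
            PipelineSettings(tophat_width=w, threshold=t)
            for w in self.DEFAULT_WIDTHS
            for t in self.DEFAULT_THRESHOLDS
        ]

    def fit(self, X: ImageStack, y=None) -> "SettingsCalibrator":
        if self.mask is None:
            raise ValueError("a ContactMask is required")
        self.flm_ = mean_mask_intensity(X, self.mask)
        chart = knockout_sweep(X, self.mask, self._grid(), self.flm_,
                               self.cycle_period, self.n_cycles)
        self.chart_ = eliminate_opposite(chart)
        self.result_ = select_setting(self.chart_, X, self.mask, self.flm_,
                                      self.cycle_period)
        self.settings_ = self.result_.chosen
        return self
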