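"""Synthetic contact recordings and force logs with planted ground truth.

No raw recordings from the original instrument are published, so the
pipeline is exercised on generated data that emulates its statistical
structure: a bright circular contact with spatially correlated "pore"
noise, sparse isotropic Gaussian clusters of labelled protein whose count
decays over the cycles, global multiplicative photobleaching, and a
reciprocating friction trace with a preloaded sensor offset and a rising
coefficient of friction.  Every generator is deterministic given the seed
and returns the planted truth alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging import ContactMask
from .io_formats import ForceRecord, ImageStack
from .trends import TrendSeries

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_contact_stack",
    "generate_force_log",
    "generate_static_loading",
]


@dataclass
class SyntheticSpec:
    """Scenario description for the generators.

    Imaging defaults follow the sliding experiment: 60 cycles of a 20 mm
    stroke at 10 mm/s (2 s per cycle, 120 s of motion) recorded at 1 Hz
    on a 256 x 214 px frame — a desk-scale stand-in for the camera's
    2560 x 2140 px snaps.  Cluster amplitude 30 over pore-noise sigma 2
    gives a signal-to-noise ratio of 15.
    """

    # imaging geometry
    shape: tuple = (214, 256)          # (height, width) px
    pixel_scale: float = 3.75          # um / px
    frame_rate: float = 1.0            # Hz
    duration: float = 120.0            # s
    mask: ContactMask | None = None    # default: centered, radius 100 px

    # background and pore noise
    background: float = 40.0           # native units
    noise_sigma: float = 2.0           # native units
    noise_corr_px: float = 3.0         # spatial correlation length, px

    # cluster model
    n0: int = 40                       # initial cluster count
    amplitude: float | tuple = 30.0    # peak above background, or (lo, hi)
    diameter_mean: float = 6.0         # px
    diameter_sigma: float = 1.0        # px
    count_schedule: str = "linear"     # or "exponential"
    f_end: float = 0.75                # final count as fraction of n0
    min_spacing_factor: float = 3.0    # min center distance in diameters
    bleach_rate: float = 0.0025        # 1/s, global multiplicative decay

    # friction model (Table-2-style sliding experiment)
    load: float = 10.0                 # N
    stroke: float = 20.0               # mm
    velocity: float = 10.0             # mm/s
    n_cycles: int = 60
    cof_start: float = 0.02
    cof_end: float = 0.0323
    cof_hold_frac: float = 0.1         # plateau fraction at each end
    preload_offset: float = 2.3        # N
    force_noise_sigma: float = 0.01    # N
    force_rate: float = 100.0          # Hz
    static_duration: float = 5.0       # s before motion starts

    # static-loading experiment
    ramp_duration: float = 12.0        # s of linearly rising load
    hold_duration: float = 18.0        # s at full load afterwards
    count_start: int = 120
    count_end: int = 40
    diameter_start: float = 5.0        # px
    diameter_end: float = 9.0          # px

    seed: int = 0

    def __post_init__(self) -> None:
        if self.mask is None:
            h, w = self.shape
            self.mask = ContactMask(center_x=w / 2, center_y=h / 2,
                                    radius=min(h, w) * 0.47)
        if self.n0 < 0 or self.f_end < 0:
            raise ValueError("n0 and f_end must be nonnegative")
        if np.min(self.amplitude) <= 0:
            raise ValueError("cluster amplitude must be positive")
        if self.noise_sigma < 0 or self.force_noise_sigma < 0:
            raise ValueError("noise sigmas must be nonnegative")

    @property
    def cycle_period(self) -> float:
        return self.stroke / self.velocity


@dataclass
class SyntheticTruth:
    """Planted ground truth of one generated recording."""

    counts: np.ndarray | None = None           # per frame
    centroids: list = field(default_factory=list)   # per frame: (n, 2) y,x
    diameters: list = field(default_factory=list)   # per frame: (n,) px
    amplitudes: list = field(default_factory=list)  # per frame: (n,)
    intensity_trend: TrendSeries | None = None
    cof_trend: TrendSeries | None = None
    percent_count: float | None = None
    count_direction: str | None = None
    percent_cof: float | None = None
    cof_direction: str | None = None

    def to_json(self, path) -> None:
        def _ser(x):
            if isinstance(x, TrendSeries):
                return {"time": x.time.tolist(), "value": x.value.tolist(),
                        "label": x.label}
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, list):
                return [_ser(v) for v in x]
            return x

        payload = {k: _ser(v) for k, v in vars(self).items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        for key in ("intensity_trend", "cof_trend"):
            if payload.get(key) is not None:
                payload[key] = TrendSeries(**payload[key])
        if payload.get("counts") is not None:
            payload["counts"] = np.asarray(payload["counts"])
        return cls(**payload)


# ---------------------------------------------------------------------------
# helpers

def _stochastic_round(rng, x: float) -> int:
    base = int(np.floor(x))
    return base + (1 if rng.random() < x - base else 0)


def _sample_positions(rng, count: int, mask: ContactMask, margin: float,
                      min_dist: float, max_tries: int = 400):
    """Uniform positions in the contact disk with a minimum pairwise spacing."""
    r_max = mask.radius - margin
    if r_max <= 0:
        raise ValueError("clusters too large for the contact mask")
    pts: list = []
    tries = 0
    while len(pts) < count:
        tries += 1
        if tries > max_tries * max(count, 1):
            raise ValueError(
                "cannot place clusters at the requested spacing inside the mask"
            )
        rho = r_max * np.sqrt(rng.random())
        phi = 2 * np.pi * rng.random()
        y = mask.center_y + rho * np.sin(phi)
        x = mask.center_x + rho * np.cos(phi)
        if all((y - py) ** 2 + (x - px) ** 2 >= min_dist**2 for py, px in pts):
            pts.append((y, x))
    return np.asarray(pts, dtype=float).reshape(count, 2)


def _pore_noise(rng, shape, sigma: float, corr_px: float,
                inside: np.ndarray) -> np.ndarray:
    if sigma == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    smooth = gaussian_filter(white, corr_px) if corr_px > 0 else white
    smooth *= sigma / smooth.std()
    return np.where(inside, smooth, 0.0)


def _add_gaussians(img: np.ndarray, centroids, diameters, amplitudes) -> None:
    h, w = img.shape
    for (cy, cx), d, a in zip(centroids, diameters, amplitudes):
        sg = max(d / 4.0, 0.5)
        r = int(np.ceil(3 * sg))
        y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
        x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += a * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sg * sg)
        )


def _draw_amplitudes(rng, amplitude, n: int) -> np.ndarray:
    if np.ndim(amplitude) == 0:
        return np.full(n, float(amplitude))
    lo, hi = amplitude
    return rng.uniform(lo, hi, size=n)


def _percent_of(first: float, last: float):
    d = last - first
    pct = 100.0 * abs(d) / abs(first) if first else 0.0
    return pct, ("increase" if d > 0 else "decrease" if d < 0 else "increase")


# ---------------------------------------------------------------------------
# generators

def _render_stack(spec, rng, times, counts_sched, diam_mean_sched,
                  spacing_sched):
    """Shared renderer: returns (frames uint16, truth arrays)."""
    h, w = spec.shape
    inside = spec.mask.boolean((h, w))
    frames = np.empty((len(times), h, w), dtype=np.uint16)
    counts, cents, diams, amps = [], [], [], []
    for i, t in enumerate(times):
        n = _stochastic_round(rng, counts_sched[i])
        dmean = diam_mean_sched[i]
        diameters = np.clip(
            rng.normal(dmean, spec.diameter_sigma, size=n), 2.0, None
        )
        positions = _sample_positions(
            rng, n, spec.mask, margin=dmean,
            min_dist=spacing_sched[i],
        )
        amplitudes = _draw_amplitudes(rng, spec.amplitude, n)
        img = np.full((h, w), float(spec.background))
        img += _pore_noise(rng, (h, w), spec.noise_sigma, spec.noise_corr_px,
                           inside)
        _add_gaussians(img, positions, diameters, amplitudes)
        img *= np.exp(-spec.bleach_rate * t)
        frames[i] = np.clip(np.rint(img), 0, np.iinfo(np.uint16).max)
        counts.append(n)
        cents.append(positions)
        diams.append(diameters)
        amps.append(amplitudes)
    return frames, np.asarray(counts), cents, diams, amps


def generate_contact_stack(spec: SyntheticSpec):
    """Sliding-experiment recording: decaying cluster count plus bleaching.

    Returns
    -------
    (ImageStack, SyntheticTruth)
        The truth carries realized per-frame counts/centroids/diameters,
        the planted intensity trend and the planted six-cycle percent
        decrease of the count schedule.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration * spec.frame_rate))
    if n_frames < 1:
        raise ValueError("duration too short for a single frame")
    times = np.arange(n_frames) / spec.frame_rate
    t_last = times[-1] if n_frames > 1 else 1.0

    if spec.count_schedule == "linear":
        sched = spec.n0 + (spec.f_end - 1.0) * spec.n0 * times / t_last
    elif spec.count_schedule == "exponential":
        sched = spec.n0 * spec.f_end ** (times / t_last)
    else:
        raise ValueError(f"unknown count schedule {spec.count_schedule!r}")

    spacing = np.full(n_frames, spec.min_spacing_factor * spec.diameter_mean)
    dmeans = np.full(n_frames, spec.diameter_mean)
    frames, counts, cents, diams, amps = _render_stack(
        spec, rng, times, sched, dmeans, spacing
    )
    stack = ImageStack(frames=frames, timestamps=times,
                       pixel_scale=spec.pixel_scale)

    intensity = TrendSeries(
        time=times,
        value=spec.background * np.exp(-spec.bleach_rate * times),
        label="planted_intensity",
    )
    # planted six-cycle statistic of the noise-free schedule
    from .trends import percent_decrease_cycles

    sched_trend = TrendSeries(time=times, value=sched, label="planted_counts")
    try:
        dev = percent_decrease_cycles(sched_trend, spec.cycle_period)
        pct, direction = dev.percent, dev.direction
    except ValueError:
        pct, direction = None, None
    truth = SyntheticTruth(
        counts=counts, centroids=cents, diameters=diams, amplitudes=amps,
        intensity_trend=intensity, percent_count=pct,
        count_direction=direction,
    )
    return stack, truth


def _cof_schedule(spec, t_motion: np.ndarray) -> np.ndarray:
    """Plateau-ramp-plateau CoF: holds at each end keep the endpoint
    windows on the planted levels."""
    total = spec.n_cycles * spec.cycle_period
    hold = spec.cof_hold_frac * total
    ramp = np.clip((t_motion - hold) / max(total - 2 * hold, 1e-12), 0.0, 1.0)
    return spec.cof_start + (spec.cof_end - spec.cof_start) * ramp


def generate_force_log(spec: SyntheticSpec):
    """Reciprocating friction trace with preload offset and rising CoF.

    The friction channel is ``sign(stroke direction) * mu(t) * load``
    plus the preload offset and sensor noise, preceded by a static
    segment of pure offset.
    """
    rng = np.random.default_rng(spec.seed + 1)
    period = spec.cycle_period
    motion_duration = spec.n_cycles * period
    if motion_duration < period:
        raise ValueError("duration shorter than one cycle")
    dt = 1.0 / spec.force_rate
    n_total = int(round((spec.static_duration + motion_duration) / dt))
    time = np.arange(n_total) * dt
    motion = time > spec.static_duration
    t_motion = time[motion] - spec.static_duration

    normal = spec.load + rng.normal(0, spec.force_noise_sigma, n_total)
    friction = np.full(n_total, spec.preload_offset)
    friction += rng.normal(0, spec.force_noise_sigma, n_total)
    mu = _cof_schedule(spec, t_motion)
    sgn = np.where(np.floor(t_motion / period).astype(int) % 2 == 0, 1.0, -1.0)
    friction[motion] += sgn * mu * spec.load

    record = ForceRecord(time=time, normal_raw=normal, friction_raw=friction,
                         static_segment_end=spec.static_duration)
    pct, direction = _percent_of(spec.cof_start, spec.cof_end)
    truth = SyntheticTruth(
        cof_trend=TrendSeries(time=time[motion], value=mu, label="planted_cof"),
        percent_cof=pct, cof_direction=direction,
    )
    return record, truth


def generate_static_loading(spec: SyntheticSpec):
    """Static-loading recording: load ramps linearly 0 -> load, the cluster
    count falls and the cluster size rises during the ramp.

    Spacing is relaxed to 1.5 diameters here — the scene is denser than
    the sliding fixture and only trend directions are asserted on it.

    Returns
    -------
    (ImageStack, TrendSeries, SyntheticTruth)
        Stack, load trace and planted truth.
    """
    rng = np.random.default_rng(spec.seed + 2)
    total = spec.ramp_duration + spec.hold_duration
    n_frames = max(int(round(total * spec.frame_rate)), 1)
    times = np.arange(n_frames) / spec.frame_rate

    if spec.ramp_duration == 0:
        counts_sched = np.full(n_frames, float(spec.count_start))
        dmeans = np.full(n_frames, spec.diameter_start)
        load_vals = np.full(n_frames, spec.load)
    else:
        ramp = np.clip(times / spec.ramp_duration, 0.0, 1.0)
        counts_sched = spec.count_start + (spec.count_end - spec.count_start) * ramp
        # slight further decrease after the ramp, as seen post-loading
        after = np.clip((times - spec.ramp_duration) /
                        max(spec.hold_duration, 1e-12), 0.0, 1.0)
        counts_sched = counts_sched - 0.05 * spec.count_end * after
        dmeans = spec.diameter_start + (spec.diameter_end - spec.diameter_start) * ramp
        load_vals = spec.load * ramp

    spacing = 1.5 * dmeans
    frames, counts, cents, diams, amps = _render_stack(
        spec, rng, times, counts_sched, dmeans, spacing
    )
    stack = ImageStack(frames=frames, timestamps=times,
                       pixel_scale=spec.pixel_scale)
    load_trace = TrendSeries(time=times, value=load_vals, label="load_N")
    truth = SyntheticTruth(
        counts=counts, centroids=cents, diameters=diams, amplitudes=amps,
        intensity_trend=TrendSeries(
            time=times,
            value=spec.background * np.exp(-spec.bleach_rate * times),
            label="planted_intensity",
        ),
    )
    return stack, load_trace, truth
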