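"""Readers and writers for contact recordings, force logs and result tables.

The experiment produces two parallel data streams: a fluorescence video of
the cartilage-glass contact (here an :class:`ImageStack`) and a force log
from the tribometer's normal-load and friction sensors (a
:class:`ForceRecord`).  This module also holds the experiment-configuration
types and their planning arithmetic (total sliding distance, Hertzian mean
contact pressure).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

__all__ = [
    "ImageStack",
    "ForceRecord",
    "ExperimentConfig",
    "ImagingConfig",
    "read_image_stack",
    "write_image_stack",
    "read_force_log",
    "write_force_log",
    "plan_total_distance",
    "hertz_mean_pressure",
    "write_results",
]

# Filter sets of the fluorescence microscope: excitation/emission in nm.
FILTER_BANDS = {"FITC": (490, 525), "TRITC": (557, 576)}


@dataclass
class ImageStack:
    """Ordered fluorescence frames of one recording.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Intensities in native camera units, nonnegative.
    timestamps : ndarray, shape (n_frames,)
        Seconds from recording start, strictly increasing.
    pixel_scale : float
        Micrometers per pixel (3.75 for the double-magnification lens).
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_scale: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3 or len(self.frames) == 0:
            raise ValueError("stack must contain at least one 2-D frame")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be nonnegative")
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]


@dataclass
class ForceRecord:
    """Raw force log: normal and friction channels before offset correction.

    ``static_segment_end`` marks the end (in seconds) of the pre-motion
    segment used to estimate the friction-sensor preload offset.
    """

    time: np.ndarray
    normal_raw: np.ndarray
    friction_raw: np.ndarray
    static_segment_end: float = 0.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.normal_raw = np.asarray(self.normal_raw, dtype=float)
        self.friction_raw = np.asarray(self.friction_raw, dtype=float)
        n = len(self.time)
        if len(self.normal_raw) != n or len(self.friction_raw) != n:
            raise ValueError("channel lengths must match")
        if n == 0:
            raise ValueError("empty force record")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (0 <= self.static_segment_end <= self.time[-1]):
            raise ValueError("static_segment_end outside the record")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class ExperimentConfig:
    """Operating conditions of a reciprocating experiment.

    One cycle is one stroke-long pass, so the cycle period is
    ``stroke / velocity`` and the planned total distance is
    ``stroke * n_cycles``.
    """

    load: float = 10.0            # N
    contact_pressure: float = 0.8  # MPa, informational
    velocity: float = 10.0        # mm/s
    stroke: float = 20.0          # mm
    n_cycles: int = 60
    temperature: float = 37.0     # degC
    frame_rate: float = 1.0       # Hz

    def __post_init__(self) -> None:
        if not self.load > 0:
            raise ValueError("load must be positive")
        if not self.velocity > 0:
            raise ValueError("velocity must be positive")
        if not self.stroke > 0:
            raise ValueError("stroke must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def cycle_period(self) -> float:
        """Seconds per reciprocating cycle (one pass)."""
        return self.stroke / self.velocity


@dataclass
class ImagingConfig:
    """Imaging geometry and the fluorescence filter set in use."""

    pixel_scale: float = 3.75          # um per pixel
    resolution: tuple = (2560, 2140)   # (width, height) px
    filter_name: str = "TRITC"
    excitation_nm: int | None = None
    emission_nm: int | None = None

    def __post_init__(self) -> None:
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be positive")
        if self.resolution[0] <= 0 or self.resolution[1] <= 0:
            raise ValueError("resolution must be positive")
        if self.filter_name in FILTER_BANDS:
            exc, emi = FILTER_BANDS[self.filter_name]
            if self.excitation_nm is None:
                self.excitation_nm = exc
            if self.emission_nm is None:
                self.emission_nm = emi
            if (self.excitation_nm, self.emission_nm) != (exc, emi):
                raise ValueError(
                    f"filter {self.filter_name} implies "
                    f"excitation/emission {exc}/{emi} nm"
                )


# ---------------------------------------------------------------------------
# Image stacks

_FRAME_SUFFIXES = {".tif", ".tiff", ".png"}


def read_image_stack(path, pixel_scale: float, frame_rate: float) -> ImageStack:
    """Read a multi-page TIFF or a directory of same-shaped frames.

    Timestamps embedded by :func:`write_image_stack` (JSON in the TIFF
    ImageDescription) are honored; otherwise timestamps are synthesized
    as ``index / frame_rate``.
    """
    path = Path(path)
    timestamps = None
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
        )
        if not files:
            raise ValueError(f"no frames found in {path}")
        frames = [iio.imread(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"mixed frame shapes: {sorted(shapes)}")
        frames = np.stack(frames)
    else:
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            desc = tif.pages[0].description
        if frames.size == 0:
            raise ValueError(f"empty stack: {path}")
        if frames.ndim == 2:
            frames = frames[None]
        if desc:
            try:
                meta = json.loads(desc)
                timestamps = np.asarray(meta["timestamps"], dtype=float)
                pixel_scale = float(meta.get("pixel_scale", pixel_scale))
            except (json.JSONDecodeError, KeyError, TypeError):
                timestamps = None
    if timestamps is None or len(timestamps) != len(frames):
        if not frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        timestamps = np.arange(len(frames)) / frame_rate
    return ImageStack(frames=frames, timestamps=timestamps, pixel_scale=pixel_scale)


def write_image_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page TIFF with timestamps in the description."""
    meta = {
        "timestamps": [float(t) for t in stack.timestamps],
        "pixel_scale": stack.pixel_scale,
    }
    tifffile.imwrite(path, stack.frames, description=json.dumps(meta),
                     photometric="minisblack")


# ---------------------------------------------------------------------------
# Force logs

_STATIC_KEY = "static_segment_end"


def read_force_log(path) -> ForceRecord:
    """Read a force log CSV with header ``time,normal,friction``.

    A leading comment line ``# static_segment_end=<s>`` (written by
    :func:`write_force_log`) carries the static-segment boundary.
    """
    path = Path(path)
    static_end = 0.0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and _STATIC_KEY in first:
        static_end = float(first.split("=", 1)[1])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = {"time", "normal", "friction"} - set(df.columns)
    if missing:
        raise ValueError(f"force log missing columns: {sorted(missing)}")
    return ForceRecord(
        time=df["time"].to_numpy(),
        normal_raw=df["normal"].to_numpy(),
        friction_raw=df["friction"].to_numpy(),
        static_segment_end=static_end,
    )


def write_force_log(record: ForceRecord, path) -> None:
    df = pd.DataFrame(
        {
            "time": record.time,
            "normal": record.normal_raw,
            "friction": record.friction_raw,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# {_STATIC_KEY}={record.static_segment_end!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Planning arithmetic

def plan_total_distance(config: ExperimentConfig) -> float:
    """Planned total sliding distance in mm: stroke x number of cycles."""
    return config.stroke * config.n_cycles


def hertz_mean_pressure(load: float, effective_modulus: float,
                        sphere_radius: float) -> float:
    """Mean Hertzian contact pressure for a sphere-on-flat contact.

    Parameters
    ----------
    load : float
        Normal load F in N.
    effective_modulus : float
        Contact modulus E* in MPa (= N/mm^2).
    sphere_radius : float
        Radius R of the spherical specimen in mm.

    Returns
    -------
    float
        Mean pressure F / (pi a^2) in MPa with contact radius
        a = (3 F R / (4 E*))^(1/3).
    """
    if load <= 0 or effective_modulus <= 0 or sphere_radius <= 0:
        raise ValueError("load, effective_modulus and sphere_radius must be > 0")
    a = (3.0 * load * sphere_radius / (4.0 * effective_modulus)) ** (1.0 / 3.0)
    return load / (math.pi * a * a)


# ---------------------------------------------------------------------------
# Result tables

def write_results(rows: pd.DataFrame, path) -> None:
    """Write a result table as CSV (or JSON for a .json path) at full precision."""
    path = Path(path)
    df = pd.DataFrame(rows)
    if path.suffix.lower() == ".json":
        path.write_text(df.to_json(orient="records", double_precision=15, indent=1))
    else:
        df.to_csv(path, index=False, float_format="%.17g")
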