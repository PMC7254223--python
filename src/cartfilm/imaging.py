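"""The snap-processing chain that counts labelled-protein clusters in contact.

Each fluorescence frame ("snap") is reduced to a particle count and a mean
cluster size by: (1) suppressing everything outside the circular contact
area, (2) a white top-hat transform — the frame minus its grayscale
morphological opening with a disk structuring element — which removes the
slowly varying pore background while preserving bright clusters narrower
than the disk, (3) thresholding, and (4) 8-connected component labeling.

The two tunable parameters mirror the original acquisition software:
``tophat_width`` (the disk diameter in pixels, sensitivity to local maxima)
and ``threshold`` (background cut in native camera units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure, morphology
from sklearn.base import BaseEstimator, TransformerMixin

from .io_formats import ImageStack

__all__ = [
    "ContactMask",
    "PipelineSettings",
    "ParticleSet",
    "FrameResult",
    "disk_structuring_element",
    "apply_contact_mask",
    "morphological_open",
    "white_tophat",
    "threshold_binarize",
    "label_particles",
    "measure_particles",
    "process_frame",
    "process_stack",
    "ParticleDetector",
]


@dataclass(frozen=True)
class ContactMask:
    """Circular contact region in pixel coordinates; may be clipped at borders."""

    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("mask radius must be positive")

    def boolean(self, shape: tuple) -> np.ndarray:
        """Boolean in-disk image of the given (height, width) shape."""
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        return (yy - self.center_y) ** 2 + (xx - self.center_x) ** 2 <= self.radius**2


@dataclass(frozen=True)
class PipelineSettings:
    """Snap-processing parameters: disk diameter and background threshold."""

    tophat_width: int = 15
    threshold: float = 4.0

    def __post_init__(self) -> None:
        if self.tophat_width < 1:
            raise ValueError("tophat_width must be >= 1")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


@dataclass
class ParticleSet:
    """Per-particle records of one frame: centroid, pixel area, diameter in um."""

    particles: pd.DataFrame  # columns: centroid_y, centroid_x, area_px[, diameter_um]
    timestamp: float = 0.0

    def __len__(self) -> int:
        return len(self.particles)


@dataclass(frozen=True)
class FrameResult:
    """Particle count and mean equivalent diameter (um) of one snap.

    ``mean_size`` is NaN when no particle was detected.
    """

    timestamp: float
    particle_count: int
    mean_size: float


def disk_structuring_element(width: int) -> np.ndarray:
    """Binary disk of diameter ``width`` pixels.

    The disk keeps pixels whose center lies within radius ``(width - 1) / 2``
    of the element center, so width 1 is a single pixel and width 3 the
    5-pixel plus shape.  The element is symmetric under 90-degree rotation.
    """
    width = int(width)
    if width < 1:
        raise ValueError("structuring-element width must be >= 1")
    r = (width - 1) / 2.0
    half = int(np.ceil(r))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    return (yy * yy + xx * xx <= r * r + 1e-9).astype(np.uint8)


def apply_contact_mask(frame: np.ndarray, mask: ContactMask) -> np.ndarray:
    """Zero all pixels outside the circular contact area."""
    frame = np.asarray(frame)
    return np.where(mask.boolean(frame.shape), frame, 0)


def _check_se(frame: np.ndarray, se: np.ndarray) -> None:
    if se.shape[0] > frame.shape[0] or se.shape[1] > frame.shape[1]:
        raise ValueError("structuring element larger than the frame")


def morphological_open(frame: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Grayscale opening (erosion then dilation); anti-extensive and idempotent."""
    frame = np.asarray(frame)
    _check_se(frame, se)
    return morphology.opening(frame, np.asarray(se, dtype=np.uint8))


def white_tophat(frame: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Frame minus its opening: nonnegative, flat backgrounds map to zero."""
    frame = np.asarray(frame)
    _check_se(frame, se)
    return morphology.white_tophat(frame, np.asarray(se, dtype=np.uint8))


def threshold_binarize(frame: np.ndarray, threshold: float) -> np.ndarray:
    """Binary frame: 1 where intensity >= threshold (below is suppressed)."""
    return (np.asarray(frame) >= threshold).astype(np.uint8)


def label_particles(binary: np.ndarray, mask: ContactMask,
                    timestamp: float = 0.0) -> ParticleSet:
    """8-connected components of an already-masked binary frame.

    Components touching the mask rim are kept; the circular mask itself
    bounds the region of interest.
    """
    labels = measure.label(np.asarray(binary) > 0, connectivity=2)
    props = measure.regionprops(labels)
    df = pd.DataFrame(
        {
            "centroid_y": [p.centroid[0] for p in props],
            "centroid_x": [p.centroid[1] for p in props],
            "area_px": [int(p.area) for p in props],
        }
    )
    return ParticleSet(particles=df, timestamp=timestamp)


def measure_particles(particles: ParticleSet, pixel_scale: float) -> ParticleSet:
    """Attach the equivalent diameter ``2 sqrt(area/pi) * pixel_scale`` in um."""
    if not pixel_scale > 0:
        raise ValueError("pixel_scale must be positive")
    df = particles.particles.copy()
    df["diameter_um"] = 2.0 * np.sqrt(df["area_px"] / np.pi) * pixel_scale
    return ParticleSet(particles=df, timestamp=particles.timestamp)


def process_frame(frame: np.ndarray, mask: ContactMask,
                  settings: PipelineSettings, pixel_scale: float,
                  timestamp: float = 0.0) -> FrameResult:
    """Full chain: white top-hat -> threshold -> contact mask -> label -> measure.

    The contact mask is intersected at the binary stage rather than by
    zeroing the frame first: zeroing introduces an intensity step at the
    rim that the top-hat would turn into a spurious bright ring.
    """
    se = disk_structuring_element(settings.tophat_width)
    th = white_tophat(frame, se)
    binary = threshold_binarize(th, settings.threshold)
    binary &= mask.boolean(binary.shape)
    parts = measure_particles(label_particles(binary, mask, timestamp), pixel_scale)
    n = len(parts)
    mean_size = float(parts.particles["diameter_um"].mean()) if n else float("nan")
    return FrameResult(timestamp=timestamp, particle_count=n, mean_size=mean_size)


def process_stack(stack: ImageStack, mask: ContactMask,
                  settings: PipelineSettings):
    """Per-frame counts and mean sizes of a whole recording.

    Returns
    -------
    (TrendSeries, TrendSeries)
        Particle count and mean equivalent diameter (um) vs time.
    """
    from .trends import TrendSeries

    results = [
        process_frame(f, mask, settings, stack.pixel_scale, timestamp=t)
        for f, t in zip(stack.frames, stack.timestamps)
    ]
    counts = TrendSeries(
        time=stack.timestamps.copy(),
        value=np.array([r.particle_count for r in results], dtype=float),
        label="particle_count",
    )
    sizes = TrendSeries(
        time=stack.timestamps.copy(),
        value=np.array([r.mean_size for r in results], dtype=float),
        label="mean_size_um",
    )
    return counts, sizes


class ParticleDetector(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer wrapping the snap-processing chain.

    Parameters
    ----------
    tophat_width : int
        Disk structuring-element diameter in pixels.
    threshold : float
        Background threshold in native camera units.
    mask : ContactMask or None
        Circular contact area; required before transforming.
    pixel_scale : float or None
        Micrometers per pixel; defaults to the stack's own scale.

    After :meth:`fit`, ``se_`` holds the binary disk in use.
    """

    def __init__(self, tophat_width: int = 15, threshold: float = 4.0,
                 mask: ContactMask | None = None,
                 pixel_scale: float | None = None):
        self.tophat_width = tophat_width
        self.threshold = threshold
        self.mask = mask
        self.pixel_scale = pixel_scale

    def fit(self, X: ImageStack | None = None, y=None) -> "ParticleDetector":
        if self.mask is None:
            raise ValueError("a ContactMask is required")
        self.settings_ = PipelineSettings(
            tophat_width=self.tophat_width, threshold=self.threshold
        )
        self.se_ = disk_structuring_element(self.tophat_width)
        return self

    def transform(self, X: ImageStack) -> pd.DataFrame:
        """Process a stack into a frame-result table."""
        if not hasattr(self, "settings_"):
            self.fit(X)
        scale = self.pixel_scale if self.pixel_scale is not None else X.pixel_scale
        rows = [
            process_frame(f, self.mask, self.settings_, scale, timestamp=t)
            for f, t in zip(X.frames, X.timestamps)
        ]
        return pd.DataFrame(
            {
                "timestamp": [r.timestamp for r in rows],
                "particle_count": [r.particle_count for r in rows],
                "mean_size_um": [r.mean_size for r in rows],
            }
        )
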