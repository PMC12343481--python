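"""Two-stage segmentation of cavitation bubbles in high-speed video.

The pipeline quantifies the primary bubble (PB) that forms at the laser
fiber tip (FT) and the secondary cavitation (SC) nucleated at a distance,
frame by frame:

PB stage
    background subtraction -> Gaussian blur (sigma 3 px) -> threshold at
    75 % of the frame maximum -> morphological opening (disk r=5) ->
    closing (r=5) -> convex-hull fill (seals the gap the dark fiber tip
    cuts into the top of the bubble) -> opening (r=10) -> largest
    8-connected component.

SC stage
    the background-subtracted frame with the (dilated) PB mask zeroed ->
    mild Gaussian blur (sigma 0.7 px) -> threshold at 76 % of the frame
    maximum -> intersection with a horizontal region-of-interest band
    extending 2.3 mm downward from the fiber-tip row.

Pixel counts are converted to mm² through the pixel-size calibration.
All intensities are assumed normalized to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

from .physics import ConfigurationError

__all__ = [
    "FrameSequence",
    "DetectionParams",
    "SegmentationResult",
    "subtract_background",
    "threshold_fraction",
    "morph_open",
    "morph_close",
    "convex_hull_fill",
    "detect_pb",
    "detect_sc",
    "areas",
    "segment_sequence",
]


@dataclass
class FrameSequence:
    """Ordered grayscale frames with uniform frame interval and pixel size.

    ``frames`` has shape (n_frames, height, width), values in [0, 1].
    ``t0_index`` marks the laser-onset frame used as background.
    """

    frames: np.ndarray
    frame_interval_us: float
    pixel_size_um: float
    t0_index: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ConfigurationError("frames must be a (n, h, w) array")
        if self.frame_interval_us <= 0:
            raise ConfigurationError("frame interval must be positive")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel size must be positive")
        if not 0 <= self.t0_index < len(self.frames):
            raise ConfigurationError("t0_index outside sequence")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times_us(self) -> np.ndarray:
        """Frame times in µs relative to the laser-onset frame."""
        return (np.arange(len(self.frames)) - self.t0_index) * self.frame_interval_us


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the two-stage segmentation.

    Defaults are the algorithm's standard operating point; geometry
    fields (fiber-tip row/column) come from the recording calibration.
    ``pb_exclusion_dilation_px`` grows the PB mask before it is zeroed out
    of the SC-stage image so the bubble's bright rim, which may fall just
    outside the 75 % PB contour, is not misread as secondary cavitation.
    """

    ft_tip_row_px: int
    ft_column_px: int
    pb_gauss_sigma_px: float = 3.0
    pb_threshold_fraction: float = 0.75
    pb_open_radius_px: int = 5
    pb_close_radius_px: int = 5
    pb_final_open_radius_px: int = 10
    sc_gauss_sigma_px: float = 0.7
    sc_threshold_fraction: float = 0.76
    sc_roi_depth_mm: float = 2.3
    pb_exclusion_dilation_px: int = 5
    subtract_mode: str = "clip"

    def __post_init__(self) -> None:
        for frac in (self.pb_threshold_fraction, self.sc_threshold_fraction):
            if not 0.0 < frac < 1.0:
                raise ConfigurationError("threshold fractions must be in (0, 1)")
        for r in (
            self.pb_open_radius_px,
            self.pb_close_radius_px,
            self.pb_final_open_radius_px,
        ):
            if r < 1:
                raise ConfigurationError("morphology radii must be >= 1")
        if self.pb_gauss_sigma_px <= 0 or self.sc_gauss_sigma_px <= 0:
            raise ConfigurationError("Gaussian sigmas must be positive")
        if self.sc_roi_depth_mm <= 0:
            raise ConfigurationError("ROI depth must be positive")
        if self.pb_exclusion_dilation_px < 0:
            raise ConfigurationError("PB exclusion dilation must be >= 0")
        if self.subtract_mode not in ("clip", "abs"):
            raise ConfigurationError("subtract_mode must be 'clip' or 'abs'")


@dataclass
class SegmentationResult:
    """Per-frame PB/SC masks and calibrated area time series (mm²)."""

    pb_masks: np.ndarray
    sc_masks: np.ndarray
    a_pb_mm2: np.ndarray
    a_sc_mm2: np.ndarray
    times_us: np.ndarray
    pixel_size_um: float


def subtract_background(
    frame: np.ndarray, background: np.ndarray, mode: str = "clip"
) -> np.ndarray:
    """Remove the static background from a frame.

    ``clip`` (default) keeps only positive excess brightness, assuming the
    bubble appears brighter than the background after subtraction; ``abs``
    takes the absolute difference.
    """
    frame = np.asarray(frame, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    if frame.shape != background.shape:
        raise ValueError(
            f"shape mismatch: frame {frame.shape} vs background {background.shape}"
        )
    diff = frame - background
    if mode == "clip":
        return np.clip(diff, 0.0, 1.0)
    if mode == "abs":
        return np.clip(np.abs(diff), 0.0, 1.0)
    raise ValueError(f"unknown subtraction mode {mode!r}")


def threshold_fraction(image: np.ndarray, fraction: float) -> np.ndarray:
    """Binary mask of pixels at or above ``fraction`` of the image maximum.

    An all-zero (or non-positive) image yields an empty mask rather than
    selecting everything.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    image = np.asarray(image, dtype=np.float64)
    peak = image.max() if image.size else 0.0
    if peak <= 0.0:
        return np.zeros(image.shape, dtype=bool)
    return image >= fraction * peak


def _disk(radius: int) -> np.ndarray:
    # discrete Euclidean disk {(dx, dy): dx^2 + dy^2 <= r^2}
    return morphology.disk(radius)


def morph_open(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Morphological opening (erosion then dilation) with a Euclidean disk.

    Pixels outside the image count as background, i.e. the pure
    set-arithmetic definition on the finite grid.
    """
    if radius_px < 1:
        raise ValueError("radius must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    eroded = ndi.binary_erosion(mask, structure=_disk(radius_px), border_value=0)
    return ndi.binary_dilation(eroded, structure=_disk(radius_px), border_value=0)


def morph_close(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Morphological closing (dilation then erosion) with a Euclidean disk."""
    if radius_px < 1:
        raise ValueError("radius must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    dilated = ndi.binary_dilation(mask, structure=_disk(radius_px), border_value=0)
    return ndi.binary_erosion(dilated, structure=_disk(radius_px), border_value=0)


def _largest_component(mask: np.ndarray, tie_break_column: float | None = None) -> np.ndarray:
    """Largest 8-connected component; ties go to the component whose
    centroid is nearest ``tie_break_column`` (the fiber-tip column)."""
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return np.zeros(mask.shape, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = counts.max()
    candidates = np.flatnonzero(counts == best)
    if len(candidates) > 1 and tie_break_column is not None:
        dists = []
        for lab in candidates:
            cols = np.nonzero(labels == lab)[1]
            dists.append(abs(cols.mean() - tie_break_column))
        winner = candidates[int(np.argmin(dists))]
    else:
        winner = candidates[0]
    return labels == winner


def convex_hull_fill(mask: np.ndarray) -> np.ndarray:
    """Filled convex hull of the largest 8-connected foreground component.

    Seals the discontinuity the dark fiber tip introduces at the top of the
    primary bubble. The hull is rasterized by pixel-center inclusion, which
    makes the operation exactly idempotent. An empty mask maps to an empty
    mask; degenerate (collinear) components are returned unchanged.
    """
    from scipy.spatial import ConvexHull, QhullError

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=bool)
    component = _largest_component(mask)
    points = np.column_stack(np.nonzero(component)).astype(float)
    try:
        hull = ConvexHull(points)
    except QhullError:
        return component
    h, w = mask.shape
    rr, cc = np.mgrid[:h, :w]
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    inside = np.ones(len(grid), dtype=bool)
    for a, b, c in hull.equations:
        inside &= grid @ np.array([a, b]) + c <= 1e-9
    return inside.reshape(h, w)


def _blur(image: np.ndarray, sigma: float) -> np.ndarray:
    # reflect padding avoids dark frame-edge artifacts that would fake SC
    return ndi.gaussian_filter(image, sigma=sigma, mode="reflect")


def detect_pb(seq: FrameSequence, params: DetectionParams) -> np.ndarray:
    """Per-frame primary-bubble masks, shape (n_frames, h, w) bool."""
    if len(seq) < 2:
        raise ConfigurationError("sequence must contain at least 2 frames")
    background = seq.frames[seq.t0_index]
    masks = np.zeros(seq.frames.shape, dtype=bool)
    for i, frame in enumerate(seq.frames):
        sub = subtract_background(frame, background, mode=params.subtract_mode)
        blurred = _blur(sub, params.pb_gauss_sigma_px)
        mask = threshold_fraction(blurred, params.pb_threshold_fraction)
        if not mask.any():
            continue
        mask = morph_open(mask, params.pb_open_radius_px)
        mask = morph_close(mask, params.pb_close_radius_px)
        mask = convex_hull_fill(mask)
        mask = morph_open(mask, params.pb_final_open_radius_px)
        masks[i] = _largest_component(mask, tie_break_column=params.ft_column_px)
    return masks


def roi_band_rows(params: DetectionParams, pixel_size_um: float, height: int) -> tuple[int, int]:
    """Row span [start, stop) of the SC region-of-interest band.

    The band runs from the fiber-tip row downward by the ROI depth
    (mm -> px conversion rounds half away from zero) and is clipped to the
    image; a band entirely outside the image is a configuration error.
    """
    depth_px = int(math.floor(params.sc_roi_depth_mm * 1000.0 / pixel_size_um + 0.5))
    start = params.ft_tip_row_px
    stop = start + depth_px
    if start >= height or stop <= 0:
        raise ConfigurationError("SC ROI band lies fully outside the image")
    return max(start, 0), min(stop, height)


def detect_sc(
    seq: FrameSequence, params: DetectionParams, pb_masks: np.ndarray
) -> np.ndarray:
    """Per-frame secondary-cavitation masks; disjoint from the PB masks."""
    pb_masks = np.asarray(pb_masks, dtype=bool)
    if pb_masks.shape != seq.frames.shape:
        raise ConfigurationError("pb_masks shape does not match the sequence")
    n, height, width = seq.frames.shape
    r0, r1 = roi_band_rows(params, seq.pixel_size_um, height)
    band = np.zeros((height, width), dtype=bool)
    band[r0:r1, :] = True

    background = seq.frames[seq.t0_index]
    excl_disk = (
        _disk(params.pb_exclusion_dilation_px)
        if params.pb_exclusion_dilation_px > 0
        else None
    )
    masks = np.zeros(seq.frames.shape, dtype=bool)
    for i, frame in enumerate(seq.frames):
        sub = subtract_background(frame, background, mode=params.subtract_mode)
        exclusion = pb_masks[i]
        if excl_disk is not None and exclusion.any():
            exclusion = morphology.dilation(exclusion, excl_disk).astype(bool)
        sub = np.where(exclusion, 0.0, sub)
        blurred = _blur(sub, params.sc_gauss_sigma_px)
        mask = threshold_fraction(blurred, params.sc_threshold_fraction)
        masks[i] = mask & band & ~pb_masks[i]
    return masks


def areas(masks: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Calibrated area series in mm²: pixel count × (pixel size / 1000)²."""
    if pixel_size_um <= 0:
        raise ConfigurationError("pixel size must be positive")
    masks = np.asarray(masks, dtype=bool)
    pixel_area_mm2 = (pixel_size_um / 1000.0) ** 2
    if masks.ndim == 2:
        return np.array(masks.sum() * pixel_area_mm2)
    return masks.reshape(masks.shape[0], -1).sum(axis=1) * pixel_area_mm2


def segment_sequence(seq: FrameSequence, params: DetectionParams) -> SegmentationResult:
    """Run both detection stages and return masks plus area time series."""
    pb = detect_pb(seq, params)
    sc = detect_sc(seq, params, pb)
    return SegmentationResult(
        pb_masks=pb,
        sc_masks=sc,
        a_pb_mm2=areas(pb, seq.pixel_size_um),
        a_sc_mm2=areas(sc, seq.pixel_size_um),
        times_us=seq.times_us,
        pixel_size_um=seq.pixel_size_um,
    )
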