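"""Synthetic phantoms with exact ground truth.

Emulates the imaging geometry of zero-gap pocket cavitation recordings so
the quantification pipeline can be exercised against known truth:

* cavitation video phantoms — a static background, a bright primary
  bubble (PB) growing and collapsing under the fiber tip with a dark
  vertical fiber-tip occlusion notching its top, and small bright
  secondary-cavitation (SC) blobs scattered in a band below the tip;
* stained-monolayer micrographs — dark, Gaussian-profile bacterial cells
  on a bright, unevenly illuminated background, optionally with touching
  pairs to exercise watershed splitting;
* particle frame pairs displaced by a known velocity for velocimetry;
* synthetic ASW delay-sweep pulse records following a known unimodal law.

Default geometry matches a typical high-speed recording: 128×256 px
frames at 10 µs intervals with a 20 µm pixel and a 400 µm (20 px) fiber.

Bubble and blob appearance is calibrated so that the pipeline's default
threshold fractions (75 % / 76 % of frame maximum) locate the true object
boundary: features carry a dimmer halo skirt around a saturated core,
emulating the bright-rimmed look of real transmitted-light bubble imagery
on which those thresholds were empirically tuned. See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .physics import ConfigurationError
from .detection import FrameSequence
from .pulses import PulseRecord

__all__ = [
    "PhantomConfig",
    "BubbleTruth",
    "MicrographTruth",
    "ParticlePairTruth",
    "make_cavitation_sequence",
    "make_micrograph",
    "make_particle_pair",
    "make_sweep_records",
]

# Appearance constants fixed by the rasterization calibration study
# (scripts are re-runnable; see docs/methods.md "Phantom appearance").
FEATURE_AMPLITUDE = 0.6          # additive brightness of a feature core
PB_HALO_WIDTH_PX = 5.0           # bubble halo skirt width
PB_HALO_LEVEL = 0.71             # halo brightness relative to the core
SC_HALO_WIDTH_PX = 1.5           # SC blob halo skirt width
SC_HALO_LEVEL = 0.55
FIBER_VALUE = 0.08               # absolute brightness of the fiber-tip shadow
SC_CLEARANCE_PX = 12.0           # min gap between SC blobs and the PB footprint
PB_TIP_POKE_PX = 6.0             # max protrusion of the bubble top above the tip row
PB_TIP_POKE_ONSET_PX = 20.0      # semi-minor axis at which the bubble reaches the tip
PB_TIP_POKE_FRACTION = 0.35      # protrusion growth rate past the onset


def _tip_poke(semi_minor_px: float) -> float:
    """How far the bubble top protrudes above the fiber-tip row.

    Small bubbles sit below the tip; once grown past it they envelop the
    fiber, whose dark stripe then cuts the gap the hull stage must seal.
    """
    grown = max(semi_minor_px - PB_TIP_POKE_ONSET_PX, 0.0)
    return min(PB_TIP_POKE_PX, PB_TIP_POKE_FRACTION * grown)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, calibration and noise settings shared by all phantoms."""

    image_height_px: int = 128
    image_width_px: int = 256
    pixel_size_um: float = 20.0
    frame_interval_us: float = 10.0
    n_frames: int = 100
    seed: int = 0
    noise_sigma: float = 0.01
    ft_column_px: int = 128
    ft_tip_row_px: int = 32
    ft_width_px: int = 20

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ConfigurationError("image extents must be positive")
        if self.pixel_size_um <= 0 or self.frame_interval_us <= 0:
            raise ConfigurationError("pixel size and frame interval must be positive")
        if self.n_frames < 1:
            raise ConfigurationError("need at least one frame")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise sigma must be >= 0")
        if not 0 <= self.ft_column_px < self.image_width_px:
            raise ConfigurationError("fiber-tip column outside image")
        if not 0 <= self.ft_tip_row_px < self.image_height_px:
            raise ConfigurationError("fiber-tip row outside image")
        if not 0 < self.ft_width_px <= self.image_width_px:
            raise ConfigurationError("fiber-tip width outside image bounds")

    @property
    def pixel_area_mm2(self) -> float:
        return (self.pixel_size_um / 1000.0) ** 2


@dataclass
class BubbleTruth:
    """Ground truth for a cavitation video phantom.

    ``pb_area_mm2`` / ``sc_area_mm2`` are exact rasterized mask areas
    (pixel count × pixel area); ``pb_nominal_area_mm2`` is the continuous
    growth-law value A(t) = A_max sin²(π t / T) the rasterization targets.
    """

    pb_masks: np.ndarray
    sc_masks: np.ndarray
    pb_area_mm2: np.ndarray
    sc_area_mm2: np.ndarray
    pb_nominal_area_mm2: np.ndarray
    center_trajectory_px: np.ndarray


@dataclass
class MicrographTruth:
    """Ground truth for a stained-monolayer micrograph phantom."""

    centers_px: np.ndarray          # (n, 2) float rows/cols
    count_total: int
    quadrant_counts: tuple[int, int, int, int]
    touching_fraction: float


@dataclass
class ParticlePairTruth:
    """Ground truth for a particle-displacement frame pair."""

    centers_a_px: np.ndarray
    centers_b_px: np.ndarray
    displacement_px: np.ndarray     # (dy, dx), identical for all particles
    in_frame_b: np.ndarray          # bool, particle still visible in frame 2


def _background(cfg: PhantomConfig) -> np.ndarray:
    """Static scene: gentle vertical illumination gradient + fiber shadow."""
    rows = np.linspace(0.25, 0.35, cfg.image_height_px)[:, None]
    bg = np.broadcast_to(rows, (cfg.image_height_px, cfg.image_width_px)).copy()
    _stamp_fiber(bg, cfg)
    return bg


def _stamp_fiber(img: np.ndarray, cfg: PhantomConfig) -> None:
    c0 = cfg.ft_column_px - cfg.ft_width_px // 2
    c1 = c0 + cfg.ft_width_px
    img[: cfg.ft_tip_row_px, max(c0, 0) : min(c1, cfg.image_width_px)] = FIBER_VALUE


def _halo(mask: np.ndarray, width: float) -> np.ndarray:
    if not mask.any() or width <= 0:
        return np.zeros(mask.shape, dtype=bool)
    dist = ndi.distance_transform_edt(~mask)
    return (dist <= width) & ~mask


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], semi_row: float, semi_col: float
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / semi_row) ** 2 + ((cc - center[1]) / semi_col) ** 2 <= 1.0


def make_cavitation_sequence(
    cfg: PhantomConfig,
    a_max_mm2: float = 1.8,
    period_us: float = 200.0,
    sc_density_per_mm2: float = 3.0,
    sc_band_depth_mm: float = 1.5,
    aspect: float = 1.0,
) -> tuple[FrameSequence, BubbleTruth]:
    """Cavitation video phantom with exact per-frame ground truth.

    Frame 0 is pure background. The PB is a bright filled ellipse
    (column/row semi-axis ratio ``aspect``) centered under the fiber tip
    whose area follows A(t) = A_max sin²(π t / T) for t in [0, T]; the
    dark fiber-tip stripe overwrites the bubble where they overlap,
    creating the upper gap the pipeline's convex-hull step must seal.
    SC blobs (core radius 1-3 px) are scattered uniformly in the band
    below the fiber tip, clear of the bubble's maximal footprint, and are
    present on every frame on which the bubble is active.
    """
    if a_max_mm2 < 0 or sc_density_per_mm2 < 0 or sc_band_depth_mm <= 0:
        raise ConfigurationError("bubble/SC parameters must be non-negative")
    if aspect <= 0:
        raise ConfigurationError("aspect must be positive")
    duration_us = (cfg.n_frames - 1) * cfg.frame_interval_us
    if period_us > duration_us:
        raise ConfigurationError("growth period exceeds the sequence duration")

    h, w = cfg.image_height_px, cfg.image_width_px
    pix_area = cfg.pixel_area_mm2
    a_max_px = a_max_mm2 / pix_area
    b_max = math.sqrt(a_max_px / (math.pi * aspect)) if a_max_px > 0 else 0.0
    a_col_max = aspect * b_max
    center_row_max = cfg.ft_tip_row_px + b_max - _tip_poke(b_max)
    if center_row_max + b_max + PB_HALO_WIDTH_PX >= h:
        raise ConfigurationError("maximal bubble does not fit below the fiber tip")
    if (
        cfg.ft_column_px - a_col_max - PB_HALO_WIDTH_PX < 0
        or cfg.ft_column_px + a_col_max + PB_HALO_WIDTH_PX >= w
    ):
        raise ConfigurationError("maximal bubble does not fit across the image")

    rng = np.random.default_rng(cfg.seed)
    bg = _background(cfg)
    times = np.arange(cfg.n_frames) * cfg.frame_interval_us

    # maximal bubble footprint used to keep SC blobs clear of the PB
    if b_max > 0:
        pb_max_mask = _ellipse_mask((h, w), (center_row_max, cfg.ft_column_px), b_max, a_col_max)
        dist_to_pb = ndi.distance_transform_edt(~pb_max_mask)
    else:
        dist_to_pb = np.full((h, w), np.inf)

    band_depth_px = int(math.floor(sc_band_depth_mm * 1000.0 / cfg.pixel_size_um + 0.5))
    band_top = cfg.ft_tip_row_px
    band_bottom = min(band_top + band_depth_px, h)
    band_area_mm2 = (band_bottom - band_top) * w * pix_area
    n_blobs = int(round(sc_density_per_mm2 * band_area_mm2))

    sc_static = np.zeros((h, w), dtype=bool)
    placed: list[tuple[float, float, int]] = []
    attempts = 0
    while len(placed) < n_blobs and attempts < 200 * max(n_blobs, 1):
        attempts += 1
        radius = int(rng.integers(1, 4))
        margin = radius + SC_HALO_WIDTH_PX
        row = rng.uniform(band_top + margin, band_bottom - margin)
        col = rng.uniform(margin, w - 1 - margin)
        ri, ci = int(round(row)), int(round(col))
        if dist_to_pb[ri, ci] < radius + SC_HALO_WIDTH_PX + SC_CLEARANCE_PX:
            continue
        if any(
            math.hypot(row - r0, col - c0) < radius + r0_rad + 2 * SC_HALO_WIDTH_PX + 1
            for r0, c0, r0_rad in placed
        ):
            continue
        placed.append((row, col, radius))
        rr, cc = np.ogrid[:h, :w]
        sc_static |= (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
    sc_halo_static = _halo(sc_static, SC_HALO_WIDTH_PX)

    frames = np.empty((cfg.n_frames, h, w), dtype=np.float64)
    pb_masks = np.zeros((cfg.n_frames, h, w), dtype=bool)
    sc_masks = np.zeros((cfg.n_frames, h, w), dtype=bool)
    nominal = np.zeros(cfg.n_frames)
    trajectory = np.full((cfg.n_frames, 2), np.nan)

    for i, t in enumerate(times):
        profile = np.zeros((h, w), dtype=np.float64)
        active = 0.0 < t <= period_us
        if i > 0 and 0.0 < t <= period_us:
            nominal[i] = a_max_mm2 * math.sin(math.pi * t / period_us) ** 2
        if i > 0 and nominal[i] > 0:
            area_px = nominal[i] / pix_area
            b = math.sqrt(area_px / (math.pi * aspect))
            a_col = aspect * b
            center = (
                cfg.ft_tip_row_px + b - _tip_poke(b),
                float(cfg.ft_column_px),
            )
            pb = _ellipse_mask((h, w), center, b, a_col)
            pb_masks[i] = pb
            trajectory[i] = center
            profile[_halo(pb, PB_HALO_WIDTH_PX)] = PB_HALO_LEVEL
            profile[pb] = 1.0
        if i > 0 and active and sc_static.any():
            sc_masks[i] = sc_static
            np.maximum(profile, np.where(sc_halo_static, SC_HALO_LEVEL, 0.0), out=profile)
            profile[sc_static] = 1.0

        frame = bg + FEATURE_AMPLITUDE * profile
        _stamp_fiber(frame, cfg)  # fiber shadow occludes the bubble top
        if cfg.noise_sigma > 0:
            frame = frame + rng.normal(0.0, cfg.noise_sigma, size=frame.shape)
        frames[i] = np.clip(frame, 0.0, 1.0)

    truth = BubbleTruth(
        pb_masks=pb_masks,
        sc_masks=sc_masks,
        pb_area_mm2=pb_masks.reshape(cfg.n_frames, -1).sum(axis=1) * pix_area,
        sc_area_mm2=sc_masks.reshape(cfg.n_frames, -1).sum(axis=1) * pix_area,
        pb_nominal_area_mm2=nominal,
        center_trajectory_px=trajectory,
    )
    seq = FrameSequence(
        frames=frames,
        frame_interval_us=cfg.frame_interval_us,
        pixel_size_um=cfg.pixel_size_um,
        t0_index=0,
    )
    return seq, truth


def _quadrant_index(row: float, col: float, height: int, width: int) -> int:
    # 2x2 floor-split tiling: 0=top-left, 1=top-right, 2=bottom-left, 3=bottom-right
    return 2 * int(row >= height // 2) + int(col >= width // 2)


def make_micrograph(
    cfg: PhantomConfig,
    n_cells: int,
    cell_radius_px: float = 4.0,
    touching_fraction: float = 0.0,
    stain_contrast: float = 0.55,
) -> tuple[np.ndarray, MicrographTruth]:
    """Stained-monolayer micrograph phantom.

    Dark Gaussian-profile cells on a bright, radially shaded background.
    ``touching_fraction`` of the cells are placed in pairs with
    center distance < 2 × radius to exercise watershed splitting.
    """
    if cell_radius_px <= 0:
        raise ConfigurationError("cell radius must be positive")
    if not 0.0 <= touching_fraction <= 1.0:
        raise ConfigurationError("touching fraction must be in [0, 1]")
    if n_cells < 0:
        raise ConfigurationError("n_cells must be >= 0")
    if not 0.0 < stain_contrast <= 1.0:
        raise ConfigurationError("stain contrast must be in (0, 1]")

    h, w = cfg.image_height_px, cfg.image_width_px
    rng = np.random.default_rng(cfg.seed)

    # bright field with a mild vignette; the gamma step corrects this
    yy, xx = np.mgrid[:h, :w]
    r2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
    image = 0.92 - 0.06 * r2

    n_pairs = int(round(touching_fraction * n_cells / 2.0))
    n_singles = n_cells - 2 * n_pairs
    margin = 3.0 * cell_radius_px
    min_sep = 4.0 * cell_radius_px
    pair_sep = 1.4 * cell_radius_px  # < 2 r: the pair genuinely touches

    centers: list[tuple[float, float]] = []

    def _far_enough(row: float, col: float, skip_last: int = 0) -> bool:
        for r0, c0 in centers[: len(centers) - skip_last]:
            if math.hypot(row - r0, col - c0) < min_sep:
                return False
        return True

    attempts, placed_pairs, placed_singles = 0, 0, 0
    max_attempts = 500 * max(n_cells, 1)
    while placed_pairs < n_pairs and attempts < max_attempts:
        attempts += 1
        row = rng.uniform(margin + pair_sep, h - 1 - margin - pair_sep)
        col = rng.uniform(margin + pair_sep, w - 1 - margin - pair_sep)
        theta = rng.uniform(0, 2 * math.pi)
        row2 = row + pair_sep * math.sin(theta)
        col2 = col + pair_sep * math.cos(theta)
        if _far_enough(row, col) and _far_enough(row2, col2):
            centers.append((row, col))
            centers.append((row2, col2))
            placed_pairs += 1
    while placed_singles < n_singles and attempts < max_attempts:
        attempts += 1
        row = rng.uniform(margin, h - 1 - margin)
        col = rng.uniform(margin, w - 1 - margin)
        if _far_enough(row, col):
            centers.append((row, col))
            placed_singles += 1
    if len(centers) < n_cells:
        raise ConfigurationError(
            f"could not place {n_cells} cells of radius {cell_radius_px} in a "
            f"{h}x{w} image; reduce the density"
        )

    sigma = cell_radius_px / 2.0
    half = int(math.ceil(4 * sigma))
    for row, col in centers:
        r0, c0 = int(round(row)), int(round(col))
        rr = np.arange(max(r0 - half, 0), min(r0 + half + 1, h))
        cc = np.arange(max(c0 - half, 0), min(c0 + half + 1, w))
        d2 = (rr[:, None] - row) ** 2 + (cc[None, :] - col) ** 2
        image[np.ix_(rr, cc)] -= stain_contrast * np.exp(-d2 / (2 * sigma**2))

    if cfg.noise_sigma > 0:
        image = image + rng.normal(0.0, cfg.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    quadrants = [0, 0, 0, 0]
    for row, col in centers:
        quadrants[_quadrant_index(row, col, h, w)] += 1
    truth = MicrographTruth(
        centers_px=np.array(centers, dtype=float).reshape(-1, 2),
        count_total=len(centers),
        quadrant_counts=tuple(quadrants),  # type: ignore[arg-type]
        touching_fraction=(2 * placed_pairs) / n_cells if n_cells else 0.0,
    )
    return image, truth


def make_particle_pair(
    cfg: PhantomConfig,
    n_particles: int = 30,
    velocity_m_s: tuple[float, float] = (0.0, 10.0),
    particle_sigma_px: float = 1.5,
    min_separation_px: float = 12.0,
) -> tuple[np.ndarray, ParticlePairTruth]:
    """Two consecutive frames of a particle field moving at a known velocity.

    ``velocity_m_s`` is (v_row, v_col); the per-frame displacement in px is
    v × frame_interval / pixel_size. The second frame is the first with
    every particle translated by exactly that displacement; particles
    carried outside the image simply disappear. Particles keep a minimum
    mutual separation (distinct tracer particles) and, when the
    displacement is small enough, a border margin in both frames so their
    full intensity profile stays in view; larger displacements let
    particles run off the edge.
    """
    if n_particles < 1:
        raise ConfigurationError("need at least one particle")
    h, w = cfg.image_height_px, cfg.image_width_px
    disp = (
        np.asarray(velocity_m_s, dtype=float)
        * cfg.frame_interval_us
        / cfg.pixel_size_um
    )
    rng = np.random.default_rng(cfg.seed)
    margin = 4.0 * particle_sigma_px
    full_lo = np.array([margin, margin])
    full_hi = np.array([h - 1 - margin, w - 1 - margin])
    if np.any(full_hi <= full_lo):
        raise ConfigurationError("image too small for the particle margin")
    shrunk_lo = full_lo + np.maximum(-disp, 0.0)
    shrunk_hi = full_hi - np.maximum(disp, 0.0)

    def _place(lo: np.ndarray, hi: np.ndarray) -> list[np.ndarray] | None:
        pts: list[np.ndarray] = []
        for _ in range(500 * n_particles):
            cand = rng.uniform(lo, hi)
            if all(np.hypot(*(cand - c)) >= min_separation_px for c in pts):
                pts.append(cand)
                if len(pts) == n_particles:
                    return pts
        return None

    # prefer a window that keeps every particle fully in view in both frames
    placed = None
    if np.all(shrunk_hi > shrunk_lo):
        placed = _place(shrunk_lo, shrunk_hi)
    if placed is None:
        placed = _place(full_lo, full_hi)
    if placed is None:
        raise ConfigurationError(
            f"could not place {n_particles} particles {min_separation_px} px apart"
        )
    centers = np.array(placed)
    centers_b = centers + disp
    in_b = (
        (centers_b[:, 0] >= 0)
        & (centers_b[:, 0] <= h - 1)
        & (centers_b[:, 1] >= 0)
        & (centers_b[:, 1] <= w - 1)
    )
    if not in_b.any():
        raise ConfigurationError("displacement pushes every particle out of frame")

    def _render(pts: np.ndarray) -> np.ndarray:
        img = np.full((h, w), 0.05)
        half = int(math.ceil(4 * particle_sigma_px))
        for row, col in pts:
            r0, c0 = int(round(row)), int(round(col))
            rr = np.arange(max(r0 - half, 0), min(r0 + half + 1, h))
            cc = np.arange(max(c0 - half, 0), min(c0 + half + 1, w))
            if len(rr) == 0 or len(cc) == 0:
                continue
            d2 = (rr[:, None] - row) ** 2 + (cc[None, :] - col) ** 2
            img[np.ix_(rr, cc)] += 0.9 * np.exp(-d2 / (2 * particle_sigma_px**2))
        return img

    frame_a = _render(centers)
    frame_b = _render(centers_b[in_b])
    if cfg.noise_sigma > 0:
        frame_a = frame_a + rng.normal(0.0, cfg.noise_sigma, size=frame_a.shape)
        frame_b = frame_b + rng.normal(0.0, cfg.noise_sigma, size=frame_b.shape)
    pair = np.clip(np.stack([frame_a, frame_b]), 0.0, 1.0)
    truth = ParticlePairTruth(
        centers_a_px=centers,
        centers_b_px=centers_b,
        displacement_px=disp,
        in_frame_b=in_b,
    )
    return pair, truth


def make_sweep_records(
    seed: int,
    optimal_delay_us: float = 400.0,
    peak_mm2: float = 0.4,
    width_us: float = 50.0,
    noise_sd_mm2: float = 0.02,
    n_per_delay: int = 16,
    pulse_energy_mJ: float = 20.0,
    delays: list[float] | None = None,
) -> tuple[list[PulseRecord], float]:
    """Synthetic ASW delay-sweep records with a known unimodal response.

    A_SC(2nd pulse) follows a Gaussian resonance bump
    peak × exp(-(t_d - t_opt)² / 2 width²) plus additive noise (clipped at
    zero, mirroring that pulses without SC contribute zero). Returns the
    records and the true optimal delay.
    """
    from .physics import delay_grid

    rng = np.random.default_rng(seed)
    grid = delay_grid() if delays is None else list(delays)
    records = []
    for td in grid:
        law = peak_mm2 * math.exp(-((td - optimal_delay_us) ** 2) / (2 * width_us**2))
        for k in range(n_per_delay):
            value = max(0.0, law + rng.normal(0.0, noise_sd_mm2))
            records.append(
                PulseRecord(
                    pulse_id=f"td{int(td)}_{k}",
                    modality="ASW",
                    pulse_energy_mJ=pulse_energy_mJ,
                    a_pb_max_mm2=max(0.0, 1.5 + rng.normal(0.0, 0.1)),
                    a_sc_max_mm2=max(0.0, 0.5 * law + rng.normal(0.0, noise_sd_mm2)),
                    t_d_us=float(td),
                    a_sc_max_2nd_mm2=value,
                )
            )
    return records, optimal_delay_us
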