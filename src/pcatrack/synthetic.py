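"""Synthetic microscopy-like sequences with ground truth.

The generator emulates what a fluorescence time-lapse of a bright roundish
cell over cluttered background looks like to a tracker: an isotropic
Gaussian-profile blob (sigma = radius / 2) translating at constant velocity
over a dim background with static distractor blobs, optional per-frame
illumination drift, gradual scale change, a partial occluder bar, and
additive Gaussian pixel noise.  Everything is deterministic given the seed,
and every frame ships with the square ground-truth box (side = 2 x current
radius) centered on the object.

``generate_cell_field`` instead populates the frame with many independently
moving cells of varied brightness and exports ground truth for one
designated cell — a Mitocheck-like clutter scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import BoundingBox, Frame

__all__ = ["OccluderConfig", "SceneConfig", "generate_sequence",
           "generate_cell_field"]


@dataclass(frozen=True)
class OccluderConfig:
    """A full-width horizontal bar drawn over the object for a frame span."""

    start_frame: int
    n_frames: int
    coverage: float = 0.5  # fraction of the object's box height covered
    intensity: float = 0.6


@dataclass(frozen=True)
class SceneConfig:
    frame_size: tuple[int, int] = (128, 128)  # (H, W)
    n_frames: int = 50
    radius: float = 10.0
    peak_intensity: float = 0.9
    velocity: tuple[float, float] = (5.0, 2.0)  # px/frame, clamped to fit
    n_distractors: int = 10
    distractor_intensity: float = 0.45
    background: float = 0.1
    noise_sigma: float = 0.02
    illumination_drift: float = 1.0  # per-frame multiplicative factor
    occluder: OccluderConfig | None = None
    scale_rate: float = 1.0  # per-frame radius multiplier
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.frame_size
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if not (0 < self.peak_intensity <= 1):
            raise ValueError("peak intensity must lie in (0, 1]")
        margin = self.max_radius + 1
        if 2 * margin >= min(h, w):
            raise ValueError("object cannot fit in the frame at this radius")

    @property
    def max_radius(self) -> float:
        rates = [self.scale_rate ** t for t in range(self.n_frames)]
        return self.radius * max(rates)


def _clamped_path(cfg: SceneConfig) -> np.ndarray:
    """Object centers over time; velocity is clamped so the object never
    leaves the frame by less than its radius."""
    h, w = cfg.frame_size
    margin = cfg.max_radius + 1
    steps = max(1, cfg.n_frames - 1)
    path = np.empty((cfg.n_frames, 2))
    for axis, (v, dim) in enumerate(zip(cfg.velocity, (w, h))):
        travel = dim - 1 - 2 * margin
        v_eff = np.sign(v) * min(abs(v), travel / steps)
        start = (dim - 1) / 2 if v_eff == 0 else (margin if v_eff > 0 else dim - 1 - margin)
        path[:, axis] = start + v_eff * np.arange(cfg.n_frames)
    return path  # columns: (cx, cy)


def _render_blobs(shape: tuple[int, int], centers, radii, peaks) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.zeros(shape)
    for (cx, cy), r, p in zip(centers, radii, peaks):
        sigma = r / 2.0
        img += p * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma ** 2))
    return img


def _place_distractors(cfg: SceneConfig, path: np.ndarray,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Static clutter blobs kept clear of the object's path."""
    h, w = cfg.frame_size
    centers = np.empty((cfg.n_distractors, 2))
    radii = np.empty(cfg.n_distractors)
    placed = 0
    attempts = 0
    while placed < cfg.n_distractors:
        attempts += 1
        if attempts > 500 * max(1, cfg.n_distractors):
            raise ValueError("cannot place distractors clear of the object path")
        c = rng.uniform([0, 0], [w - 1, h - 1])
        r = cfg.radius * rng.uniform(0.6, 1.2)
        clearance = cfg.max_radius + r + 2.0
        if np.min(np.hypot(*(path - c).T)) < clearance:
            continue
        centers[placed] = c
        radii[placed] = r
        placed += 1
    return centers, radii


def generate_sequence(cfg: SceneConfig) -> tuple[list[Frame], list[BoundingBox]]:
    """Render the scene; returns frames and per-frame ground-truth boxes."""
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.frame_size
    path = _clamped_path(cfg)
    if cfg.n_distractors > 0:
        d_centers, d_radii = _place_distractors(cfg, path, rng)
        d_peaks = cfg.distractor_intensity * rng.uniform(0.6, 1.4, cfg.n_distractors)
        clutter = _render_blobs((h, w), d_centers, d_radii, d_peaks)
    else:
        clutter = np.zeros((h, w))
    frames: list[Frame] = []
    gt: list[BoundingBox] = []
    for t in range(cfg.n_frames):
        r_t = cfg.radius * cfg.scale_rate ** t
        cx, cy = path[t]
        img = cfg.background + clutter + _render_blobs(
            (h, w), [(cx, cy)], [r_t], [cfg.peak_intensity])
        occ = cfg.occluder
        if occ is not None and occ.start_frame <= t < occ.start_frame + occ.n_frames:
            half = occ.coverage * r_t  # bar height = coverage * (2 r) total
            y0 = int(round(cy - half))
            y1 = int(round(cy + half))
            img[max(0, y0):max(0, y1), :] = occ.intensity
        img *= cfg.illumination_drift ** t
        if cfg.noise_sigma > 0:
            img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
        frames.append(Frame(np.clip(img, 0.0, 1.0), index=t))
        gt.append(BoundingBox(cx - r_t, cy - r_t, 2 * r_t, 2 * r_t))
    return frames, gt


def generate_cell_field(cfg: SceneConfig, n_cells: int = 20
                        ) -> tuple[list[Frame], list[BoundingBox]]:
    """Many independently drifting cells; ground truth for the designated one.

    The designated cell (index 0) has the configured radius and peak
    intensity; the rest vary in size, brightness, and velocity.  All cells
    reflect off the frame borders so they stay in view.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    h, w = cfg.frame_size
    rng = np.random.default_rng(cfg.seed)
    radii = np.concatenate([[cfg.radius],
                            cfg.radius * rng.uniform(0.5, 1.3, n_cells - 1)])
    if np.sum(np.pi * radii ** 2) > 0.6 * h * w:
        raise ValueError("overcrowded configuration: blob area exceeds 60% of frame")
    peaks = np.concatenate([[cfg.peak_intensity],
                            cfg.peak_intensity * rng.uniform(0.4, 0.9, n_cells - 1)])
    margins = radii + 1
    centers = rng.uniform(0, 1, (n_cells, 2))
    centers[:, 0] = margins + centers[:, 0] * (w - 1 - 2 * margins)
    centers[:, 1] = margins + centers[:, 1] * (h - 1 - 2 * margins)
    vels = rng.uniform(-2.0, 2.0, (n_cells, 2))
    frames: list[Frame] = []
    gt: list[BoundingBox] = []
    for t in range(cfg.n_frames):
        img = cfg.background + _render_blobs((h, w), centers, radii, peaks)
        if cfg.noise_sigma > 0:
            img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
        frames.append(Frame(np.clip(img, 0.0, 1.0), index=t))
        gt.append(BoundingBox(centers[0, 0] - cfg.radius, centers[0, 1] - cfg.radius,
                              2 * cfg.radius, 2 * cfg.radius))
        centers = centers + vels
        for axis, dim in ((0, w), (1, h)):
            low = margins
            high = dim - 1 - margins
            over = centers[:, axis] > high
            under = centers[:, axis] < low
            centers[over, axis] = 2 * high[over] - centers[over, axis]
            centers[under, axis] = 2 * low[under] - centers[under, axis]
            vels[over | under, axis] *= -1
    return frames, gt
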