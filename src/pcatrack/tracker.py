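"""Bounding-box particle filter with a PCANet-feature observation model.

State per particle is ``(cx, cy, w, h)`` — box center and size.  Each frame
the filter (1) diffuses particles under a Gaussian motion model, (2) weighs
each particle by the classifier score of its 32x32 patch (the likelihood is
the score itself), (3) reports the maximum-weight particle as the MAP box,
(4) systematically resamples, and (5) harvests fresh labeled samples around
the MAP box into the buffer, periodically re-fitting the appearance model.
Harvesting only happens when the MAP score clears a confidence gate, which
limits drift from poor detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .appearance import (Classifier, LabeledSample, SampleBuffer,
                         refresh_model, sample_training_patches,
                         train_classifier, update_buffer)
from .imaging import BoundingBox, Frame, extract_patch, extract_patches
from .pcanet import PCANetModel, extract_features, learn_pcanet

__all__ = [
    "MotionConfig",
    "TrackerConfig",
    "TrackerState",
    "init_tracker",
    "propagate",
    "weigh",
    "select_map",
    "resample",
    "step",
    "track_sequence",
]

MIN_SIZE = 4.0  # particles never shrink below 4 px a side


@dataclass(frozen=True)
class MotionConfig:
    """Gaussian random-walk motion model.

    Position noise is additive in pixels; size noise is multiplicative
    (``w *= 1 + N(0, std_w^2)``) so the stated 0.1 acts as a relative
    scale deviation.
    """

    std_x: float = 15.0
    std_y: float = 15.0
    std_w: float = 0.1
    std_h: float = 0.1
    n_particles: int = 1000

    def __post_init__(self) -> None:
        if min(self.std_x, self.std_y, self.std_w, self.std_h) < 0:
            raise ValueError("motion stds must be non-negative")
        if self.n_particles < 1:
            raise ValueError("need at least one particle")


@dataclass(frozen=True)
class TrackerConfig:
    motion: MotionConfig = field(default_factory=MotionConfig)
    # feature pipeline
    n_stages: int = 2
    filter_size: int = 7
    filters_per_stage: int = 8
    block_size: int = 8
    block_overlap_fraction: float = 0.0
    # appearance model
    hidden_units: int = 64
    epochs: int = 200
    refresh_epochs: int = 50
    learning_rate: float = 0.5
    n_pos: int = 5
    n_neg: int = 20
    buffer_capacity: int = 25
    refresh_every: int = 5
    refresh_filters: bool = False
    min_harvest_score: float = 0.5
    score_chunk: int = 250  # particles scored per batch (memory bound)


@dataclass
class TrackerState:
    particles: np.ndarray  # (N, 4): cx, cy, w, h
    weights: np.ndarray  # (N,), normalized
    model: PCANetModel
    classifier: Classifier
    buffer: SampleBuffer
    config: TrackerConfig
    frame_index: int
    motion_rng: np.random.Generator
    sample_rng: np.random.Generator
    seed_rng: np.random.Generator  # yields classifier seeds for refits
    last_map_score: float = 1.0


def _box_to_state(box: BoundingBox) -> np.ndarray:
    cx, cy = box.center
    return np.array([cx, cy, box.w, box.h])


def _state_to_box(row: np.ndarray) -> BoundingBox:
    cx, cy, w, h = row
    return BoundingBox(cx - w / 2.0, cy - h / 2.0, w, h)


def init_tracker(frame: Frame, box: BoundingBox,
                 config: TrackerConfig | None = None, seed: int = 0) -> TrackerState:
    """Learn the appearance model on the first frame and spawn the particles.

    The filter stages are learned from the positive (target) patches; the
    classifier is trained on positives plus background negatives.  The
    ground-truth patch enters the buffer as its permanent anchor.  All
    particles start at the given box with uniform weights.
    """
    config = config or TrackerConfig()
    ss = np.random.SeedSequence(seed)
    motion_rng, sample_rng, seed_rng = (np.random.default_rng(c)
                                        for c in ss.spawn(3))
    anchor = LabeledSample(extract_patch(frame, box), True, frame.index,
                           is_anchor=True)
    drawn = sample_training_patches(frame, box, config.n_pos, config.n_neg,
                                    sample_rng)
    samples = [anchor] + drawn
    pos_patches = [s.patch for s in samples if s.label]
    model = learn_pcanet(
        pos_patches, n_stages=config.n_stages, k1=config.filter_size,
        k2=config.filter_size, filters_per_stage=config.filters_per_stage,
        block_size=config.block_size,
        block_overlap_fraction=config.block_overlap_fraction)
    feats = extract_features(np.stack([s.patch.pixels for s in samples]), model)
    for s, f in zip(samples, feats):
        s.feature = f
    clf_seed = int(seed_rng.integers(2 ** 31))
    classifier = train_classifier(
        samples, hidden_units=config.hidden_units, epochs=config.epochs,
        learning_rate=config.learning_rate, seed=clf_seed)
    buffer = update_buffer(SampleBuffer([anchor], capacity=config.buffer_capacity),
                           drawn)
    n = config.motion.n_particles
    particles = np.tile(_box_to_state(box), (n, 1))
    weights = np.full(n, 1.0 / n)
    return TrackerState(particles, weights, model, classifier, buffer, config,
                        frame.index, motion_rng, sample_rng, seed_rng)


def propagate(particles: np.ndarray, motion: MotionConfig,
              rng: np.random.Generator) -> np.ndarray:
    """Diffuse particle states under the Gaussian motion model."""
    out = particles.copy()
    n = out.shape[0]
    out[:, 0] += rng.normal(0.0, motion.std_x, n) if motion.std_x > 0 else 0.0
    out[:, 1] += rng.normal(0.0, motion.std_y, n) if motion.std_y > 0 else 0.0
    if motion.std_w > 0:
        out[:, 2] *= 1.0 + rng.normal(0.0, motion.std_w, n)
    if motion.std_h > 0:
        out[:, 3] *= 1.0 + rng.normal(0.0, motion.std_h, n)
    out[:, 2:] = np.maximum(np.abs(out[:, 2:]), MIN_SIZE)
    return out


def _in_frame_mask(particles: np.ndarray, frame: Frame) -> np.ndarray:
    left = particles[:, 0] - particles[:, 2] / 2
    top = particles[:, 1] - particles[:, 3] / 2
    right = left + particles[:, 2]
    bottom = top + particles[:, 3]
    return (right > 0) & (bottom > 0) & (left < frame.width) & (top < frame.height)


def weigh(particles: np.ndarray, frame: Frame, model: PCANetModel,
          classifier: Classifier, chunk: int = 250) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood weights for all particles.

    Returns ``(weights, raw_scores)``; weights are the classifier scores of
    each particle's patch, zeroed for out-of-frame particles and normalized
    to sum 1 (uniform fallback when everything scores 0).
    """
    n = particles.shape[0]
    scores = np.zeros(n)
    mask = _in_frame_mask(particles, frame)
    idx = np.flatnonzero(mask)
    for i in range(0, idx.size, chunk):
        sel = idx[i:i + chunk]
        boxes = [_state_to_box(particles[j]) for j in sel]
        patches = extract_patches(frame, boxes)
        feats = extract_features(patches, model)
        scores[sel] = classifier.scores(feats)
    weights = scores * mask
    total = weights.sum()
    if total <= 0:
        weights = np.full(n, 1.0 / n)
    else:
        weights = weights / total
    return weights, scores


def select_map(particles: np.ndarray, weights: np.ndarray) -> BoundingBox:
    """Box of the maximum-weight particle (ties: lowest index)."""
    if particles.shape[0] == 0:
        raise ValueError("empty particle set")
    return _state_to_box(particles[int(np.argmax(weights))])


def resample(particles: np.ndarray, weights: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Systematic resampling: copy counts of particle i concentrate on N*w_i."""
    n = particles.shape[0]
    positions = (np.arange(n) + rng.uniform()) / n
    cumulative = np.cumsum(weights)
    cumulative[-1] = 1.0  # guard against rounding shortfall
    idx = np.searchsorted(cumulative, positions, side="right")
    return particles[np.minimum(idx, n - 1)].copy()


def step(state: TrackerState, frame: Frame) -> tuple[TrackerState, BoundingBox]:
    """Advance the tracker by one frame; returns the updated state and MAP box."""
    cfg = state.config
    state.particles = propagate(state.particles, cfg.motion, state.motion_rng)
    state.weights, scores = weigh(state.particles, frame, state.model,
                                  state.classifier, chunk=cfg.score_chunk)
    map_idx = int(np.argmax(state.weights))
    map_box = _state_to_box(state.particles[map_idx])
    state.last_map_score = float(scores[map_idx])
    state.particles = resample(state.particles, state.weights, state.motion_rng)
    state.weights = np.full(len(state.weights), 1.0 / len(state.weights))
    state.frame_index += 1
    if state.last_map_score > cfg.min_harvest_score:
        try:
            new = sample_training_patches(frame, map_box, cfg.n_pos, cfg.n_neg,
                                          state.sample_rng)
        except ValueError:
            # target too close to the border to place clean negatives; a frame
            # we cannot sample safely is a frame we do not learn from
            return state, map_box
        feats = extract_features(np.stack([s.patch.pixels for s in new]),
                                 state.model)
        for s, f in zip(new, feats):
            s.feature = f
        state.buffer = update_buffer(state.buffer, new)
        if state.frame_index % cfg.refresh_every == 0:
            clf_seed = int(state.seed_rng.integers(2 ** 31))
            state.model, state.classifier = refresh_model(
                state.buffer, state.model, state.classifier,
                refresh_filters=cfg.refresh_filters, seed=clf_seed,
                epochs=cfg.refresh_epochs, learning_rate=cfg.learning_rate,
                hidden_units=cfg.hidden_units)
    return state, map_box


def track_sequence(frames, init_box: BoundingBox,
                   config: TrackerConfig | None = None, seed: int = 0,
                   progress=None) -> list[BoundingBox]:
    """Track through a full sequence; the first reported box is the init box."""
    frames = list(frames)
    if not frames:
        raise ValueError("empty sequence")
    state = init_tracker(frames[0], init_box, config, seed)
    trajectory = [init_box]
    for frame in frames[1:]:
        state, box = step(state, frame)
        trajectory.append(box)
        if progress is not None:
            progress(frame.index, box, state.last_map_score)
    return trajectory
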