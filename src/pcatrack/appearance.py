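"""Discriminative appearance model: a one-hidden-layer network on PCANet
features, plus the online buffer of labeled samples that keeps it current.

The network maps a feature vector to a target-likeness score in [0, 1] used
directly as the particle likelihood.  The buffer is a capacity-bounded pool
(default 25) holding the first-frame ground-truth sample as a permanent
anchor; when full, the most redundant non-anchor sample — the one whose
feature lies closest to its nearest neighbor — is evicted first, which keeps
the retained set diverse while the anchor keeps it representative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .imaging import BoundingBox, Frame, Patch, extract_patch

__all__ = [
    "LabeledSample",
    "SampleBuffer",
    "Classifier",
    "sample_boxes",
    "sample_training_patches",
    "fit_mlp",
    "train_classifier",
    "score",
    "update_buffer",
    "refresh_model",
]


@dataclass(eq=False)  # samples compare by identity; features are arrays
class LabeledSample:
    patch: Patch
    label: bool  # True = positive (target), False = negative (background)
    frame_index: int = 0
    feature: np.ndarray | None = None
    is_anchor: bool = False

    def __post_init__(self) -> None:
        if self.is_anchor and not self.label:
            raise ValueError("the anchor sample must be positive")


@dataclass
class SampleBuffer:
    samples: list[LabeledSample] = field(default_factory=list)
    capacity: int = 25

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def anchor(self) -> LabeledSample:
        for s in self.samples:
            if s.is_anchor:
                return s
        raise ValueError("buffer has lost its anchor sample")

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=bool)

    def features(self) -> np.ndarray:
        return np.stack([s.feature for s in self.samples])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class Classifier:
    """Fully connected net: input -> sigmoid hidden layer -> sigmoid output."""

    w1: np.ndarray  # (input_dim, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    input_scale: float = 1.0  # fixed rescaling applied to inputs at train time

    @property
    def input_dim(self) -> int:
        return self.w1.shape[0]

    @property
    def hidden_units(self) -> int:
        return self.w1.shape[1]

    def scores(self, features: np.ndarray) -> np.ndarray:
        """Forward pass for a (n, input_dim) batch; returns scores in [0, 1].

        float32 input runs the matrix products in float32 (the tracking fast
        path); anything else is evaluated in float64.
        """
        x = np.asarray(features)
        if x.dtype != np.float32:
            x = x.astype(np.float64)
        if x.ndim == 1:
            x = x[None]
        if x.shape[1] != self.input_dim:
            raise ValueError(
                f"feature dim {x.shape[1]} != classifier input dim {self.input_dim}"
            )
        if x.dtype == np.float32:
            w1, b1, w2 = self._f32
            hidden = _sigmoid(x * np.float32(self.input_scale) @ w1 + b1)
            return _sigmoid(hidden @ w2 + np.float32(self.b2))
        hidden = _sigmoid(x * self.input_scale @ self.w1 + self.b1)
        return _sigmoid(hidden @ self.w2 + self.b2)

    @property
    def _f32(self):
        cached = getattr(self, "_f32_cache", None)
        if cached is None:
            cached = (self.w1.astype(np.float32), self.b1.astype(np.float32),
                      self.w2.astype(np.float32))
            object.__setattr__(self, "_f32_cache", cached)
        return cached


def score(classifier: Classifier, feature: np.ndarray) -> float:
    """Target-likeness of a single feature vector; higher = more target-like."""
    return float(classifier.scores(np.asarray(feature)[None])[0])


def _loss(clf: Classifier, x: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(clf.scores(x), 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_mlp(features: np.ndarray, labels: np.ndarray, hidden_units: int = 64,
            epochs: int = 200, learning_rate: float = 0.5, seed: int = 0,
            init: Classifier | None = None) -> Classifier:
    """Train the one-hidden-layer net by full-batch gradient descent.

    Cross-entropy loss; weights start from a seeded standard normal scaled
    by ``1/sqrt(fan_in)`` (or warm-start from ``init``).  The returned
    classifier is the best iterate seen, so warm-started retraining on the
    same data can never end with a higher loss than it started with.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("features must be (n, d) with one label per row")
    if len(np.unique(y)) < 2:
        raise ValueError("training needs both positive and negative samples")
    n, d = x.shape
    if init is None:
        rng = np.random.default_rng(seed)
        peak = float(np.abs(x).max())
        scale = 1.0 / peak if peak > 0 else 1.0
        w1 = rng.standard_normal((d, hidden_units)) / np.sqrt(d)
        b1 = np.zeros(hidden_units)
        w2 = rng.standard_normal(hidden_units) / np.sqrt(hidden_units)
        b2 = 0.0
    else:
        scale = init.input_scale
        w1, b1 = init.w1.copy(), init.b1.copy()
        w2, b2 = init.w2.copy(), float(init.b2)
        hidden_units = init.hidden_units
    xs = x * scale
    # Full-batch GD updates to the input weights always lie in the row space
    # of the training matrix, so iterate on the n x hidden dual coefficients
    # A (w1 = w1_init + xs^T A) instead of the d x hidden weights.  This is
    # the same gradient-descent trajectory, at O(n^2) instead of O(n d) per
    # epoch, which is what makes re-training cheap at d ~ 10^5.
    base = xs @ w1  # (n, hidden), fixed during training
    gram = xs @ xs.T
    A = np.zeros((n, hidden_units))

    def mean_ce(p):
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def forward(A, b1, w2, b2):
        hidden = _sigmoid(base + gram @ A + b1)
        return hidden, _sigmoid(hidden @ w2 + b2)

    _, p0 = forward(A, b1, w2, b2)
    best = (A.copy(), b1.copy(), w2.copy(), b2)
    best_loss = mean_ce(p0)
    for epoch in range(epochs):
        hidden, p = forward(A, b1, w2, b2)
        delta_out = (p - y) / n  # d(mean CE)/d(logit)
        grad_w2 = hidden.T @ delta_out
        grad_b2 = delta_out.sum()
        delta_hid = np.outer(delta_out, w2) * hidden * (1 - hidden)
        A -= learning_rate * delta_hid  # == w1 -= lr * xs^T delta_hid
        b1 -= learning_rate * delta_hid.sum(axis=0)
        w2 -= learning_rate * grad_w2
        b2 -= learning_rate * grad_b2
        if not (np.isfinite(A).all() and np.isfinite(w2).all()):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        _, p = forward(A, b1, w2, b2)
        loss = mean_ce(p)
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        if loss < best_loss:
            best_loss = loss
            best = (A.copy(), b1.copy(), w2.copy(), b2)
    A_b, b1_b, w2_b, b2_b = best
    return Classifier(w1 + xs.T @ A_b, b1_b, w2_b, b2_b, input_scale=scale)


def train_classifier(samples, hidden_units: int = 64, epochs: int = 200,
                     learning_rate: float = 0.5, seed: int = 0,
                     init: Classifier | None = None) -> Classifier:
    """Train from labeled samples carrying cached feature vectors."""
    feats = np.stack([s.feature for s in samples])
    labels = np.array([s.label for s in samples], dtype=float)
    return fit_mlp(feats, labels, hidden_units=hidden_units, epochs=epochs,
                   learning_rate=learning_rate, seed=seed, init=init)


def sample_boxes(frame: Frame, box: BoundingBox, n_pos: int, n_neg: int,
                 rng: np.random.Generator) -> tuple[list[BoundingBox], list[BoundingBox]]:
    """Draw positive and negative example boxes around a seed box.

    Positives share the seed's size with centers jittered inside a disc of
    radius ``0.1 * min(w, h)`` (IoU with the seed stays above 0.7).
    Negatives are displaced by ``[0.5, 1.5] * min(w, h)`` and half of them
    are additionally rescaled by a factor outside ``[0.7, 1.3]``; both
    together keep negative IoU below 0.5.
    """
    cx, cy = box.center
    s = min(box.w, box.h)
    positives: list[BoundingBox] = []
    for _ in range(n_pos):
        r = 0.1 * s * np.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        positives.append(BoundingBox(box.x + r * np.cos(theta),
                                     box.y + r * np.sin(theta), box.w, box.h))
    negatives: list[BoundingBox] = []
    attempts = 0
    while len(negatives) < n_neg:
        attempts += 1
        if attempts > 200 * max(1, n_neg):
            raise ValueError("frame too small to place negative samples")
        r = s * rng.uniform(0.5, 1.5)
        theta = rng.uniform(0, 2 * np.pi)
        ncx, ncy = cx + r * np.cos(theta), cy + r * np.sin(theta)
        w, h = box.w, box.h
        if rng.uniform() < 0.5:
            f = rng.uniform(0.4, 0.7) if rng.uniform() < 0.5 else rng.uniform(1.3, 2.0)
            w, h = w * f, h * f
        cand = BoundingBox(ncx - w / 2, ncy - h / 2, w, h)
        # negatives must be clean background patches: fully inside the frame
        if (cand.x < 0 or cand.y < 0 or cand.x + cand.w > frame.width
                or cand.y + cand.h > frame.height):
            continue
        negatives.append(cand)
    return positives, negatives


def sample_training_patches(frame: Frame, box: BoundingBox, n_pos: int,
                            n_neg: int, rng: np.random.Generator) -> list[LabeledSample]:
    """Harvest labeled 32x32 patches around a seed box (features not yet cached)."""
    positives, negatives = sample_boxes(frame, box, n_pos, n_neg, rng)
    out = [LabeledSample(extract_patch(frame, b), True, frame.index) for b in positives]
    out += [LabeledSample(extract_patch(frame, b), False, frame.index) for b in negatives]
    return out


def update_buffer(buffer: SampleBuffer, new_samples) -> SampleBuffer:
    """Append samples, then evict the most redundant non-anchor ones.

    While over capacity, the non-anchor sample whose feature is closest to
    its nearest neighbor in the buffer is removed (ties: oldest first).
    The anchor is never evicted.  Samples must carry cached features.

    Pairwise distances are computed once; evicting a sample only removes its
    row and column, so the loop works on the shrinking submatrix.
    """
    buffer.anchor  # raises if the invariant is already broken
    samples = list(buffer.samples) + list(new_samples)
    excess = len(samples) - buffer.capacity
    if excess <= 0:
        return SampleBuffer(samples, capacity=buffer.capacity)
    feats = np.stack([np.asarray(s.feature, dtype=np.float64) for s in samples])
    sq = np.sum(feats ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (feats @ feats.T)
    np.fill_diagonal(d2, np.inf)
    alive = list(range(len(samples)))
    for _ in range(excess):
        sub = d2[np.ix_(alive, alive)]
        nn = np.sqrt(np.maximum(sub.min(axis=1), 0.0))
        order = np.argsort(nn, kind="stable")
        victim = next(i for i in order if not samples[alive[i]].is_anchor)
        alive.pop(victim)
    return SampleBuffer([samples[i] for i in alive], capacity=buffer.capacity)


def refresh_model(buffer: SampleBuffer, model, old_classifier: Classifier,
                  refresh_filters: bool = False, seed: int = 0,
                  epochs: int = 50, learning_rate: float = 0.5,
                  hidden_units: int = 64):
    """Re-fit the appearance model from the current buffer.

    Always retrains the classifier warm-started from the old weights; when
    ``refresh_filters`` is set, the PCA stages are first re-learned from the
    buffer's positive patches and every buffered feature is re-extracted.
    A one-class buffer leaves everything unchanged (with a warning).
    """
    from .pcanet import extract_features, learn_pcanet

    labels = buffer.labels()
    if labels.all() or not labels.any():
        warnings.warn("one-class sample buffer: skipping model refresh")
        return model, old_classifier
    if refresh_filters:
        pos = [s.patch for s in buffer.samples if s.label]
        model = learn_pcanet(
            pos, n_stages=len(model.stages), k1=model.stages[0].k1,
            k2=model.stages[0].k2,
            filters_per_stage=[s.n_filters for s in model.stages],
            block_size=model.block_size,
            block_overlap_fraction=model.block_overlap_fraction)
        batch = np.stack([s.patch.pixels for s in buffer.samples])
        feats = extract_features(batch, model)
        for s, f in zip(buffer.samples, feats):
            s.feature = f
        old_classifier = None  # feature space changed; cold start
    clf = train_classifier(buffer.samples, hidden_units=hidden_units, seed=seed,
                           epochs=epochs, learning_rate=learning_rate,
                           init=old_classifier)
    return model, clf
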