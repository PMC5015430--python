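"""Cascaded PCA eigenfilter learning, binary hashing, and block histograms.

The descriptor is built in three steps.  First, filters are learned without
supervision: every overlapping ``k1 x k2`` window of the training patches is
vectorized and mean-removed, and the leading eigenvectors of the pooled
scatter matrix become convolution kernels ("eigenfilters").  Stages cascade:
later stages are learned on the response maps of earlier ones.  Second, the
final stage's responses are binarized at zero and read per pixel as a
``hash_width``-bit integer code (first filter = most significant bit).
Third, each integer code map is split into spatial blocks and each block is
summarized by a count histogram over all ``2**hash_width`` codes; the
concatenation over blocks and maps is the feature vector.

The nonlinearity is the Heaviside step in the hashing; the pooling is the
block histogram — there is no learned nonlinear layer.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass

import numba
import numpy as np

from .imaging import PATCH_SIZE, Patch

__all__ = [
    "FilterStage",
    "PCANetModel",
    "collect_patches",
    "learn_filter_stage",
    "convolve_stage",
    "binary_hash",
    "block_histogram",
    "block_starts",
    "learn_pcanet",
    "extract_feature",
    "extract_features",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class FilterStage:
    """An ordered bank of orthonormal ``k1 x k2`` eigenfilters."""

    filters: np.ndarray  # (L, k1, k2), descending eigenvalue order

    def __post_init__(self) -> None:
        f = np.asarray(self.filters, dtype=np.float64)
        if f.ndim != 3:
            raise ValueError("filters must be a (L, k1, k2) array")
        object.__setattr__(self, "filters", f)

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]

    @property
    def k1(self) -> int:
        return self.filters.shape[1]

    @property
    def k2(self) -> int:
        return self.filters.shape[2]


@dataclass(frozen=True)
class PCANetModel:
    """Learned filter stages plus the hashing/histogram geometry.

    Two stages is the standard configuration; three stages is the deeper
    variant.  The last stage's filter count is the hash width; every map
    produced by the preceding stages is hashed into one integer code map.
    """

    stages: tuple[FilterStage, ...]
    block_size: int = 8
    block_overlap_fraction: float = 0.0
    patch_size: int = PATCH_SIZE

    def __post_init__(self) -> None:
        stages = tuple(self.stages)
        if len(stages) < 2:
            raise ValueError("a model needs at least 2 filter stages")
        if stages[-1].n_filters > 30:
            raise ValueError("hash width above 30 bits does not fit the code range")
        if not (0 <= self.block_overlap_fraction < 1):
            raise ValueError("block_overlap_fraction must lie in [0, 1)")
        object.__setattr__(self, "stages", stages)

    @property
    def hash_width(self) -> int:
        return self.stages[-1].n_filters

    @property
    def n_code_maps(self) -> int:
        """Number of decimal code maps = product of all but the last stage's L."""
        n = 1
        for s in self.stages[:-1]:
            n *= s.n_filters
        return n

    @property
    def n_blocks(self) -> int:
        starts = block_starts(self.patch_size, self.block_size,
                              self.block_overlap_fraction)
        return len(starts) ** 2

    @property
    def feature_dim(self) -> int:
        return self.n_code_maps * self.n_blocks * (1 << self.hash_width)


def collect_patches(image: np.ndarray, k1: int, k2: int) -> np.ndarray:
    """All overlapping ``k1 x k2`` windows of ``image``, one mean-removed column each.

    Returns a ``(k1*k2, n_windows)`` matrix; stride 1, valid positions only.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    if h < k1 or w < k2:
        raise ValueError(f"image {img.shape} smaller than filter ({k1}, {k2})")
    windows = np.lib.stride_tricks.sliding_window_view(img, (k1, k2))
    cols = windows.reshape(-1, k1 * k2).T.copy()
    cols -= cols.mean(axis=0, keepdims=True)
    return cols


def learn_filter_stage(images, k1: int, k2: int, L: int) -> FilterStage:
    """Learn ``L`` eigenfilters from the pooled windows of ``images``.

    Filters are the leading eigenvectors of the pooled scatter matrix
    ``X X^T`` of mean-removed windows, ordered by descending eigenvalue,
    each sign-fixed so its largest-magnitude entry is positive.
    """
    images = list(images)
    if not images:
        raise ValueError("need at least one training image")
    if L > k1 * k2:
        raise ValueError(f"cannot learn {L} filters of size {k1}x{k2}")
    scatter = np.zeros((k1 * k2, k1 * k2))
    for img in images:
        x = collect_patches(np.asarray(img, dtype=np.float64), k1, k2)
        scatter += x @ x.T
    eigvals, eigvecs = np.linalg.eigh(scatter)
    eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
    if eigvals[0] <= 0 or eigvals[L - 1] <= 1e-12 * eigvals[0]:
        raise ValueError(
            "degenerate training data: pooled patch scatter has rank "
            f"< {L} (e.g. constant images)"
        )
    filters = np.empty((L, k1, k2))
    for i in range(L):
        v = eigvecs[:, i]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        filters[i] = v.reshape(k1, k2)
    return FilterStage(filters)


@functools.lru_cache(maxsize=None)
def _make_corr_kernel(k1: int, k2: int):
    # closure constants let LLVM fully unroll the filter taps (SIMD-friendly)
    @numba.njit
    def kern(padded, filters, out):
        b, hp, wp = padded.shape
        L = filters.shape[0]
        h = hp - (k1 - 1)
        w = wp - (k2 - 1)
        zero = filters[0, 0, 0] * numba.float32(0.0)
        for i in range(b):
            for l in range(L):
                for y in range(h):
                    for x in range(w):
                        acc = zero
                        for u in range(k1):
                            for v in range(k2):
                                acc += padded[i, y + u, x + v] * filters[l, u, v]
                        out[i, l, y, x] = acc

    return kern


def _correlate_bank(images: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """Same-size zero-padded correlation of a batch of images with a filter bank.

    ``images`` is ``(B, H, W)``; returns ``(B, L, H, W)`` in the input dtype.
    """
    b, h, w = images.shape
    L, k1, k2 = filters.shape
    if h < k1 or w < k2:
        raise ValueError(f"image {(h, w)} smaller than filter ({k1}, {k2})")
    ph, pw = (k1 - 1) // 2, (k2 - 1) // 2
    padded = np.zeros((b, h + k1 - 1, w + k2 - 1), dtype=images.dtype)
    padded[:, ph:ph + h, pw:pw + w] = images
    out = np.empty((b, L, h, w), dtype=images.dtype)
    kern = _make_corr_kernel(k1, k2)
    kern(padded, np.ascontiguousarray(filters.astype(images.dtype)), out)
    return out


def convolve_stage(image: np.ndarray, stage: FilterStage) -> list[np.ndarray]:
    """Correlate ``image`` with every filter of ``stage`` (same-size, zero pad).

    No mean removal happens here — window mean removal belongs to filter
    learning only.
    """
    img = np.asarray(image, dtype=np.float64)
    resp = _correlate_bank(img[None], stage.filters)
    return [resp[0, ell] for ell in range(stage.n_filters)]


def binary_hash(responses) -> np.ndarray:
    """Threshold a stack of response maps at zero and read codes per pixel.

    ``bit_l = 1`` iff ``response_l > 0`` (exact zeros hash to 0); the first
    map contributes the most significant bit.  Returns an integer map.
    """
    stack = [np.asarray(r) for r in responses]
    shape = stack[0].shape
    if any(r.shape != shape for r in stack):
        raise ValueError("response maps must share a common shape")
    width = len(stack)
    codes = np.zeros(shape, dtype=np.int64)
    for ell, r in enumerate(stack):
        codes |= (r > 0).astype(np.int64) << (width - 1 - ell)
    return codes


def block_starts(side: int, block_size: int, overlap_fraction: float) -> list[int]:
    """Top/left offsets of the blocks tiling one axis of a code map.

    Stride is ``round(block_size * (1 - overlap_fraction))``; the final block
    is anchored to the far edge so the map is always fully covered.
    """
    if block_size > side:
        raise ValueError(f"block size {block_size} exceeds map side {side}")
    stride = max(1, int(round(block_size * (1.0 - overlap_fraction))))
    starts = list(range(0, side - block_size + 1, stride))
    if starts[-1] != side - block_size:
        starts.append(side - block_size)
    return starts


def block_histogram(decimal_map: np.ndarray, block_size: int,
                    overlap_fraction: float = 0.0,
                    n_bins: int | None = None) -> np.ndarray:
    """Concatenated per-block count histograms of a decimal code map.

    Blocks are enumerated row-major; each contributes ``n_bins`` counts
    (default: enough bins for the largest code present).
    """
    codes = np.asarray(decimal_map)
    if codes.ndim != 2:
        raise ValueError("decimal map must be 2-D")
    if n_bins is None:
        n_bins = int(codes.max()) + 1
    h, w = codes.shape
    rows = block_starts(h, block_size, overlap_fraction)
    cols = block_starts(w, block_size, overlap_fraction)
    hists = []
    for r in rows:
        for c in cols:
            block = codes[r:r + block_size, c:c + block_size]
            hists.append(np.bincount(block.ravel(), minlength=n_bins))
    return np.concatenate(hists).astype(np.float64)


def _propagate_maps(patches: np.ndarray, stages, upto: int) -> np.ndarray:
    """Run a batch of patches through stages ``[0, upto)``; returns (B, M, H, W)."""
    maps = patches[:, None, :, :]
    for stage in stages[:upto]:
        b, m, h, w = maps.shape
        resp = _correlate_bank(maps.reshape(b * m, h, w), stage.filters)
        maps = resp.reshape(b, m * stage.n_filters, h, w)
    return maps


def learn_pcanet(training_patches, n_stages: int = 2, k1: int = 7, k2: int = 7,
                 filters_per_stage: int | list[int] = 8, block_size: int = 8,
                 block_overlap_fraction: float = 0.0) -> PCANetModel:
    """Learn a full cascade from training patches.

    Stage 1 is learned on the raw patches; each deeper stage on all response
    maps of the patches propagated through the stages before it.
    """
    patches = [p.pixels if isinstance(p, Patch) else np.asarray(p, dtype=np.float64)
               for p in training_patches]
    if not patches:
        raise ValueError("need at least one training patch")
    if isinstance(filters_per_stage, int):
        counts = [filters_per_stage] * n_stages
    else:
        counts = list(filters_per_stage)
        if len(counts) != n_stages:
            raise ValueError("filters_per_stage length must equal n_stages")
    batch = np.stack(patches)
    stages: list[FilterStage] = []
    for s, L in enumerate(counts):
        maps = _propagate_maps(batch, stages, s)
        images = maps.reshape(-1, maps.shape[2], maps.shape[3])
        stages.append(learn_filter_stage(images, k1, k2, L))
    return PCANetModel(tuple(stages), block_size=block_size,
                       block_overlap_fraction=block_overlap_fraction,
                       patch_size=batch.shape[1])


@functools.lru_cache(maxsize=None)
def _make_hash_hist_kernel(L: int, block_size: int):
    """Fused hashing + block histograms; one pass per code map.

    The kernel takes ``resp`` of shape ``(M, L, h, w)`` and accumulates into
    ``out`` of shape ``(M, n_blocks * n_bins)`` (zero-initialized).  Matches
    binary_hash + block_histogram bit for bit.
    """
    @numba.njit
    def kern(resp, row_starts, col_starts, n_bins, out):
        M = resp.shape[0]
        h = resp.shape[2]
        w = resp.shape[3]
        codes = np.empty((h, w), dtype=np.int64)
        for j in range(M):
            for y in range(h):
                for x in range(w):
                    code = 0
                    for ell in range(L):
                        if resp[j, ell, y, x] > 0:
                            code |= 1 << (L - 1 - ell)
                    codes[y, x] = code
            bi = 0
            for r in row_starts:
                for c in col_starts:
                    base = bi * n_bins
                    for yy in range(r, r + block_size):
                        for xx in range(c, c + block_size):
                            out[j, base + codes[yy, xx]] += 1
                    bi += 1

    return kern


def extract_features(patches: np.ndarray, model: PCANetModel,
                     dtype=np.float32) -> np.ndarray:
    """Feature vectors for a batch of patches; shape ``(B, model.feature_dim)``.

    Histogram counts are exact small integers, so the default float32 output
    is lossless; the convolution path runs in the same dtype for speed.
    """
    batch = np.asarray(patches, dtype=dtype)
    if batch.ndim == 2:
        batch = batch[None]
    b = batch.shape[0]
    penult = _propagate_maps(batch, model.stages, len(model.stages) - 1)
    _, m, h, w = penult.shape
    last = model.stages[-1]
    resp = _correlate_bank(penult.reshape(b * m, h, w), last.filters)
    n_bins = 1 << last.n_filters
    rows = block_starts(h, model.block_size, model.block_overlap_fraction)
    cols = block_starts(w, model.block_size, model.block_overlap_fraction)
    n_blocks = len(rows) * len(cols)
    feats = np.zeros((b * m, n_blocks * n_bins), dtype=dtype)
    kern = _make_hash_hist_kernel(last.n_filters, model.block_size)
    kern(resp, np.asarray(rows, dtype=np.int64),
         np.asarray(cols, dtype=np.int64), n_bins, feats)
    # layout per patch: code maps major, blocks (row-major) next, bins innermost
    return feats.reshape(b, m * n_blocks * n_bins)


def extract_feature(patch, model: PCANetModel) -> np.ndarray:
    """Descriptor of one patch: hashed block histograms over all code maps."""
    px = patch.pixels if isinstance(patch, Patch) else np.asarray(patch)
    return extract_features(px[None], model)[0]


_FORMAT_TAG = "pcatrack-model-v1"


def save_model(path, model: PCANetModel, classifier=None) -> None:
    """Serialize a model (and optionally its classifier) to an ``.npz`` archive."""
    meta = {
        "format": _FORMAT_TAG,
        "n_stages": len(model.stages),
        "block_size": model.block_size,
        "block_overlap_fraction": model.block_overlap_fraction,
        "patch_size": model.patch_size,
        "has_classifier": classifier is not None,
    }
    if classifier is not None:
        meta["input_scale"] = float(classifier.input_scale)
    arrays = {f"stage_{i}": s.filters for i, s in enumerate(model.stages)}
    if classifier is not None:
        arrays.update(
            clf_w1=classifier.w1, clf_b1=classifier.b1,
            clf_w2=classifier.w2, clf_b2=np.asarray([classifier.b2]),
        )
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path):
    """Inverse of :func:`save_model`; returns ``(model, classifier_or_None)``."""
    from .appearance import Classifier

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta.get("format") != _FORMAT_TAG:
            raise ValueError(f"unrecognized model format tag in {path}")
        stages = tuple(FilterStage(data[f"stage_{i}"])
                       for i in range(meta["n_stages"]))
        model = PCANetModel(stages, block_size=meta["block_size"],
                            block_overlap_fraction=meta["block_overlap_fraction"],
                            patch_size=meta["patch_size"])
        clf = None
        if meta["has_classifier"]:
            clf = Classifier(w1=data["clf_w1"], b1=data["clf_b1"],
                             w2=data["clf_w2"], b2=float(data["clf_b2"][0]),
                             input_scale=float(meta["input_scale"]))
    return model, clf
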