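"""Cascaded ensemble-of-regression-trees landmark localization.

The predictor is a cascade of T stages; each stage is an ensemble of K
shallow regression trees fitted by gradient boosting with a
sum-of-squares loss and shrinkage ``nu``.  A stage samples a pool of
shape-indexed feature points — positions expressed in the mean-shape
frame, anchored to their nearest landmark — and every tree node tests
the difference of image intensities at two pool points against a
threshold.  Each leaf stores an additive update for the full 52-vector
of landmark coordinates; after every tree the current shape estimate
moves, so later trees (and later stages, which re-index their features
against the updated shape) see progressively better-registered
features.

Training examples are built by oversampling: each training image is
used R times with different initial shapes (the mean shape, then ground
truths of other images), so the cascade learns to pull a range of
plausible initializations onto the target configuration.

Everything is deterministic given the training seed.  Total work scales
with F·R·T (tree depth × oversampling × cascade depth), matching the
gradient-boosting accounting exposed by the model's counters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import N_LANDMARKS, LandmarkSet
from .synthetic import AnnotatedImage

_MODEL_FORMAT_VERSION = 1
_SHAPE_DIM = 2 * N_LANDMARKS


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the cascaded regression-tree trainer.

    ``nu`` (shrinkage), ``cascade_depth`` (T), ``tree_depth`` (F) and
    ``oversampling`` (R) are the parameters the method is usually tuned
    on; defaults follow the tuning optimum on the reference task
    (nu=0.2, F=1, R=20).  The remaining knobs — trees per stage K,
    feature-pool size, split proposals per node, and the locality scale
    of the exponential pair-distance prior — follow common practice for
    this algorithm family and are freely overridable.
    ``feature_locality_lambda`` is in pixels; ``None`` resolves to
    0.1 × image width at training time.
    """

    nu: float = 0.2
    cascade_depth: int = 10
    tree_depth: int = 1
    oversampling: int = 20
    trees_per_stage: int = 500
    feature_pool_size: int = 400
    candidate_splits_per_node: int = 20
    feature_locality_lambda: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.nu <= 1.0:
            raise ValueError("nu must be in (0, 1]")
        if self.cascade_depth < 0:
            raise ValueError("cascade_depth must be >= 0")
        if self.tree_depth < 0:
            raise ValueError("tree_depth must be >= 0")
        if self.oversampling < 1:
            raise ValueError("oversampling must be >= 1")
        if self.trees_per_stage < 1 or self.feature_pool_size < 2:
            raise ValueError("trees_per_stage >= 1 and feature_pool_size >= 2 required")
        if self.candidate_splits_per_node < 1:
            raise ValueError("candidate_splits_per_node must be >= 1")


# ----------------------------------------------------------------------
# similarity alignment
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityTransform:
    """Least-squares similarity (scale · rotation + translation)."""

    scale: float
    rotation: float          # radians, y-down frame
    translation: np.ndarray  # (2,)

    @property
    def linear(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.linear.T + self.translation


def align_similarity(src: LandmarkSet | np.ndarray,
                     dst: LandmarkSet | np.ndarray) -> SimilarityTransform:
    """Closed-form least-squares similarity transform src → dst.

    Minimizes the summed squared distances over corresponding points
    (Procrustes with scaling, no reflection).  Raises ``ValueError`` on
    degenerate input (all source points coincident).
    """
    a = src.coords if isinstance(src, LandmarkSet) else np.asarray(src, float)
    b = dst.coords if isinstance(dst, LandmarkSet) else np.asarray(dst, float)
    lin, t = _batch_similarity(a[None], b[None])
    sr = lin[0]
    scale = float(np.sqrt(np.linalg.det(sr)))
    if not np.isfinite(scale) or scale <= 0:
        raise ValueError("degenerate point configuration: similarity undefined")
    rot = float(np.arctan2(sr[1, 0], sr[0, 0]))
    return SimilarityTransform(scale, rot, t[0])


def _batch_similarity(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Umeyama similarity fits for stacked correspondences.

    ``src``/``dst`` have shape (n, p, 2); returns the linear parts
    (n, 2, 2) and translations (n, 2) such that dst ≈ src·Aᵀ + t.
    """
    mu_s = src.mean(axis=1, keepdims=True)
    mu_d = dst.mean(axis=1, keepdims=True)
    cs = src - mu_s
    cd = dst - mu_d
    p = src.shape[1]
    cov = np.einsum("npi,npj->nij", cd, cs) / p          # (n,2,2)
    var_s = np.einsum("npi,npi->n", cs, cs) / p
    u, s, vt = np.linalg.svd(cov)
    det = np.linalg.det(u @ vt)
    d = np.ones((src.shape[0], 2))
    d[:, 1] = np.sign(det)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = (s * d).sum(axis=1) / var_s
    rot = u @ (d[:, :, None] * vt)
    lin = scale[:, None, None] * rot
    t = mu_d[:, 0, :] - np.einsum("nij,nj->ni", lin, mu_s[:, 0, :])
    return lin, t


# ----------------------------------------------------------------------
# model containers
# ----------------------------------------------------------------------

@dataclass
class RegressionTree:
    """Complete binary tree of pixel-difference splits of depth F.

    Internal nodes are stored heap-style in arrays of length 2^F − 1;
    ``leaves`` holds 2^F additive shape updates of length 52.  A sample
    goes left when intensity[idx_a] − intensity[idx_b] > threshold.
    """

    idx_a: np.ndarray      # (2^F - 1,) int
    idx_b: np.ndarray
    thresholds: np.ndarray  # (2^F - 1,) float
    leaves: np.ndarray      # (2^F, 52) float

    @property
    def depth(self) -> int:
        return int(np.log2(len(self.leaves))) if len(self.leaves) > 1 else 0

    def leaf_indices(self, intensities: np.ndarray) -> np.ndarray:
        """Leaf index per example for pool-intensity rows (n, pool)."""
        n = intensities.shape[0]
        node = np.zeros(n, dtype=int)
        for _ in range(self.depth):
            diff = (intensities[np.arange(n), self.idx_a[node]]
                    - intensities[np.arange(n), self.idx_b[node]])
            go_left = diff > self.thresholds[node]
            node = 2 * node + np.where(go_left, 1, 2)
        return node - (len(self.leaves) - 1)


@dataclass
class CascadeStage:
    """One boosting stage: its shape-indexed feature pool and K trees."""

    anchor_idx: np.ndarray   # (pool,) int — nearest landmark per feature point
    offsets: np.ndarray      # (pool, 2) float — offset in mean-shape frame
    trees: list[RegressionTree]


@dataclass
class ShapeModel:
    """Trained cascade with its mean shape (in the unit-square frame)."""

    mean_shape: np.ndarray           # (26, 2), coordinates in [0, 1]
    stages: list[CascadeStage]
    train_config: TrainConfig
    train_history: list[float] = field(default_factory=list)  # mean sq. residual per stage

    # structural accounting -------------------------------------------
    @property
    def n_trees(self) -> int:
        return sum(len(st.trees) for st in self.stages)

    @property
    def leaves_per_tree(self) -> int:
        return 2 ** self.train_config.tree_depth


# ----------------------------------------------------------------------
# feature extraction
# ----------------------------------------------------------------------

def _placed_mean_shape(mean_shape: np.ndarray, shape_hw: tuple[int, int]) -> np.ndarray:
    h, w = shape_hw
    return mean_shape * np.array([w - 1, h - 1])


def _pool_positions(current: np.ndarray, mean_placed: np.ndarray,
                    stage: CascadeStage) -> np.ndarray:
    """Feature-point image positions for a batch of current shapes.

    Offsets live in the mean-shape frame; they are carried into each
    image by the linear part of the similarity aligning the placed mean
    shape to the current estimate, then attached to the anchor
    landmark's current position.
    """
    lin, _ = _batch_similarity(np.broadcast_to(mean_placed, current.shape), current)
    warped = np.einsum("nij,pj->npi", lin, stage.offsets)
    return current[:, stage.anchor_idx, :] + warped


def _sample_intensities(images: Sequence[np.ndarray], image_idx: np.ndarray,
                        positions: np.ndarray) -> np.ndarray:
    """Nearest-pixel intensities at (n, pool, 2) positions; OOB reads 0."""
    n, p, _ = positions.shape
    out = np.empty((n, p), dtype=float)
    cols = np.rint(positions[:, :, 0]).astype(int)
    rows = np.rint(positions[:, :, 1]).astype(int)
    for img_i in np.unique(image_idx):
        sel = np.flatnonzero(image_idx == img_i)
        img = images[img_i]
        h, w = img.shape
        r, c = rows[sel], cols[sel]
        ok = (r >= 0) & (r < h) & (c >= 0) & (c < w)
        vals = np.zeros(r.shape, dtype=float)
        vals[ok] = img[r[ok], c[ok]]
        out[sel] = vals
    return out


def extract_features(image: np.ndarray, current_shape: LandmarkSet | np.ndarray,
                     stage: CascadeStage, mean_shape: np.ndarray) -> np.ndarray:
    """Pool intensities for one image/shape pair (the tree inputs).

    Returns the (pool,) vector of shape-indexed intensities; each tree
    node's feature is the difference of two entries per its split.
    """
    cur = current_shape.coords if isinstance(current_shape, LandmarkSet) else np.asarray(current_shape, float)
    mean_placed = _placed_mean_shape(mean_shape, image.shape)
    pos = _pool_positions(cur[None], mean_placed, stage)
    return _sample_intensities([np.asarray(image)], np.zeros(1, int), pos)[0]


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------

def _sample_stage_pool(mean_placed: np.ndarray, cfg: TrainConfig,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw the stage's feature-point pool and the pair-sampling prior."""
    lo = mean_placed.min(axis=0)
    hi = mean_placed.max(axis=0)
    span = hi - lo
    pts = rng.uniform(lo - 0.05 * span, hi + 0.05 * span,
                      size=(cfg.feature_pool_size, 2))
    d2 = ((pts[:, None, :] - mean_placed[None, :, :]) ** 2).sum(axis=2)
    anchor_idx = d2.argmin(axis=1)
    offsets = pts - mean_placed[anchor_idx]
    lam = cfg.feature_locality_lambda
    pair_d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    prior = np.exp(-pair_d / lam)
    np.fill_diagonal(prior, 0.0)
    prior /= prior.sum(axis=1, keepdims=True)
    return anchor_idx, offsets, prior


def _fit_node(intensities, residuals, members, depth, max_depth, cfg, prior, rng,
              idx_a, idx_b, thresholds, leaves, node):
    """Greedy split search at one node; recurses to the full depth F."""
    if depth == max_depth:
        leaf = node - (len(leaves) - 1)
        if members.size:
            leaves[leaf] = residuals[members].mean(axis=0)
        return

    n_cand = cfg.candidate_splits_per_node
    a_idx = rng.integers(0, intensities.shape[1], size=n_cand)
    b_idx = np.array([rng.choice(prior.shape[1], p=prior[a]) for a in a_idx])

    best = (0, 1, 0.0)  # (a, b, threshold) fallback for empty/constant nodes
    best_gain = -np.inf
    if members.size:
        sub = intensities[members]
        res = residuals[members]
        total = res.sum(axis=0)
        diffs = sub[:, a_idx] - sub[:, b_idx]             # (m, n_cand)
        lo = diffs.min(axis=0)
        hi = diffs.max(axis=0)
        thr = rng.uniform(lo, hi)
        for c in range(n_cand):
            left = diffs[:, c] > thr[c]
            n_left = int(left.sum())
            n_right = members.size - n_left
            if n_left == 0 or n_right == 0:
                gain = 0.0
            else:
                sum_left = res[left].sum(axis=0)
                sum_right = total - sum_left
                gain = (sum_left @ sum_left) / n_left + (sum_right @ sum_right) / n_right
            if gain > best_gain:
                best_gain = gain
                best = (int(a_idx[c]), int(b_idx[c]), float(thr[c]))
    else:
        # node receives no examples: record an arbitrary valid split
        thr = rng.uniform(-1.0, 1.0, size=n_cand)
        best = (int(a_idx[0]), int(b_idx[0]), float(thr[0]))

    idx_a[node], idx_b[node], thresholds[node] = best
    if members.size:
        go_left = (intensities[members, best[0]] - intensities[members, best[1]]) > best[2]
        left_members = members[go_left]
        right_members = members[~go_left]
    else:
        left_members = right_members = members
    _fit_node(intensities, residuals, left_members, depth + 1, max_depth, cfg,
              prior, rng, idx_a, idx_b, thresholds, leaves, 2 * node + 1)
    _fit_node(intensities, residuals, right_members, depth + 1, max_depth, cfg,
              prior, rng, idx_a, idx_b, thresholds, leaves, 2 * node + 2)


def _fit_tree(intensities: np.ndarray, residuals: np.ndarray, cfg: TrainConfig,
              prior: np.ndarray, rng: np.random.Generator) -> RegressionTree:
    depth = cfg.tree_depth
    n_internal = 2 ** depth - 1
    n_leaves = 2 ** depth
    idx_a = np.zeros(n_internal, dtype=int)
    idx_b = np.ones(n_internal, dtype=int)
    thresholds = np.zeros(n_internal, dtype=float)
    leaves = np.zeros((n_leaves, _SHAPE_DIM), dtype=float)
    members = np.arange(intensities.shape[0])
    if depth == 0:
        if members.size:
            leaves[0] = residuals.mean(axis=0)
    else:
        _fit_node(intensities, residuals, members, 0, depth, cfg, prior, rng,
                  idx_a, idx_b, thresholds, leaves, 0)
    # guard idx_a == idx_b on untrained fallback nodes
    clash = idx_a == idx_b
    idx_b[clash] = (idx_a[clash] + 1) % max(2, intensities.shape[1])
    return RegressionTree(idx_a, idx_b, thresholds, leaves)


def train(train_set: Sequence[AnnotatedImage], cfg: TrainConfig) -> ShapeModel:
    """Fit the cascaded ensemble on annotated images.

    The mean shape is the average of the training shapes after
    normalization to the unit square.  Each image contributes R
    examples with distinct initial shapes (the placed mean shape first,
    then ground truths of other randomly chosen images).  Stages fit K
    trees by greedy gradient boosting on the shape residuals with
    shrinkage ``nu``; training is bit-deterministic given ``cfg.seed``.
    """
    if not train_set:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    images = [np.asarray(ai.image) for ai in train_set]
    n_img = len(images)
    shapes = np.stack([ai.landmarks.coords for ai in train_set])
    sizes = np.array([[img.shape[1] - 1, img.shape[0] - 1] for img in images], float)
    mean_shape = (shapes / sizes[:, None, :]).mean(axis=0)

    if cfg.feature_locality_lambda is None:
        cfg = replace(cfg, feature_locality_lambda=0.1 * images[0].shape[1])

    # build oversampled examples
    R = cfg.oversampling
    image_idx = np.repeat(np.arange(n_img), R)
    targets = shapes[image_idx]
    current = np.empty_like(targets)
    mean_placed_per_img = mean_shape[None] * sizes[:, None, :]
    for i in range(n_img):
        base = i * R
        current[base] = mean_placed_per_img[i]
        for r in range(1, R):
            j = int(rng.integers(0, n_img))
            if n_img > 1:
                while j == i:
                    j = int(rng.integers(0, n_img))
            current[base + r] = shapes[j]

    mean_placed = mean_shape * sizes[0]  # reference frame for pools
    stages: list[CascadeStage] = []
    history: list[float] = []
    residuals = (targets - current).reshape(len(current), _SHAPE_DIM)

    for _t in range(cfg.cascade_depth):
        anchor_idx, offsets, prior = _sample_stage_pool(mean_placed, cfg, rng)
        stage = CascadeStage(anchor_idx, offsets, trees=[])
        positions = _pool_positions(current, mean_placed, stage)
        intensities = _sample_intensities(images, image_idx, positions)
        for _k in range(cfg.trees_per_stage):
            tree = _fit_tree(intensities, residuals, cfg, prior, rng)
            leaf_idx = tree.leaf_indices(intensities)
            update = cfg.nu * tree.leaves[leaf_idx]
            residuals -= update
            current += update.reshape(current.shape)
            stage.trees.append(tree)
        stages.append(stage)
        history.append(float((residuals ** 2).sum(axis=1).mean()))

    return ShapeModel(mean_shape, stages, cfg, history)


# ----------------------------------------------------------------------
# prediction
# ----------------------------------------------------------------------

def predict(model: ShapeModel, image: np.ndarray) -> LandmarkSet:
    """Localize the 26 landmarks on one image.

    Starts from the mean shape placed in the full image frame and
    applies every stage's trees with shrinkage ``nu``.  Deterministic.
    """
    img = np.asarray(image)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ValueError("image must be 2-D and at least 2x2")
    mean_placed = _placed_mean_shape(model.mean_shape, img.shape)
    current = mean_placed.copy()[None]  # (1, 26, 2)
    nu = model.train_config.nu
    for stage in model.stages:
        positions = _pool_positions(current, mean_placed, stage)
        intensities = _sample_intensities([img], np.zeros(1, int), positions)
        for tree in stage.trees:
            leaf = tree.leaf_indices(intensities)[0]
            current += nu * tree.leaves[leaf].reshape(1, N_LANDMARKS, 2)
    return LandmarkSet(current[0])


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------

class ModelFormatError(ValueError):
    """Raised for malformed or unsupported model files."""


def save_model(model: ShapeModel, path) -> None:
    """Write the model as versioned JSON (full float precision)."""
    doc = {
        "format_version": _MODEL_FORMAT_VERSION,
        "train_config": asdict(model.train_config),
        "train_history": model.train_history,
        "mean_shape": model.mean_shape.tolist(),
        "stages": [
            {
                "anchor_idx": st.anchor_idx.tolist(),
                "offsets": st.offsets.tolist(),
                "trees": [
                    {
                        "idx_a": tr.idx_a.tolist(),
                        "idx_b": tr.idx_b.tolist(),
                        "thresholds": tr.thresholds.tolist(),
                        "leaves": tr.leaves.tolist(),
                    }
                    for tr in st.trees
                ],
            }
            for st in model.stages
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> ShapeModel:
    """Read a model file; rejects unknown versions and malformed input."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: malformed model file: {exc}") from exc
    if not isinstance(doc, dict) or "format_version" not in doc:
        raise ModelFormatError(f"{path}: not a model file (no format_version)")
    if doc["format_version"] != _MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported model format version {doc['format_version']!r} "
            f"(supported: {_MODEL_FORMAT_VERSION})"
        )
    try:
        cfg = TrainConfig(**doc["train_config"])
        stages = [
            CascadeStage(
                anchor_idx=np.asarray(st["anchor_idx"], dtype=int),
                offsets=np.asarray(st["offsets"], dtype=float),
                trees=[
                    RegressionTree(
                        idx_a=np.asarray(tr["idx_a"], dtype=int),
                        idx_b=np.asarray(tr["idx_b"], dtype=int),
                        thresholds=np.asarray(tr["thresholds"], dtype=float),
                        leaves=np.asarray(tr["leaves"], dtype=float),
                    )
                    for tr in st["trees"]
                ],
            )
            for st in doc["stages"]
        ]
        return ShapeModel(
            mean_shape=np.asarray(doc["mean_shape"], dtype=float),
            stages=stages,
            train_config=cfg,
            train_history=[float(x) for x in doc.get("train_history", [])],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"{path}: malformed model file: {exc}") from exc
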