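"""Evaluation harness: error reports, parameter sweeps, transform-novelty
assessment, augmentation-gain curves, and error-directionality summaries.

Every experiment is deterministic given its seeds, writes tabular output
(pandas DataFrames, trivially exported to CSV), and asserts nothing by
itself — the findings (monotone training error, the elastic transform's
outsized novelty, diminishing-but-real gains from augmented images) are
properties checked by the test-suite on scaled-down runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .augment import AugmentationPolicy, TransformSpec, apply_transform, augment_dataset
from .geometry import (
    FEATURE_LANDMARKS,
    FEATURE_NAMES,
    LANDMARK_NAMES,
    LandmarkError,
    compute_features,
    landmark_errors,
)
from .ert import ShapeModel, TrainConfig, predict, train
from .synthetic import AnnotatedImage


@dataclass
class ErrorReport:
    """Per-landmark and per-feature prediction errors over a dataset.

    ``per_landmark`` maps each landmark name to its errors over the
    evaluated images; ``per_feature`` maps each angular feature to its
    signed errors in degrees (predicted − true).  Landmarks flagged
    out-of-frame on an image are excluded, as are features depending on
    a flagged landmark, so lists may be shorter than ``n_images`` for
    transformed datasets.  ``mean_error`` averages every included
    magnitude over all landmarks and images.
    """

    per_landmark: dict[str, list[LandmarkError]]
    per_feature: dict[str, list[float]]
    mean_error: float
    n_images: int
    image_ids: list[str] = field(default_factory=list)

    def landmark_frame(self) -> pd.DataFrame:
        rows = [
            {"landmark": name, "magnitude": e.magnitude, "direction": e.direction}
            for name, errs in self.per_landmark.items()
            for e in errs
        ]
        return pd.DataFrame(rows, columns=["landmark", "magnitude", "direction"])

    def feature_frame(self) -> pd.DataFrame:
        rows = [
            {"feature": name, "error_deg": v}
            for name, errs in self.per_feature.items()
            for v in errs
        ]
        return pd.DataFrame(rows, columns=["feature", "error_deg"])


def evaluate(model: ShapeModel, ds: Sequence[AnnotatedImage]) -> ErrorReport:
    """Predict every image and assemble the error report."""
    if not ds:
        raise ValueError("cannot evaluate on an empty dataset")
    per_landmark: dict[str, list[LandmarkError]] = {n: [] for n in LANDMARK_NAMES}
    per_feature: dict[str, list[float]] = {n: [] for n in FEATURE_NAMES}
    magnitudes: list[float] = []
    for img in ds:
        pred = predict(model, img.image)
        errs = landmark_errors(pred, img.landmarks)
        flagged = set(img.flagged)
        for name, err in errs.items():
            if name in flagged:
                continue
            per_landmark[name].append(err)
            magnitudes.append(err.magnitude)
        fp = compute_features(pred).as_dict()
        ft = compute_features(img.landmarks).as_dict()
        for fname in FEATURE_NAMES:
            if flagged.intersection(FEATURE_LANDMARKS[fname]):
                continue
            per_feature[fname].append(fp[fname] - ft[fname])
    return ErrorReport(
        per_landmark=per_landmark,
        per_feature=per_feature,
        mean_error=float(np.mean(magnitudes)),
        n_images=len(ds),
        image_ids=[img.id for img in ds],
    )


# ----------------------------------------------------------------------
# parameter sweep
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SweepGrid:
    """One-dimensional grids for the four tuned hyperparameters."""

    nu_values: tuple[float, ...] = (0.05, 0.1, 0.2, 0.5, 1.0)
    cascade_depths: tuple[int, ...] = (2, 5, 10, 15)
    tree_depths: tuple[int, ...] = (1, 2, 3, 4)
    oversampling_values: tuple[int, ...] = (1, 5, 10, 20)

    def __post_init__(self) -> None:
        for f in ("nu_values", "cascade_depths", "tree_depths", "oversampling_values"):
            if not getattr(self, f):
                raise ValueError(f"{f} must be non-empty")


def run_sweep(train_set: Sequence[AnnotatedImage], test_set: Sequence[AnnotatedImage],
              grid: SweepGrid, base_cfg: TrainConfig) -> pd.DataFrame:
    """Train one model per grid point, varying one parameter at a time.

    Mirrors per-parameter tuning panels: each row fixes three of
    (nu, T, F, R) at the base configuration and varies the fourth.
    Columns include train/test mean error and work counters (number of
    trees T·K, examples n·R, leaves per tree 2^F) whose product tracks
    the F·R·T work proportionality of training.
    """
    axes = [
        ("nu", grid.nu_values),
        ("cascade_depth", grid.cascade_depths),
        ("tree_depth", grid.tree_depths),
        ("oversampling", grid.oversampling_values),
    ]
    rows = []
    for param, values in axes:
        for value in values:
            cfg = replace(base_cfg, **{param: value})
            model = train(train_set, cfg)
            tr = evaluate(model, train_set)
            te = evaluate(model, test_set)
            rows.append({
                "param": param,
                "value": value,
                "train_error": tr.mean_error,
                "test_error": te.mean_error,
                "n_trees": model.n_trees,
                "n_examples": len(train_set) * cfg.oversampling,
                "leaves_per_tree": model.leaves_per_tree,
            })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# transform novelty
# ----------------------------------------------------------------------

def run_novelty(train_set: Sequence[AnnotatedImage], test_set: Sequence[AnnotatedImage],
                specs: Sequence[TransformSpec], cfg: TrainConfig,
                model: ShapeModel | None = None) -> pd.DataFrame:
    """How novel does each transform make familiar images look?

    Trains a single model on the untransformed training set (unless one
    is passed in), then evaluates it on the untransformed and
    per-transform versions of both splits.  High error on a transformed
    training image means the transform made it effectively unseen.
    Rows: 2 × (1 + len(specs)).
    """
    if model is None:
        model = train(train_set, cfg)
    rows = []
    for split_name, ds in (("train", train_set), ("test", test_set)):
        rows.append({
            "split": split_name, "transform": "original",
            "mean_error": evaluate(model, ds).mean_error,
        })
        for spec in specs:
            transformed = [apply_transform(img, spec) for img in ds]
            rows.append({
                "split": split_name, "transform": spec.kind,
                "mean_error": evaluate(model, transformed).mean_error,
            })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# augmentation gain
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class GainCurvePoint:
    """One point of the augmentation-gain experiment."""

    train_size: int
    source: str              # "original" | "augmented"
    mean_test_error: float
    replicate_seed: int


def _augmented_copies(base: list[AnnotatedImage], n: int,
                      policy: AugmentationPolicy, seed: int) -> list[AnnotatedImage]:
    """Draw n landmark-in-frame augmented copies of the base set.

    Transforms whose landmarks leave the frame are discarded and
    redrawn (the annotation is no longer fully usable), with a bounded
    number of rounds.
    """
    out: list[AnnotatedImage] = []
    round_seed = seed
    for _ in range(50):
        need = n - len(out)
        if need <= 0:
            break
        copies = int(np.ceil(need / len(base)))
        pol = replace(policy, copies_per_image=copies, seed=round_seed)
        fresh = augment_dataset(base, pol)[len(base):]
        out.extend(img for img in fresh if not img.flagged)
        round_seed += 1
    if len(out) < n:
        raise RuntimeError("could not draw enough in-frame augmented copies")
    return out[:n]


def run_gain_curve(pool: Sequence[AnnotatedImage], test_set: Sequence[AnnotatedImage],
                   base_n: int, increments: Sequence[int],
                   policy: AugmentationPolicy, cfg: TrainConfig,
                   replicates: int = 3) -> list[GainCurvePoint]:
    """Error vs training-set size: new originals vs augmented copies.

    For each replicate, a base set of ``base_n`` images is drawn from
    the pool; each increment is satisfied either by unseen originals
    from the pool ("original" arm) or by random transforms of the base
    set ("augmented" arm).  Both arms share the baseline point
    (increment 0).
    """
    max_inc = max(increments)
    if base_n + max_inc > len(pool):
        raise ValueError(
            f"pool of {len(pool)} images cannot supply base {base_n} + {max_inc} originals"
        )
    points: list[GainCurvePoint] = []
    for rep in range(replicates):
        rep_seed = cfg.seed + 1000 * (rep + 1)
        order = np.random.default_rng(rep_seed).permutation(len(pool))
        base = [pool[i] for i in order[:base_n]]
        extras = [pool[i] for i in order[base_n:]]
        baseline_err: float | None = None
        for inc in increments:
            if inc == 0:
                # baseline shared by both arms: train once, record under both
                if baseline_err is None:
                    model = train(base, replace(cfg, seed=rep_seed))
                    baseline_err = evaluate(model, test_set).mean_error
                for source in ("original", "augmented"):
                    points.append(GainCurvePoint(base_n, source, baseline_err, rep_seed))
                continue
            for source in ("original", "augmented"):
                if source == "original":
                    train_ds = base + extras[:inc]
                else:
                    train_ds = base + _augmented_copies(base, inc, policy, rep_seed)
                model = train(train_ds, replace(cfg, seed=rep_seed))
                err = evaluate(model, test_set).mean_error
                points.append(GainCurvePoint(len(train_ds), source, err, rep_seed))
    return points


def gain_summary(points: Sequence[GainCurvePoint]) -> pd.DataFrame:
    """Mean test error per (train_size, source) over replicates."""
    df = pd.DataFrame([p.__dict__ for p in points])
    return (df.groupby(["train_size", "source"], as_index=False)
              .agg(mean_test_error=("mean_test_error", "mean"),
                   n_replicates=("replicate_seed", "nunique")))


def gain_recovery(points: Sequence[GainCurvePoint], base_n: int,
                  increment: int) -> dict[str, float]:
    """Two readings of "how much of the benefit augmentation recovers".

    ``ratio_of_gains``: 100 × (baseline − augmented) / (baseline −
    original) at the matched size — the share of the new-originals
    error reduction recovered by augmented copies.
    ``error_reduction_pct``: the augmented arm's own error reduction as
    a percentage of the baseline error.
    """
    df = gain_summary(points).set_index(["train_size", "source"])
    baseline = df.loc[(base_n, "original"), "mean_test_error"]
    target = base_n + increment
    orig = df.loc[(target, "original"), "mean_test_error"]
    aug = df.loc[(target, "augmented"), "mean_test_error"]
    gain_orig = baseline - orig
    gain_aug = baseline - aug
    return {
        "baseline_error": float(baseline),
        "original_arm_error": float(orig),
        "augmented_arm_error": float(aug),
        "ratio_of_gains": float(100.0 * gain_aug / gain_orig),
        "error_reduction_pct": float(100.0 * gain_aug / baseline),
    }


# ----------------------------------------------------------------------
# directionality
# ----------------------------------------------------------------------

def summarize_directionality(report: ErrorReport) -> pd.DataFrame:
    """Circular statistics of error directions, per landmark.

    Returns the circular mean direction (degrees in [0, 360)) and the
    mean resultant length R̄ ∈ [0, 1] (0 = directions spread uniformly,
    1 = perfectly aligned).  Zero-magnitude errors carry no direction
    and are excluded; landmarks with no directed errors get NaN.
    """
    rows = []
    for name, errs in report.per_landmark.items():
        dirs = np.array([e.direction for e in errs if e.direction_defined])
        if dirs.size == 0:
            rows.append({"landmark": name, "n": 0,
                         "mean_direction": np.nan, "resultant_length": np.nan})
            continue
        res = stats.directional_stats(
            np.stack([np.cos(np.radians(dirs)), np.sin(np.radians(dirs))], axis=1)
        )
        mean_dir = float(np.degrees(np.arctan2(res.mean_direction[1],
                                               res.mean_direction[0])) % 360.0)
        rows.append({
            "landmark": name, "n": int(dirs.size),
            "mean_direction": mean_dir,
            "resultant_length": float(res.mean_resultant_length),
        })
    return pd.DataFrame(rows)
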