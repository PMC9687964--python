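"""Cascaded regression-tree predictor: alignment, training, prediction,
serialization."""

import json

import numpy as np
import pytest
from skimage.transform import SimilarityTransform as SkSimilarity

from cephalo import (
    LandmarkSet,
    ShapeModel,
    TrainConfig,
    align_similarity,
    load_model,
    make_template,
    predict,
    save_model,
    train,
)
from cephalo.ert import ModelFormatError, extract_features, _placed_mean_shape
from cephalo.experiments import evaluate


# ----------------------------------------------------------------------
# similarity alignment
# ----------------------------------------------------------------------

def test_align_identity():
    t = make_template(256)
    tf = align_similarity(t, t)
    assert tf.scale == pytest.approx(1.0)
    assert tf.rotation == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(tf.translation, 0.0, atol=1e-9)


def test_align_recovers_exact_similarity():
    src = make_template(256).coords
    theta = np.radians(25.0)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    dst = 1.5 * src @ rot.T + np.array([10.0, -4.0])
    tf = align_similarity(src, dst)
    assert tf.scale == pytest.approx(1.5, abs=1e-6)
    assert tf.rotation == pytest.approx(theta, abs=1e-6)
    np.testing.assert_allclose(tf.translation, [10.0, -4.0], atol=1e-6)
    np.testing.assert_allclose(tf.apply(src), dst, atol=1e-6)


def test_align_matches_skimage_procrustes_on_noisy_data():
    rng = np.random.default_rng(11)
    src = make_template(256).coords
    dst = 1.2 * src + rng.normal(0, 4.0, src.shape) + [5.0, 7.0]
    ours = align_similarity(src, dst)
    sk = SkSimilarity()
    assert sk.estimate(src, dst)
    assert ours.scale == pytest.approx(sk.scale, rel=1e-9)
    assert ours.rotation == pytest.approx(sk.rotation, abs=1e-9)
    np.testing.assert_allclose(ours.translation, sk.translation, atol=1e-9)


def test_align_degenerate_raises():
    pts = np.ones((26, 2))
    with pytest.raises(ValueError):
        align_similarity(pts, make_template(256).coords)


# ----------------------------------------------------------------------
# feature extraction
# ----------------------------------------------------------------------

def test_extract_features_constant_image(small_model):
    img = np.full((128, 128), 77, dtype=np.uint8)
    stage = small_model.stages[0]
    placed = _placed_mean_shape(small_model.mean_shape, img.shape)
    vals = extract_features(img, placed, stage, small_model.mean_shape)
    inside = vals[vals != 0]
    assert (inside == 77).all()  # all in-bounds samples identical -> zero diffs


def test_extract_features_identity_placement_matches_direct_lookup(small_model):
    rng = np.random.default_rng(12)
    img = rng.integers(0, 256, size=(128, 128), dtype=np.uint8)
    stage = small_model.stages[0]
    placed = _placed_mean_shape(small_model.mean_shape, img.shape)
    vals = extract_features(img, placed, stage, small_model.mean_shape)
    # at the mean shape the similarity is the identity: anchor + offset
    pos = placed[stage.anchor_idx] + stage.offsets
    cols = np.rint(pos[:, 0]).astype(int)
    rows = np.rint(pos[:, 1]).astype(int)
    ok = (rows >= 0) & (rows < 128) & (cols >= 0) & (cols < 128)
    expect = np.where(ok, img[rows.clip(0, 127), cols.clip(0, 127)], 0).astype(float)
    np.testing.assert_array_equal(vals, expect)


# ----------------------------------------------------------------------
# training and prediction
# ----------------------------------------------------------------------

def test_empty_cascade_predicts_placed_mean_shape(small_split):
    train_set, test_set = small_split
    cfg = TrainConfig(cascade_depth=0, oversampling=1, trees_per_stage=1, seed=1)
    model = train(train_set, cfg)
    img = test_set[0].image
    pred = predict(model, img)
    placed = _placed_mean_shape(model.mean_shape, img.shape)
    np.testing.assert_allclose(pred.coords, placed, atol=1e-9)


def test_vanishing_learning_rate_stays_at_mean_shape(small_split):
    train_set, test_set = small_split
    cfg = TrainConfig(nu=1e-12, cascade_depth=3, oversampling=2,
                      trees_per_stage=10, feature_pool_size=50, seed=2)
    model = train(train_set, cfg)
    img = test_set[0].image
    placed = _placed_mean_shape(model.mean_shape, img.shape)
    np.testing.assert_allclose(predict(model, img).coords, placed, atol=1e-6)


def test_single_image_overfit(small_dataset):
    cfg = TrainConfig(nu=0.2, cascade_depth=10, tree_depth=2, oversampling=1,
                      trees_per_stage=50, feature_pool_size=150, seed=3)
    one = [small_dataset[0]]
    model = train(one, cfg)
    rep = evaluate(model, one)
    assert rep.mean_error <= 1.0


def test_training_residual_monotone_across_stages(small_model):
    hist = small_model.train_history
    assert len(hist) == small_model.train_config.cascade_depth
    assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))


def test_model_structural_accounting(small_model):
    cfg = small_model.train_config
    assert small_model.n_trees == cfg.cascade_depth * cfg.trees_per_stage
    assert small_model.leaves_per_tree == 2 ** cfg.tree_depth
    for stage in small_model.stages:
        assert len(stage.anchor_idx) == cfg.feature_pool_size
        for tree in stage.trees:
            assert tree.leaves.shape == (2 ** cfg.tree_depth, 52)
            assert (tree.idx_a != tree.idx_b).all()
            assert (tree.idx_a < cfg.feature_pool_size).all()
            assert (tree.idx_b < cfg.feature_pool_size).all()


def test_training_deterministic(small_split):
    train_set, test_set = small_split
    cfg = TrainConfig(nu=0.3, cascade_depth=2, oversampling=2,
                      trees_per_stage=10, feature_pool_size=60, seed=9)
    m1 = train(train_set, cfg)
    m2 = train(train_set, cfg)
    img = test_set[0].image
    np.testing.assert_array_equal(predict(m1, img).coords, predict(m2, img).coords)


def test_prediction_deterministic(small_model, small_split):
    _, test_set = small_split
    img = test_set[0].image
    np.testing.assert_array_equal(
        predict(small_model, img).coords, predict(small_model, img).coords
    )


def test_model_beats_mean_shape_baseline(small_model, small_split):
    _, test_set = small_split
    baseline = ShapeModel(small_model.mean_shape, [], small_model.train_config)
    err_model = evaluate(small_model, test_set).mean_error
    err_base = evaluate(baseline, test_set).mean_error
    assert err_model < 0.5 * err_base


def test_train_input_validation(small_dataset):
    with pytest.raises(ValueError):
        train([], TrainConfig())
    with pytest.raises(ValueError):
        TrainConfig(cascade_depth=-1)
    with pytest.raises(ValueError):
        TrainConfig(nu=0.0)
    with pytest.raises(ValueError):
        predict(train([small_dataset[0]], TrainConfig(cascade_depth=0)), np.zeros((1, 1), np.uint8))


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------

def test_save_load_round_trip(small_model, small_split, tmp_path):
    _, test_set = small_split
    path = tmp_path / "model.json"
    save_model(small_model, path)
    back = load_model(path)
    np.testing.assert_array_equal(back.mean_shape, small_model.mean_shape)
    for img in test_set[:10]:
        np.testing.assert_array_equal(
            predict(back, img.image).coords, predict(small_model, img.image).coords
        )


def test_truncated_model_file_rejected(small_model, tmp_path):
    path = tmp_path / "model.json"
    save_model(small_model, path)
    data = path.read_text()
    path.write_text(data[: len(data) // 2])
    with pytest.raises(ModelFormatError, match="malformed"):
        load_model(path)


def test_unsupported_version_rejected(small_model, tmp_path):
    path = tmp_path / "model.json"
    save_model(small_model, path)
    doc = json.loads(path.read_text())
    doc["format_version"] = 99
    path.write_text(json.dumps(doc))
    with pytest.raises(ModelFormatError, match="version"):
        load_model(path)
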