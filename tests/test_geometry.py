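"""Angle primitives, diagnostic features, and error metrics."""

import math

import numpy as np
import pytest

from cephalo import (
    FEATURE_NAMES,
    LANDMARK_NAMES,
    LandmarkSet,
    angle_at_vertex,
    compute_features,
    directed_line_angle,
    feature_errors,
    landmark_errors,
    make_template,
)
from cephalo.geometry import DegenerateGeometryError, landmark_index


def _acos_oracle(u, v):
    u, v = np.asarray(u, float), np.asarray(v, float)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(c, -1, 1)))


def _random_landmarks(rng, scale=200.0):
    return LandmarkSet(rng.uniform(10, scale, size=(26, 2)))


# ----------------------------------------------------------------------
# angle primitives
# ----------------------------------------------------------------------

@pytest.mark.parametrize(
    "a,v,b,expected",
    [
        ((1, 0), (0, 0), (0, 1), 90.0),
        ((5, 5), (0, 0), (10, 10), 0.0),
        ((-1, 0), (0, 0), (1, 0), 180.0),
    ],
)
def test_vertex_angle_known_values(a, v, b, expected):
    assert angle_at_vertex(a, v, b) == pytest.approx(expected, abs=1e-5)


def test_vertex_angle_matches_trig_oracle():
    rng = np.random.default_rng(5)
    for _ in range(200):
        a, v, b = rng.uniform(-50, 50, size=(3, 2))
        if np.allclose(a, v) or np.allclose(b, v):
            continue
        assert angle_at_vertex(a, v, b) == pytest.approx(
            _acos_oracle(a - v, b - v), abs=1e-9
        )


def test_vertex_angle_rejects_degenerate_rays():
    with pytest.raises(DegenerateGeometryError):
        angle_at_vertex((1, 1), (1, 1), (0, 3))
    with pytest.raises(DegenerateGeometryError):
        angle_at_vertex((0, 3), (1, 1), (1, 1))


@pytest.mark.parametrize(
    "p,q,expected",
    [
        ((((0, 0), (1, 0)), ((0, 0), (0, 1))), None, 90.0),
        ((((0, 0), (2, 2)), ((5, 5), (9, 9))), None, 0.0),
        ((((0, 0), (1, 0)), ((3, 3), (1, 3))), None, 180.0),
    ],
)
def test_directed_line_angle_known_values(p, q, expected):
    (pf, pt), (qf, qt) = p
    assert directed_line_angle(pf, pt, qf, qt) == pytest.approx(expected, abs=1e-5)


def test_directed_line_angle_matches_trig_oracle():
    rng = np.random.default_rng(6)
    for _ in range(200):
        pf, pt, qf, qt = rng.uniform(-50, 50, size=(4, 2))
        assert directed_line_angle(pf, pt, qf, qt) == pytest.approx(
            _acos_oracle(pt - pf, qt - qf), abs=1e-9
        )


def test_directed_line_angle_rejects_zero_length():
    with pytest.raises(DegenerateGeometryError):
        directed_line_angle((1, 2), (1, 2), (0, 0), (1, 1))


# ----------------------------------------------------------------------
# diagnostic features
# ----------------------------------------------------------------------

def test_features_match_per_angle_oracle():
    ls = make_template(256)
    f = compute_features(ls)
    assert f.sna == pytest.approx(_acos_oracle(ls["S"] - ls["N"], ls["A"] - ls["N"]))
    assert f.snb == pytest.approx(_acos_oracle(ls["S"] - ls["N"], ls["B"] - ls["N"]))
    assert f.anb == pytest.approx(f.sna - f.snb, abs=1e-12)
    assert f.uc_ur_sn == pytest.approx(_acos_oracle(ls["Uc"] - ls["Ur"], ls["N"] - ls["S"]))
    assert f.lc_lr_gome == pytest.approx(_acos_oracle(ls["Lc"] - ls["Lr"], ls["Me"] - ls["Go"]))
    assert f.sn_gome == pytest.approx(_acos_oracle(ls["N"] - ls["S"], ls["Me"] - ls["Go"]))
    assert f.g_sn_pgs == pytest.approx(_acos_oracle(ls["G"] - ls["Sn"], ls["PgS"] - ls["Sn"]))


def test_anb_zero_when_a_equals_b():
    coords = make_template(256).coords.copy()
    coords[landmark_index("B")] = coords[landmark_index("A")]
    f = compute_features(LandmarkSet(coords))
    assert f.anb == pytest.approx(0.0, abs=1e-12)


def test_features_invariant_under_similarity():
    rng = np.random.default_rng(7)
    for _ in range(20):
        ls = _random_landmarks(rng)
        theta = math.radians(30.0)
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        moved = LandmarkSet(2.0 * (ls.coords - 80.0) @ rot.T + rng.uniform(-30, 30, 2))
        f0 = compute_features(ls).as_dict()
        f1 = compute_features(moved).as_dict()
        for name in FEATURE_NAMES:
            assert f1[name] == pytest.approx(f0[name], abs=1e-9)


def test_anb_identity_over_random_sets():
    rng = np.random.default_rng(8)
    for _ in range(50):
        f = compute_features(_random_landmarks(rng))
        assert f.anb == pytest.approx(f.sna - f.snb, abs=1e-9)


# ----------------------------------------------------------------------
# error metrics
# ----------------------------------------------------------------------

def test_identical_sets_have_zero_undirected_errors():
    ls = make_template(256)
    errs = landmark_errors(ls, ls)
    assert all(e.magnitude == 0.0 for e in errs.values())
    assert not any(e.direction_defined for e in errs.values())
    assert all(v == pytest.approx(0.0) for v in feature_errors(ls, ls).values())


def test_uniform_345_offset():
    truth = make_template(256)
    pred = LandmarkSet(truth.coords + np.array([3.0, 4.0]))
    errs = landmark_errors(pred, truth)
    for e in errs.values():
        assert e.magnitude == pytest.approx(5.0)
        assert e.direction == pytest.approx(math.degrees(math.atan2(4, 3)), abs=1e-9)


def test_error_symmetry_and_direction_reversal():
    rng = np.random.default_rng(9)
    truth = _random_landmarks(rng)
    pred = LandmarkSet(truth.coords + rng.normal(0, 3, size=(26, 2)))
    fwd = landmark_errors(pred, truth)
    rev = landmark_errors(truth, pred)
    for name in LANDMARK_NAMES:
        assert fwd[name].magnitude == pytest.approx(rev[name].magnitude)
        if fwd[name].direction_defined:
            assert (fwd[name].direction - rev[name].direction) % 360.0 == pytest.approx(
                180.0, abs=1e-9
            )


def test_errors_match_hypot_atan2_oracle():
    rng = np.random.default_rng(10)
    truth = _random_landmarks(rng)
    pred = LandmarkSet(truth.coords + rng.normal(0, 5, size=(26, 2)))
    errs = landmark_errors(pred, truth)
    for i, name in enumerate(LANDMARK_NAMES):
        dx, dy = pred.coords[i] - truth.coords[i]
        assert errs[name].magnitude == pytest.approx(math.hypot(dx, dy))
        assert errs[name].direction == pytest.approx(math.degrees(math.atan2(dy, dx)) % 360)


def test_displacing_b_only_cancels_in_anb():
    truth = make_template(256)
    coords = truth.coords.copy()
    coords[landmark_index("B")] += np.array([4.0, -2.0])
    fe = feature_errors(LandmarkSet(coords), truth)
    assert fe["sna"] == pytest.approx(0.0, abs=1e-12)
    assert fe["snb"] != 0.0
    assert fe["anb"] == pytest.approx(-fe["snb"], abs=1e-12)


def test_anb_error_cancellation_constructions():
    """Antagonistic SNA/SNB errors cancel in ANB.

    Rotating A and B about N by a common angle perturbs SNA and SNB
    equally, so their difference is untouched; sliding A and B together
    along the A-B line bounds the ANB error by the triangle inequality.
    """
    truth = make_template(256)
    coords = truth.coords.copy()
    n = coords[landmark_index("N")]
    theta = math.radians(2.0)
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    for name in ("A", "B"):
        i = landmark_index(name)
        coords[i] = (coords[i] - n) @ rot.T + n
    fe = feature_errors(LandmarkSet(coords), truth)
    assert abs(fe["sna"]) > 1.0 and abs(fe["snb"]) > 1.0
    assert fe["anb"] == pytest.approx(0.0, abs=1e-9)

    coords = truth.coords.copy()
    iA, iB = landmark_index("A"), landmark_index("B")
    d = coords[iB] - coords[iA]
    d /= np.linalg.norm(d)
    coords[iA] += 3.0 * d
    coords[iB] += 3.0 * d
    fe = feature_errors(LandmarkSet(coords), truth)
    assert abs(fe["anb"]) <= abs(fe["sna"]) + abs(fe["snb"]) + 1e-12


# ----------------------------------------------------------------------
# landmark-set container and points files
# ----------------------------------------------------------------------

def test_points_csv_round_trip(tmp_path):
    ls = make_template(256)
    path = tmp_path / "pts.csv"
    ls.write_csv(path)
    back = LandmarkSet.read_csv(path)
    np.testing.assert_array_equal(back.coords, ls.coords)


def test_points_csv_missing_landmark_named(tmp_path):
    ls = make_template(256)
    df = ls.to_frame()[:-1]  # drop Co
    path = tmp_path / "pts.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="Co"):
        LandmarkSet.read_csv(path)


def test_landmark_set_validation():
    with pytest.raises(ValueError):
        LandmarkSet(np.zeros((25, 2)))
    bad = np.zeros((26, 2))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        LandmarkSet(bad)
    with pytest.raises(ValueError, match="missing"):
        LandmarkSet.from_mapping({"S": (0, 0)})
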