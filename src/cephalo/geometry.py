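"""Landmark schema, angular diagnostic features, and prediction-error metrics.

Cephalometric analysis works on a fixed roster of 26 named anatomical
landmarks digitized on a lateral skull radiograph.  From their relative
positions a handful of angular features are derived — SNA, SNB, ANB,
incisor inclinations, the mandibular-plane angle and the soft-tissue
convexity — which carry the diagnostic content.  This module defines the
landmark roster, the angle computations, and the per-landmark /
per-feature error metrics used to score a predictor.

Coordinates are 0-based pixel positions with the raster convention:
origin at the top-left corner, x increasing rightward (columns), y
increasing downward (rows).  All angles are computed in this frame; the
diagnostic features are invariant under translation, rotation and
uniform scaling of the whole landmark set, so the frame choice does not
affect them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Canonical landmark names, in the fixed order used for every array,
#: file and report in this package.
LANDMARK_NAMES: tuple[str, ...] = (
    "S", "P", "Go", "N", "O", "A", "B", "Me", "G", "Sn", "Ls", "Li",
    "PgS", "Ur", "Uc", "Lc", "Lr", "ANS", "PNS", "U6M", "U6D", "L6M",
    "L6D", "SEM", "Pn", "Co",
)

N_LANDMARKS = len(LANDMARK_NAMES)

_NAME_TO_INDEX = {name: i for i, name in enumerate(LANDMARK_NAMES)}

#: Angular feature names in report order.
FEATURE_NAMES: tuple[str, ...] = (
    "sna", "snb", "anb", "uc_ur_sn", "lc_lr_gome", "sn_gome", "g_sn_pgs",
)

#: Landmarks each angular feature depends on (used by evaluation code to
#: drop features whose constituent landmarks were flagged, e.g. pushed
#: out of frame by an augmentation transform).
FEATURE_LANDMARKS: dict[str, tuple[str, ...]] = {
    "sna": ("S", "N", "A"),
    "snb": ("S", "N", "B"),
    "anb": ("S", "N", "A", "B"),
    "uc_ur_sn": ("Ur", "Uc", "S", "N"),
    "lc_lr_gome": ("Lr", "Lc", "Go", "Me"),
    "sn_gome": ("S", "N", "Go", "Me"),
    "g_sn_pgs": ("G", "Sn", "PgS"),
}


class DegenerateGeometryError(ValueError):
    """Raised when an angle is requested for coincident points."""


def landmark_index(name: str) -> int:
    """Index of a canonical landmark name in the fixed ordering."""
    try:
        return _NAME_TO_INDEX[name]
    except KeyError:
        raise KeyError(f"unknown landmark name: {name!r}") from None


@dataclass(frozen=True)
class LandmarkSet:
    """The 26 canonical landmarks of one cephalogram, in pixel coordinates.

    Wraps a ``(26, 2)`` float array in the canonical landmark order with
    columns ``(x, y)``.  Construct from an array, a name→point mapping
    (:meth:`from_mapping`) or a points CSV (:meth:`read_csv`).
    """

    coords: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.coords, dtype=float)
        if arr.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"expected coordinates of shape ({N_LANDMARKS}, 2), got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("landmark coordinates must be finite")
        object.__setattr__(self, "coords", arr)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_mapping(cls, points: Mapping[str, Iterable[float]]) -> "LandmarkSet":
        missing = [n for n in LANDMARK_NAMES if n not in points]
        if missing:
            raise ValueError(f"missing landmarks: {', '.join(missing)}")
        extra = [n for n in points if n not in _NAME_TO_INDEX]
        if extra:
            raise ValueError(f"unknown landmarks: {', '.join(sorted(extra))}")
        arr = np.array([points[n] for n in LANDMARK_NAMES], dtype=float)
        return cls(arr)

    @classmethod
    def read_csv(cls, path) -> "LandmarkSet":
        """Read a points file: CSV with header ``name,x,y``, 26 rows in order."""
        df = pd.read_csv(path, float_precision="round_trip")
        if list(df.columns) != ["name", "x", "y"]:
            raise ValueError(
                f"{path}: expected header 'name,x,y', got {list(df.columns)}"
            )
        names = list(df["name"])
        if names != list(LANDMARK_NAMES):
            missing = [n for n in LANDMARK_NAMES if n not in names]
            if missing:
                raise ValueError(f"{path}: missing landmark rows: {', '.join(missing)}")
            raise ValueError(f"{path}: landmark rows out of canonical order")
        coords = df[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            bad = df.loc[~np.isfinite(coords).all(axis=1), "name"].tolist()
            raise ValueError(f"{path}: non-finite coordinates for {', '.join(bad)}")
        return cls(coords)

    # -- accessors ----------------------------------------------------
    def __getitem__(self, name: str) -> np.ndarray:
        return self.coords[landmark_index(name)]

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {n: (float(x), float(y)) for n, (x, y) in zip(LANDMARK_NAMES, self.coords)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": LANDMARK_NAMES, "x": self.coords[:, 0], "y": self.coords[:, 1]}
        )

    def write_csv(self, path) -> None:
        # repr() keeps every bit of the float64; pandas' writer does not
        with open(path, "w") as fh:
            fh.write("name,x,y\n")
            for name, (x, y) in zip(LANDMARK_NAMES, self.coords):
                fh.write(f"{name},{float(x)!r},{float(y)!r}\n")


@dataclass(frozen=True)
class AngularFeatureSet:
    """The seven angular diagnostic features, in degrees.

    ``anb`` is reported signed as ``sna - snb`` (it may be negative);
    every other feature is an unsigned angle in [0, 180].
    """

    sna: float
    snb: float
    anb: float
    uc_ur_sn: float
    lc_lr_gome: float
    sn_gome: float
    g_sn_pgs: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


@dataclass(frozen=True)
class LandmarkError:
    """Prediction error for one landmark on one image.

    ``magnitude`` is the Euclidean distance in pixels between prediction
    and truth.  ``direction`` is the angle of (pred − truth) in degrees,
    with 0° pointing toward +x (image right) and angles increasing toward
    +y (image down), mapped to [0, 360).  A zero-magnitude error has no
    direction; it is reported as NaN and excluded from directional
    summaries.
    """

    magnitude: float
    direction: float = field(default=math.nan)

    @property
    def direction_defined(self) -> bool:
        return not math.isnan(self.direction)


# ----------------------------------------------------------------------
# angle primitives
# ----------------------------------------------------------------------

def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    nu = float(np.hypot(*u))
    nv = float(np.hypot(*v))
    cosang = float(np.dot(u, v)) / (nu * nv)
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def angle_at_vertex(a, v, b) -> float:
    """Unsigned angle in degrees, in [0, 180], between rays v→a and v→b.

    Raises :class:`DegenerateGeometryError` if either ray has zero length.
    """
    a = np.asarray(a, dtype=float)
    v = np.asarray(v, dtype=float)
    b = np.asarray(b, dtype=float)
    u1, u2 = a - v, b - v
    if not u1.any() or not u2.any():
        raise DegenerateGeometryError("angle undefined: ray endpoint coincides with vertex")
    return _angle_between(u1, u2)


def directed_line_angle(p_from, p_to, q_from, q_to) -> float:
    """Unsigned angle in [0, 180] between two directed segments.

    The angle is measured between the direction vectors ``p_to - p_from``
    and ``q_to - q_from``; reversing one segment maps the value to its
    supplement, so the direction conventions fixed in
    :func:`compute_features` matter for absolute values (error
    differences are unaffected).
    """
    p = np.asarray(p_to, dtype=float) - np.asarray(p_from, dtype=float)
    q = np.asarray(q_to, dtype=float) - np.asarray(q_from, dtype=float)
    if not p.any() or not q.any():
        raise DegenerateGeometryError("angle undefined for a zero-length segment")
    return _angle_between(p, q)


def compute_features(ls: LandmarkSet) -> AngularFeatureSet:
    """Compute the seven angular diagnostic features of a landmark set.

    Conventions: SNA and SNB are vertex angles at Nasion; ANB = SNA − SNB
    (signed); incisor axes run root→crown (Ur→Uc, Lr→Lc); the
    anterior cranial base runs S→N and the mandibular plane Go→Me; the
    soft-tissue convexity is the vertex angle at Subnasale between
    Glabella and soft-tissue Pogonion.
    """
    sna = angle_at_vertex(ls["A"], ls["N"], ls["S"])
    snb = angle_at_vertex(ls["B"], ls["N"], ls["S"])
    return AngularFeatureSet(
        sna=sna,
        snb=snb,
        anb=sna - snb,
        uc_ur_sn=directed_line_angle(ls["Ur"], ls["Uc"], ls["S"], ls["N"]),
        lc_lr_gome=directed_line_angle(ls["Lr"], ls["Lc"], ls["Go"], ls["Me"]),
        sn_gome=directed_line_angle(ls["S"], ls["N"], ls["Go"], ls["Me"]),
        g_sn_pgs=angle_at_vertex(ls["G"], ls["Sn"], ls["PgS"]),
    )


# ----------------------------------------------------------------------
# error metrics
# ----------------------------------------------------------------------

def landmark_errors(pred: LandmarkSet, truth: LandmarkSet) -> dict[str, LandmarkError]:
    """Per-landmark error magnitude (pixels) and direction (degrees).

    Direction follows the raster frame: 0° = +x (right), 90° = +y (down),
    in [0, 360).  Zero-magnitude errors get a NaN direction.
    """
    delta = pred.coords - truth.coords
    mags = np.hypot(delta[:, 0], delta[:, 1])
    dirs = np.degrees(np.arctan2(delta[:, 1], delta[:, 0])) % 360.0
    out: dict[str, LandmarkError] = {}
    for i, name in enumerate(LANDMARK_NAMES):
        if mags[i] == 0.0:
            out[name] = LandmarkError(0.0)
        else:
            out[name] = LandmarkError(float(mags[i]), float(dirs[i]))
    return out


def feature_errors(pred: LandmarkSet, truth: LandmarkSet) -> dict[str, float]:
    """Signed per-feature angular error in degrees (predicted − true)."""
    fp = compute_features(pred).as_dict()
    ft = compute_features(truth).as_dict()
    return {name: fp[name] - ft[name] for name in FEATURE_NAMES}
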