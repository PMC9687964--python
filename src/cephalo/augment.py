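"""Landmark-consistent image transforms for training-set augmentation.

Six transform kinds: zoom, height-axis shift, width-axis shift, shear,
rotation (all affine, exact on landmark coordinates) and an elastic
deformation (random affine composed with a Gaussian-smoothed random
displacement field).  Every transform maps the image and its landmark
annotation jointly, preserves the image dimensions and 8-bit range, and
flags — never silently clips — landmarks pushed outside the frame.

Naming note: "h_shift" displaces along the height axis (y, downward)
and "w_shift" along the width axis (x, rightward).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import LANDMARK_NAMES, LandmarkSet
from .synthetic import AnnotatedImage

AFFINE_KINDS: tuple[str, ...] = ("zoom", "h_shift", "w_shift", "shear", "rotate")
ALL_KINDS: tuple[str, ...] = AFFINE_KINDS + ("elastic",)


@dataclass(frozen=True)
class TransformSpec:
    """One concrete transform: a kind plus the parameters it uses.

    Only the fields relevant to ``kind`` are meaningful — e.g. a zoom
    reads ``zoom_fraction``, an elastic reads the three ``elastic_*``
    parameters and ``seed``.
    """

    kind: str
    zoom_fraction: float = 0.0
    shift_pixels: float = 0.0
    shear_degrees: float = 0.0
    rotate_degrees: float = 0.0
    elastic_alpha: float = 0.0
    elastic_sigma: float = 1.0
    elastic_alpha_affine: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ALL_KINDS:
            raise ValueError(f"unknown transform kind: {self.kind!r}")
        if self.kind == "elastic" and self.elastic_sigma <= 0:
            raise ValueError("elastic_sigma must be > 0")

    def label(self) -> str:
        """Short provenance tag appended to augmented-image ids."""
        if self.kind == "zoom":
            return f"zoom{self.zoom_fraction:+g}"
        if self.kind in ("h_shift", "w_shift"):
            return f"{self.kind}{self.shift_pixels:+g}px"
        if self.kind == "shear":
            return f"shear{self.shear_degrees:+g}deg"
        if self.kind == "rotate":
            return f"rotate{self.rotate_degrees:+g}deg"
        return (f"elastic_a{self.elastic_alpha:g}_s{self.elastic_sigma:g}"
                f"_aa{self.elastic_alpha_affine:g}_seed{self.seed}")


def table_transform_specs(elastic_seed: int = 0) -> list[TransformSpec]:
    """The six reference transforms at their standard magnitudes.

    Zoom 10%, shifts 50 px along each axis, shear 10°, rotation 10°,
    elastic with alpha=100, sigma=5, alpha_affine=50.
    """
    return [
        TransformSpec("zoom", zoom_fraction=0.10),
        TransformSpec("h_shift", shift_pixels=50.0),
        TransformSpec("w_shift", shift_pixels=50.0),
        TransformSpec("shear", shear_degrees=10.0),
        TransformSpec("rotate", rotate_degrees=10.0),
        TransformSpec("elastic", elastic_alpha=100.0, elastic_sigma=5.0,
                      elastic_alpha_affine=50.0, seed=elastic_seed),
    ]


@dataclass(frozen=True)
class AugmentationPolicy:
    """Random-augmentation policy: kinds and symmetric sampling ranges.

    Defaults follow the augmentation-gain protocol: zoom ±20%, shifts
    ±70 px, shear and rotation ±15°, affine kinds only.
    """

    kinds: tuple[str, ...] = AFFINE_KINDS
    zoom_range: float = 0.20
    shift_range: float = 70.0
    shear_range: float = 15.0
    rotate_range: float = 15.0
    copies_per_image: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.copies_per_image < 1:
            raise ValueError("copies_per_image must be >= 1")
        for f in ("zoom_range", "shift_range", "shear_range", "rotate_range"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        bad = [k for k in self.kinds if k not in ALL_KINDS]
        if bad:
            raise ValueError(f"unknown transform kinds: {bad}")


# ----------------------------------------------------------------------
# affine transforms
# ----------------------------------------------------------------------

def affine_matrix(spec: TransformSpec, shape_hw: tuple[int, int]) -> np.ndarray:
    """3x3 homogeneous matrix of an affine spec, acting on (x, y) points.

    All transforms are taken about the image center.  Zoom scales by
    1 + zoom_fraction; shear displaces x in proportion to y
    (tan(shear_degrees)); rotation is by rotate_degrees in the y-down
    frame.
    """
    if spec.kind == "elastic":
        raise ValueError("elastic transform has no affine matrix")
    h, w = shape_hw
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    m = np.eye(3)
    if spec.kind == "zoom":
        s = 1.0 + spec.zoom_fraction
        m[0, 0] = m[1, 1] = s
    elif spec.kind == "h_shift":
        m[1, 2] = spec.shift_pixels
    elif spec.kind == "w_shift":
        m[0, 2] = spec.shift_pixels
    elif spec.kind == "shear":
        m[0, 1] = math.tan(math.radians(spec.shear_degrees))
    elif spec.kind == "rotate":
        th = math.radians(spec.rotate_degrees)
        m[0, 0], m[0, 1] = math.cos(th), -math.sin(th)
        m[1, 0], m[1, 1] = math.sin(th), math.cos(th)
    center = np.eye(3)
    center[:2, 2] = (cx, cy)
    uncenter = np.eye(3)
    uncenter[:2, 2] = (-cx, -cy)
    if spec.kind in ("h_shift", "w_shift"):
        return m  # translation is center-independent
    return center @ m @ uncenter


def _warp_affine_image(img: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Bilinear warp of an 8-bit image by a forward (x, y) matrix."""
    minv = np.linalg.inv(m)
    # ndimage works in (row, col) = (y, x): swap axes of the inverse map
    mat = np.array([[minv[1, 1], minv[1, 0]], [minv[0, 1], minv[0, 0]]])
    off = np.array([minv[1, 2], minv[0, 2]])
    out = ndimage.affine_transform(img.astype(float), mat, offset=off,
                                   order=1, mode="constant", cval=0.0)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _flag_oob(coords: np.ndarray, shape_hw: tuple[int, int]) -> tuple[str, ...]:
    h, w = shape_hw
    oob = ((coords[:, 0] < 0) | (coords[:, 0] > w - 1)
           | (coords[:, 1] < 0) | (coords[:, 1] > h - 1))
    return tuple(np.array(LANDMARK_NAMES)[oob])


def apply_affine(img: AnnotatedImage, spec: TransformSpec) -> AnnotatedImage:
    """Apply one affine transform jointly to image and landmarks.

    The image is bilinearly resampled (constant 0 fill, size unchanged);
    landmark coordinates go through the same matrix exactly.  Landmarks
    leaving the frame are flagged on the output, not clipped.
    """
    m = affine_matrix(spec, img.image.shape)
    coords = img.landmarks.coords
    new_coords = coords @ m[:2, :2].T + m[:2, 2]
    warped = _warp_affine_image(img.image, m)
    return AnnotatedImage(
        warped, LandmarkSet(new_coords), f"{img.id}~{spec.label()}",
        flagged=_flag_oob(new_coords, warped.shape),
    )


# ----------------------------------------------------------------------
# elastic transform
# ----------------------------------------------------------------------

def apply_elastic(img: AnnotatedImage, spec: TransformSpec) -> AnnotatedImage:
    """Random affine + Gaussian-smoothed random displacement field.

    The affine is defined by displacing three reference points uniformly
    within ±alpha_affine.  The nonlinear part draws per-pixel
    uniform[−1, 1] fields, smooths them with ``elastic_sigma`` and
    scales by ``elastic_alpha``; the image is resampled through the
    composed backward map, and each landmark is moved by the (negated)
    displacement evaluated at its position — a forward approximation to
    the exact inverse, accurate to first order in the field gradient.
    Deterministic given ``spec.seed``.
    """
    if spec.kind != "elastic":
        raise ValueError("apply_elastic requires an elastic spec")
    image = img.image
    h, w = image.shape
    rng = np.random.default_rng(spec.seed)

    # random affine from three displaced reference points
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    side = min(h, w) / 3.0
    src = np.array([c + (-side, -side), c + (side, -side), c + (-side, side)])
    dst = src + rng.uniform(-spec.elastic_alpha_affine, spec.elastic_alpha_affine,
                            size=(3, 2))
    # solve [x y 1] A^T = dst for the 2x3 affine A
    g = np.hstack([src, np.ones((3, 1))])
    a23 = np.linalg.solve(g, dst).T            # (2, 3)
    # snap solver noise to exact integers (sub-nanopixel): keeps the
    # zero-displacement case an exact identity for the resampler
    near_int = np.rint(a23)
    a23 = np.where(np.abs(a23 - near_int) < 1e-9, near_int, a23)
    m = np.vstack([a23, [0.0, 0.0, 1.0]])

    # smoothed displacement fields (backward map, in pixels)
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), spec.elastic_sigma) * spec.elastic_alpha
    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), spec.elastic_sigma) * spec.elastic_alpha

    affine_img = _warp_affine_image(image, m).astype(float)
    rows, cols = np.mgrid[0:h, 0:w]
    sample_r = rows + dy
    sample_c = cols + dx
    out = ndimage.map_coordinates(affine_img, [sample_r, sample_c],
                                  order=1, mode="constant", cval=0.0)
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)

    coords = img.landmarks.coords @ m[:2, :2].T + m[:2, 2]
    # backward field d: out(x) = in(x + d(x)); landmarks move by -d
    lx = ndimage.map_coordinates(dx, [coords[:, 1], coords[:, 0]], order=1,
                                 mode="constant", cval=0.0)
    ly = ndimage.map_coordinates(dy, [coords[:, 1], coords[:, 0]], order=1,
                                 mode="constant", cval=0.0)
    new_coords = coords - np.stack([lx, ly], axis=1)
    return AnnotatedImage(
        out, LandmarkSet(new_coords), f"{img.id}~{spec.label()}",
        flagged=_flag_oob(new_coords, out.shape),
    )


def apply_transform(img: AnnotatedImage, spec: TransformSpec) -> AnnotatedImage:
    """Dispatch to the affine or elastic implementation."""
    if spec.kind == "elastic":
        return apply_elastic(img, spec)
    return apply_affine(img, spec)


# ----------------------------------------------------------------------
# random augmentation
# ----------------------------------------------------------------------

def sample_spec(policy: AugmentationPolicy, rng: np.random.Generator) -> TransformSpec:
    """Draw one transform kind and parameters from the policy ranges."""
    kind = policy.kinds[int(rng.integers(0, len(policy.kinds)))]
    if kind == "zoom":
        return TransformSpec("zoom", zoom_fraction=float(rng.uniform(-policy.zoom_range, policy.zoom_range)))
    if kind in ("h_shift", "w_shift"):
        return TransformSpec(kind, shift_pixels=float(rng.uniform(-policy.shift_range, policy.shift_range)))
    if kind == "shear":
        return TransformSpec("shear", shear_degrees=float(rng.uniform(-policy.shear_range, policy.shear_range)))
    if kind == "rotate":
        return TransformSpec("rotate", rotate_degrees=float(rng.uniform(-policy.rotate_range, policy.rotate_range)))
    return TransformSpec("elastic", elastic_alpha=100.0, elastic_sigma=5.0,
                         elastic_alpha_affine=50.0, seed=int(rng.integers(0, 2**31 - 1)))


def augment_dataset(ds: Sequence[AnnotatedImage],
                    policy: AugmentationPolicy) -> list[AnnotatedImage]:
    """Originals plus ``copies_per_image`` random transforms of each.

    Every output id records its provenance (source id + transform
    label).  Deterministic given ``policy.seed``.
    """
    if not ds:
        raise ValueError("cannot augment an empty dataset")
    if not policy.kinds:
        raise ValueError("augmentation policy has no transform kinds")
    rng = np.random.default_rng(policy.seed)
    out = list(ds)
    for img in ds:
        for _ in range(policy.copies_per_image):
            out.append(apply_transform(img, sample_spec(policy, rng)))
    return out
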