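"""Synthetic cephalogram generator.

Produces deterministic, annotation-perfect datasets of grayscale
radiograph-like images with the statistical structure a landmark
localizer needs to see: 26 landmarks riding on rendered anatomical
contours at consistent relative positions, inter-subject variation from
a global similarity placement plus spatially correlated per-landmark
deformation, and imaging degradation (intensity gradient, blur,
additive noise).

The generator makes no attempt at radiographic realism (no DRR
simulation, scatter or beam hardening); it emulates only the features
the regression method conditions on — edges at landmark positions and
smooth shape variation across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import interpolate, ndimage
from skimage import draw as skdraw

from .geometry import LANDMARK_NAMES, N_LANDMARKS, LandmarkSet, landmark_index

# ----------------------------------------------------------------------
# template anatomy
# ----------------------------------------------------------------------

# Canonical 26-point configuration on a 256x256 canvas (x right, y down;
# subject faces right, as on a standard lateral cephalogram).  The values
# are implementation constants chosen so the derived angular features sit
# in clinically plausible ranges (ANB small and positive, facial
# convexity near 165 deg, mandibular plane ~25 deg).
_TEMPLATE_256: dict[str, tuple[float, float]] = {
    "S": (110.0, 90.0),
    "P": (95.0, 105.0),
    "Go": (105.0, 185.0),
    "N": (170.0, 85.0),
    "O": (150.0, 105.0),
    "A": (178.0, 140.0),
    "B": (175.0, 185.0),
    "Me": (172.0, 210.0),
    "G": (178.0, 70.0),
    "Sn": (192.0, 140.0),
    "Ls": (196.0, 155.0),
    "Li": (194.0, 172.0),
    "PgS": (188.0, 200.0),
    "Ur": (170.0, 145.0),
    "Uc": (176.0, 165.0),
    "Lc": (174.0, 168.0),
    "Lr": (168.0, 188.0),
    "ANS": (176.0, 132.0),
    "PNS": (130.0, 135.0),
    "U6M": (152.0, 160.0),
    "U6D": (144.0, 158.0),
    "L6M": (150.0, 170.0),
    "L6D": (142.0, 172.0),
    "SEM": (125.0, 75.0),
    "Pn": (200.0, 125.0),
    "Co": (100.0, 100.0),
}

#: Soft-tissue landmark → skeletal counterpart; the soft-tissue point
#: always lies at or anterior to (x >=) its counterpart on the template.
SOFT_TISSUE_COUNTERPARTS: dict[str, str] = {
    "G": "N", "Pn": "ANS", "Sn": "A", "Ls": "Uc", "Li": "Lc", "PgS": "B",
}

#: Landmark groups rendered as smooth contours (in drawing order), with
#: the intensity each contour is drawn at.
_CONTOUR_GROUPS: tuple[tuple[tuple[str, ...], float], ...] = (
    (("Co", "S", "SEM", "N", "G"), 210.0),        # cranial base / outline
    (("Co", "Go", "Me", "B"), 220.0),             # mandibular border
    (("PNS", "ANS", "A"), 200.0),                 # maxilla
    (("Ur", "Uc"), 230.0),                        # upper incisor axis
    (("Lr", "Lc"), 230.0),                        # lower incisor axis
    (("G", "Pn", "Sn", "Ls", "Li", "PgS"), 150.0),  # soft-tissue profile
)

#: Landmarks rendered as small disk marks (molar cusps, porion, orbitale).
_MARK_POINTS: tuple[tuple[str, float], ...] = (
    ("P", 190.0), ("O", 190.0),
    ("U6M", 230.0), ("U6D", 230.0), ("L6M", 230.0), ("L6D", 230.0),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic dataset generator.

    Jitters control inter-subject variation: a global similarity
    placement (translation / scale / rotation about the image center)
    plus spatially correlated per-landmark deformation.  Degradation is
    a Gaussian blur followed by additive Gaussian noise.  All units are
    pixels and degrees on the generated image grid.
    """

    n_images: int = 362
    image_size: int = 256
    seed: int = 0
    placement_jitter: float = 25.0  # s.d. of global translation, px
    scale_jitter: float = 0.07      # s.d. of global scale factor
    rotation_jitter: float = 6.0    # s.d. of global rotation, deg
    shape_jitter: float = 4.0       # s.d. of correlated per-landmark offset, px
    blur_sigma: float = 1.0
    noise_sd: float = 5.0
    margin: int = 8                 # min landmark distance from border, px
    max_retries: int = 100          # placement resampling bound

    def __post_init__(self) -> None:
        if self.n_images < 0:
            raise ValueError("n_images must be >= 0")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        for name in ("placement_jitter", "scale_jitter", "rotation_jitter",
                     "shape_jitter", "blur_sigma", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


@dataclass
class AnnotatedImage:
    """One grayscale image with its ground-truth landmark set.

    ``flagged`` lists landmark names whose coordinates fell outside the
    image bounds (only augmentation transforms produce these; generated
    images always respect the margin).
    """

    image: np.ndarray
    landmarks: LandmarkSet
    id: str
    flagged: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 2:
            raise ValueError("image must be a 2-D grayscale array")
        if img.dtype != np.uint8:
            raise ValueError("image must be 8-bit (uint8)")
        self.image = img


class MarginError(RuntimeError):
    """Placement could not satisfy the margin within the retry bound."""


def make_template(image_size: int) -> LandmarkSet:
    """The canonical landmark configuration scaled to ``image_size``.

    Deterministic; satisfies the qualitative anatomical ordering
    constraints of a lateral view facing right (Menton most inferior,
    soft-tissue profile anterior to the skeleton, etc.).
    """
    if image_size < 64:
        raise ValueError("image_size must be >= 64")
    s = image_size / 256.0
    coords = np.array([_TEMPLATE_256[n] for n in LANDMARK_NAMES], dtype=float) * s
    return LandmarkSet(coords)


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------

def _draw_curve(canvas: np.ndarray, pts: np.ndarray, value: float) -> None:
    """Rasterize a smooth open curve through ``pts`` ((x, y) rows)."""
    n = len(pts)
    if n == 2:
        dense = np.linspace(pts[0], pts[1], 200)
    else:
        k = min(3, n - 1)
        tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], s=0, k=k)
        u = np.linspace(0.0, 1.0, 60 * n)
        dense = np.stack(interpolate.splev(u, tck), axis=1)
    cols = np.clip(np.rint(dense[:, 0]).astype(int), 0, canvas.shape[1] - 1)
    rows = np.clip(np.rint(dense[:, 1]).astype(int), 0, canvas.shape[0] - 1)
    canvas[rows, cols] = np.maximum(canvas[rows, cols], value)
    # thicken by one pixel downward/rightward so contours survive blur
    rows2 = np.clip(rows + 1, 0, canvas.shape[0] - 1)
    cols2 = np.clip(cols + 1, 0, canvas.shape[1] - 1)
    canvas[rows2, cols] = np.maximum(canvas[rows2, cols], value)
    canvas[rows, cols2] = np.maximum(canvas[rows, cols2], value)


def render(landmarks: LandmarkSet, cfg: GeneratorConfig, noise_seed: int) -> np.ndarray:
    """Render one synthetic cephalogram for a landmark configuration.

    Draws smooth contours through anatomically grouped landmark subsets
    over a background intensity gradient, applies Gaussian blur
    (``cfg.blur_sigma``) and additive Gaussian noise (``cfg.noise_sd``),
    and clips to 8-bit range.  Deterministic given ``noise_seed``.
    """
    size = cfg.image_size
    xy = landmarks.coords
    if (xy < 0).any() or (xy > size - 1).any():
        raise ValueError("landmark out of image bounds; cannot render")

    yy, xx = np.mgrid[0:size, 0:size]
    canvas = 30.0 + 50.0 * (xx / size) + 15.0 * (yy / size)

    for names, value in _CONTOUR_GROUPS:
        pts = np.array([landmarks[n] for n in names])
        _draw_curve(canvas, pts, value)
    for name, value in _MARK_POINTS:
        x, y = landmarks[name]
        rr, cc = skdraw.disk((y, x), 2.5, shape=canvas.shape)
        canvas[rr, cc] = value

    if cfg.blur_sigma > 0:
        canvas = ndimage.gaussian_filter(canvas, cfg.blur_sigma)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(noise_seed)
        canvas = canvas + rng.normal(0.0, cfg.noise_sd, canvas.shape)
    return np.clip(canvas, 0, 255).astype(np.uint8)


# ----------------------------------------------------------------------
# dataset sampling
# ----------------------------------------------------------------------

def _neighbor_smoother(template: np.ndarray, k: int = 4, rounds: int = 2) -> np.ndarray:
    """Row-stochastic smoothing operator over the landmark k-NN graph.

    Applying it to i.i.d. per-landmark offsets yields spatially
    correlated deformation: neighboring landmarks move coherently, the
    cheap stand-in for biological shape covariance.
    """
    d = np.linalg.norm(template[:, None, :] - template[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    w = np.zeros((N_LANDMARKS, N_LANDMARKS))
    nearest = np.argsort(d, axis=1)[:, :k]
    for i in range(N_LANDMARKS):
        w[i, nearest[i]] = 1.0
    np.fill_diagonal(w, 2.0)  # self-weight keeps some local variance
    w /= w.sum(axis=1, keepdims=True)
    return np.linalg.matrix_power(w, rounds)


def _place(template: np.ndarray, cfg: GeneratorConfig,
           rng: np.random.Generator, smoother: np.ndarray) -> np.ndarray:
    """Draw one subject's landmark configuration."""
    c = (cfg.image_size - 1) / 2.0
    scale = 1.0 + rng.normal(0.0, cfg.scale_jitter)
    theta = np.radians(rng.normal(0.0, cfg.rotation_jitter))
    shift = rng.normal(0.0, cfg.placement_jitter, size=2)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    placed = (template - c) @ (scale * rot).T + c + shift
    offsets = rng.normal(0.0, cfg.shape_jitter, size=(N_LANDMARKS, 2))
    return placed + smoother @ offsets


def sample_dataset(cfg: GeneratorConfig) -> list[AnnotatedImage]:
    """Generate ``cfg.n_images`` annotated images, bit-deterministically.

    Each subject is a similarity-placed, coherently deformed copy of the
    template, rendered with an independent noise realization.
    Placements violating the border margin are resampled up to
    ``cfg.max_retries`` times; exhaustion raises :class:`MarginError`.
    """
    template = make_template(cfg.image_size).coords
    smoother = _neighbor_smoother(template)
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.margin, cfg.image_size - cfg.margin
    out: list[AnnotatedImage] = []
    for i in range(cfg.n_images):
        for attempt in range(cfg.max_retries + 1):
            coords = _place(template, cfg, rng, smoother)
            if (coords >= lo).all() and (coords <= hi).all():
                break
        else:
            raise MarginError(
                f"image {i}: could not place landmarks within margin "
                f"{cfg.margin} after {cfg.max_retries} retries"
            )
        noise_seed = int(rng.integers(0, 2**31 - 1))
        ls = LandmarkSet(coords)
        out.append(AnnotatedImage(render(ls, cfg, noise_seed), ls, f"synth{i:04d}"))
    return out


def split_dataset(ds: Sequence[AnnotatedImage], train_fraction: float,
                  seed: int) -> tuple[list[AnnotatedImage], list[AnnotatedImage]]:
    """Shuffle and split into train/test; train size = floor(fraction * n)."""
    if not ds:
        raise ValueError("cannot split an empty dataset")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    order = np.random.default_rng(seed).permutation(len(ds))
    n_train = int(np.floor(train_fraction * len(ds)))
    return [ds[i] for i in order[:n_train]], [ds[i] for i in order[n_train:]]
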