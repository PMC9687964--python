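"""Dataset and report I/O: PNG images, points CSVs, manifests, metadata.

On-disk layout of a dataset directory::

    manifest.csv          # header: id,image_path,points_path (paths relative)
    images/<id>.png       # 8-bit grayscale
    points/<id>.csv       # header: name,x,y — 26 rows in canonical order

Readers validate aggressively and report the offending manifest row or
landmark by name; writers round-trip coordinates at full precision.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .geometry import LandmarkSet
from .synthetic import AnnotatedImage


class ManifestError(ValueError):
    """A manifest or one of its referenced files failed validation."""


def write_image(image: np.ndarray, path) -> None:
    Image.fromarray(image, mode="L").save(path, format="PNG")


def read_image(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L"))


def write_dataset(ds: Sequence[AnnotatedImage], out_dir) -> Path:
    """Write images, points files and the manifest; returns manifest path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "points").mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "image_path", "points_path"])
        for img in ds:
            img_rel = f"images/{img.id}.png"
            pts_rel = f"points/{img.id}.csv"
            write_image(img.image, out / img_rel)
            img.landmarks.write_csv(out / pts_rel)
            writer.writerow([img.id, img_rel, pts_rel])
    return manifest


def read_manifest(path) -> list[AnnotatedImage]:
    """Load a dataset from its manifest, validating every row.

    Errors name the manifest row (1-based, excluding the header) and
    the file or landmark at fault.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    base = path.parent
    out: list[AnnotatedImage] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["id", "image_path", "points_path"]:
            raise ManifestError(
                f"{path}: expected header 'id,image_path,points_path', got {header}"
            )
        for row_no, row in enumerate(reader, start=1):
            if len(row) != 3:
                raise ManifestError(f"{path} row {row_no}: expected 3 fields, got {len(row)}")
            img_id, img_rel, pts_rel = row
            img_path = base / img_rel
            pts_path = base / pts_rel
            if not img_path.exists():
                raise ManifestError(f"{path} row {row_no}: missing image file {img_path}")
            if not pts_path.exists():
                raise ManifestError(f"{path} row {row_no}: missing points file {pts_path}")
            try:
                landmarks = LandmarkSet.read_csv(pts_path)
            except ValueError as exc:
                raise ManifestError(f"{path} row {row_no}: {exc}") from exc
            out.append(AnnotatedImage(read_image(img_path), landmarks, img_id))
    return out


def write_feature_report(rows: dict[str, dict[str, float]], path) -> None:
    """Feature report CSV: image_id followed by the seven feature columns."""
    from .geometry import FEATURE_NAMES

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", *FEATURE_NAMES])
        for image_id, feats in rows.items():
            writer.writerow([image_id, *(repr(feats[f]) for f in FEATURE_NAMES)])


def write_run_metadata(path, command: str, config: dict, seed: int) -> None:
    """Record everything needed to reproduce a run."""
    from . import __version__

    doc = {
        "command": command,
        "config": config,
        "seed": seed,
        "package_version": __version__,
        "model_format_version": 1,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
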