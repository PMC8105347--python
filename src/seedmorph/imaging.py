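"""Mask reading, outline tracing and traditional seed descriptors.

Images are binary seed masks (foreground > 0, one seed per image).  All
coordinates are handled internally in the mathematical convention: x to the
right, y upward, 0-based pixel centers.  When a mask of height H is read,
image row r maps to y = (H - 1) - r, so "top of the seed" means maximal y.
Landmark files (CSV or TPS) are expected to store coordinates already in
this y-up convention, as written by the simulator and by standard TPS
digitizers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import measure

__all__ = [
    "Outline",
    "LandmarkSet",
    "SeedRecord",
    "extract_outline",
    "read_mask",
    "read_landmarks",
    "write_landmarks_csv",
    "bounding_box_size",
    "read_descriptor_table",
]


@dataclass
class Outline:
    """Ordered closed 2-D point sequence tracing one seed silhouette."""

    points: np.ndarray
    closed: bool = True
    scale: float = 1.0                # physical units (mm) per coordinate unit
    touches_border: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(pts) >= 2:
            dup = np.all(pts[1:] == pts[:-1], axis=1)
            if dup.any():
                pts = pts[np.concatenate([[True], ~dup])]
        if len(pts) >= 2 and np.all(pts[0] == pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ValueError("an outline needs at least 3 distinct points")
        self.points = pts

    @property
    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def is_ccw(self) -> bool:
        return self.signed_area > 0

    def as_ccw(self) -> "Outline":
        if self.is_ccw:
            return self
        return replace(self, points=self.points[::-1].copy())

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class LandmarkSet:
    """The five anchor points of one seed image.

    Landmarks 1-3 sit on the hilum arch (2 is the outline start point);
    landmarks 4 and 5 mark the top and bottom length extremes.
    """

    coords: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (5, 2):
            raise ValueError(
                f"landmark set for {self.image_id or '<image>'} must have "
                f"exactly 5 (x, y) points, got shape {c.shape}")
        self.coords = c

    def landmark(self, idx: int) -> np.ndarray:
        """1-based accessor matching the field convention (1..5)."""
        if not 1 <= idx <= 5:
            raise IndexError("landmark index must be 1..5")
        return self.coords[idx - 1]


@dataclass
class SeedRecord:
    """One analysed specimen: identity, traditional descriptors, shape."""

    id: str
    taxon: str                         # taxon label or "unknown"
    length_mm: float
    width_mm: float
    cells: int
    coeffs: object = None              # EFTCoefficients, filled by efa stage
    outline_mm: object = None          # ground-truth outline when simulated
    touches_border: bool = False

    @property
    def log_length(self) -> float:
        return float(np.log(self.length_mm))

    @property
    def log_width(self) -> float:
        return float(np.log(self.width_mm))


# ---------------------------------------------------------------------------
# outline extraction

def read_mask(path) -> np.ndarray:
    """Load a PNG/TIFF mask as a boolean foreground array."""
    arr = np.asarray(Image.open(path).convert("L"))
    return arr > 0


def extract_outline(mask: np.ndarray, scale: float = 1.0) -> Outline:
    """Trace the boundary of the largest foreground component of a mask.

    Returns the sub-pixel marching-squares contour at the 0.5 iso-level,
    counterclockwise in y-up coordinates.  Multi-component masks keep only
    the largest blob; a component touching the image border is kept but
    flagged on the outline.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        mask = mask > 0
    if not mask.any():
        raise ValueError("empty mask: no foreground pixels")
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    biggest = int(np.argmax(counts))
    blob = labels == biggest
    rows, cols = np.nonzero(blob)
    touches = bool(rows.min() == 0 or cols.min() == 0 or
                   rows.max() == mask.shape[0] - 1 or
                   cols.max() == mask.shape[1] - 1)
    padded = np.pad(blob, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("no contour found at the 0.5 iso-level")
    contour = max(contours, key=len)          # (row, col) in padded frame
    h = mask.shape[0]
    x = contour[:, 1] - 1.0
    y = (h - 1) - (contour[:, 0] - 1.0)
    out = Outline(points=np.column_stack([x, y]), closed=True, scale=scale,
                  touches_border=touches)
    return out.as_ccw()


# ---------------------------------------------------------------------------
# landmark IO

def _landmarks_from_csv(path) -> dict:
    df = pd.read_csv(path)
    required = {"image", "ldk", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark CSV must have columns {sorted(required)}")
    sets = {}
    for image, grp in df.groupby("image", sort=False):
        if len(grp) != 5 or set(grp["ldk"]) != {1, 2, 3, 4, 5}:
            raise ValueError(
                f"image {image!r} must have exactly landmarks 1..5, "
                f"got {sorted(grp['ldk'])}")
        grp = grp.sort_values("ldk")
        sets[str(image)] = LandmarkSet(
            coords=grp[["x", "y"]].to_numpy(float), image_id=str(image))
    return sets


def _landmarks_from_tps(path) -> dict:
    sets = {}
    lm_count = None
    coords: list = []
    image = None
    order = 0

    def flush():
        nonlocal coords, image, lm_count
        if lm_count is None:
            return
        if lm_count != 5 or len(coords) != 5:
            raise ValueError(
                f"image {image or '<unnamed>'} must have exactly 5 landmarks,"
                f" got {len(coords)} (LM={lm_count})")
        key = image if image is not None else f"tps_{len(sets)}"
        sets[key] = LandmarkSet(coords=np.asarray(coords, float), image_id=key)
        coords, image, lm_count = [], None, None

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            if lm_count is not None:
                flush()
            lm_count = int(line.split("=", 1)[1])
        elif upper.startswith("IMAGE="):
            image = line.split("=", 1)[1].strip()
        elif upper.startswith(("ID=", "SCALE=")):
            continue
        else:
            parts = line.split()
            if len(parts) == 2 and lm_count is not None:
                coords.append([float(parts[0]), float(parts[1])])
            else:
                raise ValueError(f"unparseable TPS line: {raw!r}")
        order += 1
    flush()
    return sets


def read_landmarks(path, dialect: str | None = None) -> dict:
    """Read landmark files; returns {image_id: LandmarkSet}.

    ``dialect`` is "csv" (columns image,ldk,x,y) or "tps" (LM=5 blocks);
    inferred from the file extension when omitted.
    """
    if dialect is None:
        suffix = Path(path).suffix.lower()
        dialect = {"csv": "csv", ".csv": "csv", ".tps": "tps"}.get(suffix)
        if dialect is None:
            raise ValueError(f"cannot infer landmark dialect from {path!r}")
    if dialect == "csv":
        return _landmarks_from_csv(path)
    if dialect == "tps":
        return _landmarks_from_tps(path)
    raise ValueError(f"unknown landmark dialect {dialect!r}")


def write_landmarks_csv(sets, path) -> None:
    rows = []
    for s in (sets.values() if isinstance(sets, dict) else sets):
        for i in range(5):
            rows.append({"image": s.image_id, "ldk": i + 1,
                         "x": s.coords[i, 0], "y": s.coords[i, 1]})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# traditional descriptors

def bounding_box_size(outline: Outline) -> tuple[float, float]:
    """Axis-aligned bounding-box (length, width) in mm.

    Under the standard acquisition orientation (hilum right, broader part at
    the bottom), length is the vertical extent — the landmark 4-5 axis — and
    width the horizontal extent.  The box is axis-aligned by convention, not
    rotated to the major axis.
    """
    pts = outline.points
    width = float(pts[:, 0].max() - pts[:, 0].min()) * outline.scale
    length = float(pts[:, 1].max() - pts[:, 1].min()) * outline.scale
    if length <= 0 or width <= 0:
        raise ValueError("degenerate outline: zero bounding-box extent")
    return length, width


def read_descriptor_table(path) -> pd.DataFrame:
    """Read the specimen descriptor table (id, taxon, length, width, cells)."""
    df = pd.read_csv(path)
    required = {"id", "taxon", "length", "width", "cells"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"descriptor table missing columns {sorted(missing)}")
    return df
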