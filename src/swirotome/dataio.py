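"""Frame, mask, annotation and manifest I/O.

All on-disk formats are plain standard containers: 16-bit single-channel
PNG/TIFF for frames, 8-bit {0,1} PNG for masks, CSV for manifests and JSON
for polygon annotations.  Coordinates are 0-based ``(row, col)`` with the
origin at the top-left corner; pixel ``(r, c)`` is the unit square centred
on the point ``(r, c)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

#: Maximum representable intensity count (14-bit ADC).
MAX_COUNT = 16383

#: Allowed effusion labels in manifests.
LABELS = ("effusion", "no_effusion")

#: Manifest column order.
MANIFEST_COLUMNS = (
    "frame_path",
    "mask_path",
    "patient_id",
    "ear_id",
    "frame_index",
    "label",
    "subset_tag",
)

SUBSET_TAGS = ("best_frame", "frame_range", "other")


class FormatError(ValueError):
    """Raised for files that exist but cannot be interpreted."""


@dataclass(frozen=True)
class Frame:
    """One 2-D grayscale SWIR frame with identifiers and effusion label.

    Parameters
    ----------
    pixels
        2-D integer array of intensity counts in ``[0, 16383]``.
    patient_id, ear_id
        Cohort identifiers.
    frame_index
        Non-negative index of the frame within its clip.
    label
        ``"effusion"``, ``"no_effusion"`` or ``"unknown"``.
    """

    pixels: np.ndarray
    patient_id: str = ""
    ear_id: str = ""
    frame_index: int = 0
    label: str = "unknown"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise FormatError(f"frame pixels must be 2-D, got shape {px.shape}")
        if px.shape[0] <= 0 or px.shape[1] <= 0:
            raise ValueError("frame dimensions must be positive")
        if px.size and (px.min() < 0 or px.max() > MAX_COUNT):
            raise ValueError(f"pixel values outside [0, {MAX_COUNT}]")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if self.label not in LABELS + ("unknown",):
            raise ValueError(f"label must be one of {LABELS + ('unknown',)}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ROIMask:
    """Per-pixel binary ROI membership; class 1 = ROI, class 0 = not-ROI."""

    mask: np.ndarray
    provenance: str = "annotation"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        object.__setattr__(self, "mask", m.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class Polygon:
    """Closed polygon in ``(row, col)`` pixel coordinates."""

    vertices: np.ndarray  # (n, 2) float
    polarity: str = "include"  # {"include", "exclude"}

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("polygon needs >= 3 (row, col) vertices")
        if self.polarity not in ("include", "exclude"):
            raise ValueError("polarity must be 'include' or 'exclude'")
        object.__setattr__(self, "vertices", v)


@dataclass(frozen=True)
class Annotation:
    """A set of include/exclude polygons describing one frame's ROI."""

    polygons: tuple[Polygon, ...] = ()
    frame: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "polygons", tuple(self.polygons))


@dataclass
class Manifest:
    """Cohort manifest: one row per frame.

    Thin wrapper over a :class:`pandas.DataFrame` with the documented
    columns, so CSV round-trips stay bit-exact.
    """

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(MANIFEST_COLUMNS))
    )

    def __post_init__(self) -> None:
        df = self.rows.copy()
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        df = df[list(MANIFEST_COLUMNS)].reset_index(drop=True)
        if len(df):
            bad = sorted(set(df["label"]) - set(LABELS))
            if bad:
                raise ValueError(
                    f"unknown labels {bad}; allowed labels are {list(LABELS)}"
                )
            df["frame_index"] = df["frame_index"].astype(int)
            dup = df.duplicated(subset=["ear_id", "frame_index"])
            if dup.any():
                pair = df.loc[dup.idxmax(), ["ear_id", "frame_index"]].tolist()
                raise ValueError(f"duplicate (ear_id, frame_index): {pair}")
            _warn_nonconsecutive_frame_ranges(df)
        self.rows = df

    def __len__(self) -> int:
        return len(self.rows)


def _warn_nonconsecutive_frame_ranges(df: pd.DataFrame) -> None:
    fr = df[df["subset_tag"] == "frame_range"]
    for ear_id, grp in fr.groupby("ear_id"):
        idx = np.sort(grp["frame_index"].to_numpy())
        if len(idx) > 1 and not np.array_equal(idx, np.arange(idx[0], idx[0] + len(idx))):
            warnings.warn(
                f"frame_range rows for ear {ear_id!r} are not consecutive",
                stacklevel=3,
            )


# ---------------------------------------------------------------------------
# Frame / mask files
# ---------------------------------------------------------------------------

def read_frame(
    path: str | Path,
    patient_id: str = "",
    ear_id: str = "",
    frame_index: int = 0,
    label: str = "unknown",
) -> Frame:
    """Read a single-channel <=16-bit image file as a :class:`Frame`.

    Pixel values are clipped to the 14-bit range ``[0, 16383]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such frame file: {path}")
    try:
        px = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise FormatError(f"unreadable image file {path}: {exc}") from exc
    if px.ndim == 3:
        raise FormatError(f"multi-channel input not supported: {path}")
    if px.ndim != 2:
        raise FormatError(f"expected a 2-D image in {path}, got shape {px.shape}")
    if px.dtype.itemsize > 2:
        raise FormatError(f"bit depth above 16 not supported: {path}")
    px = np.clip(px.astype(np.int64), 0, MAX_COUNT).astype(np.uint16)
    return Frame(px, patient_id=patient_id, ear_id=ear_id,
                 frame_index=frame_index, label=label)


def write_frame(frame: Frame, path: str | Path) -> Path:
    """Write ``frame`` as a 16-bit single-channel image; lossless round-trip."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    iio.imwrite(path, frame.pixels.astype(np.uint16))
    return path


def read_mask(path: str | Path, provenance: str = "annotation") -> ROIMask:
    """Read a {0,1} mask image."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask file: {path}")
    m = iio.imread(path)
    if m.ndim != 2:
        raise FormatError(f"mask must be single-channel: {path}")
    return ROIMask(m > 0, provenance=provenance)


def write_mask(mask: ROIMask, path: str | Path) -> Path:
    path = Path(path)
    iio.imwrite(path, mask.mask.astype(np.uint8))
    return path


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def rasterize_annotation(ann: Annotation, shape: tuple[int, int]) -> ROIMask:
    """Rasterize include/exclude polygons into a binary ROI mask.

    The mask is the union of the include polygons minus the union of the
    exclude polygons.  A pixel belongs to a polygon when its centre
    ``(r, c)`` lies inside the polygon (even-odd rule, 0-based indices,
    top-left origin).
    """
    nr, nc = int(shape[0]), int(shape[1])
    if nr <= 0 or nc <= 0:
        raise ValueError("shape must be positive")
    rr, cc = np.mgrid[0:nr, 0:nc]
    centers = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    include = np.zeros(nr * nc, dtype=bool)
    exclude = np.zeros(nr * nc, dtype=bool)
    for poly in ann.polygons:
        inside = _points_in_polygon(centers, poly.vertices)
        if poly.polarity == "include":
            include |= inside
        else:
            exclude |= inside
    return ROIMask((include & ~exclude).reshape(nr, nc), provenance="annotation")


def _points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Vectorized even-odd (crossing number) point-in-polygon test."""
    x = points[:, 0][:, None]
    y = points[:, 1][:, None]
    v1 = vertices
    v2 = np.roll(vertices, -1, axis=0)
    x1, y1 = v1[:, 0][None, :], v1[:, 1][None, :]
    x2, y2 = v2[:, 0][None, :], v2[:, 1][None, :]
    # edge crosses the horizontal ray through (x, y) in the +y direction
    cond = (x1 <= x) != (x2 <= x)
    with np.errstate(divide="ignore", invalid="ignore"):
        ycross = y1 + (x - x1) * (y2 - y1) / np.where(x2 == x1, np.inf, x2 - x1)
    crossings = np.sum(cond & (ycross > y), axis=1)
    return (crossings % 2) == 1


def read_annotation(path: str | Path) -> Annotation:
    """Read a JSON annotation ``{frame, polygons: [{polarity, vertices}]}``."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    polys = tuple(
        Polygon(np.asarray(p["vertices"], dtype=float), p.get("polarity", "include"))
        for p in doc.get("polygons", [])
    )
    return Annotation(polygons=polys, frame=doc.get("frame", ""))


def write_annotation(ann: Annotation, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "frame": ann.frame,
        "polygons": [
            {"polarity": p.polarity, "vertices": p.vertices.tolist()}
            for p in ann.polygons
        ],
    }
    path.write_text(json.dumps(doc, indent=1))
    return path


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> Manifest:
    """Read and validate a manifest CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such manifest: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if len(df):
        df["frame_index"] = df["frame_index"].astype(int)
    return Manifest(df)


def write_manifest(manifest: Manifest, path: str | Path) -> Path:
    path = Path(path)
    manifest.rows.to_csv(path, index=False)
    return path


def build_manifest(rows: Iterable[dict]) -> Manifest:
    """Construct a validated manifest from row dicts."""
    return Manifest(pd.DataFrame(list(rows), columns=list(MANIFEST_COLUMNS)))
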