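"""ROI intensity parameterization.

Input Set 1 is the average ROI intensity alone; Input Set 2 is the full
11-statistic list computed globally over the ROI pixel multiset:

====================  ====================================================
mean_intensity        mean of all ROI pixels
median_intensity      median of all ROI pixels
mean_iqr, median_iqr  mean/median of pixels with Q1 <= v <= Q3
mean_above            mean of pixels strictly above the median
median_above          median of pixels strictly above the median
mean_below            mean of pixels strictly below the median
median_below          median of pixels strictly below the median
diff_max_median       max - median
diff_median_min       median - min
iqr                   Q3 - Q1
====================  ====================================================

Quantiles use linear interpolation between order statistics at rank
``(n - 1) * q``.  Empty above/below/IQR subsets fall back to the median.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import Frame, Manifest, ROIMask

log = logging.getLogger(__name__)

#: Input Set 2 feature names, in canonical column order.
FEATURE_NAMES = (
    "mean_intensity",
    "median_intensity",
    "mean_iqr",
    "median_iqr",
    "mean_above",
    "median_above",
    "mean_below",
    "median_below",
    "diff_max_median",
    "diff_median_min",
    "iqr",
)

ID_COLUMNS = ("patient_id", "ear_id", "frame_index", "label")

INPUT_SETS = {"set1": ("mean_intensity",), "set2": FEATURE_NAMES}


def quantile(values: Sequence[float] | np.ndarray, q: float) -> float:
    """Quantile by linear interpolation at rank ``(n - 1) * q``."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("quantile of an empty list")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    return float(np.quantile(v, q, method="linear"))


def extract_features(
    frame: Frame,
    mask: ROIMask,
    input_set: str = "set2",
) -> dict[str, float]:
    """Compute the ROI intensity statistics for one frame.

    ``set1`` populates only ``mean_intensity``; ``set2`` the full list.
    Raises on an empty ROI.
    """
    if input_set not in INPUT_SETS:
        raise ValueError(f"input_set must be one of {sorted(INPUT_SETS)}")
    if mask.shape != frame.shape:
        raise ValueError("frame and mask shapes differ")
    v = frame.pixels[mask.mask].astype(float)
    if v.size == 0:
        raise ValueError("empty ROI")
    if input_set == "set1":
        return {"mean_intensity": float(v.mean())}
    return compute_statistics(v)


def compute_statistics(values: np.ndarray) -> dict[str, float]:
    """The 11 Input Set 2 statistics over a nonempty value multiset."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty ROI")
    med = quantile(v, 0.5)
    q1 = quantile(v, 0.25)
    q3 = quantile(v, 0.75)

    def _loc(subset: np.ndarray) -> tuple[float, float]:
        if subset.size == 0:  # fallback: degenerate subset collapses to median
            return med, med
        return float(subset.mean()), float(np.quantile(subset, 0.5, method="linear"))

    mean_iqr, median_iqr = _loc(v[(v >= q1) & (v <= q3)])
    mean_above, median_above = _loc(v[v > med])
    mean_below, median_below = _loc(v[v < med])
    return {
        "mean_intensity": float(v.mean()),
        "median_intensity": med,
        "mean_iqr": mean_iqr,
        "median_iqr": median_iqr,
        "mean_above": mean_above,
        "median_above": median_above,
        "mean_below": mean_below,
        "median_below": median_below,
        "diff_max_median": float(v.max()) - med,
        "diff_median_min": med - float(v.min()),
        "iqr": q3 - q1,
    }


def featurize_frames(
    frames_and_masks: Iterable[tuple[Frame, ROIMask]],
    input_set: str = "set2",
) -> pd.DataFrame:
    """One feature row per (frame, mask) pair; empty-ROI frames are dropped
    with a logged warning."""
    cols = INPUT_SETS[input_set]
    rows = []
    n_dropped = 0
    for frame, mask in frames_and_masks:
        try:
            feats = extract_features(frame, mask, input_set)
        except ValueError as exc:
            if "empty ROI" in str(exc):
                n_dropped += 1
                continue
            raise
        row = {
            "patient_id": frame.patient_id,
            "ear_id": frame.ear_id,
            "frame_index": frame.frame_index,
            "label": frame.label,
        }
        row.update({c: feats[c] for c in cols})
        rows.append(row)
    if n_dropped:
        log.warning("dropped %d frames with empty ROI masks", n_dropped)
    table = pd.DataFrame(rows, columns=list(ID_COLUMNS) + list(cols))
    table.attrs["input_set"] = input_set
    table.attrs["n_dropped_empty_roi"] = n_dropped
    return table


def featurize_dataset(
    manifest: Manifest,
    root: str | Path = ".",
    input_set: str = "set2",
    masks: Mapping[tuple[str, int], ROIMask] | None = None,
) -> pd.DataFrame:
    """Featurize every manifest frame.

    Masks come either from the manifest's ``mask_path`` column or from an
    explicit ``masks`` mapping keyed by ``(ear_id, frame_index)`` (e.g.
    predictions from a segmenter).
    """
    from .dataio import read_frame, read_mask

    root = Path(root)
    pairs = []
    for _, row in manifest.rows.iterrows():
        frame = read_frame(
            root / row["frame_path"],
            patient_id=row["patient_id"],
            ear_id=row["ear_id"],
            frame_index=int(row["frame_index"]),
            label=row["label"],
        )
        key = (row["ear_id"], int(row["frame_index"]))
        if masks is not None:
            mask = masks[key]
        else:
            if not row["mask_path"]:
                raise FileNotFoundError(f"no mask for frame {key}")
            mask = read_mask(root / row["mask_path"])
        pairs.append((frame, mask))
    return featurize_frames(pairs, input_set=input_set)
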