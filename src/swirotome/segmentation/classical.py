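"""Classical (non-learned) ROI segmentation baselines.

Six methods: static thresholding, adaptive (local) thresholding, K-means on
intensities, Hough circle selection, morphological active contours, and
blurred-parts detection (low local variance exclusion).  Defaults are
deliberately conservative: each method prefers missing ROI pixels over
admitting non-ROI pixels.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import filters, segmentation, transform
from skimage.segmentation import morphological_chan_vese

from ..dataio import MAX_COUNT, Frame, ROIMask

METHODS = (
    "static_threshold",
    "adaptive_threshold",
    "kmeans",
    "hough_circle",
    "active_contour",
    "blur_detect",
)


def segment_classical(frame: Frame, method: str, **params) -> ROIMask:
    """Dispatch to one classical segmentation method.

    All methods are deterministic given their parameters (K-means is
    seeded).  Unknown method names or invalid parameters raise
    ``ValueError``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    px = frame.pixels.astype(float)
    mask = _DISPATCH[method](px, **params)
    return ROIMask(mask, provenance=f"classical:{method}")


def _static_threshold(px: np.ndarray, threshold: float = 8500.0) -> np.ndarray:
    if not 0 <= threshold <= MAX_COUNT:
        raise ValueError(f"threshold must be in [0, {MAX_COUNT}]")
    return px > threshold


def _adaptive_threshold(
    px: np.ndarray, window: int = 101, offset: float = -1200.0
) -> np.ndarray:
    # pixel is ROI when above its local mean minus offset (negative offset
    # demands a margin above the local mean: conservative)
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    local = filters.threshold_local(px, block_size=window, method="mean",
                                    offset=offset)
    return px > local


def _kmeans(px: np.ndarray, k: int = 3, seed: int = 0) -> np.ndarray:
    """1-D k-means on intensities; the brightest cluster is the ROI."""
    if k < 2:
        raise ValueError("k must be >= 2")
    v = px.ravel()
    rng = np.random.default_rng(seed)
    # deterministic quantile-based initialization, then Lloyd iterations
    centers = np.quantile(v, (np.arange(k) + 0.5) / k)
    centers = centers + rng.normal(0, 1e-9, k)  # break exact ties
    for _ in range(100):
        assign = np.argmin(np.abs(v[:, None] - centers[None, :]), axis=1)
        new = np.array([
            v[assign == j].mean() if np.any(assign == j) else centers[j]
            for j in range(k)
        ])
        if np.allclose(new, centers):
            centers = new
            break
        centers = new
    bright = int(np.argmax(centers))
    assign = np.argmin(np.abs(v[:, None] - centers[None, :]), axis=1)
    return (assign == bright).reshape(px.shape)


def _hough_circle(
    px: np.ndarray,
    radius_fractions: tuple[float, float] = (0.30, 0.46),
    n_radii: int = 10,
) -> np.ndarray:
    """Fill the strongest circle on the binarized membrane boundary.

    The circle locks onto one boundary arc of the (elliptical) membrane,
    so it sits inside the disc and under-covers the ROI.
    """
    lo, hi = radius_fractions
    if not 0 < lo < hi:
        raise ValueError("radius_fractions must satisfy 0 < lo < hi")
    binary = px > filters.threshold_otsu(px)
    edges = segmentation.find_boundaries(binary, mode="outer")
    rmin = int(lo * min(px.shape))
    rmax = int(hi * min(px.shape))
    radii = np.unique(np.linspace(rmin, rmax, n_radii).astype(int))
    h = transform.hough_circle(edges, radii)
    _, cx, cy, found = transform.hough_circle_peaks(h, radii, total_num_peaks=1)
    mask = np.zeros(px.shape, dtype=bool)
    if len(found) == 0:
        return mask
    rr, cc = np.mgrid[0 : px.shape[0], 0 : px.shape[1]]
    mask = (rr - cy[0]) ** 2 + (cc - cx[0]) ** 2 <= found[0] ** 2
    return mask


def _active_contour(
    px: np.ndarray, iterations: int = 35, contract_px: int = 15
) -> np.ndarray:
    """Morphological Chan–Vese; the brighter phase, contracted, is the ROI.

    ``contract_px`` erodes the converged region so the boundary band stays
    outside the mask (conservative).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if contract_px < 0:
        raise ValueError("contract_px must be >= 0")
    norm = px / max(px.max(), 1.0)
    ls = morphological_chan_vese(norm, num_iter=iterations,
                                 init_level_set="checkerboard")
    inside = ls.astype(bool)
    if not inside.any() or inside.all():
        return inside
    if norm[inside].mean() < norm[~inside].mean():
        inside = ~inside
    if contract_px:
        inside = ndimage.binary_erosion(inside, iterations=contract_px)
    return inside


def _blur_detect(
    px: np.ndarray, window: int = 9, std_threshold: float = 230.0
) -> np.ndarray:
    """Exclude low-local-variance (blurred or flat) pixels from the ROI."""
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    mean = ndimage.uniform_filter(px, size=window)
    sq = ndimage.uniform_filter(px * px, size=window)
    local_var = np.maximum(sq - mean * mean, 0.0)
    return np.sqrt(local_var) > std_threshold


_DISPATCH = {
    "static_threshold": _static_threshold,
    "adaptive_threshold": _adaptive_threshold,
    "kmeans": _kmeans,
    "hough_circle": _hough_circle,
    "active_contour": _active_contour,
    "blur_detect": _blur_detect,
}
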