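"""Synthetic SWIR otoscopy cohort generator.

Produces per-ear clips of grayscale frames with ground-truth ROI masks and
effusion labels.  The generative model is deliberately simple: an elliptical
membrane disc carrying smooth low-frequency texture around a per-ear
baseline intensity, a radial vignette, multiplicative AR(1) frame-to-frame
flicker, and composited artifacts (cerumen blobs, hair strokes, a defocus
band, dark unlit border) that are excluded from the ground-truth ROI.
Effusion lowers the baseline and (optionally) boosts texture dispersion.

Everything is a pure function of ``(config.seed, ear index, frame_index)``,
so cohorts are byte-reproducible and individual frames can be re-rendered
in isolation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy import ndimage

from .dataio import (
    MAX_COUNT,
    Frame,
    Manifest,
    ROIMask,
    build_manifest,
    write_frame,
    write_mask,
    write_manifest,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator parameters; see module docstring for the model."""

    n_ears: int = 55
    prevalence: float = 0.35
    frames_per_ear: tuple[int, int] = (20, 22)
    frame_shape: tuple[int, int] = (256, 320)  # rows x cols (320x256 sensor)
    base_level: float = 9000.0
    effusion_shift: float = 2200.0
    ear_sd: float = 1300.0
    texture_sd: float = 450.0
    texture_ear_jitter: float = 0.3  # lognormal sigma on per-ear texture sd
    heterogeneity_boost: float = 1.8
    cerumen_rate: float = 1.5  # Poisson mean blobs per ear
    hair_rate: float = 1.2  # Poisson mean strokes per ear
    defocus_prob: float = 0.6  # probability of a defocus band per ear
    flicker_rho: float = 0.8
    flicker_sd: float = 0.06
    noise_sd: float = 120.0  # white per-pixel sensor noise, whole frame
    vignette_range: tuple[float, float] = (0.15, 0.3)  # per-ear radial falloff
    border_px: int = 4  # unlit border ring excluded from the ROI
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.effusion_shift < 0:
            raise ValueError("effusion_shift must be >= 0")
        if self.base_level - self.effusion_shift < 0:
            raise ValueError("base_level - effusion_shift must be >= 0")
        for name in ("ear_sd", "texture_sd", "cerumen_rate", "hair_rate",
                     "defocus_prob", "flicker_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_ears < 2:
            raise ValueError("n_ears must be >= 2")
        lo, hi = self.frames_per_ear
        if lo < 1 or hi < lo:
            raise ValueError("frames_per_ear must be a nondecreasing positive range")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self)))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("frames_per_ear", "frame_shape", "vignette_range"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass(frozen=True)
class EarState:
    """Realized per-ear random effects and artifact layout."""

    ear_id: str
    patient_id: str
    label: str  # {"effusion", "no_effusion"}
    baseline: float  # realized mean ROI intensity
    texture_sd: float  # realized texture dispersion (boost applied)
    disc_center: tuple[float, float]
    disc_axes: tuple[float, float]  # semi-axes (rows, cols)
    vignette: float
    cerumen: tuple[tuple[float, float, float, float], ...]  # (r, c, ar, ac)
    hairs: tuple[tuple[float, float, float, float], ...]  # (r0, c0, r1, c1)
    defocus_band: Optional[tuple[float, float, float]]  # (angle, offset, halfwidth)
    flicker_gains: tuple[float, ...]
    entropy: int  # per-ear RNG root
    config: SyntheticConfig = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.label not in ("effusion", "no_effusion"):
            raise ValueError("label must be effusion/no_effusion")
        if not 0 <= self.baseline <= MAX_COUNT:
            raise ValueError("baseline outside 14-bit range")


_MAX_FRAMES = 64  # flicker gains precomputed up to this index
_MAX_LAYOUT_RETRIES = 10  # artifact layouts leaving < 10% ROI are redrawn


def _draw_artifact_layout(erng, config, shape, center, axes):
    """Draw cerumen blobs, hair strokes and the defocus band for one ear.

    Layouts whose ground-truth ROI would fall below 10% of the frame are
    resampled (bounded retries).
    """
    nr, nc = shape
    for attempt in range(_MAX_LAYOUT_RETRIES):
        n_cer = erng.poisson(config.cerumen_rate)
        cerumen = tuple(
            (
                float(erng.uniform(center[0] - axes[0], center[0] + axes[0])),
                float(erng.uniform(center[1] - axes[1], center[1] + axes[1])),
                float(erng.uniform(0.03, 0.08) * nr),
                float(erng.uniform(0.03, 0.08) * nc),
            )
            for _ in range(n_cer)
        )
        n_hair = erng.poisson(config.hair_rate)
        hairs = tuple(
            (
                float(erng.uniform(0, nr)),
                float(erng.uniform(0, nc)),
                float(erng.uniform(0, nr)),
                float(erng.uniform(0, nc)),
            )
            for _ in range(n_hair)
        )
        defocus = None
        if erng.uniform() < config.defocus_prob:
            defocus = (
                float(erng.uniform(0, np.pi)),
                float(erng.uniform(-0.25, 0.25) * min(nr, nc)),
                float(erng.uniform(0.06, 0.14) * min(nr, nc)),
            )
        disc = _disc_mask(shape, center, axes)
        fp = _footprints(cerumen, hairs, defocus, shape)
        roi = disc & ~fp["cerumen"] & ~fp["hair"] & ~fp["defocus"]
        roi &= ~_border_ring(disc, config.border_px)
        if roi.sum() >= 0.10 * roi.size:
            return cerumen, hairs, defocus
    raise RuntimeError(
        f"could not draw an artifact layout leaving >= 10% ROI in "
        f"{_MAX_LAYOUT_RETRIES} attempts"
    )


def _ear_entropy(seed: int, ear_index: int) -> int:
    # stable across processes (no reliance on PYTHONHASHSEED)
    h = hashlib.sha256(f"{seed}:{ear_index}".encode()).digest()
    return int.from_bytes(h[:8], "big")


def sample_cohort(config: SyntheticConfig) -> list[EarState]:
    """Draw the per-ear states for one cohort.

    The number of effusion ears is exactly ``round(n_ears * prevalence)``;
    baselines are ``base_level (- effusion_shift) + N(0, ear_sd)`` clipped
    to the 14-bit range.  Fully determined by ``config.seed``.
    """
    n_eff = int(round(config.n_ears * config.prevalence))
    if n_eff == 0 or n_eff == config.n_ears:
        raise ValueError(
            f"prevalence {config.prevalence} leaves a class empty for "
            f"n_ears={config.n_ears}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    labels = np.array(["effusion"] * n_eff + ["no_effusion"] * (config.n_ears - n_eff))
    rng.shuffle(labels)

    nr, nc = config.frame_shape
    ears: list[EarState] = []
    for i in range(config.n_ears):
        ent = _ear_entropy(config.seed, i)
        erng = np.random.default_rng(np.random.SeedSequence([ent, 1]))
        label = str(labels[i])
        mean = config.base_level - (config.effusion_shift if label == "effusion" else 0.0)
        baseline = float(np.clip(mean + erng.normal(0.0, config.ear_sd), 0, MAX_COUNT))
        tex_sd = config.texture_sd * float(
            np.exp(erng.normal(0.0, config.texture_ear_jitter))
        )
        if label == "effusion":
            tex_sd *= config.heterogeneity_boost
        center = (
            nr / 2 + erng.uniform(-0.04, 0.04) * nr,
            nc / 2 + erng.uniform(-0.04, 0.04) * nc,
        )
        axes = (
            nr * erng.uniform(0.36, 0.42),
            nc * erng.uniform(0.38, 0.44),
        )
        vignette = float(erng.uniform(*config.vignette_range))
        cerumen, hairs, defocus = _draw_artifact_layout(
            erng, config, (nr, nc), center, axes
        )
        # AR(1) multiplicative flicker, stationary initialization
        frng = np.random.default_rng(np.random.SeedSequence([ent, 2]))
        gains = np.empty(_MAX_FRAMES)
        if config.flicker_sd > 0:
            x = frng.normal(0.0, config.flicker_sd)
            innov_sd = config.flicker_sd * np.sqrt(max(1 - config.flicker_rho**2, 0.0))
            for t in range(_MAX_FRAMES):
                gains[t] = 1.0 + x
                x = config.flicker_rho * x + frng.normal(0.0, innov_sd)
        else:
            gains[:] = 1.0
        ears.append(
            EarState(
                ear_id=f"E{i:03d}",
                patient_id=f"P{i // 2:03d}",
                label=label,
                baseline=baseline,
                texture_sd=tex_sd,
                disc_center=center,
                disc_axes=axes,
                vignette=vignette,
                cerumen=cerumen,
                hairs=hairs,
                defocus_band=defocus,
                flicker_gains=tuple(gains),
                entropy=ent,
                config=config,
            )
        )
    return ears


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _disc_mask(shape, center, axes) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _footprints(cerumen, hairs, defocus_band, shape) -> dict[str, np.ndarray]:
    """Binary footprints of every artifact class, for compositing and truth."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    cer = np.zeros(shape, dtype=bool)
    for r0, c0, ar, ac in cerumen:
        cer |= ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0
    hair = np.zeros(shape, dtype=bool)
    for r0, c0, r1, c1 in hairs:
        d = np.hypot(r1 - r0, c1 - c0)
        if d < 1:
            continue
        # distance from each pixel to the segment, thin stroke ~2 px
        t = np.clip(((rr - r0) * (r1 - r0) + (cc - c0) * (c1 - c0)) / d**2, 0, 1)
        dist = np.hypot(rr - (r0 + t * (r1 - r0)), cc - (c0 + t * (c1 - c0)))
        hair |= dist <= 1.5
    defocus = np.zeros(shape, dtype=bool)
    if defocus_band is not None:
        angle, offset, halfwidth = defocus_band
        proj = (rr - shape[0] / 2) * np.cos(angle) + (cc - shape[1] / 2) * np.sin(angle)
        defocus = np.abs(proj - offset) <= halfwidth
    return {"cerumen": cer, "hair": hair, "defocus": defocus}


def _artifact_footprints(ear: EarState, shape) -> dict[str, np.ndarray]:
    return _footprints(ear.cerumen, ear.hairs, ear.defocus_band, shape)


def _border_ring(disc: np.ndarray, width: int = 4) -> np.ndarray:
    """Unlit outer ring of the membrane disc (excluded from the ROI)."""
    if width <= 0:
        return np.zeros_like(disc)
    eroded = ndimage.binary_erosion(disc, iterations=width)
    return disc & ~eroded


def ground_truth_roi(ear: EarState, shape) -> np.ndarray:
    """ROI = membrane disc minus artifacts, defocus band and unlit border."""
    disc = _disc_mask(shape, ear.disc_center, ear.disc_axes)
    fp = _artifact_footprints(ear, shape)
    roi = disc & ~fp["cerumen"] & ~fp["hair"] & ~fp["defocus"]
    roi &= ~_border_ring(disc, ear.config.border_px)
    return roi


def render_frame(
    ear: EarState,
    frame_index: int,
    rng: np.random.Generator | None = None,
) -> tuple[Frame, ROIMask]:
    """Render one frame and its ground-truth ROI mask.

    With ``rng=None`` (the default) the per-frame noise stream is derived
    from ``(ear.entropy, frame_index)``, making the output a pure function
    of the ear state and index.
    """
    config = ear.config
    shape = config.frame_shape
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([ear.entropy, 3, frame_index]))

    disc = _disc_mask(shape, ear.disc_center, ear.disc_axes)
    fp = _artifact_footprints(ear, shape)
    roi = disc & ~fp["cerumen"] & ~fp["hair"] & ~fp["defocus"]
    roi &= ~_border_ring(disc, config.border_px)
    if roi.sum() < 0.10 * roi.size:
        raise RuntimeError(
            f"ground-truth ROI below 10% of the frame for ear {ear.ear_id}"
        )

    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    # dark background (ear canal / unlit surround)
    frame = np.full(shape, 350.0)

    # membrane disc: baseline x radial vignette + smooth texture
    radius2 = ((rr - ear.disc_center[0]) / ear.disc_axes[0]) ** 2 + (
        (cc - ear.disc_center[1]) / ear.disc_axes[1]
    ) ** 2
    vig = 1.0 - ear.vignette * np.clip(radius2, 0, 1)
    if ear.texture_sd > 0:
        tex = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=6.0)
        sd = tex.std()
        if sd > 0:
            tex *= ear.texture_sd / sd
    else:
        tex = np.zeros(shape)
    membrane = ear.baseline * vig + tex
    frame = np.where(disc, membrane, frame)
    if config.noise_sd > 0:  # white sensor noise; the defocus blur removes it
        frame = frame + config.noise_sd * rng.standard_normal(shape)

    # artifacts darken whatever they cover
    frame = np.where(fp["cerumen"], frame * 0.30, frame)
    frame = np.where(fp["hair"], frame * 0.25, frame)
    if fp["defocus"].any():
        blurred = ndimage.gaussian_filter(frame, sigma=7.0)
        frame = np.where(fp["defocus"], blurred, frame)

    gain = ear.flicker_gains[min(frame_index, _MAX_FRAMES - 1)]
    frame = frame * gain

    pixels = np.clip(np.rint(frame), 0, MAX_COUNT).astype(np.uint16)
    fr = Frame(
        pixels,
        patient_id=ear.patient_id,
        ear_id=ear.ear_id,
        frame_index=frame_index,
        label=ear.label,
    )
    return fr, ROIMask(roi, provenance="annotation")


def clip_plan(ear: EarState, config: SyntheticConfig) -> tuple[int, int]:
    """(start_index, n_frames) of the ear's consecutive clip."""
    crng = np.random.default_rng(np.random.SeedSequence([ear.entropy, 4]))
    lo, hi = config.frames_per_ear
    n_frames = int(crng.integers(lo, hi + 1))
    start = int(crng.integers(0, max(_MAX_FRAMES - n_frames, 1)))
    return start, n_frames


def cohort_plan(config: SyntheticConfig) -> "pd.DataFrame":
    """Per-ear bookkeeping (label, clip start, frame count) without rendering."""
    import pandas as pd

    rows = []
    for ear in sample_cohort(config):
        start, n_frames = clip_plan(ear, config)
        rows.append(
            {
                "ear_id": ear.ear_id,
                "patient_id": ear.patient_id,
                "label": ear.label,
                "start": start,
                "n_frames": n_frames,
            }
        )
    return pd.DataFrame(rows)


def iter_cohort_frames(config: SyntheticConfig):
    """Yield ``(EarState, Frame, ROIMask)`` for every frame of the cohort.

    Frame counts per ear are drawn from ``config.frames_per_ear`` and clip
    start indices are randomized, both deterministically from the seed.
    """
    for ear in sample_cohort(config):
        start, n_frames = clip_plan(ear, config)
        for j in range(n_frames):
            frame, mask = render_frame(ear, start + j)
            yield ear, frame, mask


def generate_dataset(config: SyntheticConfig, outdir: str | Path) -> Manifest:
    """Render the whole cohort to ``outdir`` and write its manifest CSV.

    Layout: ``frames/<ear>_<index>.png`` (16-bit), ``masks/...png`` (8-bit
    {0,1}) and ``manifest.csv`` at the top level.
    """
    outdir = Path(outdir)
    (outdir / "frames").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for ear, frame, mask in iter_cohort_frames(config):
        stem = f"{ear.ear_id}_{frame.frame_index:04d}"
        fpath = outdir / "frames" / f"{stem}.png"
        mpath = outdir / "masks" / f"{stem}.png"
        write_frame(frame, fpath)
        write_mask(mask, mpath)
        rows.append(
            {
                "frame_path": str(fpath.relative_to(outdir)),
                "mask_path": str(mpath.relative_to(outdir)),
                "patient_id": ear.patient_id,
                "ear_id": ear.ear_id,
                "frame_index": frame.frame_index,
                "label": ear.label,
                "subset_tag": "frame_range",
            }
        )
    manifest = build_manifest(rows)
    write_manifest(manifest, outdir / "manifest.csv")
    config.to_yaml(outdir / "config.yaml")
    return manifest
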