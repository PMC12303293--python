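"""Seeded generator of lesion-like images and PAD-UFES-20-schema metadata.

The generator emulates the two modalities the pipeline consumes, so every
stage is testable without downloading data:

* **Images** — a lighter skin-toned background with a smooth illumination
  gradient and pixel noise, one multifocal lesion (a cluster of small
  hard-edged pigmented lobes over an elliptical extent), plus optional thin
  dark hair strokes that exercise the black-hat transform.  Lesion
  contrast, extent and lobe-size irregularity are class-conditional, which
  is the planted image signal.
* **Metadata** — all 26 schema columns with class-conditional clinical
  distributions (age, cancer history, Fitzpatrick type, diameters, symptom
  booleans) and per-column missingness at the ~35% rate of the real
  lifestyle/demographic columns.

Everything is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk, line_aa

from .imaging import CLASS_NAMES, decode_class

__all__ = [
    "SynthConfig",
    "LesionMasks",
    "SynthDataset",
    "generate_lesion_image",
    "generate_clinical_record",
    "generate_dataset",
    "class_counts_from_mix",
]

#: Class proportions of the real 2298-lesion collection
#: (ACK 730, BCC 845, MEL 52, NEV 244, SCC 192, SEK 235).
DEFAULT_CLASS_MIX = (730 / 2298, 845 / 2298, 52 / 2298, 244 / 2298, 192 / 2298, 235 / 2298)

#: Columns carrying ~35% missing cells in the real metadata.
MISSING_COLUMNS = (
    "smoke", "drink", "background_father", "background_mother", "age",
    "pesticide", "gender", "skin_cancer_history", "cancer_history",
    "has_piped_water", "has_sewage_system", "region", "diameter_1",
    "diameter_2",
)

_BACKGROUNDS = ("POMERANIA", "GERMANY", "BRAZIL", "ITALY", "PORTUGAL", "NETHERLANDS", "SPAIN")
_BACKGROUND_P = (0.35, 0.15, 0.20, 0.10, 0.10, 0.05, 0.05)
#: Radius of one pigmented lobe and the minimum spacing between lobe
#: centres; lobes smaller than the thresholding window are what keeps the
#: lesion segmentable by a local mean.
LOBE_RADIUS = 4.0
LOBE_MIN_SPACING = 9.0

_REGIONS = (
    "FACE", "SCALP", "NOSE", "EAR", "NECK", "CHEST", "BACK", "ABDOMEN",
    "ARM", "FOREARM", "HAND", "THIGH", "SHIN", "FOOT", "LIP",
)

# Class-conditional clinical profiles, indexed ACK, BCC, MEL, NEV, SCC, SEK.
_AGE_MEAN = (57.0, 63.0, 54.0, 34.0, 67.0, 59.0)
_AGE_SD = 9.0
_P_SKIN_CANCER_HISTORY = (0.45, 0.60, 0.50, 0.10, 0.65, 0.30)
_P_CANCER_HISTORY = (0.35, 0.50, 0.45, 0.15, 0.55, 0.30)
_FITZPATRICK_MEAN = (2.2, 2.0, 2.1, 3.0, 1.8, 2.6)
_FITZPATRICK_SD = 0.9
_DIAMETER_MEAN = (9.0, 11.0, 7.0, 5.0, 14.0, 10.0)
_P_ITCH = (0.60, 0.40, 0.25, 0.10, 0.50, 0.45)
_P_GREW = (0.50, 0.60, 0.70, 0.15, 0.70, 0.30)
_P_HURT = (0.20, 0.30, 0.15, 0.05, 0.45, 0.10)
_P_CHANGED = (0.30, 0.40, 0.60, 0.10, 0.50, 0.20)
_P_BLED = (0.15, 0.45, 0.30, 0.05, 0.50, 0.10)
_P_ELEVATION = (0.30, 0.70, 0.50, 0.40, 0.60, 0.75)
_P_BIOPSIED = (0.60, 0.95, 0.95, 0.50, 0.95, 0.55)


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic cohort.

    Class-conditional image parameters follow ``base + step * class_code``
    with uniform jitter, e.g. the blob darkness contrast of class k is drawn
    from ``contrast_base + contrast_step*k ± contrast_jitter``.
    ``signal_strength`` scales the deviation of every clinical profile from
    its across-class mean (0 = identical distributions for all classes).
    """

    n_samples: int = 120
    class_mix: tuple[float, ...] = DEFAULT_CLASS_MIX
    image_side: int = 224
    blob_radius_base: float = 9.0
    blob_radius_step: float = 1.2
    blob_radius_jitter: float = 1.0
    contrast_base: float = 105.0
    contrast_step: float = 8.0
    contrast_jitter: float = 6.0
    irregularity_base: float = 0.04
    irregularity_step: float = 0.015
    hair_count_max: int = 6
    hair_thickness: int = 2
    hair_darkness: tuple[float, float] = (60.0, 110.0)
    illumination: float = 20.0
    noise_sigma: float = 4.0
    missing_rate: float = 0.35
    signal_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_mix) != len(CLASS_NAMES):
            raise ValueError("class_mix needs one proportion per class")
        if abs(sum(self.class_mix) - 1.0) > 1e-6:
            raise ValueError("class_mix must sum to 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.image_side < 32:
            raise ValueError("image_side too small for a lesion blob")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")

    @staticmethod
    def strong_signal(n_samples: int = 600, seed: int = 0) -> "SynthConfig":
        """Well-separated class signal in both modalities.

        Contrast bands per class become disjoint and clinical effect sizes
        are amplified; used for planted-signal-recovery checks.
        """
        return SynthConfig(
            n_samples=n_samples,
            contrast_step=14.0,
            contrast_jitter=3.0,
            blob_radius_step=2.0,
            blob_radius_jitter=0.5,
            hair_count_max=0,
            signal_strength=1.3,
            seed=seed,
        )


@dataclasses.dataclass(frozen=True)
class LesionMasks:
    """Ground-truth pixel masks of a generated image."""

    blob: np.ndarray  # bool, lesion interior
    hair: np.ndarray  # bool, hair-stroke pixels


@dataclasses.dataclass
class SynthDataset:
    """In-memory paired dataset: images, masks, metadata table, labels."""

    images: np.ndarray  # (n, side, side, 3) uint8
    masks: list[LesionMasks]
    metadata: pd.DataFrame
    labels: np.ndarray
    config: SynthConfig

    @property
    def img_ids(self) -> list[str]:
        return list(self.metadata["img_id"])


def class_counts_from_mix(n: int, mix) -> np.ndarray:
    """Largest-remainder apportionment of ``n`` samples over the classes."""
    mix = np.asarray(mix, dtype=float)
    exact = n * mix
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    short = n - counts.sum()
    for c in np.argsort(-remainder)[:short]:
        counts[c] += 1
    return counts


def _blend(profile, strength: float) -> np.ndarray:
    """Scale a class-conditional profile about its across-class mean."""
    p = np.asarray(profile, dtype=float)
    return p.mean() + strength * (p - p.mean())


def generate_lesion_image(
    cfg: SynthConfig, cls: int, seed: int
) -> tuple[np.ndarray, LesionMasks]:
    """One synthetic lesion photograph plus its ground-truth masks.

    Deterministic per ``(cfg, cls, seed)``.
    """
    cls = int(cls)
    if not 0 <= cls < len(CLASS_NAMES):
        raise ValueError(f"class code {cls} out of range")
    rng = np.random.default_rng(seed)
    side = cfg.image_side

    # skin-toned background sampled across a range of base colours
    r0 = rng.uniform(200.0, 235.0)
    g0 = r0 - rng.uniform(20.0, 35.0)
    b0 = g0 - rng.uniform(15.0, 30.0)
    img = np.empty((side, side, 3), dtype=np.float64)
    img[:, :, 0], img[:, :, 1], img[:, :, 2] = r0, g0, b0

    # smooth illumination gradient in a random direction
    phi = rng.uniform(0.0, 2.0 * np.pi)
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    ramp = (np.cos(phi) * xx + np.sin(phi) * yy) / side
    img += cfg.illumination * (ramp - ramp.mean())[:, :, None]

    # Class-conditional lesion: a cluster of small, hard-edged pigmented
    # lobes scattered over an elliptical extent.  Each lobe stays below the
    # adaptive-threshold window scale, so every lesion pixel sits well
    # under its background-dominated local mean (one large uniform blob
    # would locally look flat and threshold white in its interior).
    extent = cfg.blob_radius_base + cfg.blob_radius_step * cls \
        + rng.uniform(-cfg.blob_radius_jitter, cfg.blob_radius_jitter)
    contrast = cfg.contrast_base + cfg.contrast_step * cls \
        + rng.uniform(-cfg.contrast_jitter, cfg.contrast_jitter)
    irregularity = cfg.irregularity_base + cfg.irregularity_step * cls
    cy, cx = rng.uniform(0.35 * side, 0.65 * side, size=2)
    aspect = rng.uniform(0.75, 1.0)
    n_lobes = max(3, int(round(0.8 * (extent / LOBE_RADIUS) ** 2)))
    depth = np.zeros((side, side))
    blob = np.zeros((side, side), dtype=bool)
    centers: list[tuple[float, float]] = []
    for _ in range(n_lobes):
        for _attempt in range(20):  # keep lobes from piling up
            rho = extent * np.sqrt(rng.uniform())
            ang = rng.uniform(0.0, 2.0 * np.pi)
            ly = cy + rho * np.sin(ang) * aspect
            lx = cx + rho * np.cos(ang)
            if all((ly - py) ** 2 + (lx - px) ** 2 >= LOBE_MIN_SPACING**2
                   for py, px in centers):
                break
        centers.append((ly, lx))
        lobe_r = LOBE_RADIUS * (1.0 + irregularity * rng.uniform(-3.0, 3.0))
        rr, cc = draw_disk((ly, lx), max(lobe_r, 1.5), shape=(side, side))
        lobe_depth = contrast * (1.0 + rng.uniform(-0.08, 0.08))
        depth[rr, cc] = np.maximum(depth[rr, cc], lobe_depth)
        blob[rr, cc] = True
    # brownish darkening: green/blue drop slightly more than red
    img -= depth[:, :, None] * np.array([0.9, 1.0, 1.05])

    # hair-like dark strokes
    hair = np.zeros((side, side), dtype=bool)
    n_hair = int(rng.integers(0, cfg.hair_count_max + 1))
    for _ in range(n_hair):
        y0, x0 = rng.uniform(0, side, size=2)
        angle = rng.uniform(0.0, np.pi)
        length = rng.uniform(0.3 * side, 0.8 * side)
        y1 = y0 + length * np.sin(angle)
        x1 = x0 + length * np.cos(angle)
        pts = np.clip(np.array([y0, x0, y1, x1]), 0, side - 1).astype(int)
        darkness = rng.uniform(*cfg.hair_darkness)
        for off in range(cfg.hair_thickness):
            rr, cc, val = line_aa(pts[0], pts[1] + off, pts[2], pts[3] + off)
            keep = (cc >= 0) & (cc < side) & (rr >= 0) & (rr < side)
            rr, cc, val = rr[keep], cc[keep], val[keep]
            img[rr, cc] -= (darkness * val)[:, None]
            hair[rr, cc] |= val > 0.5

    img += rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return img, LesionMasks(blob=blob, hair=hair)


def generate_clinical_record(
    cfg: SynthConfig,
    cls: int,
    seed: int,
    patient_id: str = "PAT_1",
    lesion_id: int = 1,
    img_id: str = "PAT_1_1_000",
) -> dict:
    """One metadata row (all 26 schema columns) for a lesion of class ``cls``.

    Class-conditional fields are drawn from the per-class profiles scaled by
    ``cfg.signal_strength``; missing cells are then punched per column at
    ``cfg.missing_rate``.  Deterministic per ``(cfg, cls, seed)``.
    """
    cls = int(cls)
    rng = np.random.default_rng(seed)
    s = cfg.signal_strength

    def p_of(profile) -> float:
        return float(np.clip(_blend(profile, s)[cls], 0.01, 0.99))

    def bern(profile) -> bool:
        return bool(rng.random() < p_of(profile))

    age = float(np.clip(rng.normal(_blend(_AGE_MEAN, s)[cls], _AGE_SD), 6, 95))
    fitz = int(np.clip(
        np.floor(rng.normal(_blend(_FITZPATRICK_MEAN, s)[cls], _FITZPATRICK_SD) + 0.5),
        1, 6,
    ))
    d_mean = float(np.clip(_blend(_DIAMETER_MEAN, s)[cls], 1.0, None))
    diameter_1 = float(np.clip(rng.normal(d_mean, 0.3 * d_mean), 0.5, 60.0))
    diameter_2 = diameter_1 * rng.uniform(0.6, 1.0)

    record = {
        "patient_id": patient_id,
        "lesion_id": lesion_id,
        "smoke": bool(rng.random() < 0.20),
        "drink": bool(rng.random() < 0.30),
        "background_father": str(rng.choice(_BACKGROUNDS, p=_BACKGROUND_P)),
        "background_mother": str(rng.choice(_BACKGROUNDS, p=_BACKGROUND_P)),
        "age": round(age),
        "pesticide": bool(rng.random() < 0.25),
        "gender": "MALE" if rng.random() < 0.55 else "FEMALE",
        "skin_cancer_history": bern(_P_SKIN_CANCER_HISTORY),
        "cancer_history": bern(_P_CANCER_HISTORY),
        "has_piped_water": bool(rng.random() < 0.85),
        "has_sewage_system": bool(rng.random() < 0.80),
        "fitzpatrick": fitz,
        "region": str(rng.choice(_REGIONS)),
        "diameter_1": round(diameter_1, 1),
        "diameter_2": round(diameter_2, 1),
        "diagnostic": decode_class(cls),
        "itch": bern(_P_ITCH),
        "grew": bern(_P_GREW),
        "hurt": bern(_P_HURT),
        "changed": bern(_P_CHANGED),
        "bled": bern(_P_BLED),
        "elevation": bern(_P_ELEVATION),
        "img_id": img_id,
        "biopsied": bern(_P_BIOPSIED),
    }

    for col in MISSING_COLUMNS:
        if rng.random() < cfg.missing_rate:
            record[col] = np.nan
    return record


def generate_dataset(cfg: SynthConfig, out_dir: str | Path | None = None) -> SynthDataset:
    """Paired, id-linked images and metadata for ``cfg.n_samples`` lesions.

    Class counts follow ``cfg.class_mix`` by largest-remainder rounding.
    When ``out_dir`` is given, PNG images, ``metadata.csv`` (empty cells for
    missing values) and ``labels.csv`` are written there; regeneration with
    the same config reproduces identical bytes.
    """
    counts = class_counts_from_mix(cfg.n_samples, cfg.class_mix)
    labels = np.repeat(np.arange(len(CLASS_NAMES)), counts)

    master = np.random.default_rng(cfg.seed)
    img_seeds = master.integers(0, 2**31, size=cfg.n_samples)
    rec_seeds = master.integers(0, 2**31, size=cfg.n_samples)
    tags = master.integers(0, 1000, size=cfg.n_samples)

    images = np.empty((cfg.n_samples, cfg.image_side, cfg.image_side, 3), dtype=np.uint8)
    masks: list[LesionMasks] = []
    rows: list[dict] = []
    for i, cls in enumerate(labels):
        pid, lid = f"PAT_{i + 1}", i + 1
        img_id = f"PAT_{i + 1}_{lid}_{tags[i]:03d}"
        images[i], mask = generate_lesion_image(cfg, cls, int(img_seeds[i]))
        masks.append(mask)
        rows.append(
            generate_clinical_record(
                cfg, cls, int(rec_seeds[i]),
                patient_id=pid, lesion_id=lid, img_id=img_id,
            )
        )

    from .clinical import TABLE_COLUMNS

    metadata = pd.DataFrame(rows)[list(TABLE_COLUMNS)]
    dataset = SynthDataset(
        images=images, masks=masks, metadata=metadata, labels=labels, config=cfg
    )

    if out_dir is not None:
        out = Path(out_dir)
        img_dir = out / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
        from .imaging import save_image

        for i, img_id in enumerate(dataset.img_ids):
            save_image(img_dir / f"{img_id}.png", images[i])
        metadata.to_csv(out / "metadata.csv", index=False)
        pd.DataFrame(
            {"img_id": dataset.img_ids, "label": labels}
        ).to_csv(out / "labels.csv", index=False)
    return dataset
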