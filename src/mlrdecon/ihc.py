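"""Positive-pixel-count quantification of IHC staining.

Brightfield DAB staining absorbs light, so darker pixels mean stronger
staining.  Pixels of an 8-bit intensity channel are classified into four
bands at the standard thresholds — strong [0, 100], medium (100, 175],
weak (175, 220], negative (220, 255] — and summarized per region of interest
by two statistics:

* NSR, the number-of-strong-positive-pixels ratio: strong / (weak + medium +
  strong), a staining-density measure per positive area;
* the weighted score: (1*weak + 2*medium + 3*strong) / all pixels, a labeling
  intensity per unit region area in [0, 3].

Gland regions may carry unstained lumen whose pixels (above the weak
threshold) are excluded before scoring.  A pseudocolor rendering (blue /
yellow / orange / red for negative / weak / medium / strong) round-trips
losslessly back to the band counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


class EmptyRegionError(ValueError):
    """Mask selects no pixels."""


@dataclass(frozen=True)
class ThresholdConfig:
    """Intensity band bounds (upper bound inclusive toward stronger
    staining) and per-band weights."""

    weak_upper: int = 220
    medium_upper: int = 175
    strong_upper: int = 100
    weight_weak: int = 1
    weight_medium: int = 2
    weight_strong: int = 3
    colors: dict = field(
        default_factory=lambda: {
            "negative": (0, 0, 255),   # blue
            "weak": (255, 255, 0),     # yellow
            "medium": (255, 165, 0),   # orange
            "strong": (255, 0, 0),     # red
        }
    )

    def __post_init__(self) -> None:
        if not 0 <= self.strong_upper < self.medium_upper < self.weak_upper <= 255:
            raise ValueError("thresholds must satisfy 0 <= strong < medium < weak <= 255")


@dataclass(frozen=True)
class PixelClassCounts:
    """Per-region pixel counts by staining band."""

    region_id: str
    n_negative: int
    n_weak: int
    n_medium: int
    n_strong: int

    @property
    def total(self) -> int:
        return self.n_negative + self.n_weak + self.n_medium + self.n_strong

    @property
    def n_positive(self) -> int:
        return self.n_weak + self.n_medium + self.n_strong


def _as_uint8(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.dtype != np.uint8:
        log.warning("converting %s image to 8-bit", img.dtype)
        if np.issubdtype(img.dtype, np.floating) and img.max() <= 1.0:
            img = img * 255.0
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img


def band_image(image: np.ndarray, cfg: ThresholdConfig = ThresholdConfig()) -> np.ndarray:
    """Per-pixel band labels: 0 negative, 1 weak, 2 medium, 3 strong."""
    img = _as_uint8(image)
    bands = np.zeros(img.shape, np.uint8)
    bands[img <= cfg.weak_upper] = 1
    bands[img <= cfg.medium_upper] = 2
    bands[img <= cfg.strong_upper] = 3
    return bands


def classify_pixels(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    cfg: ThresholdConfig = ThresholdConfig(),
    region_id: str = "region",
) -> PixelClassCounts:
    """Count masked pixels per intensity band."""
    img = _as_uint8(image)
    if mask is None:
        mask = np.ones(img.shape, bool)
    if mask.shape != img.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise EmptyRegionError(f"mask for {region_id!r} selects no pixels")
    bands = band_image(img, cfg)[mask]
    counts = np.bincount(bands, minlength=4)
    return PixelClassCounts(
        region_id=region_id,
        n_negative=int(counts[0]),
        n_weak=int(counts[1]),
        n_medium=int(counts[2]),
        n_strong=int(counts[3]),
    )


def nsr(counts: PixelClassCounts) -> float:
    """Strong positive pixels over all positive pixels; NaN (flagged) when
    the region has no positive pixels."""
    if counts.n_positive == 0:
        log.warning("region %s has no positive pixels; NSR undefined", counts.region_id)
        return float("nan")
    return counts.n_strong / counts.n_positive


def weighted_score(counts: PixelClassCounts, cfg: ThresholdConfig = ThresholdConfig()) -> float:
    """Weighted positive pixels per unit region area, in [0, 3]."""
    if counts.total == 0:
        raise EmptyRegionError(f"region {counts.region_id!r} is empty")
    weighted = (
        cfg.weight_weak * counts.n_weak
        + cfg.weight_medium * counts.n_medium
        + cfg.weight_strong * counts.n_strong
    )
    return weighted / counts.total


def pseudocolor(image: np.ndarray, cfg: ThresholdConfig = ThresholdConfig()) -> np.ndarray:
    """RGB rendering with one fixed color per band."""
    bands = band_image(image, cfg)
    lut = np.array(
        [cfg.colors["negative"], cfg.colors["weak"], cfg.colors["medium"], cfg.colors["strong"]],
        np.uint8,
    )
    return lut[bands]


def bands_from_pseudocolor(rgb: np.ndarray, cfg: ThresholdConfig = ThresholdConfig()) -> np.ndarray:
    """Invert :func:`pseudocolor`: recover band labels from the colors."""
    lut = {tuple(v): k for k, v in enumerate(
        (cfg.colors["negative"], cfg.colors["weak"], cfg.colors["medium"], cfg.colors["strong"])
    )}
    flat = rgb.reshape(-1, 3)
    out = np.empty(flat.shape[0], np.uint8)
    for color, k in lut.items():
        out[(flat == color).all(axis=1)] = k
    return out.reshape(rgb.shape[:2])


def region_scores(
    image: np.ndarray,
    masks: dict[str, np.ndarray],
    cfg: ThresholdConfig = ThresholdConfig(),
    lumen_exclude_prefixes: tuple[str, ...] = ("gland",),
) -> pd.DataFrame:
    """Score a named set of regions.

    Regions whose name starts with one of ``lumen_exclude_prefixes`` get
    lumen exclusion: pixels above the weak threshold (unstained lumen /
    pseudolumen) are dropped from the mask before scoring.  Returns a table
    indexed by region name with band counts, NSR and weighted score.
    """
    if not masks:
        raise ValueError("no region masks supplied")
    img = _as_uint8(image)
    rows = []
    for name, mask in masks.items():
        mask = np.asarray(mask, bool)
        if mask.shape != img.shape:
            raise ValueError(f"mask {name!r} shape differs from image")
        if not mask.any():
            raise EmptyRegionError(f"mask {name!r} selects no pixels")
        if any(name.startswith(p) for p in lumen_exclude_prefixes):
            mask = mask & (img <= cfg.weak_upper)
            if not mask.any():
                raise EmptyRegionError(f"mask {name!r} empty after lumen exclusion")
        counts = classify_pixels(img, mask, cfg, region_id=name)
        rows.append(
            {
                "region": name,
                "n_negative": counts.n_negative,
                "n_weak": counts.n_weak,
                "n_medium": counts.n_medium,
                "n_strong": counts.n_strong,
                "nsr": nsr(counts),
                "weighted_score": weighted_score(counts, cfg),
            }
        )
    return pd.DataFrame(rows).set_index("region")


def compare_groups(scores_a, scores_b) -> tuple[float, float]:
    """Welch two-sample t-test (two-sided) between per-region score groups.

    Degenerate rule: both groups constant -> p = 1 when the means are equal,
    p = 0 otherwise.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
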