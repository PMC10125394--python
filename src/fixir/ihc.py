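"""Brightfield IHC quantitation: tissue segmentation, DAB positivity
classification by stain unmixing, percent positivity, hot-spot density
maps, and the rank-sum comparison across fixation-time groups."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SegmentationResult",
    "PositivityRecord",
    "segment_tissue",
    "classify_positive",
    "percent_positivity",
    "hotspot_map",
    "normalize_to_max",
    "ranksum_test",
    "HDAB_STAIN_VECTORS",
]

# H-DAB optical-density stain vectors (rows: hematoxylin, DAB, residual),
# the standard Ruifrok-Johnston values, unit-normalized.
_H = np.array([0.650, 0.704, 0.286])
_DAB = np.array([0.268, 0.570, 0.776])
_RES = np.cross(_H, _DAB)
HDAB_STAIN_VECTORS = np.vstack(
    [_H / np.linalg.norm(_H), _DAB / np.linalg.norm(_DAB), _RES / np.linalg.norm(_RES)]
)


@dataclass
class SegmentationResult:
    active_mask: np.ndarray
    excluded_mask: np.ndarray
    positive_mask: np.ndarray

    def __post_init__(self) -> None:
        for name in ("active_mask", "excluded_mask", "positive_mask"):
            setattr(self, name, np.asarray(getattr(self, name), bool))
        if np.any(self.active_mask & self.excluded_mask):
            raise ValueError("active and excluded masks overlap")
        if np.any(self.positive_mask & ~self.active_mask):
            raise ValueError("positive pixels must lie inside the active mask")


@dataclass(frozen=True)
class PositivityRecord:
    slide_id: str
    marker: str
    fixation_time: float
    percent_positive: float

    def __post_init__(self) -> None:
        if not 0 <= self.percent_positive <= 100:
            raise ValueError("percent_positive must be in [0, 100]")


def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image (H x W x 3)")
    if image.dtype == np.uint8:
        return image.astype(float) / 255.0
    return np.clip(image.astype(float), 0.0, 1.0)


def _local_std(channel: np.ndarray, size: int = 7) -> np.ndarray:
    from scipy.ndimage import uniform_filter

    mean = uniform_filter(channel, size)
    sq = uniform_filter(channel**2, size)
    return np.sqrt(np.clip(sq - mean**2, 0.0, None))


def segment_tissue(
    image: np.ndarray,
    background_luminance: float = 0.92,
    dark_luminance: float = 0.08,
    stroma_saturation: float = 0.18,
    stroma_texture: float = 0.30,
) -> SegmentationResult:
    """Split an IHC brightfield tile into analyzed vs excluded regions.

    Background is excluded by extreme luminance (very bright slide glass or
    a very dark/empty field, regardless of hue); stroma-like regions are
    excluded by low stain saturation combined with low local texture.
    """
    rgb = _as_float_rgb(image)
    lum = rgb.mean(axis=2)
    mx = rgb.max(axis=2)
    mn = rgb.min(axis=2)
    sat = (mx - mn) / (mx + 1e-9)
    background = ((lum > background_luminance) & (sat < 0.12)) | (lum < dark_luminance)
    texture = _local_std(lum)
    stroma = ~background & (sat < stroma_saturation) & (texture < stroma_texture) & (lum > 0.5)
    active = ~background & ~stroma
    return SegmentationResult(
        active_mask=active,
        excluded_mask=background | stroma,
        positive_mask=np.zeros_like(active, bool),
    )


def classify_positive(
    image: np.ndarray,
    active_mask: np.ndarray,
    od_threshold: float = 0.15,
    stain_vectors: np.ndarray = HDAB_STAIN_VECTORS,
) -> np.ndarray:
    """DAB-positive pixels inside the active mask.

    RGB is converted to optical density (-log10), unmixed against the
    H-DAB stain matrix, and a pixel is positive when its DAB concentration
    exceeds ``od_threshold``.
    """
    import warnings

    rgb = _as_float_rgb(image)
    active_mask = np.asarray(active_mask, bool)
    if not active_mask.any():
        warnings.warn("empty active mask; returning an empty positive mask")
        return np.zeros(rgb.shape[:2], bool)
    od = -np.log10(np.clip(rgb, 1e-6, 1.0))
    conc = od @ np.linalg.pinv(stain_vectors)
    dab = conc[..., 1]
    return active_mask & (dab > od_threshold)


def percent_positivity(seg: SegmentationResult) -> float:
    """100 * |positive| / |active|."""
    n_active = int(seg.active_mask.sum())
    if n_active == 0:
        raise ValueError("active mask is empty")
    return 100.0 * float(seg.positive_mask.sum()) / n_active


def hotspot_map(seg: SegmentationResult, kernel_radius_px: int = 25) -> np.ndarray:
    """Local positive-pixel density (0..1) via a uniform circular kernel,
    normalized by the local tissue area so uniform positivity maps to a
    constant; zero off tissue."""
    from scipy.ndimage import convolve

    if kernel_radius_px < 1:
        raise ValueError("kernel radius must be >= 1")
    r = int(kernel_radius_px)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (yy**2 + xx**2 <= r**2).astype(float)
    pos = convolve(seg.positive_mask.astype(float), disk, mode="constant")
    act = convolve(seg.active_mask.astype(float), disk, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(act > 0, pos / np.maximum(act, 1e-12), 0.0)
    return np.where(seg.active_mask, density, 0.0)


def normalize_to_max(
    records: Sequence[PositivityRecord], anchor_time: float = 24.0
) -> dict[float, float]:
    """Per-fixation-time mean positivity of one marker divided by the
    anchor-group (24 h) mean; the anchor maps to exactly 1."""
    if not records:
        raise ValueError("no records")
    markers = {r.marker for r in records}
    if len(markers) != 1:
        raise ValueError(f"records mix markers: {sorted(markers)}")
    by_time: dict[float, list[float]] = {}
    for r in records:
        by_time.setdefault(r.fixation_time, []).append(r.percent_positive)
    if anchor_time not in by_time:
        raise ValueError(f"no {anchor_time} h group present to normalize against")
    anchor = float(np.mean(by_time[anchor_time]))
    if anchor == 0:
        raise ValueError("anchor-group mean positivity is zero")
    return {t: float(np.mean(v)) / anchor for t, v in sorted(by_time.items())}


# ---------------------------------------------------------------------------
# Wilcoxon-Mann-Whitney rank-sum test
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of group a vs b with half credit for ties."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by enumerating all C(n+m, n) group labelings of
    the pooled values."""
    pooled = np.concatenate([a, b])
    n, total = len(a), len(pooled)
    u_obs = _u_statistic(a, b)
    mean_u = len(a) * len(b) / 2.0
    dev = abs(u_obs - mean_u)
    count = 0
    n_comb = 0
    idx_all = np.arange(total)
    for comb in combinations(range(total), n):
        sel = np.zeros(total, bool)
        sel[list(comb)] = True
        u = _u_statistic(pooled[sel], pooled[~sel])
        if abs(u - mean_u) >= dev - 1e-12:
            count += 1
        n_comb += 1
    return count / n_comb


def _normal_p(a: np.ndarray, b: np.ndarray) -> float:
    """Normal approximation with tie correction and continuity correction."""
    from scipy.stats import norm

    n, m = len(a), len(b)
    big_n = n + m
    u = _u_statistic(a, b)
    mean_u = n * m / 2.0
    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = n * m / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if var_u <= 0:
        return 1.0
    z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    return float(2.0 * norm.sf(z))


def ranksum_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value.

    Exact enumeration for n + m <= 12; normal approximation with tie and
    continuity corrections otherwise.  Identical pooled values give p = 1.
    """
    a = np.asarray(list(group_a), float)
    b = np.asarray(list(group_b), float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    if a.size + b.size <= 12:
        return min(1.0, _exact_p(a, b))
    return min(1.0, _normal_p(a, b))
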