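"""Whole-organ fixation mapping: per-pixel band metrics over a spectral
raster and flagging of under-fixed interior regions."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import Spectrum, WavenumberGrid

__all__ = [
    "SpectralGrid",
    "MetricMap",
    "METRIC_NAMES",
    "compute_metric_map",
    "underfixed_mask",
    "reference_metric",
    "render_maps",
]

METRIC_NAMES = ("amide1_deriv_peak", "amide1_deriv_fwhm", "amideA_magnitude")


@dataclass
class SpectralGrid:
    """2-D raster of spectra for whole-organ mapping."""

    shape: tuple[int, int]
    pixel_mm: float
    grid: WavenumberGrid
    data: np.ndarray          # (rows, cols, n_wavenumbers), NaN off tissue
    tissue_mask: np.ndarray   # boolean raster
    t_eff: Optional[np.ndarray] = None  # generator ground truth, if known

    def __post_init__(self) -> None:
        self.tissue_mask = np.asarray(self.tissue_mask, bool)
        if self.data.shape != (*self.shape, len(self.grid)):
            raise ValueError("data array shape does not match grid")
        if self.tissue_mask.shape != tuple(self.shape):
            raise ValueError("tissue_mask shape does not match grid")
        on = np.isfinite(self.data).all(axis=2)
        if not np.array_equal(on, self.tissue_mask):
            raise ValueError("spectra must be present exactly on the tissue mask")

    def spectrum_at(self, row: int, col: int) -> Spectrum:
        if not self.tissue_mask[row, col]:
            raise ValueError(f"no tissue at pixel ({row}, {col})")
        return Spectrum(self.grid, self.data[row, col])


@dataclass
class MetricMap:
    metric_name: str
    values: np.ndarray  # raster; NaN off mask
    mask: np.ndarray
    pixel_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.metric_name not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.metric_name!r}")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("metric values must be finite on the tissue mask")


def compute_metric_map(
    grid: SpectralGrid,
    metric_name: str,
    preprocess_config=None,
    windows=None,
) -> MetricMap:
    """Preprocess every tissue pixel and evaluate one band metric."""
    from .features import (
        DEFAULT_WINDOWS,
        band_peak_magnitude,
        derivative_band_metrics,
        savgol_first_derivative,
    )
    from .preprocess import PreprocessConfig, preprocess_values

    if metric_name not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric_name!r}; known: {METRIC_NAMES}")
    windows = windows or DEFAULT_WINDOWS
    preprocess_config = preprocess_config or PreprocessConfig()

    rows_idx = np.nonzero(grid.tissue_mask.ravel())[0]
    stack = grid.data.reshape(-1, len(grid.grid))[rows_idx]
    processed = preprocess_values(grid.grid, stack, preprocess_config)

    out = np.full(grid.shape, np.nan)
    flat = out.ravel()
    for pos, vals in zip(rows_idx, processed):
        spec = Spectrum(grid.grid, vals)
        if metric_name == "amideA_magnitude":
            flat[pos] = band_peak_magnitude(spec, windows["amide_a"])
        else:
            deriv = savgol_first_derivative(spec)
            peak, fwhm = derivative_band_metrics(deriv, windows["amide_i"])
            flat[pos] = peak if metric_name == "amide1_deriv_peak" else fwhm
    return MetricMap(metric_name, out, grid.tissue_mask.copy(), grid.pixel_mm)


def reference_metric(
    metric_name: str,
    t: float,
    bands=None,
    config=None,
    preprocess_config=None,
) -> float:
    """Study-level reference value of a metric at fixation time ``t``,
    computed from a noise-free simulated spectrum (the mean over a cohort
    converges to this)."""
    from .core import DEFAULT_BANDS, StudyConfig
    from .features import extract_features
    from .preprocess import PreprocessConfig, preprocess_spectrum
    from .synth import simulate_spectrum

    bands = bands if bands is not None else DEFAULT_BANDS
    config = (config or StudyConfig()).with_(
        noise_sd=0.0, baseline_scale=0.0, atmospheric_scale=0.0
    )
    rng = np.random.default_rng(0)
    spec = simulate_spectrum(t, bands, config, rng)
    spec = preprocess_spectrum(spec, preprocess_config or PreprocessConfig())
    feats = extract_features(spec)
    return {
        "amide1_deriv_peak": feats.amide1_peak_location,
        "amide1_deriv_fwhm": feats.amide1_fwhm,
        "amideA_magnitude": feats.amideA_peak_magnitude,
    }[metric_name]


def underfixed_mask(
    metric_map: MetricMap,
    reference_fixed_value: float,
    reference_unfixed_value: float,
    threshold_frac: float = 0.5,
    min_component_px: int = 5,
) -> tuple[np.ndarray, float]:
    """Flag pixels whose metric sits on the unfixed side of the threshold
    ``unfixed + threshold_frac * (fixed - unfixed)``; small flagged
    components (< ``min_component_px``) are removed as speckle.

    Returns the boolean raster and the flagged fraction of tissue pixels.
    """
    from scipy.ndimage import label

    if reference_fixed_value == reference_unfixed_value:
        raise ValueError("fixed and unfixed reference values must differ")
    thresh = reference_unfixed_value + threshold_frac * (
        reference_fixed_value - reference_unfixed_value
    )
    vals = metric_map.values
    if reference_fixed_value > reference_unfixed_value:
        flagged = metric_map.mask & (vals < thresh)
    else:
        flagged = metric_map.mask & (vals > thresh)
    labeled, _ = label(flagged)
    sizes = np.bincount(labeled.ravel())
    keep = sizes >= min_component_px
    keep[0] = False
    flagged = keep[labeled]
    n_tissue = int(metric_map.mask.sum())
    fraction = float(flagged.sum() / n_tissue) if n_tissue else 0.0
    return flagged, fraction


def _colorize(values: np.ndarray, mask: np.ndarray, vmin: float, vmax: float,
              cmap_name: str) -> np.ndarray:
    import matplotlib

    cmap = matplotlib.colormaps[cmap_name]
    span = vmax - vmin if vmax > vmin else 1.0
    norm = np.clip((values - vmin) / span, 0.0, 1.0)
    rgba = cmap(np.nan_to_num(norm))
    rgb = (rgba[..., :3] * 255).astype(np.uint8)
    rgb[~mask] = 0
    return rgb


def render_maps(
    maps: Sequence[MetricMap],
    out_dir: str | Path,
    cmap: str = "viridis",
    scalebar_mm: float = 2.0,
) -> list[Path]:
    """Write one false-color PNG per map.

    Color limits are shared per metric across the series so a panel row is
    directly comparable; a white scale bar (``scalebar_mm``) is drawn from
    ``pixel_mm``.
    """
    from PIL import Image

    if not maps:
        raise ValueError("no maps to render")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    limits: dict[str, tuple[float, float]] = {}
    for m in maps:
        vals = m.values[m.mask]
        lo = float(vals.min()) if vals.size else 0.0
        hi = float(vals.max()) if vals.size else 1.0
        if m.metric_name in limits:
            plo, phi = limits[m.metric_name]
            limits[m.metric_name] = (min(lo, plo), max(hi, phi))
        else:
            limits[m.metric_name] = (lo, hi)
    paths = []
    for i, m in enumerate(maps):
        vmin, vmax = limits[m.metric_name]
        rgb = _colorize(m.values, m.mask, vmin, vmax, cmap)
        if m.pixel_mm > 0:
            bar_px = min(max(int(round(scalebar_mm / m.pixel_mm)), 1), rgb.shape[1] - 2)
            rgb[-2:, 1 : 1 + bar_px] = 255
        path = out / f"{i:02d}_{m.metric_name}.png"
        Image.fromarray(rgb).save(path)
        paths.append(path)
    return paths
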