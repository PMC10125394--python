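"""Synthetic-data generators for the fixation-metrology pipeline.

Emulates a differential-fixation study: MID-IR absorbance spectra whose
amide bands deform with fixation time, whole-organ spectral rasters with
diffusion-limited fixation gradients, and brightfield IHC images with known
percent positivity.  Every generator is bit-reproducible from its seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import erfc

from .core import (
    DEFAULT_BANDS,
    BandModel,
    Spectrum,
    StudyConfig,
    TissueRecord,
    WavenumberGrid,
    atmospheric_profile,
)
from .spatial import SpectralGrid

__all__ = [
    "band_sum",
    "simulate_spectrum",
    "simulate_study",
    "simulate_tonsil_grid",
    "simulate_ihc_image",
    "ihc_positivity_curve",
    "write_study",
    "IHC_MARKERS",
]

#: Saturated fixation time (hours) assigned to a fully crosslinked pixel in
#: the whole-organ simulator.
FULL_FIXATION_H = 24.0


def band_sum(t: float, bands: Sequence[BandModel], grid: WavenumberGrid) -> np.ndarray:
    """Noise-free expected absorbance: sum of saturating Gaussian bands."""
    w = grid.values
    out = np.zeros_like(w)
    for band in bands:
        out += band.profile(t, w)
    return out


def _scatter_baseline(grid: WavenumberGrid, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth concave-up scattering background, non-negative, O(scale)."""
    if scale == 0:
        return np.zeros(len(grid))
    w = grid.values
    x = (w - w.mean()) / (w[-1] - w[0])  # in [-0.5, 0.5]
    c2 = rng.uniform(0.5, 1.5)
    c1 = rng.uniform(-0.4, 0.4)
    c0 = rng.uniform(0.3, 0.8)
    base = c2 * x**2 + c1 * x + c0
    base -= base.min()
    return scale * (base + 0.1)


def simulate_spectrum(
    t: float,
    bands: Sequence[BandModel],
    config: StudyConfig,
    rng: np.random.Generator,
) -> Spectrum:
    """One absorbance spectrum at fixation time ``t`` on ``config.grid``.

    The noise-free expectation is the Gaussian band sum; scattering
    baseline, atmospheric lines and white noise are layered on top with the
    scales from ``config``.
    """
    if t < 0:
        raise ValueError(f"fixation time must be non-negative, got {t}")
    if not bands:
        raise ValueError("band list must be non-empty")
    grid = config.grid
    values = band_sum(t, bands, grid)
    values = values + _scatter_baseline(grid, config.baseline_scale, rng)
    if config.atmospheric_scale > 0:
        values = values + (
            config.atmospheric_scale
            * rng.uniform(0.5, 1.5)
            * atmospheric_profile(grid.values)
        )
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, len(grid))
    return Spectrum(grid, values)


def _jitter_bands(
    bands: Sequence[BandModel], rng: np.random.Generator
) -> list[BandModel]:
    """Per-tissue random effects: small multiplicative jitter on tau and
    amplitude plus a sub-grid center jitter.

    Because tau enters the saturation law, tissues at intermediate fixation
    times inherit more response variability than the 0 h / 24 h extremes.
    """
    out = []
    for band in bands:
        out.append(
            replace(
                band,
                tau=band.tau * float(np.exp(rng.normal(0.0, 0.03))),
                amp0=band.amp0 * float(np.exp(rng.normal(0.0, 0.02))),
                center0=band.center0 + float(rng.normal(0.0, 0.05)),
            )
        )
    return out


def simulate_study(
    config: StudyConfig, bands: Sequence[BandModel] = DEFAULT_BANDS
) -> list[TissueRecord]:
    """Generate the full differential-fixation study.

    Emits ``len(fixation_times) * tissues_per_time * replicates_per_tissue``
    slide-level records, each carrying ``regions_per_slide`` spectra.
    Replicate slides share their tissue's random effects (they are cuts of
    one block) but have independent region noise.
    """
    rng = np.random.default_rng(config.seed)
    records: list[TissueRecord] = []
    for t in config.fixation_times:
        for i in range(config.tissues_per_time):
            tissue_bands = _jitter_bands(bands, rng)
            tissue_id = f"t{t:g}h_{i:03d}"
            for r in range(config.replicates_per_tissue):
                spectra = [
                    simulate_spectrum(t, tissue_bands, config, rng)
                    for _ in range(config.regions_per_slide)
                ]
                records.append(
                    TissueRecord(
                        tissue_id=tissue_id,
                        replicate_id=f"r{r + 1}",
                        fixation_time=t,
                        spectra=spectra,
                    )
                )
    return records


def fixation_extent_map(
    tissue_mask: np.ndarray,
    cold_soak: float,
    pixel_mm: float,
    diffusivity: float,
) -> np.ndarray:
    """Local fixation extent f in [0, 1] from a diffusion-front profile.

    f(x) = erfc(d(x) / (2 * sqrt(diffusivity * cold_soak))) where d(x) is the
    distance (mm) from pixel x to the nearest tissue edge; edge pixels have
    d = 0 and are fully fixed.  cold_soak = 0 is the limit: f = 1 exactly on
    edge pixels, 0 in the interior.
    """
    from scipy.ndimage import distance_transform_edt

    if diffusivity <= 0:
        raise ValueError("diffusivity must be positive")
    if cold_soak < 0:
        raise ValueError("cold_soak must be non-negative")
    d_px = distance_transform_edt(tissue_mask)
    d_mm = np.clip(d_px - 1.0, 0.0, None) * pixel_mm
    if cold_soak == 0:
        f = np.where(d_mm == 0, 1.0, 0.0)
    else:
        f = erfc(d_mm / (2.0 * math.sqrt(diffusivity * cold_soak)))
    return np.where(tissue_mask, f, 0.0)


def _ellipse_mask(shape: tuple[int, int], margin: int = 1) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    ry, rx = cy - margin, cx - margin
    if ry <= 0 or rx <= 0:
        raise ValueError("grid too small for a tissue blob")
    return ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0


def simulate_tonsil_grid(
    cold_soak: float,
    shape: tuple[int, int] = (40, 40),
    pixel_mm: float = 0.2,
    diffusivity: float = 0.1,
    bands: Sequence[BandModel] = DEFAULT_BANDS,
    config: Optional[StudyConfig] = None,
    tissue_mask: Optional[np.ndarray] = None,
) -> SpectralGrid:
    """Whole-organ spectral raster after a cold-soak + warm-fix protocol.

    Short cold soaks leave under-fixed interiors: the local effective
    fixation time is ``24 h * f`` with f the diffusion-front extent, and the
    spectrum at each pixel is simulated at that local time.
    """
    if shape[0] < 2 or shape[1] < 2:
        raise ValueError("grid shape must be at least 2x2")
    config = config or StudyConfig()
    mask = _ellipse_mask(shape) if tissue_mask is None else np.asarray(tissue_mask, bool)
    if mask.shape != tuple(shape):
        raise ValueError("tissue_mask shape must match grid shape")
    f = fixation_extent_map(mask, cold_soak, pixel_mm, diffusivity)
    t_eff = FULL_FIXATION_H * f
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    data = np.full((shape[0], shape[1], len(grid)), np.nan)
    for r in range(shape[0]):
        for c in range(shape[1]):
            if mask[r, c]:
                data[r, c] = simulate_spectrum(t_eff[r, c], bands, config, rng).values
    return SpectralGrid(
        shape=tuple(shape),
        pixel_mm=pixel_mm,
        grid=grid,
        data=data,
        tissue_mask=mask,
        t_eff=np.where(mask, t_eff, np.nan),
    )


# ---------------------------------------------------------------------------
# IHC image simulation
# ---------------------------------------------------------------------------

_BG_COLOR = np.array([248, 248, 248], float)
_STROMA_COLOR = np.array([230, 216, 220], float)
_HEMATOXYLIN_COLOR = np.array([95, 105, 175], float)
_DAB_COLOR = np.array([125, 80, 35], float)


def simulate_ihc_image(
    percent_positive: float,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Brightfield-like IHC tile with known ground truth.

    Returns ``(image, active_mask, positive_mask)``: an RGB uint8 image with
    a white background, a pale stroma wedge (excluded from analysis), blue
    hematoxylin-stained tissue and brown DAB-positive pixels placed in
    clusters so the positive fraction of the active region matches the
    request to within 0.5 percentage points.
    """
    if not 0 <= percent_positive <= 100:
        raise ValueError("percent_positive must be in [0, 100]")
    rng = np.random.default_rng(seed)
    rows, cols = shape
    tissue = _ellipse_mask(shape, margin=max(2, rows // 16))
    # stroma wedge: an off-center ellipse strip inside the tissue
    rr, cc = np.mgrid[0:rows, 0:cols]
    stroma = tissue & (
        ((rr - rows * 0.32) / (rows * 0.12)) ** 2
        + ((cc - cols * 0.60) / (cols * 0.28)) ** 2
        <= 1.0
    )
    active = tissue & ~stroma

    n_active = int(active.sum())
    n_pos = int(round(percent_positive / 100.0 * n_active))
    positive = np.zeros(shape, bool)
    if n_pos > 0:
        # clustered placement: rank active pixels by a smooth random field
        from scipy.ndimage import gaussian_filter

        field = gaussian_filter(rng.standard_normal(shape), sigma=rows / 16)
        field = np.where(active, field, -np.inf)
        flat_order = np.argsort(field, axis=None)[::-1]
        sel = flat_order[:n_pos]
        positive.flat[sel] = True

    img = np.empty((rows, cols, 3), float)
    img[:] = _BG_COLOR
    img[stroma] = _STROMA_COLOR
    img[active] = _HEMATOXYLIN_COLOR
    img[positive] = _DAB_COLOR
    img += rng.normal(0.0, 3.0, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return img, active, positive


#: Positivity-curve parameters per marker: (max_percent, kind, tau_h).
IHC_MARKERS: dict[str, tuple[float, str, float]] = {
    "bcl2": (55.0, "saturating", 6.0),
    "foxp3": (20.0, "saturating", 8.0),
    "ki67": (40.0, "step_plateau", 2.0),
}


def ihc_positivity_curve(marker: str, t: float | np.ndarray) -> np.ndarray:
    """Expected percent positivity for a marker at fixation time ``t``.

    bcl-2 and FOXP3 are fixation-labile: positivity rises monotonically and
    is anchored to its configured maximum at 24 h.  ki-67 is robust once the
    tissue has seen >= 1 h of fixation (>= 90% of its 24 h value).
    """
    key = marker.lower().replace("-", "")
    if key not in IHC_MARKERS:
        raise ValueError(f"unknown marker {marker!r}; known: {sorted(IHC_MARKERS)}")
    maximum, kind, tau = IHC_MARKERS[key]
    t = np.asarray(t, float)
    if kind == "saturating":
        # normalized so the 24 h anchor equals the configured maximum exactly
        val = maximum * (1.0 - np.exp(-t / tau)) / (1.0 - np.exp(-24.0 / tau))
    else:  # step_plateau (ki-67): fast ramp over the first hour, then a
        # slow approach to the 24 h anchor; value at 1 h is 92% of 24 h.
        plateau = (1.0 - 0.08 * np.exp(-(np.clip(t, 1.0, None) - 1.0) / tau)) / (
            1.0 - 0.08 * np.exp(-23.0 / tau)
        )
        val = maximum * np.clip(t, 0.0, 1.0) * plateau
    return np.clip(val, 0.0, 100.0)


def attach_ihc(records: Sequence[TissueRecord], seed: int = 0, sd: float = 2.0) -> None:
    """Attach noisy per-marker positivity values drawn around the marker
    curves to each record, in place."""
    rng = np.random.default_rng(seed)
    for rec in records:
        rec.ihc = {
            m: float(
                np.clip(
                    ihc_positivity_curve(m, rec.fixation_time)
                    + rng.normal(0.0, sd),
                    0.0,
                    100.0,
                )
            )
            for m in IHC_MARKERS
        }


def write_study(records: Sequence[TissueRecord], out_dir: str | Path, seed: int | None = None) -> None:
    """Write a study as one directory per record: two-column CSV spectra plus
    a JSON metadata sidecar."""
    from .io import write_spectrum_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in records:
        rec_dir = out / f"{rec.tissue_id}_{rec.replicate_id}"
        rec_dir.mkdir(exist_ok=True)
        for i, spec in enumerate(rec.spectra):
            write_spectrum_csv(spec, rec_dir / f"spectrum_{i:03d}.csv")
        meta = {
            "tissue_id": rec.tissue_id,
            "replicate_id": rec.replicate_id,
            "fixation_time_h": rec.fixation_time,
        }
        if seed is not None:
            meta["seed"] = seed
        if rec.ihc is not None:
            meta["ihc"] = rec.ihc
        (rec_dir / "meta.json").write_text(json.dumps(meta, indent=1))
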