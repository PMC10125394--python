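"""Spectral preprocessing chain: absorbance, atmospheric correction,
concave rubber-band baseline removal, amplitude normalization, averaging.

The chain order is fixed: atmospheric correction, then baseline, then
normalization per spectrum, then spatial averaging over a tissue's regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Spectrum, TissueRecord, WavenumberGrid, atmospheric_profile

__all__ = [
    "PreprocessConfig",
    "compute_absorbance",
    "atmospheric_correction",
    "atmospheric_reference",
    "rubberband_baseline",
    "normalize_amplitude",
    "average_spectra",
    "preprocess_spectrum",
    "preprocess_tissue",
    "ATMOSPHERIC_WINDOWS",
]

#: Wavenumber windows (cm^-1) over which the atmospheric scale is fitted:
#: the CO2 doublet region and the water-vapour comb region.
ATMOSPHERIC_WINDOWS: tuple[tuple[float, float], ...] = ((2300.0, 2400.0), (1400.0, 1800.0))


@dataclass
class PreprocessConfig:
    baseline_points: int = 64
    baseline_iterations: int = 9
    atmospheric_reference: Optional[Spectrum] = None
    normalization: str = "global_max"

    def __post_init__(self) -> None:
        if self.baseline_points < 3:
            raise ValueError("baseline_points must be >= 3")
        if self.baseline_iterations < 1:
            raise ValueError("baseline_iterations must be >= 1")
        if self.normalization != "global_max":
            raise ValueError(f"unknown normalization {self.normalization!r}")


def compute_absorbance(sample_transmission: Spectrum, background_transmission: Spectrum) -> Spectrum:
    """A(nu) = -log10(I / I0); unit transmittance maps to zero absorbance."""
    if sample_transmission.grid != background_transmission.grid:
        raise ValueError("sample and background must share one grid")
    i0 = background_transmission.values
    bad = np.nonzero(i0 <= 0)[0]
    if bad.size:
        nu = background_transmission.wavenumbers[bad[0]]
        raise ValueError(
            f"background transmission is non-positive at {nu:g} cm^-1"
        )
    return Spectrum(
        sample_transmission.grid,
        -np.log10(sample_transmission.values / i0),
    )


def atmospheric_reference(grid: WavenumberGrid) -> Spectrum:
    """Bundled synthetic CO2 / water-vapour reference on ``grid``."""
    return Spectrum(grid, atmospheric_profile(grid.values))


def _window_mask(grid: WavenumberGrid) -> np.ndarray:
    w = grid.values
    mask = np.zeros(len(grid), bool)
    for lo, hi in ATMOSPHERIC_WINDOWS:
        mask |= (w >= lo) & (w <= hi)
    return mask


def _atmos_alpha(values: np.ndarray, ref: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Least-squares scale(s) of the reference inside the atmospheric
    windows; ``values`` may be 1-D or 2-D (rows = spectra)."""
    r = ref[mask]
    denom = float(r @ r)
    if denom == 0.0:
        return np.zeros(values.shape[:-1])
    return values[..., mask] @ r / denom


def atmospheric_correction(spectrum: Spectrum, reference: Spectrum) -> Spectrum:
    """Subtract alpha * reference with alpha fitted by least squares
    restricted to the atmospheric windows."""
    if spectrum.grid != reference.grid:
        raise ValueError("spectrum and reference must share one grid")
    mask = _window_mask(spectrum.grid)
    alpha = _atmos_alpha(spectrum.values, reference.values, mask)
    return Spectrum(spectrum.grid, spectrum.values - float(alpha) * reference.values)


def _segment_bounds(n: int, n_segments: int) -> np.ndarray:
    """Start indices of ``n_segments`` near-equal segments of range(n)."""
    return np.linspace(0, n, n_segments + 1).astype(int)[:-1]


def _hull_interp(x: np.ndarray, y: np.ndarray, cand: np.ndarray) -> np.ndarray:
    """Lower convex hull (monotone chain) through candidate indices,
    linearly interpolated back onto the full axis."""
    cx = x[cand].tolist()
    cy = y[cand].tolist()
    hx: list[float] = []
    hy: list[float] = []
    for xi, yi in zip(cx, cy):
        while len(hx) >= 2:
            x1, y1, x2, y2 = hx[-2], hy[-2], hx[-1], hy[-1]
            # pop while the last hull point lies on/above segment (p1, p_new)
            if (y2 - y1) * (xi - x1) >= (yi - y1) * (x2 - x1):
                hx.pop()
                hy.pop()
            else:
                break
        hx.append(xi)
        hy.append(yi)
    return np.interp(x, hx, hy)


def _lower_hull_baseline(x: np.ndarray, y: np.ndarray, n_points: int) -> np.ndarray:
    """One rubber-band pass: interval minima -> lower convex hull ->
    linear interpolation back onto the full axis."""
    n = len(x)
    bounds = np.linspace(0, n, n_points + 1).astype(int)
    cand = [a + int(np.argmin(y[a:b])) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]
    cand = np.array(sorted({0, *cand, n - 1}))
    return _hull_interp(x, y, cand)


def _rubberband_many(x: np.ndarray, values: np.ndarray, n_points: int, iterations: int) -> np.ndarray:
    """Accumulated concave rubber-band baselines for a stack of spectra.

    Each iteration re-estimates hull supports on the current corrected
    signal and adds the increment, letting the net baseline bend into
    concave regions of the original spectrum.  Segment minima are computed
    vectorized across the stack; the small hull is solved per spectrum.
    """
    values = np.atleast_2d(values)
    n_spec, n = values.shape
    bounds = np.linspace(0, n, n_points + 1).astype(int)
    segs = [(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]
    resid = values.astype(float).copy()
    total = np.zeros_like(resid)
    cand_idx = np.empty((n_spec, len(segs)), dtype=int)
    for _ in range(iterations):
        for j, (a, b) in enumerate(segs):
            cand_idx[:, j] = a + np.argmin(resid[:, a:b], axis=1)
        for i in range(n_spec):
            cand = np.unique(np.concatenate(([0], cand_idx[i], [n - 1])))
            b = _hull_interp(x, resid[i], cand)
            resid[i] -= b
            total[i] += b
    return total


def rubberband_baseline(
    spectrum: Spectrum, config: PreprocessConfig | None = None
) -> tuple[Spectrum, Spectrum]:
    """Concave rubber-band baseline estimate.

    Returns ``(baseline, corrected)`` with ``corrected = spectrum -
    baseline``; the baseline never exceeds the spectrum at its hull support
    points, so the corrected spectrum is non-negative there.
    """
    config = config or PreprocessConfig()
    if len(spectrum.grid) < config.baseline_points:
        raise ValueError(
            f"spectrum has {len(spectrum.grid)} points; need at least "
            f"{config.baseline_points}"
        )
    base = _rubberband_many(
        spectrum.wavenumbers,
        spectrum.values,
        config.baseline_points,
        config.baseline_iterations,
    )[0]
    return Spectrum(spectrum.grid, base), Spectrum(spectrum.grid, spectrum.values - base)


def normalize_amplitude(spectrum: Spectrum) -> Spectrum:
    """Scale so the global maximum over the full range equals one."""
    peak = float(np.max(spectrum.values))
    if peak <= 0:
        raise ValueError("cannot normalize: spectrum maximum is non-positive")
    return Spectrum(spectrum.grid, spectrum.values / peak)


def average_spectra(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean over spectra sharing one grid."""
    if not spectra:
        raise ValueError("cannot average an empty list of spectra")
    grid = spectra[0].grid
    if any(s.grid != grid for s in spectra):
        raise ValueError("spectra have mixed wavenumber grids")
    return Spectrum(grid, np.mean([s.values for s in spectra], axis=0))


def preprocess_values(
    grid: WavenumberGrid, values: np.ndarray, config: PreprocessConfig
) -> np.ndarray:
    """Vectorized chain (atmospheric -> baseline -> normalize) over a stack
    of raw spectra ``values`` with rows as spectra."""
    values = np.atleast_2d(np.asarray(values, float))
    if config.atmospheric_reference is not None:
        ref = config.atmospheric_reference
        if ref.grid != grid:
            raise ValueError("atmospheric reference grid mismatch")
        mask = _window_mask(grid)
        alpha = _atmos_alpha(values, ref.values, mask)
        values = values - np.outer(alpha, ref.values)
    base = _rubberband_many(
        grid.values, values, config.baseline_points, config.baseline_iterations
    )
    values = values - base
    peaks = values.max(axis=1)
    if np.any(peaks <= 0):
        raise ValueError("cannot normalize: a corrected spectrum has a non-positive maximum")
    return values / peaks[:, None]


def preprocess_spectrum(spectrum: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    config = config or PreprocessConfig()
    out = preprocess_values(spectrum.grid, spectrum.values, config)[0]
    return Spectrum(spectrum.grid, out)


def preprocess_tissue(record: TissueRecord, config: PreprocessConfig | None = None) -> Spectrum:
    """Per-spectrum chain followed by spatial averaging: the tissue's
    high-quality representative spectrum."""
    config = config or PreprocessConfig()
    if not record.spectra:
        raise ValueError("record has no spectra")
    grid = record.grid
    stack = np.vstack([s.values for s in record.spectra])
    processed = preprocess_values(grid, stack, config)
    return Spectrum(grid, processed.mean(axis=0))
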