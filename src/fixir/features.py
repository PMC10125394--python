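"""Amide band deformation metrics.

Savitzky-Golay first derivative, positive-lobe peak location and FWHM of
the Amide I derivative, and Amide A peak magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .core import Spectrum

__all__ = [
    "BandWindow",
    "BandFeatures",
    "DEFAULT_WINDOWS",
    "savgol_first_derivative",
    "derivative_band_metrics",
    "band_peak_magnitude",
    "extract_features",
    "SAVGOL_WINDOW_PTS",
    "SAVGOL_POLYORDER",
]

SAVGOL_WINDOW_PTS = 9
SAVGOL_POLYORDER = 3

#: Grid points the half-max search may extend past the window edge before
#: a truncated lobe is reported as an error.
EDGE_EXTENSION_PTS = 5


@dataclass(frozen=True)
class BandWindow:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError(f"window {self.name}: lo must be < hi")

    def indices(self, spectrum: Spectrum, min_points: int = 7) -> np.ndarray:
        w = spectrum.wavenumbers
        idx = np.nonzero((w >= self.lo) & (w <= self.hi))[0]
        if idx.size < min_points:
            raise ValueError(
                f"window {self.name} [{self.lo}, {self.hi}] contains only "
                f"{idx.size} grid points (need >= {min_points})"
            )
        return idx


# Literature band assignments; the analysis windows are conventions, not
# fitted quantities.
DEFAULT_WINDOWS: dict[str, BandWindow] = {
    "amide_i": BandWindow("amide_i", 1600.0, 1700.0),
    "amide_ii": BandWindow("amide_ii", 1500.0, 1580.0),
    "amide_a": BandWindow("amide_a", 3200.0, 3400.0),
    "amide_b": BandWindow("amide_b", 3050.0, 3100.0),
}


@dataclass(frozen=True)
class BandFeatures:
    amide1_peak_location: float
    amide1_fwhm: float
    amideA_peak_magnitude: float

    def __post_init__(self) -> None:
        if self.amide1_fwhm <= 0:
            raise ValueError("FWHM must be positive")


def savgol_first_derivative(
    spectrum: Spectrum,
    window_pts: int = SAVGOL_WINDOW_PTS,
    polyorder: int = SAVGOL_POLYORDER,
) -> Spectrum:
    """dA/dnu by Savitzky-Golay local polynomial fitting (exact for
    polynomials up to ``polyorder``; boundary handled by polynomial fit)."""
    if window_pts % 2 == 0:
        raise ValueError("window_pts must be odd")
    if not window_pts > polyorder >= 1:
        raise ValueError("need window_pts > polyorder >= 1")
    if window_pts > len(spectrum.grid):
        raise ValueError("Savitzky-Golay window exceeds spectrum length")
    deriv = savgol_filter(
        spectrum.values,
        window_length=window_pts,
        polyorder=polyorder,
        deriv=1,
        delta=spectrum.grid.step,
        mode="interp",
    )
    return Spectrum(spectrum.grid, deriv)


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through the 3 points around index ``i``."""
    if i == 0 or i == len(y) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid point
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = x[1] - x[0]
    peak_x = float(x[i] + delta * step)
    peak_y = float(y1 - 0.25 * (y0 - y2) * delta)
    return peak_x, peak_y


def _half_crossing(x: np.ndarray, y: np.ndarray, start: int, stop_lim: int,
                   direction: int, half: float) -> float:
    """Walk from ``start`` toward ``stop_lim`` until y drops below
    ``half``; return the linearly interpolated crossing wavenumber."""
    i = start
    while 0 <= i + direction <= len(y) - 1 and (direction * (i - stop_lim) < 0):
        j = i + direction
        if y[j] < half:
            # linear interpolation between i (>= half) and j (< half)
            frac = (y[i] - half) / (y[i] - y[j])
            return float(x[i] + frac * (x[j] - x[i]))
        i = j
    raise ValueError(
        "half-maximum crossing not found: derivative lobe truncated at the "
        "search boundary (non-protein-like spectrum?)"
    )


def derivative_band_metrics(
    deriv: Spectrum, window: BandWindow, edge_extension: int = EDGE_EXTENSION_PTS
) -> tuple[float, float]:
    """Peak location and FWHM of the positive lobe of a first-derivative
    spectrum inside ``window``.

    The peak is the parabola-refined maximum; the FWHM spans the two
    half-maximum crossings located by linear interpolation, searching up to
    ``edge_extension`` grid points past the window edge for truncated lobes.
    """
    idx = window.indices(deriv)
    x, y = deriv.wavenumbers, deriv.values
    seg = y[idx]
    i_max = int(idx[np.argmax(seg)])
    if y[i_max] <= 0:
        raise ValueError(
            f"no positive derivative lobe inside window {window.name}: "
            "spectrum does not look protein-like"
        )
    peak_x, peak_y = _parabolic_refine(x, y, i_max)
    half = 0.5 * peak_y
    lo_lim = max(0, idx[0] - edge_extension)
    hi_lim = min(len(y) - 1, idx[-1] + edge_extension)
    left = _half_crossing(x, y, i_max, lo_lim, -1, half)
    right = _half_crossing(x, y, i_max, hi_lim, +1, half)
    return peak_x, right - left


def band_peak_magnitude(spectrum: Spectrum, window: BandWindow) -> float:
    """Maximum absorbance inside the window."""
    idx = window.indices(spectrum)
    return float(np.max(spectrum.values[idx]))


def extract_features(
    tissue_spectrum: Spectrum,
    windows: dict[str, BandWindow] | None = None,
    savgol_window_pts: int = SAVGOL_WINDOW_PTS,
    savgol_polyorder: int = SAVGOL_POLYORDER,
) -> BandFeatures:
    """Bundle the three deformation metrics for one preprocessed spectrum."""
    windows = windows or DEFAULT_WINDOWS
    deriv = savgol_first_derivative(tissue_spectrum, savgol_window_pts, savgol_polyorder)
    peak, fwhm = derivative_band_metrics(deriv, windows["amide_i"])
    mag = band_peak_magnitude(tissue_spectrum, windows["amide_a"])
    return BandFeatures(peak, fwhm, mag)
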