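"""Plain-text IO: two-column CSV spectra, study directories, spatial grid
directories, and feature/prediction tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Spectrum, TissueRecord, WavenumberGrid

__all__ = [
    "write_spectrum_csv",
    "read_spectrum_csv",
    "read_study",
    "write_grid_dir",
    "read_grid_dir",
]

_HEADER = "wavenumber_cm-1,absorbance"


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    lines = [_HEADER]
    for w, v in zip(spectrum.wavenumbers, spectrum.values):
        lines.append(f"{w:.6g},{v:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def _grid_from_wavenumbers(w: np.ndarray) -> WavenumberGrid:
    steps = np.diff(w)
    if w.size < 2 or not np.allclose(steps, steps[0]):
        raise ValueError("wavenumber axis is not equally spaced")
    return WavenumberGrid(start=float(w[0]), stop=float(w[-1]), step=float(steps[0]))


def read_spectrum_csv(path: str | Path, grid: Optional[WavenumberGrid] = None) -> Spectrum:
    """Read a two-column CSV spectrum.

    JCAMP-DX-style comment headers (lines starting with ``##``) and a
    column-name header line are tolerated and ignored.
    """
    ws, vs = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("##"):
            continue
        first = line.split(",")[0]
        try:
            float(first)
        except ValueError:
            continue  # header row
        a, b = line.split(",")[:2]
        ws.append(float(a))
        vs.append(float(b))
    w = np.asarray(ws)
    if grid is None:
        grid = _grid_from_wavenumbers(w)
    elif not np.allclose(grid.values, w):
        raise ValueError(f"{path}: wavenumber axis does not match expected grid")
    return Spectrum(grid, np.asarray(vs))


def read_study(study_dir: str | Path) -> list[TissueRecord]:
    """Read a directory-of-CSV study written by ``synth.write_study``."""
    study_dir = Path(study_dir)
    records = []
    for rec_dir in sorted(p for p in study_dir.iterdir() if p.is_dir()):
        meta_path = rec_dir / "meta.json"
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        spectra = [
            read_spectrum_csv(p) for p in sorted(rec_dir.glob("spectrum_*.csv"))
        ]
        if not spectra:
            continue
        records.append(
            TissueRecord(
                tissue_id=meta.get("tissue_id", rec_dir.name),
                replicate_id=meta.get("replicate_id", "r1"),
                fixation_time=float(meta.get("fixation_time_h", 0.0)),
                spectra=spectra,
                ihc=meta.get("ihc"),
            )
        )
    if not records:
        raise ValueError(f"no records found under {study_dir}")
    return records


def write_grid_dir(grid, out_dir: str | Path) -> None:
    """Spatial grid layout: grid.json + per-pixel r{row}_c{col}.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "grid.json").write_text(
        json.dumps({"shape": list(grid.shape), "pixel_mm": grid.pixel_mm})
    )
    for r in range(grid.shape[0]):
        for c in range(grid.shape[1]):
            if grid.tissue_mask[r, c]:
                write_spectrum_csv(
                    Spectrum(grid.grid, grid.data[r, c]), out / f"r{r}_c{c}.csv"
                )


def read_grid_dir(in_dir: str | Path):
    from .spatial import SpectralGrid

    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "grid.json").read_text())
    shape = tuple(meta["shape"])
    pixel_mm = float(meta["pixel_mm"])
    grid = None
    mask = np.zeros(shape, bool)
    data = None
    for path in sorted(in_dir.glob("r*_c*.csv")):
        r, c = (int(s[1:]) for s in path.stem.split("_"))
        spec = read_spectrum_csv(path, grid)
        if grid is None:
            grid = spec.grid
            data = np.full((*shape, len(grid)), np.nan)
        mask[r, c] = True
        data[r, c] = spec.values
    if grid is None:
        raise ValueError(f"no pixel spectra found under {in_dir}")
    return SpectralGrid(shape=shape, pixel_mm=pixel_mm, grid=grid, data=data, tissue_mask=mask)
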