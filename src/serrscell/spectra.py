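"""Spectral containers and spectrum I/O.

A :class:`Spectrum` is the unit of all spectral computation in this package:
a vector of intensities (counts) on an evenly spaced Raman-shift grid in
cm^-1.  Spectra are exchanged on disk as two-column CSV files
(``wavenumber_cm1,intensity``); a reference library is three such files plus
a YAML manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


@dataclass(frozen=True)
class SpectralGrid:
    """Evenly spaced Raman-shift axis in cm^-1."""

    start: float
    stop: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"grid start ({self.start}) must be < stop ({self.stop})")
        if self.n_points < 64:
            raise ValueError(f"grid needs >= 64 points, got {self.n_points}")

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_points)

    @property
    def step(self) -> float:
        return (self.stop - self.start) / (self.n_points - 1)


#: Default acquisition window: the dye fingerprint region under 632.8 nm
#: excitation.
DEFAULT_GRID = SpectralGrid(start=400.0, stop=1800.0, n_points=1024)


@dataclass
class Spectrum:
    """Intensities (counts) on a :class:`SpectralGrid`."""

    grid: SpectralGrid
    intensities: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.grid.n_points,):
            raise ValueError(
                f"intensity vector of length {self.intensities.shape} does not "
                f"match grid with {self.grid.n_points} points"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("spectrum contains non-finite intensities")

    def is_constant(self) -> bool:
        return bool(np.ptp(self.intensities) == 0)


def resample_to_grid(spectrum: Spectrum, target: SpectralGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target``.

    Extrapolation is refused: the target grid must lie within the source
    wavenumber range.
    """
    src = spectrum.grid
    if target.start < src.start or target.stop > src.stop:
        raise ValueError(
            f"target grid [{target.start}, {target.stop}] extends outside the "
            f"source range [{src.start}, {src.stop}]; extrapolation is not supported"
        )
    if target == src:
        return Spectrum(grid=target, intensities=spectrum.intensities.copy())
    values = np.interp(target.wavenumbers, src.wavenumbers, spectrum.intensities)
    return Spectrum(grid=target, intensities=values)


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    df = pd.DataFrame(
        {"wavenumber_cm1": spectrum.grid.wavenumbers, "intensity": spectrum.intensities}
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_spectrum_csv(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    if not {"wavenumber_cm1", "intensity"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns wavenumber_cm1, intensity")
    wn = df["wavenumber_cm1"].to_numpy(dtype=float)
    steps = np.diff(wn)
    if len(wn) < 64 or not np.allclose(steps, steps[0], rtol=1e-4, atol=1e-6 * max(abs(wn[-1]), 1.0)):
        raise ValueError(f"{path}: wavenumber axis must be evenly spaced, >= 64 points")
    grid = SpectralGrid(start=float(wn[0]), stop=float(wn[-1]), n_points=len(wn))
    return Spectrum(grid=grid, intensities=df["intensity"].to_numpy(dtype=float))


def write_library_manifest(paths: dict[str, str | Path], manifest: str | Path) -> None:
    """Write a YAML manifest mapping reporter names (NS1/NS2/NS3) to CSV files."""
    with open(manifest, "w") as fh:
        yaml.safe_dump({k: str(v) for k, v in paths.items()}, fh)


def read_library_manifest(manifest: str | Path) -> dict[str, Spectrum]:
    base = Path(manifest).parent
    with open(manifest) as fh:
        mapping = yaml.safe_load(fh)
    out: dict[str, Spectrum] = {}
    for name, rel in mapping.items():
        p = Path(rel)
        out[name] = read_spectrum_csv(p if p.is_absolute() else base / p)
    return out
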