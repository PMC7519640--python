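"""Pearson-correlation spectral scoring against the reporter references.

Each cell's recorded spectrum is compared with the three reference reporter
spectra (NS-1, NS-2, NS-3) by the product-moment correlation coefficient;
the triple (r1, r2, r3) is the spectral feature vector of the cell.  A
positivity call flags reporters whose correlation reaches a threshold
(inclusive), reported for interpretation; the classifier consumes the raw
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum, resample_to_grid

REPORTERS = ("NS1", "NS2", "NS3")


@dataclass(frozen=True)
class ReferenceLibrary:
    """Exactly three reference spectra keyed NS1/NS2/NS3 on a shared grid."""

    spectra: dict[str, Spectrum]

    def __post_init__(self) -> None:
        if set(self.spectra) != set(REPORTERS):
            raise ValueError(f"library must contain exactly {REPORTERS}")
        grid = self.spectra["NS1"].grid
        for name in REPORTERS:
            s = self.spectra[name]
            if s.grid != grid:
                raise ValueError("reference spectra must share one grid")
            if s.is_constant():
                raise ValueError(f"reference {name} is constant")

    @property
    def grid(self):
        return self.spectra["NS1"].grid

    def __getitem__(self, key: str) -> Spectrum:
        return self.spectra[key]


@dataclass(frozen=True)
class PearsonFeatures:
    cell_id: int
    r1: float
    r2: float
    r3: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.r1, self.r2, self.r3)


@dataclass(frozen=True)
class PositivityCall:
    cell_id: int
    ns1: bool
    ns2: bool
    ns3: bool
    tau_pos: float


def pearson(a: Spectrum, b: Spectrum) -> float:
    """Product-moment correlation of two spectra on the same grid."""
    if a.grid != b.grid:
        raise ValueError("spectra live on different grids; resample first")
    if a.is_constant() or b.is_constant():
        raise ValueError("correlation with a constant spectrum is undefined")
    r = float(np.corrcoef(a.intensities, b.intensities)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def _subtract_linear_baseline(s: Spectrum) -> Spectrum:
    x = s.grid.wavenumbers
    slope, intercept = np.polyfit(x, s.intensities, 1)
    return Spectrum(grid=s.grid, intensities=s.intensities - (slope * x + intercept))


def score_cell(
    spectrum: Spectrum,
    library: ReferenceLibrary,
    preprocess: str = "none",
    cell_id: int = -1,
    allow_resampling: bool = False,
) -> PearsonFeatures:
    """Correlate one cell spectrum with the three references.

    ``preprocess`` is ``"none"`` (raw intensities; background is negligible
    under plasmonic fluorescence quenching) or ``"linear"`` (least-squares
    linear baseline subtraction).
    """
    if preprocess not in ("none", "linear"):
        raise ValueError(f"unknown preprocessing {preprocess!r}")
    if spectrum.grid != library.grid:
        if not allow_resampling:
            raise ValueError("spectrum grid differs from library grid; enable resampling")
        spectrum = resample_to_grid(spectrum, library.grid)
    if preprocess == "linear":
        spectrum = _subtract_linear_baseline(spectrum)
    r = [pearson(spectrum, library[name]) for name in REPORTERS]
    return PearsonFeatures(cell_id=cell_id, r1=r[0], r2=r[1], r3=r[2])


def call_positivity(features: PearsonFeatures, tau_pos: float = 0.5) -> PositivityCall:
    """Flag reporters with r >= tau_pos (inclusive boundary)."""
    if not -1.0 < tau_pos < 1.0:
        raise ValueError("tau_pos must be in (-1, 1)")
    return PositivityCall(
        cell_id=features.cell_id,
        ns1=features.r1 >= tau_pos,
        ns2=features.r2 >= tau_pos,
        ns3=features.r3 >= tau_pos,
        tau_pos=tau_pos,
    )
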