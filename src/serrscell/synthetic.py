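"""Synthetic SERRS experiments with known ground truth.

Every downstream stage of the pipeline (detection, scoring, gating, forest
attribution, calibration, enumeration) is exercised on data from this module,
which emulates a spiked-sample experiment: epithelial (LNCaP-like) and
mesenchymal (U251-like) tumor cells at tens per ml among PBMCs, incubated
with three antibody-functionalized nanostructures (NS-1/2/3) each carrying a
distinct SERRS reporter dye, imaged in a 3.5 x 3.5 mm chamber, and measured
one cell at a time.

The three reporter signatures are synthetic surrogates: Lorentzian line
lists loosely placed at strong bands of Malachite Green (NS-1), Texas Red
(NS-2) and Nile Blue (NS-3), chosen disjoint enough that noise-free
references correlate pairwise below 0.3 so that Pearson scoring can
multiplex them.  The published work prints no peak tables, so no attempt is
made to match real line positions quantitatively.

Phenotype-dependent mixing encodes the targeting biology: NS-2
(anti-EpCAM/E-Cad) dominates on epithelial cells, while NS-1
(anti-CD44/N-Cad) and NS-3 (anti-CD45) bind both mesenchymal cells and
PBMCs with different relative abundances -- which is exactly what makes the
U251/PBMC distinction the hard part of the classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .spectra import DEFAULT_GRID, SpectralGrid, Spectrum

CLASS_ORDER = ("LNCaP", "PBMC", "U251")

#: Photon budget used when shot noise is enabled (counts at unit intensity).
_SHOT_SCALE = 1000.0

#: Rendered foreground intensity (arbitrary camera counts, background 0).
FOREGROUND_INTENSITY = 200.0


@dataclass(frozen=True)
class Peak:
    center_cm1: float
    fwhm_cm1: float
    height: float


@dataclass(frozen=True)
class ReporterSignature:
    """Lorentzian line list of one SERRS reporter."""

    name: str
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        if len(self.peaks) < 3:
            raise ValueError(f"{self.name}: a signature needs >= 3 peaks")
        for p in self.peaks:
            if p.height <= 0 or p.fwhm_cm1 <= 0:
                raise ValueError(f"{self.name}: peak at {p.center_cm1} has non-positive height/width")


def _sig(name: str, rows: list[tuple[float, float, float]]) -> ReporterSignature:
    return ReporterSignature(name=name, peaks=tuple(Peak(*r) for r in rows))


#: Surrogate line lists (center cm^-1, FWHM cm^-1, relative height).
DEFAULT_SIGNATURES: dict[str, ReporterSignature] = {
    "NS1": _sig("NS1", [  # Malachite Green-like
        (798.0, 12.0, 0.35),
        (1175.0, 10.0, 0.55),
        (1219.0, 10.0, 0.70),
        (1365.0, 12.0, 0.50),
        (1590.0, 11.0, 0.65),
        (1617.0, 10.0, 1.00),
    ]),
    "NS2": _sig("NS2", [  # Texas Red-like
        (508.0, 13.0, 0.40),
        (1120.0, 11.0, 0.45),
        (1260.0, 12.0, 0.55),
        (1504.0, 10.0, 1.00),
        (1649.0, 11.0, 0.80),
    ]),
    "NS3": _sig("NS3", [  # Nile Blue-like
        (592.0, 11.0, 1.00),
        (662.0, 12.0, 0.45),
        (1430.0, 12.0, 0.40),
        (1544.0, 11.0, 0.55),
        (1695.0, 12.0, 0.35),
    ]),
}


def build_reference_spectrum(signature: ReporterSignature, grid: SpectralGrid = DEFAULT_GRID) -> Spectrum:
    """Noise-free sum of Lorentzian peaks, max-normalized to 1. Deterministic."""
    x = grid.wavenumbers
    y = np.zeros_like(x)
    for p in signature.peaks:
        if not (grid.start <= p.center_cm1 <= grid.stop):
            raise ValueError(
                f"{signature.name}: peak at {p.center_cm1} cm^-1 lies outside the "
                f"grid [{grid.start}, {grid.stop}]"
            )
        hw = p.fwhm_cm1 / 2.0
        y += p.height * hw**2 / ((x - p.center_cm1) ** 2 + hw**2)
    return Spectrum(grid=grid, intensities=y / y.max())


def default_reference_library(grid: SpectralGrid = DEFAULT_GRID) -> dict[str, Spectrum]:
    return {name: build_reference_spectrum(sig, grid) for name, sig in DEFAULT_SIGNATURES.items()}


@dataclass(frozen=True)
class NoiseModel:
    """Instrument noise and background for synthetic cell spectra.

    ``baseline_coeffs`` are polynomial coefficients in ascending powers of the
    normalized wavenumber x in [0, 1]; the fluorescence background is a broad
    Gaussian bump (quenched in the real experiment, hence small by default).
    """

    baseline_coeffs: tuple[float, ...] = (0.05, 0.05)
    additive_sd: float = 0.20
    shot_noise: bool = False
    fluorescence_amplitude: float = 0.05

    def __post_init__(self) -> None:
        if self.additive_sd < 0:
            raise ValueError("additive_sd must be >= 0")
        if self.fluorescence_amplitude < 0:
            raise ValueError("fluorescence_amplitude must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(baseline_coeffs=(0.0,), additive_sd=0.0, shot_noise=False,
                   fluorescence_amplitude=0.0)

    def baseline(self, grid: SpectralGrid) -> np.ndarray:
        x = np.linspace(0.0, 1.0, grid.n_points)
        background = np.polynomial.polynomial.polyval(x, np.asarray(self.baseline_coeffs))
        if self.fluorescence_amplitude > 0:
            background = background + self.fluorescence_amplitude * np.exp(
                -0.5 * ((x - 0.5) / 0.25) ** 2
            )
        return background


@dataclass
class SyntheticCell:
    """One ground-truth cell: phenotype, footprint and reporter loading."""

    true_class: str
    area_um2: float
    weights: np.ndarray  # (w1, w2, w3) >= 0, loading of NS1/NS2/NS3
    centroid_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.true_class not in CLASS_ORDER:
            raise ValueError(f"unknown class {self.true_class!r}")
        if self.area_um2 <= 0:
            raise ValueError("cell area must be > 0")
        if self.weights.shape != (3,) or np.any(self.weights < 0):
            raise ValueError("weights must be three non-negative numbers")


@dataclass(frozen=True)
class ClassModel:
    """Per-phenotype generative model: reporter loadings and footprint area.

    Mixing weights are the mean loading times independent lognormal jitter
    (``exp(sigma * z)`` per channel); areas are lognormal in um^2, resampled
    into (0, area_max).
    """

    mean_weights: tuple[float, float, float]
    weight_sigma: float = 0.5
    area_median_um2: float = 80.0
    area_sigma: float = 0.35
    area_max_um2: float = 300.0


#: Encodes the targeting pattern: NS-2 on epithelial cells; NS-1 and NS-3 on
#: both mesenchymal cells and PBMCs with different relative abundance (the
#: NS1:NS3 loading ratio differs ~2.5-fold between U251 and PBMC, with
#: lognormal per-cell jitter making the two phenotypes partially overlap).
#: PBMC areas are mostly below the 30 um^2 gate; tumor areas sit in 30-180.
DEFAULT_CLASS_MODELS: dict[str, ClassModel] = {
    "LNCaP": ClassModel(mean_weights=(0.10, 1.00, 0.12), area_median_um2=80.0, area_sigma=0.35),
    "U251": ClassModel(mean_weights=(1.00, 0.04, 0.70), area_median_um2=65.0, area_sigma=0.35),
    "PBMC": ClassModel(mean_weights=(0.72, 0.04, 1.00), area_median_um2=16.0, area_sigma=0.42),
}


def noise_free_class_models() -> dict[str, ClassModel]:
    """Jitter-free copies of the default class models (separable phenotypes)."""
    return {
        name: ClassModel(
            mean_weights=m.mean_weights,
            weight_sigma=0.0,
            area_median_um2=m.area_median_um2,
            area_sigma=m.area_sigma,
            area_max_um2=m.area_max_um2,
        )
        for name, m in DEFAULT_CLASS_MODELS.items()
    }


@dataclass(frozen=True)
class ExperimentSpec:
    """Composition and geometry of one spiked-sample experiment."""

    lncap_per_ml: float = 24.0
    u251_per_ml: float = 29.0
    pbmc_per_ml: float = 1.0e7
    depletion: float = 0.9999
    efficiency: float = 0.84
    volume_ml: float = 1.0
    chamber_mm: float = 3.5
    pixel_size_um: float = 1.0
    pbmc_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depletion <= 1.0:
            raise ValueError("depletion must be in [0, 1]")
        if not 0.0 < self.efficiency <= 1.0:
            raise ValueError("efficiency must be in (0, 1]")
        if min(self.lncap_per_ml, self.u251_per_ml, self.pbmc_per_ml) < 0:
            raise ValueError("cell concentrations must be >= 0")
        if self.volume_ml <= 0 or self.chamber_mm <= 0 or self.pixel_size_um <= 0:
            raise ValueError("volume, chamber size and pixel size must be > 0")
        if not 0.0 < self.pbmc_scale <= 1.0:
            raise ValueError("pbmc_scale must be in (0, 1]")


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _draw_area(model: ClassModel, rng: np.random.Generator) -> float:
    for _ in range(1000):
        a = float(rng.lognormal(math.log(model.area_median_um2), model.area_sigma))
        if 0.0 < a < model.area_max_um2:
            return a
    raise RuntimeError("area resampling failed; check class model parameters")


def _draw_cell(true_class: str, model: ClassModel, rng: np.random.Generator) -> SyntheticCell:
    jitter = np.exp(model.weight_sigma * rng.standard_normal(3))
    weights = np.asarray(model.mean_weights) * jitter
    return SyntheticCell(true_class=true_class, area_um2=_draw_area(model, rng), weights=weights)


def sample_cell_population(
    spec: ExperimentSpec,
    class_models: dict[str, ClassModel] | None = None,
    seed: int | np.random.Generator = 0,
) -> list[SyntheticCell]:
    """Draw the retained (captured-and-fixed) cells of a spiked experiment.

    Tumor cells are thinned by the capture-and-fixing efficiency only
    (binomial); PBMCs are additionally thinned by immunomagnetic depletion.
    Each retained cell carries its ground-truth class, reporter loadings and
    a uniformly drawn centroid inside the chamber.
    """
    models = class_models or DEFAULT_CLASS_MODELS
    rng = _as_rng(seed)
    n_spiked = {
        "LNCaP": int(round(spec.lncap_per_ml * spec.volume_ml)),
        "U251": int(round(spec.u251_per_ml * spec.volume_ml)),
        "PBMC": int(round(spec.pbmc_per_ml * spec.volume_ml * spec.pbmc_scale)),
    }
    retain_p = {
        "LNCaP": spec.efficiency,
        "U251": spec.efficiency,
        "PBMC": (1.0 - spec.depletion) * spec.efficiency,
    }
    cells: list[SyntheticCell] = []
    chamber_um = spec.chamber_mm * 1000.0
    margin = 12.0  # um, keeps whole footprints inside the chamber
    for name in CLASS_ORDER:
        n_kept = int(rng.binomial(n_spiked[name], retain_p[name])) if n_spiked[name] else 0
        for _ in range(n_kept):
            cell = _draw_cell(name, models[name], rng)
            cell.centroid_um = (
                float(rng.uniform(margin, chamber_um - margin)),
                float(rng.uniform(margin, chamber_um - margin)),
            )
            cells.append(cell)
    return cells


def generate_cell_spectrum(
    cell: SyntheticCell,
    refs: dict[str, Spectrum],
    noise: NoiseModel,
    seed: int | np.random.Generator = 0,
) -> Spectrum:
    """Mix the three reference spectra by the cell's loadings, add background
    and noise, clip at zero.  Deterministic for a fixed seed."""
    ordered = [refs[k] for k in ("NS1", "NS2", "NS3")]
    grid = ordered[0].grid
    for r in ordered[1:]:
        if r.grid != grid:
            raise ValueError("reference spectra must share one grid")
    rng = _as_rng(seed)
    y = sum(w * r.intensities for w, r in zip(cell.weights, ordered))
    y = y + noise.baseline(grid)
    if noise.shot_noise:
        y = rng.poisson(np.clip(y, 0.0, None) * _SHOT_SCALE) / _SHOT_SCALE
    if noise.additive_sd > 0:
        y = y + rng.normal(0.0, noise.additive_sd, size=grid.n_points)
    return Spectrum(grid=grid, intensities=np.clip(y, 0.0, None))


_B3 = np.ones((3, 3), dtype=bool)


def _ellipse_offsets(target_px: int, axis_ratio: float, theta: float) -> tuple[np.ndarray, np.ndarray]:
    """Integer pixel offsets of an elliptical disc with ``target_px`` pixels.

    The disc is built as a 3x3 dilation of a core set (so it is invariant
    under a radius-1 morphological opening and survives the detector's
    cleanup unchanged): core pixels are added in order of the elliptical
    metric, sized by bisection and topped up greedily to reach ``target_px``
    exactly whenever the dilated geometry allows (always to within 2 px).
    """
    from scipy import ndimage as _ndi

    b = math.sqrt(max(target_px, 9) / (math.pi * axis_ratio))
    a = axis_ratio * b
    r = int(math.ceil(max(a, b))) + 3
    side = 2 * r + 1
    dy, dx = np.mgrid[-r: r + 1, -r: r + 1]
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    m = (u / a) ** 2 + (v / b) ** 2
    order = np.lexsort((dx.ravel(), dy.ravel(), m.ravel()))
    # keep candidates away from the frame edge so dilation stays in-bounds
    rows, cols = np.unravel_index(order, (side, side))
    keep = (rows >= 1) & (rows < side - 1) & (cols >= 1) & (cols < side - 1)
    rows, cols = rows[keep], cols[keep]

    def blob_of(k: int) -> np.ndarray:
        core = np.zeros((side, side), dtype=bool)
        core[rows[:k], cols[:k]] = True
        return _ndi.binary_dilation(core, structure=_B3)

    # smallest core size whose dilation reaches the target
    lo, hi = 1, len(rows)
    while lo < hi:
        mid = (lo + hi) // 2
        if int(blob_of(mid).sum()) < target_px:
            lo = mid + 1
        else:
            hi = mid
    blob = blob_of(lo)
    if int(blob.sum()) != target_px and lo > 1:
        blob = blob_of(lo - 1)
        in_core = np.zeros(len(rows), dtype=bool)
        in_core[: lo - 1] = True
        remaining = target_px - int(blob.sum())
        while remaining > 0:
            conv = _ndi.convolve(blob.astype(np.int8), _B3.astype(np.int8), mode="constant")
            gains = 9 - conv[rows, cols]
            ok = np.flatnonzero(~in_core & (gains >= 1) & (gains <= remaining))
            if ok.size == 0:
                # overshoot with the smallest available gain, trim below
                any_ok = np.flatnonzero(~in_core & (gains >= 1))
                if any_ok.size == 0:
                    break
                undershoot = blob.copy()
                j = int(any_ok[np.argmin(gains[any_ok])])
            else:
                undershoot = None
                j = int(ok[0])
            in_core[j] = True
            blob[max(rows[j] - 1, 0): rows[j] + 2, max(cols[j] - 1, 0): cols[j] + 2] = True
            remaining = target_px - int(blob.sum())
            if remaining < 0:
                blob = _trim_blob(blob, -remaining, rows, cols)
                if undershoot is not None and abs(int(blob.sum()) - target_px) > abs(
                    int(undershoot.sum()) - target_px
                ):
                    blob = undershoot
                break
    br, bc = np.nonzero(blob)
    return br - r, bc - r


def _trim_blob(blob: np.ndarray, excess: int, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Remove up to ``excess`` outermost pixels while keeping the blob
    invariant under radius-1 opening and 8-connected."""
    from scipy import ndimage as _ndi

    while excess > 0:
        removed = False
        for j in range(len(rows) - 1, -1, -1):  # outermost candidates first
            p = (rows[j], cols[j])
            if not blob[p]:
                continue
            cand = blob.copy()
            cand[p] = False
            opened = _ndi.binary_dilation(
                _ndi.binary_erosion(cand, structure=_B3, border_value=0), structure=_B3
            ) & cand
            if not (opened == cand).all():
                continue
            if _ndi.label(cand, structure=_B3.astype(int))[1] != 1:
                continue
            blob = cand
            excess -= 1
            removed = True
            break
        if not removed:
            break
    return blob


def render_chamber_image(
    cells: list[SyntheticCell],
    spec: ExperimentSpec,
    seed: int | np.random.Generator = 0,
    max_tries: int = 200,
) -> tuple[np.ndarray, list[SyntheticCell]]:
    """Rasterize cells into a grayscale chamber image (background 0).

    Each cell is a filled elliptical disc whose pixel count times the pixel
    area matches its true area to within half a pixel.  Cells are placed at
    their stored centroids; a placement that would touch an existing cell
    (8-connectivity) is redrawn uniformly, up to ``max_tries`` times, after
    which the chamber is declared too crowded.  Returns the image and the
    cells with final centroids.
    """
    rng = _as_rng(seed)
    px = spec.pixel_size_um
    size = int(round(spec.chamber_mm * 1000.0 / px))
    image = np.zeros((size, size), dtype=float)
    # occupancy = foreground dilated by one pixel, so placed cells never touch
    occupancy = np.zeros((size, size), dtype=bool)
    placed: list[SyntheticCell] = []
    for cell in cells:
        if cell.centroid_um is None:
            raise ValueError("cells must carry centroids before rendering")
        target_px = max(1, int(round(cell.area_um2 / px**2)))
        axis_ratio = float(rng.uniform(0.75, 1.0))
        theta = float(rng.uniform(0.0, math.pi))
        off_r, off_c = _ellipse_offsets(target_px, axis_ratio, theta)
        x, y = cell.centroid_um
        for attempt in range(max_tries):
            col = int(round(x / px))
            row = int(round(y / px))
            rows, cols = row + off_r, col + off_c
            if rows.min() < 1 or cols.min() < 1 or rows.max() >= size - 1 or cols.max() >= size - 1:
                x, y = rng.uniform(12.0, size * px - 12.0, size=2)
                continue
            if occupancy[rows, cols].any():
                x, y = rng.uniform(12.0, size * px - 12.0, size=2)
                continue
            image[rows, cols] = FOREGROUND_INTENSITY
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    occupancy[rows + dr, cols + dc] = True
            updated = SyntheticCell(
                true_class=cell.true_class,
                area_um2=cell.area_um2,
                weights=cell.weights.copy(),
                centroid_um=(col * px, row * px),
            )
            placed.append(updated)
            break
        else:
            raise RuntimeError(
                f"could not place a {cell.area_um2:.0f} um^2 cell without overlap "
                f"after {max_tries} tries; chamber too crowded"
            )
    return image, placed
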