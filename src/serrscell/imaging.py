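"""Chamber-image cell detection and morphometry.

The instrument records a camera image of the capture chamber; cells are
found by binarizing the image and labelling connected foreground components
after light morphological cleanup (opening with a radius-1 disc, then hole
filling).  Each detected cell reports its centroid in physical micrometres
and its area as the pixel sum times the squared pixel size.

Conventions: pixels are 0-based with row 0 / column 0 at the top-left;
x = column * pixel_size, y = row * pixel_size; bounding boxes are half-open
in pixel coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import io as skio
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import opening


@dataclass(frozen=True)
class ChamberImage:
    """Grayscale chamber raster with a known pixel size in um/pixel."""

    data: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("chamber image must be a non-empty 2-D raster")


@dataclass(frozen=True)
class DetectedCell:
    """One detected cell: centroid (um), pixel count, area (um^2), bbox."""

    id: int
    x_um: float
    y_um: float
    pixel_count: int
    area_um2: float
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col), half-open


def read_chamber_image(path: str | Path, pixel_size_um: float) -> ChamberImage:
    """Read a TIFF/PNG raster; multichannel images are averaged to grayscale."""
    data = np.asarray(skio.imread(str(path)), dtype=float)
    if data.ndim == 3:
        data = data.mean(axis=-1)
    return ChamberImage(data=data, pixel_size_um=pixel_size_um)


def binarize(image: ChamberImage, method: str = "otsu", threshold: float | None = None) -> np.ndarray:
    """Foreground mask: intensity >= threshold (fixed) or >= Otsu's global
    threshold.  A constant image under Otsu yields an all-background mask
    with a warning rather than an error."""
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed binarization requires a threshold")
        return image.data >= threshold
    if method == "otsu":
        if np.ptp(image.data) == 0:
            warnings.warn("constant image: Otsu threshold undefined, returning all-background mask")
            return np.zeros_like(image.data, dtype=bool)
        return image.data >= threshold_otsu(image.data)
    raise ValueError(f"unknown binarization method {method!r}; use 'fixed' or 'otsu'")


def area_um2(pixel_count: float, pixel_size: float) -> float:
    """Cell area as summed pixels times the squared pixel size."""
    if pixel_count <= 0 or pixel_size <= 0:
        raise ValueError("pixel_count and pixel_size must be > 0")
    return pixel_count * pixel_size**2


def detect_cells(
    mask: np.ndarray,
    pixel_size_um: float,
    min_pixels: int = 4,
    connectivity: int = 8,
) -> list[DetectedCell]:
    """Label connected foreground components as cells.

    The mask is opened with a radius-1 disc and hole-filled first; components
    smaller than ``min_pixels`` are dropped.  Cells are returned ordered by
    the (row, column) of their bounding-box top-left corner, so the output is
    independent of labelling order.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be > 0")
    # radius-1 opening in the Chebyshev metric (3x3 footprint): removes
    # single-pixel specks and protrusions without clipping square corners
    cleaned = opening(np.asarray(mask, dtype=bool), footprint=np.ones((3, 3), dtype=bool))
    cleaned = ndimage.binary_fill_holes(cleaned)
    labels = label(cleaned, connectivity=1 if connectivity == 4 else 2)
    cells = []
    for region in regionprops(labels):
        if region.num_pixels < min_pixels:
            continue
        row_c, col_c = region.centroid
        cells.append(
            (
                region.bbox,
                DetectedCell(
                    id=-1,
                    x_um=col_c * pixel_size_um,
                    y_um=row_c * pixel_size_um,
                    pixel_count=int(region.num_pixels),
                    area_um2=area_um2(region.num_pixels, pixel_size_um),
                    bbox=tuple(int(v) for v in region.bbox),
                ),
            )
        )
    cells.sort(key=lambda item: (item[0][0], item[0][1]))
    return [
        DetectedCell(id=i, x_um=c.x_um, y_um=c.y_um, pixel_count=c.pixel_count,
                     area_um2=c.area_um2, bbox=c.bbox)
        for i, (_, c) in enumerate(cells)
    ]


def cells_to_frame(cells: list[DetectedCell]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [c.id for c in cells],
            "x_um": [c.x_um for c in cells],
            "y_um": [c.y_um for c in cells],
            "pixel_count": [c.pixel_count for c in cells],
            "area_um2": [c.area_um2 for c in cells],
        }
    )


def write_cells_csv(cells: list[DetectedCell], path: str | Path) -> None:
    cells_to_frame(cells).to_csv(path, index=False, float_format="%.6f")


def match_to_truth(
    detected: list[DetectedCell],
    true_centroids_um: list[tuple[float, float]],
    max_dist_um: float = 5.0,
) -> list[tuple[int, int]]:
    """Greedy nearest-centroid matching of detections to ground-truth cells.

    Returns (detected_index, truth_index) pairs; each truth cell is used at
    most once.  Used to attach the simulated spectrum of a ground-truth cell
    to its detection in the rendered chamber.
    """
    if not detected or not true_centroids_um:
        return []
    det = np.array([[c.x_um, c.y_um] for c in detected])
    tru = np.asarray(true_centroids_um, dtype=float)
    d2 = ((det[:, None, :] - tru[None, :, :]) ** 2).sum(axis=2)
    pairs: list[tuple[int, int]] = []
    used_det: set[int] = set()
    used_tru: set[int] = set()
    order = np.argsort(d2, axis=None)
    for flat in order:
        i, j = np.unravel_index(flat, d2.shape)
        if int(i) in used_det or int(j) in used_tru:
            continue
        if d2[i, j] > max_dist_um**2:
            break
        pairs.append((int(i), int(j)))
        used_det.add(int(i))
        used_tru.add(int(j))
    return sorted(pairs)
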