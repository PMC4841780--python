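"""Colony-size measurement from scanned plate images.

Fits the colony grid (origin, pitch, rotation) from detected colony
centroids, then measures each grid cell's colony as the foreground pixel
count of the connected component nearest the cell centre, thresholded per
cell by Otsu's criterion.  Per-cell thresholding is robust to the
vignetting of transmission scans; transmission polarity (dark colonies) is
normalized by inversion before thresholding.

Measurements are invariant to global affine intensity rescaling, since
both Otsu's criterion and the contrast guard scale with the image.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from spiscreen.io_cli.layout import PlateLayout
import pandas as pd

logger = logging.getLogger(__name__)


class GridFitError(ValueError):
    pass


@dataclass
class GridGeometry:
    """Fitted affine lattice: centre of cell (0, 0), basis vectors per grid
    step, plus derived pitch/rotation for reporting."""

    origin_y: float
    origin_x: float
    pitch_y: float
    pitch_x: float
    rotation_deg: float
    n_rows: int
    n_cols: int
    residual: float = 0.0  # median |centroid - lattice| in units of pitch
    v_row: tuple[float, float] = (0.0, 0.0)  # (dy, dx) per row step
    v_col: tuple[float, float] = (0.0, 0.0)  # (dy, dx) per column step

    def __post_init__(self) -> None:
        if self.v_row == (0.0, 0.0):
            self.v_row = (self.pitch_y, 0.0)
        if self.v_col == (0.0, 0.0):
            self.v_col = (0.0, self.pitch_x)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (self.origin_y + row * self.v_row[0] + col * self.v_col[0],
                self.origin_x + row * self.v_row[1] + col * self.v_col[1])


def _normalize_polarity(image: np.ndarray, polarity: str) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if polarity == "colonies_dark":
        return img.max() - img
    if polarity != "colonies_bright":
        raise ValueError(f"unknown polarity {polarity!r}")
    return img


def _colony_centroids(img: np.ndarray, min_area: int = 5) -> np.ndarray:
    thr = threshold_otsu(img)
    labels = sk_label(img > thr, connectivity=2)
    cents = [p.centroid for p in regionprops(labels) if p.area >= min_area]
    return np.array(cents) if cents else np.empty((0, 2))


def fit_grid(
    image: np.ndarray,
    n_rows: int,
    n_cols: int,
    polarity: str = "colonies_bright",
    min_area: int = 5,
) -> GridGeometry:
    """Estimate grid origin, pitch and rotation from colony centroids.

    Rotation comes from the median angle of near-axis neighbour vectors;
    pitch and origin from the median spacing of rotation-corrected
    centroids snapped to integer lattice indices.
    """
    img = _normalize_polarity(image, polarity)
    cents = _colony_centroids(img, min_area=min_area)
    if len(cents) < max(9, (n_rows * n_cols) // 2):
        raise GridFitError(
            f"only {len(cents)} colonies detected; need at least half of "
            f"{n_rows * n_cols} and 3 rows/columns")

    tree = cKDTree(cents)
    dists, idx = tree.query(cents, k=min(5, len(cents)))
    angles = []
    spacings_h, spacings_v = [], []
    for i in range(len(cents)):
        for j, d in zip(idx[i][1:], dists[i][1:]):
            dy = cents[j][0] - cents[i][0]
            dx = cents[j][1] - cents[i][1]
            ang = math.degrees(math.atan2(dy, dx))
            # fold to the nearest lattice axis; deviation estimates rotation
            dev = ((ang + 45.0) % 90.0) - 45.0
            if abs(dev) < 20.0:
                angles.append(dev)
                if abs(((ang % 180.0) + 90.0) % 180.0 - 90.0) < 30.0:
                    spacings_h.append(d)
                else:
                    spacings_v.append(d)
    if not angles:
        raise GridFitError("no near-axis neighbour pairs; cannot estimate rotation")
    theta0 = math.radians(float(np.median(angles)))
    pitch0_x = float(np.median(spacings_h)) if spacings_h else \
        (cents[:, 1].max() - cents[:, 1].min()) / max(n_cols - 1, 1)
    pitch0_y = float(np.median(spacings_v)) if spacings_v else pitch0_x

    # initial de-rotation and index assignment
    cy, cx = np.array(img.shape) / 2.0
    dyc, dxc = cents[:, 0] - cy, cents[:, 1] - cx
    ry = cy + dyc * math.cos(theta0) - dxc * math.sin(theta0)
    rx = cx + dxc * math.cos(theta0) + dyc * math.sin(theta0)
    ridx = np.round((ry - ry.min()) / pitch0_y)
    cidx = np.round((rx - rx.min()) / pitch0_x)
    if len(np.unique(ridx)) < 3 or len(np.unique(cidx)) < 3:
        raise GridFitError("fewer than 3 detectable rows or columns")

    def affine_solve(ridx, cidx):
        # centroid ~ origin + row * v_row + col * v_col (least squares)
        A = np.column_stack([np.ones(len(cents)), ridx, cidx])
        coef_y, *_ = np.linalg.lstsq(A, cents[:, 0], rcond=None)
        coef_x, *_ = np.linalg.lstsq(A, cents[:, 1], rcond=None)
        origin = (coef_y[0], coef_x[0])
        v_row = (coef_y[1], coef_x[1])
        v_col = (coef_y[2], coef_x[2])
        return origin, v_row, v_col

    for _ in range(2):
        origin, v_row, v_col = affine_solve(ridx, cidx)
        # re-assign indices by inverting the affine model
        M = np.array([[v_row[0], v_col[0]], [v_row[1], v_col[1]]])
        rel = cents - np.array(origin)
        sol = np.linalg.solve(M, rel.T).T
        ridx, cidx = np.round(sol[:, 0]), np.round(sol[:, 1])

    model = np.array(origin) + np.outer(ridx, v_row) + np.outer(cidx, v_col)
    resid = np.linalg.norm(cents - model, axis=1)
    pitch_y = float(np.hypot(*v_row))
    pitch_x = float(np.hypot(*v_col))
    rotation = math.degrees(math.atan2(v_col[0], v_col[1]))
    residual = float(np.median(resid)) / min(pitch_y, pitch_x)
    if residual >= 0.25:
        raise GridFitError(f"lattice residual {residual:.2f} x pitch >= 0.25")
    # shift the origin so index (0, 0) is the top-left lattice point
    r0, c0 = ridx.min(), cidx.min()
    origin = (origin[0] + r0 * v_row[0] + c0 * v_col[0],
              origin[1] + r0 * v_row[1] + c0 * v_col[1])
    return GridGeometry(origin[0], origin[1], pitch_y, pitch_x, rotation,
                        n_rows, n_cols, residual,
                        v_row=tuple(v_row), v_col=tuple(v_col))


def measure_colonies(
    image: np.ndarray,
    geometry: GridGeometry,
    layout: PlateLayout,
    polarity: str = "colonies_bright",
    min_foreground_px: int = 5,
    edge_fraction: float = 0.25,
    contrast_sigmas: float = 2.0,
) -> pd.DataFrame:
    """Measure per-cell colony areas on a fitted grid.

    Each cell is thresholded by Otsu's criterion; the measured colony is
    the connected component nearest the cell centre.  Cells whose
    foreground is below ``min_foreground_px`` or whose foreground/background
    contrast is within ``contrast_sigmas`` global noise sigmas are flagged
    empty (size absent).  Components touching the cell boundary on more
    than ``edge_fraction`` of their perimeter are flagged edge_touching.
    """
    if (geometry.n_rows, geometry.n_cols) != (layout.n_rows, layout.n_cols):
        raise GridFitError(
            f"geometry grid {geometry.n_rows}x{geometry.n_cols} does not match "
            f"layout {layout.n_rows}x{layout.n_cols}")
    img = _normalize_polarity(image, polarity)

    # global noise scale from the background class of a global Otsu split
    global_thr = threshold_otsu(img)
    noise_sigma = float(img[img <= global_thr].std())

    rows = []
    half_y, half_x = geometry.pitch_y / 2.0, geometry.pitch_x / 2.0
    for (r, c), strain in sorted(layout.position_map.items()):
        if strain is None:
            continue
        cy, cx = geometry.cell_center(r, c)
        y0, y1 = int(round(cy - half_y)), int(round(cy + half_y))
        x0, x1 = int(round(cx - half_x)), int(round(cx + half_x))
        y0, x0 = max(y0, 0), max(x0, 0)
        y1, x1 = min(y1, img.shape[0]), min(x1, img.shape[1])
        cell = img[y0:y1, x0:x1]
        record = {"plate_id": layout.plate_id, "row": r, "col": c, "strain": strain,
                  "size": np.nan, "circularity": np.nan,
                  "edge_touching": False, "empty": True}
        rows.append(record)
        if cell.size == 0 or cell.max() == cell.min():
            continue
        thr = threshold_otsu(cell)
        fg = cell > thr
        if fg.sum() < min_foreground_px:
            continue
        if float(cell[fg].mean() - cell[~fg].mean()) < contrast_sigmas * noise_sigma:
            continue  # likely pure background split in half by Otsu
        labels = sk_label(fg, connectivity=2)
        props = regionprops(labels)
        center = np.array([cell.shape[0] / 2.0, cell.shape[1] / 2.0])
        props = [p for p in props if p.area >= min_foreground_px] or props
        best = min(props, key=lambda p: float(np.hypot(*(np.array(p.centroid) - center))))
        area = int(best.area)
        if area < min_foreground_px:
            continue
        perimeter = float(best.perimeter) if best.perimeter > 0 else 1.0
        circularity = min(1.0, 4.0 * math.pi * area / perimeter ** 2)
        comp = labels == best.label
        border = np.zeros_like(comp)
        border[0], border[-1] = True, True
        border[:, 0], border[:, -1] = True, True
        on_border = int((comp & border).sum())
        record.update({
            "size": float(area), "circularity": circularity,
            "edge_touching": on_border > edge_fraction * perimeter,
            "empty": False,
        })
    return pd.DataFrame(rows)
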