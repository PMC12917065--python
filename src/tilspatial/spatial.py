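"""Spatial preparation: nearest distances, TIL filtering, quadrat counting
and kernel intensity maps.

The central object is the :class:`QuadratGrid`: a regular tessellation of
the subject's observation window into square quadrats (default 0.5 mm =
500 um on a side) with paired (cancer, CD8+) counts per quadrat.  Quadrats
that contain neither cell type — in tissue terms, quadrats outside the
cancer region — are flagged inactive and excluded from downstream
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import SubjectPattern, Window

logger = logging.getLogger(__name__)

UM_PER_MM = 1e3

DEFAULT_QUADRAT_MM = 0.5
DEFAULT_TIL_THRESHOLD_UM = 50.0


@dataclass
class QuadratGrid:
    """Fixed-size rectangular tessellation with per-quadrat class counts.

    ``active_mask`` is False exactly where both counts are zero.  Count
    matrices are indexed ``[row, col]`` with row 0 at the window's minimum
    y edge.
    """

    subject_id: str
    origin: tuple[float, float]  # (x0, y0) mm
    cell_size: float  # mm
    n_rows: int
    n_cols: int
    cancer_counts: np.ndarray
    cd8_counts: np.ndarray

    @property
    def active_mask(self) -> np.ndarray:
        return (self.cancer_counts > 0) | (self.cd8_counts > 0)

    @property
    def n_active(self) -> int:
        return int(self.active_mask.sum())

    def active_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(cancer, cd8) count vectors over active quadrats, row-major order."""
        m = self.active_mask
        return self.cancer_counts[m], self.cd8_counts[m]

    def to_long(self) -> "pd.DataFrame":
        import pandas as pd

        rows, cols = np.indices((self.n_rows, self.n_cols))
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "row": rows.ravel(),
                "col": cols.ravel(),
                "cancer_count": self.cancer_counts.ravel(),
                "cd8_count": self.cd8_counts.ravel(),
                "active": self.active_mask.ravel(),
            }
        )


@dataclass
class QuadratSummary:
    """Quadrat-wise mean and sample SD per class, over active quadrats."""

    subject_id: str
    n_active: int
    quadrat_mean_cancer: float
    quadrat_sd_cancer: float
    quadrat_mean_cd8: float
    quadrat_sd_cd8: float


@dataclass
class DensityMap:
    """Kernel-smoothed intensity raster, cells per mm^2."""

    values: np.ndarray  # (n_rows, n_cols)
    origin: tuple[float, float]
    pixel_size: float  # mm
    bandwidth: float  # mm
    kernel: str = "quartic"


def nearest_cancer_distance(
    cd8_points: np.ndarray, cancer_points: np.ndarray
) -> np.ndarray:
    """Euclidean distance from each CD8+ cell to its nearest cancer cell.

    Inputs are (n, 2) arrays in mm; the result is in um, matching the
    platform's exported distance unit.
    """
    cancer_points = np.asarray(cancer_points, dtype=float).reshape(-1, 2)
    if len(cancer_points) == 0:
        raise ValueError("cannot compute nearest cancer distance: no cancer cells")
    cd8_points = np.asarray(cd8_points, dtype=float).reshape(-1, 2)
    if len(cd8_points) == 0:
        return np.empty(0)
    d_mm, _ = cKDTree(cancer_points).query(cd8_points, k=1)
    return d_mm * UM_PER_MM


def filter_tils(
    pattern: SubjectPattern,
    threshold_um: float = DEFAULT_TIL_THRESHOLD_UM,
    use_precomputed: bool = True,
) -> SubjectPattern:
    """Restrict CD8+ cells to tumor-infiltrating lymphocytes.

    Keeps CD8+ cells whose distance to the tumor gland is <= ``threshold_um``
    (default 50 um).  The platform-provided distance column is used when
    present (it measures distance to annotated gland objects); otherwise the
    nearest cancer-cell centroid distance stands in, and the choice is
    recorded in ``dist_source``.  Cancer cells are unchanged.  Idempotent,
    and monotone in the threshold.
    """
    if use_precomputed and pattern.cd8_dist_um is not None:
        dist = np.asarray(pattern.cd8_dist_um, dtype=float)
        source = "platform"
    else:
        dist = nearest_cancer_distance(pattern.cd8, pattern.cancer)
        source = "nearest-centroid"
    keep = dist <= threshold_um
    logger.info(
        "subject %s: TIL filter (%s, <=%g um) kept %d/%d CD8+ cells",
        pattern.subject_id, source, threshold_um, keep.sum(), len(keep),
    )
    return SubjectPattern(
        subject_id=pattern.subject_id,
        cancer=pattern.cancer,
        cd8=pattern.cd8[keep],
        window=pattern.window,
        cd8_dist_um=dist[keep],
        dist_source=source,
        til_filtered=True,
    )


def _bin_indices(coords: np.ndarray, lo: float, size: float, n_bins: int) -> np.ndarray:
    # half-open cells [lo + j*size, lo + (j+1)*size); final bin closed above
    idx = np.floor((coords - lo) / size).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def make_quadrat_grid(
    pattern: SubjectPattern, cell_size: float = DEFAULT_QUADRAT_MM
) -> QuadratGrid:
    """Tessellate the window into square quadrats and count both classes.

    The grid is anchored at the window's minimum corner; column/row numbers
    are ``ceil(extent / cell_size)``, so edge quadrats may extend past the
    window.  Points are assigned by the half-open rule (a point on an
    interior boundary belongs to the higher-index quadrat) with the final
    row/column closed so no point at the maximum edge is lost.
    """
    w = pattern.window
    if w.area <= 0:
        raise ValueError("window must have positive area")
    n_cols = max(1, int(np.ceil(w.width / cell_size - 1e-12)))
    n_rows = max(1, int(np.ceil(w.height / cell_size - 1e-12)))
    counts = {}
    for name, pts in (("cancer", pattern.cancer), ("cd8", pattern.cd8)):
        mat = np.zeros((n_rows, n_cols), dtype=int)
        if len(pts):
            j = _bin_indices(pts[:, 0], w.x0, cell_size, n_cols)
            i = _bin_indices(pts[:, 1], w.y0, cell_size, n_rows)
            np.add.at(mat, (i, j), 1)
        counts[name] = mat
    return QuadratGrid(
        subject_id=pattern.subject_id,
        origin=(w.x0, w.y0),
        cell_size=cell_size,
        n_rows=n_rows,
        n_cols=n_cols,
        cancer_counts=counts["cancer"],
        cd8_counts=counts["cd8"],
    )


def quadrat_summaries(grid: QuadratGrid) -> QuadratSummary:
    """Quadrat-wise mean and sample SD (ddof=1) over active quadrats."""
    cancer, cd8 = grid.active_counts()
    n = len(cancer)
    if n == 0:
        raise ValueError(f"subject {grid.subject_id}: no active quadrats")
    if n == 1:
        logger.warning(
            "subject %s: single active quadrat, SD reported as 0", grid.subject_id
        )
        sd_cancer = sd_cd8 = 0.0
    else:
        sd_cancer = float(np.std(cancer, ddof=1))
        sd_cd8 = float(np.std(cd8, ddof=1))
    return QuadratSummary(
        subject_id=grid.subject_id,
        n_active=n,
        quadrat_mean_cancer=float(np.mean(cancer)),
        quadrat_sd_cancer=sd_cancer,
        quadrat_mean_cd8=float(np.mean(cd8)),
        quadrat_sd_cd8=sd_cd8,
    )


def quartic_kernel(u: np.ndarray) -> np.ndarray:
    """Radially symmetric quartic (biweight) kernel, unit mass in 2D.

    K(u) = (3/pi) (1 - ||u||^2)^2 for ||u|| <= 1, else 0.
    """
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    inside = u <= 1.0
    out[inside] = (3.0 / np.pi) * (1.0 - u[inside] ** 2) ** 2
    return out


def density_map(
    points: np.ndarray,
    window: Window,
    bandwidth: float = 0.25,
    resolution: float = 0.05,
) -> DensityMap:
    """Quartic-kernel intensity surface on a regular raster.

    Each point contributes kernel mass 1, so the discrete integral of the
    surface approximates the point count (no edge correction; maps are
    presentation-layer only).  ``bandwidth`` is the kernel support radius
    in mm; ``resolution`` the raster pixel size in mm.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        raise ValueError("density_map needs at least one point")
    n_cols = max(1, int(np.ceil(window.width / resolution)))
    n_rows = max(1, int(np.ceil(window.height / resolution)))
    xc = window.x0 + (np.arange(n_cols) + 0.5) * resolution
    yc = window.y0 + (np.arange(n_rows) + 0.5) * resolution
    values = np.zeros((n_rows, n_cols))
    # accumulate per point over its local pixel neighbourhood only
    for px, py in points:
        j0 = max(0, int((px - bandwidth - window.x0) / resolution))
        j1 = min(n_cols, int((px + bandwidth - window.x0) / resolution) + 1)
        i0 = max(0, int((py - bandwidth - window.y0) / resolution))
        i1 = min(n_rows, int((py + bandwidth - window.y0) / resolution) + 1)
        if j0 >= j1 or i0 >= i1:
            continue
        dx = (xc[j0:j1] - px) / bandwidth
        dy = (yc[i0:i1] - py) / bandwidth
        r = np.sqrt(dy[:, None] ** 2 + dx[None, :] ** 2)
        values[i0:i1, j0:j1] += quartic_kernel(r) / bandwidth**2
    return DensityMap(
        values=values,
        origin=(window.x0, window.y0),
        pixel_size=resolution,
        bandwidth=bandwidth,
    )


def write_density_raster(dm: DensityMap, path) -> None:
    """Delimited raster with a world-file-style header (mm units)."""
    with open(path, "w") as fh:
        fh.write(f"# origin_x_mm {dm.origin[0]:.6f}\n")
        fh.write(f"# origin_y_mm {dm.origin[1]:.6f}\n")
        fh.write(f"# pixel_size_mm {dm.pixel_size:.6f}\n")
        fh.write(f"# bandwidth_mm {dm.bandwidth:.6f}\n")
        fh.write(f"# kernel {dm.kernel}\n")
        np.savetxt(fh, dm.values, fmt="%.6f", delimiter="\t")
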