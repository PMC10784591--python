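"""KDE cluster segmentation and blink-corrected molecule counting.

The existence-probability map of a localization dataset is the average of
per-localization isotropic Gaussian kernels,

    p_i(x, y) = N(( x_i, y_i ), (A u_i)^2 I),     p = (1/N) sum_i p_i,

with kernel SD proportional to the localization uncertainty ``u_i``
(coefficient ``A``, default 6).  The map histogram is bimodal — dense
cluster pixels against sparse background — so a classical Otsu threshold
separates the two; 8-connected supra-threshold components are clusters.
Localization counts inside each cluster mask divided by the blinking
multiplicity ``1 + <N_blink>`` give molecule counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from scipy.ndimage import binary_erosion

from .io import FieldBounds, LocalizationTable

DEFAULT_A = 6.0
DEFAULT_GRID_PIXEL_NM = 20.0
DEFAULT_MIN_CLUSTER_PIXELS = 4
KERNEL_TRUNCATION_SD = 4.0


@dataclass
class KDEMap:
    """Rasterized existence-probability map."""

    grid: np.ndarray  # (ny, nx), row i = y band, col j = x band
    grid_pixel_nm: float
    origin_nm: tuple[float, float]  # (x0, y0) of pixel (0, 0)
    A: float
    n_spots_used: int
    excluded: int = 0

    @property
    def pixel_area_nm2(self) -> float:
        return self.grid_pixel_nm**2

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin_nm
        ny, nx = self.grid.shape
        xc = x0 + (np.arange(nx) + 0.5) * self.grid_pixel_nm
        yc = y0 + (np.arange(ny) + 0.5) * self.grid_pixel_nm
        return xc, yc


@dataclass
class ClusterSet:
    """Labeled cluster masks with per-cluster records.

    ``clusters`` columns: id, n_pixels, area_um2, localization_count,
    corrected_count, centroid_x, centroid_y (nm).
    """

    label_map: np.ndarray  # 0 = outside
    grid_pixel_nm: float
    origin_nm: tuple[float, float]
    clusters: pd.DataFrame
    boundaries: dict[int, np.ndarray] = field(default_factory=dict)
    multiplicity: float = 1.0
    threshold: float = float("nan")
    n_outside: int = 0

    def __len__(self) -> int:
        return len(self.clusters)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Cluster label (0 = outside) under each (x, y) position in nm."""
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        x0, y0 = self.origin_nm
        j = np.floor((x - x0) / self.grid_pixel_nm).astype(int)
        i = np.floor((y - y0) / self.grid_pixel_nm).astype(int)
        ny, nx = self.label_map.shape
        ok = (i >= 0) & (i < ny) & (j >= 0) & (j < nx)
        out = np.zeros(len(x), dtype=self.label_map.dtype)
        out[ok] = self.label_map[i[ok], j[ok]]
        return out


@dataclass
class ClusterStats:
    """Summary statistics of corrected molecule counts per cluster."""

    mean_per_cluster: float | None
    per_cell_means: dict[str, float]
    per_cell_mean: float | None
    per_cell_sem: float | None
    large_cluster_density: dict[str, float]  # molecules in large clusters per um^2
    n_clusters: int
    large_threshold: float


def filter_uncertainties(
    table: LocalizationTable, low_pct: float = 1.0, high_pct: float = 99.0
) -> LocalizationTable:
    """Drop localizations with extreme uncertainty (likely noise).

    Retains rows whose uncertainty lies inside the [low_pct, high_pct]
    percentile band of the table's uncertainty distribution.
    """
    if not 0.0 <= low_pct < high_pct <= 100.0:
        raise ValueError("require 0 <= low_pct < high_pct <= 100")
    u = table.uncertainty
    lo, hi = np.percentile(u, [low_pct, high_pct])
    keep = (u >= lo) & (u <= hi)
    if not keep.any():
        raise ValueError("uncertainty band removed every localization")
    out = table.with_df(table.df[keep])
    out.df.attrs["excluded_by_uncertainty"] = int((~keep).sum())
    return out


def compute_kde_map(
    table: LocalizationTable,
    A: float = DEFAULT_A,
    grid_pixel_nm: float = DEFAULT_GRID_PIXEL_NM,
) -> KDEMap:
    """Existence-probability map: the average of truncated Gaussian kernels.

    Each localization contributes an isotropic Gaussian of SD ``A * u_i``
    evaluated at pixel centers and truncated where either axis offset
    exceeds ``4 * A * u_i``.
    """
    if len(table) == 0:
        raise ValueError("cannot build a KDE map from an empty table")
    if A <= 0:
        raise ValueError("A must be positive")
    fb = table.field_bounds
    nx = int(np.ceil(fb.width / grid_pixel_nm))
    ny = int(np.ceil(fb.height / grid_pixel_nm))
    x, y, u = table.x, table.y, table.uncertainty
    sigmas = A * u
    if grid_pixel_nm > sigmas.min():
        warnings.warn("grid_pixel_nm exceeds the smallest kernel SD: under-resolved")
    xc = fb.x0 + (np.arange(nx) + 0.5) * grid_pixel_nm
    yc = fb.y0 + (np.arange(ny) + 0.5) * grid_pixel_nm
    grid = np.zeros((ny, nx))
    trunc = KERNEL_TRUNCATION_SD
    for xi, yi, si in zip(x, y, sigmas):
        r = trunc * si
        j0, j1 = np.searchsorted(xc, [xi - r, xi + r])
        i0, i1 = np.searchsorted(yc, [yi - r, yi + r])
        if j0 == j1 or i0 == i1:
            continue
        gx = np.exp(-0.5 * ((xc[j0:j1] - xi) / si) ** 2)
        gy = np.exp(-0.5 * ((yc[i0:i1] - yi) / si) ** 2)
        grid[i0:i1, j0:j1] += np.outer(gy, gx) / (2.0 * np.pi * si**2)
    grid /= len(table)
    return KDEMap(
        grid=grid,
        grid_pixel_nm=grid_pixel_nm,
        origin_nm=(fb.x0, fb.y0),
        A=A,
        n_spots_used=len(table),
        excluded=int(table.df.attrs.get("excluded_by_uncertainty", 0)),
    )


def otsu_threshold(kde_map: KDEMap | np.ndarray, nbins: int = 256) -> float:
    """Classical Otsu threshold on the histogram of map values.

    Exhaustively scores ``nbins`` equal-width candidate levels over
    [min(p), max(p)] by between-class variance; ties break toward the
    lower threshold.  Returns a level with min(p) < theta <= max(p).
    """
    values = kde_map.grid.ravel() if isinstance(kde_map, KDEMap) else np.asarray(kde_map).ravel()
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise ValueError("constant map: Otsu threshold undefined")
    counts, edges = np.histogram(values, bins=nbins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts.astype(float)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    mean_all = cum_m[-1] / total
    # candidate thresholds: interior bin edges; class 0 = bins below edge k
    w0 = cum_w[:-1] / total
    m0 = np.divide(cum_m[:-1], cum_w[:-1], out=np.zeros(nbins - 1), where=cum_w[:-1] > 0)
    w1 = 1.0 - w0
    m1 = np.divide(
        cum_m[-1] - cum_m[:-1], total - cum_w[:-1], out=np.zeros(nbins - 1),
        where=(total - cum_w[:-1]) > 0,
    )
    valid = (w0 > 0) & (w1 > 0)
    between = np.where(valid, w0 * w1 * (m0 - m1) ** 2, -np.inf)
    k = int(np.argmax(between))  # argmax returns the first (lowest) maximizer
    return float(edges[k + 1])


def segment_clusters(
    kde_map: KDEMap,
    threshold: float,
    multiplicity: float,
    table: LocalizationTable,
    min_cluster_pixels: int = DEFAULT_MIN_CLUSTER_PIXELS,
) -> ClusterSet:
    """Binarize the map at ``threshold`` and count molecules per cluster.

    8-connected components of ``p >= threshold`` with at least
    ``min_cluster_pixels`` pixels become clusters; each localization whose
    pixel carries a cluster label increments that cluster's localization
    count, and ``corrected_count = localization_count / multiplicity``.
    Boundary pixels are mask pixels adjacent to background.
    """
    grid = kde_map.grid
    if threshold >= grid.max():
        warnings.warn("threshold at or above map maximum: no clusters")
        empty = pd.DataFrame(
            columns=["id", "n_pixels", "area_um2", "localization_count",
                     "corrected_count", "centroid_x", "centroid_y"]
        )
        return ClusterSet(
            label_map=np.zeros_like(grid, dtype=np.int32),
            grid_pixel_nm=kde_map.grid_pixel_nm,
            origin_nm=kde_map.origin_nm,
            clusters=empty,
            multiplicity=multiplicity,
            threshold=threshold,
            n_outside=len(table),
        )
    mask = grid >= threshold
    labels = cc_label(mask, connectivity=2)
    ids, sizes = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[sizes >= min_cluster_pixels]
    relabel = np.zeros(labels.max() + 1, dtype=np.int32)
    relabel[keep] = np.arange(1, len(keep) + 1)
    label_map = relabel[labels]

    cs = ClusterSet(
        label_map=label_map,
        grid_pixel_nm=kde_map.grid_pixel_nm,
        origin_nm=kde_map.origin_nm,
        clusters=pd.DataFrame(),
        multiplicity=multiplicity,
        threshold=threshold,
    )
    loc_labels = cs.contains(table.x, table.y)
    n_clusters = len(keep)
    counts = np.bincount(loc_labels, minlength=n_clusters + 1)
    px_nm = kde_map.grid_pixel_nm
    x0, y0 = kde_map.origin_nm
    rows = []
    boundaries: dict[int, np.ndarray] = {}
    for cid in range(1, n_clusters + 1):
        m = label_map == cid
        npix = int(m.sum())
        ii, jj = np.nonzero(m)
        edge = m & ~binary_erosion(m)
        ei, ej = np.nonzero(edge)
        boundaries[cid] = np.column_stack(
            [x0 + (ej + 0.5) * px_nm, y0 + (ei + 0.5) * px_nm]
        )
        rows.append(
            {
                "id": cid,
                "n_pixels": npix,
                "area_um2": npix * px_nm**2 / 1e6,
                "localization_count": int(counts[cid]),
                "corrected_count": counts[cid] / multiplicity,
                "centroid_x": x0 + (jj.mean() + 0.5) * px_nm,
                "centroid_y": y0 + (ii.mean() + 0.5) * px_nm,
            }
        )
    cs.clusters = pd.DataFrame(
        rows,
        columns=["id", "n_pixels", "area_um2", "localization_count",
                 "corrected_count", "centroid_x", "centroid_y"],
    )
    cs.boundaries = boundaries
    cs.n_outside = int(counts[0])
    return cs


def cluster_statistics(
    clusters_by_cell: dict[str, ClusterSet] | ClusterSet,
    cell_areas_um2: dict[str, float] | float | None = None,
    large_threshold: float = 800.0,
) -> ClusterStats:
    """Per-cluster and per-cell averages of corrected molecule counts.

    ``large_cluster_density`` is the summed corrected count over clusters
    whose corrected count exceeds ``large_threshold``, per square micron
    of cell area (one value per cell).
    """
    if isinstance(clusters_by_cell, ClusterSet):
        clusters_by_cell = {"cell0": clusters_by_cell}
        if cell_areas_um2 is not None and not isinstance(cell_areas_um2, dict):
            cell_areas_um2 = {"cell0": float(cell_areas_um2)}
    all_counts: list[np.ndarray] = []
    per_cell_means: dict[str, float] = {}
    large_density: dict[str, float] = {}
    for cell, cs in clusters_by_cell.items():
        counts = cs.clusters["corrected_count"].to_numpy(float)
        if len(counts):
            all_counts.append(counts)
            per_cell_means[cell] = float(counts.mean())
        if cell_areas_um2 is not None:
            area = cell_areas_um2[cell]
            if area <= 0:
                raise ValueError(f"cell {cell}: area must be positive")
            big = counts[counts > large_threshold] if len(counts) else np.array([])
            large_density[cell] = float(big.sum() / area)
    if not all_counts:
        warnings.warn("no clusters: statistics reported as absent")
        return ClusterStats(None, {}, None, None, large_density, 0, large_threshold)
    pooled = np.concatenate(all_counts)
    means = np.array(list(per_cell_means.values()))
    sem = float(means.std(ddof=1) / np.sqrt(len(means))) if len(means) > 1 else None
    return ClusterStats(
        mean_per_cluster=float(pooled.mean()),
        per_cell_means=per_cell_means,
        per_cell_mean=float(means.mean()),
        per_cell_sem=sem,
        large_cluster_density=large_density,
        n_clusters=len(pooled),
        large_threshold=large_threshold,
    )


def masks_from_discs(
    centers: np.ndarray,
    radius_nm: float,
    field_bounds: FieldBounds,
    grid_pixel_nm: float = DEFAULT_GRID_PIXEL_NM,
) -> ClusterSet:
    """Rasterize circular discs into a synthetic ClusterSet.

    Convenience for building ground-truth masks (e.g. to host simulated
    trajectories) without running the KDE pipeline.
    """
    centers = np.atleast_2d(np.asarray(centers, float))
    nx = int(np.ceil(field_bounds.width / grid_pixel_nm))
    ny = int(np.ceil(field_bounds.height / grid_pixel_nm))
    xc = field_bounds.x0 + (np.arange(nx) + 0.5) * grid_pixel_nm
    yc = field_bounds.y0 + (np.arange(ny) + 0.5) * grid_pixel_nm
    label_map = np.zeros((ny, nx), dtype=np.int32)
    rows = []
    boundaries = {}
    for cid, (cx, cy) in enumerate(centers, start=1):
        dist2 = (xc[None, :] - cx) ** 2 + (yc[:, None] - cy) ** 2
        m = dist2 <= radius_nm**2
        label_map[m] = cid
        edge = m & ~binary_erosion(m)
        ei, ej = np.nonzero(edge)
        boundaries[cid] = np.column_stack(
            [field_bounds.x0 + (ej + 0.5) * grid_pixel_nm,
             field_bounds.y0 + (ei + 0.5) * grid_pixel_nm]
        )
        ii, jj = np.nonzero(m)
        rows.append(
            {
                "id": cid, "n_pixels": int(m.sum()),
                "area_um2": m.sum() * grid_pixel_nm**2 / 1e6,
                "localization_count": 0, "corrected_count": 0.0,
                "centroid_x": cx, "centroid_y": cy,
            }
        )
    return ClusterSet(
        label_map=label_map,
        grid_pixel_nm=grid_pixel_nm,
        origin_nm=(field_bounds.x0, field_bounds.y0),
        clusters=pd.DataFrame(rows),
        boundaries=boundaries,
    )
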