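"""Coordinate-based colocalization (CBC) of two localization channels.

For each localization A_i, the radial density profiles of its own channel
and of the other channel,

    D_Ai,A(r_j) = N_Ai,A(r_j) / N_Ai,A(R_max) * R_max^2 / r_j^2
    D_Ai,B(r_j) = N_Ai,B(r_j) / N_Ai,B(R_max) * R_max^2 / r_j^2

are compared over r_j = dR, 2 dR, ..., R_max by Spearman rank correlation
S_Ai; the CBC score weights it by the nearest-neighbour distance E_Ai,B to
the other channel,

    C_Ai = S_Ai * exp(-E_Ai,B / R_max),

ranging from -1 (segregated) through 0 (random) to +1 (colocalized).  A
uniform channel gives D(r) = 1 at every radius.  The neighbour counts
N_Ai,A exclude A_i itself.  Scores are skipped where the counts within
R_max are too small for a stable profile.  A 180-degree field rotation of
one channel serves as the negative control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from .io import LocalizationTable


@dataclass(frozen=True)
class CBCParams:
    R_max: float = 500.0
    dR: float = 50.0
    min_count: int | None = None  # default (R_max/dR) * 5
    skip_rule: str = "and"  # skip when BOTH (and) / EITHER (or) count < min_count

    def __post_init__(self) -> None:
        nb = self.R_max / self.dR
        if abs(nb - round(nb)) > 1e-9 or nb <= 0:
            raise ValueError("R_max must be a positive integer multiple of dR")
        if self.skip_rule not in ("and", "or"):
            raise ValueError("skip_rule must be 'and' or 'or'")
        if self.min_count is None:
            object.__setattr__(self, "min_count", int(round(nb)) * 5)

    @property
    def radii(self) -> np.ndarray:
        n = int(round(self.R_max / self.dR))
        return self.dR * np.arange(1, n + 1)


@dataclass
class CBCResult:
    scores_A_rel_B: np.ndarray  # per A-localization; NaN where skipped
    scores_B_rel_A: np.ndarray
    params: CBCParams
    n_skipped_A: int = 0
    n_skipped_B: int = 0

    def computed(self, direction: str = "A") -> np.ndarray:
        s = self.scores_A_rel_B if direction == "A" else self.scores_B_rel_A
        return s[np.isfinite(s)]


def _directional_scores(
    pts_self: np.ndarray, pts_other: np.ndarray, params: CBCParams
) -> np.ndarray:
    """CBC scores of every point in pts_self relative to pts_other."""
    radii = params.radii
    R = params.R_max
    tree_self = cKDTree(pts_self)
    tree_other = cKDTree(pts_other)
    nn_dist, _ = tree_other.query(pts_self, k=1)
    # query_ball_point at R_max once; cumulative counts via distance sorting
    neigh_self = tree_self.query_ball_point(pts_self, R)
    neigh_other = tree_other.query_ball_point(pts_self, R)
    scores = np.full(len(pts_self), np.nan)
    jsq = np.arange(1, len(radii) + 1, dtype=float) ** 2
    for i, p in enumerate(pts_self):
        idx_s = np.asarray(neigh_self[i], dtype=int)
        idx_s = idx_s[idx_s != i]  # self-exclusion
        idx_o = np.asarray(neigh_other[i], dtype=int)
        n_s_max = len(idx_s)
        n_o_max = len(idx_o)
        low_s = n_s_max < params.min_count
        low_o = n_o_max < params.min_count
        skip = (low_s and low_o) if params.skip_rule == "and" else (low_s or low_o)
        if skip or n_s_max == 0 or n_o_max == 0:
            continue
        d_s = np.sort(np.hypot(*(pts_self[idx_s] - p).T))
        d_o = np.sort(np.hypot(*(pts_other[idx_o] - p).T))
        counts_s = np.searchsorted(d_s, radii, side="right")
        counts_o = np.searchsorted(d_o, radii, side="right")
        # Rank on counts_j / j^2, a positive scalar multiple of the density
        # profile D(r_j): integer operands make mathematically tied profile
        # values exactly tied floats, so Spearman tie handling is stable.
        key_s = counts_s / jsq
        key_o = counts_o / jsq
        if len(np.unique(key_s)) < 3 or len(np.unique(key_o)) < 3:
            continue  # Spearman undefined on (near-)constant profiles
        rho = spearmanr(key_s, key_o).statistic
        if not np.isfinite(rho):
            continue
        scores[i] = rho * np.exp(-nn_dist[i] / R)
    return scores


def cbc_scores(
    tableA: LocalizationTable, tableB: LocalizationTable, params: CBCParams = CBCParams()
) -> CBCResult:
    """Per-localization CBC scores in both directions.

    Requires both tables to share a coordinate frame (equal declared field
    bounds).  Scores are NaN where the minimum-count rule fires or where
    the rank correlation is undefined.
    """
    fa, fb = tableA.field_bounds, tableB.field_bounds
    if fa is not None and fb is not None:
        if not np.allclose([fa.x0, fa.y0, fa.x1, fa.y1], [fb.x0, fb.y0, fb.x1, fb.y1]):
            raise ValueError("channel tables declare different field bounds")
    ptsA = np.column_stack([tableA.x, tableA.y])
    ptsB = np.column_stack([tableB.x, tableB.y])
    sA = _directional_scores(ptsA, ptsB, params)
    sB = _directional_scores(ptsB, ptsA, params)
    return CBCResult(
        scores_A_rel_B=sA,
        scores_B_rel_A=sB,
        params=params,
        n_skipped_A=int(np.isnan(sA).sum()),
        n_skipped_B=int(np.isnan(sB).sum()),
    )


def rotate_control(
    table: LocalizationTable, center: tuple[float, float] | None = None
) -> LocalizationTable:
    """Rotate a channel by 180 degrees about ``center`` (default: field center).

    Maps (x, y) -> (2 cx - x, 2 cy - y); frames, uncertainties and
    intensities are preserved.  An involution and an isometry.
    """
    if center is None:
        if table.field_bounds is None:
            raise ValueError("need field bounds or an explicit center")
        center = table.field_bounds.center
    cx, cy = center
    df = table.df.copy()
    df["x"] = 2.0 * cx - df["x"]
    df["y"] = 2.0 * cy - df["y"]
    return table.with_df(df)


def cbc_histogram(
    scores: np.ndarray, bin_width: float = 0.1
) -> dict:
    """Normalized score histogram and the [0.7, 1.0] high-bin sum.

    ``bin_width`` must divide 0.3 so the [0.7, 1.0] band is whole bins.
    Frequencies are normalized to sum to 1 over computed scores.
    """
    k = 0.3 / bin_width
    if abs(k - round(k)) > 1e-9:
        raise ValueError("bin_width must divide 0.3")
    scores = np.asarray(scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    nb = int(round(2.0 / bin_width))
    edges = -1.0 + bin_width * np.arange(nb + 1)
    if len(scores) == 0:
        warnings.warn("no computed CBC scores: histogram absent")
        return {"edges": edges, "frequency": None, "high_bin_sum": None, "n": 0}
    counts, _ = np.histogram(scores, bins=edges)
    freq = counts / counts.sum()
    in_band = (edges[:-1] >= 0.7 - 1e-12) & (edges[1:] <= 1.0 + 1e-12)
    return {
        "edges": edges,
        "frequency": freq,
        "high_bin_sum": float(freq[in_band].sum()),
        "n": int(len(scores)),
    }


def high_bin_sum_by_cell(scores_by_cell: dict[str, np.ndarray], bin_width: float = 0.1) -> dict:
    """Across-cell mean and SEM of the [0.7, 1.0] high-bin sum."""
    vals = []
    for cell, s in scores_by_cell.items():
        h = cbc_histogram(s, bin_width)
        if h["high_bin_sum"] is not None:
            vals.append(h["high_bin_sum"])
    if not vals:
        return {"mean": None, "sem": None, "n_cells": 0}
    vals = np.asarray(vals)
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else None
    return {"mean": float(vals.mean()), "sem": sem, "n_cells": len(vals)}
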