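"""Synthetic SMLM data with the statistical structure the analysis assumes.

The photophysics follows a four-state kinetic scheme for a photoconvertible
fluorescent protein: nonactive (N) -> active/emitting (A) by photoactivation
at rate ``k_a``; from A the molecule either photobleaches (B, rate ``k_b``)
or enters a reversible dark state (D, rate ``k_d``); recovery D -> A is a
two-component exponential mixture with fast rate ``k_r2`` (weight ``alpha``)
and slow rate ``k_r1``.  Consequences used throughout the package:

* the number of dark excursions before bleaching (the blink count) is
  geometric, ``P(N_blink = n) = h^n (1 - h)`` with ``h = k_d/(k_d + k_b)``,
  hence ``<N_blink> = k_d/k_b``;
* on-times are exponential with rate ``k_b + k_d``;
* each emission burst (on-interval) yields one localization, so a molecule
  produces ``1 + N_blink`` localizations on average ``1/(1 - h)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FieldBounds, LocalizationTable, Trajectory

#: default single-molecule localization precision, nm
DEFAULT_PRECISION_NM = 20.0


@dataclass(frozen=True)
class KineticModelParams:
    """Rates (1/s) of the four-state photophysics scheme."""

    k_a: float = 0.05
    k_b: float = 10.0
    k_d: float = 17.0
    k_r1: float = 2.0
    k_r2: float = 50.0
    alpha: float = 0.2

    def __post_init__(self) -> None:
        for name in ("k_a", "k_b", "k_d", "k_r1", "k_r2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k_b <= 0:
            raise ValueError("k_b must be positive (no emission termination)")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def h(self) -> float:
        """Dark-branch probability k_d / (k_d + k_b)."""
        return self.k_d / (self.k_d + self.k_b)

    @property
    def mean_nblink(self) -> float:
        return self.k_d / self.k_b

    @property
    def on_rate(self) -> float:
        """Decay rate of the on-time distribution, k_b + k_d."""
        return self.k_b + self.k_d


@dataclass
class ClusterSpec:
    """Geometry of a clustered 2-D molecule field."""

    centers: np.ndarray  # (n_clusters, 2) in nm
    molecules_per_cluster: int = 52
    cluster_radius_nm: float = 60.0
    background_density_um2: float = 0.0  # molecules per square micron
    precision_nm: float = DEFAULT_PRECISION_NM
    field_bounds: FieldBounds | None = None

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.molecules_per_cluster < 0:
            raise ValueError("molecules_per_cluster must be >= 0")
        if self.precision_nm <= 0:
            raise ValueError("precision_nm must be positive")


@dataclass
class TrajectorySpec:
    """Kinetics of tracked molecules transiently binding to clusters."""

    residency_tau_ms: float = 150.0
    bleach_tau_s: float = 7.3
    diffusion_step_nm: float = 150.0
    free_tau_ms: float = 300.0  # mean unbound period between dwells
    n_trajectories: int = 100
    frame_interval_ms: float = 33.0

    def __post_init__(self) -> None:
        if self.residency_tau_ms <= 0:
            raise ValueError("residency_tau_ms must be positive")
        if self.bleach_tau_s <= 0:
            raise ValueError("bleach_tau_s must be positive")


@dataclass
class SimulatedTrace:
    """Ground-truth emission history of one molecule."""

    molecule_id: int
    activation_time_s: float
    on_times_s: np.ndarray  # one per on-interval
    dark_times_s: np.ndarray  # one per blink (len = n_blink)
    on_intervals_frames: list[tuple[int, int]]  # (first_frame, last_frame), 1-based

    @property
    def n_blink(self) -> int:
        return len(self.dark_times_s)


def _draw_dark_times(params: KineticModelParams, n: int, rng: np.random.Generator):
    """Dark durations ~ alpha * Exp(k_r2) + (1 - alpha) * Exp(k_r1)."""
    fast = rng.random(n) < params.alpha
    out = np.empty(n)
    if params.k_r2 > 0:
        out[fast] = rng.exponential(1.0 / params.k_r2, fast.sum())
    else:
        out[fast] = np.inf
    if params.k_r1 > 0:
        out[~fast] = rng.exponential(1.0 / params.k_r1, (~fast).sum())
    else:
        out[~fast] = np.inf
    return out


def _interval_to_frames(t0: float, t1: float, dt: float) -> tuple[int, int]:
    """Frame span (1-based) of a continuous on-interval [t0, t1)."""
    f0 = int(np.floor(t0 / dt)) + 1
    f1 = int(np.floor(max(t1 - 1e-12, t0) / dt)) + 1
    return f0, max(f1, f0)


def simulate_emission_traces(
    params: KineticModelParams,
    n_molecules: int,
    frame_interval_ms: float = 33.0,
    n_frames: int = 20000,
    seed: int | np.random.Generator = 0,
) -> list[SimulatedTrace]:
    """Simulate per-molecule emission histories under the kinetic scheme.

    Each molecule activates at Exp(k_a), emits for Exp(k_b + k_d), then
    branches to the dark state with probability h (else bleaches); dark
    times follow the two-component exponential mixture.  The true blink
    structure is preserved: on-intervals remain distinct in the returned
    traces even when the separating dark time is shorter than one frame.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if params.k_b + params.k_d <= 0:
        raise ValueError("k_b + k_d must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dt = frame_interval_ms / 1000.0
    traces: list[SimulatedTrace] = []
    for mol in range(n_molecules):
        t_act = rng.exponential(1.0 / params.k_a) if params.k_a > 0 else 0.0
        t = t_act
        on_times: list[float] = []
        dark_times: list[float] = []
        frames: list[tuple[int, int]] = []
        while True:
            t_on = rng.exponential(1.0 / params.on_rate)
            on_times.append(t_on)
            frames.append(_interval_to_frames(t, t + t_on, dt))
            t += t_on
            if rng.random() < params.h:  # dark excursion
                t_dark = float(_draw_dark_times(params, 1, rng)[0])
                dark_times.append(t_dark)
                t += t_dark
            else:  # photobleach
                break
        traces.append(
            SimulatedTrace(
                molecule_id=mol,
                activation_time_s=t_act,
                on_times_s=np.asarray(on_times),
                dark_times_s=np.asarray(dark_times),
                on_intervals_frames=frames,
            )
        )
    return traces


def _uncertainties(n: int, precision_nm: float, rng: np.random.Generator) -> np.ndarray:
    """Per-localization uncertainty: narrow lognormal around the precision (CV 0.2)."""
    cv = 0.2
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(precision_nm) - 0.5 * sigma**2
    return rng.lognormal(mu, sigma, n)


def _place_molecules(
    spec: ClusterSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """True molecule positions and their cluster ids (-1 = background)."""
    pts = []
    cluster_ids = []
    for ci, (cx, cy) in enumerate(spec.centers):
        n = spec.molecules_per_cluster
        r = spec.cluster_radius_nm * np.sqrt(rng.random(n))
        phi = rng.uniform(0, 2 * np.pi, n)
        pts.append(np.column_stack([cx + r * np.cos(phi), cy + r * np.sin(phi)]))
        cluster_ids.append(np.full(n, ci))
    if spec.background_density_um2 > 0:
        fb = spec.field_bounds
        if fb is None:
            raise ValueError("background placement requires field_bounds")
        area_um2 = fb.width * fb.height / 1e6
        n_bg = rng.poisson(spec.background_density_um2 * area_um2)
        bg = np.column_stack(
            [rng.uniform(fb.x0, fb.x1, n_bg), rng.uniform(fb.y0, fb.y1, n_bg)]
        )
        pts.append(bg)
        cluster_ids.append(np.full(n_bg, -1))
    positions = np.vstack(pts) if pts else np.empty((0, 2))
    return positions, np.concatenate(cluster_ids) if cluster_ids else np.empty(0, int)


def default_field_bounds(spec: ClusterSpec, margin_nm: float = 500.0) -> FieldBounds:
    c = spec.centers
    r = spec.cluster_radius_nm + margin_nm
    return FieldBounds(
        float(c[:, 0].min() - r),
        float(c[:, 1].min() - r),
        float(c[:, 0].max() + r),
        float(c[:, 1].max() + r),
    )


def grid_centers(
    n_clusters: int, spacing_nm: float = 2000.0, origin_nm: float = 1000.0
) -> np.ndarray:
    """Cluster centers on a square grid, a convenient well-separated layout."""
    ncol = int(np.ceil(np.sqrt(n_clusters)))
    idx = np.arange(n_clusters)
    return np.column_stack(
        [origin_nm + (idx % ncol) * spacing_nm, origin_nm + (idx // ncol) * spacing_nm]
    )


def simulate_cluster_field(
    spec: ClusterSpec,
    params: KineticModelParams = KineticModelParams(),
    frame_interval_ms: float = 33.0,
    n_frames: int = 5400,
    seed: int | np.random.Generator = 0,
) -> tuple[LocalizationTable, pd.DataFrame]:
    """Render a clustered molecule field to a localization table.

    Every molecule emits per the kinetic scheme; each emission burst yields
    one localization at the true position plus isotropic Gaussian noise
    (SD ``precision_nm``), stamped at the frame containing the burst
    midpoint.  Bursts whose midpoint falls beyond the acquisition window
    are lost, mirroring a finite recording.

    Returns the table and a ground-truth frame with one row per molecule
    (id, true position, cluster id, true blink count, localization count).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fb = spec.field_bounds or default_field_bounds(spec)
    cr = spec.cluster_radius_nm
    for cx, cy in spec.centers:
        if not (fb.x0 <= cx - cr and cx + cr <= fb.x1 and fb.y0 <= cy - cr and cy + cr <= fb.y1):
            raise ValueError("cluster disc extends outside field_bounds")
    positions, cluster_ids = _place_molecules(spec, rng)
    n_mol = len(positions)
    dt = frame_interval_ms / 1000.0
    t_max = n_frames * dt

    # per-molecule burst counts are geometric by construction of the scheme
    nblink = rng.geometric(1.0 - params.h, n_mol) - 1
    rows = []
    truth_rows = []
    for mol in range(n_mol):
        t = rng.exponential(1.0 / params.k_a) if params.k_a > 0 else 0.0
        n_bursts = nblink[mol] + 1
        n_emitted = 0
        for b in range(n_bursts):
            t_on = rng.exponential(1.0 / params.on_rate)
            mid = t + 0.5 * t_on
            if mid < t_max:
                frame = int(np.floor(mid / dt)) + 1
                rows.append((mol, frame))
                n_emitted += 1
            t += t_on
            if b < n_bursts - 1:
                t += float(_draw_dark_times(params, 1, rng)[0])
        truth_rows.append(
            (mol, positions[mol, 0], positions[mol, 1], cluster_ids[mol], nblink[mol], n_emitted)
        )

    rows_arr = np.asarray(rows, dtype=int).reshape(-1, 2)
    mol_idx = rows_arr[:, 0]
    n_loc = len(mol_idx)
    noise = rng.normal(0.0, spec.precision_nm, (n_loc, 2))
    xy = positions[mol_idx] + noise
    df = pd.DataFrame(
        {
            "frame": rows_arr[:, 1],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "uncertainty": _uncertainties(n_loc, spec.precision_nm, rng),
            "intensity": rng.lognormal(np.log(500.0), 0.35, n_loc),
            "molecule_id": mol_idx,
        }
    ).sort_values("frame", kind="stable").reset_index(drop=True)
    inside = fb.contains(df["x"].to_numpy(), df["y"].to_numpy())
    df = df[inside].reset_index(drop=True)
    table = LocalizationTable(
        df=df, frame_interval_ms=frame_interval_ms, field_bounds=fb
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["molecule_id", "true_x", "true_y", "cluster_id", "n_blink_true", "n_localizations"],
    )
    return table, truth


def add_noise_localizations(
    table: LocalizationTable,
    fraction: float = 0.02,
    seed: int | np.random.Generator = 0,
    u_small_nm: tuple[float, float] = (1.0, 4.0),
    u_large_nm: tuple[float, float] = (80.0, 150.0),
) -> LocalizationTable:
    """Append spurious localizations with out-of-range uncertainties.

    Real localization tables contain false detections whose uncertainty
    estimates fall far outside the single-molecule range; the percentile
    uncertainty filter exists to remove them.  This plants that population
    (half with implausibly small, half with implausibly large uncertainty)
    uniformly over the field so the filter has its genuine target.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(fraction * len(table)))
    if n == 0:
        return table
    fb = table.field_bounds
    n_small = n // 2
    u = np.concatenate(
        [
            rng.uniform(*u_small_nm, n_small),
            rng.uniform(*u_large_nm, n - n_small),
        ]
    )
    max_frame = int(table.df["frame"].max()) if len(table) else 1
    noise = pd.DataFrame(
        {
            "frame": rng.integers(1, max_frame + 1, n),
            "x": rng.uniform(fb.x0, fb.x1, n),
            "y": rng.uniform(fb.y0, fb.y1, n),
            "uncertainty": u,
            "intensity": rng.lognormal(np.log(100.0), 0.5, n),
        }
    )
    if "molecule_id" in table.df.columns:
        noise["molecule_id"] = -1
    df = (
        pd.concat([table.df, noise], ignore_index=True)
        .sort_values("frame", kind="stable")
        .reset_index(drop=True)
    )
    return table.with_df(df)


def simulate_two_channel(
    specA: ClusterSpec,
    specB: ClusterSpec,
    coloc_fraction: float = 1.0,
    params: KineticModelParams = KineticModelParams(),
    seed: int | np.random.Generator = 0,
) -> tuple[LocalizationTable, LocalizationTable, pd.DataFrame]:
    """Two-channel field where a fraction of B clusters share A centers.

    Channel-B clusters are relocated onto randomly chosen A centers with
    probability ``coloc_fraction``; the rest keep their own (independent)
    centers.  Both channels share field bounds and coordinate frame.
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValueError("coloc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    centersB = specB.centers.copy()
    shared = rng.random(len(centersB)) < coloc_fraction
    if shared.any():
        pick = rng.integers(0, len(specA.centers), shared.sum())
        centersB[shared] = specA.centers[pick]
    fb = specA.field_bounds or default_field_bounds(specA)
    specA = ClusterSpec(
        centers=specA.centers,
        molecules_per_cluster=specA.molecules_per_cluster,
        cluster_radius_nm=specA.cluster_radius_nm,
        background_density_um2=specA.background_density_um2,
        precision_nm=specA.precision_nm,
        field_bounds=fb,
    )
    specB = ClusterSpec(
        centers=centersB,
        molecules_per_cluster=specB.molecules_per_cluster,
        cluster_radius_nm=specB.cluster_radius_nm,
        background_density_um2=specB.background_density_um2,
        precision_nm=specB.precision_nm,
        field_bounds=fb,
    )
    tableA, _ = simulate_cluster_field(specA, params, seed=rng)
    tableB, _ = simulate_cluster_field(specB, params, seed=rng)
    tableB.channel = "B"
    pairing = pd.DataFrame(
        {
            "b_cluster": np.arange(len(centersB)),
            "center_x": centersB[:, 0],
            "center_y": centersB[:, 1],
            "shared_with_A": shared,
        }
    )
    return tableA, tableB, pairing


def simulate_trajectories(
    spec: TrajectorySpec,
    clusters: "ClusterSet",
    seed: int | np.random.Generator = 0,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Trajectories alternating free diffusion and cluster-bound dwells.

    A trajectory starts unbound at a random in-field position.  Unbound
    periods last Exp(``free_tau_ms``) during which the position performs a
    Gaussian random walk kept outside cluster masks; each bound period
    teleports the molecule into a random cluster and holds it inside that
    cluster's mask for Exp(``residency_tau_ms``); the trajectory ends at a
    photobleach time Exp(``bleach_tau_s``).  Positions are sampled every
    frame; ground-truth dwell durations (continuous, ms) are returned with
    a censoring flag for dwells cut short by bleaching.
    """
    import warnings

    from .segmentation import ClusterSet  # local import to avoid a cycle

    if not isinstance(clusters, ClusterSet) or clusters.label_map.max() == 0:
        raise ValueError("cluster_masks must be a non-empty ClusterSet")
    if spec.residency_tau_ms < spec.frame_interval_ms / 10.0:
        warnings.warn("residency_tau_ms below frame_interval/10: dwells unresolvable")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lm = clusters.label_map
    px = clusters.grid_pixel_nm
    x0, y0 = clusters.origin_nm
    h_px, w_px = lm.shape
    labels = np.unique(lm[lm > 0])
    # pixel coordinate lists per cluster, for uniform in-mask sampling
    mask_pixels = {int(l): np.argwhere(lm == l) for l in labels}

    def in_mask(x: float, y: float) -> bool:
        i = int((y - y0) // px)
        j = int((x - x0) // px)
        return 0 <= i < h_px and 0 <= j < w_px and lm[i, j] > 0

    dt_ms = spec.frame_interval_ms
    trajectories: list[Trajectory] = []
    dwell_rows = []
    for tid in range(spec.n_trajectories):
        t_bleach_ms = rng.exponential(spec.bleach_tau_s * 1000.0)
        n_frames_total = int(t_bleach_ms // dt_ms) + 1
        # state timeline in continuous ms
        t = 0.0
        bound = False
        dwell_end = 0.0
        cluster_pix = None
        # start free, outside masks
        while True:
            x = rng.uniform(x0, x0 + w_px * px)
            y = rng.uniform(y0, y0 + h_px * px)
            if not in_mask(x, y):
                break
        free_end = rng.exponential(spec.free_tau_ms)
        xs, ys, fs = [], [], []
        for f in range(n_frames_total):
            t = f * dt_ms
            if bound and t >= dwell_end:
                bound = False
                free_end = t + rng.exponential(spec.free_tau_ms)
                # step out of the mask near the cluster
                for _ in range(100):
                    cand_x = x + rng.normal(0, spec.diffusion_step_nm + px)
                    cand_y = y + rng.normal(0, spec.diffusion_step_nm + px)
                    if not in_mask(cand_x, cand_y):
                        x, y = cand_x, cand_y
                        break
            if not bound and t >= free_end:
                bound = True
                dwell = rng.exponential(spec.residency_tau_ms)
                dwell_end = t + dwell
                censored = dwell_end > t_bleach_ms
                dwell_rows.append([tid, dwell, censored, 0])
                cl = int(rng.choice(labels))
                cluster_pix = mask_pixels[cl]
            if bound:
                dwell_rows[-1][3] += 1  # realized in-mask samples
                i, j = cluster_pix[rng.integers(len(cluster_pix))]
                x = x0 + (j + rng.random()) * px
                y = y0 + (i + rng.random()) * px
            else:
                if spec.diffusion_step_nm > 0:
                    for _ in range(100):
                        cand_x = x + rng.normal(0, spec.diffusion_step_nm)
                        cand_y = y + rng.normal(0, spec.diffusion_step_nm)
                        if not in_mask(cand_x, cand_y):
                            x, y = cand_x, cand_y
                            break
            xs.append(x)
            ys.append(y)
            fs.append(f + 1)
        if xs:
            trajectories.append(
                Trajectory(
                    id=f"traj{tid:05d}",
                    frames=np.asarray(fs),
                    x=np.asarray(xs),
                    y=np.asarray(ys),
                    frame_interval_ms=dt_ms,
                )
            )
    truth = pd.DataFrame(
        dwell_rows, columns=["trajectory", "dwell_ms", "censored", "realized_frames"]
    )
    return trajectories, truth
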