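"""Config-driven pipeline runner.

A config is a flat mapping with a ``stages`` list (or single ``stage``),
a ``seed``, an output directory and per-stage parameters; defaults are
the package defaults.  Every stage writes its result tables under
``out_dir`` and appends the parameters it actually used, plus n-in/n-out
counts, to a machine-readable run log (``run_log.json``).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    CBCParams,
    ClusterSpec,
    KineticModelParams,
    cbc_histogram,
    cbc_scores,
    cluster_statistics,
    compute_kde_map,
    filter_uncertainties,
    fit_geometric_nblink,
    fit_lifetime,
    fit_ton_exponential,
    grid_centers,
    group_localizations_into_traces,
    otsu_threshold,
    read_localizations,
    read_trajectories,
    residency_durations,
    rotate_control,
    segment_clusters,
    simulate_cluster_field,
    simulate_two_channel,
    write_localizations,
)
from .io import FieldBounds

logger = logging.getLogger("smlmclust")

KNOWN_STAGES = ("simulate", "calibrate", "segment", "count", "cbc", "recruit")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


def _kinetics(config: dict) -> KineticModelParams:
    kw = {k: config[k] for k in ("k_a", "k_b", "k_d", "k_r1", "k_r2", "alpha") if k in config}
    try:
        return KineticModelParams(**kw)
    except ValueError as e:
        raise ConfigError(str(e)) from e


def _load_table(config: dict, key: str = "input"):
    if key not in config:
        raise ConfigError(f"stage requires '{key}' (a localization CSV path)")
    return read_localizations(
        config[key], frame_interval_ms=config.get("frame_interval_ms", 33.0)
    )


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run the configured stage chain; returns the run log."""
    out_dir = Path(out_dir or config.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages") or [config.get("stage")]
    if not stages or stages == [None]:
        raise ConfigError("config must name a stage or stages")
    for s in stages:
        if s not in KNOWN_STAGES:
            raise ConfigError(f"unknown stage {s!r}; known: {KNOWN_STAGES}")
    seed = int(config.get("seed", 0))
    log: dict = {"seed": seed, "stages": []}
    state: dict = {}
    for stage in stages:
        entry = {"stage": stage, "parameters": {}}
        fn = globals()[f"_stage_{stage}"]
        fn(config, seed, out_dir, state, entry)
        log["stages"].append(entry)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return log


def _stage_simulate(config, seed, out_dir, state, entry):
    n_clusters = int(config.get("n_clusters", 100))
    mpc = int(config.get("molecules_per_cluster", 52))
    spec = ClusterSpec(
        centers=grid_centers(n_clusters, spacing_nm=config.get("spacing_nm", 2000.0)),
        molecules_per_cluster=mpc,
        cluster_radius_nm=config.get("cluster_radius_nm", 60.0),
        background_density_um2=config.get("background_density_um2", 0.0),
        precision_nm=config.get("precision_nm", 20.0),
    )
    params = _kinetics(config)
    table, truth = simulate_cluster_field(
        spec, params,
        frame_interval_ms=config.get("frame_interval_ms", 33.0),
        n_frames=int(config.get("n_frames", 5400)),
        seed=seed,
    )
    write_localizations(table, out_dir / "localizations.csv")
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    state["table"] = table
    entry["parameters"] = {
        "n_clusters": n_clusters, "molecules_per_cluster": mpc,
        "cluster_radius_nm": spec.cluster_radius_nm,
        "precision_nm": spec.precision_nm, "h": params.h, "seed": seed,
    }
    entry["n_out"] = len(table)


def _stage_calibrate(config, seed, out_dir, state, entry):
    table = state.get("table") or _load_table(config)
    traces = group_localizations_into_traces(
        table,
        dark_time_threshold_s=config.get("dark_time_threshold_s", 2.5),
        link_radius_nm=config.get("link_radius_nm"),
    )
    cal = fit_geometric_nblink(traces)
    rate, rate_se = fit_ton_exponential(traces)
    doc = {
        "h": cal.h, "mean_nblink": cal.mean_nblink, "multiplicity": cal.multiplicity,
        "mean_nblink_se": cal.fit_diagnostics.get("mean_nblink_se"),
        "k_on_decay": rate, "k_on_decay_se": rate_se, "n_traces": cal.n_traces,
    }
    with open(out_dir / "calibration.json", "w") as fh:
        json.dump(doc, fh, indent=2)
    state["multiplicity"] = cal.multiplicity
    entry["parameters"] = {
        "dark_time_threshold_s": config.get("dark_time_threshold_s", 2.5),
        "link_radius_nm": config.get("link_radius_nm"),
    }
    entry["n_in"] = len(table)
    entry["n_out"] = cal.n_traces
    entry["result"] = doc


def _stage_segment(config, seed, out_dir, state, entry):
    A = config.get("A", 6.0)
    if A <= 0:
        raise ConfigError("A must be positive")
    table = state.get("table") or _load_table(config)
    n_in = len(table)
    filtered = filter_uncertainties(
        table, config.get("low_pct", 1.0), config.get("high_pct", 99.0)
    )
    kde = compute_kde_map(filtered, A=A, grid_pixel_nm=config.get("grid_pixel_nm", 20.0))
    theta = otsu_threshold(kde)
    mult = config.get("multiplicity", state.get("multiplicity", 1.0))
    cs = segment_clusters(
        kde, theta, mult, filtered,
        min_cluster_pixels=int(config.get("min_cluster_pixels", 4)),
    )
    cs.clusters.to_csv(out_dir / "clusters.csv", index=False)
    rows = [
        (cid, bx, by) for cid, b in cs.boundaries.items() for bx, by in b
    ]
    pd.DataFrame(rows, columns=["cluster", "x [nm]", "y [nm]"]).to_csv(
        out_dir / "boundaries.csv", index=False
    )
    _write_pgm(cs.label_map, out_dir / "label_map.pgm")
    state["clusters"] = cs
    entry["parameters"] = {
        "A": A, "grid_pixel_nm": kde.grid_pixel_nm, "threshold": theta,
        "multiplicity": mult,
        "min_cluster_pixels": int(config.get("min_cluster_pixels", 4)),
        "uncertainty_band_pct": [config.get("low_pct", 1.0), config.get("high_pct", 99.0)],
    }
    entry["n_in"] = n_in
    entry["n_used"] = len(filtered)
    entry["n_out"] = len(cs)


def _stage_count(config, seed, out_dir, state, entry):
    cs = state.get("clusters")
    if cs is None:
        raise ConfigError("count stage needs a preceding segment stage")
    stats = cluster_statistics(
        cs,
        cell_areas_um2=config.get("cell_area_um2"),
        large_threshold=config.get("large_threshold", 800.0),
    )
    doc = {
        "mean_per_cluster": stats.mean_per_cluster,
        "per_cell_means": stats.per_cell_means,
        "large_cluster_density": stats.large_cluster_density,
        "n_clusters": stats.n_clusters,
    }
    with open(out_dir / "cluster_stats.json", "w") as fh:
        json.dump(doc, fh, indent=2)
    entry["parameters"] = {"large_threshold": config.get("large_threshold", 800.0)}
    entry["result"] = doc


def _stage_cbc(config, seed, out_dir, state, entry):
    tableA = _load_table(config, "input")
    tableB = _load_table(config, "input_b")
    tableB.field_bounds = tableA.field_bounds
    params = CBCParams(
        R_max=config.get("R_max", 500.0), dR=config.get("dR", 50.0),
        skip_rule=config.get("skip_rule", "and"),
    )
    res = cbc_scores(tableA, tableB, params)
    rot = cbc_scores(tableA, rotate_control(tableB), params)
    for name, scores in (
        ("cbc_A_rel_B", res.scores_A_rel_B), ("cbc_B_rel_A", res.scores_B_rel_A),
        ("cbc_A_rel_B_rotated", rot.scores_A_rel_B),
    ):
        pd.DataFrame({"score": scores}).to_csv(out_dir / f"{name}.csv", index=False)
    hist = cbc_histogram(res.scores_A_rel_B)
    hist_rot = cbc_histogram(rot.scores_A_rel_B)
    pd.DataFrame(
        {"bin_left": hist["edges"][:-1], "frequency": hist["frequency"]}
    ).to_csv(out_dir / "cbc_histogram.csv", index=False)
    doc = {"high_bin_sum": hist["high_bin_sum"], "high_bin_sum_rotated": hist_rot["high_bin_sum"]}
    with open(out_dir / "cbc_summary.json", "w") as fh:
        json.dump(doc, fh, indent=2)
    entry["parameters"] = {"R_max": params.R_max, "dR": params.dR,
                           "min_count": params.min_count, "skip_rule": params.skip_rule}
    entry["n_in"] = [len(tableA), len(tableB)]
    entry["result"] = doc


def _stage_recruit(config, seed, out_dir, state, entry):
    cs = state.get("clusters")
    if cs is None:
        raise ConfigError("recruit stage needs a preceding segment stage")
    if "trajectories" not in config:
        raise ConfigError("recruit stage requires 'trajectories' (a CSV path)")
    trajs = read_trajectories(
        config["trajectories"], frame_interval_ms=config.get("frame_interval_ms", 33.0)
    )
    durations, censored = residency_durations(trajs, cs, return_censoring=True)
    fit = fit_lifetime(
        durations[~censored], frame_interval_ms=config.get("frame_interval_ms", 33.0)
    )
    pd.DataFrame({"duration_ms": durations, "censored": censored}).to_csv(
        out_dir / "durations.csv", index=False
    )
    doc = {"tau_ms": fit.tau_ms, "tau_ci_ms": fit.tau_ci_ms, "n_events": fit.n_events}
    with open(out_dir / "lifetime.json", "w") as fh:
        json.dump(doc, fh, indent=2)
    entry["parameters"] = {"frame_interval_ms": config.get("frame_interval_ms", 33.0)}
    entry["n_in"] = len(trajs)
    entry["n_out"] = int(len(durations))
    entry["result"] = doc


def _write_pgm(label_map: np.ndarray, path: Path) -> None:
    """Plain-text PGM (P2) label image, values clipped to 16 bits."""
    arr = np.asarray(label_map, dtype=int)
    maxval = max(int(arr.max()), 1)
    with open(path, "w") as fh:
        fh.write(f"P2\n{arr.shape[1]} {arr.shape[0]}\n{min(maxval, 65535)}\n")
        for row in arr[::-1]:  # PGM top row first; our row 0 is the bottom
            fh.write(" ".join(map(str, row)) + "\n")
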