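"""File formats, session manifests and the end-to-end analysis pipeline.

Trajectories are delimited text with a ``t,x,y,hd`` header (seconds, cm, cm,
radians); spike trains are one spike time per line.  A session manifest (YAML)
lists trials (environment, trajectory file, duration, seed) and cells (id,
generator type, ground-truth parameters, per-trial spike files), so every
number in a report is reproducible from the manifest and its seeds alone.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import yaml

from . import classify as _classify
from . import spatial_stats, temporal_stats
from .environment import Environment, insert_barrier, make_standard_environment
from .ratemaps import compute_rate_map, compute_polar_map, filter_positions, windowed_maps
from .synth import (
    BoundaryOffParams,
    BVCParams,
    HDParams,
    SpikeTrain,
    Trajectory,
    boundary_off_rate_field,
    bvc_rate_field,
    generate_spikes,
    hd_rate_fn,
    simulate_trajectory,
)

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_spikes",
    "write_spikes",
    "write_rate_map",
    "generate_session",
    "run_pipeline",
    "FormatError",
]


class FormatError(ValueError):
    """Malformed input file; the message carries the offending line number."""


def write_trajectory(path, trajectory: Trajectory) -> None:
    arr = np.c_[trajectory.t, trajectory.x, trajectory.y, trajectory.hd]
    np.savetxt(path, arr, fmt="%.6f", delimiter=",", header="t,x,y,hd", comments="")


def read_trajectory(path) -> Trajectory:
    """Read a ``t,x,y,hd`` delimited-text trajectory, validating the header,
    row shape and time monotonicity (errors carry line numbers)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().lower().replace(" ", "")
        if header != "t,x,y,hd":
            raise FormatError(f"{path}:1: expected header 't,x,y,hd', got {header!r}")
        rows = []
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise FormatError(f"{path}:{ln}: expected 4 comma-separated values")
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-numeric value in {line!r}") from None
    if not rows:
        raise FormatError(f"{path}: no samples")
    arr = np.asarray(rows)
    bad = np.nonzero(np.diff(arr[:, 0]) <= 0)[0]
    if len(bad):
        raise FormatError(f"{path}:{int(bad[0]) + 3}: time not strictly increasing")
    return Trajectory(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


def write_spikes(path, spikes: SpikeTrain) -> None:
    with open(path, "w") as fh:
        fh.write(f"# duration_s={spikes.duration:.6f}\n")
        for t in spikes.times:
            fh.write(f"{t:.6f}\n")


def read_spikes(path, duration: float | None = None) -> SpikeTrain:
    """Read a one-spike-time-per-line file; a ``# duration_s=`` comment sets
    the trial length unless overridden."""
    path = Path(path)
    times = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "duration_s=" in line and duration is None:
                    duration = float(line.split("duration_s=")[1])
                continue
            try:
                times.append(float(line))
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-numeric spike time {line!r}") from None
    times = np.asarray(times)
    if len(times) and np.any(np.diff(times) < 0):
        raise FormatError(f"{path}: spike times not sorted")
    if duration is None:
        duration = float(times[-1]) if len(times) else 0.0
    return SpikeTrain(times, duration)


def write_rate_map(path, rate_map) -> None:
    """Rate map as a delimited text grid with a small header."""
    with open(path, "w") as fh:
        fh.write(f"# bin_size_cm={rate_map.bin_size}\n")
        fh.write(f"# x0={rate_map.x_edges[0]} y0={rate_map.y_edges[0]}\n")
        fh.write(f"# peak_rate_hz={rate_map.peak_rate:.4f}\n")
        np.savetxt(fh, rate_map.rate.T[::-1], fmt="%.4f", delimiter=",")


# ---------------------------------------------------------------------- #
# synthetic sessions


_PARAM_TYPES = {"bvc": BVCParams, "hd": HDParams, "boundary_off": BoundaryOffParams}


def _params_to_dict(p) -> dict:
    d = dataclasses.asdict(p)
    return d


def _params_from_dict(kind: str, d: dict):
    if kind == "boundary_off":
        d = dict(d, bvc=BVCParams(**d["bvc"]))
    return _PARAM_TYPES[kind](**d)


def generate_session(
    out_dir,
    seed: int = 0,
    n_bvc: int = 3,
    n_hd: int = 1,
    n_boundary_off: int = 0,
    duration: float = 600.0,
    environment: str = "walled_circle",
    theta: dict | None = None,
) -> Path:
    """Write a complete synthetic session (trajectories, spike files, YAML
    manifest) and return the manifest path.

    Every cell gets a baseline trial and a barrier trial with the barrier
    perpendicular to the cell's (ground-truth) preferred direction, mirroring
    the experimental sampling procedure.  All randomness derives from
    ``seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    env = make_standard_environment(environment)
    cells = []
    trials = []
    cell_idx = 0

    def _trial(cell_id: str, kind: str, params, trial_seed: int):
        if kind == "bvc":
            phi = params.phi_pref
        elif kind == "boundary_off":
            phi = params.bvc.phi_pref
        else:
            # location-independent cells get an arbitrary (but reproducible)
            # barrier orientation, as in the recorded comparison sample
            phi = params.mu
        entries = []
        for trial_name, barrier_orient in (("baseline", None), ("barrier", phi)):
            if barrier_orient is None:
                trial_env = env
            else:
                trial_env = insert_barrier(env, (0.0, 0.0), barrier_orient + math.pi / 2)
            traj_seed = trial_seed * 2 + (0 if trial_name == "baseline" else 1)
            traj = simulate_trajectory(trial_env, duration=duration, seed=traj_seed)
            traj_path = out_dir / f"{cell_id}_{trial_name}_trajectory.csv"
            write_trajectory(traj_path, traj)
            if kind == "bvc":
                rate_fn = bvc_rate_field(params, trial_env).as_rate_fn()
            elif kind == "hd":
                rate_fn = hd_rate_fn(params)
            else:
                rate_fn = boundary_off_rate_field(params, trial_env).as_rate_fn()
            spikes = generate_spikes(rate_fn, traj, seed=traj_seed + 10_000, theta=theta)
            spike_path = out_dir / f"{cell_id}_{trial_name}_spikes.txt"
            write_spikes(spike_path, spikes)
            entries.append(
                {
                    "trial": trial_name,
                    "environment": environment,
                    "barrier_orientation": None if barrier_orient is None else float(barrier_orient + math.pi / 2),
                    "trajectory": traj_path.name,
                    "spikes": spike_path.name,
                    "duration_s": float(duration),
                    "seed": int(traj_seed),
                }
            )
        return entries

    for kind, count in (("bvc", n_bvc), ("hd", n_hd), ("boundary_off", n_boundary_off)):
        for _ in range(count):
            cell_id = f"cell{cell_idx:02d}_{kind}"
            if kind == "bvc":
                params = BVCParams(
                    d_pref=float(rng.uniform(5.0, 12.0)),
                    phi_pref=float(rng.uniform(0.0, 2 * math.pi)),
                )
            elif kind == "hd":
                params = HDParams(mu=float(rng.uniform(0.0, 2 * math.pi)))
            else:
                params = BoundaryOffParams(
                    baseline=8.0, suppression=1.0,
                    bvc=BVCParams(
                        d_pref=float(rng.uniform(5.0, 12.0)),
                        phi_pref=float(rng.uniform(0.0, 2 * math.pi)),
                    ),
                )
            cells.append(
                {
                    "id": cell_id,
                    "type": kind,
                    "params": _params_to_dict(params),
                    "trials": _trial(cell_id, kind, params, cell_idx),
                }
            )
            cell_idx += 1

    manifest = {"seed": int(seed), "environment": environment, "theta": theta, "cells": cells}
    manifest_path = out_dir / "session.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


# ---------------------------------------------------------------------- #
# pipeline


def run_pipeline(manifest_path, config: dict | None = None) -> dict:
    """Run the full analysis on a session manifest.

    Per cell: baseline and barrier rate maps, polar plot, field-repetition
    classification, corrected information statistics and temporal statistics;
    plus a session-level Monte Carlo test of the observed field-peak
    distances.  Per-cell failures become error entries; the run continues.
    Deterministic given the manifest.
    """
    config = dict(config or {})
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    env = make_standard_environment(manifest["environment"])
    report: dict = {"environment": manifest["environment"], "cells": {}}
    peak_distances = []
    for cell in manifest.get("cells", []):
        cid = cell["id"]
        try:
            entry = _analyse_cell(cell, base, env, config)
            report["cells"][cid] = entry
            if entry["classification"]["eligible"]:
                peak_distances.append(entry["baseline"]["peak_distance_cm"])
        except Exception as exc:  # per-cell failure must not kill the run
            report["cells"][cid] = {"error": f"{type(exc).__name__}: {exc}"}
    if peak_distances and env.is_circular:
        null = spatial_stats.mc_field_peak_null(
            n=len(peak_distances), R=env.radius,
            seed=int(manifest.get("seed", 0)),
            reps=int(config.get("mc_reps", 100_000)),
        )
        observed = float(np.mean(peak_distances))
        report["field_peak_monte_carlo"] = {
            "n": len(peak_distances),
            "R_cm": env.radius,
            "observed_mean_cm": observed,
            "null_mean_cm": null.null_mean,
            "percentile": spatial_stats.percentile_of(null, observed),
        }
    return report


def _analyse_cell(cell: dict, base: Path, env: Environment, config: dict) -> dict:
    bin_size = float(config.get("bin_size", 3.0))
    trials = {t["trial"]: t for t in cell["trials"]}
    out: dict = {"type": cell["type"]}

    base_t = filter_positions(read_trajectory(base / trials["baseline"]["trajectory"]))
    base_s = read_spikes(base / trials["baseline"]["spikes"])
    baseline_map = compute_rate_map(base_t, base_s, bin_size=bin_size)
    polar = compute_polar_map(base_t, base_s)
    gmean = temporal_stats.global_mean_rate(base_s)
    out["baseline"] = {
        "peak_rate_hz": baseline_map.peak_rate,
        "directional_peak_hz": polar.peak_rate,
        "global_mean_rate_hz": gmean,
    }
    try:
        pk = _classify.field_peak(baseline_map, env)
        out["baseline"]["peak_distance_cm"] = pk.distance_to_centre
    except ValueError:
        out["baseline"]["peak_distance_cm"] = None

    # time-segmented maps (three equal segments, as in segment-stability checks)
    xmin, ymin, xmax, ymax = env.floor.bounds
    ext = (xmin, xmax, ymin, ymax)
    seg = base_t.duration / 3
    out["baseline"]["segment_peak_rates_hz"] = [
        windowed_maps(base_t, base_s, k * seg, (k + 1) * seg, bin_size=bin_size, extent=ext).peak_rate
        for k in range(3)
    ]

    info = spatial_stats.matched_bin_stats(base_t, base_s, env)
    out["corrected_info"] = {
        "locational_bits_per_s": info.locational_info,
        "directional_bits_per_s": info.directional_info,
        "locational_selectivity": info.locational_selectivity,
        "directional_selectivity": info.directional_selectivity,
        "n_visited_locational_bins": info.n_visited_locational,
    }

    runs = temporal_stats.extract_runs(base_t)
    run_spikes = temporal_stats.spikes_in_intervals(base_s, runs)
    if len(run_spikes) >= 2:
        _, acg = temporal_stats.spike_autocorrelogram(run_spikes)
        if acg.sum() > 0:
            ts = temporal_stats.theta_modulation_score(acg)
            out["theta"] = {"peak_freq_hz": ts.peak_freq, "score": ts.score}

    if "barrier" in trials:
        tr = trials["barrier"]
        env_b = insert_barrier(env, (0.0, 0.0), float(tr["barrier_orientation"]))
        bar_t = filter_positions(read_trajectory(base / tr["trajectory"]))
        bar_s = read_spikes(base / tr["spikes"])
        barrier_map = compute_rate_map(bar_t, bar_s, bin_size=bin_size)
        res = _classify.classify_bvc(baseline_map, barrier_map, env, env_b)
        out["classification"] = {
            "eligible": res.eligible,
            "is_bvc": res.is_bvc,
            "reason": res.reason,
            "coverage_percent": None if res.coverage is None else res.coverage.coverage,
            "predicted_side": None if res.side is None else res.side.label,
        }
    else:
        out["classification"] = {"eligible": False, "is_bvc": False, "reason": "no barrier trial"}
    return out


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
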