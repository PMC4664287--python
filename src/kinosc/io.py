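"""Plain-text I/O for trajectories, state paths, priors and fit outputs.

Trajectory CSV (one file per sister pair): optional ``#``-prefixed
``key=value`` metadata lines (pair_id, cell_id, r_um, dt_s), then a header
``frame,time_s,x1_um,x2_um,theta_rad``.  Ground-truth or sampled states go
in a companion CSV ``frame,sigma1,sigma2`` with values ``+``/``-``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mcmc import ConvergenceReport, PosteriorSamples, PriorSpec
from .model import StatePath, Trajectory

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "read_trajectories",
    "write_states_csv",
    "read_states_csv",
    "write_posterior",
    "write_prior_yaml",
    "read_prior_yaml",
]

_COLUMNS = ["frame", "time_s", "x1_um", "x2_um", "theta_rad"]


def write_trajectory_csv(trajectory: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    meta = {
        "pair_id": trajectory.pair_id,
        "cell_id": trajectory.cell_id,
        "dt_s": trajectory.dt,
    }
    if trajectory.radial_position is not None:
        meta["r_um"] = trajectory.radial_position
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write(",".join(_COLUMNS) + "\n")
        for i in range(trajectory.n_frames):
            fh.write(
                f"{i + 1},{(i) * trajectory.dt:.6g},"
                f"{trajectory.x1[i]:.9f},{trajectory.x2[i]:.9f},"
                f"{trajectory.theta[i]:.9f}\n"
            )
    return path


def _parse_metadata(path: Path) -> tuple[dict, int]:
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta, skip


def read_trajectory_csv(path: str | Path) -> Trajectory:
    """Read one trajectory; truncates to the longest contiguous tracked span.

    Trajectories must contain no missing frames for the likelihood, so a
    gap in the ``frame`` column truncates to the longest run of consecutive
    frames (with a warning).  Non-canonical sister order (mean x1 <= mean
    x2) is corrected by swapping, with a warning.
    """
    path = Path(path)
    meta, skip = _parse_metadata(path)
    df = pd.read_csv(path, skiprows=skip)
    missing = [c for c in _COLUMNS if c not in df.columns and c != "theta_rad"]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df[["frame", "x1_um", "x2_um"]].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + skip + 2).tolist()
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    frames = df["frame"].to_numpy(dtype=int)
    # longest run of consecutive frame numbers
    breaks = np.flatnonzero(np.diff(frames) != 1)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, len(frames) - 1]
    j = int(np.argmax(ends - starts))
    if len(starts) > 1:
        warnings.warn(
            f"{path}: gap in frames; truncated to contiguous span "
            f"{frames[starts[j]]}..{frames[ends[j]]}",
            stacklevel=2,
        )
    sel = slice(starts[j], ends[j] + 1)
    theta = (
        df["theta_rad"].to_numpy(dtype=float)[sel]
        if "theta_rad" in df.columns
        else None
    )
    dt = float(meta.get("dt_s", 2.0))
    traj = Trajectory(
        x1=df["x1_um"].to_numpy(dtype=float)[sel],
        x2=df["x2_um"].to_numpy(dtype=float)[sel],
        theta=theta,
        dt=dt,
        pair_id=meta.get("pair_id", path.stem),
        cell_id=meta.get("cell_id", "unknown"),
        radial_position=float(meta["r_um"]) if "r_um" in meta else None,
    )
    if not traj.is_canonical():
        warnings.warn(f"{path}: swapping sisters to satisfy mean(x1) > mean(x2)",
                      stacklevel=2)
        traj = traj.canonical()
    return traj


def read_trajectories(path: str | Path, pattern: str = "*.csv") -> list[Trajectory]:
    """Read every trajectory CSV in a directory (or a single file)."""
    path = Path(path)
    if path.is_file():
        return [read_trajectory_csv(path)]
    files = sorted(p for p in path.glob(pattern) if not p.stem.endswith("_states"))
    if not files:
        raise FileNotFoundError(f"no trajectory CSVs under {path}")
    return [read_trajectory_csv(p) for p in files]


def write_states_csv(states: StatePath, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("frame,sigma1,sigma2\n")
        for i, (a, b) in enumerate(states.sigma):
            fh.write(f"{i + 1},{'+' if a > 0 else '-'},{'+' if b > 0 else '-'}\n")
    return path


def read_states_csv(path: str | Path) -> StatePath:
    df = pd.read_csv(path)
    sig = np.stack(
        [
            np.where(df["sigma1"].astype(str).str.strip() == "+", 1, -1),
            np.where(df["sigma2"].astype(str).str.strip() == "+", 1, -1),
        ],
        axis=1,
    )
    return StatePath(sig)


def write_posterior(
    post: PosteriorSamples,
    report: ConvergenceReport,
    out_dir: str | Path,
    stem: str,
) -> dict:
    """Write parameter draws, state marginals and a JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    draws_path = out_dir / f"{stem}_draws.csv"
    cols = ["v_plus", "v_minus", "kappa", "L", "alpha", "tau", "p_c", "p_ic"]
    df = post.params.copy()
    df.insert(0, "draw_index", np.arange(len(df)))
    df[["draw_index"] + cols].rename(columns={"draw_index": "draw"}).to_csv(
        draws_path, index=False
    )
    marg_path = out_dir / f"{stem}_state_marginals.csv"
    marg = pd.DataFrame(
        post.state_marginals, columns=["p_pp", "p_pm", "p_mp", "p_mm"]
    )
    marg.insert(0, "frame", np.arange(1, len(marg) + 1))
    marg.to_csv(marg_path, index=False)
    summary_path = out_dir / f"{stem}_summary.json"
    payload = {
        "summary": post.summary,
        "n_draws": post.n_draws,
        "burn_in": post.burn_in,
        "n_chains": post.n_chains,
        "dt_s": post.dt,
        "convergence": {
            "converged": report.converged,
            "rhat": report.rhat,
            "ess": report.ess,
            "threshold": report.threshold,
        },
    }
    with open(summary_path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return {"draws": draws_path, "marginals": marg_path, "summary": summary_path}


def write_prior_yaml(prior: PriorSpec, path: str | Path) -> Path:
    path = Path(path)
    from dataclasses import asdict

    with open(path, "w") as fh:
        yaml.safe_dump(asdict(prior), fh, sort_keys=False)
    return path


def read_prior_yaml(path: str | Path) -> PriorSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PriorSpec(**data).validate()
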