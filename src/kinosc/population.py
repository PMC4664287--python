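"""Population-level metaphase-plate statistics and pipeline orchestration.

Summarises many fitted trajectories into one table (posterior means,
quality statistics, event counts) and computes the plate statistics used to
characterise spatial structure: alignment deviation (s.d. over trajectories
of the time-averaged sister midpoint), oscillation amplitude (per-trajectory
s.d. of the midpoint over time) and plate thickness (s.d. of midpoints
pooled over time and trajectories).  These three use the population (ddof=0)
convention so the exact between/within variance decomposition holds; other
summaries use sample (ddof=1) standard deviations.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import events as ev
from . import selection as sel
from .io import read_trajectories, write_posterior, write_trajectory_csv, write_states_csv
from .mcmc import MCMCConfig, PriorSpec, run_mcmc
from .model import ModelParameters, SimulationConfig, Trajectory, fig1b_parameters, simulate_trajectory

__all__ = [
    "plate_statistics",
    "radial_binning",
    "parameter_trend",
    "fit_trajectory",
    "run_pipeline",
]


def plate_statistics(trajectories: list[Trajectory]) -> dict:
    """Alignment deviation, oscillation amplitude, plate thickness and mean
    inter-sister distance (um).

    With a single trajectory only the within-trajectory statistics are
    returned.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    mids = [t.midpoint() for t in trajectories]
    amplitude = np.array([m.std(ddof=0) for m in mids])
    mean_d = float(np.mean([t.distance.mean() for t in trajectories]))
    out = {
        "oscillation_amplitude": amplitude,
        "oscillation_amplitude_mean": float(amplitude.mean()),
        "mean_intersister_distance": mean_d,
    }
    if len(trajectories) >= 2:
        means = np.array([m.mean() for m in mids])
        pooled = np.concatenate(mids)
        out["alignment_deviation"] = float(means.std(ddof=0))
        out["plate_thickness"] = float(pooled.std(ddof=0))
    else:
        warnings.warn("single trajectory: between-trajectory statistics unavailable",
                      stacklevel=2)
    return out


def radial_binning(
    table: pd.DataFrame,
    n_bins: int = 4,
    columns: list[str] | None = None,
    r_column: str = "r_um",
) -> pd.DataFrame:
    """Bin trajectories by radial distance with ~equal counts per bin and
    return per-bin mean ± s.d. of the requested columns."""
    if r_column not in table.columns or table[r_column].isna().all():
        raise ValueError(f"radial position column '{r_column}' unavailable")
    df = table.dropna(subset=[r_column]).copy()
    columns = columns or [
        c for c in df.columns if c != r_column and pd.api.types.is_numeric_dtype(df[c])
    ]
    df["_bin"] = pd.qcut(df[r_column].rank(method="first"), q=n_bins, labels=False)
    rows = []
    for b, grp in df.groupby("_bin"):
        row = {"bin": int(b), "count": len(grp),
               "r_mean": grp[r_column].mean()}
        for c in columns:
            row[f"{c}_mean"] = grp[c].mean()
            row[f"{c}_sd"] = grp[c].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("bin").reset_index(drop=True)


def parameter_trend(
    table: pd.DataFrame,
    column: str,
    r_column: str = "r_um",
    method: str = "spearman",
) -> tuple[float, float]:
    """Correlation of a fitted quantity with radial position.

    Rank (Spearman) correlation by default, matching how spatial parameter
    trends are reported; Pearson available via ``method``.
    """
    df = table.dropna(subset=[column, r_column])
    if len(df) < 10:
        raise ValueError("need at least 10 trajectories for a trend")
    x, y = df[r_column].to_numpy(), df[column].to_numpy()
    if np.allclose(y, y[0]):
        raise ValueError(f"column '{column}' is constant; trend undefined")
    if method == "spearman":
        r, p = sps.spearmanr(x, y)
    elif method == "pearson":
        r, p = sps.pearsonr(x, y)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return float(r), float(p)


def fit_trajectory(
    trajectory: Trajectory,
    prior: PriorSpec,
    mcmc_config: MCMCConfig,
    seed: int,
    estimate_marginal: bool = True,
    reduced_sweeps: int = 800,
) -> dict:
    """Fit one trajectory and compute its row of the population table."""
    post, report = run_mcmc(trajectory, prior, mcmc_config, seed=seed)
    mean = post.mean_parameters()
    row = {
        "pair_id": trajectory.pair_id,
        "cell_id": trajectory.cell_id,
        "r_um": trajectory.radial_position,
        "n_frames": trajectory.n_frames,
        "converged": report.converged,
    }
    for name in ("v_plus", "v_minus", "kappa", "L", "alpha", "tau", "p_c", "p_ic"):
        row[name] = post.summary[name]["mean"]
        row[f"{name}_sd"] = post.summary[name]["sd"]
    row["ev"] = sel.explained_variance(trajectory, post)
    margs = sel.fit_bm_variants(trajectory)
    if estimate_marginal and report.converged:
        logm, se = sel.estimate_log_marginal_chen(
            post, trajectory, prior, seed=seed + 1, reduced_sweeps=reduced_sweeps
        )
    else:
        logm, se = float("nan"), float("nan")
    row["log_marginal_coh"] = logm
    row["log_bf_bm"] = logm - margs["bm"]
    row["log_bf_springbm"] = logm - margs["spring_bm"]
    row["log_bf_springdriftbm"] = logm - margs["spring_drift_bm"]
    for n_sub in (1, 2, 4):
        row[f"d_{n_sub}"] = sel.directional_statistic(trajectory, n_sub)
    hp = sel.half_period_autocorrelation(trajectory) if trajectory.n_frames >= 20 else None
    row["half_period_s"] = hp if hp is not None else float("nan")
    # events
    samples = post.state_samples(max_samples=200, rng=seed + 2)
    events = ev.detect_switch_events(samples, min_samples=50)
    events = [ev.classify_lids_tids(e, samples) for e in events]
    row["n_events"] = len(events)
    row["n_lids"] = sum(e.classification == "LIDS" for e in events)
    row["n_tids"] = sum(e.classification == "TIDS" for e in events)
    return {"row": row, "post": post, "report": report, "events": events}


DEFAULT_CONFIG = {
    "io": {"input": None, "out": "kinosc-out"},
    "prior": {},
    "mcmc": {"n_sweeps": 3200, "n_chains": 2},
    "selection": {"estimate_marginal": True, "band_sds": 2.0, "reduced_sweeps": 800},
    "events": {"window": 10},
    "simulate": {"n_pairs": 0, "n_frames": 150},
    "seed": 0,
}


def run_pipeline(config: dict | str | Path) -> pd.DataFrame:
    """Fit → select → events → population, end to end, reproducibly.

    ``config`` is a YAML path or dict with sections io / prior / mcmc /
    selection / events / seed (all optional except io.input, unless
    ``simulate.n_pairs`` > 0).  Per-trajectory failures are isolated and
    recorded; the run continues.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    for key in DEFAULT_CONFIG:
        if isinstance(DEFAULT_CONFIG[key], dict):
            cfg[key] = {**DEFAULT_CONFIG[key], **(cfg.get(key) or {})}
    out_dir = Path(cfg["io"]["out"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    prior = PriorSpec(**cfg["prior"]).validate()
    mcfg = MCMCConfig(**cfg["mcmc"])

    if cfg["simulate"]["n_pairs"] > 0:
        traj_dir = out_dir / "simulated"
        simulate_population(
            n_pairs=int(cfg["simulate"]["n_pairs"]),
            n_frames=int(cfg["simulate"]["n_frames"]),
            out_dir=traj_dir,
            seed=seed,
        )
        trajectories = read_trajectories(traj_dir)
    else:
        if cfg["io"]["input"] is None:
            raise ValueError("config io.input is required unless simulate.n_pairs > 0")
        trajectories = _read_resilient(cfg["io"]["input"], out_dir)

    rows = []
    failures = []
    for i, traj in enumerate(trajectories):
        try:
            res = fit_trajectory(
                traj,
                prior,
                mcfg,
                seed=seed + 1000 * (i + 1),
                estimate_marginal=bool(cfg["selection"]["estimate_marginal"]),
                reduced_sweeps=int(cfg["selection"]["reduced_sweeps"]),
            )
            rows.append(res["row"])
            write_posterior(res["post"], res["report"], out_dir / "fits", traj.pair_id)
            _write_events(res["events"], out_dir / "fits", traj.pair_id, traj.dt)
        except Exception as exc:  # noqa: BLE001 - per-trajectory isolation
            failures.append({"pair_id": traj.pair_id, "error": f"{type(exc).__name__}: {exc}"})
            warnings.warn(f"fit failed for {traj.pair_id}: {exc}", stacklevel=2)

    table = pd.DataFrame(rows)
    if len(table) >= 10 and table["log_bf_bm"].notna().all():
        table["filter_pass"] = sel.filter_trajectories(
            table["ev"].to_numpy(), table["log_bf_bm"].to_numpy(),
            band_sds=float(cfg["selection"]["band_sds"]),
        )
    else:
        table["filter_pass"] = True
    table.to_csv(out_dir / "population.csv", index=False)
    if failures:
        pd.DataFrame(failures).to_csv(out_dir / "failures.csv", index=False)
    if len(table) >= 2:
        ps = plate_statistics(trajectories)
        pd.Series(
            {k: v for k, v in ps.items() if np.isscalar(v)}
        ).to_csv(out_dir / "plate_statistics.csv", header=False)
    return table


def _read_resilient(path, out_dir) -> list[Trajectory]:
    from .io import read_trajectory_csv

    path = Path(path)
    if path.is_file():
        return [read_trajectory_csv(path)]
    files = sorted(p for p in path.glob("*.csv") if not p.stem.endswith("_states"))
    out = []
    failures = []
    for p in files:
        try:
            out.append(read_trajectory_csv(p))
        except Exception as exc:  # noqa: BLE001
            failures.append({"pair_id": p.stem, "error": f"{type(exc).__name__}: {exc}"})
            warnings.warn(f"could not read {p}: {exc}", stacklevel=2)
    if failures:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        pd.DataFrame(failures).to_csv(Path(out_dir) / "read_failures.csv", index=False)
    if not out:
        raise FileNotFoundError(f"no readable trajectory CSVs under {path}")
    return out


def _write_events(events, out_dir: Path, pair_id: str, dt: float) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "pair_id": pair_id,
            "event_frame": e.frame,
            "type": "end",
            "p_lids": e.p_lids,
            "p_tids": e.p_tids,
            "class": e.classification,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=["pair_id", "event_frame", "type", "p_lids", "p_tids", "class"]).to_csv(
        out_dir / f"{pair_id}_events.csv", index=False
    )


def simulate_population(
    n_pairs: int,
    n_frames: int,
    out_dir: str | Path,
    seed: int = 0,
    params: ModelParameters | None = None,
    radial_spread: float = 4.0,
) -> list[Path]:
    """Write a synthetic population of trajectory CSVs (plus ground-truth
    state CSVs) with radial positions drawn uniformly over the plate."""
    params = params or fig1b_parameters()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = []
    for i in range(n_pairs):
        cfg = SimulationConfig(
            params=params,
            n_frames=n_frames,
            seed=int(rng.integers(2**31 - 1)),
            pair_id=f"sim-{i:03d}",
            cell_id=f"cell-{i // 10:02d}",
        )
        traj, states = simulate_trajectory(cfg)
        traj.radial_position = float(rng.uniform(0, radial_spread))
        p = write_trajectory_csv(traj, out_dir / f"{cfg.pair_id}.csv")
        write_states_csv(states, out_dir / f"{cfg.pair_id}_states.csv")
        paths.append(p)
    return paths
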