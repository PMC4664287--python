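"""Directional-switch event detection, LIDS/TIDS classification and force
decomposition.

A *coherent run* is a maximal stretch of one coherent pair state (+/- or
-/+) that tolerates interruptions of at most 3 consecutive frames and must
contain at least 5 consecutive uninterrupted frames in that state.  Run
boundaries define start and end events; the end of a run initiates a
directional switch.  Aggregating run detection over MCMC state-path samples
yields per-frame event probabilities, and tallying which sister's K-fibre
changed state first at run end classifies each switch as lead- (LIDS) or
trail-sister-initiated (TIDS) — the leading sister being the one attached
to the depolymerising K-fibre during the run.

Forces are drag-normalised (velocity-commensurate, um/s).  In the
anti-poleward sign convention (positive force pushes the sister away from
its own pole, the convention used for all reported profiles) the
decomposition is particularly simple:

    f_kfibre = v_sigma     f_spring = kappa (d - L cos theta)
    f_pef    = -(-1)^k alpha x_k

and ``f_total = f_kfibre + f_spring + f_pef`` exactly at every frame.
Absolute forces in pN follow from Stokes' law given an assumed chromosome
radius and spindle viscosity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import COHERENT_PAIR_STATES, PAIR_STATES, ModelParameters, StatePath, Trajectory

__all__ = [
    "Run",
    "SwitchEvent",
    "ForceProfile",
    "AlignedProfiles",
    "detect_runs",
    "event_probabilities",
    "detect_switch_events",
    "classify_lids_tids",
    "force_decompose",
    "opposing_force_ratio",
    "align_switch_profiles",
    "stokes_force",
]

MIN_RUN = 5  # minimum consecutive uninterrupted frames in the coherent state
MAX_BLIP = 3  # longest tolerated transient interruption, frames


@dataclass(frozen=True)
class Run:
    """A coherent run over state-path interval indices [start, end]."""

    state: int  # pair-state index (1: +/-, 2: -/+)
    start: int
    end: int

    @property
    def leading_sister(self) -> int:
        """0-based index of the sister with the depolymerising K-fibre."""
        return 1 if self.state == 1 else 0  # (+,-): sister 2 leads; (-,+): sister 1


@dataclass
class SwitchEvent:
    frame: int  # run-end frame (switch initiation), interval index
    prob: float  # windowed end-event probability
    start_frame: int | None = None
    median_switch_frame: float | None = None
    p_lids: float = 0.0
    p_tids: float = 0.0
    classification: str = "unclassified"
    leading_sister: int | None = None

    @property
    def is_classified(self) -> bool:
        return self.classification in ("LIDS", "TIDS")


def detect_runs(
    state_path: StatePath, min_run: int = MIN_RUN, max_blip: int = MAX_BLIP
) -> list[Run]:
    """Find coherent runs in a single sampled state path.

    For each coherent state, consecutive in-state segments separated by at
    most ``max_blip`` frames of any other state are merged; a merged run is
    valid only if at least one constituent segment has length >= ``min_run``.
    """
    idx = state_path.pair_index
    runs: list[Run] = []
    for s in COHERENT_PAIR_STATES:
        mask = idx == s
        segments = _segments(mask)
        if not segments:
            continue
        merged = [list(segments[0])]
        for seg in segments[1:]:
            gap = seg[0] - merged[-1][1] - 1
            if gap <= max_blip:
                merged[-1][1] = seg[1]
            else:
                merged.append(list(seg))
        for start, end in merged:
            seg_lengths = [
                b - a + 1 for a, b in _segments(mask[start : end + 1])
            ]
            if max(seg_lengths) >= min_run:
                runs.append(Run(state=s, start=start, end=end))
    runs.sort(key=lambda r: r.start)
    return runs


def _segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index pairs of True stretches."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(mask) - 1))
    return out


def event_probabilities(
    state_samples: list[StatePath] | np.ndarray,
    min_run: int = MIN_RUN,
    max_blip: int = MAX_BLIP,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame probabilities of run start and end events.

    Each MCMC state-path sample is scanned for coherent runs; the returned
    arrays give, per frame, the fraction of samples in which a run starts /
    ends there.
    """
    paths = _as_paths(state_samples)
    if len(paths) == 0:
        raise ValueError("no state samples supplied")
    n1 = paths[0].n_intervals
    p_start = np.zeros(n1)
    p_end = np.zeros(n1)
    for path in paths:
        for run in detect_runs(path, min_run, max_blip):
            p_start[run.start] += 1.0
            p_end[run.end] += 1.0
    g = len(paths)
    return p_start / g, p_end / g


def _as_paths(state_samples) -> list[StatePath]:
    if isinstance(state_samples, np.ndarray):
        return [StatePath(s) for s in state_samples]
    return list(state_samples)


def detect_switch_events(
    state_samples: list[StatePath] | np.ndarray,
    threshold: float = 0.5,
    window: int = 1,
    min_run: int = MIN_RUN,
    max_blip: int = MAX_BLIP,
    min_samples: int = 100,
) -> list[SwitchEvent]:
    """Consolidate per-frame end-event probabilities into switch events.

    A frame becomes an event when the probability mass within ±``window``
    frames reaches ``threshold``; overlapping candidates are merged
    greedily, keeping the frame with the largest windowed mass.
    """
    paths = _as_paths(state_samples)
    if len(paths) < min_samples:
        warnings.warn(
            f"only {len(paths)} state samples (recommended >= {min_samples}); "
            "event probabilities will be coarse",
            stacklevel=2,
        )
    _, p_end = event_probabilities(paths, min_run, max_blip)
    n1 = len(p_end)
    kernel = np.ones(2 * window + 1)
    windowed = np.convolve(p_end, kernel, mode="same")
    order = np.argsort(-windowed, kind="stable")
    taken = np.zeros(n1, dtype=bool)
    events = []
    for i in order:
        if windowed[i] < threshold:
            break
        lo, hi = max(0, i - 2 * window), min(n1, i + 2 * window + 1)
        if taken[lo:hi].any():
            continue
        taken[lo:hi] = True
        events.append(SwitchEvent(frame=int(i), prob=float(windowed[i])))
    events.sort(key=lambda e: e.frame)
    return events


def classify_lids_tids(
    event: SwitchEvent,
    state_samples: list[StatePath] | np.ndarray,
    match_window: int = 2,
    min_run: int = MIN_RUN,
    max_blip: int = MAX_BLIP,
) -> SwitchEvent:
    """Attach LIDS/TIDS probabilities to a switch event.

    Over the samples containing a coherent run ending within
    ±``match_window`` frames of the event, tallies which sister's K-fibre
    state changed first at run end: the leading (depolymerising) sister
    gives a LIDS tally, the trailing one a TIDS tally; samples where both
    sisters switch on the same frame count half to each.  Samples without a
    matching resolvable run end leave residual probability mass, so
    p_lids + p_tids <= 1.
    """
    paths = _as_paths(state_samples)
    g = len(paths)
    lids = tids = 0.0
    switch_frames = []
    start_frames = []
    lead_votes = []
    for path in paths:
        run = _matching_run(path, event.frame, match_window, min_run, max_blip)
        if run is None:
            continue
        if run.end + 1 >= path.n_intervals:
            continue  # run ends at the trajectory boundary: unresolvable
        state_now = PAIR_STATES[run.state]
        nxt = path.sigma[run.end + 1]
        changed = [
            (nxt[k] > 0) != (state_now[k] == "+") for k in range(2)
        ]
        lead = run.leading_sister
        switch_frames.append(run.end)
        start_frames.append(run.start)
        lead_votes.append(lead)
        if changed[lead] and not changed[1 - lead]:
            lids += 1.0
        elif changed[1 - lead] and not changed[lead]:
            tids += 1.0
        elif changed[0] and changed[1]:
            lids += 0.5
            tids += 0.5
        # neither changed: the "run end" was a blip boundary; unresolved
    event.p_lids = lids / g
    event.p_tids = tids / g
    if not switch_frames:
        event.classification = "unclassifiable"
        return event
    event.median_switch_frame = float(np.median(switch_frames))
    event.start_frame = int(np.median(start_frames))
    event.leading_sister = int(np.round(np.mean(lead_votes)))
    if event.p_lids > event.p_tids:
        event.classification = "LIDS"
    elif event.p_tids > event.p_lids:
        event.classification = "TIDS"
    else:
        event.classification = "tie"
    return event


def _matching_run(path, frame, match_window, min_run, max_blip):
    best = None
    for run in detect_runs(path, min_run, max_blip):
        dist = abs(run.end - frame)
        if dist <= match_window and (best is None or dist < abs(best.end - frame)):
            best = run
    return best


# --------------------------------------------------------------------------
# force decomposition
# --------------------------------------------------------------------------


@dataclass
class ForceProfile:
    """Per-frame, per-sister force components in um/s.

    Arrays have shape (n_frames, 2).  The K-fibre component uses the state
    of the following displacement as the estimate at each frame, so it is
    undefined (NaN) at the last frame.  ``convention`` is either
    "antipoleward" (positive away from the sister's own pole, as in the
    reported profiles) or "plate_normal" (positive towards +x, in which
    case f_total * dt is the deterministic drift displacement).
    """

    f_kfibre: np.ndarray
    f_spring: np.ndarray
    f_pef: np.ndarray
    dt: float = 2.0
    convention: str = "antipoleward"

    @property
    def f_total(self) -> np.ndarray:
        return self.f_kfibre + self.f_spring + self.f_pef

    @property
    def n_frames(self) -> int:
        return self.f_kfibre.shape[0]

    def component(self, name: str) -> np.ndarray:
        return {"f_kfibre": self.f_kfibre, "f_spring": self.f_spring,
                "f_pef": self.f_pef, "f_total": self.f_total}[name]


def force_decompose(
    trajectory: Trajectory,
    params: ModelParameters,
    states: StatePath,
    convention: str = "antipoleward",
) -> ForceProfile:
    """Decompose the drag-normalised force on each sister at each frame.

    Components are the three drift terms of the model evaluated at the
    supplied (typically posterior-mean) parameters and state assignment
    (typically per-frame modal states).
    """
    if convention not in ("antipoleward", "plate_normal"):
        raise ValueError("convention must be 'antipoleward' or 'plate_normal'")
    params.validate()
    n = trajectory.n_frames
    if states.n_intervals != n - 1:
        raise ValueError("states must cover n-1 intervals")
    x = np.stack([trajectory.x1, trajectory.x2], axis=1)  # (n, 2)
    d = trajectory.distance
    cth = np.cos(trajectory.theta)
    stretch = d - params.L * cth

    v = np.where(states.sigma > 0, params.v_plus, params.v_minus)  # (n-1, 2)
    f_kfibre = np.full((n, 2), np.nan)
    f_kfibre[:-1] = v  # anti-poleward: polymerising -> +v_plus > 0
    f_spring = np.repeat(stretch[:, None], 2, axis=1) * params.kappa
    sgn = np.array([-1.0, 1.0])  # (-1)^k
    f_pef = -sgn * params.alpha * x  # (-1)^(k+1) alpha x_k
    if convention == "plate_normal":
        f_kfibre = sgn * f_kfibre
        f_spring = sgn * f_spring
        f_pef = sgn * f_pef
    return ForceProfile(
        f_kfibre=f_kfibre, f_spring=f_spring, f_pef=f_pef,
        dt=trajectory.dt, convention=convention,
    )


def opposing_force_ratio(
    profile: ForceProfile,
    leading_sister: int,
    frames: np.ndarray | slice | None = None,
) -> np.ndarray:
    """|f_spring + f_pef| / |f_kfibre| on the leading sister.

    Values >= 1 indicate that the spring and PEF together could stall the
    depolymerisation pull.  Frames with zero K-fibre force return NaN with a
    warning.
    """
    if leading_sister not in (0, 1):
        raise ValueError("leading_sister must be 0 or 1")
    sel = slice(None) if frames is None else frames
    opp = np.abs(profile.f_spring[sel, leading_sister] + profile.f_pef[sel, leading_sister])
    den = np.abs(profile.f_kfibre[sel, leading_sister])
    out = np.full_like(opp, np.nan)
    nz = den > 0
    if not np.all(nz | np.isnan(den)):
        warnings.warn("zero K-fibre force encountered; ratio undefined there", stacklevel=2)
    out[nz] = opp[nz] / den[nz]
    return out


@dataclass
class AlignedProfiles:
    """Switch-aligned force traces.

    ``class_stats`` maps event class to (mean, sem, counts) arrays over
    lags; ``heatmap`` holds per-bin mean traces with events binned by
    p_lids - p_tids.
    """

    lags_s: np.ndarray
    component: str
    class_stats: dict = field(default_factory=dict)
    heatmap: np.ndarray | None = None
    heatmap_bins: np.ndarray | None = None
    heatmap_counts: np.ndarray | None = None


def align_switch_profiles(
    events: list[SwitchEvent],
    profiles: list[ForceProfile],
    window: int = 10,
    component: str = "f_spring",
    n_heatmap_bins: int = 5,
) -> AlignedProfiles:
    """Average force traces around switch events, split by LIDS/TIDS.

    Each event contributes the trace of ``component`` on its leading sister
    in a ±``window``-frame window around its median switching time; events
    near trajectory boundaries contribute only their valid frames (per-lag
    counts are reported).  Also produces a heat map of mean traces with
    events binned by p_lids - p_tids.
    """
    if len(events) != len(profiles):
        raise ValueError("need one ForceProfile per event")
    lags = np.arange(-window, window + 1)
    traces = []
    classes = []
    discr = []
    for ev, prof in zip(events, profiles):
        if ev.median_switch_frame is None or ev.leading_sister is None:
            continue
        centre = int(round(ev.median_switch_frame))
        comp = prof.component(component)[:, ev.leading_sister]
        tr = np.full(len(lags), np.nan)
        for j, lag in enumerate(lags):
            i = centre + lag
            if 0 <= i < len(comp):
                tr[j] = comp[i]
        traces.append(tr)
        classes.append(ev.classification)
        discr.append(ev.p_lids - ev.p_tids)
    if not traces:
        raise ValueError("no classifiable events to align")
    traces = np.asarray(traces)
    discr = np.asarray(discr)
    out = AlignedProfiles(lags_s=lags * profiles[0].dt, component=component)
    for cls in ("LIDS", "TIDS"):
        sel = np.array([c == cls for c in classes])
        if sel.sum() < 2:
            continue
        sub = traces[sel]
        counts = np.sum(~np.isnan(sub), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(sub, axis=0)
            sd = np.nanstd(sub, axis=0, ddof=1)
        sem = np.where(counts > 0, sd / np.sqrt(np.maximum(counts, 1)), np.nan)
        out.class_stats[cls] = (mean, sem, counts)
    # percentile heat map by p_lids - p_tids
    n_bins = min(n_heatmap_bins, len(traces))
    if n_bins >= 1:
        edges = np.quantile(discr, np.linspace(0, 1, n_bins + 1))
        edges[0] -= 1e-12
        bin_idx = np.clip(np.searchsorted(edges, discr, side="left") - 1, 0, n_bins - 1)
        heat = np.full((n_bins, len(lags)), np.nan)
        counts = np.zeros(n_bins, dtype=int)
        for b in range(n_bins):
            sel = bin_idx == b
            counts[b] = sel.sum()
            if counts[b]:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    heat[b] = np.nanmean(traces[sel], axis=0)
        out.heatmap = heat
        out.heatmap_bins = edges
        out.heatmap_counts = counts
    return out


def stokes_force(velocity_um_s: float, radius_um: float = 0.5, viscosity_pa_s: float = 190.0) -> float:
    """Absolute force in pN from Stokes' law, F = 6 pi eta r v.

    With eta in Pa s, r in um and v in um/s the unit conversion cancels:
    F[pN] = 6 pi * eta * r * v.
    """
    if radius_um <= 0 or viscosity_pa_s <= 0:
        raise ValueError("radius and viscosity must be > 0")
    return float(6.0 * np.pi * viscosity_pa_s * radius_um * velocity_um_s)
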