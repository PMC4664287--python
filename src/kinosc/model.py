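"""Coherence–incoherence model of metaphase sister-kinetochore dynamics.

Sister kinetochores are described by their positions ``(x1, x2)`` normal to
the metaphase plate (plate at x = 0, sister 1 on the right, poles at ±∞).
Three drag-normalised forces act on each sister: a constant effective
velocity from its K-fibre (``+v_plus`` when polymerising, ``v_minus < 0``
when depolymerising), a Hookean centromeric spring of natural length ``L``
(projected by the twist angle θ), and a linearised polar ejection force
``-alpha * x`` pulling the pair onto the plate.  Over one frame of length
``dt`` the displacement of sister k is

    dx^k = dt * [ (-1)^k v_{sigma^k} + (-1)^k kappa (x1 - x2 - L cos θ)
                  - alpha x^k ] + dt * N(0, 1/tau)

where ``sigma^k ∈ {+, -}`` is the hidden K-fibre state.  The states follow a
hidden Markov chain: each sister keeps its state with probability ``p_c``
per frame while the pair is coherent (sisters moving in the same spatial
direction, states +/- or -/+) and with probability ``p_ic`` while incoherent
(contracting +/+ or expanding -/-).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Trajectory",
    "ModelParameters",
    "StatePath",
    "SimulationConfig",
    "PAIR_STATES",
    "COHERENT_PAIR_STATES",
    "drift_displacement",
    "pair_transition_matrix",
    "simulate_states",
    "simulate_trajectory",
]

#: Pair-state ordering used throughout: index = 2*(sigma1 == '-') + (sigma2 == '-').
PAIR_STATES = (("+", "+"), ("+", "-"), ("-", "+"), ("-", "-"))
#: Indices of the coherent pair states (+/- and -/+).
COHERENT_PAIR_STATES = (1, 2)


def _require_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite value in '{name}'")
    return arr


@dataclass
class ModelParameters:
    """Drag-normalised model parameters in physical (seconds-based) units."""

    v_plus: float  # um/s, polymerising K-fibre effective velocity (> 0 expected)
    v_minus: float  # um/s, depolymerising (< 0 expected)
    kappa: float  # 1/s, spring constant over drag
    L: float  # um, spring natural length
    alpha: float  # 1/s, PEF gradient over drag
    tau: float  # s^2/um^2, noise precision tau = s^-2
    p_c: float  # per-frame probability of remaining coherent
    p_ic: float  # per-frame probability of remaining incoherent

    def validate(self) -> "ModelParameters":
        for name in ("v_plus", "v_minus", "kappa", "L", "alpha", "tau"):
            _require_finite(name, getattr(self, name))
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.kappa < 0 or self.alpha < 0 or self.L < 0:
            raise ValueError("kappa, alpha and L must be >= 0")
        for name in ("p_c", "p_ic"):
            p = getattr(self, name)
            if not (0.0 < p < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {p}")
        return self

    def v(self, sigma: str) -> float:
        return self.v_plus if sigma == "+" else self.v_minus


@dataclass
class Trajectory:
    """A paired sister-kinetochore trajectory sampled at fixed interval dt.

    Positions are measured normal to the metaphase plate in micrometres, with
    time-averaged x1 > x2 (sister 1 to the right).  ``theta`` is the twist
    angle between the sister axis and the plate normal, projecting the spring
    natural length as L cos(theta).  Frames are contiguous: there is no
    missing data (upstream readers truncate to the longest tracked span).
    """

    x1: np.ndarray
    x2: np.ndarray
    theta: np.ndarray | None = None
    dt: float = 2.0
    radial_position: float | None = None
    pair_id: str = "pair-0"
    cell_id: str = "cell-0"

    def __post_init__(self) -> None:
        self.x1 = _require_finite("x1", self.x1)
        self.x2 = _require_finite("x2", self.x2)
        if self.theta is None:
            self.theta = np.zeros_like(self.x1)
        else:
            self.theta = _require_finite("theta", self.theta)
        if not (len(self.x1) == len(self.x2) == len(self.theta)):
            raise ValueError("x1, x2 and theta must have identical length")
        if len(self.x1) < 2:
            raise ValueError("trajectory needs at least 2 frames")
        if not np.isfinite(self.dt) or self.dt <= 0:
            raise ValueError("dt must be a positive finite number")

    @property
    def n_frames(self) -> int:
        return len(self.x1)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    @property
    def distance(self) -> np.ndarray:
        """Projected inter-sister distance d_i = x1_i - x2_i."""
        return self.x1 - self.x2

    def displacements(self) -> np.ndarray:
        """Frame displacements, shape (n-1, 2)."""
        return np.stack([np.diff(self.x1), np.diff(self.x2)], axis=1)

    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.x1 + self.x2)

    def is_canonical(self) -> bool:
        return float(np.mean(self.x1)) > float(np.mean(self.x2))

    def canonical(self) -> "Trajectory":
        """Return a copy satisfying the sister-1-right convention."""
        if self.is_canonical():
            return self
        return replace(self, x1=self.x2.copy(), x2=self.x1.copy())

    def validate(self) -> "Trajectory":
        if not self.is_canonical():
            raise ValueError(
                "sister-1-right convention violated: mean(x1) <= mean(x2); "
                "use Trajectory.canonical() to swap sisters"
            )
        return self


@dataclass
class StatePath:
    """Per-interval K-fibre states for both sisters.

    ``sigma`` has shape (n-1, 2) with entries +1 (polymerising, '+') or -1
    (depolymerising, '-'); row i governs the displacement from frame i to
    i+1.
    """

    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma)
        if self.sigma.ndim != 2 or self.sigma.shape[1] != 2:
            raise ValueError("sigma must have shape (n_intervals, 2)")
        if not np.all(np.isin(self.sigma, (-1, 1))):
            raise ValueError("sigma entries must be +1 or -1")
        self.sigma = self.sigma.astype(np.int8)

    @property
    def n_intervals(self) -> int:
        return self.sigma.shape[0]

    @property
    def coherent(self) -> np.ndarray:
        """Boolean mask: sisters in a coherent pair state (+/- or -/+)."""
        return self.sigma[:, 0] != self.sigma[:, 1]

    @property
    def pair_index(self) -> np.ndarray:
        """Integer pair-state index following :data:`PAIR_STATES` order."""
        return (2 * (self.sigma[:, 0] < 0) + (self.sigma[:, 1] < 0)).astype(np.int64)

    @classmethod
    def from_pair_index(cls, idx: np.ndarray) -> "StatePath":
        idx = np.asarray(idx, dtype=np.int64)
        s1 = np.where(idx // 2 == 0, 1, -1)
        s2 = np.where(idx % 2 == 0, 1, -1)
        return cls(np.stack([s1, s2], axis=1))

    def labels(self) -> list[tuple[str, str]]:
        return [PAIR_STATES[i] for i in self.pair_index]


@dataclass
class SimulationConfig:
    """Configuration for a forward simulation.

    The random stream is fixed by ``seed`` with a fixed order (all states
    first, then all displacement noise) so runs are reproducible; the
    generator algorithm is recorded in ``generator``.
    """

    params: ModelParameters
    n_frames: int = 150
    seed: int = 0
    x1_0: float | None = None  # defaults to +L/2
    x2_0: float | None = None  # defaults to -L/2
    theta: np.ndarray | None = None  # defaults to all-zero (1D simulation)
    dt: float = 2.0
    pair_id: str = "sim-0"
    cell_id: str = "sim-cell"
    generator: str = field(default="numpy-PCG64", init=False)

    def validate(self) -> "SimulationConfig":
        self.params.validate()
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.theta is not None and len(np.atleast_1d(self.theta)) != self.n_frames:
            raise ValueError("theta series must have length n_frames")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        return self


def drift_displacement(
    params: ModelParameters,
    sigma1: str,
    sigma2: str,
    x1: float,
    x2: float,
    theta: float = 0.0,
    dt: float = 2.0,
) -> tuple[float, float]:
    """Deterministic (noise-free) one-frame displacement pair in micrometres.

    Sister 1 moves with ``-v_sigma1`` (its pole lies at +infinity), sister 2
    with ``+v_sigma2``; the spring term for sister 2 is
    ``-kappa*(x2 - x1 + L cos theta)``.
    """
    params.validate()
    for name, val in (("x1", x1), ("x2", x2), ("theta", theta), ("dt", dt)):
        _require_finite(name, val)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    stretch = x1 - x2 - params.L * np.cos(theta)
    dx1 = dt * (-params.v(sigma1) - params.kappa * stretch - params.alpha * x1)
    dx2 = dt * (+params.v(sigma2) + params.kappa * stretch - params.alpha * x2)
    return float(dx1), float(dx2)


def pair_transition_matrix(p_c: float, p_ic: float) -> np.ndarray:
    """4x4 transition matrix of the pair chain in :data:`PAIR_STATES` order.

    Each sister persists independently with probability p_c (pair coherent)
    or p_ic (pair incoherent).
    """
    for name, p in (("p_c", p_c), ("p_ic", p_ic)):
        if not (0.0 < p < 1.0):
            raise ValueError(f"{name} must lie in (0, 1)")
    T = np.empty((4, 4))
    for s, (a, b) in enumerate(PAIR_STATES):
        p = p_c if a != b else p_ic
        for t, (c, d) in enumerate(PAIR_STATES):
            T[s, t] = (p if a == c else 1 - p) * (p if b == d else 1 - p)
    return T


def coherent_stationary_fraction(p_c: float, p_ic: float) -> float:
    """Stationary coherent fraction of the induced coherent/incoherent chain."""
    to_ic = 2 * p_c * (1 - p_c)
    to_c = 2 * p_ic * (1 - p_ic)
    return to_c / (to_c + to_ic)


def mean_dwell_frames(p_c: float, p_ic: float) -> tuple[float, float]:
    """Mean (coherent, incoherent) dwell lengths in frames (geometric dwell)."""
    return 1.0 / (2 * p_c * (1 - p_c)), 1.0 / (2 * p_ic * (1 - p_ic))


def simulate_states(
    p_c: float,
    p_ic: float,
    n_intervals: int,
    seed: int | np.random.Generator = 0,
    initial: tuple[str, str] | None = None,
) -> StatePath:
    """Simulate the hidden pair-state chain for ``n_intervals`` frames.

    The initial pair state is drawn uniformly from the four states unless
    ``initial`` is given.  Each subsequent frame, each sister independently
    keeps its state with probability p_c (pair currently coherent) or p_ic
    (incoherent).
    """
    for name, p in (("p_c", p_c), ("p_ic", p_ic)):
        if not (0.0 < p < 1.0):
            raise ValueError(f"{name} must lie in (0, 1)")
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sigma = np.empty((n_intervals, 2), dtype=np.int8)
    if initial is None:
        first = rng.integers(4)
        sigma[0, 0] = 1 if first // 2 == 0 else -1
        sigma[0, 1] = 1 if first % 2 == 0 else -1
    else:
        sigma[0] = [1 if s == "+" else -1 for s in initial]
    u = rng.random((n_intervals - 1, 2))
    for i in range(1, n_intervals):
        p = p_c if sigma[i - 1, 0] != sigma[i - 1, 1] else p_ic
        keep = u[i - 1] < p
        sigma[i] = np.where(keep, sigma[i - 1], -sigma[i - 1])
    return StatePath(sigma)


def simulate_trajectory(config: SimulationConfig) -> tuple[Trajectory, StatePath]:
    """Simulate a paired trajectory; returns it with the ground-truth states.

    States are drawn first (full path), then Gaussian displacement noise
    ``dt * N(0, 1/tau)``, so the random stream order is fixed and seeds are
    portable across runs.
    """
    config.validate()
    p = config.params
    n = config.n_frames
    rng = np.random.default_rng(config.seed)
    states = simulate_states(p.p_c, p.p_ic, n - 1, seed=rng)
    noise = rng.normal(0.0, np.sqrt(1.0 / p.tau), size=(n - 1, 2)) * config.dt

    theta = np.zeros(n) if config.theta is None else np.asarray(config.theta, dtype=float)
    x1 = np.empty(n)
    x2 = np.empty(n)
    x1[0] = p.L / 2 if config.x1_0 is None else config.x1_0
    x2[0] = -p.L / 2 if config.x2_0 is None else config.x2_0
    sig = states.sigma
    v = np.where(sig > 0, p.v_plus, p.v_minus)  # (n-1, 2)
    cth = np.cos(theta)
    dt = config.dt
    for i in range(n - 1):
        stretch = x1[i] - x2[i] - p.L * cth[i]
        x1[i + 1] = x1[i] + dt * (-v[i, 0] - p.kappa * stretch - p.alpha * x1[i]) + noise[i, 0]
        x2[i + 1] = x2[i] + dt * (+v[i, 1] + p.kappa * stretch - p.alpha * x2[i]) + noise[i, 1]

    traj = Trajectory(
        x1=x1,
        x2=x2,
        theta=theta,
        dt=config.dt,
        pair_id=config.pair_id,
        cell_id=config.cell_id,
    )
    if not traj.is_canonical():
        warnings.warn(
            "simulated trajectory violates the sister-1-right convention "
            "(mean x1 <= mean x2); downstream fits expect canonical order",
            stacklevel=2,
        )
    return traj, states


def fig1b_parameters() -> ModelParameters:
    """The fully printed generative parameter set used throughout the tests.

    p_c=0.94, p_ic=0.61, v+=0.05 um/s, v-=-0.03 um/s, L=0.8 um,
    kappa=0.05 1/s, alpha=0.03 1/s, tau=1000 s^2/um^2 (dt = 2 s).
    """
    return ModelParameters(
        v_plus=0.05,
        v_minus=-0.03,
        kappa=0.05,
        L=0.8,
        alpha=0.03,
        tau=1000.0,
        p_c=0.94,
        p_ic=0.61,
    )
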