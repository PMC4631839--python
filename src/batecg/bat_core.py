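"""Bat-algorithm optimizer engines over a bounded continuous search space.

Two variants are provided:

* ``mode="ba"`` — the standard bat algorithm: each bat carries a scalar
  loudness ``A`` and pulse rate ``r``.  Candidate moves combine a
  frequency-scaled velocity update with an occasional random walk around
  the global best, gated by ``r``; greedy acceptance is gated by ``A``.
* ``mode="iba"`` — the improved variant: ``A`` and ``r`` are carried
  *per dimension*, and the local random walk, loudness decay and pulse
  growth are gated independently for every coordinate.

Both engines are fully deterministic given a seed.  Random draws happen
in a fixed, documented order each step: frequencies, per-bat (BA) or
per-dimension (IBA) gates, walk perturbations, acceptance uniforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ConfigError",
    "DimensionError",
    "EvaluationError",
    "SwarmConfig",
    "BatState",
    "Swarm",
    "OptimizerTrace",
    "OptimizeResult",
    "rosenbrock",
    "draw_frequency",
    "update_velocity",
    "update_position",
    "local_search_ba",
    "decay_loudness",
    "grow_pulse_rate",
    "local_search_iba",
    "update_loudness_iba",
    "update_pulse_iba",
    "init_swarm",
    "step_ba",
    "step_iba",
    "run_optimizer",
]


class ConfigError(ValueError):
    """Invalid optimizer configuration."""


class DimensionError(ValueError):
    """Vector arguments of mismatched or insufficient length."""


class EvaluationError(RuntimeError):
    """Objective returned a non-finite value."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SwarmConfig:
    """Parameters of a BA/IBA run.

    ``bounds`` is a sequence of (lo, hi) pairs, one per search dimension;
    it may be left ``None`` at construction but must be set before a run.
    """

    bounds: Sequence[tuple[float, float]] | None = None
    pop_size: int = 25
    generations: int = 30
    fmin: float = 0.0
    fmax: float = 2.0
    alpha: float = 0.95
    gamma: float = 0.95
    r0: float = 0.2
    a_min: float = 1.0
    a_max: float = 3.0
    seed: int = 0
    local_base: str = "best"  # base vector of the IBA walk: "best" | "self"
    classic_velocity: bool = False  # flip the (x - gbest) sign for comparison

    _FIELDS = (
        "bounds", "pop_size", "generations", "fmin", "fmax", "alpha",
        "gamma", "r0", "a_min", "a_max", "seed", "local_base",
        "classic_velocity",
    )

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ConfigError("pop_size must be >= 2")
        if self.generations < 0:
            raise ConfigError("generations must be >= 0")
        if self.fmin > self.fmax:
            raise ConfigError("fmin must be <= fmax")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.gamma <= 0.0:
            raise ConfigError("gamma must be > 0")
        if not (0.0 < self.r0 <= 1.0):
            raise ConfigError("r0 must lie in (0, 1]")
        if not (self.a_max >= self.a_min > 0.0):
            raise ConfigError("loudness range must satisfy a_max >= a_min > 0")
        if self.local_base not in ("best", "self"):
            raise ConfigError("local_base must be 'best' or 'self'")
        if self.bounds is not None:
            b = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
            if any(lo > hi for lo, hi in b):
                raise ConfigError("each bound must satisfy lo <= hi")
            object.__setattr__(self, "bounds", b)

    @property
    def dim(self) -> int:
        if self.bounds is None:
            raise ConfigError("bounds not set")
        return len(self.bounds)

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if self.bounds is None:
            raise ConfigError("bounds not set")
        arr = np.asarray(self.bounds, dtype=float)
        return arr[:, 0], arr[:, 1]

    @classmethod
    def from_dict(cls, d: dict) -> "SwarmConfig":
        """Build from a JSON-style dict; unknown keys are rejected."""
        unknown = set(d) - set(cls._FIELDS)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "bounds": None if self.bounds is None else [list(b) for b in self.bounds],
            "pop_size": self.pop_size,
            "generations": self.generations,
            "fmin": self.fmin,
            "fmax": self.fmax,
            "alpha": self.alpha,
            "gamma": self.gamma,
            "r0": self.r0,
            "a_min": self.a_min,
            "a_max": self.a_max,
            "seed": self.seed,
            "local_base": self.local_base,
            "classic_velocity": self.classic_velocity,
        }


# ---------------------------------------------------------------------------
# primitive operations


def rosenbrock(x: Iterable[float]) -> float | np.ndarray:
    """Benchmark valley function; >= 0 with global minimum 0 at all-ones.

    Accepts a single vector (returns a float) or a 2-D batch of row
    vectors (returns a 1-D array).
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim not in (1, 2) or arr.shape[-1] < 2:
        raise DimensionError("rosenbrock requires vectors of length >= 2")
    a = arr[..., :-1]
    b = arr[..., 1:]
    val = np.sum(100.0 * (b - a**2) ** 2 + (a - 1.0) ** 2, axis=-1)
    return float(val) if arr.ndim == 1 else val


def draw_frequency(fmin: float, fmax: float, u: float) -> float:
    """Map a uniform draw u in [0, 1] onto the frequency band."""
    if fmin > fmax:
        raise ConfigError("fmin must be <= fmax")
    return fmin + (fmax - fmin) * u


def update_velocity(
    v: np.ndarray,
    x: np.ndarray,
    x_gbest: np.ndarray,
    f: float,
    classic: bool = False,
) -> np.ndarray:
    """Frequency-scaled velocity update.

    Default sign convention adds ``(x - x_gbest) * f``; ``classic=True``
    flips it to the attraction form used by most BA implementations.
    """
    v = np.asarray(v, dtype=float)
    x = np.asarray(x, dtype=float)
    g = np.asarray(x_gbest, dtype=float)
    if not (v.shape == x.shape == g.shape):
        raise DimensionError("velocity/position/best length mismatch")
    delta = (g - x) if classic else (x - g)
    return v + delta * f


def update_position(
    x: np.ndarray, v: np.ndarray, bounds: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Advance position by velocity and clamp into the bounds box."""
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    if x.shape != v.shape:
        raise DimensionError("position/velocity length mismatch")
    arr = np.asarray(bounds, dtype=float)
    return np.clip(x + v, arr[:, 0], arr[:, 1])


def local_search_ba(
    x_gbest: np.ndarray,
    A_bar: float,
    epsilon: np.ndarray,
    bounds: Sequence[tuple[float, float]] | None = None,
) -> np.ndarray:
    """Random walk around the global best scaled by mean loudness."""
    if A_bar <= 0:
        raise ConfigError("average loudness must be > 0")
    out = np.asarray(x_gbest, dtype=float) + np.asarray(epsilon, dtype=float) * A_bar
    if bounds is not None:
        arr = np.asarray(bounds, dtype=float)
        out = np.clip(out, arr[:, 0], arr[:, 1])
    return out


def decay_loudness(A: float, alpha: float) -> float:
    """Multiplicative loudness decay applied on accepted improvements."""
    if not (0.0 < alpha < 1.0):
        raise ConfigError("alpha must lie in (0, 1)")
    if A <= 0:
        raise ValueError("loudness must be > 0")
    return alpha * A


def grow_pulse_rate(r0: float, gamma: float, t: int) -> float:
    """Saturating pulse-rate schedule r0 * (1 - exp(-gamma * t))."""
    if gamma <= 0:
        raise ConfigError("gamma must be > 0")
    if t < 0:
        raise ValueError("t must be >= 0")
    return r0 * (1.0 - math.exp(-gamma * t))


def local_search_iba(
    base: np.ndarray,
    x_i: np.ndarray,
    A_bar_dims: np.ndarray,
    r_i_dims: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
    bounds: Sequence[tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-dimension gated walk around ``base``.

    For every dimension j a uniform gate is drawn; where it exceeds the
    bat's per-dimension pulse rate the coordinate is replaced by
    ``alpha * base_j + eps_j * A_bar_j`` (eps uniform in [-1, 1], A_bar_j
    the population-average loudness of dimension j), otherwise the
    coordinate of ``x_i`` is kept.  Returns (new position, gate mask).
    """
    base = np.asarray(base, dtype=float)
    x_i = np.asarray(x_i, dtype=float)
    A_bar_dims = np.asarray(A_bar_dims, dtype=float)
    r_i_dims = np.asarray(r_i_dims, dtype=float)
    if not (base.shape == x_i.shape == A_bar_dims.shape == r_i_dims.shape):
        raise DimensionError("per-dimension vectors must share one length")
    gates = rng.random(base.shape) > r_i_dims
    eps = rng.uniform(-1.0, 1.0, size=base.shape)
    out = np.where(gates, alpha * base + eps * A_bar_dims, x_i)
    if bounds is not None:
        arr = np.asarray(bounds, dtype=float)
        out = np.clip(out, arr[:, 0], arr[:, 1])
    return out, gates


def update_loudness_iba(A_ij: float, gated: bool, alpha: float) -> float:
    """Decay a single per-dimension loudness entry when its gate fired."""
    if not (0.0 < alpha < 1.0):
        raise ConfigError("alpha must lie in (0, 1)")
    return alpha * A_ij if gated else A_ij


def update_pulse_iba(r_ij: float, gated: bool, r0: float, gamma: float, t: int) -> float:
    """Refresh a per-dimension pulse rate from the saturating schedule."""
    if gamma <= 0:
        raise ConfigError("gamma must be > 0")
    return grow_pulse_rate(r0, gamma, t) if gated else r_ij


# ---------------------------------------------------------------------------
# swarm state


@dataclass
class BatState:
    """Snapshot of one bat (loudness/pulse scalar in BA, vector in IBA)."""

    position: np.ndarray
    velocity: np.ndarray
    loudness: np.ndarray | float
    pulse_rate: np.ndarray | float
    fitness: float


@dataclass
class Swarm:
    """Mutable population state; arrays are (N, D) except where noted."""

    positions: np.ndarray
    velocities: np.ndarray
    loudness: np.ndarray  # (N,) in BA mode, (N, D) in IBA mode
    pulse: np.ndarray  # same shape as loudness
    fitness: np.ndarray  # (N,)
    accept_counts: np.ndarray  # (N,) int — per-bat accepted-update clock
    best_position: np.ndarray
    best_fitness: float
    mode: str
    last_accepted: np.ndarray | None = None  # (N,) bool, set by each step

    @property
    def size(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    def bat(self, i: int) -> BatState:
        A = self.loudness[i]
        r = self.pulse[i]
        return BatState(
            position=self.positions[i].copy(),
            velocity=self.velocities[i].copy(),
            loudness=A.copy() if isinstance(A, np.ndarray) else float(A),
            pulse_rate=r.copy() if isinstance(r, np.ndarray) else float(r),
            fitness=float(self.fitness[i]),
        )

    def copy(self) -> "Swarm":
        return Swarm(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            loudness=self.loudness.copy(),
            pulse=self.pulse.copy(),
            fitness=self.fitness.copy(),
            accept_counts=self.accept_counts.copy(),
            best_position=self.best_position.copy(),
            best_fitness=self.best_fitness,
            mode=self.mode,
            last_accepted=None if self.last_accepted is None else self.last_accepted.copy(),
        )


@dataclass
class OptimizerTrace:
    """Per-iteration diagnostics; entry 0 describes the initial population."""

    best_fitness: list[float] = field(default_factory=list)
    best_position: list[list[float]] = field(default_factory=list)
    mean_loudness: list[float] = field(default_factory=list)
    mean_pulse_rate: list[float] = field(default_factory=list)
    acceptance_count: int = 0

    def record(self, swarm: Swarm, accepted: int = 0) -> None:
        self.best_fitness.append(float(swarm.best_fitness))
        self.best_position.append([float(v) for v in swarm.best_position])
        self.mean_loudness.append(float(np.mean(swarm.loudness)))
        self.mean_pulse_rate.append(float(np.mean(swarm.pulse)))
        self.acceptance_count += accepted

    def __len__(self) -> int:
        return len(self.best_fitness)

    def to_dict(self) -> dict:
        return {
            "iterations": [
                {
                    "iteration": i,
                    "best_fitness": self.best_fitness[i],
                    "mean_loudness": self.mean_loudness[i],
                    "mean_pulse_rate": self.mean_pulse_rate[i],
                }
                for i in range(len(self))
            ],
            "best_position": self.best_position[-1] if self.best_position else None,
            "acceptance_count": self.acceptance_count,
        }


class OptimizeResult(NamedTuple):
    best_position: np.ndarray
    best_fitness: float
    trace: OptimizerTrace


# ---------------------------------------------------------------------------
# engine internals


def _evaluate(objective: Callable, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0], dtype=float)
    for i, row in enumerate(X):
        val = float(objective(row))
        if not math.isfinite(val):
            raise EvaluationError(f"objective returned non-finite value for bat {i}")
        out[i] = val
    return out


def init_swarm(
    config: SwarmConfig,
    objective: Callable,
    mode: str,
    rng: np.random.Generator,
) -> Swarm:
    """Uniform positions, zero velocities, uniform loudness, pulse at r0."""
    if mode not in ("ba", "iba"):
        raise ConfigError(f"unknown mode {mode!r}")
    lo, hi = config.bounds_arrays()
    n, d = config.pop_size, config.dim
    positions = rng.uniform(lo, hi, size=(n, d))
    shape = (n,) if mode == "ba" else (n, d)
    loudness = rng.uniform(config.a_min, config.a_max, size=shape)
    # pulse starts at its configured initial value r0; accepted updates
    # then follow the saturating schedule on the per-bat acceptance clock
    pulse = np.full(shape, config.r0)
    fitness = _evaluate(objective, positions)
    best = int(np.argmin(fitness))
    return Swarm(
        positions=positions,
        velocities=np.zeros((n, d)),
        loudness=loudness,
        pulse=pulse,
        fitness=fitness,
        accept_counts=np.zeros(n, dtype=int),
        best_position=positions[best].copy(),
        best_fitness=float(fitness[best]),
        mode=mode,
    )


def _finish_step(
    swarm: Swarm,
    candidates: np.ndarray,
    new_velocities: np.ndarray,
    cand_fitness: np.ndarray,
    accept: np.ndarray,
) -> None:
    swarm.positions[accept] = candidates[accept]
    swarm.velocities[accept] = new_velocities[accept]
    swarm.fitness[accept] = cand_fitness[accept]
    swarm.accept_counts[accept] += 1
    swarm.last_accepted = accept
    best = int(np.argmin(swarm.fitness))
    if swarm.fitness[best] < swarm.best_fitness:
        swarm.best_fitness = float(swarm.fitness[best])
        swarm.best_position = swarm.positions[best].copy()


def step_ba(
    swarm: Swarm,
    objective: Callable,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> Swarm:
    """One synchronous generation of the scalar-gated bat algorithm."""
    if swarm.mode != "ba":
        raise ConfigError("step_ba requires a swarm initialized in 'ba' mode")
    lo, hi = config.bounds_arrays()
    n, d = swarm.size, swarm.dim

    freqs = config.fmin + (config.fmax - config.fmin) * rng.random(n)
    gate_u = rng.random(n)
    eps = rng.uniform(-1.0, 1.0, size=(n, d))
    accept_u = rng.random(n)

    delta = swarm.best_position - swarm.positions if config.classic_velocity else (
        swarm.positions - swarm.best_position
    )
    new_v = swarm.velocities + delta * freqs[:, None]
    candidates = np.clip(swarm.positions + new_v, lo, hi)

    a_bar = float(np.mean(swarm.loudness))
    local = np.clip(swarm.best_position + eps * a_bar, lo, hi)
    use_local = gate_u < swarm.pulse
    candidates[use_local] = local[use_local]

    cand_fitness = _evaluate(objective, candidates)
    accept = (accept_u < swarm.loudness) & (cand_fitness < swarm.fitness)

    swarm.loudness[accept] *= config.alpha
    new_counts = swarm.accept_counts[accept] + 1
    swarm.pulse[accept] = config.r0 * (1.0 - np.exp(-config.gamma * new_counts))
    _finish_step(swarm, candidates, new_v, cand_fitness, accept)
    return swarm


def step_iba(
    swarm: Swarm,
    objective: Callable,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> Swarm:
    """One generation with per-dimension loudness/pulse gating."""
    if swarm.mode != "iba":
        raise ConfigError("step_iba requires a swarm initialized in 'iba' mode")
    lo, hi = config.bounds_arrays()
    n, d = swarm.size, swarm.dim

    freqs = config.fmin + (config.fmax - config.fmin) * rng.random(n)
    gates = rng.random((n, d)) > swarm.pulse
    eps = rng.uniform(-1.0, 1.0, size=(n, d))
    accept_u = rng.random(n)

    delta = swarm.best_position - swarm.positions if config.classic_velocity else (
        swarm.positions - swarm.best_position
    )
    new_v = swarm.velocities + delta * freqs[:, None]
    moved = np.clip(swarm.positions + new_v, lo, hi)

    a_bar_dims = swarm.loudness.mean(axis=0)  # (D,)
    base = (
        np.broadcast_to(swarm.best_position, (n, d))
        if config.local_base == "best"
        else swarm.positions
    )
    walk = config.alpha * base + eps * a_bar_dims
    candidates = np.clip(np.where(gates, walk, moved), lo, hi)

    cand_fitness = _evaluate(objective, candidates)
    accept = (accept_u < swarm.loudness.mean(axis=1)) & (cand_fitness < swarm.fitness)

    upd = accept[:, None] & gates
    swarm.loudness[upd] *= config.alpha
    new_counts = swarm.accept_counts + 1  # clock value after this acceptance
    r_new = config.r0 * (1.0 - np.exp(-config.gamma * new_counts))
    swarm.pulse = np.where(upd, r_new[:, None], swarm.pulse)
    _finish_step(swarm, candidates, new_v, cand_fitness, accept)
    return swarm


def run_optimizer(
    config: SwarmConfig,
    objective: Callable,
    mode: str = "ba",
) -> OptimizeResult:
    """Initialize a swarm from ``config.seed`` and run ``generations`` steps.

    The returned trace has ``generations + 1`` entries; entry 0 is the
    evaluated initial population.
    """
    rng = np.random.default_rng(config.seed)
    swarm = init_swarm(config, objective, mode, rng)
    step = step_ba if mode == "ba" else step_iba
    trace = OptimizerTrace()
    trace.record(swarm)
    for _ in range(config.generations):
        step(swarm, objective, config, rng)
        trace.record(swarm, accepted=int(np.sum(swarm.last_accepted)))
    return OptimizeResult(swarm.best_position.copy(), float(swarm.best_fitness), trace)
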