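"""Stochastic two-cell modified repressilator and its discretisation.

The model couples two identical three-gene oscillators (the "repressilator":
*tetR* -> *cI* -> *lacI* -> *tetR*, each protein repressing the next gene's
transcription through a Hill term with coefficient ``m``) through a small
autoinducer (AI) molecule.  The AI is synthesised under the control of the
CI protein, diffuses across the cell membrane and activates a second copy of
*lacI*, closing a phase-repulsive quorum-sensing feedback loop.  Each cell
carries seven dimensionless concentrations,

    ``[a, b, c, A, B, C, S]``

(mRNA of *tetR*, *cI*, *lacI*; proteins TetR, CI, LacI; intracellular AI),
so the two-cell state has 14 components.  The extracellular AI concentration
is eliminated by a quasi-steady-state approximation,
``S_e = Q * (S_1 + S_2) / 2`` with coupling strength ``Q``.

Each concentration is driven by independent multiplicative Wiener noise, and
the SDE system is integrated with the Euler-Maruyama scheme: per step of
size ``h`` every component ``x`` receives the increment

    ``h * drift + sigma * x * sqrt(h) * z``,   ``z ~ N(0, 1)``,

followed by clamping at zero (concentrations are non-negative; the
multiplicative-noise Euler update can overshoot below zero even though the
continuous-time model cannot).  A ``literal`` noise convention is kept as an
option, with per-step increment ``sigma**2 * x * z`` and no ``h`` scaling,
mirroring a reading of the discretised update in which the Gaussian variate
itself has variance ``sigma**2``.

Four parameters are treated as unknown and given independent uniform priors:

    ``Q ~ U(0,1)``, ``m ~ U(1,5)``, ``alpha ~ U(50,300)``, ``beta_a ~ U(0,1)``.

With the standard parameter values (``theta = (0.85, 2.6, 216, 0.85)`` plus
the fixed constants below) the deterministic system is chaotic, which is
what makes the inference problem hard: trajectories from nearby parameter
vectors decorrelate quickly, so likelihood surfaces are rugged.

Observations are partial and noisy: every ``m0`` integration steps the pair
``(a_1, a_2)`` is recorded with additive isotropic Gaussian noise of
standard deviation ``sigma_y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _kernel

__all__ = [
    "N_STATE",
    "COMPONENT_NAMES",
    "OBSERVED_INDICES",
    "SUPPORT_LO",
    "SUPPORT_HI",
    "SUPPORT_WIDTH",
    "THETA_NAMES",
    "THETA_STANDARD",
    "X0_MEAN",
    "LOG_PRIOR_CONST",
    "InvalidStateError",
    "BlowupError",
    "ThetaVector",
    "FixedParameters",
    "NoiseScales",
    "SimulationGrid",
    "ObservationModel",
    "InitialStateModel",
    "RepressilatorModel",
    "Trajectory",
    "ObservationSeries",
    "extracellular_ai",
    "drift",
    "noise_amplitudes",
    "em_step",
    "propagate",
    "simulate",
    "observe",
    "sample_prior",
    "log_prior",
    "in_support",
    "sample_initial_state",
    "spawn_rngs",
]

N_STATE = 14

COMPONENT_NAMES = (
    "a1", "b1", "c1", "A1", "B1", "C1", "S1",
    "a2", "b2", "c2", "A2", "B2", "C2", "S2",
)

#: indices of the observed components (tetR mRNA in each cell)
OBSERVED_INDICES = (0, 7)

THETA_NAMES = ("Q", "m", "alpha", "beta_a")

#: support set S of the unknown parameters (uniform, independent priors)
SUPPORT_LO = np.array([0.0, 1.0, 50.0, 0.0])
SUPPORT_HI = np.array([1.0, 5.0, 300.0, 1.0])
SUPPORT_WIDTH = SUPPORT_HI - SUPPORT_LO
LOG_PRIOR_CONST = -float(np.log(SUPPORT_WIDTH.prod()))

#: ground-truth parameter values of the chaotic regime
THETA_STANDARD = np.array([0.85, 2.6, 216.0, 0.85])

#: default mean of the initial-state distribution
X0_MEAN = np.array(
    [4.5, 6.0, 3.0, 4.2, 19.0, 4.3, 0.1, 7.3, 1.5, 3.4, 7.0, 6.5, 3.6, 0.08]
)


class InvalidStateError(ValueError):
    """A state vector violates the model's domain (negative or non-finite)."""


class BlowupError(FloatingPointError):
    """The integrator produced a non-finite value."""


@dataclass(frozen=True)
class ThetaVector:
    """The four unknown parameters: coupling, Hill coefficient,
    transcription rate and TetR mRNA/protein lifetime ratio."""

    Q: float
    m: float
    alpha: float
    beta_a: float

    def as_array(self) -> np.ndarray:
        return np.array([self.Q, self.m, self.alpha, self.beta_a])

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "ThetaVector":
        q, m, a, b = (float(v) for v in np.asarray(arr))
        return cls(q, m, a, b)

    def __post_init__(self) -> None:
        if not in_support(self.as_array()):
            raise ValueError(f"theta {self.as_array()} outside the support set S")


@dataclass(frozen=True)
class FixedParameters:
    """Constants assumed known throughout: lifetime ratios of cI/lacI,
    AI membrane diffusion, LuxR-promoter transcription rate and AI
    degradation/synthesis rates (all dimensionless)."""

    beta_b: float = 0.1
    beta_c: float = 0.1
    eta: float = 2.0
    kappa: float = 25.0
    k_s0: float = 1.0
    k_s1: float = 0.01

    def __post_init__(self) -> None:
        if min(self.beta_b, self.beta_c, self.eta, self.kappa, self.k_s0, self.k_s1) <= 0:
            raise ValueError("fixed parameters must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.beta_b, self.beta_c, self.eta, self.kappa, self.k_s0, self.k_s1]
        )


@dataclass(frozen=True)
class NoiseScales:
    """Multiplicative dynamical-noise scale factors, one per equation.
    All zero recovers the deterministic modified repressilator."""

    sigma_a: float = 0.0
    sigma_b: float = 0.0
    sigma_c: float = 0.0
    sigma_A: float = 0.0
    sigma_B: float = 0.0
    sigma_C: float = 0.0
    sigma_S: float = 0.0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.per_cell()):
            raise ValueError("noise scales must be non-negative")

    def per_cell(self) -> tuple[float, ...]:
        return (
            self.sigma_a, self.sigma_b, self.sigma_c,
            self.sigma_A, self.sigma_B, self.sigma_C, self.sigma_S,
        )

    def as_array(self) -> np.ndarray:
        """Scale per state component, cells stacked: shape (14,)."""
        return np.array(self.per_cell() * 2)

    @classmethod
    def uniform(cls, sigma: float) -> "NoiseScales":
        return cls(*([float(sigma)] * 7))

    @classmethod
    def zero(cls) -> "NoiseScales":
        return cls()

    @property
    def is_zero(self) -> bool:
        return all(s == 0.0 for s in self.per_cell())


@dataclass(frozen=True)
class SimulationGrid:
    """Integration step ``h``, observation thinning ``m0`` (discrete steps
    per observation) and record length ``t_total`` in continuous-time
    units.  The number of integration steps must be a positive multiple of
    ``m0`` so that the observation record has an integer length."""

    h: float = 1e-3
    m0: int = 20
    t_total: float = 80.0

    def __post_init__(self) -> None:
        if self.h <= 0 or self.t_total <= 0:
            raise ValueError("h and t_total must be positive")
        if int(self.m0) != self.m0 or self.m0 < 1:
            raise ValueError("m0 must be a positive integer")
        n = self.t_total / self.h
        if abs(n - round(n)) > 1e-6 or round(n) % self.m0 != 0:
            raise ValueError(
                "t_total/h must be a positive integer multiple of m0 "
                f"(got t_total={self.t_total}, h={self.h}, m0={self.m0})"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.h))

    @property
    def n_observations(self) -> int:
        return self.n_steps // self.m0


@dataclass(frozen=True)
class ObservationModel:
    """Additive isotropic Gaussian observation noise on (a1, a2)."""

    sigma_y: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_y <= 0:
            raise ValueError("sigma_y must be positive")


@dataclass(frozen=True)
class InitialStateModel:
    """Isotropic Gaussian initial-state distribution (floored at zero).
    ``sigma_0 = 0`` degenerates to a point mass at the mean."""

    mean: tuple[float, ...] = tuple(X0_MEAN)
    sigma_0: float = 0.05

    def __post_init__(self) -> None:
        if len(self.mean) != N_STATE:
            raise ValueError(f"mean must have {N_STATE} components")
        if self.sigma_0 < 0:
            raise ValueError("sigma_0 must be non-negative")

    def mean_array(self) -> np.ndarray:
        return np.asarray(self.mean, dtype=float)


@dataclass(frozen=True)
class RepressilatorModel:
    """Bundle of everything except theta needed to simulate and observe."""

    fixed: FixedParameters = field(default_factory=FixedParameters)
    noise: NoiseScales = field(default_factory=NoiseScales)
    grid: SimulationGrid = field(default_factory=SimulationGrid)
    obs: ObservationModel = field(default_factory=ObservationModel)
    init: InitialStateModel = field(default_factory=InitialStateModel)
    noise_convention: str = "em_standard"

    def __post_init__(self) -> None:
        if self.noise_convention not in ("em_standard", "literal"):
            raise ValueError("noise_convention must be 'em_standard' or 'literal'")

    def with_noise(self, noise: NoiseScales) -> "RepressilatorModel":
        return replace(self, noise=noise)


@dataclass(frozen=True)
class Trajectory:
    """A discrete-time state record: states[k] is the state after k steps."""

    states: np.ndarray  # (n_steps + 1, 14)
    grid: SimulationGrid
    theta: np.ndarray  # (4,)
    seed: int | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.states.shape[0]) * self.grid.h

    def observable(self) -> np.ndarray:
        """Noise-free readout (a1, a2) at the observation times."""
        m0 = self.grid.m0
        return self.states[m0::m0, list(OBSERVED_INDICES)]


@dataclass(frozen=True)
class ObservationSeries:
    """Noisy 2-dimensional records y_1..y_R (y_n taken at state index n*m0)."""

    y: np.ndarray  # (R, 2)
    grid: SimulationGrid
    sigma_y: float

    def __post_init__(self) -> None:
        if self.y.ndim != 2 or self.y.shape[1] != 2:
            raise ValueError("y must have shape (R, 2)")

    def __len__(self) -> int:
        return self.y.shape[0]

    @property
    def times(self) -> np.ndarray:
        return (np.arange(len(self)) + 1) * self.grid.m0 * self.grid.h


# ---------------------------------------------------------------------------
# deterministic part of the dynamics


def extracellular_ai(s1, s2, Q):
    """Quasi-steady-state extracellular AI concentration Q * (S1 + S2) / 2."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if np.any(s1 < 0) or np.any(s2 < 0):
        raise InvalidStateError("AI concentrations must be non-negative")
    return Q * 0.5 * (s1 + s2)


def _theta_parts(theta) -> tuple:
    arr = theta.as_array() if isinstance(theta, ThetaVector) else np.asarray(theta, float)
    if arr.shape[-1] != 4:
        raise ValueError("theta must have 4 components")
    return arr[..., 0], arr[..., 1], arr[..., 2], arr[..., 3]


def drift(state, theta, fixed: FixedParameters = FixedParameters()) -> np.ndarray:
    """Deterministic rate vector d(state)/dt; supports (..., 14) batches."""
    x = np.asarray(state, dtype=float)
    if x.shape[-1] != N_STATE:
        raise InvalidStateError(f"state must have {N_STATE} components")
    if not np.all(np.isfinite(x)):
        raise InvalidStateError("state contains non-finite components")
    Q, m, al, ba = _theta_parts(theta)
    return _kernel.drift_vec(x, Q, m, al, ba, fixed.as_array())


def noise_amplitudes(
    noise: NoiseScales, h: float, convention: str = "em_standard"
) -> np.ndarray:
    """Per-component factor ``amp`` such that the per-step noise increment is
    ``amp * x * z`` with ``z ~ N(0, 1)``.

    ``em_standard``: ``amp = sigma * sqrt(h)`` (Wiener increment of variance
    ``h``).  ``literal``: ``amp = sigma**2`` (the Gaussian variate itself has
    variance ``sigma**2`` and no step-size scaling).
    """
    sig = noise.as_array()
    if convention == "em_standard":
        return sig * np.sqrt(h)
    if convention == "literal":
        return sig**2
    raise ValueError(f"unknown noise convention {convention!r}")


def _check_finite(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        bad = np.argwhere(~np.isfinite(x))
        comp = COMPONENT_NAMES[int(bad[0][-1])]
        raise BlowupError(f"integration blow-up in component {comp!r}")


def em_step(
    state,
    theta,
    fixed: FixedParameters = FixedParameters(),
    noise: NoiseScales = NoiseScales(),
    h: float = 1e-3,
    rng: np.random.Generator | None = None,
    convention: str = "em_standard",
) -> np.ndarray:
    """One Euler-Maruyama step with multiplicative noise and positivity floor.

    When every noise scale is zero no random numbers are consumed, so the
    deterministic model leaves any RNG stream untouched.
    """
    if h < 0:
        raise ValueError("h must be non-negative")
    x = np.asarray(state, dtype=float)
    d = drift(x, theta, fixed)
    amp = noise_amplitudes(noise, h, convention)
    # overflow here is the signal the blow-up check reports on, not an error
    with np.errstate(over="ignore", invalid="ignore"):
        if noise.is_zero:
            new = x + h * d
        else:
            if rng is None:
                raise ValueError("rng required when noise scales are non-zero")
            z = rng.standard_normal(x.shape)
            new = x + h * d + amp * x * z
    _check_finite(new)
    return np.maximum(new, 0.0)


def _as_block(state, theta) -> tuple[np.ndarray, np.ndarray, tuple[int, ...]]:
    """Normalise (state, theta) to (P, 14) / (P, 4) row blocks."""
    x = np.array(state, dtype=float)
    shape = x.shape
    x = np.atleast_2d(x)
    arr = theta.as_array() if isinstance(theta, ThetaVector) else np.asarray(theta, float)
    th = np.atleast_2d(arr)
    if th.shape[0] == 1 and x.shape[0] > 1:
        th = np.broadcast_to(th, (x.shape[0], 4)).copy()
    return np.ascontiguousarray(x), np.ascontiguousarray(th), shape


def propagate(
    state,
    theta,
    m0: int,
    fixed: FixedParameters = FixedParameters(),
    noise: NoiseScales = NoiseScales(),
    h: float = 1e-3,
    rng: np.random.Generator | None = None,
    convention: str = "em_standard",
) -> np.ndarray:
    """Apply ``m0`` Euler-Maruyama steps: one draw from the composite Markov
    kernel that carries the state from one observation time to the next.

    Accepts a single state ``(14,)`` or a particle block ``(P, 14)`` with a
    shared or per-row theta.
    """
    if m0 < 1:
        raise ValueError("m0 must be >= 1")
    x, th, shape = _as_block(state, theta)
    fv = fixed.as_array()
    if noise.is_zero:
        _kernel.em_chunk_det(x, th, fv, h, m0)
    else:
        if rng is None:
            raise ValueError("rng required when noise scales are non-zero")
        amp = noise_amplitudes(noise, h, convention)
        z = rng.standard_normal((m0,) + x.shape)
        _kernel.em_chunk(x, th, fv, amp, h, z)
    _check_finite(x)
    return x.reshape(shape)


def simulate(
    theta,
    x0,
    grid: SimulationGrid,
    fixed: FixedParameters = FixedParameters(),
    noise: NoiseScales = NoiseScales(),
    seed: int | np.random.Generator | None = None,
    convention: str = "em_standard",
    chunk: int = 1000,
) -> Trajectory:
    """Integrate a full trajectory of ``grid.n_steps`` steps from ``x0``.

    Deterministic given ``seed`` (or a caller-owned ``Generator``); with all
    noise scales zero it is a pure function of (theta, x0, grid).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (N_STATE,):
        raise InvalidStateError(f"x0 must have shape ({N_STATE},)")
    if np.any(x0 < 0) or not np.all(np.isfinite(x0)):
        raise InvalidStateError("x0 must be finite and non-negative")
    arr = theta.as_array() if isinstance(theta, ThetaVector) else np.asarray(theta, float)
    n = grid.n_steps
    out = np.empty((n + 1, N_STATE))
    out[0] = x0
    x = np.ascontiguousarray(x0[None, :].copy())
    th = np.ascontiguousarray(arr[None, :])
    fv = fixed.as_array()
    amp = noise_amplitudes(noise, grid.h, convention)
    zero = noise.is_zero
    done = 0
    while done < n:
        # chunked so that per-step states can be recorded without a huge
        # noise array resident in memory
        step = min(chunk, n - done)
        if zero:
            for s in range(step):
                _kernel.em_chunk_det(x, th, fv, grid.h, 1)
                out[done + s + 1] = x[0]
        else:
            z = rng.standard_normal((step, 1, N_STATE))
            for s in range(step):
                _kernel.em_chunk(x, th, fv, amp, grid.h, z[s : s + 1])
                out[done + s + 1] = x[0]
        done += step
    _check_finite(out)
    return Trajectory(
        states=out,
        grid=grid,
        theta=arr.copy(),
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def observe(
    traj: Trajectory,
    m0: int | None = None,
    sigma_y: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> ObservationSeries:
    """Noisy partial readout y_n = (a1, a2) at state index n*m0, n = 1..R.

    The state at time zero is never observed.
    """
    m0 = traj.grid.m0 if m0 is None else int(m0)
    n_steps = traj.states.shape[0] - 1
    if m0 < 1 or m0 > n_steps:
        raise ValueError(f"m0={m0} incompatible with trajectory of {n_steps} steps")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    latent = traj.states[m0 :: m0, list(OBSERVED_INDICES)]
    y = latent + sigma_y * rng.standard_normal(latent.shape)
    grid = SimulationGrid(h=traj.grid.h, m0=m0, t_total=latent.shape[0] * m0 * traj.grid.h)
    return ObservationSeries(y=y, grid=grid, sigma_y=sigma_y)


# ---------------------------------------------------------------------------
# priors and initial states


def sample_prior(rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Independent uniform draws of theta over the support set S."""
    shape = (4,) if size is None else (size, 4)
    u = rng.random(shape)
    return SUPPORT_LO + SUPPORT_WIDTH * u


def in_support(theta) -> np.ndarray | bool:
    arr = np.asarray(theta, dtype=float)
    ok = np.all((arr > SUPPORT_LO) & (arr < SUPPORT_HI), axis=-1)
    return bool(ok) if ok.ndim == 0 else ok


def log_prior(theta) -> np.ndarray | float:
    """Log-density of the uniform prior on S (vectorised)."""
    ok = in_support(theta)
    out = np.where(ok, LOG_PRIOR_CONST, -np.inf)
    return float(out) if np.ndim(out) == 0 else out


def sample_initial_state(
    init: InitialStateModel, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Gaussian initial-state draw with the positivity floor applied."""
    mean = init.mean_array()
    if init.sigma_0 == 0.0:
        return mean.copy() if size is None else np.tile(mean, (size, 1))
    shape = (N_STATE,) if size is None else (size, N_STATE)
    x = mean + init.sigma_0 * rng.standard_normal(shape)
    return np.maximum(x, 0.0)


def spawn_rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    """Named independent RNG streams derived from one master seed.

    One stream per consumer (trajectory noise, initial state, observation
    noise, each inference algorithm) keeps scenario components individually
    reproducible.
    """
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}
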