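"""Particle Metropolis-Hastings sampler over the unknown parameters.

A pseudo-marginal Metropolis-Hastings chain on theta = (Q, m, alpha,
beta_a): each proposal is drawn from a Gaussian random-walk kernel
truncated to the support set S, its marginal likelihood is estimated with
the bootstrap filter, and the usual MH ratio decides acceptance.  Because
the likelihood estimate is unbiased, the chain targets the exact posterior
despite the likelihood being approximated (the pseudo-marginal argument).

The stored log-likelihood of the current state is retained across
rejections and never re-estimated.  Estimates discard the first half of
the chain as burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import ndtr

from . import filtering, model

__all__ = [
    "PMHConfig",
    "ChainResult",
    "propose",
    "kernel_logdensity",
    "acceptance_prob",
    "pmh_sample",
    "run_pmh",
    "pmh_estimates",
]

#: proposal variance multipliers for (Q, m, alpha, beta_a); the large entry
#: sits on alpha, whose support (50, 300) is far wider than the others
DEFAULT_DIAG = (0.01, 0.01, 100.0, 0.01)

_MAX_REJECT = 10**6


@dataclass(frozen=True)
class PMHConfig:
    """Chain length L (even), kernel scale sigma^2, per-parameter variance
    multipliers and the particle budget of the embedded filter."""

    L: int = 4000
    scale2: float = 0.1
    diag: tuple[float, float, float, float] = DEFAULT_DIAG
    n_particles: int = 100

    def __post_init__(self) -> None:
        if self.L < 2 or self.L % 2 != 0:
            raise ValueError("chain length L must be even and >= 2")
        if self.scale2 <= 0:
            raise ValueError("scale2 must be positive")
        if any(d <= 0 for d in self.diag):
            raise ValueError("diag entries must be strictly positive")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")

    @property
    def proposal_sd(self) -> np.ndarray:
        return np.sqrt(self.scale2 * np.asarray(self.diag))


@dataclass
class ChainResult:
    """PMH output: the chain, per-step accept flags and the stored
    log-likelihood trace."""

    chain: np.ndarray  # (L, 4)
    accepted: np.ndarray  # (L,) bool; entry 0 marks the initial draw
    loglik_trace: np.ndarray  # (L,)
    config: PMHConfig | None = None
    seed: int | None = None

    @property
    def acceptance_rate(self) -> float:
        if self.chain.shape[0] < 2:
            return float("nan")
        return float(np.mean(self.accepted[1:]))


def propose(
    theta_prev,
    sd: np.ndarray,
    rng: np.random.Generator,
    lo: np.ndarray = model.SUPPORT_LO,
    hi: np.ndarray = model.SUPPORT_HI,
) -> np.ndarray:
    """Draw from the Gaussian kernel centred at theta_prev, truncated to S
    by rejection."""
    centre = np.asarray(theta_prev, dtype=float)
    if not np.all((centre > lo) & (centre < hi)):
        raise ValueError("proposal centre must lie inside the support set")
    tries = 0
    while tries < _MAX_REJECT:
        cand = centre + sd * rng.standard_normal(4)
        if np.all((cand > lo) & (cand < hi)):
            return cand
        tries += 1
    raise RuntimeError(
        "truncated-Gaussian proposal rejected 1e6 consecutive draws; the "
        "kernel scale is grossly inconsistent with the support set"
    )


def kernel_logdensity(
    theta_to,
    theta_from,
    sd: np.ndarray,
    lo: np.ndarray = model.SUPPORT_LO,
    hi: np.ndarray = model.SUPPORT_HI,
) -> float:
    """Log-density of the truncated-Gaussian kernel M(theta_to | theta_from).

    The normalisation over S depends on the centre, so it must be included
    for the MH ratio to be exact near the boundary: per coordinate it is
    the Gaussian interval probability of (lo, hi).
    """
    to = np.asarray(theta_to, dtype=float)
    frm = np.asarray(theta_from, dtype=float)
    for name, v in (("theta_to", to), ("theta_from", frm)):
        if not np.all((v > lo) & (v < hi)):
            raise ValueError(f"{name} outside the support set S")
    z = (to - frm) / sd
    log_norm = np.log(ndtr((hi - frm) / sd) - ndtr((lo - frm) / sd))
    logpdf = -0.5 * z**2 - 0.5 * np.log(2.0 * np.pi) - np.log(sd)
    return float(np.sum(logpdf - log_norm))


def acceptance_prob(
    loglik_new: float,
    loglik_old: float,
    logprior_new: float,
    logprior_old: float,
    logkernel_fwd: float,
    logkernel_bwd: float,
) -> float:
    """min(1, exp[(l' + p' + k_bwd) - (l + p + k_fwd)]); a -inf candidate
    log-likelihood (degenerate filter) yields probability zero."""
    if np.isneginf(loglik_new) or np.isneginf(logprior_new):
        return 0.0
    log_ratio = (loglik_new + logprior_new + logkernel_bwd) - (
        loglik_old + logprior_old + logkernel_fwd
    )
    return float(min(1.0, np.exp(min(log_ratio, 0.0))))


def pmh_sample(
    loglik_fn: Callable[[np.ndarray, np.random.Generator], float],
    cfg: PMHConfig,
    rng: np.random.Generator,
    sample_prior: Callable = model.sample_prior,
    log_prior: Callable = model.log_prior,
    lo: np.ndarray = model.SUPPORT_LO,
    hi: np.ndarray = model.SUPPORT_HI,
) -> ChainResult:
    """Run the PMH chain with an arbitrary (estimated or exact) log-likelihood.

    ``loglik_fn(theta, rng)`` returns log l(y|theta); a fresh filter seed is
    effectively used at every call because the shared stream advances.
    """
    sd = cfg.proposal_sd
    chain = np.empty((cfg.L, 4))
    accepted = np.zeros(cfg.L, dtype=bool)
    trace = np.empty(cfg.L)
    theta = np.asarray(sample_prior(rng), dtype=float)
    ll = float(loglik_fn(theta, rng))
    lp = float(log_prior(theta))
    chain[0] = theta
    trace[0] = ll
    accepted[0] = True
    for k in range(1, cfg.L):
        cand = propose(theta, sd, rng, lo, hi)
        ll_cand = float(loglik_fn(cand, rng))
        lp_cand = float(log_prior(cand))
        alpha = acceptance_prob(
            ll_cand,
            ll,
            lp_cand,
            lp,
            kernel_logdensity(cand, theta, sd, lo, hi),
            kernel_logdensity(theta, cand, sd, lo, hi),
        )
        if rng.random() < alpha:
            theta, ll, lp = cand, ll_cand, lp_cand
            accepted[k] = True
        chain[k] = theta
        trace[k] = ll
    return ChainResult(chain=chain, accepted=accepted, loglik_trace=trace, config=cfg)


def run_pmh(
    y: model.ObservationSeries,
    cfg: PMHConfig,
    mdl: model.RepressilatorModel,
    seed: int | np.random.Generator | None = None,
) -> ChainResult:
    """PMH over the repressilator posterior, with the bootstrap filter
    supplying the likelihood estimates."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def loglik(theta: np.ndarray, r: np.random.Generator) -> float:
        est = filtering.bf_loglik(theta, y, cfg.n_particles, mdl, r)
        return est.log_value

    result = pmh_sample(loglik, cfg, rng)
    result.seed = seed if isinstance(seed, (int, np.integer)) else None
    return result


def pmh_estimates(chain: ChainResult | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and covariance from the second half of the chain."""
    arr = chain.chain if isinstance(chain, ChainResult) else np.asarray(chain)
    L = arr.shape[0]
    if L % 2 != 0:
        raise ValueError("chain length must be even")
    half = arr[L // 2 :]
    mean = half.mean(axis=0)
    dev = half - mean
    cov = dev.T @ dev / half.shape[0]
    return mean, cov
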