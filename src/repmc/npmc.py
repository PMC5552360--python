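"""Nonlinear population Monte Carlo with clipped importance weights.

Iterated importance sampling for the parameter posterior: iteration k draws
M samples from a Gaussian proposal fitted (by weighted mean and covariance)
to the previous weighted population, computes importance weights

    ``w~_i = l^N(y|theta_i) p0(theta_i) / q_k(theta_i)``

(with the bootstrap-filter likelihood estimate) and then *clips* them: the
Mc largest raw weights are flattened to the Mc-th largest value before
normalisation.  Clipping bounds each normalised transformed weight by
~1/Mc, curbing the weight degeneracy that otherwise cripples importance
sampling when the likelihood is extremely peaked, at the price of a small,
vanishing bias.  The default Mc = floor(sqrt(M)) is the largest choice that
retains asymptotic convergence.

All weight arithmetic is done in the log domain; clipping commutes with the
log transform because it is monotone and order-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from . import filtering, model

__all__ = [
    "NPMCConfig",
    "WeightedEnsemble",
    "DegenerateEnsembleError",
    "clip_weights",
    "fit_proposal",
    "npmc_estimates",
    "npmc_sample",
    "run_npmc",
]

#: diagonal jitter added per unit squared support width when the fitted
#: proposal covariance is numerically singular
_JITTER = 1e-8


class DegenerateEnsembleError(RuntimeError):
    """All raw importance weights of an iteration vanished."""


@dataclass(frozen=True)
class NPMCConfig:
    """M samples per iteration, K iterations, clipping parameter Mc
    (default floor(sqrt(M))) and the particle budget of the embedded
    filter."""

    M: int = 200
    K: int = 20
    Mc: int | None = None
    n_particles: int = 100

    def __post_init__(self) -> None:
        if self.M < 1 or self.K < 0:
            raise ValueError("require M >= 1 and K >= 0")
        if self.Mc is not None and not (1 <= self.Mc <= self.M):
            raise ValueError("require 1 <= Mc <= M")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")

    @property
    def clip_count(self) -> int:
        return self.Mc if self.Mc is not None else max(1, int(np.floor(np.sqrt(self.M))))


@dataclass
class WeightedEnsemble:
    """One NPMC population: samples, raw/clipped log-weights and the
    normalised transformed weights (which sum to one)."""

    samples: np.ndarray  # (M, 4)
    log_raw: np.ndarray  # (M,) log of non-normalised IWs (up to a constant)
    log_clipped: np.ndarray  # (M,) log of TIWs
    norm_weights: np.ndarray  # (M,)
    iteration: int

    @property
    def ess(self) -> float:
        """Effective sample size 1 / sum(w^2) of the normalised TIWs."""
        return float(1.0 / np.sum(self.norm_weights**2))


def clip_weights(raw, mc: int) -> np.ndarray:
    """Flatten the ``mc`` largest weights to the ``mc``-th largest value.

    Works identically on plain weights and on log-weights (the transform is
    monotone).  Ties are broken by a stable sort on (weight, index), and
    entries strictly below the clipping threshold are left untouched, so
    their relative order is preserved.
    """
    w = np.asarray(raw, dtype=float)
    if not (1 <= mc <= w.size):
        raise ValueError(f"clipping parameter Mc={mc} out of range for {w.size} weights")
    order = np.argsort(w, kind="stable")[::-1]  # descending, stable in index
    out = w.copy()
    out[order[:mc]] = w[order[mc - 1]]
    return out


def fit_proposal(
    samples: np.ndarray,
    weights: np.ndarray,
    support_width: np.ndarray = model.SUPPORT_WIDTH,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted mean and covariance of a population, regularised to be
    usable as a Gaussian proposal.

    If the weighted covariance is not positive definite (e.g. the mass sits
    on a single sample), a diagonal jitter proportional to the squared
    prior support widths is added until it is.
    """
    s = np.atleast_2d(np.asarray(samples, dtype=float))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mu = w @ s
    dev = s - mu
    sigma = (dev * w[:, None]).T @ dev
    sigma = 0.5 * (sigma + sigma.T)
    jitter = _JITTER * np.diag(np.asarray(support_width) ** 2)
    for _ in range(32):
        try:
            np.linalg.cholesky(sigma)
            break
        except np.linalg.LinAlgError:
            sigma = sigma + jitter
            jitter = jitter * 10.0
    return mu, sigma


def npmc_estimates(ensemble: WeightedEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and covariance under the normalised TIWs."""
    w = ensemble.norm_weights
    mu = w @ ensemble.samples
    dev = ensemble.samples - mu
    cov = (dev * w[:, None]).T @ dev
    return mu, cov


def _make_ensemble(samples: np.ndarray, log_raw: np.ndarray, mc: int, k: int) -> WeightedEnsemble:
    if not np.any(np.isfinite(log_raw)):
        raise DegenerateEnsembleError(
            f"all raw importance weights vanished at iteration {k}; "
            "increase the filter particle count N or the population size M"
        )
    # with fewer than Mc nonzero raw weights a literal clip would zero the
    # whole population; cap the clip count at the number of live samples
    mc = min(mc, int(np.sum(np.isfinite(log_raw))))
    log_clipped = clip_weights(log_raw, mc)
    norm = np.exp(log_clipped - logsumexp(log_clipped))
    norm = norm / norm.sum()
    return WeightedEnsemble(
        samples=samples,
        log_raw=log_raw,
        log_clipped=log_clipped,
        norm_weights=norm,
        iteration=k,
    )


def npmc_sample(
    loglik_fn: Callable[[np.ndarray, np.random.Generator], np.ndarray],
    cfg: NPMCConfig,
    rng: np.random.Generator,
    sample_prior: Callable = model.sample_prior,
    log_prior: Callable = model.log_prior,
) -> list[WeightedEnsemble]:
    """Run NPMC with an arbitrary batched log-likelihood.

    ``loglik_fn(thetas, rng)`` maps an (M, 4) block to (M,) log-likelihood
    values; rows outside the prior support are never evaluated (their raw
    weight is exactly zero).  Returns K+1 ensembles: the prior-sampled
    initialisation (iteration 0) plus one per adaptation step.
    """
    mc = cfg.clip_count
    # iteration 0: prior sampling, so the proposal density cancels the prior
    # factor and the raw weight is the likelihood alone
    samples = sample_prior(rng, cfg.M)
    log_raw = np.asarray(loglik_fn(samples, rng), dtype=float)
    ensembles = [_make_ensemble(samples, log_raw, mc, 0)]
    for k in range(1, cfg.K + 1):
        prev = ensembles[-1]
        mu, sigma = fit_proposal(prev.samples, prev.norm_weights)
        chol = np.linalg.cholesky(sigma)
        samples = mu + rng.standard_normal((cfg.M, 4)) @ chol.T
        lp = np.asarray(log_prior(samples), dtype=float)
        inside = np.isfinite(lp)
        loglik = np.full(cfg.M, -np.inf)
        if np.any(inside):
            loglik[inside] = np.asarray(loglik_fn(samples[inside], rng), dtype=float)
        logq = multivariate_normal(mean=mu, cov=sigma, allow_singular=True).logpdf(samples)
        log_raw = np.where(inside, loglik + lp - logq, -np.inf)
        ensembles.append(_make_ensemble(samples, log_raw, mc, k))
    return ensembles


def run_npmc(
    y: model.ObservationSeries,
    cfg: NPMCConfig,
    mdl: model.RepressilatorModel,
    seed: int | np.random.Generator | None = None,
) -> list[WeightedEnsemble]:
    """NPMC over the repressilator posterior with bootstrap-filter weights."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def loglik(thetas: np.ndarray, r: np.random.Generator) -> np.ndarray:
        ests = filtering.bf_loglik_batch(thetas, y, cfg.n_particles, mdl, r)
        return np.array([e.log_value for e in ests])

    return npmc_sample(loglik, cfg, rng)
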