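"""Shared fixtures.

The expensive fixture here is ``desk_benchmark``: five independently seeded
desk-scale datasets (deterministic trajectories, 10 time units, 500 noisy
observations) with a full NPMC / PMH / ABC-SMC run on each.  It is session
scoped and shared between the sampler-level qualitative tests and the
end-to-end acceptance tests, so the three-method comparison is computed
once per test session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings

from repmc import abc_smc, experiments, model, npmc, pmh

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

DESK_SEEDS = (1, 2, 3, 4, 5)


@dataclass
class DeskRun:
    seed: int
    y: model.ObservationSeries
    x0: np.ndarray
    ensembles: list  # NPMC, K = 10 iterations
    chain: pmh.ChainResult  # PMH, L = 250
    populations: list  # ABC-SMC, 5 tolerance stages

    def npmc_estimate(self, iteration: int = -1) -> np.ndarray:
        mean, _ = npmc.npmc_estimates(self.ensembles[iteration])
        return mean

    def pmh_estimate(self) -> np.ndarray:
        mean, _ = pmh.pmh_estimates(self.chain)
        return mean

    def abc_estimate(self) -> np.ndarray:
        return abc_smc.abc_estimate(self.populations[-1])


@pytest.fixture(scope="session")
def desk_scenario() -> experiments.ScenarioConfig:
    return experiments.desk_scenario(stochastic=False, t_total=10.0)


@pytest.fixture(scope="session")
def desk_benchmark(desk_scenario) -> list[DeskRun]:
    """Five-seed desk-scale three-method comparison on shared records."""
    runs = []
    for seed in DESK_SEEDS:
        _, y, x0 = experiments.generate_dataset(desk_scenario, seed)
        streams = model.spawn_rngs(1000 + seed, ["npmc", "pmh", "abc"])
        ensembles = npmc.run_npmc(
            y,
            npmc.NPMCConfig(M=50, K=10, n_particles=50),
            desk_scenario.inference_model(),
            streams["npmc"],
        )
        chain = pmh.run_pmh(
            y,
            pmh.PMHConfig(L=250, scale2=0.04, n_particles=100),
            desk_scenario.inference_model(),
            streams["pmh"],
        )
        with warnings.catch_warnings():
            # the draw cap may legitimately truncate the last population
            warnings.simplefilter("ignore", RuntimeWarning)
            populations = abc_smc.run_abc_smc(
                y,
                abc_smc.ABCConfig(
                    tolerances=experiments.DESK_TOLERANCES,
                    J=100,
                    max_draws_factor=50,
                ),
                desk_scenario.abc_model(),
                x0,
                streams["abc"],
            )
        runs.append(
            DeskRun(
                seed=seed,
                y=y,
                x0=x0,
                ensembles=ensembles,
                chain=chain,
                populations=populations,
            )
        )
    return runs
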