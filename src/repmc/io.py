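"""CSV/JSON serialisation of trajectories, records, chains and ensembles.

Tables go to CSV through pandas (one row per time index / sample); run
metadata (parameters, seeds, grid) goes to JSON sidecars so a results
directory is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import abc_smc, model, npmc, pmh

__all__ = [
    "trajectory_to_csv",
    "trajectory_from_csv",
    "observations_to_csv",
    "observations_from_csv",
    "chain_to_csv",
    "ensembles_to_csv",
    "populations_to_csv",
    "write_json",
]


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    raise TypeError(f"not JSON serialisable: {type(value)}")


def _sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.json")


def trajectory_to_csv(traj: model.Trajectory, path) -> None:
    df = pd.DataFrame(traj.states, columns=list(model.COMPONENT_NAMES))
    df.insert(0, "t", traj.times)
    df.to_csv(path, index=False)
    write_json(
        {
            "theta": traj.theta,
            "seed": traj.seed,
            "h": traj.grid.h,
            "m0": traj.grid.m0,
            "t_total": traj.grid.t_total,
        },
        _sidecar(path),
    )


def trajectory_from_csv(path) -> model.Trajectory:
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    grid = model.SimulationGrid(h=meta["h"], m0=meta["m0"], t_total=meta["t_total"])
    return model.Trajectory(
        states=df[list(model.COMPONENT_NAMES)].to_numpy(),
        grid=grid,
        theta=np.asarray(meta["theta"], dtype=float),
        seed=meta.get("seed"),
    )


def observations_to_csv(obs: model.ObservationSeries, path) -> None:
    df = pd.DataFrame(obs.y, columns=["y1", "y2"])
    df.insert(0, "t", obs.times)
    df.insert(0, "n", np.arange(1, len(obs) + 1))
    df.to_csv(path, index=False)
    write_json(
        {
            "sigma_y": obs.sigma_y,
            "h": obs.grid.h,
            "m0": obs.grid.m0,
            "t_total": obs.grid.t_total,
        },
        _sidecar(path),
    )


def observations_from_csv(path) -> model.ObservationSeries:
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    grid = model.SimulationGrid(h=meta["h"], m0=meta["m0"], t_total=meta["t_total"])
    return model.ObservationSeries(
        y=df[["y1", "y2"]].to_numpy(), grid=grid, sigma_y=meta["sigma_y"]
    )


def chain_to_csv(result: pmh.ChainResult, path) -> None:
    df = pd.DataFrame(result.chain, columns=list(model.THETA_NAMES))
    df.insert(0, "step", np.arange(result.chain.shape[0]))
    df["accepted"] = result.accepted.astype(int)
    df["loglik"] = result.loglik_trace
    df.to_csv(path, index=False)
    mean, cov = pmh.pmh_estimates(result)
    write_json(
        {
            "estimate_mean": mean,
            "estimate_cov": cov,
            "acceptance_rate": result.acceptance_rate,
            "L": result.chain.shape[0],
            "seed": result.seed,
        },
        _sidecar(path),
    )


def ensembles_to_csv(ensembles: list[npmc.WeightedEnsemble], path) -> None:
    frames = []
    for ens in ensembles:
        df = pd.DataFrame(ens.samples, columns=list(model.THETA_NAMES))
        df.insert(0, "sample", np.arange(ens.samples.shape[0]))
        df.insert(0, "iteration", ens.iteration)
        df["log_raw_weight"] = ens.log_raw
        df["log_clipped_weight"] = ens.log_clipped
        df["norm_weight"] = ens.norm_weights
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    mean, cov = npmc.npmc_estimates(ensembles[-1])
    write_json(
        {
            "estimate_mean": mean,
            "estimate_cov": cov,
            "iterations": len(ensembles) - 1,
            "ess_final": ensembles[-1].ess,
        },
        _sidecar(path),
    )


def populations_to_csv(populations: list[abc_smc.ABCPopulation], path) -> None:
    frames = []
    for pop in populations:
        df = pd.DataFrame(pop.samples, columns=list(model.THETA_NAMES))
        df.insert(0, "sample", np.arange(len(pop)))
        df.insert(0, "population", pop.t)
        df["weight"] = pop.weights
        df["distance"] = pop.distances
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    write_json(
        {
            "estimate_mean": abc_smc.abc_estimate(populations[-1]),
            "tolerances": [p.tolerance for p in populations],
            "acceptance_rates": [p.acceptance_rate for p in populations],
            "draws_used": [p.draws_used for p in populations],
            "sizes": [len(p) for p in populations],
        },
        _sidecar(path),
    )
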