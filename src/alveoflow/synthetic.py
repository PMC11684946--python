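"""Synthetic replicates and noisy hemodynamic observations with known truth.

Emulates the study's replicate scheme — two fresh randomized pore layouts
plus their mirror images, four geometries in total — and generates noisy
(velocity, pressure-drop) observation pairs around solver outputs for
inference-recovery experiments.  Noise is multiplicative log-normal
(observations stay positive) with a default coefficient of variation of 3%,
bracketing the replicate-to-replicate variability of the flow targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGeometryError
from .geometry import ConnectivityConfig, MorphoParams, SheetDomain, mirror_domain
from .experiments import build_replicate_domain
from .inference import Observation, infer
from .sheetflow import BoundaryConditions, FluidModel, SheetFlowProblem, solve_sheet

__all__ = [
    "ReplicateSpec",
    "SyntheticObservation",
    "make_replicates",
    "generate_observations",
    "recovery_experiment",
]

DEFAULT_NOISE_CV = 0.03


@dataclass(frozen=True)
class ReplicateSpec:
    """Replicate scheme: fresh seeded layouts, optionally with mirrors."""

    n_fresh: int = 2
    include_mirrors: bool = True
    base_seed: int = 11

    def __post_init__(self):
        if self.n_fresh < 1:
            raise InvalidGeometryError("need at least one fresh replicate")

    @property
    def total(self) -> int:
        return self.n_fresh * (2 if self.include_mirrors else 1)


@dataclass(frozen=True)
class SyntheticObservation:
    """One noisy observation pair with its generating configuration."""

    config: ConnectivityConfig
    v_obs: float       # mm/s
    dp_obs: float      # mmHg
    noise_cv: float
    seed: int


def make_replicates(spec: ReplicateSpec,
                    params: MorphoParams | None = None,
                    config: ConnectivityConfig | None = None,
                    target_edge_length: float = 4.0) -> list[SheetDomain]:
    """Fresh replicates differ only in pore placement; mirrors are exact."""
    params = params or MorphoParams()
    config = config or ConnectivityConfig()
    fresh = [build_replicate_domain(config, params,
                                    seed=spec.base_seed + i,
                                    target_edge_length=target_edge_length)
             for i in range(spec.n_fresh)]
    domains = list(fresh)
    if spec.include_mirrors:
        domains += [mirror_domain(d) for d in fresh]
    return domains


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative factors with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def generate_observations(config: ConnectivityConfig, n_obs: int,
                          noise_cv: float, seed: int,
                          solver=None,
                          truth: tuple | None = None,
                          params: MorphoParams | None = None,
                          target_edge_length: float = 4.0) -> list[SyntheticObservation]:
    """Solve once for the configuration, then perturb the targets.

    ``truth`` may supply a precomputed (velocity mm/s, Δp mmHg) pair — e.g.
    replicate means from a sweep — to skip the solve; otherwise ``solver``
    (defaulting to the sheet solver on a fresh replicate) provides it.
    """
    if truth is None:
        if solver is None:
            domain = build_replicate_domain(config, params, seed=seed,
                                            target_edge_length=target_edge_length)
            sol = solve_sheet(SheetFlowProblem(domain=domain))
            truth = (sol.mean_capillary_speed_mm_s, sol.pressure_drop_mmhg)
        else:
            truth = solver(config)
    v_true, dp_true = truth
    rng = np.random.default_rng(seed)
    fv = _lognormal_factors(rng, noise_cv, n_obs)
    fdp = _lognormal_factors(rng, noise_cv, n_obs)
    return [SyntheticObservation(config=config, v_obs=float(v_true * a),
                                 dp_obs=float(dp_true * b),
                                 noise_cv=noise_cv, seed=seed)
            for a, b in zip(fv, fdp)]


def recovery_experiment(configs_with_truth: list, regressions: dict,
                        noise_cv: float = DEFAULT_NOISE_CV,
                        n_trials: int = 50, seed: int = 0,
                        tol: float = 0.10) -> float:
    """Fraction of noisy trials whose true configuration is recovered.

    ``configs_with_truth`` is a list of (ConnectivityConfig, (v mm/s, Δp mmHg))
    ground-truth pairs, typically replicate means from the connectivity sweep;
    ``regressions`` is the output of
    :func:`alveoflow.experiments.regression_table`.  A trial is recovered when
    the generating (n_art, d_art) appears in the inferred candidate set.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for k in range(n_trials):
        config, (v_true, dp_true) = configs_with_truth[k % len(configs_with_truth)]
        fv, fdp = _lognormal_factors(rng, noise_cv, 2)
        obs = Observation(v_obs=float(v_true * fv), dp_obs=float(dp_true * fdp))
        try:
            result = infer(obs, regressions, tol=tol)
        except Exception:
            continue
        if any(c.n_art == config.n_arterioles and c.d_art == config.d_arteriole
               for c in result.candidates):
            hits += 1
    return hits / n_trials
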