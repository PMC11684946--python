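"""Shared fixtures: default geometry, default solves and the full sweep.

The expensive artifacts (connectivity sweep over six model sets and four
replicates, sensitivity grids, default Newtonian/Carreau solves) are built
once per session and shared between the unit tests and the acceptance tests.
"""

import numpy as np
import pytest

from alveoflow import (BoundaryConditions, ConnectivityConfig, FluidModel,
                       MorphoParams, SheetFlowProblem,
                       assemble_and_solve_newtonian, build_pillar_lattice,
                       solve_carreau)
from alveoflow.experiments import (build_replicate_domain, regression_table,
                                   run_full_study)

REPLICATE_SEEDS = (11, 12)


@pytest.fixture(scope="session")
def params():
    return MorphoParams()


@pytest.fixture(scope="session")
def base(params):
    return params.solve_base()


@pytest.fixture(scope="session")
def lattice(params):
    return build_pillar_lattice(params, "square")


@pytest.fixture(scope="session")
def default_domain(params):
    return build_replicate_domain(ConnectivityConfig(), params,
                                  seed=REPLICATE_SEEDS[0])


@pytest.fixture(scope="session")
def newtonian_solution(default_domain):
    return assemble_and_solve_newtonian(SheetFlowProblem(domain=default_domain))


@pytest.fixture(scope="session")
def carreau_solution(default_domain):
    return solve_carreau(SheetFlowProblem(domain=default_domain,
                                          fluid=FluidModel.carreau()))


@pytest.fixture(scope="session")
def replicate_domains(params):
    """The study's four-replicate scheme: two fresh layouts plus mirrors."""
    from alveoflow.synthetic import ReplicateSpec, make_replicates
    return make_replicates(ReplicateSpec(base_seed=REPLICATE_SEEDS[0]), params)


@pytest.fixture(scope="session")
def sweep_df():
    """Full connectivity study: six model sets × four replicates."""
    return run_full_study(replicate_seeds=REPLICATE_SEEDS)


@pytest.fixture(scope="session")
def regressions(sweep_df):
    return regression_table(sweep_df)
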