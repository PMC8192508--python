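import numpy as np
import pandas as pd
import pytest

from ageflow.containers import CohortTable, SignedGRN
from ageflow.pipeline import run_analysis
from ageflow.simulate import SimulationConfig, simulate_all


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """Reduced study for fast unit tests (not the reference conditions)."""
    base = dict(
        n_samples=60,
        n_cpg=300,
        n_genes=120,
        n_tf=24,
        n_input_tf=6,
        n_drugs=8,
    )
    base.update(overrides)
    return SimulationConfig(seed=seed, **base)


@pytest.fixture(scope="session")
def study():
    return simulate_all(small_config())


@pytest.fixture(scope="session")
def analysis(study):
    edges = study.network.edge_table()[["source", "target"]]
    return run_analysis(
        study.methylation,
        study.expression,
        study.cohort,
        study.truth.annotation,
        edges,
        study.profiles,
    )


@pytest.fixture
def toy_cohort():
    rng = np.random.default_rng(0)
    n = 20
    return CohortTable(
        pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n)],
                "age": np.linspace(20, 74, n),
                "sex": ["male", "female"] * (n // 2),
                "smoking": ["non_smoker"] * n,
            }
        )
    )


def chain_network(sign: int = 1) -> SignedGRN:
    """Two-node chain A -> B used as the hand-solvable worked example."""
    return SignedGRN.from_edges([("A", "B", sign)], inputs=["A"], outputs=["B"])


from ageflow.evaluation import random_signed_network  # noqa: E402  (re-export for tests)
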