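import numpy as np
import pandas as pd
import pytest

from geodebut.synthetic import (
    CovariateDef,
    SimulationConfig,
    StudyDomain,
    TrueFieldSpec,
    simulate_cohort,
)

TWO_BUMP_FIELD = TrueFieldSpec(
    bumps=((0.25, 0.75, 0.6, 0.18), (0.75, 0.25, -0.6, 0.18)), centered=True
)


def binary_cov(name: str, beta: float, p: float = 0.5) -> CovariateDef:
    return CovariateDef(name, ("0", "1"), (1.0 - p, p), (0.0, beta))


def small_cohort(
    seed: int,
    n_clusters: int = 50,
    persons: int = 8,
    betas=(np.log(1.5), np.log(0.7)),
    field: TrueFieldSpec | None = None,
    rounding: bool = False,
    equal_weights: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Compact two-covariate cohort used across the model-fitting tests."""
    cfg = SimulationConfig(
        n_clusters=n_clusters,
        persons_per_cluster=persons,
        covariates=(binary_cov("a", betas[0]), binary_cov("b", betas[1], p=0.4)),
        integer_year_rounding=rounding,
        selection_prob_low=1.0 if equal_weights else 0.1,
        selection_prob_high=1.0,
        seed=seed,
    )
    rec = simulate_cohort(cfg, StudyDomain(), field)
    return rec, {"a": ("0", "1"), "b": ("0", "1")}


@pytest.fixture(scope="session")
def toy_records() -> pd.DataFrame:
    """Four-record hand-computable survival dataset."""
    return pd.DataFrame(
        {
            "id": range(4),
            "cluster": 0,
            "lat": 0.0,
            "lon": 0.0,
            "time_years": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 0, 1, 0],
            "weight": 1.0,
        }
    )


@pytest.fixture(scope="session")
def cohort_and_spec():
    """Moderate simulated cohort shared by the slower fitting tests."""
    return small_cohort(seed=5, n_clusters=50, persons=10)
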