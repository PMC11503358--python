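import numpy as np
import pandas as pd
import pytest

from medcf import Covariate, DGP, TrialDataset, generate_trial, stress_dgps


@pytest.fixture(scope="session")
def mixed_dgp() -> DGP:
    """Binary covariate, both mediation and direct pathways active."""
    return stress_dgps()["mixed"]


@pytest.fixture(scope="session")
def mixed_trial(mixed_dgp) -> TrialDataset:
    import dataclasses

    return generate_trial(dataclasses.replace(mixed_dgp, n=2000), seed=42)


@pytest.fixture()
def tiny_trial() -> TrialDataset:
    """Five hand-written records for round-trip and validation tests."""
    data = pd.DataFrame(
        {
            "id": [0, 1, 2, 3, 4],
            "t": [1, 0, 1, 1, 0],
            "m": [1, 0, 0, 1, 1],
            "vitrectomy": [0, 0, 1, 0, 0],
            "y": [1, 0, 0, 1, 0],
            "age": [61.5, 70.0, 55.25, 66.0, 72.5],
            "erm": [0, 1, 0, 0, 1],
        }
    )
    return TrialDataset(data, outcomes=["y"], covariates=["age", "erm"])


def coin_dgp(p_t: float = 0.5) -> DGP:
    """Mediator and outcome driven by intercepts only."""
    return DGP(
        n=200,
        alloc_ratio=p_t,
        covariates=[Covariate("c", "binary", p=0.5)],
        mediator_terms=[("1", 0.3)],
        outcome_terms={"y": [("1", -0.4)]},
        seed=5,
    )
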