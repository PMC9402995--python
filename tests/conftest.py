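import numpy as np
import pytest

from neobili import (
    CohortDesign,
    Covariates,
    PopulationModel,
    StructuralParameters,
    default_truth,
    generate_cohort,
)


@pytest.fixture(scope="session")
def truth_model() -> PopulationModel:
    return default_truth()


@pytest.fixture(scope="session")
def typical_params(truth_model) -> StructuralParameters:
    return truth_model.theta_pop


@pytest.fixture
def reference_covariates() -> Covariates:
    return Covariates(gestational_age=265.0, birth_weight=2500.0, delivery_mode="vaginal")


@pytest.fixture(scope="session")
def small_cohort(truth_model):
    """60 neonates, ~2.8 measurements each, 10% noise (seeded)."""
    design = CohortDesign(n_neonates=60, seed=42)
    return generate_cohort(design, truth_model)


def random_structural_parameters(rng: np.random.Generator) -> StructuralParameters:
    """Physiologically plausible random parameter draw for property tests."""
    return StructuralParameters(
        b0=rng.uniform(10.0, 120.0),
        p_ss=rng.uniform(0.5, 5.0),
        a_p=rng.uniform(0.0, 3.0),
        t_p=rng.uniform(10.0, 80.0),
        k_ss=rng.uniform(0.01, 0.15),
        m_e=rng.uniform(0.0, 0.97),
        t_e=rng.uniform(10.0, 120.0),
    )
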