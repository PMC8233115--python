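import warnings

import numpy as np
import pandas as pd
import pytest

from lesionatoms.atoms import fit_nmf
from lesionatoms.model import ModelSpec, build_model, build_model_data, sample_posterior
from lesionatoms.simulate import SimulationConfig, generate_cohort, make_toy_atlas

warnings.filterwarnings("ignore", message="Maximum number of iterations")
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


def lesion_log_matrix(cohort) -> pd.DataFrame:
    """Log1p region-load matrix straight from the simulated counts."""
    loads = cohort.lesion_loads
    return pd.DataFrame(
        np.log1p(loads.to_numpy(dtype=float)), index=loads.index, columns=loads.columns
    )


@pytest.fixture(scope="session")
def toy_atlas():
    return make_toy_atlas(n_regions=54)


@pytest.fixture(scope="session")
def tiny_atlas():
    return make_toy_atlas(n_regions=4, cube=3)


@pytest.fixture(scope="session")
def small_cohort():
    """150-patient cohort used across unit tests (defaults otherwise)."""
    return generate_cohort(SimulationConfig(n_patients=150, seed=11))


@pytest.fixture(scope="session")
def fitted_small_model(small_cohort):
    """One small end-to-end fit shared by model/relevance unit tests."""
    matrix = lesion_log_matrix(small_cohort)
    basis, loadings, _ = fit_nmf(matrix, k=4, seed=0, n_restarts=2)
    spec = ModelSpec(draws=600, tune=500, chains=2, seed=21)
    data = build_model_data(loadings, small_cohort.covariates, small_cohort.outcomes)
    model = build_model(data, spec)
    samples = sample_posterior(model, spec)
    return {
        "cohort": small_cohort,
        "basis": basis,
        "loadings": loadings,
        "data": data,
        "model": model,
        "spec": spec,
        "samples": samples,
    }
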