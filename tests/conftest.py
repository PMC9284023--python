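import pytest

import tissuecage as tc
from tissuecage import estimate, simulate


@pytest.fixture(scope="session")
def model():
    return tc.reference_model()


@pytest.fixture(scope="session")
def noise_free_model(model):
    """Reference model with all variability switched off."""
    return tc.PopulationModel(
        plasma=model.plasma,
        cage=model.cage,
        covariates=model.covariates,
        omegas=tc.RandomEffectSDs(0.0, 0.0, 0.0, 0.0),
        error=tc.ErrorModel(0.0, 0.0),
        dose_mg_per_kg=model.dose_mg_per_kg,
    )


@pytest.fixture(scope="session")
def design():
    return simulate.make_default_design(11)


@pytest.fixture(scope="session")
def trial(design, model):
    """One complete simulated trial at the study's own size."""
    return simulate.simulate_trial(design, model, 29)


@pytest.fixture(scope="session")
def noise_free_trial(design, noise_free_model):
    return simulate.simulate_trial(design, noise_free_model, 29)


@pytest.fixture(scope="session")
def plasma_fit(trial):
    return estimate.fit_plasma(trial, 4.0, compute_se=True)


@pytest.fixture(scope="session")
def individuals(plasma_fit, trial):
    return estimate.individual_estimates(plasma_fit, trial, 4.0)


@pytest.fixture(scope="session")
def cage_fit(trial, individuals):
    return estimate.fit_cages(trial, individuals, 4.0, compute_se=True)
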