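import numpy as np
import pytest

from badnet.estimation import ObservationTable
from badnet.model_core import ApoptosisParams, ParameterSet
from badnet.reference import reference_parameters
from badnet.synthetic_data import (
    APOPTOSIS_HOLDOUT_TREATMENTS,
    APOPTOSIS_TRAIN_TREATMENTS,
    GeneratorConfig,
    apoptosis_fit_times,
    generate,
)


@pytest.fixture(scope="session")
def ref_params() -> ParameterSet:
    return reference_parameters()


def random_parameter_set(rng: np.random.Generator) -> ParameterSet:
    """A random valid parameter set with states of order 1."""
    return ParameterSet(
        vmax=rng.uniform(0.5, 6.0, 14),
        km=rng.uniform(0.3, 2.0, 14),
        hill_n=rng.choice([1.0, 2.0], 14),
        decay_time_scaled=rng.uniform(0.5, 5.0, 4),
        decay_zero_baseline=rng.uniform(0.5, 5.0, 5),
        apoptosis=ApoptosisParams(
            k_a=rng.uniform(1e-4, 5e-3),
            bad_total=rng.uniform(1.0, 3.0),
            k_bad=rng.uniform(0.2, 0.8),
            n_bad=rng.uniform(1.0, 4.0),
            w_s136=rng.uniform(0.2, 1.5),
            k_creb=rng.uniform(0.2, 0.8),
            n_creb=rng.uniform(1.0, 4.0),
        ),
    )


@pytest.fixture(scope="session")
def noiseless_signaling(ref_params) -> ObservationTable:
    """The 56-point signaling fit set (both designs), zero noise."""
    epi = generate(GeneratorConfig(
        params=ref_params, design="epi_dose_series", seed=101,
        noise_lognorm_sd=0.0, n_cells=0,
    ))
    tc = generate(GeneratorConfig(
        params=ref_params, design="ly_egf_timecourse", seed=102,
        noise_lognorm_sd=0.0, n_cells=0,
    ))
    return ObservationTable.concat([epi, tc])


@pytest.fixture(scope="session")
def noiseless_apoptosis_train(ref_params) -> ObservationTable:
    """The 27-point apoptosis fit set (3 treatments x 9 times), zero noise."""
    return generate(GeneratorConfig(
        params=ref_params, design="apoptosis_panel", seed=103,
        noise_lognorm_sd=0.0, n_cells=0,
        treatments=APOPTOSIS_TRAIN_TREATMENTS, times=tuple(apoptosis_fit_times()),
    ))


@pytest.fixture(scope="session")
def noiseless_apoptosis_holdout(ref_params) -> ObservationTable:
    return generate(GeneratorConfig(
        params=ref_params, design="apoptosis_panel", seed=104,
        noise_lognorm_sd=0.0, n_cells=0,
        treatments=APOPTOSIS_HOLDOUT_TREATMENTS, times=(48.0,),
    ))
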