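import numpy as np
import pandas as pd
import pytest

from petresponse.simulate import CohortConfig, generate_lesion_table_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A 25-patient cohort under the default study conditions."""
    return generate_lesion_table_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """A cohort with no measurability/comparability exclusions and fixed seed."""
    config = CohortConfig(
        n_patients=40,
        p_nonmeasurable_patient=0.0,
        p_liver_drift_patient=0.0,
        seed=5,
    )
    return generate_lesion_table_cohort(config)


def zero_noise_config(n_patients=200, seed=17, **overrides):
    """Study conditions with all effect-size SDs at zero (deterministic changes)."""
    base = dict(
        n_patients=n_patients,
        fraction_complete=0.10,
        fraction_responder=0.30,
        fraction_stable=0.25,
        fraction_progressor=0.35,
        responder_change_mean_sd=(-55.0, 0.0),
        progressor_change_mean_sd=(92.0, 0.0),
        stable_change_mean_sd=(0.0, 0.0),
        responder_mtv_change_mean_sd=(-52.0, 0.0),
        progressor_mtv_change_mean_sd=(38.0, 0.0),
        p_nonmeasurable_patient=0.0,
        p_liver_drift_patient=0.0,
        seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """200 patients with deterministic, unambiguous per-class changes."""
    return generate_lesion_table_cohort(zero_noise_config())


def exponential_groups(rng, n_a, n_b, hazard_a, hazard_b, censor=0.0):
    """Two exponential survival samples, optionally censored, as arrays."""
    def draw(n, hazard):
        t = rng.exponential(1.0 / hazard, size=n)
        if censor > 0:
            c = rng.exponential((1.0 - censor) / (hazard * censor), size=n)
            return np.minimum(t, c), t <= c
        return t, np.ones(n, dtype=bool)

    ta, ea = draw(n_a, hazard_a)
    tb, eb = draw(n_b, hazard_b)
    return ta, ea, tb, eb
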