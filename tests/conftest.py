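import numpy as np
import pytest

import craniodim as cd


@pytest.fixture(scope="session")
def template():
    return cd.make_template()


@pytest.fixture(scope="session")
def small_cohort():
    """60-subject single-group cohort with injected dimorphism."""
    spec = cd.default_spec(
        n_per_cell={("adult", "M"): 30, ("adult", "F"): 30},
        effect_scale=1.0,
        noise_sd=0.5,
        seed=7734,
    )
    return cd.simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_arrays(small_cohort):
    ids, configs = small_cohort.landmark_array()
    meta = {s.subject_id: s for s in small_cohort.subjects}
    sex = np.array([meta[i].sex for i in ids])
    ages = np.array([meta[i].age for i in ids])
    heights = np.array([meta[i].height for i in ids])
    return ids, configs, sex, ages, heights
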