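import numpy as np
import pytest

import brainstates as bs


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced planted cohort: 4 participants, 210 volumes, 5 drug states."""
    spec = bs.default_cohort_spec(
        seed=11, n_participants=4, n_volumes=210, injection_volume=60, noise_sd=0.5
    )
    return bs.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_subtraction(small_cohort):
    c = small_cohort
    sims = {
        cond: [bs.time_similarity_matrix(c.series[(p, cond)]) for p in c.participants]
        for cond in ("DMT", "PCB")
    }
    return bs.subtraction_matrix(
        bs.group_mean_matrix(sims["DMT"]), bs.group_mean_matrix(sims["PCB"])
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
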