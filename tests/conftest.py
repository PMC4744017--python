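import numpy as np
import pytest
from hypothesis import settings

from gazecontrast.model import Dataset
from gazecontrast.synth import (
    GeneratorParams,
    compute_start_points,
    generate_dataset,
    generate_trial_fixations,
    template_layout,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def template():
    return template_layout()


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    """4 participants, 8 study trials per race plus test phase; fixed seed."""
    return generate_dataset(
        GeneratorParams(
            n_participants=4, trials_per_race_study=8, faces_per_race=16, seed=42
        )
    )


@pytest.fixture(scope="session")
def tiny_two_condition_dataset() -> Dataset:
    """2 participants, 1 trial per condition, 3 fixations per trial: one
    exchangeable token pair per (participant x ordinal) cell."""
    params = GeneratorParams(seed=5)
    lay = template_layout("f0")
    sps = compute_start_points(lay)
    rng = np.random.default_rng(2)
    trials = []
    for pid in ("p0", "p1"):
        for ti, race in enumerate(("caucasian", "chinese")):
            trials.append(
                generate_trial_fixations(
                    lay, sps["up"], race, 3, params, rng,
                    participant_id=pid, trial_index=ti + 1,
                )
            )
    return Dataset(layouts=[lay], trials=trials)
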