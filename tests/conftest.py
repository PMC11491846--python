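import numpy as np
import pytest

from cravedecode import synth


@pytest.fixture(scope="session")
def brain():
    mask, atlas = synth.make_brain((12, 12, 10))
    return mask, atlas


@pytest.fixture(scope="session")
def small_brain():
    mask, atlas = synth.make_brain((6, 6, 5))
    return mask, atlas


@pytest.fixture(scope="session")
def designs():
    return [
        synth.make_run_design("no_feedback", 2.0, 11),
        synth.make_run_design("feedback", 2.0, 12),
        synth.make_run_design("feedback", 2.0, 13),
    ]


@pytest.fixture(scope="session")
def noiseless_subject(brain, designs):
    """One subject with zero noise/drift/motion for exact-recovery checks."""
    mask, atlas = brain
    rng = np.random.default_rng(5)
    w = np.zeros(mask.size)
    w[mask] = rng.standard_normal(mask.sum())
    w /= np.linalg.norm(w)
    spec = synth.SubjectSpec(
        "sub-clean", w_true=w, noise_sd=0.0, drift_amplitude=0.0, motion_sd=0.0
    )
    runs = synth.simulate_subject(spec, designs, seed=7, mask=mask, atlas=atlas)
    return spec, runs


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort used by several integration tests."""
    return synth.simulate_cohort(4, synth.CohortSpec(), seed=21)
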