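import numpy as np
import pytest

from wpaimc.generate import GeneratorConfig, generate_trial


@pytest.fixture(scope="session")
def default_trial():
    """One medium synthetic trial shared across tests (complete data)."""
    return generate_trial(GeneratorConfig(n_subjects=300, seed=2024))


@pytest.fixture(scope="session")
def subject_table(default_trial):
    from wpaimc.pipeline import _subject_table

    subj, summary = _subject_table(default_trial)
    return subj, summary


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
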