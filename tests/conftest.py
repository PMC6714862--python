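import pytest

from eegemo.datasets import DatasetDescriptor
from eegemo.synthetic import EffectSpec, generate_feature_table, generate_trialset


@pytest.fixture(scope="session")
def small_valence_trialset():
    """6 subjects × 16 trials × 6 channels, 3 s at 128 Hz, strong alpha
    effect on channels 0–2."""
    desc = DatasetDescriptor(6, 16, 1, 6, 128.0, 3.0, "continuous_valence")
    effect = EffectSpec(discriminative_channels=(0, 1, 2), band="alpha",
                        effect_size=3.0, subject_sd=0.1, seed=11)
    ts, truth = generate_trialset(desc, effect)
    return ts, truth, effect


@pytest.fixture(scope="session")
def small_categorical_trialset():
    """4 subjects × 2 sessions × 9 trials (3/3/3 classes), 4 channels."""
    desc = DatasetDescriptor(4, 9, 2, 4, 128.0, 3.0, "categorical")
    effect = EffectSpec(discriminative_channels=(0,), band="alpha",
                        effect_size=2.5, subject_sd=0.1, seed=5)
    ts, truth = generate_trialset(desc, effect)
    return ts, truth


@pytest.fixture(scope="session")
def informative_table():
    """Fast tabular matrix: 8 subjects × 20 trials, 5 informative of 30."""
    return generate_feature_table(n_subjects=8, n_trials=20, n_features=30,
                                  n_informative=5, delta=2.0,
                                  subject_sd=0.3, seed=21)
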