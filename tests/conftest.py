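import numpy as np
import pytest

import apexri as ax


@pytest.fixture(scope="session")
def schedules():
    """Schedule + design constants for all four groups."""
    return {g: ax.build_schedule(ax.make_group_spec(g))
            for g in ax.GROUP_LABELS}


@pytest.fixture(scope="session")
def default_params():
    return ax.DEFAULT_TRUE_PARAMS


@pytest.fixture(scope="session")
def noisefree_m10():
    """Noise-free online-generated M10 group, scored and averaged."""
    cfg = ax.SyntheticConfig(noise_cv=0.0, error_prob=0.0,
                             warmup_inflation=1.0, n_participants=1, seed=11)
    spec = ax.make_group_spec("M10")
    presses = ax.generate_participant(cfg, spec, np.random.default_rng(11))
    seqs = ax.score_sequences(presses)
    series = ax.average_over_participants(seqs, spec)
    schedule, consts = ax.build_schedule(spec)
    return cfg, series, schedule, consts


@pytest.fixture(scope="session")
def noisy_m10():
    """Online-generated M10 group with realistic noise, 10 participants."""
    cfg = ax.SyntheticConfig(noise_cv=0.10, error_prob=0.04,
                             n_participants=10, seed=23)
    spec = ax.make_group_spec("M10")
    presses = ax.generate_group(cfg, "M10")
    seqs = ax.score_sequences(presses)
    series = ax.average_over_participants(seqs, spec)
    schedule, consts = ax.build_schedule(spec)
    return cfg, series, schedule, consts
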