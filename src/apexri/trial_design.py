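"""Observation schedule for the 2x2 massed/spaced finger-tapping design.

The experiment crosses sequences-per-trial (5 spaced / 15 massed) with
between-trial break duration (10 s / 30 s), holding the total number of
correct sequences constant at 180 training + 30 test per participant.
The first completed sequence of every trial is a warm-up and is removed
before modeling, so each trial contributes ``seqs_per_trial - 1`` modeled
observations. All model equations consume the index frame built here:
within-trial sequence number ST, cumulative modeled sequence number S,
training-trial number T, test-trial number T_test, cumulative trial number
across phases, and the train/test indicator X.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUP_LABELS = ("S30", "S10", "M30", "M10")

#: Correct sequences per participant (training + test), warm-ups included.
TOTAL_SEQUENCES = 210
TRAIN_SEQUENCES = 180
TEST_SEQUENCES = 30

SCHEDULE_COLUMNS = [
    "group", "phase", "trial", "trial_cum", "trial_test", "st", "s", "x",
]


@dataclass(frozen=True)
class GroupSpec:
    """Design cell of the 2x2 experiment.

    ``seqs_per_trial`` counts correct sequences including the warm-up;
    spaced groups run three trials for every massed trial so that every
    group completes 180 training and 30 test sequences.
    """

    label: str
    seqs_per_trial: int
    break_s: float
    n_train_trials: int
    n_test_trials: int
    rest_s: float = 300.0

    def __post_init__(self) -> None:
        if self.label not in GROUP_LABELS:
            # custom (e.g. reduced) designs skip the 180/30 volume check
            return
        if self.n_train_trials * self.seqs_per_trial != TRAIN_SEQUENCES:
            raise ValueError(
                f"{self.label}: {self.n_train_trials} training trials x "
                f"{self.seqs_per_trial} sequences != {TRAIN_SEQUENCES}"
            )
        if self.n_test_trials * self.seqs_per_trial != TEST_SEQUENCES:
            raise ValueError(
                f"{self.label}: {self.n_test_trials} test trials x "
                f"{self.seqs_per_trial} sequences != {TEST_SEQUENCES}"
            )


@dataclass(frozen=True)
class DesignConstants:
    """Totals the skill and hybrid equations need.

    ``btot`` counts every break: the gaps between training trials, the
    5-min rest between phases, and the gaps between test trials.  ``stot``
    is the number of modeled (non-warm-up) sequences, which equals the
    number of averaged RT observations entering each fit.
    """

    stot: int
    btot: int
    n_obs: int

    @property
    def j_max(self) -> float:
        """Upper bound on offline learning units per break (Stot/Btot)."""
        return self.stot / self.btot


_GROUPS = {
    "S30": dict(seqs_per_trial=5, break_s=30.0, n_train_trials=36, n_test_trials=6),
    "S10": dict(seqs_per_trial=5, break_s=10.0, n_train_trials=36, n_test_trials=6),
    "M30": dict(seqs_per_trial=15, break_s=30.0, n_train_trials=12, n_test_trials=2),
    "M10": dict(seqs_per_trial=15, break_s=10.0, n_train_trials=12, n_test_trials=2),
}


def make_group_spec(label: str) -> GroupSpec:
    """Return the fully populated design spec for a group label."""
    try:
        kwargs = _GROUPS[label]
    except KeyError:
        raise ValueError(
            f"unknown group label {label!r}; valid labels: {', '.join(GROUP_LABELS)}"
        ) from None
    return GroupSpec(label=label, **kwargs)


def count_breaks(spec: GroupSpec) -> int:
    """Total breaks including the post-training rest.

    Between-trial breaks during training, one rest break between phases,
    and between-trial breaks during test: equivalently one break per trial
    boundary, ``n_train + n_test - 1``.
    """
    return (spec.n_train_trials - 1) + 1 + (spec.n_test_trials - 1)


def design_constants(spec: GroupSpec) -> DesignConstants:
    stot = (spec.n_train_trials + spec.n_test_trials) * (spec.seqs_per_trial - 1)
    return DesignConstants(stot=stot, btot=count_breaks(spec), n_obs=stot)


def build_schedule(spec: GroupSpec) -> tuple[pd.DataFrame, DesignConstants]:
    """One row per modeled correct sequence, in execution order.

    Columns
    -------
    phase : 'train' or 'test'
    trial : within-phase trial number (T during training, T_test during test)
    trial_cum : trial number cumulative across phases; skill accrual through
        breaks keeps counting through the rest period and test phase
    trial_test : test-phase trial number, 0 during training
    st : within-trial modeled sequence number, 1..seqs_per_trial-1 (the
        warm-up sequence of every trial is removed before st = 1)
    s : cumulative modeled sequence number, 1..Stot
    x : 0 during training, 1 during test
    """
    consts = design_constants(spec)
    n_mod = spec.seqs_per_trial - 1
    rows = []
    trial_cum = 0
    for phase, n_trials in (("train", spec.n_train_trials),
                            ("test", spec.n_test_trials)):
        for trial in range(1, n_trials + 1):
            trial_cum += 1
            rows.append((phase, trial, trial_cum))
    frames = []
    s0 = 0
    for phase, trial, tcum in rows:
        st = np.arange(1, n_mod + 1)
        frames.append(pd.DataFrame({
            "group": spec.label,
            "phase": phase,
            "trial": trial,
            "trial_cum": tcum,
            "trial_test": trial if phase == "test" else 0,
            "st": st,
            "s": s0 + st,
            "x": 0 if phase == "train" else 1,
        }))
        s0 += n_mod
    schedule = pd.concat(frames, ignore_index=True)[SCHEDULE_COLUMNS]
    assert len(schedule) == consts.stot
    return schedule, consts
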