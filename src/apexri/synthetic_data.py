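"""Participant-level keypress simulator with known ground truth.

Each participant executes the full trial structure of their group: every
scheduled correct sequence is emitted as the five target presses, with
per-press latencies whose geometric-mean-times-five equals the generating
model's predicted RT at that schedule row, perturbed by lognormal noise.
The first sequence of every trial is a warm-up whose RT is inflated by a
multiplicative factor, mirroring the warm-up effect seen in real data.
Error presses are inserted before sequences at a configurable per-press
probability that can grow with within-trial position (error-rate build-up
in massed practice).  Error presses never use the sequence-initial key 4,
so an error run can never blend into the following correct sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import model_core
from .model_core import ModelParams, predict_rt
from .preprocess import KEYPRESS_COLUMNS, TARGET_SEQUENCE
from .trial_design import GROUP_LABELS, GroupSpec, build_schedule, make_group_spec

__all__ = ["DEFAULT_TRUE_PARAMS", "SyntheticConfig", "generate_participant",
           "generate_group", "generate_dataset"]

#: Generator defaults: an online learner whose curve spans the 2-4 s range
#: typical of early five-key sequence practice, with RI slopes of the
#: magnitude estimated from real massed/spaced groups (y ~ 8-32 ms per
#: sequence, z ~ 1-19 ms per trial).
DEFAULT_TRUE_PARAMS = ModelParams(a=1800.0, b=2500.0, c=0.004, k=0.12,
                                  y=20.0, z=8.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth settings for one simulated dataset.

    noise_cv : lognormal sigma of each keypress log-latency; 0 disables
        noise entirely (exact closed loop with the generating model).
    warmup_inflation : multiplicative RT factor on the first sequence of
        every trial (>= 1).
    error_prob : per-keypress probability of an error press before a
        sequence (5 draws per sequence), optionally growing by
        ``error_slope`` per within-trial position.
    """

    model: str = "online"
    params: ModelParams = field(default_factory=lambda: DEFAULT_TRUE_PARAMS)
    n_participants: int = 20
    noise_cv: float = 0.10
    warmup_inflation: float = 1.5
    error_prob: float = 0.04
    error_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.error_prob < 1:
            raise ValueError("error_prob must be in [0, 1)")
        if self.warmup_inflation < 1:
            raise ValueError("warmup_inflation must be >= 1")
        model_core.get_model(self.model)

    def ground_truth(self) -> dict:
        d = asdict(self)
        d["params"] = self.params.asdict()
        return d


_ERROR_KEYS = np.array([k for k in (1, 2, 3) if k != TARGET_SEQUENCE[0]])


def generate_participant(config: SyntheticConfig, spec: GroupSpec,
                         rng: np.random.Generator,
                         participant: str = "p1") -> pd.DataFrame:
    """Simulate one participant's full keypress log (train + test)."""
    schedule, consts = build_schedule(spec)
    base_rt = predict_rt(config.model, config.params, schedule, consts)
    n_target = len(TARGET_SEQUENCE)

    rows = []
    i_row = 0
    for phase, n_trials in (("train", spec.n_train_trials),
                            ("test", spec.n_test_trials)):
        for trial in range(1, n_trials + 1):
            press_index = 0
            for seq_in_trial in range(1, spec.seqs_per_trial + 1):
                if seq_in_trial == 1:
                    # warm-up: the trial's first modeled RT, inflated
                    rt = base_rt[i_row] * config.warmup_inflation
                else:
                    rt = base_rt[i_row]
                    i_row += 1
                per_press = rt / n_target
                p_err = min(0.99, config.error_prob
                            + config.error_slope * (seq_in_trial - 1))
                n_err = rng.binomial(n_target, p_err) if p_err > 0 else 0
                if n_err:
                    err_keys = rng.choice(_ERROR_KEYS, size=n_err)
                    err_lat = per_press * _noise(rng, n_err, config.noise_cv)
                    for kk, ll in zip(err_keys, err_lat):
                        press_index += 1
                        rows.append((participant, spec.label, phase, trial,
                                     press_index, int(kk), float(ll)))
                lat = per_press * _noise(rng, n_target, config.noise_cv)
                for kk, ll in zip(TARGET_SEQUENCE, lat):
                    press_index += 1
                    rows.append((participant, spec.label, phase, trial,
                                 press_index, int(kk), float(ll)))
    return pd.DataFrame(rows, columns=KEYPRESS_COLUMNS)


def _noise(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    return np.exp(rng.normal(0.0, cv, size=n))


def generate_group(config: SyntheticConfig, label: str,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """All participants of one group, independently simulated."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    spec = make_group_spec(label)
    parts = [
        generate_participant(config, spec, rng,
                             participant=f"{label}_p{i + 1:03d}")
        for i in range(config.n_participants)
    ]
    return pd.concat(parts, ignore_index=True)


def generate_dataset(config: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Four-group dataset plus the serializable ground-truth record."""
    rng = np.random.default_rng(config.seed)
    frames = [generate_group(config, label, rng) for label in GROUP_LABELS]
    return pd.concat(frames, ignore_index=True), config.ground_truth()


def save_dataset(presses: pd.DataFrame, truth: dict, presses_path,
                 truth_path) -> None:
    presses.to_csv(presses_path, index=False, float_format="%.10g")
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2)
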