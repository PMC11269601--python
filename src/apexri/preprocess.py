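"""Keypress logs -> modeled sequence RTs and error summaries.

A correct sequence is a run of presses matching the target 4-1-3-2-4.
Its completion time is 5 times the geometric mean of its five inter-press
latencies (log-transform, average, anti-log, times five), which damps the
influence of single slow presses relative to an arithmetic mean.  The
first completed sequence of every trial is a warm-up with inflated RT and
error rate and is removed before fitting; remaining sequences align one
to one with the trial-design schedule.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .trial_design import GroupSpec, build_schedule

__all__ = [
    "TARGET_SEQUENCE", "KEYPRESS_COLUMNS", "SEQUENCE_COLUMNS",
    "sequence_rt", "score_sequences", "remove_warmups",
    "error_rate_summary", "error_seq_correlation",
    "average_over_participants",
]

#: The practiced five-key sequence, typed with the non-dominant left hand.
TARGET_SEQUENCE = (4, 1, 3, 2, 4)

KEYPRESS_COLUMNS = [
    "participant", "group", "phase", "trial", "press_index", "key",
    "latency_ms",
]
SEQUENCE_COLUMNS = [
    "participant", "group", "phase", "trial", "seq_in_trial", "rt_ms",
    "n_errors_before", "warmup",
]


def sequence_rt(latencies: Sequence[float]) -> float:
    """5 x geometric mean of the five keypress latencies of one sequence."""
    lat = np.asarray(latencies, dtype=float)
    if lat.shape != (5,):
        raise ValueError(f"expected exactly 5 latencies, got {lat.shape}")
    if np.any(lat <= 0):
        raise ValueError("latencies must be positive")
    return 5.0 * float(np.exp(np.mean(np.log(lat))))


def _score_trial(keys: np.ndarray, lats: np.ndarray,
                 target: tuple[int, ...]) -> list[tuple[float, int]]:
    """Greedy left-to-right match; an incorrect press resets the match.

    Returns (rt, n_errors_before) per completed sequence.  Presses after
    the last completed sequence go to a trailing bucket and are excluded
    from per-sequence error counts.
    """
    n_target = len(target)
    out = []
    buf: list[int] = []  # indices of the current partial match
    pending_errors = 0
    for i, key in enumerate(keys):
        if key == target[len(buf)]:
            buf.append(i)
            if len(buf) == n_target:
                out.append((sequence_rt(lats[buf]), pending_errors))
                buf, pending_errors = [], 0
        else:
            pending_errors += len(buf)
            buf = []
            if key == target[0]:
                buf.append(i)
            else:
                pending_errors += 1
    return out


def score_sequences(presses: pd.DataFrame,
                    target: tuple[int, ...] = TARGET_SEQUENCE,
                    expected_per_trial: int | None = None) -> pd.DataFrame:
    """Extract completed correct sequences from a keypress log.

    Presses must be ordered within participant x phase x trial.  Each
    completed match of ``target`` yields one row; incorrect presses are
    attributed to the next completed sequence of the same trial.  With
    ``expected_per_trial`` set, trials completing fewer sequences are
    flagged with a warning rather than silently passed through.
    """
    rows = []
    short_trials = []
    for (pid, grp, phase, trial), chunk in presses.groupby(
            ["participant", "group", "phase", "trial"], sort=False):
        chunk = chunk.sort_values("press_index")
        scored = _score_trial(chunk["key"].to_numpy(),
                              chunk["latency_ms"].to_numpy(dtype=float),
                              target)
        if expected_per_trial is not None and len(scored) < expected_per_trial:
            short_trials.append((pid, grp, phase, trial, len(scored)))
        for pos, (rt, n_err) in enumerate(scored, start=1):
            rows.append((pid, grp, phase, trial, pos, rt, n_err, pos == 1))
    if short_trials:
        warnings.warn(
            f"{len(short_trials)} trial(s) completed fewer than "
            f"{expected_per_trial} sequences: {short_trials[:5]}...",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=SEQUENCE_COLUMNS)


def remove_warmups(seqs: pd.DataFrame) -> pd.DataFrame:
    """Drop the first completed sequence of every training and test trial."""
    if len(seqs) == 0:
        return seqs.copy()
    out = seqs.loc[~seqs["warmup"]].copy()
    out["st"] = out["seq_in_trial"] - 1
    return out.reset_index(drop=True)


def error_rate_summary(seqs: pd.DataFrame,
                       phase: str = "train") -> pd.DataFrame:
    """Mean error presses before each within-trial sequence position.

    Averages over trials and participants per group; position 1 is the
    warm-up sequence, reported separately from the modeled positions.
    """
    sel = seqs.loc[seqs["phase"] == phase]
    by_pos = (sel.groupby(["group", "seq_in_trial"])["n_errors_before"]
              .agg(["mean", "sem", "count"]).reset_index())
    grand = (sel.groupby("group")["n_errors_before"].mean()
             .rename("grand_mean").reset_index())
    return by_pos.merge(grand, on="group")


def error_seq_correlation(seqs: pd.DataFrame, group: str,
                          phase: str = "train") -> float:
    """Pearson r between within-trial position and error count, warm-ups
    excluded, pooled over trials and participants."""
    sel = seqs.loc[(seqs["group"] == group) & (seqs["phase"] == phase)
                   & (~seqs["warmup"])]
    if len(sel) < 3:
        raise ValueError("need at least 3 (position, error) points")
    pos = sel["seq_in_trial"].to_numpy(dtype=float)
    err = sel["n_errors_before"].to_numpy(dtype=float)
    if np.std(pos) == 0 or np.std(err) == 0:
        warnings.warn("zero variance; correlation reported as 0",
                      stacklevel=2)
        return 0.0
    return float(np.corrcoef(pos, err)[0, 1])


def average_over_participants(seqs: pd.DataFrame,
                              spec: GroupSpec) -> pd.DataFrame:
    """Participant-averaged modeled sequence RTs aligned to the schedule.

    Input may still contain warm-ups (they are removed here).  Returns the
    schedule frame with ``rt_mean``, ``rt_sem`` and ``n_participants``
    columns, one row per modeled sequence, in schedule order.
    """
    schedule, consts = build_schedule(spec)
    modeled = remove_warmups(seqs.loc[seqs["group"] == spec.label])
    per_part = modeled.groupby("participant").size()
    bad = per_part[per_part != consts.stot]
    if len(bad):
        raise ValueError(
            f"participants misaligned with schedule (expect {consts.stot} "
            f"modeled sequences): {dict(bad)}"
        )
    stats = (modeled.groupby(["phase", "trial", "st"])["rt_ms"]
             .agg(rt_mean="mean", rt_sem="sem", n_participants="count")
             .reset_index())
    out = schedule.merge(stats, on=["phase", "trial", "st"], how="left")
    if out["rt_mean"].isna().any():
        raise ValueError("schedule rows without observations after merge")
    return out
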