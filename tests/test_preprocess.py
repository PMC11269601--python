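import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import apexri as ax
from apexri.preprocess import KEYPRESS_COLUMNS, TARGET_SEQUENCE


def _presses(keys, latencies=None, participant="p1", trial=1,
             phase="train", group="M10"):
    if latencies is None:
        latencies = [200.0] * len(keys)
    return pd.DataFrame({
        "participant": participant, "group": group, "phase": phase,
        "trial": trial, "press_index": range(1, len(keys) + 1),
        "key": list(keys), "latency_ms": latencies,
    })[KEYPRESS_COLUMNS]


class TestSequenceRt:
    def test_equal_latencies(self):
        assert ax.sequence_rt([200] * 5) == pytest.approx(1000.0)

    def test_geometric_not_arithmetic_mean(self):
        lats = [100, 100, 100, 100, 1600]
        got = ax.sequence_rt(lats)
        assert got == pytest.approx(5 * 100 * 16 ** 0.2, rel=1e-12)
        assert got == pytest.approx(870.55, abs=0.01)
        arithmetic = 5 * np.mean(lats)
        assert arithmetic == pytest.approx(2000.0)
        assert got != pytest.approx(arithmetic, rel=0.1)

    def test_rejects_nonpositive_and_wrong_arity(self):
        with pytest.raises(ValueError, match="positive"):
            ax.sequence_rt([100, 100, -1, 100, 100])
        with pytest.raises(ValueError, match="5"):
            ax.sequence_rt([100, 100, 100])

    @settings(deadline=None, max_examples=50)
    @given(lats=st.lists(st.floats(1.0, 5000.0), min_size=5, max_size=5),
           lam=st.floats(0.1, 10.0))
    def test_scale_equivariance(self, lats, lam):
        scaled = ax.sequence_rt([x * lam for x in lats])
        assert scaled == pytest.approx(lam * ax.sequence_rt(lats), rel=1e-9)


class TestScoreSequences:
    def test_clean_sequence(self):
        seqs = ax.score_sequences(_presses(TARGET_SEQUENCE))
        assert len(seqs) == 1
        assert seqs.loc[0, "n_errors_before"] == 0
        assert seqs.loc[0, "rt_ms"] == pytest.approx(1000.0)
        assert bool(seqs.loc[0, "warmup"])

    def test_leading_error_press(self):
        seqs = ax.score_sequences(_presses([2, 4, 1, 3, 2, 4]))
        assert len(seqs) == 1
        assert seqs.loc[0, "n_errors_before"] == 1

    def test_partial_match_reset_counts_buffered_presses(self):
        # 4,1 then a stray 4 restarts the match; both buffered presses
        # count as errors before the completed sequence
        seqs = ax.score_sequences(_presses([4, 1, 4, 1, 3, 2, 4]))
        assert len(seqs) == 1
        assert seqs.loc[0, "n_errors_before"] == 2

    def test_target_has_no_self_overlap(self):
        # back-to-back repetitions parse unambiguously: 41324 has no
        # proper border, so greedy restart cannot split a completion
        keys = list(TARGET_SEQUENCE) * 3
        seqs = ax.score_sequences(_presses(keys))
        assert len(seqs) == 3
        assert (seqs["n_errors_before"] == 0).all()

    def test_five_sequence_trial_marks_first_as_warmup(self):
        keys = list(TARGET_SEQUENCE) * 5
        seqs = ax.score_sequences(_presses(keys))
        assert len(seqs) == 5
        assert seqs["warmup"].tolist() == [True] + [False] * 4
        assert seqs["seq_in_trial"].tolist() == [1, 2, 3, 4, 5]

    def test_short_trial_flagged_not_dropped(self):
        with pytest.warns(UserWarning, match="fewer than"):
            seqs = ax.score_sequences(_presses(list(TARGET_SEQUENCE) * 2),
                                      expected_per_trial=5)
        assert len(seqs) == 2


class TestRemoveWarmups:
    @pytest.mark.parametrize("label,kept", [("M10", 196), ("S30", 168)])
    def test_participant_counts(self, label, kept):
        cfg = ax.SyntheticConfig(noise_cv=0.0, error_prob=0.0,
                                 warmup_inflation=1.0, seed=2)
        spec = ax.make_group_spec(label)
        presses = ax.generate_participant(cfg, spec,
                                          np.random.default_rng(2))
        seqs = ax.score_sequences(presses)
        assert len(seqs) == 210
        modeled = ax.remove_warmups(seqs)
        assert len(modeled) == kept
        assert (modeled["st"] == modeled["seq_in_trial"] - 1).all()

    def test_empty_input(self):
        empty = ax.score_sequences(_presses([]))
        assert len(ax.remove_warmups(empty)) == 0


class TestErrorSummary:
    def test_all_zero_errors(self):
        keys = list(TARGET_SEQUENCE) * 3
        seqs = ax.score_sequences(_presses(keys))
        summary = ax.error_rate_summary(seqs)
        assert (summary["mean"] == 0).all()
        assert (summary["grand_mean"] == 0).all()

    def test_warmup_position_reported_separately(self):
        keys = [2, 2] + list(TARGET_SEQUENCE) + list(TARGET_SEQUENCE)
        seqs = ax.score_sequences(_presses(keys))
        summary = ax.error_rate_summary(seqs)
        assert summary.loc[summary["seq_in_trial"] == 1, "mean"].item() == 2
        assert summary.loc[summary["seq_in_trial"] == 2, "mean"].item() == 0

    def test_generator_error_rate_matches_binomial_expectation(self):
        p_err = 0.04
        cfg = ax.SyntheticConfig(error_prob=p_err, noise_cv=0.0,
                                 warmup_inflation=1.0, n_participants=8,
                                 seed=7)
        presses = ax.generate_group(cfg, "M10")
        seqs = ax.score_sequences(presses)
        grand = ax.error_rate_summary(seqs)["grand_mean"].iloc[0]
        expect = 5 * p_err
        n = (seqs["phase"] == "train").sum()
        # 3-sigma binomial band around 0.2 errors/sequence
        sd = np.sqrt(5 * p_err * (1 - p_err) / n)
        assert abs(grand - expect) < 3 * sd


class TestErrorCorrelation:
    def test_perfectly_linear_rates(self):
        rows = []
        for trial in range(1, 4):
            for pos in range(1, 6):
                rows.append(("p1", "S30", "train", trial, pos, 1000.0,
                             pos, pos == 1))
        seqs = pd.DataFrame(rows, columns=[
            "participant", "group", "phase", "trial", "seq_in_trial",
            "rt_ms", "n_errors_before", "warmup"])
        assert ax.error_seq_correlation(seqs, "S30") == pytest.approx(1.0)

    def test_constant_rates_return_zero_with_warning(self):
        keys = list(TARGET_SEQUENCE) * 5
        seqs = ax.score_sequences(_presses(keys, group="S30"))
        with pytest.warns(UserWarning, match="zero variance"):
            assert ax.error_seq_correlation(seqs, "S30") == 0.0

    def test_too_few_points_rejected(self):
        seqs = ax.score_sequences(_presses(list(TARGET_SEQUENCE) * 2))
        with pytest.raises(ValueError, match="3"):
            ax.error_seq_correlation(seqs, "M10")

    def test_increasing_error_probability_yields_positive_r(self):
        cfg = ax.SyntheticConfig(error_prob=0.02, error_slope=0.02,
                                 noise_cv=0.0, warmup_inflation=1.0,
                                 n_participants=10, seed=13)
        presses = ax.generate_group(cfg, "M10")
        seqs = ax.score_sequences(presses)
        assert ax.error_seq_correlation(seqs, "M10") > 0.1


class TestAveraging:
    def test_identity_for_single_participant(self, noisefree_m10):
        _, series, schedule, consts = noisefree_m10
        assert len(series) == consts.stot
        assert (series["n_participants"] == 1).all()

    def test_mean_of_two_constant_participants_is_midpoint(self):
        frames = []
        for pid, lat in (("p1", 100.0), ("p2", 300.0)):
            keys = list(TARGET_SEQUENCE) * 15
            for trial, phase in [(t, "train") for t in range(1, 13)] + \
                                [(t, "test") for t in range(1, 3)]:
                frames.append(_presses(keys, [lat] * len(keys),
                                       participant=pid, trial=trial,
                                       phase=phase))
        seqs = ax.score_sequences(pd.concat(frames, ignore_index=True))
        series = ax.average_over_participants(seqs, ax.make_group_spec("M10"))
        # arithmetic mean across participants of the two constant RTs
        assert np.allclose(series["rt_mean"], (5 * 100.0 + 5 * 300.0) / 2)

    def test_sem_shrinks_with_participants(self):
        sems = []
        for n in (4, 16):
            cfg = ax.SyntheticConfig(noise_cv=0.10, error_prob=0.0,
                                     n_participants=n, seed=31)
            presses = ax.generate_group(cfg, "S30")
            seqs = ax.score_sequences(presses)
            series = ax.average_over_participants(
                seqs, ax.make_group_spec("S30"))
            sems.append(series["rt_sem"].mean())
        assert sems[1] < sems[0] * 0.75

    def test_misaligned_participant_rejected(self):
        cfg = ax.SyntheticConfig(noise_cv=0.0, error_prob=0.0,
                                 warmup_inflation=1.0, seed=2)
        spec = ax.make_group_spec("M10")
        presses = ax.generate_participant(cfg, spec,
                                          np.random.default_rng(2))
        seqs = ax.score_sequences(presses).iloc[:-5]  # drop a sequence
        with pytest.raises(ValueError, match="misaligned"):
            ax.average_over_participants(seqs, spec)


def test_pipeline_closed_loop_matches_predictions(noisefree_m10):
    """Noise-free generation -> scoring -> averaging reproduces the
    generating model's predictions after warm-up removal."""
    cfg, series, schedule, consts = noisefree_m10
    pred = ax.predict_rt(cfg.model, cfg.params, schedule, consts)
    np.testing.assert_allclose(series["rt_mean"].to_numpy(), pred,
                               rtol=0, atol=1e-9)
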