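"""Staircase engine: sequences, step arithmetic, delayed-response ledger."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dapasat.staircase import (
    ConfigurationError,
    StaircaseConfig,
    StaircaseState,
    apply_outcome,
    correct_sum,
    generate_digit_sequence,
    run_session,
    scripted_responder,
    step_adjust,
)


# ---------------------------------------------------------------- sequences
class TestDigitSequence:
    def test_block_constraint(self, default_config):
        seq = generate_digit_sequence(default_config, seed=7)
        assert len(seq) == 55
        for start in range(0, 50, 10):
            counts = Counter(seq[start:start + 10])
            assert counts == {d: 2 for d in range(1, 6)}

    def test_partial_final_block_is_truncated_block(self):
        cfg = StaircaseConfig(n_trials=9)
        seq = generate_digit_sequence(cfg, seed=0)
        assert len(seq) == 10
        assert Counter(seq) == {d: 2 for d in range(1, 6)}

    def test_determinism_and_seed_sensitivity(self, default_config):
        a = generate_digit_sequence(default_config, seed=3)
        b = generate_digit_sequence(default_config, seed=3)
        assert a == b
        others = [generate_digit_sequence(default_config, seed=s) for s in range(10, 30)]
        assert any(o != a for o in others)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            StaircaseConfig(block_size=9).validate()
        with pytest.raises(ConfigurationError):
            StaircaseConfig(step_fraction=1.5).validate()
        with pytest.raises(ConfigurationError):
            StaircaseConfig(initial_soa_ms=100).validate()


class TestCorrectSum:
    @pytest.mark.parametrize("prev,cur,expected", [(2, 5, 7), (5, 3, 8), (1, 1, 2)])
    def test_examples(self, prev, cur, expected):
        assert correct_sum(prev, cur) == expected

    def test_out_of_range_digit(self):
        with pytest.raises(ValueError):
            correct_sum(0, 3)
        with pytest.raises(ValueError):
            correct_sum(2, 9)


# ------------------------------------------------------------- step arithmetic
class TestStepAdjust:
    @pytest.mark.parametrize("soa,units,expected", [
        (2000, -1, 1900),
        (1995, -2, 1796),   # 1995 * 0.90 = 1795.5, half rounds away from zero
        (3500, +1, 3675),
        (3500, -1, 3325),
        (2000, 0, 2000),
    ])
    def test_single_multiplicative_application(self, soa, units, expected):
        assert step_adjust(soa, units, 0.05) == expected

    def test_not_composed_per_unit(self):
        # -2 units means x0.90, not x0.95^2 (which would give 1800 from 1995)
        assert step_adjust(1995, -2, 0.05) != round(1995 * 0.95 * 0.95)

    def test_floor_clamp(self):
        assert step_adjust(205, -2, 0.05, soa_floor_ms=200) == 200


# -------------------------------------------------------------- unit ledger
def _fresh_state(soa=3500):
    return StaircaseState(current_soa_ms=soa, step_fraction=0.05)


class TestApplyOutcome:
    def test_printed_delayed_hit_sequence(self):
        st_ = _fresh_state(2000)
        st_ = apply_outcome(st_, "hit")
        assert st_.current_soa_ms == 2000 and st_.pair_count == 1
        st_ = apply_outcome(st_, "hit")
        assert st_.current_soa_ms == 1900 and st_.pair_count == 0
        st_ = apply_outcome(st_, "pending")
        assert st_.current_soa_ms == 1995
        st_ = apply_outcome(st_, "hit", {"outcome": "hit"})
        assert st_.current_soa_ms == 1796

    def test_twenty_hits_reach_2100_ms(self):
        st_ = _fresh_state(3500)
        for _ in range(20):
            st_ = apply_outcome(st_, "hit")
        assert st_.n_down_units == 10
        assert abs(st_.current_soa_ms - 2100) <= 5

    def test_delayed_hit_starting_pair_then_miss_nets_zero(self):
        st_ = _fresh_state(2000)
        st_ = apply_outcome(st_, "pending")       # +1 provisional
        assert st_.current_soa_ms == 2100
        st_ = apply_outcome(st_, "miss", {"outcome": "hit"})
        # retro -1 (hit began a pair) plus miss +1 = net 0
        assert st_.current_soa_ms == 2100

    def test_resolution_without_pending_is_an_error(self):
        from dapasat.staircase import StateError
        with pytest.raises(StateError):
            apply_outcome(_fresh_state(), "hit", {"outcome": "hit"})

    def test_pair_never_spans_miss(self):
        st_ = _fresh_state(2000)
        st_ = apply_outcome(st_, "hit")
        st_ = apply_outcome(st_, "miss")
        assert st_.pair_count == 0


# ------------------------------------------------------------- full sessions
def _final_soa_all_correct(n_reductions, initial=3500, f=0.05):
    soa = initial
    for _ in range(n_reductions):
        soa = step_adjust(soa, -1, f)
    return soa


class TestRunSession:
    def test_worked_13_sequence_units(self, worked_13_session):
        sess = worked_13_session
        # four down-steps, three up-steps, net one step down
        down = sum(
            tr.soa_after_ms < tr.soa_ms for tr in sess.trials
        )
        up = sum(tr.soa_after_ms > tr.soa_ms for tr in sess.trials)
        assert (down, up) == (4, 3)

    def test_never_answering_responder(self, default_config):
        sess = run_session(default_config, lambda *a: (None, None), seed=0)
        soas = [tr.soa_ms for tr in sess.trials]
        assert all(tr.outcome == "miss" for tr in sess.trials)
        assert soas == sorted(soas) and soas[0] == 3500
        assert min(soas) == 3500

    def test_all_correct_descent(self, all_correct_session):
        sess = all_correct_session
        assert sess.trials[20].soa_ms == 2096  # 2.10 s at trial 21
        # 27 reductions in 54 trials; trial 54 presented after 26 of them
        assert sess.trials[53].soa_ms == _final_soa_all_correct(26)
        assert sess.trials[53].soa_after_ms == _final_soa_all_correct(27)

    def test_replay_determinism(self, default_config):
        script = "hHmLhIimhH" * 6
        a = run_session(default_config, scripted_responder(script), seed=5)
        b = run_session(default_config, scripted_responder(script), seed=5)
        assert a.trials == b.trials

    def test_quit_terminates_early(self, default_config):
        sess = run_session(default_config, scripted_responder("hhq" + "h" * 51), seed=0)
        assert sess.terminated_early and sess.termination_reason == "quit"
        assert len(sess.trials) == 2 and not sess.completed

    def test_trailing_pending_resolved_without_new_trial(self):
        cfg = StaircaseConfig(initial_soa_ms=2000, n_trials=3)
        sess = run_session(cfg, scripted_responder("hHL"), seed=0)
        # trial 3 delayed hit: +5% at trial 3, then retro -5% in bookkeeping
        assert [tr.soa_ms for tr in sess.trials] == [2000, 2000, 1900]
        assert sess.trials[-1].outcome == "delayed_hit"
        assert sess.trials[-1].soa_after_ms == step_adjust(
            step_adjust(1900, 1, 0.05), -1, 0.05
        )


# ------------------------------------------------- reference replay oracle
def _reference_trajectory(script, initial=3500, f=0.05, dialect="two-key"):
    """Straightforward token-level transcription of the adjustment rules."""
    soa, pair, pending = initial, 0, None
    presented, after = [], []
    for tok in script:
        if dialect == "one-key" and tok in ("i", "I"):
            tok = "m"
        presented.append(soa)
        units = 0
        if pending is not None:
            was_hit, p = pending
            if was_hit:
                if p + 1 >= 2:
                    units -= 2
                    pair = 0
                else:
                    units -= 1
                    pair = p + 1
            else:
                pair = 0
            pending = None
        if tok in ("h", "H"):
            pair += 1
            if pair == 2:
                units -= 1
                pair = 0
        elif tok in ("m", "i"):
            units += 1
            pair = 0
        else:  # late response, registers next trial
            units += 1
            pending = (tok == "L", pair)
        soa = step_adjust(soa, units, f)
        after.append(soa)
    if pending is not None:
        was_hit, p = pending
        units = 0
        if was_hit:
            units = -2 if p + 1 >= 2 else -1
        soa = step_adjust(soa, units, f)
        after[-1] = soa
    return presented, after


script_strategy = st.lists(
    st.sampled_from("hmLiI"), min_size=1, max_size=40
).map("".join)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(script=script_strategy)
def test_engine_matches_reference_ledger(script):
    """Every SOA trajectory replays under an independent rule transcription."""
    cfg = StaircaseConfig(n_trials=len(script))
    sess = run_session(cfg, scripted_responder(script), seed=1)
    presented, after = _reference_trajectory(script)
    assert [tr.soa_ms for tr in sess.trials] == presented
    assert [tr.soa_after_ms for tr in sess.trials] == after


@settings(max_examples=150, deadline=None, derandomize=True)
@given(script=script_strategy)
def test_session_invariants(script):
    cfg = StaircaseConfig(n_trials=len(script))
    sess = run_session(cfg, scripted_responder(script), seed=1)
    soas = [tr.soa_ms for tr in sess.trials]
    assert min(soas) <= cfg.initial_soa_ms
    assert soas[0] == cfg.initial_soa_ms
    hits = sum(tr.is_hit for tr in sess.trials)
    reductions = sum(tr.soa_after_ms < tr.soa_ms for tr in sess.trials)
    assert reductions <= hits // 2 + 1  # +1: a combined (-2 retro +1) trial


@settings(max_examples=100, deadline=None, derandomize=True)
@given(script=script_strategy)
def test_one_key_equals_two_key_with_incorrects_as_misses(script):
    cfg1 = StaircaseConfig(n_trials=len(script), scoring_dialect="one-key")
    cfg2 = StaircaseConfig(n_trials=len(script), scoring_dialect="two-key")
    relabeled = script.replace("i", "m").replace("I", "m")
    a = run_session(cfg1, scripted_responder(script), seed=1)
    b = run_session(cfg2, scripted_responder(relabeled), seed=1)
    assert [tr.soa_ms for tr in a.trials] == [tr.soa_ms for tr in b.trials]
    assert [tr.soa_after_ms for tr in a.trials] == [tr.soa_after_ms for tr in b.trials]
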