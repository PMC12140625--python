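"""History labeling vs a literal sequence-matching oracle, plus structural
invariants (nesting, partition, session isolation)."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selhist import (HistoryCondition, enumerate_sequences, label_joint,
                     label_lagged_event, label_outcome_run, label_pattern,
                     label_run, label_sequence, parse_condition)

from conftest import make_table


# ---------------------------------------------------------------- oracle --
# A deliberately naive re-statement of the verbal sequence definitions:
# walk each session as a list and compare literal value strings.

def _session_lists(table, column):
    out = []
    for _, idx in table.session_groups():
        out.append(list(table.data[column].to_numpy()[idx]))
    return out


def oracle_mask(table, variable, check):
    """check(preceding_values_most_recent_first, current_value) -> bool"""
    column = {"color": "target_color", "location": "target_location",
              "outcome": "correct"}[variable]
    mask = []
    for values in _session_lists(table, column):
        for i, cur in enumerate(values):
            preceding = values[:i][::-1]  # most recent first
            mask.append(check(preceding, cur))
    return np.array(mask, bool)


def oracle_run(table, variable, rel, depth):
    def check(prev, cur):
        if len(prev) < depth:
            return False
        for v in prev[:depth]:
            if variable == "outcome":
                if v != (rel == "C"):
                    return False
            elif (v == cur) != (rel == "S"):
                return False
        return True
    return oracle_mask(table, variable, check)


def oracle_lagged(table, variable, rel, lag):
    def check(prev, cur):
        if len(prev) < lag + 1:
            return False
        v = prev[lag]
        if variable == "outcome":
            return v == (rel == "C")
        return (v == cur) == (rel == "S")
    return oracle_mask(table, variable, check)


def oracle_pattern(table, variable, pattern):
    def check(prev, cur):
        if len(prev) < len(pattern):
            return False
        for v, ch in zip(prev, pattern):
            if variable == "outcome":
                if v != (ch == "C"):
                    return False
            elif (v == cur) != (ch == "S"):
                return False
        return True
    return oracle_mask(table, variable, check)


# ---------------------------------------------------- documented examples --

class TestVerbalDefinitions:
    def test_color_repeat_run(self):
        """red-red-red: the third trial is both 1S and 2S."""
        t = make_table(["red", "red", "red"])
        assert label_run(t, "color", "S", 1).tolist() == [False, True, True]
        assert label_run(t, "color", "S", 2).tolist() == [False, False, True]

    def test_color_switch(self):
        """green-red: the second trial is 1D."""
        t = make_table(["green", "red"])
        assert label_run(t, "color", "D", 1).tolist() == [False, True]

    def test_location_different_means_any_other(self):
        """left-down-right: a D run accepts any non-matching locations."""
        t = make_table(["red"] * 3, locations=["left", "down", "right"])
        assert label_run(t, "location", "D", 2).tolist()[-1]

    def test_outcome_runs_are_absolute(self):
        t = make_table(["red"] * 3, correct=[True, True, False])
        assert label_outcome_run(t, "C", 1).tolist() == [False, True, True]
        assert label_outcome_run(t, "C", 2).tolist() == [False, False, True]
        t2 = make_table(["red"] * 2, correct=[False, True])
        assert label_outcome_run(t2, "E", 1).tolist() == [False, True]

    def test_alternating_outcomes_never_form_depth2_runs(self):
        t = make_table(["red"] * 4, correct=[True, False, True, False])
        assert not label_outcome_run(t, "C", 2).any()
        assert not label_outcome_run(t, "E", 2).any()

    def test_lagged_event_with_unconstrained_intervening(self):
        """red-x-x-red is 1S2x for color on the last trial."""
        t = make_table(["red", "green", "green", "red"])
        assert label_lagged_event(t, "color", "S", 2).tolist()[-1]
        assert not label_lagged_event(t, "color", "S", 1).tolist()[-1]

    def test_lag_zero_reduces_to_depth_one_run(self, small_biased_table):
        for var in ("color", "location"):
            for rel in ("S", "D"):
                a = label_lagged_event(small_biased_table, var, rel, 0)
                b = label_run(small_biased_table, var, rel, 1)
                assert (a == b).all()

    def test_joint_is_conjunction(self):
        t = make_table(["red", "red"], locations=["up", "up"],
                       correct=[True, True])
        joint = label_joint(t, [HistoryCondition("color", "S"),
                                HistoryCondition("location", "S"),
                                HistoryCondition("outcome", "C")])
        assert joint.tolist() == [False, True]

    def test_joint_subset_of_components(self, small_biased_table):
        conds = [HistoryCondition("color", "SS"),
                 HistoryCondition("outcome", "CC")]
        joint = label_joint(small_biased_table, conds)
        for c in conds:
            assert not (joint & ~label_pattern(small_biased_table, c)).any()

    def test_incompatible_depths_rejected(self):
        t = make_table(["red", "red"])
        with pytest.raises(ValueError, match="depth"):
            label_joint(t, [HistoryCondition("color", "S"),
                            HistoryCondition("outcome", "CC")])


# ------------------------------------------------------ oracle equivalence --

class TestOracleEquivalence:
    def test_exhaustive_color_sequences_up_to_depth(self):
        """Every color string of length <= 6: all run and lag labels agree
        with the literal oracle."""
        for n in range(1, 7):
            for seq in itertools.product("rg", repeat=n):
                t = make_table(["red" if c == "r" else "green" for c in seq])
                for depth in (1, 2, 3):
                    for rel in "SD":
                        lib = label_run(t, "color", rel, depth)
                        assert (lib == oracle_run(t, "color", rel,
                                                  depth)).all(), (seq, rel,
                                                                  depth)
                for lag in (0, 1, 2):
                    for rel in "SD":
                        lib = label_lagged_event(t, "color", rel, lag)
                        assert (lib == oracle_lagged(t, "color", rel,
                                                     lag)).all()

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_random_small_tables_all_ops(self, data):
        """Tables of <= 12 trials over 2 colors x 4 locations x outcomes,
        split into 1-2 sessions: every labeling op matches the oracle."""
        n = data.draw(st.integers(1, 12))
        colors = data.draw(st.lists(st.integers(0, 1), min_size=n,
                                    max_size=n))
        locs = data.draw(st.lists(st.integers(0, 3), min_size=n,
                                  max_size=n))
        outcomes = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        split = data.draw(st.integers(0, n))
        sessions = ["s1"] * split + ["s2"] * (n - split)
        t = make_table(colors, locations=locs, correct=outcomes,
                       sessions=sessions)
        for var in ("color", "location"):
            for rel in "SD":
                for depth in (1, 2, 3):
                    assert (label_run(t, var, rel, depth) ==
                            oracle_run(t, var, rel, depth)).all()
                for lag in (0, 1, 3):
                    assert (label_lagged_event(t, var, rel, lag) ==
                            oracle_lagged(t, var, rel, lag)).all()
        for rel in "CE":
            for depth in (1, 2):
                assert (label_outcome_run(t, rel, depth) ==
                        oracle_run(t, "outcome", rel, depth)).all()
        # fully specified mixed patterns
        pattern = data.draw(st.text(alphabet="SD", min_size=1, max_size=3))
        for var in ("color", "location"):
            assert (label_pattern(t, HistoryCondition(var, pattern)) ==
                    oracle_pattern(t, var, pattern)).all()


# ------------------------------------------------------------- invariants --

class TestInvariants:
    def test_nesting_deeper_runs_imply_shallower(self, small_biased_table):
        for var, rel in (("color", "S"), ("color", "D"), ("location", "S"),
                         ("location", "D")):
            shallower = label_run(small_biased_table, var, rel, 1)
            for depth in (2, 3, 4):
                deeper = label_run(small_biased_table, var, rel, depth)
                assert not (deeper & ~shallower).any()
                shallower = deeper

    def test_fully_specified_patterns_partition_eligible_trials(
            self, small_biased_table):
        t = small_biased_table
        for H in (1, 2):
            pos = np.concatenate([np.arange(len(idx))
                                  for _, idx in t.session_groups()])
            eligible = pos >= H
            total = np.zeros(len(t), dtype=int)
            for key in enumerate_sequences(("color", "location"), H):
                total += label_sequence(t, key).astype(int)
            assert (total[eligible] == 1).all()
            assert (total[~eligible] == 0).all()

    def test_session_isolation_under_permutation(self):
        t = make_table(["red", "red", "green", "green"],
                       sessions=["a", "a", "b", "b"])
        swapped = make_table(["green", "green", "red", "red"],
                             sessions=["b", "b", "a", "a"])
        m1 = label_run(t, "color", "S", 1)
        m2 = label_run(swapped, "color", "S", 1)
        assert m1.tolist() == [False, True, False, True]
        assert m2.tolist() == [False, True, False, True]

    def test_first_trials_of_session_carry_no_label(self, small_biased_table):
        pos = np.concatenate([np.arange(len(idx))
                              for _, idx in small_biased_table.session_groups()])
        for depth in (1, 3):
            m = label_run(small_biased_table, "color", "S", depth)
            assert not m[pos < depth].any()

    def test_iid_label_frequencies(self, unbiased_table):
        """Under uniform independent assignment: P(1S color) ~ 1/2,
        P(2S color) ~ 1/4, P(1S location) ~ 1/4, and lagged repeat
        probabilities are flat in the lag."""
        t = unbiased_table
        pos = np.concatenate([np.arange(len(idx))
                              for _, idx in t.session_groups()])
        checks = [
            (label_run(t, "color", "S", 1), pos >= 1, 0.5),
            (label_run(t, "color", "S", 2), pos >= 2, 0.25),
            (label_run(t, "location", "S", 1), pos >= 1, 0.25),
            (label_lagged_event(t, "color", "S", 4), pos >= 5, 0.5),
        ]
        for mask, eligible, p0 in checks:
            p = mask[eligible].mean()
            se = np.sqrt(p0 * (1 - p0) / eligible.sum())
            assert abs(p - p0) < 4 * se


# ------------------------------------------------------------ enumeration --

class TestEnumeration:
    def test_documented_counts(self):
        assert len(enumerate_sequences(("color", "location"), 2)) == 16
        assert len(enumerate_sequences(("color", "location", "outcome"),
                                       1)) == 8
        assert [k.name for k in enumerate_sequences(("color",), 1)] == \
            ["1S", "1D"]

    @pytest.mark.parametrize("variables,H", [
        (("color",), 3), (("color", "location"), 1),
        (("color", "location"), 4), (("color", "outcome"), 2),
        (("color", "location", "outcome"), 2),
    ])
    def test_count_formula_and_uniqueness(self, variables, H):
        keys = enumerate_sequences(variables, H)
        assert len(keys) == (2 ** len(variables)) ** H
        assert len({k.name for k in keys}) == len(keys)

    def test_canonical_order_starts_all_s(self):
        keys = enumerate_sequences(("color", "location"), 1)
        assert [k.name for k in keys] == ["1SS", "1SD", "1DS", "1DD"]

    def test_depth_out_of_range(self):
        with pytest.raises(ValueError):
            enumerate_sequences(("color",), 0)
        with pytest.raises(ValueError):
            enumerate_sequences(("color",), 5)


class TestConditionParsing:
    @pytest.mark.parametrize("text,expected", [
        ("1S:color", [HistoryCondition("color", "S")]),
        ("3D:location", [HistoryCondition("location", "DDD")]),
        ("2C", [HistoryCondition("outcome", "CC")]),
        ("1D2x:location", [HistoryCondition("location", "D", lag=2)]),
        ("2SC:color", [HistoryCondition("color", "SS"),
                       HistoryCondition("outcome", "CC")]),
        ("1SSC", [HistoryCondition("color", "S"),
                  HistoryCondition("location", "S"),
                  HistoryCondition("outcome", "C")]),
        ("2DS", [HistoryCondition("color", "DD"),
                 HistoryCondition("location", "SS")]),
    ])
    def test_labels_decode_to_conditions(self, text, expected):
        assert parse_condition(text) == expected

    @pytest.mark.parametrize("bad", ["XS:color", "1S", "2S2x:color",
                                     "1SS:color", "0S:color"])
    def test_malformed_labels_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_condition(bad)
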