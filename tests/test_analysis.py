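"""Repeat-context summaries, regressions and region statistics."""

import numpy as np
import pandas as pd
import pytest

from indeldrift.analysis import (
    CONTEXT_ADJACENT,
    CONTEXT_NONREPEAT,
    CONTEXT_REPEAT,
    assign_repeat_context,
    compare_repertoires,
    fit_loglinear,
    indel_length_distribution,
    pooled_length_means,
    region_summary,
    si_ratio,
    summarize_by_repeat,
    tolerated_positions,
)
from indeldrift.published import REPEAT_TABLE
from indeldrift.reference import GeneReference, find_homonucleotide_runs


def make_table(rows):
    """Rows: (position, type, payload, count, coverage, corrected)."""
    return pd.DataFrame(
        [
            {
                "position": p, "region": "orf", "type": t, "payload": pl,
                "count": c, "coverage": cov, "raw": c / cov,
                "corrected": corr, "flag": "", "repertoire": "G0",
            }
            for p, t, pl, c, cov, corr in rows
        ]
    )


@pytest.fixture()
def toy_ref():
    seq = "TTGCCAAAAAAAAGCCTTTG"  # A x8 at 6..13, C x2 at 15..16, T x3 at 17..19
    return GeneReference(seq, (1, len(seq)))


@pytest.fixture()
def toy_runs(toy_ref):
    return find_homonucleotide_runs(toy_ref.sequence)


class TestContext:
    def test_deletion_in_long_run(self, toy_ref, toy_runs):
        table = make_table([(6, "del", 1, 10, 100, 0.1)])
        ann = assign_repeat_context(table, toy_ref, toy_runs)
        assert ann.iloc[0]["context"] == CONTEXT_REPEAT
        assert (ann.iloc[0]["run_base"], ann.iloc[0]["run_length"]) == ("A", 8)

    def test_insertion_of_different_base_at_run_end_is_adjacent(self, toy_ref, toy_runs):
        # ins C before position 14, i.e. at the right end of the A x8 run
        table = make_table([(14, "ins", "C", 10, 100, 0.1)])
        ann = assign_repeat_context(table, toy_ref, toy_runs)
        assert ann.iloc[0]["context"] == CONTEXT_ADJACENT
        assert ann.iloc[0]["run_length"] == 8

    def test_call_at_length1_run_is_non_repeat(self, toy_ref, toy_runs):
        table = make_table([(3, "del", 1, 5, 100, 0.05)])  # the lone G at 3
        ann = assign_repeat_context(table, toy_ref, toy_runs)
        assert ann.iloc[0]["context"] == CONTEXT_NONREPEAT


class TestRepeatSummary:
    def test_single_run_class(self, toy_ref, toy_runs):
        table = make_table([(6, "del", 1, 50, 1000, 50.25e-3)])
        ann = assign_repeat_context(table, toy_ref, toy_runs)
        summ = summarize_by_repeat(ann, toy_runs, background_indel=1e-5)
        row = summ[(summ["length"] == 8) & (summ["base"] == "A")].iloc[0]
        assert row["mean_frequency"] == pytest.approx(50.25e-3)
        assert row["occurrence"] == 1 and row["n_above_background"] == 1

    def test_runs_without_calls_contribute_zero(self):
        seq = "GCAAAGGCAAAGGCAAAGG"  # three A x3 runs
        ref = GeneReference(seq, (1, len(seq)))
        runs = find_homonucleotide_runs(seq)
        table = make_table([(3, "del", 1, 3, 1000, 3e-3)])
        ann = assign_repeat_context(table, ref, runs)
        summ = summarize_by_repeat(ann, runs, background_indel=1e-5)
        row = summ[(summ["length"] == 3) & (summ["base"] == "A")].iloc[0]
        assert row["mean_frequency"] == pytest.approx(1e-3)
        assert row["n_above_background"] == 1 and row["occurrence"] == 3

    def test_no_calls_gives_all_zero_means(self, toy_ref, toy_runs):
        empty = make_table([(3, "sub", "A", 1, 100, 1e-2)])  # subs only
        ann = assign_repeat_context(empty, toy_ref, toy_runs)
        summ = summarize_by_repeat(ann, toy_runs, background_indel=0.0)
        assert (summ["mean_frequency"] == 0).all()

    def test_order_invariance(self, toy_ref, toy_runs):
        rows = [(5, "del", 1, 5, 100, 0.05), (17, "ins", "T", 3, 100, 0.03)]
        a = summarize_by_repeat(
            assign_repeat_context(make_table(rows), toy_ref, toy_runs), toy_runs, 0.0
        )
        b = summarize_by_repeat(
            assign_repeat_context(make_table(rows[::-1]), toy_ref, toy_runs), toy_runs, 0.0
        )
        pd.testing.assert_frame_equal(a, b)


class TestRegression:
    def test_exact_exponential_recovered_to_machine_precision(self):
        means = {L: 1e-4 * 2.5 ** (L - 1) for L in range(1, 9)}
        fit = fit_loglinear(means)
        assert fit.fold_per_nt == pytest.approx(2.5, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.predict(1) == pytest.approx(1e-4, rel=1e-9)

    def test_zero_classes_excluded_and_reported(self):
        means = {3: 1e-3, 4: 2e-3, 5: 0.0, 6: 8e-3, 8: 5e-2}
        fit = fit_loglinear(means)
        assert fit.excluded_zero_lengths == (5,)
        assert set(fit.lengths_used) == {3, 4, 6, 8}

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_loglinear({3: 1e-3, 8: 5e-2})

    def test_published_g0_and_g17_folds(self):
        """Occurrence-weighted published means give ~2.5-fold (naive) and
        ~3.4-fold (selected) per repeat nucleotide."""
        t = REPEAT_TABLE
        for col, expected in (("g0_mean_e3", 2.5), ("g17_mean_e3", 3.4)):
            w = (t[col] * t["occurrence"]).groupby(t["length"]).sum()
            means = w / t.groupby("length")["occurrence"].sum()
            fit = fit_loglinear(means)
            assert fit.fold_per_nt == pytest.approx(expected, rel=0.15)


class TestRatiosAndDistributions:
    @pytest.mark.parametrize(
        "S, I, expected", [(1e-2, 1e-3, 10.0), (0.0, 1e-3, 0.0), (0.0, 0.0, 0.0)]
    )
    def test_si_ratio(self, S, I, expected):
        assert si_ratio(S, I) == pytest.approx(expected)

    def test_si_ratio_undefined_when_no_indels(self):
        assert si_ratio(1e-2, 0.0) is None

    def test_length_distribution_all_deletions(self):
        table = make_table([(5, "del", 1, 10, 100, 0.1)])
        assert indel_length_distribution(table) == {"-1": 100.0}

    def test_length_distribution_balanced(self):
        table = make_table([(5, "del", 1, 7, 100, 0.07), (9, "ins", "A", 7, 100, 0.07)])
        dist = indel_length_distribution(table)
        assert dist == {"-1": 50.0, "+1": 50.0}

    def test_percentages_always_sum_to_100(self):
        rng = np.random.default_rng(8)
        rows = []
        for i, (t, pl) in enumerate(
            [("del", 1), ("del", 2), ("ins", "A"), ("ins", "AA"), ("ins", "AAA"), ("ins", "AAAA")]
        ):
            rows.append((5 + i, t, pl, int(rng.integers(1, 50)), 1000, 0.01))
        dist = indel_length_distribution(make_table(rows))
        assert sum(dist.values()) == pytest.approx(100.0, abs=0.1)
        assert set(dist) <= {"<-1", "-1", "+1", "+2", "+3", ">+3"}

    def test_no_indels_rejected(self):
        with pytest.raises(ValueError):
            indel_length_distribution(make_table([(5, "sub", "A", 1, 100, 1e-2)]))


class TestTolerated:
    def test_threshold_inclusive(self):
        bg = 1.6e-5
        table = make_table(
            [(5, "del", 1, 1, 100, 10 * bg),      # exactly 10x: tolerated
             (9, "ins", "A", 1, 100, 0.2e-3),     # well above: tolerated
             (13, "del", 1, 1, 100, 1e-5)]        # below: not
        )
        tol = tolerated_positions(table, bg)
        assert tol == {(5, "del"), (9, "ins")}


class TestRegions:
    def test_region_without_calls_is_zero(self, toy_ref):
        table = make_table([(5, "del", 1, 5, 100, 0.05)])
        summ = region_summary(table, toy_ref, {"empty": (14, 16)})
        row = summ.iloc[0]
        assert row["S"] == 0 and row["I"] == 0

    def test_single_position_region_equals_its_frequency(self, toy_ref):
        table = make_table([(5, "del", 1, 5, 100, 0.05), (5, "sub", "G", 2, 100, 0.02)])
        row = region_summary(table, toy_ref, {"one": (5, 5)}).iloc[0]
        assert row["I"] == pytest.approx(0.05)
        assert row["S"] == pytest.approx(0.02)
        assert row["S_over_I"] == pytest.approx(0.4)

    def test_empty_region_rejected(self, toy_ref):
        with pytest.raises(ValueError, match="empty"):
            region_summary(make_table([(5, "del", 1, 5, 100, 0.05)]), toy_ref, {"bad": (9, 5)})


class TestCompare:
    def test_flags_reflect_single_repertoire_detection(self):
        g0 = make_table([(5, "del", 1, 50, 1000, 5e-2)])
        g17 = make_table([(9, "ins", "A", 50, 1000, 5e-2)])
        joint = compare_repertoires(g0, g17, 2.1e-5, 1.6e-5)
        at5 = joint[joint["position"] == 5].iloc[0]
        assert at5["g0_ge_10x"] and not at5["g17_ge_10x"]
        at9 = joint[joint["position"] == 9].iloc[0]
        assert at9["g17_ge_10x"] and not at9["g0_ge_10x"]

    def test_empty_tables_give_empty_join(self):
        empty = make_table([(5, "sub", "A", 1, 100, 1e-2)])  # no indels
        joint = compare_repertoires(empty, empty, 1e-5, 1e-5)
        assert joint.empty
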