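import numpy as np
import pandas as pd
import pytest

from metasdt import (
    apply_exclusions,
    compute_trial_score,
    compute_type1_sdt,
    levene_holm,
    mixed_anova,
    paired_t_with_bf,
    summarize_participants,
)
from metasdt.behavioral import holm_adjust, post_by_pre_level, trial_validity
from metasdt.counts import RatingCounts
from conftest import clean_participant_rows, make_trials
from oracles import jzs_bf10, split_plot_anova


class TestScore:
    @pytest.mark.parametrize("pre,correct,points", [
        (2, True, 2),   # high-risk bet pays double
        (2, False, -1),  # ... but loses a point when wrong
        (1, True, 1),
        (1, False, 0),  # low-risk has no penalty
    ])
    def test_wagering_payoffs(self, pre, correct, points):
        assert compute_trial_score(pre, correct) == points

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_trial_score(float("nan"), True)
        with pytest.raises(ValueError):
            compute_trial_score(3, True)


class TestExclusions:
    def test_fast_response_invalidates_trial(self):
        trials = make_trials({"p1": ("bet", [{"rt_pre": 50.0}, {}])})
        valid = trial_validity(trials)
        assert list(valid) == [False, True]

    def test_missing_rt_treated_as_missing_response(self):
        trials = make_trials({"p1": ("bet", [{"rt_post": np.nan}])})
        assert not trial_validity(trials).iloc[0]

    def test_hand_enumerated_cohort(self):
        """One clean participant kept; fixed pre-ratings and missing answers
        each knock a participant out, attributed to the right rule."""
        clean = clean_participant_rows()
        fixer = clean_participant_rows(alternate_pre=True)
        for r in fixer:
            if r["difficulty"] == "easy":
                r["pre_rating"] = 2  # identical pre-rating on every easy trial
        sleeper = clean_participant_rows()
        for r in sleeper[36:56]:  # 20 hard trials without an answer
            r["type1_response"] = None
        trials = make_trials({
            "clean": ("bet", clean),
            "fixer": ("bet", fixer),
            "sleeper": ("confidence", sleeper),
        })
        kept, report = apply_exclusions(trials)
        assert set(kept["participant_id"]) == {"clean"}
        rep = report.set_index("participant_id")
        assert not rep.loc["clean", "excluded"]
        assert "identical pre_rating" in rep.loc["fixer", "reasons"]
        assert "fewer than 18" in rep.loc["sleeper", "reasons"]
        assert rep.loc["sleeper", "n_valid_hard"] == 16

    def test_participant_below_18_valid_trials_dropped(self):
        rows = clean_participant_rows(n_easy=36, n_hard=17)
        trials = make_trials({"p": ("bet", rows)})
        kept, report = apply_exclusions(trials)
        assert kept.empty
        assert report["excluded"].all()

    def test_idempotent(self):
        cohort = make_trials({
            "a": ("bet", clean_participant_rows()),
            "b": ("confidence", clean_participant_rows()),
        })
        once, rep1 = apply_exclusions(cohort)
        twice, rep2 = apply_exclusions(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_input(self):
        kept, report = apply_exclusions(pd.DataFrame(columns=make_trials({}).columns))
        assert kept.empty and report.empty


class TestSummaries:
    def test_accuracy_and_score_conservation(self, small_cohort):
        _, trials, _ = small_cohort
        kept, _ = apply_exclusions(trials)
        summary = summarize_participants(kept)
        pid = summary["participant_id"].iloc[0]
        diff = summary["difficulty"].iloc[0]
        sub = kept[(kept["participant_id"] == pid) & (kept["difficulty"] == diff)]
        correct = sub["type1_response"] == sub["stimulus"]
        row = summary.iloc[0]
        assert row["accuracy"] == pytest.approx(correct.mean())
        assert row["n_valid_trials"] == len(sub)
        expected = sum(compute_trial_score(r, c)
                       for r, c in zip(sub["pre_rating"], correct))
        assert row["total_score"] == expected

    def test_dprime_equals_sdt_on_same_margins(self, small_cohort):
        _, trials, _ = small_cohort
        kept, _ = apply_exclusions(trials)
        summary = summarize_participants(kept)
        row = summary.iloc[1]
        sub = kept[(kept["participant_id"] == row["participant_id"])
                   & (kept["difficulty"] == row["difficulty"])]
        rc = RatingCounts.from_trials(
            sub["stimulus"].to_numpy(), sub["type1_response"].to_numpy(),
            sub["pre_rating"].to_numpy(dtype=np.int64), 2)
        assert row["d_prime"] == pytest.approx(compute_type1_sdt(rc).d_prime)


def anova_frame(values: np.ndarray, n_per_group: int) -> pd.DataFrame:
    rows = []
    i = 0
    for grp in ("bet", "confidence"):
        for p in range(n_per_group):
            for j, diff in enumerate(("easy", "hard")):
                rows.append(dict(participant_id=f"{grp}{p}", instruction=grp,
                                 difficulty=diff, value=values[i]))
                i += 1
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_hand_computed_sums_of_squares(self):
        rng = np.random.default_rng(42)
        df = anova_frame(rng.normal(size=8) + np.tile([0.0, 0.8], 4), 2)
        result = mixed_anova(df).set_index("effect")
        oracle = split_plot_anova(df)
        for effect in ("instruction", "difficulty", "interaction"):
            assert result.loc[effect, "F"] == pytest.approx(
                oracle[effect]["F"], abs=1e-10)
            assert result.loc[effect, "eta_g"] == pytest.approx(
                oracle[effect]["eta_g"], abs=1e-10)

    def test_constant_values_give_zero_f(self):
        df = anova_frame(np.full(12, 2.5), 3)
        result = mixed_anova(df)
        assert (result["F"] == 0.0).all()
        assert (result["eta_g"] == 0.0).all()

    def test_pure_within_effect(self):
        rng = np.random.default_rng(0)
        base = np.tile([0.0, 1.0], 10)  # difficulty adds +1 for everyone
        df = anova_frame(base + rng.normal(0, 1e-3, 20), 5)
        result = mixed_anova(df).set_index("effect")
        assert result.loc["difficulty", "F"] > 1e4
        assert result.loc["instruction", "F"] < 10

    def test_missing_cell_names_participant(self):
        df = anova_frame(np.arange(8.0), 2).iloc[:-1]
        with pytest.raises(ValueError, match="confidence1"):
            mixed_anova(df)

    def test_eta_g_stays_in_unit_interval(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            df = anova_frame(rng.normal(size=24) * rng.uniform(0.1, 5), 6)
            result = mixed_anova(df)
            assert ((result["eta_g"] >= 0) & (result["eta_g"] <= 1)).all()

    def test_permuted_labels_yield_null_instruction_rate(self):
        """Type-I error of the instruction F-test stays near alpha."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 120
        for _ in range(n_rep):
            df = anova_frame(rng.normal(size=32), 8)
            result = mixed_anova(df).set_index("effect")
            rejections += result.loc["instruction", "p"] < 0.05
        assert 0.005 < rejections / n_rep < 0.13


class TestPairedT:
    def test_near_identical_samples_favor_the_null(self):
        x = np.arange(20.0)
        y = x + np.where(np.arange(20) % 2 == 0, 1e-6, -1e-6)
        res = paired_t_with_bf(x, y)
        assert abs(res["t"]) < 1e-9
        assert res["cohen_d"] == pytest.approx(0.0, abs=1e-9)
        assert res["bf10"] < 1

    def test_identical_samples_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            paired_t_with_bf(np.arange(10.0), np.arange(10.0))

    def test_decisive_effect(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=20)
        res = paired_t_with_bf(y + 1 + rng.normal(0, 1e-6, 20), y)
        assert abs(res["t"]) > 1e4
        assert res["bf10"] > 3

    def test_bf_matches_quadrature_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.4, 1, 10)
        y = rng.normal(0, 1, 10)
        res = paired_t_with_bf(x, y)
        expected = jzs_bf10(res["t"], 10)
        assert res["bf10"] == pytest.approx(expected, rel=1e-6)


class TestLeveneHolm:
    def test_holm_arithmetic(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_unequal_spread_detected_after_correction(self):
        rng = np.random.default_rng(3)
        rows = []
        for diff in ("easy", "hard"):
            for i in range(100):
                rows.append(dict(participant_id=f"b{i}", instruction="bet",
                                 difficulty=diff, value=rng.normal(0, 1)))
                rows.append(dict(participant_id=f"c{i}", instruction="confidence",
                                 difficulty=diff, value=rng.normal(0, 4)))
        result = levene_holm(pd.DataFrame(rows))
        assert (result["adjusted_p"] < 0.05).all()
        assert (result["adjusted_p"] >= result["p"] - 1e-15).all()

    def test_degenerate_groups_rejected(self):
        rows = []
        for diff in ("easy", "hard"):
            for i in range(5):
                rows.append(dict(participant_id=f"b{i}", instruction="bet",
                                 difficulty=diff, value=1.0))
                rows.append(dict(participant_id=f"c{i}", instruction="confidence",
                                 difficulty=diff, value=2.0))
        with pytest.raises(ValueError, match="identical"):
            levene_holm(pd.DataFrame(rows))


def test_post_by_pre_pairs_only_complete_participants():
    trials = make_trials({
        "a": ("bet", [{"pre_rating": 1, "post_rating": 2},
                      {"pre_rating": 2, "post_rating": 4}]),
        "b": ("bet", [{"pre_rating": 1, "post_rating": 3}]),  # never bets high
    })
    pairs = post_by_pre_level(trials)
    assert list(pairs["participant_id"]) == ["a"]
    assert pairs.loc[0, "post_low"] == 2 and pairs.loc[0, "post_high"] == 4
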