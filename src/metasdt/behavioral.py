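"""Exclusion rules, behavioral indices, and frequentist/Bayesian tests.

Implements the trial- and participant-level exclusion policy, the per-cell
behavioral summaries (accuracy, d', score, mean ratings), the two-way mixed
ANOVA with generalized eta squared, the paired t-test with Cohen's d and the
JZS (Cauchy-prior) Bayes factor, and Levene's test with Holm correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import RatingCounts
from .sdt import compute_type1_sdt

TRIAL_COLUMNS = [
    "participant_id", "instruction", "difficulty", "session", "trial",
    "stimulus", "pre_rating", "type1_response", "post_rating",
    "rt_pre", "rt_answer", "rt_post",
]

MIN_RT_MS = 100.0
MIN_VALID_TRIALS = 18

# (pre_rating level, correct) -> points; level 2 = high-risk/high-belief
_SCORE = {(2, True): 2, (2, False): -1, (1, True): 1, (1, False): 0}


def compute_trial_score(pre_rating: int, correct: bool) -> int:
    """Points earned on one trial under the wagering rule.

    High-risk bets pay +2 when correct and -1 when wrong; low-risk bets pay
    +1 when correct with no penalty.  For the confidence group the score is
    emulated by mapping the high belief level to the high-risk option.
    """
    if pre_rating is None or (isinstance(pre_rating, float) and np.isnan(pre_rating)):
        raise ValueError("pre_rating is missing; cannot score the trial")
    if correct is None or (isinstance(correct, float) and np.isnan(correct)):
        raise ValueError("correctness is missing; cannot score the trial")
    key = (int(pre_rating), bool(correct))
    if key[0] not in (1, 2):
        raise ValueError(f"pre_rating must be 1 (low) or 2 (high), got {pre_rating}")
    return _SCORE[key]


def trial_validity(trials: pd.DataFrame) -> pd.Series:
    """Boolean mask of valid trials.

    A trial is invalid when any of the three responses (pre-rating, type-1
    answer, post-rating) is missing or was given in under 100 ms.
    """
    ok = pd.Series(True, index=trials.index)
    for resp, rt in (("pre_rating", "rt_pre"),
                     ("type1_response", "rt_answer"),
                     ("post_rating", "rt_post")):
        ok &= trials[resp].notna() & trials[rt].notna() & (trials[rt] >= MIN_RT_MS)
    return ok


def apply_exclusions(
    trials: pd.DataFrame, identity_column: str = "pre_rating"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop invalid trials, then participants violating the validity rules.

    A participant is removed entirely when, within either difficulty
    condition, they (a) gave one identical response (``identity_column``,
    default the pre-rating) on every valid trial, or (b) retained fewer than
    18 valid trials.  Returns the kept trials and a per-participant report
    with counts and the applicable exclusion reasons.
    """
    if trials.empty:
        return trials.copy(), pd.DataFrame(
            columns=["participant_id", "n_trials", "n_invalid_trials",
                     "n_valid_easy", "n_valid_hard", "excluded", "reasons"])
    valid = trial_validity(trials)
    kept_trials = trials[valid]
    rows = []
    keep_pids = []
    for pid, sub in trials.groupby("participant_id", sort=True):
        sub_valid = kept_trials[kept_trials["participant_id"] == pid]
        reasons = []
        n_by_diff = {}
        for diff in ("easy", "hard"):
            cell = sub_valid[sub_valid["difficulty"] == diff]
            n_by_diff[diff] = len(cell)
            if len(cell) < MIN_VALID_TRIALS:
                reasons.append(f"fewer than {MIN_VALID_TRIALS} valid {diff} trials")
            elif cell[identity_column].nunique() == 1:
                reasons.append(f"identical {identity_column} on all valid {diff} trials")
        excluded = bool(reasons)
        if not excluded:
            keep_pids.append(pid)
        rows.append({
            "participant_id": pid,
            "n_trials": len(sub),
            "n_invalid_trials": int(len(sub) - len(sub_valid)),
            "n_valid_easy": n_by_diff["easy"],
            "n_valid_hard": n_by_diff["hard"],
            "excluded": excluded,
            "reasons": "; ".join(reasons),
        })
    report = pd.DataFrame(rows)
    kept = kept_trials[kept_trials["participant_id"].isin(keep_pids)].copy()
    return kept, report


def _correct(trials: pd.DataFrame) -> pd.Series:
    return trials["type1_response"] == trials["stimulus"]


def summarize_participants(trials: pd.DataFrame) -> pd.DataFrame:
    """Per (participant, difficulty): accuracy, d', total score, mean ratings.

    Expects exclusions to have been applied.  d' comes from the type-1
    margins of the pre-rating contingency table (edge-corrected); the score
    sums the wagering payoff over valid trials.
    """
    trials = trials.copy()
    trials["correct"] = _correct(trials)
    rows = []
    for (pid, instr, diff), sub in trials.groupby(
        ["participant_id", "instruction", "difficulty"], sort=True
    ):
        counts = RatingCounts.from_trials(
            sub["stimulus"].to_numpy(),
            sub["type1_response"].to_numpy(),
            sub["pre_rating"].to_numpy(dtype=np.int64),
            k=2,
        )
        t1 = compute_type1_sdt(counts)
        score = int(sum(
            compute_trial_score(r, c)
            for r, c in zip(sub["pre_rating"], sub["correct"])
        ))
        rows.append({
            "participant_id": pid,
            "instruction": instr,
            "difficulty": diff,
            "n_valid_trials": len(sub),
            "accuracy": float(sub["correct"].mean()),
            "d_prime": t1.d_prime,
            "criterion": t1.criterion,
            "total_score": score,
            "mean_pre_rating": float(sub["pre_rating"].astype(float).mean()),
            "mean_post_rating": float(sub["post_rating"].astype(float).mean()),
        })
    return pd.DataFrame(rows)


def mixed_anova(values: pd.DataFrame, dv: str = "value") -> pd.DataFrame:
    """Two-way mixed ANOVA (instruction between, difficulty within).

    ``values`` needs columns ``participant_id``, ``instruction``,
    ``difficulty`` and the dependent variable ``dv``, one row per
    participant x difficulty.  Returns one row per effect with F, degrees of
    freedom, p, and generalized eta squared (Olejnik-Algina, with the
    participant variance components in the denominator).
    """
    counts = values.groupby("participant_id")["difficulty"].nunique()
    bad = counts[counts != 2]
    if len(bad):
        raise ValueError(
            f"participant(s) missing a difficulty cell: {list(bad.index)[:5]}"
        )
    if values.groupby("instruction")["participant_id"].nunique().min() < 2:
        raise ValueError("need >=2 participants per instruction group")
    n = values["participant_id"].nunique()
    if np.ptp(values[dv].to_numpy(dtype=float)) == 0.0:
        # perfectly constant data: every effect SS is exactly zero
        return pd.DataFrame([
            {"effect": e, "F": 0.0, "df1": 1, "df2": n - 2, "p": 1.0, "eta_g": 0.0}
            for e in ("instruction", "difficulty", "interaction")
        ])
    aov = pg.mixed_anova(
        data=values, dv=dv, within="difficulty", subject="participant_id",
        between="instruction", effsize="ng2",
    )
    name_map = {"instruction": "instruction", "difficulty": "difficulty",
                "Interaction": "interaction"}
    p_col = "p-unc" if "p-unc" in aov.columns else "p_unc"
    out = []
    for _, row in aov.iterrows():
        f, p, eta = float(row["F"]), float(row[p_col]), float(row["ng2"])
        if not np.isfinite(f) and float(row["SS"]) == 0.0:
            # degenerate 0/0 when the effect's sum of squares vanishes
            f, p, eta = 0.0, 1.0, 0.0
        out.append({
            "effect": name_map[row["Source"]],
            "F": f,
            "df1": int(row["DF1"]),
            "df2": int(row["DF2"]),
            "p": p,
            "eta_g": eta,
        })
    return pd.DataFrame(out)


def paired_t_with_bf(
    x: np.ndarray, y: np.ndarray, cauchy_scale: float = np.sqrt(2) / 2
) -> dict:
    """Paired t-test with Cohen's d and the JZS Bayes factor.

    BF10 uses the default Jeffreys-Zellner-Siow prior (Cauchy on the
    standardized effect, scale sqrt(2)/2) evaluated by one-dimensional
    numerical integration.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences; t statistic undefined")
    res = stats.ttest_rel(x, y)
    bf10 = float(pg.bayesfactor_ttest(float(res.statistic), nx=n, paired=True,
                                      r=cauchy_scale))
    return {
        "t": float(res.statistic),
        "df": n - 1,
        "p": float(res.pvalue),
        "cohen_d": float(diff.mean() / sd),
        "bf10": bf10,
    }


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    return multipletests(np.asarray(p_values, float), method="holm")[1]


def levene_holm(values: pd.DataFrame, dv: str = "value") -> pd.DataFrame:
    """Levene's test of instruction-group variance per difficulty, Holm-corrected.

    ``values`` holds one participant-level number per row (columns
    ``participant_id``, ``instruction``, ``difficulty``, ``dv``); the test
    uses absolute deviations from the group mean (original Levene), and the
    two per-difficulty p-values are jointly Holm-adjusted.
    """
    rows = []
    for diff in ("easy", "hard"):
        sub = values[values["difficulty"] == diff]
        groups = [g[dv].to_numpy(dtype=float)
                  for _, g in sub.groupby("instruction", sort=True)]
        if len(groups) != 2 or min(len(g) for g in groups) < 2:
            raise ValueError(f"need two instruction groups with >=2 participants ({diff})")
        if all(np.ptp(g) == 0 for g in groups):
            raise ValueError(f"all values identical within both groups ({diff})")
        w, p = stats.levene(*groups, center="mean")
        rows.append({"difficulty": diff, "W": float(w),
                     "df1": 1, "df2": int(sum(len(g) for g in groups) - 2),
                     "p": float(p)})
    out = pd.DataFrame(rows)
    out["adjusted_p"] = holm_adjust(out["p"].to_numpy())
    return out


def post_by_pre_level(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean post-rating within each pre-rating level.

    Only participants who used both pre-rating levels contribute; the result
    feeds the paired t-test of post-rating (high vs low pre-rating).
    """
    means = (
        trials.groupby(["participant_id", "pre_rating"])["post_rating"]
        .mean().unstack()
    )
    means = means.dropna()
    if means.shape[1] != 2:
        raise ValueError("need both pre-rating levels present in the data")
    means.columns = ["post_low", "post_high"]
    return means.reset_index()
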