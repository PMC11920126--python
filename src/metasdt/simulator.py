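"""Generative observer for the auditory delayed match-to-sample task.

Each simulated trial presents a match or nonmatch probe; a type-1 evidence
sample ``x ~ Normal(+-d'/2, 1)`` drives the match/nonmatch response through a
criterion.  Metacognitive evidence is a degraded copy of the same sample,
``y = x + noise``: the prospective pre-rating (binary bet / memory belief)
and the retrospective 5-point post-rating threshold ``y`` relative to the
response side.  The amount of metacognitive degradation per participant and
condition is solved numerically so that the *asymptotic* fitted
meta-d'/d' equals a target M-ratio drawn from a two-way mixed linear model
on the M-ratio scale (instruction between participants, difficulty within).

Super-optimal efficiency (M-ratio > 1) is supported by adding
stimulus-locked signal to ``y`` instead of noise; requesting it triggers a
warning because it implies metacognition outperforming the decision itself.

Task structure follows the behavioral design: two instruction groups
(bet N=104, confidence N=100), six sessions of 12 trials, difficulty blocked
in session halves and counterbalanced across participants, equal match /
nonmatch base rates.  Difficulty acts solely through per-condition d',
calibrated so unbiased accuracy is ~70% (easy) and ~60% (hard).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri
from scipy.stats import multivariate_normal

from .sdt import _fit_meta_d

PRE_K = 2
POST_K = 5


@dataclass(frozen=True)
class PhaseEffects:
    """Two-way mixed linear model on M-ratio for one rating phase.

    Instruction is effect-coded +0.5 for the confidence group, difficulty
    +0.5 for the hard condition, so each beta is a full cell difference in
    M-ratio units (e.g. ``instruction = -0.3`` means the confidence group's
    M-ratio is 0.3 lower).
    """

    mean: float
    instruction: float
    difficulty: float
    interaction: float
    sigma_participant: float = 0.2
    sigma_cell: float = 0.1

    def cell_mean(self, x_instruction: float, x_difficulty: float) -> float:
        return (
            self.mean
            + self.instruction * x_instruction
            + self.difficulty * x_difficulty
            + self.interaction * x_instruction * x_difficulty
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one simulated cohort.

    ``d_prime_easy``/``d_prime_hard`` default to values calibrated so an
    unbiased observer scores ~70% / ~60% correct.  ``seed`` is mandatory:
    the dataset is a pure function of the config.
    """

    seed: int
    n_bet: int = 104
    n_confidence: int = 100
    sessions: int = 6
    trials_per_session: int = 12
    target_accuracy_easy: float = 0.70
    target_accuracy_hard: float = 0.60
    d_prime_easy: float | None = None
    d_prime_hard: float | None = None
    criterion: float = 0.0
    pre_effects: PhaseEffects = field(
        default_factory=lambda: PhaseEffects(mean=0.75, instruction=-0.35,
                                             difficulty=0.0, interaction=0.0)
    )
    post_effects: PhaseEffects = field(
        default_factory=lambda: PhaseEffects(mean=0.75, instruction=-0.2,
                                             difficulty=-0.25, interaction=0.0)
    )
    pre_threshold: float = 0.6
    post_thresholds: tuple[float, ...] = (0.4, 0.8, 1.2, 1.6)
    meta_noise_corr: float = 0.3
    p_match: float = 0.5
    lapse_rate: float = 0.02
    rt_median_ms: float = 800.0
    rt_sigma: float = 0.4
    fast_rt_max_ms: float = 99.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("p_match", "lapse_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for eff in (self.pre_effects, self.post_effects):
            if eff.sigma_participant < 0 or eff.sigma_cell < 0:
                raise ValueError("dispersion parameters must be non-negative")
        if not -1.0 <= self.meta_noise_corr <= 1.0:
            raise ValueError("meta_noise_corr must lie in [-1, 1]")

    def resolved_d_primes(self) -> tuple[float, float]:
        """(easy, hard) d', calibrating from target accuracies when unset."""
        easy = self.d_prime_easy
        hard = self.d_prime_hard
        if easy is None:
            easy = calibrate_dprime(self.target_accuracy_easy, self.criterion)
        if hard is None:
            hard = calibrate_dprime(self.target_accuracy_hard, self.criterion)
        if easy <= 0 or hard <= 0:
            raise ValueError("per-difficulty d' must be positive")
        return float(easy), float(hard)


@dataclass(frozen=True)
class GroundTruth:
    """Generative record for recovery tests; regenerable from (config, seed)."""

    config: SimulationConfig
    cells: pd.DataFrame  # one row per participant x difficulty

    def to_json(self, path) -> None:
        payload = {
            "config": _config_to_dict(self.config),
            "cells": self.cells.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["post_thresholds"] = list(config.post_thresholds)
    return d


def calibrate_dprime(target_accuracy: float, criterion: float = 0.0) -> float:
    """d' at which the expected accuracy of a fixed-criterion observer
    (equal match/nonmatch base rates) equals ``target_accuracy``.

    For an unbiased criterion, accuracy = Phi(d'/2), so the solution is
    ``2 * Phi^-1(accuracy)``.
    """
    if not 0.5 < target_accuracy < 1.0:
        raise ValueError(
            f"target accuracy must lie in (0.5, 1), got {target_accuracy}"
        )

    def acc(d: float) -> float:
        return 0.5 * (ndtr(d / 2 - criterion) + ndtr(d / 2 + criterion))

    if criterion == 0.0:
        return float(2.0 * ndtri(target_accuracy))
    return float(brentq(lambda d: acc(d) - target_accuracy, 1e-9, 20.0))


# ---------------------------------------------------------------------------
# Metacognitive-noise calibration
# ---------------------------------------------------------------------------

def _rect_prob(mean: np.ndarray, cov: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> float:
    """P(lo < (x, y) < hi) for a bivariate normal, clipping infinite bounds."""
    sd = np.sqrt(np.diag(cov))
    lo = np.maximum(lo, mean - 10 * sd)
    hi = np.minimum(hi, mean + 10 * sd)
    if np.any(hi <= lo):
        return 0.0
    return float(multivariate_normal.cdf(hi, mean=mean, cov=cov, lower_limit=lo))


def _expected_joint_probs(
    d: float, c: float, nu: float, thresholds: tuple[float, ...]
) -> np.ndarray:
    """Exact joint P(stimulus, response, rating) under the generative observer.

    ``nu >= 0`` adds Gaussian noise of SD ``nu`` to the metacognitive sample;
    ``nu < 0`` adds stimulus-locked signal (boost ``-nu``), the super-optimal
    regime.  Ratings bin ``z = sign(response) * (y - c)`` at ``thresholds``.
    """
    th = np.asarray(thresholds, float)
    k = th.size + 1
    edges = np.concatenate([[-np.inf], th, [np.inf]])
    sigma = max(nu, 0.0)
    boost = max(-nu, 0.0)
    out = np.zeros((2, 2, k))
    for s_idx, t in ((0, -1.0), (1, 1.0)):
        mx = t * d / 2.0
        my = t * d / 2.0 * (1.0 + boost)
        for r_idx in (0, 1):
            x_lo, x_hi = (c, np.inf) if r_idx == 1 else (-np.inf, c)
            for ki in range(k):
                z_lo, z_hi = edges[ki], edges[ki + 1]
                if r_idx == 1:
                    y_lo, y_hi = c + z_lo, c + z_hi
                else:
                    y_lo, y_hi = c - z_hi, c - z_lo
                if sigma < 1e-9:
                    # degenerate: y = x + boost term, a 1-D interval intersection
                    lo = max(x_lo, y_lo - (my - mx))
                    hi = min(x_hi, y_hi - (my - mx))
                    p = max(ndtr(min(hi - mx, 10)) - ndtr(max(lo - mx, -10)), 0.0) \
                        if hi > lo else 0.0
                else:
                    cov = np.array([[1.0, 1.0], [1.0, 1.0 + sigma**2]])
                    p = _rect_prob(
                        np.array([mx, my]), cov,
                        np.array([x_lo, y_lo]), np.array([x_hi, y_hi]),
                    )
                out[s_idx, r_idx, ki] = 0.5 * p
    # guard tiny negative round-off from the MVN integrator
    return np.clip(out, 0.0, None)


def _asymptotic_m_ratio(
    d: float, c: float, nu: float, thresholds: tuple[float, ...]
) -> float:
    """M-ratio that the MLE recovers in the infinite-trial limit."""
    probs = _expected_joint_probs(d, c, nu, thresholds)
    hr = probs[1, 1].sum() / probs[1].sum()
    fa = probs[0, 1].sum() / probs[0].sum()
    d_emp = float(ndtri(hr) - ndtri(fa))
    c_emp = float(-0.5 * (ndtri(hr) + ndtri(fa)))
    meta_d, _, _, _ = _fit_meta_d(probs, d_emp, c_emp, len(thresholds) + 1)
    return meta_d / d_emp


_NU_GRID = np.concatenate(
    [np.linspace(-1.5, -0.1, 8), [0.0], np.linspace(0.08, 1.2, 15),
     np.linspace(1.45, 4.0, 9)]
)


@lru_cache(maxsize=64)
def _mratio_curve(
    d: float, c: float, thresholds: tuple[float, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Tabulated (nu, M-ratio) pairs with M decreasing in nu."""
    m = np.array([_asymptotic_m_ratio(d, c, nu, thresholds) for nu in _NU_GRID])
    # enforce strict monotonicity against integrator round-off
    m = np.minimum.accumulate(m)
    return _NU_GRID.copy(), m


def meta_noise_for_mratio(
    m_ratio: float, d: float, c: float, thresholds: tuple[float, ...]
) -> float:
    """Invert the calibration curve: noise parameter nu for a target M-ratio."""
    if m_ratio == 1.0:
        return 0.0  # exact by construction: ratings reuse the decision evidence
    nu_grid, m_grid = _mratio_curve(round(d, 9), round(c, 9), tuple(thresholds))
    m_lo, m_hi = m_grid[-1], m_grid[0]
    target = float(np.clip(m_ratio, m_lo, m_hi))
    # m_grid decreasing -> reverse for np.interp
    return float(np.interp(target, m_grid[::-1], nu_grid[::-1]))


def simulate_rating_counts(
    n_trials: int,
    d_prime: float,
    m_ratio: float | None = None,
    meta_noise: float | None = None,
    criterion: float = 0.0,
    thresholds: tuple[float, ...] = (0.4, 0.8, 1.2, 1.6),
    p_match: float = 0.5,
    seed: int | None = None,
):
    """Rating-count table for one generative observer.

    Exactly one of ``m_ratio`` (inverted through the calibration curve) or
    ``meta_noise`` (the raw noise/boost parameter nu) must be given.  With
    ``m_ratio=1`` the rating thresholds the very evidence sample that drove
    the decision.  Returns a :class:`~metasdt.counts.RatingCounts` with
    ``K = len(thresholds) + 1`` levels.
    """
    from .counts import RatingCounts

    if (m_ratio is None) == (meta_noise is None):
        raise ValueError("give exactly one of m_ratio or meta_noise")
    if seed is None:
        raise ValueError("seed is mandatory")
    nu = (meta_noise if meta_noise is not None
          else meta_noise_for_mratio(m_ratio, d_prime, criterion, tuple(thresholds)))
    rng = np.random.default_rng(seed)
    t = np.where(rng.random(n_trials) < p_match, 1.0, -1.0)
    x = t * d_prime / 2.0 + rng.standard_normal(n_trials)
    resp = x > criterion
    sigma, boost = max(nu, 0.0), max(-nu, 0.0)
    y = x + boost * t * d_prime / 2.0 + sigma * rng.standard_normal(n_trials)
    s = np.where(resp, 1.0, -1.0)
    z = s * (y - criterion)
    th = np.asarray(thresholds)
    rating = 1 + (z[:, None] >= th[None, :]).sum(axis=1)
    return RatingCounts.from_trials(
        (t > 0).astype(int), resp.astype(int), rating, len(thresholds) + 1
    )


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = [
    "participant_id", "instruction", "difficulty", "session", "trial",
    "stimulus", "pre_rating", "type1_response", "post_rating",
    "rt_pre", "rt_answer", "rt_post",
]


def simulate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a full cohort; returns (trial table, ground truth).

    The trial table follows the behavioral CSV schema (one row per trial);
    missing responses are encoded as NA.  Identical configs (including the
    seed) produce byte-identical tables.
    """
    d_easy, d_hard = config.resolved_d_primes()
    _warn_if_superoptimal(config)
    rng = np.random.default_rng(config.seed)

    n_total = config.n_bet + config.n_confidence
    pid = np.array(
        [f"bet_{i + 1:03d}" for i in range(config.n_bet)]
        + [f"conf_{i + 1:03d}" for i in range(config.n_confidence)]
    )
    instruction = np.array(["bet"] * config.n_bet + ["confidence"] * config.n_confidence)
    x_instr = np.where(instruction == "confidence", 0.5, -0.5)
    # difficulty order counterbalanced by participant parity within group
    order_flip = (np.concatenate(
        [np.arange(config.n_bet), np.arange(config.n_confidence)]) % 2 == 1)

    x_diff = np.array([-0.5, 0.5])  # easy, hard
    d_by_diff = np.array([d_easy, d_hard])

    cell_rows = []
    m_target = {}
    for phase, eff in (("pre", config.pre_effects), ("post", config.post_effects)):
        u = rng.normal(0.0, eff.sigma_participant, size=n_total)
        eps = rng.normal(0.0, eff.sigma_cell, size=(n_total, 2))
        fixed = eff.cell_mean(x_instr[:, None], x_diff[None, :])
        # M-ratio below ~0 has no generative counterpart; draws are floored
        m_target[phase] = np.maximum(fixed + u[:, None] + eps, 0.02)

    thresholds = {"pre": (config.pre_threshold,), "post": tuple(config.post_thresholds)}
    nu = {}
    for phase in ("pre", "post"):
        nu_arr = np.empty((n_total, 2))
        for j in range(2):
            for i in range(n_total):
                nu_arr[i, j] = meta_noise_for_mratio(
                    float(m_target[phase][i, j]), d_by_diff[j],
                    config.criterion, thresholds[phase],
                )
        nu[phase] = nu_arr

    for i in range(n_total):
        for j, diff in enumerate(("easy", "hard")):
            cell_rows.append({
                "participant_id": pid[i], "instruction": instruction[i],
                "difficulty": diff, "d_prime": d_by_diff[j],
                "m_ratio_pre": m_target["pre"][i, j],
                "m_ratio_post": m_target["post"][i, j],
                "nu_pre": nu["pre"][i, j], "nu_post": nu["post"][i, j],
            })

    # ---- trial level ----
    spt = config.sessions * config.trials_per_session
    half = config.sessions // 2
    frames = []
    theta_post = np.asarray(config.post_thresholds)
    for i in range(n_total):
        sess = np.repeat(np.arange(1, config.sessions + 1), config.trials_per_session)
        trial_no = np.tile(np.arange(1, config.trials_per_session + 1), config.sessions)
        first_hard = bool(order_flip[i])
        in_second_half = sess > half
        is_hard = in_second_half != first_hard  # first block hard when flipped
        j_idx = is_hard.astype(int)
        d_tr = d_by_diff[j_idx]

        t = np.where(rng.random(spt) < config.p_match, 1.0, -1.0)
        x = t * d_tr / 2.0 + rng.standard_normal(spt)
        resp_match = x > config.criterion
        s = np.where(resp_match, 1.0, -1.0)

        w = rng.standard_normal(spt)
        rho = config.meta_noise_corr
        mix = (np.sqrt(max(rho, 0.0)) * w[:, None]
               + np.sqrt(1.0 - max(rho, 0.0)) * rng.standard_normal((spt, 2)))
        y = {}
        for col, phase in ((0, "pre"), (1, "post")):
            nu_tr = nu[phase][i, j_idx]
            sigma = np.maximum(nu_tr, 0.0)
            boost = np.maximum(-nu_tr, 0.0)
            y[phase] = x + boost * t * d_tr / 2.0 + sigma * mix[:, col]

        z_pre = s * (y["pre"] - config.criterion)
        pre_rating = np.where(z_pre >= config.pre_threshold, 2, 1)
        z_post = s * (y["post"] - config.criterion)
        post_rating = 1 + (z_post[:, None] >= theta_post[None, :]).sum(axis=1)

        rts = rng.lognormal(np.log(config.rt_median_ms), config.rt_sigma, size=(spt, 3))
        lapse = rng.random(spt) < config.lapse_rate
        lapse_slot = rng.integers(0, 3, size=spt)
        lapse_fast = rng.random(spt) < 0.5
        fast_rt = rng.uniform(0.0, config.fast_rt_max_ms, size=spt)

        pre_out = pre_rating.astype(float)
        resp_out = np.where(resp_match, "match", "nonmatch").astype(object)
        post_out = post_rating.astype(float)
        for slot, (resp_col, rt_col) in enumerate(
            ((pre_out, 0), (resp_out, 1), (post_out, 2))
        ):
            hit = lapse & (lapse_slot == slot)
            rts[hit & lapse_fast, rt_col] = fast_rt[hit & lapse_fast]
            miss = hit & ~lapse_fast
            rts[miss, rt_col] = np.nan
            if slot == 1:
                resp_col[miss] = None
            else:
                resp_col[miss] = np.nan

        frames.append(pd.DataFrame({
            "participant_id": pid[i],
            "instruction": instruction[i],
            "difficulty": np.where(is_hard, "hard", "easy"),
            "session": sess,
            "trial": trial_no,
            "stimulus": np.where(t > 0, "match", "nonmatch"),
            "pre_rating": pre_out,
            "type1_response": resp_out,
            "post_rating": post_out,
            "rt_pre": rts[:, 0],
            "rt_answer": rts[:, 1],
            "rt_post": rts[:, 2],
        }))

    trials = pd.concat(frames, ignore_index=True)
    trials["pre_rating"] = trials["pre_rating"].astype("Int64")
    trials["post_rating"] = trials["post_rating"].astype("Int64")
    truth = GroundTruth(config=config, cells=pd.DataFrame(cell_rows))
    return trials, truth


def _warn_if_superoptimal(config: SimulationConfig) -> None:
    for phase, eff in (("pre", config.pre_effects), ("post", config.post_effects)):
        cell_means = [
            eff.cell_mean(xi, xd) for xi in (-0.5, 0.5) for xd in (-0.5, 0.5)
        ]
        if max(cell_means) > 1:
            warnings.warn(
                f"{phase}-phase configuration targets M-ratio > 1 in at least one "
                "design cell (super-optimal metacognition)",
                UserWarning,
                stacklevel=3,
            )
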