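"""Hierarchical Bayesian estimation of M-ratio under a two-way mixed design.

Per participant ``s`` (instruction group between participants) and
difficulty condition ``c`` (within participants), the observed rating counts
follow the response-conditional type-2 multinomial likelihood of
:mod:`metasdt.sdt` with

    meta-d'_{s,c} = m_{s,c} * d'_{s,c},

type-1 ``d'`` and criterion fixed at their (stabilized) per-cell point
estimates, and a linear model on the M-ratio scale

    m_{s,c} = mu + b_I x_I(s) + b_D x_D(c) + b_ID x_I x_D + u_s + eps_{s,c},

with effect coding ``x_I = +0.5`` for the confidence group, ``x_D = +0.5``
for the hard condition, a participant random intercept ``u_s ~ N(0, s_u^2)``
and cell-level noise ``eps ~ N(0, s_e^2)``.  ``m`` is deliberately left
unbounded: at a few dozen trials per cell the type-2 signal of some cells is
negative by sampling noise, and forcing M-ratio positive (e.g. through a log
link) turns that noise into a one-sided pile-up that biases the group mean.
Priors: ``mu ~ N(0.5, 1)``, ``b ~ N(0, 1)``, ``s_u, s_e ~ HalfNormal(1)``;
per-cell type-2 criterion log-increments are partially pooled toward an
instruction x difficulty group mean with ``HalfNormal(0.5)`` spread.

Sampling is Metropolis-within-Gibbs: the per-cell M-ratios and type-2
criteria take vectorized adaptive random-walk Metropolis steps against the
multinomial likelihood, while ``u_s``, the fixed effects, the criterion
group means and (via log-scale Metropolis steps) the dispersion parameters
are updated from their full conditionals.  The two difficulty-level d'
values are treated as errors-in-variables nuisances shared across
instruction groups (see ``_shrink_type1``).  Proposal scales adapt only
during burn-in.
Effects are summarized by the posterior median, the 95% highest-density
interval, the probability of direction, rank-normalized split R-hat and tail
effective sample size; an effect is declared present when the HDI excludes
zero and pd exceeds 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .counts import RatingCounts
from .sdt import _type2_loglik

EFFECT_NAMES = ("instruction", "difficulty", "interaction")
_CRIT_PRIOR_MEAN = np.log(0.5)
_CRIT_PRIOR_SD = 1.0
_BETA_PRIOR_MEAN = np.array([0.5, 0.0, 0.0, 0.0])  # weakly centers mu mid-range


@dataclass(frozen=True)
class CellAssignment:
    """One participant x difficulty cell of the design."""

    participant_id: str
    instruction: str  # "bet" | "confidence"
    difficulty: str  # "easy" | "hard"
    counts: RatingCounts
    d_prime: float
    criterion: float


@dataclass(frozen=True)
class PosteriorSamples:
    """Posterior draws, shaped (chains, retained iterations) per parameter.

    ``draws`` maps parameter names (``mu``, ``beta_instruction``,
    ``beta_difficulty``, ``beta_interaction``, ``sigma_participant``,
    ``sigma_cell``, ``sigma_criteria``) to (chains, draws) arrays;
    ``cell_m_ratio`` has shape (chains, draws, n_participants, 2) and
    ``participant_intercept`` (chains, draws, n_participants).
    """

    draws: dict[str, np.ndarray]
    phase: str
    participant_ids: tuple[str, ...]
    accept_rates: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws["mu"].shape[0]

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)


@dataclass(frozen=True)
class EffectSummary:
    """Posterior summary of one design effect."""

    effect: str
    median: float
    hdi_low: float
    hdi_high: float
    pd: float
    rhat: float
    ess_tail: float
    decision: str  # "effect" | "no-effect"
    converged: bool


def compute_hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws."""
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must lie in (0, 1), got {mass}")
    x = np.sort(np.asarray(draws, float).ravel())
    n = x.size
    if n < 100:
        raise ValueError(f"need at least 100 draws for an HDI, got {n}")
    m = int(np.ceil(mass * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def compute_pd(draws: np.ndarray) -> float:
    """Probability of direction: posterior mass on the dominant side of zero."""
    x = np.asarray(draws, float).ravel()
    if x.size == 0:
        raise ValueError("cannot compute pd of an empty sample")
    p_zero = np.mean(x == 0)
    p_pos = np.mean(x > 0) + 0.5 * p_zero
    return float(max(p_pos, 1.0 - p_pos))


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _prepare(cells: list[CellAssignment]):
    by_pid: dict[str, dict[str, CellAssignment]] = {}
    for cell in cells:
        if cell.difficulty not in ("easy", "hard"):
            raise ValueError(f"unknown difficulty {cell.difficulty!r}")
        if cell.instruction not in ("bet", "confidence"):
            raise ValueError(f"unknown instruction {cell.instruction!r}")
        if not np.isfinite(cell.d_prime):
            raise ValueError(
                f"non-finite d' in cell ({cell.participant_id}, {cell.difficulty})"
            )
        by_pid.setdefault(cell.participant_id, {})[cell.difficulty] = cell
    pids = sorted(by_pid)
    for pid in pids:
        have = by_pid[pid]
        if set(have) != {"easy", "hard"}:
            raise ValueError(f"participant {pid} lacks one difficulty cell")
        if have["easy"].instruction != have["hard"].instruction:
            raise ValueError(f"participant {pid} has inconsistent instruction labels")
    n_groups = {g: sum(by_pid[p]["easy"].instruction == g for p in pids)
                for g in ("bet", "confidence")}
    if min(n_groups.values()) < 2:
        raise ValueError(f"need >=2 participants per instruction group, got {n_groups}")

    k = by_pid[pids[0]]["easy"].counts.k
    P = len(pids)
    counts = np.empty((P, 2, 2, 2, k))
    d = np.empty((P, 2))
    c = np.empty((P, 2))
    x_i = np.empty(P)
    for i, pid in enumerate(pids):
        for j, diff in enumerate(("easy", "hard")):
            cell = by_pid[pid][diff]
            if cell.counts.k != k:
                raise ValueError("all cells must share the same rating granularity")
            counts[i, j] = cell.counts.counts
            d[i, j] = cell.d_prime
            c[i, j] = cell.criterion
        x_i[i] = 0.5 if by_pid[pid]["easy"].instruction == "confidence" else -0.5
    x_d = np.array([-0.5, 0.5])
    return pids, counts, d, c, x_i, x_d, k


def _type1_sampling_vars(counts: np.ndarray, k: int) -> tuple[float, float]:
    """Delta-method variances of the edge-corrected (d', c) estimates."""
    from scipy.stats import norm

    adj = counts + 1.0 / (2 * k)
    n1, n2 = adj[0].sum(), adj[1].sum()
    fa = adj[0, 1].sum() / n1
    hr = adj[1, 1].sum() / n2
    v_zh = hr * (1 - hr) / (n2 * norm.pdf(norm.ppf(hr)) ** 2)
    v_zf = fa * (1 - fa) / (n1 * norm.pdf(norm.ppf(fa)) ** 2)
    return float(v_zh + v_zf), float(0.25 * (v_zh + v_zf))


def _eb_shrink(est: np.ndarray, noise: np.ndarray) -> np.ndarray:
    """James-Stein style shrinkage toward the mean of one estimate group."""
    var_between = max(est.var(ddof=1) - noise.mean(), 0.0)
    w = var_between / (var_between + noise)
    return est.mean() + w * (est - est.mean())


def _shrink_type1(
    d: np.ndarray, c: np.ndarray, counts: np.ndarray, x_i: np.ndarray, k: int,
    floor: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical-Bayes stabilization of the fixed per-cell type-1 estimates.

    At a few dozen trials per cell the raw d' in the M-ratio denominator is
    noisy enough to sit near zero or below, which makes the per-cell M-ratio
    explode, and the raw criterion misplaces the anchor of the type-2
    criteria.  Within each instruction x difficulty cell of the design both
    estimates are shrunk toward their group mean with weights from the usual
    variance decomposition (between-participant variance over total), and d'
    is floored at a small positive value.  Groups are never pooled across
    instructions, so group contrasts cannot leak.

    Also returns, per difficulty, the standard error of the cohort-level d'
    (pooled over both instruction groups, which share the stimuli and hence
    the true d'): the shrinkage targets are noisy means whose error moves
    every cell of a difficulty coherently, so the sampler treats the two
    difficulty-level d' values as errors-in-variables nuisances with these
    SEs as prior scales.  The offsets are deliberately shared across
    instruction groups: a shared nuisance cannot absorb a group contrast.
    """
    d_out, c_out = d.copy(), c.copy()
    v_d = np.empty_like(d)
    v_c = np.empty_like(c)
    for i in range(d.shape[0]):
        for j in range(2):
            v_d[i, j], v_c[i, j] = _type1_sampling_vars(counts[i, j], k)
    for group in (-0.5, 0.5):
        rows = x_i == group
        if not rows.any():
            continue
        for j in range(2):
            d_out[rows, j] = _eb_shrink(d[rows, j], v_d[rows, j])
            c_out[rows, j] = _eb_shrink(c[rows, j], v_c[rows, j])
    d_se = np.sqrt(v_d.mean(axis=0) / d.shape[0])  # (2,) per difficulty
    return np.maximum(d_out, floor), c_out, d_se


def _cell_loglik(counts, d, c, m_ratio, a, k):
    """Vectorized type-2 log-likelihood per cell, shape (P, 2).

    ``a`` holds log-increments of the type-2 criteria away from the scaled
    criterion, shape (P, 2, 2(K-1)): first K-1 entries step downward
    (nonmatch side), last K-1 upward (match side).
    """
    meta_d = m_ratio * d
    cprime = c * m_ratio
    inc = np.exp(a)
    km1 = k - 1
    t_n = cprime[..., None] - np.cumsum(inc[..., :km1], axis=-1)
    t_m = cprime[..., None] + np.cumsum(inc[..., km1:], axis=-1)
    return _type2_loglik(counts, meta_d, cprime, t_n, t_m)


def fit_hierarchical_mratio(
    cells: list[CellAssignment],
    phase: str,
    chains: int = 3,
    iterations: int = 10_000,
    burnin: int = 1_000,
    seed: int | None = None,
    stabilize_type1: str = "shrink",
    metropolis_sweeps: int = 3,
) -> PosteriorSamples:
    """Sample the joint posterior of the two-way mixed model on log M-ratio.

    ``iterations`` counts total MCMC iterations per chain, of which the first
    ``burnin`` are discarded (and used for proposal adaptation).  ``seed`` is
    required; given identical data and seed the draws are bit-identical.
    ``stabilize_type1="shrink"`` (default) applies empirical-Bayes shrinkage
    to the fixed per-cell d' estimates (see :func:`_shrink_dprimes`);
    ``"none"`` uses the raw per-cell values.
    """
    if seed is None:
        raise ValueError("seed must be provided (reproducibility contract)")
    if burnin >= iterations:
        raise ValueError("burnin must be smaller than iterations")
    pids, counts, d, c, x_i, x_d, k = _prepare(cells)
    d_se = None
    if stabilize_type1 == "shrink":
        d, c, d_se = _shrink_type1(d, c, counts, x_i, k)
    elif stabilize_type1 == "none":
        if (d == 0).any():
            i, j = map(int, np.argwhere(d == 0)[0])
            raise ValueError(
                f"zero d' in cell ({pids[i]}, {('easy', 'hard')[j]}); "
                "meta-d' is not identified without type-1 stabilization"
            )
    else:
        raise ValueError(f"unknown stabilize_type1 policy {stabilize_type1!r}")
    P = counts.shape[0]
    km1 = k - 1
    n_keep = iterations - burnin

    # design matrix for (mu, b_I, b_D, b_ID) over the 2P cells
    XI = np.broadcast_to(x_i[:, None], (P, 2))
    XD = np.broadcast_to(x_d[None, :], (P, 2))
    X = np.stack([np.ones((P, 2)), XI, XD, XI * XD], axis=-1).reshape(-1, 4)
    XtX = X.T @ X

    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(chains)

    out = {name: np.empty((chains, n_keep)) for name in
           ("mu", "beta_instruction", "beta_difficulty", "beta_interaction",
            "sigma_participant", "sigma_cell", "sigma_criteria")}
    out["cell_m_ratio"] = np.empty((chains, n_keep, P, 2))
    out["participant_intercept"] = np.empty((chains, n_keep, P))
    acc_tot = {"lambda": 0.0, "criteria": 0.0}

    gi_idx = (x_i > 0).astype(int)  # 0 = bet, 1 = confidence
    n_group = np.bincount(gi_idx, minlength=2)
    M = 2 * km1
    se_j = d_se  # (2,) per difficulty, or None

    for ch in range(chains):
        rng = np.random.default_rng(chain_seeds[ch])
        lam = rng.normal(0.7, 0.1, size=(P, 2))
        a = rng.normal(_CRIT_PRIOR_MEAN, 0.1, size=(P, 2, M))
        A = rng.normal(_CRIT_PRIOR_MEAN, 0.1, size=(2, 2, M))
        u = np.zeros(P)
        beta = np.zeros(4)
        sig_u, sig_e, sig_a = 0.3, 0.2, 0.2
        s_lam = np.full((P, 2), 0.4)
        s_a = np.full((P, 2), 0.3)
        s_sig = np.array([0.3, 0.3, 0.3])  # log-scale proposals: sig_e, sig_u, sig_a
        s_shift_u = np.full(P, 0.2)
        s_shift_b = np.full(4, 0.1)
        delta_d = np.zeros(2)
        s_delta = se_j.copy() if se_j is not None else None
        acc_delta = np.zeros(2)
        d_cur = d.copy()

        ll = _cell_loglik(counts, d_cur, c, lam, a, k)
        acc_lam = np.zeros((P, 2))
        acc_a = np.zeros((P, 2))
        acc_sig = np.zeros(3)
        acc_shift_u = np.zeros(P)
        acc_shift_b = np.zeros(4)
        window = 25
        X_cols = X.reshape(P, 2, 4)

        for it in range(iterations):
            if it == burnin:  # accept-rate bookkeeping for the retained phase
                acc_lam[:] = 0
                acc_a[:] = 0
                acc_sig[:] = 0
                acc_shift_u[:] = 0
                acc_shift_b[:] = 0
            mean_lam = (X @ beta).reshape(P, 2) + u[:, None]

            for _ in range(metropolis_sweeps):
                # --- per-cell log M-ratio: vectorized random-walk Metropolis
                lam_prop = lam + s_lam * rng.standard_normal((P, 2))
                ll_prop = _cell_loglik(counts, d_cur, c, lam_prop, a, k)
                log_alpha = (ll_prop - ll
                             + 0.5 * ((lam - mean_lam) ** 2
                                      - (lam_prop - mean_lam) ** 2) / sig_e**2)
                accept = np.log(rng.random((P, 2))) < log_alpha
                lam = np.where(accept, lam_prop, lam)
                ll = np.where(accept, ll_prop, ll)
                acc_lam += accept

                # --- type-2 criteria increments: joint per-cell Metropolis,
                #     partially pooled toward their instruction x difficulty mean
                A_cell = A[gi_idx]  # (P, 2, M)
                a_prop = a + s_a[..., None] * rng.standard_normal(a.shape)
                ll_prop = _cell_loglik(counts, d_cur, c, lam, a_prop, k)
                prior_diff = 0.5 * (
                    ((a - A_cell) ** 2).sum(axis=-1)
                    - ((a_prop - A_cell) ** 2).sum(axis=-1)
                ) / sig_a**2
                log_alpha = ll_prop - ll + prior_diff
                accept = np.log(rng.random((P, 2))) < log_alpha
                a = np.where(accept[..., None], a_prop, a)
                ll = np.where(accept, ll_prop, ll)
                acc_a += accept

            # --- criterion group means: conjugate normal update
            for g in (0, 1):
                rows = gi_idx == g
                n_g = n_group[g]
                prec = n_g / sig_a**2 + 1.0 / _CRIT_PRIOR_SD**2
                mean_A = (a[rows].sum(axis=0) / sig_a**2
                          + _CRIT_PRIOR_MEAN / _CRIT_PRIOR_SD**2) / prec
                A[g] = mean_A + rng.standard_normal((2, M)) / np.sqrt(prec)

            # --- participant intercepts: conjugate normal update
            resid = lam - (X @ beta).reshape(P, 2)
            prec = 2.0 / sig_e**2 + 1.0 / sig_u**2
            mean_u = (resid.sum(axis=1) / sig_e**2) / prec
            u = mean_u + rng.standard_normal(P) / np.sqrt(prec)

            # --- fixed effects: conjugate multivariate normal (prior N(0,1))
            y = (lam - u[:, None]).reshape(-1)
            prec_mat = XtX / sig_e**2 + np.eye(4)
            chol = np.linalg.cholesky(prec_mat)
            rhs = X.T @ y / sig_e**2 + _BETA_PRIOR_MEAN
            mean_beta = np.linalg.solve(prec_mat, rhs)
            z = rng.standard_normal(4)
            beta = mean_beta + np.linalg.solve(chol.T, z)

            # --- blocked location moves along the slow hierarchical directions:
            # shift a participant's intercept together with both of their cell
            # M-ratios (residuals invariant), then each fixed effect together
            # with every cell it loads on
            delta = s_shift_u * rng.standard_normal(P)
            lam_prop = lam + delta[:, None]
            ll_prop = _cell_loglik(counts, d_cur, c, lam_prop, a, k)
            u_prop = u + delta
            log_alpha = ((ll_prop - ll).sum(axis=1)
                         + (u**2 - u_prop**2) / (2 * sig_u**2))
            accept = np.log(rng.random(P)) < log_alpha
            lam = np.where(accept[:, None], lam_prop, lam)
            ll = np.where(accept[:, None], ll_prop, ll)
            u = np.where(accept, u_prop, u)
            acc_shift_u += accept

            for col in range(4):
                delta = s_shift_b[col] * rng.standard_normal()
                lam_prop = lam + delta * X_cols[:, :, col]
                ll_prop = _cell_loglik(counts, d_cur, c, lam_prop, a, k)
                b_new = beta[col] + delta
                prior_diff = ((beta[col] - _BETA_PRIOR_MEAN[col]) ** 2
                              - (b_new - _BETA_PRIOR_MEAN[col]) ** 2) / 2.0
                if np.log(rng.random()) < (ll_prop - ll).sum() + prior_diff:
                    lam = lam_prop
                    ll = ll_prop
                    beta[col] = b_new
                    acc_shift_b[col] += 1

            # --- errors-in-variables step for the stabilized d' levels: the
            # shrinkage target per difficulty is a noisy cohort mean whose
            # error shifts every cell of that difficulty coherently, so it is
            # sampled (shared across instruction groups, which cannot then
            # absorb a group contrast) with its estimated SE as prior
            if se_j is not None:
                for j in (0, 1):
                    prop = delta_d[j] + s_delta[j] * rng.standard_normal()
                    d_col = d[:, j] + prop
                    if (d_col < 0.02).any():
                        continue
                    ll_prop = _cell_loglik(
                        counts[:, j:j + 1], d_col[:, None], c[:, j:j + 1],
                        lam[:, j:j + 1], a[:, j:j + 1], k,
                    )
                    log_alpha = (float(ll_prop.sum() - ll[:, j].sum())
                                 + (delta_d[j] ** 2 - prop ** 2)
                                 / (2 * se_j[j] ** 2))
                    if np.log(rng.random()) < log_alpha:
                        delta_d[j] = prop
                        d_cur[:, j] = d_col
                        ll[:, j] = ll_prop[:, 0]
                        acc_delta[j] += 1

            # --- dispersions: log-scale Metropolis with half-normal priors
            resid2 = ((lam - (X @ beta).reshape(P, 2) - u[:, None]) ** 2).sum()
            crit_resid2 = ((a - A[gi_idx]) ** 2).sum()
            updates = []
            for pi, (val, ssq, n_terms, prior_sd) in enumerate((
                (sig_e, resid2, 2 * P, 1.0),
                (sig_u, (u**2).sum(), P, 1.0),
                (sig_a, crit_resid2, 2 * P * M, 0.5),
            )):
                prop = val * np.exp(s_sig[pi] * rng.standard_normal())

                def _lp(s):
                    # likelihood + half-normal prior + log-scale jacobian
                    return (-n_terms * np.log(s) - ssq / (2 * s**2)
                            - s**2 / (2 * prior_sd**2) + np.log(s))

                if np.log(rng.random()) < _lp(prop) - _lp(val):
                    val = prop
                    acc_sig[pi] += 1
                updates.append(val)
            sig_e, sig_u, sig_a = updates

            # --- proposal adaptation (burn-in only)
            if it < burnin and (it + 1) % window == 0:
                s_lam *= np.exp(0.8 * (acc_lam / (window * metropolis_sweeps) - 0.44))
                s_a *= np.exp(0.8 * (acc_a / (window * metropolis_sweeps) - 0.30))
                s_sig *= np.exp(0.8 * (acc_sig / window - 0.44))
                s_shift_u *= np.exp(0.8 * (acc_shift_u / window - 0.44))
                s_shift_b *= np.exp(0.8 * (acc_shift_b / window - 0.44))
                if s_delta is not None:
                    s_delta *= np.exp(0.8 * (acc_delta / window - 0.44))
                    np.clip(s_delta, 1e-4, 1.0, out=s_delta)
                    acc_delta[:] = 0
                np.clip(s_lam, 1e-3, 5.0, out=s_lam)
                np.clip(s_a, 1e-3, 5.0, out=s_a)
                np.clip(s_sig, 1e-3, 5.0, out=s_sig)
                np.clip(s_shift_u, 1e-3, 5.0, out=s_shift_u)
                np.clip(s_shift_b, 1e-3, 5.0, out=s_shift_b)
                acc_lam[:] = 0
                acc_a[:] = 0
                acc_sig[:] = 0
                acc_shift_u[:] = 0
                acc_shift_b[:] = 0

            if it >= burnin:
                j = it - burnin
                out["mu"][ch, j] = beta[0]
                out["beta_instruction"][ch, j] = beta[1]
                out["beta_difficulty"][ch, j] = beta[2]
                out["beta_interaction"][ch, j] = beta[3]
                out["sigma_participant"][ch, j] = sig_u
                out["sigma_cell"][ch, j] = sig_e
                out["sigma_criteria"][ch, j] = sig_a
                out["cell_m_ratio"][ch, j] = lam
                out["participant_intercept"][ch, j] = u

        post_iters = (iterations - burnin) * metropolis_sweeps
        acc_tot["lambda"] += acc_lam.mean() / post_iters / chains
        acc_tot["criteria"] += acc_a.mean() / post_iters / chains

    return PosteriorSamples(
        draws=out, phase=phase, participant_ids=tuple(pids), accept_rates=acc_tot
    )


def summarize_effects(
    samples: PosteriorSamples,
    hdi_mass: float = 0.95,
    pd_threshold: float = 0.95,
    rhat_threshold: float = 1.01,
) -> list[EffectSummary]:
    """Median / HDI / pd / convergence summary for each fixed effect.

    The effect decision follows the preregistered-style rule: "effect" when
    the HDI excludes zero *and* pd exceeds the threshold.  A summary with
    R-hat above ``rhat_threshold`` is still returned but flagged
    non-converged.
    """
    if samples.n_chains < 2:
        raise ValueError("need >=2 chains for split-R-hat diagnostics")
    results = []
    for effect, name in zip(EFFECT_NAMES,
                            ("beta_instruction", "beta_difficulty", "beta_interaction")):
        arr = samples.draws[name]
        pooled = arr.reshape(-1)
        lo, hi = compute_hdi(pooled, hdi_mass)
        pd_val = compute_pd(pooled)
        rhat = float(az.rhat(arr))
        ess_tail = float(az.ess(arr, method="tail"))
        excludes_zero = (lo > 0) or (hi < 0)
        decision = "effect" if (excludes_zero and pd_val > pd_threshold) else "no-effect"
        results.append(EffectSummary(
            effect=effect,
            median=float(np.median(pooled)),
            hdi_low=lo,
            hdi_high=hi,
            pd=pd_val,
            rhat=rhat,
            ess_tail=ess_tail,
            decision=decision,
            converged=bool(rhat < rhat_threshold),
        ))
    return results


def effects_frame(summaries: list[EffectSummary], phase: str) -> pd.DataFrame:
    """Flatten effect summaries into the report-table schema."""
    return pd.DataFrame([
        {
            "phase": phase, "effect": s.effect, "median": s.median,
            "hdi_low": s.hdi_low, "hdi_high": s.hdi_high, "pd": s.pd,
            "rhat": s.rhat, "ess_tail": s.ess_tail, "decision": s.decision,
            "converged": s.converged,
        }
        for s in summaries
    ])
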