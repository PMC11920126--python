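"""Independent reference implementations used only as test oracles.

Everything here is deliberately written from first principles (brute-force
grids, direct quadrature, explicit sums of squares) and shares no code with
the package implementations it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import norm


def grid_meta_d_k2(counts: np.ndarray, d_prime: float, criterion: float,
                   step: float = 0.01, md_range=(-3.0, 3.0),
                   off_max: float = 4.0) -> tuple[float, float]:
    """Exhaustive grid search for the meta-d' MLE on a (2, 2, 2) count table.

    Exploits the fact that, conditional on meta-d', the likelihood separates
    into a "nonmatch"-response part (depending only on the lower criterion)
    and a "match" part (only the upper criterion), so each can be maximized
    on an independent 1-D offset grid.  Returns (meta_d, log-likelihood).
    """
    counts = np.asarray(counts, float)
    offs = np.arange(step / 2, off_max, step)
    mds = np.arange(md_range[0], md_range[1] + 1e-9, step)
    best_ll, best_md = -np.inf, None
    eps = 1e-12
    for md in mds:
        cp = criterion * md / d_prime
        t_m = cp + offs
        t_n = cp - offs
        ll_m = np.zeros_like(offs)
        ll_n = np.zeros_like(offs)
        for s_idx, sign in ((0, -1.0), (1, 1.0)):
            mu = sign * md / 2.0
            denom_m = max(1.0 - norm.cdf(cp - mu), eps)
            p_low = np.clip((norm.cdf(t_m - mu) - norm.cdf(cp - mu)) / denom_m, eps, 1)
            p_high = np.clip((1.0 - norm.cdf(t_m - mu)) / denom_m, eps, 1)
            ll_m += counts[s_idx, 1, 0] * np.log(p_low) + counts[s_idx, 1, 1] * np.log(p_high)
            denom_n = max(norm.cdf(cp - mu), eps)
            p_high_n = np.clip(norm.cdf(t_n - mu) / denom_n, eps, 1)
            p_low_n = np.clip((norm.cdf(cp - mu) - norm.cdf(t_n - mu)) / denom_n, eps, 1)
            ll_n += counts[s_idx, 0, 0] * np.log(p_low_n) + counts[s_idx, 0, 1] * np.log(p_high_n)
        total = ll_m.max() + ll_n.max()
        if total > best_ll:
            best_ll, best_md = total, md
    return float(best_md), float(best_ll)


def type2_probs_by_quadrature(meta_d: float, criterion_scaled: float,
                              t_nonmatch: np.ndarray, t_match: np.ndarray) -> np.ndarray:
    """Response-conditional rating probabilities by direct density integration."""
    km1 = len(t_match)
    k = km1 + 1
    out = np.empty((2, 2, k))
    for s_idx, sign in ((0, -1.0), (1, 1.0)):
        mu = sign * meta_d / 2.0

        def dens(x):
            return norm.pdf(x, loc=mu)

        edges_m = np.concatenate([[criterion_scaled], np.sort(t_match), [np.inf]])
        edges_n = np.concatenate([[-np.inf], np.sort(t_nonmatch), [criterion_scaled]])
        segs_m = [integrate.quad(dens, edges_m[i], min(edges_m[i + 1], mu + 12),
                                 limit=200)[0] for i in range(k)]
        segs_n = [integrate.quad(dens, max(edges_n[i], mu - 12), edges_n[i + 1],
                                 limit=200)[0] for i in range(k)]
        out[s_idx, 1, :] = np.array(segs_m) / sum(segs_m)
        out[s_idx, 0, :] = np.array(segs_n[::-1]) / sum(segs_n)
    return out


def split_plot_anova(df: pd.DataFrame, dv: str = "value") -> dict:
    """Hand-computed split-plot (two-way mixed) sums-of-squares decomposition.

    Returns per effect a dict with F, p is omitted (not needed by the
    tests), and generalized eta squared with the participant and residual
    variance components in the denominator.
    """
    piv = df.pivot_table(index=["instruction", "participant_id"],
                         columns="difficulty", values=dv)
    y = piv.to_numpy()
    groups = piv.index.get_level_values(0).to_numpy()
    gm = y.mean()
    n_total = y.shape[0]
    subj_means = y.mean(axis=1)
    ss_total = ((y - gm) ** 2).sum()
    ss_between = 2 * ((subj_means - gm) ** 2).sum()
    ss_a = sum(2 * (groups == g).sum() * (y[groups == g].mean() - gm) ** 2
               for g in np.unique(groups))
    ss_subj = ss_between - ss_a
    level_means = y.mean(axis=0)
    ss_b = n_total * ((level_means - gm) ** 2).sum()
    ss_ab = 0.0
    for g in np.unique(groups):
        sel = groups == g
        a_mean = y[sel].mean()
        for j in range(2):
            ss_ab += sel.sum() * (y[sel][:, j].mean() - a_mean - level_means[j] + gm) ** 2
    ss_err = ss_total - ss_between - ss_b - ss_ab
    df_err = n_total - len(np.unique(groups))
    return {
        "instruction": {"F": ss_a / (ss_subj / df_err),
                        "eta_g": ss_a / (ss_a + ss_subj + ss_err)},
        "difficulty": {"F": ss_b / (ss_err / df_err),
                       "eta_g": ss_b / (ss_b + ss_subj + ss_err)},
        "interaction": {"F": ss_ab / (ss_err / df_err),
                        "eta_g": ss_ab / (ss_ab + ss_subj + ss_err)},
    }


def jzs_bf10(t: float, n: int, r: float = np.sqrt(2) / 2) -> float:
    """Rouder JZS paired-sample Bayes factor by high-resolution quadrature."""
    nu = n - 1

    def integrand(g):
        scale = 1.0 + n * g * r * r
        return (scale ** -0.5
                * (1.0 + t * t / (scale * nu)) ** (-(nu + 1) / 2)
                * (2 * np.pi) ** -0.5 * g ** -1.5 * np.exp(-1.0 / (2 * g)))

    num, _ = integrate.quad(integrand, 0, np.inf, limit=400)
    den = (1.0 + t * t / nu) ** (-(nu + 1) / 2)
    return num / den
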