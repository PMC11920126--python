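"""Type-1 and type-2 signal detection theory.

Type-1 sensitivity (d') and criterion (c) are computed from the response
margins of a rating-contingency table.  Type-2 (metacognitive) sensitivity is
quantified by meta-d': the type-1 sensitivity an SDT-ideal observer would
need in order to produce the observed rating data.  meta-d' is estimated by
maximum likelihood under the response-conditional Gaussian model of
Maniscalco & Lau, in which the metacognitive evidence distributions sit at
``+/- meta_d / 2`` and the type-1 criterion is rescaled to
``c' = c * meta_d / d'``.  Metacognitive efficiency is the ratio
``M-ratio = meta_d / d'``; a value of 1 means the ratings use all of the
evidence available to the type-1 decision.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from .counts import RatingCounts

_P_FLOOR = 1e-12
META_D_BOUNDS = (-5.0, 5.0)


@dataclass(frozen=True)
class Type1Fit:
    """Point estimates of type-1 performance."""

    d_prime: float
    criterion: float
    hit_rate: float
    fa_rate: float


@dataclass(frozen=True)
class MetaDFit:
    """Single-subject type-2 fit.

    ``type2_criteria`` is the full ascending vector of 2(K-1) criteria:
    the first K-1 lie below the scaled type-1 criterion (the "nonmatch"
    response side), the last K-1 above it (the "match" side).
    """

    meta_d: float
    m_ratio: float
    type2_criteria: np.ndarray
    log_likelihood: float
    converged: bool
    d_prime: float
    criterion: float


def compute_type1_sdt(counts: RatingCounts, correction: str = "hautus") -> Type1Fit:
    """d' and criterion from the stimulus x response margins.

    The hit rate is P(respond match | match stimulus) and the false-alarm
    rate is P(respond match | nonmatch stimulus).  With
    ``correction="hautus"`` (default), 1/(2K) is added to every cell of the
    table before computing the rates, which keeps both z-transforms finite
    even for perfect performance.  ``correction="none"`` uses raw rates.
    """
    totals = counts.stimulus_totals()
    for idx, name in enumerate(("nonmatch", "match")):
        if totals[idx] == 0:
            raise ValueError(f"no trials in stimulus class {name!r}; cannot fit type-1 SDT")
    if correction == "hautus":
        adj = counts.counts + 1.0 / (2 * counts.k)
    elif correction == "none":
        adj = counts.counts.astype(float)
    else:
        raise ValueError(f"unknown edge-correction policy {correction!r}")
    hit = adj[1, 1].sum() / adj[1].sum()
    fa = adj[0, 1].sum() / adj[0].sum()
    z_hit, z_fa = ndtri(hit), ndtri(fa)
    return Type1Fit(
        d_prime=float(z_hit - z_fa),
        criterion=float(-0.5 * (z_hit + z_fa)),
        hit_rate=float(hit),
        fa_rate=float(fa),
    )


def type2_probabilities(
    meta_d: float,
    d_prime: float,
    criterion: float,
    type2_criteria: np.ndarray,
    k: int,
) -> np.ndarray:
    """Response-conditional rating probabilities P(rating | stimulus, response).

    Returns an array of shape ``(2, 2, K)`` over (stimulus, response,
    rating).  ``type2_criteria`` is the ascending length-2(K-1) vector
    described in :class:`MetaDFit`; it must straddle the scaled criterion
    ``c' = criterion * meta_d / d_prime``, K-1 values on each side.
    """
    if d_prime == 0:
        raise ValueError("d_prime must be nonzero to scale the type-1 criterion")
    t2 = np.asarray(type2_criteria, dtype=float)
    if t2.shape != (2 * (k - 1),):
        raise ValueError(f"expected {2 * (k - 1)} type-2 criteria, got shape {t2.shape}")
    cprime = criterion * meta_d / d_prime
    full = np.concatenate([t2[: k - 1], [cprime], t2[k - 1 :]])
    bad = np.nonzero(np.diff(full) < 0)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"type-2 criterion ordering violated between {full[i]:.4f} and "
            f"{full[i + 1]:.4f} (positions {i}, {i + 1} of the augmented vector)"
        )
    return _type2_prob_table(
        np.asarray(meta_d, float), np.asarray(cprime, float), t2[: k - 1], t2[k - 1 :]
    )


def _type2_prob_table(
    meta_d: np.ndarray,
    cprime: np.ndarray,
    t_nonmatch: np.ndarray,
    t_match: np.ndarray,
) -> np.ndarray:
    """Vectorized response-conditional probability table.

    ``meta_d`` and ``cprime`` broadcast with leading batch dimensions;
    ``t_nonmatch``/``t_match`` have shape ``batch + (K-1,)`` and are the
    ascending criteria below/above ``cprime``.  Returns ``batch + (2, 2, K)``.
    """
    meta_d = np.asarray(meta_d, float)
    cprime = np.asarray(cprime, float)
    t_nonmatch = np.sort(np.asarray(t_nonmatch, float), axis=-1)
    t_match = np.sort(np.asarray(t_match, float), axis=-1)
    batch = np.broadcast_shapes(
        meta_d.shape, cprime.shape, t_nonmatch.shape[:-1], t_match.shape[:-1]
    )
    km1 = t_match.shape[-1]
    k = km1 + 1
    meta_d = np.broadcast_to(meta_d, batch)
    cprime = np.broadcast_to(cprime, batch)[..., None]
    t_nonmatch = np.broadcast_to(t_nonmatch, batch + (km1,))
    t_match = np.broadcast_to(t_match, batch + (km1,))

    inf = np.full(batch + (1,), np.inf)
    # ascending bin edges on each response side
    edges_m = np.concatenate([cprime, t_match, inf], axis=-1)  # (..., K+1)
    edges_n = np.concatenate([-inf, t_nonmatch, cprime], axis=-1)

    out = np.empty(batch + (2, 2, k))
    for s, sign in ((0, -1.0), (1, 1.0)):
        mu = sign * meta_d[..., None] / 2.0
        cdf_m = ndtr(edges_m - mu)
        cdf_n = ndtr(edges_n - mu)
        seg_m = np.diff(cdf_m, axis=-1)  # ascending bins above c'
        seg_n = np.diff(cdf_n, axis=-1)  # ascending bins below c'
        denom_m = np.clip(cdf_m[..., -1] - cdf_m[..., 0], _P_FLOOR, None)[..., None]
        denom_n = np.clip(cdf_n[..., -1] - cdf_n[..., 0], _P_FLOOR, None)[..., None]
        # match responses: rating grows with evidence above c'
        out[..., s, 1, :] = seg_m / denom_m
        # nonmatch responses: rating grows away from c' (toward -inf)
        out[..., s, 0, :] = seg_n[..., ::-1] / denom_n
    return out


def _type2_loglik(
    counts: np.ndarray,
    meta_d: np.ndarray,
    cprime: np.ndarray,
    t_nonmatch: np.ndarray,
    t_match: np.ndarray,
) -> np.ndarray:
    """Multinomial log-likelihood of rating counts conditional on (stimulus, response).

    ``counts`` has shape ``batch + (2, 2, K)`` (float-valued weights are
    accepted, which supports expected-count calibrations).
    """
    probs = _type2_prob_table(meta_d, cprime, t_nonmatch, t_match)
    return np.sum(counts * np.log(np.clip(probs, _P_FLOOR, None)), axis=(-1, -2, -3))


def _unpack(params: np.ndarray, k: int, criterion: float, d_prime: float):
    meta_d = params[0]
    cprime = criterion * meta_d / d_prime
    inc_n = np.exp(params[1:k])
    inc_m = np.exp(params[k : 2 * k - 1])
    t_n = (cprime - np.cumsum(inc_n))[::-1]
    t_m = cprime + np.cumsum(inc_m)
    return meta_d, cprime, t_n, t_m


def fit_meta_d_mle(counts: RatingCounts, correction: str = "hautus") -> MetaDFit:
    """Maximum-likelihood meta-d' with type-1 parameters fixed.

    The type-1 d' and criterion are point-estimated from the table's
    response margins (edge-corrected), then meta-d' and the 2(K-1) type-2
    criteria are found by maximizing the raw-count multinomial likelihood of
    ratings conditional on (stimulus, response).  Criterion ordering is
    enforced through a log-increment reparameterization; the optimizer is
    restarted from three initial points and ties are broken by likelihood,
    then by smaller absolute meta-d'.
    """
    t1 = compute_type1_sdt(counts, correction=correction)
    meta_d, t2, ll, ok = _fit_meta_d(
        counts.counts.astype(float), t1.d_prime, t1.criterion, counts.k
    )
    return MetaDFit(
        meta_d=meta_d,
        m_ratio=meta_d / t1.d_prime if t1.d_prime != 0 else np.nan,
        type2_criteria=t2,
        log_likelihood=ll,
        converged=ok,
        d_prime=t1.d_prime,
        criterion=t1.criterion,
    )


def _fit_meta_d(
    counts: np.ndarray, d_prime: float, criterion: float, k: int
) -> tuple[float, np.ndarray, float, bool]:
    """Core optimizer on a raw (2,2,K) count array; returns
    (meta_d, criteria vector, log-likelihood, converged)."""
    if d_prime == 0:
        raise ValueError("type-1 d' is zero; meta-d' is not identified")

    def nll(params: np.ndarray) -> float:
        meta_d, cprime, t_n, t_m = _unpack(params, k, criterion, d_prime)
        return -float(_type2_loglik(counts, meta_d, cprime, t_n, t_m))

    lo, hi = META_D_BOUNDS
    starts = []
    for frac in (0.5, 1.0, 1.5):
        md0 = float(np.clip(frac * d_prime, lo + 0.1, hi - 0.1))
        starts.append(np.concatenate([[md0], np.full(2 * (k - 1), np.log(0.5))]))
    bounds = [(lo, hi)] + [(-6.0, 3.0)] * (2 * (k - 1))

    best = None
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
        res2 = minimize(nll, res.x, method="Nelder-Mead",
                        options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000})
        cand = res2 if res2.fun <= res.fun else res
        cand_ok = bool(res.success or res2.success)
        key = (round(cand.fun, 9), round(abs(cand.x[0]), 9))
        if best is None or key < best[0]:
            best = (key, cand, cand_ok)
    _, res, ok = best
    meta_d, cprime, t_n, t_m = _unpack(res.x, k, criterion, d_prime)
    return float(meta_d), np.concatenate([t_n, t_m]), -float(res.fun), ok
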