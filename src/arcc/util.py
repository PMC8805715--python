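"""Small shared helpers: multiple testing, interval arithmetic on sorted arrays."""

from __future__ import annotations

import numpy as np


def bh_qvalues(pvalues: np.ndarray, n_tests: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values.

    ``n_tests`` may exceed ``len(pvalues)`` when untested hypotheses are known
    to have p = 1 (e.g. zero-count bin pairs); they can never be rejected but
    still count toward the correction.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = int(n_tests) if n_tests is not None else p.size
    if m < p.size:
        raise ValueError("n_tests smaller than the number of p-values given")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def binomial_sf(n_obs, n_trials: int, rate, max_terms: int = 4000) -> np.ndarray:
    """Upper-tail binomial probability P(X >= n_obs), X ~ Binomial(N, f).

    Direct tail summation with a multiplicative term recurrence; the leading
    binomial coefficient is accumulated as a product of small ratios, so no
    precision is lost to lgamma cancellation at large N (relative accuracy
    ~1e-13, versus ~1e-11 for the incomplete-beta route). Elements whose
    tail would need more than ``max_terms`` terms (p ~ 1 territory, or huge
    observed counts) fall back to scipy.
    """
    from scipy.stats import binom as _binom

    n = np.atleast_1d(np.asarray(n_obs, dtype=np.int64)).copy()
    f = np.broadcast_to(np.asarray(rate, dtype=float), n.shape).copy()
    N = int(n_trials)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("rate must be in (0, 1)")
    out = np.ones(n.shape, dtype=float)
    mean = N * f
    # terms to convergence ~ (mean - n)+ + 10 sqrt(mean); also need n ratios
    # for the leading coefficient
    feasible = (n <= max_terms) & (np.maximum(mean - n, 0) + 10 * np.sqrt(mean) + 40 < max_terms)
    todo = np.flatnonzero((n > 0) & feasible)
    if todo.size:
        nn = n[todo]
        ff = f[todo]
        log_coeff = np.zeros(todo.size)
        kmax = int(nn.max())
        for i in range(1, kmax + 1):
            act = nn >= i
            log_coeff[act] += np.log((N - nn[act] + i) / i)
        log_term = log_coeff + nn * np.log(ff) + (N - nn) * np.log1p(-ff)
        term = np.exp(log_term)
        total = term.copy()
        k = nn.astype(float).copy()
        ratio = ff / (1.0 - ff)
        active = np.ones(todo.size, dtype=bool)
        for _ in range(max_terms):
            if not active.any():
                break
            a = np.flatnonzero(active)
            term[a] *= (N - k[a]) / (k[a] + 1.0) * ratio[a]
            total[a] += term[a]
            k[a] += 1.0
            active[a] = (term[a] > total[a] * 1e-18) & (k[a] < N)
        out[todo] = np.minimum(total, 1.0)
    fallback = np.flatnonzero((n > 0) & ~feasible)
    if fallback.size:
        out[fallback] = _binom.sf(n[fallback] - 1, N, f[fallback])
    if np.ndim(n_obs) == 0:
        return float(out[0])
    return out


def merge_intervals(
    starts: np.ndarray, ends: np.ndarray, gap: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted half-open intervals; intervals separated by <= ``gap`` merge."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts.copy(), ends.copy()
    if np.any(np.diff(starts) < 0):
        raise ValueError("intervals must be sorted by start")
    out_s = [int(starts[0])]
    out_e = [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s - out_e[-1] <= gap:
            out_e[-1] = max(out_e[-1], int(e))
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def points_in_intervals(
    points: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Boolean mask: does each point fall inside any sorted disjoint half-open interval."""
    points = np.asarray(points)
    if len(starts) == 0:
        return np.zeros(points.shape, dtype=bool)
    idx = np.searchsorted(starts, points, side="right") - 1
    ok = idx >= 0
    hit = np.zeros(points.shape, dtype=bool)
    hit[ok] = points[ok] < np.asarray(ends)[idx[ok]]
    return hit


def intervals_overlap_any(
    qstarts: np.ndarray,
    qends: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
) -> np.ndarray:
    """Mask of query intervals overlapping any of the sorted disjoint intervals."""
    qstarts = np.asarray(qstarts)
    qends = np.asarray(qends)
    if len(starts) == 0:
        return np.zeros(qstarts.shape, dtype=bool)
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    # first interval whose end is beyond the query start
    i = np.searchsorted(ends, qstarts, side="right")
    hit = np.zeros(qstarts.shape, dtype=bool)
    ok = i < len(starts)
    hit[ok] = starts[i[ok]] < qends[ok]
    return hit
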