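"""Independent oracles for the test suite.

These deliberately avoid the package's estimation code paths: probabilities
are computed by plain exponential sums (no log-space tricks), the likelihood
is maximised by cyclic coordinate ascent over a fixed 0.01-logit grid instead
of Newton steps, and the signed-rank distribution is enumerated sign pattern
by sign pattern with itertools.
"""

from __future__ import annotations

import itertools

import numpy as np

GRID = np.arange(-600, 601) / 100.0  # 0.01-logit grid over [-6, 6]


def naive_cell_probs(theta: float, delta: float, tau: np.ndarray) -> np.ndarray:
    """Category probabilities by direct exponential sums."""
    m = len(tau)
    weights = []
    for k in range(m + 1):
        s = sum(theta - delta - tau[j] for j in range(k))  # empty sum = 0
        weights.append(np.exp(s))
    w = np.array(weights)
    return w / w.sum()


def naive_log_likelihood(x: np.ndarray, theta: np.ndarray, delta: np.ndarray,
                         tau: np.ndarray) -> float:
    ll = 0.0
    for n in range(x.shape[0]):
        for i in range(x.shape[1]):
            if np.isnan(x[n, i]):
                continue
            p = naive_cell_probs(theta[n], delta[i], tau)
            ll += np.log(p[int(x[n, i])])
    return ll


def _row_ll_over_grid(xrow: np.ndarray, delta: np.ndarray,
                      tau: np.ndarray) -> np.ndarray:
    """Log-likelihood of one person's responses for every grid ability."""
    m = len(tau)
    cum = np.concatenate(([0.0], np.cumsum(tau)))
    k = np.arange(m + 1)
    z = GRID[:, None] - delta[None, :]
    w = np.exp(k[None, None, :] * z[:, :, None] - cum[None, None, :])
    p = w / w.sum(axis=-1, keepdims=True)
    cols = np.arange(len(delta))
    keep = ~np.isnan(xrow)
    x = xrow[keep].astype(int)
    return np.log(p[:, cols[keep], x]).sum(axis=1)


def grid_search_jmle(x: np.ndarray, m: int, max_sweeps: int = 200):
    """Maximise the joint RSM likelihood by coordinate ascent on the grid.

    Each parameter in turn is replaced by its best grid value (persons, then
    items, then thresholds), iterated to a fixed point; the result is then
    translated to the same anchoring the calibration uses (mean item
    difficulty 0, thresholds summing to 0) via likelihood-preserving shifts.
    """
    n, i = x.shape
    theta = np.zeros(n)
    delta = np.zeros(i)
    tau = np.zeros(m)
    for _ in range(max_sweeps):
        changed = False
        for r in range(n):
            best = GRID[np.argmax(_row_ll_over_grid(x[r], delta, tau))]
            if best != theta[r]:
                theta[r] = best
                changed = True
        for c in range(i):
            lls = _col_ll_over_grid(x[:, c], theta, tau)
            best = GRID[np.argmax(lls)]
            if best != delta[c]:
                delta[c] = best
                changed = True
        for j in range(m):
            lls = _tau_ll_over_grid(x, theta, delta, tau, j)
            best = GRID[np.argmax(lls)]
            if best != tau[j]:
                tau[j] = best
                changed = True
        if not changed:
            break
    # canonical anchoring by likelihood-preserving translations
    c = tau.mean()
    tau = tau - c
    delta = delta + c
    d = delta.mean()
    delta = delta - d
    theta = theta - d
    return theta, delta, tau


def _col_ll_over_grid(xcol: np.ndarray, theta: np.ndarray,
                      tau: np.ndarray) -> np.ndarray:
    m = len(tau)
    cum = np.concatenate(([0.0], np.cumsum(tau)))
    k = np.arange(m + 1)
    z = theta[None, :] - GRID[:, None]
    w = np.exp(k[None, None, :] * z[:, :, None] - cum[None, None, :])
    p = w / w.sum(axis=-1, keepdims=True)
    rows = np.arange(len(theta))
    keep = ~np.isnan(xcol)
    x = xcol[keep].astype(int)
    return np.log(p[:, rows[keep], x]).sum(axis=1)


def _tau_ll_over_grid(xmat: np.ndarray, theta: np.ndarray, delta: np.ndarray,
                      tau: np.ndarray, j: int) -> np.ndarray:
    m = len(tau)
    k = np.arange(m + 1)
    z = theta[:, None] - delta[None, :]
    lls = np.empty(GRID.size)
    keep = ~np.isnan(xmat)
    rows, cols = np.nonzero(keep)
    x = xmat[rows, cols].astype(int)
    for g, val in enumerate(GRID):
        t = tau.copy()
        t[j] = val
        cum = np.concatenate(([0.0], np.cumsum(t)))
        w = np.exp(k[None, None, :] * z[:, :, None] - cum[None, None, :])
        p = w / w.sum(axis=-1, keepdims=True)
        lls[g] = np.log(p[rows, cols, x]).sum()
    return lls


def brute_force_signed_rank_p(d: np.ndarray) -> tuple[float, float]:
    """(W+, two-sided p) by explicit enumeration of every sign assignment."""
    from scipy.stats import rankdata

    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    dist = [sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product((False, True), repeat=len(d))]
    dist = np.array(dist)
    lo = np.mean(dist <= w_obs + 1e-9)
    hi = np.mean(dist >= w_obs - 1e-9)
    return float(w_obs), float(min(1.0, 2 * min(lo, hi)))
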