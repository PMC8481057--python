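"""Closed-form probability machinery of the Andrich rating scale model (RSM).

For a person of ability theta facing an item of difficulty delta rated on a
shared 0..m rubric with category thresholds tau_1..tau_m (sum tau = 0), the
probability of category k is

    P(X = k)  propto  exp( sum_{j<=k} (theta - delta - tau_j) )
              =       exp( k (theta - delta) - sum_{j<=k} tau_j ),

with the empty sum equal to 0 for k = 0.  All items of an instrument share
one threshold vector, which is the right structure when every item uses the
same rating rubric.  With m = 1 the model reduces to the dichotomous Rasch
model exp(theta - delta) / (1 + exp(theta - delta)).

Everything is computed in log space with max-subtraction before
normalisation, so |theta - delta| of 30+ logits is safe.
"""

from __future__ import annotations

import numpy as np

from .data_model import RaschParameters, ResponseMatrix, ValidationError

__all__ = [
    "category_probs",
    "expected_score",
    "score_variance",
    "log_likelihood",
    "probability_array",
    "expected_and_variance",
]


def _cumulative_thresholds(tau) -> np.ndarray:
    """(0, tau_1, tau_1+tau_2, ...) — the cumulative penalty per category."""
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if tau.ndim != 1 or tau.size < 1:
        raise ValidationError("tau must be a 1-D vector of length >= 1")
    if not np.all(np.isfinite(tau)):
        raise ValidationError("non-finite threshold")
    return np.concatenate(([0.0], np.cumsum(tau)))


def probability_array(theta, delta, tau) -> np.ndarray:
    """Category probabilities for every (person, item) pair.

    Parameters
    ----------
    theta, delta : array-like
        Person abilities (length N) and item difficulties (length I), logits.
    tau : array-like
        Shared thresholds (length m).

    Returns
    -------
    ndarray of shape (N, I, m + 1), rows normalised over the last axis.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    ct = _cumulative_thresholds(tau)
    k = np.arange(ct.size)
    z = theta[:, None] - delta[None, :]
    logw = k[None, None, :] * z[:, :, None] - ct[None, None, :]
    logw -= logw.max(axis=-1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=-1, keepdims=True)


def category_probs(theta: float, delta: float, tau) -> np.ndarray:
    """Probability vector over categories 0..m for a single person-item pair."""
    if not (np.isfinite(theta) and np.isfinite(delta)):
        raise ValidationError("theta and delta must be finite")
    return probability_array([theta], [delta], tau)[0, 0]


def expected_and_variance(theta, delta, tau) -> tuple[np.ndarray, np.ndarray]:
    """Model-expected score E and score variance W per (person, item) cell."""
    p = probability_array(theta, delta, tau)
    k = np.arange(p.shape[-1])
    e = (p * k).sum(axis=-1)
    v = (p * k**2).sum(axis=-1) - e**2
    return e, v


def expected_score(theta: float, delta: float, tau) -> float:
    """Expected category value sum_k k P(X=k); strictly increasing in theta."""
    if not (np.isfinite(theta) and np.isfinite(delta)):
        raise ValidationError("theta and delta must be finite")
    e, _ = expected_and_variance([theta], [delta], tau)
    return float(e[0, 0])


def score_variance(theta: float, delta: float, tau) -> float:
    """Variance of the category value; > 0 for finite arguments."""
    if not (np.isfinite(theta) and np.isfinite(delta)):
        raise ValidationError("theta and delta must be finite")
    _, v = expected_and_variance([theta], [delta], tau)
    return float(v[0, 0])


def log_likelihood(data: ResponseMatrix, params: RaschParameters) -> float:
    """Joint log-likelihood of the observed responses under the RSM.

    Missing cells are skipped.  Invariant under adding one constant to every
    theta and every delta (which is why calibration needs anchoring).
    """
    if len(params.theta) != data.n_persons or len(params.delta) != data.n_items:
        raise ValidationError("parameter dimensions do not match data")
    if len(params.tau) != data.max_category:
        raise ValidationError(
            f"expected {data.max_category} thresholds, got {len(params.tau)}"
        )
    p = probability_array(params.theta, params.delta, params.tau)
    mask = data.observed
    rows, cols = np.nonzero(mask)
    cats = data.values[rows, cols].astype(int)
    cell_p = p[rows, cols, cats]
    return float(np.log(cell_p).sum())
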