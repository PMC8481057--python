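"""Joint maximum-likelihood (JMLE / UCON) calibration of the rating scale model.

The estimation alternates damped Newton updates on the score residuals:

    theta_n <- theta_n + (r_n - sum_i E_ni) / sum_i W_ni
    delta_i <- delta_i - (s_i - sum_n E_ni) / sum_n W_ni
    tau_j   <- tau_j + (E[#X >= j] - #{x >= j}) / sum_ni G_j (1 - G_j)

where E and W are the model-expected cell score and its variance and
G_j = P(X >= j).  After every sweep the identification constraints are
re-imposed (mean item difficulty 0 over non-extreme items, thresholds summing
to 0) by likelihood-preserving translations.  Starting values come from the
PROX log-odds transform of the raw margins.

Zero and perfect raw scores have no finite maximiser; such persons/items are
excluded from the joint fit, then assigned finite measures by solving their
estimating equation with the raw score pulled in by ``extreme_adjust`` score
points, and flagged.  Standard errors are model-based Fisher information,
1 / sqrt(sum W).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .data_model import (
    CalibrationError,
    CalibrationResult,
    RaschParameters,
    ResponseMatrix,
)
from .rsm import expected_and_variance, probability_array

__all__ = ["CalibrationConfig", "prox_initialize", "calibrate",
           "result_from_parameters"]

_MAX_STEP = 1.0  # damping: largest Newton step per sweep, logits


@dataclass
class CalibrationConfig:
    """Convergence and policy settings for :func:`calibrate`.

    score_tol is the largest absolute raw-score residual accepted at
    convergence; change_tol the largest parameter move in the final sweep.
    Both defaults comfortably exceed two-decimal reporting precision.
    Estimation is deterministic; there is no seed.
    """

    max_iter: int = 100
    score_tol: float = 0.01
    change_tol: float = 0.001
    extreme_adjust: float = 0.3
    bias_correct: bool = False

    def __post_init__(self) -> None:
        if self.score_tol <= 0 or self.change_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not 0.0 < self.extreme_adjust < 1.0:
            raise ValueError("extreme_adjust must be in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _category_counts(data: ResponseMatrix) -> np.ndarray:
    obs = data.values[data.observed].astype(int)
    return np.bincount(obs, minlength=data.max_category + 1)


def prox_initialize(data: ResponseMatrix,
                    extreme_adjust: float = 0.3) -> RaschParameters:
    """PROX starting values: log-odds of the (adjusted) raw margins.

    theta0_n = ln(r'_n / (R_n - r'_n)) with r'_n the raw score pulled off the
    boundary by ``extreme_adjust``; delta0_i = -ln(s'_i / (S_i - s'_i)),
    centred to mean 0; tau0_j = ln(c_{j-1} / c_j) from the overall category
    counts, centred to sum 0.
    """
    m = data.max_category
    obs = data.observed
    counts = _category_counts(data)
    if np.any(counts == 0):
        empty = [str(j) for j in np.nonzero(counts == 0)[0]]
        raise CalibrationError(
            f"category {', '.join(empty)} never observed; collapse categories "
            f"(e.g. --collapse) or recode before calibrating"
        )
    r = np.nansum(data.values, axis=1)
    rmax = m * obs.sum(axis=1)
    rr = np.clip(r, extreme_adjust, rmax - extreme_adjust)
    theta0 = np.log(rr / (rmax - rr))

    s = np.nansum(data.values, axis=0)
    smax = m * obs.sum(axis=0)
    ss = np.clip(s, extreme_adjust, smax - extreme_adjust)
    delta0 = -np.log(ss / (smax - ss))
    delta0 -= delta0.mean()

    tau0 = np.log(counts[:-1] / counts[1:])
    tau0 -= tau0.mean()

    params = RaschParameters(
        person_ids=list(data.person_ids), item_ids=list(data.item_ids),
        theta=theta0, delta=delta0, tau=tau0,
        se_theta=np.full(data.n_persons, np.nan),
        se_delta=np.full(data.n_items, np.nan),
        extreme_person=np.zeros(data.n_persons, bool),
        extreme_item=np.zeros(data.n_items, bool),
        anchoring={"items": "mean zero", "thresholds": "sum zero",
                   "method": "PROX"},
    )
    _fill_standard_errors(params, data)
    return params


def _fill_standard_errors(params: RaschParameters, data: ResponseMatrix) -> None:
    _, w = expected_and_variance(params.theta, params.delta, params.tau)
    w = np.where(data.observed, w, 0.0)
    with np.errstate(divide="ignore"):
        params.se_theta = 1.0 / np.sqrt(w.sum(axis=1))
        params.se_delta = 1.0 / np.sqrt(w.sum(axis=0))


def _find_extremes(values: np.ndarray, m: int,
                   active_p: np.ndarray, active_i: np.ndarray) -> bool:
    """One screening pass; marks newly extreme persons/items. True if changed."""
    changed = False
    sub = values[np.ix_(active_p, active_i)]
    obs = ~np.isnan(sub)
    if sub.size == 0:
        return False
    r = np.nansum(sub, axis=1)
    rmax = m * obs.sum(axis=1)
    bad_p = (r <= 0) | (r >= rmax)
    if bad_p.any():
        idx = np.nonzero(active_p)[0][bad_p]
        active_p[idx] = False
        changed = True
    s = np.nansum(sub, axis=0)
    smax = m * obs.sum(axis=0)
    bad_i = (s <= 0) | (s >= smax)
    if bad_i.any():
        idx = np.nonzero(active_i)[0][bad_i]
        active_i[idx] = False
        changed = True
    return changed


def _solve_person(r_target: float, row_obs_delta: np.ndarray,
                  tau: np.ndarray) -> float:
    """theta such that the expected raw score over the given items = r_target."""
    def f(th: float) -> float:
        e, _ = expected_and_variance([th], row_obs_delta, tau)
        return e.sum() - r_target
    return brentq(f, -40.0, 40.0, xtol=1e-10)


def _solve_item(s_target: float, col_obs_theta: np.ndarray,
                tau: np.ndarray) -> float:
    """delta such that the expected column score over the given persons = s_target."""
    def f(d: float) -> float:
        e, _ = expected_and_variance(col_obs_theta, [d], tau)
        return e.sum() - s_target
    return brentq(f, -40.0, 40.0, xtol=1e-10)


def calibrate(data: ResponseMatrix,
              config: CalibrationConfig | None = None) -> CalibrationResult:
    """Fit the rating scale model to a response matrix by JMLE.

    Returns a :class:`CalibrationResult`; non-convergence is reported via
    ``converged=False`` plus a warning, never silently.  Update order within
    a sweep is persons, then items, then thresholds.
    """
    cfg = config or CalibrationConfig()
    m = data.max_category
    values = data.values
    n, k = values.shape
    if (data.observed.sum(axis=1) == 0).any():
        raise CalibrationError("a person has no observed responses")
    if (data.observed.sum(axis=0) == 0).any():
        raise CalibrationError("an item has no observed responses")

    # iterative extreme screening: dropping a ceiling person can push an item
    # to the boundary, and vice versa
    active_p = np.ones(n, bool)
    active_i = np.ones(k, bool)
    while _find_extremes(values, m, active_p, active_i):
        pass
    if not active_p.any() or not active_i.any():
        raise CalibrationError("all persons or all items have extreme scores")

    core = data.subset([p for p, a in zip(data.person_ids, active_p) if a],
                       [i for i, a in zip(data.item_ids, active_i) if a])
    init = prox_initialize(core, cfg.extreme_adjust)
    theta = init.theta.copy()
    delta = init.delta.copy()
    tau = init.tau.copy()

    cobs = core.observed
    cvals = np.where(cobs, core.values, 0.0)
    r = cvals.sum(axis=1)
    s = cvals.sum(axis=0)
    ge_counts = np.array([(np.where(cobs, core.values, -1) >= j).sum()
                          for j in range(1, m + 1)], dtype=float)

    trace: list[tuple[int, float, float]] = []
    converged = False
    n_iter = 0
    max_resid = np.inf
    for it in range(1, cfg.max_iter + 1):
        n_iter = it
        change = 0.0

        e, w = expected_and_variance(theta, delta, tau)
        e, w = np.where(cobs, e, 0.0), np.where(cobs, w, 0.0)
        step = np.clip((r - e.sum(axis=1)) / w.sum(axis=1), -_MAX_STEP, _MAX_STEP)
        theta = theta + step
        change = max(change, np.abs(step).max())

        e, w = expected_and_variance(theta, delta, tau)
        e, w = np.where(cobs, e, 0.0), np.where(cobs, w, 0.0)
        step = np.clip((s - e.sum(axis=0)) / w.sum(axis=0), -_MAX_STEP, _MAX_STEP)
        delta = delta - step
        change = max(change, np.abs(step).max())

        p = probability_array(theta, delta, tau)
        for j in range(1, m + 1):
            g = p[:, :, j:].sum(axis=-1)
            g = np.where(cobs, g, 0.0)
            info = (g * (1.0 - g))[cobs].sum()
            tstep = np.clip((g.sum() - ge_counts[j - 1]) / info,
                            -_MAX_STEP, _MAX_STEP)
            tau[j - 1] += tstep
            change = max(change, abs(tstep))
            p = probability_array(theta, delta, tau)

        # re-impose anchoring by likelihood-preserving translations:
        # tau -> tau - c is compensated by delta -> delta + c; centring delta
        # is compensated through theta.
        c = tau.mean()
        tau -= c
        delta += c
        d = delta.mean()
        delta -= d
        theta -= d

        e, w = expected_and_variance(theta, delta, tau)
        e = np.where(cobs, e, 0.0)
        max_resid = max(np.abs(r - e.sum(axis=1)).max(),
                        np.abs(s - e.sum(axis=0)).max())
        trace.append((it, float(max_resid), float(change)))
        if max_resid <= cfg.score_tol and change <= cfg.change_tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"calibration did not converge in {cfg.max_iter} sweeps "
            f"(max score residual {max_resid:.4g})", RuntimeWarning)

    # scatter core estimates back to the full index
    full_theta = np.full(n, np.nan)
    full_delta = np.full(k, np.nan)
    full_theta[active_p] = theta
    full_delta[active_i] = delta

    # extreme entities: solve the adjusted-score estimating equation against
    # the fixed co-parameters (active side only)
    adj = cfg.extreme_adjust
    for pi in np.nonzero(~active_p)[0]:
        row = values[pi, active_i]
        keep = ~np.isnan(row)
        if not keep.any():
            continue
        rmax = m * keep.sum()
        rt = float(np.clip(np.nansum(row), adj, rmax - adj))
        full_theta[pi] = _solve_person(rt, delta[keep], tau)
    for ii in np.nonzero(~active_i)[0]:
        col = values[active_p, ii]
        keep = ~np.isnan(col)
        if not keep.any():
            continue
        smax = m * keep.sum()
        st = float(np.clip(np.nansum(col), adj, smax - adj))
        full_delta[ii] = _solve_item(st, theta[keep], tau)

    if cfg.bias_correct:
        li = int(active_i.sum())
        scale = (li - 1) / li
        full_theta *= scale
        full_delta *= scale
        tau *= scale

    params = RaschParameters(
        person_ids=list(data.person_ids), item_ids=list(data.item_ids),
        theta=full_theta, delta=full_delta, tau=tau,
        se_theta=np.full(n, np.nan), se_delta=np.full(k, np.nan),
        extreme_person=~active_p, extreme_item=~active_i,
        anchoring={"items": "mean zero over non-extreme items",
                   "thresholds": "sum zero",
                   "method": "JMLE",
                   "bias_correct": cfg.bias_correct},
    )
    _fill_standard_errors(params, data)
    result = result_from_parameters(data, params)
    result.converged = converged
    result.n_iter = n_iter
    result.max_residual = float(max_resid)
    result.trace = trace
    return result


def result_from_parameters(data: ResponseMatrix,
                           params: RaschParameters) -> CalibrationResult:
    """Expected scores, variances and standardised residuals at fixed parameters."""
    e, w = expected_and_variance(params.theta, params.delta, params.tau)
    obs = data.observed
    e = np.where(obs, e, np.nan)
    w = np.where(obs, w, np.nan)
    with np.errstate(invalid="ignore"):
        z = (data.values - e) / np.sqrt(w)
    return CalibrationResult(params=params, expected=e, resid_var=w,
                             std_resid=z, converged=True, n_iter=0,
                             max_residual=np.nan, data=data)
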