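"""Psychometric quality panel and Rasch fit statistics.

Covers the attributes practitioners report for a checklist instrument:
separation/reliability for persons and items, Cronbach's alpha, the share of
raw variance explained by the Rasch measures, the first principal contrast of
the standardised residuals (unidimensionality screen), and infit/outfit
mean-square statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CalibrationResult, ResponseMatrix, ValidationError

__all__ = ["PsychometricPanel", "separation_reliability", "cronbach_alpha",
           "fit_statistics", "variance_explained", "psychometric_panel",
           "panel_to_frame"]


@dataclass
class PsychometricPanel:
    """One instrument/occasion worth of quality indices.

    Percentages are on the 0-100 scale.  Reliability R and separation G obey
    R = G^2 / (1 + G^2).
    """

    raw_variance_explained: float
    first_contrast_eigenvalue: float
    unexplained_first_contrast: float
    cronbach_alpha: float
    person_reliability: float
    person_separation: float
    item_reliability: float
    item_separation: float

    def to_dict(self) -> dict:
        return {k: (None if v is None or not np.isfinite(v) else float(v))
                for k, v in self.__dict__.items()}


def separation_reliability(measures, ses) -> tuple[float, float]:
    """Separation reliability R and separation index G from measures and SEs.

    Observed variance SD^2 (sample variance of the measures), error variance
    MSE = mean(se^2), true variance T = max(SD^2 - MSE, 0); R = T / SD^2 and
    G = sqrt(T / MSE).  Identical measures give (0, 0); MSE = 0 is degenerate
    and capped at R = 1 with a warning.
    """
    measures = np.asarray(measures, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if measures.size < 2:
        raise ValidationError("need at least 2 measures")
    sd2 = float(np.var(measures, ddof=1))
    mse = float(np.mean(ses**2))
    if mse == 0.0:
        warnings.warn("zero error variance: reliability capped at 1",
                      RuntimeWarning)
        return (1.0, np.inf) if sd2 > 0 else (0.0, 0.0)
    t = max(sd2 - mse, 0.0)
    if sd2 == 0.0 or t == 0.0:
        return 0.0, 0.0
    return t / sd2, float(np.sqrt(t / mse))


def cronbach_alpha(data: ResponseMatrix) -> float:
    """Classical internal-consistency alpha on listwise-complete persons.

    alpha = k/(k-1) * (1 - sum of item variances / total-score variance).
    """
    complete = data.observed.all(axis=1)
    x = data.values[complete]
    if x.shape[0] < 2:
        raise ValidationError("fewer than 2 complete persons")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValidationError("zero total-score variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def fit_statistics(cal: CalibrationResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Infit/outfit mean squares per person and per item.

    outfit = mean of squared standardised residuals z^2 = (x-E)^2 / W;
    infit = sum (x-E)^2 / sum W (information-weighted).  Both are ~1 when the
    data fit the model; missing cells are skipped.
    """
    if cal.data is None:
        raise ValidationError("calibration result carries no data")
    x = cal.data.values
    e, w, z = cal.expected, cal.resid_var, cal.std_resid
    sq = (x - e) ** 2

    def _frame(axis: int, ids: list[str]) -> pd.DataFrame:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            outfit = np.nanmean(z**2, axis=axis)
            infit = np.nansum(sq, axis=axis) / np.nansum(w, axis=axis)
        return pd.DataFrame({"infit": infit, "outfit": outfit},
                            index=pd.Index(ids, name="id"))

    persons = _frame(1, cal.params.person_ids)
    items = _frame(0, cal.params.item_ids)
    return persons, items


def variance_explained(cal: CalibrationResult) -> tuple[float, float, float]:
    """Rasch variance decomposition and first residual contrast.

    The variance explained by the measures is the variance of the expected
    scores E over observed cells; the unexplained part is the mean model
    variance W.  The first contrast is the largest eigenvalue of the
    item-by-item correlation matrix of standardised residuals (pairwise
    complete), reported together with its share of the unexplained variance
    in percent of the total.
    """
    obs = cal.data.observed if cal.data is not None else ~np.isnan(cal.expected)
    v_expl = float(np.var(cal.expected[obs]))
    v_unexpl = float(np.mean(cal.resid_var[obs]))
    total = v_expl + v_unexpl
    raw_pct = 100.0 * v_expl / total if total > 0 else 0.0

    n_items = cal.expected.shape[1]
    if n_items < 3:
        return raw_pct, np.nan, np.nan
    zdf = pd.DataFrame(cal.std_resid)
    corr = zdf.corr(min_periods=2).to_numpy()
    corr = np.where(np.isnan(corr), 0.0, corr)
    np.fill_diagonal(corr, 1.0)
    lam1 = float(np.linalg.eigvalsh(corr).max())
    unexpl_pct = 100.0 * (lam1 / n_items) * v_unexpl / total if total > 0 else np.nan
    return raw_pct, lam1, unexpl_pct


def psychometric_panel(cal: CalibrationResult) -> PsychometricPanel:
    """Assemble the full quality panel from one converged calibration."""
    p = cal.params
    ok_p = ~p.extreme_person & np.isfinite(p.theta)
    ok_i = ~p.extreme_item & np.isfinite(p.delta)
    pr, ps = separation_reliability(p.theta[ok_p], p.se_theta[ok_p])
    ir, isep = separation_reliability(p.delta[ok_i], p.se_delta[ok_i])
    raw_pct, lam1, unexpl_pct = variance_explained(cal)
    alpha = cronbach_alpha(cal.data) if cal.data is not None else np.nan
    return PsychometricPanel(
        raw_variance_explained=raw_pct,
        first_contrast_eigenvalue=lam1,
        unexplained_first_contrast=unexpl_pct,
        cronbach_alpha=alpha,
        person_reliability=pr, person_separation=ps,
        item_reliability=ir, item_separation=isep,
    )


def panel_to_frame(panel: PsychometricPanel, label: str = "value") -> pd.DataFrame:
    """One-row data frame with conventional report row names as columns."""
    d = {
        "Raw variance explained by measures (%)": panel.raw_variance_explained,
        "Unexplained variance: first contrast (%)": panel.unexplained_first_contrast,
        "First contrast eigenvalue": panel.first_contrast_eigenvalue,
        "Cronbach's alpha": panel.cronbach_alpha,
        "Person reliability": panel.person_reliability,
        "Person separation": panel.person_separation,
        "Item reliability": panel.item_reliability,
        "Item separation": panel.item_separation,
    }
    return pd.DataFrame([d], index=[label])
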