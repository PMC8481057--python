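"""Stacking and racking pre/post analysis with paired nonparametric testing.

Stacking isolates person change: pre and post response rows are concatenated
(each person appears twice, occasion-tagged) and calibrated jointly, so item
difficulties are shared across occasions and each person receives one ability
per occasion.  Racking isolates item change: pre and post columns are
concatenated (each item appears twice), so person abilities are shared and
each item receives one difficulty per occasion.  Per-entity differences are
summarised and tested with the Wilcoxon signed-rank test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .calibration import CalibrationConfig, calibrate
from .data_model import (
    CalibrationResult,
    PrePostDesign,
    ResponseMatrix,
    ValidationError,
)

__all__ = ["WilcoxonResult", "EffectRecord", "EffectSummary", "stack", "rack",
           "wilcoxon_signed_rank", "difficulty_crossplot", "summarize_effects",
           "PRE_PREFIX", "POST_PREFIX"]

# occasion tags used in stacked/racked identifiers and Wright maps:
# pretest entities are prefixed "P", posttest entities "0"
PRE_PREFIX = "P"
POST_PREFIX = "0"

EXACT_MAX_N = 12  # full 2^n enumeration up to here; normal approximation beyond


@dataclass
class WilcoxonResult:
    n_nonzero: int
    w_plus: float
    p_two_sided: float
    method: str  # "exact" | "normal-approximation"


@dataclass
class EffectRecord:
    id: str
    measure_pre: float
    measure_post: float

    @property
    def difference(self) -> float:
        return self.measure_post - self.measure_pre


@dataclass
class EffectSummary:
    """Per-entity pre/post logit pairs with group summary and paired test.

    ``entity_kind`` is "person" (ability change; LVP in the checklist
    literature) or "item" (difficulty change; LVI).  ``mean_difference`` is
    mean_post - mean_pre over the common entity set; for items a negative
    difference means the item became easier.  ``co_measures`` carries the
    shared co-parameters of the joint calibration (item difficulties for a
    person summary, person abilities for an item summary) for Wright maps.
    """

    entity_kind: str
    records: list[EffectRecord]
    mean_pre: float
    mean_post: float
    range_pre: tuple[float, float]
    range_post: tuple[float, float]
    mean_difference: float
    test: WilcoxonResult | None
    co_measures: list[tuple[str, float]] = field(default_factory=list)
    calibration: CalibrationResult | None = None

    def differences(self) -> np.ndarray:
        return np.array([r.difference for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": [r.id for r in self.records],
             "measure_pre": [r.measure_pre for r in self.records],
             "measure_post": [r.measure_post for r in self.records],
             "difference": [r.difference for r in self.records]})

    def to_dict(self) -> dict:
        d = {
            "entity_kind": self.entity_kind,
            "n": len(self.records),
            "mean_pre": self.mean_pre,
            "mean_post": self.mean_post,
            "range_pre": list(self.range_pre),
            "range_post": list(self.range_post),
            "mean_difference": self.mean_difference,
            "mean_difference_magnitude": abs(self.mean_difference),
        }
        if self.test is not None:
            d["wilcoxon"] = {"n_nonzero": self.test.n_nonzero,
                             "w_plus": self.test.w_plus,
                             "p_two_sided": self.test.p_two_sided,
                             "method": self.test.method}
        else:
            d["wilcoxon"] = None
        return d


def wilcoxon_signed_rank(differences) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are dropped; absolute differences are ranked with midranks for
    ties.  For n <= 12 the two-sided p comes from full enumeration of the
    2^n sign assignments of the (mid)ranks; beyond that, the normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction toward the mean.
    """
    d = np.asarray(differences, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValidationError("non-finite difference")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValidationError("all differences are zero: no evidence either way")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0

    if n <= EXACT_MAX_N:
        # distribution of W+ over all sign assignments (handles midranks)
        signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
        dist = signs @ ranks
        # symmetric about mu, so the two-sided p doubles the smaller tail
        p_lo = float(np.mean(dist <= w_plus + 1e-9))
        p_hi = float(np.mean(dist >= w_plus - 1e-9))
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        return WilcoxonResult(n, w_plus, p, "exact")

    # tie-corrected variance
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((counts**3 - counts).sum()) / 48.0
    dev = w_plus - mu
    cc = 0.5 * np.sign(dev)  # continuity correction toward the mean
    z = (dev - cc) / np.sqrt(var) if var > 0 else 0.0
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return WilcoxonResult(n, w_plus, p, "normal-approximation")


def summarize_effects(entity_kind: str, ids: list[str], pre, post,
                      co_measures: list[tuple[str, float]] | None = None,
                      calibration: CalibrationResult | None = None,
                      ) -> EffectSummary:
    """Build an :class:`EffectSummary` from paired pre/post logit vectors."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or len(ids) != pre.size:
        raise ValidationError("pre/post measure vectors must align with ids")
    records = [EffectRecord(i, float(a), float(b))
               for i, a, b in zip(ids, pre, post)]
    diffs = post - pre
    if np.all(diffs == 0.0):
        warnings.warn("all paired differences are zero; no signed-rank test",
                      RuntimeWarning)
        test = None
    else:
        test = wilcoxon_signed_rank(diffs)
    return EffectSummary(
        entity_kind=entity_kind, records=records,
        mean_pre=float(pre.mean()), mean_post=float(post.mean()),
        range_pre=(float(pre.min()), float(pre.max())),
        range_post=(float(post.min()), float(post.max())),
        mean_difference=float(diffs.mean()),
        test=test, co_measures=co_measures or [],
        calibration=calibration,
    )


def _check_aligned(design: PrePostDesign) -> None:
    if design.pre.person_ids != design.post.person_ids:
        raise ValidationError("design persons not aligned; use align_prepost")
    if design.pre.item_ids != design.post.item_ids:
        raise ValidationError("design items not aligned; use align_prepost")
    if design.pre.max_category != design.post.max_category:
        raise ValidationError("occasions disagree on max_category")


def stack(design: PrePostDesign,
          config: CalibrationConfig | None = None) -> EffectSummary:
    """Person-change analysis: one joint calibration of the stacked matrix.

    The stacked matrix has 2N rows (pretest rows first, tagged "P", then
    posttest rows tagged "0") against the common I items, so the item
    difficulties are shared across occasions and each person gets a separate
    ability per occasion.  The Wilcoxon test is applied to the N paired
    person differences (post - pre).
    """
    _check_aligned(design)
    n = design.pre.n_persons
    if n < 5:
        warnings.warn("fewer than 5 persons: the exact signed-rank test has "
                      "very little power", RuntimeWarning)
    ids = design.pre.person_ids
    stacked = ResponseMatrix(
        person_ids=[PRE_PREFIX + p for p in ids] + [POST_PREFIX + p for p in ids],
        item_ids=list(design.pre.item_ids),
        values=np.vstack([design.pre.values, design.post.values]),
        max_category=design.pre.max_category,
        occasion_label="stacked",
    )
    cal = calibrate(stacked, config)
    theta = cal.params.theta
    co = list(zip(cal.params.item_ids,
                  (float(d) for d in cal.params.delta)))
    design.mode = "stack"
    return summarize_effects("person", ids, theta[:n], theta[n:],
                             co_measures=co, calibration=cal)


def rack(design: PrePostDesign,
         config: CalibrationConfig | None = None) -> EffectSummary:
    """Item-change analysis: one joint calibration of the racked matrix.

    The racked matrix has 2I columns (pretest items tagged "P", posttest
    items tagged "0") against the common N persons, so each person keeps a
    single ability across occasions and each item gets a separate difficulty
    per occasion.  The difference is reported as post - pre: negative when
    the item became easier after training.
    """
    _check_aligned(design)
    ids = design.pre.item_ids
    k = design.pre.n_items
    racked = ResponseMatrix(
        person_ids=list(design.pre.person_ids),
        item_ids=[PRE_PREFIX + i for i in ids] + [POST_PREFIX + i for i in ids],
        values=np.hstack([design.pre.values, design.post.values]),
        max_category=design.pre.max_category,
        occasion_label="racked",
    )
    cal = calibrate(racked, config)
    delta = cal.params.delta
    co = list(zip(cal.params.person_ids,
                  (float(t) for t in cal.params.theta)))
    design.mode = "rack"
    return summarize_effects("item", ids, delta[:k], delta[k:],
                             co_measures=co, calibration=cal)


def difficulty_crossplot(summary: EffectSummary) -> pd.DataFrame:
    """Classify items against the identity line in (pre, post) space.

    Both axes are median-centred first, so the identity line marks "difficulty
    changed by the typical amount".  Items above the line stayed relatively
    difficult (their difficulty dropped less than typical); items below became
    relatively easier.  This is the table behind the pre/post difficulty
    scatter plots.
    """
    if summary.entity_kind != "item":
        raise ValidationError("difficulty_crossplot needs an item summary")
    df = summary.to_frame().rename(columns={"measure_pre": "pre",
                                            "measure_post": "post"})
    pre_c = df["pre"] - df["pre"].median()
    post_c = df["post"] - df["post"].median()
    df["above_line"] = (post_c - pre_c) > 1e-9
    return df[["id", "pre", "post", "above_line"]]
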