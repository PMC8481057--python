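"""Synthetic pre/post checklist data with the structure the analysis assumes.

The generator emulates a one-day skills training of community health
volunteers scored by observers on a 3-category rubric (0 = cannot perform,
1 = imperfect, 2 = perfect): 41 trainees, 11 items (infant instrument) or 13
items (toddler instrument).  Pretest abilities are Normal(mu_pre, sigma_theta)
logits; training adds a uniform shift (about 2.7 logits for the infant
instrument, 3.3 for the toddler one) plus person-level noise, and optional
item-specific difficulty shifts gamma_i model item blocks that stay hard
(e.g. mid-upper-arm-circumference items).  Post responses near the scale
ceiling are a deliberate feature: they exercise the extreme-score policy of
the calibration.

One random stream per call, consumed in a fixed documented order (pretest
abilities, training-effect noise, pretest cell uniforms row-major, posttest
cell uniforms row-major, then missingness masks), so a seed pins the output
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ResponseMatrix, ValidationError
from .rsm import probability_array

__all__ = ["SimulationDesign", "infant_design", "toddler_design",
           "simulate_prepost", "simulate_responses", "ceiling_rate"]


@dataclass
class SimulationDesign:
    """Generating truth for one pre/post pair.

    Defaults mirror the assessment shape the pipeline targets: N=41 trainees,
    items equally spaced over [-2, +2] logits, shared thresholds (-1, +1),
    pretest abilities Normal(0.3, 1.0), a uniform training effect with 0.5
    logits of person noise, and no missingness.
    """

    n_persons: int = 41
    item_difficulties: np.ndarray | None = None
    n_items: int = 11
    thresholds: tuple[float, ...] = (-1.0, 1.0)
    mu_pre: float = 0.3
    sigma_theta: float = 1.0
    effect: float = 2.7
    sigma_effect: float = 0.5
    item_shifts: np.ndarray | None = None
    missing_rate: float = 0.0
    seed: int = 0
    label: str = "infant"

    def __post_init__(self) -> None:
        if self.item_difficulties is None:
            self.item_difficulties = np.linspace(-2.0, 2.0, self.n_items)
        self.item_difficulties = np.asarray(self.item_difficulties, float)
        self.n_items = len(self.item_difficulties)
        if self.item_shifts is None:
            self.item_shifts = np.zeros(self.n_items)
        self.item_shifts = np.asarray(self.item_shifts, float)
        if len(self.item_shifts) != self.n_items:
            raise ValidationError("item_shifts length must match items")
        if self.sigma_theta <= 0:
            raise ValidationError("sigma_theta must be > 0")
        if self.sigma_effect < 0:
            raise ValidationError("sigma_effect must be >= 0")
        if np.any(np.abs(self.item_shifts) >= 10):
            raise ValidationError("item shifts must satisfy |gamma| < 10")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.n_persons < 2 or self.n_items < 2:
            raise ValidationError("need at least 2 persons and 2 items")


def infant_design(**overrides) -> SimulationDesign:
    """11-item instrument; training effect ~2.7 logits."""
    kw = dict(n_items=11, effect=2.7, label="infant")
    kw.update(overrides)
    return SimulationDesign(**kw)


def toddler_design(**overrides) -> SimulationDesign:
    """13-item instrument; training effect ~3.3 logits."""
    kw = dict(n_items=13, effect=3.3, label="toddler")
    kw.update(overrides)
    return SimulationDesign(**kw)


def simulate_responses(theta, delta, tau, rng: np.random.Generator,
                       person_ids: list[str] | None = None,
                       item_ids: list[str] | None = None,
                       occasion_label: str = "") -> ResponseMatrix:
    """Draw one response matrix from the rating scale model.

    One uniform per cell, consumed row-major, inverted through the category
    CDF — categories follow the RSM closed form exactly.
    """
    theta = np.asarray(theta, float)
    delta = np.asarray(delta, float)
    p = probability_array(theta, delta, tau)
    cdf = np.cumsum(p, axis=-1)
    u = rng.random((theta.size, delta.size))
    x = (u[:, :, None] >= cdf[:, :, :-1]).sum(axis=-1).astype(float)
    m = p.shape[-1] - 1
    pids = person_ids or [f"C{i + 1:02d}" for i in range(theta.size)]
    iids = item_ids or [f"i{j + 1:02d}" for j in range(delta.size)]
    return ResponseMatrix(pids, iids, x, m, occasion_label)


def simulate_prepost(design: SimulationDesign,
                     ) -> tuple[ResponseMatrix, ResponseMatrix, dict]:
    """Generate an aligned pre/post pair plus the generating truth.

    Pre responses come from RSM(theta_n, delta_i, tau); post responses from
    RSM(theta_n + effect + eta_n, delta_i - gamma_i, tau) where eta_n is the
    person-level effect noise.  The truth record carries every generated
    quantity for recovery scoring.
    """
    rng = np.random.default_rng(design.seed)
    n, k = design.n_persons, design.n_items
    theta = rng.normal(design.mu_pre, design.sigma_theta, n)
    eta = rng.normal(0.0, design.sigma_effect, n) if design.sigma_effect > 0 \
        else np.zeros(n)
    tau = np.asarray(design.thresholds, float)
    pids = [f"C{i + 1:02d}" for i in range(n)]
    iids = [f"i{j + 1:02d}" for j in range(k)]

    pre = simulate_responses(theta, design.item_difficulties, tau, rng,
                             pids, iids, "pre")
    post = simulate_responses(theta + design.effect + eta,
                              design.item_difficulties - design.item_shifts,
                              tau, rng, pids, iids, "post")
    if design.missing_rate > 0:
        for mat in (pre, post):
            mask = rng.random((n, k)) < design.missing_rate
            mat.values[mask] = np.nan

    truth = {
        "theta_pre": theta,
        "eta": eta,
        "theta_post": theta + design.effect + eta,
        "delta": design.item_difficulties.copy(),
        "delta_post": design.item_difficulties - design.item_shifts,
        "tau": tau,
        "effect": design.effect,
        "item_shifts": design.item_shifts.copy(),
        "seed": design.seed,
        "label": design.label,
    }
    return pre, post, truth


def ceiling_rate(matrix: ResponseMatrix) -> float:
    """Fraction of persons at the maximum possible raw score."""
    obs = matrix.observed
    r = np.nansum(matrix.values, axis=1)
    rmax = matrix.max_category * obs.sum(axis=1)
    return float(np.mean((r >= rmax) & (rmax > 0)))
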