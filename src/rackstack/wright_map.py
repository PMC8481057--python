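"""Text rendering of person-item Wright maps.

A Wright map places person abilities and item difficulties on one vertical
logit axis: persons on the left, items on the right, binned at a fixed logit
width.  For stacked or racked summaries the two occasions share the map, with
pretest entities prefixed "P" and posttest entities prefixed "0", so skill
gain reads as the same label climbing the axis.  The monospace text block is
the primary artifact (diff-able and parseable); PNG output is a thin layer on
top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_model import CalibrationResult, ValidationError
from .prepost import POST_PREFIX, PRE_PREFIX, EffectSummary

__all__ = ["WrightMapSpec", "render_wright_map", "save_wright_map_png"]


@dataclass
class WrightMapSpec:
    """Layout of the map: bin width in logits and optional fixed axis range."""

    bin_width: float = 0.5
    axis_min: float | None = None
    axis_max: float | None = None

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be positive")


def _entities(obj) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """(persons, items) label/measure pairs for either input kind.

    For a calibration every person appears (extremes carry adjusted finite
    measures); items appear if non-extreme.  For an effect summary each
    entity appears once per occasion with the occasion prefix, and the joint
    calibration's shared co-parameters fill the other side.
    """
    if isinstance(obj, CalibrationResult):
        p = obj.params
        persons = [(pid, float(t)) for pid, t in zip(p.person_ids, p.theta)
                   if np.isfinite(t)]
        items = [(iid, float(d))
                 for iid, d, ex in zip(p.item_ids, p.delta, p.extreme_item)
                 if not ex and np.isfinite(d)]
        return persons, items
    if isinstance(obj, EffectSummary):
        tagged = [(PRE_PREFIX + r.id, r.measure_pre) for r in obj.records]
        tagged += [(POST_PREFIX + r.id, r.measure_post) for r in obj.records]
        co = [(i, m) for i, m in obj.co_measures if np.isfinite(m)]
        if obj.entity_kind == "person":
            return tagged, co
        return co, tagged
    raise ValidationError(f"cannot render a {type(obj).__name__}")


def _landmarks(measures: np.ndarray) -> dict[float, str]:
    """Logit positions of the mean (M), +-1 SD (S) and +-2 SD (T) marks."""
    if measures.size == 0:
        return {}
    mu = float(measures.mean())
    sd = float(measures.std(ddof=1)) if measures.size > 1 else 0.0
    marks = {mu: "M"}
    if sd > 0:
        for s, tag in ((1, "S"), (2, "T")):
            marks[mu + s * sd] = tag
            marks[mu - s * sd] = tag
    return marks


def render_wright_map(obj, spec: WrightMapSpec | None = None) -> str:
    """Render a monospace Wright map for a calibration or effect summary.

    Each row covers one bin of ``spec.bin_width`` logits, highest bin first:

        <bin lower edge> <person glyphs> |<P><axis><I>| <item glyphs>

    where the axis column carries M/S/T landmarks of the person (left) and
    item (right) distributions.  Ties within a bin sort lexicographically.
    """
    spec = spec or WrightMapSpec()
    persons, items = _entities(obj)
    if not persons and not items:
        raise ValidationError("nothing to render")
    all_m = np.array([m for _, m in persons + items])
    lo = spec.axis_min if spec.axis_min is not None else all_m.min()
    hi = spec.axis_max if spec.axis_max is not None else all_m.max()
    bw = spec.bin_width
    b_lo = math.floor(lo / bw)
    b_hi = math.floor(hi / bw)

    def _bin(m: float) -> int:
        return min(max(math.floor(m / bw), b_lo), b_hi)

    pbins: dict[int, list[str]] = {}
    ibins: dict[int, list[str]] = {}
    for label, m in persons:
        pbins.setdefault(_bin(m), []).append(label)
    for label, m in items:
        ibins.setdefault(_bin(m), []).append(label)

    pmarks = _landmarks(np.array([m for _, m in persons]))
    imarks = _landmarks(np.array([m for _, m in items]))

    def _mark(marks: dict[float, str], b: int) -> str:
        tags = [t for pos, t in marks.items() if _bin(pos) == b]
        for pref in ("M", "S", "T"):
            if pref in tags:
                return pref
        return " "

    left_w = max([len(" ".join(sorted(v))) for v in pbins.values()] + [6])
    lines = [f"{'logit':>7} {'persons':>{left_w}} |MAP| items"]
    for b in range(b_hi, b_lo - 1, -1):
        left = " ".join(sorted(pbins.get(b, [])))
        right = " ".join(sorted(ibins.get(b, [])))
        edge = b * bw
        lines.append(
            f"{edge:7.2f} {left:>{left_w}} |{_mark(pmarks, b)}+{_mark(imarks, b)}| {right}".rstrip()
        )
    return "\n".join(lines) + "\n"


def save_wright_map_png(obj, path, spec: WrightMapSpec | None = None) -> None:
    """Scatter version of the map (persons left, items right) as a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    persons, items = _entities(obj)
    fig, ax = plt.subplots(figsize=(6, 8))
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    if persons:
        y = [m for _, m in persons]
        ax.scatter(-0.5 + 0.25 * rng.standard_normal(len(y)), y,
                   s=12, label="persons")
    if items:
        y = [m for _, m in items]
        ax.scatter(0.5 + 0.25 * rng.standard_normal(len(y)), y,
                   s=20, marker="s", label="items")
    ax.axvline(0.0, color="grey", lw=0.5)
    ax.set_xlim(-1.5, 1.5)
    ax.set_xticks([])
    ax.set_ylabel("logit")
    ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
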