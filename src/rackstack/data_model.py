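"""Core data containers and I/O for ordinal skill-checklist response tables.

The unit of analysis is a persons x items matrix of ordinal observer ratings
(0 .. max_category), one matrix per assessment occasion.  Missing cells are
carried as NaN and excluded from every downstream sum.  Person and item
identifiers are strings and are matched exactly (case-sensitive): silent
fuzzy matching would corrupt paired pre/post designs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = np.nan

DEFAULT_MISSING_CODES = ("", "NA", ".")


class ValidationError(ValueError):
    """A response table or parameter set violates a structural invariant."""


class ParseError(ValueError):
    """A cell of an input file could not be interpreted."""


class AlignmentError(ValueError):
    """Pre and post tables share no persons or no items."""


class CalibrationError(RuntimeError):
    """Estimation cannot proceed (degenerate data, all-extreme, ...)."""


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {kind} id: {x!r}")
        seen.add(x)


@dataclass
class ResponseMatrix:
    """Persons x items ordinal ratings with missing-value support.

    ``values`` is a float array where each non-missing entry is an integer in
    ``{0, ..., max_category}`` and missing cells are NaN.  ``max_category`` is
    the declared scale maximum, not the observed one: an occasion where nobody
    scores 2 still has ``max_category=2``.
    """

    person_ids: list[str]
    item_ids: list[str]
    values: np.ndarray
    max_category: int
    occasion_label: str = ""

    def __post_init__(self) -> None:
        self.person_ids = [str(p) for p in self.person_ids]
        self.item_ids = [str(i) for i in self.item_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        n, k = self.values.shape
        if n != len(self.person_ids) or k != len(self.item_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.person_ids)} persons x {len(self.item_ids)} items"
            )
        if n < 2 or k < 2:
            raise ValidationError("need at least 2 persons and 2 items")
        if int(self.max_category) != self.max_category or self.max_category < 1:
            raise ValidationError("max_category must be an integer >= 1")
        self.max_category = int(self.max_category)
        _check_unique(self.person_ids, "person")
        _check_unique(self.item_ids, "item")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and not np.all(obs == np.round(obs)):
            raise ValidationError("non-integer rating found")
        if obs.size and (obs.min() < 0 or obs.max() > self.max_category):
            raise ValidationError(
                f"ratings must lie in 0..{self.max_category}; "
                f"found range [{obs.min():g}, {obs.max():g}]"
            )

    # -- basic geometry -------------------------------------------------

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing cells."""
        return ~np.isnan(self.values)

    def person_scores(self) -> np.ndarray:
        """Raw score per person over that person's observed items."""
        return np.nansum(self.values, axis=1)

    def item_scores(self) -> np.ndarray:
        return np.nansum(self.values, axis=0)

    def subset(self, persons: list[str] | None = None,
               items: list[str] | None = None) -> "ResponseMatrix":
        """Restrict to the given ids, in the given order."""
        pids = self.person_ids if persons is None else list(persons)
        iids = self.item_ids if items is None else list(items)
        prow = {p: r for r, p in enumerate(self.person_ids)}
        icol = {i: c for c, i in enumerate(self.item_ids)}
        rows = [prow[p] for p in pids]
        cols = [icol[i] for i in iids]
        return ResponseMatrix(pids, iids, self.values[np.ix_(rows, cols)],
                              self.max_category, self.occasion_label)

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(list(self.person_ids), list(self.item_ids),
                              self.values.copy(), self.max_category,
                              self.occasion_label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.person_ids, name="person_id"),
                            columns=self.item_ids)


def collapse_categories(matrix: ResponseMatrix) -> ResponseMatrix:
    """Renumber observed categories to consecutive integers starting at 0.

    Used when a category of the declared scale was never observed (which
    leaves its threshold inestimable).  The scale maximum becomes the number
    of distinct observed categories minus one.
    """
    obs = matrix.values[matrix.observed]
    cats = np.unique(obs)
    mapping = {c: r for r, c in enumerate(cats)}
    vals = matrix.values.copy()
    mask = matrix.observed
    vals[mask] = np.vectorize(mapping.get)(vals[mask])
    return ResponseMatrix(matrix.person_ids, matrix.item_ids, vals,
                          max(len(cats) - 1, 1), matrix.occasion_label)


@dataclass
class RaschParameters:
    """Person abilities, item difficulties and shared category thresholds.

    All measures are logits.  Anchoring: item difficulties are centred to
    mean 0 over non-extreme items and thresholds sum to 0; the record of the
    constraints applied is kept in ``anchoring``.
    """

    person_ids: list[str]
    item_ids: list[str]
    theta: np.ndarray
    delta: np.ndarray
    tau: np.ndarray
    se_theta: np.ndarray
    se_delta: np.ndarray
    extreme_person: np.ndarray
    extreme_item: np.ndarray
    anchoring: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.se_theta = np.asarray(self.se_theta, dtype=float)
        self.se_delta = np.asarray(self.se_delta, dtype=float)
        self.extreme_person = np.asarray(self.extreme_person, dtype=bool)
        self.extreme_item = np.asarray(self.extreme_item, dtype=bool)
        if len(self.theta) != len(self.person_ids):
            raise ValidationError("theta length does not match person_ids")
        if len(self.delta) != len(self.item_ids):
            raise ValidationError("delta length does not match item_ids")

    @property
    def n_thresholds(self) -> int:
        return len(self.tau)


@dataclass
class CalibrationResult:
    """Parameters plus model-expected scores, score variances and residuals.

    ``expected``, ``resid_var`` and ``std_resid`` share the missingness
    pattern of the input matrix.  ``trace`` records one
    (iteration, max score residual, max logit change) triple per sweep.
    """

    params: RaschParameters
    expected: np.ndarray
    resid_var: np.ndarray
    std_resid: np.ndarray
    converged: bool
    n_iter: int
    max_residual: float
    trace: list = field(default_factory=list)
    data: ResponseMatrix | None = None


@dataclass
class PrePostDesign:
    """A pair of response matrices with aligned person and item identifiers."""

    pre: ResponseMatrix
    post: ResponseMatrix
    n_dropped_persons: int = 0
    n_dropped_items: int = 0
    mode: str | None = None  # "stack" | "rack" | None (set by the analysis)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_response_csv(path: str | Path, max_category: int,
                      missing_codes: tuple[str, ...] = DEFAULT_MISSING_CODES,
                      occasion_label: str = "") -> ResponseMatrix:
    """Read a wide response CSV: first column person id, one column per item.

    Cells matching ``missing_codes`` (after stripping whitespace) become
    missing.  Any other non-integer cell raises :class:`ParseError` naming
    the offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValidationError("need a person-id column and at least 2 item columns")
    person_ids = [s.strip() for s in df.iloc[:, 0].tolist()]
    item_ids = [str(c).strip() for c in df.columns[1:]]
    missing = {c.strip() for c in missing_codes} | {""}
    values = np.full((len(person_ids), len(item_ids)), np.nan)
    for r in range(len(person_ids)):
        for c, item in enumerate(item_ids):
            cell = df.iat[r, c + 1].strip()
            if cell in missing:
                continue
            try:
                v = int(cell)
            except ValueError as exc:
                raise ParseError(
                    f"non-integer cell {cell!r} at row {r + 2} "
                    f"(person {person_ids[r]!r}), column {item!r}"
                ) from exc
            values[r, c] = v
    return ResponseMatrix(person_ids, item_ids, values, max_category,
                          occasion_label or path.stem)


def write_response_csv(matrix: ResponseMatrix, path: str | Path) -> None:
    """Write a wide response CSV; missing cells become empty fields."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(["person_id"] + list(matrix.item_ids)) + "\n")
        for r, pid in enumerate(matrix.person_ids):
            cells = [pid]
            for v in matrix.values[r]:
                cells.append("" if np.isnan(v) else str(int(v)))
            fh.write(",".join(cells) + "\n")


def align_prepost(pre: ResponseMatrix, post: ResponseMatrix) -> PrePostDesign:
    """Restrict both occasions to shared persons and items, in pre's order."""
    if pre.max_category != post.max_category:
        raise ValidationError(
            f"occasions disagree on max_category: {pre.max_category} vs "
            f"{post.max_category}"
        )
    post_p = set(post.person_ids)
    post_i = set(post.item_ids)
    persons = [p for p in pre.person_ids if p in post_p]
    items = [i for i in pre.item_ids if i in post_i]
    if not persons:
        raise AlignmentError("no persons shared between occasions")
    if not items:
        raise AlignmentError("no items shared between occasions")
    dropped_p = (pre.n_persons - len(persons)) + (post.n_persons - len(persons))
    dropped_i = (pre.n_items - len(items)) + (post.n_items - len(items))
    return PrePostDesign(pre=pre.subset(persons, items),
                         post=post.subset(persons, items),
                         n_dropped_persons=dropped_p,
                         n_dropped_items=dropped_i)


# ---------------------------------------------------------------------------
# Parameter I/O
# ---------------------------------------------------------------------------

def _float_list(a: np.ndarray) -> list:
    return [None if not np.isfinite(x) else float(x) for x in np.asarray(a, float)]


def write_parameters_json(params: RaschParameters, path: str | Path) -> None:
    payload = {
        "persons": [
            {"id": pid, "measure": m, "se": s, "extreme": bool(e)}
            for pid, m, s, e in zip(params.person_ids,
                                    _float_list(params.theta),
                                    _float_list(params.se_theta),
                                    params.extreme_person)
        ],
        "items": [
            {"id": iid, "measure": m, "se": s, "extreme": bool(e)}
            for iid, m, s, e in zip(params.item_ids,
                                    _float_list(params.delta),
                                    _float_list(params.se_delta),
                                    params.extreme_item)
        ],
        "thresholds": _float_list(params.tau),
        "anchoring": params.anchoring,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def read_parameters_json(path: str | Path) -> RaschParameters:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    persons = payload["persons"]
    items = payload["items"]
    return RaschParameters(
        person_ids=[p["id"] for p in persons],
        item_ids=[i["id"] for i in items],
        theta=np.array([p["measure"] for p in persons], dtype=float),
        delta=np.array([i["measure"] for i in items], dtype=float),
        tau=np.array(payload["thresholds"], dtype=float),
        se_theta=np.array([np.nan if p["se"] is None else p["se"] for p in persons], dtype=float),
        se_delta=np.array([np.nan if i["se"] is None else i["se"] for i in items], dtype=float),
        extreme_person=np.array([p["extreme"] for p in persons], dtype=bool),
        extreme_item=np.array([i["extreme"] for i in items], dtype=bool),
        anchoring=payload.get("anchoring", {}),
    )


def write_parameters_csv(params: RaschParameters, path: str | Path) -> None:
    """Tidy long format: entity,id,measure,se,extreme (thresholds included)."""
    rows = []
    for pid, m, s, e in zip(params.person_ids, params.theta, params.se_theta,
                            params.extreme_person):
        rows.append(("person", pid, m, s, bool(e)))
    for iid, m, s, e in zip(params.item_ids, params.delta, params.se_delta,
                            params.extreme_item):
        rows.append(("item", iid, m, s, bool(e)))
    for j, t in enumerate(params.tau, start=1):
        rows.append(("threshold", f"tau{j}", t, np.nan, False))
    df = pd.DataFrame(rows, columns=["entity", "id", "measure", "se", "extreme"])
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def parameters_to_dict(params: RaschParameters) -> dict:
    """Round-trippable plain-dict form (used by the report bundle)."""
    return {
        "person_ids": list(params.person_ids),
        "item_ids": list(params.item_ids),
        "theta": _float_list(params.theta),
        "delta": _float_list(params.delta),
        "tau": _float_list(params.tau),
    }
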