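"""MDS-UPDRS part III scoring and subscore cross-correlation.

The motor examination (part III) of the MDS-UPDRS instrument comprises 18
items; each item is the sum of one or more rated sub-elements scored 0-4
(e.g. rigidity is rated separately for neck and four limbs). Items are
grouped into four symptom-domain subscores:

* tremor — items 15-18 (postural, kinetic and rest tremor);
* rigidity — item 3;
* bradykinesia — items 2, 4-9 and 14;
* axial — items 1 and 9-13 (speech, arising, gait, freezing, postural
  stability, posture).

Item 9 (arising from chair) appears in both the bradykinesia and the axial
grouping; the groupings are applied exactly as defined, so the item is
double-counted across the two subscores but counted once in the total.
Users who prefer a non-overlapping convention can pass a different
``axial_items`` tuple to :func:`compute_subscores`.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TREMOR_ITEMS",
    "RIGIDITY_ITEMS",
    "BRADYKINESIA_ITEMS",
    "AXIAL_ITEMS",
    "SUBSCORE_LABELS",
    "ClinicalRecord",
    "SubscoreSet",
    "CorrelationMatrix",
    "compute_subscores",
    "select_nearest_visit",
    "critical_r",
    "variance_explained_pct",
    "cross_correlation_matrix",
    "aggregate_subelements",
    "read_clinical_csv",
    "subscore_table",
    "write_correlation_csv",
]

TREMOR_ITEMS: tuple[int, ...] = (15, 16, 17, 18)
RIGIDITY_ITEMS: tuple[int, ...] = (3,)
BRADYKINESIA_ITEMS: tuple[int, ...] = (2, 4, 5, 6, 7, 8, 9, 14)
AXIAL_ITEMS: tuple[int, ...] = (1, 9, 10, 11, 12, 13)

#: Column order used by every correlation table in the package.
SUBSCORE_LABELS: tuple[str, ...] = ("axial", "bradykinesia", "rigidity", "tremor", "total")

#: Raw instrument sub-element -> item mapping (lower-cased PPMI-style names).
#: 33 rated sub-elements aggregate to the 18 items.
SUBELEMENT_ITEM_MAP: dict[str, int] = {
    "np3spch": 1,
    "np3facxp": 2,
    "np3rign": 3, "np3rigru": 3, "np3riglu": 3, "np3rigrl": 3, "np3rigll": 3,
    "np3ftapr": 4, "np3ftapl": 4,
    "np3hmovr": 5, "np3hmovl": 5,
    "np3prspr": 6, "np3prspl": 6,
    "np3ttapr": 7, "np3ttapl": 7,
    "np3lgagr": 8, "np3lgagl": 8,
    "np3risng": 9,
    "np3gait": 10,
    "np3frzgk": 11,
    "np3pstbl": 12,
    "np3postr": 13,
    "np3brady": 14,
    "np3ptrmr": 15, "np3ptrml": 15,
    "np3ktrmr": 16, "np3ktrml": 16,
    "np3rtaru": 17, "np3rtalu": 17, "np3rtarl": 17, "np3rtall": 17, "np3rtalj": 17,
    "np3rtcon": 18,
}


@dataclass(frozen=True)
class ClinicalRecord:
    """One motor-examination visit for one subject.

    ``item_scores`` maps item index 1..18 to the non-negative integer item
    score (sub-elements already summed).  ``sex`` is coded female=0, male=1.
    """

    subject_id: str
    visit_date: _dt.date
    item_scores: Mapping[int, int]
    age: float
    sex: int
    on_medication: bool

    def __post_init__(self) -> None:
        missing = [i for i in range(1, 19) if i not in self.item_scores]
        if missing:
            raise ValueError(
                f"subject {self.subject_id}: missing MDS-UPDRS III item(s) {missing}"
            )
        for i in range(1, 19):
            v = self.item_scores[i]
            if v < 0:
                raise ValueError(
                    f"subject {self.subject_id}: item {i} score {v} is negative"
                )
            if int(v) != v:
                raise ValueError(
                    f"subject {self.subject_id}: item {i} score {v} is not an integer"
                )
        if self.age <= 0:
            raise ValueError(f"subject {self.subject_id}: age must be positive")


@dataclass(frozen=True)
class SubscoreSet:
    """Symptom-domain sums and the total part III score."""

    tremor: int
    rigidity: int
    bradykinesia: int
    axial: int
    total: int

    def __post_init__(self) -> None:
        for name in ("tremor", "rigidity", "bradykinesia", "axial", "total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} subscore is negative")

    def as_dict(self) -> dict[str, int]:
        return {
            "axial": self.axial,
            "bradykinesia": self.bradykinesia,
            "rigidity": self.rigidity,
            "tremor": self.tremor,
            "total": self.total,
        }


@dataclass
class CorrelationMatrix:
    """Pearson cross-correlation of the subscores and total.

    ``values`` is symmetric with unit diagonal in the order of ``labels``.
    ``critical_value`` is the two-tailed critical |r| at ``alpha`` for
    ``df`` degrees of freedom; pairs with |r| above it are significant.
    ``variance_explained_pct`` gives 100*r^2 (rounded to integer percent)
    of each subscore against the total.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    df: int
    alpha: float
    critical_value: float
    variance_explained_pct: dict[str, int] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


def compute_subscores(
    record: ClinicalRecord,
    *,
    tremor_items: Sequence[int] = TREMOR_ITEMS,
    rigidity_items: Sequence[int] = RIGIDITY_ITEMS,
    bradykinesia_items: Sequence[int] = BRADYKINESIA_ITEMS,
    axial_items: Sequence[int] = AXIAL_ITEMS,
) -> SubscoreSet:
    """Sum item scores into the four motor subscores and the total.

    The default groupings overlap on item 9 (in both bradykinesia and
    axial); the total is always the plain sum of all 18 items, so the item
    is never double-counted in the total.
    """
    s = record.item_scores

    def group_sum(items: Sequence[int]) -> int:
        return int(sum(s[i] for i in items))

    return SubscoreSet(
        tremor=group_sum(tremor_items),
        rigidity=group_sum(rigidity_items),
        bradykinesia=group_sum(bradykinesia_items),
        axial=group_sum(axial_items),
        total=int(sum(s[i] for i in range(1, 19))),
    )


def select_nearest_visit(
    records: Sequence[ClinicalRecord], scan_date: _dt.date
) -> ClinicalRecord:
    """Pick the visit closest in time to the MRI scan.

    Ties (equal absolute day offset before and after the scan) resolve to
    the earlier visit, a deterministic, pre-treatment-leaning rule.
    """
    if not records:
        raise ValueError("no clinical records supplied")
    ids = {r.subject_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records span multiple subjects: {sorted(ids)}")
    return min(records, key=lambda r: (abs((r.visit_date - scan_date).days), r.visit_date))


def critical_r(alpha: float, df: int, tails: str = "two") -> float:
    """Critical Pearson |r| at significance ``alpha`` for ``df = n - 2``.

    Inverts the r -> t map ``t = r * sqrt(df / (1 - r^2))``:
    ``r* = t* / sqrt(t*^2 + df)`` where t* is the alpha-level Student-t
    critical value (two-tailed by default).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if tails == "two":
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    elif tails == "one":
        tcrit = stats.t.ppf(1.0 - alpha, df)
    else:
        raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
    return float(tcrit / np.sqrt(tcrit**2 + df))


def variance_explained_pct(r: float) -> int:
    """Share of variance explained by a correlation, as an integer percent.

    ``100 * r^2`` rounded to the nearest integer — the convention used when
    summarising how much of the total score a subscore accounts for.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    return int(round(100.0 * r * r))


def cross_correlation_matrix(
    subscores: Sequence[SubscoreSet] | pd.DataFrame, alpha: float = 0.05
) -> CorrelationMatrix:
    """Pearson cross-correlation of the four subscores and the total.

    Accepts a sequence of :class:`SubscoreSet` or a DataFrame with the
    :data:`SUBSCORE_LABELS` columns.  Zero-variance columns yield NaN
    correlations (flagged, never silently zero).  ``df = n - 2``; the
    attached critical value is two-tailed at ``alpha``.
    """
    if isinstance(subscores, pd.DataFrame):
        table = subscores.loc[:, list(SUBSCORE_LABELS)].astype(float)
    else:
        table = pd.DataFrame([s.as_dict() for s in subscores], columns=list(SUBSCORE_LABELS))
    n = len(table)
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")

    x = table.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.corrcoef(x, rowvar=False)
    values[degenerate, :] = np.nan
    values[:, degenerate] = np.nan
    np.fill_diagonal(values, 1.0)

    df = n - 2
    rcrit = critical_r(alpha, df, tails="two")
    var_expl = {
        lab: variance_explained_pct(values[i, -1])
        for i, lab in enumerate(SUBSCORE_LABELS[:-1])
        if np.isfinite(values[i, -1])
    }
    return CorrelationMatrix(
        labels=SUBSCORE_LABELS,
        values=values,
        df=df,
        alpha=alpha,
        critical_value=rcrit,
        variance_explained_pct=var_expl,
    )


def aggregate_subelements(frame: pd.DataFrame) -> pd.DataFrame:
    """Sum 33 raw ``np3_*`` sub-element columns into the 18 item columns.

    Column matching is case-insensitive and ignores underscores, so both
    ``np3_rig_ru`` and ``NP3RIGRU`` are accepted.  Returns a copy of the
    frame with ``item_1`` .. ``item_18`` columns appended.
    """
    canon = {c: c.lower().replace("_", "") for c in frame.columns}
    by_item: dict[int, list[str]] = {}
    for col, key in canon.items():
        if key in SUBELEMENT_ITEM_MAP:
            by_item.setdefault(SUBELEMENT_ITEM_MAP[key], []).append(col)
    missing = sorted(set(range(1, 19)) - set(by_item))
    if missing:
        raise ValueError(f"no sub-element columns found for item(s) {missing}")
    out = frame.copy()
    for item, cols in sorted(by_item.items()):
        out[f"item_{item}"] = frame[cols].sum(axis=1).astype(int)
    return out


def read_clinical_csv(path) -> list[ClinicalRecord]:
    """Read an item-level clinical table.

    Requires columns ``subject_id, visit_date`` (ISO-8601),
    ``item_1 .. item_18, age, sex, on_medication``; if the item columns are
    absent but raw ``np3_*`` sub-element columns are present they are
    aggregated first.  Non-ISO dates are rejected.
    """
    frame = pd.read_csv(path)
    item_cols = [f"item_{i}" for i in range(1, 19)]
    if not set(item_cols).issubset(frame.columns):
        frame = aggregate_subelements(frame)
    required = ["subject_id", "visit_date", "age", "sex", "on_medication", *item_cols]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"clinical table missing column(s): {missing}")

    records = []
    for _, row in frame.iterrows():
        try:
            date = _dt.date.fromisoformat(str(row["visit_date"]))
        except ValueError as exc:
            raise ValueError(
                f"subject {row['subject_id']}: visit_date {row['visit_date']!r} "
                "is not ISO-8601 (YYYY-MM-DD)"
            ) from exc
        records.append(
            ClinicalRecord(
                subject_id=str(row["subject_id"]),
                visit_date=date,
                item_scores={i: int(row[f"item_{i}"]) for i in range(1, 19)},
                age=float(row["age"]),
                sex=int(row["sex"]),
                on_medication=bool(row["on_medication"]),
            )
        )
    return records


def subscore_table(records: Sequence[ClinicalRecord], **groupings) -> pd.DataFrame:
    """Score every record; returns one row per record with id/covariates."""
    rows = []
    for rec in records:
        sub = compute_subscores(rec, **groupings)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "visit_date": rec.visit_date.isoformat(),
                **sub.as_dict(),
                "age": rec.age,
                "sex": rec.sex,
                "on_medication": rec.on_medication,
            }
        )
    return pd.DataFrame(rows)


def write_correlation_csv(matrix: CorrelationMatrix, path) -> None:
    """Write the correlation matrix with a footer recording alpha/df/critical r."""
    frame = matrix.as_frame()
    with open(path, "w") as fh:
        frame.to_csv(fh, float_format="%.4f")
        fh.write(f"# alpha,{matrix.alpha}\n")
        fh.write(f"# df,{matrix.df}\n")
        fh.write(f"# critical_r,{matrix.critical_value:.4f}\n")
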