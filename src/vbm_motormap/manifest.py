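"""Cohort accounting: who entered, who was excluded, and why.

Exclusion precedence is deterministic: segmentation failures are counted
first, missing motor scores second, so a subject failing both is counted
once, under segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["CohortManifest", "build_manifest", "unmedicated_percent"]


def unmedicated_percent(n_final: int, n_medicated: int, decimals: int = 1) -> float:
    """Percentage of included subjects not on medication, truncated.

    Truncation (not rounding) at ``decimals`` matches the convention of
    reporting e.g. 247/364 as 67.8%.
    """
    if not 0 <= n_medicated <= n_final:
        raise ValueError("need 0 <= n_medicated <= n_final")
    pct = 100.0 * (n_final - n_medicated) / n_final
    scale = 10.0**decimals
    return int(pct * scale) / scale


@dataclass
class CohortManifest:
    n_initial: int
    n_excluded_segmentation: int
    n_excluded_missing_scores: int
    n_final: int
    n_male: int
    exclusion_reasons: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = self.n_initial - self.n_excluded_segmentation - self.n_excluded_missing_scores
        if self.n_final != expected:
            raise ValueError(
                f"inconsistent manifest: {self.n_initial} - {self.n_excluded_segmentation} "
                f"- {self.n_excluded_missing_scores} != {self.n_final}"
            )

    def as_dict(self) -> dict:
        return {
            "n_initial": self.n_initial,
            "n_excluded_segmentation": self.n_excluded_segmentation,
            "n_excluded_missing_scores": self.n_excluded_missing_scores,
            "n_final": self.n_final,
            "n_male": self.n_male,
            "exclusion_reasons": dict(self.exclusion_reasons),
        }


def build_manifest(subjects: pd.DataFrame | Sequence[Mapping]) -> CohortManifest:
    """Build the cohort manifest from per-subject flags.

    ``subjects`` needs columns ``subject_id``, ``segmentation_ok`` (bool),
    ``has_scores`` (bool) and optionally ``sex`` (male = 1).  A subject
    flagged ``included=True`` anywhere while failing a check is an error:
    the flags must be mutually consistent.
    """
    frame = pd.DataFrame(subjects)
    for col in ("subject_id", "segmentation_ok", "has_scores"):
        if col not in frame.columns:
            raise ValueError(f"subject table missing column {col!r}")
    if frame["subject_id"].duplicated().any():
        dups = frame.loc[frame["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dups}")
    if "included" in frame.columns:
        bad = frame[frame["included"] & ~(frame["segmentation_ok"] & frame["has_scores"])]
        if len(bad):
            raise ValueError(
                f"inconsistent flags: subjects marked included but failing checks: "
                f"{bad['subject_id'].tolist()}"
            )

    reasons: dict[str, str] = {}
    for _, row in frame.iterrows():
        if not row["segmentation_ok"]:
            reasons[str(row["subject_id"])] = "segmentation"
        elif not row["has_scores"]:
            reasons[str(row["subject_id"])] = "missing_scores"

    n_seg = sum(1 for r in reasons.values() if r == "segmentation")
    n_missing = sum(1 for r in reasons.values() if r == "missing_scores")
    kept = frame[frame["segmentation_ok"] & frame["has_scores"]]
    n_male = int((kept["sex"] == 1).sum()) if "sex" in frame.columns else 0
    return CohortManifest(
        n_initial=len(frame),
        n_excluded_segmentation=n_seg,
        n_excluded_missing_scores=n_missing,
        n_final=len(kept),
        n_male=n_male,
        exclusion_reasons=reasons,
    )
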