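"""Reading, writing and summarising the study's tabular layouts.

Two layouts are supported: the long per-window table (one row per
participant-fortnight, symptom columns plus one column per linguistic
feature) and the wide per-participant means table used for the
between-subject analysis. Blank cells encode missingness; tables are
UTF-8 delimited text with a configurable delimiter.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import RESERVED_COLUMNS, AssessmentWindow, LongitudinalDataset

logger = logging.getLogger(__name__)

TARGET_COLUMNS = {
    "depression": "phq9_total",
    "anxiety": "gad7_total",
    "suicidality": "item9",
}


class EmptyCohortError(ValueError):
    """Raised when a filter leaves no analysable participants."""


# ---------------------------------------------------------------------------
# long (per-window) layout


def write_individual_data(
    data: LongitudinalDataset, path, delimiter: str = ","
) -> None:
    data.to_frame().to_csv(path, sep=delimiter, index=False)


def read_individual_data(
    path,
    delimiter: str = ",",
    feature_columns: Sequence[str] | None = None,
) -> LongitudinalDataset:
    """Read a long per-window table into a validated dataset.

    Columns outside the reserved set and ``feature_columns`` are preserved
    as passthrough extras. Duplicate (participant, window) keys, ragged
    feature rows and non-numeric symptom cells each raise ``ValueError``
    with a message naming the problem.
    """
    df = pd.read_csv(path, sep=delimiter)
    required = {"participant_id", "window_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"table lacks required columns: {sorted(missing)}")
    return LongitudinalDataset.from_frame(df, feature_names=feature_columns)


# ---------------------------------------------------------------------------
# final-sample filter and cross-section (per-participant means) table


def matched_windows(data: LongitudinalDataset) -> list[AssessmentWindow]:
    """Windows where a completed assessment and a feature vector co-occur."""
    return [r for r in data.records if r.has_assessment and r.has_features]


def filter_final_sample(data: LongitudinalDataset) -> LongitudinalDataset:
    """Retain participants with >= 1 fortnight pairing an assessment with features.

    All windows of retained participants are kept; unmatched windows are
    dropped later, when analysis tables are built. Raises
    :class:`EmptyCohortError` when nobody qualifies.
    """
    keep = {r.participant_id for r in matched_windows(data)}
    removed = [p for p in data.participants if p not in keep]
    if removed:
        logger.info(
            "final-sample filter removed %d of %d participants",
            len(removed),
            data.n_participants,
        )
    kept_records = [r for r in data.records if r.participant_id in keep]
    if not kept_records:
        raise EmptyCohortError(
            "no participant has a fortnight with both an assessment and blog features"
        )
    return LongitudinalDataset(records=kept_records, feature_names=list(data.feature_names))


@dataclass
class CrossSectionTable:
    """Per-participant means of features and symptoms over matched fortnights.

    Means use only fortnights where the feature vector exists and the
    respective symptom scale was completed, so the table recomputes exactly
    from the long layout.
    """

    table: pd.DataFrame  # index participant_id; feature cols + mean_* + n_windows_used
    feature_names: list[str]

    @property
    def n_participants(self) -> int:
        return len(self.table)

    def features_matrix(self) -> np.ndarray:
        return self.table[self.feature_names].to_numpy(dtype=float)

    def targets_matrix(self) -> np.ndarray:
        cols = [f"mean_{t}" for t in TARGET_COLUMNS]
        return self.table[cols].to_numpy(dtype=float)

    @property
    def target_names(self) -> list[str]:
        return list(TARGET_COLUMNS)

    def write(self, path, delimiter: str = ",") -> None:
        self.table.to_csv(path, sep=delimiter, index=True)

    @classmethod
    def read(cls, path, delimiter: str = ",") -> "CrossSectionTable":
        df = pd.read_csv(path, sep=delimiter, index_col="participant_id")
        non_features = [f"mean_{t}" for t in TARGET_COLUMNS] + ["n_windows_used"]
        feature_names = [c for c in df.columns if c not in non_features]
        return cls(table=df, feature_names=feature_names)


def cross_section(data: LongitudinalDataset) -> CrossSectionTable:
    """Average features and symptom scores across matched fortnights per participant."""
    rows = []
    for pid in data.participants:
        windows = [
            r for r in data.windows_for(pid) if r.has_assessment and r.has_features
        ]
        if not windows:
            continue
        feats = np.mean([w.features for w in windows], axis=0)
        row = dict(zip(data.feature_names, feats))
        for target, col in TARGET_COLUMNS.items():
            vals = [getattr(w, col) for w in windows if getattr(w, col) is not None]
            row[f"mean_{target}"] = float(np.mean(vals)) if vals else np.nan
        row["n_windows_used"] = len(windows)
        row["participant_id"] = pid
        rows.append(row)
    if not rows:
        raise EmptyCohortError("no matched participant-fortnights to average")
    df = pd.DataFrame(rows).set_index("participant_id")
    order = (
        list(data.feature_names)
        + [f"mean_{t}" for t in TARGET_COLUMNS]
        + ["n_windows_used"]
    )
    return CrossSectionTable(table=df[order], feature_names=list(data.feature_names))


# ---------------------------------------------------------------------------
# activity summaries


@dataclass
class ActivitySummary:
    """Per-participant completion/posting totals with cohort-level aggregates.

    Cohort SDs use the sample (n-1) convention; ``mean_words_per_post`` is
    the per-participant mean, and its cohort mean averages those
    per-participant values (not total words over total posts).
    """

    per_participant: pd.DataFrame
    cohort: pd.DataFrame  # index: column name; columns: mean, sd, min, max

    COLUMNS = (
        "phq9_completed",
        "gad7_completed",
        "total_posts",
        "total_words",
        "mean_words_per_post",
    )

    @classmethod
    def from_participant_table(cls, table: pd.DataFrame) -> "ActivitySummary":
        missing = [c for c in cls.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"participant table lacks columns: {missing}")
        if table.empty:
            raise EmptyCohortError("cannot summarise an empty cohort")
        stats = {}
        for col in cls.COLUMNS:
            vals = table[col].astype(float)
            stats[col] = {
                "mean": vals.mean(),
                "sd": vals.std(ddof=1),
                "min": vals.min(),
                "max": vals.max(),
            }
        cohort = pd.DataFrame(stats).T[["mean", "sd", "min", "max"]]
        return cls(per_participant=table.reset_index(drop=True), cohort=cohort)

    def to_json_dict(self) -> dict:
        return {
            "n_participants": int(len(self.per_participant)),
            "cohort": {
                col: {k: float(v) for k, v in row.items()}
                for col, row in self.cohort.iterrows()
            },
        }


def summarize_activity(data: LongitudinalDataset) -> ActivitySummary:
    """Survey-completion and blog-activity totals per participant and cohort-wide."""
    rows = []
    for pid in data.participants:
        windows = data.windows_for(pid)
        total_posts = sum(w.n_posts for w in windows)
        total_words = sum(w.total_words for w in windows)
        rows.append(
            {
                "participant_id": pid,
                "phq9_completed": sum(w.phq9_total is not None for w in windows),
                "gad7_completed": sum(w.gad7_total is not None for w in windows),
                "total_posts": total_posts,
                "total_words": total_words,
                "mean_words_per_post": (
                    total_words / total_posts if total_posts else np.nan
                ),
            }
        )
    return ActivitySummary.from_participant_table(pd.DataFrame(rows))


def load_reference_activity_profile() -> pd.DataFrame:
    """Activity profile of the 38-participant reference blogging cohort.

    Per-participant survey-completion and posting totals for a published
    36-week blogging cohort; used as the canonical unbalanced completion
    pattern when degrading synthetic cohorts and in validation checks.
    """
    ref = importlib.resources.files("blogmood.datasets").joinpath(
        "reference_cohort_activity.csv"
    )
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
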