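"""Core longitudinal data containers.

A cohort is a collection of fortnightly assessment windows. Each window
pairs self-reported symptom scales (PHQ-9 depression total, GAD-7 anxiety
total, the PHQ-9 self-harm item, and a panic-attack count) with the
window-averaged linguistic feature vector extracted from the participant's
blog posts in the same fortnight. Either side of a window can be missing:
the participant may have skipped the assessment, or published no posts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Reserved (non-feature) column names in the long per-window table layout.
RESERVED_COLUMNS = (
    "participant_id",
    "window_index",
    "phq9_total",
    "gad7_total",
    "item9",
    "panic_attacks",
    "n_posts",
    "post_word_counts",
)

PHQ9_MAX = 27
GAD7_MAX = 21
ITEM9_MAX = 3


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


@dataclass
class AssessmentWindow:
    """One participant-fortnight: symptom scales plus averaged blog features.

    ``features`` is the element-wise mean of the per-post linguistic scores
    for the fortnight and is ``None`` exactly when ``n_posts == 0``.
    Symptom fields are ``None`` when the assessment was not completed.
    """

    participant_id: str
    window_index: int
    phq9_total: int | None = None
    gad7_total: int | None = None
    item9: int | None = None
    panic_attacks: int | None = None
    n_posts: int = 0
    post_word_counts: tuple[int, ...] = ()
    features: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_index < 0:
            raise ValueError(f"window_index must be >= 0, got {self.window_index}")
        for name, value, hi in (
            ("phq9_total", self.phq9_total, PHQ9_MAX),
            ("gad7_total", self.gad7_total, GAD7_MAX),
            ("item9", self.item9, ITEM9_MAX),
        ):
            if value is not None and not (0 <= value <= hi):
                raise ValueError(f"{name}={value} outside [0, {hi}]")
        if self.phq9_total is not None and self.item9 is not None:
            if self.phq9_total < self.item9:
                raise ValueError(
                    "phq9_total < item9 is impossible: item 9 contributes to the total"
                )
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
        if (self.features is None) != (self.n_posts == 0):
            raise ValueError("features must be missing exactly when n_posts == 0")
        self.post_word_counts = tuple(int(w) for w in self.post_word_counts)
        if self.post_word_counts and len(self.post_word_counts) != self.n_posts:
            raise ValueError("post_word_counts length must equal n_posts")

    @property
    def has_assessment(self) -> bool:
        """True when at least one symptom scale was completed this fortnight."""
        return any(
            v is not None for v in (self.phq9_total, self.gad7_total, self.item9)
        )

    @property
    def has_features(self) -> bool:
        return self.features is not None

    @property
    def total_words(self) -> int:
        return int(sum(self.post_word_counts))


@dataclass
class LongitudinalDataset:
    """Long-format cohort: one :class:`AssessmentWindow` per participant-fortnight."""

    records: list[AssessmentWindow]
    feature_names: list[str]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        k = len(self.feature_names)
        for rec in self.records:
            key = (rec.participant_id, rec.window_index)
            if key in seen:
                raise ValueError(f"duplicate (participant, window) key {key}")
            seen.add(key)
            if rec.features is not None and rec.features.shape != (k,):
                raise ValueError(
                    f"feature vector length {rec.features.shape} != {k} for {key}"
                )

    @property
    def participants(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for rec in self.records:
            if rec.participant_id not in seen:
                seen.add(rec.participant_id)
                out.append(rec.participant_id)
        return out

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def windows_for(self, participant_id: str) -> list[AssessmentWindow]:
        rows = [r for r in self.records if r.participant_id == participant_id]
        if not rows:
            raise KeyError(f"participant {participant_id!r} not in dataset")
        return sorted(rows, key=lambda r: r.window_index)

    def to_frame(self) -> pd.DataFrame:
        """Long table: reserved columns, then one column per feature, then extras."""
        rows = []
        extra_keys: list[str] = []
        for rec in self.records:
            row: dict = {
                "participant_id": rec.participant_id,
                "window_index": rec.window_index,
                "phq9_total": rec.phq9_total,
                "gad7_total": rec.gad7_total,
                "item9": rec.item9,
                "panic_attacks": rec.panic_attacks,
                "n_posts": rec.n_posts,
                "post_word_counts": ";".join(str(w) for w in rec.post_word_counts),
            }
            feats = (
                rec.features
                if rec.features is not None
                else [np.nan] * len(self.feature_names)
            )
            row.update(dict(zip(self.feature_names, feats)))
            for key, value in rec.extras.items():
                if key not in extra_keys:
                    extra_keys.append(key)
                row[key] = value
            rows.append(row)
        cols = list(RESERVED_COLUMNS) + list(self.feature_names) + extra_keys
        df = pd.DataFrame(rows)
        for c in cols:
            if c not in df.columns:
                df[c] = np.nan
        return df[cols]

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        feature_names: Sequence[str] | None = None,
    ) -> "LongitudinalDataset":
        """Build a dataset from a long table.

        When ``feature_names`` is not given, every non-reserved column is
        treated as a linguistic feature; otherwise the remaining unknown
        columns are carried through as passthrough extras.
        """
        if feature_names is None:
            feature_names = [c for c in df.columns if c not in RESERVED_COLUMNS]
        feature_names = list(feature_names)
        missing_cols = [c for c in feature_names if c not in df.columns]
        if missing_cols:
            raise ValueError(f"feature columns absent from table: {missing_cols}")
        extra_cols = [
            c
            for c in df.columns
            if c not in RESERVED_COLUMNS and c not in feature_names
        ]
        records = []
        for _, row in df.iterrows():
            n_posts = int(row.get("n_posts", 0) or 0)
            feats = row[feature_names].to_numpy(dtype=float)
            if n_posts == 0:
                features = None
            else:
                features = feats
            wc_raw = row.get("post_word_counts", "")
            if _is_missing(wc_raw) or str(wc_raw) == "":
                word_counts: tuple[int, ...] = ()
            else:
                word_counts = tuple(int(float(t)) for t in str(wc_raw).split(";"))

            def _int_or_none(name: str) -> int | None:
                v = row.get(name)
                if _is_missing(v):
                    return None
                try:
                    fv = float(v)
                except (TypeError, ValueError) as exc:
                    raise ValueError(
                        f"non-numeric value {v!r} in column {name!r}"
                    ) from exc
                return int(round(fv))

            records.append(
                AssessmentWindow(
                    participant_id=str(row["participant_id"]),
                    window_index=int(row["window_index"]),
                    phq9_total=_int_or_none("phq9_total"),
                    gad7_total=_int_or_none("gad7_total"),
                    item9=_int_or_none("item9"),
                    panic_attacks=_int_or_none("panic_attacks"),
                    n_posts=n_posts,
                    post_word_counts=word_counts,
                    features=features,
                    extras={
                        c: row[c] for c in extra_cols if not _is_missing(row[c])
                    },
                )
            )
        return cls(records=records, feature_names=feature_names)

    def equals(self, other: "LongitudinalDataset") -> bool:
        if self.feature_names != other.feature_names:
            return False
        if len(self.records) != len(other.records):
            return False
        key = lambda r: (r.participant_id, r.window_index)
        for a, b in zip(sorted(self.records, key=key), sorted(other.records, key=key)):
            if (
                a.participant_id != b.participant_id
                or a.window_index != b.window_index
                or a.phq9_total != b.phq9_total
                or a.gad7_total != b.gad7_total
                or a.item9 != b.item9
                or a.panic_attacks != b.panic_attacks
                or a.n_posts != b.n_posts
                or a.post_word_counts != b.post_word_counts
            ):
                return False
            if (a.features is None) != (b.features is None):
                return False
            if a.features is not None and not np.allclose(
                a.features, b.features, rtol=0, atol=1e-9
            ):
                return False
        return True
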