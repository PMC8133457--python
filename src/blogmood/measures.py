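"""Scoring rules for the self-report symptom scales.

PHQ-9 (depression, 0-27) and GAD-7 (generalised anxiety, 0-21) totals are
classified into the conventional severity bands. Suicidal ideation is read
off item 9 of the PHQ-9 ("thoughts that you would be better off dead or of
hurting yourself", 0-3): any non-zero frequency flags suicidal thoughts,
while the raw 0-3 value serves as the continuous suicidality target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import GAD7_MAX, ITEM9_MAX, PHQ9_MAX

SCALE_MAX = {"PHQ9": PHQ9_MAX, "GAD7": GAD7_MAX}

# (label, low, high-before-cap); the top band runs to the scale maximum.
_BAND_EDGES = [
    ("nil-minimal", 0, 4),
    ("mild", 5, 9),
    ("moderate", 10, 14),
    ("moderately-severe", 15, 19),
]


@dataclass(frozen=True)
class SeverityBand:
    label: str
    low: int
    high: int  # inclusive

    def __contains__(self, total: int) -> bool:
        return self.low <= total <= self.high


def severity_bands(scale: str) -> list[SeverityBand]:
    """The five severity bands partitioning ``0..scale_max`` for PHQ9 or GAD7."""
    try:
        top = SCALE_MAX[scale]
    except KeyError:
        raise ValueError(f"unknown scale {scale!r}; expected 'PHQ9' or 'GAD7'")
    bands = [SeverityBand(label, lo, hi) for label, lo, hi in _BAND_EDGES]
    bands.append(SeverityBand("severe", 20, top))
    return bands


def severity_band(total: int, scale: str) -> SeverityBand:
    """Map a scale total to its unique severity band.

    Raises ``ValueError`` for totals outside the scale range.
    """
    bands = severity_bands(scale)
    if not (0 <= total <= SCALE_MAX[scale]):
        raise ValueError(f"{scale} total {total} outside [0, {SCALE_MAX[scale]}]")
    for band in bands:
        if total in band:
            return band
    raise AssertionError("bands must partition the scale range")  # pragma: no cover


def suicidal_flag(item9: int) -> bool:
    """True when the PHQ-9 self-harm item indicates suicidal thoughts (score > 0)."""
    if not (0 <= item9 <= ITEM9_MAX):
        raise ValueError(f"item9 score {item9} outside [0, {ITEM9_MAX}]")
    return item9 > 0


def average_window_features(post_level_scores) -> np.ndarray | None:
    """Element-wise mean of per-post feature vectors within one fortnight.

    An empty list signals a fortnight without blog posts and yields ``None``
    (a missing window), not an exception.
    """
    vectors = [np.asarray(v, dtype=float) for v in post_level_scores]
    if not vectors:
        return None
    lengths = {v.shape for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"post vectors have unequal lengths: {sorted(lengths)}")
    return np.mean(vectors, axis=0)
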