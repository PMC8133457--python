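"""Synthetic longitudinal blogging cohorts.

The generator draws a latent severity trait per participant and builds
fortnightly symptom scores and linguistic feature vectors around it:

* the window-level latent mood is ``trait + mood_within_sd * delta(i, w)``,
  a stable between-subject component plus fortnight-to-fortnight fluctuation;
* PHQ-9 / GAD-7 totals are affine transforms of that mood plus occasion
  noise, rounded and clipped to their bounded integer scales; the PHQ-9
  self-harm item is a monotone coarsening of the PHQ-9 total, so the
  item-9 <= total invariant holds by construction;
* feature ``j`` tracks ``between_loadings[j] x`` a mixture of the window
  mood and the stable trait. ``within_coupling`` = 1 makes the
  within-subject feature-symptom relation identical to the between-subject
  one (an ergodic cohort); 0 freezes features at their trait-driven level
  while symptoms keep fluctuating (non-ergodic). A shared per-window factor
  induces correlation among features, and values are truncated at zero
  because the upstream text analyser reports percent-of-words scores;
* assessments and blog fortnights are deleted independently at the
  configured rates; post counts per fortnight and words per post are
  over-dispersed (gamma-mixed Poisson) counts, matching the heavy-tailed
  activity profiles seen in real blogging cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .dataset import GAD7_MAX, PHQ9_MAX, AssessmentWindow, LongitudinalDataset

_DEFAULT_INFORMATIVE = {0: 1.0, 1: 0.8, 2: -0.8, 3: -1.0}


def default_between_loadings(n_features: int) -> np.ndarray:
    """Four informative features (two positive, two negative), the rest null."""
    loadings = np.zeros(n_features)
    for idx, value in _DEFAULT_INFORMATIVE.items():
        if idx < n_features:
            loadings[idx] = value
    return loadings


@dataclass
class SyntheticConfig:
    """Cohort-generation parameters.

    Scale anchors default to a moderately-severe cohort (PHQ-9 mean 14.5,
    GAD-7 mean 11.6, between-subject SDs ~5); missingness and posting rates
    default to a sparse 18-fortnight design in which roughly 42% of
    assessments are completed and posts are strongly over-dispersed.
    """

    n_participants: int
    n_windows: int = 18
    n_features: int = 68
    feature_names: list[str] | None = None
    between_loadings: np.ndarray | None = None  # feature units per trait SD
    within_coupling: float = 0.5
    symptom_noise_sd: float = 2.0  # occasion noise, scale points
    feature_noise_sd: float = 1.0  # window-level noise, percent-of-words points
    p_missing_assessment: float = 0.58
    p_missing_blog: float = 0.30
    posts_per_window_mean: float = 1.83
    words_per_post_mean: float = 192.76
    seed: int = 0
    # secondary shape parameters (trait units unless noted)
    mood_within_sd: float = 0.4
    phq9_mean: float = 14.5
    phq9_trait_sd: float = 5.0
    gad7_mean: float = 11.6
    gad7_trait_sd: float = 4.2
    feature_baseline: float | np.ndarray | None = None  # percent-of-words
    feature_common_sd: float = 0.4  # shared per-window factor loading scale
    posts_gamma_shape: float = 0.5
    words_gamma_shape: float = 1.2

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        for name in ("p_missing_assessment", "p_missing_blog"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0.0 <= self.within_coupling <= 1.0):
            raise ValueError(f"within_coupling={self.within_coupling} outside [0, 1]")
        for name in ("symptom_noise_sd", "feature_noise_sd", "mood_within_sd",
                     "feature_common_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("posts_per_window_mean", "words_per_post_mean",
                     "posts_gamma_shape", "words_gamma_shape"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.feature_names is None:
            self.feature_names = [f"feat_{j:02d}" for j in range(self.n_features)]
        if len(self.feature_names) != self.n_features:
            raise ValueError("feature_names length must equal n_features")
        if self.between_loadings is None:
            self.between_loadings = default_between_loadings(self.n_features)
        self.between_loadings = np.asarray(self.between_loadings, dtype=float)
        if self.between_loadings.shape != (self.n_features,):
            raise ValueError("between_loadings length must equal n_features")

    def to_json_dict(self) -> dict:
        out = {}
        for key, value in self.__dict__.items():
            if isinstance(value, np.ndarray):
                value = value.tolist()
            out[key] = value
        return out


def _coarsen_item9(phq9_total: np.ndarray) -> np.ndarray:
    # monotone coarsening of the total onto 0..3; floor(x/9) <= x for x >= 0
    return np.minimum(phq9_total // 9, 3)


def generate_cohort(config: SyntheticConfig) -> LongitudinalDataset:
    """Draw a cohort; identical config + seed reproduces a bit-identical dataset."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, w, p = cfg.n_participants, cfg.n_windows, cfg.n_features

    # fixed per-cohort feature geometry
    if cfg.feature_baseline is None:
        baseline = rng.gamma(shape=2.0, scale=2.0, size=p)
    else:
        baseline = np.broadcast_to(
            np.asarray(cfg.feature_baseline, dtype=float), (p,)
        ).copy()
    common_loadings = rng.uniform(0.5, 1.5, size=p) * cfg.feature_common_sd

    trait = rng.standard_normal(n)  # latent severity, SD 1
    mood = trait[:, None] + cfg.mood_within_sd * rng.standard_normal((n, w))

    phq = cfg.phq9_mean + cfg.phq9_trait_sd * mood \
        + cfg.symptom_noise_sd * rng.standard_normal((n, w))
    gad = cfg.gad7_mean + cfg.gad7_trait_sd * mood \
        + cfg.symptom_noise_sd * rng.standard_normal((n, w))
    phq = np.clip(np.rint(phq), 0, PHQ9_MAX).astype(int)
    gad = np.clip(np.rint(gad), 0, GAD7_MAX).astype(int)
    item9 = _coarsen_item9(phq)
    panic = rng.poisson(np.maximum(gad, 0) * 0.08)

    # feature signal: within_coupling blends window mood vs. stable trait
    signal = cfg.within_coupling * mood + (1.0 - cfg.within_coupling) * trait[:, None]
    shared = rng.standard_normal((n, w))

    # posting activity: participant-level gamma rates mixed with Poisson counts
    post_rate = rng.gamma(cfg.posts_gamma_shape,
                          cfg.posts_per_window_mean / cfg.posts_gamma_shape, size=n)
    word_rate = rng.gamma(cfg.words_gamma_shape,
                          cfg.words_per_post_mean / cfg.words_gamma_shape, size=n)

    blog_present = rng.random((n, w)) >= cfg.p_missing_blog
    assess_present = rng.random((n, w)) >= cfg.p_missing_assessment
    n_posts = np.where(blog_present, 1 + rng.poisson(post_rate[:, None], (n, w)), 0)

    noise = rng.standard_normal((n, w, p))

    records: list[AssessmentWindow] = []
    width = len(str(n))
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        for t in range(w):
            k = int(n_posts[i, t])
            if k > 0:
                word_counts = tuple(
                    int(c) for c in 1 + rng.poisson(word_rate[i], size=k)
                )
                feats = (
                    baseline
                    + cfg.between_loadings * signal[i, t]
                    + common_loadings * shared[i, t]
                    + cfg.feature_noise_sd * noise[i, t]
                )
                feats = np.maximum(feats, 0.0)
            else:
                word_counts = ()
                feats = None
            has_assessment = bool(assess_present[i, t])
            records.append(
                AssessmentWindow(
                    participant_id=pid,
                    window_index=t,
                    phq9_total=int(phq[i, t]) if has_assessment else None,
                    gad7_total=int(gad[i, t]) if has_assessment else None,
                    item9=int(item9[i, t]) if has_assessment else None,
                    panic_attacks=int(panic[i, t]) if has_assessment else None,
                    n_posts=k,
                    post_word_counts=word_counts,
                    features=feats,
                )
            )
    return LongitudinalDataset(records=records, feature_names=list(cfg.feature_names))


def degrade_to_study_profile(
    data: LongitudinalDataset,
    completion_counts: Sequence[int],
    seed: int,
) -> LongitudinalDataset:
    """Thin each participant's assessments down to an exact completion count.

    Reproduces unbalanced real-world completion profiles: participant ``i``
    keeps a seeded random subset of exactly ``completion_counts[i]`` of their
    completed assessments; the rest are blanked (blog data is untouched).
    """
    participants = data.participants
    if len(completion_counts) != len(participants):
        raise ValueError(
            f"completion_counts has {len(completion_counts)} entries for "
            f"{len(participants)} participants"
        )
    rng = np.random.default_rng(seed)
    by_pid = {pid: data.windows_for(pid) for pid in participants}
    new_records: list[AssessmentWindow] = []
    for pid, count in zip(participants, completion_counts):
        windows = by_pid[pid]
        completed = [w for w in windows if w.has_assessment]
        n_windows = len(windows)
        if count > n_windows:
            raise ValueError(
                f"requested {count} completions for {pid} with only "
                f"{n_windows} windows"
            )
        if count > len(completed):
            raise ValueError(
                f"participant {pid} has only {len(completed)} completed "
                f"assessments; cannot retain {count}"
            )
        keep_idx = set(
            rng.choice(
                [w.window_index for w in completed], size=count, replace=False
            ).tolist()
        )
        for w in windows:
            if w.has_assessment and w.window_index not in keep_idx:
                new_records.append(
                    replace(
                        w,
                        phq9_total=None,
                        gad7_total=None,
                        item9=None,
                        panic_attacks=None,
                    )
                )
            else:
                new_records.append(w)
    return LongitudinalDataset(
        records=new_records, feature_names=list(data.feature_names)
    )
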