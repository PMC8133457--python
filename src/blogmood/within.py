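"""Group-to-individual generalizability (ergodicity) testing.

The group-level PLS model is applied to each participant's own fortnightly
series: predicted symptom scores are correlated with observed scores over
time, the per-participant coefficients are Fisher z-transformed, and the
mean z is tested against zero with a one-sample t-test. The test is swept
over minimum-assessment thresholds (participants with at least n usable
fortnights, n = 3..18) because series length varies widely in sparse
longitudinal cohorts. A relationship that holds between subjects but not
within them (mean z ~ 0) indicates non-ergodicity: the group-level model
does not track individual symptom change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import TARGET_COLUMNS
from .dataset import LongitudinalDataset
from .pls import PLSModel

logger = logging.getLogger(__name__)


def per_participant_correlation(pred, obs, method: str = "pearson") -> float:
    """Correlation between predicted and observed series across timepoints.

    Pearson by default (the prediction stage is interval-scale); a rank
    variant is available. Returns NaN for a constant series (undefined
    correlation signal).
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("series lengths differ")
    if pred.size < 3:
        raise ValueError("need >= 3 paired timepoints")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(pred, obs).statistic)
    if method == "spearman":
        return float(stats.spearmanr(pred, obs).statistic)
    raise ValueError(f"unknown method {method!r}")


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform, atanh(r); infinite at |r| = 1."""
    if abs(r) > 1:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    with np.errstate(divide="ignore"):
        return float(np.arctanh(r))


def predict_trajectory(
    model: PLSModel, data: LongitudinalDataset, participant_id: str
) -> pd.DataFrame:
    """Predicted and observed symptom series for one participant.

    One row per (window, target) at which both the feature vector and that
    target's assessment exist; predictions are on the original symptom
    scale via the model's stored centers and scales.
    """
    windows = data.windows_for(participant_id)  # raises KeyError if absent
    missing = [f for f in model.feature_names if f not in data.feature_names]
    if missing:
        raise ValueError(f"dataset lacks model features: {missing}")
    col_idx = [data.feature_names.index(f) for f in model.feature_names]
    rows = []
    for w in windows:
        if not w.has_features:
            continue
        pred = model.predict(w.features[col_idx][None, :])[0]
        for t, target in enumerate(model.target_names):
            col = TARGET_COLUMNS.get(target)
            observed = getattr(w, col) if col else None
            if observed is None:
                continue
            rows.append(
                {
                    "participant_id": participant_id,
                    "window_index": w.window_index,
                    "target": target,
                    "predicted": float(pred[t]),
                    "observed": float(observed),
                }
            )
    return pd.DataFrame(
        rows, columns=["participant_id", "window_index", "target", "predicted",
                       "observed"]
    )


@dataclass
class WithinSubjectResult:
    """Per-participant time-series correlations and threshold-swept aggregates."""

    per_participant: pd.DataFrame  # participant_id, target, n_timepoints, r_time, z, usable
    aggregates: pd.DataFrame  # n_min, target, n_participants, mean_z, ci, t, p
    n_excluded: dict


def within_subject_analysis(
    model: PLSModel,
    data: LongitudinalDataset,
    n_min_range=range(3, 19),
    method: str = "pearson",
    ci_level: float = 0.95,
) -> WithinSubjectResult:
    """Apply the group model within subjects and aggregate Fisher z per threshold.

    Participants with fewer than 3 usable fortnights, a constant predicted
    or observed series, or |r| = 1 (infinite z) are excluded from
    aggregation and counted. Aggregates with fewer than 2 eligible
    participants are marked unavailable (NaN), not raised.
    """
    per_rows = []
    n_excluded = {"short_series": 0, "constant_series": 0, "infinite_z": 0}
    for pid in data.participants:
        traj = predict_trajectory(model, data, pid)
        for target in model.target_names:
            sub = traj[traj["target"] == target]
            n_t = len(sub)
            r_time = np.nan
            z = np.nan
            usable = False
            if n_t < 3:
                n_excluded["short_series"] += 1
            else:
                r_time = per_participant_correlation(
                    sub["predicted"].to_numpy(), sub["observed"].to_numpy(),
                    method=method,
                )
                if np.isnan(r_time):
                    n_excluded["constant_series"] += 1
                elif abs(r_time) >= 1.0 - 1e-12:
                    z = fisher_z(np.sign(r_time))
                    n_excluded["infinite_z"] += 1
                else:
                    z = fisher_z(r_time)
                    usable = True
            per_rows.append(
                {
                    "participant_id": pid,
                    "target": target,
                    "n_timepoints": n_t,
                    "r_time": r_time,
                    "fisher_z": z,
                    "usable": usable,
                }
            )
    per_df = pd.DataFrame(per_rows)
    agg_df = threshold_sweep(per_df, n_min_range=n_min_range, ci_level=ci_level)
    return WithinSubjectResult(
        per_participant=per_df, aggregates=agg_df, n_excluded=n_excluded
    )


def threshold_sweep(
    per_participant: pd.DataFrame,
    n_min_range=range(3, 19),
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Aggregate an existing per-participant table across minimum-assessment thresholds."""
    rows = []
    for target in per_participant["target"].unique():
        tdf = per_participant[
            (per_participant["target"] == target) & per_participant["usable"]
        ]
        for n_min in n_min_range:
            zs = tdf.loc[tdf["n_timepoints"] >= n_min, "fisher_z"].to_numpy()
            row = {"n_min": int(n_min), "target": target,
                   "n_participants": int(zs.size)}
            if zs.size >= 2 and np.ptp(zs) > 0:
                mean_z = float(zs.mean())
                sem = float(zs.std(ddof=1) / np.sqrt(zs.size))
                tcrit = float(stats.t.ppf(0.5 + ci_level / 2.0, zs.size - 1))
                tt = stats.ttest_1samp(zs, 0.0)
                row.update(mean_z=mean_z, ci_low=mean_z - tcrit * sem,
                           ci_high=mean_z + tcrit * sem,
                           t_stat=float(tt.statistic), p_value=float(tt.pvalue))
            elif zs.size >= 2:
                mean_z = float(zs.mean())
                row.update(mean_z=mean_z, ci_low=mean_z, ci_high=mean_z,
                           t_stat=0.0 if mean_z == 0 else float("inf") * np.sign(mean_z),
                           p_value=1.0 if mean_z == 0 else 0.0)
            else:
                row.update(mean_z=np.nan, ci_low=np.nan, ci_high=np.nan,
                           t_stat=np.nan, p_value=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
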