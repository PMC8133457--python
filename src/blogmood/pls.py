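"""Partial least squares regression between linguistic features and symptoms.

Features and targets are z-transformed; components are extracted by the
SIMPLS algorithm (de Jong 1993, Chemometr. Intell. Lab. Syst. 18:251-263),
which maximises the covariance between feature and target scores subject
to orthogonal score vectors. Components are deterministic and nested; at
full rank the coefficients coincide with the ordinary least-squares
solution, and with a single target the first weight vector is proportional
to the feature-target covariance vector.

Model size is chosen by k-fold cross-validation over participants: the
component count is increased until the cross-validated mean squared error
(on the standardized target scale) stops decreasing. A restricted model is
built by bootstrap feature selection: the one-component feature weights are
re-estimated over participant resamples, each feature receives a stability
z-score (bootstrap mean / bootstrap SD, sign-aligned to the full-sample
fit), and the top-k features by |z| are refit.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# standardization


@dataclass
class Standardizer:
    """Column-wise z-transform with the sample (n-1) SD; constant columns dropped."""

    center: np.ndarray
    scale: np.ndarray
    kept: np.ndarray  # indices of retained (non-constant) columns

    @classmethod
    def fit(cls, matrix: np.ndarray) -> "Standardizer":
        M = np.asarray(matrix, dtype=float)
        if M.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        center = M.mean(axis=0)
        scale = M.std(axis=0, ddof=1)
        kept = np.flatnonzero(scale > 0)
        if kept.size == 0:
            raise ValueError("all columns are constant; nothing to standardize")
        if kept.size < M.shape[1]:
            warnings.warn(
                f"dropping {M.shape[1] - kept.size} constant column(s)",
                stacklevel=2,
            )
        return cls(center=center[kept], scale=scale[kept], kept=kept)

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        M = np.asarray(matrix, dtype=float)
        return (M[:, self.kept] - self.center) / self.scale

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.scale + self.center


def zscore_fit_apply(matrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize columns to mean 0, SD 1 (n-1 convention).

    Returns ``(Z, center, scale)``; constant columns are dropped with a
    warning and an all-constant matrix is rejected.
    """
    scaler = Standardizer.fit(matrix)
    return scaler.transform(matrix), scaler.center.copy(), scaler.scale.copy()


# ---------------------------------------------------------------------------
# SIMPLS core


def _simpls(X: np.ndarray, Y: np.ndarray, n_components: int):
    """SIMPLS on centered (standardized) matrices.

    Returns weights R (T = X R), score matrix T, feature loadings P and
    target loadings Q, with the sign of each component fixed so the
    largest-magnitude entry of its weight vector is positive.
    """
    n, p = X.shape
    t = Y.shape[1]
    R = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((t, n_components))
    V = np.zeros((p, n_components))
    S = X.T @ Y
    for a in range(n_components):
        if t == 1:
            r = S[:, 0].copy()
        else:
            U_, _, _ = np.linalg.svd(S, full_matrices=False)
            r = U_[:, 0]
        scores = X @ r
        scores = scores - scores.mean()
        norm_t = np.linalg.norm(scores)
        if norm_t < 1e-12 * max(1.0, np.linalg.norm(X)):
            raise ValueError(
                f"component {a + 1} exceeds the rank of the feature matrix"
            )
        scores /= norm_t
        r = r / norm_t
        p_load = X.T @ scores
        q_load = Y.T @ scores
        # sign convention: dominant weight entry positive
        if r[np.argmax(np.abs(r))] < 0:
            r, scores, p_load, q_load = -r, -scores, -p_load, -q_load
        v = p_load.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_load)
        v /= np.linalg.norm(v)
        S = S - np.outer(v, v @ S)
        R[:, a], T[:, a], P[:, a], Q[:, a], V[:, a] = r, scores, p_load, q_load, v
    return R, T, P, Q


@dataclass
class PLSModel:
    """Fitted PLS regression with stored standardization parameters."""

    feature_names: list[str]
    target_names: list[str]
    n_components: int
    x_scaler: Standardizer
    y_scaler: Standardizer
    x_weights: np.ndarray  # (p_used, A)
    x_loadings: np.ndarray  # (p_used, A)
    y_loadings: np.ndarray  # (t, A)
    coef: np.ndarray  # (p_used, t), standardized scale
    restricted: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def features_used(self) -> list[str]:
        return [self.feature_names[i] for i in self.x_scaler.kept]

    def predict_standardized(self, X: np.ndarray) -> np.ndarray:
        return self.x_scaler.transform(np.asarray(X, dtype=float)) @ self.coef

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predictions on the original target scale."""
        return self.y_scaler.inverse_transform(self.predict_standardized(X))

    def to_json_dict(self) -> dict:
        return {
            "format_version": 1,
            "feature_names": self.feature_names,
            "target_names": self.target_names,
            "n_components": int(self.n_components),
            "restricted": bool(self.restricted),
            "x_center": self.x_scaler.center.tolist(),
            "x_scale": self.x_scaler.scale.tolist(),
            "x_kept": self.x_scaler.kept.tolist(),
            "y_center": self.y_scaler.center.tolist(),
            "y_scale": self.y_scaler.scale.tolist(),
            "y_kept": self.y_scaler.kept.tolist(),
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "meta": self.meta,
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)

    @classmethod
    def from_json_dict(cls, doc: dict) -> "PLSModel":
        return cls(
            feature_names=list(doc["feature_names"]),
            target_names=list(doc["target_names"]),
            n_components=int(doc["n_components"]),
            x_scaler=Standardizer(
                center=np.asarray(doc["x_center"], dtype=float),
                scale=np.asarray(doc["x_scale"], dtype=float),
                kept=np.asarray(doc["x_kept"], dtype=int),
            ),
            y_scaler=Standardizer(
                center=np.asarray(doc["y_center"], dtype=float),
                scale=np.asarray(doc["y_scale"], dtype=float),
                kept=np.asarray(doc["y_kept"], dtype=int),
            ),
            x_weights=np.asarray(doc["x_weights"], dtype=float),
            x_loadings=np.asarray(doc["x_loadings"], dtype=float),
            y_loadings=np.asarray(doc["y_loadings"], dtype=float),
            coef=np.asarray(doc["coef"], dtype=float),
            restricted=bool(doc["restricted"]),
            meta=dict(doc.get("meta", {})),
        )

    @classmethod
    def load(cls, path) -> "PLSModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json_dict(json.load(fh))


def fit_pls(
    X,
    Y,
    n_components: int,
    feature_names: list[str] | None = None,
    target_names: list[str] | None = None,
    restricted: bool = False,
) -> PLSModel:
    """Standardize raw feature/target matrices and fit a SIMPLS model.

    ``n_components`` may not exceed the rank of the standardized feature
    matrix. The fit is deterministic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    x_scaler = Standardizer.fit(X)
    y_scaler = Standardizer.fit(Y)
    Xz = x_scaler.transform(X)
    Yz = y_scaler.transform(Y)
    rank = np.linalg.matrix_rank(Xz)
    if not (1 <= n_components <= rank):
        raise ValueError(
            f"n_components={n_components} outside [1, rank(X)={rank}]"
        )
    R, T, P, Q = _simpls(Xz, Yz, n_components)
    coef = R @ Q.T
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    if target_names is None:
        target_names = [f"y{t}" for t in range(Y.shape[1])]
    return PLSModel(
        feature_names=list(feature_names),
        target_names=list(target_names),
        n_components=n_components,
        x_scaler=x_scaler,
        y_scaler=y_scaler,
        x_weights=R,
        x_loadings=P,
        y_loadings=Q,
        coef=coef,
        restricted=restricted,
    )


# ---------------------------------------------------------------------------
# cross-validated component selection


@dataclass
class CVCurve:
    """Cross-validated MSE per component count and the selected model size.

    ``mse_by_ncomp[0]`` is the train-fold-mean predictor (zero on the
    standardized target scale); ``selected_ncomp`` is the last count before
    the MSE first fails to decrease. ``relative_change_pct`` is
    ``100 * (mse[selected] - mse[0]) / mse[0]``.
    """

    mse_by_ncomp: np.ndarray
    selected_ncomp: int
    relative_change_pct: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_components": np.arange(len(self.mse_by_ncomp)),
                "cv_mse": self.mse_by_ncomp,
                "selected": [
                    i == self.selected_ncomp
                    for i in range(len(self.mse_by_ncomp))
                ],
            }
        )


def cv_select_ncomp(
    X,
    Y,
    k_folds: int = 5,
    max_ncomp: int = 10,
    seed: int | None = None,
    global_standardize: bool = False,
) -> CVCurve:
    """Select the PLS component count by k-fold cross-validated MSE.

    Rows (participants) are partitioned into seeded shuffled folds. By
    default standardization is re-fit on each training fold and applied to
    its held-out fold (no leakage); ``global_standardize=True`` standardizes
    once on the full sample, mirroring a single up-front z-transform.
    MSE is measured on the standardized target scale, averaged over all
    held-out rows and targets. The stopping rule picks the smallest m with
    ``mse[m+1] >= mse[m]``, else ``max_ncomp``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if n < k_folds:
        raise ValueError(f"need >= {k_folds} rows for {k_folds}-fold CV")
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X))
    if min(len(tr) for tr, _ in folds) < 2:
        raise ValueError("every training fold needs >= 2 rows")

    if global_standardize:
        gx = Standardizer.fit(X)
        gy = Standardizer.fit(Y)

    # cap components by what every training fold can support
    cap = max_ncomp
    for train, _ in folds:
        if global_standardize:
            Xtr = gx.transform(X[train])
        else:
            Xtr = Standardizer.fit(X[train]).transform(X[train])
        cap = min(cap, int(np.linalg.matrix_rank(Xtr - Xtr.mean(axis=0))), len(train) - 1)
    if cap < 1:
        raise ValueError("training folds cannot support a single component")

    sq_err = np.zeros(cap + 1)
    n_cells = 0
    for train, test in folds:
        if global_standardize:
            sx, sy = gx, gy
        else:
            sx = Standardizer.fit(X[train])
            sy = Standardizer.fit(Y[train])
        Xtr, Ytr = sx.transform(X[train]), sy.transform(Y[train])
        Xte, Yte = sx.transform(X[test]), sy.transform(Y[test])
        R, T, P, Q = _simpls(Xtr - Xtr.mean(axis=0), Ytr - Ytr.mean(axis=0), cap)
        Xte_c = Xte - Xtr.mean(axis=0)
        Yte_c = Yte - Ytr.mean(axis=0)
        sq_err[0] += float((Yte_c**2).sum())
        for m in range(1, cap + 1):
            B = R[:, :m] @ Q[:, :m].T
            resid = Yte_c - Xte_c @ B
            sq_err[m] += float((resid**2).sum())
        n_cells += Yte.size
    mse = sq_err / n_cells

    selected = cap
    for m in range(cap):
        if mse[m + 1] >= mse[m]:
            selected = m
            break
    rel = 100.0 * (mse[selected] - mse[0]) / mse[0]
    return CVCurve(mse_by_ncomp=mse, selected_ncomp=selected, relative_change_pct=rel)


# ---------------------------------------------------------------------------
# bootstrap feature-stability selection


@dataclass
class FeatureSelectionResult:
    """Bootstrap stability z-scores and the selected top-k feature set."""

    z_by_feature: pd.Series
    selected: list[str]
    k: int
    n_boot: int
    n_redrawn: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = self.z_by_feature.rename("z").rename_axis("feature").reset_index()
        df["selected"] = df["feature"].isin(self.selected)
        return df


def _one_component_weights(Xz: np.ndarray, yz: np.ndarray) -> np.ndarray:
    """First PLS direction for a single standardized target: X'y, normalized."""
    w = Xz.T @ yz
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("feature-target covariance vector is zero")
    return w / norm


def bootstrap_select_features(
    X,
    y,
    n_boot: int = 10_000,
    k: int = 4,
    seed: int | None = None,
    feature_names: list[str] | None = None,
    max_redraw_rounds: int = 50,
) -> FeatureSelectionResult:
    """Stability-select features from the bootstrapped one-component weights.

    Participants are resampled with replacement; per resample the
    one-component feature weight vector is recomputed and sign-aligned to
    the full-sample direction. Each feature's z-score is bootstrap mean /
    bootstrap SD; the k features with the largest |z| are selected, ties
    broken by feature label. Degenerate resamples (constant target) are
    redrawn and counted.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 10:
        raise ValueError("need >= 10 participants for bootstrap selection")
    if not (1 <= k <= p):
        raise ValueError(f"k={k} outside [1, {p}]")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]

    def _weights(Xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
        xc = Xb - Xb.mean(axis=0)
        xs = xc.std(axis=0, ddof=1)
        yc = yb - yb.mean()
        ys = yc.std(ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            Xz = np.where(xs > 0, xc / xs, 0.0)
        w = Xz.T @ (yc / ys)
        return w / np.linalg.norm(w)

    w_full = _weights(X, y)
    rng = np.random.default_rng(seed)
    W = np.empty((n_boot, p))
    filled = 0
    redrawn = 0
    rounds = 0
    while filled < n_boot:
        if rounds >= max_redraw_rounds:
            raise RuntimeError("bootstrap kept producing degenerate resamples")
        rounds += 1
        need = n_boot - filled
        idx = rng.integers(0, n, size=(need, n))
        for row in idx:
            yb = y[row]
            if np.ptp(yb) == 0:
                redrawn += 1
                continue
            wb = _weights(X[row], yb)
            if wb @ w_full < 0:
                wb = -wb
            W[filled] = wb
            filled += 1
    if redrawn:
        logger.info(
            "bootstrap_select_features redrew %d degenerate resamples", redrawn
        )
    mean = W.mean(axis=0)
    sd = W.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, mean / sd, 0.0)
    series = pd.Series(z, index=list(feature_names))
    order = sorted(range(p), key=lambda j: (-abs(z[j]), feature_names[j]))
    selected = [feature_names[j] for j in order[:k]]
    return FeatureSelectionResult(
        z_by_feature=series, selected=selected, k=k, n_boot=n_boot, n_redrawn=redrawn
    )


# ---------------------------------------------------------------------------
# model evaluation


@dataclass
class PredObsResult:
    target: str
    r: float
    r_squared: float
    ci_low: float
    ci_high: float


def predicted_vs_observed(
    model: PLSModel,
    X,
    Y,
    n_boot: int = 1_000,
    level: float = 0.95,
    seed: int | None = None,
) -> list[PredObsResult]:
    """Pearson r (and r^2) between model predictions and observations per target.

    The confidence interval is a percentile bootstrap over participants.
    Constant predictions yield NaN (undefined-correlation signal).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    preds = model.predict(X)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    lo_q = (1.0 - level) / 2.0
    out = []
    for t, target in enumerate(model.target_names):
        p_t, y_t = preds[:, t], Y[:, t]
        if np.ptp(p_t) == 0 or np.ptp(y_t) == 0:
            out.append(PredObsResult(target, float("nan"), float("nan"),
                                     float("nan"), float("nan")))
            continue
        r = float(stats.pearsonr(p_t, y_t).statistic)
        pb, yb = p_t[idx], y_t[idx]
        pc = pb - pb.mean(axis=1, keepdims=True)
        yc = yb - yb.mean(axis=1, keepdims=True)
        den = np.sqrt((pc**2).sum(axis=1) * (yc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rb = (pc * yc).sum(axis=1) / den
        rb = rb[np.isfinite(rb)]
        out.append(
            PredObsResult(
                target=target,
                r=r,
                r_squared=r * r,
                ci_low=float(np.quantile(rb, lo_q)),
                ci_high=float(np.quantile(rb, 1.0 - lo_q)),
            )
        )
    return out


def fit_multitarget(
    X,
    Y_all,
    k_folds: int = 5,
    max_ncomp: int = 10,
    seed: int | None = None,
    feature_names: list[str] | None = None,
    target_names: list[str] | None = None,
) -> tuple[PLSModel, CVCurve]:
    """Fit one PLS model jointly predicting all targets, with CV-selected size."""
    curve = cv_select_ncomp(X, Y_all, k_folds=k_folds, max_ncomp=max_ncomp, seed=seed)
    ncomp = max(curve.selected_ncomp, 1)
    model = fit_pls(
        X,
        Y_all,
        n_components=ncomp,
        feature_names=feature_names,
        target_names=target_names,
    )
    model.meta["cv_selected_ncomp"] = int(curve.selected_ncomp)
    return model, curve
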