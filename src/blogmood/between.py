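"""Between-subject mass bivariate screening.

Each linguistic feature is correlated with each of the three symptom
targets (depression, anxiety, suicidality) across participants using
Spearman's rank-order correlation. Family-wise error over the whole
feature-by-target family is controlled with a max-statistic permutation
test: symptom rows are shuffled across participants, every correlation in
the family is recomputed, and the most extreme |rho| per permutation forms
the null distribution from which adjusted p-values and the significance
threshold are read. Percentile-bootstrap confidence intervals accompany
each observed coefficient.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import CrossSectionTable

logger = logging.getLogger(__name__)

EXACT_P_MAX_N = 10  # exact Spearman null by enumeration up to this n
_EXHAUSTIVE_MAX_N = 8


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    return x[mask], y[mask]


def spearman_rho(x, y) -> float:
    """Spearman's rho: Pearson correlation of midranks, pairwise-complete.

    Returns NaN (an undefined-correlation signal, not an exception) when
    either vector is constant after pairwise deletion of missing entries.
    """
    xc, yc = _pairwise_complete(x, y)
    if xc.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {xc.size}")
    if np.ptp(xc) == 0 or np.ptp(yc) == 0:
        return float("nan")
    return float(stats.spearmanr(xc, yc).statistic)


def _rank_z(matrix: np.ndarray) -> np.ndarray:
    """Column-wise midranks standardized to mean 0, SD 1 (n-1 convention)."""
    ranks = stats.rankdata(matrix, axis=0)
    centred = ranks - ranks.mean(axis=0)
    sd = centred.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = centred / sd
    z[:, sd == 0] = np.nan
    return z


def spearman_pvalue(x, y, exact_max_n: int = EXACT_P_MAX_N) -> float:
    """Two-sided uncorrected p for Spearman's rho.

    Exact permutation enumeration of the rank pairings for small samples
    (n <= ``exact_max_n``); the t approximation otherwise.
    """
    xc, yc = _pairwise_complete(x, y)
    if xc.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {xc.size}")
    if np.ptp(xc) == 0 or np.ptp(yc) == 0:
        return float("nan")
    n = xc.size
    if n <= exact_max_n:
        rx = stats.rankdata(xc)
        ry = stats.rankdata(yc)

        def statistic(rx_perm, axis=-1):
            rxc = rx_perm - rx_perm.mean(axis=axis, keepdims=True)
            ryc = ry - ry.mean()
            num = (rxc * ryc).sum(axis=axis)
            den = np.sqrt((rxc**2).sum(axis=axis) * (ryc**2).sum())
            return num / den

        res = stats.permutation_test(
            (rx,),
            statistic,
            permutation_type="pairings",
            n_resamples=np.inf,
            batch=50_000,
            alternative="two-sided",
            vectorized=True,
        )
        return float(res.pvalue)
    return float(stats.spearmanr(xc, yc).pvalue)


@dataclass
class CorrelationResult:
    """One feature-target screening result (Table-style row)."""

    feature: str
    target: str
    rho: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_uncorr: float = float("nan")
    p_corr: float = float("nan")
    n_used: int = 0


@dataclass
class PermutationNull:
    """Family null: max |rho| per permutation and the derived threshold."""

    n_perm: int
    max_abs_stat: np.ndarray
    alpha: float
    threshold: float
    exhaustive: bool = False
    n_dropped_rows: int = 0

    def to_json_dict(self) -> dict:
        return {
            "n_perm": int(self.n_perm),
            "alpha": float(self.alpha),
            "threshold": float(self.threshold),
            "exhaustive": bool(self.exhaustive),
            "n_dropped_rows": int(self.n_dropped_rows),
            "max_abs_stat_quantiles": {
                str(q): float(np.quantile(self.max_abs_stat, q))
                for q in (0.5, 0.9, 0.95, 0.99)
            },
        }


def mass_correlations(
    table: CrossSectionTable, exact_max_n: int = EXACT_P_MAX_N
) -> list[CorrelationResult]:
    """One Spearman screen per (feature, target) pair, pairwise-complete.

    The family has ``n_features x n_targets`` members; undefined pairs
    (constant vectors) carry NaN coefficients but stay in the family count.
    """
    if not table.feature_names:
        raise ValueError("empty feature set")
    if table.n_participants < 3:
        raise ValueError("need >= 3 participants for the between-subject screen")
    X = table.features_matrix()
    Y = table.targets_matrix()
    results = []
    for j, feature in enumerate(table.feature_names):
        for t, target in enumerate(table.target_names):
            xc, yc = _pairwise_complete(X[:, j], Y[:, t])
            if xc.size < 3 or np.ptp(xc) == 0 or np.ptp(yc) == 0:
                rho, p = float("nan"), float("nan")
                n_used = int(xc.size)
            else:
                rho = float(stats.spearmanr(xc, yc).statistic)
                p = spearman_pvalue(xc, yc, exact_max_n=exact_max_n)
                n_used = int(xc.size)
            results.append(
                CorrelationResult(
                    feature=feature, target=target, rho=rho, p_uncorr=p, n_used=n_used
                )
            )
    return results


def _family_matrices(table: CrossSectionTable) -> tuple[np.ndarray, np.ndarray, int]:
    """Complete-case feature/target matrices for the permutation family."""
    X = table.features_matrix()
    Y = table.targets_matrix()
    complete = ~(np.isnan(X).any(axis=1) | np.isnan(Y).any(axis=1))
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "permutation family: dropped %d incomplete participants", n_dropped
        )
    return X[complete], Y[complete], n_dropped


def max_stat_permutation(
    table: CrossSectionTable,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
    joint_targets: bool = True,
    exhaustive: bool = False,
) -> tuple[PermutationNull, np.ndarray]:
    """Max-statistic permutation correction over the whole screening family.

    Per permutation the symptom rows are shuffled across participants
    (jointly for the three targets by default, preserving their mutual
    association) and every family correlation is recomputed; the most
    extreme |rho| is recorded. Adjusted p-values use the add-one convention
    ``(1 + #{max >= |rho_obs|}) / (n_perm + 1)``, or the exact fraction when
    all n! permutations are enumerated. The significance threshold is the
    empirical (1 - alpha) quantile (higher order statistic) of the null.

    Returns the null and the (n_features x n_targets) adjusted p matrix.
    """
    X, Y, n_dropped = _family_matrices(table)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 complete participants, got {n}")
    zX = _rank_z(X)
    zY = _rank_z(Y)
    denom = n - 1
    obs = zX.T @ zY / denom  # (p, t); NaN columns propagate
    # rank correlations take discrete values; round before >= comparisons so
    # permutations tied with the observed statistic count as at least as extreme
    abs_obs = np.round(np.abs(obs), 10)

    if exhaustive:
        if n > _EXHAUSTIVE_MAX_N:
            raise ValueError(
                f"exhaustive enumeration limited to n <= {_EXHAUSTIVE_MAX_N}"
            )
        perms = list(itertools.permutations(range(n)))
        if not joint_targets:
            raise ValueError("exhaustive mode enumerates joint permutations only")
        max_abs = np.empty(len(perms))
        for b, perm in enumerate(perms):
            rho_p = zX.T @ zY[list(perm)] / denom
            max_abs[b] = np.round(np.nanmax(np.abs(rho_p)), 10)
        counts = (max_abs[None, None, :] >= abs_obs[:, :, None]).sum(axis=2)
        p_corr = counts / len(perms)
        n_eff = len(perms)
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        max_abs = np.empty(n_perm)
        for b in range(n_perm):
            if joint_targets:
                rho_p = zX.T @ zY[rng.permutation(n)] / denom
            else:
                cols = [
                    zX.T @ zY[rng.permutation(n), t : t + 1]
                    for t in range(zY.shape[1])
                ]
                rho_p = np.hstack(cols)
            max_abs[b] = np.round(np.nanmax(np.abs(rho_p)), 10)
        counts = (max_abs[None, None, :] >= abs_obs[:, :, None]).sum(axis=2)
        p_corr = (1.0 + counts) / (n_perm + 1.0)
        n_eff = n_perm

    p_corr = np.where(np.isnan(abs_obs), np.nan, p_corr)
    threshold = float(np.quantile(max_abs, 1.0 - alpha, method="higher"))
    null = PermutationNull(
        n_perm=n_eff,
        max_abs_stat=max_abs,
        alpha=alpha,
        threshold=threshold,
        exhaustive=exhaustive,
        n_dropped_rows=n_dropped,
    )
    return null, p_corr


def bootstrap_ci(
    x,
    y,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    max_redraw_rounds: int = 50,
) -> tuple[float, float]:
    """Percentile bootstrap interval for Spearman's rho over participants.

    Resamples yielding an undefined coefficient (constant vector) are
    redrawn and the redraw count logged.
    """
    xc, yc = _pairwise_complete(x, y)
    n = xc.size
    if min(np.unique(xc).size, np.unique(yc).size) < 2 or n < 3:
        raise ValueError("need >= 3 pairs with non-constant values")
    rng = np.random.default_rng(seed)
    rhos = np.full(n_boot, np.nan)
    pending = np.arange(n_boot)
    redrawn = 0
    for _ in range(max_redraw_rounds):
        if pending.size == 0:
            break
        idx = rng.integers(0, n, size=(pending.size, n))
        xb, yb = xc[idx], yc[idx]
        ok = (np.ptp(xb, axis=1) > 0) & (np.ptp(yb, axis=1) > 0)
        if ok.any():
            rxb = stats.rankdata(xb[ok], axis=1)
            ryb = stats.rankdata(yb[ok], axis=1)
            rxc = rxb - rxb.mean(axis=1, keepdims=True)
            ryc = ryb - ryb.mean(axis=1, keepdims=True)
            num = (rxc * ryc).sum(axis=1)
            den = np.sqrt((rxc**2).sum(axis=1) * (ryc**2).sum(axis=1))
            rhos[pending[ok]] = num / den
        redrawn += int((~ok).sum())
        pending = pending[~ok]
    if pending.size:
        raise RuntimeError("bootstrap resampling kept producing constant vectors")
    if redrawn:
        logger.info("bootstrap_ci redrew %d degenerate resamples", redrawn)
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(rhos, lo)),
        float(np.quantile(rhos, 1.0 - lo)),
    )


def between_subject_analysis(
    table: CrossSectionTable,
    n_perm: int = 10_000,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
    joint_targets: bool = True,
) -> tuple[list[CorrelationResult], PermutationNull]:
    """Full screening stage: rho, uncorrected p, bootstrap CI, adjusted p."""
    results = mass_correlations(table)
    null, p_corr = max_stat_permutation(
        table, n_perm=n_perm, alpha=alpha, seed=seed, joint_targets=joint_targets
    )
    X = table.features_matrix()
    Y = table.targets_matrix()
    ss = np.random.SeedSequence(seed)
    ci_seeds = ss.generate_state(len(results)) % (2**31)
    k = 0
    for j, _ in enumerate(table.feature_names):
        for t, _ in enumerate(table.target_names):
            res = results[k]
            res.p_corr = float(p_corr[j, t])
            if not math.isnan(res.rho):
                res.ci_low, res.ci_high = bootstrap_ci(
                    X[:, j], Y[:, t], n_boot=n_boot, seed=int(ci_seeds[k])
                )
            k += 1
    return results, null


def results_table(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tidy screening table sorted by target then |rho| (ties by feature label)."""
    df = pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "target": [r.target for r in results],
            "rho": [r.rho for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p_uncorr": [r.p_uncorr for r in results],
            "p_corr": [r.p_corr for r in results],
            "n_used": [r.n_used for r in results],
        }
    )
    df["_abs"] = df["rho"].abs()
    df = (
        df.sort_values(
            ["target", "_abs", "feature"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        .drop(columns="_abs")
        .reset_index(drop=True)
    )
    return df
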