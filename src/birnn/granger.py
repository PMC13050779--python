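"""Pairwise Granger-causality baseline on network-level time series.

For each ordered pair of networks the target series is regressed on its own
past (restricted model) and additionally on the source's past (full model)
at every lag from 1 to ``max_lag``; the joint contribution of the lagged
source coefficients is F-tested and the lag with the minimum p-value is
selected.  F statistics are unsigned: the baseline detects directed
temporal dependence but cannot distinguish facilitation from inhibition,
which is precisely the contrast with the signed couplings of the
constrained recurrent model.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import ConnectivityMatrix, group_connection_tests

__all__ = [
    "GrangerResult",
    "granger_f_test",
    "pairwise_granger",
    "group_granger_tests",
]


class LengthError(ValueError):
    """Series too short for the requested maximum lag."""


class RankError(ValueError):
    """Singular design matrix (e.g. constant series)."""


@dataclasses.dataclass
class GrangerResult:
    """Per-subject directed dependence matrices.

    ``f_matrix[i, j]`` is the F statistic for source ``j`` -> target ``i``
    at that pair's selected lag; the diagonal is fixed at zero by
    convention (self-connections undefined).  ``lag_pvalues[i][j]`` holds
    the per-lag p-values when requested.
    """

    f_matrix: np.ndarray
    p_matrix: np.ndarray
    selected_lag: np.ndarray
    network_names: tuple[str, ...]
    subject_id: str = ""
    condition: str = "rest"
    lag_pvalues: dict | None = None


def _lag_design(y: np.ndarray, lag: int) -> np.ndarray:
    """Columns ``y_{t-1} ... y_{t-lag}`` for targets ``y_lag ... y_{T-1}``."""
    return np.column_stack([y[lag - k : len(y) - k] for k in range(1, lag + 1)])


def granger_f_test(
    target: np.ndarray, source: np.ndarray, lag: int
) -> tuple[float, float]:
    """Nested-model F-test of source -> target at a fixed lag.

    Both models use the last ``T - lag`` samples as targets and include an
    intercept; the restricted model has the target's own ``lag`` past
    values, the full model adds the source's.  F has ``(lag, n - 2 lag - 1)``
    degrees of freedom with ``n = T - lag``.
    """
    y = np.asarray(target, dtype=float)
    x = np.asarray(source, dtype=float)
    T = y.size
    n = T - lag
    df_den = n - 2 * lag - 1
    if df_den <= 0:
        raise LengthError(f"need T > 3*lag + 1, got T={T} at lag {lag}")
    yy = y[lag:]
    Xr = np.column_stack([np.ones(n), _lag_design(y, lag)])
    Xf = np.column_stack([Xr, _lag_design(x, lag)])
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        raise RankError("singular design (constant or collinear series)")
    rss_r = _rss(Xr, yy)
    rss_f = _rss(Xf, yy)
    if rss_f <= 0:
        raise RankError("perfect fit; F undefined")
    F = ((rss_r - rss_f) / lag) / (rss_f / df_den)
    F = max(F, 0.0)
    p = float(sps.f.sf(F, lag, df_den))
    return float(F), p


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def pairwise_granger(
    network_series: np.ndarray,
    max_lag: int = 10,
    network_names: Sequence[str] | None = None,
    subject_id: str = "",
    condition: str = "rest",
    keep_lag_pvalues: bool = False,
) -> GrangerResult:
    """All-pairs Granger analysis with minimum-p lag selection.

    ``network_series`` has shape ``(K, T)`` with ``T > 10 * max_lag``.  For
    each ordered (source, target) pair the F statistic and p-value of the
    best (minimum-p) lag in ``1..max_lag`` are stored; note this selection
    is not corrected across lags (``keep_lag_pvalues`` exposes the per-lag
    values for callers who want to).
    """
    z = np.asarray(network_series, dtype=float)
    K, T = z.shape
    if T <= 10 * max_lag:
        raise LengthError(f"need T > 10*max_lag = {10 * max_lag}, got {T}")
    F = np.zeros((K, K))
    P = np.ones((K, K))
    L = np.zeros((K, K), dtype=int)
    lag_p: dict[tuple[int, int], np.ndarray] = {}
    for j in range(K):  # source
        for i in range(K):  # target
            if i == j:
                continue
            ps = np.empty(max_lag)
            fs = np.empty(max_lag)
            for k in range(1, max_lag + 1):
                fs[k - 1], ps[k - 1] = granger_f_test(z[i], z[j], k)
            best = int(np.argmin(ps))
            F[i, j] = fs[best]
            P[i, j] = ps[best]
            L[i, j] = best + 1
            if keep_lag_pvalues:
                lag_p[(i, j)] = ps.copy()
    names = tuple(network_names) if network_names else tuple(
        f"net{k}" for k in range(K)
    )
    return GrangerResult(
        F, P, L, names, subject_id, condition,
        lag_pvalues=lag_p if keep_lag_pvalues else None,
    )


def group_granger_tests(
    results: Sequence[GrangerResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Group-level aggregation of subject F matrices.

    Entrywise mean F across subjects plus one-sample t-tests per
    off-diagonal cell (12 tests per condition) with BH FDR correction,
    using the same machinery as the model-based connectivity tests.
    """
    mats = [
        ConnectivityMatrix(r.f_matrix, r.network_names, r.subject_id, r.condition)
        for r in results
    ]
    return group_connection_tests(mats, alpha=alpha, include_diagonal=False)
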