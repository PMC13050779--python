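"""Group-level statistics over fitted network-coupling matrices.

Per subject and condition the trained model yields a small signed, directed
network-to-network coupling matrix.  This module extracts those matrices,
runs one-sample t-tests per connection across subjects with
Benjamini-Hochberg FDR correction, produces mean/median summary tables, and
fits the covariate (imagery-score) regressions with Hochberg ("Simes-
Bonferroni") step-up correction.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .core import BIRNNParameters

__all__ = [
    "ConnectivityMatrix",
    "extract_network_connectivity",
    "group_connection_tests",
    "benjamini_hochberg",
    "hochberg",
    "summarize_connectivity",
    "imagery_regression",
    "RegressionResult",
]


class ExtractionError(ValueError):
    """Raised when a parameter set has no usable coupling matrix."""


@dataclasses.dataclass
class ConnectivityMatrix:
    """Signed directed network coupling for one subject/condition.

    ``values[i, j]`` is the directed influence of network ``j`` (source) on
    network ``i`` (target).
    """

    values: np.ndarray
    network_names: tuple[str, ...]
    subject_id: str = ""
    condition: str = "rest"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.network_names = tuple(self.network_names)
        k = len(self.network_names)
        if self.values.shape != (k, k):
            raise ValueError("values must be square and match network_names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("connectivity entries must be finite")

    def entry(self, target: str, source: str) -> float:
        i = self.network_names.index(target)
        j = self.network_names.index(source)
        return float(self.values[i, j])


def extract_network_connectivity(
    params: BIRNNParameters,
    network_names: Sequence[str],
    subject_id: str = "",
    condition: str = "rest",
) -> ConnectivityMatrix:
    """Copy the learned network-coupling matrix out of a fitted model.

    Values are taken verbatim (no transformation) in the (target, source)
    orientation.  Non-finite couplings indicate a failed fit and raise
    :class:`ExtractionError`.
    """
    w = np.asarray(params.W_net, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ExtractionError("W_net contains non-finite entries")
    return ConnectivityMatrix(w.copy(), tuple(network_names), subject_id, condition)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR-adjusted p-values, original order.

    ``adjusted_(k) = min_{j >= k} m p_(j) / j`` on the ascending sort,
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Hochberg (1988) step-up adjusted p-values (the 'Simes-Bonferroni'
    procedure), original order."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="simes-hochberg")[1]


def _one_sample_cell(samples: np.ndarray) -> tuple[float, float, bool]:
    """t statistic, two-sided p, degenerate flag for one connection's
    across-subject samples, with the zero-variance conventions:
    all-equal-to-zero -> (0, 1); all-equal-nonzero -> degenerate, p -> 0."""
    sd = samples.std(ddof=1)
    mean = samples.mean()
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0, False
        return np.inf if mean > 0 else -np.inf, 0.0, True
    t, p = sps.ttest_1samp(samples, 0.0)
    return float(t), float(p), False


def group_connection_tests(
    matrices: Sequence[ConnectivityMatrix],
    alpha: float = 0.05,
    include_diagonal: bool = True,
) -> pd.DataFrame:
    """One-sample t-tests of every directed connection against zero.

    All matrices must share a condition and network ordering.  Returns one
    row per ordered (source, target) pair (source-major order) with group
    mean/median, t, degrees of freedom, raw p, BH-adjusted p (corrected
    within this condition's family), and a significance flag at
    ``q < alpha``.  With ``include_diagonal=False`` self-connections are
    excluded from both the table and the correction family (used for the
    Granger baseline, where the diagonal is undefined).
    """
    if len(matrices) < 2:
        raise ValueError("need at least two subjects")
    names = matrices[0].network_names
    cond = matrices[0].condition
    for m in matrices:
        if m.network_names != names:
            raise ValueError("inconsistent network ordering across subjects")
        if m.condition != cond:
            raise ValueError("matrices mix conditions; test each separately")
    stack = np.stack([m.values for m in matrices])  # (n_subj, K, K)
    n = stack.shape[0]
    rows = []
    for j, source in enumerate(names):  # source-major row order
        for i, target in enumerate(names):
            if not include_diagonal and i == j:
                continue
            cell = stack[:, i, j]
            t, p, degen = _one_sample_cell(cell)
            rows.append(
                {
                    "source": source,
                    "target": target,
                    "mean": cell.mean(),
                    "median": float(np.median(cell)),
                    "t": t,
                    "df": n - 1,
                    "p_raw": p,
                    "degenerate": degen,
                }
            )
    table = pd.DataFrame(rows)
    table["p_fdr"] = benjamini_hochberg(table["p_raw"].to_numpy())
    table["significant"] = table["p_fdr"] < alpha
    table.attrs["condition"] = cond
    return table


def summarize_connectivity(
    matrices: Sequence[ConnectivityMatrix]
) -> pd.DataFrame:
    """Entrywise mean and median across subjects, one row per ordered
    network pair (``Connection`` formatted ``source -> target``)."""
    if len(matrices) == 0:
        raise ValueError("empty cohort")
    names = matrices[0].network_names
    stack = np.stack([m.values for m in matrices])
    rows = []
    for j, source in enumerate(names):
        for i, target in enumerate(names):
            rows.append(
                {
                    "Connection": f"{source} -> {target}",
                    "mean": stack[:, i, j].mean(),
                    "median": float(np.median(stack[:, i, j])),
                }
            )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class RegressionResult:
    """Association between a coupling strength and a per-subject covariate."""

    r: float            # correlation coefficient, sign-matched to the fit
    r2: float           # variance explained by the (monotone or linear) fit
    p_raw: float
    p_corrected: float
    method: str
    n: int


def imagery_regression(
    weights: Sequence[float],
    scores: Sequence[float],
    method: str = "spearman",
    n_tests: int = 1,
) -> RegressionResult:
    """Robust association between per-subject coupling weights and a
    covariate (e.g. imagery-vividness scores).

    Default is rank-based: Spearman correlation for ``r`` and its p-value,
    with ``r2`` the variance explained by a monotone (isotonic) fit of
    scores on weights.  ``method="ols"`` gives the ordinary linear fit
    instead (``r2 = r**2`` exactly).  The raw p-value is multiplied by the
    family size ``n_tests`` (capped at 1) — the Hochberg step-up bound for
    the member of the family under consideration; for a full family use
    :func:`hochberg` on all raw p-values.
    """
    w = np.asarray(weights, dtype=float)
    s = np.asarray(scores, dtype=float)
    if w.shape != s.shape or w.size < 4:
        raise ValueError("weights and scores must be equal-length, n >= 4")
    if not (np.all(np.isfinite(w)) and np.all(np.isfinite(s))):
        raise ValueError("missing values are not supported")
    if w.std() == 0:
        raise ValueError("degenerate predictor: weights have zero variance")
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    if method == "spearman":
        rho, p = sps.spearmanr(w, s)
        iso = IsotonicRegression(increasing=rho >= 0, out_of_bounds="clip")
        fitted = iso.fit_transform(w, s)
        r2 = 1.0 - float(np.sum((s - fitted) ** 2)) / ss_tot if ss_tot > 0 else 0.0
        r = float(rho)
    elif method == "ols":
        res = sps.linregress(w, s)
        r = float(res.rvalue)
        r2 = r * r
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return RegressionResult(
        r=r,
        r2=float(r2),
        p_raw=float(p),
        p_corrected=min(1.0, float(p) * n_tests),
        method=method,
        n=w.size,
    )
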