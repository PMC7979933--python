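"""Predictor screening: correlation pruning, splitting, best-subset OLS.

Mirrors the pre-processing protocol of the continental SOC analysis: Pearson
pruning of collinear numeric predictors at |r| > 0.70 (keeping, within each
flagged pair, the predictor whose effect on SOC dynamics ranks higher in a
caller-supplied priority), an unstratified 75/25 train/test split, and a
best-subset multiple regression constrained by overall-F and per-coefficient
t significance at alpha = 0.05, ranked by adjusted R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import floor

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InvalidArgumentError

log = logging.getLogger(__name__)


@dataclass
class ScreeningReport:
    """What screening saw and decided, for the report bundle."""

    correlation_matrix: pd.DataFrame = None
    dropped_by_correlation: list = field(default_factory=list)  # (dropped, kept, r)
    selected_predictors: list = field(default_factory=list)
    selection_r2: float = float("nan")
    split_sizes: tuple = (0, 0)


def indicator_columns(X: pd.DataFrame) -> list[str]:
    """Columns whose values are a subset of {0, 1} (one-hot indicators)."""
    out = []
    for c in X.columns:
        v = X[c].dropna().unique()
        if len(v) and np.isin(v, [0.0, 1.0]).all():
            out.append(c)
    return out


def correlation_prune(
    X: pd.DataFrame,
    threshold: float = 0.70,
    priority: list[str] | None = None,
):
    """Single-pass Pearson pruning of collinear continuous predictors.

    Pairs with |r| > threshold (on the *initial* correlation matrix; nothing
    is recomputed after drops) are visited in decreasing |r|; within a pair
    still intact, the predictor ranked lower in ``priority`` is dropped.
    Indicator (0/1) columns are exempt.  Returns ``(pruned, report)`` where
    the report fragment carries the matrix and the (dropped, kept, r) list.
    """
    indicators = set(indicator_columns(X))
    numeric = [c for c in X.columns if c not in indicators]
    if priority is None:
        priority = list(numeric)
    missing = [c for c in numeric if c not in priority]
    if missing:
        raise InvalidArgumentError(f"priority list missing predictors: {missing}")
    rank = {c: i for i, c in enumerate(priority)}

    report = ScreeningReport()
    if len(numeric) >= 2:
        corr = X[numeric].corr(method="pearson")
        report.correlation_matrix = corr
        pairs = [
            (abs(corr.iat[i, j]), numeric[i], numeric[j], corr.iat[i, j])
            for i in range(len(numeric))
            for j in range(i + 1, len(numeric))
            if abs(corr.iat[i, j]) > threshold
        ]
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        dropped = set()
        for _, a, b, r in pairs:
            if a in dropped or b in dropped:
                continue
            drop = a if rank[a] > rank[b] else b
            keep = b if drop == a else a
            dropped.add(drop)
            report.dropped_by_correlation.append((drop, keep, float(r)))
            log.info("pruning %s (|r|=%.3f with %s)", drop, abs(r), keep)
        keep_cols = [c for c in X.columns if c not in dropped]
    else:
        report.correlation_matrix = X[numeric].corr() if numeric else pd.DataFrame()
        keep_cols = list(X.columns)
    return X[keep_cols], report


def nonlinearity_screen(X: pd.DataFrame, y) -> pd.DataFrame:
    """Diagnostic only: Pearson vs Spearman correlation of each continuous
    predictor with the response; a large gap flags a monotone nonlinearity.
    Logged, never acted on automatically."""
    indicators = set(indicator_columns(X))
    rows = []
    y = np.asarray(y, dtype=float)
    for c in X.columns:
        if c in indicators:
            continue
        x = X[c].to_numpy(dtype=float)
        rows.append((c, stats.pearsonr(x, y)[0], stats.spearmanr(x, y)[0]))
    out = pd.DataFrame(rows, columns=["predictor", "pearson_r", "spearman_r"])
    for r in out.itertuples(index=False):
        if abs(r.spearman_r) - abs(r.pearson_r) > 0.1:
            log.info(
                "predictor %s: spearman %.2f vs pearson %.2f — possible nonlinearity",
                r.predictor, r.spearman_r, r.pearson_r,
            )
    return out


def train_test_split(table: pd.DataFrame, train_fraction: float = 0.75, seed: int = 0):
    """Simple random, unstratified split; n_train = floor(fraction * n)."""
    if not 0 < train_fraction < 1:
        raise InvalidArgumentError("train_fraction must lie in (0, 1)")
    n = len(table)
    if n < 8:
        raise InvalidArgumentError("need at least 8 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = floor(train_fraction * n)
    return table.iloc[np.sort(perm[:n_train])], table.iloc[np.sort(perm[n_train:])]


def _fit_ols(X: pd.DataFrame, z, subset):
    return sm.OLS(np.asarray(z, dtype=float), sm.add_constant(X[list(subset)])).fit()


def best_subset_select(
    X_train: pd.DataFrame,
    z_train,
    max_subset_size: int | None = None,
    alpha: float = 0.05,
    exhaustive_limit: int = 15,
    adj_r2_tol: float = 1e-4,
):
    """Best-subset OLS under F-test and per-coefficient significance.

    Among all subsets of size <= ``max_subset_size`` (exhaustive when the
    candidate pool has <= ``exhaustive_limit`` predictors, otherwise forward
    stepwise proposing one candidate per size), returns the subset with the
    largest adjusted R^2 whose overall regression F-test and every slope's
    partial t-test reach p < alpha.  Subsets whose adjusted R^2 lies within
    ``adj_r2_tol`` of the best are treated as practically equivalent and the
    tie breaks toward the smaller subset, then lexicographic predictor
    order — a marginally significant predictor that moves adjusted R^2 by
    less than one part in 10^4 does not buy its way in.  If no subset
    qualifies, the null model (empty list) is returned with a warning.

    Returns ``(selected_names, training_r2_of_selection)``.
    """
    cols = list(X_train.columns)
    zero_var = [c for c in cols if np.std(X_train[c].to_numpy(dtype=float)) == 0]
    if zero_var:
        raise InvalidArgumentError(f"zero-variance predictors: {zero_var}")
    p = len(cols)
    if max_subset_size is None:
        max_subset_size = p
    max_subset_size = min(max_subset_size, p)

    if p <= exhaustive_limit:
        candidates = [
            list(s)
            for size in range(1, max_subset_size + 1)
            for s in combinations(cols, size)
        ]
    else:
        log.warning(
            "%d candidate predictors exceed the exhaustive cap (%d); "
            "falling back to forward stepwise", p, exhaustive_limit,
        )
        candidates = []
        current: list[str] = []
        remaining = list(cols)
        for _ in range(max_subset_size):
            best_add, best_adj = None, -np.inf
            for c in remaining:
                adj = _fit_ols(X_train, z_train, current + [c]).rsquared_adj
                if adj > best_adj:
                    best_add, best_adj = c, adj
            current = current + [best_add]
            remaining.remove(best_add)
            candidates.append(list(current))

    valid = []  # (adj_r2, size, sorted names, r2, subset)
    for subset in candidates:
        res = _fit_ols(X_train, z_train, subset)
        if not np.isfinite(res.f_pvalue) or res.f_pvalue >= alpha:
            continue
        slope_p = res.pvalues.iloc[1:]  # exclude the intercept
        if (slope_p >= alpha).any() or slope_p.isna().any():
            continue
        valid.append((float(res.rsquared_adj), len(subset), tuple(sorted(subset)),
                      float(res.rsquared), subset))
    if not valid:
        log.warning("no predictor subset reached significance; returning null model")
        return [], 0.0
    top = max(v[0] for v in valid)
    tied = [v for v in valid if v[0] >= top - adj_r2_tol]
    best = min(tied, key=lambda v: (v[1], v[2]))
    return list(best[4]), best[3]
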