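"""Model diagnostics: per-region bias, test-set R^2, and coefficient PCA.

Bias per ecoregion is the signed mean of (predicted - observed) stocks with
a percent form |mean residual| / mean observed * 100 — the convention that
reproduces a region with mean observed 776.6 Mg/ha and mean residual
-643.2 Mg/ha having 82.8% bias.  The PCA relates ecoregions to predictors
through the region-mean local GWR coefficients: columns are standardized,
the correlation matrix eigendecomposed, and regions scored on the
components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UndefinedR2Error
from .gwr import GWRFit

log = logging.getLogger(__name__)


def region_bias(predicted, observed, regions) -> pd.DataFrame:
    """Signed mean residual and percent bias per ecoregion.

    Columns: region, n, mean_observed, mean_residual (predicted - observed,
    Mg/ha), bias_percent = |mean_residual| / mean_observed * 100.  Pairs
    with a missing prediction are dropped (logged); regions left empty are
    reported with NaN statistics.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    regions = np.asarray(regions)
    if not (len(predicted) == len(observed) == len(regions)):
        raise InvalidArgumentError("predicted, observed and regions must be co-indexed")
    ok = ~np.isnan(predicted) & ~np.isnan(observed)
    if (~ok).any():
        log.warning("dropping %d pair(s) with missing values", int((~ok).sum()))
    rows = []
    for lab in np.unique(regions):
        sel = ok & (regions == lab)
        n = int(sel.sum())
        if n == 0:
            rows.append((lab, 0, np.nan, np.nan, np.nan))
            continue
        mo = float(observed[sel].mean())
        mr = float((predicted[sel] - observed[sel]).mean())
        rows.append((lab, n, mo, mr, abs(mr) / mo * 100.0))
    return pd.DataFrame(
        rows, columns=["region", "n", "mean_observed", "mean_residual", "bias_percent"]
    )


def test_r2(predicted, observed) -> float:
    """Coefficient of determination 1 - RSS/TSS on the stock (Mg/ha) scale."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    ok = ~np.isnan(predicted) & ~np.isnan(observed)
    if (~ok).any():
        log.warning("test_r2: dropping %d missing pair(s)", int((~ok).sum()))
    predicted, observed = predicted[ok], observed[ok]
    if len(observed) < 3:
        raise InvalidArgumentError("need at least 3 pairs")
    tss = float(np.sum((observed - observed.mean()) ** 2))
    if tss == 0:
        raise UndefinedR2Error("observed values have zero variance")
    return 1.0 - float(np.sum((observed - predicted) ** 2)) / tss


@dataclass
class CoefficientPCA:
    """PCA of region-mean local coefficients on the correlation matrix."""

    region_means: pd.DataFrame = field(repr=False)  # region x predictor
    loadings: pd.DataFrame = field(repr=False)  # predictor x component
    scores: pd.DataFrame = field(repr=False)  # region x component
    explained_variance: np.ndarray = None

    @property
    def explained_fraction(self) -> np.ndarray:
        return self.explained_variance / self.explained_variance.sum()


def coefficient_pca(fit: GWRFit, regions) -> CoefficientPCA:
    """Relate ecoregions to predictors through the local GWR coefficients.

    Local coefficients are averaged per region, columns standardized, and
    the correlation matrix eigendecomposed; loadings are the orthonormal
    eigenvectors (descending eigenvalue order) and region scores the
    projections of the standardized means.  Constant coefficient columns
    are dropped with a warning.
    """
    regions = np.asarray(regions)
    if len(regions) != fit.local_coefficients.shape[0]:
        raise InvalidArgumentError("regions must be co-indexed with calibration points")
    coef = pd.DataFrame(fit.local_coefficients, columns=fit.predictor_names)
    means = coef.groupby(regions).mean()
    if means.shape[0] < 3:
        raise InvalidArgumentError("need at least 3 regions for a PCA")
    std = means.std(ddof=1)
    constant = std[std <= 1e-12].index.tolist()
    if constant:
        log.warning("dropping constant coefficient column(s): %s", constant)
        means = means.drop(columns=constant)
    if means.shape[1] < 2:
        raise InvalidArgumentError("need at least 2 varying predictors for a PCA")
    Z = (means - means.mean()) / means.std(ddof=1)
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.maximum(eigval[order], 0.0), eigvec[:, order]
    comp = [f"PC{i + 1}" for i in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=means.columns, columns=comp)
    scores = pd.DataFrame(Z.to_numpy() @ eigvec, index=means.index, columns=comp)
    return CoefficientPCA(
        region_means=means,
        loadings=loadings,
        scores=scores,
        explained_variance=eigval,
    )
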