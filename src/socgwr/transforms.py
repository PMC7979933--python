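"""Box-Cox normalization of the positively skewed SOC stock response.

The transform is z = (y^lambda - 1) / lambda for lambda != 0 and z = ln y at
lambda = 0; its inverse is defined where lambda*z + 1 > 0.  The exponent is
estimated by maximizing the profile log-likelihood

    ll(lambda) = -(n/2) ln(RSS(lambda)/n) + (lambda - 1) sum(ln y)

(RSS about the mean of the transformed values) with a coarse grid over
[-2, 2] followed by golden-section refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import boxcox_llf

from .errors import DomainError, InvalidArgumentError


@dataclass(frozen=True)
class BoxCoxTransform:
    """Fitted Box-Cox exponent and its profile log-likelihood."""

    lambda_: float
    loglik: float

    def apply(self, y):
        return boxcox_apply(y, self.lambda_)

    def invert(self, z, out_of_domain="raise"):
        return boxcox_invert(z, self.lambda_, out_of_domain=out_of_domain)


def boxcox_apply(y, lambda_):
    """z = (y^lambda - 1)/lambda, or ln y at lambda = 0.  Requires y > 0."""
    y = np.asarray(y, dtype=float)
    if np.any(~(y > 0)):
        raise DomainError("Box-Cox transform requires strictly positive values")
    if lambda_ == 0.0:
        return np.log(y)
    # expm1 form is stable as lambda -> 0
    return np.expm1(lambda_ * np.log(y)) / lambda_


def boxcox_invert(z, lambda_, out_of_domain="raise"):
    """Inverse transform; defined where lambda*z + 1 > 0 (lambda != 0).

    ``out_of_domain="nan"`` maps undefined entries to NaN instead of
    raising, which prediction uses to emit missing cells.
    """
    z = np.asarray(z, dtype=float)
    if lambda_ == 0.0:
        return np.exp(z)
    lz = lambda_ * z
    bad = ~(lz + 1.0 > 0)
    if bad.any():
        if out_of_domain == "raise":
            raise DomainError(
                f"Box-Cox inverse undefined for {int(bad.sum())} value(s): "
                "lambda*z + 1 <= 0"
            )
        lz = np.where(bad, np.nan, lz)
    # log1p form is stable as lambda -> 0
    return np.exp(np.log1p(lz) / lambda_)


def fit_boxcox(y, grid_step: float = 0.01, tol: float = 1e-4) -> BoxCoxTransform:
    """Maximum-profile-likelihood Box-Cox exponent over lambda in [-2, 2].

    Coarse grid search at ``grid_step`` resolution, then golden-section
    refinement of the bracketing interval to ``tol``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 10:
        raise InvalidArgumentError("need a 1-d sample with n >= 10")
    if np.any(~(y > 0)):
        raise DomainError("Box-Cox fitting requires strictly positive values")

    grid = np.arange(-2.0, 2.0 + grid_step / 2, grid_step)
    ll = np.array([boxcox_llf(l, y) for l in grid])
    i = int(np.argmax(ll))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda l: -boxcox_llf(l, y),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol},
    )
    lam = float(res.x)
    if -res.fun < ll[i]:  # refinement must never lose to the grid point
        lam = float(grid[i])
    return BoxCoxTransform(lambda_=lam, loglik=float(boxcox_llf(lam, y)))
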