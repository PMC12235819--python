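"""Restricted cubic spline logistic regression for dose-response curves.

A restricted (natural) cubic spline is piecewise cubic between knots and
constrained to be linear beyond the boundary knots, which stabilizes the
tails where exposure data are sparse.  With k knots the basis has k-1
columns: the exposure itself plus k-2 curvature terms.  The joint
likelihood-ratio test of the curvature coefficients is the test of departure
from log-linearity — the check that flags, e.g., an inverted-U relation
between a metal and outcome risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ers import SeparationError, _fit_logit, covariate_design

__all__ = ["KNOT_QUANTILES", "rcs_basis", "rcs_logistic", "SplineFit"]

#: Default knot placement quantiles by knot count (Harrell's convention).
KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic basis: column 0 is x, columns 1..k-2 are curvature terms.

    Column j (j >= 1) is the truncated-cube combination

        [(x-t_j)^3_+ - (x-t_{k-1})^3_+ (t_k-t_j)/(t_k-t_{k-1})
                     + (x-t_k)^3_+ (t_{k-1}-t_j)/(t_k-t_{k-1})] / (t_k-t_1)^2

    which vanishes for x below the first knot and is linear beyond the last
    (zero second derivative), with the squared knot span keeping the columns
    on the scale of x.
    """
    x = np.asarray(x, dtype=float).ravel()
    t = np.asarray(knots, dtype=float).ravel()
    if len(t) < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"knots must be strictly increasing, got {t.tolist()}")
    k = len(t)
    span2 = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        cub = np.clip(x - t[j], 0, None) ** 3 \
            - np.clip(x - t[-2], 0, None) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2]) \
            + np.clip(x - t[-1], 0, None) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2])
        cols.append(cub / span2)
    return np.column_stack(cols)


@dataclass
class SplineFit:
    """A fitted dose-response curve and its nonlinearity test."""

    exposure: str
    knots: np.ndarray
    basis_coefficients: pd.Series
    covariate_coefficients: pd.Series
    reference_value: float
    curve: pd.DataFrame = field(repr=False)   # x, log_or, ci_low, ci_high
    p_nonlinear: float = np.nan
    lr_statistic: float = np.nan
    llf: float = np.nan
    result: object = field(default=None, repr=False)

    def log_or_at(self, x) -> np.ndarray:
        """Log-odds relative to the reference value (0 there by construction)."""
        B = rcs_basis(np.asarray(x, dtype=float), self.knots)
        Bref = rcs_basis(np.array([self.reference_value]), self.knots)
        return (B - Bref) @ self.basis_coefficients.to_numpy()


def rcs_logistic(x, y, covariates: pd.DataFrame | None = None,
                 n_knots: int = 4, knots=None, reference: float | None = None,
                 exposure_name: str = "exposure", grid_points: int = 200,
                 test: str = "lrt") -> SplineFit:
    """Covariate-adjusted spline logistic fit with a nonlinearity test.

    Knots default to the quantile convention in :data:`KNOT_QUANTILES`; the
    curve is the fitted log-OR relative to ``reference`` (sample median by
    default) on a uniform grid, with pointwise Wald bands.  ``p_nonlinear``
    is the LRT (or Wald, ``test="wald"``) of all curvature coefficients
    jointly zero — the reduced model is plain logistic in x.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if knots is None:
        if n_knots not in KNOT_QUANTILES:
            raise ValueError(f"n_knots must be in {sorted(KNOT_QUANTILES)}")
        knots = np.quantile(x, KNOT_QUANTILES[n_knots])
    knots = np.asarray(knots, dtype=float)
    if len(np.unique(x)) < len(knots):
        raise ValueError("exposure has fewer distinct values than knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError(f"tied knots {knots.tolist()}; use fewer knots")
    if reference is None:
        reference = float(np.median(x))

    B = rcs_basis(x, knots)
    names = [exposure_name] + [f"{exposure_name}_s{j}" for j in range(1, B.shape[1])]
    design = pd.DataFrame(B, columns=names)
    adj_cols = []
    if covariates is not None and len(covariates.columns):
        cd = covariate_design(covariates).reset_index(drop=True)
        design = pd.concat([design, cd], axis=1)
        adj_cols = list(cd.columns)
    design = sm.add_constant(design, has_constant="add")
    full = _fit_logit(y, design)

    reduced = _fit_logit(y, design.drop(columns=names[1:]))
    df_nl = len(names) - 1
    if test == "wald":
        constr = " = 0, ".join(names[1:]) + " = 0"
        wres = full.wald_test(constr, scalar=True)
        lr = float(wres.statistic)
        p_nl = float(wres.pvalue)
    else:
        lr = float(2.0 * (full.llf - reduced.llf))
        p_nl = float(stats.chi2.sf(lr, df_nl))

    basis_coefs = full.params[names]
    grid = np.linspace(x.min(), x.max(), grid_points)
    Bg = rcs_basis(grid, knots) - rcs_basis(np.full(grid_points, reference), knots)
    log_or = Bg @ basis_coefs.to_numpy()
    cov_bb = full.cov_params().loc[names, names].to_numpy()
    var = np.einsum("ij,jk,ik->i", Bg, cov_bb, Bg)
    hw = 1.959963984540054 * np.sqrt(np.clip(var, 0, None))
    curve = pd.DataFrame({"x": grid, "log_or": log_or,
                          "ci_low": log_or - hw, "ci_high": log_or + hw})
    return SplineFit(
        exposure=exposure_name,
        knots=knots,
        basis_coefficients=basis_coefs,
        covariate_coefficients=full.params[adj_cols],
        reference_value=reference,
        curve=curve,
        p_nonlinear=p_nl,
        lr_statistic=lr,
        llf=float(full.llf),
        result=full,
    )
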