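"""Quantile g-computation for the joint mixture effect on a binary outcome.

Each exposure is replaced by its quantile score (0..q-1, quartiles by
default) and the outcome is regressed on all scores plus covariates.  Under
this linear marginal structural model the effect of raising *every* exposure
by one quantile simultaneously is psi, the sum of the exposure coefficients;
exp(psi) is the mixture odds ratio.  The coefficients also decompose the
mixture effect into signed weights: within the positive (negative) group,
each exposure's share of the summed positive (negative) coefficient mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata

from .ers import _fit_logit, covariate_design

__all__ = ["quantize", "qgcomp_fit", "MixtureEffect"]


def quantize(x, q: int = 4) -> np.ndarray:
    """Integer quantile scores 0..q-1, ties broken by average rank.

    Group sizes are equal up to ties; if every value is identical all scores
    are 0 (with a warning) rather than an error.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    x = np.asarray(x, dtype=float).ravel()
    if len(np.unique(x)) == 1:
        warnings.warn("exposure is constant; all quantile scores are 0",
                      stacklevel=2)
        return np.zeros(len(x), dtype=int)
    r = rankdata(x, method="average")
    edges = np.quantile(r, np.arange(1, q) / q)
    return np.searchsorted(edges, r, side="right").astype(int)


@dataclass
class MixtureEffect:
    """The joint one-quantile mixture effect and its decomposition."""

    psi: float                 # log-OR per simultaneous one-quantile increase
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p_value: float
    q: int
    exposure_names: list[str]
    coefficients: pd.Series    # per-exposure quantized-scale log-ORs
    weights_positive: pd.Series
    weights_negative: pd.Series
    n: int
    bootstrap: dict | None = field(default=None, repr=False)


def _weights(coefs: pd.Series) -> tuple[pd.Series, pd.Series]:
    pos = coefs[coefs > 0]
    neg = coefs[coefs < 0]
    wp = pos / pos.sum() if len(pos) else pd.Series(dtype=float)
    wn = neg.abs() / neg.abs().sum() if len(neg) else pd.Series(dtype=float)
    return wp, wn


def qgcomp_fit(exposures: pd.DataFrame, y, covariates: pd.DataFrame | None = None,
               q: int = 4, n_bootstrap: int = 0, seed: int = 0) -> MixtureEffect:
    """Fit the quantile g-computation model (non-bootstrap estimator).

    psi is exactly the sum of the quantized-exposure coefficients; its SE is
    the delta method on the sum, sqrt(1' Sigma 1) over the exposure block.
    ``n_bootstrap > 0`` adds a nonparametric percentile CI with a fixed seed.
    """
    if exposures.shape[1] < 2:
        raise ValueError("need at least 2 exposures for a mixture effect")
    y = np.asarray(y, dtype=float).ravel()
    names = list(exposures.columns)
    Xq = pd.DataFrame({c: quantize(exposures[c].to_numpy(), q) for c in names},
                      index=exposures.index).astype(float)

    def _design(Xq_, cov_):
        design = Xq_.reset_index(drop=True)
        if cov_ is not None and len(cov_.columns):
            design = pd.concat([design, covariate_design(cov_).reset_index(drop=True)],
                               axis=1)
        return sm.add_constant(design, has_constant="add")

    def _fit(Xq_, y_, cov_):
        res = _fit_logit(y_, _design(Xq_, cov_))
        coefs = res.params[names]
        psi_ = float(coefs.sum())
        Sigma = res.cov_params().loc[names, names].to_numpy()
        se_ = float(np.sqrt(np.ones(len(names)) @ Sigma @ np.ones(len(names))))
        return psi_, se_, coefs

    def _psi_boot(Xq_, y_, cov_):
        # replicate fits only need a finite psi; a quasi-separated nuisance
        # covariate (e.g. a sparse smoking cell in a resample) is tolerable
        with np.errstate(all="ignore"):
            res = sm.Logit(y_, _design(Xq_, cov_)).fit(
                disp=0, method="lbfgs", maxiter=500)
        psi_ = float(res.params[names].sum())
        if not np.isfinite(psi_):
            raise RuntimeError("non-finite psi in bootstrap replicate")
        return psi_

    psi, se, coefs = _fit(Xq, y, covariates)
    wp, wn = _weights(coefs)
    z = psi / se
    boot = None
    ci_low, ci_high = psi - 1.959963984540054 * se, psi + 1.959963984540054 * se
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        psis = []
        failures = 0
        n = len(y)
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            try:
                psis.append(_psi_boot(
                    Xq.iloc[idx], y[idx],
                    covariates.iloc[idx] if covariates is not None else None))
            except Exception:
                failures += 1
        if failures > 0.1 * n_bootstrap:
            raise RuntimeError(
                f"{failures}/{n_bootstrap} bootstrap replicates failed")
        lo, hi = np.percentile(psis, [2.5, 97.5])
        boot = {"replicates": len(psis), "seed": seed,
                "ci_low": float(np.exp(lo)), "ci_high": float(np.exp(hi)),
                "psi_draws_sd": float(np.std(psis, ddof=1))}
    return MixtureEffect(
        psi=psi, se=se, or_=float(np.exp(psi)),
        ci_low=float(np.exp(ci_low)), ci_high=float(np.exp(ci_high)),
        p_value=float(2 * norm.sf(abs(z))), q=q, exposure_names=names,
        coefficients=coefs, weights_positive=wp, weights_negative=wn,
        n=len(y), bootstrap=boot,
    )
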