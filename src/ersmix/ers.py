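"""Environmental risk score construction and association analyses.

After the adaptive elastic net has screened terms, an *unpenalized*
covariate-adjusted logistic refit supplies the weights: the selected terms
plus the main effect of every metal appearing in a selected quadratic or
interaction (so the nonlinear/product coefficients stay interpretable).
The per-subject score is the weighted sum of exposure terms only,

    ERS_i = sum_j b_j Z_i^j + sum_{k<l} b_kl Z_i^k Z_i^l + sum_m b_m (Z_i^m)^2

with covariates and the intercept excluded — the score is a pure mixture
burden.  Association analyses then treat ERS (or any single exposure) as the
exposure of interest: per-unit logistic odds ratios, quintile odds ratios
against the lowest fifth, stratified fits with a two-sample z-test on the
log-odds difference, and sensitivity refits under variant covariate sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .expansion import Scaling, Term, TermSet

__all__ = [
    "ERSModel",
    "AssociationResult",
    "SeparationError",
    "covariate_design",
    "hierarchical_refit",
    "compute_ers",
    "continuous_association",
    "quintile_association",
    "stratified_association",
    "sensitivity_refits",
]

PRIMARY_COVARIATES = ["age", "sex", "bmi", "income", "smoking", "alcohol",
                      "physical_activity"]


class SeparationError(RuntimeError):
    """The unpenalized logistic MLE did not exist or did not converge.

    Typically caused by (quasi-)separation; consider a penalized fallback or
    collapsing sparse categories.
    """


def covariate_design(covariates: pd.DataFrame,
                     include: list[str] | None = None) -> pd.DataFrame:
    """Numeric design columns for the adjustment set.

    age/bmi enter linearly; sex becomes an indicator for male; the five-level
    ordered income category is dummy-coded against its lowest bracket;
    smoking/alcohol/physical_activity are 0/1 indicators.
    """
    if include is None:
        include = [c for c in PRIMARY_COVARIATES if c in covariates.columns]
    cols = {}
    for c in include:
        if c not in covariates.columns:
            raise KeyError(f"covariate {c!r} missing")
        v = covariates[c]
        if c == "sex":
            cols["sex_male"] = (v.astype(str) == "male").astype(float)
        elif c == "income":
            lv = v.astype(int)
            for k in sorted(lv.unique())[1:]:
                cols[f"income_{k}"] = (lv == k).astype(float)
        else:
            cols[c] = v.astype(float)
    return pd.DataFrame(cols, index=covariates.index)


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Tightly-converged Newton fit; raises SeparationError on failure."""
    try:
        model = sm.Logit(y, X)
        with np.errstate(all="ignore"):
            res = model.fit(disp=0, method="newton", maxiter=200, tol=1e-10)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as e:
        raise SeparationError(str(e)) from e
    if not res.mle_retvals.get("converged", True):
        raise SeparationError("logistic MLE did not converge (possible separation)")
    if not np.all(np.isfinite(res.bse)):
        raise SeparationError("infinite standard errors (possible separation)")
    return res


@dataclass
class ERSModel:
    """Hierarchical refit coefficients plus per-subject scores."""

    refit_terms: list[str]
    term_coefficients: pd.Series
    covariate_coefficients: pd.Series
    intercept: float
    standard_errors: pd.Series
    covariance: pd.DataFrame = field(repr=False)
    ers_values: np.ndarray = field(repr=False)
    quintile_breaks: np.ndarray = field(default=None, repr=False)
    scaling: Scaling | None = field(default=None, repr=False)
    metal_names: list[str] = field(default_factory=list)


def _implied_refit_terms(selected: list[str], metal_names: list[str]) -> list[str]:
    """Selected terms plus the mains their quadratics/interactions imply.

    Ordered: mains in panel order, then quadratics, then interactions.
    """
    terms = [Term.parse(s, metal_names) for s in selected]
    mains = {m for t in terms for m in t.metals}
    order = {m: i for i, m in enumerate(metal_names)}
    main_terms = sorted(mains, key=lambda m: order.get(m, 10**6))
    quads = [t.label for t in terms if t.kind == "quadratic"]
    inters = [t.label for t in terms if t.kind == "interaction"]
    return main_terms + quads + inters


def hierarchical_refit(selected_terms, termset: TermSet, y,
                       covariates: pd.DataFrame | None = None) -> ERSModel:
    """Unpenalized logistic refit of [selected terms + implied mains + covariates].

    ``selected_terms`` may be term labels or an AENETFit's ``selected_terms``.
    An empty selection yields an intercept-only model whose ERS is
    identically zero.
    """
    y = np.asarray(y, dtype=float).ravel()
    labels = list(selected_terms)
    refit_labels = _implied_refit_terms(labels, termset.metal_names)
    Z = termset.values[[lab for lab in refit_labels]] if refit_labels else \
        pd.DataFrame(index=termset.values.index)
    parts = [Z]
    if covariates is not None and len(covariates.columns):
        parts.append(covariate_design(covariates))
    X = pd.concat(parts, axis=1) if parts else Z
    X = sm.add_constant(X, has_constant="add")
    res = _fit_logit(y, X)
    params = res.params
    term_coefs = params[refit_labels] if refit_labels else pd.Series(dtype=float)
    cov_names = [c for c in X.columns if c not in refit_labels and c != "const"]
    model = ERSModel(
        refit_terms=refit_labels,
        term_coefficients=term_coefs,
        covariate_coefficients=params[cov_names],
        intercept=float(params["const"]),
        standard_errors=res.bse,
        covariance=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        ers_values=np.zeros(len(y)),
        metal_names=termset.metal_names,
        scaling=termset.scaling,
    )
    model.ers_values = compute_ers(model, _mains_matrix(termset))
    if len(np.unique(model.ers_values)) >= 5:
        model.quintile_breaks = np.percentile(model.ers_values, [20, 40, 60, 80])
    return model


def _mains_matrix(termset: TermSet) -> pd.DataFrame:
    """Standardized main-effect columns from a term set."""
    return termset.values[termset.metal_names]


def compute_ers(model: ERSModel, Z: pd.DataFrame) -> np.ndarray:
    """Per-subject ERS from refit coefficients and standardized exposures.

    Only metal terms contribute; covariates and the intercept are excluded.
    ``Z`` must be on the training scaling (use ``model.scaling.apply`` for
    new data).
    """
    ers = np.zeros(len(Z))
    for lab, coef in model.term_coefficients.items():
        term = Term.parse(lab, model.metal_names)
        ers += coef * term.evaluate(Z)
    return ers


@dataclass
class AssociationResult:
    """One exposure-outcome contrast from a covariate-adjusted logistic fit."""

    exposure: str
    comparison: str           # "per-unit" or "Q2 vs Q1" etc.
    estimate: float           # log-odds
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_cases: int
    adjustment: list[str] = field(default_factory=list)
    non_estimable: bool = False

    @classmethod
    def from_fit(cls, res, name: str, exposure: str, comparison: str,
                 n: int, n_cases: int, adjustment: list[str]):
        b = float(res.params[name])
        se = float(res.bse[name])
        return cls(exposure=exposure, comparison=comparison, estimate=b, se=se,
                   or_=float(np.exp(b)),
                   ci_low=float(np.exp(b - 1.959963984540054 * se)),
                   ci_high=float(np.exp(b + 1.959963984540054 * se)),
                   p_value=float(res.pvalues[name]), n=n, n_cases=n_cases,
                   adjustment=adjustment)


def continuous_association(ers_values, y, covariates: pd.DataFrame | None = None,
                           exposure_name: str = "ERS") -> AssociationResult:
    """Per-unit odds ratio for a continuous exposure, covariate-adjusted."""
    v = np.asarray(ers_values, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(v) == 0:
        raise ValueError("exposure is constant; per-unit OR undefined")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; logistic fit refused")
    X = pd.DataFrame({exposure_name: v})
    adj = []
    if covariates is not None and len(covariates.columns):
        cd = covariate_design(covariates).reset_index(drop=True)
        X = pd.concat([X, cd], axis=1)
        adj = list(cd.columns)
    X = sm.add_constant(X, has_constant="add")
    res = _fit_logit(y, X)
    return AssociationResult.from_fit(res, exposure_name, exposure_name,
                                      "per-unit", len(y), int(y.sum()), adj)


def quintile_groups(values, n_groups: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Quintile assignment with half-open intervals, top interval closed.

    Breaks sit at the 20/40/60/80th sample percentiles; subject counts sum to
    n and differ by at most 1 except under ties.
    """
    v = np.asarray(values, dtype=float).ravel()
    if len(np.unique(v)) < n_groups:
        raise ValueError(f"need >= {n_groups} distinct values for {n_groups} groups")
    qs = np.linspace(0, 100, n_groups + 1)[1:-1]
    breaks = np.percentile(v, qs)
    groups = np.searchsorted(breaks, v, side="right")
    sizes = np.bincount(groups, minlength=n_groups)
    if (sizes == 0).any():
        raise ValueError(
            f"heavy ties collapsed the grouping; achievable group sizes {sizes.tolist()}")
    return groups, breaks


def quintile_association(values, y, covariates: pd.DataFrame | None = None,
                         exposure_name: str = "ERS",
                         n_groups: int = 5) -> list[AssociationResult]:
    """Odds ratios for upper quintiles against the lowest fifth (Q1 reference).

    With a binary outcome the indicator-coded binary logistic fit is the
    multinomial model; quintiles whose 2x2 table against Q1 has an empty cell
    are structurally non-estimable, flagged, and held out of the fit.
    """
    v = np.asarray(values, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    groups, _ = quintile_groups(v, n_groups)
    results: list[AssociationResult] = []
    estimable = []
    for g in range(1, n_groups):
        a = int(((groups == g) & (y == 1)).sum())   # cases in Qg
        b = int(((groups == g) & (y == 0)).sum())
        c = int(((groups == 0) & (y == 1)).sum())   # cases in Q1
        d = int(((groups == 0) & (y == 0)).sum())
        if min(a, b, c, d) == 0:
            results.append(AssociationResult(
                exposure=exposure_name, comparison=f"Q{g + 1} vs Q1",
                estimate=np.nan, se=np.nan, or_=np.nan, ci_low=np.nan,
                ci_high=np.nan, p_value=np.nan,
                n=int((groups == g).sum() + (groups == 0).sum()),
                n_cases=a + c, non_estimable=True))
        else:
            estimable.append(g)
            results.append(None)  # filled after the joint fit
    keep = np.isin(groups, [0] + estimable)
    dummies = pd.DataFrame(
        {f"Q{g + 1}": (groups[keep] == g).astype(float) for g in estimable})
    adj = []
    if covariates is not None and len(covariates.columns):
        cd = covariate_design(covariates).loc[keep].reset_index(drop=True)
        dummies = pd.concat([dummies.reset_index(drop=True), cd], axis=1)
        adj = list(cd.columns)
    X = sm.add_constant(dummies, has_constant="add")
    yk = y[keep]
    res = _fit_logit(yk, X) if estimable else None
    for idx, g in enumerate(range(1, n_groups)):
        if results[idx] is None:
            results[idx] = AssociationResult.from_fit(
                res, f"Q{g + 1}", exposure_name, f"Q{g + 1} vs Q1",
                n=int((groups == g).sum() + (groups == 0).sum()),
                n_cases=int(y[np.isin(groups, [0, g])].sum()),
                adjustment=adj)
    return results


def per_metal_quintiles(table: pd.DataFrame, metal: str, y,
                        covariates: pd.DataFrame | None = None) -> list[AssociationResult]:
    """The single-metal quintile analysis (one exposure, Q1 reference)."""
    return quintile_association(table[metal].to_numpy(dtype=float), y,
                                covariates, exposure_name=metal)


@dataclass
class StratifiedComparison:
    per_stratum: dict
    z: float
    p_value: float


def stratified_association(ers_values, y, covariates: pd.DataFrame | None,
                           stratum_values, stratum_name: str = "stratum",
                           drop_covariates: list[str] | None = None
                           ) -> StratifiedComparison:
    """Continuous-exposure fit within each stratum plus a difference test.

    The stratifying variable is dropped from the adjustment set.  The
    between-stratum difference in per-unit log-odds is tested with
    z = (b1 - b2) / sqrt(SE1^2 + SE2^2), two-sided.
    """
    v = np.asarray(ers_values, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    s = np.asarray(stratum_values).ravel()
    levels = pd.unique(s)
    if len(levels) < 2:
        raise ValueError("need at least two strata")
    per = {}
    for lev in levels:
        m = s == lev
        if m.sum() == 0 or len(np.unique(y[m])) < 2:
            raise ValueError(f"stratum {lev!r} lacks both outcome classes")
        cov = None
        if covariates is not None:
            cov = covariates.loc[m].reset_index(drop=True)
            drops = drop_covariates or []
            cov = cov[[c for c in cov.columns if c not in drops]]
        per[lev] = continuous_association(v[m], y[m], cov,
                                          exposure_name="ERS")
    (l1, r1), (l2, r2) = list(per.items())[:2]
    z = (r1.estimate - r2.estimate) / np.sqrt(r1.se ** 2 + r2.se ** 2)
    from scipy.stats import norm
    p = float(2 * norm.sf(abs(z)))
    return StratifiedComparison(per_stratum=per, z=float(z), p_value=p)


def sensitivity_refits(ers_values, y, covariates: pd.DataFrame,
                       variants: dict[str, list[str]]) -> pd.DataFrame:
    """Continuous association re-estimated under each covariate-set variant.

    ``variants`` maps a variant name to the list of covariate columns to
    adjust for (empty list = crude model).  Returns a side-by-side table.
    """
    rows = []
    for name, cols in variants.items():
        cov = covariates[cols] if cols else None
        r = continuous_association(ers_values, y, cov)
        rows.append((name, r.estimate, r.se, r.or_, r.ci_low, r.ci_high, r.p_value))
    return pd.DataFrame(rows, columns=["variant", "log_or", "se", "or",
                                       "ci_low", "ci_high", "p_value"])
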