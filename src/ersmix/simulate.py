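"""Synthetic cohort generator for the mixture-exposure analysis.

Emulates the statistical structure the pipeline assumes: a panel of 18
mutually correlated, right-skewed blood metal concentrations; demographic
and lifestyle covariates of a young-adult college cohort; and a rare binary
depressive-symptom outcome (~5.18% prevalence) generated from a logistic
model whose exposure terms live on the standardized log10 scale — main
effects, squares, and a pairwise product, with default coefficients taken
from the refit model the risk-score analysis produces (Ag 0.174, Sb 0.128,
Sn −0.149, La −0.026, Ce −0.058, Sn² −0.173, Ce² −0.065, La×Ce −0.437).

Metals are drawn from a Gaussian copula with log10-normal marginals: a
latent multivariate normal with unit-diagonal correlation matrix is mapped
per metal to ``10**(median + sd * z)``.  The copula preserves ranks, so the
Spearman correlation of any two generated metals equals that of their latent
normals (closed form ``6/pi * arcsin(rho/2)``), letting tests verify the
dependence structure exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .expansion import Term

__all__ = [
    "METAL_PANEL",
    "DEFAULT_TRUE_TERMS",
    "GeneratorConfig",
    "default_correlation",
    "generate_metals",
    "generate_covariates",
    "generate_outcome",
    "generate_cohort",
]

#: 18-metal whole-blood panel (µg/L), panel order fixes all term canonicalization.
METAL_PANEL = [
    "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "As", "Se",
    "Ag", "Cd", "Sn", "Sb", "La", "Ce", "Hg", "Pb", "Ge",
]

#: True outcome model on the standardized log10 scale: the five selected
#: exposure terms plus the main effects of every metal they involve.
DEFAULT_TRUE_TERMS: list[tuple[str, float]] = [
    ("Ag", 0.174),
    ("Sb", 0.128),
    ("Sn", -0.149),
    ("La", -0.026),
    ("Ce", -0.058),
    ("Sn^2", -0.173),
    ("Ce^2", -0.065),
    ("La:Ce", -0.437),
]

# Plausible whole-blood location/scale on log10 µg/L; the real panel's
# medians are unpublished, so these are placeholders with realistic orders
# of magnitude (Fe ~ 4.5e5, Zn ~ 6e3, Ag ~ 0.1, rare earths ~ 0.05 µg/L).
_LOG10_MEDIANS = {
    "Cr": -0.5, "Mn": 1.0, "Fe": 5.65, "Co": -0.7, "Ni": 0.0, "Cu": 2.95,
    "Zn": 3.80, "As": 0.30, "Se": 2.20, "Ag": -1.0, "Cd": -0.30, "Sn": -0.30,
    "Sb": -0.50, "La": -1.30, "Ce": -1.20, "Hg": 0.0, "Pb": 1.30, "Ge": 0.30,
}
_LOG10_SDS = {
    "Cr": 0.30, "Mn": 0.18, "Fe": 0.08, "Co": 0.25, "Ni": 0.30, "Cu": 0.10,
    "Zn": 0.10, "As": 0.35, "Se": 0.12, "Ag": 0.35, "Cd": 0.30, "Sn": 0.35,
    "Sb": 0.30, "La": 0.35, "Ce": 0.35, "Hg": 0.35, "Pb": 0.25, "Ge": 0.25,
}

#: Covariate marginals of the cohort the generator emulates (N = 2027 college
#: students): age 18.39 ± 0.64 y, BMI 22.45 ± 5.00 kg/m², 1178 women of 2027,
#: smoking 24/2027, alcohol 105/2027, physical activity 1567/2027, family
#: income in five ordered brackets.
COVARIATE_MARGINALS = {
    "age_mean": 18.39, "age_sd": 0.64,
    "bmi_mean": 22.45, "bmi_sd": 5.00,
    "p_female": 1178 / 2027,
    "p_smoking": 24 / 2027,
    "p_alcohol": 105 / 2027,
    "p_physical_activity": 1567 / 2027,
    "income_probs": (832 / 2027, 727 / 2027, 287 / 2027, 94 / 2027, 87 / 2027),
}

#: Default covariate log-odds effects in the true outcome model.  Smoking,
#: alcohol and inactivity carry the qualitative excess risk the emulated
#: cohort shows; age, sex, BMI and income are null there (group p-values
#: ~0.3-1.0 for the continuous ones, identical prevalence by sex).
DEFAULT_COVARIATE_EFFECTS = {
    "age": 0.0, "sex": 0.0, "bmi": 0.0, "income": 0.0,
    "smoking": 1.3, "alcohol": 0.7, "physical_activity": -0.65,
}

def default_correlation(n_metals: int = 18) -> np.ndarray:
    """Two-block latent correlation: within-block 0.4–0.7, between 0.2.

    Within a block the correlation decays linearly with panel distance from
    0.7 (adjacent) to 0.4 (far), giving the "ranging from 0.1 to 0.7" spread
    of pairwise Spearman correlations once mapped through the copula.
    """
    R = np.full((n_metals, n_metals), 0.2)
    half = n_metals // 2
    blocks = [np.arange(half), np.arange(half, n_metals)]
    for b in blocks:
        span = max(len(b) - 1, 1)
        for ii, i in enumerate(b):
            for jj, j in enumerate(b):
                if i != j:
                    R[i, j] = 0.7 - 0.3 * (abs(ii - jj) - 1) / max(span - 1, 1)
    np.fill_diagonal(R, 1.0)
    return R

@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort, with study-condition defaults."""

    n_subjects: int = 2027
    metal_names: list[str] = field(default_factory=lambda: list(METAL_PANEL))
    latent_correlation: np.ndarray | None = None
    log10_medians: dict[str, float] = field(default_factory=lambda: dict(_LOG10_MEDIANS))
    log10_sds: dict[str, float] = field(default_factory=lambda: dict(_LOG10_SDS))
    true_terms: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_TRUE_TERMS))
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    target_prevalence: float = 0.0518
    phq9_items: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_correlation is None:
            self.latent_correlation = default_correlation(len(self.metal_names))

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0.0 < self.target_prevalence < 1.0):
            raise ValueError("target_prevalence must lie strictly in (0, 1)")
        R = np.asarray(self.latent_correlation, dtype=float)
        p = len(self.metal_names)
        if R.shape != (p, p):
            raise ValueError(f"latent_correlation must be {p}x{p}, got {R.shape}")
        if not np.allclose(R, R.T):
            raise ValueError("latent_correlation must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("latent_correlation must have unit diagonal")
        evals = np.linalg.eigvalsh(R)
        if evals.min() <= 1e-10:
            raise ValueError(
                "latent_correlation is not positive-definite: "
                f"smallest eigenvalue {evals.min():.3e}")
        for lab, _ in self.true_terms:
            t = Term.parse(lab, self.metal_names)
            for m in t.metals:
                if m not in self.metal_names:
                    raise ValueError(f"true term {lab!r} references unknown metal {m!r}")

    def streams(self) -> dict[str, np.random.Generator]:
        """Independent per-stage RNG streams spawned from the root seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("metals", "covariates", "outcome", "items")
        return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}

def generate_metals(config: GeneratorConfig,
                    rng: np.random.Generator | None = None,
                    return_latent: bool = False):
    """Draw the metal concentration matrix from the Gaussian copula.

    Returns a DataFrame of strictly positive concentrations in µg/L (and the
    latent normal draw when ``return_latent`` is set, for rank-based checks).
    """
    config.validate()
    if rng is None:
        rng = config.streams()["metals"]
    p = len(config.metal_names)
    R = np.asarray(config.latent_correlation, dtype=float)
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((config.n_subjects, p)) @ L.T
    med = np.array([config.log10_medians[m] for m in config.metal_names])
    sd = np.array([config.log10_sds[m] for m in config.metal_names])
    conc = np.power(10.0, med + sd * z)
    df = pd.DataFrame(conc, columns=config.metal_names)
    if return_latent:
        return df, pd.DataFrame(z, columns=config.metal_names)
    return df

def generate_covariates(config: GeneratorConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw covariates from the emulated cohort's marginals, independently."""
    config.validate()
    if rng is None:
        rng = config.streams()["covariates"]
    n = config.n_subjects
    m = COVARIATE_MARGINALS
    df = pd.DataFrame({
        "age": m["age_mean"] + m["age_sd"] * rng.standard_normal(n),
        "sex": np.where(rng.random(n) < m["p_female"], "female", "male"),
        "bmi": np.clip(m["bmi_mean"] + m["bmi_sd"] * rng.standard_normal(n), 13.0, None),
        "income": rng.choice(np.arange(1, 6), size=n, p=m["income_probs"]),
        "smoking": (rng.random(n) < m["p_smoking"]).astype(int),
        "alcohol": (rng.random(n) < m["p_alcohol"]).astype(int),
        "physical_activity": (rng.random(n) < m["p_physical_activity"]).astype(int),
    })
    return df

def _linear_predictor_terms(metals: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    """Exposure part of the true linear predictor, on z-scored log10 metals."""
    logx = np.log10(metals[config.metal_names].astype(float))
    Z = (logx - logx.mean()) / logx.std(ddof=1)
    lp = np.zeros(len(metals))
    for lab, coef in config.true_terms:
        lp += coef * Term.parse(lab, config.metal_names).evaluate(Z)
    return lp

def _covariate_predictor(covariates: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    eff = config.covariate_effects
    lp = np.zeros(len(covariates))
    if "age" in eff:
        lp += eff["age"] * covariates["age"].to_numpy(dtype=float)
    if "sex" in eff:
        lp += eff["sex"] * (covariates["sex"] == "male").to_numpy(dtype=float)
    if "bmi" in eff:
        lp += eff["bmi"] * covariates["bmi"].to_numpy(dtype=float)
    if "income" in eff:
        lp += eff["income"] * covariates["income"].to_numpy(dtype=float)
    for b in ("smoking", "alcohol", "physical_activity"):
        if b in eff:
            lp += eff[b] * covariates[b].to_numpy(dtype=float)
    return lp

def calibrate_intercept(lp_rest: np.ndarray, target: float,
                        lo: float = -20.0, hi: float = 20.0,
                        tol: float = 1e-4) -> float:
    """Bisect the intercept so mean(expit(b0 + lp)) hits the target prevalence.

    The expectation is over the realized draw of exposures/covariates (no
    fresh Monte Carlo), so the calibration is deterministic given the cohort.
    """
    def mean_prev(b0: float) -> float:
        return float(np.mean(expit(b0 + lp_rest)))

    f_lo, f_hi = mean_prev(lo) - target, mean_prev(hi) - target
    if f_lo > 0 or f_hi < 0:
        raise RuntimeError(
            "intercept calibration failed to bracket the target prevalence: "
            f"prevalence range [{f_lo + target:.4g}, {f_hi + target:.4g}] "
            f"does not cover {target:.4g}")
    a, b = lo, hi
    for _ in range(100):
        mid = 0.5 * (a + b)
        if mean_prev(mid) < target:
            a = mid
        else:
            b = mid
    b0 = 0.5 * (a + b)
    if abs(mean_prev(b0) - target) > tol:
        raise RuntimeError("intercept calibration did not reach the prevalence tolerance")
    return b0

def _item_cutpoint(severity: np.ndarray, target: float) -> float:
    """Bisect the proportional-odds base threshold so E[P(sum >= 10)] ≈ target.

    Given latent severity s, each of the 9 items is ordinal with
    P(item >= c) = expit(s - tau_c), tau = (t, t+1.5, t+3).  The distribution
    of the item sum given s is an exact 9-fold convolution, so the expected
    caseness rate is computable without simulation.
    """
    def p_case(t: float) -> float:
        taus = np.array([t, t + 1.5, t + 3.0])
        ge = expit(severity[:, None] - taus[None, :])  # P(item >= 1,2,3)
        pmf_item = np.stack([
            1.0 - ge[:, 0], ge[:, 0] - ge[:, 1], ge[:, 1] - ge[:, 2], ge[:, 2]
        ], axis=1)
        dist = np.zeros((len(severity), 28))
        dist[:, 0] = 1.0
        for _ in range(9):
            new = np.zeros_like(dist)
            for k in range(4):
                new[:, k:] += dist[:, : 28 - k] * pmf_item[:, [k]]
            dist = new
        return float(dist[:, 10:].sum(axis=1).mean())

    a, b = -10.0, 15.0
    if p_case(a) < target or p_case(b) > target:
        raise RuntimeError("item cutpoint calibration failed to bracket the target")
    for _ in range(100):
        mid = 0.5 * (a + b)
        if p_case(mid) > target:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)

def generate_outcome(metals: pd.DataFrame, covariates: pd.DataFrame,
                     config: GeneratorConfig,
                     rng: np.random.Generator | None = None,
                     item_rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the depressive-symptom outcome (and optionally PHQ-9 items).

    The linear predictor is intercept + exposure terms + covariate effects;
    the intercept is calibrated by bisection so the expected prevalence over
    the realized cohort equals ``target_prevalence``.  When item generation
    is on, the nine items are proportional-odds draws on a latent severity
    (linear predictor plus standard logistic noise) and the binary flag is
    re-derived as item sum >= 10.
    """
    config.validate()
    streams = None
    if rng is None or (config.phq9_items and item_rng is None):
        streams = config.streams()
    if rng is None:
        rng = streams["outcome"]
    lp_rest = _linear_predictor_terms(metals, config) + _covariate_predictor(covariates, config)
    b0 = calibrate_intercept(lp_rest, config.target_prevalence)
    lp = b0 + lp_rest
    out = pd.DataFrame(index=metals.index)
    if not config.phq9_items:
        out["depressed"] = (rng.random(len(lp)) < expit(lp)).astype(int)
        return out
    if item_rng is None:
        item_rng = streams["items"]
    severity = lp + item_rng.logistic(size=len(lp))
    t = _item_cutpoint(severity, config.target_prevalence)
    taus = np.array([t, t + 1.5, t + 3.0])
    # item score = number of thresholds exceeded by severity + fresh logistic noise
    noise = item_rng.logistic(size=(len(lp), 9))
    latent = severity[:, None] + noise
    items = (latent[:, :, None] >= taus[None, None, :]).sum(axis=2)
    for k in range(9):
        out[f"phq9_{k + 1}"] = items[:, k].astype(int)
    total = items.sum(axis=1)
    out["phq9_total"] = total.astype(int)
    out["depressed"] = (total >= 10).astype(int)
    return out

def generate_cohort(config: GeneratorConfig | None = None, **overrides) -> pd.DataFrame:
    """One call, one cohort: metals + covariates + outcome, reproducibly.

    Each stage draws from its own RNG stream spawned from the root seed, so
    e.g. regenerating outcomes does not perturb the metal draw.
    """
    if config is None:
        config = GeneratorConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    config.validate()
    streams = config.streams()
    metals = generate_metals(config, rng=streams["metals"])
    covariates = generate_covariates(config, rng=streams["covariates"])
    outcome = generate_outcome(metals, covariates, config,
                               rng=streams["outcome"], item_rng=streams["items"])
    df = pd.concat([metals, covariates, outcome], axis=1)
    df.insert(0, "subject_id", np.arange(1, len(df) + 1))
    return df
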