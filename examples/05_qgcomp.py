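"""Quantile g-computation: the joint effect of the five-metal mixture.

Each exposure is recoded to quartile scores; psi is the log-OR of raising
every exposure one quartile simultaneously, decomposed into signed weights.
"""

from ersmix import GeneratorConfig, generate_cohort, qgcomp_fit

cohort = generate_cohort(GeneratorConfig(n_subjects=2027, seed=1))
covariates = cohort[["age", "sex", "bmi", "income", "smoking", "alcohol",
                     "physical_activity"]]

eff = qgcomp_fit(cohort[["Ag", "Sb", "Sn", "La", "Ce"]],
                 cohort["depressed"].to_numpy(), covariates,
                 q=4, n_bootstrap=200, seed=3)

print(f"psi = {eff.psi:.4f} per simultaneous one-quartile increase")
print(f"mixture OR = {eff.or_:.3f} (delta-method 95% CI "
      f"{eff.ci_low:.3f}-{eff.ci_high:.3f})")
print(f"bootstrap 95% CI ({eff.bootstrap['replicates']} replicates): "
      f"{eff.bootstrap['ci_low']:.3f}-{eff.bootstrap['ci_high']:.3f}")
print("\npositive-direction weights (share of the harmful coefficient mass):")
print(eff.weights_positive.round(3).to_string())
print("negative-direction weights:")
print(eff.weights_negative.round(3).to_string())
print("\nA mixture OR near 1 with split signs means the metals' individual"
      "\neffects partly cancel when all are raised together - the quadratic"
      "\nand antagonistic interaction terms in the truth are invisible to this"
      "\nstrictly additive estimator, which is why it is a sensitivity check.")
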