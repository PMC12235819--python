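"""Term selection and environmental risk score construction, end to end.

Expands the 18 metals into 189 candidate terms, screens them with the
two-stage adaptive elastic net, refits the survivors (plus the main effects
they imply) without penalty, sums the weighted exposure terms into a
per-subject ERS, and reports the continuous and quintile odds ratios.
"""

from ersmix import (
    GeneratorConfig,
    continuous_association,
    cv_fit,
    expand,
    generate_cohort,
    hierarchical_refit,
    log10_metals,
    quintile_association,
    standardize,
)
from ersmix.simulate import METAL_PANEL

cohort = generate_cohort(GeneratorConfig(n_subjects=2027, seed=1))
covariates = cohort[["age", "sex", "bmi", "income", "smoking", "alcohol",
                     "physical_activity"]]
y = cohort["depressed"].to_numpy()

Z, scaling = standardize(log10_metals(cohort, METAL_PANEL))
termset = expand(Z, METAL_PANEL, scaling=scaling)
print(f"candidate terms: {termset.values.shape[1]} "
      "(18 mains + 18 squares + 153 pairwise products)")

fit = cv_fit(termset, y, folds=10, seed=7)
print(f"selected alpha={fit.selected_alpha}, lambda={fit.selected_lambda:.4g}")
print(f"selected terms: {fit.selected_terms}")

model = hierarchical_refit(fit.selected_terms, termset, y, covariates)
print(f"refit terms (selected + implied mains): {model.refit_terms}")
print("refit coefficients (these are the ERS weights):")
print(model.term_coefficients.round(3).to_string())

cont = continuous_association(model.ers_values, y, covariates)
print(f"\nper-unit ERS OR {cont.or_:.3f} (95% CI {cont.ci_low:.3f}-{cont.ci_high:.3f})")
print("note: in-sample, the per-unit log-OR is exactly 1 (OR = e) by"
      "\nconstruction - the ERS is the fitted metal-block linear predictor.")

for r in quintile_association(model.ers_values, y, covariates):
    mark = " (non-estimable)" if r.non_estimable else ""
    print(f"  {r.comparison}: OR {r.or_:.2f} "
          f"({r.ci_low:.2f}-{r.ci_high:.2f}){mark}")
print("rising quintile ORs reproduce the monotone mixture-risk gradient.")
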