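"""Score the PHQ-9, check internal consistency, and build the descriptive table.

Compares depressed vs non-depressed groups with the tests matched to each
variable type and computes the 18x18 Spearman co-exposure matrix.
"""

from ersmix import GeneratorConfig, cronbach_alpha, describe, generate_cohort, score_phq9
from ersmix.simulate import METAL_PANEL

cohort = generate_cohort(GeneratorConfig(n_subjects=2027, seed=1, phq9_items=True))

items = cohort[[f"phq9_{k}" for k in range(1, 10)]]
totals, flags = score_phq9(items)
print(f"PHQ-9 totals range {totals.min()}..{totals.max()} (scale maximum 27)")
print(f"cases by the >=10 cut-off: {flags.sum()} of {len(flags)}")
print(f"Cronbach's alpha of the nine items: {cronbach_alpha(items):.3f} "
      "(the screener is designed to be internally consistent)")

rep = describe(cohort, METAL_PANEL)
print(f"\nprevalence: {rep.n_cases}/{rep.n_total} = {rep.prevalence_pct}%")
print("\ngroup comparisons (depressed vs not):")
print(rep.comparisons.to_string(index=False))
off = rep.spearman_matrix.where(~(rep.spearman_matrix == 1.0))
print(f"\nSpearman matrix: 18x18, off-diagonal range "
      f"{off.min().min():.2f}..{off.max().max():.2f}")
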