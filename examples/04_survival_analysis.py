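"""Disease-free survival: log-rank with permutation null, dosage check, Cox.

Groups a simulated cohort by genotype at a variant with a true hazard ratio
of 2 per allele copy, tests the survival difference with the k-group
log-rank test plus a 100-permutation adjusted p-value, inspects the
gene-dosage ordering of restricted mean survival, and fits a multivariate
Cox model.
"""

import numpy as np
import pandas as pd

from cypgx import (
    HaplotypeBlock, SimulationConfig, cap_followup, cox_fit, dosage_check,
    permutation_p, simulate_cohort,
)

config = SimulationConfig(
    n_samples=900,
    blocks=[HaplotypeBlock.single_variant("rsSURV", 0.3)],
    baseline_hazard=0.01,
    survival_effects={"rsSURV": np.log(2.0)},   # HR 2 per copy
    censor_rate=0.004,
    seed=21,
)
cohort = simulate_cohort(config)
clin = cohort.clinical_by_id()
ids = cohort.genotypes.sample_ids
times, events = cap_followup(
    np.array([clin[s].dfs_months for s in ids]),
    np.array([clin[s].dfs_event for s in ids]),
)
geno = cohort.genotypes.column("rsSURV")

lr = permutation_p(times, events, geno, n_perm=100, seed=1)
print(f"log-rank chi2 = {lr.statistic:.2f} (df {lr.df}), "
      f"asymptotic p = {lr.p_asymptotic:.2e}, permutation p = {lr.p_permutation:.4f}")

dose = dosage_check(times, events, geno, variant_id="rsSURV")
rmst = ", ".join(f"{g} copies: {m:.1f} mo" for g, m in sorted(dose.rmst.items()))
print(f"restricted mean survival to 120 months -> {rmst}")
print(f"dosage monotone: {dose.monotone} ({dose.direction})")

df = pd.DataFrame({
    "dfs_months": times, "dfs_event": events, "genotype": geno.astype(float),
    "tumor_size": [clin[s].tumor_size for s in ids],
    "grade": [clin[s].grade for s in ids],
    "node_positive": [clin[s].node_positive for s in ids],
    "er_positive": [clin[s].er_positive for s in ids],
})
cox = cox_fit(df, covariates=["genotype", "tumor_size", "grade", "node_positive", "er_positive"])
hr = cox.hazard_ratios["genotype"]
print(f"Cox adjusted HR per copy = {hr:.2f} "
      f"(95% CI {cox.ci_low['genotype']:.2f}-{cox.ci_high['genotype']:.2f}, "
      f"p = {cox.p_values['genotype']:.1e})")
# The permutation p bottoms out at 1/101, mean survival falls with each added
# copy, and the adjusted hazard ratio should recover the simulated HR ~ 2.
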