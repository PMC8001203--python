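# cypgx

Two-phase pharmacogenomic variant prioritization and confirmation for
candidate-gene panels — the study design in which germline variants (here
motivated by the cytochrome P450 superfamily) are screened in a modest
discovery cohort against therapy response and disease-free survival, pruned
to an informative panel, and re-tested in a large independent cohort with
multiple-testing control.

The package is a library first (everything is importable from `cypgx`),
with narrative scripts in `examples/` and a thin `cypgx` command-line
wrapper for the file-based workflow.

## Who this is for

Biostatisticians and genetic epidemiologists running candidate-gene
pharmacogenomic analyses in oncology cohorts: binary treatment response
(e.g. RECIST good = CR/PR vs poor = SD/PD after neoadjuvant chemotherapy),
a disease-free survival endpoint, unphased diploid genotypes for at most a
few thousand variants, and clinical covariates. It is not a GWAS toolkit.

## What it computes

**Evaluation phase** (`evaluation_phase`): a filter cascade with a
per-variant audit trail.

1. Hardy–Weinberg exclusion: drop variants with HWE *p* < 0.01
   (1-df chi-square against *p*², 2*pq*, *q*² expectations by default; a
   conditional exact test is selectable).
2. Frequency / completeness: keep MAF > 0.05 and call rate ≥ 50%.
3. Association screens: per variant, Pearson chi-square of genotype group ×
   response and the k-group log-rank test on DFS (capped at 120 months),
   each with a permutation-adjusted *p* from B = 100 label permutations,
   p = (1 + #{T\* ≥ T}) / (B + 1). The union of response hits and DFS hits
   survives.
4. LD tag pruning: two-locus haplotype frequencies by EM over the
   double-heterozygote phase ambiguity; r² = D²/(p_A q_A p_B q_B); variants
   with r² > 0.8 to a better-ranked hit are absorbed as tags. Failed assays
   can be replaced by an r² = 1 proxy (`replace_failed_assays`).
5. Gene-dosage plausibility (DFS hits only): restricted mean survival time
   to 120 months must be monotone in 0/1/2 copies of the minor allele.

**Confirmation phase** (`confirmation_phase`): the prioritized panel is
re-tested — response in the NACT subgroup (carrier collapse when rare
homozygotes < 5), DFS log-rank in therapy strata (all / cytotoxic /
hormonal-only) and intrinsic-subtype strata (Luminal A/B, HER2, TNBC),
Benjamini–Hochberg FDR per endpoint × stratum family, and a multivariate
Cox proportional-hazards follow-up (Efron ties) adjusted for tumor size,
grade, nodal status and ER status for univariate DFS hits.

**Synthetic cohorts** (`cypgx.synthetic`): genotypes drawn as two
haplotypes per sample from configurable haplotype blocks (HWE holds by
construction, within-block LD is controlled), logistic genotype→response
effects, proportional-hazards genotype→DFS effects with exponential
baseline and independent censoring, MCAR genotype missingness — so every
pipeline stage can be verified against ground truth.

## Worked example

```python
import numpy as np
from cypgx import (AnalysisConfig, HaplotypeBlock, SimulationConfig,
                   simulate_cohort, evaluation_phase)

cohort = simulate_cohort(SimulationConfig(
    n_samples=400,
    blocks=[HaplotypeBlock.single_variant("rsRESP", 0.2),
            HaplotypeBlock(("rsTAG1", "rsTAG2"), ((0, 0), (1, 1)), (0.7, 0.3)),
            HaplotypeBlock.single_variant("rsRARE", 0.02),
            HaplotypeBlock.single_variant("rsNULL", 0.3)],
    therapy_probs={"nact": 0.6, "adjuvant_cytotoxic": 0.2,
                   "hormonal_only": 0.2, "none": 0.0},
    response_baseline=-1.0,
    response_effects={"rsRESP": np.log(3.5), "rsTAG1": np.log(2.5)},
    seed=11))

report = evaluation_phase(cohort, AnalysisConfig(n_perm=100, seed=5))
for vid, fate in sorted(report.fates.items()):
    print(f"{vid:8s} -> {fate}")
```

prints

```
rsNULL   -> not_associated
rsRARE   -> maf
rsRESP   -> prioritized
rsTAG1   -> prioritized
rsTAG2   -> tagged_by:rsTAG1
```

i.e. the rare variant fell to the MAF filter, the null variant screened
out, one member of the perfectly linked pair was absorbed as the other's
tag, and the two true response variants form the prioritized panel.
`examples/05_two_phase_pipeline.py` continues this into the confirmation
phase, where both replicate with FDR-adjusted *p* < 0.001.

Each `examples/` script is self-contained and prints what the numbers
mean; `cypgx simulate|qc|evaluate|confirm|report --help` shows the
file-based equivalents.

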