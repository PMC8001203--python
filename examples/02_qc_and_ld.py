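"""Per-variant QC and pairwise linkage disequilibrium on a simulated cohort.

Computes minor allele frequency, call rate and Hardy-Weinberg p-values, then
estimates haplotype frequencies between the two LD-block members by EM and
prints r-squared and D-prime.
"""

from cypgx import HaplotypeBlock, SimulationConfig, em_haplotype_freqs, simulate_cohort, variant_qc

config = SimulationConfig(
    n_samples=800,
    blocks=[
        HaplotypeBlock(("rsA", "rsB"), ((0, 0), (0, 1), (1, 1)), (0.5, 0.2, 0.3)),
    ],
    missing_rate=0.02,
    seed=7,
)
cohort = simulate_cohort(config)
matrix = cohort.genotypes.orient_minor()

print("variant  MAF    call_rate  HWE_p")
for stats in variant_qc(matrix):
    print(f"{stats.variant_id:8s} {stats.maf:.3f}  {stats.call_rate:.3f}      {stats.hwe_p:.3f}")

pair = em_haplotype_freqs(matrix.column("rsA"), matrix.column("rsB"), "rsA", "rsB")
print(f"\nEM haplotype frequencies (00,01,10,11): "
      + ", ".join(f"{f:.3f}" for f in pair.hap_freqs))
print(f"r2 = {pair.r2:.3f}, D' = {pair.d_prime:.3f} on {pair.n_used} samples")
# HWE p-values should be non-significant (genotypes are drawn from random
# haplotype pairs) and D' = 1 here: the block has only three haplotypes, so
# the rsA allele never recombines onto the 0-haplotype of rsB.
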