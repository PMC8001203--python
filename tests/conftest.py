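import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cypgx import HaplotypeBlock, SimulationConfig, simulate_cohort
from cypgx.genetics import MISSING, GenotypeMatrix
from cypgx.io import ClinicalRecord
from cypgx.synthetic import Cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def survival_effect_cohort():
    """One variant with log-HR ln(2), log-additive, moderate censoring."""
    config = SimulationConfig(
        n_samples=1200,
        blocks=[
            HaplotypeBlock.single_variant("rsSURV", 0.3),
            HaplotypeBlock.single_variant("rsNEUTRAL", 0.3),
        ],
        baseline_hazard=0.01,
        survival_effects={"rsSURV": float(np.log(2.0))},
        censor_rate=0.004,
        seed=77,
    )
    return simulate_cohort(config)


def toy_genotype_pair():
    """Phase-unambiguous two-locus toy: 16 chromosomes, hap counts 6/6/2/2."""
    a = np.array([2, 2, 2, 0, 0, 0, 2, 0], dtype=np.int8)
    b = np.array([2, 2, 2, 0, 0, 0, 0, 2], dtype=np.int8)
    return a, b


def known_fates_cohort() -> tuple[Cohort, dict[str, str]]:
    """A 240-sample cohort whose 8 variants have fates fixed by construction.

    Survival time increases linearly with sample index (all events), and
    response is a deterministic function of the causal variant's genotype,
    so each variant's fate under the cascade is known in advance:

    - v_hwe: no heterozygotes at allele frequency 0.5 -> HWE exclusion
    - v_maf: two rare-allele copies in 240 samples -> MAF exclusion
    - v_missing: 62.5% missing calls -> missingness exclusion
    - v_null: in HWE, unrelated to outcomes -> not associated
    - v_causal / v_ztag: identical columns driving response -> one is
      prioritized, the other absorbed as its tag
    - v_dfs: rare-allele dosage shortens survival monotonically -> prioritized
    - v_dfsbad: heterozygotes have the shortest survival -> dosage failure
    """
    n = 240
    idx = np.arange(n)
    rng = np.random.default_rng(42)

    v_hwe = np.where(idx % 2 == 0, 0, 2).astype(np.int8)
    v_maf = np.zeros(n, dtype=np.int8)
    v_maf[[10, 20]] = 1
    v_missing = np.full(n, MISSING, dtype=np.int8)
    v_missing[:90] = rng.permutation(np.array([0] * 23 + [1] * 45 + [2] * 22)).astype(np.int8)
    v_null = rng.permutation(np.array([0] * 118 + [1] * 100 + [2] * 22)).astype(np.int8)
    v_causal = np.tile([0, 1, 1, 2], n // 4).astype(np.int8)
    v_ztag = v_causal.copy()
    v_dfs = np.zeros(n, dtype=np.int8)
    v_dfs[idx < 60] = 2
    v_dfs[(idx >= 60) & (idx < 180)] = 1
    v_dfsbad = np.zeros(n, dtype=np.int8)
    v_dfsbad[idx < 120] = 1
    v_dfsbad[120:] = np.tile([0, 2], 60)

    variant_ids = ["v_causal", "v_dfs", "v_dfsbad", "v_hwe", "v_maf", "v_missing",
                   "v_null", "v_ztag"]
    columns = {
        "v_hwe": v_hwe, "v_maf": v_maf, "v_missing": v_missing, "v_null": v_null,
        "v_causal": v_causal, "v_ztag": v_ztag, "v_dfs": v_dfs, "v_dfsbad": v_dfsbad,
    }
    values = np.column_stack([columns[v] for v in variant_ids])
    sample_ids = [f"P{i:03d}" for i in range(n)]
    matrix = GenotypeMatrix(sample_ids, variant_ids, values)

    times = 6.0 + 0.45 * idx
    poor = (v_causal == 2) | ((v_causal == 1) & (idx % 8 < 4))
    clinical = [
        ClinicalRecord(
            sample_id=sample_ids[i],
            response="poor" if poor[i] else "good",
            dfs_months=float(times[i]),
            dfs_event=1,
            therapy="nact",
            subtype=("LumA", "LumB", "HER2", "TNBC")[i % 4],
            tumor_size=15.0 + (i % 7),
            grade=1 + (i % 3),
            node_positive=i % 2,
            er_positive=(i // 2) % 2,
        )
        for i in range(n)
    ]
    expected = {
        "v_hwe": "hwe",
        "v_maf": "maf",
        "v_missing": "missing",
        "v_null": "not_associated",
        "v_dfs": "prioritized",
        "v_dfsbad": "dosage_fail",
    }
    return Cohort(genotypes=matrix, clinical=clinical), expected
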