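"""Synthetic cohort generator.

Emulates the statistical structure the two-phase analysis assumes: unphased
diploid genotypes drawn from haplotype blocks (so Hardy-Weinberg holds by
construction and within-block linkage disequilibrium is controlled by the
haplotype frequencies), a binary therapy-response endpoint with logistic
per-copy genotype effects, disease-free survival with proportional-hazards
genotype effects and independent exponential censoring capped
administratively at 120 months, categorical therapy/subtype assignment, and
MCAR genotype missingness.

Randomness: one integer seed per cohort; every stage (haplotype draws,
missingness, therapy, response, survival, covariates) derives its own
deterministic sub-stream, so adding a variant to a block never perturbs the
clinical draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .genetics import MISSING, GenotypeMatrix
from .io import ClinicalRecord, SUBTYPES, THERAPIES
from .survival import FOLLOWUP_CAP

__all__ = [
    "HaplotypeBlock",
    "SimulationConfig",
    "Cohort",
    "simulate_genotypes",
    "simulate_clinical",
    "simulate_cohort",
    "fixture_cohort",
    "FIXTURES",
]

# Default categorical mixes follow a breast-cancer cohort in which roughly a
# fifth of patients received neoadjuvant chemotherapy, half adjuvant
# cytotoxic therapy, and the rest hormonal therapy only or no further
# treatment; subtypes follow the usual luminal-dominated distribution.
DEFAULT_THERAPY_PROBS = {
    "nact": 0.21, "adjuvant_cytotoxic": 0.46, "hormonal_only": 0.23, "none": 0.10,
}
DEFAULT_SUBTYPE_PROBS = {"LumA": 0.28, "LumB": 0.37, "HER2": 0.15, "TNBC": 0.20}


@dataclass(frozen=True)
class HaplotypeBlock:
    """A set of variants inheriting together as whole haplotypes.

    ``haplotypes[h][v]`` is the allele (0/1) of haplotype ``h`` at the
    block's ``v``-th variant; ``frequencies`` are the haplotype population
    frequencies.  Two haplotypes per sample are drawn independently, which
    enforces Hardy-Weinberg proportions at every member variant.
    """

    variant_ids: tuple[str, ...]
    haplotypes: tuple[tuple[int, ...], ...]
    frequencies: tuple[float, ...]

    def __post_init__(self):
        if len(self.haplotypes) < 1:
            raise ValueError("block needs at least one haplotype")
        if len(self.frequencies) != len(self.haplotypes):
            raise ValueError("one frequency per haplotype required")
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {sum(self.frequencies)}, not 1")
        if any(f < 0 for f in self.frequencies):
            raise ValueError("negative haplotype frequency")
        for h in self.haplotypes:
            if len(h) != len(self.variant_ids):
                raise ValueError("haplotype length differs from number of variants")
            if any(a not in (0, 1) for a in h):
                raise ValueError("haplotype alleles must be 0/1")

    @staticmethod
    def single_variant(variant_id: str, allele_freq: float) -> "HaplotypeBlock":
        return HaplotypeBlock((variant_id,), ((0,), (1,)), (1 - allele_freq, allele_freq))


@dataclass
class SimulationConfig:
    """Ground-truth description of a simulated cohort.

    Effects are log-scale per counted-allele copy: ``response_effects``
    maps variant id -> log-odds of *poor* response per copy (so a positive
    value mirrors a risk allele), ``survival_effects`` maps variant id ->
    log-hazard per copy.  A survival effect may instead be a 3-tuple of
    per-genotype log-hazards (0, 1, 2 copies) to break log-additivity, e.g.
    for dosage-violating fixtures.  ``baseline_hazard`` and ``censor_rate``
    are exponential rates in months^-1; ``weibull_shape`` = 1 keeps the
    baseline hazard constant.
    """

    n_samples: int
    blocks: list[HaplotypeBlock]
    response_baseline: float = 0.0       # log-odds of poor response at 0 copies
    response_effects: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.005       # events per month: mild-prognosis cohort
    survival_effects: dict[str, object] = field(default_factory=dict)
    weibull_shape: float = 1.0
    censor_rate: float = 0.008           # loss to follow-up, months^-1
    missing_rate: float = 0.0
    therapy_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THERAPY_PROBS))
    subtype_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_PROBS))
    followup_cap: float = FOLLOWUP_CAP
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        for name in ("baseline_hazard", "censor_rate", "weibull_shape"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        known = {v for b in self.blocks for v in b.variant_ids}
        for eff in (self.response_effects, self.survival_effects):
            unknown = set(eff) - known
            if unknown:
                raise ValueError(f"effect keys not in any block: {sorted(unknown)}")

    @property
    def variant_ids(self) -> list[str]:
        return [v for b in self.blocks for v in b.variant_ids]


@dataclass
class Cohort:
    genotypes: GenotypeMatrix
    clinical: list[ClinicalRecord]
    truth: SimulationConfig | None = None

    def __post_init__(self):
        geno = set(self.genotypes.sample_ids)
        clin = {r.sample_id for r in self.clinical}
        if geno != clin:
            raise ValueError("genotype and clinical sample sets differ")

    def clinical_by_id(self) -> dict[str, ClinicalRecord]:
        return {r.sample_id: r for r in self.clinical}


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # per-stage deterministic sub-stream
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(stage,)))


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw two haplotypes per sample per block and sum into allele counts."""
    n = config.n_samples
    sample_ids = [f"S{i:05d}" for i in range(n)]
    columns: list[np.ndarray] = []
    variant_ids: list[str] = []
    rng = _rng(config, stage=0)
    for block in config.blocks:
        haps = np.asarray(block.haplotypes, dtype=np.int8)  # (H, V)
        freqs = np.asarray(block.frequencies, dtype=float)
        freqs = freqs / freqs.sum()
        pair = rng.choice(len(freqs), size=(n, 2), p=freqs)
        geno = haps[pair[:, 0]] + haps[pair[:, 1]]          # (n, V)
        columns.append(geno.astype(np.int8))
        variant_ids.extend(block.variant_ids)
    values = np.concatenate(columns, axis=1)
    if config.missing_rate > 0:
        rng_miss = _rng(config, stage=1)
        mask = rng_miss.random(values.shape) < config.missing_rate
        values = values.copy()
        values[mask] = MISSING
    return GenotypeMatrix(sample_ids, variant_ids, values)


def _linear_predictor(
    genotypes: GenotypeMatrix, effects: dict[str, object], complete: np.ndarray
) -> np.ndarray:
    """Sum of per-variant effects on the (pre-missingness) genotype codes."""
    lp = np.zeros(genotypes.n_samples)
    for vid, eff in effects.items():
        g = complete[:, genotypes.variant_ids.index(vid)].astype(float)
        if np.isscalar(eff):
            lp += float(eff) * g
        else:
            table = np.asarray(eff, dtype=float)
            lp += table[g.astype(int)]
    return lp


def simulate_clinical(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    complete_genotypes: np.ndarray | None = None,
) -> list[ClinicalRecord]:
    """Draw therapy, response, DFS, subtype and covariates for each sample.

    Clinical outcomes depend on the underlying (complete) genotypes; MCAR
    missingness in the delivered matrix does not alter the truth, so pass
    ``complete_genotypes`` when the matrix has masked entries.  Response is
    drawn only for NACT-treated samples — for everyone else it is None, as
    in the study design.  DFS is min(event time, censoring time, cap) with
    the event flag set accordingly.
    """
    complete = (
        complete_genotypes
        if complete_genotypes is not None
        else genotypes.values.astype(np.int8)
    )
    if complete.shape != genotypes.values.shape:
        raise ValueError("complete genotype array shape mismatch")
    if (complete == MISSING).any():
        raise ValueError("complete genotypes may not contain missing entries")
    n = genotypes.n_samples

    rng_ther = _rng(config, stage=2)
    therapies = list(config.therapy_probs)
    probs = np.array([config.therapy_probs[t] for t in therapies], dtype=float)
    therapy = rng_ther.choice(therapies, size=n, p=probs / probs.sum())

    rng_resp = _rng(config, stage=3)
    lp_resp = config.response_baseline + _linear_predictor(
        genotypes, config.response_effects, complete
    )
    p_poor = 1.0 / (1.0 + np.exp(-lp_resp))
    poor = rng_resp.random(n) < p_poor

    rng_surv = _rng(config, stage=4)
    lp_surv = _linear_predictor(genotypes, config.survival_effects, complete)
    hazard = config.baseline_hazard * np.exp(lp_surv)
    u = rng_surv.random(n)
    with np.errstate(divide="ignore"):
        if config.weibull_shape == 1.0:
            event_time = -np.log(u) / hazard
        else:
            # PH Weibull: S(t) = exp(-(hazard) * t^shape)
            event_time = (-np.log(u) / hazard) ** (1.0 / config.weibull_shape)
    if config.censor_rate > 0:
        censor_time = rng_surv.exponential(1.0 / config.censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    dfs = np.minimum(np.minimum(event_time, censor_time), config.followup_cap)
    event = (event_time <= censor_time) & (event_time <= config.followup_cap)
    dfs = np.maximum(dfs, 1e-6)  # guard against zero times from extreme hazards

    rng_sub = _rng(config, stage=5)
    subtypes = list(config.subtype_probs)
    sprobs = np.array([config.subtype_probs[s] for s in subtypes], dtype=float)
    subtype = rng_sub.choice(subtypes, size=n, p=sprobs / sprobs.sum())

    rng_cov = _rng(config, stage=6)
    tumor_size = np.round(rng_cov.lognormal(mean=np.log(20), sigma=0.5, size=n), 1)  # mm
    grade = rng_cov.choice([1, 2, 3], size=n, p=[0.2, 0.45, 0.35])
    node_positive = (rng_cov.random(n) < 0.45).astype(int)
    er_positive = (rng_cov.random(n) < 0.75).astype(int)

    records = []
    for i, sid in enumerate(genotypes.sample_ids):
        is_nact = therapy[i] == "nact"
        records.append(
            ClinicalRecord(
                sample_id=sid,
                response=("poor" if poor[i] else "good") if is_nact else None,
                dfs_months=float(dfs[i]),
                dfs_event=int(event[i]),
                therapy=str(therapy[i]),
                subtype=str(subtype[i]),
                tumor_size=float(tumor_size[i]),
                grade=int(grade[i]),
                node_positive=int(node_positive[i]),
                er_positive=int(er_positive[i]),
            )
        )
    return records


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Full cohort: genotypes (with MCAR missingness) plus clinical records."""
    # draw complete genotypes first so clinical truth ignores missingness
    complete_cfg = SimulationConfig(**{**asdict_shallow(config), "missing_rate": 0.0})
    complete = simulate_genotypes(complete_cfg)
    genotypes = complete
    if config.missing_rate > 0:
        rng_miss = _rng(config, stage=1)
        values = complete.values.copy()
        mask = rng_miss.random(values.shape) < config.missing_rate
        values[mask] = MISSING
        genotypes = GenotypeMatrix(complete.sample_ids, complete.variant_ids, values)
    clinical = simulate_clinical(genotypes, config, complete_genotypes=complete.values)
    return Cohort(genotypes=genotypes, clinical=clinical, truth=config)


def asdict_shallow(config: SimulationConfig) -> dict:
    return {f: getattr(config, f) for f in config.__dataclass_fields__}


# ---------------------------------------------------------------------------
# Fixture registry
# ---------------------------------------------------------------------------

def _null_config(seed: int = 11, n: int = 400) -> SimulationConfig:
    blocks = [
        HaplotypeBlock.single_variant(f"rsNULL{i:03d}", freq)
        for i, freq in enumerate([0.3, 0.2, 0.4, 0.15, 0.25, 0.35, 0.1, 0.45, 0.3, 0.2])
    ]
    return SimulationConfig(n_samples=n, blocks=blocks, seed=seed, missing_rate=0.02)


def _strong_response_config(seed: int = 12, n: int = 800) -> SimulationConfig:
    blocks = [
        HaplotypeBlock.single_variant("rsCAUSAL", 0.25),
        # a two-variant LD block tagging nothing causal
        HaplotypeBlock(
            ("rsLINK1", "rsLINK2"),
            ((0, 0), (1, 1), (1, 0)),
            (0.6, 0.3, 0.1),
        ),
        HaplotypeBlock.single_variant("rsBYSTANDER", 0.3),
    ]
    return SimulationConfig(
        n_samples=n,
        blocks=blocks,
        therapy_probs={"nact": 1.0, "adjuvant_cytotoxic": 0.0, "hormonal_only": 0.0, "none": 0.0},
        response_baseline=-1.0,
        response_effects={"rsCAUSAL": float(np.log(4.0))},  # per-copy OR 4 for poor response
        seed=seed,
    )


def _dosage_violating_config(seed: int = 13, n: int = 900) -> SimulationConfig:
    blocks = [
        HaplotypeBlock.single_variant("rsHETBAD", 0.4),
        HaplotypeBlock.single_variant("rsADDITIVE", 0.3),
    ]
    return SimulationConfig(
        n_samples=n,
        blocks=blocks,
        baseline_hazard=0.01,
        # heterozygotes have the most extreme (worst) survival: non-monotone
        survival_effects={
            "rsHETBAD": (0.0, float(np.log(4.0)), 0.0),
            "rsADDITIVE": float(np.log(1.8)),
        },
        censor_rate=0.004,
        seed=seed,
    )


FIXTURES = {
    "null": _null_config,
    "strong_response_effect": _strong_response_config,
    "dosage_violating": _dosage_violating_config,
}


def fixture_cohort(name: str, seed: int | None = None) -> Cohort:
    """A small deterministic cohort with documented ground truth.

    Registry: "null" (ten independent variants, no effects anywhere),
    "strong_response_effect" (one causal variant with per-copy odds ratio 4
    for poor response in an all-NACT cohort, plus an LD block and a
    bystander), "dosage_violating" (heterozygotes carry the worst survival,
    breaking dosage monotonicity, next to a well-behaved log-additive
    variant).
    """
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    config = factory() if seed is None else factory(seed=seed)
    return simulate_cohort(config)
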