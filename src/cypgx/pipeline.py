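"""Two-phase orchestration.

Evaluation phase: QC filter cascade (Hardy-Weinberg, minor-allele
frequency, missingness) -> permutation-adjusted response and survival
screens -> LD tag pruning -> gene-dosage plausibility filter, with a full
per-variant audit trail.  Confirmation phase: the prioritized panel is
re-tested for response in the NACT subgroup and for DFS across therapy and
subtype strata, Benjamini-Hochberg FDR is applied per endpoint x stratum
family, and variants significant in a univariate DFS test get a
multivariate Cox follow-up adjusted for tumor size, grade, nodal status and
estrogen-receptor status.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import association as assoc
from . import genetics as gen
from . import survival as surv
from .genetics import MISSING
from .synthetic import Cohort

__all__ = [
    "AnalysisConfig",
    "PrioritizationReport",
    "StratifiedResults",
    "evaluation_phase",
    "confirmation_phase",
    "bh_fdr",
    "summarize_annotation",
]

CYTOTOXIC_THERAPIES = ("nact", "adjuvant_cytotoxic")


@dataclass
class AnalysisConfig:
    """Every analysis threshold in one place.

    hwe_alpha: exclusion level for Hardy-Weinberg departure.
    maf_min: minimum minor allele frequency retained (strict >).
    missing_max: maximum tolerated fraction of missing calls per variant.
    assoc_alpha: screening significance for the adjusted response/DFS tests.
    r2_tag: LD threshold above which a variant is a redundant tag (strict >).
    r2_replace: minimum LD for a replacement assay (default: perfect proxy).
    min_homozygotes: below this rare-homozygote count the carrier collapse
        is used in place of the codominant model.
    followup_cap: administrative censoring horizon in months.
    n_perm: permutations behind each adjusted p-value.
    fdr_alpha: Benjamini-Hochberg significance level in confirmation.
    """

    hwe_alpha: float = 0.01
    maf_min: float = 0.05
    missing_max: float = 0.5
    assoc_alpha: float = 0.05
    r2_tag: float = 0.8
    r2_replace: float = 1.0
    min_homozygotes: int = 5
    followup_cap: float = 120.0
    n_perm: int = 100
    fdr_alpha: float = 0.05
    hwe_method: str = "chi_square"
    seed: int = 0

    def __post_init__(self):
        for name, lo, hi in [
            ("hwe_alpha", 0, 1), ("maf_min", 0, 0.5), ("missing_max", 0, 1),
            ("assoc_alpha", 0, 1), ("fdr_alpha", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.followup_cap <= 0:
            raise ValueError("followup_cap must be positive")

    @staticmethod
    def from_file(path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return AnalysisConfig(**data)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class PrioritizationReport:
    """Per-variant audit trail of the evaluation-phase cascade.

    ``fates`` maps every input variant to exactly one of: "prioritized",
    "hwe", "maf", "missing", "not_associated", "tagged_by:<rep>",
    "dosage_fail".  ``stage_counts`` aggregates the fates; the counts sum
    to the number of input variants.
    """

    fates: dict[str, str]
    prioritized: list[str]
    stage_counts: dict[str, int]
    response_hits: list[str] = field(default_factory=list)
    dfs_hits: list[str] = field(default_factory=list)
    tag_map: dict[str, list[str]] = field(default_factory=dict)
    replacements: dict[str, str | None] = field(default_factory=dict)
    qc: list = field(default_factory=list)

    def __post_init__(self):
        assert sum(self.stage_counts.values()) == len(self.fates)


def _clinical_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for r in cohort.clinical:
        rows.append(
            {
                "sample_id": r.sample_id, "response": r.response,
                "dfs_months": r.dfs_months, "dfs_event": r.dfs_event,
                "therapy": r.therapy, "subtype": r.subtype,
                "tumor_size": r.tumor_size, "grade": r.grade,
                "node_positive": r.node_positive, "er_positive": r.er_positive,
            }
        )
    df = pd.DataFrame(rows)
    return df.set_index("sample_id").loc[cohort.genotypes.sample_ids].reset_index()


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def evaluation_phase(cohort: Cohort, config: AnalysisConfig) -> PrioritizationReport:
    """Filter cascade and prioritization with a complete audit trail.

    Order of elimination: Hardy-Weinberg departure (p < hwe_alpha) ->
    MAF <= maf_min -> call rate < 1 - missing_max -> neither adjusted
    screen significant (response chi-square and DFS log-rank, both
    permutation-adjusted, union of hits survives) -> absorbed as an LD tag
    (r^2 > r2_tag of a better-ranked hit) -> dosage violation (DFS hits
    only).  Survivors are the prioritized panel.
    """
    clin = _clinical_frame(cohort)
    required = {"response", "dfs_months", "dfs_event"}
    missing_cols = [c for c in required if clin[c].isna().all()]
    if clin["dfs_months"].isna().all():
        raise ValueError(f"clinical table lacks usable columns: {sorted(missing_cols)}")

    matrix = cohort.genotypes.orient_minor()
    fates: dict[str, str] = {}
    qc = gen.variant_qc(matrix, hwe_method=config.hwe_method)

    survivors: list[str] = []
    for stats in qc:
        if not math.isnan(stats.hwe_p) and stats.hwe_p < config.hwe_alpha:
            fates[stats.variant_id] = "hwe"
        elif math.isnan(stats.maf) or stats.maf <= config.maf_min:
            fates[stats.variant_id] = "maf"
        elif stats.call_rate < 1.0 - config.missing_max:
            fates[stats.variant_id] = "missing"
        else:
            survivors.append(stats.variant_id)

    # Adjusted association screens on the QC survivors.
    responses = {r.sample_id: r.response for r in cohort.clinical}
    sub = matrix.subset_variants(survivors) if survivors else None
    response_hits: list[str] = []
    dfs_hits: list[str] = []
    screen_p: dict[str, float] = {}
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(101,)))
    if sub is not None:
        have_response = any(r.response in ("good", "poor") for r in cohort.clinical)
        if have_response:
            for j, vid in enumerate(sub.variant_ids):
                geno = sub.values[:, j]
                resp = np.array(
                    [responses.get(s) or "missing" for s in sub.sample_ids], dtype=object
                )
                usable = (geno != MISSING) & np.isin(resp, ("good", "poor"))
                counts = gen.genotype_counts(geno[usable])
                model = gen.select_model(counts, config.min_homozygotes)
                try:
                    p_perm = assoc.permutation_p_chi2(
                        geno, resp, model, config.n_perm, rng
                    )
                except gen.DegenerateDataError:
                    continue
                screen_p[vid] = min(screen_p.get(vid, 1.0), p_perm)
                if p_perm < config.assoc_alpha:
                    response_hits.append(vid)
        times = clin["dfs_months"].to_numpy(dtype=float)
        events = clin["dfs_event"].to_numpy(dtype=float)
        has_dfs = ~(np.isnan(times) | np.isnan(events))
        for j, vid in enumerate(sub.variant_ids):
            geno = sub.values[:, j]
            usable = (geno != MISSING) & has_dfs
            if usable.sum() < 2:
                continue
            t, e = surv.cap_followup(times[usable], events[usable].astype(int), config.followup_cap)
            g = geno[usable]
            counts = gen.genotype_counts(g)
            model = gen.select_model(counts, config.min_homozygotes)
            groups = gen.collapse_genotypes(g, model)
            if np.unique(groups).size < 2:
                continue
            res = surv.permutation_p(
                t, e, groups, n_perm=config.n_perm,
                seed=int(rng.integers(2**31)),
            )
            screen_p[vid] = min(screen_p.get(vid, 1.0), res.p_permutation)
            if res.p_permutation < config.assoc_alpha:
                dfs_hits.append(vid)

    hits = sorted(set(response_hits) | set(dfs_hits))
    for vid in survivors:
        if vid not in hits:
            fates[vid] = "not_associated"

    # Tag pruning among the hits, best (smallest) adjusted p first.
    tag_map: dict[str, list[str]] = {}
    representatives = list(hits)
    if len(hits) > 1:
        hit_matrix = matrix.subset_variants(hits)
        pairs = []
        for a, b in itertools.combinations(hits, 2):
            pairs.append(
                gen.em_haplotype_freqs(hit_matrix.column(a), hit_matrix.column(b), a, b)
            )
        representatives, tag_map = gen.prune_tags(
            hits, pairs, r2_threshold=config.r2_tag, priority=screen_p
        )
        for rep, absorbed in tag_map.items():
            for vid in absorbed:
                fates[vid] = f"tagged_by:{rep}"

    # Dosage plausibility, DFS-associated representatives only.
    prioritized: list[str] = []
    times = clin["dfs_months"].to_numpy(dtype=float)
    events = clin["dfs_event"].to_numpy(dtype=float)
    has_dfs = ~(np.isnan(times) | np.isnan(events))
    for vid in representatives:
        if vid in dfs_hits:
            geno = matrix.column(vid)
            usable = (geno != MISSING) & has_dfs
            t, e = surv.cap_followup(times[usable], events[usable].astype(int), config.followup_cap)
            check = surv.dosage_check(t, e, geno[usable], variant_id=vid)
            if not check.monotone:
                fates[vid] = "dosage_fail"
                continue
        fates[vid] = "prioritized"
        prioritized.append(vid)

    stage_counts: dict[str, int] = {}
    for fate in fates.values():
        key = fate.split(":")[0] if fate.startswith("tagged_by") else fate
        stage_counts[key] = stage_counts.get(key, 0) + 1
    return PrioritizationReport(
        fates=fates,
        prioritized=sorted(prioritized),
        stage_counts=stage_counts,
        response_hits=sorted(response_hits),
        dfs_hits=sorted(dfs_hits),
        tag_map=tag_map,
        qc=qc,
    )


def replace_failed_assays(
    report: PrioritizationReport,
    cohort: Cohort,
    failed: list[str],
    config: AnalysisConfig,
) -> PrioritizationReport:
    """Swap prioritized variants whose assay failed for perfect LD proxies.

    For each failed variant, every other cohort variant is a candidate; the
    best candidate with r^2 >= r2_replace steps in, otherwise the variant
    is dropped without replacement.  Records the outcome per failed id.
    """
    matrix = cohort.genotypes.orient_minor()
    panel = [v for v in report.prioritized if v not in failed]
    for vid in failed:
        if vid not in report.prioritized:
            continue
        candidates = [v for v in matrix.variant_ids if v != vid and v not in panel]
        pairs = [
            gen.em_haplotype_freqs(matrix.column(vid), matrix.column(c), vid, c)
            for c in candidates
        ]
        chosen = gen.find_replacement_tag(vid, candidates, pairs, min_r2=config.r2_replace)
        report.replacements[vid] = chosen
        if chosen is not None:
            panel.append(chosen)
    report.prioritized = sorted(panel)
    return report


@dataclass
class StratifiedResults:
    """Confirmation-phase output keyed by endpoint and stratum.

    ``response``: per-variant association results in the NACT subgroup.
    ``dfs``: stratum name -> list of per-variant log-rank results, where
    strata are "all", "cytotoxic", "hormonal_only" and the four intrinsic
    subtypes; a stratum with no usable samples maps to None (N/A).
    ``cox``: variant -> CoxResult for univariate DFS hits.
    ``hwe_recheck``: variant -> HWE p in the confirmation cohort.
    """

    response: list
    dfs: dict[str, list | None]
    cox: dict[str, object]
    hwe_recheck: dict[str, float]


@dataclass
class VariantLogRank:
    variant_id: str
    model: str
    statistic: float
    df: int
    p: float
    p_fdr: float | None = None
    n_used: int = 0
    group_sizes: tuple[int, ...] = ()
    skipped: bool = False
    skip_reason: str | None = None


def _stratum_masks(clin: pd.DataFrame) -> dict[str, np.ndarray]:
    therapy = clin["therapy"].to_numpy(dtype=object)
    subtype = clin["subtype"].to_numpy(dtype=object)
    masks = {
        "all": np.ones(len(clin), dtype=bool),
        "cytotoxic": np.isin(therapy, CYTOTOXIC_THERAPIES),
        "hormonal_only": therapy == "hormonal_only",
    }
    for s in ("LumA", "LumB", "HER2", "TNBC"):
        masks[s] = subtype == s
    return masks


def confirmation_phase(
    cohort: Cohort, variant_list: list[str], config: AnalysisConfig
) -> StratifiedResults:
    """Targeted re-testing of a prioritized panel in an independent cohort.

    Response associations run on the NACT subgroup with per-subset model
    selection; DFS log-rank tests run per stratum; BH-FDR is applied
    within each endpoint x stratum family across the panel.  Variants with
    univariate DFS p < assoc_alpha in a therapy stratum get a multivariate
    Cox fit with tumor size, grade, nodal status and ER status.
    """
    unknown = [v for v in variant_list if v not in cohort.genotypes.variant_ids]
    if unknown:
        raise ValueError(f"variants not in cohort: {unknown}")
    clin = _clinical_frame(cohort)
    if not variant_list:
        return StratifiedResults([], {}, {}, {})
    matrix = cohort.genotypes.orient_minor().subset_variants(variant_list)

    hwe_recheck = {
        s.variant_id: s.hwe_p for s in gen.variant_qc(matrix, hwe_method=config.hwe_method)
    }

    # Response in the NACT subgroup.
    nact = clin["therapy"].to_numpy(dtype=object) == "nact"
    nact_ids = [s for s, keep in zip(matrix.sample_ids, nact) if keep]
    responses = {r.sample_id: r.response for r in cohort.clinical}
    if nact_ids:
        response_results = assoc.associate_response(
            matrix.subset_samples(nact_ids), responses,
            min_homozygotes=config.min_homozygotes,
        )
        tested = [r for r in response_results if not r.skipped]
        adjusted = bh_fdr([r.p for r in tested])
        for r, p_adj in zip(tested, adjusted):
            r.p_fdr = float(p_adj)
    else:
        response_results = []

    # DFS by stratum.
    times_all = clin["dfs_months"].to_numpy(dtype=float)
    events_all = clin["dfs_event"].to_numpy(dtype=float)
    has_dfs = ~(np.isnan(times_all) | np.isnan(events_all))
    dfs_results: dict[str, list | None] = {}
    for stratum, mask in _stratum_masks(clin).items():
        use = mask & has_dfs
        if use.sum() == 0:
            dfs_results[stratum] = None
            continue
        results = []
        for vid in variant_list:
            geno = matrix.column(vid)
            usable = use & (geno != MISSING)
            g = geno[usable]
            counts = gen.genotype_counts(g)
            model = gen.select_model(counts, config.min_homozygotes)
            groups = gen.collapse_genotypes(g, model)
            sizes = tuple(int(c) for c in np.bincount(groups[groups != MISSING]) if c > 0)
            if np.unique(groups).size < 2 or usable.sum() < 2:
                results.append(
                    VariantLogRank(vid, model.name, float("nan"), 0, float("nan"),
                                   n_used=int(usable.sum()), group_sizes=sizes,
                                   skipped=True, skip_reason="fewer than 2 genotype groups")
                )
                continue
            t, e = surv.cap_followup(
                times_all[usable], events_all[usable].astype(int), config.followup_cap
            )
            if e.sum() == 0:
                results.append(
                    VariantLogRank(vid, model.name, float("nan"), 0, float("nan"),
                                   n_used=int(usable.sum()), group_sizes=sizes,
                                   skipped=True, skip_reason="no events in stratum")
                )
                continue
            lr = surv.logrank(t, e, groups)
            results.append(
                VariantLogRank(vid, model.name, lr.statistic, lr.df, lr.p_asymptotic,
                               n_used=int(usable.sum()), group_sizes=sizes)
            )
        tested = [r for r in results if not r.skipped]
        if tested:
            adjusted = bh_fdr([r.p for r in tested])
            for r, p_adj in zip(tested, adjusted):
                r.p_fdr = float(p_adj)
        dfs_results[stratum] = results

    # Multivariate Cox follow-up for univariate DFS hits in therapy strata.
    cox_results: dict[str, surv.CoxResult] = {}
    covariates = ["tumor_size", "grade", "node_positive", "er_positive"]
    for stratum in ("all", "cytotoxic", "hormonal_only"):
        results = dfs_results.get(stratum)
        if not results:
            continue
        mask = _stratum_masks(clin)[stratum] & has_dfs
        for r in results:
            if r.skipped or r.p >= config.assoc_alpha:
                continue
            key = f"{r.variant_id}@{stratum}"
            if key in cox_results:
                continue
            geno = matrix.column(r.variant_id)
            usable = mask & (geno != MISSING)
            g = geno[usable]
            model = gen.select_model(gen.genotype_counts(g), config.min_homozygotes)
            geno_cov = (
                (gen.collapse_genotypes(g, model) > 0).astype(float)
                if model.name == "carrier"
                else g.astype(float)
            )
            t, e = surv.cap_followup(
                times_all[usable], events_all[usable].astype(int), config.followup_cap
            )
            df = pd.DataFrame(
                {
                    "dfs_months": t, "dfs_event": e, "genotype": geno_cov,
                    **{c: clin[c].to_numpy(dtype=float)[usable] for c in covariates},
                }
            )
            try:
                cox_results[key] = surv.cox_fit(
                    df, covariates=["genotype"] + covariates
                )
            except ValueError:
                continue
    return StratifiedResults(
        response=response_results, dfs=dfs_results, cox=cox_results,
        hwe_recheck=hwe_recheck,
    )


def summarize_annotation(
    annotations,
    transcript_kb: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Functional-class composition of a variant panel.

    Accepts either a list of :class:`cypgx.io.VariantAnnotation` or a
    mapping class -> count.  Returns counts with percentages to one
    decimal place; if per-gene transcript lengths (kb) are supplied, a
    second frame of per-gene counts per transcript kilobase is attached as
    ``result.attrs['per_gene_per_kb']``.
    """
    from .io import FUNCTIONAL_CLASSES, CODING_CONSEQUENCES, VariantAnnotation

    if isinstance(annotations, dict):
        counts = dict(annotations)
        known = set(FUNCTIONAL_CLASSES) | set(CODING_CONSEQUENCES)
        unknown = set(counts) - known
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        gene_counts = {}
    else:
        counts = {}
        gene_counts: dict[str, int] = {}
        for ann in annotations:
            if not isinstance(ann, VariantAnnotation):
                raise TypeError("expected VariantAnnotation items or a class->count mapping")
            counts[ann.functional_class] = counts.get(ann.functional_class, 0) + 1
            gene_counts[ann.gene] = gene_counts.get(ann.gene, 0) + 1
    total = sum(counts.values())
    rows = [
        {
            "class": cls,
            "count": n,
            "percentage": round(100.0 * n / total, 1) if total else 0.0,
        }
        for cls, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    df = pd.DataFrame(rows, columns=["class", "count", "percentage"])
    if transcript_kb:
        per_kb = {
            g: gene_counts.get(g, 0) / kb for g, kb in sorted(transcript_kb.items())
        }
        df.attrs["per_gene_per_kb"] = per_kb
    return df
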