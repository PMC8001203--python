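"""Genotype-response contingency analysis.

Builds genotype-group x response tables under a genetic model, tests them
with the Pearson chi-square (no continuity correction), and reports odds
ratios with Woolf confidence intervals.  Response is binary: "good"
(complete/partial remission) versus "poor" (stable/progressive disease).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2_contingency, norm

from .genetics import (
    MISSING,
    DegenerateDataError,
    GeneticModel,
    collapse_genotypes,
    genotype_counts,
    select_model,
)

GOOD, POOR = "good", "poor"

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "build_table",
    "chi_square",
    "odds_ratio",
    "associate_response",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Genotype groups (rows) by response good/poor (columns)."""

    row_labels: tuple[str, ...]
    counts: np.ndarray  # shape (rows, 2)
    col_labels: tuple[str, str] = (GOOD, POOR)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[1] != 2 or counts.shape[0] < 2:
            raise ValueError("contingency table must be (>=2 rows) x 2 columns")
        if (counts < 0).any():
            raise ValueError("negative cell count")
        if counts.sum() == 0:
            raise DegenerateDataError("empty contingency table")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class AssociationResult:
    variant_id: str
    model: str
    statistic: float
    df: int
    p: float
    p_fdr: float | None = None
    p_perm: float | None = None
    odds_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    or_corrected: bool = False
    n_used: int = 0
    skipped: bool = False
    skip_reason: str | None = None
    table: ContingencyTable | None = field(default=None, repr=False)


_GROUP_NAMES = {
    "codominant": ("common_hom", "het", "rare_hom"),
    "additive_trend": ("common_hom", "het", "rare_hom"),
    "carrier": ("common_hom", "carrier"),
}


def build_table(
    genotypes: np.ndarray, responses: np.ndarray, model: GeneticModel
) -> ContingencyTable:
    """Cross-tabulate collapsed genotype groups against good/poor response.

    Samples missing either the genotype or the response are dropped; rows
    for genotype groups absent from the data are dropped (a group that
    nobody occupies is not a table row), but a present group with zero
    count in one response column is retained.
    """
    geno = np.asarray(genotypes)
    resp = np.asarray(responses, dtype=object)
    keep = (geno != MISSING) & np.isin(resp, (GOOD, POOR))
    geno, resp = geno[keep], resp[keep]
    collapsed = collapse_genotypes(geno, model)
    names = _GROUP_NAMES.get(model.name, tuple(str(g) for g in sorted(set(model.collapse))))
    groups = sorted(set(model.collapse))
    rows, labels = [], []
    for g, name in zip(groups, names):
        in_group = collapsed == g
        if not in_group.any():
            continue
        rows.append([int((resp[in_group] == GOOD).sum()), int((resp[in_group] == POOR).sum())])
        labels.append(name)
    if len(rows) < 2:
        raise DegenerateDataError(
            f"fewer than 2 non-empty genotype groups under model {model.name!r}"
        )
    return ContingencyTable(tuple(labels), np.array(rows))


def chi_square(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    Returns (statistic, df, p) with df = (rows-1)(cols-1).  A zero row or
    column margin makes the expectation degenerate and is rejected.
    """
    counts = table.counts
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    if (row_tot == 0).any():
        bad = table.row_labels[int(np.argmin(row_tot))]
        raise DegenerateDataError(f"zero row margin for group {bad!r}")
    if (col_tot == 0).any():
        bad = table.col_labels[int(np.argmin(col_tot))]
        raise DegenerateDataError(f"zero column margin for response {bad!r}")
    stat, p, df, _ = chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


def chi_square_statistic(counts: np.ndarray) -> float:
    """Pearson statistic only, for permutation loops (margins assumed valid)."""
    counts = np.asarray(counts, dtype=float)
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row @ col / counts.sum()
    return float(((counts - expected) ** 2 / expected).sum())


def odds_ratio(
    table: ContingencyTable, alpha: float = 0.05
) -> tuple[float | None, float | None, float | None, bool]:
    """Cross-product odds ratio of poor response, rare group versus reference.

    Rows must be 2 (collapse first); row 0 is the reference (common
    homozygote) and row 1 the rare group, so OR > 1 means the rare group
    has higher odds of poor response.  The CI is Woolf's log-OR +/- z * SE.
    If any cell is zero the Haldane-Anscombe 0.5 correction is added to
    every cell and the returned flag is set; if an entire row or column of
    the 2x2 is zero the OR is undefined and (None, None, None, True) is
    returned.
    """
    if table.counts.shape[0] != 2:
        raise ValueError("odds ratio requires a 2x2 table; collapse genotype groups first")
    a, b = table.counts[0]  # reference: good, poor
    c, d = table.counts[1]  # rare group: good, poor
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return None, None, None, True
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    or_ = (d * a) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(1 - alpha / 2)
    lo, hi = or_ * math.exp(-z * se), or_ * math.exp(z * se)
    return float(or_), float(lo), float(hi), corrected


def permutation_p_chi2(
    genotypes: np.ndarray,
    responses: np.ndarray,
    model: GeneticModel,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Permutation p for the chi-square: shuffle responses against genotypes.

    Uses the add-one estimator (1 + #{perm >= obs}) / (B + 1); permuted
    tables that turn degenerate count as non-exceeding.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    obs_table = build_table(genotypes, responses, model)
    obs = chi_square_statistic(obs_table.counts)
    geno = np.asarray(genotypes)
    resp = np.asarray(responses, dtype=object)
    keep = (geno != MISSING) & np.isin(resp, (GOOD, POOR))
    geno, resp = geno[keep], resp[keep]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(resp)
        try:
            t = build_table(geno, perm, model)
            stat = chi_square_statistic(t.counts)
        except DegenerateDataError:
            continue
        if stat >= obs - 1e-12:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def associate_response(
    genotype_matrix,
    responses: dict[str, str],
    min_homozygotes: int = 5,
    n_perm: int | None = None,
    seed: int | None = None,
) -> list[AssociationResult]:
    """Per-variant genotype-response association on the responding subgroup.

    For each variant: genotype counts on the samples with a recorded
    response pick the model (carrier collapse when rare homozygotes number
    fewer than ``min_homozygotes``), the collapsed table is tested by
    Pearson chi-square, and an odds ratio is attached (computed on the
    carrier collapse when the tested table has three rows).  Degenerate
    variants become skip records rather than aborting the scan.  Results
    are sorted by ascending p.  When ``n_perm`` is given a permutation
    p-value is attached per variant.
    """
    resp = np.array(
        [responses.get(s, "missing") or "missing" for s in genotype_matrix.sample_ids],
        dtype=object,
    )
    rng = np.random.default_rng(seed)
    results: list[AssociationResult] = []
    for j, vid in enumerate(genotype_matrix.variant_ids):
        geno = genotype_matrix.values[:, j]
        usable = (geno != MISSING) & np.isin(resp, (GOOD, POOR))
        counts = genotype_counts(geno[usable])
        model = select_model(counts, min_homozygotes)
        try:
            table = build_table(geno, resp, model)
            stat, df, p = chi_square(table)
        except DegenerateDataError as exc:
            results.append(
                AssociationResult(
                    vid, model.name, float("nan"), 0, float("nan"),
                    n_used=int(usable.sum()), skipped=True, skip_reason=str(exc),
                )
            )
            continue
        if table.counts.shape[0] > 2:
            from .genetics import CARRIER

            try:
                or_table = build_table(geno, resp, CARRIER)
            except DegenerateDataError:
                or_table = None
        else:
            or_table = table
        if or_table is not None:
            or_, lo, hi, flag = odds_ratio(or_table)
        else:
            or_, lo, hi, flag = None, None, None, True
        p_perm = (
            permutation_p_chi2(geno, resp, model, n_perm, rng)
            if n_perm
            else None
        )
        results.append(
            AssociationResult(
                vid, model.name, stat, df, p,
                p_perm=p_perm, odds_ratio=or_, ci_low=lo, ci_high=hi,
                or_corrected=flag, n_used=table.n, table=table,
            )
        )
    results.sort(key=lambda r: (r.skipped, r.p if not math.isnan(r.p) else float("inf"), r.variant_id))
    return results
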