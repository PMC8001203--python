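"""Per-variant genetic computations.

Minor-allele frequency, call rate, Hardy-Weinberg testing, genetic-model
collapsing, two-locus EM haplotype-frequency estimation with r^2 / D', and
greedy LD-based tag pruning.

Genotypes are coded as the count of one allele per sample: 0 (common
homozygote), 1 (heterozygote), 2 (rare homozygote), with -1 for a missing
call.  File readers code the ALT allele; :meth:`GenotypeMatrix.orient_minor`
flips columns once, on the full cohort, so that the code counts the minor
allele everywhere downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "VariantQCStats",
    "LDPair",
    "GeneticModel",
    "CODOMINANT",
    "CARRIER",
    "ADDITIVE_TREND",
    "compute_maf",
    "call_rate",
    "hwe_test",
    "collapse_genotypes",
    "select_model",
    "genotype_counts",
    "em_haplotype_freqs",
    "genotype_r2",
    "prune_tags",
    "find_replacement_tag",
]


class DegenerateDataError(ValueError):
    """Raised when an operation receives data it cannot meaningfully analyze."""


@dataclass
class GenotypeMatrix:
    """Samples x variants allele-count matrix.

    ``values`` is int8 with entries in {0, 1, 2, MISSING}. ``flipped`` marks
    variants whose coding was swapped relative to the input REF/ALT so that
    the code counts the minor allele.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    values: np.ndarray
    flipped: dict[str, bool] = field(default_factory=dict)
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.values[i, j]} at sample "
                f"{self.sample_ids[i]!r}, variant {self.variant_ids[j]!r}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def column(self, variant_id: str) -> np.ndarray:
        return self.values[:, self.variant_ids.index(variant_id)]

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            variant_ids=list(self.variant_ids),
            values=self.values[rows, :].copy(),
            flipped=dict(self.flipped),
            metadata=dict(self.metadata),
        )

    def subset_variants(self, variant_ids: list[str]) -> "GenotypeMatrix":
        cols = [self.variant_ids.index(v) for v in variant_ids]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variant_ids=list(variant_ids),
            values=self.values[:, cols].copy(),
            flipped={v: self.flipped.get(v, False) for v in variant_ids},
            metadata={v: self.metadata[v] for v in variant_ids if v in self.metadata},
        )

    def orient_minor(self) -> "GenotypeMatrix":
        """Return a copy where every column counts the minor allele.

        The orientation is decided once, on the full matrix; subgroup
        analyses must reuse it so a subgroup allele-frequency excursion
        past 0.5 never flips the reference group.
        """
        values = self.values.copy()
        flipped: dict[str, bool] = {}
        for j, vid in enumerate(self.variant_ids):
            col = values[:, j]
            called = col[col != MISSING]
            flip = called.size > 0 and called.mean() / 2.0 > 0.5
            if flip:
                mask = col != MISSING
                col[mask] = 2 - col[mask]
            flipped[vid] = bool(self.flipped.get(vid, False) ^ flip)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variant_ids=list(self.variant_ids),
            values=values,
            flipped=flipped,
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class VariantQCStats:
    variant_id: str
    maf: float
    call_rate: float
    hwe_p: float
    genotype_counts: tuple[int, int, int]  # (common hom, het, rare hom)


@dataclass(frozen=True)
class LDPair:
    """Pairwise linkage disequilibrium from EM haplotype frequencies.

    ``hap_freqs`` orders haplotypes (00, 01, 10, 11) where the first digit
    is variant_a's counted allele and the second variant_b's.
    """

    variant_a: str
    variant_b: str
    hap_freqs: tuple[float, float, float, float]
    r2: float
    d_prime: float
    n_used: int
    log_likelihood: float = float("nan")
    n_iter: int = 0


@dataclass(frozen=True)
class GeneticModel:
    """A rule collapsing allele-count codes {0,1,2} into analysis groups.

    ``collapse`` maps each code to a group label; labels shared between
    codes merge those genotype classes.  The carrier model pools
    heterozygotes with rare homozygotes against common homozygotes — the
    collapse applied when rare homozygotes are too few to analyze alone.
    """

    name: str
    collapse: tuple[int, int, int]
    ordered: bool = False

    @property
    def n_groups(self) -> int:
        return len(set(self.collapse))


CODOMINANT = GeneticModel("codominant", (0, 1, 2))
CARRIER = GeneticModel("carrier", (0, 1, 1))
COMMON_VS_REST = CARRIER  # alias; identical collapse
ADDITIVE_TREND = GeneticModel("additive_trend", (0, 1, 2), ordered=True)

_MODELS = {
    "codominant": CODOMINANT,
    "carrier": CARRIER,
    "common_vs_rest": CARRIER,
    "additive_trend": ADDITIVE_TREND,
}


def get_model(name: str) -> GeneticModel:
    try:
        return _MODELS[name]
    except KeyError:
        raise ValueError(f"unknown genetic model {name!r}") from None


def genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    """Counts of codes (0, 1, 2) among called genotypes in a column."""
    col = np.asarray(column)
    called = col[col != MISSING]
    return (int((called == 0).sum()), int((called == 1).sum()), int((called == 2).sum()))


def compute_maf(counts: tuple[int, int, int]) -> float:
    """Minor allele frequency (het + 2 x rare hom) / (2 x called), folded to <= 0.5.

    The fold only matters if the caller passed counts oriented to the major
    allele; matrices run through :meth:`GenotypeMatrix.orient_minor` never
    fold here.
    """
    n0, n1, n2 = counts
    n = n0 + n1 + n2
    if n == 0:
        raise DegenerateDataError("MAF undefined: variant has no called genotypes")
    freq = (n1 + 2 * n2) / (2 * n)
    return min(freq, 1.0 - freq)


def call_rate(column: np.ndarray) -> float:
    col = np.asarray(column)
    if col.size == 0:
        raise DegenerateDataError("call rate undefined for an empty genotype column")
    return float((col != MISSING).sum() / col.size)


def hwe_test(counts: tuple[int, int, int], method: str = "chi_square") -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts.

    chi_square: 1-df Pearson test of observed genotype counts against the
    p^2 / 2pq / q^2 expectation.  exact: conditional-on-allele-counts exact
    test summing the probabilities of all heterozygote configurations no
    more probable than the observed one (Wigginton-style).  Monomorphic
    variants return p = 1: no departure is testable.
    """
    n0, n1, n2 = counts
    n = n0 + n1 + n2
    if n < 1:
        raise DegenerateDataError("HWE test needs at least one called genotype")
    n_rare = n1 + 2 * n2
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    if method == "chi_square":
        q = n_rare / (2 * n)
        p = 1.0 - q
        expected = np.array([p * p, 2 * p * q, q * q]) * n
        stat = float((((np.array([n0, n1, n2]) - expected) ** 2) / expected).sum())
        return float(chi2.sf(stat, df=1))
    if method == "exact":
        return _hwe_exact(n0, n1, n2)
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact(n0: int, n1: int, n2: int) -> float:
    # Exact test conditional on allele counts: enumerate heterozygote counts
    # of the same parity, compute probabilities by the stable ratio
    # recurrence, sum those <= the observed probability.
    n = n0 + n1 + n2
    rare = n1 + 2 * n2
    if rare > n:  # fold so `rare` is the minor allele count
        rare = 2 * n - rare
    hets = np.arange(rare % 2, rare + 1, 2)
    probs = np.empty(hets.size)
    probs[0] = 1.0
    for k in range(1, hets.size):
        h = hets[k]
        # P(h) / P(h-2) = 4 * n_rarehom(h-2) * n_comhom(h-2) / (h * (h-1))
        h_prev = h - 2
        rare_hom = (rare - h_prev) // 2
        com_hom = n - h_prev - rare_hom
        probs[k] = probs[k - 1] * 4.0 * rare_hom * com_hom / (h * (h - 1))
    probs /= probs.sum()
    observed = min(n1, rare)  # n1 already consistent with parity
    p_obs = probs[np.searchsorted(hets, n1)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def collapse_genotypes(column: np.ndarray, model: GeneticModel) -> np.ndarray:
    """Map allele-count codes through the model's collapse rule; missing propagates."""
    col = np.asarray(column)
    out = np.full(col.shape, MISSING, dtype=np.int8)
    for code, group in enumerate(model.collapse):
        out[col == code] = group
    return out


def select_model(
    counts: tuple[int, int, int], min_homozygotes: int = 5
) -> GeneticModel:
    """Carrier collapse when rare homozygotes are scarce, codominant otherwise.

    Counts must come from the analysis subset (e.g. the NACT-treated
    subgroup), not the full cohort: the rule guards the power of the test
    actually run.
    """
    n2 = counts[2]
    return CARRIER if n2 < min_homozygotes else CODOMINANT


# ---------------------------------------------------------------------------
# Two-locus haplotype frequency estimation (EM over phase ambiguity)
# ---------------------------------------------------------------------------

def em_haplotype_freqs(
    col_a: np.ndarray,
    col_b: np.ndarray,
    variant_a: str = "a",
    variant_b: str = "b",
    tol: float = 1e-8,
    max_iter: int = 1000,
    ll_trace: list | None = None,
) -> LDPair:
    """Maximum-likelihood two-locus haplotype frequencies from unphased diploids.

    Every genotype pair resolves its two haplotypes uniquely except the
    double heterozygote, which is either {01,10} or {00,11}.  The EM step
    splits the 2 x (number of double heterozygotes) ambiguous chromosomes
    between the two phases in proportion to the current product
    frequencies, then re-normalizes.  r^2 = D^2 / (pA qA pB qB) and
    D' = |D| / Dmax follow from the fitted frequencies — the convention
    haplotype-block tagging tools use, rather than genotype correlation.
    """
    a = np.asarray(col_a)
    b = np.asarray(col_b)
    if a.shape != b.shape:
        raise ValueError("genotype columns differ in length")
    mask = (a != MISSING) & (b != MISSING)
    a, b = a[mask].astype(np.int64), b[mask].astype(np.int64)
    n = a.size
    if n < 2:
        raise DegenerateDataError("EM needs at least 2 samples called at both variants")

    p_a = a.mean() / 2.0
    p_b = b.mean() / 2.0
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        warnings.warn(
            f"monomorphic variant in pair ({variant_a}, {variant_b}); r2 = 0 by convention",
            stacklevel=2,
        )
        f = (
            (1 - p_a) * (1 - p_b),
            (1 - p_a) * p_b,
            p_a * (1 - p_b),
            p_a * p_b,
        )
        return LDPair(variant_a, variant_b, f, 0.0, 0.0, n, 0.0, 0)

    # Unambiguous haplotype counts. Genotype pair (ga, gb) with not both ==1
    # contributes known chromosomes: e.g. (2,1) -> one 11 and one 10.
    counts9 = np.bincount(3 * a + b, minlength=9).astype(float)
    n_dh = counts9[4]  # double heterozygotes
    # fixed[haplotype 2*i+j] = chromosomes known to carry alleles (i, j)
    fixed = np.zeros(4)
    for ga in range(3):
        for gb in range(3):
            if ga == 1 and gb == 1:
                continue
            c = counts9[3 * ga + gb]
            if c == 0:
                continue
            for ha, hb in _phase_pairs(ga, gb):
                fixed[2 * ha + hb] += c
    total = 2.0 * n

    # init from allele-frequency products (linkage-equilibrium start)
    f = np.array(
        [
            (1 - p_a) * (1 - p_b),
            (1 - p_a) * p_b,
            p_a * (1 - p_b),
            p_a * p_b,
        ]
    )
    ll_prev = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step: split double-het chromosomes between cis (00/11) and
        # trans (01/10) phase.
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        denom = cis + trans
        w = 0.5 if denom == 0 else cis / denom
        expected = fixed.copy()
        expected[0] += n_dh * w
        expected[3] += n_dh * w
        expected[1] += n_dh * (1 - w)
        expected[2] += n_dh * (1 - w)
        f_new = expected / total
        ll = _pair_loglik(f_new, fixed, n_dh)
        if ll_trace is not None:
            ll_trace.append(ll)
        if np.abs(f_new - f).max() < tol and ll - ll_prev < tol:
            f = f_new
            break
        f = f_new
        ll_prev = ll
    ll = _pair_loglik(f, fixed, n_dh)

    pa = f[2] + f[3]
    pb = f[1] + f[3]
    d = f[3] - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    r2 = 0.0 if denom == 0 else d * d / denom
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = 0.0 if dmax == 0 else abs(d) / dmax
    return LDPair(
        variant_a,
        variant_b,
        tuple(float(x) for x in f),
        float(min(r2, 1.0)),
        float(min(d_prime, 1.0)),
        int(n),
        float(ll),
        n_iter,
    )


def _phase_pairs(ga: int, gb: int) -> list[tuple[int, int]]:
    """The two haplotypes of an unambiguous genotype pair (not both het)."""
    ha = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[ga]
    hb = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[gb]
    if ga != 1:
        return [(ha[0], hb[0]), (ha[0], hb[1])]
    if gb != 1:
        return [(ha[0], hb[0]), (ha[1], hb[0])]
    raise AssertionError("double heterozygote has ambiguous phase")


def _pair_loglik(f: np.ndarray, fixed: np.ndarray, n_dh: float) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = float(np.sum(fixed[fixed > 0] * np.log(f[fixed > 0])))
    if n_dh > 0:
        mix = 2.0 * (f[0] * f[3] + f[1] * f[2])
        ll += n_dh * (np.log(mix) if mix > 0 else -np.inf)
    return ll


def genotype_r2(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Squared Pearson correlation of allele counts (composite LD measure)."""
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    mask = (a != MISSING) & (b != MISSING)
    a, b = a[mask], b[mask]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# Tag pruning and assay replacement
# ---------------------------------------------------------------------------

def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def build_ld_index(pairs: list[LDPair]) -> dict[tuple[str, str], LDPair]:
    return {_pair_key(p.variant_a, p.variant_b): p for p in pairs}


def prune_tags(
    variants: list[str],
    ld: list[LDPair] | dict[tuple[str, str], LDPair],
    r2_threshold: float = 0.8,
    priority: dict[str, float] | None = None,
) -> tuple[list[str], dict[str, list[str]]]:
    """Greedy LD pruning: keep one representative per group of linked variants.

    Variants are visited in ascending ``priority`` (association p-value;
    ties broken by ascending variant id, missing priorities last).  Each
    selected representative absorbs every not-yet-assigned variant with
    r^2 strictly above the threshold.  Returns the representatives and a
    map representative -> absorbed tags.
    """
    index = ld if isinstance(ld, dict) else build_ld_index(ld)
    prio = priority or {}
    order = sorted(variants, key=lambda v: (prio.get(v, float("inf")), v))
    assigned: set[str] = set()
    representatives: list[str] = []
    tag_map: dict[str, list[str]] = {}
    for v in order:
        if v in assigned:
            continue
        representatives.append(v)
        assigned.add(v)
        absorbed = []
        for other in order:
            if other in assigned:
                continue
            key = _pair_key(v, other)
            if key not in index:
                raise KeyError(f"no LD entry for pair {key}")
            if index[key].r2 > r2_threshold:
                absorbed.append(other)
                assigned.add(other)
        tag_map[v] = sorted(absorbed)
    return representatives, tag_map


def find_replacement_tag(
    failed_variant: str,
    candidates: list[str],
    ld: list[LDPair] | dict[tuple[str, str], LDPair],
    min_r2: float = 1.0,
) -> str | None:
    """Best-linked stand-in for a variant whose assay failed, or None.

    Candidates below ``min_r2`` never qualify; ties on r^2 resolve to the
    lexicographically smaller id.
    """
    index = ld if isinstance(ld, dict) else build_ld_index(ld)
    best: tuple[float, str] | None = None
    for cand in sorted(candidates):
        if cand == failed_variant:
            continue
        pair = index.get(_pair_key(failed_variant, cand))
        if pair is None:
            continue
        if pair.r2 >= min_r2 and (best is None or pair.r2 > best[0]):
            best = (pair.r2, cand)
    return None if best is None else best[1]


def variant_qc(matrix: GenotypeMatrix, hwe_method: str = "chi_square") -> list[VariantQCStats]:
    """QC statistics for every variant of a minor-oriented matrix."""
    out = []
    for j, vid in enumerate(matrix.variant_ids):
        col = matrix.values[:, j]
        counts = genotype_counts(col)
        n_called = sum(counts)
        out.append(
            VariantQCStats(
                variant_id=vid,
                maf=compute_maf(counts) if n_called else float("nan"),
                call_rate=call_rate(col),
                hwe_p=hwe_test(counts, method=hwe_method) if n_called else float("nan"),
                genotype_counts=counts,
            )
        )
    return out
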