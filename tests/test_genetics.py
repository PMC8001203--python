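"""Per-variant genetics: MAF, call rate, HWE, models, EM haplotypes, pruning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2

import cypgx.genetics as gen
from cypgx.genetics import (
    CARRIER,
    CODOMINANT,
    MISSING,
    GenotypeMatrix,
    call_rate,
    collapse_genotypes,
    compute_maf,
    em_haplotype_freqs,
    find_replacement_tag,
    genotype_r2,
    hwe_test,
    prune_tags,
    select_model,
)
from conftest import toy_genotype_pair

counts_strategy = st.tuples(
    st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
).filter(lambda c: sum(c) > 0)


class TestMaf:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((362, 354, 77), 0.32),   # confirmation-set distribution, common variant
            ((653, 125, 8), 0.09),    # low-frequency variant
            ((225, 401, 158), 0.46),  # near-balanced variant
            ((100, 0, 0), 0.0),       # monomorphic
        ],
    )
    def test_known_frequencies(self, counts, expected):
        assert compute_maf(counts) == pytest.approx(expected, abs=5e-3)

    def test_all_missing_is_an_error(self):
        with pytest.raises(gen.DegenerateDataError):
            compute_maf((0, 0, 0))

    @given(counts_strategy)
    @settings(max_examples=200, deadline=None)
    def test_folded_into_minor_range(self, counts):
        maf = compute_maf(counts)
        assert 0.0 <= maf <= 0.5
        # folding = taking the min of the two allele frequencies
        n0, n1, n2 = counts
        raw = (n1 + 2 * n2) / (2 * sum(counts))
        assert maf == pytest.approx(min(raw, 1 - raw))


class TestCallRate:
    def test_counts_non_missing_fraction(self):
        col = np.array([0, 1, 2, MISSING, 1, MISSING, MISSING, 0, MISSING, MISSING])
        assert call_rate(col) == pytest.approx(0.5)
        assert call_rate(np.array([0, 1, 2])) == 1.0

    def test_empty_column_is_an_error(self):
        with pytest.raises(gen.DegenerateDataError):
            call_rate(np.array([], dtype=np.int8))


class TestHWE:
    def test_perfect_proportions_give_p_one(self):
        # (25, 50, 25) sits exactly on p^2 / 2pq / q^2
        assert hwe_test((25, 50, 25)) == pytest.approx(1.0)

    def test_statistic_matches_direct_formula(self):
        # oracle: explicit Pearson sum on the expectation under p=0.32
        n0, n1, n2 = 362, 354, 77
        n = n0 + n1 + n2
        q = (n1 + 2 * n2) / (2 * n)
        e = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2]) * n
        stat = (((np.array([n0, n1, n2]) - e) ** 2) / e).sum()
        assert stat == pytest.approx(0.505, abs=1e-3)
        assert hwe_test((n0, n1, n2)) == pytest.approx(float(chi2.sf(stat, 1)))

    def test_heterozygote_deficit_rejected(self):
        assert hwe_test((50, 0, 50)) < 1e-10
        assert hwe_test((50, 0, 50), method="exact") < 1e-10

    def test_monomorphic_convention(self):
        assert hwe_test((100, 0, 0)) == 1.0
        assert hwe_test((0, 0, 100), method="exact") == 1.0

    def test_exact_matches_enumeration_oracle(self):
        # brute-force conditional distribution over heterozygote counts
        from math import comb

        def exact_oracle(n0, n1, n2):
            n = n0 + n1 + n2
            rare = n1 + 2 * n2
            probs = {}
            for het in range(rare % 2, min(rare, 2 * n - rare) + 1, 2):
                hom_r = (rare - het) // 2
                hom_c = n - het - hom_r
                # P(het | rare alleles) ∝ n! / (hom_c! het! hom_r!) * 2^het
                probs[het] = (
                    comb(n, hom_c) * comb(n - hom_c, het) * 2**het
                )
            total = sum(probs.values())
            p_obs = probs[n1]
            return sum(v for v in probs.values() if v <= p_obs) / total

        for counts in [(5, 5, 5), (40, 12, 3), (10, 1, 10), (70, 25, 5)]:
            assert hwe_test(counts, method="exact") == pytest.approx(
                exact_oracle(*counts), abs=1e-9
            )

    def test_chi_square_and_exact_agree_on_equilibrium_data(self, rng):
        # simulated HWE-consistent variants: both methods reject at 0.01
        # on at most a few percent, and agree on >= 95% of decisions
        agree = 0
        n_rep = 200
        for _ in range(n_rep):
            p = rng.uniform(0.1, 0.5)
            g = rng.binomial(1, p, size=(500, 2)).sum(axis=1)
            counts = tuple(int((g == k).sum()) for k in range(3))
            r_chi = hwe_test(counts) < 0.01
            r_ex = hwe_test(counts, method="exact") < 0.01
            agree += r_chi == r_ex
        assert agree / n_rep >= 0.95


class TestModels:
    def test_carrier_pools_rare_groups(self):
        col = np.array([0] * 111 + [1] * 11 + [2] * 14)
        grouped = collapse_genotypes(col, CARRIER)
        assert (grouped == 0).sum() == 111
        assert (grouped == 1).sum() == 25

    def test_codominant_is_identity_and_missing_propagates(self):
        col = np.array([0, 1, 2, MISSING])
        assert np.array_equal(collapse_genotypes(col, CODOMINANT), col)
        assert np.array_equal(
            collapse_genotypes(np.full(4, MISSING, dtype=np.int8), CARRIER),
            np.full(4, MISSING),
        )

    @pytest.mark.parametrize(
        "counts,threshold,expected",
        [
            ((111, 12, 1), 5, "carrier"),    # scarce rare homozygotes
            ((63, 57, 10), 5, "codominant"), # enough for three groups
            ((63, 57, 10), 0, "codominant"), # threshold 0 never collapses
            ((100, 50, 4), 0, "codominant"),
        ],
    )
    def test_selection_rule(self, counts, threshold, expected):
        assert select_model(counts, threshold).name == expected


class TestEMHaplotypes:
    def test_self_ld_is_one(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 1])
        pair = em_haplotype_freqs(col, col.copy())
        assert pair.r2 == pytest.approx(1.0, abs=1e-9)
        assert pair.d_prime == pytest.approx(1.0, abs=1e-9)

    def test_phase_unambiguous_toy_recovers_known_frequencies(self):
        a, b = toy_genotype_pair()
        pair = em_haplotype_freqs(a, b)
        # haplotype proportions by construction: 00=6/16, 11=6/16, 10=2/16, 01=2/16
        assert pair.hap_freqs == pytest.approx((0.375, 0.125, 0.125, 0.375), abs=1e-6)
        assert pair.r2 == pytest.approx(0.25, abs=1e-6)

    def test_em_equals_phase_known_r2_without_double_heterozygotes(self, rng):
        # with no sample heterozygous at both loci the phase is fully
        # observed, so EM r2 must equal the haplotype-count r2 exactly
        for _ in range(20):
            haps = rng.integers(0, 2, size=(40, 2))
            # pair haplotypes so that no (1,x)+(0,y) pairing makes a double het
            geno = haps[::2] + haps[1::2]
            dh = (geno[:, 0] == 1) & (geno[:, 1] == 1)
            geno = geno[~dh]
            if np.unique(geno[:, 0]).size < 2 or np.unique(geno[:, 1]).size < 2:
                continue
            pair = em_haplotype_freqs(geno[:, 0], geno[:, 1])
            # phase-known r2 from the actual haplotypes of the kept samples
            assert pair.r2 == pytest.approx(genotype_phase_known_r2(geno), abs=1e-9)

    def test_matches_likelihood_grid_oracle(self, rng):
        # the EM MLE keeps marginals at the observed allele frequencies, so
        # the likelihood has a single free parameter f11: grid-search it
        for _ in range(10):
            f = rng.dirichlet([2, 2, 2, 2])
            pairs = rng.choice(4, size=(60, 2), p=f)
            alleles = np.array([(0, 0), (0, 1), (1, 0), (1, 1)])
            ga = alleles[pairs[:, 0], 0] + alleles[pairs[:, 1], 0]
            gb = alleles[pairs[:, 0], 1] + alleles[pairs[:, 1], 1]
            if np.unique(ga).size < 2 or np.unique(gb).size < 2:
                continue
            pair = em_haplotype_freqs(ga, gb)
            pa = ga.mean() / 2
            pb = gb.mean() / 2
            counts9 = np.bincount(3 * ga + gb, minlength=9)
            best_ll, best_f11 = -np.inf, None
            for f11 in np.linspace(max(0, pa + pb - 1), min(pa, pb), 20001):
                hf = np.array([1 - pa - pb + f11, pb - f11, pa - f11, f11])
                if (hf < -1e-12).any():
                    continue
                hf = np.clip(hf, 1e-300, None)
                ll = _pair_ll(hf, counts9)
                if ll > best_ll:
                    best_ll, best_f11 = ll, f11
            d = best_f11 - pa * pb
            r2_oracle = d * d / (pa * (1 - pa) * pb * (1 - pb))
            assert pair.r2 == pytest.approx(r2_oracle, abs=1e-4)

    def test_log_likelihood_never_decreases(self, rng):
        for _ in range(20):
            ga = rng.integers(0, 3, 80)
            gb = rng.integers(0, 3, 80)
            trace: list = []
            em_haplotype_freqs(ga, gb, ll_trace=trace)
            diffs = np.diff(trace)
            assert (diffs >= -1e-10).all()

    def test_marginals_match_observed_allele_frequencies(self, rng):
        for _ in range(20):
            ga = rng.integers(0, 3, 50)
            gb = rng.integers(0, 3, 50)
            pair = em_haplotype_freqs(ga, gb)
            f = np.array(pair.hap_freqs)
            assert f.sum() == pytest.approx(1.0, abs=1e-9)
            assert f[2] + f[3] == pytest.approx(ga.mean() / 2, abs=1e-6)
            assert f[1] + f[3] == pytest.approx(gb.mean() / 2, abs=1e-6)

    def test_independent_variants_have_negligible_r2(self, rng):
        ga = rng.binomial(2, 0.3, 5000)
        gb = rng.binomial(2, 0.4, 5000)
        assert em_haplotype_freqs(ga, gb).r2 < 0.01

    def test_monomorphic_member_warns_and_returns_zero(self):
        poly = np.array([0, 1, 2, 1])
        mono = np.zeros(4, dtype=np.int8)
        with pytest.warns(UserWarning, match="monomorphic"):
            assert em_haplotype_freqs(poly, mono).r2 == 0.0


def genotype_phase_known_r2(geno: np.ndarray) -> float:
    """Phase-known r2 for samples with at most one heterozygous locus."""
    hapcounts = np.zeros(4)
    for ga, gb in geno:
        if ga == 1 and gb == 1:
            raise AssertionError("ambiguous sample in phase-known oracle")
        from cypgx.genetics import _phase_pairs

        for ha, hb in _phase_pairs(int(ga), int(gb)):
            hapcounts[2 * ha + hb] += 1
    f = hapcounts / hapcounts.sum()
    pa, pb = f[2] + f[3], f[1] + f[3]
    d = f[3] - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def _pair_ll(hf: np.ndarray, counts9: np.ndarray) -> float:
    # genotype-pair likelihood under random haplotype pairing; counts9 is
    # the 3x3 genotype-cell count table flattened as 3*ga + gb
    cell = np.zeros(9)
    for h1 in range(4):
        for h2 in range(4):
            a = (h1 >> 1) + (h2 >> 1)
            b = (h1 & 1) + (h2 & 1)
            cell[3 * a + b] += hf[h1] * hf[h2]
    with np.errstate(divide="ignore"):
        logcell = np.log(cell)
    mask = counts9 > 0
    return float((counts9[mask] * logcell[mask]).sum())


class TestPruning:
    def _ld(self, r2_by_pair):
        return {
            tuple(sorted(k)): gen.LDPair(k[0], k[1], (0.25,) * 4, v, v, 10)
            for k, v in r2_by_pair.items()
        }

    def test_mutually_linked_trio_keeps_one(self):
        ld = self._ld({("v1", "v2"): 1.0, ("v1", "v3"): 1.0, ("v2", "v3"): 1.0})
        reps, tag_map = prune_tags(["v1", "v2", "v3"], ld)
        assert reps == ["v1"]
        assert tag_map == {"v1": ["v2", "v3"]}

    def test_unlinked_variants_all_retained(self):
        ld = self._ld({("v1", "v2"): 0.0, ("v1", "v3"): 0.0, ("v2", "v3"): 0.0})
        reps, tag_map = prune_tags(["v1", "v2", "v3"], ld)
        assert reps == ["v1", "v2", "v3"]
        assert all(not v for v in tag_map.values())

    def test_unattainable_threshold_retains_all(self):
        ld = self._ld({("v1", "v2"): 1.0})
        reps, _ = prune_tags(["v1", "v2"], ld, r2_threshold=1.01)
        assert reps == ["v1", "v2"]

    def test_priority_order_decides_the_representative(self):
        ld = self._ld({("v1", "v2"): 0.9})
        reps, tag_map = prune_tags(["v1", "v2"], ld, priority={"v2": 0.001, "v1": 0.04})
        assert reps == ["v2"]
        assert tag_map["v2"] == ["v1"]

    def test_partition_property(self):
        # every variant is a representative or absorbed by exactly one
        ld = self._ld(
            {("v1", "v2"): 0.9, ("v1", "v3"): 0.2, ("v2", "v3"): 0.95,
             ("v1", "v4"): 0.0, ("v2", "v4"): 0.0, ("v3", "v4"): 0.0}
        )
        variants = ["v1", "v2", "v3", "v4"]
        reps, tag_map = prune_tags(variants, ld)
        absorbed = [v for vs in tag_map.values() for v in vs]
        assert sorted(reps + absorbed) == sorted(variants)
        assert len(set(absorbed)) == len(absorbed)

    def test_missing_ld_entry_is_an_error(self):
        with pytest.raises(KeyError):
            prune_tags(["v1", "v2"], {})


class TestReplacement:
    def _ld(self, r2s):
        return {
            tuple(sorted(("failed", c))): gen.LDPair("failed", c, (0.25,) * 4, r, r, 10)
            for c, r in r2s.items()
        }

    def test_perfect_proxy_found(self):
        assert find_replacement_tag("failed", ["cand"], self._ld({"cand": 1.0})) == "cand"

    def test_insufficient_ld_returns_none(self):
        ld = self._ld({"cand": 0.7})
        assert find_replacement_tag("failed", ["cand"], ld, min_r2=0.8) is None

    def test_tie_breaks_to_smaller_id(self):
        ld = self._ld({"candB": 1.0, "candA": 1.0})
        assert find_replacement_tag("failed", ["candB", "candA"], ld) == "candA"


class TestGenotypeMatrix:
    def test_orient_minor_flips_major_coded_columns(self):
        values = np.array([[2, 0], [2, 1], [1, 0], [2, 0]], dtype=np.int8)
        m = GenotypeMatrix(["a", "b", "c", "d"], ["v1", "v2"], values)
        oriented = m.orient_minor()
        assert oriented.flipped == {"v1": True, "v2": False}
        assert np.array_equal(oriented.column("v1"), [0, 0, 1, 0])
        assert np.array_equal(oriented.column("v2"), [0, 1, 0, 0])

    def test_invalid_code_rejected_with_location(self):
        with pytest.raises(ValueError, match="v2"):
            GenotypeMatrix(["s1"], ["v1", "v2"], np.array([[0, 3]], dtype=np.int8))
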