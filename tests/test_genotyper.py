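"""Dosage genotyping: model enumeration, likelihood, BIC selection, recovery."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import radosage as rd
from radosage.genotyper import (
    DosageModel,
    _preference_key,
    call_genotype,
    enumerate_dosage_models,
    genotype_sample,
    model_loglik,
    prepare_counts,
)
from radosage.types import AlleleCounts


def _rec(counts, phreds=None, alleles=None, locus="c:1"):
    alleles = alleles or tuple("ACGT"[: len(counts)])
    phreds = phreds or tuple(40.0 for _ in counts)
    return AlleleCounts("s", locus, tuple(alleles), tuple(counts), tuple(phreds))


def _model(n, *m):
    return DosageModel(n=n, m=tuple(m) + (0,) * (n - len(m)))


class TestEnumeration:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (2, ["2:0", "1:1"]),
            (3, ["3:0:0", "2:1:0", "1:1:1"]),
            (4, ["4:0:0:0", "3:1:0:0", "2:2:0:0", "2:1:1:0", "1:1:1:1"]),
        ],
    )
    def test_partitions_match_model_tables(self, n, expected):
        assert [str(m) for m in enumerate_dosage_models(n)] == expected

    def test_invalid_ploidy(self):
        with pytest.raises(ValueError):
            enumerate_dosage_models(0)


class TestPrepareCounts:
    def test_sort_carries_qualities_along(self):
        x, q, alleles = prepare_counts(_rec([5, 10], phreds=(28.0, 30.0)), 2)
        assert x == (10, 5) and q == (30.0, 28.0) and alleles == ("C", "A")

    def test_truncation_to_ploidy_on_right(self):
        x, q, alleles = prepare_counts(_rec([50, 30, 2]), 2)
        assert x == (50, 30) and alleles == ("A", "C")

    def test_count_ties_broken_by_allele_label(self):
        x, q, alleles = prepare_counts(_rec([10, 10], alleles=("T", "A")), 2)
        assert alleles == ("A", "T")


class TestModelLoglik:
    def test_perfect_homozygote_has_loglik_zero(self):
        assert model_loglik([20], [40.0], _model(2, 2)) == pytest.approx(0.0)

    def test_balanced_heterozygote_exact_value(self):
        # C(20,10)/2^20 computed in exact rational arithmetic
        expected = math.log(184756) - 20 * math.log(2)
        assert model_loglik([10, 10], [30.0, 30.0], _model(2, 1, 1)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_error_term_from_phred(self):
        # two unexpected reads at phred 20 -> (10^-2)^2
        got = model_loglik([18, 2], [30.0, 20.0], _model(2, 2))
        assert got == pytest.approx(2 * math.log(0.01), abs=1e-12)

    def test_expected_allele_with_zero_count_is_legal(self):
        got = model_loglik([20], [40.0], _model(2, 1, 1))
        assert got == pytest.approx(-20 * math.log(2), abs=1e-12)


class TestCallGenotype:
    def test_skewed_tetraploid_prefers_three_one(self):
        call = call_genotype(_rec([15, 5]), 4)
        assert str(call.model) == "3:1:0:0"
        assert call.allele_dosages == {"A": 3, "C": 1}
        assert call.delta_bic_runnerup > 0

    def test_single_allele_gives_full_homozygote(self):
        call = call_genotype(_rec([30]), 4)
        assert str(call.model) == "4:0:0:0" and call.allele_dosages == {"A": 4}

    @pytest.mark.parametrize(
        "total,status",
        [
            (19, "missing_low_cov"),
            (20, "called"),
            (200, "called"),
            (201, "missing_high_cov"),
        ],
    )
    def test_tetraploid_coverage_window_inclusive(self, total, status):
        call = call_genotype(_rec([total - total // 2, total // 2]), 4)
        assert call.status == status

    def test_diploid_low_coverage_threshold_is_ten(self):
        assert call_genotype(_rec([5, 4]), 2).status == "missing_low_cov"
        assert call_genotype(_rec([5, 5]), 2).status == "called"

    def test_called_dosage_sums_to_ploidy(self):
        for n in (2, 3, 4):
            call = call_genotype(_rec([40, 21]), n)
            assert sum(call.allele_dosages.values()) == n

    def test_likelihoods_never_exceed_one(self):
        x, q, _ = prepare_counts(_rec([17, 8, 3]), 4)
        for model in enumerate_dosage_models(4):
            assert model_loglik(x, q, model) <= 1e-12


# ---------------------------------------------------------------------------
# Exact-arithmetic brute-force oracle
# ---------------------------------------------------------------------------


def exact_oracle_model(counts, phreds, n):
    """Enumerate partitions; evaluate L1*L2 and compare BIC in exact rationals.

    Requires phred scores that are multiples of 10 so p = 10^(-q/10) is an
    exact Fraction. BIC comparison k1*lnN - 2lnL1 < k2*lnN - 2lnL2 is done
    exactly as N^k1 * L2^2 < N^k2 * L1^2 in big-integer arithmetic.
    """
    pairs = sorted(zip(counts, phreds), key=lambda t: -t[0])[:n]
    x = [int(c) for c, _ in pairs]
    q = [int(p) for _, p in pairs]
    N = sum(x)
    best = None
    for model in enumerate_dosage_models(n):
        xs = x + [0] * (n - len(x))
        qs = q + [0] * (n - len(q))
        L = Fraction(math.factorial(sum(xs[i] for i in range(n) if model.m[i] > 0)))
        for i in range(n):
            if model.m[i] > 0:
                L /= math.factorial(xs[i])
                L *= Fraction(model.m[i], n) ** xs[i]
            else:
                assert qs[i] % 10 == 0
                L *= Fraction(1, 10 ** (qs[i] // 10)) ** xs[i]
        k = model.n_alleles
        if best is None:
            best = (k, L, model)
            continue
        bk, bL, bm = best
        cand_side = Fraction(N) ** k * bL * bL
        best_side = Fraction(N) ** bk * L * L
        if cand_side < best_side or (
            cand_side == best_side and _preference_key(model) < _preference_key(bm)
        ):
            best = (k, L, model)
    return best[2]


def run_oracle_suite(seed, n_records, max_cov=60):
    """Randomized oracle-agreement suite; returns the fraction agreeing."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_records):
        n = int(rng.integers(2, 5))
        n_alleles = int(rng.integers(1, 5))
        counts = rng.integers(0, max_cov + 1, size=n_alleles)
        if counts.sum() == 0:
            counts[0] = 1
        phreds = rng.choice([10, 20, 30, 40], size=n_alleles).astype(float)
        rec = _rec(tuple(int(c) for c in counts), phreds=tuple(phreds))
        call = call_genotype(rec, n, cov_min=1, cov_max=10**9)
        if str(call.model) == str(exact_oracle_model(list(counts), list(phreds), n)):
            agree += 1
    return agree / n_records


class TestOracleEquivalence:
    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        n=st.integers(2, 4),
        counts=st.lists(st.integers(0, 60), min_size=1, max_size=4),
        data=st.data(),
    )
    def test_bic_selection_matches_exact_arithmetic(self, n, counts, data):
        if sum(counts) == 0:
            counts[0] = 1
        phreds = [
            data.draw(st.sampled_from([10.0, 20.0, 30.0, 40.0])) for _ in counts
        ]
        rec = _rec(tuple(counts), phreds=tuple(phreds))
        call = call_genotype(rec, n, cov_min=1, cov_max=10**9)
        assert str(call.model) == str(exact_oracle_model(counts, phreds, n))


class TestGenotypeSample:
    def test_simulated_diploid_loci_called_correctly(self):
        cfg = rd.SimConfig(
            n_samples={2: 1}, n_loci=150, seed=17,
            coverage_law=("constant", {"value": 60}), error_rate=0.001,
        )
        sim = rd.simulate_cohort(cfg)
        (sample,) = sim.counts
        calls = genotype_sample(sim.counts[sample], 2)
        truth = sim.truth.genotypes[sample]
        correct = sum(
            1 for c in calls if c.is_called and c.allele_dosages == truth[c.locus_id]
        )
        assert correct >= 0.99 * len(calls)

    def test_empty_stream(self):
        assert genotype_sample([], 2) == []

    def test_pure_function_determinism(self):
        recs = [_rec([30, 12], locus=f"c:{i}") for i in range(5)]
        a = genotype_sample(recs, 4)
        b = genotype_sample(recs, 4)
        assert [(str(c.model), c.bic) for c in a] == [(str(c.model), c.bic) for c in b]

    def test_accuracy_improves_with_coverage(self):
        # P(true 3:1 model recovered) should rise with read depth
        rng = np.random.default_rng(3)
        acc = {}
        for cov in (20, 80):
            hits = 0
            for _ in range(800):
                x1 = rng.binomial(cov, 0.75)
                call = call_genotype(_rec([x1, cov - x1], phreds=(40.0, 40.0)), 4)
                hits += str(call.model) == "3:1:0:0"
            acc[cov] = hits / 800
        assert acc[80] > acc[20]
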