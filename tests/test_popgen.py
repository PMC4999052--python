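"""Population summaries: frequencies, imputation, F_ST, PCA, cline fit."""

import math

import numpy as np
import pandas as pd
import pytest

import radosage as rd
from radosage.popgen import FreqMatrix, cline_fit, fst, fst_outliers, impute_missing, pca_scores
from radosage.types import GenotypeMatrix


def _fm(values, ploidy=2, samples=None, loci=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    loci = loci or [f"l{j}" for j in range(values.shape[1])]
    return FreqMatrix(
        frame=pd.DataFrame(values, index=samples, columns=loci),
        counted_allele=pd.Series({l: "T" for l in loci}, dtype=object),
        ploidy=pd.Series({s: ploidy for s in samples}),
    )


class TestFreqMatrix:
    def test_dosage_normalized_by_ploidy(self, toy_matrix):
        fm = rd.freq_matrix(toy_matrix)
        # counted allele at ctg1:100 is T (sorted second of {A, T})
        assert fm.frame.loc["t1", "ctg1:100"] == 0.25  # A:3,T:1 tetraploid
        assert fm.frame.loc["d1", "ctg1:100"] == 0.5  # A:1,T:1 diploid
        assert fm.frame.loc["d2", "ctg1:100"] == 0.0  # A:2 homozygote

    def test_non_biallelic_loci_excluded_and_counted(self, toy_matrix):
        fm = rd.freq_matrix(toy_matrix)
        # ctg1:200 monomorphic (C only) -> excluded
        assert list(fm.frame.columns) == ["ctg1:100", "ctg1:300"]
        assert fm.n_excluded_loci == 1

    def test_values_are_exact_ploidy_rationals(self):
        cfg = rd.SimConfig(n_samples={2: 5, 4: 5}, n_loci=60, seed=3)
        sim = rd.simulate_cohort(cfg)
        fm = rd.freq_matrix(sim.truth.matrix())
        for s in fm.frame.index:
            k = fm.ploidy[s]
            vals = fm.frame.loc[s].dropna() * k
            assert np.allclose(vals, np.round(vals))

    def test_planted_biallelic_fraction(self):
        cfg = rd.SimConfig(
            n_samples={4: 30}, n_loci=100, seed=11, error_rate=0.0,
            extra_allelic={3: 10},
        )
        sim = rd.simulate_cohort(cfg)
        fm = rd.freq_matrix(sim.truth.matrix())
        # the 10 planted triallelic loci must be excluded
        planted = {ld.locus_id for ld in sim.truth.locus_defs if len(ld.alleles) == 3}
        assert planted.isdisjoint(fm.frame.columns)


class TestImputation:
    def test_mean_method_uses_locus_mean(self):
        fm = _fm([[0.0, 0.5], [1.0, np.nan]])
        out = impute_missing(fm, method="mean")
        assert out.frame.loc["s1", "l1"] == 0.5

    def test_complete_matrix_unchanged(self):
        fm = _fm(np.random.default_rng(0).random((5, 4)))
        for method in ("mean", "iterative-lowrank"):
            out = impute_missing(fm, method=method)
            assert np.allclose(out.frame, fm.frame)

    def test_all_missing_locus_is_error(self):
        fm = _fm([[np.nan, 0.5], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="l0"):
            impute_missing(fm)

    def test_lowrank_beats_random_imputation_under_masking(self):
        rng = np.random.default_rng(42)
        # rank-2 structure: two clusters of samples
        base = np.vstack([np.tile([0.1, 0.9], (15, 25)), np.tile([0.8, 0.2], (15, 25))])
        noisy = np.clip(base + rng.normal(0, 0.05, base.shape), 0, 1)
        mask = rng.random(base.shape) < 0.05
        masked = noisy.copy()
        masked[mask] = np.nan
        out = impute_missing(_fm(masked), method="iterative-lowrank")
        rmse = np.sqrt(np.mean((out.frame.values[mask] - noisy[mask]) ** 2))
        rmse_random = np.sqrt(np.mean((rng.random(mask.sum()) - noisy[mask]) ** 2))
        assert rmse < rmse_random


class TestFst:
    GROUPS = {"s0": "x", "s1": "x", "s2": "y", "s3": "y"}

    def test_fixed_differences_give_one(self):
        fm = _fm([[0, 0], [0, 0], [1, 1], [1, 1]])
        assert fst(fm, self.GROUPS) == pytest.approx(1.0)

    def test_identical_profiles_give_zero(self):
        fm = _fm([[0.5, 0.25], [0.0, 0.75], [0.5, 0.25], [0.0, 0.75]])
        assert fst(fm, self.GROUPS) == pytest.approx(0.0, abs=1e-12)

    def test_balding_nichols_divergence_recovered(self):
        cfg = rd.SimConfig(
            n_samples={2: 100}, n_loci=1500, seed=77,
            group_divergence=0.1, n_groups=2,
        )
        sim = rd.simulate_cohort(cfg)
        fm = rd.freq_matrix(sim.truth.matrix())
        est = fst(fm, sim.truth.groups)
        assert est == pytest.approx(0.1, abs=0.02)
        # the sample-size-corrected Weir-Cockerham variant agrees
        est_wc = fst(fm, sim.truth.groups, estimator="weir-cockerham")
        assert est_wc == pytest.approx(0.1, abs=0.02)

    def test_per_locus_and_pairwise_modes(self):
        fm = _fm([[0, 0.5], [0, 0.5], [1, 0.5], [1, 0.5]])
        per_locus = fst(fm, self.GROUPS, mode="per_locus")
        assert per_locus["l0"] == pytest.approx(1.0)
        assert per_locus["l1"] == pytest.approx(0.0, abs=1e-12)
        pair = fst(fm, self.GROUPS, mode="pairwise")
        assert pair.loc["x", "y"] == pytest.approx(fst(fm, self.GROUPS))

    def test_outlier_flagging(self):
        vals = pd.Series(np.r_[np.full(99, 0.05), 0.9])
        assert list(fst_outliers(vals)) == [99]

    def test_group_without_data_is_error(self):
        fm = _fm([[0.5, 0.5], [np.nan, np.nan]])
        with pytest.raises(ValueError, match="y"):
            fst(fm, {"s0": "x", "s1": "y"})


class TestPca:
    def test_planted_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(1)
        a = 0.1 + rng.normal(0, 0.02, (20, 50))
        b = 0.9 + rng.normal(0, 0.02, (20, 50))
        fm = _fm(np.vstack([a, b]))
        scores, explained = pca_scores(fm, n_components=2)
        pc1 = scores["PC1"]
        ga, gb = pc1.iloc[:20], pc1.iloc[20:]
        assert abs(ga.mean() - gb.mean()) > 5 * max(ga.std(), gb.std())
        assert explained.is_monotonic_decreasing

    def test_identical_rows_give_zero_scores(self):
        fm = _fm(np.tile([0.2, 0.7, 0.4], (6, 1)))
        scores, explained = pca_scores(fm, n_components=2)
        assert np.allclose(scores, 0.0)
        assert np.allclose(explained, 0.0)

    def test_scores_invariant_to_locus_permutation(self):
        rng = np.random.default_rng(2)
        X = rng.random((12, 30))
        fm = _fm(X)
        perm = rng.permutation(30)
        fm_perm = _fm(X[:, perm])
        s1, _ = pca_scores(fm, 3)
        s2, _ = pca_scores(fm_perm, 3)
        assert np.allclose(s1.values, s2.values, atol=1e-8)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            pca_scores(_fm(np.zeros((3, 5))), n_components=4)

    def test_missing_data_rejected(self):
        with pytest.raises(ValueError, match="impute"):
            pca_scores(_fm([[0.5, np.nan]]), 1)


class TestClineFit:
    def test_slope_recovered_within_two_se(self):
        df = rd.simulate_admixture_records(seed=314)
        fit = cline_fit(df)
        assert abs(fit.slope - (-0.01)) <= 2 * fit.slope_se
        assert fit.variance_components[0] >= 0
        assert set(fit.population_effects) == set(df["population_id"])
        assert set(fit.population_means) == set(df["population_id"])

    def test_arcsine_transform_preserves_ordering(self):
        q = np.sort(np.random.default_rng(0).random(50))
        y = np.arcsin(np.sqrt(q))
        assert np.all(np.diff(y) >= 0)

    def test_noise_free_linear_data_fit_exactly(self):
        lats = np.linspace(50, 60, 12)
        rows = [
            {
                "sample_id": f"s{i}_{j}",
                "population_id": f"p{i}",
                "latitude": la,
                "Q": math.sin(0.9 - 0.01 * la) ** 2,
            }
            for i, la in enumerate(lats)
            for j in range(3)
        ]
        fit = cline_fit(pd.DataFrame(rows))
        assert fit.slope == pytest.approx(-0.01, abs=1e-8)
        assert fit.variance_components[0] < 1e-8
        assert fit.variance_components[1] < 1e-8

    def test_degenerate_designs_rejected(self):
        df = rd.simulate_admixture_records(n_populations=2, seed=1)
        with pytest.raises(ValueError, match="populations"):
            cline_fit(df)
        df2 = rd.simulate_admixture_records(seed=1, latitude_range=(55.0, 55.0))
        df2["latitude"] = 55.0
        with pytest.raises(ValueError, match="latitude"):
            cline_fit(df2)

    def test_null_slope_rarely_detected(self):
        hits = 0
        for rep in range(20):
            df = rd.simulate_admixture_records(
                slope=0.0, intercept=0.5, seed=1000 + rep
            )
            fit = cline_fit(df)
            hits += fit.p_value < 0.05
        assert hits <= 3
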