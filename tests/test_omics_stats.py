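"""Tests of LFQ imputation, differential abundance, RPKM and rank-sum checks."""

import itertools

import numpy as np
import pandas as pd
import pytest

from stromamech import (
    ImputationRule,
    LfqSimParams,
    ProteinMatrix,
    classify_regulation,
    differential_abundance,
    generate_lfq_matrix,
    housekeeping_stability,
    impute_missing,
    rpkm,
)


def _matrix(values, groups=None):
    df = pd.DataFrame(values)
    if groups is None:
        half = df.shape[1] // 2
        groups = ["a"] * half + ["b"] * (df.shape[1] - half)
    return ProteinMatrix(intensities=df,
                         groups=pd.Series(groups, index=df.columns))


class TestImputation:
    def test_no_missing_values_is_identity(self):
        m = _matrix({"s1": [1.0, 2.0], "s2": [3.0, 4.0],
                     "s3": [5.0, 6.0], "s4": [7.0, 8.0]})
        out, report = impute_missing(m)
        pd.testing.assert_frame_equal(out.intensities, m.intensities)
        assert report.n_imputed == 0

    def test_observed_values_preserved_bit_exactly(self):
        df = pd.DataFrame({"s1": [200.0, np.nan], "s2": [np.nan, 50.0],
                           "s3": [400.0, 75.0], "s4": [300.0, np.nan]},
                          index=["p1", "p2"])
        m = ProteinMatrix(intensities=df,
                          groups=pd.Series(["a", "a", "b", "b"],
                                           index=df.columns))
        out, report = impute_missing(m, ImputationRule(seed=0))
        assert not out.intensities.isna().any().any()
        observed = ~df.isna()
        assert np.array_equal(out.intensities.to_numpy()[observed],
                              df.to_numpy()[observed])
        assert report.n_imputed == 3

    def test_draws_follow_min_over_100_rule(self):
        """Protein with non-zero minimum 200 gets Normal(2, 0.02) draws:
        sample moments of 1e5 draws match within 1%/2%."""
        n = 100_000
        cols = {f"m{i}": np.nan for i in range(n)}
        cols["obs1"], cols["obs2"] = 200.0, 350.0
        df = pd.DataFrame([cols], index=["prot"])
        groups = pd.Series(["a"] * (n // 2 + 1) + ["b"] * (n - n // 2 + 1),
                           index=df.columns)
        m = ProteinMatrix(intensities=df, groups=groups)
        out, _ = impute_missing(m, ImputationRule(seed=1))
        draws = out.intensities.loc["prot"].drop(["obs1", "obs2"]).to_numpy()
        assert draws.mean() == pytest.approx(2.0, rel=0.01)
        assert draws.std(ddof=1) == pytest.approx(0.02, rel=0.02)

    def test_all_missing_protein_dropped_with_report(self):
        df = pd.DataFrame({"s1": [np.nan, 5.0], "s2": [np.nan, 6.0],
                           "s3": [np.nan, 7.0], "s4": [np.nan, 8.0]},
                          index=["gone", "kept"])
        m = ProteinMatrix(intensities=df,
                          groups=pd.Series(["a", "a", "b", "b"],
                                           index=df.columns))
        out, report = impute_missing(m)
        assert report.dropped_proteins == ["gone"]
        assert list(out.intensities.index) == ["kept"]

    def test_imputation_deterministic_per_seed(self):
        df = pd.DataFrame({"s1": [100.0], "s2": [np.nan],
                           "s3": [np.nan], "s4": [150.0]}, index=["p"])
        m = ProteinMatrix(intensities=df,
                          groups=pd.Series(["a", "a", "b", "b"],
                                           index=df.columns))
        o1, _ = impute_missing(m, ImputationRule(seed=7))
        o2, _ = impute_missing(m, ImputationRule(seed=7))
        pd.testing.assert_frame_equal(o1.intensities, o2.intensities)


class TestDifferentialAbundance:
    def test_identical_groups_make_no_calls(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(10, 100, 50)
        jitter = rng.normal(0, 0.01, (50, 6))
        df = pd.DataFrame(base[:, None] + jitter,
                          columns=[f"s{i}" for i in range(6)])
        m = ProteinMatrix(intensities=df,
                          groups=pd.Series(["a"] * 3 + ["b"] * 3,
                                           index=df.columns))
        res = differential_abundance(m)
        assert (res.table.call == "unchanged").all()
        assert np.allclose(res.table.fold_change, 1.0, atol=0.01)

    def test_doubled_group_called_up(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "a1": 10 + rng.normal(0, 0.01, 5), "a2": 10 + rng.normal(0, 0.01, 5),
            "a3": 10 + rng.normal(0, 0.01, 5), "b1": 20 + rng.normal(0, 0.01, 5),
            "b2": 20 + rng.normal(0, 0.01, 5), "b3": 20 + rng.normal(0, 0.01, 5)})
        m = ProteinMatrix(intensities=df,
                          groups=pd.Series(["a"] * 3 + ["b"] * 3,
                                           index=df.columns))
        res = differential_abundance(m)
        assert (res.table.call == "up").all()
        assert np.allclose(res.table.fold_change, 2.0, rtol=0.01)

    def test_missing_values_rejected(self):
        m = _matrix({"s1": [1.0, np.nan], "s2": [2.0, 2.0],
                     "s3": [3.0, 3.0], "s4": [4.0, 4.0]})
        with pytest.raises(ValueError, match="impute"):
            differential_abundance(m)

    def test_zero_variance_equal_means_flagged_with_p_one(self):
        df = pd.DataFrame([[5.0] * 6], columns=[f"s{i}" for i in range(6)])
        m = ProteinMatrix(intensities=df,
                          groups=pd.Series(["a"] * 3 + ["b"] * 3,
                                           index=df.columns))
        res = differential_abundance(m)
        assert res.table.p.iloc[0] == 1.0
        assert res.table.flag.iloc[0] == "zero-variance"

    def test_bh_q_monotone_in_p_and_at_least_p(self):
        m, _ = generate_lfq_matrix(LfqSimParams(n_proteins=500, seed=3))
        res = differential_abundance(m)
        tab = res.table.sort_values("p")
        assert (tab.q.to_numpy() >= tab.p.to_numpy() - 1e-12).all()
        assert (np.diff(tab.q.to_numpy()) >= -1e-12).all()

    def test_null_type_one_error_calibrated(self):
        """Raw p < 0.05 on null simulations occurs at ~5% frequency."""
        fracs = []
        for rep in range(20):
            m, _ = generate_lfq_matrix(LfqSimParams(n_proteins=1000, seed=rep))
            res = differential_abundance(m)
            fracs.append((res.table.p < 0.05).mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.015)

    def test_welch_flag_changes_unequal_variance_result(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            np.column_stack([rng.normal(100, 1, (200, 4)),
                             rng.normal(100, 30, (200, 4))]),
            columns=[f"s{i}" for i in range(8)]).clip(lower=0.0)
        m = ProteinMatrix(intensities=df,
                          groups=pd.Series(["a"] * 4 + ["b"] * 4,
                                           index=df.columns))
        p_student = differential_abundance(m).table.p
        p_welch = differential_abundance(m, welch=True).table.p
        assert not np.allclose(p_student, p_welch)


class TestRegulationCalls:
    def test_counts_partition_all_proteins(self):
        m, _ = generate_lfq_matrix(
            LfqSimParams(n_proteins=400, effect_fraction=0.2,
                         effect_log2fc=1.5, seed=11))
        res = differential_abundance(m)
        counts = classify_regulation(res)
        assert sum(counts.values()) == 400

    def test_no_significant_proteins_all_unchanged(self):
        m, _ = generate_lfq_matrix(LfqSimParams(n_proteins=100, seed=21))
        res = differential_abundance(m, p_threshold=1e-12)
        counts = classify_regulation(res)
        assert counts["n_up"] == 0 and counts["n_down"] == 0
        assert counts["n_unchanged"] == 100

    def test_spiked_effects_detected_at_oracle_power(self):
        """Detected up-calls among 50 true 2-fold effects fall within
        binomial bounds of the power measured by repeated simulation."""
        def run(seed):
            m, labels = generate_lfq_matrix(
                LfqSimParams(n_proteins=500, effect_fraction=0.1,
                             effect_log2fc=1.0, seed=seed))
            res = differential_abundance(m)
            up_true = (labels == 1)
            hits = (res.table.call == "up") & up_true
            return int(hits.sum()), int(up_true.sum())
        # power oracle: average detection rate over independent replicates
        rates = []
        for seed in range(60, 72):
            h, n = run(seed)
            if n:
                rates.append(h / n)
        power = np.mean(rates)
        h, n = run(99)
        sd = np.sqrt(power * (1 - power) * n)
        assert abs(h - power * n) <= 4 * sd + 1


class TestLfqSimulator:
    def test_zero_effect_fraction_all_null(self):
        _, labels = generate_lfq_matrix(LfqSimParams(n_proteins=200, seed=0))
        assert (labels == 0).all()

    def test_flat_dropout_rate_matches_target(self):
        """Slope 0 with intercept logit(0.2) gives ~20% missing cells."""
        intercept = float(np.log(0.2 / 0.8))
        m, _ = generate_lfq_matrix(
            LfqSimParams(n_proteins=2000, dropout_intercept=intercept,
                         dropout_slope=0.0, seed=1))
        frac = m.intensities.isna().to_numpy().mean()
        assert frac == pytest.approx(0.2, abs=0.02)

    def test_negative_slope_dropout_is_abundance_dependent(self):
        m, _ = generate_lfq_matrix(
            LfqSimParams(n_proteins=2000, dropout_intercept=22.0,
                         dropout_slope=-1.0, seed=2))
        log2 = np.log2(m.intensities.to_numpy())
        observed_mean = np.nanmean(log2)
        overall_mean = 23.0
        assert observed_mean > overall_mean  # low-abundance cells vanish

    def test_same_seed_identical_matrix(self):
        m1, _ = generate_lfq_matrix(LfqSimParams(n_proteins=50, seed=5))
        m2, _ = generate_lfq_matrix(LfqSimParams(n_proteins=50, seed=5))
        pd.testing.assert_frame_equal(m1.intensities, m2.intensities)


class TestRpkm:
    def test_textbook_value(self):
        """100 reads on a 1 kb gene in a 10M library give RPKM = 10."""
        counts = pd.DataFrame({"s1": [100]}, index=["g1"])
        out = rpkm(counts, pd.Series({"g1": 1000}),
                   pd.Series({"s1": 10_000_000}))
        assert out.loc["g1", "s1"] == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        counts = pd.DataFrame({"s1": [0, 5]}, index=["g1", "g2"])
        out = rpkm(counts, pd.Series({"g1": 500, "g2": 500}),
                   pd.Series({"s1": 1_000_000}))
        assert out.loc["g1", "s1"] == 0.0

    def test_linear_in_counts_inverse_in_library(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 1000, (20, 3)).astype(float),
                              index=[f"g{i}" for i in range(20)],
                              columns=["s1", "s2", "s3"])
        lengths = pd.Series(rng.integers(200, 5000, 20),
                            index=counts.index)
        libs = pd.Series([1e6, 2e6, 4e6], index=counts.columns)
        base = rpkm(counts, lengths, libs)
        assert np.allclose(rpkm(counts * 3, lengths, libs), base * 3)
        assert np.allclose(rpkm(counts, lengths, libs * 2), base / 2)

    def test_zero_library_size_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g1"])
        with pytest.raises(ValueError):
            rpkm(counts, pd.Series({"g1": 100}), pd.Series({"s1": 0}))


def exact_ranksum_two_sided_p(x, y):
    """Enumeration oracle: all C(n1+n2, n1) rank assignments of pooled data."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(x)
    observed = ranks[:n1].sum()
    sums = [sum(ranks[list(idx)])
            for idx in itertools.combinations(range(len(pooled)), n1)]
    sums = np.array(sums)
    mean = sums.mean()
    extreme = np.abs(sums - mean) >= abs(observed - mean) - 1e-9
    return extreme.mean()


class TestHousekeepingStability:
    def test_identical_groups_p_one(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], index=["TUBB"],
                          columns=list("abcdef"))
        groups = pd.Series(["c"] * 3 + ["t"] * 3, index=df.columns)
        res = housekeeping_stability(df, ["TUBB"], groups)
        assert res.per_gene_p["TUBB"] == 1.0

    def test_fully_separated_3v3_gives_exact_tenth(self):
        """Complete separation at n=3 vs 3: two-sided exact p = 2/20 = 0.1,
        matching exhaustive enumeration of the 20 rank assignments."""
        x, y = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        df = pd.DataFrame([x + y], index=["TUBA1A"], columns=list("abcdef"))
        groups = pd.Series(["c"] * 3 + ["t"] * 3, index=df.columns)
        res = housekeeping_stability(df, ["TUBA1A"], groups)
        assert res.min_p == pytest.approx(0.1)
        assert res.min_p == pytest.approx(
            exact_ranksum_two_sided_p(np.array(x), np.array(y)))

    def test_exact_p_matches_enumeration_on_random_data(self, rng):
        x = rng.normal(0, 1, 4)
        y = rng.normal(1, 1, 4)
        df = pd.DataFrame([np.concatenate([x, y])], index=["g"],
                          columns=[f"s{i}" for i in range(8)])
        groups = pd.Series(["c"] * 4 + ["t"] * 4, index=df.columns)
        res = housekeeping_stability(df, ["g"], groups)
        assert res.per_gene_p["g"] == pytest.approx(
            exact_ranksum_two_sided_p(x, y))

    def test_absent_genes_reported_skipped(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["TUBB"],
                          columns=list("abcd"))
        groups = pd.Series(["c", "c", "t", "t"], index=df.columns)
        res = housekeeping_stability(df, ["TUBB", "NOPE"], groups)
        assert res.skipped_genes == ["NOPE"]

    def test_empty_gene_set_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError):
            housekeeping_stability(
                df, [], pd.Series(["c", "t"], index=["a", "b"]))
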