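"""Generator contracts: profiles, counts, covariate studies, induction, qPCR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import polyprof as pp
from polyprof.containers import FRACTIONS, TRANSLATED_FRACTIONS
from polyprof.synthetic import (DEFAULT_BETA_TRUE, standardized_effect_columns)


class TestFractionProfile:
    def test_zero_occupancy_puts_all_mass_in_a(self):
        for peak in TRANSLATED_FRACTIONS:
            assert np.allclose(pp.simulate_fraction_profile(0, peak),
                               [100, 0, 0, 0, 0, 0, 0])

    def test_degenerate_kernel_concentrates_on_peak(self):
        prof = pp.simulate_fraction_profile(100, "B", spread=0)
        assert np.allclose(prof, [0, 100, 0, 0, 0, 0, 0])

    def test_plain_binomial_kernel_matches_direct_evaluation(self):
        # peak E is bin 3 of 6; spread 1 is the untempered Binomial(5, 3/5)
        prof = pp.simulate_fraction_profile(80, "E", spread=1)
        expected = 80 * stats.binom.pmf(np.arange(6), 5, 3 / 5)
        assert np.allclose(prof, [20, *expected])
        assert prof.sum() == pytest.approx(100)

    @pytest.mark.parametrize("bad", [dict(ro_true=50, peak="A"),
                                     dict(ro_true=50, peak="E", spread=-1),
                                     dict(ro_true=101, peak="E")])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            pp.simulate_fraction_profile(**bad)

    @given(ro=st.floats(0, 100), peak=st.sampled_from(list(TRANSLATED_FRACTIONS)),
           spread=st.floats(0, 5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_profiles_sum_to_100_and_peak_is_argmax(self, ro, peak, spread):
        prof = pp.simulate_fraction_profile(ro, peak, spread)
        assert prof.sum() == pytest.approx(100, abs=1e-9)
        assert (prof >= 0).all()
        if ro > 0 and spread < 1:
            translated = prof[1:]
            assert TRANSLATED_FRACTIONS[int(np.argmax(translated))] == peak


class TestSimulateCounts:
    def test_same_seed_reproduces_counts_bit_for_bit(self):
        a, _ = pp.simulate_counts(n_genes=30, seed=42)
        b, _ = pp.simulate_counts(n_genes=30, seed=42)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_series_equal(a.ribodepleted_ng, b.ribodepleted_ng)

    def test_noiseless_limit_reproduces_true_proportions(self):
        # no replicate noise, unit distortions, expected counts: raw per-gene
        # shares already match the truth
        fcm, truth = pp.simulate_counts(n_genes=15, depth=1e5, noise_conc=None,
                                        seed=1, sampling="expected")
        per_rep = fcm.counts.T.groupby(level=1).sum().T
        rep1 = fcm.counts.xs(1, axis=1, level=1)
        shares = rep1.div(rep1.sum(axis=1), axis=0) * 100
        assert np.allclose(shares, truth.profiles, atol=1e-9)

    def test_mean_proportion_error_bounded_by_high_depth_oracle(self):
        # Monte-Carlo oracle at 100x depth bounds the sampling error floor
        def mean_abs_err(depth, seed):
            fcm, truth = pp.simulate_counts(n_genes=100, depth=depth,
                                            noise_conc=None, seed=seed)
            est = pp.compute_proportions(pp.normalize_counts(fcm)).mean_proportions
            return (est - truth.profiles).abs().to_numpy().mean()

        err = mean_abs_err(5e4, 7)
        oracle_floor = mean_abs_err(5e6, 8)
        assert oracle_floor < err < 1.0
        assert err < 100 * oracle_floor  # scales roughly with 1/sqrt(depth)

    def test_nonpositive_distortion_rejected(self):
        with pytest.raises(ValueError, match="distortion"):
            pp.simulate_counts(n_genes=10, seed=0, lib_distortion=np.zeros(21))

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            pp.simulate_counts(n_genes=10)


class TestCovariateStudy:
    def test_noiseless_single_effect_recovered_exactly(self):
        cov, truth = pp.simulate_covariate_study(
            n_genes=200, beta_true={"mrna_conc": 0.4}, sigma=0.0, seed=3)
        X = standardized_effect_columns(cov)[["mrna_conc"]]
        fit = pp.fit_ols(X, truth.table["ro_true"])
        assert fit.params["mrna_conc"] == pytest.approx(0.4, abs=1e-8)
        assert fit.rsquared == pytest.approx(1.0, abs=1e-8)

    def test_null_betas_leave_only_residual_variance(self):
        sigma = 0.7
        variances = []
        for seed in range(10):
            _, truth = pp.simulate_covariate_study(
                n_genes=400, beta_true={}, sigma=sigma, seed=seed)
            variances.append(truth.table["ro_true"].var(ddof=1))
        assert np.mean(variances) == pytest.approx(sigma**2, rel=0.15)

    def test_positive_mrna_effect_gives_positive_spearman(self):
        cov, truth = pp.simulate_covariate_study(
            n_genes=1000, beta_true={"mrna_conc": 0.5}, sigma=0.3, seed=4)
        rho, _ = stats.spearmanr(np.log(cov["mrna_conc"]), truth.table["ro_true"])
        assert rho > 0.5

    def test_unknown_predictor_rejected(self):
        with pytest.raises(ValueError, match="unknown predictors"):
            pp.simulate_covariate_study(beta_true={"codon_bias": 1.0}, seed=0)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            pp.simulate_covariate_study(n_genes=5, seed=0)

    def test_truth_invariants_hold(self):
        _, truth = pp.simulate_covariate_study(n_genes=300, seed=5)
        assert truth.table["ro_true"].between(15, 100).all()
        assert (truth.table["rd_true"] > 0).all()


class TestInductionPair:
    def test_identity_shift_gives_zero_log_ratios_in_expectation(self):
        base = (66, 10, 6, 6, 6, 3, 3)
        low, high, _ = pp.simulate_induction_pair(base, mrna_fold=10, shift=None,
                                                  seed=2, noise_conc=None)
        comp = pp.compare_conditions(low, high, genes=["induced_gene"])
        ratios = comp.table.loc["induced_gene", [f"log_ratio_{f}" for f in FRACTIONS]]
        assert np.abs(ratios).max() < 0.2

    def test_shifting_all_of_a_yields_full_occupancy(self):
        base = (40, 10, 10, 10, 10, 10, 10)
        low, high, truth = pp.simulate_induction_pair(
            base, mrna_fold=10, shift=pp.shift_from_a(1.0, ("G",)), seed=3,
            noise_conc=None)
        assert truth.loc["induced_gene", "ro_high"] == pytest.approx(100.0)
        comp = pp.compare_conditions(low, high, genes=["induced_gene"])
        assert comp.table.loc["induced_gene", "ro_high"] > 99.0

    def test_negative_shift_result_rejected(self):
        def bad_shift(profile):
            out = profile.copy()
            out[0] -= 200
            out[6] += 200
            return out

        with pytest.raises(ValueError, match="negative"):
            pp.simulate_induction_pair((66, 10, 6, 6, 6, 3, 3), mrna_fold=2,
                                       shift=bad_shift, seed=1)

    def test_mrna_fold_must_exceed_one(self):
        with pytest.raises(ValueError, match="mrna_fold"):
            pp.simulate_induction_pair((66, 10, 6, 6, 6, 3, 3), mrna_fold=1.0,
                                       seed=1)


class TestQpcr:
    def test_unit_abundance_gives_spike_ct(self):
        tab = pp.simulate_qpcr({"lacZ": 1.0}, spike_ct=21.5, noise_sd=0, seed=0)
        assert tab["ct_target"].iloc[0] == pytest.approx(21.5)

    def test_doubling_abundance_shifts_ct_one_cycle(self):
        tab = pp.simulate_qpcr({"lacZ": 2.0}, spike_ct=20.0, efficiency=2,
                               noise_sd=0, seed=0)
        assert tab["ct_target"].iloc[0] == pytest.approx(19.0)

    def test_same_seed_gives_identical_table(self):
        a = pp.simulate_qpcr({"g1": 2.0, "g2": 0.5}, noise_sd=0.4, seed=6,
                             n_primer_pairs=5)
        b = pp.simulate_qpcr({"g1": 2.0, "g2": 0.5}, noise_sd=0.4, seed=6,
                             n_primer_pairs=5)
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_abundance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pp.simulate_qpcr({"g1": 0.0}, seed=0)


class TestGeneratorInvariants:
    def test_all_simulated_profiles_sum_to_100(self, study_dataset):
        _, truth = study_dataset
        assert np.allclose(truth.profiles.sum(axis=1), 100.0, atol=1e-9)

    def test_distortion_invariance_of_recovered_proportions(self):
        # multiplying libraries' counts by arbitrary factors (metadata
        # untouched: size factors absorb the scaling) leaves the recovered
        # proportions unchanged
        fcm, truth = pp.simulate_counts(n_genes=40, depth=1e5, seed=9)
        distortion = np.random.default_rng(1).uniform(0.25, 4.0, 21)
        distorted = fcm.with_counts(fcm.counts * distortion)
        base = pp.compute_proportions(pp.normalize_counts(fcm)).proportions
        pert = pp.compute_proportions(pp.normalize_counts(distorted)).proportions
        assert np.allclose(base, pert, atol=1e-9, equal_nan=True)
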