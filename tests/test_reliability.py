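import numpy as np
import pytest
from scipy import stats

from fearsense.fixtures import (
    CORRELATION_MATRIX,
    COHORT_SUMMARIES,
    PUBLISHED_CORRELATION_SUMS,
    PUBLISHED_EFFECT_SIZES,
    PUBLISHED_WELCH_P,
)
from fearsense.reliability import (
    GroupSummary,
    build_report,
    cohens_d,
    correlation_matrix,
    correlation_sums,
    effect_size_label,
    neutral_compensation,
    pairwise_regression,
    rank_modalities,
    sign_align,
    welch_t_test,
)
from fearsense.synthetic import CohortSpec, gen_cohort


class TestWelch:
    def test_identical_groups(self):
        g = GroupSummary(10.0, 2.0, 16)
        result = welch_t_test(g, g)
        assert result.t == 0 and result.p == pytest.approx(1.0)

    def test_constant_equal_groups(self):
        result = welch_t_test(GroupSummary(5.0, 0.0, 8), GroupSummary(5.0, 0.0, 8))
        assert result.t == 0 and result.p == 1.0

    def test_subjective_score_summaries_near_published_p(self):
        result = welch_t_test(
            COHORT_SUMMARIES["subjective_evaluation"]["pre"],
            COHORT_SUMMARIES["subjective_evaluation"]["post"],
        )
        assert result.p == pytest.approx(PUBLISHED_WELCH_P["subjective_evaluation"], rel=0.2)

    def test_matches_scipy_on_raw_vectors(self, rng):
        for _ in range(100):
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 4), rng.integers(4, 40))
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 4), rng.integers(4, 40))
            ours = welch_t_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert ours.t == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_paired_matches_scipy(self, rng):
        a = rng.normal(0, 1, 16)
        b = a + rng.normal(0.5, 0.3, 16)
        ours = welch_t_test(a, b, paired=True)
        ref = stats.ttest_rel(a, b)
        assert ours.t == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_invalid_group_size_rejected(self):
        with pytest.raises(ValueError):
            GroupSummary(1.0, 1.0, 1)


class TestCohensD:
    @pytest.mark.parametrize("modality", list(PUBLISHED_EFFECT_SIZES))
    def test_reproduces_published_values_to_summary_precision(self, modality):
        """d from the printed group summaries agrees with the published d to
        the precision the rounded summaries support (|diff| < 5e-4)."""
        phases = COHORT_SUMMARIES[modality]
        d = cohens_d(phases["pre"], phases["post"])
        published, label = PUBLISHED_EFFECT_SIZES[modality]
        assert d == pytest.approx(published, abs=5e-4)
        assert effect_size_label(d) == label

    def test_equal_means_give_zero(self):
        assert cohens_d(GroupSummary(3.0, 1.0, 16), GroupSummary(3.0, 2.0, 16)) == 0

    def test_direction_agnostic(self):
        a, b = GroupSummary(3.0, 1.0, 16), GroupSummary(5.0, 1.0, 16)
        assert cohens_d(a, b) == cohens_d(b, a) == pytest.approx(2.0)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(GroupSummary(1.0, 0.0, 4), GroupSummary(2.0, 0.0, 4))


class TestEffectSizeLabel:
    @pytest.mark.parametrize(
        "d, label",
        [
            (0.1605, "Small"),
            (0.5713, "Medium"),
            (1.6868, "Large"),
            (1.8675, "Large"),
            (0.0, "Small"),
            (0.35, "Medium"),  # tie between anchors resolves to the larger
            (0.65, "Large"),
            (0.79, "Large"),
            (-0.5, "Medium"),  # negative d handled by magnitude
        ],
    )
    def test_nearest_anchor_rule(self, d, label):
        assert effect_size_label(d) == label


class TestSignAlign:
    def test_fear_decreasing_modalities_negated(self):
        deltas = {
            "facial_temperature": np.array([-78.9]),
            "blinking_rate": np.array([2.1]),
            "EEG": np.array([-0.18]),
            "subjective_evaluation": np.array([2.9]),
        }
        aligned = sign_align(deltas)
        assert aligned["facial_temperature"][0] == pytest.approx(78.9)
        assert aligned["EEG"][0] == pytest.approx(0.18)
        assert aligned["blinking_rate"][0] == pytest.approx(2.1)

    def test_involution(self, rng):
        deltas = {m: rng.normal(0, 1, 16) for m in PUBLISHED_EFFECT_SIZES}
        twice = sign_align(sign_align(deltas))
        for m in deltas:
            assert twice[m] == pytest.approx(deltas[m])


class TestRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        gradient, r2 = pairwise_regression(x, 2 * x)
        assert gradient == pytest.approx(2.0) and r2 == pytest.approx(1.0)

    def test_orthogonal_data_has_zero_r2(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # even function, no linear part
        gradient, r2 = pairwise_regression(x, y)
        assert gradient == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form(self, rng):
        x = rng.normal(0, 2, 30)
        y = rng.normal(1, 3, 30)
        gradient, r2 = pairwise_regression(x, y)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        r = np.corrcoef(x, y)[0, 1]
        assert gradient == pytest.approx(slope, abs=1e-10)
        assert r2 == pytest.approx(r**2, abs=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            pairwise_regression(np.ones(5), np.arange(5.0))


class TestCorrelation:
    def test_self_and_negated(self, rng):
        v = rng.normal(0, 1, 16)
        mat = correlation_matrix({"EEG": v, "blinking_rate": v, "facial_temperature": -v,
                                  "subjective_evaluation": rng.normal(0, 1, 16)})
        assert mat.loc["EEG", "blinking_rate"] == pytest.approx(1.0)
        assert mat.loc["EEG", "facial_temperature"] == pytest.approx(-1.0)

    def test_matrix_matches_covariance_oracle(self, rng):
        data = {m: rng.normal(0, 1, 20) for m in PUBLISHED_EFFECT_SIZES}
        mat = correlation_matrix(data)
        for a in data:
            for b in data:
                x, y = data[a], data[b]
                oracle = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
                assert mat.loc[a, b] == pytest.approx(oracle, abs=1e-12)

    def test_constant_modality_named_in_error(self, rng):
        data = {"EEG": np.ones(10), "blinking_rate": rng.normal(0, 1, 10),
                "facial_temperature": rng.normal(0, 1, 10),
                "subjective_evaluation": rng.normal(0, 1, 10)}
        with pytest.raises(ValueError, match="EEG"):
            correlation_matrix(data)


class TestCorrelationSums:
    def test_reference_matrix_row_sums(self):
        sums = correlation_sums(CORRELATION_MATRIX)
        for modality, published in PUBLISHED_CORRELATION_SUMS.items():
            assert sums[modality] == pytest.approx(published, abs=5e-5)

    def test_identity_matrix_sums_to_zero(self):
        sums = correlation_sums(np.eye(4))
        assert all(v == 0 for v in sums.values())

    def test_non_unit_diagonal_rejected(self):
        bad = np.eye(4) * 0.9
        with pytest.raises(ValueError, match="diagonal"):
            correlation_sums(bad)

    def test_asymmetric_rejected(self):
        bad = np.eye(3)
        bad[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            correlation_sums(bad)


class TestRanking:
    def test_published_orderings(self):
        d_order = rank_modalities(
            {m: d for m, (d, _) in PUBLISHED_EFFECT_SIZES.items()},
            PUBLISHED_CORRELATION_SUMS,
        )
        assert d_order.by_effect_size == (
            "subjective_evaluation", "facial_temperature", "EEG", "blinking_rate"
        )
        assert d_order.by_correlation_sum == (
            "facial_temperature", "subjective_evaluation", "EEG", "blinking_rate"
        )
        assert set(d_order.top2_consensus) == {"subjective_evaluation", "facial_temperature"}
        assert not d_order.tied

    def test_all_equal_flags_tie_and_keeps_order(self):
        values = {m: 1.0 for m in PUBLISHED_EFFECT_SIZES}
        result = rank_modalities(values, values)
        assert result.tied
        assert result.by_effect_size == tuple(values)


class TestNeutralCompensation:
    def test_zero_neutral_change_is_identity(self):
        horror = {"s1": 2.0, "s2": -1.0}
        assert neutral_compensation(horror, {"s1": 0.0, "s2": 0.0}) == horror

    def test_equal_changes_cancel(self):
        horror = {"s1": 2.0}
        assert neutral_compensation(horror, horror) == {"s1": 0.0}

    def test_nested_modality_maps(self):
        horror = {"EEG": {"s1": -0.18, "s2": -0.2}}
        neutral = {"EEG": {"s1": -0.04, "s2": 0.01}}
        out = neutral_compensation(horror, neutral)
        assert out["EEG"]["s1"] == pytest.approx(-0.14)

    def test_unmatched_subjects_rejected(self):
        with pytest.raises(ValueError):
            neutral_compensation({"s1": 1.0}, {"s2": 1.0})

    def test_commanded_condition_effects_recovered(self):
        """Compensated cohort changes recover the fear-specific effect within 3 SE."""
        spec = CohortSpec(n_subjects=200, conditions=("horror", "neutral"), seed=11)
        cohort = gen_cohort(spec)
        from fearsense.reliability import cohort_deltas

        horror = cohort_deltas(cohort, "horror")
        neutral = cohort_deltas(cohort, "neutral")
        params = spec.parameters["subjective_evaluation"]
        commanded = (
            params["horror"]["post"][0] - params["horror"]["pre"][0]
            - (params["neutral"]["post"][0] - params["neutral"]["pre"][0])
        )
        compensated = (
            np.asarray(horror["subjective_evaluation"])
            - np.asarray(neutral["subjective_evaluation"])
        )
        se = compensated.std(ddof=1) / np.sqrt(len(compensated))
        assert abs(compensated.mean() - commanded) < 3 * se


@pytest.fixture(scope="module")
def replicate_ds():
    reps = 500
    ds = {m: np.empty(reps) for m in COHORT_SUMMARIES}
    for r in range(reps):
        cohort = gen_cohort(CohortSpec(seed=10_000 + r))
        for modality, grp in cohort.groupby("modality", sort=False):
            pre = grp.loc[grp["phase"] == "pre", "value"].to_numpy()
            post = grp.loc[grp["phase"] == "post", "value"].to_numpy()
            ds[modality][r] = cohens_d(pre, post)
    return ds


class TestCohortSimulation:
    """Monte-Carlo behaviour of the effect-size estimator on cohorts drawn
    from the published group parameters."""

    def test_published_d_within_sampling_spread(self, replicate_ds):
        """Each published d lies inside the simulated sampling distribution."""
        for modality, (published, _) in PUBLISHED_EFFECT_SIZES.items():
            d_hat = replicate_ds[modality]
            assert d_hat.mean() - 3 * d_hat.std() < published < d_hat.mean() + 3 * d_hat.std()

    def test_top2_modalities_separate_in_most_replicates(self, replicate_ds):
        """Facial temperature and subjective evaluation outrank EEG and blink
        rate (the study's reliability conclusion) in at least 95% of cohorts."""
        top2 = np.minimum(
            replicate_ds["subjective_evaluation"], replicate_ds["facial_temperature"]
        )
        bottom2 = np.maximum(replicate_ds["EEG"], replicate_ds["blinking_rate"])
        assert np.mean(top2 > bottom2) >= 0.95

    def test_magnitude_bias_of_small_effects(self, replicate_ds):
        """|d̂| of the near-null blink-rate effect concentrates near the folded-
        normal expectation implied by its sampling SD, not near the tiny true d."""
        d_true = 0.1608
        sampling_sd = np.sqrt(2 / 16 + d_true**2 / 64)
        folded_mean = sampling_sd * np.sqrt(2 / np.pi) * np.exp(
            -(d_true**2) / (2 * sampling_sd**2)
        ) + d_true * (1 - 2 * stats.norm.cdf(-d_true / sampling_sd))
        observed = replicate_ds["blinking_rate"].mean()
        mc_se = replicate_ds["blinking_rate"].std() / np.sqrt(len(replicate_ds["blinking_rate"]))
        # generous band: the folded-normal model ignores the estimator's own df
        assert observed == pytest.approx(folded_mean, abs=10 * mc_se)


class TestBuildReport:
    def test_full_report_on_default_cohort(self):
        cohort = gen_cohort(CohortSpec(seed=3))
        report = build_report(cohort)
        assert set(report.effect_sizes) == set(COHORT_SUMMARIES)
        assert report.correlation.shape == (4, 4)
        assert np.allclose(np.diag(report.correlation.to_numpy()), 1.0)
        assert set(report.ranking.by_effect_size) == set(COHORT_SUMMARIES)

    def test_compensated_report_runs(self):
        cohort = gen_cohort(CohortSpec(conditions=("horror", "neutral"), seed=3))
        report = build_report(cohort, neutral_condition="neutral")
        assert report.correlation.shape == (4, 4)
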