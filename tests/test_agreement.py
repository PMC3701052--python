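"""Bland-Altman, normality-gated paired tests, replicate CV, stain index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import cytoscreen as cs


class TestBlandAltman:
    def test_identical_pairs_zero_bias_zero_loa(self):
        res = cs.bland_altman([1, 2, 3], [1, 2, 3])
        assert res.bias == 0 and res.sd == 0
        assert res.loa_lower == 0 and res.loa_upper == 0

    def test_hand_computed_two_differences(self):
        # diffs {1, 3}: bias 2, sample sd sqrt(2)
        res = cs.bland_altman([2.0, 6.0], [1.0, 3.0])
        assert res.bias == pytest.approx(2.0)
        assert res.sd == pytest.approx(np.sqrt(2))
        assert res.loa_lower == pytest.approx(2 - 1.96 * np.sqrt(2))
        assert res.loa_upper == pytest.approx(2 + 1.96 * np.sqrt(2))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.floats(0.01, 100), st.floats(0.01, 100)),
                    min_size=2, max_size=30))
    def test_loa_identity_exact(self, pairs):
        a, b = zip(*pairs)
        res = cs.bland_altman(a, b)
        assert res.loa_lower == res.bias - 1.96 * res.sd
        assert res.loa_upper == res.bias + 1.96 * res.sd

    def test_bias_sign_follows_a_minus_b(self):
        res = cs.bland_altman([1.0, 1.0], [2.0, 4.0])
        assert res.bias < 0

    def test_log_scale_percent_bias(self):
        # a is uniformly 44% lower than b -> percent bias exactly 44
        b = np.array([1.0, 2.0, 5.0, 10.0])
        res = cs.bland_altman(0.56 * b, b, scale="log")
        assert res.percent_bias == pytest.approx(44.0)
        assert res.sd == pytest.approx(0.0, abs=1e-12)

    def test_log_scale_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="positive"):
            cs.bland_altman([0.0, 1.0], [1.0, 1.0], scale="log")

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="at least 2"):
            cs.bland_altman([1.0], [2.0])

    def test_programmed_il10_reduction_recovered(self, screened):
        # platform effect: group A reads IL-10+ 44% lower than group B
        averaged = screened.averaged
        donors = sorted({c.split("/")[0] for c in averaged.columns})
        a = [averaged.loc["IL10+", f"{d}/CFP"] for d in donors]
        b = [averaged.loc["IL10+", f"{d}/LFP"] for d in donors]
        res = cs.bland_altman(a, b, scale="log")
        assert res.percent_bias == pytest.approx(44.0, abs=6.0)


class TestPairedTest:
    def test_bonferroni_threshold_value(self):
        th = cs.bonferroni_threshold(0.05, 24)
        assert th == pytest.approx(0.05 / 24)
        assert round(th, 3) == 0.002

    def test_identical_samples_not_significant(self):
        res = cs.paired_test([1.0] * 12, [1.0] * 12)
        assert res.test == "none"
        assert not res.significant

    def test_shifted_gaussian_takes_t_branch_and_significant(self):
        rng = np.random.default_rng(4)
        b = rng.normal(10.0, 1.0, 12)
        a = b + rng.normal(1.0, 0.5, 12)  # delta 1, sigma 0.5, n 12
        res = cs.paired_test(a, b)
        assert res.test == "paired-t"
        assert res.normality_p >= 0.05
        assert res.threshold == pytest.approx(0.002083, abs=1e-5)
        assert res.significant
        # closed-form check: the t statistic has overwhelming power here
        t = (a - b).mean() / ((a - b).std(ddof=1) / np.sqrt(12))
        assert 2 * stats.t.sf(abs(t), 11) < 0.002

    def test_skewed_differences_take_wilcoxon_branch(self):
        rng = np.random.default_rng(1)
        b = rng.normal(10.0, 0.5, 20)
        a = b + rng.lognormal(0.0, 1.0, 20) ** 2  # heavily skewed shift
        res = cs.paired_test(a, b)
        assert res.normality_p < 0.05
        assert res.test == "wilcoxon"

    def test_small_n_falls_back_to_wilcoxon_flagged(self):
        res = cs.paired_test([1.0, 2.0, 3.0, 4.0], [0.5, 1.0, 2.0, 3.0])
        assert res.test == "wilcoxon"
        assert np.isnan(res.normality_p)
        assert "untestable" in res.note

    def test_branch_is_pure_function_of_normality_gate(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            r = np.random.default_rng(seed)
            a = r.normal(0, 1, 15)
            b = a + r.exponential(1.0, 15) * r.integers(0, 2, 15)
            res = cs.paired_test(a, b)
            with np.errstate(all="ignore"):
                p = stats.normaltest(a - b).pvalue
            assert res.test == ("paired-t" if p >= 0.05 else "wilcoxon")


class TestReplicateCV:
    def test_constant_triplicate_zero_cv(self):
        out = cs.cv_triplicates([10, 10, 10], ["d1"] * 3)
        assert out.loc["d1", "cv_percent"] == 0.0

    def test_exact_sample_sd_cv(self):
        out = cs.cv_triplicates([8, 10, 12], ["d1"] * 3)
        assert out.loc["d1", "sd"] == pytest.approx(2.0)
        assert out.loc["d1", "cv_percent"] == pytest.approx(20.0)

    def test_zero_mean_flagged(self):
        out = cs.cv_triplicates([-1.0, 1.0], ["d1"] * 2)
        assert out.loc["d1", "undefined"]
        assert np.isnan(out.loc["d1", "cv_percent"])

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.floats(0.1, 100), min_size=2, max_size=6),
           st.floats(0.01, 1000))
    def test_scale_invariance(self, values, c):
        base = cs.cv_triplicates(values, ["d"] * len(values))
        scaled = cs.cv_triplicates([v * c for v in values],
                                   ["d"] * len(values))
        assert scaled.loc["d", "cv_percent"] == pytest.approx(
            base.loc["d", "cv_percent"], rel=1e-6, abs=1e-9
        )


class TestStainIndex:
    def test_formula_with_known_medians_and_spread(self):
        mad = 9.0 / 1.4826
        neg = [10.0 - mad, 10.0, 10.0 + mad]  # median 10, rSD 9
        pos = [100.0, 100.0, 100.0]
        res = cs.stain_index(pos, neg)
        assert res.d == pytest.approx(90.0)
        assert res.w == pytest.approx(18.0)
        assert res.si == pytest.approx(5.0)
        assert res.rsd_definition == "1.4826*MAD"

    def test_identical_populations_zero_si(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        assert cs.stain_index(vals, vals).si == 0.0

    def test_shift_invariance_and_linear_scaling(self):
        rng = np.random.default_rng(3)
        neg = rng.normal(1, 0.3, 500)
        pos = rng.normal(4, 0.5, 500)
        base = cs.stain_index(pos, neg)
        shifted = cs.stain_index(pos + 7.5, neg + 7.5)
        assert shifted.si == pytest.approx(base.si)
        # shifting the positive median alone scales SI linearly in D
        stretched = cs.stain_index(pos + (pos - np.median(pos) + 2 * base.d
                                          + np.median(neg) - np.median(pos)),
                                   neg)
        assert stretched.d == pytest.approx(2 * base.d, rel=1e-6)

    def test_zero_spread_negatives_rejected(self):
        with pytest.raises(ValueError, match="spread"):
            cs.stain_index([5.0, 6.0], [1.0, 1.0, 1.0])

    def test_generator_hits_target_stain_index(self):
        # Foxp3 model is parameterized to SI 5.1; recover it empirically
        spec = cs.CohortSpec(n_donors=1, n_replicates=1,
                             n_events_per_sample=45_000, seed=6)
        model = spec.intensity["Foxp3"]
        assert model.target_stain_index == pytest.approx(5.1)
        samples, _meta, truth = cs.generate_cohort(spec)
        em = samples[0]
        states = truth.events[em.sample_id]["Foxp3"].to_numpy()
        values = em.marker_values("Foxp3")
        res = cs.stain_index(values[states], values[~states])
        assert res.si == pytest.approx(5.1, rel=0.15)


class TestAgreementReport:
    def test_report_columns_and_identity_row(self):
        pops = {"M+": ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]),
                "N+": ([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])}
        rep = cs.agreement_report(pops)
        assert rep.loc["M+", "bias"] == 0.0
        assert rep.loc["N+", "bias"] == pytest.approx(1.0)
        assert set(rep.columns) >= {"bias", "loa_lower", "loa_upper",
                                    "test", "p", "significant"}
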