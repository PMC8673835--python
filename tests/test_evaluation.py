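"""Statistical evaluation: exact binomial, group t, 2x2 RM-ANOVA, paired
comparisons, cross-model correlations and the break-exclusion control."""

import math

import numpy as np
import pytest

from alphadec.evaluation import (
    cross_model_correlation,
    exact_binomial_test,
    group_mean_test,
    paired_comparison,
    rm_anova_2x2,
    run_break_exclusion_control,
)


def _binom_pmf(n, k):
    return math.comb(n, k) * 0.5**n


def _brute_force_two_sided(n, k):
    """Oracle: sum all pmf values not exceeding pmf(k)."""
    pk = _binom_pmf(n, k)
    return sum(p for p in (_binom_pmf(n, i) for i in range(n + 1)) if p <= pk * (1 + 1e-9))


def _brute_force_greater(n, k):
    return sum(_binom_pmf(n, i) for i in range(k, n + 1))


class TestExactBinomial:
    def test_matches_brute_force_all_n_up_to_200(self):
        rng = np.random.default_rng(0)
        for n in range(1, 201):
            for k in {0, n // 2, n, int(rng.integers(0, n + 1))}:
                assert exact_binomial_test(k, n) == pytest.approx(
                    min(1.0, _brute_force_two_sided(n, k)), rel=1e-9
                )
                assert exact_binomial_test(k, n, sided="greater") == pytest.approx(
                    _brute_force_greater(n, k), rel=1e-9
                )

    def test_at_chance_is_one(self):
        assert exact_binomial_test(90, 180) == pytest.approx(1.0, abs=1e-9)

    def test_perfect_decoding_closed_form(self):
        assert exact_binomial_test(180, 180) == pytest.approx(2 * 0.5**180, rel=1e-12)

    def test_smallest_significant_count_at_180(self):
        """The one-sided significance threshold at n=180, via the oracle."""
        k_star = next(
            k for k in range(90, 181) if _brute_force_greater(180, k) < 0.05
        )
        assert exact_binomial_test(k_star, 180, sided="greater") < 0.05
        assert exact_binomial_test(k_star - 1, 180, sided="greater") >= 0.05

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            exact_binomial_test(10, 5)


class TestGroupMean:
    def test_all_at_chance(self):
        with pytest.raises(ValueError):
            group_mean_test(np.full(10, 0.5))  # zero variance

    def test_above_chance(self, rng):
        t, p = group_mean_test(0.6 + 0.02 * rng.standard_normal(20))
        assert t > 0 and p < 0.01

    def test_hand_computed_example(self):
        x = np.array([0.55, 0.60, 0.52, 0.58, 0.50])
        t_manual = (x.mean() - 0.5) / (x.std(ddof=1) / np.sqrt(5))
        from scipy.stats import t as tdist

        t, p = group_mean_test(x)
        assert t == pytest.approx(t_manual, rel=1e-12)
        assert p == pytest.approx(tdist.sf(t_manual, 4), rel=1e-12)

    def test_too_few(self):
        with pytest.raises(ValueError):
            group_mean_test(np.array([0.6, 0.7]))


class TestRmAnova:
    def test_identical_values_zero_f(self):
        out = rm_anova_2x2(np.full((8, 2, 2), 0.6))
        assert all(v[0] == 0.0 for v in out.values())

    def test_constant_model_offset(self, rng):
        scores = 0.5 + 0.01 * rng.standard_normal((10, 2, 2))
        scores[:, 0, :] += 0.1  # model 1 uniformly better
        out = rm_anova_2x2(scores)
        assert out["model"][0] > 10
        assert out["model"][1] < 0.01
        assert out["interaction"][0] < out["model"][0] / 10

    def test_subject_permutation_invariance(self, rng):
        scores = rng.random((12, 2, 2))
        a = rm_anova_2x2(scores)
        b = rm_anova_2x2(scores[rng.permutation(12)])
        for key in a:
            assert a[key][0] == pytest.approx(b[key][0], rel=1e-12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        scores = rng.random((9, 2, 2))
        rows = [
            {"subject": s, "model": m, "cond": c, "dv": scores[s, m, c]}
            for s in range(9)
            for m in range(2)
            for c in range(2)
        ]
        df = pd.DataFrame(rows)
        ref = pg.rm_anova(data=df, dv="dv", within=["model", "cond"], subject="subject")
        ours = rm_anova_2x2(scores)
        for effect, key in [("model", "model"), ("cond", "condition"),
                            ("model * cond", "interaction")]:
            f_ref = float(ref.loc[ref["Source"] == effect, "F"].iloc[0])
            assert ours[key][0] == pytest.approx(f_ref, rel=1e-6)

    def test_bad_shape(self):
        with pytest.raises(ValueError):
            rm_anova_2x2(np.zeros((5, 3, 2)))


class TestPaired:
    def test_identical_vectors(self):
        assert paired_comparison(np.arange(5.0), np.arange(5.0)) == (0.0, 1.0)

    def test_constant_nonzero_difference_errors(self):
        with pytest.raises(ValueError):
            paired_comparison(np.arange(5.0) + 1.0, np.arange(5.0))

    def test_hand_computed_four_pairs(self):
        a = np.array([0.70, 0.65, 0.72, 0.60])
        b = np.array([0.66, 0.64, 0.65, 0.62])
        d = a - b
        t_manual = d.mean() / (d.std(ddof=1) / 2.0)
        from scipy.stats import t as tdist

        t, p = paired_comparison(a, b)
        assert t == pytest.approx(t_manual, rel=1e-12)
        assert p == pytest.approx(2 * tdist.sf(abs(t_manual), 3), rel=1e-12)


class TestCrossModel:
    def test_near_identical_metrics_correlate(self, rng):
        base = rng.random(10)
        out = cross_model_correlation(
            {"csp": base, "lstm": base + 1e-6 * rng.standard_normal(10)}
        )
        r, p = out[("csp", "lstm")]
        assert r == pytest.approx(1.0, abs=1e-3)

    def test_bonferroni_cap(self, rng):
        metrics = {name: rng.random(8) for name in "abcd"}
        out = cross_model_correlation(metrics)
        assert len(out) == 6
        assert all(0 <= p <= 1 for _, p in out.values())

    def test_shared_signal_strength_couples_models(self):
        """Subjects with stronger planted signal score higher on both
        binary decoders, so their accuracies correlate positively."""
        rs = []
        for cohort in range(10):
            rng = np.random.default_rng(cohort)
            strength = rng.uniform(0, 0.3, 12)
            csp = 0.5 + strength + 0.05 * rng.standard_normal(12)
            lstm = 0.5 + 0.8 * strength + 0.05 * rng.standard_normal(12)
            rs.append(np.corrcoef(csp, lstm)[0, 1])
        assert np.median(rs) > 0

    def test_constant_vector_errors(self, rng):
        with pytest.raises(ValueError):
            cross_model_correlation({"a": np.ones(5), "b": rng.random(5)})


class TestBreakExclusionControl:
    def test_rides_only_pipeline(self, planted):
        out = run_break_exclusion_control(
            planted["recording"], planted["trace"], planted["peak"],
            n_perm=100, seed=0,
        )
        assert out["kept"]
        # 240 epochs -> 80 per tertile; the planted effect survives
        assert out["spoc_r"] < 0
        assert out["csp_auc"] > 0.5
        assert 0 <= out["csp_block_p"] <= 1

    def test_240s_split_is_80_80_80(self, planted):
        from alphadec.preprocess import crop_experience, tertile_labels
        from alphadec.synth import RatingTrace

        rec240 = crop_experience(planted["recording"], include_break=False)
        assert rec240.duration_s == pytest.approx(240.0)
        keep = np.r_[np.arange(0, 148), np.arange(178, 270)]
        labels = tertile_labels(RatingTrace(values=planted["trace"].values[keep]))
        np.testing.assert_array_equal(np.bincount(labels.classes), [80, 80, 80])
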