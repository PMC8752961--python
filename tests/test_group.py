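"""Statistical primitives and the cohort-level workflow.

The primitive tests (Welch, one-sample t, Cohen's d_s) are implemented
from their formulas in the package; here they are held against
hand-computed values and against SciPy/pingouin as independent
references.  Workflow tests run on hand-built or simulated cohorts with
known structure.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twroi import (
    GroupAnalysis,
    bonferroni,
    cohens_ds,
    one_sample_t_test,
    welch_t_test,
)
from twroi.group import (
    bias_analysis,
    bias_tf_correlation,
    effect_size_comparison,
    mean_tf_group_comparison,
    periventricular_bias_comparison,
)
from conftest import make_cohort_frame

X, Y = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]


class TestWelch:
    def test_hand_example(self):
        res = welch_t_test(X, Y)
        assert res.statistic == pytest.approx(-2 / np.sqrt(5 / 3), rel=1e-12)
        assert res.dof == pytest.approx(
            (5 / 3) ** 2 / ((1 / 3) ** 2 / 2 + (4 / 3) ** 2 / 2), rel=1e-12
        )

    def test_identical_groups(self):
        res = welch_t_test(X, X)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_equal_variance_reduces_to_student(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 0.7
        mine = welch_t_test(x, y)
        ref_t, ref_p = stats.ttest_ind(x, y, equal_var=True)
        assert mine.statistic == pytest.approx(ref_t, rel=1e-12)
        assert mine.p_value == pytest.approx(ref_p, rel=1e-10)

    def test_matches_scipy_on_random_inputs(self, rng):
        for _ in range(50):
            x = rng.normal(0, 1 + rng.random(), rng.integers(2, 40))
            y = rng.normal(rng.random(), 1, rng.integers(2, 40))
            mine = welch_t_test(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)
            assert mine.dof == pytest.approx(ref.df, abs=1e-10)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero variance"):
            welch_t_test([1.0, 1.0], [2.0, 2.0])


class TestOneSample:
    def test_hand_example(self):
        res = one_sample_t_test([0.01, 0.02, 0.03], 0.0)
        assert res.statistic == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert res.dof == 2

    def test_null_mean(self):
        res = one_sample_t_test([1.0, 2.0, 3.0], 2.0)
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_negation_symmetry(self):
        x = np.array([0.3, -0.1, 0.4, 0.2])
        a, b = one_sample_t_test(x), one_sample_t_test(-x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_matches_scipy_on_random_inputs(self, rng):
        for _ in range(50):
            x = rng.normal(0.1, 0.5, rng.integers(2, 30))
            mine = one_sample_t_test(x, 0.05)
            ref = stats.ttest_1samp(x, 0.05)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_off_null_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            one_sample_t_test([0.2, 0.2], 0.0)
        res = one_sample_t_test([0.2, 0.2], 0.2)
        assert res.p_value == 1.0


class TestBonferroni:
    def test_family_of_48(self):
        adj, sig = bonferroni([0.001, 0.002], k=48)
        np.testing.assert_allclose(adj, [0.048, 0.096])
        np.testing.assert_array_equal(sig, [True, False])

    def test_single_test_unchanged(self):
        adj, sig = bonferroni([0.03])
        assert adj[0] == pytest.approx(0.03) and sig[0]

    def test_caps_at_one_and_validates(self):
        adj, _ = bonferroni([0.9, 0.2], k=10)
        np.testing.assert_allclose(adj, [1.0, 1.0])
        assert bonferroni([])[0].size == 0
        with pytest.raises(ValueError):
            bonferroni([1.2])


class TestCohensDs:
    def test_hand_example(self):
        assert cohens_ds(X, Y) == pytest.approx(-2 / np.sqrt(2.5), rel=1e-12)

    def test_antisymmetry_and_null(self):
        assert cohens_ds(X, X) == 0.0
        assert cohens_ds(X, Y) == pytest.approx(-cohens_ds(Y, X))

    def test_matches_pingouin_on_random_inputs(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(20):
            x = rng.normal(0, 1, rng.integers(3, 30))
            y = rng.normal(0.4, 1.5, rng.integers(3, 30))
            ref = pingouin.compute_effsize(x, y, eftype="cohen")
            assert cohens_ds(x, y) == pytest.approx(ref, abs=1e-10)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_ds([1.0, 1.0], [2.0, 2.0])


def _tf_cohort(delta, n=20, sd=0.02, n_rois=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for roi in [f"R{i}" for i in range(n_rois)]:
        base = 0.8
        for g, shift in (("A", 0.0), ("B", -delta)):
            for k in range(n):
                rows.append(
                    {"subject_id": f"{g}{k}", "group": g, "roi": roi,
                     "metric": "NDI", "n_voxels": 100,
                     "mean_tf": base + shift + rng.normal(0, sd)}
                )
    return make_cohort_frame(rows)


class TestWorkflow:
    def test_mean_tf_comparison_detects_large_drop(self):
        cohort = _tf_cohort(delta=0.1)
        out = mean_tf_group_comparison(cohort)
        assert out["significant"].all()
        assert (out["statistic"] > 0).all()  # A minus B, A higher

    def test_mean_tf_comparison_null_mostly_quiet(self):
        cohort = _tf_cohort(delta=0.0, seed=5)
        out = mean_tf_group_comparison(cohort)
        assert not out["significant"].any()

    def test_bias_analysis_detects_injected_covariance(self, small_cohort):
        cohort, _ = small_cohort
        out = bias_analysis(cohort)
        one = out["one_sample"]
        # ODI couples negatively to TF in the generator => positive bias
        odi = one[one["metric"] == "ODI"]
        assert (odi["mean_bias"] > 0).all()
        assert odi["significant"].mean() > 0.8
        # stored bias equals the difference of the stored means
        recomputed = cohort["conventional_mean"] - cohort["tissue_weighted_mean"]
        np.testing.assert_allclose(cohort["bias"], recomputed, atol=1e-12)

    def test_bias_tf_correlation_exact_proportionality(self):
        rows = []
        for i, tf in enumerate([0.5, 0.6, 0.7, 0.8, 0.9]):
            for k in range(3):
                rows.append(
                    {"subject_id": f"s{k}", "group": "A", "roi": f"R{i}",
                     "metric": "NDI", "mean_tf": tf, "bias": 0.01 / tf}
                )
        out = bias_tf_correlation(make_cohort_frame(rows))
        assert out["r"].iloc[0] == pytest.approx(1.0)
        # flipped relationship
        for r in rows:
            r["bias"] = 0.01 * r["mean_tf"]
        out = bias_tf_correlation(make_cohort_frame(rows))
        assert out["r"].iloc[0] < 0

    def test_bias_tf_correlation_needs_variation(self):
        rows = [
            {"subject_id": "s", "group": "A", "roi": f"R{i}",
             "metric": "NDI", "mean_tf": 0.8, "bias": 0.01}
            for i in range(4)
        ]
        with pytest.raises(ValueError, match="constant"):
            bias_tf_correlation(make_cohort_frame(rows))

    def test_periventricular_comparison_constructed_effect(self, roidefs):
        rng = np.random.default_rng(2)
        rows = []
        for rec in roidefs.itertuples(index=False):
            scale = 0.03 if rec.periventricular else 0.01
            for k in range(5):
                rows.append(
                    {"subject_id": f"s{k}", "group": "A",
                     "roi": rec.abbreviation, "metric": "NDI",
                     "mean_tf": 0.8,
                     "bias": rng.normal(scale, 0.002)}
                )
        out = periventricular_bias_comparison(
            make_cohort_frame(rows), roidefs
        )
        assert out["significant"].all()
        assert (out["mean_abs_bias_pv"] > out["mean_abs_bias_npv"]).all()

    def test_periventricular_comparison_degenerate_class(self, roidefs):
        rows = [
            {"subject_id": "s", "group": "A", "roi": "GCC",
             "metric": "NDI", "mean_tf": 0.8, "bias": 0.01},
            {"subject_id": "s", "group": "A", "roi": "BCC",
             "metric": "NDI", "mean_tf": 0.8, "bias": 0.01},
        ]
        with pytest.raises(ValueError, match="class"):
            periventricular_bias_comparison(make_cohort_frame(rows), roidefs)

    def test_effect_sizes_equal_when_bias_is_zero(self):
        rng = np.random.default_rng(3)
        rows = []
        for g, mu in (("A", 0.6), ("B", 0.55)):
            for k in range(10):
                v = mu + rng.normal(0, 0.02)
                rows.append(
                    {"subject_id": f"{g}{k}", "group": g, "roi": "R0",
                     "metric": "NDI", "mean_tf": 0.9,
                     "conventional_mean": v, "tissue_weighted_mean": v,
                     "bias": 0.0}
                )
        out = effect_size_comparison(make_cohort_frame(rows))
        assert out["d_conventional"].iloc[0] == out["d_tissue_weighted"].iloc[0]
        assert out["difference"].iloc[0] == 0.0

    def test_group_b_only_bias_shrinks_conventional_effect(self):
        """Positive bias confined to the lower-metric group masks part of
        the true group difference when the conventional mean is used."""
        rng = np.random.default_rng(4)
        rows = []
        for g, mu, bias in (("A", 0.45, 0.0), ("B", 0.41, 0.012)):
            for k in range(25):
                tw = mu + rng.normal(0, 0.02)
                rows.append(
                    {"subject_id": f"{g}{k}", "group": g, "roi": "R0",
                     "metric": "ODI", "mean_tf": 0.8,
                     "conventional_mean": tw + bias,
                     "tissue_weighted_mean": tw, "bias": bias}
                )
        out = effect_size_comparison(make_cohort_frame(rows))
        assert out["d_conventional"].iloc[0] < out["d_tissue_weighted"].iloc[0]

    def test_model_wrapper_runs_everything(self, small_cohort):
        cohort, _ = small_cohort
        res = GroupAnalysis(cohort, alpha=0.05).fit()
        assert len(res.mean_tf) == cohort["roi"].nunique()
        assert len(res.effect_sizes) == cohort["roi"].nunique() * 2
        assert {"NDI", "ODI"} == set(res.bias_tf_correlation["metric"])
        text = res.summary()
        assert "contrast" in text and "r =" in text

    def test_results_save_round_trip(self, small_cohort, tmp_path):
        cohort, _ = small_cohort
        res = GroupAnalysis(cohort).fit()
        written = res.save(tmp_path / "out")
        assert len(written) == 7
        back = pd.read_csv(tmp_path / "out" / "effect_sizes.csv")
        np.testing.assert_allclose(
            back["d_conventional"], res.effect_sizes["d_conventional"],
            atol=1e-12,
        )

    def test_duplicate_rows_rejected(self, small_cohort):
        cohort, _ = small_cohort
        dup = pd.concat([cohort, cohort.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            GroupAnalysis(dup)
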