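import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clipscore import PipelineConfig
from clipscore.io import QuantTable
from clipscore.scoring import (
    RegressionFit,
    classify_targets,
    clip_score,
    cross_condition_classes,
    fit_abundance_regression,
    score_table,
)


def series(vals, idx=None):
    return pd.Series(vals, index=idx or [f"t{i}" for i in range(len(vals))], dtype=float)


class TestRegression:
    def test_collinear_points_exact(self):
        fit = fit_abundance_regression(series([1, 3, 5]), series([0, 1, 2]))
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)

    def test_flat_response(self):
        fit = fit_abundance_regression(series([4, 4, 4, 4]), series([0, 1, 2, 3]))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(4.0, abs=1e-12)

    def test_matches_scipy_linregress(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = series(rng.normal(size=100))
            y = series(rng.normal(size=100))
            fit = fit_abundance_regression(y, x)
            ref = stats.linregress(x.values, y.values)
            assert fit.slope == pytest.approx(ref.slope, abs=1e-10)
            assert fit.intercept == pytest.approx(ref.intercept, abs=1e-10)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_abundance_regression(series([1, 2, 3]), series([5, 5, 5]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_abundance_regression(series([1, 2]), series([0, 1]))


class TestClipScore:
    FIT = RegressionFit("Control", "r1", slope=1.0, intercept=1.0,
                        n_points=10, residual_sd=0.1)

    def test_printed_formula(self):
        assert clip_score(5.0, 2.0, self.FIT, "as_printed") == pytest.approx(4.0)

    def test_point_on_line_residual_zero(self):
        y = self.FIT.slope * 3.0 + self.FIT.intercept
        assert clip_score(y, 3.0, self.FIT, "residual") == pytest.approx(0.0)

    def test_point_on_line_as_printed_two_a(self):
        y = self.FIT.slope * 3.0 + self.FIT.intercept
        assert clip_score(y, 3.0, self.FIT, "as_printed") == pytest.approx(
            2 * self.FIT.intercept)


def two_condition_tables(rng, n=60, reps=3, identical=False):
    idx = [f"t{i}" for i in range(n)]
    ribo, clip = {}, {}
    for cond in ("Control", "Opto"):
        r = pd.DataFrame(rng.uniform(1, 100, (n, reps)),
                         index=idx, columns=[f"{cond}_R{k}" for k in range(reps)])
        ribo[cond] = QuantTable(r / r.sum() * 1e6, scale="linear")
        if identical:
            col = rng.uniform(1, 100, n)
            c = pd.DataFrame({f"{cond}_C{k}": col for k in range(reps)}, index=idx)
        else:
            c = pd.DataFrame(rng.uniform(0, 100, (n, reps)),
                             index=idx, columns=[f"{cond}_C{k}" for k in range(reps)])
        clip[cond] = QuantTable(c / c.sum() * 1e6, scale="linear")
    return clip, ribo


class TestScoreTable:
    def test_identical_replicates_equal_scores_and_mean(self):
        rng = np.random.default_rng(0)
        clip, ribo = two_condition_tables(rng, identical=True)
        st = score_table(clip, ribo, PipelineConfig())
        block = st.scores["Control"]
        assert np.allclose(block.iloc[:, 0], block.iloc[:, 1])
        assert np.allclose(st.means["Control"], block.iloc[:, 0])

    def test_convention_switch_shifts_by_two_intercepts(self):
        rng = np.random.default_rng(1)
        clip, ribo = two_condition_tables(rng)
        ap = score_table(clip, ribo, PipelineConfig(score_convention="as_printed"))
        rs = score_table(clip, ribo, PipelineConfig(score_convention="residual"))
        for key, fit in ap.fits.items():
            diff = ap.scores[key] - rs.scores[key]
            assert np.allclose(diff.dropna(), 2 * fit.intercept, atol=1e-12)

    def test_convention_never_reorders_within_replicate(self):
        rng = np.random.default_rng(2)
        clip, ribo = two_condition_tables(rng)
        ap = score_table(clip, ribo, PipelineConfig(score_convention="as_printed"))
        rs = score_table(clip, ribo, PipelineConfig(score_convention="residual"))
        for key in ap.fits:
            a = ap.scores[key].dropna().rank()
            b = rs.scores[key].dropna().rank()
            pd.testing.assert_series_equal(a, b)

    def test_residuals_of_fitted_transcripts_sum_to_zero(self):
        rng = np.random.default_rng(3)
        clip, ribo = two_condition_tables(rng)
        st = score_table(clip, ribo, PipelineConfig(score_convention="residual"))
        for key in st.fits:
            assert abs(st.scores[key].dropna().sum()) < 1e-8

    def test_zero_tpm_gives_missing_score(self):
        rng = np.random.default_rng(4)
        clip, ribo = two_condition_tables(rng)
        clip["Control"].values.iloc[0, 0] = 0.0
        st = score_table(clip, ribo, PipelineConfig())
        assert np.isnan(st.scores[("Control", clip["Control"].values.columns[0])].iloc[0])


class TestClassification:
    def mk_scores(self, per_rep, conds=("Control", "Opto")):
        """Build a ClipScoreTable-like object from per-replicate rows."""
        from clipscore.scoring import ClipScoreTable

        idx = [f"t{i}" for i in range(len(per_rep))]
        cols = {}
        for cond in conds:
            for r in range(len(per_rep[0])):
                cols[(cond, f"r{r}")] = [row[r] for row in per_rep]
        scores = pd.DataFrame(cols, index=idx)
        scores.columns = pd.MultiIndex.from_tuples(scores.columns,
                                                   names=["condition", "replicate"])
        means = scores.T.groupby(level="condition").mean().T
        return ClipScoreTable(scores, means, {}, "as_printed")

    def test_all_replicates_above_two_is_stringent(self):
        st = self.mk_scores([[2.5, 2.2, 3.0, 2.1]])
        tiers = classify_targets(st, PipelineConfig())
        assert tiers.iloc[0]["Control"] == "stringent"

    def test_mean_one_and_a_half_is_high(self):
        st = self.mk_scores([[1.5, 1.5, 1.5, 1.5]])
        tiers = classify_targets(st, PipelineConfig(stringency_mode="mean"))
        assert tiers.iloc[0]["Control"] == "high"

    def test_mean_exactly_two_is_high_not_stringent(self):
        st = self.mk_scores([[2.0, 2.0, 2.0, 2.0]])
        tiers = classify_targets(st, PipelineConfig(stringency_mode="mean"))
        assert tiers.iloc[0]["Control"] == "high"

    def test_one_failing_replicate_blocks_per_replicate_stringency(self):
        st = self.mk_scores([[2.5, 2.5, 1.9, 2.5]])
        tiers = classify_targets(st, PipelineConfig(stringency_mode="per_replicate"))
        assert tiers.iloc[0]["Control"] == "high"

    def test_missing_replicate_blocks_stringency(self):
        st = self.mk_scores([[2.5, 2.5, np.nan, 2.5]])
        tiers = classify_targets(st, PipelineConfig(stringency_mode="per_replicate"))
        assert tiers.iloc[0]["Control"] != "stringent"

    def test_negative_mean_is_nontarget(self):
        st = self.mk_scores([[-1.0, -0.5, -0.2, -0.1]])
        tiers = classify_targets(st, PipelineConfig())
        assert tiers.iloc[0]["Control"] == "nontarget"

    def test_tiers_partition_scored_set(self):
        rng = np.random.default_rng(5)
        st = self.mk_scores(rng.normal(1, 2, (200, 4)).tolist())
        tiers = classify_targets(st, PipelineConfig())
        counts = tiers["Control"].value_counts()
        assert counts.sum() == 200
        assert set(counts.index) <= {"stringent", "high", "low", "nontarget"}


class TestCrossCondition:
    def tiers(self, ctrl, opto):
        return pd.DataFrame({"Control": ctrl, "Opto": opto})

    def test_definitions(self):
        t = self.tiers(["stringent", "stringent", "high", "low"],
                       ["stringent", "high", "stringent", "nontarget"])
        cls = cross_condition_classes(t)
        assert cls.tolist() == ["stringent_both", "control_only", "opto_only", "neither"]

    def test_partition(self):
        rng = np.random.default_rng(6)
        opts = ["stringent", "high", "low", "nontarget"]
        t = self.tiers(rng.choice(opts, 100), rng.choice(opts, 100))
        cls = cross_condition_classes(t)
        assert cls.value_counts().sum() == 100

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="missing condition"):
            cross_condition_classes(pd.DataFrame({"Control": ["high"]}))
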