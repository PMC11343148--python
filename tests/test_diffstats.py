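import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from clipscore.diffstats import (
    bh_adjust,
    fit_f_dist,
    moderated_t,
    nb_wald_test,
    size_factors,
)


def brute_force_bh(p):
    """Literal step-up: q_i = min over j with p_j >= p_i of p_(j) * m / rank_j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank, i in enumerate(order, start=1):
        q[i] = min(min(p[j] * m / (list(order).index(j) + 1)
                       for j in order[rank - 1:]), 1.0)
    return q


class TestBH:
    def test_equally_spaced_example(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_all_equal_stay_equal(self):
        out = bh_adjust(np.full(7, 0.02))
        assert np.allclose(out, 0.02)

    def test_matches_brute_force_small(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            p = rng.uniform(size=rng.integers(1, 12))
            assert np.allclose(bh_adjust(p), brute_force_bh(p))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=80))
    def test_matches_statsmodels_and_dominates_p(self, plist):
        p = np.array(plist)
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref)
        assert (ours >= p - 1e-15).all()

    def test_preserves_series_index(self):
        s = pd.Series([0.5, 0.01], index=["a", "b"])
        out = bh_adjust(s)
        assert list(out.index) == ["a", "b"]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust(np.array([0.5, 1.2]))


def score_matrices(rng, n=300, n1=4, n2=4, effect=0.0, sd=None):
    sd = sd if sd is not None else rng.uniform(0.2, 1.0, n)
    c = rng.normal(0, np.atleast_1d(sd)[:, None] * np.ones((n, n1)))
    o = rng.normal(effect, np.atleast_1d(sd)[:, None] * np.ones((n, n2)))
    idx = [f"t{i}" for i in range(n)]
    return pd.DataFrame(c, index=idx), pd.DataFrame(o, index=idx)


class TestModeratedT:
    def test_d0_zero_equals_pooled_t(self):
        rng = np.random.default_rng(1)
        c, o = score_matrices(rng, n=100)
        res = moderated_t(c, o, d0_override=0.0)
        ref = stats.ttest_ind(o.values.T, c.values.T)
        assert np.abs(res["statistic"].values - ref.statistic).max() < 1e-8
        assert np.abs(res["p"].values - ref.pvalue).max() < 1e-8

    def test_d0_infinite_pins_variance_at_prior(self):
        rng = np.random.default_rng(2)
        c, o = score_matrices(rng, n=100)
        res = moderated_t(c, o, d0_override=1e12)
        s02 = res["prior_var"].iloc[0]
        post = (res["prior_df"] * s02 + res["df_resid"] * res["s2"]) / (
            res["prior_df"] + res["df_resid"])
        assert np.allclose(post, s02, rtol=1e-6)

    def test_matches_limma_exactly(self, tmp_path):
        """Bioconductor limma (lmFit + eBayes, no trend) as independent
        oracle for the empirical-Bayes moderated t."""
        rng = np.random.default_rng(42)
        c, o = score_matrices(rng, n=150)
        o.iloc[:15] -= 1.5
        res = moderated_t(c, o)
        mat = pd.concat([c, o], axis=1)
        mat.columns = [f"s{i}" for i in range(mat.shape[1])]
        mat.to_csv(tmp_path / "m.tsv", sep="\t")
        r_code = textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("{tmp_path}/m.tsv", row.names=1))
            design <- cbind(Intercept=1, Opto=c(rep(0,4), rep(1,4)))
            fit <- eBayes(lmFit(m, design))
            out <- data.frame(t=fit$t[,"Opto"], p=fit$p.value[,"Opto"],
                              d0=fit$df.prior, s02=fit$s2.prior)
            write.table(out, "{tmp_path}/out.tsv", sep="\\t", quote=FALSE)
        """)
        (tmp_path / "oracle.R").write_text(r_code)
        subprocess.run(["Rscript", str(tmp_path / "oracle.R")], check=True,
                       capture_output=True)
        limma = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        assert res["prior_df"].iloc[0] == pytest.approx(limma["d0"].iloc[0], rel=1e-9)
        assert res["prior_var"].iloc[0] == pytest.approx(limma["s02"].iloc[0], rel=1e-9)
        assert np.abs(res["statistic"].values - limma["t"].values).max() < 1e-9
        assert np.abs(res["p"].values - limma["p"].values).max() < 1e-9

    def test_direction_labels_follow_sign(self):
        rng = np.random.default_rng(3)
        c, o = score_matrices(rng, n=50, effect=-3.0, sd=np.full(50, 0.3))
        res = moderated_t(c, o)
        sig = res[res["p"] < 0.05]
        assert (sig.loc[sig["effect"] < 0, "direction"] == "FMRP-Down").all()

    def test_insufficient_replicates_dropped_with_warning(self):
        c = pd.DataFrame([[1.0, np.nan, np.nan, np.nan], [0.5, 0.6, 0.4, 0.5]],
                         index=["bad", "ok"])
        o = pd.DataFrame(np.ones((2, 4)) * 0.5, index=["bad", "ok"])
        with pytest.warns(RuntimeWarning, match="fewer than 2 finite"):
            res = moderated_t(c, o)
        assert list(res.index) == ["ok"]

    def test_prior_fit_recovers_known_f_distribution(self):
        rng = np.random.default_rng(8)
        d0_true, s02_true, dg = 4.0, 0.5, 6.0
        n = 20000
        s2 = s02_true * stats.f.rvs(dg, d0_true, size=n, random_state=rng)
        d0, s02 = fit_f_dist(s2, np.full(n, dg))
        assert d0 == pytest.approx(d0_true, rel=0.1)
        assert s02 == pytest.approx(s02_true, rel=0.05)


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        df = pd.DataFrame({"a": [5, 9, 2], "b": [5, 9, 2]})
        assert np.allclose(size_factors(df), 1.0)

    def test_doubled_column_doubles_factor(self):
        df = pd.DataFrame({"a": [10, 20, 5, 8], "b": [20, 40, 10, 16],
                           "c": [10, 20, 5, 8]})
        sf = size_factors(df)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_matches_hand_median_of_ratios(self):
        # log-space median of ratios to the per-gene geometric mean
        # (the DESeq2 construction), rescaled to geometric mean 1
        df = pd.DataFrame({"s1": [4, 10, 20, 7], "s2": [8, 10, 10, 14],
                           "s3": [2, 40, 40, 7]},
                          index=list("abcd"))
        geo = stats.gmean(df.values, axis=1)
        expected = np.exp(np.median(np.log(df.values / geo[:, None]), axis=0))
        expected = expected / stats.gmean(expected)
        assert np.allclose(size_factors(df).values, expected)

    def test_no_common_nonzero_gene_is_error(self):
        df = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(df)


def nb_counts(rng, mu, lfc, dispersion, reps=3):
    r = 1.0 / dispersion
    def draw(mean):
        p = r / (r + mean)
        return rng.negative_binomial(r, p[:, None], size=(len(mean), reps))
    counts = np.hstack([draw(mu), draw(mu * 2.0**lfc)]).astype(int)
    df = pd.DataFrame(counts, index=[f"g{i}" for i in range(len(mu))],
                      columns=[f"C{i}" for i in range(reps)] + [f"O{i}" for i in range(reps)])
    design = pd.Series(["Control"] * reps + ["Opto"] * reps, index=df.columns)
    return df, design


class TestNbWald:
    def test_poisson_null_calibrated_and_centered(self):
        rng = np.random.default_rng(10)
        counts = pd.DataFrame(
            rng.poisson(300.0, size=(1000, 6)),
            index=[f"g{i}" for i in range(1000)],
            columns=[f"s{i}" for i in range(6)])
        design = pd.Series(["Control"] * 3 + ["Opto"] * 3, index=counts.columns)
        res = nb_wald_test(counts, design)
        assert abs(res["effect"].mean()) < 0.01
        assert 0.02 < (res["p"] < 0.05).mean() < 0.08
        assert (res["dispersion"] <= 0.01).mean() >= 0.95

    def test_planted_fold_change_recovered(self):
        rng = np.random.default_rng(11)
        mu = np.full(1000, 200.0)
        lfc = np.zeros(1000)
        lfc[:100] = 1.0
        counts, design = nb_counts(rng, mu, lfc, dispersion=0.05)
        res = nb_wald_test(counts, design,
                           sf=pd.Series(1.0, index=counts.columns))
        assert res["effect"].values[:100].mean() == pytest.approx(1.0, abs=0.1)

    def test_matches_pydeseq2_fold_changes(self):
        """pydeseq2 (full DESeq2 reimplementation) as independent oracle
        for the MLE log2 fold changes on well-covered genes."""
        import warnings

        rng = np.random.default_rng(3)
        m = 200
        mu = np.exp(rng.uniform(np.log(50), np.log(2000), m))
        lfc = np.where(rng.random(m) < 0.2, rng.choice([-1.0, 1.0], m), 0.0)
        counts, design = nb_counts(rng, mu, lfc, dispersion=0.1)
        res = nb_wald_test(counts, design)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from pydeseq2.dds import DeseqDataSet
            from pydeseq2.ds import DeseqStats

            meta = pd.DataFrame({"condition": design.values}, index=counts.columns)
            dds = DeseqDataSet(counts=counts.T, metadata=meta,
                               design="~condition", quiet=True)
            dds.deseq2()
            ds = DeseqStats(dds, contrast=["condition", "Opto", "Control"],
                            quiet=True)
            ds.summary()
        ref = ds.results_df["log2FoldChange"]
        diff = (res["effect"] - ref).abs()
        assert diff.max() < 0.05
        assert res["effect"].corr(ref) > 0.999

    def test_zero_group_flagged_not_crashed(self):
        counts = pd.DataFrame({"C1": [0, 10], "C2": [0, 12], "C3": [0, 9],
                               "O1": [8, 10], "O2": [6, 11], "O3": [7, 12]},
                              index=["z", "n"])
        design = pd.Series(["Control"] * 3 + ["Opto"] * 3, index=counts.columns)
        res = nb_wald_test(counts, design, sf=pd.Series(1.0, index=counts.columns))
        assert bool(res.loc["z", "zero_group"])
        assert np.isfinite(res.loc["z", "effect"])

    def test_two_group_requirement(self):
        counts = pd.DataFrame({"a": [1], "b": [2]})
        with pytest.raises(ValueError, match="2 groups"):
            nb_wald_test(counts, pd.Series(["x", "x"], index=["a", "b"]))
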