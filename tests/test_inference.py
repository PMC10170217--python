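"""Group-level mixed-model inference: the REML engine against external
oracles, Satterthwaite df, contrasts, Bonferroni, bin datasets."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import magmap.inference as inf
from magmap.evaluation import _simulate_bins


@pytest.fixture(scope="module")
def bins_fixture():
    rng = np.random.default_rng(42)
    bins = _simulate_bins(rng, n_subjects=5,
                          cond_offsets={"T": 0, "N": 3, "C": 8, "I": 4},
                          cond_slopes={"T": 30, "N": 35, "C": 25, "I": 30},
                          noise_sd=6.0)
    # unbalance so the df machinery is genuinely exercised
    return bins.drop(bins.sample(60, random_state=1).index).reset_index(drop=True)


class TestBonferroni:
    def test_hand_computation_three_contrasts(self):
        p = np.array([0.01, 0.02, 0.5])
        assert np.allclose(inf.bonferroni(p), [0.03, 0.06, 1.0])

    def test_scalar(self):
        assert inf.bonferroni(0.004, m=6) == pytest.approx(0.024)


class TestBinDataset:
    def _fits(self):
        return pd.DataFrame({
            "subject": [0] * 4, "condition": ["T"] * 4, "roi": ["A"] * 4,
            "mu_d": [40.0, 60.0, 30.0, 30.0], "mu_n": [1.0, 2.0, 3.0, 4.0],
            "distance": [0.01, 0.02, 0.51, 0.93],
        })

    def test_bin_mean(self):
        out = inf.build_bin_dataset(self._fits())
        assert out[out.bin == 0].mean_mu_d.iloc[0] == pytest.approx(50.0)

    def test_row_count_equals_nonempty_cells(self):
        out = inf.build_bin_dataset(self._fits())
        assert len(out) == 3  # bins 0, 10, 18
        assert out.n_vertices.tolist() == [2, 1, 1]

    def test_identical_mu_pass_through(self):
        fits = self._fits()
        fits["mu_d"] = 55.0
        out = inf.build_bin_dataset(fits)
        assert (out.mean_mu_d == 55.0).all()

    def test_orientation_reversal_of_decreasing_maps(self):
        bins = pd.DataFrame({
            "subject": 0, "condition": "C", "roi": "A",
            "distance": np.linspace(0.025, 0.975, 20),
            "mean_mu_d": np.linspace(80, 20, 20),
        })
        out = inf.orient_bin_dataset(bins, "mean_mu_d")
        assert out["reversed"].all()
        slope = np.polyfit(out.distance, out.mean_mu_d, 1)[0]
        assert slope > 0


class TestEngineAgainstStatsmodels:
    def test_reml_estimates_match(self, bins_fixture):
        import statsmodels.api as sm

        des = inf.FactorCovariateDesign(sorted(bins_fixture.condition.unique()))
        X = des.matrix(bins_fixture.condition, bins_fixture.distance.to_numpy())
        y = bins_fixture.mean_mu_d.to_numpy()
        g = bins_fixture.subject.to_numpy()
        mine = inf.RandomInterceptLME(X, y, g).fit()
        ref = sm.MixedLM(y, X, groups=g).fit(reml=True)
        assert mine.sigma2 == pytest.approx(ref.scale, rel=1e-4)
        assert mine.tau2 == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), rel=1e-3)
        assert np.allclose(mine.beta, ref.fe_params, atol=1e-5)
        assert np.allclose(mine.cov_beta, np.asarray(ref.cov_params())[:8, :8],
                           rtol=1e-3, atol=1e-6)


@pytest.mark.filterwarnings("ignore")
class TestAgainstLmerTest:
    """The full Satterthwaite machinery against R's lmerTest/emmeans."""

    def test_type3_f_and_marginal_means_match_r(self, bins_fixture, tmp_path):
        csv = tmp_path / "bins.csv"
        bins_fixture.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages({{library(lmerTest); library(emmeans)}})
            d <- read.csv('{csv}')
            d$condition <- factor(d$condition)
            m <- lmer(mean_mu_d ~ condition*distance + (1|subject), data=d)
            a <- anova(m, type=3)
            e <- summary(pairs(emmeans(m, ~condition, mode='satterthwaite',
                                       lmerTest.limit=1e5), adjust='none'))
            out <- rbind(
              data.frame(what='F', term=rownames(a), v1=a$`F value`, v2=a$DenDF),
              data.frame(what='mm', term=e$contrast, v1=e$estimate, v2=e$df))
            write.csv(out, '{tmp_path / "ref.csv"}', row.names=FALSE)
        """)
        subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.csv")

        res = inf.fit_lme_condition(bins_fixture, n_boot=0)
        f_ref = ref[ref.what == "F"].set_index("term")
        for term, rname in [("condition", "condition"), ("distance", "distance"),
                            ("condition:distance", "condition:distance")]:
            row = res.anova[res.anova.term == term].iloc[0]
            assert row.F == pytest.approx(f_ref.loc[rname, "v1"], rel=1e-3)
            assert row.df2 == pytest.approx(f_ref.loc[rname, "v2"], rel=0.01)
        mm_ref = ref[ref.what == "mm"].copy()
        mm_ref["pair"] = mm_ref.term.str.replace(" - ", "-")
        mm_ref = mm_ref.set_index("pair")
        for _, row in res.mm_differences.iterrows():
            assert row.estimate == pytest.approx(mm_ref.loc[row["pair"], "v1"], rel=1e-3)
            assert row.df == pytest.approx(mm_ref.loc[row["pair"], "v2"], rel=0.01)


class TestReductionToAnova:
    def test_balanced_no_random_variance_equals_ols_anova(self):
        # pure fixed-effects data: the random intercept collapses and the
        # Type III F must equal the ordinary ANOVA F
        rng = np.random.default_rng(0)
        bins = _simulate_bins(rng, n_subjects=6, subject_sd=0.0, noise_sd=4.0)
        res = inf.fit_lme_condition(bins, compute_contrasts=False, n_boot=0)
        assert res.ols_fallback

        import statsmodels.api as sm

        des = inf.FactorCovariateDesign(sorted(bins.condition.unique()))
        X = des.matrix(bins.condition, bins.distance.to_numpy())
        ols = sm.OLS(bins.mean_mu_d.to_numpy(), X).fit()
        L = inf._term_L(des.terms, "factor", X.shape[1])
        f_ols = float(ols.f_test(L).fvalue)
        row = res.anova[res.anova.term == "condition"].iloc[0]
        assert row.F == pytest.approx(f_ols, rel=1e-6)
        assert row.df2 == len(bins) - X.shape[1]


class TestRecoveryAndEquivariance:
    def test_condition_offset_recovered_in_ci(self):
        rng = np.random.default_rng(3)
        bins = _simulate_bins(rng, cond_offsets={"T": 0, "N": 0, "C": 20, "I": 0},
                              cond_slopes={c: 30.0 for c in "TNCI"})
        res = inf.fit_lme_condition(bins, n_boot=0)
        row = res.mm_differences.set_index("pair").loc["C-T"]
        assert row.ci_low <= 20.0 <= row.ci_high
        assert row.estimate == pytest.approx(20.0, abs=3.0)

    def test_roi_lsmean_difference_recovered(self):
        rng = np.random.default_rng(4)
        rows = []
        for s in range(6):
            b = rng.normal(0, 5)
            for roi, mu0 in [("A", 40.0), ("B", 60.0)]:
                d = np.linspace(0.025, 0.975, 20)
                rows.append(pd.DataFrame({
                    "subject": s, "roi": roi, "distance": d,
                    "mean_mu_d": b + mu0 + 10 * d + rng.normal(0, 3, 20)}))
        bins = pd.concat(rows, ignore_index=True)
        res = inf.fit_lme_roi(bins, n_boot=0)
        row = res.mm_differences.set_index("pair").loc["A-B"]
        assert row.estimate == pytest.approx(-20.0, abs=3.0)
        assert row.p_bonf < 0.01

    def test_identical_rois_not_significant(self):
        rng = np.random.default_rng(5)
        rows = []
        for s in range(6):
            b = rng.normal(0, 5)
            for roi in ("A", "B"):
                d = np.linspace(0.025, 0.975, 20)
                rows.append(pd.DataFrame({
                    "subject": s, "roi": roi, "distance": d,
                    "mean_mu_d": b + 50 + 10 * d + rng.normal(0, 3, 20)}))
        bins = pd.concat(rows, ignore_index=True)
        res = inf.fit_lme_roi(bins, n_boot=0)
        assert (res.mm_differences.p_bonf > 0.05).all()

    def test_roi_relabelling_permutes_differences(self):
        rng = np.random.default_rng(6)
        rows = []
        for s in range(5):
            b = rng.normal(0, 5)
            for roi, mu0 in [("A", 40.0), ("B", 60.0)]:
                d = np.linspace(0.025, 0.975, 20)
                rows.append(pd.DataFrame({
                    "subject": s, "roi": roi, "distance": d,
                    "mean_mu_d": b + mu0 + 10 * d + rng.normal(0, 3, 20)}))
        bins = pd.concat(rows, ignore_index=True)
        res1 = inf.fit_lme_roi(bins, n_boot=0)
        swapped = bins.replace({"roi": {"A": "B", "B": "A"}})
        res2 = inf.fit_lme_roi(swapped, n_boot=0)
        a = res1.mm_differences.set_index("pair").loc["A-B", "estimate"]
        b_ = res2.mm_differences.set_index("pair").loc["A-B", "estimate"]
        assert a == pytest.approx(-b_, rel=1e-6)


class TestAspectModel:
    def _aspect_table(self, rng, effect=0.0):
        rows = []
        for s in range(6):
            b = rng.normal(0, 0.3)
            for roi in ("A", "B"):
                for cond in "TNCI":
                    mean = 4.0 + (effect if cond in "TN" else 0.0)
                    rows.append({"subject": s, "roi": roi, "condition": cond,
                                 "aspect_ratio": mean + b + rng.normal(0, 0.3)})
        return pd.DataFrame(rows)

    def test_all_equal_aspects_nothing_significant(self):
        table = self._aspect_table(np.random.default_rng(7), effect=0.0)
        res = inf.fit_lme_aspect(table)
        assert (res.mm_differences.p_bonf > 0.05).all()
        assert res.anova.set_index("term").loc["condition", "p"] > 0.05

    def test_baseline_elevation_detected_with_sign(self):
        table = self._aspect_table(np.random.default_rng(8), effect=10.0)
        res = inf.fit_lme_aspect(table)
        combined_vs_base = res.mm_differences[
            res.mm_differences.pair.isin(["C-N", "C-T", "I-N", "I-T"])]
        assert (combined_vs_base.estimate < 0).all()
        assert (combined_vs_base.p_bonf < 0.05).all()

    def test_ci_contains_point_estimate(self):
        table = self._aspect_table(np.random.default_rng(9), effect=2.0)
        res = inf.fit_lme_aspect(table)
        ok = ((res.mm_differences.ci_low <= res.mm_differences.estimate)
              & (res.mm_differences.estimate <= res.mm_differences.ci_high))
        assert ok.all()
        assert (res.mm_differences.p_bonf >= res.mm_differences.p - 1e-12).all()
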