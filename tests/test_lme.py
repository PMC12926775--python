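"""REML mixed-model engine: closed-form and GLS oracles, statsmodels
cross-check, EMM/contrast arithmetic, LRT behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clusterscan.lme import (LMEModelSpec, anova_fixed_effects,
                             bonferroni_threshold, EMMTable,
                             estimated_marginal_means, fit_lme,
                             interaction_contrasts, lrt_random_structure,
                             pairwise_contrasts, percent_change,
                             timepoint_pairs, _prepare_frame)
from clusterscan.synth import SyntheticTruth, generate_cluster_dataset

from conftest import dataset_from_cells

NESTED_HOMOSCEDASTIC = LMEModelSpec(random="nested", strata=())


def cell_mean_table(ds):
    t = ds.table
    return t.groupby(["timepoint", "unit"], observed=True)["thickness_mm"] \
            .mean().unstack()


# ---------------------------------------------------------------------------
# Oracles

class TestBalancedAnovaOracle:
    """One-way random-effects ANOVA has closed-form REML estimates."""

    @pytest.mark.parametrize("seed", [101, 102, 103])
    def test_closed_form_agreement(self, seed):
        g, m = 12, 5
        rng = np.random.default_rng(seed)
        y = (2.0 + rng.normal(0, 0.3, size=g).repeat(m)
             + rng.normal(0, 0.1, size=g * m))
        # every replicate of a group shares its scan_unit, so the scan-level
        # random intercept is the classic one-way group effect
        frame = pd.DataFrame({
            "timepoint": pd.Categorical(["BL"] * (g * m)),
            "day": 1, "session": 1,
            "scan": np.arange(g).repeat(m) + 1,
            "rmspm": 3.0,
            "thickness": y})
        spec = LMEModelSpec(include_timepoint=False, include_roi=False,
                            include_motion=False, random="scan", strata=())
        fit = fit_lme(frame, spec)

        ybar = y.reshape(g, m).mean(axis=1)
        grand = y.mean()
        msb = m * np.sum((ybar - grand) ** 2) / (g - 1)
        msw = np.sum((y.reshape(g, m) - ybar[:, None]) ** 2) / (g * (m - 1))
        assert msb > msw  # interior REML solution required for closed forms
        sigma_a2 = (msb - msw) / m

        assert fit.beta[0] == pytest.approx(grand, rel=1e-9)
        assert fit.sigma2 == pytest.approx(msw, rel=1e-6)
        assert fit.varcomp["sigma2_scan"] == pytest.approx(sigma_a2, rel=1e-6)
        assert fit.cov[0, 0] == pytest.approx(msb / (g * m), rel=1e-6)


class TestGlsOracle:
    """At fixed variance parameters the fit is exactly GLS."""

    def test_beta_matches_direct_gls(self, default_dataset):
        ds, _ = default_dataset
        frame = _prepare_frame(ds, True)
        theta = np.array([np.log(0.3), np.log(0.2), np.log(0.5),
                          np.log(1.3), np.log(0.8), np.log(1.1),
                          np.log(0.9), np.log(1.2)])
        fit = fit_lme(ds, LMEModelSpec(), fixed_theta=theta)

        X = np.column_stack([
            np.ones(len(frame)),
            (frame["timepoint"] == "M3").astype(float),
            (frame["timepoint"] == "M6").astype(float),
            (frame["roi"] == "control").astype(float),
            ((frame["timepoint"] == "M3") & (frame["roi"] == "control"))
            .astype(float),
            ((frame["timepoint"] == "M6") & (frame["roi"] == "control"))
            .astype(float),
            frame["rmspm"].to_numpy()])
        V = np.zeros((len(frame), len(frame)))
        for gamma, col in zip(np.exp(theta[:3]),
                              ("day_unit", "sess_unit", "scan_unit")):
            Z = pd.get_dummies(frame[col]).to_numpy(dtype=float)
            V += gamma * Z @ Z.T
        strata = (frame["roi"].astype(str) + "|"
                  + frame["timepoint"].astype(str))
        names = np.sort(strata.unique())
        w = np.concatenate([[1.0], np.exp(theta[3:])])
        wmap = dict(zip(names, w))
        V += np.diag(strata.map(wmap).to_numpy() ** 2)
        Vi = np.linalg.inv(V)
        y = frame["thickness"].to_numpy()
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        np.testing.assert_allclose(fit.beta, beta, rtol=0, atol=1e-8)
        # covariance: sigma2 * (X' V^-1 X)^-1 with REML sigma2
        r = y - X @ beta
        sigma2 = float(r @ Vi @ r) / (len(y) - X.shape[1])
        cov = sigma2 * np.linalg.inv(X.T @ Vi @ X)
        np.testing.assert_allclose(fit.cov, cov, rtol=1e-8, atol=1e-12)


class TestStatsmodelsCrossCheck:
    """Independent REML implementation agrees on the nested model."""

    @pytest.mark.parametrize("seed", [7, 11])
    def test_mixedlm_agreement(self, seed):
        smf = pytest.importorskip("statsmodels.formula.api")
        truth = SyntheticTruth(sigma_day=0.02, sigma_session=0.015,
                               sigma_scan=0.01,
                               resid_sd={"core": 0.012, "control": 0.012},
                               seed=seed)
        ds, _ = generate_cluster_dataset(truth)
        fit = fit_lme(ds, NESTED_HOMOSCEDASTIC)
        assert not fit.singular
        frame = _prepare_frame(ds, True)
        frame["tp"] = frame["timepoint"].astype(str)
        md = smf.mixedlm(
            "thickness ~ C(tp, Treatment('BL')) * C(roi, Treatment('core'))"
            " + rmspm",
            frame, groups=frame["day_unit"], re_formula="1",
            vc_formula={"sess": "0 + C(sess_unit)",
                        "scan": "0 + C(scan_unit)"})
        mf = md.fit(reml=True)
        np.testing.assert_allclose(fit.beta, mf.fe_params.values, atol=1e-6)
        np.testing.assert_allclose(np.sqrt(np.diag(fit.cov)),
                                   mf.bse_fe.values, atol=1e-5)
        assert fit.sigma2 == pytest.approx(mf.scale, rel=1e-3)
        assert fit.varcomp["sigma2_day"] == \
            pytest.approx(float(mf.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-8)
        sm_vc = dict(zip(md.exog_vc.names, mf.vcomp))
        assert fit.varcomp["sigma2_session"] == \
            pytest.approx(sm_vc["sess"], rel=1e-3, abs=1e-8)
        assert fit.varcomp["sigma2_scan"] == \
            pytest.approx(sm_vc["scan"], rel=1e-3, abs=1e-8)


class TestDegenerateData:
    def test_noise_free_exact_cell_means(self, noise_free_dataset):
        ds, truth = noise_free_dataset
        fit = fit_lme(ds)
        assert fit.converged and fit.singular
        emms = estimated_marginal_means(fit)
        for (tp, roi), mu in truth.cell_means.items():
            got = emms.table.query("timepoint == @tp and roi == @roi")
            assert float(got["emm"].iloc[0]) == pytest.approx(mu, abs=1e-9)

    def test_lrt_on_degenerate_data_is_safe(self, noise_free_dataset):
        ds, _ = noise_free_dataset
        full = fit_lme(ds, LMEModelSpec())
        simple = fit_lme(ds, LMEModelSpec(random="scan"))
        res = lrt_random_structure(full, simple)
        assert res.statistic == 0.0
        assert res.p == 1.0


class TestObjective:
    @pytest.mark.parametrize("seed", [21, 22])
    def test_optimum_not_worse_than_truth(self, seed):
        truth = SyntheticTruth(sigma_day=0.01, sigma_session=0.008,
                               sigma_scan=0.012, seed=seed)
        ds, _ = generate_cluster_dataset(truth)
        fit = fit_lme(ds, NESTED_HOMOSCEDASTIC)
        # evaluate the objective at the generating variance ratios
        sigma2 = truth.resid_sd["core"] ** 2
        theta_truth = np.log(np.array([truth.sigma_day ** 2,
                                       truth.sigma_session ** 2,
                                       truth.sigma_scan ** 2]) / sigma2)
        at_truth = fit_lme(ds, NESTED_HOMOSCEDASTIC, fixed_theta=theta_truth)
        assert fit.loglik_reml >= at_truth.loglik_reml - 1e-6


# ---------------------------------------------------------------------------
# Marginal means, contrasts, percent change

class TestEmms:
    def test_balanced_emm_equals_raw_cell_means(self):
        truth = SyntheticTruth(motion_effect=0.0, seed=31)
        ds, _ = generate_cluster_dataset(truth)
        fit = fit_lme(ds, LMEModelSpec(include_motion=False))
        emms = estimated_marginal_means(fit)
        raw = cell_mean_table(ds)
        for _, row in emms.table.iterrows():
            assert row["emm"] == pytest.approx(
                raw.loc[row["timepoint"], row["roi"]], abs=1e-8)

    def test_shift_equivariance(self, default_dataset):
        ds, _ = default_dataset
        fit = fit_lme(ds)
        shifted = ds.table.copy()
        shifted["thickness_mm"] = shifted["thickness_mm"] + 0.5
        from clusterscan.io import ClusterScanDataset
        ds2 = ClusterScanDataset(shifted, timepoint_order=("BL", "M3", "M6"))
        fit2 = fit_lme(ds2)
        e1 = estimated_marginal_means(fit).table["emm"].to_numpy()
        e2 = estimated_marginal_means(fit2).table["emm"].to_numpy()
        np.testing.assert_allclose(e2, e1 + 0.5, atol=1e-6)

    def test_containment_dfs(self, default_dataset):
        ds, _ = default_dataset
        fit = fit_lme(ds)
        # 192 obs, 96 scans; between-scan terms: 96 - 4 = 92,
        # within-scan (ROI) terms: 192 - 96 - 3 = 93
        assert fit.df_between == 92.0
        assert fit.df_within == 93.0
        emms = estimated_marginal_means(fit)
        assert set(emms.table["df"]) == {92.0, 93.0}


class TestContrasts:
    def test_pairwise_equals_emm_differences(self, default_dataset):
        ds, _ = default_dataset
        fit = fit_lme(ds)
        emms = estimated_marginal_means(fit).table
        cons = pairwise_contrasts(fit)
        assert len(cons) == 6
        for con in cons:
            pair, roi = con.label.split(" | ")
            earlier, later = pair.split("-")
            e = emms.query("timepoint == @earlier and roi == @roi")["emm"]
            l = emms.query("timepoint == @later and roi == @roi")["emm"]
            # positive delta = thinning (earlier minus later)
            assert con.delta == pytest.approx(float(e.iloc[0])
                                              - float(l.iloc[0]), abs=1e-12)
            assert con.family_size == 6
            assert con.p_adjusted == pytest.approx(min(1.0, 6 * con.p_raw))

    def test_interaction_contrast_worked_examples(self):
        # cell means embedding the printed declines: core falls 0.029 then
        # 0.041; control falls 0.008 then 0.010 -> differential atrophy
        # 0.021 mm (3 mo) and 0.031 mm (6 mo)
        ds = dataset_from_cells({
            ("BL", "core"): 1.810, ("M3", "core"): 1.781,
            ("M6", "core"): 1.769,
            ("BL", "control"): 2.150, ("M3", "control"): 2.142,
            ("M6", "control"): 2.140})
        fit = fit_lme(ds)
        ics = interaction_contrasts(fit)
        by_pair = {c.label.split(" | ")[0]: c.delta for c in ics}
        assert by_pair["BL-M3"] == pytest.approx(0.021, abs=1e-9)
        assert by_pair["BL-M6"] == pytest.approx(0.031, abs=1e-9)
        assert all(c.family_size == 3 for c in ics)

    def test_bonferroni_thresholds(self):
        assert round(bonferroni_threshold(0.05, 6), 3) == 0.008
        assert round(bonferroni_threshold(0.05, 3), 3) == 0.017

    def test_timepoint_pairs_order(self):
        assert timepoint_pairs(("BL", "M3", "M6")) == \
            [("BL", "M3"), ("BL", "M6"), ("M3", "M6")]


class TestPercentChange:
    def make_emms(self, ref, later):
        t = pd.DataFrame({"timepoint": ["BL", "M6"], "roi": ["core", "core"],
                          "emm": [ref, later], "se": 0.01, "df": 92.0,
                          "ci_lo": 0.0, "ci_hi": 0.0})
        return EMMTable(t)

    def test_worked_example(self):
        emms = self.make_emms(2.00, 1.90)
        assert percent_change(emms, ("BL", "M6"), "core") == -5.0

    def test_zero_change(self):
        emms = self.make_emms(2.00, 2.00)
        assert percent_change(emms, ("BL", "M6"), "core") == 0.0

    def test_printed_table_consistency(self):
        # reference EMM 1.81 mm with a 0.050 mm decline -> -2.8 percent
        emms = self.make_emms(1.81, 1.81 - 0.050)
        assert percent_change(emms, ("BL", "M6"), "core") == -2.8


# ---------------------------------------------------------------------------
# F tests and LRT

class TestAnova:
    def test_structure(self, default_dataset):
        ds, _ = default_dataset
        fit = fit_lme(ds)
        tab = anova_fixed_effects(fit)
        assert list(tab["term"]) == ["timepoint", "roi", "motion",
                                     "timepoint:roi"]
        assert list(tab["df_num"]) == [2, 1, 1, 2]
        assert list(tab["df_den"]) == [92.0, 93.0, 92.0, 93.0]

    def test_null_calibration(self):
        """Marginal F p-values for Timepoint are ~Uniform(0,1) under a
        no-effect truth (KS test over 120 seeded replicates)."""
        cells = {(tp, roi): mu for tp in ("BL", "M3", "M6")
                 for roi, mu in (("core", 1.8), ("control", 2.3))}
        pvals = []
        for rep in range(120):
            truth = SyntheticTruth(cell_means=cells, motion_effect=0.0,
                                   seed=40_000 + rep)
            ds, _ = generate_cluster_dataset(truth, design=(3, 2, 2, 4))
            fit = fit_lme(ds)
            tab = anova_fixed_effects(fit)
            pvals.append(float(tab.loc[tab["term"] == "timepoint",
                                       "p"].iloc[0]))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_at_default_effects(self):
        """Default (paper-scale) decline gives overwhelming Timepoint
        evidence in most replicates; with only 2 days per timepoint the
        day-level variance occasionally inflates a replicate's p."""
        pvals = []
        for rep in range(20):
            ds, _ = generate_cluster_dataset(SyntheticTruth(seed=900 + rep))
            tab = anova_fixed_effects(fit_lme(ds))
            pvals.append(float(tab.loc[tab["term"] == "timepoint",
                                       "p"].iloc[0]))
        assert np.median(pvals) < 1e-6
        assert sum(p < 1e-3 for p in pvals) >= 16


class TestLrt:
    def test_null_prefers_simple(self):
        """With no day/session variance the nested model should rarely be
        selected (chi2(2) test at alpha=.05)."""
        retained = 0
        n_rep = 60
        for rep in range(n_rep):
            truth = SyntheticTruth(sigma_day=0.0, sigma_session=0.0,
                                   seed=50_000 + rep)
            ds, _ = generate_cluster_dataset(truth, design=(3, 2, 2, 4))
            full = fit_lme(ds, LMEModelSpec())
            simple = fit_lme(ds, LMEModelSpec(random="scan"))
            if lrt_random_structure(full, simple).retain_simple:
                retained += 1
        assert retained >= int(0.9 * n_rep)

    def test_alternative_prefers_full(self):
        """Large day/session variance should reject the scan-only model."""
        kept_full = 0
        n_rep = 30
        for rep in range(n_rep):
            truth = SyntheticTruth(sigma_day=0.05, sigma_session=0.04,
                                   seed=60_000 + rep)
            ds, _ = generate_cluster_dataset(truth)
            full = fit_lme(ds, LMEModelSpec())
            simple = fit_lme(ds, LMEModelSpec(random="scan"))
            if not lrt_random_structure(full, simple).retain_simple:
                kept_full += 1
        assert kept_full >= int(0.9 * n_rep)

    def test_mismatched_fits_rejected(self, default_dataset):
        ds, _ = default_dataset
        other, _ = generate_cluster_dataset(SyntheticTruth(seed=77))
        full = fit_lme(ds)
        simple = fit_lme(other, LMEModelSpec(random="scan"))
        with pytest.raises(Exception):
            lrt_random_structure(full, simple)
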