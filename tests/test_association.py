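"""Association models and Benjamini-Hochberg adjustment."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from afnet.association import (ModelSpec, bh_fdr, fit_incident,
                               fit_medication, fit_prevalent)
from afnet.config import SimulationConfig
from afnet.simulate import simulate_cohort, simulate_incident_gene


def brute_force_bh(p):
    """Direct step-up definition: q_(i) = min_{j>=i} p_(j) * m / j, capped."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        vals = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        q[idx] = max(min(1.0, min(vals)), p[idx])  # q >= p analytically
    return q


class TestBHFDR:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 200))
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), rtol=0, atol=0)

    def test_matches_statsmodels(self, rng):
        p = rng.random(500)
        from statsmodels.stats.multitest import multipletests

        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), q_ref, rtol=1e-12)

    def test_invariants(self, rng):
        p = rng.random(100)
        q = bh_fdr(p)
        assert (q >= p).all() and (q <= 1).all()
        # order equivariance: permuting the input permutes the output
        perm = rng.permutation(100)
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm])

    def test_single_p_is_identity(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [np.nan], [-0.1]])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(bad)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0,
                              allow_nan=False), min_size=1, max_size=60))
    def test_stepup_properties_hold_for_arbitrary_pvectors(self, p_list):
        p = np.asarray(p_list)
        q = bh_fdr(p)
        assert (q >= p).all() and (q <= 1.0).all()
        # q is monotone non-decreasing in p-rank
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()
        np.testing.assert_allclose(q, brute_force_bh(p), atol=0)


class TestPrevalent:
    def test_zero_family_variance_matches_ols(self):
        cfg = SimulationConfig(n_samples=300, n_families=100, n_genes=20,
                               n_signal_genes=5, planted_module_size=3,
                               gene_set_size_range=(5, 15),
                               family_sd=0.0, seed=21)
        expr, samples, _ = simulate_cohort(cfg)
        res = fit_prevalent(expr, samples)

        sub = samples[samples["af_group"].isin(["prevalent", "none"])].copy()
        af = (sub["af_group"] == "prevalent").astype(float).to_numpy()
        sex = sub["sex"].map({"female": 0, "male": 1}).to_numpy(float)
        X = np.column_stack([np.ones(len(sub)), af, sub["age"].to_numpy(float), sex])
        from afnet.lmm import RandomInterceptModel

        from statsmodels.regression.mixed_linear_model import MixedLM

        model = RandomInterceptModel(X, sub["pedigree_id"].to_numpy())
        groups = sub["pedigree_id"].to_numpy()
        n_exact = 0
        for _, row in res.iterrows():
            y = expr.loc[row["feature_id"], sub["sample_id"]].to_numpy(float)
            fit = model.fit(y)
            if fit.sigma_f2 == 0.0:
                # Variance estimate on the zero boundary: exact OLS collapse.
                ols = sm.OLS(y, X).fit()
                assert abs(row["effect"] - ols.params[1]) < 1e-6
                n_exact += 1
            else:
                # True variance is zero but REML estimates a small positive
                # value from noise; the fit must then agree with a general
                # mixed-model implementation, not with OLS.
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ref = MixedLM(y, X, groups=groups).fit(reml=True)
                assert abs(row["effect"] - ref.fe_params[1]) < 1e-4
        assert n_exact >= len(res) // 4

    def test_effect_recovery_over_seeds(self):
        # Parameter-recovery oracle: mean estimated AF effect of unboosted
        # signal genes within +-0.02 of the true 0.15 log2 shift.
        estimates = []
        for seed in range(20):
            cfg = SimulationConfig(seed=seed)
            expr, samples, signal = simulate_cohort(cfg)
            plain = signal[cfg.planted_module_size:]  # shift exactly 0.15
            res = fit_prevalent(expr.loc[plain], samples)
            estimates.extend(res["effect"].tolist())
        assert abs(np.mean(estimates) - 0.15) < 0.02

    def test_constant_feature_flagged(self, small_cohort):
        expr, samples, _ = small_cohort
        expr = expr.iloc[:3].copy()
        expr.iloc[0] = 5.0
        res = fit_prevalent(expr, samples)
        row = res.iloc[0]
        assert row["status"] == "constant"
        assert row["p"] == 1.0 and row["effect"] == 0.0

    def test_requires_two_samples_per_group(self, small_cohort):
        expr, samples, _ = small_cohort
        referents_only = samples[samples["af_group"] == "none"]
        with pytest.raises(ValueError, match="AF group"):
            fit_prevalent(expr.iloc[:2], referents_only)

    def test_unknown_covariate_rejected(self, small_cohort):
        expr, samples, _ = small_cohort
        spec = ModelSpec(covariate_set="age_sex", extra_covariates=("nonexistent",))
        with pytest.raises(ValueError, match="nonexistent"):
            fit_prevalent(expr.iloc[:2], samples, spec)

    def test_full_risk_factor_adjustment_runs(self, small_cohort):
        expr, samples, _ = small_cohort
        spec = ModelSpec(covariate_set="full_risk_factors")
        res = fit_prevalent(expr.iloc[:5], samples, spec)
        assert (res["status"] == "ok").all()
        assert res["se"].gt(0).all()


class TestMedication:
    def test_flag_equal_to_af_indicator_reproduces_prevalent_fit(self, small_cohort):
        expr, samples, _ = small_cohort
        sub = samples[samples["af_group"].isin(["prevalent", "none"])].copy()
        sub["fake_med"] = (sub["af_group"] == "prevalent").astype(int)
        expr_sub = expr[sub["sample_id"].tolist()]
        med = fit_medication(expr_sub.iloc[:10], sub, "fake_med")
        prev = fit_prevalent(expr.iloc[:10], samples)
        np.testing.assert_allclose(med["effect"], prev["effect"], atol=1e-10)
        np.testing.assert_allclose(med["p"], prev["p"], atol=1e-10)

    def test_planted_medication_effect_detected(self):
        # A 0.2 log2 shift in beta-blocker users (a quarter of the cohort)
        # is detected at q<0.05 in nearly every replicate.
        detected = 0
        for seed in range(10):
            cfg = SimulationConfig(n_samples=2000, n_families=700, n_genes=100,
                                   n_signal_genes=5, planted_module_size=3,
                                   gene_set_size_range=(10, 40),
                                   signal_effect=0.0, seed=100 + seed)
            expr, samples, _ = simulate_cohort(cfg)
            expr = expr.copy()
            users = samples["beta_blocker"].to_numpy() == 1
            expr.iloc[0] = expr.iloc[0].to_numpy() + 0.2 * users
            res = fit_medication(expr, samples, "beta_blocker")
            if res.set_index("feature_id").loc[expr.index[0], "q"] < 0.05:
                detected += 1
        assert detected >= 9

    def test_no_contrast_rejected(self, small_cohort):
        expr, samples, _ = small_cohort
        samples = samples.copy()
        samples["digoxin"] = 0
        with pytest.raises(ValueError, match="digoxin"):
            fit_medication(expr.iloc[:2], samples, "digoxin")


def _survival_samples(df: pd.DataFrame) -> pd.DataFrame:
    """Wrap the incident-gene simulator output as a SampleTable."""
    n = len(df)
    return pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "pedigree_id": [f"F{i}" for i in range(n)],
        "af_group": np.where(df["event"] == 1, "incident", "none"),
        "age": 66.0,
        "sex": "female",
        "followup_time": df["followup_time"].to_numpy(),
        "event": df["event"].to_numpy(),
    })


class TestIncident:
    def test_log_hazard_ratio_recovery(self):
        # Cox fit recovers a true log-HR of 0.5 per expression unit.
        estimates = []
        for seed in range(20):
            df = simulate_incident_gene(2000, log_hr=0.5, event_frac=0.075,
                                        seed=seed)
            samples = _survival_samples(df)
            expr = pd.DataFrame([df["expression"].to_numpy()],
                                index=pd.Index(["G0"], name="feature_id"),
                                columns=samples["sample_id"])
            res = fit_incident(expr, samples, ModelSpec(covariate_set="none"))
            estimates.append(res["effect"].iloc[0])
        assert abs(np.mean(estimates) - 0.5) < 0.1

    def test_null_pvalues_uniform_with_equal_followup(self, rng):
        # Equal follow-up times and random events: p of a null feature is
        # uniform across 50 simulated features.
        n = 300
        event = (rng.random(n) < 0.15).astype(int)
        samples = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "pedigree_id": [f"F{i}" for i in range(n)],
            "af_group": np.where(event == 1, "incident", "none"),
            "age": 66.0, "sex": "female",
            "followup_time": 5.0, "event": event,
        })
        expr = pd.DataFrame(rng.normal(0, 1, (50, n)),
                            index=pd.Index([f"G{i}" for i in range(50)],
                                           name="feature_id"),
                            columns=samples["sample_id"])
        res = fit_incident(expr, samples, ModelSpec(covariate_set="none"))
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_insufficient_events_rejected(self):
        df = simulate_incident_gene(30, log_hr=0.0, event_frac=0.03, seed=3)
        samples = _survival_samples(df)
        expr = pd.DataFrame([df["expression"].to_numpy()],
                            index=pd.Index(["G0"], name="feature_id"),
                            columns=samples["sample_id"])
        with pytest.raises(ValueError, match="insufficient events"):
            fit_incident(expr, samples, ModelSpec(covariate_set="none"))

    def test_prevalent_samples_excluded(self, small_cohort):
        expr, samples, _ = small_cohort
        res = fit_incident(expr.iloc[:3], samples,
                           ModelSpec(covariate_set="age_sex", min_events=5))
        assert (res["status"] == "ok").all()
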