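"""Design weights, clever covariate, fluctuation, standardization, EIC, PAF."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccwtmle import (
    bootstrap_paf_ci,
    clever_covariate,
    compute_paf,
    derive_weights,
    eic_inference,
    fluctuate,
    run_ccw_tmle,
    sample_case_control,
    target_and_standardize,
)
from ccwtmle._glm import expit, logit
from ccwtmle.synthetic import CaseControlSample
from ccwtmle.tmle import DesignError, InferenceError


class TestDeriveWeights:
    def test_registry_coverage_worked_example(self):
        # 1020 registered cases at 85% registry coverage -> 1200 source
        # cases; 787 sampled -> weight 1200/787 = 1.5248. 928 controls from
        # a source population of 1,346,630 -> weight 1451.1.
        dw = derive_weights(787, (1020, 0.85), 928, 1_346_630)
        assert dw.provenance["n_cases_source"] == 1200
        assert round(dw.case_weight, 4) == 1.5248
        assert round(dw.control_weight, 1) == 1451.1
        assert dw.case_weight == pytest.approx(1 / dw.q_case)
        assert dw.control_weight == pytest.approx(1 / dw.q_control)

    def test_census_gives_unit_weights(self):
        dw = derive_weights(1200, 1200, 5000, 5000)
        assert dw.case_weight == 1.0
        assert dw.control_weight == 1.0

    def test_reciprocal_arithmetic(self):
        dw = derive_weights(100, 1000, 10, 10_000)
        assert dw.case_weight == pytest.approx(10.0)
        assert dw.control_weight == pytest.approx(1000.0)

    def test_oversampling_and_bad_coverage_rejected(self):
        with pytest.raises(DesignError):
            derive_weights(1300, 1200, 10, 100)
        with pytest.raises(DesignError):
            derive_weights(100, (1020, 0.0), 10, 100)


class TestCleverCovariate:
    @pytest.mark.parametrize(
        "g,a,expected",
        [(0.5, 1, 2.0), (0.5, 0, -2.0), (0.25, 0, -4.0 / 3.0), (0.8, 1, 1.25)],
    )
    def test_formula(self, g, a, expected):
        H = clever_covariate(np.array([a]), np.array([g]))
        assert H.H[0] == pytest.approx(expected)

    def test_components_and_identity(self, rng):
        g = rng.uniform(0.05, 0.95, 50)
        a = rng.integers(0, 2, 50)
        H = clever_covariate(a, g)
        assert np.all(H.H1 > 0)
        assert np.all(H.H0 < 0)
        assert np.allclose(H.H, a * H.H1 + (1 - a) * H.H0)

    def test_degenerate_propensity_rejected(self):
        with pytest.raises(InferenceError):
            clever_covariate(np.array([1]), np.array([1.0]))


# 6-record hand fixture: (Y, Qbar0, H, weight)
_FLUCT_FIXTURE = pd.DataFrame(
    {
        "Y": [1, 0, 1, 1, 0, 0],
        "Q": [0.30, 0.10, 0.55, 0.80, 0.40, 0.05],
        "H": [2.5, -1.8, -1.6, 3.0, 2.2, -1.4],
        "w": [1.5, 12.0, 1.5, 1.5, 12.0, 12.0],
    }
)


def _grid_search_epsilon(df, lo=-5.0, hi=5.0, step=1e-5):
    """Independent oracle: maximize the weighted log-likelihood on a grid."""
    eps = np.arange(lo, hi + step, step)
    off = logit(df["Q"].to_numpy())
    p = expit(off[None, :] + eps[:, None] * df["H"].to_numpy()[None, :])
    p = np.clip(p, 1e-12, 1 - 1e-12)
    y = df["Y"].to_numpy()
    ll = (df["w"].to_numpy() * (y * np.log(p) + (1 - y) * np.log1p(-p))).sum(axis=1)
    return float(eps[np.argmax(ll)])


class TestFluctuate:
    def test_newton_matches_grid_search_oracle(self):
        df = _FLUCT_FIXTURE
        eps, converged = fluctuate(
            logit(df["Q"].to_numpy()), df["H"].to_numpy(),
            df["Y"].to_numpy(), df["w"].to_numpy(),
        )
        assert converged
        assert eps == pytest.approx(_grid_search_epsilon(df), abs=1e-4)

    def test_zero_at_saturated_empirical_fit(self, rng):
        # Qbar0 equal to the weighted empirical mean of Y within each (A, W)
        # cell already solves the score equation: epsilon must be ~0
        n = 400
        a = rng.integers(0, 2, n)
        w1 = rng.integers(0, 2, n)
        y = (rng.random(n) < 0.2 + 0.3 * a + 0.2 * w1).astype(float)
        wts = np.where(y == 1, 3.0, 40.0)
        df = pd.DataFrame({"A": a, "W": w1, "Y": y, "wt": wts})
        cell_mean = df.groupby(["A", "W"]).apply(
            lambda g: np.average(g["Y"], weights=g["wt"]), include_groups=False
        )
        q = df.set_index(["A", "W"]).index.map(cell_mean).to_numpy(dtype=float)
        g_w = df.groupby("W").apply(
            lambda g: np.average(g["A"], weights=g["wt"]), include_groups=False
        )
        ghat = df["W"].map(g_w).to_numpy(dtype=float)
        H = clever_covariate(a, ghat)
        eps, _ = fluctuate(logit(np.clip(q, 1e-9, 1 - 1e-9)), H, y, wts)
        assert abs(eps) < 1e-8

    def test_weight_scale_invariance(self):
        df = _FLUCT_FIXTURE
        args = (logit(df["Q"].to_numpy()), df["H"].to_numpy(), df["Y"].to_numpy())
        e1, _ = fluctuate(*args, df["w"].to_numpy())
        e2, _ = fluctuate(*args, 2.0 * df["w"].to_numpy())
        assert e1 == pytest.approx(e2, abs=1e-12)

    def test_zero_covariate_rejected(self):
        with pytest.raises(InferenceError):
            fluctuate(np.zeros(3), np.zeros(3), np.ones(3), np.ones(3))


class TestTargetAndStandardize:
    def test_hand_weighted_average_two_strata(self):
        # two confounder levels with hand-set updated predictions/weights
        Q1 = np.array([0.30, 0.30, 0.10, 0.10])
        Q0 = np.array([0.20, 0.20, 0.05, 0.05])
        H = clever_covariate(np.array([1, 0, 1, 0]), np.array([0.5, 0.5, 0.5, 0.5]))
        w = np.array([1.0, 3.0, 2.0, 2.0])
        psi1, psi0, *_ = target_and_standardize(logit(Q1), logit(Q0), 0.0, H, w)
        assert psi1 == pytest.approx((0.3 * 4 + 0.1 * 4) / 8)
        assert psi0 == pytest.approx((0.2 * 4 + 0.05 * 4) / 8)

    def test_equal_counterfactuals_give_null_contrast(self):
        Q = np.array([0.1, 0.4, 0.7])
        H = clever_covariate(np.array([1, 0, 1]), np.full(3, 0.5))
        psi1, psi0, *_ = target_and_standardize(logit(Q), logit(Q), 0.0, H, np.ones(3))
        assert psi1 - psi0 == pytest.approx(0.0, abs=1e-15)
        assert psi1 / psi0 == pytest.approx(1.0, abs=1e-12)

    def test_zero_epsilon_is_gformula_plugin(self, rng):
        Q1 = rng.uniform(0.05, 0.6, 30)
        Q0 = rng.uniform(0.01, 0.5, 30)
        w = rng.uniform(0.5, 5.0, 30)
        H = clever_covariate(rng.integers(0, 2, 30), rng.uniform(0.2, 0.8, 30))
        psi1, psi0, *_ = target_and_standardize(logit(Q1), logit(Q0), 0.0, H, w)
        assert psi1 == pytest.approx(np.average(Q1, weights=w))
        assert psi0 == pytest.approx(np.average(Q0, weights=w))


class TestEicInference:
    def test_all_zero_influence_collapses_interval(self):
        # Y equals the updated prediction and the counterfactuals agree:
        # every influence contribution is exactly zero
        y = np.array([1.0, 0.0, 1.0, 0.0])
        q = y.copy()
        H = clever_covariate(np.array([1, 0, 1, 0]), np.full(4, 0.5))
        inf = eic_inference(y, np.array([1, 0, 1, 0]), H, q, q, q, 0.5, 0.5,
                            np.ones(4))
        assert inf["se_rd"] == 0.0
        assert inf["ci_rd"][0] == inf["ci_rd"][1] == 0.0

    def test_weighted_mean_eic_zero_at_solution(self, one_binary_sample):
        res = run_ccw_tmle(
            one_binary_sample, confounders=["w1"], compute_paf_ci=False, seed=0
        )
        assert abs(res.eic.mean()) < 1e-6 * res.eic.std()


class TestPaf:
    def test_null_rr_gives_zero(self):
        assert compute_paf(1.0, 0.3) == 0.0

    def test_formula_forced_value(self):
        assert compute_paf(2.0, 0.5) == pytest.approx(0.25)

    def test_case_exposure_prevalence_worked_example(self):
        # Pc = 0.644 with RR = 1.6 gives 0.2415, within 0.01 of the printed
        # 24.4% (which used the unrounded RR)
        assert compute_paf(1.6, 0.644) == pytest.approx(0.2415, abs=1e-4)
        assert abs(compute_paf(1.6, 0.644) - 0.244) < 0.01

    def test_invalid_domain(self):
        with pytest.raises(InferenceError):
            compute_paf(-1.0, 0.5)
        with pytest.raises(InferenceError):
            compute_paf(1.5, 1.2)

    @given(
        rr=st.floats(0.05, 50.0, allow_nan=False),
        pc=st.floats(0.01, 1.0, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_paf_below_case_prevalence_and_sign(self, rr, pc):
        paf = compute_paf(rr, pc)
        assert paf < pc
        assert (paf <= 0) == (rr <= 1)


def _constant_sample():
    """All case rows identical and all control rows identical: any resample
    is the same multiset, so every bootstrap replicate must coincide."""
    n = 60
    df = pd.DataFrame({"Y": [1] * n + [0] * n, "A": [1] * n + [0] * n, "w1": 0})
    df["weight"] = np.where(df["Y"] == 1, 2.0, 50.0)
    return CaseControlSample(records=df, q_case=0.5, q_control=0.02)


class TestBootstrapPaf:
    def test_deterministic_under_seed(self, one_binary_sample):
        b1 = bootstrap_paf_ci(one_binary_sample, "Y", "A", ["w1"],
                              n_boot=200, seed=11)
        b2 = bootstrap_paf_ci(one_binary_sample, "Y", "A", ["w1"],
                              n_boot=200, seed=11)
        assert b1.ci == b2.ci

    def test_constant_data_degenerate_interval(self):
        s = _constant_sample()
        b = bootstrap_paf_ci(s, "Y", "A", [], n_boot=120, seed=3,
                             g_bounds=(0.01, 0.99))
        assert b.ci[0] == pytest.approx(b.ci[1], abs=1e-12)

    def test_minimum_replicates_enforced(self, one_binary_sample):
        with pytest.raises(InferenceError):
            bootstrap_paf_ci(one_binary_sample, "Y", "A", ["w1"], n_boot=10)


class TestRunPipeline:
    def test_rerun_same_seed_identical(self, one_binary_sample):
        r1 = run_ccw_tmle(one_binary_sample, confounders=["w1"],
                          n_boot=150, seed=4)
        r2 = run_ccw_tmle(one_binary_sample, confounders=["w1"],
                          n_boot=150, seed=4)
        assert r1.psi1 == r2.psi1
        assert r1.ci_rd == r2.ci_rd
        assert r1.paf.ci == r2.paf.ci

    def test_missing_column_raises(self, one_binary_sample):
        with pytest.raises(DesignError, match="nope"):
            run_ccw_tmle(one_binary_sample, confounders=["nope"])

    def test_result_identities_and_diagnostics(self, one_binary_sample):
        res = run_ccw_tmle(one_binary_sample, confounders=["w1"],
                           compute_paf_ci=False, seed=0)
        assert res.rd == res.psi1 - res.psi0
        assert res.rd_per_100k == pytest.approx(res.rd * 1e5)
        assert res.ci_rd[0] <= res.rd <= res.ci_rd[1]
        assert res.ci_rr[0] <= res.rr <= res.ci_rr[1]
        assert res.ci_rr[0] > 0
        assert res.paf.paf < res.paf.pc
        assert res.diagnostics["fluctuation_converged"]

    def test_null_effect_estimates_center_on_null(self):
        # replicated null-effect cohorts: mean RD within 3 MC SEs of zero,
        # mean log RR within 3 MC SEs of zero
        from ccwtmle import CohortSpec, ConfounderSpec, generate_cohort

        rds, logrrs = [], []
        for rep in range(40):
            spec = CohortSpec(
                n_cohort=40_000,
                age_distribution={"40-44": 1.0},
                confounders=(ConfounderSpec("w1", "binary", {"p": 0.4}),),
                exposure_coefficients={"intercept": -0.3, "w1": 0.8},
                outcome_coefficients={
                    "intercept": -4.0, "exposure": 0.0, "w1": 0.7,
                },
                seed=500 + rep,
            )
            s = sample_case_control(generate_cohort(spec), 300, 500,
                                    seed=900 + rep)
            res = run_ccw_tmle(s, confounders=["w1"], compute_paf_ci=False)
            rds.append(res.rd)
            logrrs.append(np.log(res.rr))
        for vals in (rds, logrrs):
            vals = np.asarray(vals)
            assert abs(vals.mean()) < 3 * vals.std(ddof=1) / np.sqrt(len(vals))
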