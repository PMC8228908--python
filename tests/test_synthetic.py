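"""Cohort generation, true effects, and case-control sampling."""

import numpy as np
import pandas as pd
import pytest

from ccwtmle import (
    Cohort,
    CohortSpec,
    ConfounderSpec,
    generate_cohort,
    sample_case_control,
    true_effects,
)
from ccwtmle._glm import expit
from ccwtmle.synthetic import ConfigurationError, SamplingError


def _null_spec(n=300_000, seed=11, confounded=False):
    # with confounded=False the exposure is independent of w1, so the crude
    # arm risks coincide under a null effect; with True only the estimands
    # (not the crude contrast) are null
    return CohortSpec(
        n_cohort=n,
        age_distribution={"40-44": 1.0},
        confounders=(ConfounderSpec("w1", "binary", {"p": 0.4}),),
        exposure_coefficients={"intercept": -0.3, "w1": 0.8 if confounded else 0.0},
        outcome_coefficients={"intercept": -3.5, "exposure": 0.0, "w1": 0.7},
        seed=seed,
    )


class TestGenerateCohort:
    def test_deterministic_under_seed(self, one_binary_spec):
        a = generate_cohort(one_binary_spec).records
        b = generate_cohort(one_binary_spec).records
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_null_exposure_effect_gives_equal_arm_risks(self):
        coh = generate_cohort(_null_spec()).records
        p1 = coh.loc[coh.A == 1, "Y"].mean()
        p0 = coh.loc[coh.A == 0, "Y"].mean()
        se = np.sqrt(
            p1 * (1 - p1) / (coh.A == 1).sum() + p0 * (1 - p0) / (coh.A == 0).sum()
        )
        assert abs(p1 - p0) < 3 * se

    def test_marginal_risk_matches_closed_form_mixture(self, one_binary_spec):
        # sum over the four (a, w) cells of the generating logistic model
        coh = generate_cohort(one_binary_spec).records
        pw = 0.4
        total = 0.0
        for w in (0, 1):
            g = expit(np.array(-0.3 + 0.8 * w))
            for a in (0, 1):
                risk = expit(np.array(-4.0 + 0.6 * a + 0.7 * w))
                p_aw = (pw if w else 1 - pw) * (g if a else 1 - g)
                total += p_aw * risk
        emp = coh.Y.mean()
        se = np.sqrt(total * (1 - total) / len(coh))
        assert abs(emp - total) < 3 * se

    def test_columns_and_binary_invariants(self, one_binary_spec):
        coh = generate_cohort(one_binary_spec)
        assert len(coh.records) == one_binary_spec.n_cohort
        assert set(coh.records.columns) == {
            "id", "age_stratum", "age_z", "w1", "A", "Y",
        }
        assert set(np.unique(coh.records.A)) <= {0, 1}
        assert set(np.unique(coh.records.Y)) <= {0, 1}


class TestSpecValidation:
    def test_stratum_probs_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="sum"):
            CohortSpec(n_cohort=10, age_distribution={"a": 0.5, "b": 0.4})

    def test_unknown_distribution_family_names_field(self):
        with pytest.raises(ConfigurationError, match="w1.*gamma|gamma"):
            ConfounderSpec("w1", "gamma", {"shape": 2})

    def test_coefficient_must_resolve_to_confounder(self):
        with pytest.raises(ConfigurationError, match="nope"):
            CohortSpec(
                n_cohort=10,
                age_distribution={"a": 1.0},
                exposure_coefficients={"intercept": 0.0, "nope": 1.0},
            )

    def test_yaml_roundtrip(self, one_binary_spec):
        again = CohortSpec.from_yaml(one_binary_spec.to_yaml())
        assert again == one_binary_spec


class TestTrueEffects:
    def test_null_effect_exact_zero_under_enumeration(self):
        te = true_effects(_null_spec(confounded=True))
        assert te.rd == pytest.approx(0.0, abs=1e-15)
        assert te.rr == pytest.approx(1.0, abs=1e-12)
        assert te.paf == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_enumeration_single_binary_confounder(
        self, one_binary_spec
    ):
        # independent oracle: direct sum over the two confounder levels
        pw = 0.4
        psi1 = psi0 = py = 0.0
        for w in (0, 1):
            p_w = pw if w else 1 - pw
            g = expit(np.array(-0.3 + 0.8 * w))
            r1 = expit(np.array(-4.0 + 0.6 + 0.7 * w))
            r0 = expit(np.array(-4.0 + 0.7 * w))
            psi1 += p_w * r1
            psi0 += p_w * r0
            py += p_w * (g * r1 + (1 - g) * r0)
        te = true_effects(one_binary_spec)
        assert te.psi1 == pytest.approx(float(psi1), abs=1e-12)
        assert te.psi0 == pytest.approx(float(psi0), abs=1e-12)
        assert te.paf == pytest.approx(float((py - psi0) / py), abs=1e-12)

    def test_monte_carlo_agrees_with_enumeration(self, one_binary_spec):
        # a zero-variance continuous confounder forces the MC path but adds
        # nothing to the estimand, so MC must agree with the enumeration of
        # the discrete spec within Monte-Carlo error
        d = one_binary_spec.to_dict()
        d["confounders"].append(
            {"name": "z0", "kind": "continuous", "params": {"mean": 0.5, "sd": 0.4}}
        )
        d["outcome_coefficients"]["z0"] = 0.0
        mc = true_effects(CohortSpec.from_dict(d), n_mc=200_000)
        exact = true_effects(one_binary_spec)
        tol = 3 * 0.016 / np.sqrt(2e5)  # 3 SE, sd of cell risks ~0.016
        assert mc.psi1 == pytest.approx(exact.psi1, abs=tol)
        assert mc.psi0 == pytest.approx(exact.psi0, abs=tol)

    def test_mc_size_floor(self, one_binary_spec):
        d = one_binary_spec.to_dict()
        d["confounders"].append(
            {"name": "z0", "kind": "continuous", "params": {"mean": 0, "sd": 1}}
        )
        with pytest.raises(ConfigurationError, match="n_mc"):
            true_effects(CohortSpec.from_dict(d), n_mc=100)


def _toy_cohort(n_cases=1200, n_controls=4000, seed=0):
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "age_stratum": rng.choice(["40-44", "45-49", "50-54"], size=n),
            "A": rng.integers(0, 2, size=n),
            "Y": np.r_[np.ones(n_cases, int), np.zeros(n_controls, int)],
        }
    )
    spec = CohortSpec(n_cohort=n, age_distribution={"40-44": 1.0})
    return Cohort(records=df, spec=spec)


class TestSampleCaseControl:
    def test_sampling_fractions_and_weights(self):
        # 787 of 1200 source cases: the case weight is 1200/787 = 1.5248
        cohort = _toy_cohort()
        s = sample_case_control(cohort, 787, 928, seed=1)
        assert s.q_case == pytest.approx(787 / 1200)
        assert s.case_weight == pytest.approx(1200 / 787)
        assert round(s.case_weight, 4) == 1.5248
        w = s.records["weight"]
        assert np.allclose(w[s.records.Y == 1], 1 / s.q_case)
        assert np.allclose(w[s.records.Y == 0], 1 / s.q_control)
        assert s.records["id"].isin(cohort.records["id"]).all()

    def test_census_sample_has_unit_weights(self):
        cohort = _toy_cohort(n_cases=50, n_controls=80)
        s = sample_case_control(cohort, 50, 80, seed=2)
        assert np.allclose(s.records["weight"], 1.0)
        assert len(s.records) == 130

    def test_frequency_matching_aligns_stratum_tables(self):
        cohort = _toy_cohort(n_cases=600, n_controls=5000, seed=3)
        s = sample_case_control(cohort, 300, 300, match_on="age_stratum", seed=4)
        rec = s.records
        cases = rec[rec.Y == 1]["age_stratum"].value_counts()
        ctrls = rec[rec.Y == 0]["age_stratum"].value_counts()
        diff = (cases - ctrls).abs().max()
        assert diff <= 1  # identical up to largest-remainder rounding

    def test_insufficient_stratum_raises_naming_stratum(self):
        # all cases in one age band, but almost no controls there
        df = pd.DataFrame(
            {
                "id": np.arange(220),
                "age_stratum": ["40-44"] * 100 + ["40-44"] * 2 + ["50-54"] * 118,
                "A": 0,
                "Y": [1] * 100 + [0] * 120,
            }
        )
        spec = CohortSpec(n_cohort=220, age_distribution={"40-44": 1.0})
        cohort = Cohort(records=df, spec=spec)
        with pytest.raises(SamplingError, match="40-44"):
            sample_case_control(cohort, 50, 50, match_on="age_stratum", seed=6)

    def test_requesting_too_many_cases_raises(self):
        cohort = _toy_cohort(n_cases=100, n_controls=100)
        with pytest.raises(SamplingError, match="cases"):
            sample_case_control(cohort, 500, 10)

    def test_weighted_means_recover_cohort_means(self, one_binary_spec):
        cohort = generate_cohort(one_binary_spec)
        s = sample_case_control(cohort, 800, 5000, seed=9)
        col = "w1"
        target = cohort.records[col].mean()
        w = s.records["weight"].to_numpy()
        est = np.average(s.records[col], weights=w)
        # dominated by the control draw: n_eff ~ number of controls
        se = cohort.records[col].std() / np.sqrt(5000)
        assert abs(est - target) < 3 * se

    def test_sample_csv_roundtrip(self, tmp_path, one_binary_sample):
        p = tmp_path / "s.csv"
        one_binary_sample.to_csv(p)
        back = pd.read_csv(p)
        assert len(back) == one_binary_sample.n
        assert np.allclose(back["weight"], one_binary_sample.records["weight"])
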