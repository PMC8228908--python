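"""Synthetic source cohorts and biased case-control sampling.

The study data this package targets are individual records from a rare-disease
case-control study nested in a well-defined source population: confounders
(age in 5-year bands plus mixed-type covariates), a binary exposure whose
probability depends on the confounders, and a rare binary outcome depending on
exposure and confounders. Cases are (almost) fully ascertained while controls
are a tiny fraction of the population, optionally frequency-matched to the
cases on age band. Because such registry data are not redistributable, this
module generates cohorts with a *known* causal mechanism so that every
downstream estimator can be checked against ground truth.

All randomness flows from a single integer seed through a named
`numpy.random.Generator`; nothing touches global state.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._glm import expit

__all__ = [
    "ConfounderSpec",
    "CohortSpec",
    "Cohort",
    "TrueEffects",
    "CaseControlSample",
    "generate_cohort",
    "true_effects",
    "sample_case_control",
    "default_cohort_spec",
]


class ConfigurationError(ValueError):
    """A cohort or analysis specification is internally inconsistent."""


class SamplingError(RuntimeError):
    """The requested case-control sample cannot be drawn from the cohort."""


# --------------------------------------------------------------------------
# Specifications


@dataclass(frozen=True)
class ConfounderSpec:
    """One baseline covariate of the source cohort.

    kind:
        "binary"      params: p, or p_by_stratum {age band -> p}
        "categorical" params: levels [..], probs [..] or probs_by_stratum
        "continuous"  params: mean, sd, or mean_by_stratum (Gaussian)

    Stratum-specific parameters tie the covariate to age, which is what makes
    an age-matched design non-ignorable without design weights.
    """

    name: str
    kind: str
    params: dict

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical", "continuous"):
            raise ConfigurationError(
                f"confounder {self.name!r}: unknown distribution family {self.kind!r}"
            )

    def levels(self) -> list:
        if self.kind == "binary":
            return [0, 1]
        if self.kind == "categorical":
            return list(self.params["levels"])
        raise ConfigurationError(
            f"confounder {self.name!r} is continuous and has no finite level set"
        )


def _age_numeric(label: str) -> float:
    """Midpoint of a 5-year band label like '20-24'; open bands '75+' -> lo+2."""
    s = str(label)
    if s.endswith("+"):
        return float(s[:-1]) + 2.0
    lo, _, hi = s.partition("-")
    return (float(lo) + float(hi)) / 2.0


@dataclass(frozen=True)
class CohortSpec:
    """Generating mechanism of a source cohort.

    The exposure and outcome models are logistic:

        logit P(A=1 | age, W) = a0 + a_age * age_z + sum_j a_j * x_j
        logit P(Y=1 | A, age, W) = b0 + b_A * A + b_age * age_z + sum_j b_j * x_j

    where age_z = (age midpoint - 45) / 10 and x_j are the confounder columns
    (categorical confounders contribute one term per non-reference level,
    addressed as "name=level" in the coefficient maps).
    """

    n_cohort: int
    age_distribution: Mapping[str, float]
    confounders: Sequence[ConfounderSpec] = ()
    exposure_coefficients: Mapping[str, float] = field(default_factory=dict)
    outcome_coefficients: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohort < 1:
            raise ConfigurationError("n_cohort must be >= 1")
        total = float(sum(self.age_distribution.values()))
        if abs(total - 1.0) > 1e-12:
            raise ConfigurationError(
                f"age stratum probabilities sum to {total!r}, not 1"
            )
        names = {c.name for c in self.confounders}
        if len(names) != len(self.confounders):
            raise ConfigurationError("duplicate confounder names")
        reserved = {"intercept", "age", "exposure"}
        for which, coeffs in (
            ("exposure_coefficients", self.exposure_coefficients),
            ("outcome_coefficients", self.outcome_coefficients),
        ):
            for key in coeffs:
                if key in reserved:
                    continue
                base = key.split("=", 1)[0]
                if base not in names:
                    raise ConfigurationError(
                        f"{which}: coefficient {key!r} does not resolve to a "
                        f"declared confounder"
                    )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_cohort": self.n_cohort,
            "age_distribution": dict(self.age_distribution),
            "confounders": [
                {"name": c.name, "kind": c.kind, "params": c.params}
                for c in self.confounders
            ],
            "exposure_coefficients": dict(self.exposure_coefficients),
            "outcome_coefficients": dict(self.outcome_coefficients),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        return cls(
            n_cohort=int(d["n_cohort"]),
            age_distribution=dict(d["age_distribution"]),
            confounders=tuple(
                ConfounderSpec(c["name"], c["kind"], dict(c["params"]))
                for c in d.get("confounders", [])
            ),
            exposure_coefficients=dict(d.get("exposure_coefficients", {})),
            outcome_coefficients=dict(d.get("outcome_coefficients", {})),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortSpec":
        return cls.from_dict(yaml.safe_load(io.StringIO(text)))

    @property
    def confounder_names(self) -> list[str]:
        return [c.name for c in self.confounders]


# --------------------------------------------------------------------------
# Realized data containers


@dataclass
class Cohort:
    """A realized source population (one row per member)."""

    records: pd.DataFrame
    spec: CohortSpec

    @property
    def n(self) -> int:
        return len(self.records)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


@dataclass(frozen=True)
class TrueEffects:
    """Marginal estimands implied by a generating mechanism."""

    psi1: float
    psi0: float
    p_outcome: float

    @property
    def rd(self) -> float:
        return self.psi1 - self.psi0

    @property
    def rr(self) -> float:
        return self.psi1 / self.psi0

    @property
    def paf(self) -> float:
        return (self.p_outcome - self.psi0) / self.p_outcome


@dataclass
class CaseControlSample:
    """A biased sample with per-record design weights.

    weight = 1/q_case on case rows (Y=1) and 1/q_control on control rows,
    the reciprocals of the status-specific sampling fractions.
    """

    records: pd.DataFrame
    q_case: float
    q_control: float
    matching_variable: str | None = None

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def case_weight(self) -> float:
        return 1.0 / self.q_case

    @property
    def control_weight(self) -> float:
        return 1.0 / self.q_control

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Generation


def _draw_confounder(
    c: ConfounderSpec, strata: np.ndarray, labels: list[str], rng: np.random.Generator
) -> np.ndarray:
    n = len(strata)
    p = c.params
    if c.kind == "binary":
        if "p_by_stratum" in p:
            probs = np.array([p["p_by_stratum"][labels[s]] for s in strata])
        else:
            probs = np.full(n, float(p["p"]))
        return (rng.random(n) < probs).astype(int)
    if c.kind == "continuous":
        sd = float(p.get("sd", 1.0))
        if "mean_by_stratum" in p:
            means = np.array([p["mean_by_stratum"][labels[s]] for s in strata])
        else:
            means = np.full(n, float(p.get("mean", 0.0)))
        return means + sd * rng.standard_normal(n)
    if c.kind == "categorical":
        levels = list(p["levels"])
        out = np.empty(n, dtype=object)
        if "probs_by_stratum" in p:
            for s, lab in enumerate(labels):
                mask = strata == s
                if mask.any():
                    out[mask] = rng.choice(
                        levels, size=int(mask.sum()), p=p["probs_by_stratum"][lab]
                    )
        else:
            out[:] = rng.choice(levels, size=n, p=list(p["probs"]))
        return out
    raise ConfigurationError(
        f"confounder {c.name!r}: unknown distribution family {c.kind!r}"
    )


def _linear_predictor(
    coeffs: Mapping[str, float],
    table: pd.DataFrame,
    spec: CohortSpec,
    exposure: np.ndarray | None = None,
) -> np.ndarray:
    eta = np.full(len(table), float(coeffs.get("intercept", 0.0)))
    if "age" in coeffs:
        eta += coeffs["age"] * table["age_z"].to_numpy(dtype=float)
    if exposure is not None and "exposure" in coeffs:
        eta += coeffs["exposure"] * np.asarray(exposure, dtype=float)
    kinds = {c.name: c.kind for c in spec.confounders}
    for key, b in coeffs.items():
        if key in ("intercept", "age", "exposure"):
            continue
        name, sep, level = key.partition("=")
        col = table[name]
        if sep:
            eta += b * (col.astype(str) == level).to_numpy(dtype=float)
        elif kinds[name] == "categorical":
            raise ConfigurationError(
                f"coefficient {key!r}: categorical confounder needs 'name=level'"
            )
        else:
            eta += b * col.to_numpy(dtype=float)
    return eta


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw the source population implied by ``spec`` (reproducible by seed)."""
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.age_distribution.keys())
    probs = np.array([spec.age_distribution[k] for k in labels], dtype=float)
    n = spec.n_cohort

    strata = rng.choice(len(labels), size=n, p=probs)
    tab = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "age_stratum": pd.Categorical.from_codes(strata, categories=labels),
        }
    )
    age_num = np.array([_age_numeric(lab) for lab in labels])
    tab["age_z"] = (age_num[strata] - 45.0) / 10.0
    for c in spec.confounders:
        tab[c.name] = _draw_confounder(c, strata, labels, rng)

    eta_a = _linear_predictor(spec.exposure_coefficients, tab, spec)
    tab["A"] = (rng.random(n) < expit(eta_a)).astype(int)
    eta_y = _linear_predictor(
        spec.outcome_coefficients, tab, spec, exposure=tab["A"].to_numpy()
    )
    tab["Y"] = (rng.random(n) < expit(eta_y)).astype(int)
    return Cohort(records=tab, spec=spec)


# --------------------------------------------------------------------------
# True effects


def _enumerate_cells(spec: CohortSpec) -> pd.DataFrame:
    """Joint distribution over (age stratum x discrete confounder) cells."""
    labels = list(spec.age_distribution.keys())
    frames = []
    for s, lab in enumerate(labels):
        cells = pd.DataFrame(
            {"age_stratum": [lab], "age_z": [(_age_numeric(lab) - 45.0) / 10.0]}
        )
        cells["prob"] = spec.age_distribution[lab]
        for c in spec.confounders:
            p = c.params
            if c.kind == "binary":
                pr1 = p["p_by_stratum"][lab] if "p_by_stratum" in p else p["p"]
                lev = pd.DataFrame({c.name: [0, 1], "_pl": [1 - pr1, pr1]})
            else:
                levels = list(p["levels"])
                pvec = (
                    p["probs_by_stratum"][lab]
                    if "probs_by_stratum" in p
                    else p["probs"]
                )
                lev = pd.DataFrame({c.name: levels, "_pl": list(pvec)})
            cells = cells.merge(lev, how="cross")
            cells["prob"] *= cells.pop("_pl")
        frames.append(cells)
    return pd.concat(frames, ignore_index=True)


def true_effects(spec: CohortSpec, n_mc: int = 1_000_000) -> TrueEffects:
    """Marginal risks under forced exposure, exactly where possible.

    With only discrete confounders the (age, W) distribution is enumerated and
    the result is exact; otherwise ``n_mc`` Monte-Carlo draws of the covariates
    are averaged (n_mc >= 10**4 required).
    """
    discrete = all(c.kind in ("binary", "categorical") for c in spec.confounders)
    if discrete:
        cells = _enumerate_cells(spec)
        pw = cells["prob"].to_numpy()
    else:
        if n_mc < 10_000:
            raise ConfigurationError("n_mc must be >= 10**4")
        rng = np.random.default_rng(spec.seed + 2_000_003)
        labels = list(spec.age_distribution.keys())
        probs = np.array([spec.age_distribution[k] for k in labels])
        strata = rng.choice(len(labels), size=n_mc, p=probs)
        cells = pd.DataFrame(
            {"age_stratum": pd.Categorical.from_codes(strata, categories=labels)}
        )
        age_num = np.array([_age_numeric(lab) for lab in labels])
        cells["age_z"] = (age_num[strata] - 45.0) / 10.0
        for c in spec.confounders:
            cells[c.name] = _draw_confounder(c, strata, labels, rng)
        pw = np.full(n_mc, 1.0 / n_mc)

    g = expit(_linear_predictor(spec.exposure_coefficients, cells, spec))
    ones = np.ones(len(cells))
    r1 = expit(
        _linear_predictor(spec.outcome_coefficients, cells, spec, exposure=ones)
    )
    r0 = expit(
        _linear_predictor(spec.outcome_coefficients, cells, spec, exposure=0 * ones)
    )
    psi1 = float(pw @ r1)
    psi0 = float(pw @ r0)
    p_outcome = float(pw @ (g * r1 + (1 - g) * r0))
    return TrueEffects(psi1=psi1, psi0=psi0, p_outcome=p_outcome)


# --------------------------------------------------------------------------
# Case-control sampling


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of `total` proportional to `targets` (sum to total)."""
    share = targets / targets.sum() * total
    base = np.floor(share).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(share - base), kind="stable")
        base[order[:short]] += 1
    return base


def sample_case_control(
    cohort: Cohort,
    n_cases: int,
    n_controls: int,
    match_on: str | None = None,
    seed: int = 0,
) -> CaseControlSample:
    """Draw a case-control sample from a realized cohort.

    Cases are sampled uniformly without replacement. Without matching,
    controls are likewise uniform; with ``match_on`` set to a discrete column
    (typically ``age_stratum``), control counts per stratum follow the sampled
    cases' stratum distribution, allocated by largest-remainder rounding —
    frequency matching as practised in registry-based studies.

    Sampling fractions are status-marginal (q_case = n_cases / cohort cases,
    q_control = n_controls / cohort controls) and the design weights are their
    reciprocals, mirroring how such weights are derived in practice from
    registry counts rather than from the matched allocation.
    """
    rng = np.random.default_rng(seed)
    rec = cohort.records
    cases = rec.index[rec["Y"] == 1].to_numpy()
    controls = rec.index[rec["Y"] == 0].to_numpy()
    if n_cases > len(cases):
        raise SamplingError(
            f"requested {n_cases} cases but cohort contains {len(cases)}"
        )
    if n_controls > len(controls):
        raise SamplingError(
            f"requested {n_controls} controls but cohort contains {len(controls)}"
        )

    take_cases = rng.choice(cases, size=n_cases, replace=False)

    if match_on is None:
        take_controls = rng.choice(controls, size=n_controls, replace=False)
    else:
        if match_on not in rec.columns:
            raise ConfigurationError(f"matching variable {match_on!r} not a column")
        strata_counts = (
            rec.loc[take_cases, match_on].astype(str).value_counts().sort_index()
        )
        alloc = _largest_remainder(
            strata_counts.to_numpy(dtype=float), n_controls
        )
        ctrl_strata = rec.loc[controls, match_on].astype(str)
        picked = []
        for stratum, want in zip(strata_counts.index, alloc):
            pool = controls[(ctrl_strata == stratum).to_numpy()]
            if want > len(pool):
                raise SamplingError(
                    f"stratum {stratum!r}: need {want} controls, "
                    f"cohort has {len(pool)}"
                )
            if want:
                picked.append(rng.choice(pool, size=int(want), replace=False))
        take_controls = (
            np.concatenate(picked) if picked else np.empty(0, dtype=np.int64)
        )

    q_case = n_cases / len(cases)
    q_control = n_controls / len(controls)
    out = rec.loc[np.concatenate([take_cases, take_controls])].copy()
    out["weight"] = np.where(out["Y"] == 1, 1.0 / q_case, 1.0 / q_control)
    out = out.reset_index(drop=True)
    return CaseControlSample(
        records=out,
        q_case=q_case,
        q_control=q_control,
        matching_variable=match_on,
    )


# --------------------------------------------------------------------------
# Default study conditions


def default_cohort_spec(
    seed: int = 0,
    n_cohort: int = 100_000,
    exposure_log_rr: float = 0.55,
) -> CohortSpec:
    """A source cohort emulating a registry-based reproductive-factor study.

    Adult women in 5-year age bands, a binary exposure (think ever-use of a
    reproductive factor, prevalence ~0.5) that declines with age and varies
    with education, and a rare outcome (~1.5% cumulative risk over the study
    window) increasing with age. Education (categorical) and a continuous
    covariate with age-dependent mean confound both relations; a binary
    urbanicity covariate affects exposure only.
    """
    age_dist = {
        "20-24": 0.145,
        "25-29": 0.140,
        "30-34": 0.130,
        "35-39": 0.120,
        "40-44": 0.105,
        "45-49": 0.090,
        "50-54": 0.080,
        "55-59": 0.065,
        "60-64": 0.050,
        "65-69": 0.035,
        "70-74": 0.022,
        "75+": 0.018,
    }
    confounders = (
        ConfounderSpec(
            "educ",
            "categorical",
            {
                "levels": ["illiterate", "primary", "secondary", "academic"],
                "probs_by_stratum": {
                    lab: p
                    for lab, p in zip(
                        age_dist,
                        [
                            [0.10, 0.25, 0.40, 0.25],
                            [0.12, 0.28, 0.38, 0.22],
                            [0.15, 0.30, 0.37, 0.18],
                            [0.18, 0.32, 0.35, 0.15],
                            [0.22, 0.34, 0.32, 0.12],
                            [0.27, 0.35, 0.28, 0.10],
                            [0.33, 0.35, 0.24, 0.08],
                            [0.40, 0.34, 0.20, 0.06],
                            [0.47, 0.32, 0.16, 0.05],
                            [0.54, 0.30, 0.12, 0.04],
                            [0.60, 0.28, 0.09, 0.03],
                            [0.66, 0.25, 0.07, 0.02],
                        ],
                    )
                },
            },
        ),
        ConfounderSpec(
            "w_cont",
            "continuous",
            {
                "mean_by_stratum": {
                    lab: round(-0.6 + 0.11 * i, 2) for i, lab in enumerate(age_dist)
                },
                "sd": 1.0,
            },
        ),
        ConfounderSpec("urban", "binary", {"p": 0.6}),
    )
    exposure_coefficients = {
        "intercept": -0.42,
        "age": -0.30,
        "educ=primary": 0.15,
        "educ=secondary": 0.30,
        "educ=academic": 0.40,
        "w_cont": 0.20,
        "urban": 0.25,
    }
    outcome_coefficients = {
        "intercept": -4.55,
        "exposure": exposure_log_rr,
        "age": 0.55,
        "educ=primary": -0.10,
        "educ=secondary": -0.20,
        "educ=academic": -0.30,
        "w_cont": 0.25,
    }
    return CohortSpec(
        n_cohort=n_cohort,
        age_distribution=age_dist,
        confounders=confounders,
        exposure_coefficients=exposure_coefficients,
        outcome_coefficients=outcome_coefficients,
        seed=seed,
    )
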