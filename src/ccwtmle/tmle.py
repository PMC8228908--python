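"""Case-control weighted TMLE for marginal risks, RD, RR and PAF.

The estimator targets the marginal risks psi_a = E[P(Y=1 | A=a, W)] in the
source population, from a case-control sample in which cases and controls
were drawn with known (derivable) status-specific sampling fractions q1, q0.
Weighting every case by 1/q1 and every control by 1/q0 makes every weighted
empirical quantity a consistent estimate of its cohort counterpart, so the
standard TMLE sequence applies with the weights multiplied into every loss:

1. derive the design weights from registry counts;
2. fit the weighted outcome regression Qbar(A, W) by super learning;
3. fit the weighted propensity g(W) = P(A=1 | W) by super learning,
   truncated to positivity bounds;
4. form the clever covariate H = A/g(W) - (1-A)/(1-g(W));
5. fluctuate: one-parameter logistic regression of Y on H with offset
   logit Qbar and no intercept, maximizing the weighted likelihood;
6. standardize: psi_a = weighted mean of the updated predictions with A
   forced to a; RD = psi1 - psi0, RR = psi1/psi0;
7. Wald intervals from the efficient influence curve, with the RR interval
   via the delta method on the log scale.

The population attributable fraction is PAF = Pc (RR - 1) / RR with Pc the
exposure prevalence among cases, and its interval is a percentile bootstrap
resampling cases and controls separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._glm import expit, fit_weighted_logit, logit
from .superlearner import (
    LearnerSpec,
    SuperLearnerFit,
    fit_super_learner,
    predict_super_learner,
)
from .synthetic import CaseControlSample

log = logging.getLogger(__name__)

__all__ = [
    "DesignWeights",
    "CleverCovariateValues",
    "NuisanceFits",
    "PafEstimate",
    "TmleResult",
    "derive_weights",
    "clever_covariate",
    "fluctuate",
    "target_and_standardize",
    "eic_inference",
    "compute_paf",
    "bootstrap_paf_ci",
    "run_ccw_tmle",
]

Z975 = 1.959963984540054  # standard normal 97.5th percentile


class DesignError(ValueError):
    pass


class InferenceError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# Step 1: design weights


@dataclass(frozen=True)
class DesignWeights:
    """Reciprocal sampling-fraction weights for cases and controls."""

    q_case: float
    q_control: float
    provenance: dict = field(default_factory=dict)

    @property
    def case_weight(self) -> float:
        return 1.0 / self.q_case

    @property
    def control_weight(self) -> float:
        return 1.0 / self.q_control


def derive_weights(
    n_cases_sampled: int,
    n_cases_source: int | tuple[int, float],
    n_controls_sampled: int,
    n_source_population: int,
) -> DesignWeights:
    """Design weights from registry counts.

    ``n_cases_source`` may be given directly, or as ``(registered, coverage)``
    when the registry captures only a known fraction of incident cases: the
    source case count is then registered/coverage, rounded to the nearest
    integer. Sampling fractions are sampled/source per status; the design
    weights are their reciprocals.
    """
    prov: dict = {
        "n_cases_sampled": int(n_cases_sampled),
        "n_controls_sampled": int(n_controls_sampled),
        "n_source_population": int(n_source_population),
    }
    if isinstance(n_cases_source, tuple):
        registered, coverage = n_cases_source
        if not (0.0 < coverage <= 1.0):
            raise DesignError(f"registry coverage must be in (0, 1], got {coverage}")
        prov["n_cases_registered"] = int(registered)
        prov["registry_coverage"] = float(coverage)
        n_cases_source = int(round(registered / coverage))
    prov["n_cases_source"] = int(n_cases_source)

    if min(n_cases_sampled, n_controls_sampled, n_cases_source,
           n_source_population) <= 0:
        raise DesignError("all design counts must be positive")
    if n_cases_sampled > n_cases_source:
        raise DesignError(
            f"sampled cases ({n_cases_sampled}) exceed source cases "
            f"({n_cases_source})"
        )
    n_controls_source = n_source_population
    if n_controls_sampled > n_controls_source:
        raise DesignError(
            f"sampled controls ({n_controls_sampled}) exceed the source "
            f"population ({n_controls_source})"
        )
    return DesignWeights(
        q_case=n_cases_sampled / n_cases_source,
        q_control=n_controls_sampled / n_controls_source,
        provenance=prov,
    )


# --------------------------------------------------------------------------
# Step 4: clever covariate


@dataclass
class CleverCovariateValues:
    """H = A/g - (1-A)/(1-g) and its arm-specific components."""

    H: np.ndarray
    H1: np.ndarray  # 1/g, the exposed component (> 0)
    H0: np.ndarray  # -1/(1-g), the unexposed component (< 0)


def clever_covariate(A: np.ndarray, ghat: np.ndarray) -> CleverCovariateValues:
    A = np.asarray(A, dtype=float)
    g = np.asarray(ghat, dtype=float)
    if np.any(g <= 0.0) or np.any(g >= 1.0):
        raise InferenceError(
            "propensity estimates at 0 or 1; apply truncation bounds upstream"
        )
    H1 = 1.0 / g
    H0 = -1.0 / (1.0 - g)
    return CleverCovariateValues(H=A * H1 + (1.0 - A) * H0, H1=H1, H0=H0)


# --------------------------------------------------------------------------
# Step 5: fluctuation


def fluctuate(
    Qbar0_logit: np.ndarray,
    H: CleverCovariateValues | np.ndarray,
    Y: np.ndarray,
    design_weights: np.ndarray,
    *,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[float, bool]:
    """Solve for the fluctuation coefficient epsilon.

    One-parameter weighted logistic regression of Y on H with the initial
    logits as fixed offset and no intercept; Newton iterations on the score
    sum_i w_i H_i (Y_i - expit(offset_i + eps H_i)) until |score| < tol
    (weights normalized to mean one, so the criterion is scale-free).

    Returns (epsilon, converged).
    """
    h = H.H if isinstance(H, CleverCovariateValues) else np.asarray(H, dtype=float)
    off = np.asarray(Qbar0_logit, dtype=float)
    y = np.asarray(Y, dtype=float)
    w = np.asarray(design_weights, dtype=float)
    if np.all(h == 0.0):
        raise InferenceError("clever covariate identically zero")
    w = w / w.mean()

    eps = 0.0
    for _ in range(max_iter):
        p = expit(off + eps * h)
        score = float(np.sum(w * h * (y - p)))
        if abs(score) < tol:
            return eps, True
        info = float(np.sum(w * h * h * p * (1.0 - p)))
        if info <= 0.0:
            break
        step = score / info
        eps += np.clip(step, -5.0, 5.0)
    p = expit(off + eps * h)
    converged = abs(float(np.sum(w * h * (y - p)))) < tol
    if not converged:
        log.warning("fluctuation did not reach |score| < %g", tol)
    return eps, converged


# --------------------------------------------------------------------------
# Step 6: targeting and standardization


def target_and_standardize(
    Q1_logit: np.ndarray,
    Q0_logit: np.ndarray,
    epsilon: float,
    H: CleverCovariateValues,
    design_weights: np.ndarray,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Updated counterfactual predictions and their weighted means.

    Q*(a, W) = expit(logit Qbar(a, W) + eps * H_a); psi_a is the
    design-weighted mean of Q*(a, W) over the whole sample, the plug-in
    standardization to the source population.

    Returns (psi1, psi0, Qstar1, Qstar0).
    """
    w = np.asarray(design_weights, dtype=float)
    Qstar1 = expit(np.asarray(Q1_logit) + epsilon * H.H1)
    Qstar0 = expit(np.asarray(Q0_logit) + epsilon * H.H0)
    psi1 = float(np.average(Qstar1, weights=w))
    psi0 = float(np.average(Qstar0, weights=w))
    return psi1, psi0, Qstar1, Qstar0


# --------------------------------------------------------------------------
# Step 7: EIC inference


def eic_inference(
    Y: np.ndarray,
    A: np.ndarray,
    H: CleverCovariateValues,
    Qstar_obs: np.ndarray,
    Qstar1: np.ndarray,
    Qstar0: np.ndarray,
    psi1: float,
    psi0: float,
    design_weights: np.ndarray,
) -> dict:
    """Influence-curve standard errors and 95% Wald intervals.

    The RD influence contribution per record is
        D_i = w_i [H_i (Y_i - Q*(A_i, W_i)) + Q*(1, W_i) - Q*(0, W_i) - RD]
    with weights normalized to mean one; se = sd(D)/sqrt(n). The RR interval
    uses the delta method on log psi1 - log psi0 with the arm-specific
    contributions divided by their psi.
    """
    y = np.asarray(Y, dtype=float)
    a = np.asarray(A, dtype=float)
    w = np.asarray(design_weights, dtype=float)
    w = w / w.mean()
    n = len(y)
    rd = psi1 - psi0
    resid = y - Qstar_obs

    D_rd = w * (H.H * resid + Qstar1 - Qstar0 - rd)
    se_rd = float(np.std(D_rd, ddof=1) / np.sqrt(n))
    ci_rd = (rd - Z975 * se_rd, rd + Z975 * se_rd)

    out = {
        "se_rd": se_rd,
        "ci_rd": ci_rd,
        "eic_rd": D_rd,
        "eic_mean_abs": float(abs(np.mean(D_rd))),
    }

    if psi0 <= 0.0 or psi1 <= 0.0:
        out.update(se_log_rr=np.nan, ci_rr=(np.nan, np.nan))
        return out
    D1 = w * (a * H.H1 * resid + Qstar1 - psi1)
    D0 = w * ((1.0 - a) * (-H.H0) * resid + Qstar0 - psi0)
    D_log_rr = D1 / psi1 - D0 / psi0
    se_log_rr = float(np.std(D_log_rr, ddof=1) / np.sqrt(n))
    log_rr = np.log(psi1) - np.log(psi0)
    ci_rr = (
        float(np.exp(log_rr - Z975 * se_log_rr)),
        float(np.exp(log_rr + Z975 * se_log_rr)),
    )
    out.update(se_log_rr=se_log_rr, ci_rr=ci_rr, eic_log_rr=D_log_rr)
    return out


# --------------------------------------------------------------------------
# PAF


def compute_paf(rr: float, pc: float) -> float:
    """Population attributable fraction, PAF = Pc (RR - 1) / RR."""
    if rr <= 0.0:
        raise InferenceError(f"risk ratio must be positive, got {rr}")
    if not 0.0 <= pc <= 1.0:
        raise InferenceError(f"case exposure prevalence must be in [0, 1], got {pc}")
    return pc * (rr - 1.0) / rr


@dataclass(frozen=True)
class PafEstimate:
    pc: float
    paf: float
    ci: tuple[float, float]
    n_boot: int
    n_dropped: int = 0


# --------------------------------------------------------------------------
# Nuisance estimation wrapper


@dataclass
class NuisanceFits:
    """Fitted outcome regression and propensity with cached predictions."""

    Qfit: SuperLearnerFit | None
    gfit: SuperLearnerFit | None
    Q_obs_logit: np.ndarray
    Q1_logit: np.ndarray
    Q0_logit: np.ndarray
    ghat: np.ndarray
    g_bounds_applied: int


def _fast_glm_nuisances(
    df: pd.DataFrame,
    outcome: str,
    exposure: str,
    confounders: Sequence[str],
    w: np.ndarray,
    g_bounds: tuple[float, float],
) -> NuisanceFits:
    """Main-terms weighted logistic nuisances via closed-form IRLS.

    Used where thousands of refits are needed (bootstrap, simulation grids);
    same estimand plumbing as the super-learner path.
    """
    from .superlearner import _Encoder, _add_intercept

    enc = _Encoder().fit(df[list(confounders)])
    W = _add_intercept(enc.transform(df[list(confounders)]))
    a = df[exposure].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)

    Xq = np.column_stack([W, a])
    bq = fit_weighted_logit(Xq, y, w)
    eta_obs = Xq @ bq
    eta1 = np.column_stack([W, np.ones(len(a))]) @ bq
    eta0 = np.column_stack([W, np.zeros(len(a))]) @ bq

    bg = fit_weighted_logit(W, a, w)
    g = expit(W @ bg)
    lo, hi = g_bounds
    clipped = int(np.sum((g < lo) | (g > hi)))
    g = np.clip(g, lo, hi)
    return NuisanceFits(
        Qfit=None, gfit=None,
        Q_obs_logit=eta_obs, Q1_logit=eta1, Q0_logit=eta0,
        ghat=g, g_bounds_applied=clipped,
    )


def _superlearner_nuisances(
    df: pd.DataFrame,
    outcome: str,
    exposure: str,
    confounders: Sequence[str],
    w: np.ndarray,
    library: Sequence[LearnerSpec],
    g_library: Sequence[LearnerSpec],
    n_folds: int,
    g_bounds: tuple[float, float],
    seed: int,
) -> NuisanceFits:
    y = df[outcome].to_numpy(dtype=float)
    a = df[exposure].to_numpy(dtype=float)
    cols = list(confounders)

    Xq = df[[exposure] + cols]
    Qfit = fit_super_learner(Xq, y, w, library, n_folds=n_folds, seed=seed)
    q_obs = predict_super_learner(Qfit, Xq)
    X1 = Xq.copy()
    X1[exposure] = 1
    X0 = Xq.copy()
    X0[exposure] = 0
    q1 = predict_super_learner(Qfit, X1)
    q0 = predict_super_learner(Qfit, X0)

    gfit = fit_super_learner(df[cols], a, w, g_library, n_folds=n_folds,
                             seed=seed + 1)
    g = predict_super_learner(gfit, df[cols])
    lo, hi = g_bounds
    clipped = int(np.sum((g < lo) | (g > hi)))
    g = np.clip(g, lo, hi)

    clamp = (1e-6, 1.0 - 1e-6)
    return NuisanceFits(
        Qfit=Qfit, gfit=gfit,
        Q_obs_logit=logit(np.clip(q_obs, *clamp)),
        Q1_logit=logit(np.clip(q1, *clamp)),
        Q0_logit=logit(np.clip(q0, *clamp)),
        ghat=g, g_bounds_applied=clipped,
    )


# --------------------------------------------------------------------------
# Results


@dataclass
class TmleResult:
    """Targeted estimates with EIC inference, PAF, and diagnostics."""

    psi1: float
    psi0: float
    epsilon: float
    se_rd: float
    ci_rd: tuple[float, float]
    se_log_rr: float
    ci_rr: tuple[float, float]
    eic: np.ndarray
    paf: PafEstimate | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def rd(self) -> float:
        return self.psi1 - self.psi0

    @property
    def rd_per_100k(self) -> float:
        return self.rd * 100_000.0

    @property
    def ci_rd_per_100k(self) -> tuple[float, float]:
        return (self.ci_rd[0] * 100_000.0, self.ci_rd[1] * 100_000.0)

    @property
    def rr(self) -> float:
        if self.psi0 <= 0.0:
            return np.nan
        return self.psi1 / self.psi0


def _tmle_core(
    df: pd.DataFrame,
    outcome: str,
    exposure: str,
    w: np.ndarray,
    nuis: NuisanceFits,
) -> dict:
    """Steps 4-7 given nuisance fits; shared by all estimation paths."""
    y = df[outcome].to_numpy(dtype=float)
    a = df[exposure].to_numpy(dtype=float)
    H = clever_covariate(a, nuis.ghat)
    eps, converged = fluctuate(nuis.Q_obs_logit, H, y, w)
    psi1, psi0, Qs1, Qs0 = target_and_standardize(
        nuis.Q1_logit, nuis.Q0_logit, eps, H, w
    )
    Qs_obs = np.where(a == 1, Qs1, Qs0)
    inf = eic_inference(y, a, H, Qs_obs, Qs1, Qs0, psi1, psi0, w)
    return {
        "psi1": psi1, "psi0": psi0, "epsilon": eps,
        "converged": converged, "H": H, **inf,
    }


# --------------------------------------------------------------------------
# Bootstrap for the PAF


def bootstrap_paf_ci(
    sample: CaseControlSample,
    outcome: str,
    exposure: str,
    confounders: Sequence[str],
    n_boot: int = 10_000,
    seed: int = 0,
    g_bounds: tuple[float, float] = (0.025, 0.975),
    nuisance_fn: Callable[..., NuisanceFits] | None = None,
) -> PafEstimate:
    """Percentile bootstrap interval for the PAF.

    Cases and controls are resampled with replacement separately at their
    observed sizes, preserving the fixed case-control margins; the whole
    weighted TMLE (with fast main-terms logistic nuisances by default) and
    the PAF are recomputed per replicate, and the 2.5th/97.5th percentiles
    returned. Replicates with an undefined RR are dropped and counted;
    more than 10% undefined raises.
    """
    if n_boot < 100:
        raise InferenceError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    df = sample.records
    w_all = df["weight"].to_numpy(dtype=float)
    y_all = df[outcome].to_numpy(dtype=int)
    case_idx = np.flatnonzero(y_all == 1)
    ctrl_idx = np.flatnonzero(y_all == 0)
    nuis_fn = nuisance_fn or _fast_glm_nuisances

    a_full = df[exposure].to_numpy(dtype=float)
    point_pc = float(a_full[case_idx].mean())

    pafs = np.empty(n_boot)
    dropped = 0
    for b in range(n_boot):
        take = np.concatenate([
            rng.choice(case_idx, size=len(case_idx), replace=True),
            rng.choice(ctrl_idx, size=len(ctrl_idx), replace=True),
        ])
        bdf = df.iloc[take].reset_index(drop=True)
        wb = w_all[take]
        try:
            nuis = nuis_fn(bdf, outcome, exposure, confounders, wb, g_bounds)
            core = _tmle_core(bdf, outcome, exposure, wb, nuis)
            if core["psi0"] <= 0.0:
                raise InferenceError("psi0 = 0 in replicate")
            rr = core["psi1"] / core["psi0"]
            pc = float(bdf.loc[bdf[outcome] == 1, exposure].mean())
            pafs[b] = compute_paf(rr, pc)
        except Exception:  # noqa: BLE001 - undefined replicates are counted
            pafs[b] = np.nan
            dropped += 1
    if dropped > 0.1 * n_boot:
        raise InferenceError(
            f"{dropped}/{n_boot} bootstrap replicates undefined"
        )
    good = pafs[~np.isnan(pafs)]
    lo, hi = np.percentile(good, [2.5, 97.5])
    return PafEstimate(
        pc=point_pc,
        paf=np.nan,  # caller fills the point estimate from the main fit
        ci=(float(lo), float(hi)),
        n_boot=n_boot,
        n_dropped=dropped,
    )


# --------------------------------------------------------------------------
# Full pipeline


def run_ccw_tmle(
    sample: CaseControlSample,
    outcome: str = "Y",
    exposure: str = "A",
    confounders: Sequence[str] = (),
    library: Sequence[LearnerSpec] | None = None,
    g_library: Sequence[LearnerSpec] | None = None,
    n_folds: int = 10,
    g_bounds: tuple[float, float] = (0.025, 0.975),
    n_boot: int = 10_000,
    compute_paf_ci: bool = True,
    seed: int = 0,
) -> TmleResult:
    """Run the full case-control weighted TMLE on a sample.

    ``library``/``g_library`` are super-learner candidate sets for the
    outcome regression and propensity; when both are None, fast main-terms
    logistic nuisances are used directly (the single-learner special case).
    Design weights are taken from the sample's ``weight`` column.
    """
    df = sample.records.reset_index(drop=True)
    for col in (outcome, exposure, *confounders, "weight"):
        if col not in df.columns:
            raise DesignError(f"column {col!r} not found in sample")
    w = df["weight"].to_numpy(dtype=float)

    if library is None and g_library is None:
        nuis = _fast_glm_nuisances(df, outcome, exposure, confounders, w, g_bounds)
    else:
        if library is None or g_library is None:
            raise DesignError("provide both libraries or neither")
        nuis = _superlearner_nuisances(
            df, outcome, exposure, confounders, w,
            library, g_library, n_folds, g_bounds, seed,
        )
    core = _tmle_core(df, outcome, exposure, w, nuis)
    psi1, psi0 = core["psi1"], core["psi0"]

    paf_est = None
    if psi0 > 0.0:
        rr = psi1 / psi0
        cases = df[df[outcome] == 1]
        pc = float(cases[exposure].mean()) if len(cases) else np.nan
        paf_point = compute_paf(rr, pc) if np.isfinite(pc) else np.nan
        if compute_paf_ci:
            boot = bootstrap_paf_ci(
                sample, outcome, exposure, confounders,
                n_boot=n_boot, seed=seed + 7, g_bounds=g_bounds,
            )
            paf_est = PafEstimate(
                pc=pc, paf=paf_point, ci=boot.ci,
                n_boot=boot.n_boot, n_dropped=boot.n_dropped,
            )
        else:
            paf_est = PafEstimate(pc=pc, paf=paf_point, ci=(np.nan, np.nan),
                                  n_boot=0)

    return TmleResult(
        psi1=psi1,
        psi0=psi0,
        epsilon=core["epsilon"],
        se_rd=core["se_rd"],
        ci_rd=core["ci_rd"],
        se_log_rr=core.get("se_log_rr", np.nan),
        ci_rr=core.get("ci_rr", (np.nan, np.nan)),
        eic=core["eic_rd"],
        paf=paf_est,
        diagnostics={
            "g_bounds": g_bounds,
            "g_bounds_applied": nuis.g_bounds_applied,
            "fluctuation_converged": core["converged"],
            "eic_mean_abs": core["eic_mean_abs"],
            "seed": seed,
            "q_case": sample.q_case,
            "q_control": sample.q_control,
            "n": len(df),
            "learner_summary": (
                nuis.Qfit.summary().to_dict("records") if nuis.Qfit else None
            ),
            "g_learner_summary": (
                nuis.gfit.summary().to_dict("records") if nuis.gfit else None
            ),
        },
    )
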