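"""Comparator estimators: IPTW, parametric g-formula, brute-force
standardization.

These serve two roles: independent oracles for the TMLE (with discrete
confounders and saturated models all of them coincide exactly), and
comparators whose behaviour under misspecification contrasts with the
double robustness of the targeted estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._glm import expit, fit_weighted_logit

__all__ = [
    "BaselineResult",
    "iptw_estimate",
    "gformula_estimate",
    "brute_force_standardization",
]


class PositivityError(RuntimeError):
    pass


@dataclass(frozen=True)
class BaselineResult:
    method: str
    psi1: float
    psi0: float

    @property
    def rd(self) -> float:
        return self.psi1 - self.psi0

    @property
    def rr(self) -> float:
        return self.psi1 / self.psi0 if self.psi0 > 0 else np.nan


def iptw_estimate(
    Y: np.ndarray,
    A: np.ndarray,
    ghat: np.ndarray,
    design_weights: np.ndarray,
) -> BaselineResult:
    """Hájek (normalized) inverse-probability-of-treatment estimator.

    psi_a = sum_i w_i 1{A_i=a} Y_i / g_a(W_i)  /  sum_i w_i 1{A_i=a} / g_a(W_i)

    The normalized form is invariant to rescaling of either set of weights.
    """
    y = np.asarray(Y, dtype=float)
    a = np.asarray(A, dtype=float)
    g = np.asarray(ghat, dtype=float)
    w = np.asarray(design_weights, dtype=float)
    if not np.any(a == 1) or not np.any(a == 0):
        raise PositivityError("an exposure arm is empty")
    ipw1 = w * a / g
    ipw0 = w * (1.0 - a) / (1.0 - g)
    psi1 = float(np.sum(ipw1 * y) / np.sum(ipw1))
    psi0 = float(np.sum(ipw0 * y) / np.sum(ipw0))
    return BaselineResult("iptw", psi1, psi0)


def gformula_estimate(
    df: pd.DataFrame,
    outcome: str,
    exposure: str,
    confounders: Sequence[str],
    design_weights: np.ndarray,
    interactions: bool = False,
) -> BaselineResult:
    """Parametric g-formula: weighted logistic outcome model, then
    standardization of the forced-exposure predictions over the weighted
    confounder distribution."""
    from .superlearner import _Encoder, _add_intercept

    w = np.asarray(design_weights, dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    a = df[exposure].to_numpy(dtype=float)
    enc = _Encoder().fit(df[list(confounders)])
    W = _add_intercept(enc.transform(df[list(confounders)]))
    X = np.column_stack([W, a])
    if interactions:
        X = np.column_stack([X, W[:, 1:] * a[:, None]])

    beta = fit_weighted_logit(X, y, w)

    def forced(val: float) -> np.ndarray:
        av = np.full(len(a), val)
        Xa = np.column_stack([W, av])
        if interactions:
            Xa = np.column_stack([Xa, W[:, 1:] * av[:, None]])
        return expit(Xa @ beta)

    psi1 = float(np.average(forced(1.0), weights=w))
    psi0 = float(np.average(forced(0.0), weights=w))
    return BaselineResult("gformula", psi1, psi0)


def brute_force_standardization(
    df: pd.DataFrame,
    outcome: str,
    exposure: str,
    confounders: Sequence[str],
    design_weights: np.ndarray,
) -> BaselineResult:
    """Exact standardization by enumeration over discrete confounder strata.

    psi_a = sum_strata [weighted P(stratum)] x [weighted mean Y among A=a in
    stratum]. Every (a, stratum) cell must be non-empty.
    """
    w = np.asarray(design_weights, dtype=float)
    work = df[[outcome, exposure, *confounders]].copy()
    work["_w"] = w
    key = [str(c) for c in confounders]
    if not key:
        # single stratum: arm-specific weighted means
        key_groups = [((), work)]
    else:
        key_groups = list(work.groupby(key, observed=True, sort=True))

    total_w = w.sum()
    psi1 = 0.0
    psi0 = 0.0
    for stratum, g in key_groups:
        p_stratum = g["_w"].sum() / total_w
        for aval, acc in ((1, "psi1"), (0, "psi0")):
            arm = g[g[exposure] == aval]
            if arm.empty:
                raise PositivityError(
                    f"empty cell: exposure={aval}, stratum={stratum!r}"
                )
            mean_y = np.average(arm[outcome], weights=arm["_w"])
            if acc == "psi1":
                psi1 += p_stratum * mean_y
            else:
                psi0 += p_stratum * mean_y
    return BaselineResult("brute_force_standardization", float(psi1), float(psi0))
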