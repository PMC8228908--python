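"""Analysis configuration: column mapping, design inputs, learner library.

A configuration document (YAML) declares either a delimited input table or a
simulation block (cohort spec + sampling sizes), the outcome column, one or
more exposure blocks each with its own confounder set, the design counts from
which the sampling-fraction weights are derived, and the estimation settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .superlearner import LearnerSpec, default_library
from .synthetic import (
    CaseControlSample,
    CohortSpec,
    generate_cohort,
    sample_case_control,
)
from .tmle import DesignWeights, derive_weights

__all__ = ["ExposureBlock", "AnalysisConfig", "load_config", "resolve_sample"]


class UsageError(ValueError):
    pass


@dataclass(frozen=True)
class ExposureBlock:
    exposure: str
    confounders: tuple[str, ...]
    label: str | None = None

    @property
    def display(self) -> str:
        return self.label or self.exposure


@dataclass
class AnalysisConfig:
    outcome: str
    exposures: list[ExposureBlock]
    input_path: str | None = None
    simulation: dict | None = None
    design: dict | None = None
    learners: list[LearnerSpec] | None = None
    g_learners: list[LearnerSpec] | None = None
    n_folds: int = 10
    g_bounds: tuple[float, float] = (0.025, 0.975)
    n_boot: int = 10_000
    seed: int = 0
    output_path: str | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise UsageError(
                "exactly one of input_path / simulation must be provided"
            )
        if not self.exposures:
            raise UsageError("at least one exposure block is required")

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "exposures": [
                {
                    "exposure": b.exposure,
                    "confounders": list(b.confounders),
                    **({"label": b.label} if b.label else {}),
                }
                for b in self.exposures
            ],
            "input_path": self.input_path,
            "simulation": self.simulation,
            "design": self.design,
            "learners": (
                None
                if self.learners is None
                else [
                    {"name": s.name, "family": s.family,
                     "hyperparameters": dict(s.hyperparameters)}
                    for s in self.learners
                ]
            ),
            "g_learners": (
                None
                if self.g_learners is None
                else [
                    {"name": s.name, "family": s.family,
                     "hyperparameters": dict(s.hyperparameters)}
                    for s in self.g_learners
                ]
            ),
            "n_folds": self.n_folds,
            "g_bounds": list(self.g_bounds),
            "n_boot": self.n_boot,
            "seed": self.seed,
            "output_path": self.output_path,
        }


def _parse_learners(raw) -> list[LearnerSpec] | None:
    if raw is None:
        return None
    if raw == "default":
        return default_library()
    out = []
    for item in raw:
        out.append(
            LearnerSpec(
                name=item["name"],
                family=item["family"],
                hyperparameters=dict(item.get("hyperparameters", {})),
            )
        )
    return out


def config_from_dict(d: Mapping) -> AnalysisConfig:
    try:
        outcome = d["outcome"]
        exposures = [
            ExposureBlock(
                exposure=b["exposure"],
                confounders=tuple(b.get("confounders", ())),
                label=b.get("label"),
            )
            for b in d["exposures"]
        ]
    except KeyError as exc:
        raise UsageError(f"missing required configuration field: {exc}") from exc
    bounds = d.get("g_bounds", (0.025, 0.975))
    return AnalysisConfig(
        outcome=outcome,
        exposures=exposures,
        input_path=d.get("input_path"),
        simulation=d.get("simulation"),
        design=d.get("design"),
        learners=_parse_learners(d.get("learners")),
        g_learners=_parse_learners(d.get("g_learners")),
        n_folds=int(d.get("n_folds", 10)),
        g_bounds=(float(bounds[0]), float(bounds[1])),
        n_boot=int(d.get("n_boot", 10_000)),
        seed=int(d.get("seed", 0)),
        output_path=d.get("output_path"),
    )


def load_config(path: str | Path) -> AnalysisConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))


def _design_weights(cfg: AnalysisConfig, n_cases: int, n_controls: int) -> DesignWeights:
    d = cfg.design or {}
    if "q_case" in d and "q_control" in d:
        return DesignWeights(
            q_case=float(d["q_case"]), q_control=float(d["q_control"]),
            provenance=dict(d),
        )
    if "n_cases_registered" in d:
        src: int | tuple = (int(d["n_cases_registered"]), float(d["coverage"]))
    elif "n_cases_source" in d:
        src = int(d["n_cases_source"])
    else:
        raise UsageError(
            "design block needs q_case/q_control, or n_cases_source, or "
            "n_cases_registered + coverage"
        )
    return derive_weights(
        n_cases_sampled=int(d.get("n_cases_sampled", n_cases)),
        n_cases_source=src,
        n_controls_sampled=int(d.get("n_controls_sampled", n_controls)),
        n_source_population=int(d["n_source_population"]),
    )


def resolve_sample(cfg: AnalysisConfig) -> CaseControlSample:
    """Materialize the analysis sample: load the table or simulate it."""
    if cfg.simulation is not None:
        sim = dict(cfg.simulation)
        spec = CohortSpec.from_dict(sim["cohort_spec"])
        cohort = generate_cohort(spec)
        return sample_case_control(
            cohort,
            n_cases=int(sim["n_cases"]),
            n_controls=int(sim["n_controls"]),
            match_on=sim.get("match_on"),
            seed=int(sim.get("seed", cfg.seed)),
        )
    df = pd.read_csv(cfg.input_path)
    needed = {cfg.outcome} | {b.exposure for b in cfg.exposures}
    for b in cfg.exposures:
        needed |= set(b.confounders)
    missing = sorted(c for c in needed if c not in df.columns)
    if missing:
        raise UsageError(f"input table is missing columns: {missing}")
    y = df[cfg.outcome].to_numpy()
    if not set(np.unique(y)) <= {0, 1}:
        raise UsageError(f"outcome column {cfg.outcome!r} must be binary 0/1")
    dw = _design_weights(cfg, int((y == 1).sum()), int((y == 0).sum()))
    out = df.copy()
    out["weight"] = np.where(y == 1, dw.case_weight, dw.control_weight)
    return CaseControlSample(
        records=out, q_case=dw.q_case, q_control=dw.q_control,
        matching_variable=None,
    )
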