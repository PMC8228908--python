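"""Run reports: machine-readable results plus a study-style summary table.

The summary table follows the reporting conventions of registry case-control
analyses: one row per exposure with the risk difference per 100,000, the risk
ratio, and the attributable fraction in percent, each with its 95% CI in
parentheses and one decimal shown.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig, resolve_sample
from .tmle import TmleResult, run_ccw_tmle

__all__ = ["EstimateRow", "RunReport", "run_analysis", "render_table"]


@dataclass(frozen=True)
class EstimateRow:
    exposure: str
    psi1: float
    psi0: float
    rd_per_100k: float
    ci_rd_per_100k: tuple[float, float]
    rr: float
    ci_rr: tuple[float, float]
    paf_pct: float
    ci_paf_pct: tuple[float, float]
    epsilon: float
    diagnostics: dict = field(default_factory=dict)

    @classmethod
    def from_result(cls, exposure: str, r: TmleResult) -> "EstimateRow":
        paf = r.paf
        return cls(
            exposure=exposure,
            psi1=r.psi1,
            psi0=r.psi0,
            rd_per_100k=r.rd_per_100k,
            ci_rd_per_100k=r.ci_rd_per_100k,
            rr=r.rr,
            ci_rr=r.ci_rr,
            paf_pct=(paf.paf * 100.0 if paf is not None else np.nan),
            ci_paf_pct=(
                (paf.ci[0] * 100.0, paf.ci[1] * 100.0)
                if paf is not None
                else (np.nan, np.nan)
            ),
            epsilon=r.epsilon,
            diagnostics=dict(r.diagnostics),
        )


@dataclass
class RunReport:
    rows: list[EstimateRow]
    config_echo: dict
    seed: int
    version: str = __version__

    def to_dict(self) -> dict:
        def _clean(x):
            if isinstance(x, dict):
                return {k: _clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [_clean(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        return _clean(
            {
                "version": self.version,
                "seed": self.seed,
                "config": self.config_echo,
                "estimates": [
                    {
                        "exposure": r.exposure,
                        "psi1": r.psi1,
                        "psi0": r.psi0,
                        "rd_per_100k": r.rd_per_100k,
                        "ci_rd_per_100k": list(r.ci_rd_per_100k),
                        "rr": r.rr,
                        "ci_rr": list(r.ci_rr),
                        "paf_pct": r.paf_pct,
                        "ci_paf_pct": list(r.ci_paf_pct),
                        "epsilon": r.epsilon,
                        "diagnostics": r.diagnostics,
                    }
                    for r in self.rows
                ],
            }
        )

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_dict(cls, d: dict) -> "RunReport":
        rows = [
            EstimateRow(
                exposure=e["exposure"],
                psi1=e["psi1"],
                psi0=e["psi0"],
                rd_per_100k=e["rd_per_100k"],
                ci_rd_per_100k=tuple(e["ci_rd_per_100k"]),
                rr=e["rr"],
                ci_rr=tuple(e["ci_rr"]),
                paf_pct=e["paf_pct"],
                ci_paf_pct=tuple(e["ci_paf_pct"]),
                epsilon=e["epsilon"],
                diagnostics=e.get("diagnostics", {}),
            )
            for e in d["estimates"]
        ]
        return cls(
            rows=rows, config_echo=d["config"], seed=d["seed"],
            version=d.get("version", __version__),
        )

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls.from_dict(json.loads(text))


def run_analysis(config: AnalysisConfig) -> RunReport:
    """Execute the full pipeline for every configured exposure."""
    sample = resolve_sample(config)
    rows = []
    for block in config.exposures:
        result = run_ccw_tmle(
            sample,
            outcome=config.outcome,
            exposure=block.exposure,
            confounders=block.confounders,
            library=config.learners,
            g_library=config.g_learners,
            n_folds=config.n_folds,
            g_bounds=config.g_bounds,
            n_boot=config.n_boot,
            seed=config.seed,
        )
        rows.append(EstimateRow.from_result(block.display, result))
    return RunReport(rows=rows, config_echo=config.to_dict(), seed=config.seed)


def _fmt(x: float, ci: tuple[float, float]) -> str:
    return f"{x:.1f} ({ci[0]:.1f}, {ci[1]:.1f})"


_HEADERS = ["exposure", "rd_per_100k_95ci", "rr_95ci", "paf_pct_95ci"]


def render_table(report: RunReport, style: str = "plain") -> str:
    """Render the estimates table.

    style "plain": aligned human-readable columns. style "delimited": TSV
    with the same numbers (one decimal), parseable back to equal values.
    """
    if style not in ("plain", "delimited"):
        raise ValueError(f"unknown table style {style!r}")
    body = [
        [
            r.exposure,
            _fmt(r.rd_per_100k, r.ci_rd_per_100k),
            _fmt(r.rr, r.ci_rr),
            _fmt(r.paf_pct, r.ci_paf_pct),
        ]
        for r in report.rows
    ]
    if style == "delimited":
        lines = ["\t".join(_HEADERS)]
        lines += ["\t".join(row) for row in body]
        return "\n".join(lines) + "\n"
    widths = [
        max(len(h), *(len(row[j]) for row in body)) if body else len(h)
        for j, h in enumerate(_HEADERS)
    ]
    lines = [
        "  ".join(h.ljust(w) for h, w in zip(_HEADERS, widths)).rstrip(),
        "  ".join("-" * w for w in widths),
    ]
    lines += [
        "  ".join(c.ljust(w) for c, w in zip(row, widths)).rstrip()
        for row in body
    ]
    return "\n".join(lines) + "\n"


def parse_delimited_table(text: str) -> pd.DataFrame:
    """Parse a delimited-style table back to numbers (round-trip check)."""
    import io
    import re

    df = pd.read_csv(io.StringIO(text), sep="\t")
    out = {"exposure": df["exposure"]}
    for col in _HEADERS[1:]:
        est, lo, hi = [], [], []
        for cell in df[col]:
            m = re.match(r"(-?[\d.]+) \((-?[\d.]+), (-?[\d.]+)\)", cell)
            est.append(float(m.group(1)))
            lo.append(float(m.group(2)))
            hi.append(float(m.group(3)))
        base = col.replace("_95ci", "")
        out[base] = est
        out[base + "_lo"] = lo
        out[base + "_hi"] = hi
    return pd.DataFrame(out)
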