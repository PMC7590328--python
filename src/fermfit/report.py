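"""Run reports: the serializable record of a full fit run and its rendering.

A :class:`RunReport` collects the growth fits (both sigmoids), the product
fits (all requested rate laws), the goodness-of-fit rankings and any
warnings, and round-trips losslessly through JSON.  ``render_text`` prints
the parameter and statistics tables in the conventional two-table layout of
fermentation kinetics reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from typing import Optional

from .fitting import FitResult
from .gof import GofStats
from .growth import GrowthParams
from .product import ProductParams

__all__ = ["RunReport", "render_text", "MODEL_LABELS"]

MODEL_LABELS = {
    "gompertz": "Modified Gompertz",
    "logistic": "Logistic",
    "luedeking_piret": "Luedeking-Piret",
    "monteagudo": "Monteagudo et al.",
    "balannec": "Balannec et al.",
}


def _tool_version() -> str:
    try:
        return version("fermfit")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class RunReport:
    """Everything produced by one fit run, JSON round-trippable."""

    provenance: dict
    growth_fits: list[FitResult] = field(default_factory=list)
    product_fits: list[FitResult] = field(default_factory=list)
    growth_ranking: list[str] = field(default_factory=list)
    product_ranking: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    seed: Optional[int] = None
    tool_version: str = field(default_factory=_tool_version)

    def as_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "growth_fits": [f.as_dict() for f in self.growth_fits],
            "product_fits": [f.as_dict() for f in self.product_fits],
            "growth_ranking": list(self.growth_ranking),
            "product_ranking": list(self.product_ranking),
            "warnings": list(self.warnings),
            "seed": self.seed,
            "tool_version": self.tool_version,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.as_dict(), indent=2, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "RunReport":
        def fit_from(fd: dict) -> FitResult:
            pd = dict(fd["params"])
            mid = pd.get("model_id")
            params = (
                GrowthParams(**pd)
                if mid in ("gompertz", "logistic")
                else ProductParams(**pd)
            )
            gof = GofStats(**fd["gof"]) if fd["gof"] is not None else None
            import numpy as np

            return FitResult(
                model_id=fd["model_id"],
                params=params,
                gof=gof,
                predicted=np.asarray(fd["predicted"], dtype=float),
                fit_window=tuple(fd["fit_window"]),
                converged=fd["converged"],
                n_iter=fd["n_iter"],
                warnings=list(fd.get("warnings", [])),
            )

        return cls(
            provenance=d["provenance"],
            growth_fits=[fit_from(f) for f in d["growth_fits"]],
            product_fits=[fit_from(f) for f in d["product_fits"]],
            growth_ranking=list(d["growth_ranking"]),
            product_ranking=list(d["product_ranking"]),
            warnings=list(d.get("warnings", [])),
            seed=d.get("seed"),
            tool_version=d.get("tool_version", "unknown"),
        )

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls.from_dict(json.loads(text))


def _param_string(f: FitResult) -> str:
    e = f.estimates
    if isinstance(f.params, GrowthParams):
        u = f.params.time_unit
        return f"mu_m = {e['mu_m']:.4g} {u}^-1, lam = {e['lam']:.4g} {u}, A = {e['A']:.4g}"
    parts = [f"m = {e['m']:.4g}", f"n = {e['n']:.4g}"]
    if "P_max" in e:
        parts.append(f"P_max = {e['P_max']:.4f} g/L")
    if "HL_inh" in e:
        parts.append(f"HL_inh = {e['HL_inh']:.4f} g/L")
    return ", ".join(parts)


def _table(title: str, fits: list[FitResult], ranking: list[str]) -> list[str]:
    order = {m: i for i, m in enumerate(ranking)}
    fits = sorted(fits, key=lambda f: order.get(f.model_id, 99))
    lines = [title, "-" * len(title)]
    header = f"{'Model':<20} {'Parameters':<52} {'R2':>8} {'chi2':>9} {'RMSE':>8} {'RSS':>9} {'MAPE%':>8}"
    lines.append(header)
    for f in fits:
        g = f.gof
        stats = (
            f"{g.r2_uncentered:>8.4f} {g.chi2_reduced:>9.4f} {g.rmse:>8.4f} "
            f"{g.rss:>9.4f} {g.mape:>8.3f}"
            if g is not None
            else "  (no statistics: degenerate fit)"
        )
        flag = "" if f.converged else "  [NOT CONVERGED]"
        lines.append(
            f"{MODEL_LABELS.get(f.model_id, f.model_id):<20} "
            f"{_param_string(f):<52} {stats}{flag}"
        )
    return lines


def render_text(report: RunReport) -> str:
    """Two-table plain-text rendering: growth models, then product models."""
    lines: list[str] = []
    if report.growth_fits:
        lines += _table("Growth models", report.growth_fits, report.growth_ranking)
        lines.append("")
    if report.product_fits:
        lines += _table(
            "Product formation models", report.product_fits, report.product_ranking
        )
        lines.append("")
    if report.growth_ranking:
        lines.append(
            "Best growth model: " + MODEL_LABELS.get(report.growth_ranking[0], "?")
        )
    if report.product_ranking:
        lines.append(
            "Best product model: " + MODEL_LABELS.get(report.product_ranking[0], "?")
        )
    for w in report.warnings:
        lines.append(f"WARNING: {w}")
    return "\n".join(lines)
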