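"""Human-readable rendering of association and cross-validation results."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["format_beta_cell", "render_association_table", "render_cv_table"]


def format_beta_cell(beta: float, z: float, stars: str) -> str:
    """One association cell: coefficient, stars, z statistic in parentheses,
    e.g. ``0.5* (2.1)``."""
    return f"{beta:.4g}{stars} ({z:.3g})"


def render_association_table(report: pd.DataFrame) -> pd.DataFrame:
    """Wide feature-by-category table of formatted coefficient cells."""
    if report.empty:
        return pd.DataFrame()
    cells = report.assign(
        cell=[
            format_beta_cell(b, z, s)
            for b, z, s in zip(report["beta"], report["z"], report["stars"].fillna(""))
        ]
    )
    return cells.pivot_table(
        index="feature", columns="category", values="cell", aggfunc="first", sort=False
    )


def render_cv_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Wide metric-by-class table of ``mean ± SD`` strings (sample SD across
    folds, ddof=1 — the convention used throughout this package)."""
    if summary.empty:
        return pd.DataFrame()
    cells = summary.assign(
        cell=[f"{m:.2f} ± {s:.2f}" for m, s in zip(summary["mean"], summary["sd"])]
    )
    return cells.pivot_table(
        index=["scenario", "feature_space", "objective", "metric"],
        columns="class",
        values="cell",
        aggfunc="first",
        sort=False,
    )


def render_text(association: pd.DataFrame | None, cv_summary: pd.DataFrame | None) -> str:
    """Plain-text report; explicit stubs for absent inputs."""
    parts = []
    if association is None or association.empty:
        parts.append("Association analysis: no results.")
    else:
        parts.append("Association analysis (beta, stars, z in parentheses):")
        parts.append(render_association_table(association).to_string())
    if cv_summary is None or cv_summary.empty:
        parts.append("Classification analysis: no results.")
    else:
        parts.append("Classification analysis (mean ± SD over folds):")
        parts.append(render_cv_table(cv_summary).to_string())
    return "\n\n".join(parts) + "\n"
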