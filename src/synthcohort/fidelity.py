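"""Fidelity audit: does an artificial cohort statistically resemble the
real cohort it was trained on?

Three components, each on a 0-100% scale, and their arithmetic mean (the
fidelity score):

* numerical stability — fraction of numerical variables whose real vs
  artificial samples are NOT rejected by a two-sample Kolmogorov-Smirnov
  test at alpha = 0.05 (asymptotic p-values, no multiplicity correction:
  each variable is its own pass/fail);
* categorical stability — mean over binary/categorical variables of
  100 x (1 - total variation distance) between level-frequency vectors;
* correlation stability — 100 x (1 - mean |Delta r|) over off-diagonal
  entries of the Pearson correlation matrices of the numerical variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .schema import CohortTable, SchemaError

KS_ALPHA = 0.05


def round1(x: float) -> float:
    """Round to one decimal, half away from zero (report convention)."""
    return float(np.sign(x) * np.floor(np.abs(x) * 10 + 0.5) / 10)


@dataclass
class FidelityReport:
    numerical_stability: float | None
    categorical_stability: float | None
    correlation_stability: float | None
    fidelity_score: float
    numerical_detail: pd.DataFrame | None = None
    categorical_detail: pd.DataFrame | None = None
    corr_real: pd.DataFrame | None = None
    corr_artificial: pd.DataFrame | None = None
    corr_difference: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def r(v):
            return None if v is None else round1(v)

        return {
            "fidelity_score": r(self.fidelity_score),
            "numerical_stability": r(self.numerical_stability),
            "categorical_stability": r(self.categorical_stability),
            "correlation_stability": r(self.correlation_stability),
            "warnings": self.warnings,
        }

    def to_markdown(self) -> str:
        d = self.to_dict()
        lines = [
            "| Scores | value, % |",
            "| --- | --- |",
            f"| **Fidelity score** | {d['fidelity_score']} |",
            f"| Numerical stability | {d['numerical_stability']} |",
            f"| Categorical stability | {d['categorical_stability']} |",
            f"| Numerical correlation stability | {d['correlation_stability']} |",
        ]
        return "\n".join(lines)


def _check_shared_schema(real: CohortTable, artificial: CohortTable) -> None:
    if real.schema.names != artificial.schema.names:
        raise SchemaError("real and artificial cohorts must share a schema")


def numerical_stability(
    real: CohortTable, artificial: CohortTable
) -> tuple[float | None, pd.DataFrame]:
    """KS pass-rate over numerical variables; returns (percent, detail)."""
    _check_shared_schema(real, artificial)
    rows = []
    for spec in real.schema.numerical():
        a = real.data[spec.name].to_numpy(dtype=float)
        b = artificial.data[spec.name].to_numpy(dtype=float)
        stat, p = stats.ks_2samp(a, b, method="asymp")
        rows.append(
            {"variable": spec.name, "ks_statistic": stat, "p_value": p,
             "stable": p >= KS_ALPHA}
        )
    detail = pd.DataFrame(rows)
    if not rows:
        return None, detail
    return 100.0 * detail["stable"].mean(), detail


def categorical_stability(
    real: CohortTable, artificial: CohortTable
) -> tuple[float | None, pd.DataFrame]:
    """Mean 100 x (1 - TVD) over binary and categorical variables."""
    _check_shared_schema(real, artificial)
    rows = []
    for spec in real.schema.discrete():
        levels = list(spec.levels)
        p = real.data[spec.name].value_counts(normalize=True).reindex(
            levels, fill_value=0.0
        )
        q = artificial.data[spec.name].value_counts(normalize=True).reindex(
            levels, fill_value=0.0
        )
        tvd = 0.5 * float(np.abs(p.to_numpy() - q.to_numpy()).sum())
        rows.append({"variable": spec.name, "tvd": tvd, "stability": 100 * (1 - tvd)})
    detail = pd.DataFrame(rows)
    if not rows:
        return None, detail
    return float(detail["stability"].mean()), detail


def correlation_stability(
    real: CohortTable, artificial: CohortTable
) -> tuple[float | None, pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    """100 x (1 - mean off-diagonal |Delta r|); returns score + 3 matrices."""
    _check_shared_schema(real, artificial)
    names = [c.name for c in real.schema.numerical()]
    warns: list[str] = []
    if len(names) < 2:
        return None, pd.DataFrame(), pd.DataFrame(), pd.DataFrame(), warns

    def corr(tbl: CohortTable) -> pd.DataFrame:
        X = tbl.data[names].astype(float)
        const = [n for n in names if X[n].nunique() <= 1]
        if const:
            warns.append(f"constant column(s) {const}: correlations set to 0")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            R = X.corr(method="pearson")
        R = R.fillna(0.0)
        np.fill_diagonal(R.values, 1.0)
        return R

    R_real, R_art = corr(real), corr(artificial)
    diff = R_real - R_art
    off = ~np.eye(len(names), dtype=bool)
    score = 100.0 * (1.0 - float(np.abs(diff.to_numpy()[off]).mean()))
    return score, R_real, R_art, diff, warns


def fidelity_score(
    num: float | None, cat: float | None, corr: float | None
) -> float:
    """Arithmetic mean of the defined components (0-100 scale)."""
    parts = [v for v in (num, cat, corr) if v is not None]
    if not parts:
        raise ValueError("all fidelity components undefined")
    for v in parts:
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"component {v} outside [0, 100]")
    if len(parts) < 3:
        warnings.warn("fidelity score computed from a subset of components")
    return float(np.mean(parts))


def audit_fidelity(real: CohortTable, artificial: CohortTable) -> FidelityReport:
    """Run all three components and assemble a :class:`FidelityReport`."""
    if len(artificial) == 0:
        raise ValueError("artificial cohort is empty")
    num, num_detail = numerical_stability(real, artificial)
    cat, cat_detail = categorical_stability(real, artificial)
    corr, R_r, R_a, R_d, warns = correlation_stability(real, artificial)
    return FidelityReport(
        numerical_stability=num,
        categorical_stability=cat,
        correlation_stability=corr,
        fidelity_score=fidelity_score(num, cat, corr),
        numerical_detail=num_detail,
        categorical_detail=cat_detail,
        corr_real=R_r,
        corr_artificial=R_a,
        corr_difference=R_d,
        warnings=warns,
    )


# --- comparison rendering -------------------------------------------------

def comparison_series(
    real: CohortTable, artificial: CohortTable, column: str
) -> dict:
    """Data series behind the overlay plot for one variable.

    Numerical variables: shared histogram bin edges plus relative-percentage
    heights per cohort.  Discrete variables: level labels plus relative
    percentages per cohort.  Returned as plain arrays so tests can assert
    on what is plotted without touching pixels.
    """
    spec = real.schema[column]
    if spec.kind == "numerical":
        a = real.data[column].to_numpy(dtype=float)
        b = artificial.data[column].to_numpy(dtype=float)
        edges = np.histogram_bin_edges(np.concatenate([a, b]), bins=20)
        ha, _ = np.histogram(a, bins=edges)
        hb, _ = np.histogram(b, bins=edges)
        return {
            "kind": "numerical",
            "edges": edges,
            "real_pct": 100.0 * ha / max(len(a), 1),
            "artificial_pct": 100.0 * hb / max(len(b), 1),
        }
    levels = list(spec.levels)
    p = real.data[column].value_counts(normalize=True).reindex(levels, fill_value=0)
    q = artificial.data[column].value_counts(normalize=True).reindex(
        levels, fill_value=0
    )
    return {
        "kind": "discrete",
        "levels": levels,
        "real_pct": 100.0 * p.to_numpy(),
        "artificial_pct": 100.0 * q.to_numpy(),
    }


def render_comparisons(
    real: CohortTable,
    artificial: CohortTable,
    output_dir: str | Path,
    report: FidelityReport | None = None,
) -> list[Path]:
    """Write one overlay plot per variable plus the three correlation
    heatmaps (real, artificial, difference) as PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(artificial) == 0:
        raise ValueError("artificial cohort is empty")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for spec in real.schema.columns:
        series = comparison_series(real, artificial, spec.name)
        fig, ax = plt.subplots(figsize=(5, 3.2))
        if series["kind"] == "numerical":
            centers = 0.5 * (series["edges"][:-1] + series["edges"][1:])
            width = np.diff(series["edges"])
            ax.bar(centers, series["real_pct"], width=width, alpha=0.55,
                   label="real")
            ax.bar(centers, series["artificial_pct"], width=width, alpha=0.55,
                   label="artificial")
        else:
            x = np.arange(len(series["levels"]))
            ax.bar(x - 0.2, series["real_pct"], width=0.4, label="real")
            ax.bar(x + 0.2, series["artificial_pct"], width=0.4,
                   label="artificial")
            ax.set_xticks(x, series["levels"], rotation=30, ha="right")
        ax.set_ylabel("relative %")
        ax.set_title(spec.name)
        ax.legend(frameon=False)
        fig.tight_layout()
        path = out / f"dist_{spec.name}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)

    if report is None:
        report = audit_fidelity(real, artificial)
    mats = [
        ("corr_real", report.corr_real, "real"),
        ("corr_artificial", report.corr_artificial, "artificial"),
        ("corr_difference", report.corr_difference, "difference"),
    ]
    for stem, M, title in mats:
        if M is None or M.empty:
            continue
        fig, ax = plt.subplots(figsize=(5.5, 4.5))
        vmax = 1.0
        im = ax.imshow(M.to_numpy(), vmin=-vmax, vmax=vmax, cmap="RdBu_r")
        ax.set_xticks(range(len(M)), M.columns, rotation=90, fontsize=5)
        ax.set_yticks(range(len(M)), M.index, fontsize=5)
        ax.set_title(f"correlation ({title})")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        path = out / f"{stem}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
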