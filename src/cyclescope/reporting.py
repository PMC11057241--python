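"""Condition-level summaries, rank-sum group comparisons and plots.

Downstream of prediction, two summaries matter: how the predicted
cell-cycle distribution shifts per (cell line, drug, concentration)
condition relative to the Fucci-gated truth, and whether the
top-importance features (total DNA intensity, nuclear area) really
differ between the G1 and S/G2/M populations — tested with the Wilcoxon
rank-sum test and shown as box plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .gating import PHASES

__all__ = [
    "ConditionSummary",
    "GroupComparison",
    "wilcoxon_rank_sum",
    "summarize_conditions",
    "top_feature_boxplot_table",
    "write_html_report",
]

#: exact-enumeration limit for the rank-sum null distribution
_EXACT_LIMIT = 12


@dataclass
class ConditionSummary:
    """Fucci class fractions and predicted-positive fractions per condition."""

    cell_line: str
    drug: str
    concentration_m: float
    n_nuclei: int
    fucci_fractions: dict[str, float]
    predicted_g1_fraction: float
    predicted_sg2m_fraction: float


@dataclass
class GroupComparison:
    """One feature compared between the G1 and S/G2/M groups."""

    feature: str
    g1_mean: float
    g1_median: float
    sg2m_mean: float
    sg2m_median: float
    statistic: float
    p_value: float


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def wilcoxon_rank_sum(x, y, exact_limit: int = _EXACT_LIMIT
                      ) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of x, p).

    Midranks resolve ties.  When the pooled sample has at most
    ``exact_limit`` observations and no ties, the p-value is exact,
    computed by enumerating all rank assignments; otherwise a normal
    approximation with tie correction and a continuity correction is
    used (``exact_limit=0`` forces the approximation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    nx, ny = len(x), len(y)
    n = nx + ny
    ranks = _midranks(pooled)
    w = float(ranks[:nx].sum())
    has_ties = len(np.unique(pooled)) < n

    if n <= exact_limit and not has_ties:
        mu = nx * (n + 1) / 2.0
        dev = abs(w - mu)
        count = 0
        total = 0
        all_ranks = np.arange(1, n + 1)
        for comb in combinations(all_ranks, nx):
            total += 1
            if abs(sum(comb) - mu) >= dev - 1e-9:
                count += 1
        return w, count / total

    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = float(min(1.0, math.erfc(z / math.sqrt(2.0))))
    return w, p


def summarize_conditions(nuclei: pd.DataFrame,
                         conditions: list[tuple] | None = None
                         ) -> list[ConditionSummary]:
    """Per-condition Fucci fractions and predicted-positive fractions.

    ``nuclei`` must carry per-nucleus columns ``cell_line``, ``drug``,
    ``concentration_M``, ``fucci_class``, ``pred_G1`` and ``pred_SG2M``.
    ``conditions`` optionally lists the (cell_line, drug, concentration)
    tuples to report; a listed condition with no nuclei is reported with
    ``n_nuclei=0`` and NaN (missing) fractions.
    """
    required = {"cell_line", "drug", "concentration_M", "fucci_class",
                "pred_G1", "pred_SG2M"}
    missing = required - set(nuclei.columns)
    if missing:
        raise KeyError(f"nuclei table lacks metadata columns: {missing}")
    groups = dict(iter(nuclei.groupby(
        ["cell_line", "drug", "concentration_M"], sort=True)))
    if conditions is None:
        conditions = sorted(groups)
    out: list[ConditionSummary] = []
    for key in conditions:
        cell, drug, conc = key
        grp = groups.get(tuple(key), nuclei.iloc[0:0])
        n = len(grp)
        if n == 0:
            fracs = {p: float("nan") for p in PHASES}
            g1 = sg2m = float("nan")
        else:
            fracs = {p: float((grp["fucci_class"] == p).mean())
                     for p in PHASES}
            g1 = float(grp["pred_G1"].mean())
            sg2m = float(grp["pred_SG2M"].mean())
        out.append(ConditionSummary(
            cell_line=cell, drug=drug, concentration_m=conc, n_nuclei=n,
            fucci_fractions=fracs, predicted_g1_fraction=g1,
            predicted_sg2m_fraction=sg2m))
    return out


def summaries_frame(summaries: list[ConditionSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"cell_line": s.cell_line, "drug": s.drug,
               "concentration_M": s.concentration_m, "n_nuclei": s.n_nuclei,
               "predicted_G1_fraction": s.predicted_g1_fraction,
               "predicted_SG2M_fraction": s.predicted_sg2m_fraction}
        row.update({f"fucci_{p}_fraction": s.fucci_fractions[p]
                    for p in PHASES})
        rows.append(row)
    return pd.DataFrame(rows)


DEFAULT_COMPARISON_FEATURES = ("Intensity Nucleus Sum", "Nucleus Area")


def top_feature_boxplot_table(validation: pd.DataFrame,
                              features=DEFAULT_COMPARISON_FEATURES,
                              out_dir: str | Path | None = None,
                              ) -> list[GroupComparison]:
    """Compare top-importance features between gated G1 and S/G2/M nuclei.

    Emits one :class:`GroupComparison` (group means/medians, rank-sum
    statistic, two-sided p) per feature and, when ``out_dir`` is given,
    a box-plot PNG per feature.  A feature with an empty group is
    reported with NaN statistics (missing comparison).
    """
    comparisons: list[GroupComparison] = []
    g1 = validation[validation["fucci_class"] == "G1"]
    sg2m = validation[validation["fucci_class"] == "SG2M"]
    for feat in features:
        if feat not in validation.columns:
            raise KeyError(f"feature {feat!r} not in validation table")
        xg, xs = g1[feat].to_numpy(float), sg2m[feat].to_numpy(float)
        if xg.size == 0 or xs.size == 0:
            comparisons.append(GroupComparison(
                feature=feat, g1_mean=float("nan"), g1_median=float("nan"),
                sg2m_mean=float("nan"), sg2m_median=float("nan"),
                statistic=float("nan"), p_value=float("nan")))
            continue
        stat, p = wilcoxon_rank_sum(xg, xs)
        comparisons.append(GroupComparison(
            feature=feat, g1_mean=float(xg.mean()),
            g1_median=float(np.median(xg)), sg2m_mean=float(xs.mean()),
            sg2m_median=float(np.median(xs)), statistic=stat, p_value=p))
        if out_dir is not None:
            _boxplot(feat, xg, xs, p, Path(out_dir))
    return comparisons


def _boxplot(feature: str, g1: np.ndarray, sg2m: np.ndarray, p: float,
             out_dir: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(3.2, 4))
    ax.boxplot([g1, sg2m], tick_labels=["G1", "S/G2/M"], showfliers=False)
    ax.set_ylabel(feature)
    star = "*" if p < 0.001 else ""
    ax.set_title(f"{feature}\np = {p:.2e} {star}", fontsize=9)
    fig.tight_layout()
    slug = feature.lower().replace(" ", "_").replace("%", "pct")
    path = out_dir / f"boxplot_{slug}.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def condition_barplot(summary: pd.DataFrame, out_dir: str | Path) -> Path:
    """Stacked-bar chart of Fucci class fractions per condition."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = [f"{r.drug}\n{r.concentration_M:g}M"
              for r in summary.itertuples()]
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(labels)), 4))
    bottom = np.zeros(len(summary))
    for phase in PHASES:
        vals = summary[f"fucci_{phase}_fraction"].to_numpy(float)
        ax.bar(labels, vals, bottom=bottom, label=phase)
        bottom += vals
    ax.plot(labels, summary["predicted_SG2M_fraction"], "ko--",
            label="predicted S/G2/M")
    ax.plot(labels, summary["predicted_G1_fraction"], "k^:",
            label="predicted G1")
    ax.set_ylabel("fraction of nuclei")
    ax.legend(fontsize=7, ncol=3)
    fig.tight_layout()
    path = out_dir / "condition_fractions.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def write_html_report(out_dir: str | Path, summary: pd.DataFrame,
                      comparisons: list[GroupComparison],
                      extra: dict | None = None) -> Path:
    """Write a small self-contained HTML report of the run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    comp_rows = "".join(
        f"<tr><td>{c.feature}</td><td>{c.g1_median:.4g}</td>"
        f"<td>{c.sg2m_median:.4g}</td><td>{c.statistic:.4g}</td>"
        f"<td>{c.p_value:.3g}</td></tr>"
        for c in comparisons)
    extra_html = "".join(f"<p><b>{k}</b>: {v}</p>"
                         for k, v in (extra or {}).items())
    html = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>cyclescope report</title>
<style>body{{font-family:sans-serif;margin:2em}}table{{border-collapse:collapse}}
td,th{{border:1px solid #999;padding:4px 8px}}</style></head><body>
<h1>Cell-cycle prediction report</h1>
{extra_html}
<h2>Per-condition distributions</h2>
{summary.to_html(index=False, float_format=lambda v: f"{v:.4g}")}
<h2>G1 vs S/G2/M group comparisons (Wilcoxon rank-sum)</h2>
<table><tr><th>feature</th><th>G1 median</th><th>S/G2/M median</th>
<th>rank-sum W</th><th>two-sided p</th></tr>{comp_rows}</table>
</body></html>
"""
    path = out_dir / "report.html"
    path.write_text(html)
    return path
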