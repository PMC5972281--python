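"""Parameter-recovery scoring and study-level aggregation.

The coefficient of congruence (Tucker's phi)

    C_k = sum(l* l) / sqrt(sum(l*^2) sum(l^2))

is the cosine between the estimated and population loading vectors; values
of 0.85-0.95 are conventionally read as "fair" and > 0.95 as "good"
similarity. Replications are aggregated into the 3 x 6 summary-table layout
of the study (loading magnitude by pooled indicator-count x sample-size
column groups), over proper solutions only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FAIR_CUTOFF = 0.85
GOOD_CUTOFF = 0.95

# Pooled column groups of the summary table, in printed order.
COLUMN_GROUPS: list[tuple[str, tuple[int, ...], tuple[int, ...]]] = [
    ("4-6 indicators, N=200-300", (4, 5, 6), (200, 300)),
    ("4-6 indicators, N=400-500", (4, 5, 6), (400, 500)),
    ("7 indicators, N=200-300", (7,), (200, 300)),
    ("7 indicators, N=400-500", (7,), (400, 500)),
    ("15 indicators, N=200-300", (15,), (200, 300)),
    ("15 indicators, N=400-500", (15,), (400, 500)),
]


@dataclass(frozen=True)
class CongruenceResult:
    c_k: float
    interpretation: str  # poor | fair | good


def congruence(estimated, population) -> CongruenceResult:
    """Coefficient of congruence between two loading vectors.

    Scale-invariant in each argument; NaN (interpretation 'undefined') when
    the estimated vector is identically zero.
    """
    est = np.asarray(estimated, dtype=float)
    pop = np.asarray(population, dtype=float)
    if est.shape != pop.shape or est.ndim != 1 or est.size < 2:
        raise ValueError("need two equal-length loading vectors of length >= 2")
    pop_norm = np.linalg.norm(pop)
    if pop_norm == 0:
        raise ValueError("population loading vector must be nonzero")
    est_norm = np.linalg.norm(est)
    if est_norm == 0:
        return CongruenceResult(float("nan"), "undefined")
    ck = float(est @ pop / (est_norm * pop_norm))
    if ck > GOOD_CUTOFF:
        label = "good"
    elif ck >= FAIR_CUTOFF:
        label = "fair"
    else:
        label = "poor"
    return CongruenceResult(ck, label)


@dataclass
class SummaryCell:
    """One cell of the study summary table (proper solutions only)."""

    lambda_magnitude: float
    column_group: str
    n_total: int
    n_proper: int
    proper_rate: float  # percent
    mean_avg_loading: float = float("nan")
    sd_avg_loading: float = float("nan")
    min_loading: float = float("nan")
    max_loading: float = float("nan")
    mean_ck: float = float("nan")
    sd_ck: float = float("nan")
    mean_rmsea: float = float("nan")
    sd_rmsea: float = float("nan")
    mean_cfi: float = float("nan")
    sd_cfi: float = float("nan")


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else float("nan")


def summarize_conditions(
    results: pd.DataFrame, column_groups=None
) -> list[SummaryCell]:
    """Aggregate per-replication results into pooled summary cells.

    ``results`` needs columns lambda_pop, p, n, status, avg_loading, ck,
    rmsea, cfi (one row per replication; see ``study.run_study``). The
    per-replication "average loading" is the mean of the p standardized
    loading estimates; its min-max across proper replications gives the
    cell's extremes. Cells with no replications are returned with NaN
    statistics rather than raising.
    """
    if column_groups is None:
        column_groups = COLUMN_GROUPS
    cells = []
    for lam in sorted(results["lambda_pop"].unique()):
        for name, ps, ns in column_groups:
            sub = results[
                (results["lambda_pop"] == lam)
                & results["p"].isin(ps)
                & results["n"].isin(ns)
            ]
            if sub.empty:
                cells.append(SummaryCell(lam, name, 0, 0, float("nan")))
                continue
            proper = sub[sub["status"] == "proper"]
            cell = SummaryCell(
                lambda_magnitude=lam,
                column_group=name,
                n_total=len(sub),
                n_proper=len(proper),
                proper_rate=100.0 * len(proper) / len(sub),
            )
            if len(proper):
                avg = proper["avg_loading"].to_numpy()
                cell.mean_avg_loading = float(avg.mean())
                cell.sd_avg_loading = _sd(avg)
                cell.min_loading = float(avg.min())
                cell.max_loading = float(avg.max())
                for field, col in (("ck", "ck"), ("rmsea", "rmsea"), ("cfi", "cfi")):
                    v = proper[col].dropna().to_numpy()
                    if v.size:
                        setattr(cell, f"mean_{field}", float(v.mean()))
                        setattr(cell, f"sd_{field}", _sd(v))
            cells.append(cell)
    return cells


def summary_table(cells: list[SummaryCell]) -> pd.DataFrame:
    """Summary cells as a tidy DataFrame (one row per lambda x column group)."""
    return pd.DataFrame([vars(c) for c in cells])


def format_summary(cells: list[SummaryCell]) -> str:
    """Text rendition of the 3 x 6 summary table layout."""
    lams = sorted({c.lambda_magnitude for c in cells})
    groups = list(dict.fromkeys(c.column_group for c in cells))
    width = 26
    out = [" " * 34 + "".join(f"{g[:24]:>{width}}" for g in groups)]
    for lam in lams:
        row = {c.column_group: c for c in cells if c.lambda_magnitude == lam}

        def line(label, fmt):
            vals = "".join(f"{fmt(row[g]):>{width}}" for g in groups if g in row)
            return f"{lam:<6}{label:<28}{vals}"

        out.append(line("Proper solutions (%)", lambda c: f"{c.proper_rate:.1f}%"))
        out.append(
            line(
                "Average loading",
                lambda c: f"{c.mean_avg_loading:.2f} ({c.sd_avg_loading:.2f})",
            )
        )
        out.append(
            line(
                "Average loading (min-max)",
                lambda c: f"{c.min_loading:.2f}-{c.max_loading:.2f}",
            )
        )
        out.append(line("C_k", lambda c: f"{c.mean_ck:.2f} ({c.sd_ck:.2f})"))
        out.append(line("RMSEA", lambda c: f"{c.mean_rmsea:.2f} ({c.sd_rmsea:.2f})"))
        out.append(line("CFI", lambda c: f"{c.mean_cfi:.2f} ({c.sd_cfi:.2f})"))
    return "\n".join(out)


def rank_congruence_vs_p(results: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Rank proper solutions by congruence and pair with chi-square p-values.

    Rank 1 is the highest C_k; ties share mean ranks. Returns the
    (ck_rank, p_value) table and the Spearman rank correlation between C_k
    and the chi-square p-value — the study's "no relationship" scatter.
    """
    proper = results[(results["status"] == "proper")].dropna(subset=["ck", "p_value"])
    ck = proper["ck"].to_numpy()
    pv = proper["p_value"].to_numpy()
    ranks = stats.rankdata(-ck, method="average")
    table = pd.DataFrame({"ck": ck, "ck_rank": ranks, "p_value": pv})
    rho = float(stats.spearmanr(ck, pv).statistic) if len(ck) > 1 else float("nan")
    return table, rho


def plot_congruence_vs_p(table: pd.DataFrame, path) -> None:
    """Scatter of congruence ranking (x) against chi-square p-value (y)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(table["ck_rank"], table["p_value"], s=4, alpha=0.3)
    ax.set_xlabel("Ranking of coefficient of congruence (1 = highest $C_k$)")
    ax.set_ylabel(r"$\chi^2$ p-value")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
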