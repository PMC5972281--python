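"""Orchestration of the full simulation study.

Runs the condition grid (by default 3 loading magnitudes x 5 indicator
counts x 4 sample sizes, 1,000 replications each), fitting every replication
by the requested discrepancy functions and collecting per-replication
records plus the pooled summary table. Fully reproducible from one master
seed; every (condition, CASE) pair owns a seed substream so single
replications are regenerable in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import (congruence, format_summary, rank_congruence_vs_p,
                         summarize_conditions, summary_table)
from .exceptions import CaseLookupError
from .model import OneFactorCFA
from .population import (DEFAULT_N_REPLICATIONS, SimulationCondition,
                         study_grid)
from .simulate import SampleData, compute_moments, generate_replication

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "method", "CASE", "lambda_pop", "p", "n", "status", "converged",
    "n_iterations", "f_min", "chi2", "df", "p_value", "rmsea", "cfi",
    "avg_loading", "ck",
]


@dataclass
class StudyConfig:
    """Configuration of one study run."""

    grid: list[SimulationCondition] = field(default_factory=list)
    methods: tuple[str, ...] = ("ml",)
    master_seed: int = 0
    n_replications: int = DEFAULT_N_REPLICATIONS
    output_dir: str | None = None
    compute_se: bool = False
    write_raw_data: bool = False

    def __post_init__(self):
        if not self.grid:
            self.grid = study_grid(self.master_seed, self.n_replications)
        self.methods = tuple(m.lower() for m in self.methods)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        """Load a config from a YAML file declaring grid, seed and sizes."""
        raw = yaml.safe_load(Path(path).read_text())
        seed = int(raw.get("master_seed", 0))
        reps = int(raw.get("n_replications", DEFAULT_N_REPLICATIONS))
        grid_spec = raw.get("grid", {})
        grid = study_grid(
            seed,
            reps,
            lambdas=tuple(grid_spec.get("lambdas", (0.2, 0.3, 0.4))),
            ps=tuple(grid_spec.get("p_per_k", (4, 5, 6, 7, 15))),
            ns=tuple(grid_spec.get("sample_sizes", (200, 300, 400, 500))),
        )
        return cls(
            grid=grid,
            methods=tuple(raw.get("methods", ["ml"])),
            master_seed=seed,
            n_replications=reps,
            output_dir=raw.get("output_dir"),
            compute_se=bool(raw.get("compute_se", False)),
            write_raw_data=bool(raw.get("write_raw_data", False)),
        )


def _fit_record(sample: SampleData, method: str, compute_se: bool) -> dict:
    cond = sample.condition
    rec = {
        "method": method.upper(),
        "CASE": sample.case_id,
        "lambda_pop": cond.lambda_magnitude,
        "p": cond.p_per_k,
        "n": cond.sample_size,
    }
    try:
        fit = OneFactorCFA(compute_moments(sample)).fit(method)
    except Exception as exc:  # per-replication failures never abort the study
        logger.warning("CASE %s (%s) failed: %s", sample.case_id, cond.label, exc)
        rec.update(status="error", converged=False)
        return rec
    rec.update(
        status=fit.status,
        converged=fit.converged,
        n_iterations=fit.n_iterations,
        f_min=fit.f_min,
    )
    std = fit.standardized_loadings
    for i, v in enumerate(std):
        rec[f"lam{i + 1}"] = v
    if fit.converged:
        rec["avg_loading"] = float(std.mean())
        rec["ck"] = congruence(std, cond.population.loadings).c_k
        if fit.model.spec.df >= 1:
            fi = fit.fit_indices
            rec.update(
                chi2=fi.chi_square, df=fi.df, p_value=fi.p_value,
                rmsea=fi.rmsea, cfi=fi.cfi,
            )
        if compute_se and method == "ml" and fit.is_proper:
            se = fit.bse
            for i, v in enumerate(se):
                rec[f"se{i + 1}"] = v
    return rec


def run_condition(
    condition: SimulationCondition,
    methods=("ml",),
    master_seed: int | None = None,
    compute_se: bool = False,
) -> pd.DataFrame:
    """All replications of one condition; one row per method x replication."""
    rows = []
    for rep in range(1, condition.n_replications + 1):
        sample = generate_replication(condition, rep, master_seed)
        for method in methods:
            rows.append(_fit_record(sample, method, compute_se))
    df = pd.DataFrame(rows)
    counts = df.groupby("method")["status"].value_counts()
    logger.info("condition %s done: %s", condition.label, counts.to_dict())
    return df


def run_study(config: StudyConfig) -> dict[str, pd.DataFrame]:
    """Run every condition of the grid for every method.

    Returns one per-replication results table per method. When
    ``config.output_dir`` is set, writes per-method results CSVs, the pooled
    summary (CSV + text), the congruence-rank vs p-value table, and
    optionally the per-condition raw-data deposit files.
    """
    frames = []
    for cond in config.grid:
        frames.append(
            run_condition(cond, config.methods, config.master_seed, config.compute_se)
        )
        if config.write_raw_data and config.output_dir:
            from .simulate import write_condition_csv

            samples = [
                generate_replication(cond, rep, config.master_seed)
                for rep in range(1, cond.n_replications + 1)
            ]
            write_condition_csv(samples, Path(config.output_dir) / "raw")
    all_results = pd.concat(frames, ignore_index=True)
    by_method = {
        m: all_results[all_results["method"] == m.upper()].reset_index(drop=True)
        for m in config.methods
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for m, df in by_method.items():
            df.to_csv(out / f"results_{m}.csv", index=False)
            cells = summarize_conditions(df)
            summary_table(cells).to_csv(out / f"summary_{m}.csv", index=False)
            (out / f"summary_{m}.txt").write_text(format_summary(cells) + "\n")
            table, rho = rank_congruence_vs_p(df)
            table.to_csv(out / f"congruence_rank_{m}.csv", index=False)
            if len(table):
                from .evaluation import plot_congruence_vs_p

                plot_congruence_vs_p(table, out / f"congruence_rank_{m}.png")
            logger.info("method %s: Spearman rho(C_k, p-value) = %.4f", m, rho)
    return by_method


def locate_case(
    case_id: int,
    results: pd.DataFrame,
    master_seed: int,
    lambda_pop: float | None = None,
    p: int | None = None,
    n: int | None = None,
    n_replications: int = DEFAULT_N_REPLICATIONS,
) -> tuple[SampleData, pd.DataFrame]:
    """Regenerate the raw data behind one CASE and return its fit records.

    CASE numbering is 1-based and sequential within each condition, so the
    condition labels (lambda_pop, p, n) disambiguate when a results table
    spans several conditions.
    """
    sel = results[results["CASE"] == case_id]
    for col, val in (("lambda_pop", lambda_pop), ("p", p), ("n", n)):
        if val is not None:
            sel = sel[sel[col] == val]
    if sel.empty:
        raise CaseLookupError(f"CASE {case_id} not found in results")
    conds = sel[["lambda_pop", "p", "n"]].drop_duplicates()
    if len(conds) > 1:
        raise CaseLookupError(
            f"CASE {case_id} is ambiguous across conditions; pass lambda_pop/p/n"
        )
    lam, pp, nn = conds.iloc[0]
    cond = SimulationCondition(float(lam), int(pp), int(nn), n_replications, master_seed)
    sample = generate_replication(cond, int(case_id), master_seed)
    return sample, sel
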