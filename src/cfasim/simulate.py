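"""Replicate data generation and sample moment matrices.

Each replication draws N rows of ``x = lambda * xi + delta`` with a standard
normal common factor ``xi`` and independent normal unique terms ``delta_i``
with variance ``theta_i``. Seeding is hierarchical: every (condition,
replicate) pair owns its own deterministic substream, so any single
replication (CASE) can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, InvalidThresholdError
from .population import PopulationModel, SimulationCondition


@dataclass
class SampleData:
    """One replication's N x p raw data matrix with its provenance labels."""

    data: np.ndarray
    condition: SimulationCondition | None = None
    replicate_index: int = 1
    case_id: int = 1

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def p(self) -> int:
        return self.data.shape[1]


@dataclass
class MomentMatrices:
    """Sample covariance S and correlation R for one replication."""

    covariance: np.ndarray
    correlation: np.ndarray
    n: int

    @property
    def p(self) -> int:
        return self.covariance.shape[0]


def replication_seed_sequence(
    master_seed: int, condition: SimulationCondition, replicate_index: int
) -> np.random.SeedSequence:
    """Deterministic substream for one replication of one condition.

    The entropy pool mixes the master seed with the condition labels and the
    1-based replicate index, so a replication is addressable without
    generating any of its predecessors.
    """
    return np.random.SeedSequence(
        [
            int(master_seed),
            round(100 * condition.lambda_magnitude),
            int(condition.p_per_k),
            int(condition.sample_size),
            int(replicate_index),
        ]
    )


def generate_sample(
    model: PopulationModel,
    n: int,
    rng: np.random.Generator | np.random.SeedSequence | int,
    condition: SimulationCondition | None = None,
    replicate_index: int = 1,
) -> SampleData:
    """Draw one N x p sample from the common factor model.

    Each row is ``lambda * xi + delta`` with ``xi ~ N(0, phi)`` and
    ``delta_i ~ N(0, theta_i)`` independent. Deterministic given ``rng``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p = model.p
    if n <= p:
        raise DegenerateDataError(
            f"n = {n} <= p = {p}: sample covariance would be rank-deficient"
        )
    xi = rng.standard_normal(n) * np.sqrt(model.factor_variance)
    delta = rng.standard_normal((n, p)) * np.sqrt(model.unique_variances)
    x = xi[:, None] * model.loadings[None, :] + delta
    return SampleData(
        data=x, condition=condition, replicate_index=replicate_index,
        case_id=replicate_index,
    )


def generate_replication(
    condition: SimulationCondition, replicate_index: int, master_seed: int | None = None
) -> SampleData:
    """Regenerate one CASE of a condition from its seed substream."""
    seed = condition.seed if master_seed is None else master_seed
    ss = replication_seed_sequence(seed, condition, replicate_index)
    return generate_sample(
        condition.population,
        condition.sample_size,
        np.random.default_rng(ss),
        condition=condition,
        replicate_index=replicate_index,
    )


def compute_moments(sample: SampleData | np.ndarray) -> MomentMatrices:
    """Sample covariance (denominator n - 1) and derived correlation matrix."""
    x = sample.data if isinstance(sample, SampleData) else np.asarray(sample, float)
    n, p = x.shape
    if n <= p:
        raise DegenerateDataError("need n > p observations for moment matrices")
    s = np.cov(x, rowvar=False, ddof=1)
    d = np.sqrt(np.diag(s))
    if np.any(d <= 0):
        raise DegenerateDataError("zero-variance column: correlation undefined")
    r = s / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return MomentMatrices(covariance=s, correlation=r, n=n)


def discretize(sample: SampleData, thresholds) -> SampleData:
    """Recode continuous indicators into ordered categories via thresholds.

    Each value maps to the number of thresholds it exceeds, giving categories
    0 .. len(thresholds).
    """
    t = np.asarray(thresholds, dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise InvalidThresholdError("thresholds must be strictly ascending")
    coded = np.searchsorted(t, sample.data, side="left")
    return SampleData(
        data=coded,
        condition=sample.condition,
        replicate_index=sample.replicate_index,
        case_id=sample.case_id,
    )


def write_condition_csv(
    samples: list[SampleData], out_dir: str | Path, label: str | None = None
) -> Path:
    """Write all replications of one condition to a single CSV deposit file.

    Columns: CASE (replicate id), REP_ROW (row within replicate), X1..Xp.
    File name follows the N{N}L{100*lambda} deposit convention.
    """
    if not samples:
        raise DegenerateDataError("no samples to write")
    cond = samples[0].condition
    if label is None:
        label = cond.label if cond is not None else "samples"
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for s in samples:
        df = pd.DataFrame(s.data, columns=[f"X{i + 1}" for i in range(s.p)])
        df.insert(0, "REP_ROW", np.arange(1, s.n + 1))
        df.insert(0, "CASE", s.case_id)
        frames.append(df)
    path = out_dir / f"{label}.csv"
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path
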