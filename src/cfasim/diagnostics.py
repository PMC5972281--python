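"""Case-study diagnostics: positive definiteness and multivariate outliers.

Tools for dissecting a single problematic replication: an eigenvalue check
of the input moment matrix (the PCA route to positive definiteness), squared
Mahalanobis-distance screening of cases against the chi-square(p) upper-alpha
quantile, and refitting after removal of flagged cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .evaluation import CongruenceResult, congruence
from .exceptions import DegenerateDataError, EstimationInputError
from .model import CFAResults, OneFactorCFA
from .simulate import SampleData, compute_moments

_PD_TOL = 1e-10


def is_positive_definite(matrix) -> tuple[bool, np.ndarray]:
    """Eigenvalue check of a symmetric matrix.

    Returns (all eigenvalues > 1e-10, ascending eigenvalues). Inputs with
    asymmetry below 1e-8 are symmetrized; larger asymmetry is an error.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise EstimationInputError("need a square matrix")
    asym = np.max(np.abs(m - m.T)) if m.size else 0.0
    if asym >= 1e-8:
        raise EstimationInputError(f"matrix asymmetry {asym:.2e} exceeds 1e-8")
    w = linalg.eigvalsh(0.5 * (m + m.T))
    return bool(w[0] > _PD_TOL), w


@dataclass
class OutlierReport:
    """Mahalanobis screening result for one raw-data matrix."""

    distances: np.ndarray  # squared Mahalanobis distances, length N
    flagged: np.ndarray  # indices with distance above the cutoff
    alpha: float
    cutoff: float


def mahalanobis_outliers(data: SampleData | np.ndarray, alpha: float = 0.05) -> OutlierReport:
    """Flag cases whose squared Mahalanobis distance is significant at alpha.

    Distances use the n-1 sample covariance; the cutoff is the upper-alpha
    quantile of chi-square(p), the large-sample reference for multivariate
    normal rows.
    """
    x = data.data if isinstance(data, SampleData) else np.asarray(data, float)
    n, p = x.shape
    if n <= p:
        raise DegenerateDataError("need more cases than variables")
    xc = x - x.mean(axis=0)
    s = np.cov(x, rowvar=False, ddof=1)
    ok, eigs = is_positive_definite(s)
    if not ok:
        raise DegenerateDataError(
            f"sample covariance is singular (min eigenvalue {eigs[0]:.2e}); "
            "run is_positive_definite on the input first"
        )
    d2 = np.einsum("ij,ij->i", xc, linalg.solve(s, xc.T, assume_a="pos").T)
    cutoff = float(stats.chi2.ppf(1.0 - alpha, p))
    flagged = np.flatnonzero(d2 > cutoff)
    return OutlierReport(distances=d2, flagged=flagged, alpha=alpha, cutoff=cutoff)


def refit_after_removal(
    data: SampleData,
    report: OutlierReport,
    method: str = "ml",
    population_loadings=None,
) -> tuple[CFAResults, CongruenceResult | None]:
    """Drop flagged cases, refit the one-factor model, rescore congruence.

    ``population_loadings`` defaults to the generating condition's loading
    vector when the sample carries one; congruence is None when no
    population vector is available.
    """
    keep = np.setdiff1d(np.arange(data.n), report.flagged)
    if keep.size <= data.p + 1:
        raise DegenerateDataError("outlier removal leaves too few cases")
    cleaned = SampleData(
        data=data.data[keep],
        condition=data.condition,
        replicate_index=data.replicate_index,
        case_id=data.case_id,
    )
    fit = OneFactorCFA(compute_moments(cleaned)).fit(method)
    if population_loadings is None and data.condition is not None:
        population_loadings = data.condition.population.loadings
    ck = None
    if population_loadings is not None:
        ck = congruence(fit.standardized_loadings, population_loadings)
    return fit, ck
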