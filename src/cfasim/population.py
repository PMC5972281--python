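"""Population one-factor models and the simulation design grid.

The study population follows the common factor model

    Sigma = Lambda Phi Lambda' + Theta

with a single common factor (k = 1), factor variance Phi fixed to 1 for
identification, and unique variances Theta chosen as 1 - lambda^2 so every
indicator has unit variance. Under that design the implied covariance matrix
is also the implied correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .exceptions import InvalidModelError

# Design grid of the simulation study.
LAMBDA_GRID = (0.2, 0.3, 0.4)
P_GRID = (4, 5, 6, 7, 15)
N_GRID = (200, 300, 400, 500)
DEFAULT_N_REPLICATIONS = 1000


@dataclass(frozen=True)
class PopulationModel:
    """One-factor population measurement model.

    Parameters
    ----------
    loadings : array-like, shape (p,)
        Population factor loadings ``lambda_ik`` (one column, k = 1).
    factor_variance : float
        Variance ``phi`` of the common factor; fixed at 1 for identification.
    unique_variances : array-like, shape (p,), optional
        Diagonal of ``Theta``. Defaults to ``1 - loadings**2`` so that
        indicators have unit variance.
    """

    loadings: np.ndarray
    factor_variance: float = 1.0
    unique_variances: np.ndarray | None = None
    n_factors: int = field(default=1)

    def __post_init__(self):
        lam = np.atleast_1d(np.asarray(self.loadings, dtype=float))
        if lam.ndim != 1 or lam.size == 0:
            raise InvalidModelError("loadings must be a non-empty vector")
        if np.any(np.abs(lam) >= 1.0) and self.unique_variances is None:
            raise InvalidModelError(
                "unit-variance design requires |lambda| < 1; pass "
                "unique_variances explicitly otherwise"
            )
        object.__setattr__(self, "loadings", lam)
        if self.factor_variance <= 0:
            raise InvalidModelError("factor variance must be positive")
        if self.unique_variances is None:
            theta = 1.0 - self.factor_variance * lam**2
        else:
            theta = np.asarray(self.unique_variances, dtype=float)
            if theta.shape != lam.shape:
                raise InvalidModelError(
                    f"unique_variances has shape {theta.shape}, expected {lam.shape}"
                )
            if np.any(theta < 0):
                raise InvalidModelError("unique variances must be nonnegative")
        object.__setattr__(self, "unique_variances", theta)
        if self.n_factors != 1:
            raise InvalidModelError("only one-factor populations are supported")

    @property
    def p(self) -> int:
        return self.loadings.size

    @classmethod
    def equal_loading(cls, magnitude: float, p: int) -> "PopulationModel":
        """Equal-loading unit-variance model used throughout the study."""
        return cls(loadings=np.full(p, float(magnitude)))

    def implied_sigma(self) -> np.ndarray:
        """Model-implied population matrix Lambda Phi Lambda' + Theta."""
        return implied_sigma(self)


def implied_sigma(model: PopulationModel) -> np.ndarray:
    """Population matrix implied by a one-factor model.

    Returns the p x p symmetric matrix ``lambda phi lambda' + diag(theta)``;
    it has unit diagonal under the equal-loading, unit-variance design.
    """
    lam = model.loadings
    sigma = model.factor_variance * np.outer(lam, lam)
    sigma[np.diag_indices_from(sigma)] += model.unique_variances
    return sigma


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation design: loading magnitude, p/k and N."""

    lambda_magnitude: float
    p_per_k: int
    sample_size: int
    n_replications: int = DEFAULT_N_REPLICATIONS
    seed: int = 0

    def __post_init__(self):
        if self.p_per_k < 2:
            raise InvalidModelError("need at least 2 indicators")
        if self.sample_size <= self.p_per_k:
            raise InvalidModelError("sample size must exceed the indicator count")
        if self.n_replications < 1:
            raise InvalidModelError("n_replications must be positive")

    @property
    def population(self) -> PopulationModel:
        return PopulationModel.equal_loading(self.lambda_magnitude, self.p_per_k)

    @property
    def label(self) -> str:
        """File label used for the per-condition raw-data deposit, e.g. N200L020."""
        return f"N{self.sample_size}L{round(100 * self.lambda_magnitude):03d}"


def study_grid(
    master_seed: int = 0,
    n_replications: int = DEFAULT_N_REPLICATIONS,
    lambdas=LAMBDA_GRID,
    ps=P_GRID,
    ns=N_GRID,
) -> list[SimulationCondition]:
    """Cartesian design grid (full study: 3 x 5 x 4 = 60 conditions)."""
    return [
        SimulationCondition(lam, p, n, n_replications, master_seed)
        for lam, p, n in product(lambdas, ps, ns)
    ]
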