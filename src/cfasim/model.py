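"""One-factor confirmatory factor analysis by discrepancy-function minimization.

The model class follows the statsmodels convention: ``OneFactorCFA`` is built
from a sample moment matrix (or raw data) and ``fit()`` returns a
``CFAResults`` object carrying estimates, standard errors, propriety status
and goodness-of-fit indices.

Two discrepancy functions are supported:

* ML  — the normal-theory likelihood discrepancy
        F_ML(S, Sigma*) = ln|Sigma*| + tr(S Sigma*^-1) - ln|S| - p,
        conventionally fitted to the covariance matrix S;
* ULS — the unweighted least-squares discrepancy F_ULS = d'd, the sum of
        squared moment residuals, conventionally fitted to the correlation
        matrix R.

The factor variance is fixed at 1 for identification; the p loadings and p
unique variances are free. Unique variances are left unconstrained during
optimization so that Heywood cases (negative unique-variance estimates) can
occur and be detected, mirroring the behaviour of classical SEM software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .exceptions import EstimationInputError, SaturatedModelError
from .fitindices import FitIndices, compute_fit_indices
from .simulate import MomentMatrices, SampleData, compute_moments

_PEN_BASE = 1.0e4
_PEN_SLOPE = 1.0e4


@dataclass(frozen=True)
class ModelSpec:
    """Dimensional bookkeeping for the one-factor model.

    Free parameters: p loadings and p unique variances; the factor variance
    is fixed to 1, giving df = p(p+1)/2 - 2p non-redundant moments minus
    free parameters.
    """

    p: int
    n_factors: int = 1
    identification: str = "factor-variance-fixed-to-1"

    @property
    def n_free_parameters(self) -> int:
        return 2 * self.p

    @property
    def df(self) -> int:
        return self.p * (self.p + 1) // 2 - 2 * self.p


def _fml_and_grad(x: np.ndarray, s: np.ndarray, logdet_s: float, p: int):
    """ML discrepancy and its analytic gradient in (lambda, theta)."""
    lam, theta = x[:p], x[p:]
    sigma = np.outer(lam, lam)
    sigma[np.diag_indices(p)] += theta
    try:
        c, low = linalg.cho_factor(sigma, check_finite=False)
    except linalg.LinAlgError:
        # Smooth push-back toward the positive-definite region.
        w, v = linalg.eigh(sigma, check_finite=False)
        vmin = v[:, 0]
        f = _PEN_BASE + _PEN_SLOPE * (1e-8 - w[0])
        g_lam = -2.0 * _PEN_SLOPE * vmin * (vmin @ lam)
        g_theta = -_PEN_SLOPE * vmin**2
        return f, np.concatenate([g_lam, g_theta])
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    sig_inv = linalg.cho_solve((c, low), np.eye(p), check_finite=False)
    a = sig_inv @ s
    f = logdet + np.trace(a) - logdet_s - p
    g = sig_inv - a @ sig_inv  # = Sigma^-1 (Sigma - S) Sigma^-1
    return f, np.concatenate([2.0 * (g @ lam), np.diag(g)])


def _fuls_and_grad(x: np.ndarray, s: np.ndarray, _logdet_s: float, p: int):
    """ULS discrepancy (sum of squared non-redundant residuals) and gradient."""
    lam, theta = x[:p], x[p:]
    sigma = np.outer(lam, lam)
    sigma[np.diag_indices(p)] += theta
    e = sigma - s
    de = np.diag(e)
    f = 0.5 * (np.sum(e * e) + np.sum(de * de))
    m = e + np.diag(de)
    return f, np.concatenate([2.0 * (m @ lam), np.diag(m)])


class OneFactorCFA:
    """One-factor CFA model for a sample moment matrix.

    Parameters
    ----------
    moments : MomentMatrices or array-like
        Sample moments. A bare square matrix is accepted together with ``n``.
    n : int, optional
        Sample size behind the moment matrix (required for bare matrices).
    """

    def __init__(self, moments: MomentMatrices | np.ndarray, n: int | None = None):
        if isinstance(moments, MomentMatrices):
            self.moments = moments
        else:
            m = np.asarray(moments, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise EstimationInputError("moment matrix must be square")
            if not np.allclose(m, m.T, atol=1e-8):
                raise EstimationInputError("moment matrix must be symmetric")
            if n is None:
                raise EstimationInputError("n is required with a bare moment matrix")
            d = np.sqrt(np.diag(m))
            if np.any(d <= 0):
                raise EstimationInputError("moment matrix has nonpositive diagonal")
            r = m / np.outer(d, d)
            np.fill_diagonal(r, 1.0)
            self.moments = MomentMatrices(covariance=m, correlation=r, n=int(n))
        self.spec = ModelSpec(p=self.moments.p)

    @classmethod
    def from_data(cls, data: SampleData | np.ndarray) -> "OneFactorCFA":
        """Build the model from a raw N x p data matrix."""
        return cls(compute_moments(data))

    def _input_matrix(self, kind: str) -> np.ndarray:
        return self.moments.covariance if kind == "S" else self.moments.correlation

    def start_values(self, kind: str = "S") -> np.ndarray:
        """First-principal-component start: lambda0 = v1 sqrt(a1), theta0 = s_ii - lambda0^2."""
        s = self._input_matrix(kind)
        w, v = linalg.eigh(s)
        lam0 = v[:, -1] * np.sqrt(max(w[-1], 1e-8))
        if lam0.sum() < 0:
            lam0 = -lam0
        diag = np.diag(s)
        theta0 = np.maximum(diag - lam0**2, 0.05 * diag)
        return np.concatenate([lam0, theta0])

    def fit(
        self,
        method: str = "ml",
        max_iter: int = 250,
        gtol: float = 1e-6,
        input_kind: str | None = None,
    ) -> "CFAResults":
        """Minimize the requested discrepancy function.

        ML fits the covariance matrix S and ULS the correlation matrix R by
        default (``input_kind`` overrides). Convergence means the gradient
        infinity-norm fell below ``gtol`` within ``max_iter`` iterations;
        non-convergence is reported through the results status, not raised.
        """
        method = method.lower()
        if method not in ("ml", "uls"):
            raise ValueError(f"unknown estimation method: {method!r}")
        kind = input_kind or ("S" if method == "ml" else "R")
        if kind not in ("S", "R"):
            raise ValueError("input_kind must be 'S' or 'R'")
        s = self._input_matrix(kind)
        p = self.spec.p
        if p == 3:
            triad = self._fit_triad(s, method, kind)
            if triad is not None:
                return triad
        if method == "ml":
            sign, logdet_s = np.linalg.slogdet(s)
            if sign <= 0:
                raise EstimationInputError("input moment matrix is singular")
            objective = _fml_and_grad
        else:
            logdet_s = 0.0
            objective = _fuls_and_grad

        x0 = self.start_values(kind)
        res = optimize.minimize(
            objective,
            x0,
            args=(s, logdet_s, p),
            method="L-BFGS-B",
            jac=True,
            options={
                "maxiter": max_iter,
                "gtol": 1e-10,
                "ftol": 1e-14,
                "maxls": 60,
            },
        )
        f_min, grad = objective(res.x, s, logdet_s, p)
        grad_norm = float(np.max(np.abs(grad)))
        converged = bool(np.isfinite(f_min)) and grad_norm < gtol
        lam = res.x[:p].copy()
        theta = res.x[p:].copy()
        if lam.sum() < 0:  # resolve reflection invariance deterministically
            lam = -lam
        if converged and theta.min() < 0:
            status = "heywood"
        elif converged:
            status = "proper"
        else:
            status = "nonconvergent"
        return CFAResults(
            model=self,
            method=method,
            input_matrix_kind=kind,
            loadings_hat=lam,
            unique_variances_hat=theta,
            converged=converged,
            n_iterations=int(res.nit),
            f_min=float(max(f_min, 0.0)) if np.isfinite(f_min) else float("inf"),
            gradient_norm=grad_norm,
            status=status,
        )

    def _fit_triad(self, s: np.ndarray, method: str, kind: str) -> "CFAResults | None":
        """Exact saturated solution for p = 3 (df = 0).

        With three indicators the one-factor model interpolates the moment
        matrix: lambda_1 = sqrt(s12 s13 / s23) (and permutations),
        theta_i = s_ii - lambda_i^2, so every discrepancy function attains 0
        there — even when the input matrix is not positive definite, which a
        likelihood minimizer could not visit. Returns None when any
        off-diagonal vanishes or the product ratio is negative (no real
        interpolation), leaving the iterative path to decide.
        """
        s12, s13, s23 = s[0, 1], s[0, 2], s[1, 2]
        if s23 == 0 or s13 == 0 or s12 * s13 * s23 <= 0:
            return None
        lam1 = np.sqrt(s12 * s13 / s23)
        lam = np.array([lam1, s12 / lam1, s13 / lam1])
        if lam.sum() < 0:
            lam = -lam
        theta = np.diag(s) - lam**2
        return CFAResults(
            model=self,
            method=method,
            input_matrix_kind=kind,
            loadings_hat=lam,
            unique_variances_hat=theta,
            converged=True,
            n_iterations=0,
            f_min=0.0,
            gradient_norm=0.0,
            status="heywood" if theta.min() < 0 else "proper",
        )

    def fit_ml(self, max_iter: int = 250, **kw) -> "CFAResults":
        return self.fit("ml", max_iter=max_iter, **kw)

    def fit_uls(self, max_iter: int = 250, **kw) -> "CFAResults":
        return self.fit("uls", max_iter=max_iter, **kw)


@dataclass
class CFAResults:
    """Estimates, uncertainty and diagnostics from one CFA fit."""

    model: OneFactorCFA
    method: str
    input_matrix_kind: str
    loadings_hat: np.ndarray
    unique_variances_hat: np.ndarray
    converged: bool
    n_iterations: int
    f_min: float
    gradient_norm: float
    status: str
    _bse: np.ndarray | None = field(default=None, repr=False)
    _bse_available: bool | None = field(default=None, repr=False)
    _indices: FitIndices | None = field(default=None, repr=False)

    # -- propriety ---------------------------------------------------------

    def classify_solution(self) -> str:
        """'proper', 'heywood' or 'nonconvergent' (the improper filter)."""
        return self.status

    @property
    def is_proper(self) -> bool:
        return self.status == "proper"

    # -- estimates in alternative metrics ---------------------------------

    @property
    def standardized_loadings(self) -> np.ndarray:
        """Loadings rescaled to unit indicator variance: lambda_i / sqrt(s_ii).

        Equal to the unstandardized loadings when the input matrix is a
        correlation matrix (or any unit-variance covariance matrix).
        """
        diag = np.diag(self.model._input_matrix(self.input_matrix_kind))
        return self.loadings_hat / np.sqrt(diag)

    @property
    def average_standardized_loading(self) -> float:
        return float(self.standardized_loadings.mean())

    def residual_vector(self) -> np.ndarray:
        """Non-redundant predicted-minus-observed moment residuals d.

        Includes the diagonal when fitting S; the fixed unit diagonal is
        excluded when the input is a correlation matrix.
        """
        p = self.model.spec.p
        sigma = np.outer(self.loadings_hat, self.loadings_hat)
        sigma[np.diag_indices(p)] += self.unique_variances_hat
        e = sigma - self.model._input_matrix(self.input_matrix_kind)
        i, j = np.tril_indices(p, k=0 if self.input_matrix_kind == "S" else -1)
        return e[i, j]

    # -- uncertainty -------------------------------------------------------

    def _information(self) -> np.ndarray:
        """Numerical Hessian of the ML discrepancy at the optimum."""
        p = self.model.spec.p
        s = self.model._input_matrix(self.input_matrix_kind)
        sign, logdet_s = np.linalg.slogdet(s)
        x = np.concatenate([self.loadings_hat, self.unique_variances_hat])
        k = x.size
        h = np.empty((k, k))
        step = 1e-5 * np.maximum(np.abs(x), 1.0)
        for a in range(k):
            xp, xm = x.copy(), x.copy()
            xp[a] += step[a]
            xm[a] -= step[a]
            _, gp = _fml_and_grad(xp, s, logdet_s, p)
            _, gm = _fml_and_grad(xm, s, logdet_s, p)
            h[a] = (gp - gm) / (2.0 * step[a])
        return 0.5 * (h + h.T)

    @property
    def bse_available(self) -> bool:
        if self._bse_available is None:
            _ = self.bse
        return bool(self._bse_available)

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of the loadings (unstandardized metric, ML only).

        Inverse observed information of the ML discrepancy scaled by
        2/(n - 1). NaN (with ``bse_available`` False) when the information
        matrix is singular or the solution is improper.
        """
        if self._bse is None:
            p = self.model.spec.p
            nan = np.full(p, np.nan)
            if self.method != "ml" or not self.converged:
                self._bse, self._bse_available = nan, False
                return self._bse
            h = self._information()
            try:
                cov = 2.0 / (self.model.moments.n - 1) * linalg.inv(h)
            except linalg.LinAlgError:
                self._bse, self._bse_available = nan, False
                return self._bse
            var = np.diag(cov)[:p]
            if np.any(var <= 0) or not np.all(np.isfinite(var)):
                self._bse, self._bse_available = nan, False
            else:
                self._bse, self._bse_available = np.sqrt(var), True
        return self._bse

    @property
    def tvalues(self) -> np.ndarray:
        """t statistics lambda_i / SE_i for the unstandardized loadings."""
        return self.loadings_hat / self.bse

    # -- overall fit -------------------------------------------------------

    @property
    def fit_indices(self) -> FitIndices:
        """Chi-square test, RMSEA and CFI (requires df >= 1)."""
        if self._indices is None:
            if self.model.spec.df < 1:
                raise SaturatedModelError(
                    f"p = {self.model.spec.p} leaves df = {self.model.spec.df}"
                )
            self._indices = compute_fit_indices(
                self.f_min, self.model.moments, self.model.spec.df, self.method
            )
        return self._indices

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        p = self.model.spec.p
        lines = [
            "One-factor CFA results",
            "=" * 58,
            f"Method: {self.method.upper():>4}    Input: {self.input_matrix_kind}"
            f"    n = {self.model.moments.n}    p = {p}"
            f"    df = {self.model.spec.df}",
            f"Status: {self.status} (converged={self.converged}, "
            f"iterations={self.n_iterations}, |grad|={self.gradient_norm:.2e})",
            f"Minimized discrepancy F = {self.f_min:.6g}",
            "-" * 58,
            f"{'indicator':>10} {'loading':>9} {'std.load':>9} "
            f"{'uniq.var':>9} {'SE':>8} {'t':>8}",
        ]
        se = self.bse if self.method == "ml" and self.converged else np.full(p, np.nan)
        std = self.standardized_loadings
        for i in range(p):
            t = self.loadings_hat[i] / se[i] if np.isfinite(se[i]) else np.nan
            lines.append(
                f"{'X' + str(i + 1):>10} {self.loadings_hat[i]:9.4f} "
                f"{std[i]:9.4f} {self.unique_variances_hat[i]:9.4f} "
                f"{se[i]:8.4f} {t:8.2f}"
            )
        if self.model.spec.df >= 1:
            fi = self.fit_indices
            lines += [
                "-" * 58,
                f"chi2({fi.df}) = {fi.chi_square:.4f}   p = {fi.p_value:.4f}   "
                f"RMSEA = {fi.rmsea:.4f}   CFI = {fi.cfi:.4f}",
            ]
        return "\n".join(lines)
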