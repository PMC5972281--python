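"""Overall-fit chi-square test and the RMSEA / CFI indices.

Definitions follow the standard SEM literature (Steiger-Lind RMSEA, Bentler
CFI) with the LISREL-style (n - 1) multiplier on the minimized discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import EstimationInputError, SaturatedModelError
from .simulate import MomentMatrices


@dataclass
class FitIndices:
    chi_square: float
    df: int
    p_value: float
    rmsea: float
    cfi: float
    baseline_chi_square: float
    baseline_df: int
    # ULS chi-squares use the same (n-1)*F transformation as ML but are not
    # on the likelihood-ratio scale; flagged so summaries can annotate them.
    comparable: bool = True


def chi_square_test(f_min: float, n: int, df: int) -> tuple[float, float]:
    """Likelihood-ratio chi-square ``(n - 1) * F`` and its upper-tail p-value."""
    if df <= 0:
        raise SaturatedModelError("chi-square test undefined for df <= 0")
    if f_min < 0:
        f_min = 0.0
    chi2 = (n - 1) * f_min
    return chi2, float(stats.chi2.sf(chi2, df))


def rmsea(chi_square: float, df: int, n: int) -> float:
    """Root-mean-square error of approximation.

    sqrt(max(chi2 - df, 0) / (df * (n - 1))); zero whenever chi2 <= df.
    """
    if df < 1 or n < 2:
        raise SaturatedModelError("RMSEA requires df >= 1 and n >= 2")
    return float(np.sqrt(max(chi_square - df, 0.0) / (df * (n - 1))))


def cfi(
    chi_square: float,
    df: int,
    baseline_chi_square: float,
    baseline_df: int,
    form: str = "ratio",
) -> float:
    """Comparative fit index against the independence baseline.

    ``form='ratio'`` (default) is the raw noncentrality ratio
    1 - (chi2 - df)/(chi2_b - df_b) clipped to [0, 1] — the relative
    noncentrality index as printed by classical SEM software, which goes to
    zero when the sample baseline noncentrality estimate is negative while
    the target model's is not smaller. ``form='bentler'`` applies Bentler's
    max(., 0) truncations to both noncentralities before taking the ratio;
    the two agree whenever the baseline noncentrality estimate is positive
    and dominant, i.e. everywhere except very weakly correlated data.
    """
    t = chi_square - df
    b = baseline_chi_square - baseline_df
    if form == "bentler":
        num = max(t, 0.0)
        den = max(t, b, 0.0)
        if den == 0.0:
            return 1.0
        return float(np.clip(1.0 - num / den, 0.0, 1.0))
    if form != "ratio":
        raise ValueError(f"unknown CFI form: {form!r}")
    if b == 0.0:
        return 1.0 if t <= 0 else 0.0
    return float(np.clip(1.0 - t / b, 0.0, 1.0))


def independence_model(
    moments: MomentMatrices, n: int | None = None, method: str = "ml"
) -> tuple[float, int]:
    """Baseline (zero-covariance) model chi-square and df.

    Under ML the diagonal implied matrix fits the variances exactly, so the
    minimized discrepancy reduces to -ln|R| and the baseline chi-square is
    -(n - 1) ln|R| with df = p(p - 1)/2. The same statistic is used as the
    ULS baseline for comparability of CFI within an estimation run.
    """
    if n is None:
        n = moments.n
    r = moments.correlation
    p = r.shape[0]
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise EstimationInputError("correlation matrix is singular")
    chi2_b = max(-(n - 1) * logdet, 0.0)
    return float(chi2_b), p * (p - 1) // 2


def compute_fit_indices(
    f_min: float, moments: MomentMatrices, df: int, method: str = "ml"
) -> FitIndices:
    """Bundle chi-square, p, RMSEA and CFI for one fitted model."""
    n = moments.n
    chi2, p_value = chi_square_test(f_min, n, df)
    chi2_b, df_b = independence_model(moments, n, method)
    return FitIndices(
        chi_square=chi2,
        df=df,
        p_value=p_value,
        rmsea=rmsea(chi2, df, n),
        cfi=cfi(chi2, df, chi2_b, df_b),
        baseline_chi_square=chi2_b,
        baseline_df=df_b,
        comparable=(method.lower() == "ml"),
    )
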