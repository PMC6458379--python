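"""Durbin-Watson statistic, exact null moments and the beta-approximation test.

The statistic d = SSRFD / SSR (sum of squared residual forward differences
over the residual sum of squares) is ~2 for uncorrelated residuals and
falls toward 0 under positive serial correlation.  Its null distribution
depends on the design: Durbin & Watson's exact first two moments are

    E(d) = p / (N - k - 1),
    V(d) = 2 (q - p E(d)) / ((N - k - 1)(N - k + 1)),

with p and q trace expressions in the tridiagonal difference-quadratic-form
matrix A and the hat projection.  For GLS the test is applied to the
P-transformed residuals (P the principal square root of S^-1); the same
trace expressions apply with X'P'APX and (X'S^-1X)^-1 substituted.

Tail probabilities model d/4 as Beta(a, b) with moments matched to
E(d), V(d); the two-tailed probability is 2 * min(F(d/4), 1 - F(d/4)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .correlation import CorrelationModel
from .data import DesignMatrix


def forward_difference_matrix(N: int) -> np.ndarray:
    """Tridiagonal matrix A with e'Ae = sum of squared forward differences."""
    if N < 2:
        raise ValueError("N must be >= 2")
    A = np.zeros((N, N))
    i = np.arange(N)
    A[i, i] = 2.0
    A[0, 0] = 1.0
    A[-1, -1] = 1.0
    A[i[:-1], i[:-1] + 1] = -1.0
    A[i[:-1] + 1, i[:-1]] = -1.0
    return A


def dw_statistic(e) -> Tuple[float, float, float]:
    """Durbin-Watson statistic of a residual vector.

    Returns ``(d, ssrfd, ssr)``.
    """
    e = np.asarray(e, dtype=float).ravel()
    if e.size < 3:
        raise ValueError("need at least 3 residuals")
    ssr = float(e @ e)
    if ssr == 0.0:
        raise ValueError("residual vector is identically zero")
    ssrfd = float(np.sum(np.diff(e) ** 2))
    return ssrfd / ssr, ssrfd, ssr


def _apply_A(M: np.ndarray) -> np.ndarray:
    # A @ M without forming A: second differences with free boundaries
    out = 2.0 * M
    out[0] = M[0]
    out[-1] = M[-1]
    out[:-1] -= M[1:]
    out[1:] -= M[:-1]
    return out


def dw_moments(design: DesignMatrix, model: Optional[CorrelationModel] = None
               ) -> Tuple[float, float]:
    """Exact null moments E(d), V(d) of the Durbin-Watson statistic.

    With ``model`` None or identity these are the OLS-residual moments;
    otherwise the transformed-residual (GLS) moments, using the model's
    principal transform P.  The OLS path never forms A or any N x N
    product, so it is usable at very large N.
    """
    X = design.X
    N, kp1 = X.shape
    k = kp1 - 1
    if N - k - 1 <= 0 or N - k + 1 <= 0:
        raise ValueError("too few observations for DW moments")
    trA = 2.0 * N - 2.0
    trA2 = 6.0 * N - 8.0
    if model is None or model.kind == "identity":
        G = np.linalg.inv(X.T @ X)
        AX = _apply_A(X.copy())
    else:
        PX = model.P @ X
        G = np.linalg.inv(X.T @ model.S_inv @ X)
        AX = _apply_A(PX.copy())
        X = PX
    XtAX = X.T @ AX          # X'AX (or X'P'APX)
    XtA2X = AX.T @ AX        # X'A'AX = X'A^2X (A symmetric)
    M = XtAX @ G
    p = trA - np.trace(M)
    q = trA2 - 2.0 * np.trace(XtA2X @ G) + np.trace(M @ M)
    E_d = p / (N - k - 1)
    V_d = 2.0 * (q - p * E_d) / ((N - k - 1) * (N - k + 1))
    if V_d <= 0:
        raise ValueError("non-positive DW variance: degenerate design")
    return float(E_d), float(V_d)


@dataclass
class DWReport:
    """Durbin-Watson test outcome.

    ``verdict`` is "pass" when d lies inside the central 1-alpha beta
    interval (no evidence of residual correlation), "fail" otherwise.
    ``context`` records whether raw OLS residuals or GLS P-transformed
    residuals were tested.
    """

    d: float
    ssrfd: float
    ssr: float
    E_d: float
    V_d: float
    beta_a: float
    beta_b: float
    p_two_tailed: float
    ci_low: float
    ci_high: float
    verdict: str
    context: str = "ols"
    alpha: float = 0.05

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"

    def summary(self) -> str:
        return (f"DW ({self.context}): d = {self.d:.4f}, E(d) = {self.E_d:.4f}, "
                f"V(d) = {self.V_d:.5f}, {100 * (1 - self.alpha):.0f}% interval "
                f"[{self.ci_low:.4f}, {self.ci_high:.4f}], two-tailed "
                f"p = {self.p_two_tailed:.4g} -> {self.verdict}")


def dw_beta_test(d: float, E_d: float, V_d: float, alpha: float = 0.05,
                 ssrfd: float = np.nan, ssr: float = np.nan,
                 context: str = "ols") -> DWReport:
    """Beta-approximation significance test for an observed d.

    d/4 ~ Beta(a, b) with a + b = E(d)(4 - E(d))/V(d), a = (a+b) E(d)/4.
    """
    if not (0 < E_d < 4):
        raise ValueError("E_d must lie in (0, 4)")
    if V_d <= 0:
        raise ValueError("V_d must be positive")
    ab = E_d * (4.0 - E_d) / V_d
    a = ab * E_d / 4.0
    b = ab - a
    if a <= 0 or b <= 0:
        raise ValueError(f"invalid beta parameters a={a:.3g}, b={b:.3g}")
    F = stats.beta.cdf(d / 4.0, a, b)
    p_two = float(min(1.0, 2.0 * min(F, 1.0 - F)))
    lo = 4.0 * stats.beta.ppf(alpha / 2.0, a, b)
    hi = 4.0 * stats.beta.ppf(1.0 - alpha / 2.0, a, b)
    verdict = "pass" if lo <= d <= hi else "fail"
    return DWReport(d=float(d), ssrfd=float(ssrfd), ssr=float(ssr),
                    E_d=E_d, V_d=V_d, beta_a=float(a), beta_b=float(b),
                    p_two_tailed=p_two, ci_low=float(lo), ci_high=float(hi),
                    verdict=verdict, context=context, alpha=alpha)


def dw_test_ols(fit, alpha: float = 0.05) -> DWReport:
    """DW test of the raw residuals of an OLS (or OLS-like) fit."""
    d, ssrfd, ssr = dw_statistic(fit.resid)
    E_d, V_d = dw_moments(fit.design)
    return dw_beta_test(d, E_d, V_d, alpha=alpha, ssrfd=ssrfd, ssr=ssr,
                        context="ols")


def dw_test_gls(fit, alpha: float = 0.05) -> DWReport:
    """DW test of the P-transformed residuals of a GLS fit.

    d = e'P'APe / e'S^-1e with the untransformed GLS residuals e, tested
    against the transformed-residual null moments.
    """
    if fit.method != "gls" or fit.corr_model is None:
        raise ValueError("dw_test_gls requires a GLS fit")
    model = fit.corr_model
    if model.kind == "identity":
        rep = dw_test_ols(fit, alpha=alpha)
        rep.context = "gls_transformed"
        return rep
    e = fit.resid
    Pe = model.P @ e
    ssr = float(e @ model.S_inv @ e)
    if ssr == 0.0:
        raise ValueError("residual vector is identically zero")
    ssrfd = float(np.sum(np.diff(Pe) ** 2))
    d = ssrfd / ssr
    E_d, V_d = dw_moments(fit.design, model)
    return dw_beta_test(d, E_d, V_d, alpha=alpha, ssrfd=ssrfd, ssr=ssr,
                        context="gls_transformed")
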