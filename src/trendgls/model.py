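"""OLS/GLS trend estimation.

The user-facing objects follow the model/results convention: build a
:class:`TrendModel` from data, call :meth:`TrendModel.fit` and read
estimates, standard errors and diagnostics off the returned
:class:`TrendResults`.  The module-level functions :func:`fit_ols`,
:func:`fit_gls` and :func:`cochrane_orcutt` are the underlying estimation
primitives and are also part of the public API.

GLS solves b = (X'S^-1 X)^-1 X'S^-1 y with residual scale
s^2 = e'S^-1 e / (N-k-1) and coefficient standard errors
s_bi = s * sqrt([(X'S^-1 X)^-1]_ii), where e = y - Xb are the
*untransformed* residuals.  Linear systems go through Cholesky /
least-squares decompositions; the explicit inverse of X'S^-1X is formed
only for the standard-error diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .correlation import CorrelationModel, clamp_rho
from .data import Dataset, DesignMatrix, build_polynomial_design, build_covariate_design

#: residual scale below this times the response scale counts as a perfect fit
PERFECT_FIT_RTOL = 1e-10


def is_equally_spaced(coords: np.ndarray, rtol: float = 1e-8) -> bool:
    c = np.asarray(coords, dtype=float)
    if c.ndim == 2:
        if c.shape[1] != 1:
            return False
        c = c[:, 0]
    d = np.diff(np.sort(c))
    if d.size == 0 or d[0] <= 0:
        return False
    return bool(np.allclose(d, d[0], rtol=rtol, atol=rtol * abs(d[0])))


@dataclass
class TrendResults:
    """Estimation results.

    Attributes
    ----------
    params, bse, tvalues : arrays of length k+1
        Coefficient estimates b, standard errors s_bi and t = b / s_bi.
        For a perfect fit (s = 0) the t-values are NaN, not infinite.
    resid : array
        Untransformed residuals e = y - Xb.
    s : float
        Residual standard error (sqrt of e'S^-1 e / df_resid for GLS).
    df_resid : int
        N - k - 1.
    method : str
        "ols", "gls" or "cochrane_orcutt".
    corr_model : CorrelationModel or None
        The correlation structure used (None for plain OLS).
    """

    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    resid: np.ndarray
    s: float
    df_resid: int
    method: str
    design: DesignMatrix
    y: np.ndarray
    corr_model: Optional[CorrelationModel] = None
    perfect_fit: bool = False
    model: Optional["TrendModel"] = None
    extra: dict = field(default_factory=dict)

    @property
    def nobs(self) -> int:
        return self.y.shape[0]

    @property
    def k(self) -> int:
        return self.design.k

    @property
    def pvalues(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return 2 * stats.t.sf(np.abs(self.tvalues), self.df_resid)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.design.X @ self.params

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return np.column_stack([self.params - q * self.bse, self.params + q * self.bse])

    def dw_report(self, alpha: float = 0.05):
        """Durbin-Watson test appropriate to the estimation method.

        OLS fits test the raw residuals; GLS fits test the P-transformed
        residuals with the matching null moments.
        """
        from . import durbin_watson as dw
        if self.method == "gls" and self.corr_model is not None \
                and self.corr_model.kind != "identity":
            return dw.dw_test_gls(self, alpha=alpha)
        return dw.dw_test_ols(self, alpha=alpha)

    def predict(self, x0, alpha: float = 0.05):
        """Pointwise prediction band at raw evaluation points ``x0``."""
        from .prediction import prediction_interval
        return prediction_interval(self.y, self.design,
                                   self.corr_model or CorrelationModel.identity(self.nobs),
                                   x0, alpha=alpha)

    def summary(self) -> str:
        lines = []
        tag = self.method.upper()
        cm = self.corr_model
        corr = "" if cm is None or cm.kind == "identity" else f" [{cm!r}]"
        lines.append(f"{tag} trend fit{corr}")
        lines.append(f"N = {self.nobs}, k = {self.k}, df_resid = {self.df_resid}, "
                     f"s = {self.s:.6g}")
        lines.append(f"{'term':>12} {'estimate':>14} {'std err':>12} {'t':>9} {'Pr(>|t|)':>10}")
        for name, b, se, t, p in zip(self.design.names, self.params, self.bse,
                                     self.tvalues, self.pvalues):
            lines.append(f"{name:>12} {b:>14.6g} {se:>12.4g} {t:>9.3f} {p:>10.4g}")
        if self.perfect_fit:
            lines.append("note: perfect fit (s = 0); t-values undefined")
        return "\n".join(lines)


def _finalize(design: DesignMatrix, y: np.ndarray, b: np.ndarray,
              cov_unscaled: np.ndarray, ssr_weighted: float, method: str,
              corr_model: Optional[CorrelationModel]) -> TrendResults:
    N, kp1 = design.X.shape
    dof = N - kp1
    if dof < 1:
        raise ValueError(f"need N >= k+2 observations; N={N}, k={kp1 - 1}")
    e = y - design.X @ b
    s2 = ssr_weighted / dof
    yscale = max(float(np.sqrt(np.mean(y ** 2))), 1.0)
    perfect = np.sqrt(max(s2, 0.0)) <= PERFECT_FIT_RTOL * yscale
    se = np.sqrt(np.clip(s2 * np.diag(cov_unscaled), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / np.where(se > 0, se, 1.0), np.nan)
    if perfect:
        t = np.full_like(b, np.nan)
    return TrendResults(params=b, bse=se, tvalues=t, resid=e,
                        s=float(np.sqrt(max(s2, 0.0))), df_resid=dof,
                        method=method, design=design, y=y,
                        corr_model=corr_model, perfect_fit=perfect)


def fit_ols(design: DesignMatrix, y) -> TrendResults:
    """Ordinary least squares: b = (X'X)^-1 X'y via QR least squares."""
    y = np.asarray(y, dtype=float).ravel()
    X = design.X
    if y.shape[0] != X.shape[0]:
        raise ValueError("y length does not match design")
    b, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    e = y - X @ b
    cov_unscaled = linalg.inv(X.T @ X)
    return _finalize(design, y, b, cov_unscaled, float(e @ e), "ols", None)


def fit_gls(design: DesignMatrix, y, model: CorrelationModel) -> TrendResults:
    """Generalized least squares under the given correlation structure.

    With the identity structure this routine defers to :func:`fit_ols`
    (same code path, exactly equal output).
    """
    y = np.asarray(y, dtype=float).ravel()
    if model.kind == "identity":
        res = fit_ols(design, y)
        res.corr_model = model
        res.method = "gls"
        return res
    X = design.X
    if y.shape[0] != X.shape[0] or model.N != X.shape[0]:
        raise ValueError("y, design and correlation model sizes disagree")
    if model.kind == "ar1":
        # Prais-Winsten banded transform: S^-1 = W'W with
        # W = [sqrt(1-rho^2) row 1; rows x_i - rho x_{i-1}] / sqrt(1-rho^2),
        # so all products are O(N k^2) and no N x N matrix is formed
        rho = model.rho
        scale = 1.0 / np.sqrt(1.0 - rho ** 2)
        W = np.empty_like(X)
        W[0] = X[0] * np.sqrt(1.0 - rho ** 2)
        W[1:] = X[1:] - rho * X[:-1]
        W *= scale
        v = np.empty_like(y)
        v[0] = y[0] * np.sqrt(1.0 - rho ** 2)
        v[1:] = y[1:] - rho * y[:-1]
        v *= scale
        XtSiX = W.T @ W
        rhs = W.T @ v
        try:
            c, low = linalg.cho_factor(XtSiX)
        except linalg.LinAlgError as exc:
            raise ValueError(
                "X'S^-1X is not invertible: the correlation model is "
                "unsuitable for this design") from exc
        b = linalg.cho_solve((c, low), rhs)
        cov_unscaled = linalg.cho_solve((c, low), np.eye(X.shape[1]))
        u = v - W @ b
        return _finalize(design, y, b, cov_unscaled, float(u @ u), "gls", model)
    S_inv = model.S_inv
    XtSi = X.T @ S_inv
    XtSiX = XtSi @ X
    try:
        c, low = linalg.cho_factor(XtSiX)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "X'S^-1X is not invertible: the correlation model is unsuitable "
            "for this design (try a smaller r0/rho or a different model)"
        ) from exc
    b = linalg.cho_solve((c, low), XtSi @ y)
    cov_unscaled = linalg.cho_solve((c, low), np.eye(X.shape[1]))
    e = y - X @ b
    return _finalize(design, y, b, cov_unscaled, float(e @ S_inv @ e), "gls", model)


def cochrane_orcutt(design: DesignMatrix, y, rho: float) -> TrendResults:
    """Cochrane-Orcutt estimation for equally spaced series.

    Subtracts rho times the previous observation from each row of y and X
    and runs OLS on the N-1 transformed observations (the first is lost).
    Coefficients estimate the original model's beta; results carry the
    transformed-sample residuals and N-2-k degrees of freedom.
    """
    y = np.asarray(y, dtype=float).ravel()
    rho = clamp_rho(float(rho))
    X = design.X
    N, kp1 = X.shape
    if N - 1 <= kp1:
        raise ValueError("too few observations after losing the first one")
    Xs = X[1:] - rho * X[:-1]
    ys = y[1:] - rho * y[:-1]
    b, _, rank, _ = np.linalg.lstsq(Xs, ys, rcond=None)
    if rank < kp1:
        raise ValueError("transformed design is rank deficient")
    es = ys - Xs @ b
    dof = (N - 1) - kp1
    s2 = float(es @ es) / dof
    cov_unscaled = linalg.inv(Xs.T @ Xs)
    se = np.sqrt(s2 * np.diag(cov_unscaled))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / np.where(se > 0, se, 1.0), np.nan)
    return TrendResults(params=b, bse=se, tvalues=t, resid=es,
                        s=float(np.sqrt(s2)), df_resid=dof,
                        method="cochrane_orcutt", design=design, y=y,
                        corr_model=CorrelationModel.ar1(rho, N))


class TrendModel:
    """Trend/regression model for correlated data.

    Parameters
    ----------
    dataset
        Observation locations and responses.
    design
        Regressor matrix; build with :func:`build_polynomial_design` or
        :func:`build_covariate_design`, or let the convenience
        constructors do it.

    Examples
    --------
    >>> import numpy as np
    >>> from trendgls import TrendModel
    >>> t = np.arange(2000, 2040, dtype=float)
    >>> y = 0.01 * (t - t.mean()) + np.random.default_rng(0).standard_normal(40)
    >>> res = TrendModel.from_series(t, y, degree=1).fit(method="ols")
    >>> res.params.shape
    (2,)
    """

    def __init__(self, dataset: Dataset, design: DesignMatrix):
        if dataset.n != design.n:
            raise ValueError("dataset and design sizes disagree")
        if dataset.n < design.k + 3:
            raise ValueError(f"need N >= k+3 (= {design.k + 3}) observations")
        self.dataset = dataset
        self.design = design

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_series(cls, times, y, degree: int = 1) -> "TrendModel":
        """Polynomial-in-time model for a (possibly unequally spaced) series."""
        times = np.asarray(times, dtype=float).ravel()
        return cls(Dataset(coords=times, y=y),
                   build_polynomial_design(times, degree))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str,
                       time: Optional[str] = None, degree: int = 1,
                       coords: Optional[list] = None,
                       covariates: Optional[list] = None,
                       group: Optional[str] = None,
                       distance_metric: str = "euclidean") -> "TrendModel":
        """Build from a tidy table.

        Exactly one of ``time`` (with ``degree``) or ``coords`` must be
        given.  With ``coords`` and no ``covariates`` the model regresses
        on the (centered) coordinates themselves.
        """
        if (time is None) == (coords is None):
            raise ValueError("specify exactly one of time= or coords=")
        pos = [time] if time is not None else list(coords)
        ds = Dataset.from_dataframe(df, response, pos, group=group,
                                    distance_metric=distance_metric)
        if time is not None and covariates is None:
            design = build_polynomial_design(ds.coords[:, 0], degree)
        else:
            cov_cols = covariates if covariates is not None else pos
            Z = df[cov_cols].to_numpy(dtype=float)
            design = build_covariate_design(Z, names=list(cov_cols))
        return cls(ds, design)

    @property
    def y(self) -> np.ndarray:
        return self.dataset.y

    @property
    def is_temporal(self) -> bool:
        """True for equally spaced 1-D data (AR(1) machinery applies)."""
        return self.dataset.ndim == 1 and is_equally_spaced(self.dataset.coords)

    def correlation_model(self, rho: Optional[float] = None,
                          r0: Optional[float] = None, k_d: float = 0.0) -> CorrelationModel:
        n = self.dataset.n
        if rho is not None and r0 is not None:
            raise ValueError("give rho or r0, not both")
        if rho is not None:
            if not self.is_temporal:
                raise ValueError("rho parameterization requires equally spaced 1-D data; "
                                 "use r0 for scattered points")
            return CorrelationModel.ar1(clamp_rho(rho), n)
        if r0 is not None:
            return CorrelationModel.exponential(
                r0, dist=self.dataset.distance_matrix(), k_d=k_d,
                group_ids=self.dataset.group_ids)
        return CorrelationModel.identity(n)

    def fit(self, method: str = "gls", rho: Optional[float] = None,
            r0: Optional[float] = None, k_d: float = 0.0,
            rho_method: Optional[str] = None) -> TrendResults:
        """Estimate the model.

        Parameters
        ----------
        method
            "ols", "gls" or "cochrane_orcutt".
        rho, r0
            Known correlation parameter (AR(1) rho for equally spaced
            series, exponential correlation length r0 otherwise).
        rho_method
            Estimate the correlation from the OLS residuals first:
            "acf", "dw", "ml" or "tadw" (spatial data supports "dw" and
            "tadw", routed through the nearest-new-neighbour path).
        """
        if method == "ols":
            res = fit_ols(self.design, self.y)
        elif method == "cochrane_orcutt":
            if rho is None and rho_method is not None:
                rho = self._estimate_rho(rho_method).rho_hat
            if rho is None:
                raise ValueError("cochrane_orcutt requires rho or rho_method")
            res = cochrane_orcutt(self.design, self.y, rho)
        elif method == "gls":
            if rho is None and r0 is None and rho_method is not None:
                if self.is_temporal:
                    rho = self._estimate_rho(rho_method).rho_hat
                else:
                    from .spatial import estimate_r0, nnn_path
                    path = nnn_path(self.dataset.coords,
                                    distance_metric=self.dataset.distance_metric)
                    e = fit_ols(self.design, self.y).resid
                    r0, _ = estimate_r0(e, path, self.design, method=rho_method)
            cm = self.correlation_model(rho=rho, r0=r0, k_d=k_d)
            res = fit_gls(self.design, self.y, cm)
        else:
            raise ValueError(f"unknown method {method!r}")
        res.model = self
        return res

    def fit_auto(self, alpha: float = 0.05):
        """Run the full decision procedure; see :func:`trendgls.auto_analyze`."""
        from .prediction import auto_analyze
        return auto_analyze(self, alpha=alpha)

    def _estimate_rho(self, rho_method: str):
        from . import rho as rho_mod
        e = fit_ols(self.design, self.y).resid
        if rho_method == "acf":
            return rho_mod.rho_acf(e)
        if rho_method == "dw":
            from .durbin_watson import dw_statistic
            return rho_mod.rho_dw(dw_statistic(e)[0])
        if rho_method == "ml":
            return rho_mod.rho_ml_iterated(self.design, self.y)
        if rho_method == "tadw":
            from .durbin_watson import dw_statistic, dw_moments
            d, _, _ = dw_statistic(e)
            E_d, V_d = dw_moments(self.design)
            return rho_mod.rho_tadw(d, E_d, V_d, self.dataset.n, self.design.k)
        raise ValueError(f"unknown rho_method {rho_method!r}")
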