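"""Prediction intervals and the end-to-end decision procedure.

The pointwise 100(1 - alpha)% prediction interval at evaluation point x0
is yhat0 +/- t_{alpha/2}(N-k-1) * s_p with

    s_p = sqrt( s^2 + s_b1^2 + sum_{i>=2} s_bi^2 (x0_i - xbar_i)^2 ),

which assumes mutually uncorrelated explanatory columns.  That is
arranged by sequentially residualizing each non-intercept column on its
predecessors (a change of basis that leaves fitted values untouched);
new evaluation points are pushed through the same transform.

:func:`auto_analyze` runs the full decision procedure: OLS plus a
residual Durbin-Watson test (path-ordered for scattered data); if
correlation is indicated, GLS under both the plain Durbin-Watson and the
tanh-adjusted (TADW) correlation estimates with transformed-residual DW
tests; the better-tested candidate is reported, extrapolated t-values
are attached only when both candidates test clean, both d values sit
below E(d) and the TADW one is closer, and a model-revision warning is
issued when every candidate fails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .correlation import CorrelationModel
from .data import DesignMatrix
from .durbin_watson import DWReport, dw_beta_test, dw_moments, dw_statistic, dw_test_gls
from .model import TrendModel, TrendResults, fit_gls, fit_ols
from .rho import (ExtrapolatedInference, extrapolate, rho_dw, rho_max,
                  rho_tadw)
from .spatial import (NNNPath, NoPositiveSpatialCorrelation, estimate_r0,
                      nnn_path, reduced_design, semivariogram_fit, spatial_dw)


def decorrelate_design(design: DesignMatrix) -> DesignMatrix:
    """Sequentially residualize each non-intercept column on its predecessors.

    Column j is replaced by its OLS residual on columns 0..j-1 (the
    intercept included, so every new column has zero mean).  The column
    span — and therefore any OLS/GLS fit — is unchanged; only the
    coefficient parameterization rotates.  The unit-upper-triangular
    change-of-basis matrix is recorded in ``meta['decorr_T']`` so raw
    evaluation points map through :meth:`DesignMatrix.row_for`.
    """
    X = design.X
    R = np.linalg.qr(X, mode="r")
    dR = np.diag(R).copy()
    if np.any(np.abs(dR) <= 1e-12 * max(1.0, np.abs(dR).max())):
        raise ValueError("design matrix is rank deficient")
    # X = QR  =>  sequential residual of column j is Q_j * R_jj,
    # so X_dec = X @ (R^-1 diag(R)), unit upper triangular inverse
    from scipy.linalg import solve_triangular
    T = solve_triangular(R, np.diag(dR))
    Xd = X @ T
    meta = dict(design.meta)
    prior = meta.get("decorr_T")
    meta["decorr_T"] = T if prior is None else prior @ T
    meta["decorr_means"] = Xd[:, 1:].mean(axis=0)
    return DesignMatrix(X=Xd, k=design.k, centered=design.centered,
                        decorrelated=True, names=list(design.names), meta=meta)


@dataclass
class PredictionBand:
    """Pointwise prediction band.

    ``x0`` holds the raw evaluation points, ``y0_hat`` the mean
    predictions, ``s_p`` the per-point prediction SE and ``lower``/
    ``upper`` the 100(1-alpha)% bounds.
    """

    x0: np.ndarray
    y0_hat: np.ndarray
    s_p: np.ndarray
    level: float
    lower: np.ndarray
    upper: np.ndarray
    se_mode: str = "standard"

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"x0": np.asarray(self.x0).reshape(len(self.y0_hat), -1)[:, 0],
                             "y0_hat": self.y0_hat, "s_p": self.s_p,
                             "lower": self.lower, "upper": self.upper})


def _band_from_fit(fit: TrendResults, se_b: np.ndarray, s: float,
                   design_dec: DesignMatrix, x0, alpha: float,
                   se_mode: str) -> PredictionBand:
    rows = design_dec.row_for(x0)
    xbar = np.concatenate([[0.0], design_dec.meta["decorr_means"]]) \
        if "decorr_means" in design_dec.meta else np.zeros(design_dec.k + 1)
    y0 = rows @ fit.params
    dev2 = (rows[:, 1:] - xbar[1:]) ** 2
    var = s ** 2 + se_b[0] ** 2
    if design_dec.k >= 1:
        var = var + dev2 @ (se_b[1:] ** 2)
    s_p = np.sqrt(var)
    q = stats.t.ppf(1.0 - alpha / 2.0, fit.df_resid)
    return PredictionBand(x0=np.atleast_1d(np.asarray(x0, dtype=float)),
                          y0_hat=y0, s_p=s_p, level=1.0 - alpha,
                          lower=y0 - q * s_p, upper=y0 + q * s_p,
                          se_mode=se_mode)


def prediction_interval(y, design: DesignMatrix, model: CorrelationModel,
                        x0, alpha: float = 0.05, se_mode: str = "standard",
                        model_dw: Optional[CorrelationModel] = None
                        ) -> PredictionBand:
    """Prediction band for new observations at raw points ``x0``.

    ``se_mode="standard"`` uses the GLS coefficient SEs under ``model``.
    ``se_mode="extrapolated"`` treats ``model`` as the TADW-estimated
    structure and ``model_dw`` as the plain Durbin-Watson one, widening
    each coefficient SE to 2 se_tadw - se_dw (mean predictions come from
    the TADW fit).
    """
    if not np.all(np.isfinite(np.asarray(x0, dtype=float))):
        raise ValueError("x0 contains non-finite values")
    dec = design if design.decorrelated else decorrelate_design(design)
    fit = fit_gls(dec, y, model)
    if se_mode == "standard":
        se_b = fit.bse
    elif se_mode == "extrapolated":
        if model_dw is None:
            raise ValueError("extrapolated mode needs the dw-estimate model")
        fit_dw_ = fit_gls(dec, y, model_dw)
        ex = extrapolate(fit_dw_, fit)
        se_b = ex.se_extrap
    else:
        raise ValueError(f"unknown se_mode {se_mode!r}")
    return _band_from_fit(fit, se_b, fit.s, dec, x0, alpha, se_mode)


@dataclass
class AnalysisReport:
    """Outcome of the automated decision procedure.

    ``branch`` is one of ``"ols"`` (no correlation detected),
    ``"gls_dw"``/``"gls_tadw"`` (GLS under the better-tested estimate),
    ``"extrapolated"`` (GLS candidates clean and the extrapolation gate
    satisfied) or ``"model_revision"`` (every candidate failed its
    transformed-residual test).
    """

    branch: str
    ols_fit: TrendResults
    ols_dw: DWReport
    candidates: dict = field(default_factory=dict)
    chosen: Optional[str] = None
    extrapolation: Optional[ExtrapolatedInference] = None
    path: Optional[NNNPath] = None
    semivariogram: Optional[object] = None
    notes: list = field(default_factory=list)
    alpha: float = 0.05

    @property
    def final_fit(self) -> TrendResults:
        if self.branch == "ols" or self.chosen is None:
            return self.ols_fit
        return self.candidates[self.chosen]["fit"]

    def summary(self) -> str:
        lines = ["=== automated trend analysis ==="]
        lines.append(self.ols_fit.summary())
        lines.append(self.ols_dw.summary())
        for name, c in self.candidates.items():
            rho = c["rho"].rho_hat
            extra = f", r0 = {c['r0']:.4g}" if c.get("r0") is not None else ""
            lines.append(f"--- GLS candidate [{name}]: rho = {rho:.4f}{extra}")
            lines.append(c["fit"].summary())
            lines.append(c["dw"].summary())
        if self.extrapolation is not None:
            lines.append(self.extrapolation.summary())
        for n in self.notes:
            lines.append(f"note: {n}")
        lines.append(f"branch: {self.branch}"
                     + (f" (chosen: {self.chosen})" if self.chosen else ""))
        if self.branch != "ols" and self.chosen is not None:
            naive = self.ols_fit.tvalues
            final = (self.extrapolation.t_extrap if self.branch == "extrapolated"
                     else self.final_fit.tvalues)
            lines.append("naive OLS t vs corrected t: "
                         + ", ".join(f"{n}: {a:.2f} -> {b:.2f}"
                                     for n, a, b in zip(self.ols_fit.design.names,
                                                        naive, final)))
        return "\n".join(lines)


def auto_analyze(model: TrendModel, alpha: float = 0.05) -> AnalysisReport:
    """Run the full decision procedure on a :class:`TrendModel`.

    1. OLS; Durbin-Watson test of the residuals (path-ordered for
       scattered data) against the beta-approximation interval.
    2. If d is inside the interval, report OLS.
    3. Otherwise fit GLS under both the plain DW and the TADW correlation
       estimates and test the transformed residuals.
    4. Report the candidate with the larger transformed-residual test
       probability; if both fail, flag the correlation (or trend) model
       as unsuitable and attach a semivariogram fit for diagnosis.
    5. Attach extrapolated t-values only when both candidates pass, both
       transformed d values are below their E(d), the TADW one is closer,
       and the TADW rho does not exceed rho_max(N).
    """
    ds = model.dataset
    design = model.design
    y = model.y
    ols = fit_ols(design, y)
    temporal = model.is_temporal
    notes = []
    path = None
    if temporal:
        d, ssrfd, ssr = dw_statistic(ols.resid)
        E_d, V_d = dw_moments(design)
        ols_dw = dw_beta_test(d, E_d, V_d, alpha=alpha, ssrfd=ssrfd, ssr=ssr)
    else:
        path = nnn_path(ds.coords, distance_metric=ds.distance_metric)
        d, ssrfd, ssr = spatial_dw(ols.resid, path)
        E_d, V_d = dw_moments(reduced_design(design, path))
        ols_dw = dw_beta_test(d, E_d, V_d, alpha=alpha, ssrfd=ssrfd, ssr=ssr)
        if path.m_coloc:
            notes.append(f"merged {path.m_coloc} co-located rows into "
                         f"{path.n_nodes} path nodes")

    report = AnalysisReport(branch="ols", ols_fit=ols, ols_dw=ols_dw,
                            path=path, notes=notes, alpha=alpha)
    if ols_dw.passed:
        notes.append("OLS residuals show no significant correlation; "
                     "OLS inference is adequate")
        return report

    # --- build both candidate correlation structures ---------------------
    candidates = {}
    for name in ("dw", "tadw"):
        try:
            if temporal:
                if name == "dw":
                    est = rho_dw(d)
                else:
                    est = rho_tadw(d, E_d, V_d, ds.n, design.k)
                if est.rho_hat <= 0:
                    raise NoPositiveSpatialCorrelation(
                        f"{name} estimate is non-positive")
                cm = CorrelationModel.ar1(est.rho_hat, ds.n)
                r0 = None
            else:
                r0, est = estimate_r0(ols.resid, path, design, method=name)
                cm = CorrelationModel.exponential(
                    r0, dist=ds.distance_matrix(), group_ids=ds.group_ids)
            fit = fit_gls(design, y, cm)
            dwrep = dw_test_gls(fit, alpha=alpha)
            candidates[name] = {"rho": est, "r0": r0, "fit": fit, "dw": dwrep}
        except (NoPositiveSpatialCorrelation, ValueError) as exc:
            notes.append(f"candidate {name} unavailable: {exc}")
    report.candidates = candidates
    if not candidates:
        notes.append("no positive correlation estimate available; "
                     "falling back to OLS")
        return report

    passing = {n: c for n, c in candidates.items() if c["dw"].passed}
    if not passing:
        report.branch = "model_revision"
        best = max(candidates, key=lambda n: candidates[n]["dw"].p_two_tailed)
        report.chosen = best
        notes.append("no candidate passes the transformed-residual test: the "
                     "AR(1)/exponential error model or the trend model is "
                     "unsuitable; inspect the semivariogram and consider a "
                     "different regression or correlation model")
        try:
            report.semivariogram = semivariogram_fit(
                ols.resid, dist=ds.distance_matrix(),
                sill=float(ols.resid @ ols.resid) / ols.df_resid)
        except ValueError:
            pass
        return report

    best = max(passing, key=lambda n: passing[n]["dw"].p_two_tailed)
    report.chosen = best
    report.branch = f"gls_{best}"

    # --- extrapolation gate ----------------------------------------------
    if len(candidates) == 2 and all(c["dw"].passed for c in candidates.values()):
        d_dw = candidates["dw"]["dw"]
        d_ta = candidates["tadw"]["dw"]
        below = d_dw.d < d_dw.E_d and d_ta.d < d_ta.E_d
        closer = abs(d_ta.d - d_ta.E_d) < abs(d_dw.d - d_dw.E_d)
        within_bound = candidates["tadw"]["rho"].rho_hat <= rho_max(path.n_nodes
                                                                    if path else ds.n)
        if below and closer and within_bound:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ex = extrapolate(candidates["dw"]["fit"], candidates["tadw"]["fit"],
                                 rho_tadw_value=candidates["tadw"]["rho"].rho_hat)
            if ex.admissible:
                report.extrapolation = ex
                report.branch = "extrapolated"
                report.chosen = "tadw"
                notes.append("extrapolation gate satisfied: reporting "
                             "t_extrap = 2 t_tadw - t_dw")
        elif not within_bound:
            notes.append("tadw rho exceeds rho_max; extrapolation withheld")
    return report
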