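"""Spatial correlation estimation for scattered data points.

The nearest new neighbour (NNN) path generalizes "successive residuals"
to points scattered in 1-3 dimensional space: start at the point with the
greatest sum of distances to all others, then repeatedly step to the
nearest not-yet-visited location.  On an equally spaced 1-D grid the path
walks the line end to end, so the path-ordered Durbin-Watson statistic
reduces exactly to the time-series one.

Co-located points (within a tiny fraction of the bounding-box diagonal)
are merged into a single node carrying the mean of the member values; the
(N - m) x N reduction matrix that performs the path ordering and the
averaging is exposed for reuse in validity testing.

The correlation length of the exponential model is recovered as
r0 = -rbar / ln(rho_hat), with rbar the mean distance between consecutive
path nodes and rho_hat a Durbin-Watson-type estimate on the path-ordered
residuals.  A semivariogram fit of the exponential model is provided as
the conventional comparator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import optimize

from .data import (DesignMatrix, colocation_groups, colocation_tolerance,
                   euclidean_matrix, haversine_matrix)
from .durbin_watson import dw_moments, dw_statistic
from .rho import RhoEstimate, rho_dw, rho_tadw


class NoPositiveSpatialCorrelation(ValueError):
    """Raised when the path-ordered residuals show no positive correlation.

    Callers should fall back to plain OLS inference.
    """


@dataclass
class NNNPath:
    """Nearest-new-neighbour path over (merged) locations.

    Attributes
    ----------
    order : array of location indices in visiting order
    merge_map : list of arrays; ``merge_map[loc]`` holds the original row
        indices merged into location ``loc``
    m_coloc : number of rows absorbed by merging (N - number of locations)
    r_bar : mean distance between consecutive path nodes
    start_index : location maximizing the total distance to all others
    R : (N - m_coloc) x N reduction matrix; row j averages the member rows
        of the j-th node on the path (rows sum to 1)
    dist : distance matrix between merged locations (unordered)
    """

    order: np.ndarray
    merge_map: list
    m_coloc: int
    r_bar: float
    start_index: int
    R: np.ndarray
    dist: np.ndarray
    coords: np.ndarray = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.order.shape[0]

    def reduce(self, v: np.ndarray) -> np.ndarray:
        """Path-ordered group means of a length-N vector (or matrix rows)."""
        return self.R @ np.asarray(v, dtype=float)

    def step_distances(self) -> np.ndarray:
        return self.dist[self.order[:-1], self.order[1:]]


def nnn_path(coords, tol: Optional[float] = None,
             distance_metric: str = "euclidean",
             dist: Optional[np.ndarray] = None) -> NNNPath:
    """Construct the nearest-new-neighbour path.

    Ties (equidistant candidates or tied start points) are broken by the
    lowest location index.  Raises if fewer than 3 distinct locations
    remain after merging co-located points.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    n = coords.shape[0]
    if tol is None:
        tol = colocation_tolerance(coords)
    labels = colocation_groups(coords, tol=tol)
    n_loc = labels.max() + 1
    if n_loc < 3:
        raise ValueError("need at least 3 distinct locations "
                         f"(found {n_loc} after merging co-located points)")
    merge_map = [np.where(labels == g)[0] for g in range(n_loc)]
    centroids = np.vstack([coords[m].mean(axis=0) for m in merge_map])
    if dist is not None:
        if dist.shape[0] != n:
            raise ValueError("dist must match the number of rows")
        # reduce a row-level distance matrix to representative locations
        reps = np.array([m[0] for m in merge_map])
        D = np.asarray(dist, dtype=float)[np.ix_(reps, reps)]
    elif distance_metric == "great-circle":
        D = haversine_matrix(centroids)
    else:
        D = euclidean_matrix(centroids)

    start = int(np.argmax(D.sum(axis=1)))  # argmax takes the lowest tied index
    order = np.empty(n_loc, dtype=int)
    order[0] = start
    remaining = np.ones(n_loc, dtype=bool)
    remaining[start] = False
    cur = start
    for step in range(1, n_loc):
        cand = np.where(remaining)[0]
        nxt = cand[int(np.argmin(D[cur, cand]))]
        order[step] = nxt
        remaining[nxt] = False
        cur = nxt
    steps = D[order[:-1], order[1:]]
    r_bar = float(steps.mean())
    if r_bar <= 0:
        raise ValueError("degenerate path: zero mean step distance")
    R = np.zeros((n_loc, n))
    for j, loc in enumerate(order):
        members = merge_map[loc]
        R[j, members] = 1.0 / members.size
    return NNNPath(order=order, merge_map=merge_map, m_coloc=n - n_loc,
                   r_bar=r_bar, start_index=start, R=R, dist=D,
                   coords=centroids)


def spatial_dw(e, path: NNNPath) -> Tuple[float, float, float]:
    """Durbin-Watson statistic of path-ordered (merged) residuals.

    Returns ``(d, ssrfd, ssr)``; identical to :func:`dw_statistic` on
    equally spaced 1-D data with no merges.
    """
    return dw_statistic(path.reduce(e))


def reduced_design(design: DesignMatrix, path: NNNPath) -> DesignMatrix:
    """Path-ordered, co-location-averaged copy of a design matrix."""
    Xr = path.reduce(design.X)
    return DesignMatrix(X=Xr, k=design.k, centered=design.centered,
                        decorrelated=design.decorrelated,
                        names=list(design.names), meta=dict(design.meta))


def estimate_r0(e, path: NNNPath, design: DesignMatrix,
                method: str = "tadw") -> Tuple[float, RhoEstimate]:
    """Correlation length r0 = -rbar / ln(rho_hat) from path-ordered residuals.

    ``method`` selects the per-step correlation estimate: "dw" (1 - d/2)
    or "tadw".  The Durbin-Watson null moments are evaluated on the
    reduced (path-ordered, merged) design.

    Raises
    ------
    NoPositiveSpatialCorrelation
        If the estimate is not positive; the exponential model then has
        no finite correlation length and OLS inference should be used.
    """
    d, _, _ = spatial_dw(e, path)
    n_nodes = path.n_nodes
    k = design.k
    if method == "dw":
        est = rho_dw(d)
    elif method == "tadw":
        E_d, V_d = dw_moments(reduced_design(design, path))
        est = rho_tadw(d, E_d, V_d, n_nodes, k)
    else:
        raise ValueError(f"unknown method {method!r} (use 'dw' or 'tadw')")
    if est.rho_hat <= 0:
        raise NoPositiveSpatialCorrelation(
            f"{method} estimate rho={est.rho_hat:.4f} <= 0: no positive "
            "spatial correlation detected; use OLS")
    r0 = -path.r_bar / np.log(est.rho_hat)
    return float(r0), est


@dataclass
class SemivariogramFit:
    """Exponential-model semivariogram fit.

    gamma_ij = (e_i - e_j)^2 / 2 binned by pair distance; class means are
    fitted by weighted least squares to sill * (1 - exp(-r / r0)) with
    weights 1 / mid-distance^2 and the sill fixed at the residual
    variance.
    """

    lags: np.ndarray
    gamma_means: np.ndarray
    counts: np.ndarray
    sill: float
    r0_hat: Optional[float]
    weights: np.ndarray
    converged: bool

    def model_curve(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return self.sill * (1.0 - np.exp(-r / self.r0_hat))


def semivariogram_fit(e, coords=None, n_classes: int = 10,
                      sill: Optional[float] = None,
                      dist: Optional[np.ndarray] = None,
                      distance_metric: str = "euclidean") -> SemivariogramFit:
    """Fit the exponential semivariogram model to residuals.

    Distance classes are ``n_classes`` equal-width bins spanning
    (0, max distance / 2].  Returns a fit with ``converged=False`` (and
    ``r0_hat=None``) when the field is flat, i.e. no class mean falls
    below the sill.
    """
    e = np.asarray(e, dtype=float).ravel()
    if dist is None:
        if coords is None:
            raise ValueError("provide coords or a distance matrix")
        dist = (haversine_matrix(coords) if distance_metric == "great-circle"
                else euclidean_matrix(coords))
    D = np.asarray(dist, dtype=float)
    iu = np.triu_indices(e.size, k=1)
    r = D[iu]
    gamma = 0.5 * (e[iu[0]] - e[iu[1]]) ** 2
    if sill is None:
        sill = float(e @ e) / e.size
    rmax = r.max() / 2.0
    if rmax <= 0:
        raise ValueError("all points are co-located")
    edges = np.linspace(0.0, rmax, n_classes + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.searchsorted(edges, r, side="right") - 1, 0, n_classes - 1)
    inside = r <= rmax
    counts = np.bincount(idx[inside], minlength=n_classes)
    sums = np.bincount(idx[inside], weights=gamma[inside], minlength=n_classes)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    ok = counts > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-empty distance classes")
    w = 1.0 / mids[ok] ** 2
    ybar = means[ok]
    x = mids[ok]
    if np.all(ybar >= sill):
        warnings.warn("flat semivariogram: no class mean below the sill; "
                      "fit failed", stacklevel=2)
        return SemivariogramFit(lags=mids, gamma_means=means, counts=counts,
                                sill=sill, r0_hat=None, weights=w,
                                converged=False)

    def loss(log_r0):
        g = sill * (1.0 - np.exp(-x / np.exp(log_r0)))
        return float(np.sum(w * (ybar - g) ** 2))

    res = optimize.minimize_scalar(
        loss, bounds=(np.log(max(x.min(), 1e-12)) - 5.0, np.log(x.max()) + 5.0),
        method="bounded", options={"xatol": 1e-8})
    r0_hat = float(np.exp(res.x))
    return SemivariogramFit(lags=mids, gamma_means=means, counts=counts,
                            sill=sill, r0_hat=r0_hat, weights=w,
                            converged=bool(res.success))


#: floor for the log argument in the co-location pseudo-distance estimate
_KD_ARG_FLOOR = 1e-6


def colocated_kd(e, pairs, sigma2_e: float) -> float:
    """Co-location pseudo-distance ratio k_d from residual pairs.

    k_d = -ln[ 1 - sum((e_i - e_j)^2) / (2 m sigma_e^2) ] over the m
    co-located pairs.  If the pair differences are as large as (or larger
    than) uncorrelated residuals would give, the log argument is clamped
    to a small floor with a warning: the datasets are then effectively
    uncorrelated even at zero distance.
    """
    e = np.asarray(e, dtype=float).ravel()
    pairs = np.atleast_2d(np.asarray(pairs, dtype=int))
    m = pairs.shape[0]
    if m < 1 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (m, 2) index array with m >= 1")
    if sigma2_e <= 0:
        raise ValueError("sigma2_e must be positive")
    ssq = float(np.sum((e[pairs[:, 0]] - e[pairs[:, 1]]) ** 2))
    arg = 1.0 - ssq / (2.0 * m * sigma2_e)
    if arg <= _KD_ARG_FLOOR:
        warnings.warn(
            f"co-located residual differences imply no zero-distance "
            f"correlation (log argument {arg:.3g}); k_d clamped", stacklevel=2)
        arg = _KD_ARG_FLOOR
    return float(-np.log(arg))
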