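"""Error-correlation structures for GLS estimation.

Three structures are supported:

* ``identity`` — uncorrelated errors (GLS reduces to OLS);
* ``ar1`` — first-order autoregressive errors on an equally spaced series,
  S[i, j] = rho^|i-j|, with the closed-form tridiagonal inverse;
* ``exponential`` — isotropic exponential decay for scattered points,
  phi_ij = exp(-r_ij / r0), the spatial equivalent of AR(1) (they coincide
  on a unit-spaced 1-D grid when r0 = -1/ln(rho)).

Co-located observations from different source datasets are imperfectly
correlated even at zero distance; this is encoded by a pseudo-distance
ratio ``k_d``, replacing the exponent with sqrt((r/r0)^2 + k_d^2) for the
affected pairs (diagonal entries stay exactly 1).
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy import linalg

from .data import euclidean_matrix, haversine_matrix

#: estimators clamp rho into (-RHO_CLAMP, RHO_CLAMP); S is singular at |rho|=1
RHO_CLAMP = 0.9999


def clamp_rho(rho: float, warn: bool = True) -> float:
    """Clamp a correlation estimate into the open stationary interval."""
    if abs(rho) > RHO_CLAMP:
        if warn:
            warnings.warn(
                f"rho={rho:.6g} clamped to +/-{RHO_CLAMP}; the AR(1) model is "
                "singular at |rho|=1", stacklevel=2)
        return float(np.sign(rho) * RHO_CLAMP)
    return float(rho)


def ar1_correlation(rho: float, N: int) -> np.ndarray:
    """AR(1) correlation matrix S[i, j] = rho^|i-j|."""
    if abs(rho) >= 1:
        raise ValueError(f"|rho| must be < 1 for a stationary AR(1); got {rho}")
    if N < 2:
        raise ValueError("N must be >= 2")
    idx = np.arange(N)
    return float(rho) ** np.abs(idx[:, None] - idx[None, :])


def ar1_inverse(rho: float, N: int) -> np.ndarray:
    """Closed-form tridiagonal inverse of the AR(1) correlation matrix.

    Diagonal (1, 1+rho^2, ..., 1+rho^2, 1) and off-diagonals -rho, all
    scaled by 1/(1-rho^2).
    """
    if abs(rho) >= 1:
        raise ValueError(f"|rho| must be < 1; got {rho}")
    if N < 2:
        raise ValueError("N must be >= 2")
    S_inv = np.zeros((N, N))
    i = np.arange(N)
    S_inv[i, i] = 1.0 + rho ** 2
    S_inv[0, 0] = 1.0
    S_inv[-1, -1] = 1.0
    S_inv[i[:-1], i[:-1] + 1] = -rho
    S_inv[i[:-1] + 1, i[:-1]] = -rho
    return S_inv / (1.0 - rho ** 2)


def exponential_correlation(dist: np.ndarray, r0: float, k_d: float = 0.0,
                            group_ids: Optional[np.ndarray] = None) -> np.ndarray:
    """Exponential correlation matrix from a distance matrix.

    Parameters
    ----------
    dist
        (N, N) symmetric matrix of pairwise distances.
    r0
        Correlation length (> 0), in the units of ``dist``.
    k_d
        Co-location pseudo-distance ratio (>= 0).  With ``group_ids``
        given, pairs from *different* groups use
        exp(-sqrt((r/r0)^2 + k_d^2)) while same-group pairs use the plain
        exp(-r/r0).  Without ``group_ids`` (replicated measurements within
        one dataset) every off-diagonal pair gets the k_d term.
        Diagonal entries are exactly 1 in all cases.
    """
    if r0 <= 0:
        raise ValueError("r0 must be > 0")
    if k_d < 0:
        raise ValueError("k_d must be >= 0")
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dist must be a square matrix")
    scaled = D / r0
    if k_d == 0:
        S = np.exp(-scaled)
    else:
        bumped = np.exp(-np.sqrt(scaled ** 2 + k_d ** 2))
        if group_ids is None:
            S = bumped
        else:
            g = np.asarray(group_ids)
            same = g[:, None] == g[None, :]
            S = np.where(same, np.exp(-scaled), bumped)
    np.fill_diagonal(S, 1.0)
    return S


def principal_sqrt_inv(S_inv: np.ndarray) -> np.ndarray:
    """Principal (symmetric PSD) square root P of S^-1, so P'P = S^-1.

    Computed by symmetric eigendecomposition with the non-negative root of
    each eigenvalue.  P is the unique symmetric positive-definite root;
    using it makes the transformed-residual Durbin-Watson statistic well
    defined (different roots of S^-1 give slightly different d).
    """
    S_inv = np.asarray(S_inv, dtype=float)
    w, V = linalg.eigh(S_inv)
    tol = -1e-8 * max(1.0, w.max())
    if w.min() < tol:
        raise ValueError(f"S^-1 is not positive definite (min eigenvalue {w.min():.3g})")
    return (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T


class CorrelationModel:
    """Realized correlation structure with S, S^-1 and P = (S^-1)^(1/2).

    Build with :meth:`identity`, :meth:`ar1` or :meth:`exponential`.
    Matrices are computed lazily and cached.
    """

    def __init__(self, kind: str, N: int, rho: Optional[float] = None,
                 r0: Optional[float] = None, k_d: float = 0.0,
                 dist: Optional[np.ndarray] = None,
                 group_ids: Optional[np.ndarray] = None):
        if kind not in ("identity", "ar1", "exponential"):
            raise ValueError(f"unknown correlation kind {kind!r}")
        self.kind = kind
        self.N = int(N)
        self.rho = rho
        self.r0 = r0
        self.k_d = float(k_d)
        self._dist = dist
        self.group_ids = group_ids
        self._S = None
        self._S_inv = None
        self._P = None

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls, N: int) -> "CorrelationModel":
        return cls("identity", N)

    @classmethod
    def ar1(cls, rho: float, N: int) -> "CorrelationModel":
        if abs(rho) >= 1:
            raise ValueError(f"|rho| must be < 1; got {rho}")
        return cls("ar1", N, rho=float(rho))

    @classmethod
    def exponential(cls, r0: float, coords=None, dist: Optional[np.ndarray] = None,
                    k_d: float = 0.0, group_ids=None,
                    distance_metric: str = "euclidean") -> "CorrelationModel":
        if dist is None:
            if coords is None:
                raise ValueError("provide coords or a distance matrix")
            dist = (haversine_matrix(coords) if distance_metric == "great-circle"
                    else euclidean_matrix(coords))
        dist = np.asarray(dist, dtype=float)
        return cls("exponential", dist.shape[0], r0=float(r0), k_d=k_d,
                   dist=dist, group_ids=group_ids)

    # -- realized matrices ------------------------------------------------
    @property
    def r_d(self) -> Optional[float]:
        """Equivalent co-location distance k_d * r0."""
        return None if self.r0 is None else self.k_d * self.r0

    @property
    def S(self) -> np.ndarray:
        if self._S is None:
            if self.kind == "identity":
                self._S = np.eye(self.N)
            elif self.kind == "ar1":
                self._S = ar1_correlation(self.rho, self.N)
            else:
                self._S = exponential_correlation(self._dist, self.r0,
                                                  self.k_d, self.group_ids)
        return self._S

    @property
    def S_inv(self) -> np.ndarray:
        if self._S_inv is None:
            if self.kind == "identity":
                self._S_inv = np.eye(self.N)
            elif self.kind == "ar1":
                self._S_inv = ar1_inverse(self.rho, self.N)
            else:
                try:
                    c, low = linalg.cho_factor(self.S)
                except linalg.LinAlgError as exc:
                    raise ValueError(
                        "exponential correlation matrix is numerically singular; "
                        "revise the correlation model (smaller r0 or nonzero k_d)"
                    ) from exc
                self._S_inv = linalg.cho_solve((c, low), np.eye(self.N))
        return self._S_inv

    @property
    def P(self) -> np.ndarray:
        if self._P is None:
            if self.kind == "identity":
                self._P = np.eye(self.N)
            else:
                self._P = principal_sqrt_inv(self.S_inv)
        return self._P

    def __repr__(self):
        if self.kind == "ar1":
            par = f", rho={self.rho:.4g}"
        elif self.kind == "exponential":
            par = f", r0={self.r0:.4g}, k_d={self.k_d:.4g}"
        else:
            par = ""
        return f"CorrelationModel({self.kind}, N={self.N}{par})"
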