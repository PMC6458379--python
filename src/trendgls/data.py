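"""Data containers and design-matrix construction.

A :class:`Dataset` holds response values observed at points on a time line
or scattered in 1-3 dimensional space.  A :class:`DesignMatrix` wraps the
regressor matrix ``X`` (leading intercept column of ones) together with the
bookkeeping needed to map *raw* coordinates of new points into design rows
(polynomial expansion, centering, decorrelation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: co-located points are merged when closer than this fraction of the
#: bounding-box diagonal
COLOCATION_RTOL = 1e-9


def _as_coords(coords) -> np.ndarray:
    c = np.asarray(coords, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.ndim != 2 or c.shape[1] not in (1, 2, 3):
        raise ValueError("coords must be an (N, D) array with D in {1, 2, 3}")
    if not np.all(np.isfinite(c)):
        raise ValueError("coords rows must be finite")
    return c


def euclidean_matrix(coords: np.ndarray) -> np.ndarray:
    c = _as_coords(coords)
    diff = c[:, None, :] - c[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def haversine_matrix(lonlat: np.ndarray, radius: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Great-circle distance matrix (km) for (lon, lat) points in degrees."""
    c = _as_coords(lonlat)
    if c.shape[1] != 2:
        raise ValueError("great-circle metric requires 2-D (lon, lat) input")
    lon = np.radians(c[:, 0])
    lat = np.radians(c[:, 1])
    dlon = lon[:, None] - lon[None, :]
    dlat = lat[:, None] - lat[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * radius * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def colocation_tolerance(coords: np.ndarray) -> float:
    """Absolute merge tolerance: a tiny fraction of the bounding-box diagonal."""
    c = _as_coords(coords)
    span = c.max(axis=0) - c.min(axis=0)
    diag = float(np.sqrt((span ** 2).sum()))
    return COLOCATION_RTOL * diag if diag > 0 else 0.0


def colocation_groups(coords: np.ndarray, tol: Optional[float] = None) -> np.ndarray:
    """Label points that share a location (within ``tol``).

    Returns integer labels, one per row, numbered by first occurrence.
    """
    c = _as_coords(coords)
    if tol is None:
        tol = colocation_tolerance(c)
    n = c.shape[0]
    labels = -np.ones(n, dtype=int)
    nxt = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        labels[i] = nxt
        if tol >= 0:
            d = np.sqrt(((c[i + 1:] - c[i]) ** 2).sum(axis=1))
            hit = np.where((d <= tol) & (labels[i + 1:] < 0))[0]
            labels[i + 1 + hit] = nxt
        nxt += 1
    return labels


@dataclass
class Dataset:
    """Responses observed at points in time or space.

    Parameters
    ----------
    coords
        (N, D) coordinates, D in {1, 2, 3}; time for equally spaced series.
    y
        N response values.
    group_ids
        Optional labels identifying which source dataset each row belongs to
        (used by the co-located-point machinery).
    distance_metric
        ``"euclidean"`` or ``"great-circle"`` (the latter only for D=2
        lon/lat input, haversine on a 6371 km sphere).
    """

    coords: np.ndarray
    y: np.ndarray
    group_ids: Optional[np.ndarray] = None
    distance_metric: str = "euclidean"

    def __post_init__(self):
        self.coords = _as_coords(self.coords)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.y.shape[0] != self.coords.shape[0]:
            raise ValueError("y and coords must have the same number of rows")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y must be finite")
        if self.distance_metric not in ("euclidean", "great-circle"):
            raise ValueError(f"unknown distance metric {self.distance_metric!r}")
        if self.distance_metric == "great-circle" and self.ndim != 2:
            raise ValueError("great-circle metric is only valid for 2-D lon/lat input")
        if self.group_ids is not None:
            self.group_ids = np.asarray(self.group_ids)
            if self.group_ids.shape[0] != self.n:
                raise ValueError("group_ids must have one label per row")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def ndim(self) -> int:
        return self.coords.shape[1]

    def distance_matrix(self) -> np.ndarray:
        if self.distance_metric == "great-circle":
            return haversine_matrix(self.coords)
        return euclidean_matrix(self.coords)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str,
                       coords: "str | list[str]", group: Optional[str] = None,
                       distance_metric: str = "euclidean") -> "Dataset":
        cols = [coords] if isinstance(coords, str) else list(coords)
        missing = [c for c in cols + [response] if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        sub = df[cols + [response]]
        bad = sub.isna().any(axis=1)
        if bad.any():
            rows = [int(i) for i in np.where(bad.to_numpy())[0]]
            raise ValueError(f"missing values in rows {rows}")
        return cls(
            coords=sub[cols].to_numpy(dtype=float),
            y=sub[response].to_numpy(dtype=float),
            group_ids=None if group is None else df[group].to_numpy(),
            distance_metric=distance_metric,
        )


@dataclass
class DesignMatrix:
    """Regressor matrix with a leading ones column.

    ``k`` is the number of non-intercept parameters; ``meta`` carries the
    construction recipe so that new evaluation points can be mapped into
    the same (centered, possibly decorrelated) coordinates.
    """

    X: np.ndarray
    k: int
    centered: bool = False
    decorrelated: bool = False
    names: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n, m = self.X.shape
        if m != self.k + 1:
            raise ValueError("X must have k+1 columns")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first column of X must be all ones")
        if not self.names:
            self.names = ["intercept"] + [f"x{i}" for i in range(1, m)]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.X))

    def row_for(self, x0) -> np.ndarray:
        """Design row(s) for raw evaluation point(s) ``x0``.

        For polynomial designs ``x0`` is a raw time value (or array of
        them); the centering and any decorrelation recorded in ``meta``
        are applied.
        """
        x0 = np.atleast_1d(np.asarray(x0, dtype=float))
        if not np.all(np.isfinite(x0)):
            raise ValueError("evaluation points must be finite")
        if self.meta.get("kind") == "polynomial":
            tc = x0 - self.meta["t_mean"]
            rows = np.column_stack([tc ** p for p in range(self.meta["degree"] + 1)])
            rows[:, 0] = 1.0
        elif self.meta.get("kind") == "covariates":
            rows = np.atleast_2d(x0)
            if rows.shape[1] != self.k:
                raise ValueError(f"expected {self.k} covariate columns")
            rows = np.column_stack([np.ones(rows.shape[0]), rows - self.meta["means"]])
        else:
            rows = np.atleast_2d(x0)
            if rows.shape[1] == self.k:  # raw covariates without intercept
                rows = np.column_stack([np.ones(rows.shape[0]), rows])
            if rows.shape[1] != self.k + 1:
                raise ValueError("x0 has wrong number of columns")
        T = self.meta.get("decorr_T")
        if T is not None:
            rows = rows @ T
        return rows


def _check_full_rank(X: np.ndarray, names: list) -> None:
    # identify the first column that is linearly dependent on its predecessors
    n, m = X.shape
    if n < m:
        raise ValueError(f"need at least {m} rows for {m} columns")
    R = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(R))
    scale = np.linalg.norm(X, axis=0)
    bad = np.where(diag <= 1e-10 * np.maximum(scale, 1.0))[0]
    if bad.size:
        raise ValueError(
            f"design matrix is rank deficient: column {names[bad[0]]!r} is "
            "linearly dependent on earlier columns"
        )


def build_polynomial_design(times, degree: int) -> DesignMatrix:
    """Centered polynomial design [1, (t-tbar), (t-tbar)^2, ...].

    Times are shifted to zero mean before the powers are taken, which keeps
    the columns well scaled and makes the intercept the fitted value at the
    mean time.

    Raises
    ------
    ValueError
        If ``degree + 1 >= N`` or there are fewer than ``degree + 1``
        distinct time values (rank-deficient design).
    """
    t = np.asarray(times, dtype=float).ravel()
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    n = t.size
    if degree + 1 >= n:
        raise ValueError(f"degree {degree} needs more than {degree + 1} observations, got {n}")
    t_mean = t.mean()
    tc = t - t_mean
    X = np.column_stack([tc ** p for p in range(degree + 1)])
    X[:, 0] = 1.0
    names = ["intercept"] + [f"t^{p}" if p > 1 else "t" for p in range(1, degree + 1)]
    _check_full_rank(X, names)
    return DesignMatrix(X=X, k=degree, centered=True, names=names,
                        meta={"kind": "polynomial", "t_mean": t_mean, "degree": degree})


def build_covariate_design(covariates: np.ndarray, names: Optional[list] = None,
                           center: bool = True) -> DesignMatrix:
    """Design from explicit covariate columns, intercept prepended.

    Non-intercept columns are centered by default.
    """
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z.shape[0] == 1 and Z.shape[1] > 1:
        Z = Z.T
    means = Z.mean(axis=0) if center else np.zeros(Z.shape[1])
    Zc = Z - means
    X = np.column_stack([np.ones(Z.shape[0]), Zc])
    colnames = ["intercept"] + (list(names) if names else [f"x{i}" for i in range(1, Z.shape[1] + 1)])
    _check_full_rank(X, colnames)
    return DesignMatrix(X=X, k=Z.shape[1], centered=center, names=colnames,
                        meta={"kind": "covariates", "means": means, "center": center})
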