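"""Ordinary kriging with a spherical variogram.

Station meteorology is observed at a handful of points and interpolated onto
the lattice with ordinary kriging, using the 12 nearest stations per cell
and a spherical semivariogram

    gamma(h) = c0 + (c - c0) * (1.5 h/a - 0.5 (h/a)^3)   for 0 < h <= a
    gamma(h) = c                                          for h > a
    gamma(0) = 0

with nugget c0, sill c and range a.  Per cell the ordinary-kriging system

    [ Gamma  1 ] [ w  ]   [ gamma_0 ]
    [ 1^T    0 ] [ mu ] = [ 1       ]

is solved; weights sum to one, and with zero nugget the predictor is exact
at station locations.  Cells sharing a neighbour set are solved in one
batched linear solve, which makes dense scenes cheap when the station count
is small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .grids import Grid, GridSpec

__all__ = ["VariogramParams", "spherical_gamma", "fit_spherical_variogram",
           "krige_spherical"]


@dataclass(frozen=True)
class VariogramParams:
    range_param: float
    sill: float
    nugget: float = 0.0

    def __post_init__(self) -> None:
        if self.range_param <= 0 or self.sill <= 0:
            raise ValueError("range and sill must be positive")
        if self.nugget < 0:
            raise ValueError("nugget must be non-negative")


def spherical_gamma(h, range_param: float, sill: float,
                    nugget: float = 0.0):
    """Spherical semivariogram; gamma(0) = 0 exactly."""
    h = np.asarray(h, dtype=float)
    r = np.minimum(h / range_param, 1.0)
    g = nugget + (sill - nugget) * (1.5 * r - 0.5 * r ** 3)
    return np.where(h == 0.0, 0.0, g)


def fit_spherical_variogram(points: Sequence[tuple[float, float, float]],
                            n_bins: int = 10) -> VariogramParams:
    """Method-of-moments fit of the spherical model to the empirical
    semivariogram of scattered observations.

    Falls back to (range = half the maximum pairwise distance,
    sill = sample variance, nugget = 0) when the least-squares fit is
    ill-posed, e.g. with very few stations.
    """
    pts = np.asarray([(x, y) for x, y, _ in points], dtype=float)
    vals = np.asarray([v for _, _, v in points], dtype=float)
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points to fit a variogram")
    d = np.hypot(pts[:, None, 0] - pts[None, :, 0],
                 pts[:, None, 1] - pts[None, :, 1])
    iu = np.triu_indices(n, k=1)
    h = d[iu]
    sv = 0.5 * (vals[:, None] - vals[None, :])[iu] ** 2
    var = float(np.var(vals))
    fallback = VariogramParams(range_param=max(float(h.max()) / 2, 1e-9),
                               sill=max(var, 1e-12))
    if n < 4 or var == 0:
        return fallback
    # bin by distance, average semivariance per bin
    edges = np.linspace(0, h.max(), n_bins + 1)
    which = np.clip(np.digitize(h, edges) - 1, 0, n_bins - 1)
    hb, gb = [], []
    for b in range(n_bins):
        m = which == b
        if m.any():
            hb.append(h[m].mean())
            gb.append(sv[m].mean())
    try:
        popt, _ = curve_fit(
            lambda hh, a, c: spherical_gamma(hh, a, c, 0.0),
            np.asarray(hb), np.asarray(gb),
            p0=[fallback.range_param, fallback.sill],
            bounds=([1e-9, 1e-12], [np.inf, np.inf]), maxfev=2000)
        return VariogramParams(range_param=float(popt[0]), sill=float(popt[1]))
    except RuntimeError:
        return fallback


def _idw(pts: np.ndarray, vals: np.ndarray, X: np.ndarray,
         Y: np.ndarray) -> np.ndarray:
    d = np.hypot(X.ravel()[:, None] - pts[None, :, 0],
                 Y.ravel()[:, None] - pts[None, :, 1])
    d = np.maximum(d, 1e-12)
    w = 1.0 / d ** 2
    return (w @ vals) / w.sum(axis=1)


def krige_spherical(station_values: Sequence[tuple[float, float, float]],
                    spec: GridSpec, n_neighbors: int = 12,
                    params: VariogramParams | None = None) -> Grid:
    """Interpolate scattered station values onto the lattice.

    Parameters default to a method-of-moments spherical-variogram fit.
    Duplicate station coordinates with conflicting values raise; a singular
    kriging system falls back to inverse-distance weighting with a warning.
    """
    pts = np.asarray([(x, y) for x, y, _ in station_values], dtype=float)
    vals = np.asarray([v for _, _, v in station_values], dtype=float)
    if len(pts) < 2:
        raise ValueError("kriging needs at least 2 stations")
    # duplicate-coordinate check
    _, inv = np.unique(pts, axis=0, return_inverse=True)
    for g in range(inv.max() + 1):
        vv = vals[inv == g]
        if len(vv) > 1 and not np.allclose(vv, vv[0]):
            raise ValueError("duplicate station coordinates with conflicting values")
    if params is None:
        params = fit_spherical_variogram(station_values)

    X, Y = spec.cell_centres()
    cx, cy = X.ravel(), Y.ravel()
    d_cell_sta = np.hypot(cx[:, None] - pts[None, :, 0],
                          cy[:, None] - pts[None, :, 1])
    n = len(pts)
    k = min(n_neighbors, n)
    if k == n:
        neigh = np.broadcast_to(np.arange(n), (len(cx), n))
    else:
        neigh = np.argpartition(d_cell_sta, k - 1, axis=1)[:, :k]
        neigh = np.sort(neigh, axis=1)

    out = np.empty(len(cx))
    # group cells by identical neighbour set -> one factorization per group
    uniq, first_idx, group = np.unique(neigh, axis=0, return_index=True,
                                       return_inverse=True)
    group = group.ravel()
    d_sta = np.hypot(pts[:, None, 0] - pts[None, :, 0],
                     pts[:, None, 1] - pts[None, :, 1])
    for gi in range(len(uniq)):
        cells = np.nonzero(group == gi)[0]
        idx = neigh[first_idx[gi]]
        A = np.empty((k + 1, k + 1))
        A[:k, :k] = spherical_gamma(d_sta[np.ix_(idx, idx)],
                                    params.range_param, params.sill,
                                    params.nugget)
        A[k, :k] = 1.0
        A[:k, k] = 1.0
        A[k, k] = 0.0
        b = np.empty((k + 1, len(cells)))
        b[:k] = spherical_gamma(d_cell_sta[np.ix_(cells, idx)].T,
                                params.range_param, params.sill,
                                params.nugget)
        b[k] = 1.0
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            warnings.warn("singular kriging system; falling back to "
                          "inverse-distance weighting", stacklevel=2)
            out[cells] = _idw(pts[idx], vals[idx], cx[cells], cy[cells])
            continue
        out[cells] = sol[:k].T @ vals[idx]
    return Grid(spec, out.reshape(spec.shape))
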