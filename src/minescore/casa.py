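"""CASA light-use-efficiency model of net primary productivity.

Monthly NPP per pixel is absorbed photosynthetically active radiation times
an actual light-use efficiency:

    NPP(x,t)  = APAR(x,t) * eps(x,t)
    APAR(x,t) = SOL(x,t) * FPAR(x,t) * 0.5
    eps(x,t)  = T1(x,t) * T2(x,t) * W(x,t) * eps_max(class)

FPAR is estimated twice — linearly from NDVI and linearly from the simple
ratio SR = (1+NDVI)/(1-NDVI), each anchored at per-vegetation-type 5th/95th
NDVI percentiles and mapped onto [0.001, 0.95] — and the two estimates are
blended with weight ``alpha`` (NDVI overestimates, SR underestimates, so the
average is the better estimate).  The temperature and water stress scalars
T1, T2, W default to 1 (unstressed); user-supplied grids or constants are
accepted.  Only the min-max-normalized multi-month NPP enters the biological
abundance index, so the absolute NPP scale is arbitrary here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import EPS_MAX, FPAR_MAX, FPAR_MIN, LANDUSE_NAMES
from .grids import Grid, minmax_normalize

logger = logging.getLogger(__name__)

__all__ = ["FparParams", "LueParams", "simple_ratio", "fpar_from_ndvi",
           "fpar_from_sr", "fpar_combined", "apar", "lue", "class_anchors",
           "npp_month", "npp_aggregate", "npp_mean_normalized"]


@dataclass(frozen=True)
class FparParams:
    fpar_min: float = FPAR_MIN
    fpar_max: float = FPAR_MAX
    alpha: float = 0.5           # weight of the NDVI-based FPAR estimate
    ndvi_low_pct: float = 5.0    # percentile defining NDVI_i,min / SR_i,min
    ndvi_high_pct: float = 95.0
    min_cells_per_class: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.fpar_min < self.fpar_max <= 1):
            raise ValueError("need 0 <= fpar_min < fpar_max <= 1")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")


def _as_stress(value, shape):
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(shape, float(arr))
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("stress values must be in [0, 1]")
    return arr


@dataclass
class LueParams:
    """Maximum light-use efficiency per vegetation type plus stress terms."""

    eps_max: Mapping[str, float] = field(default_factory=lambda: dict(EPS_MAX))
    t_stress1: float | np.ndarray = 1.0
    t_stress2: float | np.ndarray = 1.0
    w_stress: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.eps_max.values()):
            raise ValueError("eps_max values must be positive")


def simple_ratio(ndvi, clamp: bool = False):
    """SR = (1 + NDVI) / (1 - NDVI)."""
    arr = np.asarray(ndvi, dtype=float)
    if clamp:
        arr = np.clip(arr, -0.999, 0.999)
    if (arr >= 1).any() or (arr <= -1).any():
        raise ValueError("NDVI must lie strictly inside (-1, 1)")
    out = (1.0 + arr) / (1.0 - arr)
    return out if out.ndim else float(out)


def _linear_fpar(x, x_min, x_max, params: FparParams):
    if x_min >= x_max:
        raise ValueError("lower anchor must be strictly below upper anchor")
    arr = np.asarray(x, dtype=float)
    f = ((arr - x_min) / (x_max - x_min)
         * (params.fpar_max - params.fpar_min) + params.fpar_min)
    out = np.clip(f, params.fpar_min, params.fpar_max)
    return out if out.ndim else float(out)


def fpar_from_ndvi(ndvi, ndvi_min, ndvi_max,
                   params: FparParams = FparParams()):
    """Linear FPAR-NDVI relation between per-type anchors, clamped."""
    return _linear_fpar(ndvi, ndvi_min, ndvi_max, params)


def fpar_from_sr(sr, sr_min, sr_max, params: FparParams = FparParams()):
    """Linear FPAR-SR relation between per-type anchors, clamped."""
    return _linear_fpar(sr, sr_min, sr_max, params)


def fpar_combined(fpar_ndvi, fpar_sr, alpha: float = 0.5):
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    out = alpha * np.asarray(fpar_ndvi, float) + (1 - alpha) * np.asarray(fpar_sr, float)
    return out if out.ndim else float(out)


def apar(sol, fpar):
    """APAR = SOL * FPAR * 0.5; 0.5 is the PAR fraction of total radiation."""
    sol_arr = np.asarray(sol, dtype=float)
    if (sol_arr < 0).any():
        raise ValueError("solar radiation must be non-negative")
    out = sol_arr * np.asarray(fpar, dtype=float) * 0.5
    return out if out.ndim else float(out)


def lue(vegetation_type: str, params: LueParams = None):
    """Actual light-use efficiency eps = T1 * T2 * W * eps_max (scalar form)."""
    params = params or LueParams()
    if vegetation_type not in params.eps_max:
        raise KeyError(f"no eps_max registered for {vegetation_type!r}")
    return (np.asarray(params.t_stress1, float)
            * np.asarray(params.t_stress2, float)
            * np.asarray(params.w_stress, float)
            * params.eps_max[vegetation_type])


def class_anchors(ndvi: Grid, land_use: Grid,
                  params: FparParams = FparParams()) -> dict[int, tuple[float, float]]:
    """Per-land-use-class NDVI anchors at the configured percentiles.

    Classes with fewer valid cells than ``min_cells_per_class`` fall back to
    scene-wide percentiles (logged).
    """
    valid = ndvi.valid & land_use.valid
    nd = np.asarray(ndvi.values, float)
    scene_lo, scene_hi = np.percentile(
        nd[valid], [params.ndvi_low_pct, params.ndvi_high_pct])
    anchors: dict[int, tuple[float, float]] = {}
    for code in np.unique(land_use.values[valid]).astype(int):
        m = valid & (land_use.values == code)
        if m.sum() < params.min_cells_per_class:
            logger.info("land-use class %s has %d cells; using scene-wide "
                        "NDVI anchors", code, int(m.sum()))
            lo, hi = scene_lo, scene_hi
        else:
            lo, hi = np.percentile(nd[m], [params.ndvi_low_pct,
                                           params.ndvi_high_pct])
        if hi <= lo:  # degenerate class (constant NDVI)
            lo, hi = scene_lo, scene_hi
        if hi <= lo:
            raise ValueError("degenerate NDVI distribution; no usable anchors")
        anchors[code] = (float(lo), float(hi))
    return anchors


def _eps_grid(land_use: Grid, lue_params: LueParams,
              habitat: Grid | None = None) -> np.ndarray:
    """eps_max per pixel.

    Woodland pixels are differentiated by habitat subtype (woodland /
    shrubbery / sparse woodland carry their own maxima) when a habitat grid
    is supplied; all other classes use their class value.
    """
    eps = np.zeros(land_use.spec.shape)
    codes = np.unique(land_use.values[land_use.valid]).astype(int)
    for code in codes:
        name = LANDUSE_NAMES.get(code)
        if name is None or name not in lue_params.eps_max:
            raise KeyError(f"no eps_max registered for land-use code {code}")
        eps[land_use.values == code] = lue_params.eps_max[name]
    if habitat is not None:
        for sub, name in ((12, "shrubbery"), (13, "sparse_woodland")):
            if name in lue_params.eps_max:
                eps[habitat.values == sub] = lue_params.eps_max[name]
    return eps


def npp_month(sol: Grid, ndvi: Grid, land_use: Grid,
              fpar_params: FparParams = FparParams(),
              lue_params: LueParams | None = None,
              habitat: Grid | None = None,
              anchors: Mapping[int, tuple[float, float]] | None = None) -> Grid:
    """One month of NPP on the lattice: APAR(x) * eps(x)."""
    lue_params = lue_params or LueParams()
    for g in (ndvi, land_use) + ((habitat,) if habitat else ()):
        if g.spec != sol.spec:
            raise ValueError("misaligned grids in npp_month")
    if anchors is None:
        anchors = class_anchors(ndvi, land_use, fpar_params)
    nd = np.asarray(ndvi.values, float)
    fpar = np.zeros(sol.spec.shape)
    for code, (lo, hi) in anchors.items():
        m = land_use.values == code
        if not m.any():
            continue
        f_nd = fpar_from_ndvi(nd[m], lo, hi, fpar_params)
        sr = simple_ratio(nd[m], clamp=True)
        f_sr = fpar_from_sr(sr, simple_ratio(min(lo, 0.999)),
                            simple_ratio(min(hi, 0.999)), fpar_params)
        fpar[m] = fpar_combined(f_nd, f_sr, fpar_params.alpha)
    eps = (_eps_grid(land_use, lue_params, habitat)
           * _as_stress(lue_params.t_stress1, sol.spec.shape)
           * _as_stress(lue_params.t_stress2, sol.spec.shape)
           * _as_stress(lue_params.w_stress, sol.spec.shape))
    npp = apar(sol.values, fpar) * eps
    return Grid(sol.spec, npp)


def npp_aggregate(monthly: Sequence[Grid]) -> Grid:
    """Element-wise sum of monthly NPP grids over the run window."""
    if not monthly:
        raise ValueError("empty aggregation window")
    spec = monthly[0].spec
    total = np.zeros(spec.shape)
    for g in monthly:
        if g.spec != spec:
            raise ValueError("misaligned grids in npp_aggregate")
        total += g.values
    return Grid(spec, total)


def npp_mean_normalized(monthly: Sequence[Grid]) -> Grid:
    """Window-summed NPP rescaled onto [0, 1] for the biodiversity index."""
    return minmax_normalize(npp_aggregate(monthly))
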