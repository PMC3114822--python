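"""The four regression estimators and distance-curve inference.

1. ``fit_additive`` — log concentration on linear covariates (traffic per
   road, wind speed, temperature, RH, sampling-day dummies) plus smooth
   distance terms per road and a bivariate spatial smooth; independent
   errors.
2. ``fit_ar`` — two-stage: the additive fit's residuals determine an AR(p)
   error structure empirically (order + coefficients), then the same mean
   structure is refit by penalized GLS with that structure fixed.
3. ``fit_timetrend`` — adds a sampling-shift main effect and one centered
   smooth of elapsed time per shift (shared smoothing parameter), with the
   same two-stage AR treatment; day dummies are replaced by shift effects.
4. ``fit_discretized`` — replaces the per-road distance smooths by one
   pooled line-source term: each road is chopped into 10-m segments with
   traffic weights e_j, and the design column for basis function B_k is
   sum_j e_j B_k(d_ij) over all segments of both roads.

Adjusted distance-decay curves are reported relative to the closest
observed distance, with pointwise 95% CIs and the percent decrease within
100 m, 100*(1 - exp(eta(100) - eta(d_min))).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .covariates import ModelFrame, median_split
from .geometry import SegmentedSource
from . import smoothers
from .smoothers import (PenalizedFit, build_spatial_basis,
                        build_univariate_basis, fit_penalized, smooth_pvalue)

log = logging.getLogger(__name__)

__all__ = [
    "ARStructure", "DistanceCurve", "FitResult",
    "fit_additive", "select_ar_order", "fit_ar", "fit_timetrend",
    "fit_discretized", "predict_distance_curve", "sensitivity_suite",
]

DEFAULT_SEED = 20110124
CURVE_STEP = 5.0
CURVE_MAX = 500.0


@dataclass
class ARStructure:
    """Fixed-order autoregressive error structure, scoped to contiguous
    per-instrument series within a sampling shift."""

    order: int
    phi: np.ndarray
    sigma2: float

    def __post_init__(self):
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float)) \
            if self.order else np.empty(0)
        if len(self.phi) != self.order:
            raise ValueError("phi length must equal the AR order")
        if self.order and not self.is_stationary:
            raise ValueError("AR polynomial is not stationary")

    @property
    def is_stationary(self) -> bool:
        if self.order == 0:
            return True
        roots = np.roots(np.concatenate([[1.0], -self.phi])[::-1])
        return bool(np.all(np.abs(roots) > 1.0 + 1e-10))


@dataclass
class DistanceCurve:
    """Adjusted log-concentration versus distance, relative to the first
    grid point (the minimum observed distance)."""

    road_id: str
    grid: np.ndarray
    eta: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    pct_decrease_100m: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"road_id": self.road_id, "distance_m": self.grid,
                             "eta": self.eta, "lo95": self.lo95,
                             "hi95": self.hi95})


@dataclass
class FitResult:
    model_kind: str
    pollutant: str
    fit: PenalizedFit
    ar: ARStructure | None = None
    curves: dict = field(default_factory=dict)
    table: pd.DataFrame | None = None
    frame_columns: dict = field(default_factory=dict)

    @property
    def r2(self) -> float:
        return self.fit.r2

    def coefficient(self, name: str) -> float:
        i = self.fit.param_names.index(name)
        return float(self.fit.beta[self.fit.slices["parametric"]][i])

    def coefficient_ci(self, name: str):
        for row in self.fit.param_table():
            if row[0] == name:
                return row[1], row[2], row[3]
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Design assembly helpers


def _dummies(values: pd.Series, prefix: str):
    """Treatment-coded dummies, first level (sorted) as reference."""
    levels = sorted(pd.unique(values))
    if len(levels) < 2:
        log.info("%s has a single level; dummies dropped", prefix)
        return np.empty((len(values), 0)), []
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((values == lev).to_numpy(dtype=float))
        names.append(f"{prefix}[{lev}]")
    return np.column_stack(cols), names


def _parametric_design(frame: ModelFrame, roads=None, day_effects=True,
                       shift_effects=False, traffic_cols=None,
                       met_smooth=False):
    df = frame.data
    roads = roads if roads is not None else frame.road_ids
    cols = [np.ones(len(df))]
    names = ["intercept"]
    if traffic_cols is None:
        traffic_cols = [f"traffic_{rid}" for rid in roads]
    for c in traffic_cols:
        cols.append(df[c].to_numpy(dtype=float))
        names.append(c)
    if not met_smooth:
        for c in ["wind_speed", "temperature", "rh"]:
            cols.append(df[c].to_numpy(dtype=float))
            names.append(c)
    if day_effects:
        d, dn = _dummies(df["day_id"], "day")
        cols.append(d)
        names += dn
    if shift_effects:
        d, dn = _dummies(df["shift_id"], "shift")
        cols.append(d)
        names += dn
    X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
    return X, names


DISTANCE_TRANSFORM = "log"   # knot geometry for distance smooths


def _distance_smooth(frame: ModelFrame, road_id: str, k: int = 10):
    d = frame.data[f"d_{road_id}"].to_numpy(dtype=float)
    n_distinct = len(np.unique(d))
    if n_distinct < 25:
        k = max(4, min(k, n_distinct - 2))
        log.info("distance to %s has %d distinct values; basis reduced to k=%d",
                 road_id, n_distinct, k)
    return build_univariate_basis(d, k=k, name=f"f_{road_id}",
                                  transform=DISTANCE_TRANSFORM)


def _met_smooths(frame: ModelFrame, k: int = 6):
    out = []
    for c in ["wind_speed", "temperature", "rh"]:
        out.append(build_univariate_basis(
            frame.data[c].to_numpy(dtype=float), k=k, name=f"f_{c}"))
    return out


def _series_groups(frame: ModelFrame):
    """Row-index arrays of contiguous 1-min series: one backpack within one
    shift, in time order.  Autocorrelation never crosses these boundaries."""
    df = frame.data
    order = np.lexsort((df["timestamp"].to_numpy(), df["operator_id"].to_numpy(),
                        df["shift_id"].to_numpy()))
    groups = []
    keys = list(zip(df["shift_id"].to_numpy()[order], df["operator_id"].to_numpy()[order]))
    start = 0
    for i in range(1, len(keys) + 1):
        if i == len(keys) or keys[i] != keys[start]:
            groups.append(order[start:i])
            start = i
    return groups


def _smooth_table(fit: PenalizedFit, smooth_names):
    rows = []
    for name, est, lo, hi, p in fit.param_table():
        rows.append({"term": name, "estimate": est, "lo95": lo, "hi95": hi,
                     "p": p})
    for name in smooth_names:
        rows.append({"term": name, "estimate": np.nan, "lo95": np.nan,
                     "hi95": np.nan, "p": smooth_pvalue(fit, name)})
    rows.append({"term": "r2", "estimate": fit.r2, "lo95": np.nan,
                 "hi95": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Estimators


def fit_additive(frame: ModelFrame, pollutant: str | None = None,
                 k_distance: int = 10, k_spatial: int = 30,
                 method: str = "gcv", roads=None,
                 traffic_cols=None, met_smooth: bool = False) -> FitResult:
    """Initial additive model with independent errors.

    Smoothing parameters default to GCV here (the classical choice for an
    independence-assuming additive fit); the AR-error refits select theirs
    by REML on the whitened problem.  Under serially correlated noise GCV
    under-smooths, which is precisely why this model's curve bands are
    wide — the contrast the AR model then removes.
    """
    pollutant = pollutant or frame.pollutant
    roads = roads if roads is not None else frame.road_ids
    y = frame.data["y"].to_numpy(dtype=float)
    X, names = _parametric_design(frame, roads=roads, day_effects=True,
                                  traffic_cols=traffic_cols,
                                  met_smooth=met_smooth)
    smooths = [_distance_smooth(frame, rid, k=k_distance) for rid in roads]
    smooths.append(build_spatial_basis(frame.coords, k=k_spatial, name="f_s", affine="shrink"))
    if met_smooth:
        smooths += _met_smooths(frame)
    fit = fit_penalized(y, X, smooths, param_names=names, method=method)
    res = FitResult("additive", pollutant, fit,
                    table=_smooth_table(fit, [s.name for s in smooths]))
    for rid in roads:
        res.curves[rid] = predict_distance_curve(res, rid, frame=frame)
    return res


def select_ar_order(residual_groups, p_max: int = 5,
                    criterion: str = "bic") -> ARStructure:
    """Empirical AR order selection on pooled within-series residuals.

    Autocovariances are pooled across contiguous series with length
    weights (each series demeaned on its own, so leftover per-series level
    structure does not masquerade as long memory), then Levinson-Durbin
    gives AR(p) coefficients and innovation variances for p = 0..p_max; the
    information criterion (BIC by default, AIC available) picks the order.
    """
    groups = [np.asarray(g, dtype=float) for g in residual_groups]
    if all(len(g) < p_max + 6 for g in groups):
        raise ValueError(f"all residual series shorter than p_max + 6 = "
                         f"{p_max + 6}; reduce p_max")
    groups = [g for g in groups if len(g) >= p_max + 6]
    N = sum(len(g) for g in groups)
    acov = np.zeros(p_max + 1)
    for g in groups:
        gc = g - g.mean()
        for k in range(p_max + 1):
            acov[k] += np.dot(gc[: len(gc) - k], gc[k:])
    acov /= N
    if acov[0] <= 0:
        return ARStructure(0, np.empty(0), max(acov[0], 1e-300))

    # Levinson-Durbin recursion.
    sigmas = [acov[0]]
    phis = [np.empty(0)]
    phi_prev = np.empty(0)
    sig = acov[0]
    for p in range(1, p_max + 1):
        num = acov[p] - (phi_prev @ acov[p - 1:0:-1] if p > 1 else 0.0)
        kappa = num / sig
        phi_new = np.empty(p)
        phi_new[p - 1] = kappa
        if p > 1:
            phi_new[: p - 1] = phi_prev - kappa * phi_prev[::-1]
        sig = sig * (1.0 - kappa ** 2)
        sig = max(sig, 1e-300)
        sigmas.append(sig)
        phis.append(phi_new)
        phi_prev = phi_new

    pen = 2.0 if criterion == "aic" else np.log(N)
    ic = [N * np.log(sigmas[p]) + pen * (p + 1) for p in range(p_max + 1)]
    p_best = int(np.argmin(ic))
    return ARStructure(p_best, phis[p_best], float(sigmas[p_best]))


def fit_ar(frame: ModelFrame, pollutant: str | None = None,
           p_max: int = 5, criterion: str = "bic", k_distance: int = 10,
           k_spatial: int = 30, method: str = "reml",
           base_method: str = "gcv", roads=None,
           traffic_cols=None, met_smooth: bool = False,
           ar: ARStructure | None = None) -> FitResult:
    """Two-stage AR-error model: additive fit, empirical AR structure from
    its residuals, penalized GLS refit with that structure fixed."""
    pollutant = pollutant or frame.pollutant
    roads = roads if roads is not None else frame.road_ids
    base = fit_additive(frame, pollutant, k_distance=k_distance,
                        k_spatial=k_spatial, method=base_method, roads=roads,
                        traffic_cols=traffic_cols, met_smooth=met_smooth)
    groups = _series_groups(frame)
    if ar is None:
        resid_groups = [base.fit.residuals[g] for g in groups]
        ar = select_ar_order(resid_groups, p_max=p_max, criterion=criterion)

    y = frame.data["y"].to_numpy(dtype=float)
    X, names = _parametric_design(frame, roads=roads, day_effects=True,
                                  traffic_cols=traffic_cols,
                                  met_smooth=met_smooth)
    smooths = [_distance_smooth(frame, rid, k=k_distance) for rid in roads]
    smooths.append(build_spatial_basis(frame.coords, k=k_spatial, name="f_s", affine="shrink"))
    if met_smooth:
        smooths += _met_smooths(frame)
    fit = fit_penalized(y, X, smooths, param_names=names, method=method,
                        ar_phi=ar.phi if ar.order else None,
                        groups=groups if ar.order else None)
    res = FitResult("ar", pollutant, fit, ar=ar,
                    table=_smooth_table(fit, [s.name for s in smooths]))
    for rid in roads:
        res.curves[rid] = predict_distance_curve(res, rid, frame=frame)
    return res


@dataclass
class _TimeByShiftSmooth:
    """One smooth of within-shift elapsed time per shift, sharing a single
    smoothing parameter (block-diagonal design and penalty).  Each block is
    centered over its own shift's rows so shift main effects stay
    identifiable; shifts too short for a spline get an unpenalized centered
    linear column."""

    name: str
    design: np.ndarray
    penalty: np.ndarray
    coef: np.ndarray | None = None
    edf: float | None = None
    lambda_: float | None = None


def _build_time_smooth(frame: ModelFrame, k: int = 10) -> _TimeByShiftSmooth:
    df = frame.data
    n = len(df)
    blocks, penalties = [], []
    for sid in sorted(pd.unique(df["shift_id"])):
        idx = np.where((df["shift_id"] == sid).to_numpy())[0]
        t = df["t_shift"].to_numpy(dtype=float)[idx]
        n_distinct = len(np.unique(t))
        if n_distinct < k + 2:
            log.info("shift %s too short for a k=%d time smooth; linear term",
                     sid, k)
            col = np.zeros(n)
            col[idx] = t - t.mean()
            sd = col[idx].std()
            blocks.append((col / sd if sd > 0 else col)[:, None])
            penalties.append(np.zeros((1, 1)))
            continue
        sm = build_univariate_basis(t, k=k, name=f"t_{sid}")
        block = np.zeros((n, sm.design.shape[1]))
        block[idx] = sm.design
        blocks.append(block)
        penalties.append(sm.penalty)
    design = np.column_stack(blocks)
    penalty = linalg.block_diag(*penalties)
    return _TimeByShiftSmooth("f_t", design, penalty)


def fit_timetrend(frame: ModelFrame, pollutant: str | None = None,
                  p_max: int = 5, criterion: str = "bic",
                  k_distance: int = 10, k_spatial: int = 30, k_time: int = 10,
                  method: str = "reml", roads=None,
                  time_lambdas=None) -> FitResult:
    """Long-term time-trend model: shift main effects plus a smooth of
    elapsed time per shift, with the two-stage AR error treatment."""
    pollutant = pollutant or frame.pollutant
    roads = roads if roads is not None else frame.road_ids
    if frame.data["shift_id"].nunique() < 2:
        raise ValueError("time-trend model needs at least 2 shifts")

    y = frame.data["y"].to_numpy(dtype=float)
    X, names = _parametric_design(frame, roads=roads, day_effects=False,
                                  shift_effects=True)

    def build(ar_phi=None, groups=None):
        smooths = [_distance_smooth(frame, rid, k=k_distance) for rid in roads]
        smooths.append(build_spatial_basis(frame.coords, k=k_spatial, name="f_s", affine="shrink"))
        smooths.append(_build_time_smooth(frame, k=k_time))
        lambdas = None
        if time_lambdas is not None:
            lambdas = time_lambdas
        fit = fit_penalized(y, X, smooths, param_names=names, method=method,
                            ar_phi=ar_phi, groups=groups, lambdas=lambdas)
        res = FitResult("timetrend", pollutant, fit,
                        table=_smooth_table(fit, [s.name for s in smooths]))
        for rid in roads:
            res.curves[rid] = predict_distance_curve(res, rid, frame=frame)
        return res

    base = build()
    groups = _series_groups(frame)
    resid_groups = [base.fit.residuals[g] for g in groups]
    ar = select_ar_order(resid_groups, p_max=p_max, criterion=criterion)
    if ar.order == 0:
        base.ar = ar
        return base
    res = build(ar_phi=ar.phi, groups=groups)
    res.ar = ar
    return res


@dataclass
class _PooledSourceSmooth:
    """Traffic-weighted pooled line-source term g(d): the design column for
    basis function B_k is sum_j e_j B_k(d_ij) over every 10-m segment of
    every road, with segment distances sqrt(h_j^2 + horizontal^2)."""

    name: str
    inner: smoothers.UnivariateSmooth
    design: np.ndarray
    penalty: np.ndarray
    Z: np.ndarray
    coef: np.ndarray | None = None
    edf: float | None = None
    lambda_: float | None = None

    def predict_matrix(self, d) -> np.ndarray:
        return self.inner.raw_basis(d) @ self.Z


def _segment_distances(coords: np.ndarray, seg: SegmentedSource) -> np.ndarray:
    dx = coords[:, 0][:, None] - seg.midpoints[:, 0][None, :]
    dy = coords[:, 1][:, None] - seg.midpoints[:, 1][None, :]
    return np.sqrt(dx * dx + dy * dy + seg.heights[None, :] ** 2)


def fit_discretized(frame: ModelFrame, pollutant: str | None = None,
                    segmented: dict | None = None, k: int = 10,
                    method: str = "reml") -> FitResult:
    """Discretized line-source model: both roads' 10-m segments act as
    individual sources through a single pooled distance kernel g.

    Segment weights e_j are normalized to mean 1, so g is reported in log
    concentration per unit (relative) traffic weight; only the re-centered
    shape of g is interpreted.
    """
    pollutant = pollutant or frame.pollutant
    if segmented is None:
        raise ValueError("segmented sources are required (see "
                         "geometry.discretize_road)")
    coords = frame.coords
    y = frame.data["y"].to_numpy(dtype=float)
    X, names = _parametric_design(frame, day_effects=True)

    seg_list = [segmented[rid] for rid in sorted(segmented)]
    weights = np.concatenate([s.weights for s in seg_list])
    if np.all(weights == 0):
        warnings.warn("all segment weights are zero; pooled source term "
                      "dropped", stacklevel=2)
        smooths = [build_spatial_basis(coords, k=30, name="f_s", affine="shrink")]
        fit = fit_penalized(y, X, smooths, param_names=names, method=method)
        return FitResult("discretized", pollutant, fit,
                         table=_smooth_table(fit, ["f_s"]))
    weights = weights / weights.mean()

    dmat = np.column_stack([_segment_distances(coords, s) for s in seg_list])
    dsample = dmat.ravel()[:: max(1, dmat.size // 20000)]
    inner = build_univariate_basis(dsample, k=k, name="g_raw",
                                   transform=DISTANCE_TRANSFORM)
    C = np.zeros((len(y), inner.k))
    # accumulate sum_j e_j B_k(d_ij) in segment chunks to bound memory
    chunk = 64
    for j0 in range(0, dmat.shape[1], chunk):
        block = dmat[:, j0: j0 + chunk]
        w = weights[j0: j0 + chunk]
        B = inner.raw_basis(block.ravel()).reshape(block.shape[0],
                                                   block.shape[1], inner.k)
        C += np.einsum("j,ijk->ik", w, B)
    S_raw = smoothers._second_derivative_penalty(inner.knots, inner.k)
    Z = smoothers._nullspace_of_vector(C.mean(axis=0))
    pooled = _PooledSourceSmooth("g", inner, C @ Z, Z.T @ S_raw @ Z, Z)

    smooths = [pooled, build_spatial_basis(coords, k=30, name="f_s", affine="shrink")]
    fit = fit_penalized(y, X, smooths, param_names=names, method=method)
    res = FitResult("discretized", pollutant, fit,
                    table=_smooth_table(fit, ["g", "f_s"]))

    # Bare per-segment kernel g (re-centered shape only).
    dmin = float(dmat.min())
    grid = np.arange(dmin, min(CURVE_MAX, dmat.max()) + 1e-9, CURVE_STEP)
    res.curves["kernel"] = _curve_from_term(fit, pooled, grid, "kernel")

    # Net per-road source profile: the model's predicted contribution
    # sum_j e_j g(d_ij) at receptors on a perpendicular transect from the
    # road midpoint — the quantity comparable to a direct distance smooth.
    offset = 0
    for rid in sorted(segmented):
        seg = segmented[rid]
        w = weights[offset: offset + seg.n_segments]
        offset += seg.n_segments
        curve = _net_source_curve(fit, pooled, seg, w, coords)
        if curve is not None:
            res.curves[rid] = curve
    return res


def _net_source_curve(fit: PenalizedFit, pooled: "_PooledSourceSmooth",
                      seg: SegmentedSource, w: np.ndarray,
                      coords: np.ndarray) -> DistanceCurve | None:
    """Aggregate effect of one discretized road along a perpendicular
    transect from its midpoint, with pointwise 95% CI."""
    mid_idx = seg.n_segments // 2
    mid = seg.midpoints[mid_idx]
    if seg.n_segments > 1:
        axis = seg.midpoints[min(mid_idx + 1, seg.n_segments - 1)] - \
            seg.midpoints[max(mid_idx - 1, 0)]
    else:
        axis = np.array([1.0, 0.0])
    axis = axis / max(np.linalg.norm(axis), 1e-12)
    perp = np.array([-axis[1], axis[0]])
    if np.dot(coords.mean(axis=0) - mid, perp) < 0:
        perp = -perp  # walk toward the sampled side
    h_mid = seg.heights[mid_idx]
    d0 = float(np.hypot(0.0, h_mid)) if h_mid > 0 else 0.0
    grid = np.arange(max(d0, 1.0), CURVE_MAX + 1e-9, CURVE_STEP)
    receptors = mid[None, :] + grid[:, None] * perp[None, :]
    dmat = _segment_distances(receptors, seg)
    M = np.zeros((len(grid), pooled.inner.k))
    B = pooled.inner.raw_basis(dmat.ravel()).reshape(len(grid),
                                                     seg.n_segments,
                                                     pooled.inner.k)
    M = np.einsum("j,ijk->ik", w, B) @ pooled.Z
    M = M - M[0]
    sl = fit.slices[pooled.name]
    eta = M @ fit.beta[sl]
    V = fit.covariance[sl, sl]
    var = np.einsum("ij,jk,ik->i", M, V, M)
    se = np.sqrt(np.clip(var, 0.0, None))
    z = 1.959963984540054
    eta100 = np.interp(100.0, grid, eta) if grid[0] <= 100.0 <= grid[-1] \
        else np.nan
    pct = 100.0 * (1.0 - np.exp(eta100 - eta[0])) if np.isfinite(eta100) \
        else np.nan
    return DistanceCurve(seg.road_id, grid, eta, eta - z * se, eta + z * se,
                         float(pct))


def _curve_from_term(fit: PenalizedFit, term, grid, road_id) -> DistanceCurve:
    M = term.predict_matrix(grid)
    M = M - M[0]
    sl = fit.slices[term.name]
    eta = M @ fit.beta[sl]
    V = fit.covariance[sl, sl]
    var = np.einsum("ij,jk,ik->i", M, V, M)
    se = np.sqrt(np.clip(var, 0.0, None))
    z = 1.959963984540054
    eta100 = np.interp(100.0, grid, eta) if grid[0] <= 100.0 <= grid[-1] \
        else np.nan
    pct = 100.0 * (1.0 - np.exp(eta100 - eta[0])) if np.isfinite(eta100) \
        else np.nan
    return DistanceCurve(road_id, np.asarray(grid, float), eta,
                         eta - z * se, eta + z * se, float(pct))


def predict_distance_curve(result: FitResult, road_id: str, grid=None,
                           frame: ModelFrame | None = None) -> DistanceCurve:
    """Adjusted distance-decay curve with pointwise 95% CI.

    Evaluates the fitted distance smooth on the grid (default: minimum
    observed distance to 500 m in 5-m steps), re-centers at the first grid
    point, and propagates the coefficient covariance.  Grid points beyond
    the observed distance range are truncated (no extrapolation).
    """
    name = f"f_{road_id}"
    term = next((s for s in result.fit.smooths if s.name == name), None)
    if term is None:
        raise KeyError(f"fit has no distance term for road {road_id!r}")
    lo, hi = term.data_range
    if not np.isfinite(lo):
        lo, hi = float(term.knots[0]), float(term.knots[-1])
    if grid is None:
        grid = np.arange(lo, min(hi, CURVE_MAX) + 1e-9, CURVE_STEP)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
            warnings.warn("curve grid truncated to the observed distance "
                          "range (no extrapolation)", stacklevel=2)
            grid = grid[(grid >= lo) & (grid <= hi)]
    return _curve_from_term(result.fit, term, grid, road_id)


# ---------------------------------------------------------------------------
# Sensitivity analyses


def sensitivity_suite(frame: ModelFrame, pollutant: str | None = None,
                      which="all", min_rows: int = 200,
                      criterion: str = "bic") -> dict:
    """Stratified and re-specified AR-model refits.

    ``which`` selects from {"wind", "traffic", "single_road",
    "vehicle_class", "vehicle_speed", "smooth_covariates"} or "all".
    Strata with fewer than ``min_rows`` rows are skipped with a warning.
    Returns {"fits": {label: FitResult}, "comparison": DataFrame}.
    """
    pollutant = pollutant or frame.pollutant
    if which == "all":
        which = ["wind", "traffic", "single_road", "vehicle_class",
                 "vehicle_speed", "smooth_covariates"]
    elif isinstance(which, str):
        which = [which]
    fits = {}

    def try_fit(label, sub, **kw):
        if len(sub) < min_rows:
            warnings.warn(f"stratum {label!r} has {len(sub)} rows "
                          f"(< {min_rows}); skipped", stacklevel=2)
            return
        try:
            fits[label] = fit_ar(sub, pollutant, criterion=criterion, **kw)
        except ValueError as e:
            warnings.warn(f"stratum {label!r} failed: {e}", stacklevel=2)

    if "wind" in which:
        # rows stratified by the sector relative to one source; the mean
        # structure keeps both roads so the other source stays adjusted for
        for rid in frame.road_ids:
            for sector in ["upwind", "downwind"]:
                mask = (frame.data[f"sector_{rid}"] == sector).to_numpy()
                try_fit(f"{rid}_{sector}", frame.subset(mask))
    if "traffic" in which:
        for rid in frame.road_ids:
            high = median_split(frame, f"traffic_{rid}")
            try_fit(f"{rid}_high_traffic", frame.subset(high), roads=[rid])
            try_fit(f"{rid}_low_traffic", frame.subset(~high), roads=[rid])
    if "single_road" in which:
        for rid in frame.road_ids:
            try_fit(f"single_{rid}", frame, roads=[rid])
    if "vehicle_class" in which:
        cols = [c for c in frame.data.columns
                if c.endswith(("_car", "_truckbus")) and c.startswith("traffic_")]
        if cols:
            try_fit("vehicle_class", frame, traffic_cols=cols)
    if "vehicle_speed" in which:
        cols = [c for c in frame.data.columns
                if c.endswith(("_slow", "_med", "_fast")) and c.startswith("traffic_")]
        if cols:
            try_fit("vehicle_speed", frame, traffic_cols=cols)
    if "smooth_covariates" in which:
        try_fit("smooth_covariates", frame, met_smooth=True)

    rows = []
    for label, res in fits.items():
        for rid, curve in res.curves.items():
            rows.append({
                "analysis": label, "road_id": rid, "r2": res.r2,
                "pct_decrease_100m": curve.pct_decrease_100m,
                "distance_p": smooth_pvalue(res.fit, f"f_{rid}"),
                "ar_order": res.ar.order if res.ar else 0,
            })
    return {"fits": fits, "comparison": pd.DataFrame(rows)}
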