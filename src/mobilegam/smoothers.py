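"""Penalized regression splines and generalized least squares.

This is the estimation core of the package.  It implements, from first
principles:

* cubic B-spline bases with quantile knots and exact second-derivative
  roughness penalties (univariate smooths of distance or time);
* a low-rank thin-plate-style radial basis for the bivariate spatial smooth,
  with an unpenalized affine null space and the standard bending-energy
  penalty restricted to the radial coefficients;
* sum-to-zero (centering) constraint absorption by null-space
  reparameterization, so every smooth is identifiable next to an intercept;
* penalized (generalized) least squares with per-smooth smoothing
  parameters chosen by REML (default) or GCV via coordinate-wise Brent
  search on log(lambda);
* exact AR(p) innovations whitening within contiguous series, so a fit with
  autocorrelated errors reduces to an ordinary penalized solve; and
* Wald-type approximate tests for smooth terms on their effective degrees
  of freedom.

Design matrices are dense; problem sizes here (a few thousand rows, well
under a hundred coefficients) make sparse machinery unnecessary.

Notation: the model is y = X beta + sum_j f_j + eps, each f_j = B_j b_j with
penalty lambda_j * b_j' S_j b_j.  With AR errors, rows are whitened by the
innovations filter before solving; smoothing parameters are selected on the
whitened problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats
from scipy.interpolate import BSpline

__all__ = [
    "UnivariateSmooth",
    "SpatialSmooth",
    "PenalizedFit",
    "build_univariate_basis",
    "build_spatial_basis",
    "fit_penalized",
    "smooth_pvalue",
    "ar_autocovariance",
    "whiten_ar",
]

_LOG10_LAMBDA_BOUNDS = (-8.0, 10.0)


# ---------------------------------------------------------------------------
# Basis construction


def _nullspace_of_vector(c: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z of {b : c'b = 0}, shape (k, k-1)."""
    c = np.asarray(c, dtype=float)
    return linalg.null_space(c[None, :])


def _bspline_knots(values: np.ndarray, k: int) -> np.ndarray:
    """Full (clamped) cubic knot vector giving k basis functions, interior
    knots at quantiles of the observed values."""
    lo, hi = float(np.min(values)), float(np.max(values))
    n_interior = k - 4
    if n_interior > 0:
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(np.unique(values), probs)
        # nudge coincident interior knots apart
        interior = np.clip(interior, lo + 1e-9, hi - 1e-9)
        for i in range(1, len(interior)):
            if interior[i] <= interior[i - 1]:
                interior[i] = interior[i - 1] + 1e-9
    else:
        interior = np.array([])
    return np.concatenate([[lo] * 4, interior, [hi] * 4])


def _second_derivative_penalty(t: np.ndarray, k: int) -> np.ndarray:
    """Exact Gram matrix of second derivatives of the k cubic B-splines.

    B'' is piecewise linear, so Simpson's rule on each knot span integrates
    the products exactly.
    """
    spl = BSpline(t, np.eye(k), 3)
    d2 = spl.derivative(2)
    spans = np.unique(t)
    S = np.zeros((k, k))
    for a, b in zip(spans[:-1], spans[1:]):
        if b <= a:
            continue
        pa, pm, pb = d2(a + 1e-12), d2((a + b) / 2.0), d2(b - 1e-12)
        S += (b - a) / 6.0 * (np.outer(pa, pa) + 4.0 * np.outer(pm, pm)
                              + np.outer(pb, pb))
    return (S + S.T) / 2.0


@dataclass
class UnivariateSmooth:
    """A centered cubic-regression-spline smooth f(x).

    ``design`` (n, k-1) and ``penalty`` ((k-1, k-1)) live in the constrained
    space after absorbing the sum-to-zero constraint through ``Z``.
    Evaluations over the observed covariate values have mean zero.
    """

    name: str
    knots: np.ndarray
    k: int
    Z: np.ndarray
    penalty: np.ndarray
    design: np.ndarray
    transform: str = "identity"   # "identity" | "log" (knots live in the
    offset: float = 0.0           # transformed coordinate)
    data_range: tuple = (np.nan, np.nan)
    coef: np.ndarray | None = None
    edf: float | None = None
    lambda_: float | None = None

    @property
    def n_coef(self) -> int:
        return self.Z.shape[1]

    def _map(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.transform == "log":
            x = np.log(np.clip(x, 0.0, None) + self.offset)
        return x

    def raw_basis(self, x) -> np.ndarray:
        x = np.clip(self._map(x), self.knots[0], self.knots[-1])
        return BSpline.design_matrix(x, self.knots, 3).toarray()

    def predict_matrix(self, x) -> np.ndarray:
        """Constrained basis evaluated at new covariate values."""
        return self.raw_basis(x) @ self.Z

    def evaluate(self, x) -> np.ndarray:
        if self.coef is None:
            raise RuntimeError(f"smooth {self.name!r} has not been fitted")
        return self.predict_matrix(x) @ self.coef


def build_univariate_basis(values, k: int = 10, name: str = "f",
                           transform: str = "identity",
                           offset: float = 10.0) -> UnivariateSmooth:
    """Centered cubic B-spline basis with a second-derivative penalty.

    Knots sit at quantiles of the observed values; the k raw functions are a
    partition of unity, and the constraint removes exactly one coefficient.
    With ``transform="identity"`` a linear function incurs zero penalty.

    ``transform="log"`` builds the spline in log(x + offset): knot
    resolution and the roughness penalty then follow the multiplicative
    geometry of near-source dispersion, which concentrates curvature close
    to the source.  The result is still a smooth function of x; the offset
    (meters, default 10) keeps the coordinate finite at x = 0.
    """
    x_raw = np.asarray(values, dtype=float)
    if transform not in ("identity", "log"):
        raise ValueError(f"unknown transform {transform!r}")
    x = np.log(np.clip(x_raw, 0.0, None) + offset) if transform == "log" \
        else x_raw
    distinct = np.unique(x)
    if len(distinct) < 2:
        raise ValueError(f"smooth {name!r}: covariate is constant (no spread)")
    if len(distinct) < k:
        raise ValueError(
            f"smooth {name!r}: only {len(distinct)} distinct values for "
            f"k={k}; reduce the basis dimension")
    if k < 4:
        raise ValueError("cubic basis needs k >= 4")
    t = _bspline_knots(x, k)
    B = BSpline.design_matrix(x, t, 3).toarray()
    S = _second_derivative_penalty(t, k)
    Z = _nullspace_of_vector(B.mean(axis=0))
    return UnivariateSmooth(name=name, knots=t, k=k, Z=Z,
                            penalty=Z.T @ S @ Z, design=B @ Z,
                            transform=transform,
                            offset=offset if transform == "log" else 0.0,
                            data_range=(float(x_raw.min()), float(x_raw.max())))


# ---------------------------------------------------------------------------
# Bivariate spatial smooth (low-rank thin-plate-style radial basis)


def _tps_eta(r: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


def _farthest_point_knots(coords: np.ndarray, m: int) -> np.ndarray:
    """Deterministic space-filling subset: start nearest the centroid, then
    greedily add the point farthest from the chosen set."""
    uniq = np.unique(coords, axis=0)
    if len(uniq) <= m:
        return uniq
    centroid = uniq.mean(axis=0)
    start = int(np.argmin(np.linalg.norm(uniq - centroid, axis=1)))
    chosen = [start]
    dmin = np.linalg.norm(uniq - uniq[start], axis=1)
    for _ in range(m - 1):
        nxt = int(np.argmax(dmin))
        chosen.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(uniq - uniq[nxt], axis=1))
    return uniq[np.array(chosen)]


@dataclass
class SpatialSmooth:
    """Centered bivariate smooth f(easting, northing).

    Columns before constraint absorption: two (scaled, centered) affine
    coordinates — the unpenalized null space — followed by radial
    r^2 log r functions at space-filling knots, reparameterized to satisfy
    the thin-plate side conditions; the bending-energy penalty acts on the
    radial block only, so a pure affine surface incurs zero penalty.
    """

    name: str
    knots: np.ndarray
    k: int
    center: np.ndarray
    scale: float
    Zt: np.ndarray            # (m, m-3) side-condition transform, empty if affine-only
    Z: np.ndarray             # centering constraint transform
    penalty: object           # ndarray, or list of ndarrays (multi-penalty)
    design: np.ndarray
    include_affine: bool = True
    coef: np.ndarray | None = None
    edf: float | None = None
    lambda_: float | None = None

    @property
    def n_coef(self) -> int:
        return self.Z.shape[1]

    def raw_basis(self, coords) -> np.ndarray:
        s = (np.asarray(coords, dtype=float) - self.center) / self.scale
        cols = []
        if self.include_affine:
            cols += [s[:, 0], s[:, 1]]
        if self.Zt.size:
            kn = (self.knots - self.center) / self.scale
            r = np.linalg.norm(s[:, None, :] - kn[None, :, :], axis=2)
            cols.append(_tps_eta(r) @ self.Zt)
        return np.column_stack(cols)

    def predict_matrix(self, coords) -> np.ndarray:
        return self.raw_basis(coords) @ self.Z

    def evaluate(self, coords) -> np.ndarray:
        if self.coef is None:
            raise RuntimeError(f"smooth {self.name!r} has not been fitted")
        return self.predict_matrix(coords) @ self.coef


def build_spatial_basis(coords, k: int = 30, name: str = "f_s",
                        affine: str = "free") -> SpatialSmooth:
    """Low-rank thin-plate-style basis over planar coordinates.

    ``k`` is the column count before the centering constraint: 2 affine
    columns plus k-2 penalized radial columns (k <= 3 degenerates to the
    affine-only surface).  Knots are a deterministic space-filling subset of
    the observed locations.

    ``affine`` controls the bending-energy null space (the affine plane):

    ``"free"``
        unpenalized, the classical thin-plate convention;
    ``"shrink"``
        a second, separately-selected shrinkage penalty on the affine
        directions (double-penalty selection);
    ``"drop"``
        affine columns excluded entirely, leaving only the penalized
        radial part.

    Distance to a roadway is itself a near-affine function of location, so
    a free affine surface is structurally confounded with the distance
    smooths' unpenalized linear directions; next to distance terms the
    surface should be built with ``affine="drop"`` (or ``"shrink"``) so
    road-aligned gradients are attributed to the distance terms and the
    surface captures residual local heterogeneity.
    """
    if affine not in ("free", "shrink", "drop"):
        raise ValueError(f"unknown affine mode {affine!r}")
    s = np.asarray(coords, dtype=float)
    center = s.mean(axis=0)
    sc = s - center
    svals = np.linalg.svd(sc, compute_uv=False)
    if svals[1] < 1e-8 * max(svals[0], 1.0):
        raise ValueError(f"smooth {name!r}: locations are collinear; a "
                         "bivariate smooth is not identifiable")
    scale = float(np.sqrt((sc ** 2).sum(axis=1).mean()))

    if k <= 3:
        if affine == "drop":
            raise ValueError("affine='drop' needs k > 3 (radial columns)")
        knots = np.empty((0, 2))
        Zt = np.empty((0, 0))
        raw = sc / scale
        Z = np.eye(2)  # affine columns are exactly mean-centered already
        return SpatialSmooth(name=name, knots=knots, k=k, center=center,
                             scale=scale, Zt=Zt, Z=Z,
                             penalty=np.zeros((2, 2)), design=raw)

    m = k + 1  # radial knots; side conditions remove 3 -> k-2 radial columns
    knots = _farthest_point_knots(s, m)
    m = len(knots)
    kn = (knots - center) / scale
    T = np.column_stack([np.ones(m), kn])
    Zt = linalg.null_space(T.T)
    K = _tps_eta(np.linalg.norm(kn[:, None, :] - kn[None, :, :], axis=2))
    P = Zt.T @ K @ Zt
    P = (P + P.T) / 2.0
    w, V = np.linalg.eigh(P)
    P = (V * np.clip(w, 0.0, None)) @ V.T  # clip round-off negatives

    n_aff = 0 if affine == "drop" else 2
    sm = SpatialSmooth(name=name, knots=knots, k=k, center=center, scale=scale,
                       Zt=Zt, Z=np.eye(n_aff + Zt.shape[1]),
                       penalty=np.zeros((0, 0)), design=np.empty((0, 0)),
                       include_affine=(n_aff == 2))
    raw = sm.raw_basis(s)
    full_pen = np.zeros((raw.shape[1], raw.shape[1]))
    full_pen[n_aff:, n_aff:] = P
    Z = _nullspace_of_vector(raw.mean(axis=0))
    sm.Z = Z
    S1 = Z.T @ full_pen @ Z
    sm.design = raw @ Z
    if affine == "shrink":
        w2, V2 = np.linalg.eigh((S1 + S1.T) / 2.0)
        null_mask = w2 <= 1e-10 * max(w2[-1], 1e-300)
        U0 = V2[:, null_mask]
        sm.penalty = [S1, U0 @ U0.T]
    else:
        sm.penalty = S1
    return sm


# ---------------------------------------------------------------------------
# AR(p) innovations whitening


def ar_autocovariance(phi, nlags: int, sigma2: float = 1.0) -> np.ndarray:
    """Autocovariances gamma_0..gamma_nlags of a stationary AR(p) process
    with innovation variance sigma2, from the Yule-Walker equations."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    p = len(phi)
    if p == 0:
        g = np.zeros(nlags + 1)
        g[0] = sigma2
        return g
    # Solve the (p+1)-dim linear system for gamma_0..gamma_p.
    A = np.zeros((p + 1, p + 1))
    b = np.zeros(p + 1)
    A[0, 0] = 1.0
    for i in range(1, p + 1):
        A[0, i] -= phi[i - 1]
    b[0] = sigma2
    for k in range(1, p + 1):
        A[k, k] += 1.0
        for i in range(1, p + 1):
            A[k, abs(k - i)] -= phi[i - 1]
        b[k] = 0.0
    g = np.linalg.solve(A, b)
    out = np.empty(nlags + 1)
    m = min(p + 1, nlags + 1)
    out[:m] = g[:m]
    for k in range(p + 1, nlags + 1):
        out[k] = np.dot(phi, out[k - np.arange(1, p + 1)])
    return out


def _ar_whitening_rows(phi: np.ndarray, n: int):
    """Leading-block Cholesky for the first p rows of the innovations filter.

    Returns (L_p, p): whitened[:p] = solve(L_p, x[:p]); whitened[t] =
    x[t] - sum_k phi_k x[t-k] for t >= p.  Whitened series has unit
    innovation variance when the true innovations do.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    p = len(phi)
    if p == 0 or n == 0:
        return None, 0
    p_eff = min(p, n)
    g = ar_autocovariance(phi, p_eff - 1, sigma2=1.0)
    Gamma = linalg.toeplitz(g)
    return np.linalg.cholesky(Gamma), p_eff


def whiten_ar(X: np.ndarray, phi, groups) -> np.ndarray:
    """Apply the exact AR(p) innovations filter within each contiguous
    series (list of index arrays).  Correlation never crosses groups."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    p = len(phi)
    out = np.array(X, dtype=float, copy=True)
    if p == 0:
        return out
    X2 = X if X.ndim == 2 else X[:, None]
    out2 = out if out.ndim == 2 else out[:, None]
    for idx in groups:
        idx = np.asarray(idx)
        n = len(idx)
        block = X2[idx]
        L, p_eff = _ar_whitening_rows(phi, n)
        w = block.copy()
        if n > p:
            w[p:] = block[p:] - sum(
                phi[k - 1] * block[p - k: n - k] for k in range(1, p + 1))
        if L is not None:
            w[:p_eff] = linalg.solve_triangular(L, block[:p_eff], lower=True)
        out2[idx] = w
    return out


# ---------------------------------------------------------------------------
# Penalized (generalized) least squares with REML/GCV lambda selection


@dataclass
class PenalizedFit:
    """Result of a penalized least-squares fit.

    ``beta`` stacks parametric coefficients then each smooth's (constrained)
    coefficients; ``covariance`` is the conditional (posterior-style)
    covariance on the whitened problem, given the selected smoothing
    parameters (no smoothing-parameter uncertainty).  ``r2`` is
    the squared correlation of fitted and observed y on the original
    (unwhitened) scale.
    """

    beta: np.ndarray
    covariance: np.ndarray
    covariance_freq: np.ndarray
    lambdas: np.ndarray
    sigma2: float
    r2: float
    residuals: np.ndarray
    fitted: np.ndarray
    edf: dict
    edf_total: float
    slices: dict
    param_names: list
    smooths: list
    n: int
    method: str
    score: float
    rss: float

    def term_slice(self, name: str) -> slice:
        return self.slices[name]

    def term_covariance(self, name: str) -> np.ndarray:
        sl = self.slices[name]
        return self.covariance[sl, sl]

    def param_table(self, z: float = 1.959963984540054):
        """(estimate, lo95, hi95, p) per parametric column (Wald, normal)."""
        rows = []
        sl = self.slices["parametric"]
        se = np.sqrt(np.diag(self.covariance)[sl])
        for i, name in enumerate(self.param_names):
            est = self.beta[sl][i]
            s = se[i]
            p = 2.0 * stats.norm.sf(abs(est) / s) if s > 0 else np.nan
            rows.append((name, est, est - z * s, est + z * s, p))
        return rows


def _check_full_rank(X_par: np.ndarray, names) -> None:
    if X_par.shape[1] == 0:
        return
    _, R = np.linalg.qr(X_par)
    d = np.abs(np.diag(R))
    bad = d < 1e-10 * max(d.max(), 1.0)
    if bad.any():
        cols = [names[i] for i in np.where(bad)[0]]
        raise ValueError(f"parametric design is rank deficient; offending "
                         f"columns: {cols}")


def fit_penalized(y, X_par, smooths, param_names=None, ar_phi=None,
                  groups=None, method: str = "reml",
                  lambdas=None, rel_tol: float = 1e-4,
                  max_sweeps: int = 50) -> PenalizedFit:
    """Penalized least squares with data-driven smoothing parameters.

    Parameters
    ----------
    y : (n,) response.
    X_par : (n, q) parametric design (include the intercept here).
    smooths : list of UnivariateSmooth / SpatialSmooth (or any object with
        ``design``, ``penalty``, ``name``) built on the same rows.
    ar_phi : optional AR coefficients; when given, y and the design are
        whitened by the exact innovations filter within each ``groups``
        series before solving, and smoothing parameters are selected on the
        whitened problem.  The AR parameters are taken as fixed.
    groups : list of row-index arrays (contiguous-in-time series); required
        with ``ar_phi``.
    method : "reml" (default) or "gcv".
    lambdas : optional fixed smoothing parameters (skips selection).
        ``np.inf`` entries shrink a smooth to its penalty null space.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    X_par = np.asarray(X_par, dtype=float)
    n = len(y)
    param_names = list(param_names) if param_names is not None else [
        f"x{i}" for i in range(X_par.shape[1])]
    _check_full_rank(X_par, param_names)

    blocks = [X_par] + [sm.design for sm in smooths]
    X = np.column_stack(blocks) if blocks else X_par
    p_tot = X.shape[1]
    slices = {"parametric": slice(0, X_par.shape[1])}
    pos = X_par.shape[1]
    for sm in smooths:
        slices[sm.name] = slice(pos, pos + sm.design.shape[1])
        pos += sm.design.shape[1]

    # Whitened copies (identity when no AR structure).
    if ar_phi is not None and len(np.atleast_1d(ar_phi)) > 0:
        if groups is None:
            raise ValueError("groups are required for AR whitening")
        yw = whiten_ar(y, ar_phi, groups)
        Xw = whiten_ar(X, ar_phi, groups)
    else:
        yw, Xw = y, X

    XtX = Xw.T @ Xw
    Xty = Xw.T @ yw
    yty = float(yw @ yw)

    # Penalty blocks, normalized for conditioning; precompute pseudo-det
    # pieces so the REML score needs no per-evaluation eigendecomposition.
    # A smooth may carry several penalties (e.g. a null-space shrinkage
    # penalty next to the roughness penalty); blocks of distinct smooths are
    # disjoint and multiple penalties within one smooth have orthogonal
    # ranges, so log|S_lambda|+ separates into per-penalty pieces.
    pen_info = []   # (slice, normalized S, rank, logdet, owner smooth index)
    for j, sm in enumerate(smooths):
        sl = slices[sm.name]
        pens = sm.penalty if isinstance(sm.penalty, (list, tuple)) \
            else [sm.penalty]
        for S in pens:
            S = np.asarray(S, dtype=float)
            scale = float(np.linalg.eigvalsh(S)[-1]) if S.size else 0.0
            if scale <= 0:
                pen_info.append((sl, S, 0, 0.0, j))
                continue
            Sn = S / scale
            w = np.linalg.eigvalsh(Sn)
            rank = int((w > 1e-10).sum())
            logdet = float(np.log(w[w > 1e-10]).sum())
            pen_info.append((sl, Sn, rank, logdet, j))
    n_pen = len(pen_info)
    total_rank = sum(r for _, _, r, _, _ in pen_info)
    M_null = p_tot - total_rank  # dimension of the total penalty null space

    def assemble(lam):
        A = XtX.copy()
        for (sl, Sn, rank, _, _), lj in zip(pen_info, lam):
            if rank and np.isfinite(lj):
                A[sl, sl] += lj * Sn
        return A

    BIG = 1e12

    def solve_beta(lam):
        lam_eff = np.where(np.isfinite(lam), lam, BIG)
        A = assemble(lam_eff)
        try:
            c, low = linalg.cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            A = A + 1e-8 * np.trace(A) / p_tot * np.eye(p_tot)
            c, low = linalg.cho_factor(A, lower=True)
        beta = linalg.cho_solve((c, low), Xty)
        return beta, (c, low), lam_eff

    def score_fn(lam):
        beta, (c, low), lam_eff = solve_beta(lam)
        rss = max(yty - 2.0 * beta @ Xty + beta @ (XtX @ beta), 1e-300)
        if method == "reml":
            pen = 0.0
            logdet_S = 0.0
            for (sl, Sn, rank, ld, _), lj in zip(pen_info, lam_eff):
                if rank:
                    pen += lj * float(beta[sl] @ (Sn @ beta[sl]))
                    logdet_S += rank * np.log(lj) + ld
            nm = n - M_null
            sig2 = (rss + pen) / nm
            logdet_A = 2.0 * np.log(np.abs(np.diag(c))).sum()
            return (nm / 2.0 * np.log(2.0 * np.pi * sig2) + nm / 2.0
                    + 0.5 * logdet_A - 0.5 * logdet_S)
        else:  # GCV
            Ainv_XtX = linalg.cho_solve((c, low), XtX)
            tr = float(np.trace(Ainv_XtX))
            denom = max(n - tr, 1e-8)
            return n * rss / denom ** 2

    if lambdas is not None:
        lam = np.asarray(lambdas, dtype=float)
        final_score = score_fn(lam) if n_pen else np.nan
    elif n_pen == 0:
        lam = np.array([])
        final_score = np.nan
    else:
        lam = np.ones(n_pen)
        prev = score_fn(lam)
        lo, hi = _LOG10_LAMBDA_BOUNDS
        for _ in range(max_sweeps):
            for j in range(n_pen):
                if pen_info[j][2] == 0:
                    continue

                def obj(loglam, j=j):
                    trial = lam.copy()
                    trial[j] = 10.0 ** loglam
                    return score_fn(trial)

                res = optimize.minimize_scalar(
                    obj, bounds=(lo, hi), method="bounded",
                    options={"xatol": 1e-2})
                lam[j] = 10.0 ** res.x
            cur = score_fn(lam)
            if abs(prev - cur) <= rel_tol * (abs(prev) + 1e-10):
                break
            prev = cur
        final_score = prev

    beta, (c, low), lam_eff = solve_beta(lam)
    Ainv = linalg.cho_solve((c, low), np.eye(p_tot))
    F = Ainv @ XtX
    edf = {}
    diagF = np.diag(F)
    for name, sl in slices.items():
        edf[name] = float(diagF[sl].sum())
    edf_total = float(diagF.sum())

    rss_w = max(yty - 2.0 * beta @ Xty + beta @ (XtX @ beta), 0.0)
    sigma2 = rss_w / max(n - edf_total, 1.0)
    # conditional (posterior-style) covariance A^-1 sigma^2, the standard
    # basis for smooth-curve bands; conditional on the selected lambdas
    cov = Ainv * sigma2
    cov = (cov + cov.T) / 2.0
    # frequentist covariance of beta-hat for fixed lambdas (A^-1 X'X A^-1
    # sigma^2): the exact null covariance, used by the Wald smooth tests
    cov_freq = Ainv @ XtX @ Ainv * sigma2
    cov_freq = (cov_freq + cov_freq.T) / 2.0

    fitted = X @ beta
    resid = y - fitted
    vf, vy = np.var(fitted), np.var(y)
    if vf > 0 and vy > 0:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    else:
        r2 = 0.0

    fit = PenalizedFit(
        beta=beta, covariance=cov, covariance_freq=cov_freq,
        lambdas=lam, sigma2=sigma2, r2=r2,
        residuals=resid, fitted=fitted, edf=edf, edf_total=edf_total,
        slices=slices, param_names=param_names, smooths=list(smooths),
        n=n, method=method, score=float(final_score), rss=rss_w)

    for j, sm in enumerate(smooths):
        sl = slices[sm.name]
        sm.coef = beta[sl]
        sm.edf = edf[sm.name]
        own = [float(lam[i]) for i, (_, _, _, _, owner) in enumerate(pen_info)
               if owner == j]
        sm.lambda_ = own[0] if len(own) == 1 else own
    return fit


def smooth_pvalue(fit: PenalizedFit, name: str) -> float:
    """Approximate Wald test of a smooth term against zero.

    The statistic is b' Vf^+ b with Vf the frequentist covariance of the
    coefficients at the selected smoothing parameters — exactly the null
    covariance of b-hat for fixed lambdas, so penalty shrinkage cancels in
    the quadratic form — referred to a chi-square on the covariance rank.
    Documented as approximate: the reference distribution ignores
    smoothing-parameter selection.
    """
    if name not in fit.slices:
        raise KeyError(f"fit has no term {name!r}")
    sl = fit.slices[name]
    b = fit.beta[sl]
    V = fit.covariance_freq[sl, sl]
    w, U = np.linalg.eigh((V + V.T) / 2.0)
    keep = w > 1e-10 * max(w[-1], 1e-300)
    r = int(keep.sum())
    if r == 0:
        return 1.0
    proj = U[:, keep].T @ b
    stat = float(np.sum(proj * proj / w[keep]))
    return float(stats.chi2.sf(stat, df=r))
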