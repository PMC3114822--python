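"""Publication-style outputs: coefficient tables, distance-curve files,
and smoothed concentration-surface maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .models import FitResult
from .smoothers import build_spatial_basis, fit_penalized

__all__ = ["SurfaceMap", "surface_map", "results_tables", "curves_table"]


@dataclass
class SurfaceMap:
    """Smoothed pollutant surface on a regular UTM lattice, in original
    concentration units; cells far from any observation are masked."""

    easting: np.ndarray
    northing: np.ndarray
    value: np.ndarray      # 2-D (ny, nx), NaN where masked
    masked: np.ndarray     # 2-D bool
    pollutant: str
    adjustment: str

    def to_frame(self) -> pd.DataFrame:
        ee, nn = np.meshgrid(self.easting, self.northing)
        return pd.DataFrame({
            "easting": ee.ravel(), "northing": nn.ravel(),
            "value": self.value.ravel(), "masked": self.masked.ravel()})


def surface_map(coords, values, pollutant: str, adjust_by_shift: bool = False,
                shift_ids=None, resolution: float = 10.0,
                mask_radius: float = 100.0, k: int = 60) -> SurfaceMap:
    """Descriptive map: fit log concentration on a bivariate spatial smooth
    (plus shift dummies when ``adjust_by_shift``), predict on the lattice,
    exponentiate back to original units.

    The shift adjustment removes temporal offsets before mapping, as
    appropriate for a pollutant dominated by diurnal background.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(coords) < 100:
        raise ValueError("surface mapping needs at least 100 observations")
    y = np.log(values)

    cols = [np.ones(len(y))]
    names = ["intercept"]
    if adjust_by_shift:
        if shift_ids is None:
            raise ValueError("shift_ids required when adjust_by_shift=True")
        shift_ids = np.asarray(shift_ids)
        for lev in sorted(np.unique(shift_ids))[1:]:
            cols.append((shift_ids == lev).astype(float))
            names.append(f"shift[{lev}]")
    X = np.column_stack(cols)

    k = min(k, max(4, len(np.unique(coords, axis=0)) - 2))
    sm = build_spatial_basis(coords, k=k, name="f_s")
    fit = fit_penalized(y, X, [sm], param_names=names, method="reml")

    ee = np.arange(coords[:, 0].min(), coords[:, 0].max() + resolution,
                   resolution)
    nn = np.arange(coords[:, 1].min(), coords[:, 1].max() + resolution,
                   resolution)
    gx, gy = np.meshgrid(ee, nn)
    gpts = np.column_stack([gx.ravel(), gy.ravel()])
    tree = cKDTree(coords)
    dist, _ = tree.query(gpts)
    masked = dist > mask_radius

    sl = fit.slices["f_s"]
    eta = fit.beta[0] + sm.predict_matrix(gpts) @ fit.beta[sl]
    surface = np.exp(eta)
    surface[masked] = np.nan
    return SurfaceMap(ee, nn, surface.reshape(gy.shape),
                      masked.reshape(gy.shape), pollutant,
                      "shift-adjusted" if adjust_by_shift else "none")


def results_tables(fits: dict) -> pd.DataFrame:
    """Side-by-side coefficient table across models (one column block per
    model, identical row order; smooth terms carry NA estimates and a
    p-value only, plus a final R^2 row)."""
    kinds = list(fits)
    pols = {f.pollutant for f in fits.values()}
    if len(pols) > 1:
        raise ValueError(f"fits mix pollutants: {sorted(pols)}")
    base = None
    blocks = {}
    for kind in kinds:
        t = fits[kind].table.set_index("term")
        blocks[kind] = t
        if base is None:
            base = [term for term in t.index
                    if not term.startswith(("day[", "shift["))]
    out = pd.DataFrame(index=pd.Index(base, name="term"))
    for kind in kinds:
        t = blocks[kind]
        for col in ["estimate", "lo95", "hi95", "p"]:
            out[f"{kind}_{col}"] = [
                round(t.loc[term, col], 3) if term in t.index else np.nan
                for term in base]
    return out.reset_index()


def curves_table(result: FitResult) -> pd.DataFrame:
    """Long-format distance curves (grid, eta, lo95, hi95) for all roads."""
    return pd.concat([c.to_frame() for c in result.curves.values()],
                     ignore_index=True)
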