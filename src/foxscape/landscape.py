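"""Model-free barrier/corridor surfaces, circuit-theory resistance
distances, and Mantel / partial Mantel matrix tests.

The barrier surface is built without any landscape model: pairwise genetic
distance is regressed on Euclidean distance, each pair's residual (observed
minus expected genetic distance) is attached to the pair's midpoint, and the
residuals are interpolated by inverse-distance weighting onto a raster. A
row/column permutation null randomizes midpoints with respect to genetic
distances to show what such surfaces look like by chance.

Resistance distances treat the raster as an electrical network: cells are
nodes, 4-neighbor edges carry the mean of the two cells' conductances
(1/resistance), and the pairwise effective resistance comes from solving the
graph Laplacian.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, diags
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .genodata import (DataError, DistanceMatrix, RasterGrid, SiteMap,
                       require_matching_labels)

__all__ = [
    "ResidualSurface",
    "distance_decay_residuals",
    "grid_over_sites",
    "idw_residual_surface",
    "NullSurfaceSummary",
    "surface_permutation_null",
    "resistance_distance",
    "MantelResult",
    "mantel_test",
    "partial_mantel_test",
]


# ---------------------------------------------------------------------------
# Distance-decay residuals and IDW surfaces
# ---------------------------------------------------------------------------

@dataclass
class ResidualSurface:
    slope: float
    intercept: float
    pairs: list[tuple[str, str]]
    residuals: np.ndarray
    midpoints: np.ndarray          # (n_pairs, 2) planar km
    n_excluded_infinite: int = 0
    idw_power: float = 2.0
    raster: RasterGrid | None = None


def distance_decay_residuals(d_gen: DistanceMatrix,
                             sites: SiteMap) -> ResidualSurface:
    """OLS of pairwise genetic distance on Euclidean distance (km).

    Residual e_ij = observed - predicted; the pair's midpoint is the
    arithmetic midpoint of the two site coordinates. Non-finite genetic
    distances (e.g. capped linearized F_ST) are excluded with a count.
    """
    labels = d_gen.labels
    if len(labels) < 2:
        raise DataError("need >= 2 sites")
    xy = sites.array(labels)
    pairs, gvals, evals_, mids = [], [], [], []
    n_inf = 0
    for i, j in itertools.combinations(range(len(labels)), 2):
        g = d_gen.values[i, j]
        if not np.isfinite(g):
            n_inf += 1
            continue
        pairs.append((labels[i], labels[j]))
        gvals.append(g)
        evals_.append(float(np.hypot(*(xy[i] - xy[j]))))
        mids.append((xy[i] + xy[j]) / 2.0)
    g = np.asarray(gvals)
    e = np.asarray(evals_)
    if len(g) < 1:
        raise DataError("no finite genetic distances")
    if len(labels) == 2 or np.ptp(e) == 0:
        import warnings
        warnings.warn("degenerate regression (2 sites or constant Euclidean "
                      "distance); residuals are identically 0", stacklevel=2)
        slope, intercept = 0.0, float(g.mean())
    else:
        slope, intercept = np.polyfit(e, g, 1)
    resid = g - (slope * e + intercept)
    return ResidualSurface(float(slope), float(intercept), pairs, resid,
                           np.asarray(mids), n_inf)


def grid_over_sites(sites: SiteMap, n_cells: int = 100,
                    margin: float = 0.10) -> RasterGrid:
    """Empty square-celled raster over the sites' bounding box plus margin."""
    xy = sites.array()
    lo = xy.min(0)
    hi = xy.max(0)
    span = np.maximum(hi - lo, 1e-9)
    lo = lo - margin * span
    hi = hi + margin * span
    cell = float(max(hi - lo) / n_cells)
    ncols = max(int(np.ceil((hi[0] - lo[0]) / cell)), 1)
    nrows = max(int(np.ceil((hi[1] - lo[1]) / cell)), 1)
    return RasterGrid(np.zeros((nrows, ncols)), cell, (float(lo[0]), float(lo[1])))


def idw_residual_surface(rs: ResidualSurface, grid: RasterGrid,
                         idw_power: float = 2.0,
                         search_radius: float = math.inf) -> RasterGrid:
    """Inverse-distance-weighted interpolation of pair residuals.

    Cell value = sum(w_k e_k)/sum(w_k) with w_k = 1/d^power to midpoint k.
    A cell whose center coincides with a midpoint takes that residual
    exactly; cells with no midpoint within the search radius become nodata.
    """
    if len(rs.residuals) == 0:
        raise DataError("no residuals to interpolate")
    if grid.n_rows * grid.n_cols == 0:
        raise DataError("empty grid")
    cx, cy = grid.cell_centers()
    pts = np.stack([cx.ravel(), cy.ravel()], axis=1)       # (cells, 2)
    d = np.sqrt(((pts[:, None, :] - rs.midpoints[None, :, :]) ** 2).sum(-1))
    vals = np.empty(len(pts))
    exact = d < 1e-9
    with np.errstate(divide="ignore"):
        w = 1.0 / d ** idw_power
    w[d > search_radius] = 0.0
    any_exact = exact.any(1)
    wsum = w.sum(1)
    ok = (wsum > 0) & ~any_exact
    vals[ok] = (w[ok] * rs.residuals[None, :]).sum(1) / wsum[ok]
    for row in np.flatnonzero(any_exact):
        vals[row] = rs.residuals[np.flatnonzero(exact[row])[0]]
    nodata = ~ok & ~any_exact
    vals[nodata] = -9999.0
    out = vals.reshape(grid.n_rows, grid.n_cols)
    return RasterGrid(out, grid.cell_size, grid.origin,
                      nodata.reshape(grid.n_rows, grid.n_cols))


@dataclass
class NullSurfaceSummary:
    observed: RasterGrid
    quantiles: dict[float, np.ndarray]   # per-cell null quantiles
    exceedance: np.ndarray               # fraction of null <= observed
    n_perm: int


def surface_permutation_null(d_gen: DistanceMatrix, sites: SiteMap,
                             n_perm: int, seed: int,
                             grid: RasterGrid | None = None,
                             idw_power: float = 2.0,
                             quantiles=(0.025, 0.5, 0.95, 0.975)) -> NullSurfaceSummary:
    """Row/column permutation null for the residual surface.

    Each permutation relabels sites in the genetic matrix (simultaneous
    row/column permutation), then the regression, residuals, and IDW surface
    are recomputed. The identity relabeling is included as the first member,
    so the observed surface belongs to its own null set.
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = grid_over_sites(sites)
    k = len(d_gen.labels)
    stack = []
    for b in range(n_perm):
        perm = np.arange(k) if b == 0 else rng.permutation(k)
        vals = d_gen.values[np.ix_(perm, perm)]
        dm = DistanceMatrix(d_gen.labels, vals)
        rs = distance_decay_residuals(dm, sites)
        surf = idw_residual_surface(rs, grid, idw_power)
        stack.append(np.where(surf.nodata_mask, np.nan, surf.values))
    stack = np.asarray(stack)
    obs_rs = distance_decay_residuals(d_gen, sites)
    obs = idw_residual_surface(obs_rs, grid, idw_power)
    obs_vals = np.where(obs.nodata_mask, np.nan, obs.values)
    q = {float(p): np.nanquantile(stack, p, axis=0) for p in quantiles}
    exceed = np.nanmean(stack <= obs_vals[None, ...], axis=0)
    return NullSurfaceSummary(obs, q, exceed, n_perm)


# ---------------------------------------------------------------------------
# Circuit-theory resistance distance
# ---------------------------------------------------------------------------

def resistance_distance(r: RasterGrid, sites: SiteMap) -> DistanceMatrix:
    """Pairwise effective resistance between site cells on the raster.

    Cells are nodes; 4-neighbor edges carry conductance equal to the mean of
    the two cells' conductances (1/resistance). Pairs in different raster
    components get +inf. Site coordinates must fall on non-nodata cells.
    """
    ok = ~r.nodata_mask
    if not (r.values[ok] > 0).all():
        raise DataError("resistance values must be strictly positive")
    node_id = np.full(r.values.shape, -1, dtype=int)
    node_id[ok] = np.arange(ok.sum())
    n = int(ok.sum())
    cond = np.zeros(r.values.shape)
    cond[ok] = 1.0 / r.values[ok]

    rows, cols, data = [], [], []
    for dr, dc in ((0, 1), (1, 0)):
        a = node_id[: r.n_rows - dr, : r.n_cols - dc]
        b = node_id[dr:, dc:]
        ca = cond[: r.n_rows - dr, : r.n_cols - dc]
        cb = cond[dr:, dc:]
        m = (a >= 0) & (b >= 0)
        w = (ca[m] + cb[m]) / 2.0
        rows.extend(a[m]); cols.extend(b[m]); data.extend(w)
        rows.extend(b[m]); cols.extend(a[m]); data.extend(w)
    W = coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    deg = np.asarray(W.sum(axis=1)).ravel()
    L = diags(deg).tocsr() - W

    labels = sites.sites
    snode = {}
    for s in labels:
        x, y = sites[s]
        try:
            rr, cc = r.cell_of(x, y)
        except DataError as err:
            raise DataError(f"site {s} off-grid: {err}") from err
        if node_id[rr, cc] < 0:
            raise DataError(f"site {s} at ({x}, {y}) falls on a nodata cell")
        snode[s] = node_id[rr, cc]

    ncomp, comp = connected_components(W, directed=False)
    k = len(labels)
    out = np.zeros((k, k))
    # factorize the grounded Laplacian once per component that hosts sites
    lus = {}
    for c in set(comp[list(snode.values())]):
        members = np.flatnonzero(comp == c)
        ground = members[0]
        keep = members[members != ground]
        pos = {g: i for i, g in enumerate(keep)}
        sub = L[np.ix_(keep, keep)].tocsc()
        lus[c] = (splu(sub), pos, ground)
    vcache = {}
    for s, nd in snode.items():
        c = comp[nd]
        lu, pos, ground = lus[c]
        if nd == ground:
            vcache[s] = None
        else:
            e = np.zeros(len(pos))
            e[pos[nd]] = 1.0
            vcache[s] = lu.solve(e)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            na, nb = snode[a], snode[b]
            if comp[na] != comp[nb]:
                out[i, j] = out[j, i] = math.inf
                continue
            lu, pos, ground = lus[comp[na]]
            va, vb = vcache[a], vcache[b]
            if na == nb:
                val = 0.0
            elif va is None:       # a grounded
                val = vb[pos[nb]]
            elif vb is None:       # b grounded
                val = va[pos[na]]
            else:
                val = va[pos[na]] + vb[pos[nb]] - 2.0 * va[pos[nb]]
            out[i, j] = out[j, i] = max(val, 0.0)
    return DistanceMatrix(labels, out)


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    partial: bool = False
    conditioning: str | None = None
    n_dropped: int = 0
    tail: str = "greater"


def _triangle(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        raise DataError("zero-variance distance triangle; r undefined")
    return float(np.corrcoef(x, y)[0, 1])


def _perm_p(values_y: np.ndarray, xt: np.ndarray, mask: np.ndarray,
            r_obs: float, n_perm, seed: int, tail: str) -> tuple[float, int]:
    k = values_y.shape[0]
    if n_perm == "all":
        perms = list(itertools.permutations(range(k)))
        count = 0
        for perm in perms:
            yt = _triangle(values_y[np.ix_(perm, perm)])[mask]
            rp = _pearson(xt, yt)
            if _extreme(rp, r_obs, tail):
                count += 1
        return count / len(perms), len(perms)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        yt = _triangle(values_y[np.ix_(perm, perm)])[mask]
        rp = _pearson(xt, yt)
        if _extreme(rp, r_obs, tail):
            count += 1
    return (1 + count) / (n_perm + 1), n_perm


def _extreme(rp: float, r_obs: float, tail: str) -> bool:
    if tail == "greater":
        return rp >= r_obs - 1e-12
    if tail == "less":
        return rp <= r_obs + 1e-12
    return abs(rp) >= abs(r_obs) - 1e-12


def mantel_test(x: DistanceMatrix, y: DistanceMatrix, n_perm=9999,
                seed: int = 0, log_x: bool = False, log_y: bool = False,
                tail: str = "greater") -> MantelResult:
    """Mantel matrix correlation with simultaneous row/column permutation.

    r is the Pearson correlation of the off-diagonal upper triangles; the
    default test is one-tailed for positive association, p = (1 +
    #{r_perm >= r_obs})/(n_perm + 1). Pass ``n_perm='all'`` to enumerate
    every relabeling (exact p). Non-finite pairs in either matrix are
    dropped (count reported); log transforms require strictly positive
    triangles.
    """
    require_matching_labels(x, y)
    xv, yv = x.values.copy(), y.values.copy()
    for name, v, flag in (("x", xv, log_x), ("y", yv, log_y)):
        if flag:
            t = _triangle(v)
            if (t[np.isfinite(t)] <= 0).any():
                raise DataError(f"log transform of nonpositive {name}")
            np.log(v, out=v, where=~np.eye(v.shape[0], dtype=bool))
    xt_full = _triangle(xv)
    yt_full = _triangle(yv)
    mask = np.isfinite(xt_full) & np.isfinite(yt_full)
    n_dropped = int((~mask).sum())
    xt = xt_full[mask]
    r_obs = _pearson(xt, yt_full[mask])
    p, nper = _perm_p(yv, xt, mask, r_obs, n_perm, seed, tail)
    return MantelResult(r_obs, p, nper, False, None, n_dropped, tail)


def partial_mantel_test(x: DistanceMatrix, y: DistanceMatrix,
                        z: DistanceMatrix, n_perm=9999, seed: int = 0,
                        tail: str = "greater") -> MantelResult:
    """Partial Mantel correlation of x and y controlling for z.

    x and y are each regressed on z over the triangle; the permutation
    operates on the residual matrix of y (simultaneous row/column
    relabeling of residuals), the unbiased approach for partial tests.
    """
    require_matching_labels(x, y, z)
    k = len(x.labels)
    xt, yt, zt = (_triangle(m.values) for m in (x, y, z))
    mask = np.isfinite(xt) & np.isfinite(yt) & np.isfinite(zt)
    n_dropped = int((~mask).sum())

    def residual_triangle(t):
        if zt[mask].std() == 0:
            return t[mask] - t[mask].mean()
        b, a = np.polyfit(zt[mask], t[mask], 1)
        return t[mask] - (b * zt[mask] + a)

    rx = residual_triangle(xt)
    ry = residual_triangle(yt)
    r_obs = _pearson(rx, ry)
    # rebuild full symmetric residual matrices for row/column permutation
    iu = np.triu_indices(k, 1)
    ry_full = np.zeros((k, k))
    sel = np.flatnonzero(mask)
    vals = np.full(len(xt), np.nan)
    vals[sel] = ry
    ry_full[iu] = vals
    ry_full = ry_full + ry_full.T
    rx_masked = rx
    p, nper = _perm_p(ry_full, rx_masked, mask, r_obs, n_perm, seed, tail)
    return MantelResult(r_obs, p, nper, True, "z", n_dropped, tail)
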