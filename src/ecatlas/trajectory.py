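"""Linear pseudotime inference and cluster-range smoothing along a 1-D
arterio-venous-style gradient.

Pseudotime is inferred with a waypoint-polyline procedure: cells are
embedded by PCA, k-means waypoints are ordered into the shortest polyline,
and each cell's arc-length position along that polyline (min-max rescaled to
[0, 1]) is its pseudotime. Clusters occupying the trajectory are then
re-expressed as contiguous ranges using their 0.25/0.75 pseudotime
quantiles: clusters are ordered by lower quantile and the boundary between
consecutive clusters is the average of the first cluster's upper quantile
and the second cluster's lower quantile. Expression-vs-pseudotime curves use
tricube-weighted local linear regression with a span of 0.2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA


def _dense(nm: ad.AnnData) -> np.ndarray:
    return nm.X.toarray() if sparse.issparse(nm.X) else np.asarray(nm.X)


def select_hvg(
    nm: ad.AnnData,
    mean_low: float = 0.05,
    mean_high: float = 8.0,
    top_fraction: float = 0.5,
) -> list[str]:
    """Highly variable genes: mean depth-normalized expression strictly inside
    (mean_low, mean_high), ranked by dispersion (variance/mean), top fraction
    retained."""
    lin = np.expm1(_dense(nm))
    mean = lin.mean(axis=0)
    var = lin.var(axis=0, ddof=0)
    in_band = (mean > mean_low) & (mean < mean_high)
    if not in_band.any():
        raise ValueError("no genes inside the mean-expression band")
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    genes = nm.var_names[in_band]
    disp = dispersion[in_band]
    order = np.argsort(-disp, kind="stable")
    n_keep = max(1, int(round(top_fraction * len(genes))))
    return list(genes[order[:n_keep]])


@dataclass
class PseudotimeResult:
    t: pd.Series  # per cell, in [0, 1]
    k: int
    n_pcs: int


def _project_to_polyline(points: np.ndarray, way: np.ndarray) -> np.ndarray:
    """Arc-length position of each point's nearest location on the polyline.

    The first and last segments extend beyond their terminal waypoints, so
    cells past the extreme waypoints keep distinct positions instead of
    piling up at the clamp.
    """
    seg_vec = np.diff(way, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    n_seg = len(seg_vec)
    best_d = np.full(len(points), np.inf)
    best_s = np.zeros(len(points))
    for i, (a, v, L) in enumerate(zip(way[:-1], seg_vec, seg_len)):
        if L == 0:
            proj = np.zeros(len(points))
        else:
            proj = (points - a) @ v / (L * L)
            lo = -np.inf if i == 0 else 0.0
            hi = np.inf if i == n_seg - 1 else 1.0
            proj = np.clip(proj, lo, hi)
        foot = a + proj[:, None] * v
        d = np.linalg.norm(points - foot, axis=1)
        upd = d < best_d
        best_d[upd] = d[upd]
        best_s[upd] = cum[i] + proj[upd] * L
    return best_s


def infer_linear_pseudotime(
    nm: ad.AnnData,
    k: int = 3,
    n_pcs: int = 8,
    seed: int = 0,
) -> PseudotimeResult:
    """Waypoint-polyline pseudotime on the first ``n_pcs`` principal components.

    k-means finds ``k`` waypoints; for k <= 6 the waypoint order minimizing
    total polyline length is found exhaustively; cells are projected to the
    polyline and their arc-length positions min-max rescaled to [0, 1].
    """
    X = _dense(nm)
    if nm.n_obs < n_pcs + 1:
        raise ValueError("need at least n_pcs + 1 cells")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all cells identical")
    n_pcs_eff = min(n_pcs, min(X.shape) - 1)
    coords = PCA(n_components=n_pcs_eff, random_state=seed).fit_transform(X)
    way = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(coords).cluster_centers_

    if k <= 6:
        best_len, best_order = np.inf, tuple(range(k))
        for perm in itertools.permutations(range(k)):
            if perm[0] > perm[-1]:  # skip reversed duplicates
                continue
            length = np.sum(
                np.linalg.norm(np.diff(way[list(perm)], axis=0), axis=1)
            )
            if length < best_len:
                best_len, best_order = length, perm
        way = way[list(best_order)]
    s = _project_to_polyline(coords, way)
    rng = s.max() - s.min()
    t = (s - s.min()) / rng if rng > 0 else np.zeros_like(s)
    return PseudotimeResult(
        t=pd.Series(t, index=nm.obs_names, name="pseudotime"), k=k, n_pcs=n_pcs
    )


@dataclass
class SmoothedClusterRanges:
    """Ordered clusters with quantile-smoothed, contiguous pseudotime ranges
    tiling [0, 1]."""

    table: pd.DataFrame  # columns cluster, q_lo, q_hi, range_lo, range_hi
    quantile_method: str = "linear"  # type-7 order-statistic interpolation


def smooth_cluster_ranges(
    pt: PseudotimeResult | pd.Series,
    labels: pd.Series | np.ndarray,
    q_lo: float = 0.25,
    q_hi: float = 0.75,
) -> SmoothedClusterRanges:
    """Quantile smoothing of cluster occupancy along pseudotime.

    Per-cluster q_lo/q_hi pseudotime quantiles are computed (type-7 linear
    interpolation); clusters are ordered ascending by lower quantile (ties by
    upper quantile, then label); the boundary between consecutive clusters is
    the mean of the earlier cluster's upper quantile and the later cluster's
    lower quantile. The first range starts at 0 and the last ends at 1, so
    the ranges tile [0, 1] exactly.
    """
    t = pt.t if isinstance(pt, PseudotimeResult) else pt
    labels = np.asarray(labels)
    rows = []
    for c in pd.unique(labels):
        tc = np.asarray(t)[labels == c]
        if tc.size < 4:
            raise ValueError(f"cluster {c} has <4 cells on the trajectory")
        rows.append(
            {"cluster": c, "q_lo": np.quantile(tc, q_lo), "q_hi": np.quantile(tc, q_hi)}
        )
    tab = pd.DataFrame(rows).sort_values(
        ["q_lo", "q_hi", "cluster"], kind="stable"
    ).reset_index(drop=True)
    n = len(tab)
    lo = np.empty(n)
    hi = np.empty(n)
    lo[0], hi[-1] = 0.0, 1.0
    for i in range(n - 1):
        b = 0.5 * (tab.loc[i, "q_hi"] + tab.loc[i + 1, "q_lo"])
        hi[i] = b
        lo[i + 1] = b
    tab["range_lo"] = lo
    tab["range_hi"] = hi
    return SmoothedClusterRanges(table=tab)


def rolling_expression(
    t: pd.Series | np.ndarray,
    expr: pd.DataFrame,
    span: float = 0.2,
    grid_size: int = 100,
) -> pd.DataFrame:
    """Tricube-weighted local linear regression of expression on pseudotime.

    ``expr`` is genes-in-columns over the same cells as ``t``. For each of
    ``grid_size`` equispaced grid points, the span-fraction nearest cells
    (at least 3; narrower windows are widened and flagged in
    ``result.attrs['widened_windows']``) get tricube weights and a weighted
    linear fit is evaluated at the grid point.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    tv = np.asarray(t, dtype=float)
    Y = np.asarray(expr, dtype=float)
    n = tv.size
    window = int(np.ceil(span * n))
    widened = window < 3
    window = max(window, 3)
    grid = np.linspace(tv.min(), tv.max(), grid_size)
    out = np.empty((grid_size, Y.shape[1]))
    order = np.argsort(tv)
    ts, Ys = tv[order], Y[order]
    for gi, g in enumerate(grid):
        d = np.abs(ts - g)
        idx = np.argpartition(d, window - 1)[:window]
        dmax = d[idx].max()
        w = np.ones(window) if dmax == 0 else (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.maximum(w, 1e-12)
        x = ts[idx] - g
        sw, swx, swxx = w.sum(), (w * x).sum(), (w * x * x).sum()
        det = sw * swxx - swx * swx
        yw = Ys[idx] * w[:, None]
        sy, sxy = yw.sum(axis=0), (yw * x[:, None]).sum(axis=0)
        if abs(det) < 1e-12:  # degenerate window: weighted mean
            out[gi] = sy / sw
        else:
            a = (swxx * sy - swx * sxy) / det  # intercept at x = 0 (the grid point)
            out[gi] = a
    res = pd.DataFrame(out, index=pd.Index(grid, name="pseudotime"), columns=expr.columns)
    res.attrs["widened_windows"] = bool(widened)
    res.attrs["span"] = span
    return res
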