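"""Cortical map assembly: AI delineation, normalized tonotopic axis,
tonotopic index, and Voronoi tessellation maps.

The tonotopic index quantifies how far a map is from a perfect rostro-caudal
frequency gradient: each AI site contributes the perpendicular distance of its
(normalized map position, normalized log-CF) point to the identity diagonal,
and the index is the mean of those distances.  Zero means a perfect gradient;
~0.7 is the geometric maximum.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import voronoi_diagram

from .config import RunConfig
from .errors import TonomapError, ValidationError


@dataclass
class TonotopyResult:
    """Normalized axis positions and CFs of the AI sites of one map."""

    site_ids: list[str]
    pos_norm: np.ndarray
    cf_norm: np.ndarray
    tonotopic_index: float


def delineate_ai(sites: pd.DataFrame, config: Optional[RunConfig] = None
                 ) -> np.ndarray:
    """Boolean AI mask over the rows of a per-site metrics table.

    A site belongs to AI iff it (1) is responsive with a defined CF, (2) has
    threshold <= 50 dB SPL or is 4-neighbor-adjacent (within its penetration)
    to at least two such low-threshold sites, and (3) is not VAF-like, i.e.
    not significant exclusively below 30 dB SPL.  Unresponsive sites and
    high-threshold sites without supporting neighbors are excluded.

    Requires columns: x_um, y_um, penetration_id, responsive, cf_hz,
    threshold_db, max_sig_db.
    """
    config = config or RunConfig()
    responsive = sites["responsive"].to_numpy(dtype=bool)
    cf = pd.to_numeric(sites["cf_hz"], errors="coerce").to_numpy(dtype=float)
    thr = pd.to_numeric(sites["threshold_db"], errors="coerce").to_numpy(dtype=float)
    max_sig = pd.to_numeric(sites["max_sig_db"], errors="coerce").to_numpy(dtype=float)

    has_cf = responsive & np.isfinite(cf)
    vaf_like = has_cf & np.isfinite(max_sig) & (max_sig < config.vaf_intensity_db)
    low_thr = has_cf & ~vaf_like & (thr <= config.ai_threshold_db)
    candidates = has_cf & ~vaf_like & (thr > config.ai_threshold_db)

    ai = low_thr.copy()
    if candidates.any():
        x = sites["x_um"].to_numpy(dtype=float)
        y = sites["y_um"].to_numpy(dtype=float)
        pen = sites["penetration_id"].to_numpy()
        qual_keys = set()
        for i in np.flatnonzero(low_thr):
            qual_keys.add((pen[i], round(x[i], 3), round(y[i], 3)))
        for p in np.unique(pen):
            sel = pen == p
            xs = np.unique(np.round(x[sel], 3))
            ys = np.unique(np.round(y[sel], 3))
            dx = float(np.min(np.diff(xs))) if xs.size > 1 else 0.0
            dy = float(np.min(np.diff(ys))) if ys.size > 1 else 0.0
            for i in np.flatnonzero(candidates & sel):
                neigh = 0
                for ox, oy in ((dx, 0.0), (-dx, 0.0), (0.0, dy), (0.0, -dy)):
                    if (ox, oy) == (0.0, 0.0):
                        continue
                    if (p, round(x[i] + ox, 3), round(y[i] + oy, 3)) in qual_keys:
                        neigh += 1
                if neigh >= config.ai_min_qualifying_neighbors:
                    ai[i] = True
    return ai


def normalize_cf(cf_hz, lo_khz: float = 1.0, hi_khz: float = 63.0):
    """Map CF onto [0, 1] linearly in log frequency over ``lo_khz``-``hi_khz``.

    CFs outside the range are clipped rather than discarded.
    """
    cf = np.asarray(cf_hz, dtype=float)
    if np.any(cf <= 0):
        raise ValidationError("cf_hz: must be positive")
    out = np.log2(cf / (lo_khz * 1000.0)) / math.log2(hi_khz / lo_khz)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.isscalar(cf_hz) else out


def normalized_axis(x_um, y_um, cf_norm=None, method: str = "tls"
                    ) -> Optional[np.ndarray]:
    """Project map coordinates onto the fitted tonotopic axis, scaled to [0,1].

    A line is fitted to the site coordinates by least squares — by default the
    principal (total-least-squares) axis, which makes the result invariant to
    rigid rotations; ``method="ols"`` regresses y on x, swapping axes when the
    slope would exceed 1 in magnitude.  Coordinates are rotated so the line is
    horizontal, collapsed onto it, and min-max normalized.  When ``cf_norm``
    is given the orientation is flipped, if needed, so position correlates
    non-negatively with CF.  Returns None for fewer than 3 sites or a map with
    no spatial extent.
    """
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    if x.size < 3:
        return None
    xc = x - x.mean()
    yc = y - y.mean()
    if method == "tls":
        cov = np.cov(np.vstack([xc, yc]))
        w, v = np.linalg.eigh(cov)
        direction = v[:, int(np.argmax(w))]
    elif method == "ols":
        if np.ptp(xc) == 0 and np.ptp(yc) == 0:
            return None
        if np.ptp(xc) > 0:
            slope = float(np.polyfit(xc, yc, 1)[0]) if np.ptp(yc) > 0 else 0.0
        else:
            slope = np.inf
        if abs(slope) > 1:  # near-vertical: regress x on y instead
            inv = float(np.polyfit(yc, xc, 1)[0]) if np.ptp(yc) > 0 else 0.0
            direction = np.array([inv, 1.0])
        else:
            direction = np.array([1.0, slope])
        direction = direction / np.linalg.norm(direction)
    else:
        raise ValidationError("method: must be 'tls' or 'ols'")

    t = xc * direction[0] + yc * direction[1]
    extent = np.ptp(t)
    if extent == 0:
        return None
    pos = (t - t.min()) / extent
    if cf_norm is not None:
        cf = np.asarray(cf_norm, dtype=float)
        dev_p = pos - pos.mean()
        dev_c = cf - cf.mean()
        if float(np.sum(dev_p * dev_c)) < 0:
            pos = 1.0 - pos
    return pos


def tonotopic_index(pos_norm, cf_norm) -> float:
    """Mean perpendicular distance of (position, CF) points to the diagonal.

    Both inputs are in [0, 1]; the distance of (x, y) to the line through
    (0, 0) and (1, 1) is |x - y| / sqrt(2).
    """
    pos = np.asarray(pos_norm, dtype=float)
    cf = np.asarray(cf_norm, dtype=float)
    if pos.size == 0 or pos.shape != cf.shape:
        raise ValidationError("pos_norm and cf_norm must be equal-length and non-empty")
    return float(np.mean(np.abs(pos - cf)) / math.sqrt(2.0))


def compute_tonotopy(sites: pd.DataFrame, ai_mask: np.ndarray,
                     config: Optional[RunConfig] = None
                     ) -> Optional[TonotopyResult]:
    """Normalized axis + tonotopic index for the AI sites of one map."""
    config = config or RunConfig()
    ai = sites[np.asarray(ai_mask, dtype=bool)]
    if len(ai) < 3:
        return None
    lo, hi = config.cf_norm_range_khz
    cf_norm = normalize_cf(ai["cf_hz"].to_numpy(dtype=float), lo, hi)
    pos = normalized_axis(ai["x_um"].to_numpy(dtype=float),
                          ai["y_um"].to_numpy(dtype=float),
                          cf_norm, method=config.axis_fit)
    if pos is None:
        return None
    return TonotopyResult(site_ids=list(ai["site_id"]), pos_norm=pos,
                          cf_norm=cf_norm,
                          tonotopic_index=tonotopic_index(pos, cf_norm))


def voronoi_map(x_um, y_um, hull: Optional[Polygon] = None
                ) -> tuple[list[Polygon], Polygon]:
    """One clipped Voronoi polygon per recording site.

    The tessellation is clipped to ``hull``; by default the convex hull of the
    sites buffered by half the median nearest-neighbor spacing.  Returns the
    polygons in site order plus the hull.  Degenerate (collinear or duplicate)
    geometry raises.
    """
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    if x.size < 3:
        raise ValidationError("voronoi_map: need at least 3 sites")
    pts = [Point(xi, yi) for xi, yi in zip(x, y)]
    mp = MultiPoint(pts)
    if mp.convex_hull.area == 0:
        raise TonomapError("voronoi_map: sites are collinear or coincident")
    if hull is None:
        coords = np.column_stack([x, y])
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        nn = np.sqrt(d2.min(axis=1))
        hull = mp.convex_hull.buffer(float(np.median(nn)) / 2.0)
    if hull.area == 0:
        raise TonomapError("voronoi_map: degenerate (collinear) site geometry")
    try:
        cells = voronoi_diagram(mp, envelope=hull.buffer(hull.length))
    except Exception as exc:  # GEOS failure on degenerate input
        raise TonomapError(f"voronoi_map: tessellation failed ({exc})") from exc
    if len(cells.geoms) < len(pts):
        raise TonomapError("voronoi_map: degenerate site geometry "
                           "(fewer cells than sites)")
    polys: list[Polygon] = []
    for p in pts:
        cell = min(cells.geoms, key=lambda c: c.distance(p))
        polys.append(cell.intersection(hull))
    return polys, hull


def plot_map(sites: pd.DataFrame, ai_mask: np.ndarray, out_path=None,
             hull: Optional[Polygon] = None):
    """Render a CF map: Voronoi cells colored by log CF, X = unresponsive,
    O = responsive non-AI sites.  Returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    x = sites["x_um"].to_numpy(dtype=float)
    y = sites["y_um"].to_numpy(dtype=float)
    cf = pd.to_numeric(sites["cf_hz"], errors="coerce").to_numpy(dtype=float)
    responsive = sites["responsive"].to_numpy(dtype=bool)
    ai = np.asarray(ai_mask, dtype=bool)

    polys, hull = voronoi_map(x, y, hull)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    norm = LogNorm(vmin=1_000, vmax=70_000)
    cmap = plt.get_cmap("jet")
    for i, poly in enumerate(polys):
        if ai[i] and np.isfinite(cf[i]):
            color = cmap(norm(cf[i]))
        else:
            color = (0.92, 0.92, 0.92)
        if not poly.is_empty:
            xs, ys = poly.exterior.xy
            ax.fill(xs, ys, facecolor=color, edgecolor="k", linewidth=0.4)
    for i in range(len(x)):
        if not responsive[i]:
            ax.plot(x[i], y[i], "kx", ms=6)
        elif not ai[i]:
            ax.plot(x[i], y[i], "ko", mfc="none", ms=6)
    sm = plt.cm.ScalarMappable(norm=norm, cmap=cmap)
    fig.colorbar(sm, ax=ax, label="CF (Hz)")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_aspect("equal")
    if out_path is not None:
        fig.savefig(out_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
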