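"""Voronoi-tessellation multiscale segmentation of 2D single-molecule
localizations with a Monte-Carlo complete-spatial-randomness (CSR) null.

The analysis is strictly 2D (lateral x, y localizations, nm). Each
localization receives the area of its Voronoi polygon clipped to the
acquisition region; small areas mean high local density. Density thresholds
are calibrated against the Voronoi-area distribution of uniformly random
points with the same count: the first threshold is ρ = δ, the mean Voronoi
area of the uniform reference (which equals A/n exactly for a clipped
tessellation), and subsequent thresholds are the crossings between the
observed and reference area distributions restricted below the previous
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import sparse
from scipy.spatial import Delaunay, Voronoi
from scipy.stats import gaussian_kde, ks_2samp
from shapely.geometry import box

log = logging.getLogger(__name__)

_DUPLICATE_JITTER_NM = 1e-6


class TessellationError(RuntimeError):
    pass


@dataclass
class LocalizationTable:
    """2D localization coordinates (nm) with their bounding region."""

    points_nm: np.ndarray                      # (n, 2)
    region: tuple[float, float, float, float]  # (xmin, ymin, xmax, ymax)
    frame: np.ndarray | None = None
    label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points_nm = np.asarray(self.points_nm, dtype=float)
        if self.points_nm.ndim != 2 or self.points_nm.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.points_nm) < 4:
            raise ValueError("need at least 4 localizations")
        if not np.all(np.isfinite(self.points_nm)):
            raise ValueError("coordinates must be finite")
        x0, y0, x1, y1 = self.region
        if x1 <= x0 or y1 <= y0:
            raise ValueError("region must have positive area")
        p = self.points_nm
        if (p[:, 0] < x0).any() or (p[:, 0] > x1).any() or (p[:, 1] < y0).any() or (p[:, 1] > y1).any():
            raise ValueError("all localizations must lie inside the region")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       region: tuple[float, float, float, float] | None = None) -> "LocalizationTable":
        pts = df[["x_nm", "y_nm"]].to_numpy(dtype=float)
        if region is None:
            region = (pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max())
        return cls(pts, region,
                   frame=df["frame"].to_numpy() if "frame" in df else None,
                   label=df["label"].to_numpy() if "label" in df else None)

    @property
    def n(self) -> int:
        return len(self.points_nm)

    @property
    def area_nm2(self) -> float:
        x0, y0, x1, y1 = self.region
        return (x1 - x0) * (y1 - y0)


@dataclass
class VoronoiTessellation:
    """Per-localization clipped Voronoi polygon areas (nm²)."""

    areas_nm2: np.ndarray
    boundary_flag: np.ndarray
    region: tuple[float, float, float, float]
    points_nm: np.ndarray

    @property
    def n(self) -> int:
        return len(self.areas_nm2)

    @property
    def region_area_nm2(self) -> float:
        x0, y0, x1, y1 = self.region
        return (x1 - x0) * (y1 - y0)


@dataclass
class ThresholdSet:
    thresholds_nm2: list[float]     # non-increasing; thresholds_nm2[0] == delta
    delta_nm2: float
    mc_reps: int
    seed: int
    max_levels: int
    uniform_flag: bool = False      # observed indistinguishable from CSR at level 2

    def __post_init__(self) -> None:
        t = self.thresholds_nm2
        if not t or abs(t[0] - self.delta_nm2) > 1e-9 * self.delta_nm2:
            raise ValueError("first threshold must equal delta")
        if any(b > a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be non-increasing")
        if any(x <= 0 for x in t):
            raise ValueError("thresholds must be positive")


@dataclass
class Cluster:
    level: int
    member_indices: np.ndarray
    n: int
    area_nm2: float


@dataclass
class SegmentationResult:
    levels: np.ndarray                      # per-localization density level (0 = background)
    clusters: dict[int, list[Cluster]]      # level -> clusters
    thresholds: ThresholdSet


@dataclass
class EnrichmentResult:
    ratio: float
    n_high_density: int
    n_in_band: int
    undefined: bool = False


# ---------------------------------------------------------------------------
# tessellation
# ---------------------------------------------------------------------------

def _dedupe(points: np.ndarray) -> np.ndarray:
    """Perturb exact duplicate coordinates by a negligible deterministic jitter."""
    _, first = np.unique(points, axis=0, return_index=True)
    if len(first) == len(points):
        return points
    log.info("perturbing %d duplicate localization(s) by %g nm",
             len(points) - len(first), _DUPLICATE_JITTER_NM)
    out = points.copy()
    rng = np.random.default_rng(0)
    seen: set[tuple[float, float]] = set()
    for i, p in enumerate(points):
        key = (p[0], p[1])
        if key in seen:
            out[i] = p + rng.normal(0, _DUPLICATE_JITTER_NM, 2)
        seen.add(key)
    return out


def voronoi_areas(locs: LocalizationTable) -> VoronoiTessellation:
    """Voronoi polygon areas clipped to the region rectangle.

    Clipping is realised by mirroring all points across the four region
    edges before the Voronoi construction: every original point's cell is
    then finite and exactly equal to its region-clipped cell, so the areas
    partition the region (Σ areas = A to machine precision). Cells touching
    the region boundary are flagged.
    """
    pts = _dedupe(locs.points_nm)
    # a point exactly on the region boundary would mirror onto itself and
    # degenerate the tessellation; pull such points inside by a hair
    x0, y0, x1, y1 = locs.region
    eps_x = 1e-9 * (x1 - x0)
    eps_y = 1e-9 * (y1 - y0)
    if ((pts[:, 0] <= x0) | (pts[:, 0] >= x1) | (pts[:, 1] <= y0) | (pts[:, 1] >= y1)).any():
        pts = pts.copy()
        pts[:, 0] = np.clip(pts[:, 0], x0 + eps_x, x1 - eps_x)
        pts[:, 1] = np.clip(pts[:, 1], y0 + eps_y, y1 - eps_y)
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise TessellationError("all localizations are collinear; no 2D tessellation exists")

    mirrors = [
        np.column_stack([2 * x0 - pts[:, 0], pts[:, 1]]),
        np.column_stack([2 * x1 - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * y0 - pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * y1 - pts[:, 1]]),
    ]
    allpts = np.vstack([pts] + mirrors)
    vor = Voronoi(allpts)

    n = len(pts)
    areas = np.empty(n)
    boundary = np.zeros(n, dtype=bool)
    tol = 1e-9 * max(x1 - x0, y1 - y0)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise TessellationError(f"unbounded cell for localization {i}")
        v = vor.vertices[region]
        x, y = v[:, 0], v[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        if ((np.abs(x - x0) < tol) | (np.abs(x - x1) < tol)
                | (np.abs(y - y0) < tol) | (np.abs(y - y1) < tol)).any():
            boundary[i] = True
    return VoronoiTessellation(areas_nm2=areas, boundary_flag=boundary,
                               region=locs.region, points_nm=pts)


def mc_reference(n: int, region: tuple[float, float, float, float],
                 reps: int = 100, seed: int = 0) -> tuple[np.ndarray, float]:
    """Monte-Carlo CSR reference: pooled clipped-Voronoi areas of ``reps``
    independent uniform draws of ``n`` points, and δ = A/n (the exact mean
    of any clipped tessellation, also the pooled sample mean)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if n < 4:
        raise ValueError("n must be >= 4")
    x0, y0, x1, y1 = region
    rng = np.random.default_rng(seed)
    pools = []
    for _ in range(reps):
        pts = np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])
        tess = voronoi_areas(LocalizationTable(pts, region))
        pools.append(tess.areas_nm2)
    delta = (x1 - x0) * (y1 - y0) / n
    return np.concatenate(pools), delta


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def _kde_crossing(obs: np.ndarray, ref: np.ndarray) -> float | None:
    """First crossing (scanning from small areas) where the observed log-area
    density falls below the reference density, provided the observed density
    meaningfully exceeds the reference before it. Returns the area (nm²)."""
    lo_obs, lo_ref = np.log(obs), np.log(ref)
    try:
        f_obs = gaussian_kde(lo_obs)
        f_ref = gaussian_kde(lo_ref)
    except np.linalg.LinAlgError:
        return None
    lo = min(lo_obs.min(), lo_ref.min())
    hi = max(lo_obs.max(), lo_ref.max())
    grid = np.linspace(lo, hi, 512)
    d_obs = f_obs(grid)
    d_ref = f_ref(grid)
    above = d_obs > d_ref
    if not above[0]:
        return None
    # require a real excess of small areas, not KDE noise
    run_end = int(np.argmin(above)) if not above.all() else len(grid)
    if run_end == len(grid):
        return None
    excess = d_obs[:run_end] / np.clip(d_ref[:run_end], 1e-300, None)
    if excess.max() < 1.1:
        return None
    # linear interpolation of the zero crossing of d_obs - d_ref
    i = run_end
    g0, g1 = grid[i - 1], grid[i]
    y0 = d_obs[i - 1] - d_ref[i - 1]
    y1 = d_obs[i] - d_ref[i]
    t = y0 / (y0 - y1) if y0 != y1 else 0.5
    return float(np.exp(g0 + t * (g1 - g0)))


def compute_thresholds(tess: VoronoiTessellation, reference: np.ndarray,
                       max_levels: int = 4, min_count: int = 50,
                       mc_reps: int = 100, seed: int = 0,
                       ks_alpha: float = 0.01) -> ThresholdSet:
    """Multiscale density thresholds ρ₁ ≥ ρ₂ ≥ … against the CSR reference.

    ρ₁ = δ = A/n. At each subsequent level both the observed and reference
    area distributions are restricted below the previous threshold (the
    reference renormalised over the survivors) and the next threshold is the
    crossing of their log-area density estimates. Iteration stops at
    ``max_levels``, when fewer than ``min_count`` areas survive, when no
    crossing exists, or when the restricted observed distribution is
    statistically indistinguishable from the restricted reference
    (two-sample KS, p ≥ ``ks_alpha``); in the latter case at level 2 the
    ``uniform_flag`` is set.
    """
    delta = tess.region_area_nm2 / tess.n
    thresholds = [delta]
    uniform_flag = False
    obs = tess.areas_nm2
    ref = np.asarray(reference, dtype=float)

    for level in range(2, max_levels + 1):
        prev = thresholds[-1]
        obs_k = obs[obs < prev]
        ref_k = ref[ref < prev]
        if len(obs_k) < min_count or len(ref_k) < min_count:
            break
        ks = ks_2samp(obs_k, ref_k)
        if ks.pvalue >= ks_alpha:
            if level == 2:
                uniform_flag = True
            break
        crossing = _kde_crossing(obs_k, ref_k)
        if crossing is None or not (0 < crossing < prev):
            if level == 2:
                uniform_flag = True
            break
        thresholds.append(crossing)

    return ThresholdSet(thresholds_nm2=thresholds, delta_nm2=delta,
                        mc_reps=mc_reps, seed=seed, max_levels=max_levels,
                        uniform_flag=uniform_flag)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def delaunay_adjacency(points: np.ndarray) -> sparse.csr_matrix:
    """Symmetric adjacency over Delaunay-triangulation edges."""
    tri = Delaunay(points)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
    if not edges:
        return sparse.csr_matrix((len(points), len(points)))
    rows, cols = zip(*edges)
    n = len(points)
    adj = sparse.coo_matrix((np.ones(len(edges)), (rows, cols)), shape=(n, n))
    return (adj + adj.T).tocsr()


def segment_localizations(tess: VoronoiTessellation,
                          thresholds: ThresholdSet) -> SegmentationResult:
    """Assign density levels and extract clusters at each level.

    A localization is at level k when its polygon area < ρ_k; levels are
    nested because thresholds are non-increasing. Clusters at a level are
    connected components over Delaunay-neighbour edges whose both endpoints
    are at that level.
    """
    areas = tess.areas_nm2
    levels = np.zeros(tess.n, dtype=int)
    for k, rho in enumerate(thresholds.thresholds_nm2, start=1):
        levels[areas < rho] = k

    adj = delaunay_adjacency(tess.points_nm)
    clusters: dict[int, list[Cluster]] = {}
    for k in range(1, len(thresholds.thresholds_nm2) + 1):
        members = np.flatnonzero(levels >= k)
        clusters[k] = []
        if len(members) == 0:
            continue
        sub = adj[members][:, members]
        n_comp, comp = sparse.csgraph.connected_components(sub, directed=False)
        for c in range(n_comp):
            idx = members[comp == c]
            clusters[k].append(Cluster(level=k, member_indices=idx, n=len(idx),
                                       area_nm2=float(areas[idx].sum())))
    return SegmentationResult(levels=levels, clusters=clusters, thresholds=thresholds)


def peripheral_band_enrichment(result: SegmentationResult, locs: LocalizationTable,
                               band, min_level: int = 1) -> EnrichmentResult:
    """Enrichment of high-density localizations in a spatial band.

    ``band`` is either a shapely geometry or an annulus spec
    ``(cx, cy, r_inner, r_outer)`` in nm. The ratio compares the fraction of
    high-density (level ≥ ``min_level``) localizations inside the band with
    the band's share of the region area; values > 1 indicate peripheral
    enrichment. Undefined (NaN, flagged) when no localization reaches the
    requested level.
    """
    x0, y0, x1, y1 = locs.region
    region_geom = box(x0, y0, x1, y1)
    if isinstance(band, tuple):
        cx, cy, r_in, r_out = band
        if not 0 <= r_in < r_out:
            raise ValueError("annulus radii must satisfy 0 <= r_in < r_out")
        geom = shapely.Point(cx, cy).buffer(r_out, quad_segs=256).difference(
            shapely.Point(cx, cy).buffer(r_in, quad_segs=256))
    else:
        geom = band
    geom = geom.intersection(region_geom)
    if geom.is_empty or geom.area <= 0:
        raise ValueError("band does not intersect the region")

    high = np.flatnonzero(result.levels >= min_level)
    if len(high) == 0:
        return EnrichmentResult(ratio=float("nan"), n_high_density=0,
                                n_in_band=0, undefined=True)
    pts = locs.points_nm[high]
    inside = shapely.contains_xy(geom, pts[:, 0], pts[:, 1]) \
        | shapely.contains_xy(geom.boundary.buffer(1e-9), pts[:, 0], pts[:, 1])
    frac_in = inside.mean()
    ratio = float(frac_in / (geom.area / region_geom.area))
    return EnrichmentResult(ratio=ratio, n_high_density=len(high),
                            n_in_band=int(inside.sum()), undefined=False)
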