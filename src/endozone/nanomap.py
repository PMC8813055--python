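"""Nanoscale cluster geometry for SMLM localization maps.

Pipeline: DBSCAN clustering of localizations (PSD regime: eps 0.2 um /
min 100; EZ + accessory regime: eps 0.35 um / min 50), polygonal border
extraction per cluster, then the geometric measurements used to
characterize the endocytic zone relative to the postsynaptic density:

* signed border-to-centroid and point-to-border distances (negative
  inside the border),
* FWTM length/width along the cluster's principal axes,
* primary/secondary classification of multiple clathrin structures
  (largest area = primary),
* border-scaled concentric rings (0-160% of the cluster outline in 20%
  steps) and the area-normalized ring density profile of a query channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter1d
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.geometry.polygon import orient
from sklearn.cluster import DBSCAN

__all__ = [
    "DbscanParams",
    "scaled_polygon",
    "ClusterSet",
    "RingProfile",
    "DEFAULT_RING_EDGES",
    "dbscan_cluster",
    "cluster_border",
    "extract_clusters",
    "border_to_centroid_distance",
    "fwtm_dimensions",
    "classify_primary_secondary",
    "distance_to_border",
    "scaled_rings",
    "ring_area_fractions",
    "ring_density_profile",
    "normalized_radius",
]

#: ring edges as fractions of the 100% border (5 inward + 3 outward rings)
DEFAULT_RING_EDGES = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6])

GAUSSIAN_FWTM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(10.0))  # FWTM = factor * sigma


@dataclass(frozen=True)
class DbscanParams:
    """DBSCAN neighborhood radius (um) and minimum neighborhood count."""

    eps_um: float = 0.35
    min_pts: int = 50

    def __post_init__(self) -> None:
        if self.eps_um <= 0:
            raise ValueError("eps must be > 0")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")

    @property
    def eps_nm(self) -> float:
        return self.eps_um * 1000.0


#: the two regimes used for synaptic SMLM data
PSD_REGIME = DbscanParams(eps_um=0.2, min_pts=100)
EZ_REGIME = DbscanParams(eps_um=0.35, min_pts=50)


@dataclass
class ClusterSet:
    """Per-cluster geometry extracted from a labelled point set."""

    labels: np.ndarray              # per-localization id, -1 = noise
    borders: list[Polygon]          # simple polygons, CCW, nm
    centroids: np.ndarray           # (k, 2) mean of member localizations
    areas: np.ndarray               # nm^2
    fwtm_length: np.ndarray         # nm
    fwtm_width: np.ndarray          # nm

    @property
    def n_clusters(self) -> int:
        return len(self.borders)


@dataclass
class RingProfile:
    """Area-normalized ring density profile of one cluster border."""

    ring_edges: np.ndarray
    loc_fraction: np.ndarray   # fraction of query localizations per ring
    area_fraction: np.ndarray  # analytic per-ring fraction of ringed area
    density: np.ndarray        # loc_fraction/area_fraction, unit-sum


def dbscan_cluster(points: np.ndarray, params: DbscanParams) -> np.ndarray:
    """Cluster 2D points (nm) with standard DBSCAN semantics.

    Core points have >= min_pts neighbors within eps (self included);
    clusters are maximal density-connected sets; border points go to the
    first-discovered cluster under the deterministic input ordering.
    Returns per-point integer labels, -1 for noise.
    """
    points = np.asarray(points, float)
    if points.ndim != 2 or len(points) < 1:
        raise ValueError("points must be a non-empty (n, 2) array")
    return DBSCAN(eps=params.eps_nm, min_samples=params.min_pts).fit(points).labels_


def _alpha_shape(points: np.ndarray, alpha_nm: float) -> Polygon:
    """Concave hull: union of Delaunay triangles with circumradius <= alpha."""
    from scipy.spatial import Delaunay

    tri = Delaunay(points)
    keep = []
    for simplex in tri.simplices:
        pa, pb, pc = points[simplex]
        a = np.linalg.norm(pb - pc)
        b = np.linalg.norm(pa - pc)
        c = np.linalg.norm(pa - pb)
        s = (a + b + c) / 2.0
        area2 = max(s * (s - a) * (s - b) * (s - c), 0.0)
        if area2 <= 0:
            continue
        circumradius = a * b * c / (4.0 * np.sqrt(area2))
        if circumradius <= alpha_nm:
            keep.append(Polygon(points[simplex]))
    if not keep:
        raise ValueError("alpha too small: no triangles kept")
    union = shapely.unary_union(keep)
    if union.geom_type == "MultiPolygon":
        union = max(union.geoms, key=lambda g: g.area)
    return orient(Polygon(union.exterior), sign=1.0)


def cluster_border(points: np.ndarray, method: str = "convex",
                   alpha_nm: float = 100.0) -> Polygon:
    """Outline a cluster's member localizations as a simple polygon.

    ``method="convex"`` gives the convex hull; ``method="concave"`` an
    alpha-shape with maximum triangle circumradius ``alpha_nm``.  Vertices
    are counter-clockwise; the ring is closed.
    """
    points = np.asarray(points, float)
    if len(points) < 3:
        raise ValueError("border needs >= 3 points")
    if method == "convex":
        hull = MultiPoint(points).convex_hull
        if hull.geom_type != "Polygon":
            raise ValueError("degenerate (collinear) cluster")
        return orient(hull, sign=1.0)
    if method == "concave":
        return _alpha_shape(points, alpha_nm)
    raise ValueError(f"unknown border method {method!r}")


def fwtm_dimensions(points: np.ndarray, bin_nm: float = 5.0,
                    smooth_sigma_bins: float = 2.0) -> tuple[float, float]:
    """Full width at tenth maximum along the cluster's principal axes.

    Projections onto the two covariance eigenvectors are histogrammed
    (``bin_nm``-wide bins), Gaussian-smoothed, and the width of the region
    where the profile stays >= 10% of its maximum is measured with linear
    interpolation at the two crossings.  The broadening the estimator
    itself introduces (smoothing kernel plus bin quantization) is then
    subtracted in quadrature, so a Gaussian cluster of SD sigma measures
    2*sqrt(2 ln 10)*sigma without bias.  Returns (length, width) with
    length >= width.
    """
    points = np.asarray(points, float)
    if len(points) < 10:
        raise ValueError("need >= 10 points")
    centered = points - points.mean(axis=0)
    cov = np.cov(centered.T)
    _, vecs = np.linalg.eigh(cov)
    widths = []
    for k in range(2):
        proj = centered @ vecs[:, k]
        if np.ptp(proj) == 0:
            widths.append(0.0)
            continue
        lo, hi = proj.min(), proj.max()
        edges = np.arange(lo - 3 * bin_nm, hi + 3 * bin_nm + bin_nm, bin_nm)
        hist, edges = np.histogram(proj, bins=edges)
        prof = gaussian_filter1d(hist.astype(float), smooth_sigma_bins)
        if prof.max() <= 0:
            raise ValueError("empty histogram")
        centers = 0.5 * (edges[:-1] + edges[1:])
        thresh = 0.1 * prof.max()
        above = np.flatnonzero(prof >= thresh)
        i0, i1 = above[0], above[-1]
        # linear interpolation of the two threshold crossings
        if i0 > 0:
            x_left = np.interp(thresh, [prof[i0 - 1], prof[i0]], [centers[i0 - 1], centers[i0]])
        else:
            x_left = centers[i0]
        if i1 < len(prof) - 1:
            x_right = np.interp(thresh, [prof[i1 + 1], prof[i1]], [centers[i1 + 1], centers[i1]])
        else:
            x_right = centers[i1]
        raw = float(x_right - x_left)
        # remove the estimator's own blur: smoothing sigma and bin variance
        blur_var = (smooth_sigma_bins * bin_nm) ** 2 + bin_nm**2 / 12.0
        corrected_sq = raw**2 - GAUSSIAN_FWTM_FACTOR**2 * blur_var
        widths.append(float(np.sqrt(max(corrected_sq, 0.0))))
    w1, w2 = sorted(widths)
    return w2, w1


def extract_clusters(points: np.ndarray, labels: np.ndarray,
                     border_method: str = "convex", alpha_nm: float = 100.0,
                     min_border_points: int = 3) -> ClusterSet:
    """Assemble a ClusterSet (borders, centroids, areas, FWTM) from labels."""
    points = np.asarray(points, float)
    ids = [k for k in np.unique(labels) if k != -1]
    borders, centroids, areas, lengths, widths = [], [], [], [], []
    for k in ids:
        member = points[labels == k]
        if len(member) < min_border_points:
            continue
        poly = cluster_border(member, border_method, alpha_nm)
        borders.append(poly)
        centroids.append(member.mean(axis=0))
        areas.append(poly.area)
        if len(member) >= 10:
            L, W = fwtm_dimensions(member)
        else:
            L = W = float("nan")
        lengths.append(L)
        widths.append(W)
    return ClusterSet(
        labels=np.asarray(labels),
        borders=borders,
        centroids=np.asarray(centroids).reshape(-1, 2),
        areas=np.asarray(areas),
        fwtm_length=np.asarray(lengths),
        fwtm_width=np.asarray(widths),
    )


def border_to_centroid_distance(border: Polygon, centroid: np.ndarray) -> float:
    """Signed distance from a polygon border to a point (nm).

    Magnitude is the minimum Euclidean distance from the point to the
    polygon boundary; the sign is positive outside the polygon and
    negative inside (0 on the boundary).
    """
    if border.is_empty or border.area == 0:
        raise ValueError("degenerate polygon")
    p = Point(float(centroid[0]), float(centroid[1]))
    d = border.exterior.distance(p)
    return -d if border.contains(p) else d


def distance_to_border(points: np.ndarray, border: Polygon) -> np.ndarray:
    """Per-point signed distance to a polygon border; negative inside."""
    points = np.asarray(points, float).reshape(-1, 2)
    geoms = shapely.points(points)
    d = shapely.distance(geoms, border.exterior)
    inside = shapely.contains(border, geoms)
    return np.where(inside, -d, d)


def classify_primary_secondary(clusters: ClusterSet,
                               psd_border: Polygon | None = None) -> list[str]:
    """Largest-area cluster is the primary structure, the rest secondary.

    Area ties are broken in favour of the cluster nearer to the PSD border
    (requires ``psd_border``); without one, the lower index wins.
    """
    if clusters.n_clusters < 1:
        raise ValueError("need >= 1 cluster")
    areas = clusters.areas
    best = np.flatnonzero(areas == areas.max())
    if len(best) > 1 and psd_border is not None:
        dists = [
            abs(border_to_centroid_distance(psd_border, clusters.centroids[i])) for i in best
        ]
        primary = int(best[int(np.argmin(dists))])
    else:
        primary = int(best[0])
    return ["primary" if i == primary else "secondary" for i in range(clusters.n_clusters)]


# --------------------------------------------------------------------------
# Scaled rings
# --------------------------------------------------------------------------

def scaled_polygon(border: Polygon, f: float, center: np.ndarray | None = None) -> Polygon:
    """Homothety of a polygon about a point (default: its centroid).

    The scaled copy's area is exactly f^2 times the original area for any
    simple polygon; the copies are nested only if the polygon is
    star-shaped about the scaling center (always true for convex borders).
    """
    if center is None:
        center = np.asarray(border.centroid.coords[0])
    verts = np.asarray(border.exterior.coords)[:-1]
    return Polygon(center + f * (verts - center))


def ring_area_fractions(edges: np.ndarray = DEFAULT_RING_EDGES) -> np.ndarray:
    """Analytic per-ring area fraction (f2^2 - f1^2) / f_max^2.

    Under a homothety about a fixed point, any simple polygon's area
    scales with f^2, so the fractions are polygon-independent.
    """
    edges = np.asarray(edges, float)
    return (edges[1:] ** 2 - edges[:-1] ** 2) / edges[-1] ** 2


def scaled_rings(border: Polygon, edges: np.ndarray = DEFAULT_RING_EDGES,
                 ) -> tuple[list[Polygon], np.ndarray]:
    """Concentric rings obtained by scaling the border about its centroid.

    Ring k is the region between the borders scaled by ``edges[k]`` and
    ``edges[k+1]``.  Returns the ring polygons and the analytic area
    fractions.
    """
    if not border.is_valid or border.is_empty:
        raise ValueError("border must be a valid simple polygon")
    edges = np.asarray(edges, float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    center = np.asarray(border.centroid.coords[0])
    polys = [scaled_polygon(border, f, center) for f in edges]
    rings = [polys[k + 1].difference(polys[k]) for k in range(len(edges) - 1)]
    return rings, ring_area_fractions(edges)


def normalized_radius(points: np.ndarray, border: Polygon) -> np.ndarray:
    """Border-scale coordinate of each point (1.0 = on the border).

    For each point the ray from the border centroid through the point is
    intersected with the border; the normalized radius is the ratio of the
    point's centroid distance to that border crossing distance.  Exact for
    star-shaped (hence convex) borders.
    """
    points = np.asarray(points, float).reshape(-1, 2)
    center = np.asarray(border.centroid.coords[0])
    verts = np.asarray(border.exterior.coords)
    a = verts[:-1]                      # edge starts
    e = verts[1:] - verts[:-1]          # edge vectors
    d = points - center
    r = np.linalg.norm(d, axis=1)
    out = np.zeros(len(points))
    nz = r > 0
    u = d[nz] / r[nz, None]
    # ray c + t u vs edge a + s e: solve with 2D cross products
    w = a[None, :, :] - center[None, None, :]
    cross_ue = u[:, None, 0] * e[None, :, 1] - u[:, None, 1] * e[None, :, 0]
    cross_we = w[..., 0] * e[None, :, 1] - w[..., 1] * e[None, :, 0]
    cross_wu = w[..., 0] * u[:, None, 1] - w[..., 1] * u[:, None, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross_we / cross_ue
        s = cross_wu / cross_ue
    valid = (np.abs(cross_ue) > 1e-12) & (s >= -1e-9) & (s <= 1 + 1e-9) & (t > 1e-9)
    t = np.where(valid, t, np.inf)
    t_min = t.min(axis=1)
    out[nz] = r[nz] / t_min
    return out


def ring_density_profile(border: Polygon, query_points: np.ndarray,
                         edges: np.ndarray = DEFAULT_RING_EDGES,
                         normalize: str = "sum") -> RingProfile:
    """Area-normalized density of query localizations in border-scaled rings.

    ``loc_fraction[k]`` is the fraction (of all query points within the
    outermost scale) falling in ring k; ``density`` is
    ``loc_fraction/area_fraction`` renormalized to unit sum (or unit max
    with ``normalize="max"``).
    """
    edges = np.asarray(edges, float)
    f = normalized_radius(query_points, border)
    inside = f <= edges[-1]
    n_total = int(inside.sum())
    if n_total == 0:
        raise ValueError("no query points within the outermost ring")
    counts, _ = np.histogram(f[inside], bins=edges)
    loc_fraction = counts / n_total
    area_fraction = ring_area_fractions(edges)
    density = loc_fraction / area_fraction
    if normalize == "sum":
        density = density / density.sum() if density.sum() > 0 else density
    elif normalize == "max":
        density = density / density.max() if density.max() > 0 else density
    else:
        raise ValueError(f"unknown normalize {normalize!r}")
    return RingProfile(ring_edges=edges, loc_fraction=loc_fraction,
                       area_fraction=area_fraction, density=density)
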