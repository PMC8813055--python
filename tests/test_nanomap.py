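"""Cluster geometry: DBSCAN, borders, distances, FWTM, ring profiles."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from endozone import nanomap, synthetic


# --------------------------------------------------------------------------
# independent brute-force oracles
# --------------------------------------------------------------------------

def dbscan_oracle(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Textbook density-expansion DBSCAN, O(n^2), deterministic ordering."""
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        queue = [i]
        while queue:
            j = queue.pop(0)
            for q in neighbors[j]:
                if labels[q] == -1:
                    labels[q] = cid
                    if core[q]:
                        queue.append(q)
        cid += 1
    return labels


def labels_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """Exact equality up to cluster renaming (noise must match exactly)."""
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping: dict[int, int] = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(x, y) != y:
            return False
    return len(set(mapping.values())) == len(mapping)


def random_scene(rng: np.random.Generator, n_max: int = 500) -> np.ndarray:
    """Gaussian blobs plus uniform background noise."""
    n_blobs = rng.integers(1, 4)
    pts = [rng.uniform(0, 2000, size=(rng.integers(10, 80), 2))]
    for _ in range(n_blobs):
        c = rng.uniform(200, 1800, 2)
        pts.append(rng.normal(c, rng.uniform(20, 60), size=(rng.integers(30, 120), 2)))
    out = np.concatenate(pts)[:n_max]
    return out


def signed_distance_oracle(points: np.ndarray, poly: Polygon, step_nm: float = 0.05):
    """Min distance to densified boundary samples; sign by ray casting."""
    from matplotlib.path import Path

    verts = np.asarray(poly.exterior.coords)
    samples = []
    for a, b in zip(verts[:-1], verts[1:]):
        n = max(int(np.ceil(np.linalg.norm(b - a) / step_nm)), 1)
        t = np.linspace(0, 1, n, endpoint=False)[:, None]
        samples.append(a + t * (b - a))
    boundary = np.concatenate(samples)
    d = np.sqrt(((points[:, None, :] - boundary[None, :, :]) ** 2).sum(-1)).min(axis=1)
    inside = Path(verts).contains_points(points)
    return np.where(inside, -d, d)


# --------------------------------------------------------------------------
# DBSCAN
# --------------------------------------------------------------------------

class TestDbscan:
    def test_dense_disc_single_cluster_no_noise(self):
        rng = np.random.default_rng(0)
        r = 100 * np.sqrt(rng.uniform(size=150))
        th = rng.uniform(0, 2 * np.pi, 150)
        pts = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
        labels = nanomap.dbscan_cluster(pts, nanomap.DbscanParams(0.2, 100))
        assert set(labels) == {0}
        # brute-force check: every point has all 150 within 200 nm
        oracle = dbscan_oracle(pts, 200.0, 100)
        assert labels_equivalent(labels, oracle)

    def test_isolated_points_all_noise(self):
        pts = np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0]])
        labels = nanomap.dbscan_cluster(pts, nanomap.DbscanParams(0.05, 2))
        assert set(labels) == {-1}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = random_scene(rng, n_max=200)
        eps = rng.uniform(30, 100)
        min_pts = int(rng.integers(3, 10))
        labels = nanomap.dbscan_cluster(pts, nanomap.DbscanParams(eps / 1000.0, min_pts))
        assert labels_equivalent(labels, dbscan_oracle(pts, eps, min_pts))

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            nanomap.DbscanParams(0.0, 5)
        with pytest.raises(ValueError):
            nanomap.DbscanParams(0.2, 0)


# --------------------------------------------------------------------------
# Borders
# --------------------------------------------------------------------------

class TestClusterBorder:
    def test_square_corners_give_square(self):
        pts = np.array([[0, 0], [100, 0], [100, 100], [0, 100]], float)
        poly = nanomap.cluster_border(pts, "convex")
        assert poly.area == pytest.approx(1e4)
        assert poly.exterior.is_ccw

    def test_disc_hull_area_converges(self):
        rng = np.random.default_rng(1)
        r = 100 * np.sqrt(rng.uniform(size=2000))
        th = rng.uniform(0, 2 * np.pi, 2000)
        pts = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
        poly = nanomap.cluster_border(pts, "convex")
        assert poly.area == pytest.approx(np.pi * 100**2, rel=0.05)

    def test_concave_shape_smaller_than_hull(self):
        rng = np.random.default_rng(2)
        th = rng.uniform(0.25 * np.pi, 1.75 * np.pi, 2000)  # "C" opening to the right
        r = rng.uniform(70, 100, 2000)
        pts = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
        concave = nanomap.cluster_border(pts, "concave", alpha_nm=40.0)
        convex = nanomap.cluster_border(pts, "convex")
        assert concave.area < convex.area

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float)
        with pytest.raises(ValueError):
            nanomap.cluster_border(pts, "convex")


class TestSignedDistances:
    SQUARE = Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])

    def test_centroid_outside_positive(self):
        assert nanomap.border_to_centroid_distance(self.SQUARE, np.array([150.0, 50.0])) == pytest.approx(50.0)

    def test_centroid_inside_negative(self):
        assert nanomap.border_to_centroid_distance(self.SQUARE, np.array([50.0, 50.0])) == pytest.approx(-50.0)

    def test_centroid_on_boundary_zero(self):
        assert nanomap.border_to_centroid_distance(self.SQUARE, np.array([0.0, 50.0])) == pytest.approx(0.0)

    def test_point_at_center_of_circle(self):
        th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        circle = Polygon(np.stack([100 * np.cos(th), 100 * np.sin(th)], axis=1))
        d = nanomap.distance_to_border(np.array([[0.0, 0.0]]), circle)
        assert d[0] == pytest.approx(-100.0, abs=0.1)

    def test_point_on_border_zero(self):
        d = nanomap.distance_to_border(np.array([[0.0, 50.0]]), self.SQUARE)
        assert d[0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_densified_edge_oracle(self):
        rng = np.random.default_rng(3)
        th = np.sort(rng.uniform(0, 2 * np.pi, 9))
        poly = Polygon(np.stack([rng.uniform(50, 150, 9) * np.cos(th),
                                 rng.uniform(50, 150, 9) * np.sin(th)], axis=1))
        pts = rng.uniform(-200, 200, size=(100, 2))
        got = nanomap.distance_to_border(pts, poly)
        want = signed_distance_oracle(pts, poly)
        np.testing.assert_allclose(got, want, atol=0.5)

    def test_cluster_members_mean_signed_distance_negative(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 50, size=(500, 2))
        poly = nanomap.cluster_border(pts, "convex")
        assert nanomap.distance_to_border(pts, poly).mean() < 0


# --------------------------------------------------------------------------
# FWTM
# --------------------------------------------------------------------------

class TestFwtm:
    def test_isotropic_gaussian_closed_form(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 50, size=(10000, 2))
        L, W = nanomap.fwtm_dimensions(pts)
        expected = nanomap.GAUSSIAN_FWTM_FACTOR * 50
        assert L == pytest.approx(expected, rel=0.05)
        assert W == pytest.approx(expected, rel=0.05)

    def test_identical_points_zero(self):
        pts = np.zeros((20, 2))
        assert nanomap.fwtm_dimensions(pts) == (0.0, 0.0)

    def test_anisotropic_ratio(self):
        rng = np.random.default_rng(6)
        pts = np.stack([rng.normal(0, 100, 20000), rng.normal(0, 25, 20000)], axis=1)
        L, W = nanomap.fwtm_dimensions(pts)
        assert L / W == pytest.approx(4.0, rel=0.10)

    def test_length_not_smaller_than_width(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            pts = rng.normal(0, rng.uniform(10, 80, 2), size=(500, 2))
            L, W = nanomap.fwtm_dimensions(pts)
            assert L >= W


# --------------------------------------------------------------------------
# Primary/secondary classification
# --------------------------------------------------------------------------

def _cluster_set(areas, centroids):
    polys = []
    for a, c in zip(areas, centroids):
        s = np.sqrt(a) / 2
        polys.append(Polygon([(c[0] - s, c[1] - s), (c[0] + s, c[1] - s),
                              (c[0] + s, c[1] + s), (c[0] - s, c[1] + s)]))
    return nanomap.ClusterSet(
        labels=np.arange(len(areas)), borders=polys,
        centroids=np.asarray(centroids, float), areas=np.asarray(areas, float),
        fwtm_length=np.zeros(len(areas)), fwtm_width=np.zeros(len(areas)),
    )


class TestClassifyPrimarySecondary:
    def test_largest_is_primary(self):
        cs = _cluster_set([40e3, 7e3], [(0, 0), (300, 0)])
        assert nanomap.classify_primary_secondary(cs) == ["primary", "secondary"]

    def test_single_cluster_primary(self):
        cs = _cluster_set([7e3], [(0, 0)])
        assert nanomap.classify_primary_secondary(cs) == ["primary"]

    def test_tie_broken_by_psd_proximity(self):
        psd = Polygon([(-100, -100), (-50, -100), (-50, -50), (-100, -50)])
        cs = _cluster_set([1e4, 1e4], [(500, 0), (-10, -75)])
        labels = nanomap.classify_primary_secondary(cs, psd_border=psd)
        assert labels == ["secondary", "primary"]


# --------------------------------------------------------------------------
# Rings
# --------------------------------------------------------------------------

def random_star_polygon(rng, n=10, rmin=50, rmax=150):
    th = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(rmin, rmax, n)
    return Polygon(np.stack([r * np.cos(th), r * np.sin(th)], axis=1))


class TestScaledRings:
    def test_innermost_ring_area_fraction(self):
        fr = nanomap.ring_area_fractions()
        assert fr[0] == pytest.approx(0.2**2 / 1.6**2)
        assert fr[4] == pytest.approx((1.0 - 0.64) / 2.56)
        assert fr.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_polygon_ring_areas_match_analytic(self, seed):
        rng = np.random.default_rng(seed)
        poly = random_star_polygon(rng)
        edges = nanomap.DEFAULT_RING_EDGES
        scaled_areas = np.array([nanomap.scaled_polygon(poly, f).area for f in edges])
        computed = np.diff(scaled_areas) / (poly.area * 1.6**2)
        np.testing.assert_allclose(computed, nanomap.ring_area_fractions(edges), rtol=1e-6)

    def test_convex_ring_polygons_match_analytic(self):
        # for a convex border the geometric rings themselves have the law
        rng = np.random.default_rng(17)
        pts = rng.normal(0, 60, size=(200, 2))
        poly = nanomap.cluster_border(pts, "convex")
        rings, fractions = nanomap.scaled_rings(poly)
        total = poly.area * 1.6**2
        for ring, frac in zip(rings, fractions):
            assert ring.area / total == pytest.approx(frac, rel=1e-6)

    def test_non_increasing_edges_rejected(self):
        poly = random_star_polygon(np.random.default_rng(0))
        with pytest.raises(ValueError):
            nanomap.scaled_rings(poly, np.array([0.0, 0.5, 0.5, 1.6]))


class TestRingDensityProfile:
    def test_uniform_points_flat_profile(self):
        rng = np.random.default_rng(8)
        poly = random_star_polygon(rng)
        center = np.asarray(poly.centroid.coords[0])
        verts = np.asarray(poly.exterior.coords)[:-1]
        big = Polygon(center + 1.6 * (verts - center))
        minx, miny, maxx, maxy = big.bounds
        import shapely

        pts = []
        while len(pts) < 10000:
            cand = rng.uniform([minx, miny], [maxx, maxy], size=(20000, 2))
            keep = shapely.contains(big, shapely.points(cand))
            pts.extend(cand[keep].tolist())
        prof = nanomap.ring_density_profile(poly, np.array(pts[:10000]))
        np.testing.assert_allclose(prof.density, 0.125, atol=0.02)

    def test_all_points_at_centroid(self):
        poly = random_star_polygon(np.random.default_rng(9))
        c = np.asarray(poly.centroid.coords[0])
        prof = nanomap.ring_density_profile(poly, np.tile(c, (10, 1)))
        np.testing.assert_allclose(prof.density, [1, 0, 0, 0, 0, 0, 0, 0])

    def test_edge_enriched_channel_peaks_in_outer_inward_ring(self):
        params = synthetic.SynapseSceneParams(
            seed=10, edge_alpha=8.0, edge_beta=2.0,
            n_loc_ez=2000, n_loc_accessory=2000,
            precision_sigma=0.0, blink_run_length=1.0,
        )
        table, _ = synthetic.make_localization_scene(params)
        ez = table[table.channel == "ez"][["x", "y"]].to_numpy()
        acc = table[table.channel == "accessory"][["x", "y"]].to_numpy()
        labels = nanomap.dbscan_cluster(ez, nanomap.EZ_REGIME)
        clusters = nanomap.extract_clusters(ez, labels)
        prof = nanomap.ring_density_profile(
            clusters.borders[int(np.argmax(clusters.areas))], acc
        )
        assert np.argmax(prof.density) == 4  # the 80-100% ring

    def test_centrally_dense_cluster_profile_decreasing_outward(self):
        # clathrin against its own border: center rings densest
        rng = np.random.default_rng(11)
        pts = rng.normal(0, 60, size=(3000, 2))
        poly = nanomap.cluster_border(pts, "convex")
        prof = nanomap.ring_density_profile(poly, pts)
        assert prof.density[0] == prof.density.max()
        assert prof.density[5:].sum() < 0.05  # beyond the border: near zero

    def test_no_points_within_outer_scale_raises(self):
        poly = random_star_polygon(np.random.default_rng(12))
        far = np.array([[1e6, 1e6]])
        with pytest.raises(ValueError):
            nanomap.ring_density_profile(poly, far)
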