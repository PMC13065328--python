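"""Projection, geodesics, triangle enumeration, embedding, and binning."""

import itertools

import numpy as np
import pytest
import trimesh

from phasefield.cortical_geometry import (
    CorticalMesh,
    SurfacePoints,
    bin_triangles,
    enumerate_triangles,
    geodesic_distances,
    planar_embed,
    project_to_surface,
)


@pytest.fixture(scope="module")
def icosphere_mesh():
    """Unit icosphere labeled as a single left hemisphere."""
    ico = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    return CorticalMesh(
        vertices=np.asarray(ico.vertices),
        faces=np.asarray(ico.faces),
        vertex_hemisphere=np.full(len(ico.vertices), "left"),
    )


def surface_points_at_vertices(mesh: CorticalMesh, vidx) -> SurfacePoints:
    sub, _ = mesh.submesh("left")
    faces = np.array([int(sub.vertex_faces[v][0]) for v in vidx])
    return SurfacePoints(
        xyz=np.asarray(sub.vertices)[vidx],
        hemisphere=np.full(len(vidx), "left"),
        face=faces,
        barycentric=np.zeros((len(vidx), 3)),
        contact_index=np.arange(len(vidx)),
        offset=np.zeros(len(vidx)),
    )


class TestProjection:
    def test_contact_on_vertex_projects_to_itself(self, icosphere_mesh):
        v = icosphere_mesh.vertices[10]
        pts = project_to_surface(v[None, :], np.array(["left"]), icosphere_mesh)
        np.testing.assert_allclose(pts.xyz[0], v, atol=1e-12)

    def test_normal_offset_lands_at_face_centroid(self, icosphere_mesh):
        sub, _ = icosphere_mesh.submesh("left")
        f = 42
        centroid = sub.triangles[f].mean(axis=0)
        normal = np.asarray(sub.face_normals)[f]
        p = centroid + 0.005 * normal
        pts = project_to_surface(p[None, :], np.array(["left"]), icosphere_mesh)
        np.testing.assert_allclose(pts.xyz[0], centroid, atol=1e-9)
        assert pts.face[0] == f

    def test_tie_break_matches_brute_force_lowest_face(self, icosphere_mesh):
        sub, _ = icosphere_mesh.submesh("left")
        # a point far outside is equidistant-ish; compare with brute force
        p = np.array([0.0, 0.0, 2.0])
        tri = sub.triangles
        d = np.array(
            [
                np.linalg.norm(
                    trimesh.triangles.closest_point(t[None], p[None])[0] - p
                )
                for t in tri
            ]
        )
        expected_face = int(np.argmin(d))
        pts = project_to_surface(p[None, :], np.array(["left"]), icosphere_mesh,
                                 max_dist=np.inf)
        assert pts.face[0] == expected_face

    def test_distant_contact_excluded_with_warning(self, icosphere_mesh):
        p = np.array([0.0, 0.0, 5.0])
        with pytest.warns(UserWarning, match="excluded"):
            pts = project_to_surface(p[None, :], np.array(["left"]), icosphere_mesh,
                                     max_dist=0.02)
        assert len(pts) == 0 and pts.excluded == [0]


class TestGeodesics:
    def test_icosphere_distances_match_great_circle_within_one_percent(
        self, icosphere_mesh
    ):
        rng = np.random.default_rng(0)
        vidx = rng.choice(len(icosphere_mesh.vertices), size=12, replace=False)
        pts = surface_points_at_vertices(icosphere_mesh, vidx)
        D = geodesic_distances(icosphere_mesh, pts)
        V = icosphere_mesh.vertices[vidx]
        theta = np.arccos(np.clip(V @ V.T, -1, 1))
        mask = theta > 0.15
        rel = np.abs(D[mask] - theta[mask]) / theta[mask]
        assert rel.max() < 0.01

    def test_antipodal_distance_is_pi(self, icosphere_mesh):
        # vertex 0 of an icosphere has an antipodal vertex
        V = icosphere_mesh.vertices
        anti = int(np.argmin(V @ V[0]))
        pts = surface_points_at_vertices(icosphere_mesh, np.array([0, anti]))
        D = geodesic_distances(icosphere_mesh, pts)
        assert D[0, 1] == pytest.approx(np.pi, rel=0.01)

    def test_flat_rectangle_gives_euclidean_distance(self):
        n = 21
        g = np.linspace(0, 1, n)
        xx, yy = np.meshgrid(g, g)
        verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + 1, a + n])
                faces.append([a + 1, a + n + 1, a + n])
        mesh = CorticalMesh(
            vertices=verts,
            faces=np.asarray(faces),
            vertex_hemisphere=np.full(len(verts), "left"),
        )
        pts = project_to_surface(
            np.array([[0.05, 0.05, 0.0], [0.85, 0.65, 0.0]]),
            np.array(["left", "left"]),
            mesh,
        )
        D = geodesic_distances(mesh, pts)
        expected = np.linalg.norm([0.8, 0.6])
        assert D[0, 1] == pytest.approx(expected, rel=0.005)

    def test_same_point_distance_is_zero(self, icosphere_mesh):
        pts = surface_points_at_vertices(icosphere_mesh, np.array([7, 7]))
        D = geodesic_distances(icosphere_mesh, pts)
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_cross_hemisphere_distance_is_infinite(self):
        ico = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        n = len(ico.vertices)
        mesh = CorticalMesh(
            vertices=np.vstack([ico.vertices, ico.vertices + [3.0, 0, 0]]),
            faces=np.vstack([ico.faces, ico.faces + n]),
            vertex_hemisphere=np.array(["left"] * n + ["right"] * n),
        )
        pts = project_to_surface(
            np.array([[1.0, 0, 0], [4.0, 0, 0]]),
            np.array(["left", "right"]),
            mesh,
        )
        D = geodesic_distances(mesh, pts)
        assert np.isinf(D[0, 1])


class TestEnumerateTriangles:
    def build(self, dists, hemis=None, angle_min=np.pi / 4):
        n = dists.shape[0]
        if hemis is None:
            hemis = np.full(n, "left")
        return enumerate_triangles(dists, hemis, angle_min=angle_min)

    def dist_matrix(self, edges):
        (ab, bc, ca) = edges
        return np.array([[0, ab, ca], [ab, 0, bc], [ca, bc, 0]], dtype=float)

    def test_equilateral_triple_accepted(self):
        tset = self.build(self.dist_matrix((0.02, 0.02, 0.02)))
        assert len(tset) == 1

    def test_collinear_triple_rejected(self):
        tset = self.build(self.dist_matrix((0.01, 0.01, 0.02)))
        assert len(tset) == 0

    def test_law_of_cosines_angle_threshold(self):
        # edges 1, 1, 1.8: smallest angle arccos(0.9) ~ 25.8 deg < 45 deg
        assert np.degrees(np.arccos(0.9)) == pytest.approx(25.84, abs=0.01)
        tset = self.build(self.dist_matrix((1.0, 1.8, 1.0)))
        assert len(tset) == 0

    def test_triangle_count_monotone_in_angle_threshold(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(size=(15, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        counts = [len(self.build(D, np.full(15, "left"), a))
                  for a in (np.pi / 8, np.pi / 4, np.pi / 3)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(size=(12, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        tset = self.build(D, np.full(12, "left"))
        expected = set()
        for a, b, c in itertools.combinations(range(12), 3):
            ab, bc, ca = D[a, b], D[b, c], D[c, a]
            cosines = [
                (ab**2 + ca**2 - bc**2) / (2 * ab * ca),
                (ab**2 + bc**2 - ca**2) / (2 * ab * bc),
                (bc**2 + ca**2 - ab**2) / (2 * bc * ca),
            ]
            if max(cosines) < np.cos(np.pi / 4):
                expected.add((a, b, c))
        got = {tuple(row) for row in tset.ids}
        assert got == expected

    def test_cross_hemisphere_triples_never_formed(self):
        D = np.full((4, 4), 0.02)
        np.fill_diagonal(D, 0)
        tset = self.build(D, np.array(["left", "left", "left", "right"]))
        assert len(tset) == 1  # only the all-left triple


class TestPlanarEmbed:
    def test_three_four_five_recovers_edges(self):
        coords = planar_embed(np.array([3.0, 4.0, 5.0]))[0]
        A, B, C = coords
        assert np.linalg.norm(B - A) == pytest.approx(3.0, abs=1e-12)
        assert np.linalg.norm(C - B) == pytest.approx(4.0, abs=1e-12)
        assert np.linalg.norm(A - C) == pytest.approx(5.0, abs=1e-12)

    def test_equilateral_embedding(self):
        s = 0.04
        coords = planar_embed(np.array([s, s, s]))[0]
        np.testing.assert_allclose(coords[2], [s / 2, s * np.sqrt(3) / 2], atol=1e-15)

    def test_c_is_always_above_the_x_axis(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b = rng.uniform(0.5, 2.0, 2)
            c = rng.uniform(abs(a - b) + 0.05, a + b - 0.05)
            coords = planar_embed(np.array([a, b, c]))[0]
            assert coords[2, 1] > 0

    def test_degenerate_triangle_raises(self):
        with pytest.raises(ValueError):
            planar_embed(np.array([1.0, 1.0, 2.0]))

    def test_embedding_recovers_random_valid_edges(self):
        rng = np.random.default_rng(4)
        edges = []
        for _ in range(200):
            a, b = rng.uniform(0.3, 3.0, 2)
            c = rng.uniform(abs(a - b) + 0.02, a + b - 0.02)
            edges.append([a, c, b])  # (|AB|, |BC|, |CA|)
        edges = np.asarray(edges)
        coords = planar_embed(edges)
        ab = np.linalg.norm(coords[:, 1] - coords[:, 0], axis=1)
        bc = np.linalg.norm(coords[:, 2] - coords[:, 1], axis=1)
        ca = np.linalg.norm(coords[:, 0] - coords[:, 2], axis=1)
        np.testing.assert_allclose(np.stack([ab, bc, ca], axis=1), edges, atol=1e-10)


class TestBinTriangles:
    def make_set(self, sizes):
        sizes = np.asarray(sizes, dtype=float)
        edges = np.stack([sizes * 1.52] * 3, axis=1)  # near-equilateral
        tset = enumerate_triangles  # noqa: F841  (documentation only)
        from phasefield.cortical_geometry import TriangleSet

        planar = planar_embed(edges)
        area = 0.5 * planar[:, 1, 0] * planar[:, 2, 1]
        return TriangleSet(
            ids=np.tile(np.arange(3), (len(sizes), 1)),
            edges=edges,
            planar=planar,
            xi=1.0 / np.sqrt(area),
            hemisphere=np.full(len(sizes), "left"),
        )

    def test_single_bin_weights_are_reciprocal_count(self):
        tset = bin_triangles(self.make_set([0.05] * 7))
        np.testing.assert_allclose(tset.n_weight, 1.0 / 7.0)

    def test_each_nonempty_bin_sums_to_one(self):
        tset = bin_triangles(self.make_set([0.05] * 10 + [0.15]))
        sums = {}
        for b, w in zip(tset.bin_index, tset.n_weight):
            sums[b] = sums.get(b, 0.0) + w
        assert set(np.round(list(sums.values()), 12)) == {1.0}

    def test_sub_centimeter_triangle_goes_to_the_extra_bin(self):
        tset = bin_triangles(self.make_set([0.005, 0.05]))
        assert tset.bin_index[0] == 32
        assert 0 <= tset.bin_index[1] < 32

    def test_empty_set_raises(self):
        from phasefield.cortical_geometry import TriangleSet

        empty = TriangleSet(
            ids=np.empty((0, 3), int),
            edges=np.empty((0, 3)),
            planar=np.empty((0, 3, 2)),
            xi=np.empty(0),
            hemisphere=np.empty(0, dtype=object),
        )
        with pytest.raises(ValueError):
            bin_triangles(empty)
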