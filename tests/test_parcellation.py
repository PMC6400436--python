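"""Surface-parcel subdivision: areas, longest axes, splits, termination."""

import numpy as np
import pytest
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from netnorm import (
    TriMesh,
    generate_labeled_mesh,
    longest_axis,
    parcel_area,
    split_parcel,
    subdivide_to_threshold,
)


def all_pairs_oracle(mesh, parcel_vertices):
    """Exhaustive Dijkstra from every parcel vertex (independent oracle)."""
    g = mesh.edge_graph()
    pv = np.asarray(parcel_vertices)
    sub = g[pv][:, pv]
    best = (-1.0, None)
    for i in range(len(pv)):
        d = dijkstra(sub, directed=False, indices=i)
        j = int(np.argmax(d))
        if d[j] > best[0]:
            best = (float(d[j]), (int(pv[i]), int(pv[j])))
    return best


class TestParcelArea:
    def test_whole_flat_mesh(self):
        mesh, labels = generate_labeled_mesh((10, 10), 1.0)
        assert parcel_area(mesh, labels, 0) == pytest.approx(100.0)

    def test_two_halves_conserve_total(self):
        mesh, _ = generate_labeled_mesh((10, 10), 1.0)
        labels = (mesh.vertices[:, 0] > 5.0).astype(int)
        a0 = parcel_area(mesh, labels, 0)
        a1 = parcel_area(mesh, labels, 1)
        assert a0 + a1 == pytest.approx(100.0)  # exact conservation
        assert 40 < a0 < 60 and 40 < a1 < 60

    def test_boundary_face_splits_by_vertex_fraction(self):
        # single triangle with 1 of 3 vertices in parcel A -> area/3 to A
        mesh = TriMesh(
            vertices=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]]),
            faces=np.array([[0, 1, 2]]),
        )
        labels = np.array(["A", "B", "B"])
        assert parcel_area(mesh, labels, "A") == pytest.approx(0.5 / 3)
        assert parcel_area(mesh, labels, "B") == pytest.approx(2 * 0.5 / 3)

    def test_unknown_parcel_rejected(self):
        mesh, labels = generate_labeled_mesh((3, 3), 1.0)
        with pytest.raises(ValueError):
            parcel_area(mesh, labels, "nope")


class TestLongestAxis:
    def test_strip_endpoints_on_short_edges(self):
        mesh, _ = generate_labeled_mesh((40, 10), 1.0)
        (vi, vj), axis = longest_axis(mesh, np.arange(mesh.n_vertices))
        assert np.linalg.norm(axis) >= 39.0
        assert abs(axis[0]) > abs(axis[1])

    def test_two_vertex_parcel_returns_that_pair(self):
        mesh, _ = generate_labeled_mesh((4, 4), 1.0)
        pair, axis = longest_axis(mesh, np.array([0, 1]))
        assert set(pair) == {0, 1}

    def test_l_shaped_parcel_matches_all_pairs_oracle(self):
        mesh, _ = generate_labeled_mesh((12, 12), 1.0)
        v = mesh.vertices
        in_l = (v[:, 0] <= 3) | (v[:, 1] <= 3)
        pv = np.nonzero(in_l)[0]
        (vi, vj), _ = longest_axis(mesh, pv)
        best_d, _ = all_pairs_oracle(mesh, pv)
        g = mesh.edge_graph()
        sub = g[pv][:, pv]
        pos = {int(x): k for k, x in enumerate(pv)}
        d = dijkstra(sub, directed=False, indices=pos[vi])[pos[vj]]
        assert d == pytest.approx(best_d, abs=1e-10)

    def test_disconnected_parcel_is_an_error(self):
        mesh, _ = generate_labeled_mesh((6, 2), 1.0)
        corners = np.array([0, mesh.n_vertices - 1])
        with pytest.raises(ValueError, match="disconnected"):
            longest_axis(mesh, corners)


class TestSplitParcel:
    def test_strip_splits_into_equal_halves(self):
        mesh, labels = generate_labeled_mesh((20, 4), 1.0)
        pv = np.arange(mesh.n_vertices)
        _, axis = longest_axis(mesh, pv)
        a, b = split_parcel(mesh, pv, axis)
        area_a = _area_of(mesh, a)
        area_b = _area_of(mesh, b)
        assert abs(area_a - area_b) <= 4.5  # within one face row
        assert len(a) + len(b) == mesh.n_vertices

    def test_two_vertex_parcel_becomes_singletons(self):
        mesh, _ = generate_labeled_mesh((4, 4), 1.0)
        a, b = split_parcel(mesh, np.array([0, 1]), np.array([0.0, 1.0, 0.0]))
        assert len(a) == 1 and len(b) == 1

    def test_degenerate_projection_falls_back_to_parity(self):
        mesh, _ = generate_labeled_mesh((4, 4), 1.0)
        pv = np.arange(5)
        axis = np.zeros(3)  # all projections identical
        a, b = split_parcel(mesh, pv, axis)
        assert len(a) > 0 and len(b) > 0

    def test_area_imbalance_bounded_by_crossing_faces(self):
        mesh, _ = generate_labeled_mesh((9, 9), 1.0, z_amplitude=0.5, seed=4)
        v = mesh.vertices
        pv = np.nonzero((v[:, 0] <= 6) & (v[:, 1] <= 7))[0]
        _, axis = longest_axis(mesh, pv)
        a, b = split_parcel(mesh, pv, axis)
        member = np.zeros(mesh.n_vertices, dtype=bool)
        member[a] = True
        other = np.zeros(mesh.n_vertices, dtype=bool)
        other[b] = True
        in_a = member[mesh.faces].sum(axis=1)
        in_b = other[mesh.faces].sum(axis=1)
        crossing = (in_a > 0) & (in_b > 0)
        bound = mesh.face_areas().max() * crossing.sum()
        assert abs(_area_of(mesh, a) - _area_of(mesh, b)) <= bound + 1e-9


def _area_of(mesh, pv):
    member = np.zeros(mesh.n_vertices, dtype=bool)
    member[pv] = True
    frac = member[mesh.faces].sum(axis=1) / 3.0
    return float((mesh.face_areas() * frac).sum())


class TestSubdivision:
    def test_small_mesh_left_unchanged(self):
        mesh, labels = generate_labeled_mesh((10, 10), 1.0)
        parc = subdivide_to_threshold(mesh, labels, 600.0)
        assert len(parc.parcel_ids) == 1

    def test_strip_halves_twice_to_four_parcels(self):
        # 40x10 strip of 400 mm^2 at threshold 150: 400 -> 2x200 -> 4x100
        mesh, labels = generate_labeled_mesh((40, 10), 1.0)
        parc = subdivide_to_threshold(mesh, labels, 150.0)
        assert len(parc.parcel_ids) == 4
        assert all(80 < a < 150 for a in parc.parcel_areas.values())

    def test_halving_threshold_never_reduces_parcel_count(self):
        mesh, labels = generate_labeled_mesh((24, 18), 1.0)
        n_coarse = len(subdivide_to_threshold(mesh, labels, 160.0).parcel_ids)
        n_fine = len(subdivide_to_threshold(mesh, labels, 80.0).parcel_ids)
        assert n_fine > n_coarse

    def test_area_conserved_and_all_below_threshold(self):
        mesh, labels = generate_labeled_mesh((17, 13), 1.3, z_amplitude=1.0, seed=9)
        parc = subdivide_to_threshold(mesh, labels, 40.0)
        total = sum(parc.parcel_areas.values())
        assert total == pytest.approx(mesh.total_area(), rel=1e-6)
        assert all(a < 40.0 for a in parc.parcel_areas.values())

    def test_final_parcels_are_connected(self):
        from scipy.sparse.csgraph import connected_components

        mesh, labels = generate_labeled_mesh((16, 16), 1.0)
        parc = subdivide_to_threshold(mesh, labels, 50.0)
        g = mesh.edge_graph()
        for pid in parc.parcel_ids:
            pv = np.nonzero(parc.labels == pid)[0]
            sub = g[pv][:, pv]
            n, _ = connected_components(sub, directed=False)
            assert n == 1

    def test_threshold_below_face_area_rejected(self):
        mesh, labels = generate_labeled_mesh((4, 4), 1.0)
        with pytest.raises(ValueError):
            subdivide_to_threshold(mesh, labels, 0.5)


class TestIO:
    def test_off_round_trip(self, tmp_path):
        mesh, _ = generate_labeled_mesh((5, 7), 1.0, z_amplitude=0.3, seed=2)
        path = tmp_path / "m.off"
        mesh.to_file(path)
        back = TriMesh.from_file(path)
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-5)
        assert back.faces.shape == mesh.faces.shape

    def test_labels_tsv_round_trip(self, tmp_path):
        from netnorm.parcellation import read_labels

        mesh, labels = generate_labeled_mesh((8, 8), 1.0, parcel_layout=4)
        parc = subdivide_to_threshold(mesh, labels, 30.0)
        path = tmp_path / "labels.tsv"
        parc.to_tsv(path)
        back = read_labels(path, n_vertices=mesh.n_vertices)
        assert np.array_equal(back, parc.labels.astype(str))
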