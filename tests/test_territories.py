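"""Eikonal distances, outlet projection and Voronoi territory assignment."""

import numpy as np
import pytest

from conftest import make_rod
from myoperf import geometry as geo
from myoperf import territories as terr


class TestProjection:
    def test_outlet_on_node(self, small_slab):
        pos = tuple(small_slab.nodes[17])
        seeds = terr.project_outlets(small_slab,
                                     [terr.OutletSpec(1, pos, 1.0)])
        assert seeds[1] == 17

    def test_tie_goes_to_lowest_index(self):
        rod = make_rod(5, 1.0)
        seeds = terr.project_outlets(rod, [terr.OutletSpec(1, (1.5, 0, 0), 1.0)])
        assert seeds[1] == 1

    def test_duplicate_seed_pushed_to_next_nearest(self):
        rod = make_rod(5, 1.0)
        outlets = [terr.OutletSpec(1, (0.0, 0, 0), 1.0),
                   terr.OutletSpec(2, (0.1, 0, 0), 1.0)]
        with pytest.warns(UserWarning, match="next-nearest"):
            seeds = terr.project_outlets(rod, outlets)
        assert seeds[1] == 0 and seeds[2] == 1

    def test_empty_outlets_rejected(self, small_slab):
        with pytest.raises(ValueError):
            terr.project_outlets(small_slab, [])


class TestEikonal:
    def test_rod_distance_linear(self):
        rod = make_rod(11, 1.0)
        d = terr.modified_eikonal(rod, seed=0, r=1.0)
        np.testing.assert_allclose(d, np.arange(11.0), rtol=1e-12)

    def test_radius_scales_distance(self):
        rod = make_rod(11, 1.0)
        d = terr.modified_eikonal(rod, seed=0, r=2.0)
        np.testing.assert_allclose(d, np.arange(11.0) / 2.0, rtol=1e-12)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            terr.modified_eikonal(make_rod(3), 0, 0.0)

    def test_matches_brute_force_on_small_mesh(self):
        m = geo.generate_idealized_wall("slab", (6, 6, 3), 3.0)  # ≤ 30 nodes
        assert m.n_nodes <= 30
        # Floyd–Warshall all-pairs oracle on the same edge graph
        n = m.n_nodes
        W = np.full((n, n), np.inf)
        np.fill_diagonal(W, 0.0)
        for a, b in m.edges:
            w = np.linalg.norm(m.nodes[a] - m.nodes[b])
            W[a, b] = W[b, a] = w
        for k in range(n):
            W = np.minimum(W, W[:, [k]] + W[[k], :])
        for seed in range(0, n, 7):
            d = terr.modified_eikonal(m, seed, r=1.0)
            np.testing.assert_allclose(d, W[seed], rtol=1e-12)

    def test_unreachable_nodes_get_infinity(self):
        rod = make_rod(6, 1.0)
        rod.edges = rod.edges[:2]  # sever the chain after node 2
        d = terr.modified_eikonal(rod, seed=0, r=1.0)
        assert np.all(np.isinf(d[3:])) and np.all(np.isfinite(d[:3]))


class TestAssignment:
    def test_symmetric_rod_splits_in_half(self):
        rod = make_rod(11, 1.0)
        dists = {1: terr.modified_eikonal(rod, 0, 1.0),
                 2: terr.modified_eikonal(rod, 10, 1.0)}
        tmap = terr.assign_territories(rod, dists)
        # boundary at x = 5; the tied node 5 goes to the lower id
        np.testing.assert_array_equal(tmap.label[:6], 1)
        np.testing.assert_array_equal(tmap.label[6:], 2)
        assert tmap.volumes[1] == 6.0 and tmap.volumes[2] == 5.0

    def test_larger_radius_wins_more_ground(self):
        # radii (1, 2) on a 10 mm rod: equality at x = 10/3
        rod = make_rod(11, 1.0)
        dists = {1: terr.modified_eikonal(rod, 0, 1.0),
                 2: terr.modified_eikonal(rod, 10, 2.0)}
        tmap = terr.assign_territories(rod, dists)
        boundary = 10.0 / 3.0
        expect = np.where(np.arange(11) < boundary, 1, 2)
        np.testing.assert_array_equal(tmap.label, expect)
        assert tmap.volumes[2] > tmap.volumes[1]

    def test_single_outlet_claims_everything(self, small_slab):
        tmap = terr.partition(small_slab, [terr.OutletSpec(7, (0, 0, 10), 1.0)])
        assert set(np.unique(tmap.label)) == {7}
        assert tmap.volumes[7] == pytest.approx(small_slab.total_volume,
                                                rel=1e-10)

    def test_partition_conserves_volume(self, small_slab):
        outlets = [terr.OutletSpec(1, (5, 5, 10), 1.0),
                   terr.OutletSpec(2, (15, 5, 10), 0.7),
                   terr.OutletSpec(3, (10, 15, 10), 1.4)]
        tmap = terr.partition(small_slab, outlets)
        assert sum(tmap.volumes.values()) == pytest.approx(
            small_slab.total_volume, rel=1e-10)
        # every node labelled exactly once: indicators sum to one
        chi_sum = sum(tmap.indicator(k) for k in tmap.outlet_ids)
        np.testing.assert_array_equal(chi_sum, 1.0)

    def test_all_infinite_distance_is_error(self):
        rod = make_rod(4, 1.0)
        with pytest.raises(ValueError, match="unreachable"):
            terr.assign_territories(rod, {1: np.full(4, np.inf)})

    def test_radius_monotonicity(self, small_slab):
        """Enlarging an outlet's radius never shrinks its territory."""
        base = [terr.OutletSpec(1, (2, 2, 10), 1.0),
                terr.OutletSpec(2, (18, 18, 10), 1.0)]
        sizes = []
        for r in (0.5, 1.0, 2.0, 4.0):
            outlets = [terr.OutletSpec(1, (2, 2, 10), r), base[1]]
            tmap = terr.partition(small_slab, outlets)
            sizes.append(tmap.volumes[1])
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))

    def test_euclidean_mode_ignores_radius(self, small_slab):
        outlets_r1 = [terr.OutletSpec(1, (2, 2, 10), 1.0),
                      terr.OutletSpec(2, (18, 18, 10), 1.0)]
        outlets_r4 = [terr.OutletSpec(1, (2, 2, 10), 4.0),
                      terr.OutletSpec(2, (18, 18, 10), 1.0)]
        t1 = terr.partition(small_slab, outlets_r1, euclidean=True)
        t4 = terr.partition(small_slab, outlets_r4, euclidean=True)
        np.testing.assert_array_equal(t1.label, t4.label)


class TestOutletIO:
    def test_csv_roundtrip(self, tmp_path):
        outlets = [terr.OutletSpec(1, (1, 2, 3), 1.5, 0.0),
                   terr.OutletSpec(2, (4, 5, 6), 0.8, 1e9)]
        path = tmp_path / "outlets.csv"
        terr.save_outlets_csv(outlets, path)
        back = terr.load_outlets_csv(path)
        assert back == outlets

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "outlets.csv"
        path.write_text("id,x_mm,y_mm,z_mm,radius_mm,resistance_Pa_s_per_m3\n"
                        "1,0,0,0,1.0,0\n1,1,1,1,1.0,0\n")
        with pytest.raises(ValueError, match="unique"):
            terr.load_outlets_csv(path)

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            terr.OutletSpec(1, (0, 0, 0), 0.0)
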