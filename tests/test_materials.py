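"""Material library, attenuation histogram and local clustering."""

import numpy as np
import pytest

from dectmmd.images import DectImagePair
from dectmmd.materials import (Material, MaterialLibrary, assign_cluster,
                               build_histogram2d, cluster_materials,
                               default_library, iodine_solution, koh_solution,
                               update_subgroups)


def make_lib(coords, names=None):
    mats = [Material(names[i] if names else f"m{i}", 1.0, float(x), float(y))
            for i, (x, y) in enumerate(coords)]
    return MaterialLibrary(mats)


class TestMaterial:
    def test_validation(self):
        with pytest.raises(ValueError):
            Material("x", 0.0, 0.1, 0.1)
        with pytest.raises(ValueError):
            Material("x", 1.0, -0.1, 0.1)

    def test_library_rejects_duplicate_names(self):
        with pytest.raises(ValueError, match="unique"):
            MaterialLibrary([Material("x", 1, 0.1, 0.1), Material("x", 1, 0.2, 0.2)])

    def test_library_rejects_degenerate_coordinates(self):
        with pytest.raises(ValueError, match="degenerate"):
            MaterialLibrary([Material("x", 1, 0.2, 0.2), Material("y", 2, 0.2, 0.2)])

    def test_csv_round_trip(self, tmp_path, library):
        path = tmp_path / "lib.csv"
        library.to_csv(path)
        back = MaterialLibrary.from_csv(path)
        assert back.names == library.names
        np.testing.assert_allclose(back.coords, library.coords)
        np.testing.assert_allclose(back.densities, library.densities)

    def test_default_library_physics(self, library):
        # attenuation falls with energy; ordering water < blood < bone
        for m in library:
            if m.name != "air":
                assert m.mu_low > m.mu_high > 0
        assert library["fat"].mu_low < library["water"].mu_low
        assert library["water"].mu_low < library["blood"].mu_low < library["bone"].mu_low


class TestSolutions:
    def test_zero_concentration_is_water(self, library):
        w = library["water"]
        s = iodine_solution(0.0)
        assert s.mu_low == pytest.approx(w.mu_low)
        assert s.density == pytest.approx(w.density)

    def test_iodine_contrast_falls_with_energy(self):
        s = iodine_solution(5.0)
        w = default_library()["water"]
        assert (s.mu_low - w.mu_low) > (s.mu_high - w.mu_high) > 0

    def test_attenuation_linear_in_concentration(self):
        s2, s5, s10 = (iodine_solution(c) for c in (2.0, 5.0, 10.0))
        w = default_library()["water"]
        # mu(c) is linear: mu(5) interpolates mu(2), mu(10)
        t = (5.0 - 2.0) / (10.0 - 2.0)
        assert s5.mu_low == pytest.approx((1 - t) * s2.mu_low + t * s10.mu_low)

    def test_koh_mass_fraction_consistent(self):
        # the solute mass fraction recomputed from the mixture equals the input
        pct = 30.0
        s = koh_solution(pct)
        rho_k = default_library(include_solutes=True)["koh_solid"].density
        rho_w = 1.0
        f = (s.density - rho_w) / (rho_k - rho_w)  # solute volume fraction
        w = f * rho_k / s.density
        assert w == pytest.approx(pct / 100.0)

    def test_invalid_concentrations(self):
        with pytest.raises(ValueError):
            iodine_solution(-1.0)
        with pytest.raises(ValueError):
            koh_solution(100.0)


class TestHistogram2D:
    def _pair(self, low, high):
        return DectImagePair(low, high, units="mu")

    def test_degenerate_data_single_bin(self):
        low = np.full((2, 2), 0.2)
        high = np.full((2, 2), 0.15)
        h = build_histogram2d(self._pair(low, high), n_bins=4)
        assert h.counts.sum() == 4
        assert (h.counts == 4).sum() == 1

    def test_count_conservation(self):
        low = np.array([[0.1, 0.2], [0.3, 0.4]])
        high = np.array([[0.1, 0.15], [0.2, 0.25]])
        h = build_histogram2d(self._pair(low, high), n_bins=4)
        assert h.counts.sum() == 4

    def test_marginals_match_1d_histograms(self, rng):
        low = rng.uniform(0.1, 0.5, (64, 64))
        high = rng.uniform(0.1, 0.5, (64, 64))
        h = build_histogram2d(self._pair(low, high), n_bins=16)
        assert h.counts.sum() == 64 * 64
        # independent 1-D oracle along each axis
        ref_low, _ = np.histogram(low.ravel(), bins=h.edges_low)
        ref_high, _ = np.histogram(high.ravel(), bins=h.edges_high)
        np.testing.assert_array_equal(h.counts.sum(axis=1), ref_low)
        np.testing.assert_array_equal(h.counts.sum(axis=0), ref_high)

    def test_errors(self):
        with pytest.raises(ValueError):
            build_histogram2d(
                self._pair(np.zeros((2, 2)), np.zeros((2, 2))), n_bins=0
            )
        with pytest.raises(ValueError, match="shape"):
            DectImagePair(np.zeros((2, 2)), np.zeros((3, 3)), units="mu")


def brute_force_agglomerate(coords, radius):
    """Independent oracle: repeatedly try every pair merge (closest first),
    accepting a merge only if all members stay within radius of the
    centroid.  Returns the partition as a set of frozensets of indices."""
    parts = [[i] for i in range(len(coords))]
    changed = True
    while changed:
        changed = False
        best = None
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                ci = coords[parts[i]].mean(axis=0)
                cj = coords[parts[j]].mean(axis=0)
                d = np.linalg.norm(ci - cj)
                merged = parts[i] + parts[j]
                cent = coords[merged].mean(axis=0)
                if np.all(np.linalg.norm(coords[merged] - cent, axis=1) <= radius):
                    if best is None or d < best[0]:
                        best = (d, i, j)
        if best is not None:
            _, i, j = best
            parts[i] = parts[i] + parts[j]
            del parts[j]
            changed = True
    return {frozenset(p) for p in parts}


class TestClustering:
    def test_single_material(self):
        lib = make_lib([(0.2, 0.2)])
        (c,) = cluster_materials(lib, radius=0.05)
        np.testing.assert_allclose(c.agent, [0.2, 0.2])
        assert [m.name for m in c.members] == ["m0"]

    def test_two_far_materials_stay_singletons(self):
        lib = make_lib([(0.0, 0.0), (1.0, 1.0)])
        clusters = cluster_materials(lib, radius=0.1)
        assert len(clusters) == 2

    def test_matches_brute_force_oracle(self):
        coords = np.array(
            [(0.10, 0.10), (0.12, 0.11), (0.30, 0.28), (0.31, 0.30),
             (0.60, 0.55), (0.61, 0.57)]
        )
        lib = make_lib(coords)
        radius = 0.05
        clusters = cluster_materials(lib, radius=radius)
        got = {frozenset(lib.index(m.name) for m in c.members) for c in clusters}
        assert got == brute_force_agglomerate(coords, radius)
        assert len(clusters) == 3

    def test_partition_and_centroid_invariants(self, library):
        clusters = cluster_materials(library)
        names = [m.name for c in clusters for m in c.members]
        assert sorted(names) == sorted(library.names)  # disjoint cover
        for c in clusters:
            np.testing.assert_allclose(c.agent, c.member_coords().mean(axis=0))
            for m in c.members:
                assert np.linalg.norm(m.coord - c.agent) <= c.radius + 1e-12

    def test_order_invariance(self, rng):
        coords = rng.uniform(0, 1, (7, 2))
        lib = make_lib(coords)
        base = {frozenset(m.name for m in c.members)
                for c in cluster_materials(lib, radius=0.2)}
        perm = rng.permutation(7)
        lib2 = MaterialLibrary([lib.materials[i] for i in perm])
        got = {frozenset(m.name for m in c.members)
               for c in cluster_materials(lib2, radius=0.2)}
        assert got == base

    def test_invalid_radius(self, library):
        with pytest.raises(ValueError):
            cluster_materials(library, radius=0.0)


class TestAssignAndUpdate:
    def setup_method(self):
        self.lib = make_lib([(0.0, 0.0), (1.0, 0.0), (0.0, 1.0)])
        self.clusters = cluster_materials(self.lib, radius=0.2)

    def test_point_at_agent(self):
        c = assign_cluster((1.0, 0.0), self.clusters)
        assert [m.name for m in c.members] == ["m1"]

    def test_far_point_unassigned(self):
        assert assign_cluster((5.0, 5.0), self.clusters) is None

    def test_equidistant_tie_breaks_to_lower_index(self):
        from dectmmd.materials import Cluster

        m0, m1 = self.lib.materials[:2]
        wide = [Cluster(agent=m0.coord, members=[m0], radius=0.6),
                Cluster(agent=m1.coord, members=[m1], radius=0.6)]
        c = assign_cluster((0.5, 0.0), wide)  # halfway m0 <-> m1
        assert [m.name for m in c.members] == ["m0"]

    def test_empty_cluster_collection(self):
        with pytest.raises(ValueError):
            assign_cluster((0.0, 0.0), [])

    def test_update_with_no_unassigned_is_identity(self):
        out = update_subgroups(self.lib, self.clusters, [])
        assert out == list(self.clusters)

    def test_update_single_point_makes_singleton(self):
        out = update_subgroups(self.lib, self.clusters, [(5.0, 5.0)])
        assert len(out) == len(self.clusters) + 1
        np.testing.assert_allclose(out[-1].agent, [5.0, 5.0])

    def test_update_two_blobs_two_new_clusters(self, rng):
        blob1 = rng.normal((5.0, 5.0), 0.02, (10, 2))
        blob2 = rng.normal((9.0, 9.0), 0.02, (10, 2))
        pts = np.vstack([blob1, blob2])
        out = update_subgroups(self.lib, self.clusters, pts)
        assert len(out) == len(self.clusters) + 2

    def test_update_then_assign_never_fails(self, rng):
        pts = rng.uniform(-3, 3, (25, 2))
        unassigned = [p for p in pts if assign_cluster(p, self.clusters) is None]
        out = update_subgroups(self.lib, self.clusters, unassigned)
        for p in unassigned:
            assert assign_cluster(p, out) is not None
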