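"""Barycentric solver, pixel/image decomposition and mass-fraction
conversion."""

import numpy as np
import pytest

from dectmmd.decompose import (DegenerateTriangleError, Triangle,
                               decompose_image, decompose_pixel,
                               solve_barycentric, volume_to_mass_fraction)
from dectmmd.images import DectImagePair, hu_to_mu, mu_to_hu
from dectmmd.materials import Material, MaterialLibrary, cluster_materials


class TestHuMuConversion:
    @pytest.mark.parametrize("hu,expected", [(0.0, 1.0), (-1000.0, 0.0), (1000.0, 2.0)])
    def test_anchor_points(self, hu, expected):
        # water -> mu_water, air -> 0, +1000 HU -> twice water
        assert hu_to_mu(np.array(hu), 0.2)[()] == pytest.approx(0.2 * expected)

    def test_round_trip(self, rng):
        img = rng.uniform(-500, 1500, (8, 8))
        np.testing.assert_allclose(mu_to_hu(hu_to_mu(img, 0.22), 0.22), img)

    def test_invalid_mu_water(self):
        with pytest.raises(ValueError):
            hu_to_mu(np.zeros(3), 0.0)


def area(p, q, r):
    return 0.5 * abs((q[0] - p[0]) * (r[1] - p[1]) - (r[0] - p[0]) * (q[1] - p[1]))


class TestSolveBarycentric:
    def test_vertex_and_centroid(self, unit_triangle_materials):
        tri = Triangle(unit_triangle_materials)
        r = solve_barycentric((0.0, 0.0), tri)
        np.testing.assert_allclose(r.fractions, [1, 0, 0], atol=1e-12)
        assert r.inside
        c = tri.coords.mean(axis=0)
        r = solve_barycentric(c, tri)
        np.testing.assert_allclose(r.fractions, [1 / 3] * 3)

    def test_known_interior_point(self, unit_triangle_materials):
        # vertices (0,0), (1,0), (0,1); point (0.25, 0.25)
        r = solve_barycentric((0.25, 0.25), Triangle(unit_triangle_materials))
        np.testing.assert_allclose(r.fractions, [0.5, 0.25, 0.25], atol=1e-12)
        assert r.inside

    def test_exterior_point_signs(self, unit_triangle_materials):
        r = solve_barycentric((1.0, 1.0), Triangle(unit_triangle_materials))
        np.testing.assert_allclose(r.fractions, [-1.0, 1.0, 1.0], atol=1e-12)
        assert not r.inside

    def test_degenerate_triangle_names_vertices(self):
        mats = (Material("p", 1, 0.0, 0.0), Material("q", 1, 0.5, 0.5),
                Material("r", 1, 1.0, 1.0))
        with pytest.raises(DegenerateTriangleError, match="p, q, r"):
            Triangle(mats)

    def test_matches_area_ratio_oracle(self, rng):
        """Interior barycentric coordinates equal sub-triangle area ratios."""
        for _ in range(1000):
            v = rng.uniform(0, 1, (3, 2))
            if area(*v) < 1e-3:
                continue
            w = rng.dirichlet([1, 1, 1])
            p = w @ v
            tri = Triangle(tuple(
                Material(f"m{i}", 1.0, v[i, 0], v[i, 1]) for i in range(3)
            ))
            r = solve_barycentric(p, tri)
            total = area(*v)
            expected = [area(p, v[1], v[2]) / total,
                        area(p, v[0], v[2]) / total,
                        area(p, v[0], v[1]) / total]
            np.testing.assert_allclose(r.fractions, expected, atol=1e-9)

    def test_sum_to_one_even_outside(self, rng, unit_triangle_materials):
        tri = Triangle(unit_triangle_materials)
        for p in rng.uniform(-3, 3, (200, 2)):
            r = solve_barycentric(p, tri)
            assert r.fractions.sum() == pytest.approx(1.0, abs=1e-9)


class TestMassFractions:
    def test_pure_material(self):
        lib = MaterialLibrary([Material("a", 1.0, 0.1, 0.1),
                               Material("b", 2.0, 0.2, 0.15)])
        np.testing.assert_allclose(
            volume_to_mass_fraction(np.array([1.0, 0.0]), lib), [1, 0]
        )

    def test_equal_volumes_density_ratio(self):
        lib = MaterialLibrary([Material("a", 1.0, 0.1, 0.1),
                               Material("b", 2.0, 0.2, 0.15)])
        np.testing.assert_allclose(
            volume_to_mass_fraction(np.array([0.5, 0.5]), lib), [1 / 3, 2 / 3]
        )

    def test_arithmetic_oracle(self):
        lib = MaterialLibrary([Material("a", 1.0, 0.1, 0.1),
                               Material("b", 1.05, 0.2, 0.15),
                               Material("c", 0.92, 0.3, 0.25)])
        alpha = np.array([0.2, 0.5, 0.3])
        m = volume_to_mass_fraction(alpha, lib)
        weights = [0.2 * 1.0, 0.5 * 1.05, 0.3 * 0.92]
        expected = np.array(weights) / sum(weights)
        np.testing.assert_allclose(m, expected)
        assert m.sum() == pytest.approx(1.0)

    def test_zero_weighting_rejected(self):
        lib = MaterialLibrary([Material("a", 1.0, 0.1, 0.1),
                               Material("b", 2.0, 0.2, 0.15)])
        with pytest.raises(ValueError):
            volume_to_mass_fraction(np.zeros(2), lib)


class TestDecomposePixel:
    def test_point_at_material_coordinate(self, abdomen_lib):
        clusters = cluster_materials(abdomen_lib)
        fr, _ = decompose_pixel(abdomen_lib["blood"].coord, clusters, abdomen_lib)
        expected = np.zeros(len(abdomen_lib))
        expected[abdomen_lib.index("blood")] = 1.0
        np.testing.assert_allclose(fr, expected, atol=1e-9)

    def test_point_on_segment_midpoint(self, abdomen_lib):
        clusters = cluster_materials(abdomen_lib)
        mid = 0.5 * (abdomen_lib["blood"].coord + abdomen_lib["fat"].coord)
        fr, _ = decompose_pixel(mid, clusters, abdomen_lib)
        assert fr[abdomen_lib.index("blood")] == pytest.approx(0.5, abs=1e-9)
        assert fr[abdomen_lib.index("fat")] == pytest.approx(0.5, abs=1e-9)

    def test_forward_model_round_trip(self, abdomen_lib):
        clusters = cluster_materials(abdomen_lib)
        p = 0.3 * abdomen_lib["blood"].coord + 0.7 * abdomen_lib["fat"].coord
        fr, tri = decompose_pixel(p, clusters, abdomen_lib)
        assert fr[abdomen_lib.index("blood")] == pytest.approx(0.3, abs=1e-9)
        assert fr[abdomen_lib.index("fat")] == pytest.approx(0.7, abs=1e-9)
        assert {"blood", "fat"} <= set(tri.names)


class TestDecomposeImage:
    def _pure_block_pair(self, lib):
        labels = np.repeat(np.arange(len(lib)), 16).reshape(8, -1)[:, :8]
        coords = lib.coords[labels]
        return labels, DectImagePair(coords[..., 0], coords[..., 1], units="mu")

    def test_pure_blocks_argmax_recovers_labels(self, abdomen_lib):
        labels, pair = self._pure_block_pair(abdomen_lib)
        vfm = decompose_image(pair, abdomen_lib)
        np.testing.assert_array_equal(vfm.argmax_labels(), labels)

    def test_constant_water_image(self, library):
        qa = library.subset(["air", "water", "acrylic", "teflon"])
        pair = DectImagePair(np.zeros((6, 6)), np.zeros((6, 6)), units="hu")
        vfm = decompose_image(pair, qa)
        np.testing.assert_allclose(vfm.fraction_image("water"), 1.0, atol=1e-9)

    def test_chunked_execution_bit_identical(self, rng, abdomen_lib):
        low = rng.uniform(-1000, 1500, (32, 32))
        high = rng.uniform(-1000, 1200, (32, 32))
        pair = DectImagePair(low, high, units="hu")
        serial = decompose_image(pair, abdomen_lib, n_chunks=1)
        chunked = decompose_image(pair, abdomen_lib, n_chunks=5)
        np.testing.assert_array_equal(serial.fractions, chunked.fractions)
        np.testing.assert_array_equal(serial.outside_hull, chunked.outside_hull)

    def test_pixel_invariants_under_noise(self, rng, abdomen_lib):
        low = rng.uniform(-1100, 1800, (16, 16))
        high = rng.uniform(-1100, 1500, (16, 16))
        pair = DectImagePair(low, high, units="hu")
        vfm = decompose_image(pair, abdomen_lib)
        f = vfm.fractions
        assert np.all(f >= 0) and np.all(f <= 1)
        np.testing.assert_allclose(f.sum(axis=-1), 1.0, atol=1e-9)
        assert int((f > 1e-9).sum(axis=-1).max()) <= 3

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            DectImagePair(np.zeros((4, 4)), np.zeros((4, 5)), units="mu")
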