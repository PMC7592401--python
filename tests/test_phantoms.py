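"""Synthetic phantom geometry, forward rendering and ground truth."""

import numpy as np
import pytest

from dectmmd import decompose_image
from dectmmd import phantoms as ph
from dectmmd.images import WATER_MU
from dectmmd.phantoms import (PhantomShape, PhantomSpec, make_abdomen,
                              make_angio_phantom, make_qa_body, make_qa_head,
                              render_composition, render_dect)


class TestPhantomSpecValidation:
    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PhantomShape("circle", (0, 0), (10,), {"water": 0.7})

    def test_shape_must_fit_grid(self):
        big = PhantomShape("circle", (0, 0), (300,), {"water": 1.0})
        with pytest.raises(ValueError, match="fit"):
            PhantomSpec("x", (64, 64), 1.0, "air", [big])


class TestAngioPhantom:
    def test_vial_count_cap(self):
        with pytest.raises(ValueError):
            make_angio_phantom([1] * 7, [5] * 6)

    def test_zero_concentration_vials_match_water(self):
        spec = make_angio_phantom([0.0], [0.0], grid=128, spacing_mm=1.0)
        lib = ph.angio_render_library()
        truth = render_composition(spec, lib)
        mu = truth @ np.array([m.mu_low for m in lib.materials])
        # inside the water bore (away from the shell) everything is water-like
        bore = spec.roi_mask(0, 0, 45.0)
        np.testing.assert_allclose(mu[bore], lib["water"].mu_low, rtol=1e-12)

    def test_single_iodine_vial_contrast_ordering(self):
        spec = make_angio_phantom([5.0], [], grid=128, spacing_mm=1.0)
        lib = ph.angio_render_library()
        pair = render_dect(spec, lib)
        mu = pair.to_mu()
        v = spec.extras["vials"][0]
        mask = spec.roi_mask(*v["center"], 4.0)
        d_low = mu.image_low[mask].mean() - lib["water"].mu_low
        d_high = mu.image_high[mask].mean() - lib["water"].mu_high
        assert d_low > d_high > 0  # iodine contrast falls with energy

    def test_default_layout_geometry(self):
        spec = make_angio_phantom()
        vials = spec.extras["vials"]
        assert len(vials) == 12
        assert all(v["diameter"] == 12.0 for v in vials)
        centers = np.array([v["center"] for v in vials])
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 12.0  # disjoint 12 mm vials

    def test_lowest_default_concentrations(self):
        spec = make_angio_phantom()
        vials = spec.extras["vials"]
        assert min(v["concentration"] for v in vials if v["kind"] == "koh") == 5.0
        assert min(v["concentration"] for v in vials if v["kind"] == "iodine") == 1.0


class TestQaPhantoms:
    def test_head_pin_areas_scale_quadratically(self):
        spec = make_qa_head([1.0, 2.0, 3.0])
        lib = ph.qa_library()
        truth = render_composition(spec, lib)
        air = truth[..., lib.index("air")].copy()
        # subtract exterior air: count air coverage inside each pin disk
        areas = []
        for pin in spec.extras["pins"]:
            mask = spec.roi_mask(*pin["center"], pin["diameter"] / 2 + 1.0)
            areas.append(air[mask].sum())
        ratios = np.array(areas) / areas[0]
        np.testing.assert_allclose(ratios, [1.0, 4.0, 9.0], rtol=0.05)

    def test_pin_diameter_range_enforced(self):
        with pytest.raises(ValueError):
            make_qa_head([0.2])
        with pytest.raises(ValueError):
            make_qa_head([6.0])

    def test_body_inserts_are_pure(self):
        spec = make_qa_body()
        for s in spec.shapes:
            assert max(s.composition.values()) == 1.0


class TestAbdomenPhantom:
    def test_truth_sums_to_one_everywhere(self):
        spec = make_abdomen(grid=128, spacing_mm=2.5)
        truth = render_composition(spec, ph.abdomen_library())
        np.testing.assert_allclose(truth.sum(axis=-1), 1.0, atol=1e-12)

    def test_bone_contrast_falls_with_energy(self):
        spec = make_abdomen()
        pair = render_dect(spec, ph.abdomen_library())
        lib = ph.abdomen_library()
        bone = pair.truth_fractions[..., lib.index("bone")] > 0.999
        assert pair.image_low[bone].mean() > pair.image_high[bone].mean() > 0

    def test_exterior_is_pure_air(self):
        spec = make_abdomen()
        lib = ph.abdomen_library()
        truth = render_composition(spec, lib)
        corner = truth[:10, :10, :]
        np.testing.assert_allclose(corner[..., lib.index("air")], 1.0)

    def test_rois_sit_in_pure_regions(self):
        spec = make_abdomen()
        lib = ph.abdomen_library()
        truth = render_composition(spec, lib)
        for mat, disks in spec.rois.items():
            assert len(disks) == 8
            for cx, cy, r in disks:
                m = spec.roi_mask(cx, cy, r)
                assert (truth[..., lib.index(mat)][m] > 0.999).all()


class TestRenderDect:
    def test_pure_water_renders_zero_hu(self):
        shape = PhantomShape("circle", (0, 0), (40,), {"water": 1.0})
        spec = PhantomSpec("w", (64, 64), 1.0, "water", [shape])
        pair = render_dect(spec, ph.qa_library())
        np.testing.assert_allclose(pair.image_low, 0.0, atol=1e-10)
        np.testing.assert_allclose(pair.image_high, 0.0, atol=1e-10)

    def test_same_seed_is_reproducible(self):
        spec = make_qa_head()
        lib = ph.qa_library()
        a = render_dect(spec, lib, noise_sigma_hu=(8, 8), seed=42)
        b = render_dect(spec, lib, noise_sigma_hu=(8, 8), seed=42)
        np.testing.assert_array_equal(a.image_low, b.image_low)
        np.testing.assert_array_equal(a.image_high, b.image_high)

    def test_noise_sd_calibrated(self):
        spec = PhantomSpec("w", (128, 128), 1.0, "water", [])
        pair = render_dect(spec, ph.qa_library(), noise_sigma_hu=(12.0, 6.0), seed=1)
        assert abs(pair.image_low.std() - 12.0) / 12.0 < 0.1
        assert abs(pair.image_high.std() - 6.0) / 6.0 < 0.1

    def test_unknown_material_rejected(self):
        shape = PhantomShape("circle", (0, 0), (10,), {"kryptonite": 1.0})
        spec = PhantomSpec("x", (32, 32), 1.0, "water", [shape])
        with pytest.raises(KeyError):
            render_dect(spec, ph.qa_library())

    def test_noiseless_round_trip(self):
        spec = make_abdomen(grid=128, spacing_mm=2.5)
        lib = ph.abdomen_library()
        pair = render_dect(spec, lib, noise_sigma_hu=(0, 0), seed=0)
        vfm = decompose_image(pair, lib)
        mae = np.abs(vfm.fractions - pair.truth_fractions).mean()
        assert mae < 1e-6
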