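"""Vessel imaging: segmentation, extraction, synthetic fixtures, round trips."""

import numpy as np
import pytest
import shapely
from shapely.geometry import Point

from ipchemo import imaging as im
from ipchemo.errors import (
    GeometryInfeasibleError,
    NoForegroundError,
    NoVesselsError,
    UnderResolvedError,
)


def dice(a, b):
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


class TestBinarize:
    def test_constant_image_otsu_is_error(self):
        img = im.RasterImage(np.full((20, 20), 0.5), 0.01)
        with pytest.raises(NoForegroundError):
            im.equalize_and_binarize(img, "otsu")

    def test_constant_image_fixed_gives_background(self):
        img = im.RasterImage(np.full((20, 20), 0.5), 0.01)
        assert not im.equalize_and_binarize(img, "fixed").any()

    def test_two_level_image_recovers_exact_foreground(self):
        px = np.where(np.arange(400).reshape(20, 20) % 7 == 0, 255.0, 0.0)
        img = im.RasterImage(px, 0.01)
        mask = im.equalize_and_binarize(img, smooth_sigma_px=0)
        assert np.array_equal(mask, px == 255.0)

    def test_idempotent_on_binary_images(self):
        rng = np.random.default_rng(3)
        px = (rng.random((40, 40)) > 0.8).astype(float)
        img = im.RasterImage(px, 0.01)
        mask1 = im.equalize_and_binarize(img, smooth_sigma_px=0)
        mask2 = im.equalize_and_binarize(
            im.RasterImage(mask1.astype(float), 0.01), smooth_sigma_px=0
        )
        assert np.array_equal(mask1, mask2)

    def test_invalid_policy_rejected(self):
        img = im.RasterImage(np.eye(5), 0.01)
        with pytest.raises(ValueError):
            im.equalize_and_binarize(img, "median")


class TestExtract:
    def test_rectangle_area(self):
        mask = np.zeros((20, 30), dtype=bool)
        mask[5:7, 10:20] = True  # 10 x 2 px
        net = im.extract_vessel_network(mask, pixel_size=0.01)
        assert len(net.polygons) == 1
        assert net.total_area == pytest.approx(0.002, rel=0.10)

    def test_min_area_filters_small_blob(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:15, 5:15] = True          # 100 px
        mask[30:32, 30:32] = True        # 4 px
        net = im.extract_vessel_network(mask, 0.01, min_area=10 * 0.01**2)
        assert len(net.polygons) == 1

    def test_empty_mask_is_error(self):
        with pytest.raises(NoVesselsError):
            im.extract_vessel_network(np.zeros((10, 10), dtype=bool), 0.01)


class TestSyntheticNetwork:
    def test_terminal_counts_and_containment(self):
        net = im.generate_synthetic_network(5, 6, (2.425, 1.755), 0.05, seed=7)
        assert len(net.terminals) == 11
        assert len(net.inlets) == 5 and len(net.outlets) == 6
        assert [t.label for t in net.inlets] == [f"Inlet{i}" for i in range(1, 6)]
        ellipse = shapely.affinity.scale(Point(0, 0).buffer(1.0, quad_segs=64), 2.425, 1.755)
        assert all(p.within(ellipse) for p in net.polygons)
        net.validate_terminals()

    def test_degenerate_single_channel(self):
        net = im.generate_synthetic_network(1, 1, (2.0, 1.5), 0.06, seed=0)
        assert len(net.polygons) == 1
        assert len(net.terminals) == 2

    def test_deterministic_given_seed(self):
        a = im.generate_synthetic_network(3, 4, (2.425, 1.755), 0.05, seed=11)
        b = im.generate_synthetic_network(3, 4, (2.425, 1.755), 0.05, seed=11)
        for p, q in zip(a.polygons, b.polygons):
            assert np.array_equal(np.asarray(p.exterior.coords), np.asarray(q.exterior.coords))

    def test_infeasible_width_is_error(self):
        with pytest.raises(GeometryInfeasibleError):
            im.generate_synthetic_network(5, 6, (2.425, 1.755), 2.0, seed=0)

    def test_infeasible_terminal_packing_is_error(self):
        with pytest.raises(GeometryInfeasibleError):
            im.generate_synthetic_network(40, 40, (1.0, 0.8), 0.08, seed=0)


class TestRasterize:
    def test_empty_network_all_background(self):
        img, mask = im.rasterize_network(im.VesselNetwork(polygons=[]), 0.01)
        assert not mask.any()
        assert np.ptp(img.pixels) == 0

    def test_foreground_pixel_count_matches_area(self):
        net = im.generate_synthetic_network(1, 1, (2.0, 1.5), 0.1, seed=2)
        img, mask = im.rasterize_network(net, 0.01)
        expected = net.total_area / 0.01**2
        assert mask.sum() == pytest.approx(expected, rel=0.05)

    def test_under_resolved_is_error(self):
        net = im.generate_synthetic_network(1, 1, (2.0, 1.5), 0.05, seed=2)
        with pytest.raises(UnderResolvedError):
            im.rasterize_network(net, pixel_size=0.04)


class TestRoundTrip:
    @pytest.mark.parametrize("seed,n_in,n_out", [(1, 1, 2), (7, 5, 6)])
    def test_generate_rasterize_binarize_extract(self, seed, n_in, n_out):
        """Segmentation recovers the generator's own ground truth."""
        net = im.generate_synthetic_network(n_in, n_out, (2.425, 1.755), 0.05, seed=seed)
        img, gt = im.rasterize_network(net, 0.01, noise_sigma=0.05, seed=seed)
        mask = im.equalize_and_binarize(img)
        assert dice(mask, gt) >= 0.95
        rec = im.extract_vessel_network(mask, 0.01, min_area=0.001, origin=img.origin)
        assert len(rec.polygons) == len(net.polygons)
        assert rec.total_area == pytest.approx(net.total_area, rel=0.10)

    def test_network_json_round_trip(self, tmp_path, network):
        path = tmp_path / "net.json"
        im.write_network(network, path)
        back = im.read_network(path)
        assert len(back.polygons) == len(network.polygons)
        assert back.total_area == pytest.approx(network.total_area, rel=1e-9)
        assert [t.label for t in back.terminals] == [t.label for t in network.terminals]
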