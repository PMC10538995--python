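"""Tests of capillary detection, the contact graph, the morphometric panel and
diffusion distances, each against brute-force geometric oracles."""

import numpy as np
import pytest
from shapely.geometry import Point

import fiberredox as fr
from fiberredox.capillary_morphometry import (
    CapillaryMap,
    DiffusionRegressionCoefficients,
)
from fiberredox.types import ChannelImage, roi_from_mask


def _channel(arr, channel="CAP", pixel_size=1.0):
    return ChannelImage(np.asarray(arr, dtype=float), channel=channel,
                        pixel_size=pixel_size)


def _square_roi(fiber_id, r0, c0, size, shape, pixel_size=1.0):
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r0 + size, c0:c0 + size] = True
    return roi_from_mask(fiber_id, mask, pixel_size)


def brute_force_distances(roi, capillaries):
    """Per-pixel nearest-capillary distance by explicit enumeration (px)."""
    pix = roi.coords[:, ::-1].astype(float)  # (x, y)
    caps = np.asarray(capillaries, dtype=float)
    d = np.sqrt(((pix[:, None, :] - caps[None, :, :]) ** 2).sum(axis=2))
    return d.min(axis=1)


class TestDetection:
    def test_detected_set_equals_planted_at_zero_noise(self, noiseless_section):
        imgs, truth = noiseless_section
        detected = fr.detect_capillaries(imgs["CAP"])
        assert len(detected) == len(truth.capillaries)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(truth.capillaries).query(detected)
        assert d.max() < 1.0  # centroids within one pixel of planted centers

    def test_blank_channel_yields_empty_list(self):
        assert len(fr.detect_capillaries(_channel(np.zeros((50, 50))))) == 0

    def test_merged_blobs_yield_one_detection_with_warning(self):
        from skimage.draw import disk

        img = np.zeros((40, 40))
        for c in (18, 22):  # two 4 µm blobs overlapping
            rr, cc = disk((20, c), 2.5)
            img[rr, cc] = 900.0
        with pytest.warns(UserWarning, match="merged"):
            coords = fr.detect_capillaries(_channel(img), threshold=100.0,
                                           min_diameter_um=2.0,
                                           max_diameter_um=5.0)
        assert len(coords) == 1

    def test_nuclei_count_exact_on_section(self, noiseless_section):
        imgs, truth = noiseless_section
        nuc = fr.nuclei_count(imgs["DAPI"])
        assert len(nuc) == len(truth.nuclei)

    def test_blank_dapi_yields_zero_nuclei(self):
        assert len(fr.nuclei_count(_channel(np.zeros((50, 50)), "DAPI"))) == 0


class TestContactGraph:
    def test_capillary_at_three_fiber_junction_has_degree_three(self):
        shape = (62, 62)
        fibers = [
            _square_roi(1, 2, 2, 28, shape),
            _square_roi(2, 2, 32, 28, shape),
            _square_roi(3, 32, 2, 28, shape),
        ]
        cap = np.array([[31.0, 31.0]])  # at the shared corner region
        cmap = fr.build_contact_graph(fibers, cap, contact_tolerance_um=3.0,
                                      pixel_size=1.0)
        assert len(cmap.edges) == 3

    def test_interior_capillary_has_degree_one(self):
        shape = (62, 62)
        fibers = [_square_roi(1, 2, 2, 28, shape), _square_roi(2, 2, 32, 28, shape)]
        cap = np.array([[10.0, 10.0]])  # inside fiber 1
        cmap = fr.build_contact_graph(fibers, cap, contact_tolerance_um=1.5,
                                      pixel_size=1.0)
        assert cmap.edges == [(0, 1)]

    def test_graph_invariant_under_fiber_relabeling(self):
        shape = (62, 62)
        f1 = _square_roi(1, 2, 2, 28, shape)
        f2 = _square_roi(2, 2, 32, 28, shape)
        caps = np.array([[30.5, 10.0], [10.0, 10.0]])
        g12 = fr.build_contact_graph([f1, f2], caps, 2.0, pixel_size=1.0)
        f1b = _square_roi(7, 2, 2, 28, shape)
        f2b = _square_roi(5, 2, 32, 28, shape)
        g75 = fr.build_contact_graph([f1b, f2b], caps, 2.0, pixel_size=1.0)
        relabel = {1: 7, 2: 5}
        assert sorted((c, relabel[f]) for c, f in g12.edges) == sorted(g75.edges)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError, match="tolerance"):
            fr.build_contact_graph([], np.empty((0, 2)), -1.0, pixel_size=1.0)

    def test_handshake_identity_on_sections(self):
        """Sum of capillary degrees = sum of fiber degrees = number of edges."""
        for seed in (0, 1):
            params = fr.SectionParams(n_fibers=60, image_size=(384, 384),
                                      seed=seed)
            imgs, truth = fr.generate_section(params)
            rois = fr.segment_fibers(imgs["MHC1"], imgs["MHC2a"], imgs["Fp"],
                                     min_area_um2=200.0)
            caps = fr.detect_capillaries(imgs["CAP"])
            cmap = fr.build_contact_graph(rois, caps, 1.5,
                                          pixel_size=params.pixel_size)
            assert cmap.capillary_degree().sum() == len(cmap.edges)
            assert sum(cmap.fiber_degree().values()) == len(cmap.edges)


class TestPanel:
    def _two_fiber_fixture(self):
        """2 fibers, 4 capillaries, 0.01 mm^2, contact degrees (3, 2)."""
        caps = np.zeros((4, 2))
        edges = [(0, 1), (1, 1), (2, 1), (2, 2), (3, 2)]
        shape = (110, 110)
        f1 = _square_roi(1, 5, 5, 50, shape)
        f2 = _square_roi(2, 5, 60, 40, shape)
        cmap = CapillaryMap(capillaries=caps, edges=edges, area_mm2=0.01,
                            fiber_ids=[1, 2])
        return cmap, [f1, f2]

    def test_hand_countable_two_fiber_fixture(self):
        cmap, fibers = self._two_fiber_fixture()
        panel = fr.capillary_panel(cmap, fibers)
        assert panel.capillary_density == pytest.approx(400.0)
        assert panel.cf_ratio == pytest.approx(2.0)
        assert panel.cc == pytest.approx(2.5)
        assert panel.sharing_factor == pytest.approx(1.25)
        # CC/FA by hand: (3/2500 + 2/1600)/2 * 1000
        assert panel.cc_per_fa == pytest.approx((3 / 2500 + 2 / 1600) / 2 * 1000)

    def test_no_capillaries_reports_missing_sf(self):
        shape = (40, 40)
        cmap = CapillaryMap(np.empty((0, 2)), [], 0.01, [1])
        panel = fr.capillary_panel(cmap, [_square_roi(1, 5, 5, 20, shape)])
        assert panel.capillary_density == 0.0
        assert panel.cf_ratio == 0.0
        assert panel.cc == 0.0
        assert np.isnan(panel.sharing_factor)

    def test_duplicating_capillaries_doubles_counts_not_sf(self):
        cmap, fibers = self._two_fiber_fixture()
        doubled = CapillaryMap(
            capillaries=np.vstack([cmap.capillaries, cmap.capillaries]),
            edges=cmap.edges + [(c + 4, f) for c, f in cmap.edges],
            area_mm2=cmap.area_mm2,
            fiber_ids=cmap.fiber_ids,
        )
        p1 = fr.capillary_panel(cmap, fibers)
        p2 = fr.capillary_panel(doubled, fibers)
        assert p2.capillary_density == pytest.approx(2 * p1.capillary_density)
        assert p2.cf_ratio == pytest.approx(2 * p1.cf_ratio)
        assert p2.cc == pytest.approx(2 * p1.cc)
        assert p2.sharing_factor == pytest.approx(p1.sharing_factor)

    def test_zero_fibers_rejected(self):
        cmap = CapillaryMap(np.zeros((1, 2)), [], 0.01, [])
        with pytest.raises(ValueError, match="fibers"):
            fr.capillary_panel(cmap, [])

    def test_panel_matches_enumeration_on_sections(self):
        """CD, C:F, CC, SF, CC/FA equal brute-force enumeration over the
        contact graph on simulated sections."""
        for seed in (3, 4):
            params = fr.SectionParams(n_fibers=60, image_size=(384, 384),
                                      seed=seed)
            imgs, truth = fr.generate_section(params)
            rois = fr.segment_fibers(imgs["MHC1"], imgs["MHC2a"], imgs["Fp"],
                                     min_area_um2=200.0)
            caps = fr.detect_capillaries(imgs["CAP"])
            cmap = fr.build_contact_graph(rois, caps, 1.5,
                                          pixel_size=params.pixel_size)
            panel = fr.capillary_panel(cmap, rois)
            deg = {f.fiber_id: 0 for f in rois}
            for _, f in cmap.edges:
                deg[f] += 1
            assert panel.cc == pytest.approx(np.mean(list(deg.values())))
            assert panel.cf_ratio == pytest.approx(len(caps) / len(rois))
            assert panel.capillary_density == pytest.approx(
                len(caps) / cmap.area_mm2)
            assert panel.sharing_factor == pytest.approx(
                panel.cc / panel.cf_ratio)
            expected_ccfa = np.mean(
                [deg[f.fiber_id] / f.area_um2 for f in rois]) * 1000
            assert panel.cc_per_fa == pytest.approx(expected_ccfa)


class TestDiffusionDistances:
    def test_square_fiber_central_capillary_matches_oracle(self):
        shape = (60, 60)
        roi = _square_roi(1, 10, 10, 41, shape)
        caps = np.array([[30.0, 30.0]])
        mx, av = fr.diffusion_distances_geometric(roi, caps, shape, 1.0)
        d = brute_force_distances(roi, caps)
        assert av == pytest.approx(np.percentile(d, 50), abs=1.0)
        assert mx == pytest.approx(np.percentile(d, 95), abs=1.0)

    def test_capillary_at_every_boundary_pixel_bounds_avg_dd(self):
        shape = (60, 60)
        size = 41
        roi = _square_roi(1, 10, 10, size, shape)
        boundary = roi.coords[
            (roi.coords[:, 0].min() == roi.coords[:, 0])
            | (roi.coords[:, 0] == roi.coords[:, 0].max())
            | (roi.coords[:, 1] == roi.coords[:, 1].min())
            | (roi.coords[:, 1] == roi.coords[:, 1].max())
        ]
        caps = boundary[:, ::-1].astype(float)
        _, av = fr.diffusion_distances_geometric(roi, caps, shape, 1.0)
        inradius = size / 2
        assert av <= inradius / 2 + 1.0

    def test_translation_invariance(self):
        shape = (80, 80)
        roi_a = _square_roi(1, 5, 5, 30, shape)
        roi_b = _square_roi(1, 25, 35, 30, shape)
        caps_a = np.array([[12.0, 10.0]])
        caps_b = caps_a + np.array([[30.0, 20.0]])  # same shift as the fiber
        da = fr.diffusion_distances_geometric(roi_a, caps_a, shape, 1.0)
        db = fr.diffusion_distances_geometric(roi_b, caps_b, shape, 1.0)
        assert da == pytest.approx(db, abs=1e-9)

    def test_agrees_with_brute_force_on_random_fixtures(self):
        """Distance-transform percentiles match per-pixel enumeration within
        1 px * pixel_size on random fiber/capillary layouts; max >= avg."""
        rng = np.random.default_rng(123)
        shape = (90, 90)
        px = 0.8
        for _ in range(10):
            r0, c0 = rng.integers(5, 30, 2)
            size = int(rng.integers(20, 50))
            roi = _square_roi(1, r0, c0, size, shape, pixel_size=px)
            n_caps = int(rng.integers(1, 8))
            caps = rng.uniform(5, 85, size=(n_caps, 2))
            mx, av = fr.diffusion_distances_geometric(roi, caps, shape, px)
            d = brute_force_distances(roi, caps) * px
            assert av == pytest.approx(np.percentile(d, 50), abs=1.0 * px)
            assert mx == pytest.approx(np.percentile(d, 95), abs=1.0 * px)
            assert mx >= av

    def test_no_capillaries_reported_missing(self):
        roi = _square_roi(1, 5, 5, 20, (40, 40))
        mx, av = fr.diffusion_distances_geometric(roi, np.empty((0, 2)),
                                                  (40, 40), 1.0)
        assert np.isnan(mx) and np.isnan(av)


class TestDiffusionRegression:
    def test_disabled_without_coefficients(self):
        with pytest.raises(ValueError, match="disabled"):
            fr.diffusion_distances_regression(2.0, 5000.0)

    def test_constant_form_returns_constant(self):
        c = DiffusionRegressionCoefficients(a=42.0, b=0.0)
        mx, av = fr.diffusion_distances_regression(2.0, 5000.0, c, c)
        assert mx == 42.0 and av == 42.0

    def test_monotone_in_fiber_area(self):
        cmax = DiffusionRegressionCoefficients(a=0.415, b=0.477, power=0.5)
        cavg = DiffusionRegressionCoefficients(a=0.207, b=0.232, power=0.5)
        prev = -np.inf
        for fa in (1000.0, 3000.0, 5000.0, 8000.0):
            mx, _ = fr.diffusion_distances_regression(2.3, fa, cmax, cavg)
            assert mx >= prev
            prev = mx
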