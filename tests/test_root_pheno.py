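import numpy as np
import pytest

from rootscreen.plate_core import PlantId, PlateGeometry
from rootscreen.root_pheno import (
    GraphParams,
    binarize_root_image,
    build_root_graph,
    build_root_graphs,
    classify_root_orders,
    depth_profile,
    load_graph,
    measure_traits,
    save_graph,
    split_polyline_by_depth,
)
from rootscreen.synth_plate import (
    SimParams,
    rasterize_truth,
    render_root_image,
    simulate_root_system,
)

from conftest import analyze_simulated_plant


def vertical_stroke_mask(geom, length_mm, width_px=3, x_mm=None):
    mask = np.zeros((geom.height_px + 1, geom.width_px + 1), dtype=bool)
    col = int(round((x_mm if x_mm is not None else
                     geom.root_window_width_mm / 2) * geom.px_per_mm))
    n = int(round(length_mm * geom.px_per_mm))
    half = width_px // 2
    mask[0:n + 1, col - half:col + half + 1] = True
    return mask


class TestBinarize:
    def test_blank_image_empty_mask_with_warning(self):
        with pytest.warns(UserWarning):
            mask = binarize_root_image(np.full((32, 32), 7.0))
        assert not mask.any()

    def test_noise_free_rendering_recovered_exactly(self, geom1):
        truth = simulate_root_system(SimParams(rng_seed=2),
                                     PlantId("t", 0), 9, geom1, "Amb-Ctl")
        img, _ = render_root_image(truth, geom1, noise_sd=0.0, rng=0)
        np.testing.assert_array_equal(binarize_root_image(img),
                                      rasterize_truth(truth, geom1, 3))

    def test_inverted_polarity(self, geom1):
        truth = simulate_root_system(SimParams(rng_seed=2),
                                     PlantId("t", 0), 9, geom1, "Amb-Ctl")
        img, _ = render_root_image(truth, geom1, noise_sd=0.0, invert=True,
                                   rng=0)
        np.testing.assert_array_equal(
            binarize_root_image(img, polarity="dark"),
            rasterize_truth(truth, geom1, 3))

    def test_noisy_rendering_f1(self, geom1):
        truth = simulate_root_system(SimParams(rng_seed=4),
                                     PlantId("t", 0), 12, geom1, "Amb-Ctl")
        img, _ = render_root_image(truth, geom1, noise_sd=0.18, rng=7)
        mask = binarize_root_image(img)
        ref = rasterize_truth(truth, geom1, 3)
        tp = (mask & ref).sum()
        f1 = 2 * tp / (2 * tp + (mask & ~ref).sum() + (~mask & ref).sum())
        assert f1 >= 0.95


class TestGraphBuilding:
    def test_single_vertical_stroke_one_edge_length_1pct(self, geom1):
        mask = vertical_stroke_mask(geom1, 80.0)
        g = build_root_graph(mask, geom1)
        assert len(g.edges) == 1
        assert g.length_cm() == pytest.approx(8.0, rel=0.01)

    def test_t_junction_topology(self, geom1):
        mask = vertical_stroke_mask(geom1, 80.0)
        row = int(40 * geom1.px_per_mm)
        col = int(50 * geom1.px_per_mm)
        mask[row - 1:row + 2, col:col + int(20 * geom1.px_per_mm)] = True
        g = build_root_graph(mask, geom1)
        junctions = [n for n in g.graph.nodes if g.graph.degree(n) >= 3]
        assert len(junctions) == 1
        assert len(g.edges) == 3

    def test_detached_speck_excluded_as_debris(self, geom1):
        mask = vertical_stroke_mask(geom1, 50.0)
        mask[600:604, 40:44] = True  # far from the hole
        with pytest.warns(UserWarning):
            graphs = build_root_graphs(mask, geom1)
        assert list(graphs) == [0]
        pts = graphs[0].all_points()
        assert pts[:, 0].max() < 500  # speck pixels not in the plant graph

    def test_nothing_near_hole_raises(self, geom1):
        mask = np.zeros((geom1.height_px + 1, geom1.width_px + 1), bool)
        mask[600:650, 40:43] = True
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                build_root_graph(mask, geom1)


class TestClassification:
    def test_unbranched_root_is_all_primary(self, geom1):
        g = build_root_graph(vertical_stroke_mask(geom1, 60.0), geom1)
        classify_root_orders(g)
        tr = measure_traits(g, dai=9)
        assert tr.n_lat1 == tr.n_lat2 == 0
        assert tr.length_total_cm == pytest.approx(tr.length_primary_cm)
        assert np.isnan(tr.branching_angle_deg)

    def test_constructed_two_level_branching(self, geom1):
        ppm = geom1.px_per_mm
        mask = vertical_stroke_mask(geom1, 100.0)
        col = int(50 * ppm)
        # three laterals off the primary; the middle one carries two children
        for depth_mm in (30, 50, 70):
            row = int(depth_mm * ppm)
            mask[row - 1:row + 2, col:col + int(25 * ppm)] = True
        for dx_mm in (8, 16):
            c2 = col + int(dx_mm * ppm)
            row = int(50 * ppm)
            mask[row:row + int(10 * ppm), c2 - 1:c2 + 2] = True
        g = build_root_graph(mask, geom1)
        classify_root_orders(g)
        tr = measure_traits(g, dai=9)
        assert tr.n_lat1 == 3
        assert tr.n_lat2 == 2

    def test_right_angle_lateral_measures_ninety_degrees(self, geom1):
        mask = vertical_stroke_mask(geom1, 80.0)
        row, col = int(40 * geom1.px_per_mm), int(50 * geom1.px_per_mm)
        mask[row - 1:row + 2, col:col + int(20 * geom1.px_per_mm)] = True
        g = build_root_graph(mask, geom1)
        classify_root_orders(g)
        tr = measure_traits(g, dai=9)
        assert tr.branching_angle_deg == pytest.approx(90.0, abs=3.0)

    def test_vertical_reference_angle_option(self, geom1):
        mask = vertical_stroke_mask(geom1, 80.0)
        row, col = int(40 * geom1.px_per_mm), int(50 * geom1.px_per_mm)
        mask[row - 1:row + 2, col:col + int(20 * geom1.px_per_mm)] = True
        params = GraphParams(angle_reference="vertical")
        g = build_root_graph(mask, geom1, params)
        classify_root_orders(g, params)
        tr = measure_traits(g, geom1, params, dai=9)
        assert tr.branching_angle_deg == pytest.approx(90.0, abs=3.0)

    def test_simulated_counts_and_lengths_recovered(self, geom1):
        truth, _, traits = analyze_simulated_plant(3, 11, geom1)
        assert traits.n_lat1 == truth.n_lat1
        assert traits.n_lat2 == truth.n_lat2
        assert traits.length_primary_cm == pytest.approx(
            truth.length_primary_cm, rel=0.05)
        assert traits.length_lat1_cm == pytest.approx(
            truth.length_lat1_cm, rel=0.05)


class TestTraits:
    def test_vertical_root_depth_width_hull(self, geom1):
        g = build_root_graph(vertical_stroke_mask(geom1, 50.0), geom1)
        classify_root_orders(g)
        tr = measure_traits(g, dai=9)
        assert tr.system_depth_cm == pytest.approx(5.0, abs=0.1)
        assert tr.system_width_cm < 0.15          # stroke width only
        assert tr.convex_hull_area_cm2 < 0.4      # degenerate, near zero

    def test_simulated_geometry_traits_match_truth(self, geom1):
        truth, _, traits = analyze_simulated_plant(6, 12, geom1)
        assert traits.system_depth_cm == pytest.approx(truth.depth_cm, rel=0.02)
        assert traits.system_width_cm == pytest.approx(
            truth.width_cm, rel=0.02, abs=0.1)
        assert traits.convex_hull_area_cm2 == pytest.approx(
            truth.convex_hull_area_cm2, rel=0.10)

    def test_unlabeled_graph_rejected(self, geom1):
        g = build_root_graph(vertical_stroke_mask(geom1, 50.0), geom1)
        with pytest.raises(ValueError):
            measure_traits(g, dai=9)

    def test_scale_equivariance(self):
        """Doubling the calibration changes cm traits by < 2%."""
        results = []
        for ppm in (4.0, 8.0):
            geom = PlateGeometry(n_holes=1, px_per_mm=ppm)
            _, _, tr = analyze_simulated_plant(9, 10, geom, noise_sd=0.0)
            results.append(tr)
        a, b = results
        assert a.length_total_cm == pytest.approx(b.length_total_cm, rel=0.02)
        assert a.system_depth_cm == pytest.approx(b.system_depth_cm, rel=0.02)


class TestDepthProfile:
    def test_vertical_polyline_exact_split(self, geom1):
        # 5 cm of perfectly vertical root from the surface: 1 cm per layer
        poly = np.column_stack([np.linspace(0, 200, 201),
                                np.full(201, 100.0)])
        out = split_polyline_by_depth(poly, geom1, 20)
        np.testing.assert_allclose(out[:5], 1.0)
        assert out[5:].sum() == 0.0

    def test_horizontal_segment_lands_in_its_layer(self, geom1):
        row = 3.5 * 10 * geom1.px_per_mm
        poly = np.array([[row, 40.0], [row, 140.0]])  # 25 mm horizontal
        out = split_polyline_by_depth(poly, geom1, 20)
        assert out[3] == pytest.approx(2.5)
        assert out.sum() == pytest.approx(2.5)

    def test_segment_crossing_boundary_split_exactly(self, geom1):
        ppm = geom1.px_per_mm
        poly = np.array([[5 * ppm, 0.0], [15 * ppm, 0.0]])  # 0.5 -> 1.5 cm depth
        out = split_polyline_by_depth(poly, geom1, 20)
        assert out[0] == pytest.approx(0.5)
        assert out[1] == pytest.approx(0.5)

    def test_conservation_on_simulated_plant(self, geom1):
        _, graph, traits = analyze_simulated_plant(2, 12, geom1)
        prof = depth_profile(graph, dai=12)
        for key, total in (("primary", traits.length_primary_cm),
                           ("lat1", traits.length_lat1_cm),
                           ("lat2", traits.length_lat2_cm)):
            assert prof.lengths_cm[key].sum() == pytest.approx(
                total, rel=0.005, abs=1e-9)

    def test_bad_layer_count_rejected(self, geom1):
        _, graph, _ = analyze_simulated_plant(2, 7, geom1)
        with pytest.raises(ValueError):
            depth_profile(graph, n_layers=0)


def test_graph_serialization_round_trip(tmp_path, geom1):
    _, graph, traits = analyze_simulated_plant(5, 9, geom1)
    path = tmp_path / "plant.rsg"
    save_graph(graph, path)
    back = load_graph(path, geom1)
    assert back.labeled
    assert back.length_cm(0) == pytest.approx(graph.length_cm(0), rel=1e-3)
    assert {e.root_id for e in back.edges.values()} == \
        {e.root_id for e in graph.edges.values()}
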