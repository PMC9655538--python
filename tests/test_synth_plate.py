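import numpy as np
import pandas as pd
import pytest

from rootscreen.plate_core import PlantId, PlateGeometry
from rootscreen.synth_plate import (
    DEFAULT_SAMPLE_SIZES,
    SimParams,
    SimTruth,
    design_plants,
    render_root_image,
    render_rosette_image,
    rasterize_truth,
    simulate_experiment,
    simulate_root_system,
)

PLANT = PlantId("sim", 0)


class TestGrowthModel:
    def test_day_zero_nothing_has_grown(self, geom1):
        t = simulate_root_system(SimParams(rng_seed=1), PLANT, 0, geom1)
        assert t.length_total_cm == 0.0
        assert t.n_lat1 == t.n_lat2 == 0

    def test_primary_length_is_rate_times_time(self, geom1):
        p = SimParams(primary_elongation_mm_per_day=10.0,
                      lat1_initiation_per_cm=0.0, tortuosity_sd=0.0,
                      rng_seed=1)
        t = simulate_root_system(p, PLANT, 5, geom1, treatment=None)
        assert t.length_primary_cm == pytest.approx(5.0)
        assert t.n_lat1 == 0

    def test_primary_capped_at_window_depth(self, geom1):
        # 15 mm/day for 21 days would be 31.5 cm; the plate stops it at 20 cm
        p = SimParams(primary_elongation_mm_per_day=15.0,
                      lat1_initiation_per_cm=0.0, tortuosity_sd=0.0,
                      gravitropic_bend_per_mm=0.0, rng_seed=1)
        t = simulate_root_system(p, PLANT, 21, geom1)
        assert t.length_primary_cm == pytest.approx(20.0)

    def test_same_seed_bit_reproducible(self, geom1):
        p = SimParams(rng_seed=11)
        a = simulate_root_system(p, PLANT, 12, geom1, "Amb-PsJN")
        b = simulate_root_system(p, PLANT, 12, geom1, "Amb-PsJN")
        assert len(a.roots) == len(b.roots)
        for ra, rb in zip(a.roots, b.roots):
            assert ra.root_id == rb.root_id
            np.testing.assert_array_equal(ra.points, rb.points)

    def test_different_seed_different_realization(self, geom1):
        a = simulate_root_system(SimParams(rng_seed=1), PLANT, 12, geom1)
        b = simulate_root_system(SimParams(rng_seed=2), PLANT, 12, geom1)
        assert a.length_lat1_cm != b.length_lat1_cm

    def test_snapshots_nested_across_days(self, geom1):
        """The day-9 state of a plant strictly extends its day-7 state."""
        p = SimParams(rng_seed=5)
        t7 = simulate_root_system(p, PLANT, 7, geom1, "Amb-Ctl")
        t9 = simulate_root_system(p, PLANT, 9, geom1, "Amb-Ctl")
        ids7 = {r.root_id for r in t7.roots}
        ids9 = {r.root_id for r in t9.roots}
        assert ids7 <= ids9
        by9 = {r.root_id: r for r in t9.roots}
        for r in t7.roots:
            assert by9[r.root_id].length_mm >= r.length_mm - 1e-9

    def test_total_is_sum_of_types(self, geom1):
        t = simulate_root_system(SimParams(rng_seed=3), PLANT, 16, geom1)
        assert t.length_total_cm == pytest.approx(
            t.length_primary_cm + t.length_lat1_cm + t.length_lat2_cm)

    def test_lat1_start_on_primary_lat2_on_lat1(self, geom1):
        t = simulate_root_system(SimParams(rng_seed=3), PLANT, 14, geom1)
        by_id = {r.root_id: r for r in t.roots}
        for r in t.roots:
            if r.order == 0:
                continue
            parent = by_id[r.parent_id]
            assert parent.order == r.order - 1
            d = np.linalg.norm(parent.points - r.points[0], axis=1).min()
            assert d < 1.0  # start point lies on the parent polyline (mm)

    def test_heat_reduces_growth(self, geom1):
        p = SimParams(rng_seed=0)
        amb = np.mean([simulate_root_system(p, PlantId("a", 0), 21, geom1,
                                            "Amb-Ctl").length_total_cm
                       for _ in range(1)])
        ht = np.mean([simulate_root_system(p, PlantId("a", 0), 21, geom1,
                                           "HT-Ctl").length_total_cm
                      for _ in range(1)])
        assert ht < amb

    def test_negative_day_rejected(self, geom1):
        with pytest.raises(ValueError):
            simulate_root_system(SimParams(), PLANT, -1, geom1)

    @pytest.mark.parametrize("kw", [
        {"primary_elongation_mm_per_day": -1},
        {"branching_angle_mean_deg": 0.0},
        {"branching_angle_mean_deg": 95.0},
        {"treatment_multipliers": {"Amb-Ctl": {"lat1_elongation_mm_per_day": 0.0}}},
    ])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            SimParams(**kw)


class TestRootRendering:
    def test_empty_truth_blank_image(self, geom1):
        t = SimTruth(PLANT, 0, None, [])
        img, _ = render_root_image(t, geom1, noise_sd=0.0, rng=0)
        assert len(np.unique(img)) == 1  # uniform background

    def test_vertical_primary_bounding_box(self):
        geom = PlateGeometry(n_holes=1, px_per_mm=5.0)
        p = SimParams(primary_elongation_mm_per_day=10.0,
                      lat1_initiation_per_cm=0.0, tortuosity_sd=0.0,
                      gravitropic_bend_per_mm=0.0, rng_seed=1)
        t = simulate_root_system(p, PLANT, 10, geom)  # 100 mm vertical
        stroke = 3
        mask = rasterize_truth(t, geom, stroke_px=stroke)
        rows = np.flatnonzero(mask.any(axis=1))
        height = rows[-1] - rows[0] + 1
        assert abs(height - 100 * 5) <= stroke + 1

    def test_out_of_window_polyline_rejected(self, geom1):
        bad = SimTruth(PLANT, 1, None, [
            __import__("rootscreen.synth_plate", fromlist=["RootPolyline"])
            .RootPolyline("P", 0, None,
                          np.array([[50.0, 0.0], [50.0, 250.0]]), 0.0, None, 0)
        ])
        with pytest.raises(ValueError):
            render_root_image(bad, geom1)


class TestRosetteRendering:
    def test_no_leaves_means_zero_area(self, geom1):
        img, area, mask = render_rosette_image(0, 0.0, geom1, rng=1,
                                               n_specks=0, noise_sd=0.0)
        assert area == 0.0 and not mask.any()

    def test_single_leaf_area_same_scale_as_request(self, geom1):
        img, area, mask = render_rosette_image(1, 100.0, geom1, rng=2,
                                               n_specks=0, noise_sd=0.0)
        # the filled centre adds and leaf overlap removes area, so the
        # request sets the scale only; the truth is always the exact
        # rendered pixel count
        assert 50.0 < area < 250.0
        assert area == mask.sum() / geom1.px_per_mm**2

    def test_true_area_counts_rendered_pixels_exactly(self, geom1):
        img, area, mask = render_rosette_image(5, 150.0, geom1, rng=3)
        assert area * geom1.px_per_mm**2 == mask.sum()

    def test_oversized_area_rejected(self, geom1):
        with pytest.raises(ValueError):
            render_rosette_image(3, 1e6, geom1, frame_px=100)


class TestExperiment:
    def test_single_plant_single_day(self, geom1):
        from rootscreen.plate_core import ImagingSchedule

        ds = simulate_experiment(
            SimParams(rng_seed=1), geom1, ImagingSchedule((9,)),
            sample_sizes={"Amb-Ctl": 1})
        assert len(ds.truth_traits) == 1
        assert len(ds.truth_long) == 3  # one row per root type

    def test_default_design_row_count(self):
        ds = simulate_experiment(SimParams(rng_seed=2))
        assert len(ds.truth_traits) == sum(DEFAULT_SAMPLE_SIZES.values()) * 8
        counts = ds.truth_traits.groupby("treatment")["plant_id"].nunique()
        assert counts.to_dict() == DEFAULT_SAMPLE_SIZES

    def test_same_seed_byte_identical_tables(self, tmp_path):
        for d in ("a", "b"):
            simulate_experiment(SimParams(rng_seed=7), out_dir=tmp_path / d,
                                sample_sizes={"Amb-Ctl": 2, "Amb-PsJN": 2,
                                              "HT-Ctl": 2, "HT-PsJN": 2})
        for f in ("truth_traits.csv", "truth_long.csv", "shoot_truth.csv"):
            assert (tmp_path / "a" / f).read_bytes() == \
                (tmp_path / "b" / f).read_bytes()

    def test_duplicate_plant_rejected(self):
        plants = design_plants({"Amb-Ctl": 3})
        assert len({str(p) for p, _ in plants}) == 3
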