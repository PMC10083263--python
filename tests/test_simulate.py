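"""Scene generation, the fusion inverse, and the occlusion event model."""

import numpy as np
import pytest

from cropsignal import (
    SceneConfig,
    SensorArray,
    estimate_label_position,
    generate_scene,
    generate_truth,
    invert_fusion,
    line_of,
    open_mask,
    rgb_to_hsv,
    segment,
    select_signal,
    simulate_sensor_events,
)
from cropsignal.errors import NotInvertibleError
from cropsignal.simulate import hsv8_to_rgb


class TestInvertFusion:
    def test_diagonal_point(self, array):
        ser_1, ser_2, dt = invert_fusion((350, 350), array)
        assert line_of(ser_1) == "A" and line_of(ser_2) == "B"
        assert dt * array.speed_px_s == pytest.approx(10)

    def test_center_inverts_with_zero_gap(self, array):
        ser_1, ser_2, dt = invert_fusion((360, 360), array)
        assert dt == 0 and line_of(ser_1) != line_of(ser_2)

    def test_off_locus_point_rejected(self, array):
        with pytest.raises(NotInvertibleError):
            invert_fusion((100, 200), array)

    @pytest.mark.parametrize(
        "point", [(360, 500), (360, 200), (300, 420), (0, 0), (100, 620)]
    )
    def test_round_trip_on_each_locus(self, array, point):
        ser_1, ser_2, dt = invert_fusion(point, array)
        assert estimate_label_position(ser_1, ser_2, dt, array) == point

    def test_round_trip_dense_sample(self, array):
        """estimate o invert = identity on a sample of every locus."""
        c = array.center
        points = (
            [(a, a) for a in range(0, c + 1, 5)]
            + [(c, y) for y in range(0, array.image_size, 5)]
            + [(c - k, c + k) for k in range(0, c, 5)]
        )
        for p in points:
            assert estimate_label_position(*invert_fusion(p, array), array) == p


class TestGenerateScene:
    def test_deterministic(self, clean_config):
        img1, t1 = generate_scene(clean_config, seed=7)
        img2, t2 = generate_scene(clean_config, seed=7)
        assert np.array_equal(img1, img2)
        assert t1.label_point == t2.label_point
        assert t1.weed_centroids == t2.weed_centroids

    def test_different_seeds_differ(self, clean_config):
        img1, _ = generate_scene(clean_config, seed=1)
        img2, _ = generate_scene(clean_config, seed=2)
        assert not np.array_equal(img1, img2)

    def test_weed_count_honors_config(self):
        cfg = SceneConfig(n_weeds=(3, 3))
        _, truth = generate_scene(cfg, seed=11)
        assert truth.n_weeds == 3 and len(truth.weed_masks) == 3

    def test_label_point_lies_on_a_locus(self, clean_config, array):
        for seed in range(10):
            truth = generate_truth(clean_config, seed, array)
            invert_fusion(truth.label_point, array)  # raises if off-locus

    def test_plant_masks_are_disjoint(self, clean_config):
        _, truth = generate_scene(clean_config, seed=3)
        masks = [truth.crop_mask, *truth.weed_masks]
        union_count = np.zeros_like(masks[0], dtype=int)
        for m in masks:
            union_count += m
        assert union_count.max() == 1

    def test_segmentation_recovers_plants_exactly(self, clean_config):
        """Plant colors sit inside the acceptance bands, soil outside, with
        margins wide enough that the RGB round-trip never crosses them."""
        for seed in (0, 5, 9):
            img, truth = generate_scene(clean_config, seed)
            plants = truth.crop_mask.copy()
            for m in truth.weed_masks:
                plants |= m
            mask = segment(rgb_to_hsv(img))
            assert np.array_equal(mask > 0, plants)

    def test_opened_mask_covers_plant_truth(self, clean_config):
        for seed in range(8):
            img, truth = generate_scene(clean_config, seed)
            plants = truth.crop_mask.copy()
            for m in truth.weed_masks:
                plants |= m
            fg = open_mask(segment(rgb_to_hsv(img))) > 0
            assert (fg & plants).sum() >= 0.95 * plants.sum()

    def test_around_crop_placement_keeps_weeds_in_annulus(self, array):
        from cropsignal import desync_config

        cfg = desync_config()
        for seed in range(6):
            truth = generate_truth(cfg, seed, array)
            for wx, wy in truth.weed_centroids:
                d = np.hypot(wx - truth.crop_centroid[0],
                             wy - truth.crop_centroid[1])
                assert cfg.min_sep_crop_weed <= d <= cfg.around_radius[1] + 1e-9

    def test_desync_masks_remain_disjoint(self):
        from cropsignal import desync_config

        _, truth = generate_scene(desync_config(), seed=4)
        overlap = np.zeros_like(truth.crop_mask, dtype=int)
        for m in (truth.crop_mask, *truth.weed_masks):
            overlap += m
        assert overlap.max() == 1

    def test_jitter_displaces_crop_from_label(self):
        cfg = SceneConfig(jitter_px=10.0)
        shifted = 0
        for seed in range(5):
            truth = generate_truth(cfg, seed)
            d = np.hypot(truth.crop_centroid[0] - truth.label_point[0],
                         truth.crop_centroid[1] - truth.label_point[1])
            assert d <= 10.0 + 1e-9
            shifted += d > 0
        assert shifted > 0

    def test_hsv8_round_trip_stays_on_the_right_side_of_thresholds(self, rng):
        """Enumerate the generator's color bands: after HSV->RGB->HSV
        quantization, soil hue stays below the low threshold (10) and
        plant HSV stays inside all acceptance bands."""

        def round_trip(hr, sr, vr, n=4000):
            hsv = np.stack(
                [rng.integers(hr[0], hr[1] + 1, n),
                 rng.integers(sr[0], sr[1] + 1, n),
                 rng.integers(vr[0], vr[1] + 1, n)],
                axis=-1,
            ).astype(np.uint8)[None]
            return rgb_to_hsv(hsv8_to_rgb(hsv)).astype(int)[0]

        cfg = SceneConfig()
        soil = round_trip(cfg.soil_hue, cfg.soil_sat, cfg.soil_val)
        assert soil[:, 0].max() < 10
        plant = round_trip(cfg.plant_hue, cfg.plant_sat, cfg.plant_val)
        assert 10 <= plant[:, 0].min() and plant[:, 0].max() <= 120
        assert plant[:, 1].min() >= 10 and plant[:, 2].min() >= 10


class TestSensorEvents:
    def test_no_occlusion_round_trips_label_point(self, clean_config, array):
        for seed in range(10):
            truth = generate_truth(clean_config, seed, array)
            events = simulate_sensor_events(truth, array, occlusion_p=0.0, seed=seed)
            sig = select_signal(events, array)
            assert sig is not None and sig.point == truth.label_point

    def test_full_occlusion_yields_no_events(self, clean_config, array):
        truth = generate_truth(clean_config, 0, array)
        events = simulate_sensor_events(truth, array, occlusion_p=1.0, seed=0)
        assert events == [] and select_signal(events, array) is None

    def test_single_line_subset_never_detects(self, clean_config, array):
        truth = generate_truth(clean_config, 0, array)
        events = simulate_sensor_events(
            truth, array, occlusion_p=0.0, active_sensors={2, 5}, seed=0
        )
        assert select_signal(events, array) is None

    def test_both_sensors_of_each_line_fire(self, array):
        truth = generate_truth(SceneConfig(), 1, array)
        events = simulate_sensor_events(truth, array, occlusion_p=0.0, seed=0)
        lines = {line_of(e.sensor_id) for e in events}
        assert len(events) == 4 and len(lines) == 2

    def test_detection_monotone_in_occlusion_and_sensor_count(self, array):
        """Common random numbers: more occlusion never helps, more sensors
        never hurt, scene by scene."""
        cfg = SceneConfig()
        truths = [generate_truth(cfg, s, array) for s in range(100)]
        subsets = [{2, 5}, {1, 2, 4, 5}, {1, 2, 3, 4, 5, 6}]

        def detected(truth, seed, p, active):
            ev = simulate_sensor_events(truth, array, occlusion_p=p,
                                        active_sensors=active, seed=seed)
            return select_signal(ev, array) is not None

        for i, truth in enumerate(truths):
            hits = [detected(truth, i, 0.4, s) for s in subsets]
            assert hits[0] <= hits[1] <= hits[2]  # nested subsets
            # same uniform draws, higher threshold: survival sets nest in p
            assert detected(truth, i, 0.7, subsets[2]) <= detected(
                truth, i, 0.2, subsets[2]
            )
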