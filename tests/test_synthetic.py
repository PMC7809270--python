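"""Synthetic-data generators: determinism, ground-truth recovery, placement."""

import numpy as np
import pytest
from scipy.special import ive

from cellstream.synthetic import (
    ImagingConfig,
    NucleiFieldConfig,
    SimConfig,
    kappa_for_order,
    nematic_order,
    render_nuclei,
    render_timelapse,
    simulate_cells,
)
from cellstream.tracks import population_summary


class TestSimulateCells:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=7, n_frames=6, density_per_mm2=80)
        a = simulate_cells(cfg).data
        b = simulate_cells(cfg).data
        assert a.equals(b)

    def test_different_seeds_differ(self):
        a = simulate_cells(SimConfig(seed=1, n_frames=4, density_per_mm2=80)).data
        b = simulate_cells(SimConfig(seed=2, n_frames=4, density_per_mm2=80)).data
        assert not np.allclose(a[["x_um", "y_um"]], b[["x_um", "y_um"]])

    def test_cell_count_matches_density(self):
        cfg = SimConfig(
            arena_width_um=500, arena_height_um=400, density_per_mm2=150, n_frames=3
        )
        ts = simulate_cells(cfg)
        assert len(ts) == round(150 * 0.5 * 0.4) == cfg.n_cells
        # conservation: every track spans every frame
        assert (ts.data.groupby("track_id").size() == 3).all()

    def test_zero_cells_errors(self):
        cfg = SimConfig(
            arena_width_um=50, arena_height_um=50, density_per_mm2=0.1, n_frames=3
        )
        with pytest.raises(ValueError, match="zero cells"):
            simulate_cells(cfg)

    def test_invalid_parameters_error(self):
        with pytest.raises(ValueError):
            SimConfig(speed_um_per_h=float("nan"))
        with pytest.raises(ValueError):
            SimConfig(wound_bias=1.5)
        with pytest.raises(ValueError):
            SimConfig(n_frames=1)

    def test_noiseless_full_bias_gives_straight_guided_tracks(self):
        """wound_bias=1 with no noise/alignment: straight +x lines, D/T = 1."""
        cfg = SimConfig(
            arena_width_um=3000, arena_height_um=1000, density_per_mm2=20,
            speed_um_per_h=4, rot_diffusion_per_h=0.0, align_strength=0.0,
            wound_bias=1.0, n_frames=15, seed=3,
        )
        ts = simulate_cells(cfg)
        stats = population_summary(ts, t_eval_h=ts.data.t_h.max())
        assert stats.population["ratio"]["mean"] == pytest.approx(1.0)
        assert stats.population["ratio"]["sem"] == pytest.approx(0.0)
        for tid in ts.track_ids[:5]:
            _, xy = ts.track(tid)
            assert np.ptp(xy[:, 1]) == pytest.approx(0.0, abs=1e-9)

    def test_mean_step_speed_matches_parameter(self):
        """Population mean step length / dt equals the programmed speed ±5%."""
        speeds = []
        for seed in range(3):
            cfg = SimConfig(
                density_per_mm2=100, speed_um_per_h=4.0, n_frames=25, seed=seed
            )
            ts = simulate_cells(cfg)
            for tid in ts.track_ids:
                _, xy = ts.track(tid)
                step = np.diff(xy, axis=0)
                step[:, 1] = (step[:, 1] + 500) % 1000 - 500  # unwrap periodic y
                speeds.append(np.linalg.norm(step, axis=1).mean())
        assert np.mean(speeds) / (10 / 60) == pytest.approx(4.0, rel=0.05)

    def test_wound_gap_empty_at_t0(self):
        cfg = SimConfig(
            arena_width_um=1500, arena_height_um=500, density_per_mm2=400,
            gap_width_um=500, n_frames=3, seed=11,
        )
        ts = simulate_cells(cfg)
        first = ts.data[ts.data.t_h == 0.0]
        center = 1500 / 2
        assert not ((first.x_um > center - 250) & (first.x_um < center + 250)).any()

    def test_guidance_monotone_in_bias(self):
        """Mean D/T is non-decreasing in wound_bias (3-seed averages)."""
        means = []
        for wb in (0.0, 0.5, 1.0):
            vals = []
            for seed in range(3):
                cfg = SimConfig(
                    arena_width_um=2000, arena_height_um=500, density_per_mm2=40,
                    speed_um_per_h=4.0, wound_bias=wb, n_frames=31, seed=seed,
                )
                ts = simulate_cells(cfg)
                vals.append(
                    population_summary(ts, t_eval_h=5.0).population["ratio"]["mean"]
                )
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]


class TestRenderTimelapse:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(
            arena_width_um=200, arena_height_um=200, density_per_mm2=300,
            n_frames=3, seed=5,
        )
        ts = simulate_cells(cfg)
        a = render_timelapse(ts, field_size_um=(200, 200), seed=1)
        b = render_timelapse(ts, field_size_um=(200, 200), seed=1)
        assert np.array_equal(a.frames, b.frames)

    def test_static_cells_give_static_frames(self):
        """Cells that do not move render identically (up to sensor noise)."""
        import pandas as pd
        from cellstream.tracks import TrackSet

        rows = []
        for tid in range(5):
            for k in range(2):
                rows.append(
                    {"track_id": tid, "t_h": k / 6, "x_um": 40.0 + 30 * tid, "y_um": 100.0}
                )
        ts = TrackSet(pd.DataFrame(rows))
        movie = render_timelapse(
            ts, ImagingConfig(noise_sd=0.0), field_size_um=(200, 200), seed=0
        )
        assert np.array_equal(movie.frames[0], movie.frames[1])

    def test_integer_translation_moves_texture_exactly(self):
        """A (3 px, 0) shift of every cell translates the image exactly."""
        import pandas as pd
        from cellstream.tracks import TrackSet

        rows = []
        for tid in range(4):
            x0 = 50.0 + 25 * tid
            rows.append({"track_id": tid, "t_h": 0.0, "x_um": x0, "y_um": 80.0})
            rows.append({"track_id": tid, "t_h": 0.5, "x_um": x0 + 3.0, "y_um": 80.0})
        ts = TrackSet(pd.DataFrame(rows))
        movie = render_timelapse(
            ts, ImagingConfig(noise_sd=0.0), field_size_um=(200, 160), seed=0
        )
        # away from the frame edge, frame1 equals frame0 shifted 3 px in +x
        np.testing.assert_array_equal(
            movie.frames[1][:, 23:180], movie.frames[0][:, 20:177]
        )

    def test_field_too_small_errors(self):
        import pandas as pd
        from cellstream.tracks import TrackSet

        ts = TrackSet(
            pd.DataFrame(
                [{"track_id": 0, "t_h": 0.0, "x_um": 5.0, "y_um": 5.0},
                 {"track_id": 0, "t_h": 0.2, "x_um": 6.0, "y_um": 5.0}]
            )
        )
        with pytest.raises(ValueError, match="smaller than one cell"):
            render_timelapse(ts, ImagingConfig(), field_size_um=(10, 10))


class TestKappaForOrder:
    def test_zero_order_is_zero_kappa(self):
        assert kappa_for_order(0.0) == 0.0

    @pytest.mark.parametrize("target", [0.1, 0.3, 0.5, 0.7, 0.9, 0.99])
    def test_round_trip_through_bessel_ratio(self, target):
        kappa = kappa_for_order(target)
        forward = float(ive(1, kappa) / ive(0, kappa))
        assert forward == pytest.approx(target, abs=1e-6)

    def test_monotone_in_target(self):
        ks = [kappa_for_order(s) for s in (0.1, 0.2, 0.4, 0.6, 0.8, 0.95)]
        assert all(a < b for a, b in zip(ks, ks[1:]))

    def test_saturated_order_errors(self):
        with pytest.raises(ValueError):
            kappa_for_order(1.0)
        with pytest.raises(ValueError):
            kappa_for_order(-0.1)


class TestRenderNuclei:
    def test_ground_truth_row_count_and_disjointness(self):
        cfg = NucleiFieldConfig(n_nuclei=120, order_target=0.5, seed=0)
        _, truth = render_nuclei(cfg)
        assert len(truth) == 120
        xy = truth[["x_um", "y_um"]].to_numpy()
        from scipy.spatial.distance import pdist

        assert pdist(xy).min() >= cfg.major_axis_um  # bounding circles disjoint

    def test_perfect_order_is_exactly_parallel(self):
        cfg = NucleiFieldConfig(
            n_nuclei=50, order_target=1.0, mean_direction_deg=40.0, seed=1
        )
        _, truth = render_nuclei(cfg)
        assert np.allclose(truth.theta_deg, 40.0)
        S, direction = nematic_order(truth.theta_deg)
        assert S == pytest.approx(1.0)
        assert direction == pytest.approx(40.0)

    def test_zero_order_below_null_threshold(self):
        """Uniform orientations: sample S stays below the 99% null bound in
        nearly every seed."""
        from cellstream.nematic import null_order_ci

        n = 400
        threshold = null_order_ci(n, reps=4000, seed=0)
        below = 0
        seeds = range(12)
        for seed in seeds:
            cfg = NucleiFieldConfig(n_nuclei=n, order_target=0.0, seed=seed)
            _, truth = render_nuclei(cfg)
            S, _ = nematic_order(truth.theta_deg)
            below += S < threshold
        assert below >= 0.9 * len(seeds)

    def test_sample_order_tracks_target(self):
        for target, seed in ((0.3, 0), (0.7, 1)):
            cfg = NucleiFieldConfig(n_nuclei=400, order_target=target, seed=seed)
            _, truth = render_nuclei(cfg)
            S, _ = nematic_order(truth.theta_deg)
            assert S == pytest.approx(target, abs=0.07)

    def test_deterministic_given_seed(self):
        cfg = NucleiFieldConfig(n_nuclei=40, order_target=0.5, seed=9)
        img_a, truth_a = render_nuclei(cfg)
        img_b, truth_b = render_nuclei(cfg)
        assert np.array_equal(img_a, img_b)
        assert truth_a.equals(truth_b)

    def test_impossible_packing_errors(self):
        cfg = NucleiFieldConfig(
            n_nuclei=500, width_um=120, height_um=120, seed=0, max_retries=50
        )
        with pytest.raises(RuntimeError, match="without overlap"):
            render_nuclei(cfg)

    def test_region_polygons_constrain_placement(self):
        cfg = NucleiFieldConfig(
            n_nuclei=30,
            order_target=0.5,
            seed=2,
            region_polygons={"left": [(10, 10), (300, 10), (300, 690), (10, 690)]},
        )
        _, truth = render_nuclei(cfg)
        assert (truth.x_um <= 300).all()
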