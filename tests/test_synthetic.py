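"""Generators: distributional correctness, quantization, determinism."""

import numpy as np
import pytest

from dynquant import (
    AcquisitionParams,
    PeakWindow,
    RoiSpec,
    auc_fraction,
    measure_roi,
    simulate_binding_assay,
    simulate_cell_image,
    simulate_pair_geometry,
    simulate_particle_population,
    simulate_sec_trace,
    simulate_tracks,
)
from dynquant.io import write_events_csv


class TestBindingAssay:
    def test_zero_rate_gives_no_events(self):
        obs, _ = simulate_binding_assay(kon_per_site=0.0, seed=0)
        assert all(len(o.events) == 0 for o in obs)

    def test_single_phase_mean_dwell(self):
        obs, _ = simulate_binding_assay(
            fast_fraction=1.0, tau_fast_s=0.5, tau_slow_s=0.5,
            kon_per_site=1e-4, mt_lengths_um=[10.0] * 20,
            duration_s=1000.0, conc_nM=1.0, seed=5,
        )
        dwells = np.array([e.duration_s for o in obs for e in o.events if not e.censored])
        assert dwells.size > 2000
        se = 0.5 / np.sqrt(dwells.size)
        # quantized exponential keeps its mean to within half a frame
        assert abs(dwells.mean() - 0.5) < 3 * se + 0.0625

    def test_timestamps_quantized_to_frame_cycle(self):
        obs, _ = simulate_binding_assay(seed=2)
        for o in obs:
            for e in o.events:
                for t in (e.t_start_s, e.t_end_s):
                    assert abs(t / 0.125 - round(t / 0.125)) < 1e-9

    def test_determinism(self, tmp_path):
        a, _ = simulate_binding_assay(seed=9)
        b, _ = simulate_binding_assay(seed=9)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_events_csv(a, pa)
        write_events_csv(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_censored_events_flagged_at_movie_end(self):
        obs, _ = simulate_binding_assay(
            tau_fast_s=30.0, tau_slow_s=60.0, duration_s=30.0,
            kon_per_site=1e-4, seed=1,
        )
        censored = [e for o in obs for e in o.events if e.censored]
        assert censored
        assert all(e.t_end_s == pytest.approx(30.0) for e in censored)

    def test_rejects_bad_durations(self):
        with pytest.raises(ValueError):
            simulate_binding_assay(duration_s=0.3)  # not a frame multiple
        with pytest.raises(ValueError):
            simulate_binding_assay(mt_lengths_um=[-1.0])
        with pytest.raises(ValueError):
            simulate_binding_assay(tau_fast_s=2.0, tau_slow_s=1.0)


class TestTracks:
    def test_static_zero_displacement(self):
        tracks, _ = simulate_tracks(model="static", n_tracks=5, seed=0)
        assert all(t.net_displacement_um == 0.0 for t in tracks)

    def test_processive_step_size_before_quantization(self):
        tracks, _ = simulate_tracks(
            model="processive", n_tracks=3, v_um_s=0.5, mean_run_um=None,
            quantize=False, seed=0,
        )
        for tr in tracks:
            steps = np.diff(tr.positions)
            assert steps == pytest.approx(0.5 * 0.125)

    def test_positions_quantized_to_pixel(self):
        tracks, _ = simulate_tracks(model="diffusive", n_tracks=5,
                                    pixel_size_um=0.16, seed=3)
        for tr in tracks:
            ratios = tr.positions / 0.16
            assert np.allclose(ratios, np.round(ratios), atol=1e-9)

    def test_processive_run_lengths_exponential_mean(self):
        _, truth = simulate_tracks(model="processive", n_tracks=2000,
                                   mean_run_um=1.0, seed=4)
        runs = truth["true_run_um"].to_numpy()
        assert abs(runs.mean() - 1.0) < 3 / np.sqrt(runs.size)

    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            simulate_tracks(model="processive", v_um_s=-1.0)
        with pytest.raises(ValueError):
            simulate_tracks(model="unknown")


class TestParticlePopulation:
    def test_pure_phi(self):
        records, _ = simulate_particle_population(
            n_micrographs=10, class_probs={"phi": 1.0, "open": 0.0, "ambiguous": 0.0},
            seed=0,
        )
        assert all(r.class_label == "phi" for r in records)

    def test_pooled_fraction_within_binomial_se(self):
        records, _ = simulate_particle_population(
            n_micrographs=300, mean_particles_per_micrograph=40.0, seed=8,
        )
        n = len(records)
        phi = sum(r.class_label == "phi" for r in records) / n
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(phi - 0.75) < 3 * se

    def test_determinism(self):
        a, _ = simulate_particle_population(n_micrographs=20, seed=3)
        b, _ = simulate_particle_population(n_micrographs=20, seed=3)
        assert a == b

    def test_rejects_bad_probs(self):
        with pytest.raises(ValueError):
            simulate_particle_population(class_probs={"phi": 1.2, "open": -0.2, "ambiguous": 0.0})


class TestPairGeometry:
    def test_degenerate_range(self):
        geoms, _ = simulate_pair_geometry(distance_range_nm=(20.0, 20.0),
                                          n_classes=50, seed=0)
        assert all(g.distance_nm == pytest.approx(20.0) for g in geoms)

    def test_open_defaults_within_range(self):
        geoms, truth = simulate_pair_geometry(state="open", n_classes=10000, seed=1)
        d = np.array([g.distance_nm for g in geoms])
        assert truth["distance_range_nm"] == (10.0, 45.0)
        assert d.min() >= 10.0 and d.max() <= 45.0

    def test_orientation_proportions_recovered(self):
        geoms, _ = simulate_pair_geometry(state="open", n_classes=10000, seed=2)
        inv = np.mean([g.orientation_label == "inverted" for g in geoms])
        se = np.sqrt(0.52 * 0.48 / 10000)
        assert abs(inv - 0.52) < 3 * se

    def test_rejects_empty_range(self):
        with pytest.raises(ValueError):
            simulate_pair_geometry(distance_range_nm=(30.0, 20.0))


class TestSecTrace:
    def test_single_peak_window_mass(self):
        trace, truth = simulate_sec_trace(peaks=[(12.0, 0.4, 1.0)], seed=0)
        window = PeakWindow(10.0, 14.0)  # +/- 5 sigma
        frac = auc_fraction(trace, window)
        assert frac == pytest.approx(1.0, abs=1e-4)

    def test_two_equal_peaks_split_mass(self):
        trace, _ = simulate_sec_trace(peaks=[(8.0, 0.3, 0.5), (16.0, 0.3, 0.5)], seed=0)
        for window in (PeakWindow(6.0, 10.0), PeakWindow(14.0, 18.0)):
            assert auc_fraction(trace, window) == pytest.approx(0.5, abs=1e-3)

    def test_total_integral_matches_declared_area(self):
        trace, truth = simulate_sec_trace(
            peaks=[(8.0, 0.3, 0.4), (14.0, 0.6, 0.9)], seed=0,
        )
        total = np.trapezoid(trace.a280, trace.volume_mL)
        assert total == pytest.approx(truth["total_area"], abs=1e-6)

    def test_analytic_oracle_callable(self):
        _, truth = simulate_sec_trace(peaks=[(10.0, 0.5, 2.0)], seed=0)
        assert truth["analytic_window_fraction"](0.0, 24.0) == pytest.approx(1.0, abs=1e-9)

    def test_rejects_bad_grid_and_sigma(self):
        with pytest.raises(ValueError):
            simulate_sec_trace(peaks=[(10.0, 0.5, 1.0)],
                               volume_grid=np.array([0, 1, 1, 2], dtype=float))
        with pytest.raises(ValueError):
            simulate_sec_trace(peaks=[(10.0, 0.0, 1.0)])


class TestCellImage:
    def test_uniform_background_no_foci(self):
        stack, _ = simulate_cell_image(shape_zyx=(5, 32, 32), background_level=80.0, seed=0)
        assert np.all(stack.intensities == 80.0)

    def test_single_focus_roi_contrast(self):
        stack, _ = simulate_cell_image(
            shape_zyx=(5, 64, 64), foci=[(2, 32, 32, 500.0, 2.0)],
            background_level=10.0, seed=0,
        )
        img = stack.intensities[2]
        on = measure_roi(img, RoiSpec(32, 32, 12)) - 10.0
        off = measure_roi(img, RoiSpec(8, 8, 12)) - 10.0
        assert on > 0
        assert off == pytest.approx(0.0, abs=1e-6)

    def test_poisson_background_mean(self):
        level = 100.0
        stack, _ = simulate_cell_image(
            shape_zyx=(3, 64, 64), background_level=level,
            noise_model="poisson", seed=7,
        )
        roi_mean = measure_roi(stack.intensities[1], RoiSpec(32, 32, 40))
        assert abs(roi_mean - level) < 3 * np.sqrt(level / 1600)

    def test_ground_truth_integrated_signal(self):
        _, truth = simulate_cell_image(
            shape_zyx=(5, 64, 64), foci=[(2, 30, 30, 100.0, 3.0)], seed=0,
        )
        assert truth["true_integrated_signal"].iloc[0] == pytest.approx(
            2 * np.pi * 9 * 100.0
        )

    def test_rejects_out_of_bounds_focus(self):
        with pytest.raises(ValueError):
            simulate_cell_image(shape_zyx=(5, 32, 32), foci=[(10, 0, 0, 1.0, 1.0)])
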