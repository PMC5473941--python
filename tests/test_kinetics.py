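"""Binding-rate, dwell-fit and Kd calculations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynquant import (
    AcquisitionParams,
    KineticsSummary,
    TwoPhaseDecayModel,
    analyze_binding_assay,
    binding_rate,
    dimer_labeling,
    estimate_kd,
    filter_events,
    frame_rate,
    lattice_sites,
    molar_concentration,
    simulate_binding_assay,
    survival_curve,
)
from conftest import make_observation


class TestLatticeSites:
    @pytest.mark.parametrize(
        "pf,repeat,frac,expected_real,expected_int",
        [
            (13, 8.1, 0.5, 802.469, 802),   # canonical accessible-site density
            (1, 1000.0, 1.0, 1.0, 1),
            (13, 8.1, 1.0, 1604.938, 1605),
        ],
    )
    def test_values(self, pf, repeat, frac, expected_real, expected_int):
        real, rounded = lattice_sites(pf, repeat, frac)
        assert real == pytest.approx(expected_real, abs=1e-3)
        assert rounded == expected_int

    @given(
        pf=st.integers(1, 20),
        repeat=st.floats(1.0, 100.0),
        frac=st.floats(0.1, 0.9),
    )
    @settings(max_examples=50, derandomize=True)
    def test_monotonicity(self, pf, repeat, frac):
        base, _ = lattice_sites(pf, repeat, frac)
        assert lattice_sites(pf + 1, repeat, frac)[0] > base
        assert lattice_sites(pf, repeat * 1.1, frac)[0] < base
        assert lattice_sites(pf, repeat, min(frac * 1.1, 1.0))[0] > base

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            lattice_sites(13, 0.0, 0.5)
        with pytest.raises(ValueError):
            lattice_sites(0, 8.1, 0.5)
        with pytest.raises(ValueError):
            lattice_sites(13, 8.1, 0.0)


class TestScalarHelpers:
    @pytest.mark.parametrize(
        "exposure,delay,fps", [(0.100, 0.025, 8.0), (1.0, 0.0, 1.0), (0.020, 0.005, 40.0)]
    )
    def test_frame_rate(self, exposure, delay, fps):
        assert frame_rate(AcquisitionParams(exposure_s=exposure, delay_s=delay)) == pytest.approx(fps)

    @pytest.mark.parametrize("p,expected", [(0.85, 0.9775), (1.0, 1.0), (0.5, 0.75)])
    def test_dimer_labeling(self, p, expected):
        assert dimer_labeling(p) == pytest.approx(expected)
        # a monomer efficiency of 85% reads 97.8% in the dimer to one decimal
        assert round(100 * dimer_labeling(0.85), 1) == 97.8

    def test_dimer_labeling_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            dimer_labeling(1.2)

    def test_molar_concentration(self):
        assert molar_concentration(0.797340, 797340.0, 1.0) == pytest.approx(1e-6)
        assert molar_concentration(0.0) == 0.0
        conc, ratio = molar_concentration(0.797340, dye_conc_M=2e-6)
        assert ratio == pytest.approx(2.0)


class TestFilterEvents:
    def test_boundary_inclusion(self, acq):
        # threshold 2 frames = 0.25 s: the boundary event is kept
        obs = make_observation("mt0", [0.125, 0.25, 0.375])
        kept, removed = filter_events([obs], acq)
        assert [e.duration_s for e in kept[0].events] == [0.25, 0.375]
        assert len(removed) == 1

    def test_strict_mode_drops_boundary(self, acq):
        obs = make_observation("mt0", [0.125, 0.25, 0.375])
        kept, _ = filter_events([obs], acq, include_boundary=False)
        assert [e.duration_s for e in kept[0].events] == [0.375]

    def test_censored_removed_by_default(self, acq):
        obs = make_observation("mt0", [0.5, 0.5], censored_flags=[False, True])
        kept, removed = filter_events([obs], acq)
        assert len(kept[0].events) == 1
        assert removed[0].censored

    def test_empty_input(self, acq):
        kept, removed = filter_events([], acq)
        assert kept == [] and removed == []

    def test_matches_brute_force_scan(self, acq, rng):
        durations = (rng.integers(1, 20, size=200) * acq.frame_cycle_s).tolist()
        obs = make_observation("mt0", durations, duration_s=1e5)
        kept, _ = filter_events([obs], acq)
        expected = [d for d in durations if d >= acq.min_event_duration_s - 1e-9]
        assert sorted(e.duration_s for e in kept[0].events) == pytest.approx(sorted(expected))


class TestBindingRate:
    def test_direct_arithmetic(self):
        obs = make_observation("mt0", [1.0] * 12, length_um=10.0,
                               duration_s=60.0, conc_nM=1.0)
        rates, mean, _ = binding_rate([obs])
        assert mean == pytest.approx(12 / (10 * 60 * 1))

    def test_zero_events(self):
        obs = [make_observation(f"mt{i}", []) for i in range(3)]
        _, mean, sem_ = binding_rate(obs)
        assert mean == 0.0 and sem_ == 0.0

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            binding_rate([])

    def test_recovers_simulated_rate(self):
        kon_site, sites = 2.5e-5, 802.0
        w, tf, ts, cyc = 0.8, 0.3, 3.0, 0.125
        obs, _ = simulate_binding_assay(
            kon_per_site=kon_site, fast_fraction=w, tau_fast_s=tf, tau_slow_s=ts,
            mt_lengths_um=[10.0] * 50, duration_s=360.0, conc_nM=0.58, seed=3,
        )
        # unfiltered event rate = arrival rate x closed-form probability that
        # a dwell rounds to at least one whole frame (dwell >= half a frame)
        p_detect = w * np.exp(-cyc / 2 / tf) + (1 - w) * np.exp(-cyc / 2 / ts)
        rates, mean, sem_ = binding_rate(obs)
        assert abs(mean - kon_site * sites * p_detect) <= 3 * sem_


class TestSurvivalCurve:
    def test_direct_count(self):
        grid, pct = survival_curve([0.25, 0.50], bin_s=0.125)
        assert pct[0] == 100.0
        assert pct[list(grid).index(0.25)] == 100.0
        assert pct[3] == 50.0  # t = 0.375: only the 0.5 s dwell remains

    def test_single_value_step(self):
        grid, pct = survival_curve([0.5, 0.5, 0.5], bin_s=0.125)
        assert set(pct) == {100.0}
        assert grid[-1] == pytest.approx(0.5)

    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=60))
    @settings(max_examples=60, derandomize=True)
    def test_monotone_bounded_and_matches_brute_force(self, dwells):
        grid, pct = survival_curve(dwells, bin_s=0.125)
        assert np.all(np.diff(pct) <= 1e-12)
        assert np.all((pct >= 0) & (pct <= 100))
        brute = [100 * sum(d >= t - 1e-9 for d in dwells) / len(dwells) for t in grid]
        assert pct == pytest.approx(brute)

    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(ValueError):
            survival_curve([])
        with pytest.raises(ValueError):
            survival_curve([0.0, 1.0])


class TestTwoPhaseFit:
    @pytest.mark.parametrize(
        "w,tau_f,tau_s",
        [(0.8, 0.3, 3.0), (0.5, 0.2, 1.0), (0.95, 0.5, 5.0), (0.3, 1.0, 4.0)],
    )
    def test_exact_on_noise_free_curves(self, w, tau_f, tau_s):
        t = np.arange(0, 12, 0.125)
        s = 100 * (w * np.exp(-t / tau_f) + (1 - w) * np.exp(-t / tau_s))
        res = TwoPhaseDecayModel(t, s).fit()
        assert res.ss_res < 1e-8
        assert res.w_fast == pytest.approx(w, abs=1e-6)
        assert res.tau_fast_s == pytest.approx(tau_f, rel=1e-6)
        assert res.tau_slow_s == pytest.approx(tau_s, rel=1e-6)

    def test_single_exponential_is_nested(self):
        t = np.arange(0, 8, 0.125)
        s = 100 * np.exp(-t)
        res = TwoPhaseDecayModel(t, s).fit()
        assert res.rsquared > 0.999
        # either both phases collapse to tau = 1 or the fast phase takes all weight
        collapsed = math.isclose(res.tau_fast_s, 1.0, rel_tol=0.05) and (
            math.isclose(res.tau_slow_s, 1.0, rel_tol=0.05) or res.w_fast > 0.95
        )
        assert collapsed

    def test_mixture_recovery_median_over_seeds(self):
        """w within 0.05 and tau_fast within 10% (median over 20 seeds, n=2000)."""
        errs_w, errs_tf = [], []
        for seed in range(20):
            gen = np.random.default_rng(seed)
            fast = gen.random(2000) < 0.8
            dwells = np.where(
                fast, gen.exponential(0.3, 2000), gen.exponential(3.0, 2000)
            )
            res = TwoPhaseDecayModel.from_dwells(dwells).fit()
            errs_w.append(abs(res.w_fast - 0.8))
            errs_tf.append(abs(res.tau_fast_s - 0.3) / 0.3)
        assert np.median(errs_w) < 0.05
        assert np.median(errs_tf) < 0.10

    def test_high_r_squared_on_large_sample(self):
        gen = np.random.default_rng(42)
        fast = gen.random(5000) < 0.8
        dwells = np.where(fast, gen.exponential(0.3, 5000), gen.exponential(3.0, 5000))
        res = TwoPhaseDecayModel.from_dwells(dwells).fit()
        assert res.rsquared >= 0.99
        assert res.w_fast == pytest.approx(0.8, abs=0.05)

    def test_fast_label_is_smaller_tau(self):
        t = np.arange(0, 12, 0.125)
        s = 100 * (0.2 * np.exp(-t / 0.3) + 0.8 * np.exp(-t / 3.0))
        res = TwoPhaseDecayModel(t, s).fit()
        assert res.tau_fast_s <= res.tau_slow_s
        assert res.w_fast == pytest.approx(0.2, abs=1e-4)

    def test_summary_and_predict(self):
        t = np.arange(0, 6, 0.125)
        s = 100 * (0.8 * np.exp(-t / 0.3) + 0.2 * np.exp(-t / 3.0))
        res = TwoPhaseDecayModel(t, s).fit()
        assert "tau_fast_s" in res.summary()
        assert res.predict(np.array([0.0]))[0] == pytest.approx(100.0)

    def test_rejects_short_curves(self):
        with pytest.raises(ValueError):
            TwoPhaseDecayModel(np.arange(5) * 0.125, np.full(5, 100.0))

    def test_truncated_fit_recovers_untruncated_parameters(self):
        """Left-truncated dwell samples still yield the full-mixture w."""
        gen = np.random.default_rng(7)
        fast = gen.random(20000) < 0.8
        dwells = np.where(fast, gen.exponential(0.3, 20000), gen.exponential(3.0, 20000))
        kept = dwells[dwells >= 0.25]
        res = TwoPhaseDecayModel.from_dwells(kept).fit(left_truncation_s=0.25)
        assert res.w_fast == pytest.approx(0.8, abs=0.05)
        assert res.tau_fast_s == pytest.approx(0.3, rel=0.1)


class TestKd:
    def test_cancellation_case(self):
        s = estimate_kd(kon_mean=802.0, dwell_fast_s=1.0, sites_per_um=802.0)
        assert s.kd_uM == pytest.approx(0.001)

    def test_direct_arithmetic(self):
        s = estimate_kd(kon_mean=0.1, dwell_fast_s=0.5, sites_per_um=802.0)
        assert s.kd_uM == pytest.approx(16.04)

    def test_rejects_zero_kon(self):
        with pytest.raises(ValueError):
            estimate_kd(0.0, 1.0, 802.0)

    def test_summary_consistency_invariant_enforced(self):
        with pytest.raises(ValueError):
            KineticsSummary(kon_mean=1.0, kon_sem=0.0, koff=1.0,
                            sites_per_um=802.0, kd_uM=5.0)

    def test_end_to_end_recovery(self):
        obs, truth = simulate_binding_assay(
            mt_lengths_um=[10.0] * 50, duration_s=360.0, conc_nM=0.58, seed=11,
        )
        result = analyze_binding_assay(obs)
        assert abs(result["summary"].kd_uM - truth["kd_uM"]) / truth["kd_uM"] < 0.20
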