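"""Synthetic-assay generators against their analytic ground truth."""

import numpy as np
import pytest
from scipy import stats as sps

from mtbond import (
    AnisotropicBond,
    MotorLinkage,
    PullingProtocol,
    RateLaw,
    TrapConfig,
    effective_loading_rate,
    peak_loading_rate,
    simulate_dwells,
    simulate_events,
    simulate_runs,
    simulate_trace,
)
from mtbond.detection import DetectionParams, detect_events
from mtbond.synthetic import ConfigError


class TestEffectiveLoadingRate:
    def test_nominal_assay_rate(self):
        # the weak-binding operating point of the constant-pulling assay
        trap = TrapConfig(k_trap=0.025, v_stage=225.0)
        assert effective_loading_rate(trap, MotorLinkage()) == pytest.approx(5.625)

    def test_equal_series_springs_halve_the_rate(self):
        trap = TrapConfig(k_trap=0.06, v_stage=100.0)
        link = MotorLinkage.compliant(0.06)
        assert effective_loading_rate(trap, link) == pytest.approx(3.0)

    def test_series_spring_closed_form(self):
        trap = TrapConfig(k_trap=0.06, v_stage=90.0)
        link = MotorLinkage.compliant(0.2)
        expected = 90.0 / (1 / 0.06 + 1 / 0.2)
        assert effective_loading_rate(trap, link) == pytest.approx(expected)
        assert expected == pytest.approx(4.1538, abs=1e-4)

    def test_oscillatory_peak_rate(self):
        # rapid trap jumps at ~1 mm/s produce ~25,000 pN/s peak loading
        trap = TrapConfig(k_trap=0.025, v_stage=225.0)
        proto = PullingProtocol(mode="oscillatory", amplitude=250.0, trap_speed=1e6)
        assert peak_loading_rate(trap, MotorLinkage(), proto) == pytest.approx(25_000.0)


class TestSimulateEvents:
    def test_unbreakable_bond_fully_censored(self, nominal_trap, rigid_link,
                                             constant_pull):
        law = RateLaw.ideal(1e-9)
        bond = AnisotropicBond(forward=law, backward=law)
        es = simulate_events(bond, nominal_trap, rigid_link, constant_pull, 50, seed=0)
        assert all(e.censored for e in es.events)
        assert es.forces().size == 0  # censored records never enter statistics

    def test_ideal_bond_mean_force_matches_closed_form(
        self, ideal_bond, nominal_trap, rigid_link, constant_pull
    ):
        es = simulate_events(ideal_bond, nominal_trap, rigid_link, constant_pull,
                             5000, seed=1)
        f = es.forces(direction="forward")
        se = f.std(ddof=1) / np.sqrt(f.size)
        assert f.mean() == pytest.approx(5.625, abs=3 * se)

    def test_constant_loading_rate_recorded_per_event(
        self, ideal_bond, nominal_trap, rigid_link, constant_pull
    ):
        es = simulate_events(ideal_bond, nominal_trap, rigid_link, constant_pull,
                             20, seed=4)
        assert all(e.r_local == pytest.approx(5.625) for e in es.events)
        assert all(e.F_start == 0.0 and e.primary for e in es.events)

    def test_identical_seed_reproduces_table(self, wt_like_bond, nominal_trap,
                                             rigid_link, constant_pull):
        a = simulate_events(wt_like_bond, nominal_trap, rigid_link, constant_pull,
                            200, seed=9)
        b = simulate_events(wt_like_bond, nominal_trap, rigid_link, constant_pull,
                            200, seed=9)
        assert a.to_frame().equals(b.to_frame())

    def test_ideal_bond_forces_pass_ks_against_exponential(
        self, ideal_bond, nominal_trap, rigid_link, constant_pull
    ):
        es = simulate_events(ideal_bond, nominal_trap, rigid_link, constant_pull,
                             2000, seed=12)
        f = es.forces(direction="backward")
        # analytic rupture pdf of an ideal bond is exponential, scale r/k0
        res = sps.kstest(f, "expon", args=(0, 5.625))
        assert res.pvalue > 0.01

    def test_force_dependent_loading_rate_path(self, ideal_bond, nominal_trap,
                                               rigid_link, constant_pull):
        r_fn = lambda F: 4.0 + 0.5 * np.asarray(F)
        es = simulate_events(ideal_bond, nominal_trap, rigid_link, constant_pull,
                             500, seed=3, r_fn=r_fn)
        for e in es.events[:50]:
            assert e.r_local == pytest.approx(4.0 + 0.5 * abs(e.F_unbind), rel=1e-9)


class TestSimulateTrace:
    def test_no_binding_gives_pure_noise_and_empty_log(self, nominal_trap,
                                                       rigid_link, constant_pull):
        bond = AnisotropicBond(forward=RateLaw.ideal(1.0), backward=RateLaw.ideal(1.0))
        tr = simulate_trace(bond, nominal_trap, rigid_link, constant_pull,
                            duration=2.0, k_on=0.0, seed=5, bind_at_start=False)
        assert tr.truth.N == 0
        assert abs(tr.F.mean()) < 0.02
        assert tr.F.std() == pytest.approx(nominal_trap.sigma_noise, rel=0.1)

    def test_noiseless_rupture_force_matches_trace_sample(
        self, noiseless_trap, rigid_link, constant_pull, wt_like_bond
    ):
        tr = simulate_trace(wt_like_bond, noiseless_trap, rigid_link, constant_pull,
                            duration=30.0, k_on=5.0, seed=6)
        assert tr.truth.N > 0
        idx = {round(t * noiseless_trap.f_sample): i for i, t in enumerate(tr.t)}
        for e in tr.truth.events:
            i = idx[round(e.t_unbind * noiseless_trap.f_sample)]
            assert tr.F[i] == pytest.approx(e.F_unbind, abs=1e-12)

    def test_rebinding_during_relaxation_creates_secondary_events(
        self, rigid_link, constant_pull, wt_like_bond
    ):
        trap = TrapConfig(sigma_noise=0.0, tau_bead=0.05, f_sample=2000.0)
        tr = simulate_trace(wt_like_bond, trap, rigid_link, constant_pull,
                            duration=120.0, k_on=10.0, seed=7)
        f_starts = [e.F_start for e in tr.truth.events]
        assert max(f_starts) > 0.3  # rebinding before full relaxation

    def test_unresolvable_relaxation_rejected(self, rigid_link, constant_pull,
                                              wt_like_bond):
        trap = TrapConfig(f_sample=100.0, tau_bead=0.005)
        with pytest.raises(ConfigError, match="tau_bead"):
            simulate_trace(wt_like_bond, trap, rigid_link, constant_pull,
                           duration=1.0, k_on=0.0, seed=0)

    def test_trace_and_event_simulators_agree(self, noiseless_trap, rigid_link,
                                              wt_like_bond):
        # rupture forces via trace + detection vs. the event-level fast path
        proto = PullingProtocol(sweep_duration=1e6)  # single forward sweep
        params = DetectionParams(smooth_window=1)
        detected = []
        for seed in range(250):
            tr = simulate_trace(wt_like_bond, noiseless_trap, rigid_link, proto,
                                duration=12.0, k_on=0.0, seed=100 + seed)
            es = detect_events(tr, params)
            detected.extend(es.forces(direction="forward"))
        fast = simulate_events(wt_like_bond, noiseless_trap, rigid_link, proto,
                               1000, seed=999).forces(direction="forward")
        fast = fast[fast >= 0.3]  # detector cannot see sub-threshold events
        res = sps.ks_2samp(np.asarray(detected), fast)
        assert res.pvalue > 0.01


class TestSimulateDwells:
    def test_recorded_dwells_are_whole_frames(self):
        ds = simulate_dwells(rate=3.5, n=500, frame_interval=0.1, seed=0)
        ratio = ds.dwells / 0.1
        np.testing.assert_allclose(ratio, np.round(ratio), atol=1e-9)
        assert np.all(ds.dwells >= 0.1)

    def test_subframe_dwells_discarded_and_counted(self):
        ds = simulate_dwells(rate=3.5, n=10_000, frame_interval=0.1, seed=1)
        assert ds.n + ds.n_discarded == 10_000
        # P(T < frame) = 1 - exp(-rate*frame) ~ 0.295
        frac = ds.n_discarded / 10_000
        assert frac == pytest.approx(1 - np.exp(-0.35), abs=0.02)

    def test_mean_matches_frame_quantized_expectation(self):
        # E[recorded] = frame + frame/(1 - exp(-rate*frame)) for kept dwells
        rate, frame = 3.5, 0.1
        ds = simulate_dwells(rate=rate, n=10_000, frame_interval=frame, seed=2)
        expected = frame + frame / (1 - np.exp(-rate * frame))
        se = ds.dwells.std(ddof=1) / np.sqrt(ds.n)
        assert ds.dwells.mean() == pytest.approx(expected, abs=3 * se)
        # underlying continuous bound time is ~290 ms at 3.5 1/s
        assert 1.0 / rate == pytest.approx(0.29, abs=0.005)

    def test_same_seed_identical_output(self):
        a = simulate_dwells(3.5, 1000, 0.1, seed=42)
        b = simulate_dwells(3.5, 1000, 0.1, seed=42)
        np.testing.assert_array_equal(a.dwells, b.dwells)


class TestSimulateRuns:
    def test_zero_velocity_spread_is_degenerate(self):
        rs = simulate_runs(108.0, 0.0, 1.1, 0.0, 50, seed=0)
        assert np.all(rs.velocities == 108.0)

    def test_exponential_run_length_mean(self):
        rs = simulate_runs(108.0, 32.0, 1.1, 0.0, 10_000, seed=3)
        se = rs.run_lengths.std(ddof=1) / np.sqrt(rs.n)
        assert rs.run_lengths.mean() == pytest.approx(1.1, abs=3 * se)

    def test_run_lengths_respect_minimum(self):
        rs = simulate_runs(108.0, 32.0, 1.1, L_min=0.3, n=1000, seed=4)
        assert np.all(rs.run_lengths >= 0.3)
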