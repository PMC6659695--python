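"""KDE, loading-rate models, and the k(F) = r p / S reconstruction."""

import numpy as np
import pytest

from mtbond import (
    AnisotropicBond,
    MotorLinkage,
    PullingProtocol,
    RateLaw,
    TrapConfig,
    attach_zero_load_anchor,
    bootstrap_rate_bands,
    fit_kde,
    loading_rate_fn,
    simulate_events,
    unbinding_rate_curve,
)
from mtbond.reconstruction import ReconstructionError
from mtbond.synthetic import EventSet, RuptureEvent


def _events_from_forces(forces, r_local=5.625, direction="forward"):
    sign = -1.0 if direction == "forward" else 1.0
    evts = [
        RuptureEvent(F_unbind=sign * f, F_start=0.0, direction=direction,
                     r_local=r_local, primary=True, t_bind=0.0,
                     t_unbind=f / r_local, trace_id=f"e{i}")
        for i, f in enumerate(forces)
    ]
    return EventSet(events=evts)


class TestFitKde:
    def test_density_nonnegative_and_normalized(self):
        rng = np.random.default_rng(0)
        kde = fit_kde(rng.exponential(5.6, 2000))
        assert np.all(kde.density >= 0)
        integral = np.trapezoid(kde.density, kde.grid)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_known_exponential_density_recovered(self):
        rng = np.random.default_rng(1)
        kde = fit_kde(rng.exponential(5.6, 5000))
        F = np.linspace(0, 10, 101)
        true = np.exp(-F / 5.6) / 5.6
        mae = np.mean(np.abs(kde(F) - true))
        assert mae < 0.01

    def test_small_sample_rejected(self):
        with pytest.raises(ReconstructionError, match="pool"):
            fit_kde(np.ones(10))

    def test_degenerate_sample_falls_back_flagged(self):
        kde = fit_kde(np.full(100, 2.0))
        assert kde.degenerate
        assert kde.bandwidth > 0


class TestLoadingRateFn:
    def test_constant_from_recorded_rates(self):
        es = _events_from_forces(np.linspace(1, 5, 30))
        fn = loading_rate_fn(es, method="constant")
        assert fn(2.0) == pytest.approx(5.625)

    def test_series_spring_closed_form(self):
        es = _events_from_forces(np.linspace(1, 5, 30))
        fn = loading_rate_fn(es, method="series_spring", k_trap=0.06,
                             k_motor=0.2, v=90.0)
        expected = 90.0 / (1 / 0.06 + 1 / 0.2)
        assert fn(0.5) == pytest.approx(expected, abs=1e-9)
        assert fn(5.0) == fn(0.5)  # linear springs: force-independent

    def test_empirical_fit_recovers_generative_trend(self):
        # events carry r_local = 3 + 0.6 F; the fit must recover it within 10%
        rng = np.random.default_rng(2)
        F = rng.uniform(0.5, 6.0, 400)
        evts = [
            RuptureEvent(F_unbind=-f, F_start=0.0, direction="forward",
                         r_local=3.0 + 0.6 * f + rng.normal(0, 0.2),
                         primary=True, t_bind=0.0, t_unbind=1.0,
                         trace_id=str(i))
            for i, f in enumerate(F)
        ]
        fn = loading_rate_fn(EventSet(events=evts), method="empirical_fit")
        grid = np.linspace(0.5, 6.0, 12)
        np.testing.assert_allclose(fn(grid), 3.0 + 0.6 * grid, rtol=0.10)

    def test_empirical_fit_needs_enough_events(self):
        es = _events_from_forces(np.linspace(1, 5, 10))
        with pytest.raises(ReconstructionError, match="20"):
            loading_rate_fn(es, method="empirical_fit")


class TestUnbindingRateCurve:
    def test_exponential_forces_give_flat_rate(self):
        # p/S is constant for an exponential sample: k(F) = k0 everywhere
        rng = np.random.default_rng(3)
        es = _events_from_forces(rng.exponential(5.625, 5000))
        curve = unbinding_rate_curve(es, loading_rate_fn(es, method="constant"))
        mask = curve.S >= 0.1
        rel = np.abs(curve.k[mask] - 1.0)
        assert rel.mean() < 0.05

    def test_reporting_floor_at_half_picomewton(self):
        rng = np.random.default_rng(4)
        es = _events_from_forces(rng.exponential(3.0, 500))
        curve = unbinding_rate_curve(es, loading_rate_fn(es, method="constant"))
        assert curve.F.min() >= 0.5

    def test_survival_cutoff_respected(self):
        rng = np.random.default_rng(5)
        es = _events_from_forces(rng.exponential(3.0, 500))
        curve = unbinding_rate_curve(es, loading_rate_fn(es, method="constant"),
                                     S_min=0.05)
        assert np.all(curve.S >= 0.05)
        assert np.all(curve.n_beyond >= 5)

    @pytest.mark.parametrize(
        "law",
        [
            RateLaw.bell_slip(0.3, 1.5),
            RateLaw.slip_ideal(0.5, 1.2, 2.0),
        ],
        ids=["bell-slip", "slip-ideal"],
    )
    def test_simulated_law_recovered_within_fifteen_percent(self, law):
        # agreement averaged over the supported grid; single tail points
        # carry ~13% sampling noise at n=2000 so a pointwise max is not
        # a meaningful recovery metric there
        bond = AnisotropicBond(forward=law, backward=law)
        es = simulate_events(bond, TrapConfig(), MotorLinkage(),
                             PullingProtocol(), 2000, seed=6)
        sub = es.select(direction="forward")
        curve = unbinding_rate_curve(sub, loading_rate_fn(sub, method="constant"))
        mask = curve.S >= 0.1
        truth = np.asarray(law.rate(curve.F[mask]))
        rel = np.abs(curve.k[mask] / truth - 1.0)
        assert rel.mean() < 0.15
        # the well-sampled region (S >= 0.3) is accurate pointwise
        core = curve.S >= 0.3
        truth_core = np.asarray(law.rate(curve.F[core]))
        np.testing.assert_allclose(curve.k[core], truth_core, rtol=0.15)

    def test_too_few_events_rejected(self):
        es = _events_from_forces(np.linspace(1, 5, 30))
        with pytest.raises(ReconstructionError, match="50"):
            unbinding_rate_curve(es, loading_rate_fn(es, method="constant"))


class TestBootstrapRateBands:
    def test_bands_contain_point_estimate(self):
        rng = np.random.default_rng(7)
        es = _events_from_forces(rng.exponential(5.625, 500))
        curve = bootstrap_rate_bands(es, loading_rate_fn(es, method="constant"),
                                     n_boot=200, seed=8)
        assert np.all(curve.lo <= curve.k + 1e-12)
        assert np.all(curve.hi >= curve.k - 1e-12)

    def test_band_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(9)
        widths = {}
        for n in (200, 2000):
            es = _events_from_forces(rng.exponential(5.625, n))
            curve = bootstrap_rate_bands(es, loading_rate_fn(es, method="constant"),
                                         n_boot=200, seed=10)
            i = np.argmin(np.abs(curve.F - 2.0))
            widths[n] = curve.hi[i] - curve.lo[i]
        assert widths[2000] < widths[200]

    def test_ideal_bond_truth_covered_at_most_grid_points(self, ideal_bond):
        es = simulate_events(ideal_bond, TrapConfig(), MotorLinkage(),
                             PullingProtocol(), 1000, seed=11)
        sub = es.select(direction="forward")
        curve = bootstrap_rate_bands(sub, loading_rate_fn(sub, method="constant"),
                                     n_boot=400, seed=12)
        mask = curve.S >= 0.1
        covered = (curve.lo[mask] <= 1.0) & (1.0 <= curve.hi[mask])
        assert covered.mean() >= 0.9


class TestZeroLoadAnchor:
    def test_anchor_stored_without_altering_curve(self):
        rng = np.random.default_rng(13)
        es = _events_from_forces(rng.exponential(5.625, 300))
        base = unbinding_rate_curve(es, loading_rate_fn(es, method="constant"))
        anchored = attach_zero_load_anchor(base, 3.5, 0.1)
        assert anchored.anchor_rate == 3.5
        np.testing.assert_array_equal(anchored.k, base.k)

    def test_anchor_consistent_with_ideal_curve_band(self):
        # zero-load rate and the reconstructed curve describe the same bond
        law = RateLaw.ideal(3.5, F_max=120.0)
        bond = AnisotropicBond(forward=law, backward=law)
        es = simulate_events(bond, TrapConfig(), MotorLinkage(),
                             PullingProtocol(), 1000, seed=14)
        sub = es.select(direction="forward")
        curve = bootstrap_rate_bands(sub, loading_rate_fn(sub, method="constant"),
                                     n_boot=300, seed=15)
        curve = attach_zero_load_anchor(curve, 3.5, 0.1)
        assert curve.lo[0] <= curve.anchor_rate <= curve.hi[0]

    def test_nonpositive_anchor_rejected(self):
        rng = np.random.default_rng(16)
        es = _events_from_forces(rng.exponential(5.625, 300))
        base = unbinding_rate_curve(es, loading_rate_fn(es, method="constant"))
        with pytest.raises(ReconstructionError):
            attach_zero_load_anchor(base, 0.0)
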