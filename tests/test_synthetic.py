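"""Synthetic ACFs, Brownian/telegraph photon traces and the correlator."""

import numpy as np
import pytest

from petfcs import (DiffusionComponent, FocusGeometry, IntensityTrace,
                    KineticPhase, MultiTauGrid, TwoStateScheme,
                    default_lag_grid, direct_correlate, fit_acf, full_acf,
                    multi_tau_correlate, simulate_trace, split_channels,
                    synth_acf)
from petfcs.synthetic import correct_finite_box


class TestSynthAcf:
    def test_noise_free_equals_model(self, lag_grid):
        comp = DiffusionComponent(2.0, 1e-3)
        phases = [KineticPhase(0.4, 1e-5)]
        c = synth_acf(comp, phases, lag_grid, noise_scale=0.0, duration=600, seed=0)
        np.testing.assert_array_equal(c.g, full_acf(c.lags, comp, phases))
        assert c.g_se is None

    def test_same_seed_same_curve(self, lag_grid):
        comp = DiffusionComponent(1.0, 1e-3)
        a = synth_acf(comp, [], lag_grid, 0.05, 600, seed=9)
        b = synth_acf(comp, [], lag_grid, 0.05, 600, seed=9)
        np.testing.assert_array_equal(a.g, b.g)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            synth_acf(DiffusionComponent(1, 1e-3), [], np.array([]), 0.01, 600, 0)

    def test_noise_sd_matches_model(self):
        """Monte-Carlo: across 1000 replicate seeds the per-lag sample s.d.
        tracks sigma_k = noise_scale*(1+g_k)*sqrt(lag_k/duration)."""
        comp = DiffusionComponent(1.0, 0.5e-3)
        lags = np.array([1e-6, 1e-4, 1e-2])
        reps = np.array([
            synth_acf(comp, [], lags, 0.05, 600, seed=s).g for s in range(1000)
        ])
        model = full_acf(lags, comp, [])
        sigma = 0.05 * (1 + model) * np.sqrt(lags / 600)
        np.testing.assert_allclose(reps.std(axis=0), sigma, rtol=0.10)


class TestSimulateTrace:
    def test_empty_focus_gives_zero_counts(self):
        tr = simulate_trace(None, FocusGeometry(), 1e-10, 0.0, background=0.0,
                            duration=0.01, bin_width=1e-5, seed=0)
        assert tr.counts.sum() == 0

    def test_negative_occupancy_rejected(self):
        with pytest.raises(ValueError):
            simulate_trace(None, FocusGeometry(), 1e-10, -1.0,
                           duration=0.01, bin_width=1e-5, seed=0)

    def test_immobile_center_molecule_is_poisson(self):
        """A single immobile emitter at the focus centre yields i.i.d.
        Poisson counts at rate brightness*bin_width."""
        lam = 50e3 * 1e-5
        tr = simulate_trace(None, FocusGeometry(), 0.0, 1e-9,
                            brightness=50e3, background=0.0,
                            duration=1.0, bin_width=1e-5, seed=5,
                            initial_positions=np.array([[0.0, 0.0]]))
        c = tr.counts[0]
        assert c.mean() == pytest.approx(lam, rel=0.02)
        assert c.var() == pytest.approx(lam, rel=0.05)  # Poisson: var = mean

    def test_under_resolved_kinetics_warns(self):
        scheme = TwoStateScheme(1e5, 1e5)
        with pytest.warns(UserWarning, match="under-resolves"):
            simulate_trace(scheme, FocusGeometry(), 1e-10, 0.5,
                           duration=2e-3, bin_width=1e-6, seed=0)

    def test_diffusion_time_recovered(self):
        """End-to-end: planar Brownian motion with tau_D = w^2/(4D) = 200 us
        recovers that diffusion time from the correlated trace within 15%."""
        w = 250e-9
        tau_d = 200e-6
        d_coeff = w**2 / (4 * tau_d)
        taus = []
        for seed in range(3):
            tr = simulate_trace(None, FocusGeometry(waist_xy=w), d_coeff, 2.0,
                                brightness=50e3, background=0.0,
                                duration=1.5, bin_width=5e-6, seed=seed)
            sp = split_channels(tr, seed=seed + 100)
            curve = correct_finite_box(multi_tau_correlate(sp), tr)
            taus.append(fit_acf(curve, 0).diffusion.tau_d)
        assert np.mean(taus) == pytest.approx(tau_d, rel=0.15)


class TestSplitChannels:
    def test_zero_trace_splits_to_zeros(self):
        tr = IntensityTrace(1e-5, np.zeros((1, 100), dtype=int))
        sp = split_channels(tr, seed=0)
        assert sp.n_channels == 2
        assert sp.counts.sum() == 0

    def test_channel_sums_conserved(self):
        rng = np.random.default_rng(0)
        tr = IntensityTrace(1e-5, rng.poisson(3.0, size=(1, 10000)))
        sp = split_channels(tr, seed=1)
        np.testing.assert_array_equal(sp.counts.sum(axis=0), tr.counts[0])

    def test_binomial_halving(self):
        rng = np.random.default_rng(1)
        tr = IntensityTrace(1e-6, rng.poisson(2.0, size=(1, 10**6)))
        sp = split_channels(tr, seed=2)
        total = tr.counts.sum()
        # channel A is Binomial(total, 1/2): 5 sigma band
        assert abs(sp.counts[0].sum() - total / 2) < 5 * np.sqrt(total) / 2

    def test_rejects_two_channel_input(self):
        tr = IntensityTrace(1e-5, np.zeros((2, 100), dtype=int))
        with pytest.raises(ValueError):
            split_channels(tr, seed=0)


class TestMultiTauCorrelate:
    def test_constant_trace_gives_zero(self):
        tr = IntensityTrace(1e-5, np.full((1, 4096), 7, dtype=int))
        cv = multi_tau_correlate(tr, m=8)
        np.testing.assert_allclose(cv.g, 0.0, atol=1e-12)

    def test_shot_noise_uncorrelated_across_channels(self):
        """Split channels of an i.i.d. Poisson trace share no shot noise:
        the cross-correlation is zero within its standard error."""
        rng = np.random.default_rng(3)
        tr = IntensityTrace(1e-6, rng.poisson(1.0, size=(1, 2**17)),
                            n_molecules_box=0)
        sp = split_channels(tr, seed=4)
        cv = multi_tau_correlate(sp)
        assert np.all(np.abs(cv.g) < 5 * cv.g_se)

    def test_agrees_with_brute_force(self):
        """Block-1 lags equal a direct correlation exactly; every deeper
        block equals a direct correlation of the externally re-binned trace
        (the brute-force multi-tau oracle), and the whole curve stays near
        the un-binned direct estimate."""
        m, n_blocks = 8, 5
        tr = simulate_trace(None, FocusGeometry(), 7.8e-12, 1.0,
                            brightness=200e3, background=1e3,
                            duration=2**14 * 1e-5, bin_width=1e-5, seed=6)
        sp = split_channels(tr, seed=7)
        cv = multi_tau_correlate(sp, m=m, n_blocks=n_blocks)
        # oracle: per level, pairwise-rebin the counts and correlate directly
        counts = sp.counts.astype(float)
        oracle = []
        for level in range(n_blocks):
            lags = np.arange(1, 2 * m + 1) if level == 0 else np.arange(m + 1, 2 * m + 1)
            ref = IntensityTrace(tr.bin_width * 2**level, counts.astype(int))
            oracle.append(direct_correlate(ref, lags).g)
            t = counts.shape[1] - counts.shape[1] % 2
            counts = counts[:, :t].reshape(2, -1, 2).sum(axis=2)
        np.testing.assert_allclose(cv.g, np.concatenate(oracle),
                                   rtol=0, atol=1e-12)

    def test_short_trace_error_names_minimum(self):
        tr = IntensityTrace(1e-5, np.ones((1, 100), dtype=int))
        with pytest.raises(ValueError, match="at least"):
            multi_tau_correlate(tr, m=16, n_blocks=8)

    def test_invariant_under_intensity_scaling(self):
        """G is unchanged in expectation when the expected count rate is
        scaled by a constant (correlator linearity).  An immobile blinking
        emitter gives a well-averaged reference decay."""
        scheme = TwoStateScheme(1e4, 1e4)  # a = 1, tau_rel = 50 us
        def mean_g(brightness):
            gs = []
            for seed in range(3):
                tr = simulate_trace(scheme, FocusGeometry(), 0.0, 1e-9,
                                    brightness=brightness, background=0.0,
                                    duration=1.0, bin_width=2e-6, seed=seed,
                                    initial_positions=np.array([[0.0, 0.0]]))
                cv = multi_tau_correlate(split_channels(tr, seed + 50))
                gs.append(cv.g[:32])
            return np.mean(gs, axis=0)
        g1 = mean_g(100e3)
        g2 = mean_g(400e3)
        np.testing.assert_allclose(g1, g2, atol=0.05)


def test_grid_layout_and_minimum_length():
    grid = MultiTauGrid(bin_width=1e-6, m=4, n_blocks=3)
    lags = grid.lags()
    # 2m native lags, then m lags per extra block at doubled widths
    expected = np.concatenate([
        1e-6 * np.arange(1, 9), 2e-6 * np.arange(5, 9), 4e-6 * np.arange(5, 9)])
    np.testing.assert_allclose(lags, expected)
    assert grid.min_trace_bins == 2 * 4 * 2**3


def test_default_grid_spans_ns_to_s():
    lags = default_lag_grid().lags()
    assert lags[0] == pytest.approx(25e-9)
    assert lags[-1] > 0.5
    assert np.all(np.diff(lags) > 0)
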