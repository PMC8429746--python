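"""ACF fitting, nested model selection, phase assignment and comparison."""

import numpy as np
import pytest

from petfcs import (ACFModelFit, CorrelationCurve, DiffusionComponent,
                    KineticPhase, assign_phases, compare_conditions, fit_acf,
                    select_model, synth_acf)
from petfcs.datasets import DEFAULT_DIFFUSION, GLUA2_KINETICS


def make_fit(phases, converged=True):
    """Construct a fit object directly (comparison utilities are pure
    functions of fitted parameters)."""
    phases = sorted(phases, key=lambda p: -p.tau)
    return ACFModelFit(
        diffusion=DiffusionComponent(1.0, 0.5e-3), phases=list(phases),
        n_exp=len(phases), chi2=1.0, dof=100, residuals=np.array([]),
        covariance=None, converged=converged, seed=0,
        lag_min=25e-9, lag_max=0.84, weighted=True)


class TestFitAcf:
    def test_noise_free_three_phase_recovery(self, noise_free_apo_curve):
        """All 8 parameters of the three-phase apo model are recovered to
        1e-4 relative from a noise-free curve."""
        fit = fit_acf(noise_free_apo_curve, 3)
        assert fit.diffusion.n_molecules == pytest.approx(1.0, rel=1e-4)
        assert fit.diffusion.tau_d == pytest.approx(0.5e-3, rel=1e-4)
        for ph, true in zip(fit.phases, GLUA2_KINETICS["apo"]):
            assert ph.amplitude == pytest.approx(true.amplitude, rel=1e-4)
            assert ph.tau == pytest.approx(true.tau, rel=1e-4)

    def test_diffusion_only_noise_free_exact(self, lag_grid):
        c = synth_acf(DiffusionComponent(2.5, 0.3e-3), [], lag_grid, 0.0, 600, 0)
        fit = fit_acf(c, 0)
        assert fit.diffusion.n_molecules == pytest.approx(2.5, rel=1e-10)
        assert fit.diffusion.tau_d == pytest.approx(0.3e-3, rel=1e-10)
        assert fit.chi2 < 1e-12

    def test_deterministic_given_seed(self, apo_curve):
        f1 = fit_acf(apo_curve, 3, seed=1)
        f2 = fit_acf(apo_curve, 3, seed=1)
        assert f1.parameters == f2.parameters
        assert f1.chi2 == f2.chi2

    def test_constant_curve_rejected(self):
        c = CorrelationCurve(lags=np.geomspace(1e-6, 1e-2, 30),
                             g=np.full(30, 0.5))
        with pytest.raises(ValueError, match="degenerate"):
            fit_acf(c, 0)

    def test_too_few_lags_rejected(self):
        c = CorrelationCurve(lags=np.array([1e-6, 2e-6, 4e-6, 8e-6]),
                             g=np.array([1.0, 0.9, 0.8, 0.7]))
        with pytest.raises(ValueError, match="lags"):
            fit_acf(c, 1)

    def test_fix_n_molecules(self, lag_grid):
        c = synth_acf(DiffusionComponent(1.0, 0.5e-3),
                      [KineticPhase(0.3, 1e-5)], lag_grid, 0.0, 600, 0)
        fit = fit_acf(c, 1, fix_n_molecules=1.0)
        assert fit.diffusion.n_molecules == 1.0
        assert fit.phases[0].amplitude == pytest.approx(0.3, rel=1e-6)

    def test_phases_sorted_by_decreasing_tau(self, apo_curve):
        fit = fit_acf(apo_curve, 3)
        taus = [p.tau for p in fit.phases]
        assert taus == sorted(taus, reverse=True)

    def test_parameter_recovery_under_noise(self, lag_grid):
        """Median relative errors of recovered amplitudes and time
        constants stay below 10% over 100 noisy replicates."""
        true = GLUA2_KINETICS["apo"]
        errs_a, errs_t = [], []
        for seed in range(100):
            c = synth_acf(DEFAULT_DIFFUSION, true, lag_grid, 0.02, 600, seed=seed)
            fit = fit_acf(c, 3, seed=seed)
            for ph, tr in zip(fit.phases, true):
                errs_a.append(abs(ph.amplitude - tr.amplitude) / tr.amplitude)
                errs_t.append(abs(ph.tau - tr.tau) / tr.tau)
        assert np.median(errs_a) <= 0.10
        assert np.median(errs_t) <= 0.10


class TestSelectModel:
    def test_pure_diffusion_selects_zero(self, diffusion_only_curve):
        assert select_model(diffusion_only_curve).selected.n_exp == 0

    def test_one_phase_selected_reliably(self, lag_grid):
        """With one genuine phase (a=0.5, tau=10 us) plus 1% noise, the
        ladder picks n=1 in at least 95% of 50 replicates."""
        hits = 0
        for seed in range(50):
            c = synth_acf(DiffusionComponent(1.0, 0.5e-3),
                          [KineticPhase(0.5, 10e-6)], lag_grid, 0.01, 600,
                          seed=seed)
            hits += select_model(c, seed=seed).selected.n_exp == 1
        assert hits >= 48  # 95% of 50, rounded up

    def test_three_phase_apo_selects_three(self, apo_curve):
        report = select_model(apo_curve)
        assert report.selected.n_exp == 3

    def test_chi2_monotone_in_model_size(self, apo_curve):
        report = select_model(apo_curve)
        chi2s = [report.fits[n].chi2 for n in sorted(report.fits)]
        assert all(b <= a * (1 + 1e-12) for a, b in zip(chi2s, chi2s[1:]))

    def test_selected_fit_passes_own_filters(self, apo_curve):
        from petfcs.fitting import _sanity_flags
        report = select_model(apo_curve)
        assert all(_sanity_flags(report.selected).values())

    def test_rationale_recorded_for_rejection(self, apo_curve):
        report = select_model(apo_curve)
        assert 4 in report.rationale  # n=4 was tried and rejected, with a reason
        assert report.rationale[4]

    def test_information_criterion_alternative(self, diffusion_only_curve):
        assert select_model(diffusion_only_curve,
                            criterion="bic").selected.n_exp == 0


class TestAssignPhases:
    def test_threshold_filters_small_amplitudes(self):
        fit = make_fit([KineticPhase(0.06, 4e-6), KineticPhase(0.22, 180e-9)])
        assigned = assign_phases(fit)
        assert [p.amplitude for p in assigned] == [0.22]

    def test_empty_and_identity(self):
        assert assign_phases(make_fit([])) == []
        fit = make_fit([KineticPhase(0.01, 1e-6)])
        assert assign_phases(fit, amplitude_threshold=0.0) == fit.phases

    def test_requires_converged_fit(self):
        with pytest.raises(ValueError):
            assign_phases(make_fit([], converged=False))


class TestCompareConditions:
    def test_apo_versus_agonist_pattern(self):
        """Three apo phases against a single residual ns phase: the two
        slower (us) motions are stalled, the ns phase matches."""
        apo = make_fit([KineticPhase(0.17, 113e-6), KineticPhase(0.25, 6e-6),
                        KineticPhase(0.48, 320e-9)])
        glu = make_fit([KineticPhase(0.20, 300e-9)])
        comp = compare_conditions(apo, glu)
        assert sorted(p.tau for p in comp.stalled) == [6e-6, 113e-6]
        assert len(comp.matched) == 1
        assert comp.matched[0][0].tau == 320e-9
        assert not comp.emergent

    def test_identical_fits_fully_matched(self):
        fit = make_fit([KineticPhase(0.2, 1e-5), KineticPhase(0.3, 1e-6)])
        comp = compare_conditions(fit, fit)
        assert len(comp.matched) == 2
        assert not comp.stalled and not comp.emergent

    def test_emergent_phase(self):
        comp = compare_conditions(make_fit([]),
                                  make_fit([KineticPhase(0.45, 200e-9)]))
        assert not comp.stalled
        assert [p.tau for p in comp.emergent] == [200e-9]

    def test_match_factor_limits_pairing(self):
        a = make_fit([KineticPhase(0.2, 100e-6)])
        b = make_fit([KineticPhase(0.2, 1e-6)])
        comp = compare_conditions(a, b, match_factor=3.0)
        assert not comp.matched
        assert len(comp.stalled) == 1 and len(comp.emergent) == 1
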