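"""Dudko-Szabo rate law, rupture densities, sampling and fitting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import fretforce as ff
from fretforce.core_io import KBT_ROOM


def euler_survival_oracle(p, schedule, dt=1e-4, rate_mode="effective"):
    """Brute-force time-domain integration of dS/dt = -k(F(t)) S.

    Independent of the force-domain quadrature used by rupture_pdf:
    steps the survival probability on a fine time grid and differences
    it to get the rupture-force density.
    """
    if rate_mode == "effective":
        rate = schedule.effective_rate
        duration = (schedule.f_max - max(schedule.f_start, 0.0)) / rate
        t = np.arange(0.0, duration + dt, dt)
        F = max(schedule.f_start, 0.0) + rate * t
    else:
        t = np.arange(0.0, schedule.duration, dt)
        F = np.asarray(schedule.force_of_time(t), dtype=float)
    fc = p.critical_force()
    keep = F < fc * (1 - 1e-9)
    t, F = t[keep], F[keep]
    k = ff.ds_rate(F, p)
    H = np.concatenate([[0.0], np.cumsum(0.5 * (k[1:] + k[:-1]) * dt)])
    S = np.exp(-H)
    pdf = -np.gradient(S, F)
    return F, pdf, S[-1]


class TestDsRate:
    def test_zero_force_rate_is_inverse_lifetime(self):
        p = ff.DsParams(4.3, 50.0, 6.5)
        assert ff.ds_rate(0.0, p) == pytest.approx(1.0 / 50.0)

    def test_bell_limit_is_exact_at_nu_one(self):
        """At nu = 1 the rate is (1/tau0) exp(F dx / kBT) for any dG."""
        for dG in (5.0, 50.0, 500.0):
            p = ff.DsParams(4.11, 1.0, dG, nu=1.0)
            F = np.linspace(0.0, 3.0, 7)
            np.testing.assert_allclose(
                ff.ds_rate(F, p), np.exp(F * 4.11 / KBT_ROOM), rtol=1e-15
            )

    def test_hand_checked_cusp_rate(self):
        """nu=1/2, dx=4.3 nm, tau0=50 s, dG=6.5 kBT at 4 pN -> ~0.45 /s."""
        assert ff.ds_rate(4.0, ff.DsParams(4.3, 50.0, 6.5)) == pytest.approx(0.45, abs=0.01)

    def test_domain_error_names_critical_force(self):
        p = ff.DsParams(4.3, 50.0, 6.5)
        with pytest.raises(ValueError, match="F_c"):
            ff.ds_rate(p.critical_force() + 1.0, p)

    def test_hazard_increases_below_inflection(self):
        """For nu=1/2, k(F) rises until (1-u) = 1/sqrt(2 dG)."""
        p = ff.DsParams(4.3, 50.0, 6.5)
        u_star = 1.0 - 1.0 / np.sqrt(2 * p.dG_dagger)
        f_star = u_star * p.dG_dagger * KBT_ROOM / (p.nu * p.dx_dagger)
        F = np.linspace(0.0, f_star * 0.999, 200)
        assert np.all(np.diff(ff.ds_rate(F, p)) > 0)


class TestRupturePdf:
    @given(
        st.floats(min_value=2.0, max_value=8.0),
        st.floats(min_value=1.0, max_value=1e4),
        st.floats(min_value=3.0, max_value=15.0),
    )
    def test_mass_plus_survival_is_one(self, schedule, dx, tau0, dG):
        dens = ff.rupture_pdf(ff.DsParams(dx, tau0, dG), schedule)
        mass = np.trapezoid(dens.pdf, dens.grid)
        assert mass + dens.survival == pytest.approx(1.0, abs=1e-4)

    def test_bell_evans_mode_matches_closed_form(self):
        """Constant ramp, Bell limit: mode = (kBT/dx) ln(rate tau0 dx / kBT)."""
        sch = ff.constant_loading_schedule(1.0, f_max=12.0)
        p = ff.DsParams(4.11, 50.0, 500.0, nu=1.0)
        dens = ff.rupture_pdf(p, sch)
        assert dens.mode() == pytest.approx(np.log(50.0), abs=0.01)

    def test_density_agrees_with_euler_oracle_constant_rate(self, schedule):
        p = ff.DsParams(4.3, 50.0, 6.5)
        dens = ff.rupture_pdf(p, schedule)
        F, pdf_oracle, surv_oracle = euler_survival_oracle(p, schedule)
        interp = np.interp(F[5:-5], dens.grid, dens.pdf)
        np.testing.assert_allclose(interp, pdf_oracle[5:-5], rtol=2e-3, atol=1e-4)
        assert dens.survival == pytest.approx(surv_oracle, abs=1e-4)

    def test_density_agrees_with_euler_oracle_instantaneous(self, schedule):
        p = ff.DsParams(4.0, 10990.0, 11.6)
        dens = ff.rupture_pdf(p, schedule, rate_mode="instantaneous")
        F, pdf_oracle, surv_oracle = euler_survival_oracle(
            p, schedule, rate_mode="instantaneous"
        )
        interp = np.interp(F[5:-5], dens.grid, dens.pdf)
        np.testing.assert_allclose(interp, pdf_oracle[5:-5], rtol=5e-3, atol=2e-4)
        assert dens.survival == pytest.approx(surv_oracle, abs=1e-4)

    def test_truncated_component_reports_residual_survival(self, schedule):
        """A component whose barrier vanishes inside the ramp keeps its
        survival at F_c as explicit (unresolvable) mass."""
        p = ff.DsParams(4.3, 500.0, 6.5)  # F_c ~ 12.4 pN < F_max
        dens = ff.rupture_pdf(p, schedule)
        assert dens.component_fc[0] < schedule.f_max
        assert dens.component_survival[0] > 0.1
        mass = np.trapezoid(dens.pdf, dens.grid)
        assert mass + dens.survival == pytest.approx(1.0, abs=1e-4)

    def test_mixture_density_is_weighted_sum(self, schedule):
        c1 = ff.DsParams(4.3, 50.0, 6.5)
        c2 = ff.DsParams(4.0, 10990.0, 11.6)
        mix = ff.DsMixture((c1, c2), (0.7, 0.3))
        dens = ff.rupture_pdf(mix, schedule)
        d1 = ff.rupture_pdf(c1, schedule)
        d2 = ff.rupture_pdf(c2, schedule)
        np.testing.assert_allclose(dens.pdf, 0.7 * d1.pdf + 0.3 * d2.pdf, rtol=1e-9)


class TestSampling:
    def test_same_seed_reproduces_samples(self, schedule):
        p = ff.DsParams(4.3, 50.0, 6.5)
        a = ff.sample_ruptures(p, schedule, 200, seed=5)
        b = ff.sample_ruptures(p, schedule, 200, seed=5)
        np.testing.assert_array_equal(a.forces, b.forces)
        assert a.n_censored == b.n_censored

    def test_sampler_matches_quadrature_cdf(self, schedule):
        p = ff.DsParams(4.3, 50.0, 6.5)
        s = ff.sample_ruptures(p, schedule, 2000, seed=3)
        dens = ff.rupture_pdf(p, schedule)
        res = stats.kstest(s.forces, lambda x: dens.conditional_cdf(x))
        assert res.pvalue > 0.01

    def test_mixture_assignment_fractions(self, schedule):
        mix = ff.DsMixture(
            (ff.DsParams(4.3, 50.0, 6.5), ff.DsParams(4.0, 10990.0, 11.6)),
            (0.7, 0.3),
        )
        n = 2000
        s = ff.sample_ruptures(mix, schedule, n, seed=11)
        frac = np.mean(np.concatenate([s.component_labels, np.zeros(0)]) == 0)
        # labels only cover uncensored draws; compare against the
        # uncensored-conditional expectation
        d1 = ff.rupture_pdf(mix.components[0], schedule)
        d2 = ff.rupture_pdf(mix.components[1], schedule)
        expected = 0.7 * (1 - d1.survival) / (
            0.7 * (1 - d1.survival) + 0.3 * (1 - d2.survival)
        )
        assert frac == pytest.approx(expected, abs=2 * np.sqrt(0.21 / n) + 0.02)

    def test_sample_list_view(self, schedule):
        s = ff.sample_ruptures(ff.DsParams(4.3, 50.0, 6.5), schedule, 50, seed=1)
        as_list = s.to_list()
        assert len(as_list) == 50
        assert sum(r.censored for r in as_list) == s.n_censored


class TestFitDs:
    def test_single_component_recovery(self, schedule):
        truth = ff.DsParams(6.6, 30.0, 7.0)
        s = ff.sample_ruptures(truth, schedule, 500, seed=2)
        fit = ff.fit_ds(s, 1, schedule, n_starts=6, seed=2)
        c = fit.mixture.components[0]
        assert abs(c.dx_dagger - truth.dx_dagger) / truth.dx_dagger < 0.10
        assert abs(np.log(c.tau0 / truth.tau0)) < 0.3

    def test_insufficient_data_raises(self, schedule):
        s = ff.RuptureSamples(forces=[5.0, 6.0, 7.0], f_max=28.0)
        with pytest.raises(ff.InsufficientDataError):
            ff.fit_ds(s, 1, schedule)

    def test_two_component_weights_within_two_se(self, schedule):
        """Two force clusters (modes ~7 and ~17 pN, > 5 pN apart)."""
        mix = ff.DsMixture(
            (ff.DsParams(4.3, 50.0, 6.5), ff.DsParams(4.0, 10990.0, 11.6)),
            (0.6, 0.4),
        )
        for seed in (0, 1, 2):
            s = ff.sample_ruptures(mix, schedule, 600, seed=seed)
            fit = ff.fit_ds(s, 2, schedule, n_starts=8, seed=seed)
            u0 = fit.uncertainties[0]
            assert u0["weight_se"] > 0
            assert abs(u0["weight"] - 0.6) < 2 * u0["weight_se"]

    def test_censored_samples_enter_likelihood(self, schedule):
        """Dropping the censored count changes the fitted lifetime."""
        p = ff.DsParams(4.3, 500.0, 6.5)  # heavy censoring (F_c in ramp)
        s = ff.sample_ruptures(p, schedule, 400, seed=4)
        assert s.n_censored > 20
        with_cens = ff.fit_ds(s, 1, schedule, n_starts=4, seed=4)
        no_cens = ff.fit_ds(
            ff.RuptureSamples(forces=s.forces, n_censored=0, f_max=s.f_max),
            1,
            schedule,
            n_starts=4,
            seed=4,
        )
        t1 = with_cens.mixture.components[0].tau0
        t2 = no_cens.mixture.components[0].tau0
        assert abs(np.log(t1 / t2)) > 0.05


class TestReconstructProfile:
    def test_modal_force_consistent_with_density(self, schedule):
        p = ff.DsParams(4.3, 50.0, 6.5)
        prof = ff.reconstruct_profile(p, schedule)
        dens = ff.rupture_pdf(p, schedule)
        assert prof["modal_force_pN"] == pytest.approx(dens.mode(), abs=1e-3)

    def test_rate_curve_spans_to_critical_force(self, schedule):
        p = ff.DsParams(4.3, 50.0, 6.5)
        prof = ff.reconstruct_profile(p, schedule)
        assert prof["critical_force_pN"] == pytest.approx(p.critical_force())
        assert prof["force_grid_pN"][-1] <= p.critical_force()
        assert np.all(prof["rate_per_s"] > 0)


class TestValidation:
    def test_mixture_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ff.DsMixture((ff.DsParams(4.3, 50.0, 6.5),), (0.9,))

    def test_nu_restricted_to_supported_values(self):
        with pytest.raises(ValueError):
            ff.DsParams(4.3, 50.0, 6.5, nu=0.4)

    def test_positive_parameters_required(self):
        with pytest.raises(ValueError):
            ff.DsParams(-1.0, 50.0, 6.5)
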