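"""TCSPC forward models, decay fitting, MEM, moments and FRET-lines."""

import numpy as np
import pytest
from scipy import special

from conformerkit import tcspc
from conformerkit.labels import DistanceDistribution


@pytest.fixture(scope="module")
def time_grid():
    return np.arange(0.0, 32.0, 0.016)


@pytest.fixture(scope="module")
def donor_two_exp():
    return tcspc.FluorophoreReference([0.8, 0.2], [4.0, 2.0])


class TestFretInducedDonorDecay:
    def test_all_donly_is_flat(self, time_grid):
        m = tcspc.GaussianMixtureDistance(x_donly=1.0)
        eps = tcspc.fret_induced_donor_decay(m, time_grid)
        assert np.allclose(eps, 1.0)

    def test_delta_at_R0_gives_k0(self, time_grid):
        r = tcspc.default_distance_grid()
        p = np.zeros_like(r)
        p[np.argmin(np.abs(r - 52.0))] = 1.0
        dd = DistanceDistribution(r=r, p=p)
        eps = tcspc.fret_induced_donor_decay(dd, time_grid, R0=52.0, tau0=4.0)
        assert np.allclose(eps, np.exp(-time_grid / 4.0), atol=1e-12)

    def test_two_gaussian_matches_quadrature_oracle(self, time_grid):
        m = tcspc.GaussianMixtureDistance(r1=45, r2=60, w=12, x1=0.61, x_donly=0.0)
        eps = tcspc.fret_induced_donor_decay(m, time_grid)
        # adaptive quadrature oracle on a handful of time points
        from scipy.integrate import quad

        k0 = 1.0 / 4.0
        sigma = 12.0 / 2.0

        def density(r):
            g1 = np.exp(-0.5 * ((r - 45) / sigma) ** 2)
            g2 = np.exp(-0.5 * ((r - 60) / sigma) ** 2)
            return 0.61 * g1 + 0.39 * g2

        norm = quad(density, 10, 150, limit=200)[0]
        for j in [0, 100, 500, 1500]:
            t = time_grid[j]
            val = quad(
                lambda r: density(r) * np.exp(-t * k0 * (52.0 / r) ** 6),
                10, 150, limit=200,
            )[0] / norm
            assert eps[j] == pytest.approx(val, rel=1e-5)

    def test_monotone_and_bounded(self, time_grid):
        m = tcspc.GaussianMixtureDistance(x_donly=0.15)
        eps = tcspc.fret_induced_donor_decay(m, time_grid)
        assert eps[0] == pytest.approx(1.0)
        assert np.all(np.diff(eps) <= 1e-12)
        assert np.all(eps >= 0.15 - 1e-12)

    def test_negative_density_rejected(self, time_grid):
        r = tcspc.default_distance_grid()
        dd = DistanceDistribution(r=r, p=np.ones_like(r))
        dd.p[3] = -0.5  # corrupt after construction
        with pytest.raises(ValueError):
            tcspc.fret_induced_donor_decay(dd, time_grid, R0=52, tau0=4)


class TestDonorDecayWithFret:
    def test_unity_eps_returns_reference(self, time_grid, donor_two_exp):
        f = tcspc.donor_decay_with_fret(donor_two_exp, np.ones_like(time_grid), time_grid)
        assert np.allclose(f, donor_two_exp.decay(time_grid))

    def test_additive_rates_for_delta_distance(self, time_grid):
        donor = tcspc.FluorophoreReference([1.0], [4.0])
        eps = np.exp(-time_grid / 4.0)  # delta at R0
        f = tcspc.donor_decay_with_fret(donor, eps, time_grid)
        assert np.allclose(f, np.exp(-2.0 * time_grid / 4.0), atol=1e-12)

    def test_term_by_term_expansion_oracle(self, time_grid, donor_two_exp):
        m = tcspc.GaussianMixtureDistance(r1=45, r2=60, w=12, x1=0.5)
        eps = tcspc.fret_induced_donor_decay(m, time_grid)
        f = tcspc.donor_decay_with_fret(donor_two_exp, eps, time_grid)
        oracle = (
            0.8 * np.exp(-time_grid / 4.0) + 0.2 * np.exp(-time_grid / 2.0)
        ) * eps
        assert np.allclose(f, oracle, rtol=1e-12)


class TestAcceptorSensitized:
    def test_delta_acceptor_is_identity(self):
        dt = 0.05
        t = np.arange(64) * dt
        fd = np.exp(-t / 3.0)
        fa = np.zeros(64)
        fa[0] = 1.0 / dt  # discrete delta
        out = tcspc.acceptor_sensitized_decay(fd, fa, dt)
        assert np.allclose(out, fd, atol=1e-10)

    def test_matches_double_sum_oracle(self):
        rng = np.random.default_rng(1)
        dt = 0.1
        fd = rng.random(64)
        fa = rng.random(64)
        out = tcspc.acceptor_sensitized_decay(fd, fa, dt)
        oracle = np.array(
            [sum(fd[j] * fa[i - j] for j in range(i + 1)) for i in range(64)]
        ) * dt
        assert np.allclose(out, oracle, atol=1e-10)

    def test_integral_factorizes(self):
        dt = 0.02
        t = np.arange(2048) * dt
        fd = np.exp(-t / 2.0)
        fa = np.exp(-t / 0.8)
        out = tcspc.acceptor_sensitized_decay(fd, fa, dt)
        # Fubini: sum(conv)*dt = (sum fd * dt)(sum fa * dt), up to tail truncation
        assert out.sum() * dt == pytest.approx(fd.sum() * dt * fa.sum() * dt, rel=1e-3)


class TestInstrumentModel:
    def test_delta_irf_scales_only(self):
        f = np.exp(-np.arange(100) * 0.1)
        irf = np.zeros(100)
        irf[0] = 1.0
        g = tcspc.instrument_model(f, irf, n_f=3.5)
        assert np.allclose(g, 3.5 * f)

    def test_zero_fluorescence_gives_background(self):
        irf = np.zeros(50)
        irf[3] = 2.0
        g = tcspc.instrument_model(np.zeros(50), irf, n_f=5.0, n_bg=7.0, bg=0.25)
        assert np.allclose(g, 7.0 * irf / 2.0 + 0.25)

    def test_zero_irf_rejected(self):
        with pytest.raises(ValueError):
            tcspc.instrument_model(np.ones(10), np.zeros(10), 1.0)

    def test_gaussian_irf_exponential_matches_exgaussian(self):
        # fine grid so the discrete reconvolution approaches the continuous
        # exGaussian closed form
        dt = 0.0002  # ns
        t = np.arange(0.0, 8.0, dt)
        tau, mu, sigma = 4.0, 1.0, 0.108  # FWHM 254 ps
        irf = np.exp(-0.5 * ((t - mu) / sigma) ** 2)
        f = np.exp(-t / tau)
        g = tcspc.instrument_model(f, irf, n_f=1.0)
        z = (sigma**2 / tau - (t - mu)) / (np.sqrt(2) * sigma)
        oracle = (
            0.5
            * np.exp(sigma**2 / (2 * tau**2) - (t - mu) / tau)
            * special.erfc(z)
        )
        # away from the causality kink at t = mu the discrete reconvolution
        # matches the continuous closed form to machine precision
        sel = t > mu + 1.0
        assert np.abs(g[sel] - oracle[sel]).max() < 1e-8
        # across the kink the known half-sample endpoint term accounts for
        # the O(dt) difference
        corrected = oracle + 0.5 * (irf / irf.sum()) * f[0]
        assert np.abs(g - corrected).max() < 1e-6

    def test_linearization_applied_last(self):
        f = np.exp(-np.arange(64) * 0.05)
        irf = np.zeros(64)
        irf[0] = 1.0
        lin = 1.0 + 0.1 * np.sin(np.arange(64))
        g = tcspc.instrument_model(f, irf, n_f=2.0, linearization=lin)
        assert np.allclose(g, 2.0 * f * lin)


class TestFitDecays:
    def test_noiseless_round_trip(self, time_grid, donor_two_exp):
        truth = tcspc.GaussianMixtureDistance(r1=45, r2=60, w=12, x1=0.61)
        irf = np.exp(-0.5 * ((time_grid - 1.0) / 0.108) ** 2)
        eps = tcspc.fret_induced_donor_decay(truth, time_grid)
        f = tcspc.donor_decay_with_fret(donor_two_exp, eps, time_grid)
        shape = tcspc.instrument_model(f, irf, 1.0)
        counts = 2e7 * shape / shape.sum()
        curve = tcspc.DecayCurve(t=time_grid, counts=counts, irf=irf)
        res = tcspc.fit_decays(
            [curve], donor_two_exp,
            initial=tcspc.GaussianMixtureDistance(r1=42, r2=63, w=12, x1=0.5),
            vary=("r1", "r2", "x1"),
        )
        assert res.params["d0_r1"].value == pytest.approx(45.0, rel=1e-4)
        assert res.params["d0_r2"].value == pytest.approx(60.0, rel=1e-4)
        assert res.params["d0_x1"].value == pytest.approx(0.61, abs=1e-4)
        assert res.redchi < 1e-6

    def test_poisson_fit_is_consistent(self, time_grid, donor_two_exp):
        truth = tcspc.GaussianMixtureDistance(r1=45, r2=60, w=12, x1=0.61)
        irf = np.exp(-0.5 * ((time_grid - 1.0) / 0.108) ** 2)
        curve = tcspc.simulate_decay(truth, donor_two_exp, time_grid, irf,
                                     total_counts=5e6, seed=9)
        res = tcspc.fit_decays(
            [curve], donor_two_exp,
            initial=tcspc.GaussianMixtureDistance(r1=40, r2=65, w=12, x1=0.5),
            vary=("r1", "r2", "x1"),
        )
        assert res.redchi == pytest.approx(1.0, abs=0.1)
        assert res.params["d0_x1"].value == pytest.approx(0.61, abs=0.08)

    def test_joint_fit_shares_fraction(self, donor_two_exp):
        # shared-fraction global fit across several pairs beats independent fits
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 32.0, 0.032)
        irf = np.exp(-0.5 * ((t - 1.0) / 0.108) ** 2)
        curves, seps = [], []
        for i in range(4):
            r1 = rng.uniform(38, 50)
            r2 = r1 + rng.uniform(10, 20)
            truth = tcspc.GaussianMixtureDistance(r1=r1, r2=r2, w=12, x1=0.61)
            curves.append(
                tcspc.simulate_decay(truth, donor_two_exp, t, irf,
                                     total_counts=2e6, seed=int(rng.integers(2**31)))
            )
            seps.append((r1, r2))
        res = tcspc.fit_decays(
            curves, donor_two_exp,
            initial=tcspc.GaussianMixtureDistance(r1=42, r2=62, w=12, x1=0.5),
            shared=("x1",), vary=("r1", "r2", "x1"),
        )
        assert res.params["x1"].value == pytest.approx(0.61, abs=0.05)
        # sharing beats independent per-dataset estimates of the fraction
        indep_errors = []
        for c in curves:
            r_i = tcspc.fit_decays(
                [c], donor_two_exp,
                initial=tcspc.GaussianMixtureDistance(r1=42, r2=62, w=12, x1=0.5),
                vary=("r1", "r2", "x1"),
            )
            indep_errors.append(r_i.params["d0_x1"].value - 0.61)
        rmse_indep = float(np.sqrt(np.mean(np.square(indep_errors))))
        assert abs(res.params["x1"].value - 0.61) < rmse_indep

    def test_support_plane_interval_covers_truth(self, donor_two_exp):
        t = np.arange(0.0, 32.0, 0.032)
        irf = np.exp(-0.5 * ((t - 1.0) / 0.108) ** 2)
        truth = tcspc.GaussianMixtureDistance(r1=45, r2=60, w=12, x1=0.61)
        curve = tcspc.simulate_decay(truth, donor_two_exp, t, irf,
                                     total_counts=2e6, seed=17)
        windows = [curve.fit_range(0.999)]
        res = tcspc.fit_decays(
            [curve], donor_two_exp,
            initial=tcspc.GaussianMixtureDistance(r1=42, r2=62, w=12, x1=0.5),
            vary=("r1", "r2", "x1"),
        )
        args = ([curve], [donor_two_exp], [0.0], windows,
                tcspc.default_distance_grid())
        fitted = res.params["d0_x1"].value
        values = np.linspace(fitted - 0.06, fitted + 0.06, 25)
        lo, hi, chi2 = tcspc.support_plane_interval(res, args, "d0_x1", values)
        assert lo <= 0.61 <= hi
        # the profile is lowest near the fitted value
        assert values[np.argmin(chi2)] == pytest.approx(
            res.params["d0_x1"].value, abs=0.05
        )


class TestMem:
    def test_bimodal_reconstruction(self, time_grid, donor_two_exp):
        truth = tcspc.GaussianMixtureDistance(r1=45, r2=60, w=12, x1=0.61)
        irf = np.exp(-0.5 * ((time_grid - 1.0) / 0.108) ** 2)
        curve = tcspc.simulate_decay(truth, donor_two_exp, time_grid, irf,
                                     total_counts=2e7, bg_fraction=0.0, seed=21)
        r = np.arange(20.0, 90.0001, 1.0)
        out = tcspc.mem_reconstruct(curve, donor_two_exp, r_grid=r,
                                    alphas=np.logspace(0, 6, 13))
        best = out["best"]
        # the two modes are resolved on either side of the mixture midpoint
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(best.p, prominence=0.03 * best.p.max())
        modes = best.r[peaks]
        assert len(modes) == 2
        assert 40.0 < modes[0] < 52.0 < modes[1] < 65.0
        # component fractions within 0.1 of truth (split at the midpoint)
        lo = best.r <= 52.5
        frac_low = np.trapezoid(best.p[lo], best.r[lo])
        assert frac_low == pytest.approx(0.61, abs=0.1)

    def test_single_distance_mode_recovery(self, time_grid, donor_two_exp):
        truth = tcspc.GaussianMixtureDistance(r1=50, r2=50, w=8, x1=1.0)
        irf = np.exp(-0.5 * ((time_grid - 1.0) / 0.108) ** 2)
        curve = tcspc.simulate_decay(truth, donor_two_exp, time_grid, irf,
                                     total_counts=1e7, seed=5)
        r = np.arange(20.0, 90.0001, 1.0)
        out = tcspc.mem_reconstruct(curve, donor_two_exp, r_grid=r,
                                    alphas=np.logspace(-1, 3, 13))
        mode = out["best"].r[np.argmax(out["best"].p)]
        assert abs(mode - 50.0) <= 2.0

    def test_infinite_alpha_returns_flat_prior(self, time_grid, donor_two_exp):
        truth = tcspc.GaussianMixtureDistance(r1=45, r2=60, w=12, x1=0.61)
        irf = np.exp(-0.5 * ((time_grid - 1.0) / 0.108) ** 2)
        curve = tcspc.simulate_decay(truth, donor_two_exp, time_grid, irf,
                                     total_counts=1e6, seed=2)
        r = np.arange(20.0, 90.0001, 2.0)
        out = tcspc.mem_reconstruct(curve, donor_two_exp, r_grid=r,
                                    alphas=np.array([1e8, 1e9, 1e10, 1e11, 1e12]))
        flat = out["reconstructions"][-1].p  # largest alpha is first; any is near-flat
        assert np.ptp(flat) / flat.mean() < 0.05

    def test_nonpositive_alpha_rejected(self, time_grid, donor_two_exp):
        curve = tcspc.DecayCurve(t=time_grid, counts=np.ones_like(time_grid))
        with pytest.raises(ValueError):
            tcspc.mem_reconstruct(curve, donor_two_exp, alphas=np.array([0.0, 1.0]))


class TestLifetimeMoments:
    def test_no_fret_limit(self):
        out = tcspc.lifetime_moments(0.0, 4.0, 4.0)
        assert out["tau_x"] == 4.0
        assert out["var"] == pytest.approx(0.0)

    def test_single_exponential_zero_variance(self):
        out = tcspc.lifetime_moments(0.5, 4.0, 2.0)
        assert out["tau_x"] == pytest.approx(2.0)
        assert out["var"] == pytest.approx(0.0)

    def test_two_lifetime_mixture_matches_definition(self):
        # equal-amplitude 1 ns / 4 ns mixture: moments from first principles
        x = np.array([0.5, 0.5])
        tau = np.array([1.0, 4.0])
        tau_x = float(x @ tau)  # species-averaged lifetime
        tau_f = float(x @ tau**2 / (x @ tau))  # fluorescence-weighted
        var_direct = float(x @ tau**2 - tau_x**2)
        # present the mixture as E and the two mean lifetimes with tau_D0 such
        # that tau_x = (1 - E) tau_D0
        tau_d0 = 4.0
        E = 1.0 - tau_x / tau_d0
        out = tcspc.lifetime_moments(E, tau_d0, tau_f)
        assert out["tau_x"] == pytest.approx(tau_x, rel=1e-12)
        assert out["var"] == pytest.approx(var_direct, rel=1e-12)


class TestFretLines:
    def test_ideal_donor_static_line_closed_form(self):
        donor = tcspc.FluorophoreReference([1.0], [4.0])
        line = tcspc.static_fret_line(donor, R0=52.0, tau0=4.0)
        assert np.allclose(line.efficiency, 1.0 - line.tau_f / 4.0, atol=1e-9)

    def test_dynamic_endpoints_on_static_points(self):
        donor = tcspc.FluorophoreReference([0.8, 0.2], [4.0, 2.0])
        dyn = tcspc.dynamic_fret_line(donor, 45.0, 60.0)
        e1, tf1, _ = tcspc._state_point(donor, 52.0, 4.0, 60.0)
        e0, tf0, _ = tcspc._state_point(donor, 52.0, 4.0, 45.0)
        assert dyn.efficiency[0] == pytest.approx(e1)
        assert dyn.tau_f[0] == pytest.approx(tf1)
        assert dyn.efficiency[-1] == pytest.approx(e0)
        assert dyn.tau_f[-1] == pytest.approx(tf0)

    def test_dynamic_line_right_of_static(self):
        donor = tcspc.FluorophoreReference([1.0], [4.0])
        dyn = tcspc.dynamic_fret_line(donor, 40.0, 65.0, n_points=41)
        # between the endpoints the mixed tau_f exceeds the static-line value
        static_tau = 4.0 * (1.0 - dyn.efficiency)
        mid = slice(1, -1)
        assert np.all(dyn.tau_f[mid] > static_tau[mid] + 1e-9)

    def test_midpoint_matches_photon_simulation(self):
        donor = tcspc.FluorophoreReference([1.0], [4.0])
        dyn = tcspc.dynamic_fret_line(donor, 45.0, 60.0, n_points=3)
        rng = np.random.default_rng(33)
        n = 10**6
        k0 = 0.25
        k1 = k0 * (52.0 / 45.0) ** 6
        k2 = k0 * (52.0 / 60.0) ** 6
        tau1, tau2 = 1.0 / (k0 + k1), 1.0 / (k0 + k2)
        # photon yield per molecule is proportional to its donor lifetime
        w1 = 0.5 * tau1
        w2 = 0.5 * tau2
        n1 = int(n * w1 / (w1 + w2))
        arr = np.concatenate([
            rng.exponential(tau1, n1),
            rng.exponential(tau2, n - n1),
        ])
        tau_f_sim = arr.mean()
        assert dyn.tau_f[1] == pytest.approx(tau_f_sim, rel=0.01)

    def test_dynamic_needs_two_states(self):
        donor = tcspc.FluorophoreReference([1.0], [4.0])
        with pytest.raises(ValueError):
            tcspc.dynamic_fret_line(donor, 50.0, 50.0)
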