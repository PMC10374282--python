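"""Species filters, correlation, and the global kinetic model fit."""

import numpy as np
import pytest

from conformerkit import ffcs
from conformerkit.synthetic import simulate_telegraph, two_state_rate_matrix


def make_patterns(n_channels=64, tau_h=1.0, tau_l=3.0):
    """Two decay-like channel patterns (high/low FRET lifetimes)."""
    t = np.arange(n_channels)
    p_h = np.exp(-t / (tau_h * 8))
    p_l = np.exp(-t / (tau_l * 8))
    M = np.column_stack([p_h / p_h.sum(), p_l / p_l.sum()])
    return M


class TestFilters:
    def test_disjoint_support_gives_indicators(self):
        M = np.zeros((8, 2))
        M[:4, 0] = 0.25
        M[4:, 1] = 0.25
        s = M.sum(axis=1) + 0.0
        fs = ffcs.compute_filters(M, s)
        assert np.allclose(fs.weights[0, 4:], 0.0, atol=1e-12)
        assert np.allclose(fs.weights[1, :4], 0.0, atol=1e-12)

    def test_unbiasedness_identity_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            M = rng.random((64, 2)) + 0.01
            s = rng.random(64) + 0.1
            fs = ffcs.compute_filters(M, s)
            assert np.abs(fs.unbiasedness() - np.eye(2)).max() < 1e-9

    def test_matches_weighted_least_squares_oracle(self):
        rng = np.random.default_rng(1)
        M = rng.random((32, 3)) + 0.01
        M /= M.sum(axis=0)
        s = rng.random(32) + 0.1
        fs = ffcs.compute_filters(M, s)
        oracle = np.linalg.inv(M.T @ np.diag(1 / s) @ M) @ M.T @ np.diag(1 / s)
        assert np.abs(fs.weights - oracle).max() < 1e-10

    def test_collinear_patterns_rejected(self):
        M = np.ones((16, 2))
        with pytest.raises(np.linalg.LinAlgError):
            ffcs.compute_filters(M, np.ones(16))


class TestSpeciesCorrelate:
    def test_constant_signal_gives_unity(self):
        M = make_patterns(8)
        fs = ffcs.compute_filters(M, M.sum(axis=1))
        S = np.ones((8, 4096))
        c = ffcs.species_correlate(S, fs, ("H", "H"), bin_time=1e-6)
        assert np.allclose(c.g, 1.0, atol=1e-12)

    def test_shot_noise_only_is_flat(self):
        # single species, Poisson noise: G(tc) ~ 1 for tc > 0
        rng = np.random.default_rng(5)
        M = make_patterns(8)
        fs = ffcs.compute_filters(M, M.sum(axis=1))
        devs = []
        for seed in range(40):
            lam = 5.0 * M[:, 0]
            S = np.random.default_rng(seed).poisson(
                lam[:, None], size=(8, 1 << 14)
            )
            c = ffcs.species_correlate(S, fs, ("H", "H"), bin_time=1e-6)
            devs.append(c.g[:10] - 1.0)
        mean_dev = np.abs(np.mean(devs, axis=0))
        se = np.std(devs, axis=0) / np.sqrt(40)
        assert np.all(mean_dev < 3 * se + 1e-3)

    def test_telegraph_exchange_anticorrelation_time(self):
        # two-state switching at k_ex: sCCF anti-correlation decays with 1/k_ex
        t_relax_us = 50.0
        K = two_state_rate_matrix(t_relax_us, 0.5)
        bin_us = 2.0
        n_bins = 1 << 20
        states = simulate_telegraph(K, n_bins, bin_us, seed=8)
        M = make_patterns(16)
        fs = ffcs.compute_filters(M, M.mean(axis=1) * 2)
        brightness = 20.0
        lam = brightness * M[:, states]  # channel pattern follows the state
        S = np.random.default_rng(9).poisson(lam)
        c = ffcs.species_correlate(S, fs, ("H", "L"), bin_time=bin_us * 1e-6)
        # fit a single-exponential anti-correlation on the decaying part
        sel = (c.lag > 2e-6) & (c.lag < 1e-3)
        y = c.g[sel]
        x = c.lag[sel]
        amp = 1.0 - y.min()
        from scipy.optimize import curve_fit

        def model(x, a, tau, off):
            return off - a * np.exp(-x / tau)

        popt, _ = curve_fit(model, x, y, p0=(amp, 5e-5, 1.0))
        assert popt[1] == pytest.approx(t_relax_us * 1e-6, rel=0.10)

    def test_empty_signal_rejected(self):
        M = make_patterns(8)
        fs = ffcs.compute_filters(M, M.sum(axis=1))
        with pytest.raises(ValueError):
            ffcs.species_correlate(np.empty((8, 0)), fs, ("H", "H"), 1e-6)

    def test_ccf_direction_symmetry(self):
        # reversible two-state exchange: sCCF(H,L) and sCCF(L,H) agree
        K = two_state_rate_matrix(30.0, 0.5)
        states = simulate_telegraph(K, 1 << 19, 2.0, seed=12)
        M = make_patterns(16)
        fs = ffcs.compute_filters(M, M.mean(axis=1) * 2)
        S = np.random.default_rng(13).poisson(15.0 * M[:, states])
        hl = ffcs.species_correlate(S, fs, ("H", "L"), 2e-6)
        lh = ffcs.species_correlate(S, fs, ("L", "H"), 2e-6)
        sel = hl.lag < 1e-3
        assert np.allclose(hl.g[sel], lh.g[sel], atol=0.05)


class TestFcsModel:
    def test_long_lag_limit(self):
        m = ffcs.KineticModel()
        g = ffcs.fcs_model(np.array([1e3]), m, "sACF_HH")
        assert g[0] == pytest.approx(1.0, abs=1e-6)

    def test_ccf_zero_lag_algebra(self):
        m = ffcs.KineticModel(
            n_eff={"HH": 1.0, "LL": 1.0, "CC": 2.0},
            a0={"LH": 0.7, "HL": 0.4},
        )
        g = ffcs.fcs_model(np.array([1e-12]), m, "sCCF_LH")
        assert g[0] == pytest.approx(1.0 + (1.0 / 2.0) * (1.0 - 0.7), rel=1e-6)

    def test_random_draws_match_symbolic_oracle(self):
        rng = np.random.default_rng(3)
        tc = np.geomspace(1e-7, 1e-1, 25)
        for _ in range(10):
            a = rng.dirichlet([1, 1, 1])
            m = ffcs.KineticModel(
                n_eff={"HH": rng.uniform(0.5, 3), "LL": rng.uniform(0.5, 3),
                       "CC": rng.uniform(0.5, 3)},
                t_diff=rng.uniform(1e-4, 1e-2),
                axial_ratio=rng.uniform(3, 8),
                a0={"LH": rng.uniform(0, 1), "HL": rng.uniform(0, 1)},
                times=tuple(rng.uniform(1e-6, 1e-3, 3)),
                amplitudes=tuple(a),
                acf_amplitudes={"HH": tuple(rng.uniform(0, 0.5, 3)),
                                "LL": tuple(rng.uniform(0, 0.5, 3))},
                bleach_amplitude=rng.uniform(0, 0.5),
                bleach_time=rng.uniform(1e-3, 2e-2),
            )
            # independent term-by-term evaluation
            gd = (1 + tc / m.t_diff) ** -1 * (
                1 + (1 / m.axial_ratio**2) * (tc / m.t_diff)
            ) ** -0.5
            decay = sum(
                A * np.exp(-tc / T) for A, T in zip(m.amplitudes, m.times)
            )
            gk_lh = 1 - m.a0["LH"] * decay
            expect = 1 + gd * gk_lh / m.n_eff["CC"]
            got = ffcs.fcs_model(tc, m, "sCCF_LH")
            assert np.abs(got - expect).max() < 1e-12
            gk_hh = 1 + sum(
                A * (np.exp(-tc / T) - 1)
                for A, T in zip(m.acf_amplitudes["HH"], m.times)
            )
            gk_hh = gk_hh * (1 + m.bleach_amplitude * (np.exp(-tc / m.bleach_time) - 1))
            expect_hh = 1 + gd * gk_hh / m.n_eff["HH"]
            got_hh = ffcs.fcs_model(tc, m, "sACF_HH")
            assert np.abs(got_hh - expect_hh).max() < 1e-12

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ffcs.fcs_model(np.array([1e-5]), ffcs.KineticModel(), "sACF_XY")


@pytest.fixture(scope="module")
def synthetic_curves():
    return _make_synthetic_curves()


def _make_synthetic_curves():
    rng = np.random.default_rng(11)
    times = (2e-6, 23e-6, 297e-6)
    lag = np.unique(np.geomspace(1e-7, 0.05, 80))
    curves = []
    for i in range(12):
        a = rng.dirichlet([2, 2, 2])
        m = ffcs.KineticModel(
            n_eff={"HH": rng.uniform(0.5, 2), "LL": rng.uniform(0.5, 2),
                   "CC": rng.uniform(0.5, 2)},
            t_diff=rng.uniform(5e-4, 2e-3),
            a0={"LH": rng.uniform(0.3, 0.8), "HL": rng.uniform(0.3, 0.8)},
            times=times, amplitudes=tuple(a),
            acf_amplitudes={"HH": tuple(rng.uniform(0.05, 0.3, 3)),
                            "LL": tuple(rng.uniform(0.05, 0.3, 3))},
        )
        for kind in ffcs.CURVE_KINDS:
            g = ffcs.fcs_model(lag, m, kind)
            sd = np.full_like(g, 0.003)
            curves.append(ffcs.CorrCurve(
                lag=lag, g=g + rng.normal(0, sd), sd=sd, kind=kind,
                variant=f"v{i:02d}"))
    return curves, np.array(times)


class TestGlobalFit:
    def test_shared_times_recovered(self, synthetic_curves):
        curves, times = synthetic_curves
        out = ffcs.global_fit_ffcs(curves)
        assert np.all(np.abs(out["times"] / times - 1.0) < 0.25)

    def test_zero_noise_exact_recovery(self):
        lag = np.unique(np.geomspace(1e-7, 0.05, 60))
        m = ffcs.KineticModel(
            n_eff={"HH": 1.2, "LL": 0.8, "CC": 1.0}, t_diff=1e-3,
            a0={"LH": 0.6, "HL": 0.5}, times=(2e-6, 23e-6, 297e-6),
            amplitudes=(0.5, 0.3, 0.2),
            acf_amplitudes={"HH": (0.1, 0.1, 0.1), "LL": (0.2, 0.1, 0.05)},
        )
        curves = [
            ffcs.CorrCurve(lag=lag, g=ffcs.fcs_model(lag, m, kind),
                           sd=np.full_like(lag, 1e-4), kind=kind, variant="v0")
            for kind in ffcs.CURVE_KINDS
        ]
        out = ffcs.global_fit_ffcs(curves)
        assert out["result"].chisqr < 1e-10 * out["result"].ndata
        assert np.all(np.abs(out["times"] / np.array([2e-6, 23e-6, 297e-6]) - 1) < 0.02)

    def test_two_state_variant_gets_vanishing_third_amplitude(self):
        rng = np.random.default_rng(4)
        lag = np.unique(np.geomspace(1e-7, 0.05, 60))
        m = ffcs.KineticModel(
            n_eff={"HH": 1.0, "LL": 1.0, "CC": 1.0}, t_diff=1e-3,
            a0={"LH": 0.6, "HL": 0.6}, times=(23e-6, 1.0, 1.0),
            amplitudes=(1.0, 0.0, 0.0),
            acf_amplitudes={"HH": (0.2, 0.0, 0.0), "LL": (0.2, 0.0, 0.0)},
        )
        curves = []
        for kind in ffcs.CURVE_KINDS:
            g = ffcs.fcs_model(lag, m, kind)
            sd = np.full_like(g, 0.002)
            curves.append(ffcs.CorrCurve(lag=lag, g=g + rng.normal(0, sd),
                                         sd=sd, kind=kind, variant="v0"))
        out = ffcs.global_fit_ffcs(curves, initial_times=(5e-6, 5e-5, 5e-4))
        model = out["models"]["v0"]
        # one relaxation in truth: amplitude on components away from the true
        # time is negligible (components may degenerately share the true time)
        amps = np.asarray(model.amplitudes)
        times = np.asarray(model.times)
        near = np.abs(times / 23e-6 - 1.0) < 0.3
        assert amps[near].sum() > 0.8
        assert amps[~near].sum() < 0.2


class TestMeanRelaxation:
    def test_single_component(self):
        m = ffcs.KineticModel(times=(5e-6, 1, 1), amplitudes=(1.0, 0.0, 0.0))
        assert ffcs.mean_relaxation_time(m) == pytest.approx(5e-6)

    def test_arithmetic_example(self):
        m = ffcs.KineticModel(times=(2e-6, 23e-6, 297e-6), amplitudes=(0.5, 0.5, 0.0))
        assert ffcs.mean_relaxation_time(m) == pytest.approx(12.5e-6)

    def test_monotone_in_each_time(self):
        base = ffcs.KineticModel(times=(2e-6, 23e-6, 297e-6),
                                 amplitudes=(0.3, 0.3, 0.4))
        t0 = ffcs.mean_relaxation_time(base)
        longer = ffcs.KineticModel(times=(2e-6, 40e-6, 297e-6),
                                   amplitudes=(0.3, 0.3, 0.4))
        assert ffcs.mean_relaxation_time(longer) > t0


class TestRelaxationSpectrum:
    def test_two_state(self):
        K = two_state_rate_matrix(2.0, 0.61)
        times = ffcs.relaxation_spectrum(K)
        assert times == pytest.approx([2.0], rel=1e-12)

    def test_matches_eigenvalues_for_random_reversible_matrices(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            k = rng.uniform(0.01, 1.0, size=3)
            K = np.array([
                [-k[0], k[1], 0.0],
                [k[0], -(k[1] + k[2]), k[2] * 0.5],
                [0.0, k[2], -k[2] * 0.5],
            ])
            # fix column sums to zero
            K[2, 1] = k[2]
            K[1, 2] = k[2] * 0.5
            times = ffcs.relaxation_spectrum(K)
            ev = np.sort(np.linalg.eigvals(K).real)
            expect = np.sort(-1.0 / ev[np.abs(ev) > 1e-12])
            assert np.allclose(times, expect, rtol=1e-10)
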