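import mpmath as mp
import numpy as np
import pytest
from scipy import integrate, linalg, stats as sps

from mft import fixtures as fx
from mft import lif_dynamics as dyn
from mft import lif_stationary as stat
from mft.lif_stationary import InputStats, WorkingPoint
from mft.models_io import PopulationNetwork

from conftest import FIG_PARAMS, calibrate_mu


def make_wp(net, mu, sigma):
    """Working point with prescribed input statistics (single-neuron view)."""
    P = net.P
    shifted = bool(np.any(net.tau_s > 0))
    if shifted:
        nu = stat.siegert_rate_exp(np.full(P, mu), np.full(P, sigma),
                                   net.tau_m, net.tau_s, net.tau_r,
                                   net.V_th_rel, net.V_0_rel)
    else:
        nu = stat.siegert_rate_delta(np.full(P, mu), np.full(P, sigma),
                                     net.tau_m, net.tau_r,
                                     net.V_th_rel, net.V_0_rel)
    return WorkingPoint(nu=nu, stats=InputStats(mu=np.full(P, mu),
                                                sigma=np.full(P, sigma)))


class TestPhiOmega:
    def test_conjugation(self):
        v_pos, d_pos = dyn.phi_omega(1.2, 2 * np.pi * 33.0, 0.02)
        v_neg, d_neg = dyn.phi_omega(1.2, -2 * np.pi * 33.0, 0.02)
        assert v_neg == pytest.approx(np.conj(v_pos), rel=1e-12)
        assert d_neg == pytest.approx(np.conj(d_pos), rel=1e-12)

    @pytest.mark.parametrize("x", [-3.0, -0.4, 0.7, 2.5, 10.0])
    def test_zero_frequency_closed_form(self, x):
        # U(-1/2, x) = exp(-x^2/4), so Phi_0(x) = 1; and the a = 1/2 member
        # entering the derivative reduces to the scaled complementary error
        # function: exp(x^2/4) U(1/2, x) = sqrt(pi/2) erfcx(x/sqrt(2))
        v, d = dyn.phi_omega(x, 0.0, 0.02)
        assert v == pytest.approx(1.0, rel=1e-12)
        assert d == pytest.approx(0.0, abs=1e-12)
        from scipy.special import erfcx
        with mp.workdps(30):
            lhs = complex(mp.exp(x ** 2 / 4) * mp.pcfu(mp.mpf(0.5), x))
        assert lhs.real == pytest.approx(
            np.sqrt(np.pi / 2) * erfcx(x / np.sqrt(2)), rel=1e-12)

    @pytest.mark.parametrize("x,f", [(0.5, 17.0), (-2.0, 90.0), (4.0, 5.0)])
    def test_derivative_matches_central_difference(self, x, f):
        omega = 2 * np.pi * f
        h = 1e-6
        vp, _ = dyn.phi_omega(x + h, omega, 0.02)
        vm, _ = dyn.phi_omega(x - h, omega, 0.02)
        _, d = dyn.phi_omega(x, omega, 0.02)
        assert (vp - vm) / (2 * h) == pytest.approx(d, rel=1e-7)

    def test_no_overflow_moderate_box(self):
        v, d = dyn.phi_omega(60.0, 2 * np.pi * 100.0, 0.02)
        assert np.isfinite(v) and np.isfinite(d)

    def test_precision_error_in_growing_direction(self):
        with pytest.raises(dyn.PrecisionError):
            dyn.phi_omega(-60.0, 2 * np.pi * 10.0, 0.02)


class TestTransferFunction:
    def test_dc_gain_matches_rate_derivative(self, ei_exp):
        p = FIG_PARAMS
        net = fx.make_network(fx.FixtureSpec("ei_exp")).with_overrides(
            tau_m=p["tau_m"], tau_s=p["tau_s"], tau_r=p["tau_r"],
            V_th_rel=p["V_th_rel"], V_0_rel=p["V_0_rel"])
        sigma = 4e-3
        mu = calibrate_mu(10.0, sigma)
        wp = make_wp(net, mu, sigma)
        tf = dyn.transfer_function(net, wp, [0.0, 0.01], variant="cn_shift")
        h = 1e-6
        fd = (stat.siegert_rate_exp(mu + h, sigma, p["tau_m"], p["tau_s"],
                                    p["tau_r"], p["V_th_rel"], p["V_0_rel"])
              - stat.siegert_rate_exp(mu - h, sigma, p["tau_m"], p["tau_s"],
                                      p["tau_r"], p["V_th_rel"],
                                      p["V_0_rel"])) / (2 * h)
        assert tf.values[0, 0].real == pytest.approx(fd, rel=5e-3)
        assert abs(tf.values[0, 0].imag) < 1e-6 * abs(fd)
        # the f -> 0 evaluation is continuous with the exact f = 0 value
        assert tf.values[0, 1] == pytest.approx(tf.values[0, 0], rel=1e-3)

    def test_low_pass_amplitude_and_phase_lag(self):
        p = FIG_PARAMS
        net = fx.make_network(fx.FixtureSpec("ei_exp")).with_overrides(
            tau_m=p["tau_m"], tau_s=p["tau_s"], tau_r=p["tau_r"],
            V_th_rel=p["V_th_rel"], V_0_rel=p["V_0_rel"])
        sigma = 4e-3
        mu = calibrate_mu(10.0, sigma)
        wp = make_wp(net, mu, sigma)
        freqs = np.array([1.0, 10.0, 100.0, 400.0])
        tf = dyn.transfer_function(net, wp, freqs, variant="cn_shift_filtered")
        amps = np.abs(tf.values[0])
        assert amps[-1] < amps[0]
        assert np.angle(tf.values[0, -1]) < 0

    def test_filtered_amplitude_vanishes_at_high_frequency(self):
        p = FIG_PARAMS
        net = fx.make_network(fx.FixtureSpec("ei_exp")).with_overrides(
            tau_m=p["tau_m"], tau_s=p["tau_s"], tau_r=p["tau_r"],
            V_th_rel=p["V_th_rel"], V_0_rel=p["V_0_rel"])
        wp = make_wp(net, calibrate_mu(10.0, 4e-3), 4e-3)
        tf_lo = dyn.transfer_function(net, wp, [50.0],
                                      variant="cn_shift_filtered")
        tf_hi = dyn.transfer_function(net, wp, [2000.0],
                                      variant="cn_shift_filtered")
        assert np.abs(tf_hi.values[0, 0]) < 0.1 * np.abs(tf_lo.values[0, 0])

    def test_conjugation_symmetry(self, ei_exp, ei_exp_wp):
        f = 23.0
        shift = stat.COLORED_NOISE_ALPHA / 2 * np.sqrt(
            ei_exp.tau_s[0] / ei_exp.tau_m[0])
        args = (ei_exp_wp.nu[0], ei_exp_wp.mu[0], ei_exp_wp.sigma[0],
                ei_exp.tau_m[0], ei_exp.tau_r[0], ei_exp.V_th_rel[0],
                ei_exp.V_0_rel[0], shift)
        plus = dyn._transfer_scalar(f, *args)
        minus = dyn._transfer_scalar(-f, *args)
        assert minus == pytest.approx(np.conj(plus), rel=1e-10)

    def test_taylor_variant_not_implemented(self, ei_exp, ei_exp_wp):
        with pytest.raises(NotImplementedError):
            dyn.transfer_function(ei_exp, ei_exp_wp, [1.0], variant="taylor")

    def test_unknown_variant_rejected(self, ei_exp, ei_exp_wp):
        with pytest.raises(ValueError):
            dyn.transfer_function(ei_exp, ei_exp_wp, [1.0], variant="bogus")


class TestDelayKernel:
    def test_unity_at_zero_frequency(self, ei_exp):
        for kind in ("delta", "truncated_gaussian"):
            net = ei_exp.with_overrides(delay_kind=kind,
                                        delay_sd=np.full((2, 2), 0.5e-3))
            dk = dyn.delay_kernel(net, [0.0, 10.0])
            np.testing.assert_allclose(dk.values[:, :, 0], 1.0, atol=1e-14)

    def test_delta_kind_pure_phase(self, ei_exp):
        dk = dyn.delay_kernel(ei_exp, np.linspace(0, 400, 9))
        np.testing.assert_allclose(np.abs(dk.values), 1.0, rtol=1e-14)

    def test_modulus_bounded_by_one(self, ei_exp):
        net = ei_exp.with_overrides(delay_kind="truncated_gaussian",
                                    delay_sd=np.full((2, 2), 0.75e-3))
        dk = dyn.delay_kernel(net, np.linspace(0, 400, 21))
        assert np.all(np.abs(dk.values) <= 1.0 + 1e-12)

    @pytest.mark.parametrize("f", [13.0, 61.0, 211.0])
    def test_truncated_gaussian_against_quadrature(self, f):
        mean, sd = 1.5e-3, 0.75e-3
        omega = 2 * np.pi * f
        tn = sps.truncnorm(a=(0 - mean) / sd, b=np.inf, loc=mean, scale=sd)
        re = integrate.quad(lambda x: np.cos(omega * x) * tn.pdf(x),
                            0, np.inf, limit=400)[0]
        im = -integrate.quad(lambda x: np.sin(omega * x) * tn.pdf(x),
                             0, np.inf, limit=400)[0]
        val = dyn._truncated_gaussian_ft(omega, mean, sd)
        assert val == pytest.approx(re + 1j * im, abs=1e-8)

    def test_negative_sd_rejected(self, ei_exp):
        net = ei_exp.with_overrides(delay_sd=np.full((2, 2), -1e-3))
        with pytest.raises(ValueError):
            dyn.delay_kernel(net, [1.0])


class TestPowerSpectra:
    def test_shot_noise_floor_for_zero_weights(self, ei_exp, ei_exp_wp):
        net = ei_exp.with_overrides(J=np.zeros((2, 2)))
        freqs = np.linspace(1.0, 400.0, 7)
        tf = dyn.transfer_function(net, ei_exp_wp, freqs)
        dk = dyn.delay_kernel(net, freqs)
        ps = dyn.power_spectra(net, ei_exp_wp, tf, dk)
        expected = np.tile((ei_exp_wp.nu / net.n)[:, np.newaxis], (1, 7))
        np.testing.assert_allclose(ps.values, expected, rtol=1e-12)

    def test_real_positive(self, ei_exp, ei_exp_wp):
        freqs = np.linspace(1.0, 200.0, 9)
        tf = dyn.transfer_function(ei_exp, ei_exp_wp, freqs)
        dk = dyn.delay_kernel(ei_exp, freqs)
        ps = dyn.power_spectra(ei_exp, ei_exp_wp, tf, dk)
        assert np.all(ps.values > 0)
        assert np.all(np.isfinite(ps.values))

    def test_matches_dense_inverse_oracle(self, ei_exp, ei_exp_wp):
        freqs = np.linspace(5.0, 150.0, 5)
        tf = dyn.transfer_function(ei_exp, ei_exp_wp, freqs)
        dk = dyn.delay_kernel(ei_exp, freqs)
        ps = dyn.power_spectra(ei_exp, ei_exp_wp, tf, dk)
        M = dyn.effective_connectivity(ei_exp, tf, dk).values
        D = np.diag(ei_exp_wp.nu / ei_exp.n)
        for j in range(freqs.size):
            A = np.linalg.inv(np.eye(2) - M[j])
            A_minus = np.linalg.inv(np.eye(2) - M[j].conj())
            C = A @ D @ A_minus.T
            np.testing.assert_allclose(ps.values[:, j], np.diag(C).real,
                                       rtol=1e-10)
            assert np.max(np.abs(np.diag(C).imag)) < 1e-12 * np.max(
                np.abs(np.diag(C).real))

    def test_singularity_reported_with_frequency(self):
        # a synthetic system with M = 1 exactly: the solve must fail loudly
        freqs = np.array([10.0])
        with pytest.raises(dyn.SingularityError, match="10"):
            tf1 = dyn.TransferFunction(
                values=np.full((1, 1), 1.0 + 0j), frequencies=freqs,
                variant="cn_shift_filtered")
            dk1 = dyn.DelayKernel(values=np.ones((1, 1, 1), complex),
                                  frequencies=freqs, kind="delta",
                                  mean=np.zeros((1, 1)), sd=np.zeros((1, 1)))
            net1 = PopulationNetwork(
                labels=["E"], n=[100], J=[[1.0]], K=[[1.0]],
                J_ext=[[0.0]], K_ext=[[0.0]], nu_ext=[0.0],
                tau_m=1.0, tau_s=0.0, tau_r=1e-3,
                V_th_rel=1e-3, V_0_rel=0.0)
            wp1 = WorkingPoint(nu=np.array([1.0]),
                               stats=InputStats(mu=np.zeros(1),
                                                sigma=np.ones(1)))
            dyn.power_spectra(net1, wp1, tf1, dk1)


class TestSensitivity:
    @staticmethod
    def _setup(seed=3, nf=12):
        net = fx.random_network(4, seed=seed)
        wp = stat.solve_rates_ode(net)
        freqs = np.linspace(10.0, 120.0, nf)
        tf = dyn.transfer_function(net, wp, freqs)
        dk = dyn.delay_kernel(net, freqs)
        return net, wp, freqs, tf, dk

    def test_single_population_equals_matrix(self):
        net = fx.random_network(1, seed=0)
        wp = stat.solve_rates_ode(net)
        freqs = np.array([20.0])
        tf = dyn.transfer_function(net, wp, freqs)
        dk = dyn.delay_kernel(net, freqs)
        M = dyn.effective_connectivity(net, tf, dk).values[0]
        out = dyn.sensitivity_measure(net, wp, tf, dk, 20.0)
        assert out.Z[0, 0] == pytest.approx(M[0, 0], rel=1e-12)

    def test_finite_difference_oracle(self):
        net, wp, freqs, tf, dk = self._setup()
        out = dyn.sensitivity_measure(net, wp, tf, dk, freqs[5])
        M = dyn.effective_connectivity(net, tf, dk).values[5]
        eps = 1e-6
        for c in range(4):
            for d in range(4):
                if net.K[c, d] == 0:
                    assert out.Z[c, d] == 0
                    continue
                Mp = M.copy()
                Mp[c, d] *= 1 + eps
                lam_p = np.linalg.eigvals(Mp)
                lam_b = lam_p[np.argmin(np.abs(lam_p - out.eigenvalue))]
                fd = (lam_b - out.eigenvalue) / eps
                assert fd == pytest.approx(out.Z[c, d], rel=1e-4)

    def test_projection_decomposition(self):
        net, wp, freqs, tf, dk = self._setup(seed=5)
        out = dyn.sensitivity_measure(net, wp, tf, dk, freqs[3])
        np.testing.assert_allclose(out.Z_amp ** 2 + out.Z_freq ** 2,
                                   np.abs(out.Z) ** 2, rtol=1e-10, atol=1e-30)

    def test_zero_indegree_zero_sensitivity(self):
        net, wp, freqs, tf, dk = self._setup(seed=7)
        out = dyn.sensitivity_measure(net, wp, tf, dk, freqs[0])
        mask = net.K == 0
        assert np.all(out.Z[mask] == 0)


class TestSensitivityAllEigenmodes:
    def test_single_population(self):
        net = fx.random_network(1, seed=1)
        wp = stat.solve_rates_ode(net)
        freqs = np.linspace(5.0, 150.0, 30)
        tf = dyn.transfer_function(net, wp, freqs)
        dk = dyn.delay_kernel(net, freqs)
        M = dyn.effective_connectivity(net, tf, dk).values[:, 0, 0]
        outs = dyn.sensitivity_all_eigenmodes(net, wp, tf, dk)
        assert len(outs) == 1
        j_star = int(np.argmin(np.abs(1 - M)))
        assert outs[0].frequency == freqs[j_star]

    def test_block_diagonal_independence(self):
        """A decoupled two-population network analyzed jointly equals the
        two single-population problems analyzed separately."""
        net1 = fx.random_network(1, seed=11)
        net2 = fx.random_network(1, seed=12)
        J = np.diag([net1.J[0, 0], net2.J[0, 0]])
        K = np.diag([net1.K[0, 0], net2.K[0, 0]])
        dm = np.diag([net1.delay_mean[0, 0], net2.delay_mean[0, 0]])
        dsd = np.diag([net1.delay_sd[0, 0], net2.delay_sd[0, 0]])
        joint = PopulationNetwork(
            labels=["A", "B"], n=[net1.n[0], net2.n[0]], J=J, K=K,
            J_ext=np.vstack([net1.J_ext, net2.J_ext]),
            K_ext=np.vstack([net1.K_ext, net2.K_ext]),
            nu_ext=net1.nu_ext,
            tau_m=[net1.tau_m[0], net2.tau_m[0]],
            tau_s=[net1.tau_s[0], net2.tau_s[0]],
            tau_r=[net1.tau_r[0], net2.tau_r[0]],
            V_th_rel=[net1.V_th_rel[0], net2.V_th_rel[0]],
            V_0_rel=[net1.V_0_rel[0], net2.V_0_rel[0]],
            delay_mean=dm, delay_sd=dsd,
            delay_kind="truncated_gaussian").validate()
        wp = stat.solve_rates_ode(joint)
        freqs = np.linspace(5.0, 150.0, 25)
        tf = dyn.transfer_function(joint, wp, freqs)
        dk = dyn.delay_kernel(joint, freqs)
        M = dyn.effective_connectivity(joint, tf, dk).values
        outs = dyn.sensitivity_all_eigenmodes(joint, wp, tf, dk)
        crit_freqs = sorted(o.frequency for o in outs)
        expected = sorted(
            freqs[int(np.argmin(np.abs(1 - M[:, i, i])))] for i in range(2))
        assert crit_freqs == expected

    def test_reported_minimum_survives_grid_refinement(self):
        net = fx.random_network(3, seed=21)
        wp = stat.solve_rates_ode(net)
        freqs = np.linspace(10.0, 150.0, 20)
        tf = dyn.transfer_function(net, wp, freqs)
        dk = dyn.delay_kernel(net, freqs)
        outs = dyn.sensitivity_all_eigenmodes(net, wp, tf, dk)
        out = outs[0]
        # refine tenfold around the reported critical frequency
        f0 = out.frequency
        span = freqs[1] - freqs[0]
        fine = np.linspace(max(f0 - span, 1e-3), f0 + span, 21)
        tf_f = dyn.transfer_function(net, wp, fine)
        dk_f = dyn.delay_kernel(net, fine)
        M_f = dyn.effective_connectivity(net, tf_f, dk_f).values
        best = min(np.min(np.abs(1 - np.linalg.eigvals(M_f[j])))
                   for j in range(fine.size))
        assert abs(1 - out.eigenvalue) <= best * 1.05 + 1e-12


class TestSpectrumDivergence:
    def test_peak_grows_like_inverse_square_distance(self, ei_exp):
        """As J is scaled toward instability the peak power follows
        1/|1-lambda|^2 on a two-population network."""
        wp = stat.solve_rates_ode(ei_exp)
        freqs = np.linspace(1.0, 300.0, 60)
        tf = dyn.transfer_function(ei_exp, wp, freqs)
        dk = dyn.delay_kernel(ei_exp, freqs)
        M1 = dyn.effective_connectivity(ei_exp, tf, dk).values
        # find scaling that brings max eigenvalue magnitude-to-1 distance down
        lam = np.array([np.linalg.eigvals(M1[j]) for j in range(freqs.size)])
        dist = np.abs(1 - lam)
        j0, b0 = np.unravel_index(np.argmin(dist), dist.shape)
        records = []
        for scale in (1.0, 1.2, 1.4):
            Ms = M1 * scale
            dmin, pmax = np.inf, 0.0
            for j in range(freqs.size):
                lam_j = np.linalg.eigvals(Ms[j])
                dmin = min(dmin, np.min(np.abs(1 - lam_j)))
                A = np.linalg.inv(np.eye(2) - Ms[j])
                C = A @ np.diag(wp.nu / ei_exp.n) @ A.conj().T
                pmax = max(pmax, np.max(np.diag(C).real))
            records.append((dmin, pmax))
        # closer to instability -> larger peak, consistent with 1/d^2
        d, p = zip(*records)
        assert p[2] > p[1] > p[0]
        ratio = (p[2] / p[0]) / ((d[0] / d[2]) ** 2)
        assert 0.1 < ratio < 10.0
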