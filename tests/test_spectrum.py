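import math

import numpy as np
import pytest

from rotorpool.oa import OAField, integrate_layer, make_quadrature
from rotorpool.spectrum import (
    characteristic_det,
    classify_stability,
    continuous_spectrum,
    discrete_spectrum,
    jacobians,
)
from rotorpool.stationary import branch_from_root, local_profile


def F_eq(x, y, X, Y, I, s):
    """Real part of the evolution equation, coded independently."""
    return (0.5 * (1 - x * x + y * y) - I * y + 0.5 * s * X
            - 0.5 * s * X * (x * x - y * y) - s * x * y * Y)


def G_eq(x, y, X, Y, I, s):
    """Imaginary part of the evolution equation, coded independently."""
    return (-x * y + I * x + 0.5 * s * Y - s * x * y * X
            + 0.5 * s * Y * (x * x - y * y))


class TestJacobians:
    @pytest.mark.parametrize("I", [-3.5, -1.0, 0.0, 1.5, 4.0, 6.0])
    def test_matches_finite_differences(self, I, branches_ref):
        br = branches_ref[2]
        P, Q = jacobians(I, br)
        z0 = local_profile(br, I)
        x0, y0 = z0.real, z0.imag
        X0, Y0 = br.Z.real, br.Z.imag
        h = 1e-6
        s = br.sigma
        fd = lambda f, args, k: (f(*[a + h * (i == k) for i, a in enumerate(args)], I, s)
                                 - f(*[a - h * (i == k) for i, a in enumerate(args)], I, s)) / (2 * h)
        args = (x0, y0, X0, Y0)
        P_fd = np.array([[fd(F_eq, args, 0), fd(F_eq, args, 1)],
                         [fd(G_eq, args, 0), fd(G_eq, args, 1)]])
        Q_fd = np.array([[fd(F_eq, args, 2), fd(F_eq, args, 3)],
                         [fd(G_eq, args, 2), fd(G_eq, args, 3)]])
        np.testing.assert_allclose(P, P_fd, atol=1e-6)
        np.testing.assert_allclose(Q, Q_fd, atol=1e-6)

    def test_trace_matches_finite_differences(self, branches_ref):
        br = branches_ref[0]
        I = 1.2
        P, _ = jacobians(I, br)
        z0 = local_profile(br, I)
        args = (z0.real, z0.imag, br.Z.real, br.Z.imag)
        h = 1e-6
        s = br.sigma
        tr_fd = ((F_eq(args[0] + h, *args[1:], I, s) - F_eq(args[0] - h, *args[1:], I, s))
                 + (G_eq(args[0], args[1] + h, *args[2:], I, s)
                    - G_eq(args[0], args[1] - h, *args[2:], I, s))) / (2 * h)
        assert np.trace(P) == pytest.approx(tr_fd, abs=1e-6)

    def test_no_global_feedback_without_coupling(self):
        br = branch_from_root(1.0, 0.9, 2.0, 0.0, label="B1")
        _, Q = jacobians(0.5, br)
        np.testing.assert_allclose(Q, 0.0, atol=1e-14)

    def test_stationarity_of_profile(self, branches_ref):
        # the closed-form profile really is a zero of (F, G)
        for br in branches_ref:
            for I in (-2.0, 0.3, 1.7, 5.0):
                z0 = local_profile(br, I)
                resid = math.hypot(
                    F_eq(z0.real, z0.imag, br.Z.real, br.Z.imag, I, br.sigma),
                    G_eq(z0.real, z0.imag, br.Z.real, br.Z.imag, I, br.sigma))
                assert resid < 1e-8


class TestContinuousSpectrum:
    def test_always_stable_or_marginal(self, branches_ref):
        for br in branches_ref:
            _, eigs = continuous_spectrum(br)
            assert eigs.real.max() <= 1e-8

    def test_group_structure(self, branches_ref):
        # excitable inputs give real pairs, oscillating inputs complex pairs
        br = branches_ref[0]
        I_grid, eigs = continuous_spectrum(br, n_samples=500)
        exc = np.abs(I_grid) < 0.99 * br.B
        osc = np.abs(I_grid) > 1.01 * br.B
        assert np.abs(eigs[exc].imag).max() < 1e-10
        assert np.all(np.abs(eigs[osc, 0].imag) > 0)
        # conjugate pairing on the oscillating side
        np.testing.assert_allclose(eigs[osc, 0], eigs[osc, 1].conj(), atol=1e-12)

    def test_uncoupled_running_rotator_is_marginal(self):
        # sigma=0, single input I>1: pure imaginary pair (phase shift along
        # the drift orbit is neutral)
        br = branch_from_root(1.0, 2.0, 1e-6, 0.0, label="B1")
        P, _ = jacobians(2.0, br)
        eigs = np.linalg.eigvals(P)
        assert np.abs(eigs.real).max() < 1e-12
        assert np.abs(eigs.imag).max() > 0.1


class TestCharacteristicDet:
    def test_identity_at_large_mu(self, branches_ref):
        # resolvent decays like 1/mu, so |det C - 1| = O(1/|mu|)
        br = branches_ref[1]
        devs = [abs(characteristic_det(mu, br) - 1.0)
                for mu in (40.0 + 3j, 400.0 + 3j, 4000.0 + 3j)]
        assert devs[0] > devs[1] > devs[2]
        for mu, dev in zip((40.0, 400.0, 4000.0), devs):
            assert dev * mu < 20.0
        assert devs[2] < 2e-3

    def test_conjugate_symmetry(self, branches_ref):
        br = branches_ref[2]
        for mu in (0.5 + 1.2j, -0.3 + 0.7j, 1.5 + 2.5j):
            d = characteristic_det(mu, br)
            d_conj = characteristic_det(np.conj(mu), br)
            assert abs(d_conj - np.conj(d)) < 1e-10

    def test_holomorphic_off_spectrum(self, branches_ref):
        # Cauchy-Riemann residual of numerically differenced det C
        br = branches_ref[2]
        h = 1e-5
        for mu in (0.6 + 1.1j, -0.4 + 2.3j):
            d_re = (characteristic_det(mu + h, br) - characteristic_det(mu - h, br)) / (2 * h)
            d_im = (characteristic_det(mu + 1j * h, br) - characteristic_det(mu - 1j * h, br)) / (2j * h)
            assert abs(d_re - d_im) < 1e-5

    def test_rejects_mu_on_continuous_spectrum(self, branches_ref):
        br = branches_ref[0]
        I_grid, eigs = continuous_spectrum(br)
        with pytest.raises(ValueError):
            characteristic_det(complex(eigs[len(I_grid) // 2, 0]), br)


class TestDiscreteSpectrumAndClassification:
    def test_reference_classifications(self, spectra_ref):
        # coherent branch stable node; the two mixed branches unstable
        # node and unstable focus respectively
        assert spectra_ref["B1"].classification == "stable node"
        assert spectra_ref["B2"].classification == "unstable node"
        assert spectra_ref["B3"].classification == "unstable focus"

    def test_conjugate_pairs_and_residuals(self, spectra_ref, branches_ref):
        br = {b.label: b for b in branches_ref}
        for label, res in spectra_ref.items():
            eigs = res.discrete
            for mu in eigs:
                if abs(mu.imag) > 1e-6:
                    assert any(abs(mu.conjugate() - other) < 1e-9 for other in eigs)
                    # isolated roots satisfy the tight determinant tolerance
                    assert abs(characteristic_det(mu, br[label])) < 1e-8

    def test_b1_eigenvalues_negative_real(self, spectra_ref):
        for mu in spectra_ref["B1"].discrete:
            assert mu.real < 0
            assert mu.imag == 0

    def test_b2_has_positive_real_eigenvalue(self, spectra_ref):
        assert any(mu.imag == 0 and mu.real > 0 for mu in spectra_ref["B2"].discrete)

    def test_b3_unstable_complex_pair(self, spectra_ref):
        lead = max(spectra_ref["B3"].discrete, key=lambda m: m.real)
        assert lead.real > 0 and abs(lead.imag) > 0

    def test_against_discretized_operator(self, branches_ref, spectra_ref):
        # independent oracle: eigenvalues of the finite-dimensional
        # discretization J[m,n] = delta_mn P(I_m) + Q(I_m) w_n
        M = 400
        nodes, w = make_quadrature(M, "trapezoid")
        for br in branches_ref:
            I = br.r1 + br.r2 * nodes
            J = np.zeros((2 * M, 2 * M))
            for m in range(M):
                P, Q = jacobians(I[m], br)
                J[2 * m:2 * m + 2, 2 * m:2 * m + 2] += P
                for n in range(M):
                    J[2 * m:2 * m + 2, 2 * n:2 * n + 2] += Q * w[n]
            lead = np.linalg.eigvals(J)
            lead_re = lead.real.max()
            res = spectra_ref[br.label]
            if res.classification.startswith("unstable"):
                # sign of the leading real part agrees, and the growth rate
                # matches within the discretization error of the marginal
                # continuous spectrum (a few percent)
                mu_lead = max(res.discrete, key=lambda m: m.real)
                assert lead_re > 0.1
                close = lead[np.argmax(lead.real)]
                assert min(abs(close - mu_lead), abs(close - mu_lead.conjugate())) < 0.1
            else:
                # stable branch: no growth beyond the discretization noise
                # floor of the marginal modes
                assert lead_re < 0.05

    def test_synthetic_classifications(self, branches_ref):
        br = branches_ref[0]
        assert classify_stability(br, discrete=[-1.0 + 0j, -2.0 + 0j]).classification == "stable node"
        assert classify_stability(br, discrete=[0.1 + 2j, 0.1 - 2j]).classification == "unstable focus"
        assert classify_stability(br, discrete=[-0.2 + 1j, -0.2 - 1j]).classification == "stable focus"
        br.stability = None

    def test_agreement_with_layer_dynamics(self, branches_ref):
        # unstable branches depart from their profile under the layer flow;
        # the stable branch stays (quadrature-limited) close
        nodes, w = make_quadrature(201, "trapezoid")
        for br, grows in zip(branches_ref, (False, True, True)):
            z0 = local_profile(br, br.r1 + br.r2 * nodes)
            rng = np.random.default_rng(0)
            z0 = z0 + 1e-6 * rng.standard_normal(z0.size)
            z0 *= np.minimum(1.0, 0.999999 / np.abs(z0))
            field = OAField(nodes=nodes, weights=w, z=z0, r1=br.r1, r2=br.r2)
            traj = integrate_layer(field, br.sigma, 150.0, dt_out=1.0)
            dev = np.abs(traj.Z - br.Z).max()
            if grows:
                assert dev > 0.05
            else:
                # bounded by quadrature error + marginal-mode beating
                assert dev < 0.02
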