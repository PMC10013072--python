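"""Independent brute-force oracles shared by the test suite.

Everything here is implemented directly from the defining formulas,
bypassing the package's optimized evaluation paths.
"""

import numpy as np
from scipy.stats import norm

from rotorpool.oa import make_quadrature
from rotorpool.stationary import local_profile


def riemann_p_integrals(B, r1, r2, n=1_000_000):
    """Midpoint-rule evaluation of the self-consistency integrals."""
    I = np.linspace(r1 - 8 * r2, r1 + 8 * r2, n + 1)
    I = 0.5 * (I[1:] + I[:-1])
    h = I[1] - I[0]
    g = norm.pdf(I, r1, r2)
    exc = np.abs(I) < B
    p2 = np.sum(g[exc] * np.sqrt(B * B - I[exc] ** 2)) * h
    osc = ~exc
    p1 = r1 - np.sum(I[osc] * g[osc] * np.sqrt(1.0 - B * B / I[osc] ** 2)) * h
    return p1, p2


def _F(x, y, X, Y, I, s):
    return (0.5 * (1 - x * x + y * y) - I * y + 0.5 * s * X
            - 0.5 * s * X * (x * x - y * y) - s * x * y * Y)


def _G(x, y, X, Y, I, s):
    return (-x * y + I * x + 0.5 * s * Y - s * x * y * X
            + 0.5 * s * Y * (x * x - y * y))


def finite_difference_jacobians(I, branch, h=1e-6):
    """Central finite differences of the evolution equations (F, G)."""
    z0 = local_profile(branch, float(I))
    args = [z0.real, z0.imag, branch.Z.real, branch.Z.imag]
    s = branch.sigma

    def col(f, k):
        up = list(args)
        dn = list(args)
        up[k] += h
        dn[k] -= h
        return (f(*up, I, s) - f(*dn, I, s)) / (2 * h)

    P = np.array([[col(_F, 0), col(_F, 1)], [col(_G, 0), col(_G, 1)]])
    Q = np.array([[col(_F, 2), col(_F, 3)], [col(_G, 2), col(_G, 3)]])
    return P, Q


def discretized_operator_leading_eig(branch, M=300):
    """Leading eigenvalue of the finite-dimensional linearization.

    The mean-field linearization is discretized on an M-node quadrature
    grid: J = blockdiag(P(I_m)) + [Q(I_m) w_n]_{mn}.
    """
    from rotorpool.spectrum import jacobians

    nodes, w = make_quadrature(M, "trapezoid")
    I = branch.r1 + branch.r2 * nodes
    J = np.zeros((2 * M, 2 * M))
    for m in range(M):
        P, Q = jacobians(I[m], branch)
        J[2 * m:2 * m + 2, 2 * m:2 * m + 2] += P
        J[2 * m:2 * m + 2, 0::2] += np.outer(Q[:, 0], w)
        J[2 * m:2 * m + 2, 1::2] += np.outer(Q[:, 1], w)
    eigs = np.linalg.eigvals(J)
    return eigs[np.argmax(eigs.real)]
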