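"""Independent Mie reference implementation used only as a test oracle.

Deliberately takes a different computational route from the package: Mie
coefficients are built from Riccati-Bessel functions evaluated through
half-integer-order cylindrical Bessel functions of complex argument
(scipy.special.jv / yv, AMOS), with the textbook a_n/b_n expressions —
no logarithmic-derivative recursion and no shared code.
"""

import numpy as np
from scipy.special import jv, yv


def _psi(n, z):
    """Riccati-Bessel psi_n(z) = z j_n(z), complex-capable."""
    z = np.asarray(z, dtype=complex)
    return np.sqrt(np.pi * z / 2.0) * jv(n + 0.5, z)


def _chi(n, z):
    """Riccati-Bessel chi_n(z) = -z y_n(z), complex-capable."""
    z = np.asarray(z, dtype=complex)
    return -np.sqrt(np.pi * z / 2.0) * yv(n + 0.5, z)


def mie_qext_qsca(m, x, n_extra=20):
    """Reference (Qext, Qsca) for a homogeneous sphere, scalar m and x."""
    m = complex(m)
    x = float(x)
    nmax = int(np.round(x + 4.0 * x ** (1.0 / 3.0) + 2.0)) + n_extra
    n = np.arange(1, nmax + 1)

    mx = m * x
    psi_x = _psi(n, x).real  # real argument
    psi_xm1 = _psi(n - 1, x).real
    chi_x = _chi(n, x).real
    chi_xm1 = _chi(n - 1, x).real
    xi_x = psi_x - 1j * chi_x
    xi_xm1 = psi_xm1 - 1j * chi_xm1

    psi_mx = _psi(n, mx)
    psi_mxm1 = _psi(n - 1, mx)

    # derivatives via psi_n'(z) = psi_{n-1}(z) - n psi_n(z)/z
    dpsi_x = psi_xm1 - n * psi_x / x
    dxi_x = xi_xm1 - n * xi_x / x
    dpsi_mx = psi_mxm1 - n * psi_mx / mx

    a = (m * psi_mx * dpsi_x - psi_x * dpsi_mx) / (
        m * psi_mx * dxi_x - xi_x * dpsi_mx
    )
    b = (psi_mx * dpsi_x - m * psi_x * dpsi_mx) / (
        psi_mx * dxi_x - m * xi_x * dpsi_mx
    )

    w = 2.0 * n + 1.0
    qext = (2.0 / x**2) * np.sum(w * (a + b).real)
    qsca = (2.0 / x**2) * np.sum(w * (np.abs(a) ** 2 + np.abs(b) ** 2))
    return qext, qsca


def rayleigh_qext(m, x):
    """Small-x closed form: Qext ~ 4x Im[(m^2-1)/(m^2+2)] + (8/3)x^4 |...|^2."""
    m = complex(m)
    f = (m * m - 1.0) / (m * m + 2.0)
    return 4.0 * x * f.imag + (8.0 / 3.0) * x**4 * abs(f) ** 2
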