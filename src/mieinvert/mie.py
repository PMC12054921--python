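"""Forward light-scattering model for a homogeneous absorbing sphere.

Computes Lorenz-Mie extinction/scattering/absorption efficiencies from the
sphere's complex refractive index, and converts between apparent absorbance
and extinction efficiency for a single-detector transmission geometry.

The Mie coefficients use the logarithmic-derivative formulation with
downward recurrence (stable for absorbing media), Riccati-Bessel functions
of the real size parameter by upward recurrence, and Wiscombe's truncation
criterion n_max = round(x + 4 x^(1/3) + 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import spherical_jn, spherical_yn

from .dispersion import RefractiveIndexSpectrum, SpectralGrid

__all__ = [
    "SphereModel",
    "DetectorGeometry",
    "ExtinctionSpectrum",
    "AbsorbanceSpectrum",
    "size_parameter",
    "mie_efficiencies",
    "forward_qext",
    "absorbance_to_qext",
    "qext_to_absorbance",
]

#: extra recursion depth above max(n_max, |mx|) for the downward
#: log-derivative start; 30 keeps weakly absorbing large spheres (|mx| ~ 50,
#: Im(mx) << 1) converged to ~1e-10
_LOGDERIV_PAD = 30


@dataclass(frozen=True)
class SphereModel:
    """Homogeneous sphere: radius in micrometres, real host index."""

    radius_um: float = 5.0
    medium_index: float = 1.0

    def __post_init__(self):
        if not (self.radius_um > 0 and np.isfinite(self.radius_um)):
            raise ValueError("radius must be positive")
        if not (self.medium_index >= 1 and np.isfinite(self.medium_index)):
            raise ValueError("medium_index must be >= 1 (real, non-absorbing host)")


@dataclass(frozen=True)
class DetectorGeometry:
    """Detector reception area G and sample geometric cross-section g
    (same units; G >> g in the intended geometry)."""

    reception_area_G: float
    sample_cross_section_g: float

    def __post_init__(self):
        if not (self.reception_area_G > self.sample_cross_section_g > 0):
            raise ValueError("require G > g > 0")

    @property
    def ratio(self) -> float:
        return self.reception_area_G / self.sample_cross_section_g


@dataclass
class ExtinctionSpectrum:
    """Extinction efficiency Q_ext sampled on a wavenumber grid."""

    grid: SpectralGrid
    qext: np.ndarray

    def __post_init__(self):
        self.qext = np.asarray(self.qext, dtype=float)
        if self.qext.shape != self.grid.wavenumbers.shape:
            raise ValueError("qext length does not match grid")
        if not np.all(np.isfinite(self.qext)):
            raise ValueError("qext contains non-finite values")
        if np.any(self.qext < 0):
            raise ValueError("qext must be non-negative")


@dataclass
class AbsorbanceSpectrum:
    """Apparent (decadic) absorbance sampled on a wavenumber grid."""

    grid: SpectralGrid
    absorbance: np.ndarray

    def __post_init__(self):
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != self.grid.wavenumbers.shape:
            raise ValueError("absorbance length does not match grid")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")


def size_parameter(sphere: SphereModel, nu):
    """Size parameter x = 2 pi r nu (in host-medium wavelengths).

    ``nu`` in cm^-1, radius in micrometres: x = 2 pi r * nu * 1e-4 * n_host.
    """
    nu = np.asarray(nu, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("wavenumber must be positive")
    x = 2.0 * np.pi * sphere.radius_um * nu * 1.0e-4 * sphere.medium_index
    return float(x) if x.ndim == 0 else x


def _wiscombe_nmax(x: np.ndarray) -> np.ndarray:
    return np.round(x + 4.0 * np.cbrt(x) + 2.0).astype(int)


# cache of real-argument Riccati-Bessel tables keyed by the size-parameter
# grid; during a fit the grid is fixed while m varies, so these dominate
# the cost only once
_RB_CACHE: dict = {}
_RB_CACHE_MAX = 8


def _riccati_bessel_real(x: np.ndarray, N: int):
    """psi_n(x) = x j_n(x) and xi_n(x) = psi_n - i chi_n for n = 0..N.

    Library spherical Bessel routines stay accurate for n well above x,
    where the upward psi recurrence loses digits.
    """
    key = (N, x.shape, x.tobytes())
    hit = _RB_CACHE.get(key)
    if hit is not None:
        return hit
    nvec = np.arange(0, N + 1)
    psi = x * spherical_jn(nvec[:, np.newaxis], x[np.newaxis, :])
    chi = -x * spherical_yn(nvec[:, np.newaxis], x[np.newaxis, :])
    xi = psi - 1j * chi
    if len(_RB_CACHE) >= _RB_CACHE_MAX:
        _RB_CACHE.pop(next(iter(_RB_CACHE)))
    _RB_CACHE[key] = (psi, xi)
    return psi, xi


def mie_efficiencies(m, x):
    """Mie efficiencies (Qext, Qsca, Qabs) of a homogeneous sphere.

    Parameters
    ----------
    m : complex or array
        Relative refractive index (sphere over host); Re(m) > 0, Im(m) >= 0.
    x : float or array
        Size parameter, > 0.  ``m`` and ``x`` broadcast together.

    Returns
    -------
    (qext, qsca, qabs) with the broadcast shape (scalars for scalar input).
    """
    m = np.asarray(m, dtype=complex)
    x = np.asarray(x, dtype=float)
    scalar = m.ndim == 0 and x.ndim == 0
    m, x = np.broadcast_arrays(np.atleast_1d(m), np.atleast_1d(x))
    m = m.astype(complex)
    x = x.astype(float)

    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(m))):
        raise ValueError("m and x must be finite")
    if np.any(x <= 0):
        raise ValueError("size parameter must be positive")
    if np.any(m.real <= 0) or np.any(m.imag < 0):
        raise ValueError("require Re(m) > 0 and Im(m) >= 0")

    shape = x.shape
    qext = np.zeros(shape)
    qsca = np.zeros(shape)

    # zero-contrast points scatter nothing; exclude to return exact zeros
    active = m != 1.0
    if np.any(active):
        qe, qs = _mie_series(m[active], x[active])
        qext[active] = qe
        qsca[active] = qs

    qabs = qext - qsca
    if scalar:
        return float(qext[0]), float(qsca[0]), float(qabs[0])
    return qext, qsca, qabs


def _mie_series(m: np.ndarray, x: np.ndarray):
    """Lorenz-Mie partial-wave sums for flat arrays of (m, x)."""
    nmax = _wiscombe_nmax(x)
    N = int(nmax.max())
    mx = m * x

    # log-derivative of psi at mx, downward with D = 0 seed; the start
    # order must exceed both the truncation order and |mx| for convergence
    nstart = max(N, int(np.ceil(np.max(np.abs(mx))))) + _LOGDERIV_PAD
    D = np.zeros(mx.shape, dtype=complex)
    Dstore = np.empty((N + 1,) + mx.shape, dtype=complex)
    for n in range(nstart, 1, -1):
        rn = n / mx
        D = rn - 1.0 / (D + rn)  # now equals D_{n-1}
        if n - 1 <= N:
            Dstore[n - 1] = D

    psi, xi = _riccati_bessel_real(x, N)

    qext = np.zeros(x.shape)
    qsca = np.zeros(x.shape)
    inv_x = 1.0 / x
    for n in range(1, N + 1):
        psi_n, psi_nm1 = psi[n], psi[n - 1]
        xi_n, xi_nm1 = xi[n], xi[n - 1]

        Dn = Dstore[n]
        ta = Dn / m + n * inv_x
        tb = Dn * m + n * inv_x
        an = (ta * psi_n - psi_nm1) / (ta * xi_n - xi_nm1)
        bn = (tb * psi_n - psi_nm1) / (tb * xi_n - xi_nm1)

        keep = n <= nmax
        w = 2.0 * n + 1.0
        qext += np.where(keep, w * (an + bn).real, 0.0)
        qsca += np.where(keep, w * (np.abs(an) ** 2 + np.abs(bn) ** 2), 0.0)

    pref = 2.0 * inv_x**2
    return pref * qext, pref * qsca


def forward_qext(n: RefractiveIndexSpectrum, sphere: SphereModel) -> ExtinctionSpectrum:
    """Extinction-efficiency spectrum of a homogeneous sphere.

    Applies the Mie series pointwise with relative index
    m(nu) = n(nu)/n_host and size parameter from ``size_parameter``.
    """
    x = size_parameter(sphere, n.grid.wavenumbers)
    m = n.as_complex() / sphere.medium_index
    qext, _, _ = mie_efficiencies(m, x)
    # guard against tiny negative rounding residue at near-zero contrast
    return ExtinctionSpectrum(grid=n.grid, qext=np.maximum(qext, 0.0))


def absorbance_to_qext(a: AbsorbanceSpectrum, geom: DetectorGeometry) -> ExtinctionSpectrum:
    """Q_ext = (G/g) (1 - 10^-A)."""
    qext = geom.ratio * (1.0 - 10.0 ** (-a.absorbance))
    return ExtinctionSpectrum(grid=a.grid, qext=qext)


def qext_to_absorbance(q: ExtinctionSpectrum, geom: DetectorGeometry) -> AbsorbanceSpectrum:
    """A = -log10(1 - Q_ext g/G); requires Q_ext < G/g pointwise."""
    arg = 1.0 - q.qext / geom.ratio
    if np.any(arg <= 0):
        raise ValueError("qext >= G/g: inconsistent detector geometry")
    return AbsorbanceSpectrum(grid=q.grid, absorbance=-np.log10(arg))
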