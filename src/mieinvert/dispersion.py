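"""Kramers-Kronig-consistent dielectric dispersion models.

This module holds the spectral containers used throughout the package and
the two oscillator bases that can represent a material's complex
permittivity on a wavenumber grid:

* a superposition of Lorentz dielectric functions, parameterized per band
  by resonance wavenumber ``nu0``, strength ``nup`` (enters squared) and
  damping ``gamma`` (all in cm^-1), plus a constant offset ``eps_inf``;
* a sum of anti-symmetrized Lorentzians with sign-free amplitudes, kept as
  a comparison basis.

Both bases are Kramers-Kronig consistent by construction; ``kk_check``
provides an independent numerical validator based on Maclaurin's
alternating-point quadrature of the principal-value transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SpectralGrid",
    "OscillatorBand",
    "OscillatorSet",
    "DielectricSpectrum",
    "RefractiveIndexSpectrum",
    "AntisymLorentzBand",
    "AntisymLorentzSet",
    "KKReport",
    "wavenumber_to_wavelength",
    "wavelength_to_wavenumber",
    "eval_permittivity",
    "eps_to_n",
    "n_to_eps",
    "lorentzian_approximation",
    "eval_antisym_lorentzian",
    "kk_check",
]


def wavenumber_to_wavelength(nu):
    """Convert wavenumber (cm^-1) to vacuum wavelength (micrometres).

    Accepts scalars or arrays.  Raises ``ValueError`` on non-positive input.
    """
    nu = np.asarray(nu, dtype=float)
    if np.any(nu <= 0) or not np.all(np.isfinite(nu)):
        raise ValueError("wavenumber must be positive and finite")
    out = 1.0e4 / nu
    return float(out) if out.ndim == 0 else out


def wavelength_to_wavenumber(lam):
    """Convert vacuum wavelength (micrometres) to wavenumber (cm^-1)."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0) or not np.all(np.isfinite(lam)):
        raise ValueError("wavelength must be positive and finite")
    out = 1.0e4 / lam
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SpectralGrid:
    """Strictly increasing grid of positive wavenumbers (cm^-1)."""

    wavenumbers: np.ndarray

    def __post_init__(self):
        wn = np.atleast_1d(np.asarray(self.wavenumbers, dtype=float))
        if wn.ndim != 1 or wn.size < 2:
            raise ValueError("grid needs at least two points")
        if not np.all(np.isfinite(wn)):
            raise ValueError("grid contains non-finite values")
        if np.any(wn <= 0):
            raise ValueError("wavenumbers must be positive")
        if np.any(np.diff(wn) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "wavenumbers", wn)

    def __len__(self) -> int:
        return self.wavenumbers.size

    @classmethod
    def uniform(cls, low: float, high: float, n: int) -> "SpectralGrid":
        if not (low < high):
            raise ValueError("low must be < high")
        return cls(np.linspace(low, high, n))

    @property
    def spacing(self) -> float:
        """Grid spacing; raises if the grid is not uniform."""
        d = np.diff(self.wavenumbers)
        if not np.allclose(d, d[0], rtol=1e-8, atol=0.0):
            raise ValueError("grid is not uniform")
        return float(d[0])


@dataclass(frozen=True)
class OscillatorBand:
    """One Lorentz absorption band: resonance ``nu0``, strength ``nup``,
    full width at half maximum ``gamma`` (all cm^-1)."""

    nu0: float
    nup: float
    gamma: float

    def __post_init__(self):
        if not (self.nu0 > 0 and np.isfinite(self.nu0)):
            raise ValueError("nu0 must be positive")
        if not (self.nup >= 0 and np.isfinite(self.nup)):
            raise ValueError("nup must be non-negative")
        if not (self.gamma > 0 and np.isfinite(self.gamma)):
            raise ValueError("gamma must be positive")


@dataclass
class OscillatorSet:
    """Ordered collection of Lorentz bands plus the offset ``eps_inf``.

    Bands are kept in canonical order: ascending ``nu0``, ties broken by
    descending ``nup``.
    """

    bands: list
    eps_inf: float = 1.0

    def __post_init__(self):
        if len(self.bands) < 1:
            raise ValueError("need at least one band")
        if not (self.eps_inf >= 1 and np.isfinite(self.eps_inf)):
            raise ValueError("eps_inf must be >= 1")
        self.bands = sorted(
            list(self.bands), key=lambda b: (b.nu0, -b.nup)
        )

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def band_arrays(self):
        """Return (nu0, nup, gamma) as float arrays of length M."""
        nu0 = np.array([b.nu0 for b in self.bands])
        nup = np.array([b.nup for b in self.bands])
        gamma = np.array([b.gamma for b in self.bands])
        return nu0, nup, gamma

    def to_dict(self) -> dict:
        return {
            "eps_inf": self.eps_inf,
            "bands": [
                {"nu0": b.nu0, "nup": b.nup, "gamma": b.gamma}
                for b in self.bands
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OscillatorSet":
        return cls(
            bands=[
                OscillatorBand(b["nu0"], b["nup"], b["gamma"])
                for b in d["bands"]
            ],
            eps_inf=float(d["eps_inf"]),
        )


def _check_arrays(grid: SpectralGrid, *arrays):
    for a in arrays:
        if a.shape != grid.wavenumbers.shape:
            raise ValueError("array length does not match grid")
        if not np.all(np.isfinite(a)):
            raise ValueError("spectrum contains non-finite values")


@dataclass
class DielectricSpectrum:
    """Complex relative permittivity sampled on a wavenumber grid."""

    grid: SpectralGrid
    eps_real: np.ndarray
    eps_imag: np.ndarray

    def __post_init__(self):
        self.eps_real = np.asarray(self.eps_real, dtype=float)
        self.eps_imag = np.asarray(self.eps_imag, dtype=float)
        _check_arrays(self.grid, self.eps_real, self.eps_imag)

    @property
    def is_passive(self) -> bool:
        """True when eps_imag >= 0 everywhere (physical, absorbing medium)."""
        return bool(np.all(self.eps_imag >= 0))

    def as_complex(self) -> np.ndarray:
        return self.eps_real + 1j * self.eps_imag


@dataclass
class RefractiveIndexSpectrum:
    """Complex refractive index sampled on a wavenumber grid."""

    grid: SpectralGrid
    n_real: np.ndarray
    n_imag: np.ndarray

    def __post_init__(self):
        self.n_real = np.asarray(self.n_real, dtype=float)
        self.n_imag = np.asarray(self.n_imag, dtype=float)
        _check_arrays(self.grid, self.n_real, self.n_imag)
        if np.any(self.n_real <= 0):
            raise ValueError("n_real must be positive")
        if np.any(self.n_imag < 0):
            raise ValueError("n_imag must be non-negative (passivity)")

    def as_complex(self) -> np.ndarray:
        return self.n_real + 1j * self.n_imag


def _lorentz_terms(nu, nu0, nup, gamma):
    # nu: (L,), band params: (M,) -> per-band contributions of shape (M, L)
    nu = nu[np.newaxis, :]
    nu0 = nu0[:, np.newaxis]
    nup = nup[:, np.newaxis]
    gamma = gamma[:, np.newaxis]
    d = nu0**2 - nu**2
    denom = d**2 + (nu * gamma) ** 2
    re = nup**2 * d / denom
    im = nu * gamma * nup**2 / denom
    return re, im


def eval_permittivity(oscillators: OscillatorSet, grid: SpectralGrid) -> DielectricSpectrum:
    """Evaluate the multi-band Lorentz permittivity on ``grid``.

    eps'  = eps_inf + sum_m nup_m^2 (nu0_m^2 - nu^2) / [(nu0_m^2 - nu^2)^2 + (nu gamma_m)^2]
    eps'' =           sum_m nu gamma_m nup_m^2      / [(nu0_m^2 - nu^2)^2 + (nu gamma_m)^2]
    """
    nu0, nup, gamma = oscillators.band_arrays()
    re, im = _lorentz_terms(grid.wavenumbers, nu0, nup, gamma)
    return DielectricSpectrum(
        grid=grid,
        eps_real=oscillators.eps_inf + re.sum(axis=0),
        eps_imag=im.sum(axis=0),
    )


def eps_to_n(eps: DielectricSpectrum) -> RefractiveIndexSpectrum:
    """Convert complex permittivity to complex refractive index.

    n' = sqrt((|eps| + eps')/2), n'' = sqrt((|eps| - eps')/2); the branch
    with n' > 0 and n'' >= 0 is taken (passive medium).
    """
    mod = np.hypot(eps.eps_real, eps.eps_imag)
    n_real = np.sqrt(np.maximum(mod + eps.eps_real, 0.0) / 2.0)
    n_imag = np.sqrt(np.maximum(mod - eps.eps_real, 0.0) / 2.0)
    return RefractiveIndexSpectrum(grid=eps.grid, n_real=n_real, n_imag=n_imag)


def n_to_eps(n: RefractiveIndexSpectrum) -> DielectricSpectrum:
    """Convert complex refractive index to complex permittivity
    (eps' = n'^2 - n''^2, eps'' = 2 n' n'')."""
    return DielectricSpectrum(
        grid=n.grid,
        eps_real=n.n_real**2 - n.n_imag**2,
        eps_imag=2.0 * n.n_real * n.n_imag,
    )


def lorentzian_approximation(band: OscillatorBand, grid: SpectralGrid) -> np.ndarray:
    """Near-resonance Lorentzian approximation of a single band's eps''.

    Returns gamma*nup^2/(4*nu0) / [(nu0 - nu)^2 + (gamma/2)^2].  Exact at
    nu = nu0 and increasingly accurate as gamma/nu0 -> 0.
    """
    nu = grid.wavenumbers
    num = band.gamma * band.nup**2 / (4.0 * band.nu0)
    return num / ((band.nu0 - nu) ** 2 + (band.gamma / 2.0) ** 2)


@dataclass(frozen=True)
class AntisymLorentzBand:
    """Anti-symmetrized Lorentzian line: amplitude may be negative."""

    amplitude: float
    nu0: float
    gamma: float

    def __post_init__(self):
        if not (self.nu0 > 0 and np.isfinite(self.nu0)):
            raise ValueError("nu0 must be positive")
        if not (self.gamma > 0 and np.isfinite(self.gamma)):
            raise ValueError("gamma must be positive")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")


@dataclass
class AntisymLorentzSet:
    """Sum of anti-symmetrized Lorentzians plus a constant real offset."""

    bands: list
    offset: float = 1.0

    def __post_init__(self):
        if len(self.bands) < 1:
            raise ValueError("need at least one band")
        self.bands = sorted(self.bands, key=lambda b: (b.nu0, -abs(b.amplitude)))

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def band_arrays(self):
        h = np.array([b.amplitude for b in self.bands])
        nu0 = np.array([b.nu0 for b in self.bands])
        gamma = np.array([b.gamma for b in self.bands])
        return h, nu0, gamma


def eval_antisym_lorentzian(aset: AntisymLorentzSet, grid: SpectralGrid) -> DielectricSpectrum:
    """Evaluate the anti-symmetrized-Lorentzian basis on ``grid``.

    Each band contributes the complex line
    ``h * [1/(nu0 - nu - i g/2) + 1/(nu0 + nu + i g/2)]`` whose imaginary
    part is the odd pair ``h*[L(nu-nu0) - L(nu+nu0)]`` with
    ``L(u) = (g/2)/(u^2 + (g/2)^2)``, and whose real part is its exact
    Hilbert-transform partner, so each line is Kramers-Kronig consistent
    regardless of the sign of ``h``.  The returned spectrum may have
    negative imaginary part (nonphysical basis) — that is the point of
    keeping this basis for comparison.
    """
    nu = grid.wavenumbers[np.newaxis, :]
    h, nu0, gamma = aset.band_arrays()
    h = h[:, np.newaxis]
    nu0 = nu0[:, np.newaxis]
    hg = gamma[:, np.newaxis] / 2.0
    line = h * (1.0 / (nu0 - nu - 1j * hg) + 1.0 / (nu0 + nu + 1j * hg))
    total = line.sum(axis=0)
    return DielectricSpectrum(
        grid=grid,
        eps_real=aset.offset + total.real,
        eps_imag=total.imag,
    )


@dataclass(frozen=True)
class KKReport:
    """Result of a numerical Kramers-Kronig consistency check."""

    max_rel_discrepancy: float
    grid_too_narrow: bool
    eval_wavenumbers: np.ndarray
    eps_real_kk: np.ndarray


def kk_check(
    eps: DielectricSpectrum,
    eps_inf: float,
    n_eval: int = 201,
    interior: float = 0.1,
    tail_fraction: float = 1e-3,
) -> KKReport:
    """Validate eps' against the principal-value transform of eps''.

    Evaluates eps'_KK(nu) = eps_inf + (2/pi) PV int_0^inf W eps''(W)/(W^2 - nu^2) dW
    by Maclaurin's alternating-point rule on the (uniform) grid of ``eps``
    and reports the maximum of |eps'_KK - eps'| / max|eps' - eps_inf| over
    an interior sub-grid of at most ``n_eval`` points.

    The grid should extend well beyond the absorption bands; if eps'' at
    either end exceeds ``tail_fraction`` of its maximum, the report's
    ``grid_too_narrow`` flag is set.
    """
    h = eps.grid.spacing  # raises if non-uniform
    wn = eps.grid.wavenumbers
    im = eps.eps_imag
    L = wn.size

    peak = float(np.max(np.abs(im))) if np.any(im != 0) else 0.0
    too_narrow = bool(
        peak > 0
        and (abs(im[0]) > tail_fraction * peak or abs(im[-1]) > tail_fraction * peak)
    )

    lo = int(np.floor(interior * L))
    hi = int(np.ceil((1.0 - interior) * L))
    candidates = np.arange(max(lo, 1), max(hi, lo + 2))
    if candidates.size > n_eval:
        candidates = candidates[
            np.linspace(0, candidates.size - 1, n_eval).astype(int)
        ]

    parity = np.arange(L) % 2
    eps_kk = np.empty(candidates.size)
    for k, i in enumerate(candidates):
        sel = parity != (i % 2)  # opposite-parity quadrature points
        W = wn[sel]
        f = W * im[sel] / (W**2 - wn[i] ** 2)
        eps_kk[k] = eps_inf + (2.0 / np.pi) * 2.0 * h * np.sum(f)

    ref = float(np.max(np.abs(eps.eps_real - eps_inf)))
    if ref == 0.0:
        disc = float(np.max(np.abs(eps_kk - eps.eps_real[candidates])))
    else:
        disc = float(np.max(np.abs(eps_kk - eps.eps_real[candidates])) / ref)

    return KKReport(
        max_rel_discrepancy=disc,
        grid_too_narrow=too_narrow,
        eval_wavenumbers=wn[candidates],
        eps_real_kk=eps_kk,
    )
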