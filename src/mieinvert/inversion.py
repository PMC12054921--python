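"""Reconstruction engine: oscillator parameters from extinction spectra.

Fits a Kramers-Kronig-consistent superposition of Lorentz dielectric
functions to either

* a given extinction-efficiency spectrum of a homogeneous sphere, through
  the Mie forward model (``reconstruct_from_qext``), or
* a complex permittivity spectrum directly (``fit_permittivity_direct``),
  optionally with the anti-symmetrized-Lorentzian comparison basis.

Optimization is bounded trust-region nonlinear least squares on the
residual vector (scipy ``least_squares``, TRF, forward-difference
Jacobian).  The bound ``nup >= 0`` implements the physical non-negativity
of the dielectric basis; the comparison basis runs with unbounded
amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares, linear_sum_assignment

from .dispersion import (
    AntisymLorentzBand,
    AntisymLorentzSet,
    DielectricSpectrum,
    OscillatorBand,
    OscillatorSet,
    SpectralGrid,
    eps_to_n,
    eval_antisym_lorentzian,
    eval_permittivity,
)
from .mie import ExtinctionSpectrum, SphereModel, forward_qext

__all__ = [
    "FitConfig",
    "FitResult",
    "ResidualErrors",
    "BandMatch",
    "DEFAULT_INTERVALS",
    "residuals_qext",
    "objective_S",
    "init_case1",
    "init_case2",
    "reconstruct_from_qext",
    "fit_permittivity_direct",
    "match_bands",
    "reconstruction_error_metrics",
]

#: Case-II interval allocation: (low, high, band count); the two silent
#: windows 2200-2800 and 3500-4000 cm^-1 receive no bands.
DEFAULT_INTERVALS: Tuple[Tuple[float, float, int], ...] = (
    (500.0, 2200.0, 20),
    (2800.0, 3500.0, 5),
)

_INIT_NUP = 20.0    # cm^-1, initial strength for both init schemes
_INIT_GAMMA = 20.0  # cm^-1, initial width for both init schemes


@dataclass
class FitConfig:
    """Configuration of one reconstruction run."""

    n_bands: int = 25
    nu_range: Tuple[float, float] = (500.0, 4000.0)
    init_scheme: str = "case1"  # case1 | case2 | explicit
    intervals: Tuple[Tuple[float, float, int], ...] = DEFAULT_INTERVALS
    explicit_init: Optional[OscillatorSet] = None
    eps_inf_init: float = 2.25
    # bounds
    nu0_margin: float = 100.0            # nu0 allowed this far outside nu_range
    nup_bounds: Tuple[float, float] = (0.0, 2000.0)
    gamma_bounds: Tuple[float, float] = (1.0, 400.0)
    eps_inf_bounds: Tuple[float, float] = (1.0, 6.0)
    # optimizer tolerances / budget
    ftol: float = 1e-10
    xtol: float = 1e-8
    gtol: float = 1e-10
    max_nfev: int = 40000
    # optional seeded multi-start: start 1 is the configured initializer,
    # further starts jitter the band centers uniformly by +- jitter_nu0
    n_starts: int = 1
    jitter_nu0: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        lo, hi = self.nu_range
        if not lo < hi:
            raise ValueError("nu_range must be ordered (low < high)")
        if self.init_scheme not in ("case1", "case2", "explicit"):
            raise ValueError(f"unknown init scheme: {self.init_scheme!r}")
        for name, (blo, bhi) in (
            ("nup", self.nup_bounds),
            ("gamma", self.gamma_bounds),
            ("eps_inf", self.eps_inf_bounds),
        ):
            if blo > bhi:
                raise ValueError(f"{name} bounds are inverted")
            if blo < 0:
                raise ValueError(f"{name} lower bound must be >= 0")

    def to_dict(self) -> dict:
        return {
            "n_bands": self.n_bands,
            "nu_range": list(self.nu_range),
            "init_scheme": self.init_scheme,
            "intervals": [list(iv) for iv in self.intervals],
            "explicit_init": (
                self.explicit_init.to_dict() if self.explicit_init else None
            ),
            "eps_inf_init": self.eps_inf_init,
            "nu0_margin": self.nu0_margin,
            "nup_bounds": list(self.nup_bounds),
            "gamma_bounds": list(self.gamma_bounds),
            "eps_inf_bounds": list(self.eps_inf_bounds),
            "ftol": self.ftol,
            "xtol": self.xtol,
            "gtol": self.gtol,
            "max_nfev": self.max_nfev,
            "n_starts": self.n_starts,
            "jitter_nu0": self.jitter_nu0,
            "seed": self.seed,
        }


@dataclass
class FitResult:
    """Outcome of a reconstruction: optimized parameters and diagnostics."""

    params: OscillatorSet
    objective_S: float
    residuals: np.ndarray
    model_spectrum: object  # ExtinctionSpectrum or DielectricSpectrum
    converged: bool
    n_evals: int
    initial_S: float
    config: Optional[FitConfig] = None
    antisym_params: Optional[AntisymLorentzSet] = None


@dataclass
class ResidualErrors:
    """Pointwise permittivity fit errors e' = eps'_exp - eps'_fit etc."""

    grid: SpectralGrid
    e_real: np.ndarray
    e_imag: np.ndarray

    def __post_init__(self):
        self.e_real = np.asarray(self.e_real, dtype=float)
        self.e_imag = np.asarray(self.e_imag, dtype=float)
        if (
            self.e_real.shape != self.grid.wavenumbers.shape
            or self.e_imag.shape != self.grid.wavenumbers.shape
        ):
            raise ValueError("error array length does not match grid")


@dataclass
class BandMatch:
    """One-to-one pairing between fitted and truth bands."""

    pairs: list                 # (fitted OscillatorBand, truth OscillatorBand)
    delta_nu0: np.ndarray
    delta_nup: np.ndarray
    delta_gamma: np.ndarray
    n_unmatched_fitted: int
    n_unmatched_truth: int
    discarded_fitted: list      # below-floor ("dead") fitted bands


# ---------------------------------------------------------------------------
# residuals and objective

def _model_qext(params: OscillatorSet, grid: SpectralGrid, sphere: SphereModel) -> np.ndarray:
    eps = eval_permittivity(params, grid)
    return forward_qext(eps_to_n(eps), sphere).qext


def residuals_qext(
    params: OscillatorSet, given: ExtinctionSpectrum, sphere: SphereModel
) -> np.ndarray:
    """R(nu_l) = Qext_model(params; nu_l) - Qext_given(nu_l)."""
    return _model_qext(params, given.grid, sphere) - given.qext


def objective_S(
    params: OscillatorSet, given: ExtinctionSpectrum, sphere: SphereModel
) -> float:
    """Residual sum of squares S = sum_l R^2(nu_l)."""
    r = residuals_qext(params, given, sphere)
    return float(np.dot(r, r))


# ---------------------------------------------------------------------------
# initialization schemes

def init_case1(config: FitConfig) -> OscillatorSet:
    """Uninformed initializer: band centers equi-spaced over nu_range
    (both endpoints included), nup = gamma = 20 cm^-1."""
    if config.n_bands < 2:
        raise ValueError("case1 needs at least 2 bands")
    lo, hi = config.nu_range
    centers = np.linspace(lo, hi, config.n_bands)
    bands = [OscillatorBand(c, _INIT_NUP, _INIT_GAMMA) for c in centers]
    return OscillatorSet(bands=bands, eps_inf=config.eps_inf_init)


def init_case2(config: FitConfig) -> OscillatorSet:
    """Informed initializer: bands allocated per interval (endpoint
    inclusive within each), silent windows left empty."""
    total = sum(int(c) for _, _, c in config.intervals)
    if total != config.n_bands:
        raise ValueError(
            f"interval band counts sum to {total}, expected {config.n_bands}"
        )
    bands = []
    for lo, hi, count in config.intervals:
        count = int(count)
        if count == 0:
            continue
        if count == 1:
            centers = [0.5 * (lo + hi)]
        else:
            centers = np.linspace(lo, hi, count)
        bands.extend(OscillatorBand(c, _INIT_NUP, _INIT_GAMMA) for c in centers)
    return OscillatorSet(bands=bands, eps_inf=config.eps_inf_init)


def _initial_set(config: FitConfig) -> OscillatorSet:
    if config.init_scheme == "case1":
        return init_case1(config)
    if config.init_scheme == "case2":
        return init_case2(config)
    if config.explicit_init is None:
        raise ValueError("explicit init scheme requires explicit_init")
    return config.explicit_init


# ---------------------------------------------------------------------------
# parameter vector packing: theta = [eps_inf, nu0_1..M, nup_1..M, gamma_1..M]

def _pack(oset: OscillatorSet) -> np.ndarray:
    nu0, nup, gamma = oset.band_arrays()
    return np.concatenate([[oset.eps_inf], nu0, nup, gamma])


def _unpack(theta: np.ndarray, m: int) -> OscillatorSet:
    eps_inf = theta[0]
    nu0 = theta[1 : 1 + m]
    nup = theta[1 + m : 1 + 2 * m]
    gamma = theta[1 + 2 * m :]
    bands = [OscillatorBand(a, max(b, 0.0), c) for a, b, c in zip(nu0, nup, gamma)]
    return OscillatorSet(bands=bands, eps_inf=eps_inf)


def _bounds(config: FitConfig, m: int):
    lo, hi = config.nu_range
    lower = np.concatenate(
        [
            [config.eps_inf_bounds[0]],
            np.full(m, lo - config.nu0_margin),
            np.full(m, config.nup_bounds[0]),
            np.full(m, config.gamma_bounds[0]),
        ]
    )
    upper = np.concatenate(
        [
            [config.eps_inf_bounds[1]],
            np.full(m, hi + config.nu0_margin),
            np.full(m, config.nup_bounds[1]),
            np.full(m, config.gamma_bounds[1]),
        ]
    )
    return lower, upper


def _run_least_squares(fun, theta0, lower, upper, config: FitConfig, n_bands: int):
    """Single or seeded multi-start bounded least squares; returns best."""
    rng = np.random.default_rng(config.seed)
    best = None
    for k in range(max(config.n_starts, 1)):
        t0 = theta0.copy()
        if k > 0:
            t0[1 : 1 + n_bands] += rng.uniform(
                -config.jitter_nu0, config.jitter_nu0, n_bands
            )
        sol = least_squares(
            fun,
            np.clip(t0, lower, upper),
            bounds=(lower, upper),
            method="trf",
            jac="2-point",
            x_scale="jac",
            ftol=config.ftol,
            xtol=config.xtol,
            gtol=config.gtol,
            max_nfev=config.max_nfev,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    return best


# ---------------------------------------------------------------------------
# fits

def reconstruct_from_qext(
    given: ExtinctionSpectrum, sphere: SphereModel, config: FitConfig
) -> FitResult:
    """Recover oscillator parameters from an extinction-efficiency spectrum.

    Minimizes the residual sum of squares between ``given`` and the Mie
    forward model of the Lorentz-basis permittivity, under physical bounds
    (nup >= 0, gamma > 0).  Deterministic for fixed inputs.
    """
    if not np.all(np.isfinite(given.qext)):
        raise ValueError("given spectrum contains non-finite values")
    init = _initial_set(config)
    m = init.n_bands
    grid = given.grid

    def fun(theta):
        return _model_qext(_unpack(theta, m), grid, sphere) - given.qext

    theta0 = _pack(init)
    lower, upper = _bounds(config, m)
    r0 = fun(np.clip(theta0, lower, upper))
    initial_S = float(np.dot(r0, r0))

    sol = _run_least_squares(fun, theta0, lower, upper, config, m)

    params = _unpack(sol.x, m)
    model = ExtinctionSpectrum(grid=grid, qext=np.maximum(sol.fun + given.qext, 0.0))
    return FitResult(
        params=params,
        objective_S=float(2.0 * sol.cost),
        residuals=sol.fun,
        model_spectrum=model,
        converged=bool(sol.status > 0),
        n_evals=int(sol.nfev),
        initial_S=initial_S,
        config=config,
    )


def fit_permittivity_direct(
    exp_eps: DielectricSpectrum,
    config: FitConfig,
    basis: str = "dielectric",
) -> Tuple[FitResult, ResidualErrors]:
    """Fit a permittivity spectrum directly (no Mie model in the loop).

    Minimizes sum_l [e'(nu_l)^2 + e''(nu_l)^2] with e = exp - fit.  With
    ``basis="dielectric"`` the Lorentz basis is used under non-negativity
    bounds; with ``basis="antisym"`` the anti-symmetrized-Lorentzian
    comparison basis is used with sign-free amplitudes.
    """
    if basis not in ("dielectric", "antisym"):
        raise ValueError(f"unknown basis: {basis!r}")
    grid = exp_eps.grid
    target = np.concatenate([exp_eps.eps_real, exp_eps.eps_imag])
    init = _initial_set(config)
    m = init.n_bands

    if basis == "dielectric":
        def fun(theta):
            eps = eval_permittivity(_unpack(theta, m), grid)
            return np.concatenate([eps.eps_real, eps.eps_imag]) - target

        theta0 = _pack(init)
        lower, upper = _bounds(config, m)
    else:
        # amplitude scale chosen so the initial eps'' peak height matches
        # the Lorentz-basis initializer's
        nu0_init, nup_init, gamma_init = init.band_arrays()
        amp0 = nup_init**2 / (2.0 * nu0_init)

        def fun(theta):
            aset = _unpack_antisym(theta, m)
            eps = eval_antisym_lorentzian(aset, grid)
            return np.concatenate([eps.eps_real, eps.eps_imag]) - target

        theta0 = np.concatenate([[config.eps_inf_init], nu0_init, amp0, gamma_init])
        lower, upper = _bounds(config, m)
        lower[1 + m : 1 + 2 * m] = -np.inf  # sign-free amplitudes
        upper[1 + m : 1 + 2 * m] = np.inf

    r0 = fun(np.clip(theta0, lower, upper))
    initial_S = float(np.dot(r0, r0))
    sol = _run_least_squares(fun, theta0, lower, upper, config, m)

    L = len(grid)
    fit_real = sol.fun[:L] + target[:L]
    fit_imag = sol.fun[L:] + target[L:]
    model = DielectricSpectrum(grid=grid, eps_real=fit_real, eps_imag=fit_imag)
    errors = ResidualErrors(
        grid=grid,
        e_real=target[:L] - fit_real,
        e_imag=target[L:] - fit_imag,
    )

    antisym_params = None
    if basis == "antisym":
        antisym_params = _unpack_antisym(sol.x, m)
        # surrogate OscillatorSet for reporting: |amplitude| mapped back
        params = OscillatorSet(
            bands=[
                OscillatorBand(
                    b.nu0,
                    float(np.sqrt(2.0 * abs(b.amplitude) * b.nu0)),
                    b.gamma,
                )
                for b in antisym_params.bands
            ],
            eps_inf=max(antisym_params.offset, 1.0),
        )
    else:
        params = _unpack(sol.x, m)

    result = FitResult(
        params=params,
        objective_S=float(2.0 * sol.cost),
        residuals=sol.fun,
        model_spectrum=model,
        converged=bool(sol.status > 0),
        n_evals=int(sol.nfev),
        initial_S=initial_S,
        config=config,
        antisym_params=antisym_params,
    )
    return result, errors


def _unpack_antisym(theta: np.ndarray, m: int) -> AntisymLorentzSet:
    offset = theta[0]
    nu0 = theta[1 : 1 + m]
    amp = theta[1 + m : 1 + 2 * m]
    gamma = theta[1 + 2 * m :]
    bands = [AntisymLorentzBand(a, c, g) for a, c, g in zip(amp, nu0, gamma)]
    return AntisymLorentzSet(bands=bands, offset=offset)


# ---------------------------------------------------------------------------
# scoring helpers

def match_bands(
    fitted: OscillatorSet,
    truth: OscillatorSet,
    strength_floor: float = 1e-6,
) -> BandMatch:
    """Pair fitted bands with truth bands for parameter-recovery scoring.

    Fitted bands whose integrated strength nup^2 falls below
    ``strength_floor`` times the strongest fitted band's are discarded as
    dead oscillators; the remainder are assigned one-to-one to truth bands
    minimizing the total |delta nu0| (Hungarian assignment).
    """
    strengths = np.array([b.nup**2 for b in fitted.bands])
    floor = strength_floor * strengths.max() if strengths.size else 0.0
    alive = [b for b, s in zip(fitted.bands, strengths) if s > floor]
    dead = [b for b, s in zip(fitted.bands, strengths) if s <= floor]

    if not alive or not truth.bands:
        return BandMatch(
            pairs=[],
            delta_nu0=np.array([]),
            delta_nup=np.array([]),
            delta_gamma=np.array([]),
            n_unmatched_fitted=len(alive),
            n_unmatched_truth=len(truth.bands),
            discarded_fitted=dead,
        )

    cost = np.abs(
        np.subtract.outer(
            [b.nu0 for b in alive], [b.nu0 for b in truth.bands]
        )
    )
    rows, cols = linear_sum_assignment(cost)
    pairs = [(alive[i], truth.bands[j]) for i, j in zip(rows, cols)]
    d0 = np.array([f.nu0 - t.nu0 for f, t in pairs])
    dp = np.array([f.nup - t.nup for f, t in pairs])
    dg = np.array([f.gamma - t.gamma for f, t in pairs])
    return BandMatch(
        pairs=pairs,
        delta_nu0=d0,
        delta_nup=dp,
        delta_gamma=dg,
        n_unmatched_fitted=len(alive) - len(pairs),
        n_unmatched_truth=len(truth.bands) - len(pairs),
        discarded_fitted=dead,
    )


def reconstruction_error_metrics(
    fit: FitResult, truth: DielectricSpectrum
) -> Tuple[float, float]:
    """Relative L2 errors (real, imaginary) of the fitted permittivity
    against a known truth, evaluated on the truth's grid."""
    fitted = eval_permittivity(fit.params, truth.grid)
    num_r = np.linalg.norm(fitted.eps_real - truth.eps_real)
    num_i = np.linalg.norm(fitted.eps_imag - truth.eps_imag)
    den_r = np.linalg.norm(truth.eps_real)
    den_i = np.linalg.norm(truth.eps_imag)
    return (
        float(num_r / den_r) if den_r > 0 else float(num_r),
        float(num_i / den_i) if den_i > 0 else float(num_i),
    )
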