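"""Synthetic ground-truth materials and simulated extinction spectra.

Organic polymers show dense mid-IR absorption in 500-2200 cm^-1 and
2800-3500 cm^-1 and are nearly transparent in the silent windows
2200-2800 and 3500-4000 cm^-1.  ``generate_material`` draws random
oscillator sets with that structure; ``polymer_fixture`` provides
deterministic stand-ins whose band centers follow published infrared
assignments of six common polymers (strengths and widths are plausible
defaults, not measured values); ``simulate_given_qext`` closes the loop to
an observed extinction spectrum via the Mie forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .dispersion import (
    DielectricSpectrum,
    OscillatorBand,
    OscillatorSet,
    SpectralGrid,
    eps_to_n,
    eval_permittivity,
)
from .mie import ExtinctionSpectrum, SphereModel, forward_qext

__all__ = [
    "MaterialRecipe",
    "NoiseModel",
    "ABSORBING_INTERVALS",
    "SILENT_INTERVALS",
    "POLYMER_BAND_CENTERS",
    "generate_material",
    "polymer_fixture",
    "simulate_given_qext",
]

#: mid-IR intervals where organic absorption concentrates / is absent
ABSORBING_INTERVALS: Tuple[Tuple[float, float], ...] = ((500.0, 2200.0), (2800.0, 3500.0))
SILENT_INTERVALS: Tuple[Tuple[float, float], ...] = ((2200.0, 2800.0), (3500.0, 4000.0))


@dataclass(frozen=True)
class MaterialRecipe:
    """Random-material recipe: band counts per interval and parameter ranges."""

    intervals: Tuple[Tuple[float, float, int], ...] = (
        (550.0, 2150.0, 12),
        (2850.0, 3450.0, 4),
    )
    nup_range: Tuple[float, float] = (50.0, 250.0)
    gamma_range: Tuple[float, float] = (10.0, 40.0)
    eps_inf_range: Tuple[float, float] = (2.0, 2.6)
    min_separation: float = 40.0
    seed: int = 0

    def __post_init__(self):
        for lo, hi, count in self.intervals:
            if not (0 < lo < hi) or count < 0:
                raise ValueError("intervals must be positive, ordered, count >= 0")
        for name, (lo, hi) in (
            ("nup_range", self.nup_range),
            ("gamma_range", self.gamma_range),
            ("eps_inf_range", self.eps_inf_range),
        ):
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian noise on Qext: observed = truth * (1 + eta)."""

    relative_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.relative_sigma < 0:
            raise ValueError("relative_sigma must be >= 0")


def _sample_centers(rng, lo, hi, count, min_sep, max_tries=2000):
    centers: list = []
    tries = 0
    while len(centers) < count:
        c = rng.uniform(lo, hi)
        if all(abs(c - o) >= min_sep for o in centers):
            centers.append(c)
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"cannot place {count} bands with separation {min_sep} in [{lo}, {hi}]"
            )
    return centers


def generate_material(recipe: MaterialRecipe) -> OscillatorSet:
    """Draw a random polymer-like oscillator set; deterministic per seed."""
    rng = np.random.default_rng(recipe.seed)
    bands = []
    for lo, hi, count in recipe.intervals:
        centers = _sample_centers(rng, lo, hi, int(count), recipe.min_separation)
        for c in centers:
            nup = rng.uniform(*recipe.nup_range)
            gamma = rng.uniform(*recipe.gamma_range)
            bands.append(OscillatorBand(c, nup, gamma))
    eps_inf = rng.uniform(*recipe.eps_inf_range)
    return OscillatorSet(bands=bands, eps_inf=eps_inf)


# Band-center catalogs (cm^-1) following published IR assignments of the six
# polymers; printed ranges are collapsed to their midpoints by default.
POLYMER_BAND_CENTERS = {
    "PMMA": [(2800.0, 3000.0), 1730.0, (1000.0, 1300.0)],
    "PC": [2970.0, 1772.0, 1500.0, 1080.0, 1015.0, 830.0],
    "PDMS": [(789.0, 800.0), (1020.0, 1094.0), (1259.0, 1260.0), (2850.0, 2960.0)],
    "PEI": [1720.0, 1780.0, 1355.0, 743.0, 1234.0],
    "PET": [(2800.0, 3100.0), 1720.0, 1300.0, 1100.0],
    "PS": [(3025.0, 3081.0), (2850.0, 2923.0), (1452.0, 1600.0), (698.0, 756.0)],
}

_FIXTURE_SEED = 20250506  # fixes default strengths/widths per fixture version
_FIXTURE_EPS_INF = 2.25


def polymer_fixture(name: str, split_ranges: bool = False) -> OscillatorSet:
    """Deterministic polymer stand-in oscillator set.

    Band centers follow the catalog in ``POLYMER_BAND_CENTERS``; a printed
    range becomes one band at the midpoint (or one at each endpoint when
    ``split_ranges``).  Strengths are drawn once per fixture from
    [50, 250] cm^-1 and widths from [10, 40] cm^-1 with a fixed seed —
    plausible defaults, not literature values.
    """
    key = name.upper()
    if key not in POLYMER_BAND_CENTERS:
        raise KeyError(
            f"unknown polymer {name!r}; choose from {sorted(POLYMER_BAND_CENTERS)}"
        )
    centers = []
    for entry in POLYMER_BAND_CENTERS[key]:
        if isinstance(entry, tuple):
            if split_ranges:
                centers.extend(entry)
            else:
                centers.append(0.5 * (entry[0] + entry[1]))
        else:
            centers.append(entry)

    rng = np.random.default_rng(
        _FIXTURE_SEED + sorted(POLYMER_BAND_CENTERS).index(key)
    )
    bands = [
        OscillatorBand(c, rng.uniform(50.0, 250.0), rng.uniform(10.0, 40.0))
        for c in centers
    ]
    return OscillatorSet(bands=bands, eps_inf=_FIXTURE_EPS_INF)


def simulate_given_qext(
    material: OscillatorSet,
    sphere: SphereModel,
    grid: SpectralGrid,
    noise: Optional[NoiseModel] = None,
) -> Tuple[ExtinctionSpectrum, ExtinctionSpectrum]:
    """Simulate an observed extinction spectrum for ``material``.

    Returns ``(observed, truth)``; with zero noise the two are identical
    (the noiseless forward protocol).
    """
    eps = eval_permittivity(material, grid)
    truth = forward_qext(eps_to_n(eps), sphere)
    if noise is None or noise.relative_sigma == 0.0:
        observed = ExtinctionSpectrum(grid=grid, qext=truth.qext.copy())
    else:
        rng = np.random.default_rng(noise.seed)
        eta = rng.normal(0.0, noise.relative_sigma, size=truth.qext.shape)
        observed = ExtinctionSpectrum(
            grid=grid, qext=np.maximum(truth.qext * (1.0 + eta), 0.0)
        )
    return observed, truth
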