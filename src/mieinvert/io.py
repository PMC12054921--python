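"""Delimited-text readers/writers for the project's spectrum and parameter
formats, plus the run manifest.

Dialect: comma-separated, '.' decimal, '#' comment lines, UTF-8, one header
line naming the columns.  Readers validate physical invariants (passivity,
monotone positive grids) and reject malformed rows with the line number;
writers emit unit-bearing headers so every file round-trips.
"""

from __future__ import annotations

import json
import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .dispersion import (
    DielectricSpectrum,
    OscillatorSet,
    RefractiveIndexSpectrum,
    SpectralGrid,
)
from .mie import AbsorbanceSpectrum, ExtinctionSpectrum

__all__ = [
    "read_dispersion_table",
    "write_dispersion_table",
    "read_extinction_table",
    "write_extinction_table",
    "read_absorbance_table",
    "write_absorbance_table",
    "read_permittivity_table",
    "write_permittivity_table",
    "read_oscillator_set",
    "write_oscillator_set",
    "write_fit_bundle",
    "read_fit_bundle_params",
    "RunManifest",
]

_FLOAT_FMT = "%.10g"


class TableFormatError(ValueError):
    """Malformed delimited-text input."""


def _parse_table(path, n_cols: int, header_cols):
    """Parse a comma-delimited table; returns (rows array, comment lines)."""
    path = Path(path)
    rows = []
    comments = []
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                comments.append(line)
                continue
            parts = [p.strip() for p in line.split(",")]
            if not header_seen:
                if parts[: len(header_cols)] != list(header_cols):
                    raise TableFormatError(
                        f"{path}:{lineno}: expected header {','.join(header_cols)}"
                    )
                header_seen = True
                continue
            if len(parts) != n_cols:
                raise TableFormatError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise TableFormatError(f"{path}:{lineno}: {exc}") from None
    if not header_seen:
        raise TableFormatError(f"{path}: missing header line")
    if len(rows) < 2:
        raise TableFormatError(f"{path}: need at least two data rows")
    return np.array(rows), comments


def _sorted_unique_grid(path, data):
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    if np.any(np.diff(data[:, 0]) == 0):
        dup = data[np.where(np.diff(data[:, 0]) == 0)[0][0], 0]
        raise TableFormatError(f"{path}: duplicate wavenumber {dup}")
    return data


def _write_table(path, header_comment_lines, columns, arrays):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for line in header_comment_lines:
            fh.write(f"# {line}\n")
        fh.write(",".join(columns) + "\n")
        for row in zip(*arrays):
            fh.write(",".join(_FLOAT_FMT % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# dispersion tables (wavenumber, n', n'')

def read_dispersion_table(path) -> RefractiveIndexSpectrum:
    data, _ = _parse_table(path, 3, ("wavenumber_cm-1", "n_real", "n_imag"))
    data = _sorted_unique_grid(path, data)
    if np.any(data[:, 2] < 0):
        raise TableFormatError(f"{path}: negative n_imag violates passivity")
    if np.any(data[:, 1] <= 0):
        raise TableFormatError(f"{path}: n_real must be positive")
    return RefractiveIndexSpectrum(
        grid=SpectralGrid(data[:, 0]), n_real=data[:, 1], n_imag=data[:, 2]
    )


def write_dispersion_table(path, spectrum: RefractiveIndexSpectrum, comments=()):
    _write_table(
        path,
        ["complex refractive index table; units: cm^-1, dimensionless", *comments],
        ("wavenumber_cm-1", "n_real", "n_imag"),
        (spectrum.grid.wavenumbers, spectrum.n_real, spectrum.n_imag),
    )


# ---------------------------------------------------------------------------
# extinction tables (wavenumber, qext)

def read_extinction_table(path) -> ExtinctionSpectrum:
    data, _ = _parse_table(path, 2, ("wavenumber_cm-1", "qext"))
    data = _sorted_unique_grid(path, data)
    if np.any(data[:, 1] < 0):
        raise TableFormatError(f"{path}: negative qext violates passivity")
    return ExtinctionSpectrum(grid=SpectralGrid(data[:, 0]), qext=data[:, 1])


def write_extinction_table(path, spectrum: ExtinctionSpectrum, comments=()):
    _write_table(
        path,
        ["extinction efficiency table; units: cm^-1, dimensionless", *comments],
        ("wavenumber_cm-1", "qext"),
        (spectrum.grid.wavenumbers, spectrum.qext),
    )


# ---------------------------------------------------------------------------
# absorbance tables (wavenumber, absorbance) with G/g in a header comment

def read_absorbance_table(path):
    """Returns (AbsorbanceSpectrum, G_over_g or None)."""
    data, comments = _parse_table(path, 2, ("wavenumber_cm-1", "absorbance"))
    data = _sorted_unique_grid(path, data)
    ratio = None
    for c in comments:
        body = c.lstrip("#").strip()
        if body.startswith("G_over_g"):
            ratio = float(body.split("=", 1)[1])
    return (
        AbsorbanceSpectrum(grid=SpectralGrid(data[:, 0]), absorbance=data[:, 1]),
        ratio,
    )


def write_absorbance_table(path, spectrum: AbsorbanceSpectrum, g_over_g: float, comments=()):
    _write_table(
        path,
        [
            "apparent absorbance table; units: cm^-1, dimensionless (decadic)",
            f"G_over_g = {_FLOAT_FMT % g_over_g}",
            *comments,
        ],
        ("wavenumber_cm-1", "absorbance"),
        (spectrum.grid.wavenumbers, spectrum.absorbance),
    )


# ---------------------------------------------------------------------------
# permittivity tables (wavenumber, eps', eps'')

def read_permittivity_table(path) -> DielectricSpectrum:
    data, _ = _parse_table(path, 3, ("wavenumber_cm-1", "eps_real", "eps_imag"))
    data = _sorted_unique_grid(path, data)
    if np.any(data[:, 2] < 0):
        raise TableFormatError(f"{path}: negative eps_imag violates passivity")
    return DielectricSpectrum(
        grid=SpectralGrid(data[:, 0]), eps_real=data[:, 1], eps_imag=data[:, 2]
    )


def write_permittivity_table(path, spectrum: DielectricSpectrum, comments=()):
    _write_table(
        path,
        ["complex permittivity table; units: cm^-1, dimensionless", *comments],
        ("wavenumber_cm-1", "eps_real", "eps_imag"),
        (spectrum.grid.wavenumbers, spectrum.eps_real, spectrum.eps_imag),
    )


# ---------------------------------------------------------------------------
# oscillator sets (JSON)

def read_oscillator_set(path) -> OscillatorSet:
    with Path(path).open("r", encoding="utf-8") as fh:
        return OscillatorSet.from_dict(json.load(fh))


def write_oscillator_set(path, oset: OscillatorSet, metadata: Optional[dict] = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = oset.to_dict()
    d["units"] = "cm^-1"
    if metadata:
        d["metadata"] = metadata
    with path.open("w", encoding="utf-8") as fh:
        json.dump(d, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# fit bundles

def write_fit_bundle(directory, result, truth: Optional[OscillatorSet] = None):
    """Write a fit-result bundle: parameter table, model spectra, summary.

    Produces ``params.csv`` (m, nu0, nup, gamma), spectrum tables for the
    fitted model, and ``summary.json`` with the objective value, status,
    config echo and (when a truth is supplied) a band-matching report.
    """
    from .dispersion import eps_to_n, eval_permittivity
    from .inversion import match_bands

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    oset = result.params
    with (directory / "params.csv").open("w", encoding="utf-8") as fh:
        fh.write("# optimized oscillator parameters; units cm^-1\n")
        fh.write("m,nu0,nup,gamma\n")
        for i, b in enumerate(oset.bands, start=1):
            fh.write(
                f"{i},{_FLOAT_FMT % b.nu0},{_FLOAT_FMT % b.nup},{_FLOAT_FMT % b.gamma}\n"
            )

    grid = result.model_spectrum.grid
    eps = eval_permittivity(oset, grid)
    write_permittivity_table(directory / "permittivity_fit.csv", eps)
    write_dispersion_table(directory / "refractive_index_fit.csv", eps_to_n(eps))
    if isinstance(result.model_spectrum, ExtinctionSpectrum):
        write_extinction_table(directory / "qext_model.csv", result.model_spectrum)
    write_oscillator_set(directory / "oscillators.json", oset)

    summary = {
        "objective_S": result.objective_S,
        "initial_S": result.initial_S,
        "converged": result.converged,
        "n_evals": result.n_evals,
        "eps_inf": oset.eps_inf,
        "n_bands": oset.n_bands,
        "config": result.config.to_dict() if result.config else None,
    }
    if truth is not None:
        m = match_bands(oset, truth)
        summary["matching"] = {
            "delta_nu0": m.delta_nu0.tolist(),
            "delta_nup": m.delta_nup.tolist(),
            "delta_gamma": m.delta_gamma.tolist(),
            "n_unmatched_fitted": m.n_unmatched_fitted,
            "n_unmatched_truth": m.n_unmatched_truth,
            "n_discarded": len(m.discarded_fitted),
        }
    with (directory / "summary.json").open("w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1)
        fh.write("\n")
    return directory


def read_fit_bundle_params(directory) -> OscillatorSet:
    return read_oscillator_set(Path(directory) / "oscillators.json")


# ---------------------------------------------------------------------------
# run manifest

@dataclass
class RunManifest:
    """Reproducibility record written for every CLI run."""

    command: str
    config: dict
    inputs: dict
    outputs: dict
    seed: Optional[int] = None
    tool_version: str = ""
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w", encoding="utf-8") as fh:
            json.dump(
                {
                    "command": self.command,
                    "config": self.config,
                    "inputs": self.inputs,
                    "outputs": self.outputs,
                    "seed": self.seed,
                    "tool_version": self.tool_version,
                    "timestamp": self.timestamp,
                },
                fh,
                indent=1,
            )
            fh.write("\n")
        return path
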