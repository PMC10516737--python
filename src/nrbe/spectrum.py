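"""Fluence-spectrum-weighted neutron RBE.

Given a tabulated neutron fluence spectrum Phi(E) and an RBE-versus-energy
curve RBE_T(E), the beam-averaged RBE is

    RBE_T = integral Phi(E) RBE_T(E) dE / integral Phi(E) dE.

Both integrals are evaluated by the trapezoid rule on the union of the
spectrum and curve grids (robust on the non-uniform, log-spaced grids these
tables come on). The RBE curve is interpolated log-linearly in energy -
linear in (ln E, RBE) - since the curve varies over decades of energy.
Energies are eV throughout; readers convert MeV inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "NeutronSpectrum",
    "RBEEnergyCurve",
    "interpolate_rbe",
    "spectrum_weighted_rbe",
]


def _check_grid(energy: np.ndarray, what: str) -> None:
    if energy.ndim != 1 or len(energy) < 2:
        raise ValueError(f"{what} needs at least 2 grid points")
    if np.any(energy <= 0):
        raise ValueError(f"{what} energies must be positive")
    if np.any(np.diff(energy) <= 0):
        raise ValueError(f"{what} energy grid must be strictly increasing")


@dataclass(frozen=True)
class NeutronSpectrum:
    """Tabulated fluence density Phi(E) on a strictly increasing eV grid."""

    energy: np.ndarray
    fluence: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "energy", np.asarray(self.energy, dtype=float))
        object.__setattr__(self, "fluence", np.asarray(self.fluence, dtype=float))
        _check_grid(self.energy, "spectrum")
        if self.fluence.shape != self.energy.shape:
            raise ValueError("fluence and energy grids must match")
        if np.any(self.fluence < 0):
            raise ValueError("fluence density must be non-negative")
        if np.trapezoid(self.fluence, self.energy) <= 0:
            raise ValueError("zero total fluence")


@dataclass(frozen=True)
class RBEEnergyCurve:
    """Tabulated RBE_T(E) on a strictly increasing eV grid, values > 0."""

    energy: np.ndarray
    rbe: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "energy", np.asarray(self.energy, dtype=float))
        object.__setattr__(self, "rbe", np.asarray(self.rbe, dtype=float))
        _check_grid(self.energy, "RBE curve")
        if self.rbe.shape != self.energy.shape:
            raise ValueError("rbe and energy grids must match")
        if np.any(self.rbe <= 0):
            raise ValueError("RBE values must be positive")


def interpolate_rbe(curve: RBEEnergyCurve, energy) -> np.ndarray | float:
    """RBE_T at arbitrary energies by log-linear interpolation.

    Linear in (ln E, RBE); energies outside the tabulated range are
    clamped to the end values with a warning (extrapolating an empirical
    RBE-energy relation is not meaningful).
    """
    e = np.asarray(energy, dtype=float)
    if np.any(e <= 0):
        raise ValueError("energy must be positive")
    if np.any(e < curve.energy[0]) or np.any(e > curve.energy[-1]):
        warnings.warn(
            "energy outside tabulated RBE curve range; clamped to end values",
            stacklevel=2,
        )
    out = np.interp(np.log(e), np.log(curve.energy), curve.rbe)
    return float(out) if np.isscalar(energy) else out


def spectrum_weighted_rbe(spectrum: NeutronSpectrum, curve: RBEEnergyCurve) -> float:
    """Fluence-weighted average RBE of the beam.

    Trapezoidal integration of Phi(E)*RBE(E) and Phi(E) on the union of
    the spectrum grid and the curve nodes lying inside the spectrum
    support, so the integrand's kinks at curve nodes are respected.
    Scale-invariant in Phi; always lies between the min and max of the
    interpolated RBE over the support.
    """
    e_lo, e_hi = spectrum.energy[0], spectrum.energy[-1]
    inner = curve.energy[(curve.energy > e_lo) & (curve.energy < e_hi)]
    grid = np.union1d(spectrum.energy, inner)
    phi = np.interp(grid, spectrum.energy, spectrum.fluence)
    rbe = interpolate_rbe(curve, grid)
    denom = float(np.trapezoid(phi, grid))
    if denom <= 0:
        raise ValueError("zero total fluence over the spectrum support")
    return float(np.trapezoid(phi * rbe, grid)) / denom
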