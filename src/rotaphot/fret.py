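"""Spectral overlap integrals and Förster radii for donor/acceptor pairs.

The Förster radius R0 is the donor-acceptor separation at which resonance
energy transfer is 50% efficient.  In the wavelength formulation, with the
donor emission F_D area-normalized and the acceptor molar absorptivity
eps_A in M^-1 cm^-1 on a nanometer grid,

    J  = integral F_D(lam) eps_A(lam) lam^4 dlam / integral F_D(lam) dlam
         [M^-1 cm^-1 nm^4]
    R0 = 0.02108 * (kappa^2 * Phi_D * n^-4 * J)^(1/6)   [nm]

kappa^2 = 2/3 assumes isotropic orientational averaging; n is the solvent
refractive index (1.407 for THF, the default working solvent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Spectrum", "ForsterResult", "overlap_integral", "forster_radius", "fret_efficiency", "forster_analysis"]

#: prefactor of the wavelength-domain R0 formula, nm per (M^-1 cm^-1 nm^4)^(1/6)
R0_PREFACTOR_NM = 0.02108


@dataclass
class Spectrum:
    """Wavelength-resolved spectrum with a unit tag.

    ``kind`` is ``"emission"`` (arbitrary units, normalization cancels in J)
    or ``"absorptivity"`` (molar absorptivity, M^-1 cm^-1).
    """

    wavelengths: np.ndarray  # nm, strictly increasing
    values: np.ndarray
    kind: str = "emission"
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must be 1-D arrays of equal length")
        if self.wavelengths.size < 10:
            raise ValueError("need at least 10 spectral points")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("spectral values must be non-negative")
        if self.kind not in ("emission", "absorptivity"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")


@dataclass
class ForsterResult:
    """Overlap integral and Förster radius with the parameters that produced them."""

    J: float  # M^-1 cm^-1 nm^4
    R0: float  # nm
    kappa2: float
    refractive_index: float
    phi_donor: float


def overlap_integral(donor_emission: Spectrum, acceptor_absorptivity: Spectrum) -> float:
    """FRET overlap integral J in M^-1 cm^-1 nm^4.

    Both spectra are linearly interpolated onto the union of their grid
    points within the common support and integrated by the trapezoid rule.
    Disjoint supports return 0 with a warning; the donor spectrum is
    area-normalized internally, so its absolute scale is irrelevant.
    """
    if donor_emission.kind != "emission":
        raise ValueError("donor spectrum must be tagged kind='emission'")
    if acceptor_absorptivity.kind != "absorptivity":
        raise ValueError("acceptor spectrum must be tagged kind='absorptivity'")
    lo = max(donor_emission.wavelengths[0], acceptor_absorptivity.wavelengths[0])
    hi = min(donor_emission.wavelengths[-1], acceptor_absorptivity.wavelengths[-1])
    if hi <= lo:
        warnings.warn("donor and acceptor spectra have disjoint wavelength support; J = 0")
        return 0.0
    grid = np.union1d(donor_emission.wavelengths, acceptor_absorptivity.wavelengths)
    grid = grid[(grid >= lo) & (grid <= hi)]
    fd = np.interp(grid, donor_emission.wavelengths, donor_emission.values)
    ea = np.interp(grid, acceptor_absorptivity.wavelengths, acceptor_absorptivity.values)
    norm = np.trapezoid(fd, grid)
    if norm <= 0:
        warnings.warn("donor emission vanishes on the overlap region; J = 0")
        return 0.0
    return float(np.trapezoid(fd * ea * grid**4, grid) / norm)


def forster_radius(J: float, kappa2: float = 2.0 / 3.0, n_refractive: float = 1.407, phi_donor: float = 1.0) -> float:
    """Förster radius R0 in nm from J in M^-1 cm^-1 nm^4."""
    if J < 0:
        raise ValueError("overlap integral must be non-negative")
    if kappa2 <= 0 or n_refractive <= 0 or phi_donor <= 0:
        raise ValueError("kappa2, refractive index and donor quantum yield must be positive")
    return R0_PREFACTOR_NM * (kappa2 * phi_donor * n_refractive**-4 * J) ** (1.0 / 6.0)


def fret_efficiency(r: float, R0: float) -> float:
    """Transfer efficiency E = 1 / (1 + (r/R0)^6) at donor-acceptor distance r."""
    if r < 0 or R0 <= 0:
        raise ValueError("distances must be positive")
    return 1.0 / (1.0 + (r / R0) ** 6)


def forster_analysis(
    donor_emission: Spectrum,
    acceptor_absorptivity: Spectrum,
    kappa2: float = 2.0 / 3.0,
    n_refractive: float = 1.407,
    phi_donor: float = 1.0,
) -> ForsterResult:
    """Overlap integral and Förster radius in one call."""
    J = overlap_integral(donor_emission, acceptor_absorptivity)
    return ForsterResult(J, forster_radius(J, kappa2, n_refractive, phi_donor), kappa2, n_refractive, phi_donor)
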