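"""Conformer-ensemble analysis: SASA, Zn axial coordination, folding class,
and Boltzmann thermodynamics.

A conformer ensemble for a flexible Zn-porphyrin conjugate is summarized by
four quantities per conformer:

* Gibbs free energy G = E_gas + G_thermo + dG_solv, combining the electronic
  gas-phase energy, the thermal (rigid-rotor/harmonic-oscillator) correction
  and the implicit-solvation contribution, all supplied by upstream
  quantum-chemistry codes.  Only differences dG_i = G_i - min(G) matter.
* Boltzmann population w_i = exp(-dG_i/RT) / sum_j exp(-dG_j/RT).
* Solvent-accessible surface area (Shrake-Rupley), the folding proxy:
  compact (folded) conformers bury surface, extended ones expose it.
* Axial coordination of the Zn center: a donor atom (N/O/S) sitting above
  or below the porphyrin plane within bonding distance.

Folding categories follow the ensemble-normalized SASA fraction
f = (SASA_max - SASA) / (SASA_max - SASA_min): *closed* (f >= t_closed),
*open* (f <= t_open and no axial donor), *half-open* otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Conformer",
    "EnergyComponents",
    "CoordinationResult",
    "SASAResult",
    "EnsembleSummary",
    "BONDI_RADII",
    "HARTREE_TO_KCAL",
    "GAS_CONSTANT_KCAL",
    "sasa",
    "detect_axial_coordination",
    "classify",
    "gibbs_energy",
    "relative_energies",
    "boltzmann_weights",
    "ensemble_report",
]

#: CODATA conversion, kcal/mol per Hartree
HARTREE_TO_KCAL = 627.5094740631
#: gas constant in kcal mol^-1 K^-1
GAS_CONSTANT_KCAL = 0.0019872043

#: Bondi van der Waals radii in Angstrom
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "Zn": 1.39,
}

_KNOWN_ELEMENTS = set(BONDI_RADII)


@dataclass
class EnergyComponents:
    """Per-conformer energy terms with a shared unit tag ('kcal/mol' or 'hartree')."""

    e_gas: float
    g_thermo: float
    dg_solv: float
    unit: str = "kcal/mol"

    def __post_init__(self) -> None:
        if self.unit not in ("kcal/mol", "hartree"):
            raise ValueError(f"unknown energy unit {self.unit!r}")


@dataclass
class Conformer:
    """Element symbols plus Cartesian coordinates (Angstrom), optionally with energies."""

    elements: list
    coordinates: np.ndarray
    label: str = ""
    energy: EnergyComponents | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.elements = list(self.elements)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape != (len(self.elements), 3):
            raise ValueError("coordinates must be an N x 3 array matching the element list")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class SASAResult:
    total: float  # Angstrom^2
    per_atom: np.ndarray


@dataclass
class CoordinationResult:
    coordinated: bool
    ligand_atom_index: int | None
    zn_ligand_distance: float  # Angstrom; inf when no donor within range


@dataclass
class EnsembleSummary:
    """Per-conformer table plus summed Boltzmann weight per folding category.

    ``table`` columns: label, g_gibbs, delta_g, boltzmann_weight, sasa,
    folding_fraction, coordinated, category.
    """

    table: pd.DataFrame
    category_weights: dict
    thresholds: dict
    temperature: float


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points on a Fibonacci lattice."""
    i = np.arange(n)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _local_frame(xyz: np.ndarray, d2: np.ndarray, i: int, neigh: np.ndarray) -> np.ndarray:
    """Rotation matrix (rows = axes) tied to atom i's nearest neighbors.

    Anchoring the sphere-point lattice to the local geometry makes the
    Shrake-Rupley estimate exactly invariant under rigid motions of the
    molecule instead of merely approximately so.
    """
    if neigh.size == 0:
        return np.eye(3)
    order = neigh[np.argsort(d2[i, neigh])]
    z = xyz[order[0]] - xyz[i]
    z = z / np.linalg.norm(z)
    x = None
    for j in order[1:]:
        v = xyz[j] - xyz[i]
        v = v - np.dot(v, z) * z
        nv = np.linalg.norm(v)
        if nv > 1e-8:
            x = v / nv
            break
    if x is None:  # single neighbor or collinear: occlusion is axisymmetric
        v = np.eye(3)[np.argmin(np.abs(z))]
        v = v - np.dot(v, z) * z
        x = v / np.linalg.norm(v)
    return np.stack([x, np.cross(z, x), z])


def sasa(
    conformer: Conformer,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    radii: dict | None = None,
) -> SASAResult:
    """Shrake-Rupley solvent-accessible surface area.

    For each atom, test points on a Fibonacci lattice at radius
    r_vdw + probe; the accessible fraction (points outside every neighbor's
    expanded sphere) times 4 pi (r_vdw + probe)^2 is its contribution.

    Parameters use the conventional water probe (1.4 A) and Bondi radii by
    default; pass ``radii`` to override the radius set.
    """
    radii = BONDI_RADII if radii is None else radii
    try:
        r = np.array([radii[e] for e in conformer.elements]) + probe_radius
    except KeyError as exc:
        raise ValueError(f"no van der Waals radius for element {exc.args[0]!r}") from None
    xyz = conformer.coordinates
    n = conformer.n_atoms
    pts = _fibonacci_sphere(n_sphere_points)
    d2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=-1)
    per_atom = np.empty(n)
    for i in range(n):
        neigh = np.nonzero((d2[i] < (r[i] + r) ** 2) & (np.arange(n) != i))[0]
        # orient the lattice in a frame built from the nearest neighbors so
        # the quadrature is exactly invariant under rigid motions
        frame = _local_frame(xyz, d2, i, neigh)
        surface = xyz[i] + r[i] * (pts @ frame)
        if neigh.size:
            dist2 = np.sum((surface[:, None, :] - xyz[neigh][None, :, :]) ** 2, axis=-1)
            accessible = np.all(dist2 > r[neigh] ** 2, axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * r[i] ** 2
    return SASAResult(float(per_atom.sum()), per_atom)


def detect_axial_coordination(
    conformer: Conformer,
    distance_cutoff: float = 2.6,
    cone_half_angle: float = 40.0,
    donor_elements: frozenset = frozenset({"N", "O", "S"}),
) -> CoordinationResult:
    """Detect a donor atom at the axial coordination site of a Zn porphyrin.

    The porphyrin plane is the best-fit plane of the four N atoms nearest to
    Zn.  A non-porphyrin N/O/S atom coordinates when its distance to Zn is
    within ``distance_cutoff`` (Angstrom) and its direction from Zn lies
    within ``cone_half_angle`` degrees of the plane normal (either side).
    The nearest qualifying atom is reported.
    """
    elements = np.array(conformer.elements)
    zn_idx = np.nonzero(elements == "Zn")[0]
    if zn_idx.size != 1:
        raise ValueError(f"expected exactly one Zn atom, found {zn_idx.size}")
    zn = conformer.coordinates[zn_idx[0]]
    n_idx = np.nonzero(elements == "N")[0]
    if n_idx.size < 4:
        raise ValueError(f"need at least 4 N atoms for the porphyrin plane, found {n_idx.size}")
    dists = np.linalg.norm(conformer.coordinates[n_idx] - zn, axis=1)
    order = np.argsort(dists)
    porph_n = n_idx[order[:4]]
    if n_idx.size > 4 and dists[order[4]] < 2.3:
        warnings.warn("ambiguous pyrrole-N selection: a 5th N lies within 2.3 A of Zn")
    ring = conformer.coordinates[porph_n] - conformer.coordinates[porph_n].mean(axis=0)
    _, _, vh = np.linalg.svd(ring, full_matrices=False)
    normal = vh[2]

    cos_cone = np.cos(np.deg2rad(cone_half_angle))
    best = (np.inf, None)
    for i in range(conformer.n_atoms):
        if i == zn_idx[0] or i in porph_n or elements[i] not in donor_elements:
            continue
        v = conformer.coordinates[i] - zn
        d = np.linalg.norm(v)
        if d == 0 or d > distance_cutoff:
            continue
        if abs(np.dot(v / d, normal)) >= cos_cone and d < best[0]:
            best = (d, i)
    if best[1] is None:
        return CoordinationResult(False, None, float("inf"))
    return CoordinationResult(True, int(best[1]), float(best[0]))


def classify(
    folding_fraction: float | None,
    coordinated: bool,
    t_open: float = 0.3,
    t_closed: float = 0.7,
) -> str:
    """Assign a folding category from the normalized SASA fraction.

    ``folding_fraction`` is f = (SASA_max - SASA)/(SASA_max - SASA_min) over
    the ensemble (0 = most open, 1 = most folded).  Pass ``None`` for a
    degenerate single-conformer ensemble, which is classified by
    coordination alone.  Coordination alone never yields "open".
    """
    if not 0 <= t_open < t_closed <= 1:
        raise ValueError("need 0 <= t_open < t_closed <= 1")
    if folding_fraction is None:
        return "closed" if coordinated else "open"
    if not 0.0 <= folding_fraction <= 1.0 + 1e-12:
        raise ValueError("folding fraction must lie in [0, 1]")
    if folding_fraction >= t_closed:
        return "closed"
    if folding_fraction <= t_open and not coordinated:
        return "open"
    return "half-open"


def gibbs_energy(e: EnergyComponents) -> float:
    """Gibbs free energy G = E_gas + G_thermo + dG_solv in kcal/mol.

    Hartree inputs are converted with the CODATA factor 627.5094740631.
    """
    g = e.e_gas + e.g_thermo + e.dg_solv
    if e.unit == "hartree":
        g *= HARTREE_TO_KCAL
    return float(g)


def relative_energies(g_list) -> np.ndarray:
    """Energies relative to the ensemble minimum, dG_i = G_i - min(G)."""
    g = np.asarray(list(g_list), dtype=float)
    if g.size == 0:
        raise ValueError("empty energy list")
    return g - g.min()


def boltzmann_weights(delta_g, temperature: float = 298.15) -> np.ndarray:
    """Normalized Boltzmann populations from relative free energies (kcal/mol)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    dg = np.asarray(list(delta_g), dtype=float)
    if not np.all(np.isfinite(dg)):
        raise ValueError("relative energies must be finite")
    x = -dg / (GAS_CONSTANT_KCAL * temperature)
    x -= x.max()  # overflow-safe
    w = np.exp(x)
    return w / w.sum()


def ensemble_report(
    conformers,
    temperature: float = 298.15,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    t_open: float = 0.3,
    t_closed: float = 0.7,
    distance_cutoff: float = 2.6,
    cone_half_angle: float = 40.0,
) -> EnsembleSummary:
    """Joint thermodynamic and structural summary of a conformer ensemble.

    Requires every conformer to carry :class:`EnergyComponents` with a
    consistent unit.  Computes per-conformer Gibbs energies, relative
    energies, Boltzmann weights, SASA, axial coordination and folding
    category, then sums the Boltzmann weight per category.
    """
    conformers = list(conformers)
    if not conformers:
        raise ValueError("empty ensemble")
    units = {c.energy.unit for c in conformers if c.energy is not None}
    if any(c.energy is None for c in conformers):
        raise ValueError("every conformer must carry energy components")
    if len(units) > 1:
        raise ValueError(f"mixed energy units in ensemble: {sorted(units)}")

    g = np.array([gibbs_energy(c.energy) for c in conformers])
    dg = relative_energies(g)
    w = boltzmann_weights(dg, temperature)
    areas = np.array([sasa(c, probe_radius, n_sphere_points).total for c in conformers])
    coord = [detect_axial_coordination(c, distance_cutoff, cone_half_angle) for c in conformers]

    degenerate = len(conformers) == 1 or np.isclose(areas.max(), areas.min())
    if degenerate and len(conformers) > 1:
        warnings.warn("degenerate ensemble: SASA range is zero; classifying by coordination only")
    if degenerate:
        frac = np.full(len(conformers), np.nan)
        cats = [classify(None, cr.coordinated, t_open, t_closed) for cr in coord]
    else:
        frac = (areas.max() - areas) / (areas.max() - areas.min())
        cats = [classify(f, cr.coordinated, t_open, t_closed) for f, cr in zip(frac, coord)]

    table = pd.DataFrame(
        {
            "label": [c.label for c in conformers],
            "g_gibbs": g,
            "delta_g": dg,
            "boltzmann_weight": w,
            "sasa": areas,
            "folding_fraction": frac,
            "coordinated": [cr.coordinated for cr in coord],
            "category": cats,
        }
    )
    weights = {cat: float(table.loc[table.category == cat, "boltzmann_weight"].sum()) for cat in ("open", "half-open", "closed")}
    return EnsembleSummary(table, weights, {"t_open": t_open, "t_closed": t_closed}, temperature)
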