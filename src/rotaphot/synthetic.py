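"""Synthetic instrument and quantum-chemistry outputs with known ground truth.

Every downstream stage of the package is exercised against data from this
module: first-order DPBF photobleaching traces with a background channel,
IRF-convolved Poisson photon-count histograms, Gaussian-band spectra, and
toy Zn-porphyrin-like conformers in folded/half-open/extended states with
known coordination status and energy components.  All generators are
deterministic given a seed, and their noise-free modes match the closed-form
models they sample from.

The defaults mimic the working conditions of a DPBF actinometry / TCSPC
study of switchable porphyrin photosensitizers: traces sampled at 10-30 s
irradiation intervals with ~2% multiplicative intensity noise, decay
histograms with 10^4 peak counts on a ~13 ns window, and ensembles whose
"protonated-like" energy landscape makes folded (closed) conformers
dominant while the "deprotonated-like" landscape leaves the categories
energetically overlapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .conformers import Conformer, EnergyComponents
from .fret import Spectrum
from .singlet_oxygen import KineticTrace
from .tcspc import DecayHistogram, check_truncation

__all__ = [
    "GeneratorConfig",
    "LabelledConformer",
    "gen_dpbf_trace",
    "gen_tcspc",
    "gen_spectra",
    "gen_conformer_ensemble",
]

_CATEGORIES = ("open", "half-open", "closed")


@dataclass
class GeneratorConfig:
    """Bundle of generator parameters used by the CLI ``simulate`` command."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("dpbf", "tcspc", "spectra", "ensemble"):
            raise ValueError(f"unknown generator kind {self.kind!r}")


@dataclass
class LabelledConformer:
    """A toy conformer together with its generator ground truth."""

    conformer: Conformer
    true_category: str
    true_coordinated: bool

    def __post_init__(self) -> None:
        if self.true_category not in _CATEGORIES:
            raise ValueError(f"unknown category {self.true_category!r}")


def gen_dpbf_trace(
    phi_true: float,
    phi_ref_rate_constant: float = 2.5e-3,
    k_background: float = 1e-4,
    intensity0: float = 1000.0,
    n_points: int = 30,
    dt: float = 30.0,
    noise_level: float = 0.02,
    seed: int | None = None,
    absorbance: float = 0.8,
    label: str = "",
) -> KineticTrace:
    """Simulate a DPBF photobleaching trace under continuous irradiation.

    The scavenger intensity follows
    ``I(t) = I0 * exp(-(k_background + c * phi_true) * t) * (1 + eps)`` with
    ``c = phi_ref_rate_constant`` (the pseudo-first-order rate per unit
    quantum yield at the matched working absorbance) and multiplicative
    Gaussian noise ``eps ~ N(0, noise_level)``.  Intensities that the noise
    drives non-positive are clipped to 1e-6 * I0 and counted in
    ``metadata["n_clipped"]``.
    """
    if phi_true < 0 or phi_true > 1:
        raise ValueError("phi_true must lie in [0, 1]")
    if phi_ref_rate_constant < 0 or k_background < 0:
        raise ValueError("rates must be non-negative")
    if dt <= 0 or n_points < 5:
        raise ValueError("need dt > 0 and at least 5 points")
    if noise_level < 0:
        raise ValueError("noise_level must be non-negative")
    rng = np.random.default_rng(seed)
    k = k_background + phi_ref_rate_constant * phi_true
    t = np.arange(n_points) * dt
    ideal = intensity0 * np.exp(-k * t)
    eps = rng.normal(0.0, noise_level, n_points) if noise_level > 0 else np.zeros(n_points)
    intensities = ideal * (1.0 + eps)
    floor = 1e-6 * intensity0
    n_clipped = int(np.sum(intensities < floor))
    intensities = np.maximum(intensities, floor)
    meta = {
        "generator": "gen_dpbf_trace",
        "seed": seed,
        "truth": {"phi_true": phi_true, "k_total": k, "k_background": k_background,
                  "phi_ref_rate_constant": phi_ref_rate_constant, "intensity0": intensity0},
        "noise_level": noise_level,
        "n_clipped": n_clipped,
    }
    return KineticTrace(t, intensities, absorbance, label, meta)


def _gaussian(t: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def gen_tcspc(
    components,
    irf_center: float = 2.0,
    irf_fwhm: float = 0.12,
    peak_counts: float = 1e4,
    n_bins: int = 256,
    bin_width: float = 0.05,
    seed: int | None = None,
    poisson: bool = True,
    irf_poisson: bool = False,
) -> DecayHistogram:
    """Simulate a TCSPC decay histogram with a paired Gaussian IRF.

    The ideal decay ``sum_i a_i exp(-t/tau_i)`` (amplitude fractions summing
    to 1) is discretely convolved with the sum-normalized Gaussian IRF,
    scaled so the largest bin expectation equals ``peak_counts``, then
    Poisson-sampled per bin (unless ``poisson=False``, which returns the
    expectation).  The IRF histogram is returned noise-free, or
    Poisson-sampled when ``irf_poisson`` is set.  A record shorter than five
    times the slowest lifetime triggers a truncation warning.
    """
    comps = [(float(t), float(a)) for t, a in components]
    if not comps or any(t <= 0 for t, _ in comps) or any(a <= 0 for _, a in comps):
        raise ValueError("lifetimes and amplitude fractions must be positive")
    if abs(sum(a for _, a in comps) - 1.0) > 1e-6:
        raise ValueError("amplitude fractions must sum to 1")
    if peak_counts < 100:
        raise ValueError("peak_counts must be at least 100")
    rng = np.random.default_rng(seed)
    t = (np.arange(n_bins) + 0.5) * bin_width
    irf_shape = _gaussian(t, irf_center, irf_fwhm)
    if irf_shape.sum() <= 0:
        # delta-IRF limit: the Gaussian underflows between bin centers
        irf_shape = np.zeros(n_bins)
        irf_shape[int(np.argmin(np.abs(t - irf_center)))] = 1.0
    irf_norm = irf_shape / irf_shape.sum()
    decay = np.zeros(n_bins)
    for tau, a in comps:
        decay += a * np.exp(-(t - t[0]) / tau)
    expect = np.convolve(irf_norm, decay)[:n_bins]
    expect *= peak_counts / expect.max()
    counts = rng.poisson(expect).astype(float) if poisson else expect
    irf_counts = irf_shape / irf_shape.max() * peak_counts
    if irf_poisson:
        irf_counts = rng.poisson(irf_counts).astype(float)
    meta = {
        "generator": "gen_tcspc",
        "seed": seed,
        "truth": {"components": comps, "irf_center": irf_center, "irf_fwhm": irf_fwhm,
                  "peak_counts": peak_counts},
        "poisson": poisson,
    }
    hist = DecayHistogram(t, counts, irf_counts, meta)
    check_truncation(hist, max(tau for tau, _ in comps))
    return hist


def gen_spectra(
    donor_center: float = 620.0,
    donor_fwhm: float = 90.0,
    acceptor_center: float = 580.0,
    acceptor_fwhm: float = 150.0,
    eps_max: float = 38000.0,
    grid: np.ndarray | None = None,
) -> tuple[Spectrum, Spectrum]:
    """Gaussian-band donor emission and acceptor absorptivity on a shared grid.

    Defaults emulate a Zn-porphyrin donor emitting around 550-720 nm and a
    bis-azo dark-quencher acceptor absorbing broadly across 350-650 nm.
    The acceptor peak equals ``eps_max`` (M^-1 cm^-1); the donor band is in
    arbitrary units (its normalization cancels in the overlap integral).
    """
    if donor_fwhm <= 0 or acceptor_fwhm <= 0:
        raise ValueError("band widths must be positive")
    if eps_max < 0:
        raise ValueError("eps_max must be non-negative")
    if grid is None:
        grid = np.arange(300.0, 801.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    donor = Spectrum(grid, _gaussian(grid, donor_center, donor_fwhm), "emission", "donor")
    acceptor = Spectrum(grid, eps_max * _gaussian(grid, acceptor_center, acceptor_fwhm), "absorptivity", "acceptor")
    return donor, acceptor


# ---------------------------------------------------------------------------
# toy conformer scaffold
# ---------------------------------------------------------------------------

_ZN_N = 2.05  # Zn-N(pyrrole) distance, Angstrom
_RING_RADIUS = 3.4
_N_RING_C = 12
_CHAIN_SPACING = 1.5


def _core(rng: np.random.Generator, jitter: float):
    """Zn at the origin, 4 pyrrole N on the axes, a C ring as the macrocycle proxy."""
    elements = ["Zn", "N", "N", "N", "N"]
    coords = [np.zeros(3)]
    for sx, sy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        coords.append(np.array([sx * _ZN_N, sy * _ZN_N, 0.0]))
    for k in range(_N_RING_C):
        ang = 2.0 * np.pi * (k + 0.5) / _N_RING_C
        coords.append(np.array([_RING_RADIUS * np.cos(ang), _RING_RADIUS * np.sin(ang), 0.0])
                      + rng.normal(0.0, jitter, 3))
    elements += ["C"] * _N_RING_C
    return elements, coords


def _chain_elements(n_chain: int) -> list:
    # one potential donor N leading the chain, one O mid-chain, C otherwise
    elements = ["C"] * n_chain
    elements[0] = "N"
    elements[n_chain // 2] = "O"
    return elements


def _chain_open(rng, n_chain, jitter):
    """Extended chain along +x: maximal exposure, the donor N far from Zn."""
    pts = []
    start = np.array([_RING_RADIUS + 1.2, 0.0, 0.6])
    for k in range(n_chain):
        pts.append(start + np.array([k * _CHAIN_SPACING, 0.0, 0.0]) + rng.normal(0.0, jitter, 3))
    return pts


def _chain_half(rng, n_chain, jitter):
    """Hairpin: out along +x, turn, and return 3 A above — moderate burial."""
    pts = []
    half = (n_chain + 1) // 2
    start = np.array([_RING_RADIUS + 1.2, 0.0, 0.6])
    for k in range(half):
        pts.append(start + np.array([k * _CHAIN_SPACING, 0.0, 0.0]) + rng.normal(0.0, jitter, 3))
    top = start + np.array([(half - 1) * _CHAIN_SPACING, 0.0, 3.0])
    for k in range(n_chain - half):
        pts.append(top - np.array([k * _CHAIN_SPACING, 0.0, 0.0]) + rng.normal(0.0, jitter, 3))
    return pts


def _chain_closed(rng, n_chain, jitter):
    """Tight helix stacked over the porphyrin; the leading N sits axially on Zn."""
    pts = [np.array([0.0, 0.0, rng.uniform(2.2, 2.4)])]  # axial donor
    radius, dz, dang = 1.9, 0.45, np.deg2rad(100.0)
    for k in range(n_chain - 1):
        ang = k * dang
        pts.append(np.array([radius * np.cos(ang), radius * np.sin(ang), 3.0 + k * dz])
                   + rng.normal(0.0, jitter, 3))
    return pts


_CHAIN_BUILDERS = {"open": _chain_open, "half-open": _chain_half, "closed": _chain_closed}


def _build_conformer(rng, category, n_chain, jitter, label):
    for _ in range(50):
        elements, coords = _core(rng, jitter)
        chain = _CHAIN_BUILDERS[category](rng, n_chain, jitter)
        elements += _chain_elements(n_chain)
        coords = np.vstack([coords, np.vstack(chain)])
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() >= 0.9:
            return Conformer(elements, coords, label)
    raise RuntimeError(f"could not build a clash-free {category} conformer in 50 attempts")


_ENERGY_MEANS = {
    # kcal/mol relative landscape; closed strongly preferred in the
    # protonated-like (dicationic) ensemble, categories overlapping in the
    # deprotonated-like (monocationic) ensemble
    "protonated": {"closed": 0.0, "half-open": 3.0, "open": 5.0},
    "deprotonated": {"closed": 2.0, "half-open": 2.0, "open": 2.0},
}
_ENERGY_SDS = {
    "protonated": {"closed": 0.5, "half-open": 0.8, "open": 1.0},
    "deprotonated": {"closed": 1.0, "half-open": 1.0, "open": 1.0},
}


def gen_conformer_ensemble(
    n_per_category=(10, 10, 10),
    seed: int | None = None,
    kind: str = "protonated",
    n_chain: int = 22,
    jitter: float = 0.08,
) -> list[LabelledConformer]:
    """Generate a labelled toy ensemble of open / half-open / closed conformers.

    Each conformer shares a rigid scaffold — Zn at the origin, four pyrrole
    N at +-2.05 A on the x/y axes, a ring of C atoms as the macrocycle
    proxy — plus an ``n_chain``-atom flexible chain whose geometry encodes
    the category: extended (open, maximal SASA), hairpin (half-open), or a
    compact helix stacked over the porphyrin with the leading chain N placed
    2.2-2.4 A axially above Zn (closed, minimal SASA).

    ``n_per_category`` orders counts as (open, half-open, closed).  Energy
    components are drawn so that Gibbs energies follow the ``kind``
    landscape: ``"protonated"`` gives closed conformers distinctly lower G;
    ``"deprotonated"`` overlaps all categories.
    """
    if kind not in _ENERGY_MEANS:
        raise ValueError(f"unknown ensemble kind {kind!r}")
    n_open, n_half, n_closed = (int(n) for n in n_per_category)
    if min(n_open, n_half, n_closed) < 0 or n_open + n_half + n_closed == 0:
        raise ValueError("need a non-negative count per category and at least one conformer")
    if not 15 <= n_chain <= 30:
        raise ValueError("n_chain must lie in [15, 30]")
    rng = np.random.default_rng(seed)
    out: list[LabelledConformer] = []
    for category, n in zip(_CATEGORIES, (n_open, n_half, n_closed)):
        for i in range(n):
            label = f"{category}_{i}"
            conf = _build_conformer(rng, category, n_chain, jitter, label)
            g_target = rng.normal(_ENERGY_MEANS[kind][category], _ENERGY_SDS[kind][category])
            g_thermo = rng.normal(2.0, 0.5)
            dg_solv = rng.normal(-3.0, 0.5)
            conf.energy = EnergyComponents(g_target - g_thermo - dg_solv, g_thermo, dg_solv)
            coordinated = category == "closed"
            conf.metadata.update(
                true_category=category, true_coordinated=coordinated,
                generator="gen_conformer_ensemble", seed=seed, kind=kind,
            )
            out.append(LabelledConformer(conf, category, coordinated))
    return out
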