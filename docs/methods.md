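# Methods

This note records the models implemented in `rotaphot`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions that were genuinely open.

## DPBF actinometry (`singlet_oxygen`)

**Model.** Under continuous irradiation with excess
diphenylisobenzofuran, scavenger consumption by ¹O₂ is pseudo-first-order:
I(t) = I₀ exp(−k t) with k = k_bg + c·Φ_Δ, where k_bg is the slow
sensitizer-free background bleaching and c is the rate per unit quantum
yield at the matched working absorbance.  The analysis linearizes to
ln(I₀/I) = k t, subtracts the background rate, and ratios against a
reference sensitizer of known yield measured under identical conditions:
Φ = Φ_ref · k_s/k_ref.  An optional absorption-screening factor
(1−10^−A_ref)/(1−10^−A_s) is available but off by default because the
assay matches absorbances (0.8 at the Soret band).

**Fit window.** By default only the points up to the first 50%
fluorescence loss are fitted; beyond that the excess-scavenger assumption
degrades.  The window is configurable.

**Intercept convention.** The slope is obtained by ordinary least squares
with a free intercept.  Anchoring the line through the first recorded
point (the literal reading of a ln(I₀/I) plot) is available as
`intercept_mode="anchored"`, but it injects the noise of that single point
into the slope — the through-origin estimator picks up roughly
t̄/⟨t²⟩ of the I₀ error — so the free intercept is the default.

**Reporting.** Triplicate yields are summarized as mean ± sample standard
deviation (n−1).  A corrected rate that does not exceed the background is
floored at zero and flagged `below_detection`, matching the upper-bound
style of reporting ("< 0.03") used for near-zero producers.  A single
replicate reports its dispersion as missing, never as zero.

## TCSPC lifetime fitting (`tcspc`)

**Model.** counts_j = [IRF ⊛ Σᵢ aᵢ exp(−t/τᵢ)]_j + baseline, with the
measured IRF histogram sum-normalized and shifted by a continuous sub-bin
offset (linear interpolation).  Without an IRF, a tail fit from the peak
bin is performed and the shift is fixed at zero.

**Objective.** Modified Neyman weighting, wⱼ = 1/max(countsⱼ, 1), i.e.
χ² = Σ wⱼ (cⱼ − mⱼ)²; χ²_red divides by (fitted bins − parameters).  Bins
before the rising edge (below 2% of the peak, minus a 10-bin margin) are
excluded from the objective: they carry no signal but would deflate
χ²_red through the degrees-of-freedom count.  The modified Neyman
statistic has a known per-bin bias at low counts (expectation ≈ 0.59 at
μ = 1, ≈ 1.6 at μ = 5), so individual fits scatter more widely around 1
than an ideal χ² would; the package reports the statistic as defined and
leaves interpretation bands to the caller.

**Optimization.** Amplitudes and baseline enter linearly and are solved by
non-negative least squares inside the nonlinear search over (log₁₀ τᵢ,
shift) — variable projection.  Lifetime starts are log-spaced over
[bin width, record/3] with fixed multiplicative jitters (deterministic
multi-start); bounds keep τ within [bin width/20, record length].  A
component collapsing below bin width/10 triggers a refit with one
component fewer, flagged `collapsed-tau`; negligible fractions (< 1%) and
near-degenerate lifetime pairs are flagged rather than silently dropped.

**Model selection.** Components are added (up to 3) only while the
reduced χ² improves by at least 10% relative; ties favor fewer
components.  Lifetime uncertainties are asymptotic standard errors from
the Jacobian of the projected problem.

**Averages.** τ_av = Σ aᵢτᵢ / Σ aᵢ with pre-exponential fractions; this is
the convention under which relative amplitudes in percent can be averaged
directly and under which quenched subpopulations lower τ_av in proportion
to their amplitude.

## Förster analysis (`fret`)

Wavelength-domain formulation on a nanometer grid:
J = ∫F_D ε_A λ⁴ dλ / ∫F_D dλ (trapezoid rule on the union of grid points
within the common support; donor normalization built in, so its absolute
scale cancels) and R₀ = 0.02108 (κ² Φ_D n⁻⁴ J)^{1/6} nm with J in
M⁻¹cm⁻¹nm⁴.  Defaults κ² = 2/3 (isotropic averaging) and n = 1.407
(tetrahydrofuran) are documented assumptions, configurable per call.
Disjoint spectral supports give J = 0 with a warning rather than an error.

## Conformer ensembles (`conformers`)

**Thermodynamics.** G = E_gas + G_thermo + ∂G_solv, summed exactly;
Hartree inputs are converted at 627.5094740631 kcal/mol.  Only relative
values ΔG = G − min(G) are used downstream.  Boltzmann weights use
R = 0.0019872043 kcal mol⁻¹ K⁻¹ at a default 298.15 K, computed with
max-subtraction for overflow safety.

**SASA.** Shrake–Rupley with a Fibonacci point lattice (default 960
points), Bondi van der Waals radii and a 1.4 Å water probe; all three are
configurable because upstream tools rarely state their parameter sets.
Each atom's lattice is oriented in a frame built from its nearest
neighbors, which makes the estimate exactly invariant under rigid motions
of the molecule (a fixed global lattice orientation leaves an
orientation-dependent residual of up to ~1% at 960 points).

**Axial coordination.** The porphyrin plane is the best-fit plane (SVD) of
the four N atoms nearest Zn; a non-porphyrin N/O/S atom within 2.6 Å of
Zn and within a 40° cone about the plane normal (either side) counts as
an axial donor.  The cutoffs reflect typical Zn–N/O coordination
distances and are configurable.  A fifth N within 2.3 Å of Zn triggers an
ambiguity warning — an axial amine at bonding distance is
indistinguishable from a mis-assigned pyrrole N by distance alone.

**Folding classification.** f = (SASA_max − SASA)/(SASA_max − SASA_min)
over the ensemble; *closed* if f ≥ 0.7, *open* if f ≤ 0.3 and no axial
donor, *half-open* otherwise.  Coordination alone never yields "open".
The 0.3/0.7 thresholds are package defaults (reported in every output),
not values taken from any particular upstream protocol.  A one-conformer
(or zero-SASA-range) ensemble is classified by coordination alone and
flagged degenerate, since the normalization is undefined.

## Synthetic data (`synthetic`)

**What is emulated.** (i) DPBF traces: exact exponential decay with
multiplicative Gaussian noise — the default 2% noise, 30 points at 30 s
intervals, c = 2.5×10⁻³ s⁻¹ per unit yield and k_bg = 10⁻⁴ s⁻¹ give a
strong reference sensitizer (Φ = 0.72) an ~80% fluorescence loss over a
15-minute run, a realistic bench protocol; background runs are generated
twice as long because they are measured once and fitted once.  (ii) TCSPC:
discrete convolution of a Gaussian IRF (center 2 ns, FWHM 0.12 ns) with
the multiexponential decay on a 256 × 0.05 ns grid, peak-scaled (default
10⁴ counts) and Poisson-sampled per bin.  The Gaussian IRF makes an
analytic (exponentially-modified-Gaussian) oracle available; the discrete
convolution matches it to first order in the bin width.  (iii) Spectra:
Gaussian bands — a donor emitting around 620 nm and a broad acceptor band
centered at 580 nm with ε_max = 3.8×10⁴ M⁻¹cm⁻¹, proxies for a
Zn-porphyrin emitter and a bis-azo dark quencher.  (iv) Conformers: a
rigid toy scaffold (Zn, four pyrrole N at 2.05 Å, a 12-C macrocycle ring)
plus a 22-atom chain that is extended (open), hairpin-folded (half-open)
or helically packed over the porphyrin with its leading N placed
2.2–2.4 Å axially (closed).  The "protonated-like" energy landscape gives
closed conformers a ~3–5 kcal/mol advantage (folded states dominate); the
"deprotonated-like" landscape overlaps all categories.

**What is not emulated.** No real porphyrin electronic structure, no
force-field energetics, no photobleaching of the sensitizer itself, no
detector afterpulsing or dark counts, no spectral fine structure.
Passing recovery tests therefore demonstrates the correctness of the
estimators under their stated noise models, not robustness to every
instrumental artifact of real data.

**Determinism.** Every generator takes one seed and uses a single
`numpy.random.Generator`; identical seed and parameters reproduce output
bit for bit, and each output records its seed and truth parameters in
metadata.

## Problem sizes

The test suite and the acceptance script run at desk scale: 50 seeded
histogram fits for lifetime recovery, 25 triplicates per yield level for
the actinometry error survey, 10 conformers per category for
classification, 960 lattice points for SASA.  These sizes put the Monte
Carlo uncertainty of each check well inside its assertion band while
keeping a full run under a minute.

## Known limitations

* The linearized slope assumes strictly positive intensities; traces that
  decay into the noise floor must be windowed (the 50%-loss default does
  this in practice).
* Reconvolution assumes the IRF is measured on the same grid as the decay
  and is Poisson-clean enough to use as a kernel; IRF noise is not
  propagated into the fit uncertainties.
* The lifetime uncertainty estimate is asymptotic (local curvature), not a
  replicate-based error.
* SASA-based folding classification is ensemble-relative: categories are
  only comparable across ensembles if the underlying molecule is the same.
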