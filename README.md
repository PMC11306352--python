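# rotaphot

Quantitative photophysics and conformer-ensemble analysis for switchable
photosensitizers — molecules such as Zn(II)-porphyrin/dark-quencher
rotaxane conjugates whose singlet-oxygen production can be turned on and
off by a conformational switch.

The package is aimed at photochemists and computational chemists who need
to turn raw instrument and quantum-chemistry outputs into the standard
figures of merit of such a study:

* **Singlet-oxygen quantum yields** (`rotaphot.singlet_oxygen`) by relative
  DPBF actinometry.  The scavenger fluorescence decays pseudo-first-order
  under irradiation, so the slope *k* of the linearized ln(*I*₀/*I*) vs.
  time plot, after subtracting the sensitizer-free background reaction, is
  proportional to ¹O₂ production.  Against a reference of known yield at
  matched absorbance, Φ<sub>Δ</sub> = Φ<sub>ref</sub> · *k*<sub>s</sub>/*k*<sub>ref</sub>,
  with triplicate mean ± sample standard deviation.
* **Fluorescence lifetimes** (`rotaphot.tcspc`): multiexponential
  reconvolution fitting of TCSPC photon-count histograms,
  model = IRF ⊛ Σᵢ *a*ᵢ exp(−*t*/τᵢ) + baseline, minimizing the reduced
  χ² with Poisson weights, plus the amplitude-weighted average lifetime
  τ<sub>av</sub> = Σ *a*ᵢτᵢ / Σ *a*ᵢ.
* **Förster radii** (`rotaphot.fret`): the spectral overlap integral
  J = ∫F<sub>D</sub>(λ) ε<sub>A</sub>(λ) λ⁴ dλ / ∫F<sub>D</sub>(λ) dλ and
  R₀ = 0.02108 (κ² Φ<sub>D</sub> n⁻⁴ J)<sup>1/6</sup> nm.
* **Conformer ensembles** (`rotaphot.conformers`): Gibbs free energies
  G = E<sub>gas</sub> + G<sub>thermo</sub> + ∂G<sub>solv</sub> from upstream
  quantum-chemistry outputs, relative energies against the ensemble
  minimum, Boltzmann populations, Shrake–Rupley solvent-accessible surface
  areas, Zn axial-coordination detection, and classification of each
  conformer as *open*, *half-open* or *closed* by its degree of
  intramolecular folding.
* **Synthetic data** (`rotaphot.synthetic`): seeded generators for all four
  input kinds with known ground truth, so every stage is testable without
  instrument access.

## Worked example

```python
from rotaphot.synthetic import gen_dpbf_trace, gen_tcspc
from rotaphot.singlet_oxygen import quantum_yield_pipeline
from rotaphot.tcspc import reconvolution_fit

# DPBF actinometry: triplicate sample traces (true yield 0.15) against a
# reference sensitizer (yield 0.72), with a sensitizer-free background run
samples = [gen_dpbf_trace(0.15, seed=s, label="rotaxane (on)") for s in (1, 2, 3)]
references = [gen_dpbf_trace(0.72, seed=s + 500, label="ZnTPP") for s in (1, 2, 3)]
background = gen_dpbf_trace(0.0, n_points=60, seed=903, label="background")
result = quantum_yield_pipeline(samples, references, 0.72, background=background)
print(f"Phi_Delta = {result.phi:.3f} +/- {result.phi_sd:.3f}  (n = {result.n_replicates})")

# TCSPC: biexponential reconvolution fit of a simulated decay
hist = gen_tcspc([(1.76, 0.19), (0.50, 0.81)], seed=42, peak_counts=1e4)
fit = reconvolution_fit(hist, 2)
for tau, frac in fit.components:
    print(f"tau = {tau:.2f} ns  ({100 * frac:.0f}%)")
print(f"tau_av = {fit.tau_av:.3f} ns   chi2_red = {fit.chi2_reduced:.2f}")
```

prints

```
Phi_Delta = 0.155 +/- 0.002  (n = 3)
tau = 1.72 ns  (20%)
tau = 0.49 ns  (80%)
tau_av = 0.736 ns   chi2_red = 0.98
```

The recovered quantum yield agrees with the generator truth (0.15) within
the triplicate scatter, and the fitted lifetimes/amplitudes recover the
simulated two-component decay; τ<sub>av</sub> is the amplitude-weighted
average of the fitted components.

A command-line interface mirrors the library:

```bash
rotaphot simulate --kind dpbf --seed 7 --out trace.csv
rotaphot sioq --sample s1.csv --sample s2.csv --sample s3.csv \
              --reference r1.csv --reference r2.csv --reference r3.csv \
              --background bg.csv --phi-ref 0.72 --json-out phi.json
rotaphot lifetime --decay decay.csv --json-out fit.json
rotaphot fret --donor donor.csv --acceptor acceptor.csv --json-out fret.json
rotaphot ensemble --xyz conformers.xyz --json-out ensemble.json
rotaphot report --config report.yaml --out table.csv
```

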