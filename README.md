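# incoscat

Elastic and quasi-elastic incoherent neutron scattering (EINS/QENS) analysis
of hydrated protein powders, built for studies of sub-nanosecond side-chain
dynamics — e.g. comparing amyloid fibril polymorphs of hen egg white
lysozyme (HEWL). The package provides the full analysis chain as tested,
reusable model objects, plus a seeded synthetic-data generator so every
stage can be validated by parameter recovery against known ground truth.

## Who it is for

Neutron-scattering practitioners analysing reduced backscattering data
(elastic temperature scans S(Q, T) and quasi-elastic spectra S(Q, ω)) on
thermal backscattering instruments with ~8 μeV elastic resolution,
Q ∈ 0.2–4.9 Å⁻¹ and energy transfers of order ±80 μeV.

## Models

**Elastic scans.** Normalized elastic intensity is fitted two ways:

- Gaussian approximation, `S(Q) = S(0) exp(−Q²⟨u²⟩/3)`, giving the mean
  square displacement (MSD) on a self-consistent low-Q window
  `Q²⟨u²⟩ < 2.4`;
- heterogeneity model, `S(Q) = S(0) (1 + Q²⟨r²⟩/β)^(−β)`, using **all** Q
  points, giving the mean-square position fluctuation (MSPF) ⟨r²⟩ and the
  heterogeneity parameter β. The squared fluctuation λ = r²/⟨r²⟩ is
  Gamma(β, β)-distributed (unit mean); β → ∞ recovers the Gaussian model.

**Amplitude states.** Fixed thresholds in r² (0.25 and 1.0 Å²) partition the
Gamma distribution into small/medium/large amplitude states; fractions are
scaled to the 129 residues of HEWL, and occupancy ratios give free-energy
differences via `N₂/N₁ = exp(−ΔG/RT)`.

**QENS global fit.** All spectra are fitted at once with

    S(Q, ω) = C(Q) [A₀(Q) R(ω) + (1 − A₀(Q)) L(Q, ω)] ⊗ R(Q, ω) + sQ + t

where R is the instrument resolution (an asymmetric elastic peak fitted to
vanadium: Gaussian above the peak, `exp(−Δ²/(2σ² + ξ|Δ|))` below it),
L is a Lorentzian with jump-diffusion width `Γ(Q) = ħDQ²/(1 + DQ²τ)`
(alternative: a Q-independent `Γ = ħ/τ`), and the EISF is the
diffusion-inside-a-sphere form `A₀(Q) = (1 − p₀)(3j₁(Qa)/Qa)² + p₀` with
immobile fraction p₀. Shared parameters (p₀, a, τ, D, s, t) plus one free
scale C(Q) per spectrum; quoted χ² is the sum of squared standardized
residuals divided by (N − 1), N = number of Q values.

**Composition.** Bound-atom incoherent cross sections (H 80.27 barn,
D 2.05 barn, …) turn an elemental composition and mass into a scattering
budget, and the fitted p₀ into immobile-hydrogen and residue counts.

## Worked example

```python
import incoscat as ic
from incoscat import synthetic as syn

# QENS: synthesize a dataset from the LP60 preset and recover its parameters
truth = syn.qens_truth_preset("LP60", noise=0.02)
data = syn.generate_qens_dataset(truth, seed=11)
fit = ic.global_fit(data, n_starts=3, seed=0)
print(fit.summary())
```

prints

```
Global QENS fit (jump_diffusion), 1110 points, chi2 = 122.8
  p0  = 0.446 +/- 0.007
  a   = 1.342 +/- 0.052 A
  tau = 14.05 +/- 4.09 ps
  D   = 7.273 +/- 0.341 x1e-8 cm^2/s
  s = 0.001855, t = 0.02021; C(Q) = [20.066 20.072 19.997 ...]
```

i.e. the fit recovers the generating truth (p₀ = 0.45, a = 1.3 Å,
τ = 18 ps, D = 7.6×10⁻⁸ cm²/s) within its uncertainties; χ² ≈ 123 is the
expected value of this convention for 111 points per spectrum at 10 Q
values with correctly specified noise (M·N/(N−1)). Continuing with the
elastic scan and the amplitude partition:

```python
series = syn.generate_eins_series(syn.eins_truth_preset(), seed=11)
table = ic.fit_series(series)                      # MSD + MSPF per T
parts, ladder = ic.partition_series(list(table.itertuples()),
                                    ladder_temperature=306.0)
print(parts[-1].summary())
print(ladder.summary())
```

```
T = 306.0 K: S 0.167 (21.5 res), M 0.512 (66.1 res), L 0.321 (41.4 res)
T = 306.0 K: dG(S->M) = -2.859, dG(M->L) = +1.188 kJ/mol (reference S)
```

At 306 K (truth ⟨r²⟩ = 0.86 Å², β = 1.5) most residues sit in the
medium-amplitude state, which is the free-energy minimum of the ladder.
`ic.immobile_hydrogen_count(fit.params.p0)` converts the fitted immobile
fraction into hydrogen and residue counts, and
`ic.cross_section_budget().summary()` prints the protein/water scattering
budget (protein ≥ 98% for a 0.4 g D₂O/g powder).

The same chain is available from the shell:

```sh
incoscat simulate --preset LP60 --seed 11 --out run/
incoscat fit-mspf --input run/eins --out run/mspf.tsv
incoscat partition --mspf run/mspf.tsv --temperature 306 --out run/part.tsv
incoscat fit-qens --input run/qens --vanadium run/vanadium --out run/qens.json
incoscat composition --p0 0.43
```

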