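# Methods

## Scope and data model

The package analyses *reduced* incoherent neutron scattering data from
hydrated protein powders: elastic temperature scans S(Q) with 1σ errors on
a shared Q grid, and quasi-elastic spectra S(Q, ω) on a uniform
energy-transfer grid, together with vanadium spectra measured under the
same configuration. Instrument-level reduction (empty-cell subtraction,
detector efficiency, transmission and multiple-scattering handling) is
upstream and out of scope. Units throughout: Q in Å⁻¹, energies in μeV,
times in ps, diffusion coefficients internally in Å²/ps and reported in
10⁻⁸ cm²/s (1×10⁻⁸ cm²/s = 10⁻⁴ Å²/ps); ħ = 658.2119 μeV·ps converts
rates to energy half-widths.

## Elastic-scan analysis

Curves are normalized pointwise to the lowest-temperature curve (quotient
errors propagated assuming independence), so all extracted amplitudes are
relative to the reference temperature.

**MSD (Gaussian approximation).** `S(Q) = S(0) exp(−Q²⟨u²⟩/3)` is valid
only at small `Q²⟨u²⟩`; the working ceiling is `Q²⟨u²⟩ < 2.4` (default,
configurable). Because the ceiling depends on the fitted ⟨u²⟩, the window
is found self-consistently: fit on the six lowest-Q points, derive
`q_max = sqrt(limit/⟨u²⟩)`, refit on all points with `q ≤ q_max`, iterate
until stable (≤ 10 rounds; ≥ 4 points are required in every window). The
fit is weighted *nonlinear* least squares with weights 1/σ² —
log-linearization is avoided because it distorts weights where intensities
are small. For a flat (reference) curve the window grows to the full grid
and ⟨u²⟩ → 0.

**MSPF (heterogeneity model).** `S(Q) = S(0)(1 + Q²⟨r²⟩/β)^(−β)` is
fitted over *all* Q points (that is its purpose: the full-Q shape encodes
the amplitude distribution). β is bounded in (10⁻³, 10⁶]; evaluation uses
`exp(−β·log1p(·))` so the β → ∞ regime is numerically exact. Fits with
β ≥ 10⁵ are flagged `gaussian_indistinguishable`: over Q ≤ 5 Å⁻¹ the
model then deviates from the Gaussian form by less than typical counting
noise, so β is effectively unidentified and only a lower bound is
meaningful. Note the exponent conventions: ⟨u²⟩ enters as ⟨u²⟩/3, ⟨r²⟩
enters directly, so for the same curve ⟨u²⟩ ≈ 3⟨r²⟩ in the Gaussian
regime — both conventions are the ones standard for their respective
estimators.

## Amplitude partition and free energies

λ = r²/⟨r²⟩ follows a Gamma(shape β, rate β) distribution (unit mean).
State thresholds are fixed in r²-space (defaults 0.25 and 1.0 Å²) and
converted to λ-space with that temperature's ⟨r²⟩ — forced by the density
being defined in λ. Bin masses are regularized incomplete-gamma
differences; they sum to 1 by construction; ⟨r²⟩ = 0 degenerates to all
mass in the small-amplitude state. Residue counts are fractions × 129
(HEWL), kept real-valued — rounding is presentation only. Free-energy
differences use ΔG = −RT ln(N₂/N₁) in kJ/mol, with the second state the
"product" (positive ΔG when the product is less populated); the ladder
satisfies ΔG(S→L) = ΔG(S→M) + ΔG(M→L) exactly.

A direction worth stating because it is easy to get backwards: at *fixed*
⟨r²⟩, lowering β (more heterogeneity) **increases** the Gamma mass below a
sub-mean threshold — the small-amplitude state grows. The experimentally
observed drainage of the small-amplitude state on warming is a joint
effect: ⟨r²⟩ rises with temperature, shrinking the λ-threshold 0.25/⟨r²⟩
faster than the β decrease refills the bin. The tests assert both facts.

## Resolution function

The vanadium elastic peak is modelled as a Gaussian with an exponentially
broadened low-energy flank:

    R(ω) = A·exp(−Δ²/(2σ² + ξ|Δ|))  for Δ = ω − ω₀ < 0
           A·exp(−Δ²/(2σ²))          for Δ ≥ 0,   plus background B.

ξ = 0 recovers a symmetric Gaussian; for large |Δ| the broadened flank
decays like exp(−|Δ|/ξ). The asymmetry is placed inside the denominator of
the exponent: the alternative reading (an additive +ξ|Δ| term in the
exponent) produces a spurious secondary maximum at |Δ| = ξσ² for realistic
magnitudes (σ ≈ 3.4 μeV, ξ ≈ 2.8), contradicting single-peaked vanadium
data, and is therefore rejected. Each Q is fitted independently (five
parameters, weighted, via lmfit); ξ pinned at 0 is flagged symmetric.
The default σ is set from the 8 μeV (FWHM) elastic resolution of the
emulated instrument: σ = 8/2.355 ≈ 3.40 μeV.

## QENS global model and convolution

The convolution engine treats the elastic δ-component analytically
(δ ⊗ R = R — never a discretized spike, avoiding grid-width artifacts).
Only the Lorentzian is convolved numerically: the resolution shape
(background removed, normalized to unit area so C(Q) carries the
amplitude) is tabulated as a kernel of half-width max(5σ + 12ξ, 10) μeV —
wide enough that the exponential flank is negligible at the edge — and the
Lorentzian is sampled on the measurement grid padded by
min(max(40Γ, kernel half-width), 1500) μeV per side, renormalized to unit
area on that padded grid, convolved with trapezoidal weighting and
cropped. Renormalizing the discretized Lorentzian makes the convolution
conserve area exactly and makes Γ → 0 recover the purely elastic spectrum
smoothly. `3j₁(x)/x` is evaluated by series below x = 10⁻³. Γ is a
half-width at half-maximum (the standard convention for the unit-area
Lorentzian form used).

The global fit shares (p₀, a, τ, D, s, t) across spectra — the background
B(Q) = sQ + t is flat in ω — with one free scale C(Q) per spectrum
absorbing the Debye–Waller factor (no parametric form imposed). The
Q-independent width law replaces Γ(Q) with ħ/τ and drops D. Optimization
is bounded least squares (scipy `trf`) on standardized residuals with
bounds p₀ ∈ [0,1], a ∈ [0.1, 5] Å, τ ∈ [0.1, 500] ps,
D ∈ [0.1, 50]×10⁻⁸ cm²/s; multi-start uses one data-driven start (scales
from spectrum areas, mid-range physics) plus seeded Latin-hypercube draws
(τ and D sampled logarithmically). Parameter uncertainties come from
(JᵀJ)⁻¹ of the standardized-residual Jacobian. p₀ ≥ 0.99 flags the
quasi-elastic weight as vanishing and the width as unidentifiable.

The quoted χ² follows the convention `Σ_Q Σ_ω z² / (N−1)` with N the
number of Q values — *not* per degree of freedom — so for well-specified
noise it concentrates near M·N/(N−1) with M points per spectrum. It is
defined only for N ≥ 2. The D–τ pair is correlated (ρ ≈ 0.85 at the
default conditions): the width law has a nearly flat ridge along which
both rise together, so single-replicate D estimates have heavier tails
than their Gaussian uncertainty suggests, while p₀ and a are tightly
determined.

## Synthetic data

The generators emulate a thermal backscattering configuration:
Q ∈ 0.2–4.9 Å⁻¹ (30 points) for elastic scans; energy transfers −80…+85
μeV (111 points) at 10 Q values {0.5, 1.0, 1.67, 2.0, 2.5, 3.0, 3.5, 4.0,
4.25, 4.5} Å⁻¹ for QENS (1.67 Å⁻¹, the conventional reference Q, always
included). Noise is Gaussian counting statistics, σ = c·√I with c the
relative error at unit intensity (defaults: 1% elastic, 2% QENS, 0.5%
vanadium); c = 0 returns exact model curves with unit weights. The QENS
presets wire the two fibril-polymorph parameter rows
(LP27: p₀ = 0.41, a = 1.1 Å, τ = 21.4 ps, D = 4.7×10⁻⁸ cm²/s;
LP60: p₀ = 0.45, a = 1.3 Å, τ = 18.0 ps, D = 7.6×10⁻⁸ cm²/s) with
C(Q) = 20 for every Q — placing the elastic peak near unit intensity so
the configured noise is approximately the peak-relative error — and a
small background (s = 0.002, t = 0.02). The elastic preset traces the
qualitative temperature profile of a hydrated protein powder: ⟨r²⟩ rising
to 0.86 Å² at 306 K while β collapses from ~10⁶ to 1.5 above the
dynamical transition. Presets are fixtures with known truth, not claims
about any measured sample.

What the generators do *not* emulate: detector-geometry and analyzer
Monte-Carlo effects, sample-can scattering, multiple scattering,
energy-dependent efficiency, and any correlated (non-diagonal) noise.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated statistical model, not robustness to
instrument systematics.

Seeds are mandatory arguments everywhere; there is no hidden global
randomness, and identical configuration + seed reproduce results
byte-identically through the pipeline.

## Composition accounting

Bound-atom incoherent cross sections (barn): H 80.27, D 2.05, C 0.001,
N 0.50, O 0.0008, S 0.007. The shipped HEWL formula is C₆₁₃H₉₅₉N₁₉₃O₁₈₅S₁₀
at 14,300 g/mol with all hydrogens protiated (total-H accounting — the
variant excluding exchangeable hydrogens does not reproduce the reference
per-gram value, the all-H variant does); heavy water is D₂O at 20.028
g/mol. Totals are reported in cm² per stated sample mass (1 g protein,
0.4 g D₂O at the default hydration), giving ≈ 3.25 cm² for the protein
and ≈ 0.049 cm² for the water — a ≥ 98% protein share, which is why the
hydration water is neglected in the spectral analysis. Immobile-atom
arithmetic uses 689 nonexchangeable hydrogens and an average of 6 per
residue.

## Problem sizes used in tests and the acceptance script

Replicate counts are chosen to keep the default suite fast while giving
stable medians: elastic-fit recovery uses 100 replicates per truth (fits
are milliseconds); QENS recovery uses 10 fixed-seed replicates per preset
with a single optimizer start (the data-driven start suffices on
well-specified synthetic data); the width-law comparison uses 6
replicates; the acceptance script reports medians over 5 replicate
experiments per preset with 3 optimizer starts each. The χ² calibration
check uses 5 replicates at 81 energy points.

## Known limitations

- Point estimates with Gaussian covariance only; no posterior sampling.
  The D–τ ridge means D's tails are non-Gaussian at low S/N.
- The resolution used in the convolution is the fitted analytic peak, not
  the raw vanadium histogram — deliberate denoising that also makes
  synthesis and fitting self-consistent, but any lineshape feature outside
  the asymmetric-Gaussian family is not representable.
- Elastic fits treat temperatures independently (no smoothing across T);
  two-state or force-constant analyses of the dynamical transition are out
  of scope.
- The amplitude partition inherits the Gamma-distribution assumption; its
  residue counts are model-derived quantities, not structural assignments.
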