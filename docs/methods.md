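# Methods

## The binary solution

Water–cosolute mixtures are described on a Flory–Huggins lattice: one
site per water molecule, ν contiguous sites per cosolute, where
ν = V̄_C/V̄_S is the ratio of partial molar volumes. Both volumes are
treated as concentration- and temperature-independent constants; they are
fitted by ordinary least squares to the solution volume per kg of water,
V(m) = (1000/M_S)·V̄_S + m·V̄_C with V(m) = (1000 + m·M_C)/ρ(m), from a
density series that must include the pure-water point.

The solvent chemical potential of the FH mixing free energy gives the
water activity

    ln a_S = ln(1 − ϕ_C) + (1 − 1/ν)·ϕ_C + χ·ϕ_C² ,

from which χ is a linear least-squares slope at each temperature (ν held
fixed at its density-derived value). The temperature dependence is the
minimal two-parameter van't Hoff form χ(T) = a + b/T, fitted by weighted
least squares across per-temperature estimates (inverse-variance weights
when standard errors are available, unweighted otherwise); the enthalpic
part is χ_H = b/T and the entropic part χ_TS = −a, so χ = χ_H − χ_TS
identically. Fitting per temperature and then regressing, rather than one
global two-parameter fit, keeps the per-temperature residuals inspectable;
both give identical results on noiseless data. Osmotic pressure is
Π = −(RT/V̄_S)·ln a_S, which approaches the van't Hoff limit RT·c at low
concentration and grows superlinearly for ν > 1.

## The crowding model

The ternary protein–cosolute–water system is split into a bulk domain and
a protein-surface domain. Folding buries a positive area ΔSASA, expressed
in lattice units through the site length d_S = (V̄_S/N_A)^{1/3} ≈ 3.107 Å
(exposed as a parameter): N_b = ΔSASA/d_S² surface sites, and a depletion
shell of thickness δ = (d_S/2)(ν^{1/3} − 1) that vanishes for
solvent-sized cosolutes.

Surface occupancy follows from exchange equilibrium. The per-cosolute
exchange potential is

    μ̂(ϕ) = ln ϕ − ν·ln(1 − ϕ) + (1 − ν) + χ·ν·((1−ϕ)² − ϕ²)   (kT),

and the surface volume fraction solves μ̂(ϕ_s) + ν·ε = μ̂(ϕ_b): a surface
cosolute occupies ν contact sites and pays ε per contact. The three terms
of the decomposition are then (per mole of protein)

    ΔΔG_ν⁰ = −Π·ΔSASA·δ
    ΔΔG_χ⁰ = +N_b·RT·χ·(ϕ_s − ϕ_b)²
    ΔΔG_ε⁰ = −N_b·RT·ε·ϕ_s ,

summed bit-exactly into the total. The χ term is the per-site kT form of
χ(νV̄_S)²(m^surf − m)² with m^surf = ϕ_s/(νV̄_S) the surface molarity.
With χ = ε = 0 the model reduces exactly to the Asakura–Oosawa relation
ΔΔG⁰ = Π·ΔV_ex with ΔV_ex = −ΔSASA·δ; with ν = 1 and ε = 0 a cosolute
has no effect. Because ϕ_s depends on ε, the χ term inherits an implicit
ε dependence; in this construction the depletion (ν) term depends only on
the bulk state. A formulation in which ε also feeds back on the ν term
through the surface state is conceivable; the composite two-domain form
used here was chosen because it reproduces the quadratic mixing term and
the depletion limit exactly and keeps the decomposition additive.

Temperature enters only through the explicit RT factors, χ(T) and
ε(T) = ε_h·T₀/T + ε_s (so ε_H(T₀) = ε_h, ε_TS(T₀) = −ε_s and
ε = ε_H − ε_TS at the reference temperature T₀ = 298 K); molar volumes
and ΔSASA are athermal. Model enthalpies use Gibbs–Helmholtz,
ΔΔH⁰ = ∂(ΔΔG⁰/T)/∂(1/T), as a central difference with step ΔT = 0.5 K by
default; TΔΔS⁰ = ΔΔH⁰ − ΔΔG⁰ holds exactly by construction.
Preferential-hydration changes are ΔΓ_S = (1/V̄_S)·dΔΔG⁰/dΠ by central
differences along an osmotic-pressure grid; negative values mean net
cosolute exclusion upon folding, i.e. stabilization, and ΔΓ_S is
proportional to the m-value.

### Root solving

ϕ_s is found by bracketed Brent iteration (relative tolerance 1e-14,
deterministic). For χν large enough that μ̂ is non-monotonic (a
miscibility gap), the bracket is grown outward from ϕ_b in the direction
given by the local slope of μ̂ and the first sign change is taken, which
selects the solution branch continuous with the bulk state and makes
ϕ_s(ε) continuous through ε = 0; if that branch terminates without a
crossing, the opposite direction is used. Surface compositions in that
regime are reported as solutions of the mean-field condition; no spinodal
diagnostics are attempted.

## Folding thermodynamics

Two-state reduction: f_N = (MRE − MRE_D)/(MRE_N − MRE_D) with
temperature- and cosolute-independent baselines (the default, consistent
with invariant isodichroic points; a linear-in-T baseline correction is
out of scope), clipped to [1e-6, 1−1e-6] with a warning; then
ΔG⁰ = −RT·ln(f_N/(1−f_N)). The isodichroic locator minimizes the
across-condition spread of MRE over the wavelength grid and selects the
most *prominent* interior minimum: far spectral wings where all curves
merely coincide give shallow minima that noise shuffles around, whereas a
genuine crossing is flanked by steeply rising spread.

Van't Hoff fits use the integrated form with constant ΔC_P,

    ΔG⁰(T) = ΔH⁰ − T·ΔS⁰ + ΔC_P·[(T − T₀) − T·ln(T/T₀)] ,

as a linear least-squares problem; the ΔC_P basis and its derivative
vanish at T₀, so ΔH⁰ − T₀ΔS⁰ is the predicted ΔG⁰(T₀) and the residuals
are invariant to re-centering T₀ when ΔC_P is refit. ΔC_P is fixed (default
0) unless the temperature span justifies fitting it (guideline: > 25 K).
ΔΔ quantities subtract the c = 0 buffer fit, with variances added.

For densely sampled noiseless surfaces a second route extracts ΔΔH⁰
directly by Gibbs–Helmholtz central differences on ΔΔG⁰(c, T) at grid
temperatures (`gibbs_helmholtz_deltas`). The van't Hoff route applied to
model-generated surfaces carries a small systematic (order 0.01 in ε_TS
under the default study conditions) because the model's ΔΔG⁰(T) is not
exactly of the constant-ΔC_P form; the surface route, with the model side
evaluated at the same finite-difference step, closes to optimizer
precision and is what the noiseless closure suite uses.

## Fitting ε and ε_TS

ε is the only free parameter of the ΔΔG⁰(c) fit; ν and χ stay at their
binary-solution values. The objective is scalar least squares over
ε ∈ [−10, 10]. Because ε·ϕ_s saturates (strong repulsion empties the
surface), the objective can have close-spaced local minima; the minimizer
therefore runs two deterministic grid-refinement stages (41 then 21
points) before bounded Brent refinement, and a unimodality diagnostic
warns when the gradient changes sign more than once over the interval.
Estimates at the bounds are flagged non-converged.

With ε fixed, ε_TS is the sole parameter of the enthalpy–entropy fit:
ε_s = −ε_TS and ε_h = ε − ε_s, preserving ε(T₀) exactly. ΔΔH⁰ and TΔΔS⁰
points are weighted equally — their residuals are perfectly anticorrelated
about the ΔΔG⁰ constraint, so relative weighting only rescales the
objective. The fit domain is molality; inputs in molarity are converted
through the partial molar volumes and give identical estimates.

Uncertainties come from residual-resampling bootstrap (centered
residuals, B = 1000 default, percentile interval at 68% to mirror ±1σ
error bars), deterministic under a fixed seed, and labeled as such in the
`FitResult`.

## Synthetic data

The generator emulates a complete single-cosolute study under one seed
(per-table offsets make bundles reproducible piecewise):

* **Densities** from the constant-partial-molar-volume identity, σ = 5e-5
  g/cm³ by default.
* **Water activities** from the FH closed form with χ(T) = a + b/T at ≥ 3
  temperatures, σ = 1e-4; noisy values leaving (0, 1] are clipped (and
  counted) or resampled.
* **Folding surfaces** ΔG⁰(c, T) as the integrated-van't-Hoff buffer
  baseline plus the crowding-model ΔΔG⁰, σ = 0.1 kJ/mol.
* **Spectra** as f_N·MRE_N + (1−f_N)·MRE_D with Gaussian-mixture basis
  curves shaped like the α-helix (two minima) or β-sheet (one minimum)
  classes; the denatured curve is the native one plus a windowed
  separation term with a single zero, so mixtures cross exactly once at
  the configured isodichroic wavelength. These are props for testing the
  reduction pipeline, not spectroscopic models. MRE noise σ = 200
  deg·cm²/dmol.
* **H-bond tables** for N/D × water/+sugar with a controlled perturbation
  (weakened protein–water bonds, small protein–sugar terms, slightly
  reduced counts); which state is weakened more selects net H-bond
  stabilization or destabilization of folding.

Default study conditions: a trehalose-like disaccharide (M_C = 342.3
g/mol, V̄_C = 209.5 cm³/mol ⇒ ν ≈ 11.6; χ(298 K) ≈ 0.32 with χ_H < 0 and
χ_TS < 0), a marginally stable 16-residue miniprotein (ΔSASA = 800 Ų,
ε = +0.3 with ε_H and ε_TS both positive, buffer ΔH⁰ = −10 kJ/mol,
ΔS⁰ = −35 J/mol/K, ΔC_P = −100 J/mol/K), nine molalities 0–1.5 mol/kg and
nine temperatures 278–318 K. Noise scales are plausible instrument-level
defaults, configurable throughout. What the generator does **not**
emulate: instrument baselines and drift, aggregation or three-state
behavior, concentration-dependent partial molar volumes, electrolyte
activity effects, and real CD band shapes — so passing tests demonstrate
correctness of the inference machinery under the model's own assumptions,
not robustness to every feature of real data.

The closure suite runs a 3×2×3 grid of truths, ν ∈ {2, 6, 12},
χ(T₀) ∈ {0.2, 1.5}, ε ∈ {−1, 0, +1} (χ_b = −300 K, ε_TS = 0.8), with six
molalities up to 0.3 mol/kg — kept low so the FH water activity stays in
(0, 1] even at χ = 1.5, ν = 12 — and five temperatures 288–308 K. Sizes
were chosen so the whole suite completes in well under two minutes on one
CPU while exercising every fitted parameter.

## H-bond bookkeeping

Totals are count-weighted sums Σᵢ nᵢ·ΔG̅ᵢ over donor–acceptor pair
classes; per-bond free energies are consumed as inputs (their estimation
from trajectories is out of scope). Pairs present in only one condition
are zero-filled — required for sugar partners, which do not exist in pure
water. The strength/number split uses reference-condition counts times
strength changes plus count changes times perturbed strengths, an exact
telescoping decomposition; a symmetric (Shapley) variant that evaluates
both factors at mean conditions is provided alongside. Every breakdown
(state, folding, partner class, strength/number) re-sums to its parent
total exactly. Whether intramolecular protein–protein bonds are included
is left to the input table; the reader treats them as ordinary records.

## Known limitations

* Single cosolute only; no mixtures, no electrolytes.
* Planar depletion-shell geometry; no curvature corrections and no scaled
  particle theory.
* The ν term does not see the surface state, so ε influences ΔΔG_ν⁰ only
  through the fitted parameter values, not mechanistically.
* Bootstrap intervals are percentile intervals; no bias correction or
  acceleration.
* In the miscibility-gap regime the exchange-equilibrium root is a
  mean-field branch choice, not a statement about solution stability.
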