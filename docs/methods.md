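# Methods

## The cavity-shell model

The solvated xenon is idealized as a point solute inside a thin
spherical shell of radius *R* carrying *Z* featureless solvent sites
spread evenly over the surface (surface density ρ_S = Z/4πR²).  Two
binary functions of the Xe–O distance *d* drive everything: the pair
chemical shift δ_pair(d) = Σₙ Dₙ/d^Eₙ and a pair potential V(d).  For
a xenon displaced a distance *r* from the shell centre, the distances
to shell points are distributed with density u/(2Rr) on [R−r, R+r],
giving closed-form shell averages for inverse-power integrands,

    ⟨u^−E⟩(r) = [u^(2−E)] over [R−r, R+r] / (2Rr(2−E)),

and a quadrature route for arbitrary integrands.  The xenon's radial
position is Boltzmann-distributed under the mean-field shell potential
U(r) = Z·⟨V⟩(r), and the observable shift is

    δ(T) = ∫₀ᴿ S(r) e^(−U(r)/k_BT) r² dr / ∫₀ᴿ e^(−U(r)/k_BT) r² dr,

with S(r) = Z·⟨δ_pair⟩(r).  The collision factor is defined as
K(T) = δ(T)/ρ_S(T), which makes the factorization δ = ρ_S·K exact by
construction; its physical content is that K grows with temperature
because the Boltzmann weight lets hotter xenon approach the wall where
δ_pair is steepest.  The 3-D volume element r² dr is used as the
radial measure; this is a modelling choice (other measures are
conceivable), and the fit-to-experiment stage absorbs moderate
differences in the measure into its free parameters.  Consistent with
that, plugging the *published* calibrated parameters into this
reconstruction yields a K(T) rising only ~1% across the liquid range
and hence a monotone δ(T); the package's own calibration (below)
recovers the experimental maximum, which is the quantity this model is
accountable for.

Assumptions worth keeping in mind: the shell is featureless (no
hydrogen positions, no second shell), the potential acts through its
shell average (mean field) rather than per-configuration, and Z enters
both S and U linearly.  As Z → 0 the model degenerates (the
unsuppressed near-wall divergence of S dominates), so very low
densities are outside its validity range.

## Temperature trends and parameters

All structural trends are vertex-form quadratics:

| quantity | form | default parameters |
|---|---|---|
| coordination number | Z(T) = Z₀ − a_Z (T − T_Z)² | Z₀ = 21.989, a_Z = 1.26697·10⁻⁴ K⁻², T_Z = 260.56 K |
| cavity radius | R(T) = R₀ + a_R (T − T_R)² | R₀ = 4.2675 Å, a_R = 3.57311·10⁻⁶ Å/K², T_R = 292.34 K |
| surface density (D₂O) | ρ_S(T) = ρ⁰ − a_S (T − T_S)² | ρ⁰ = 0.0959701 Å⁻², a_S = 6.99326·10⁻⁷ Å⁻²K⁻², T_S = 266.975 K |
| surface density (H₂O) | same | ρ⁰ = 0.0985138 Å⁻², a_S = 8.29205·10⁻⁷ Å⁻²K⁻², T_S = 270.387 K |

The reference shift function has D₁ = 1.85791·10⁸ ppm Å¹², E₁ = 12,
D₂ = −1.81437·10¹⁰ ppm Å¹⁷, E₂ = 17, with a constant shared cavity
radius R = 4.1423 Å; the default pair potential is the Halgren
buffered 14-7 with R⁰ = 4.15 Å, ε = 2.362 kcal/mol.  The Boltzmann
constant is fixed at 1.9872041·10⁻³ kcal/(mol K).  Units are Å, K,
ppm and kcal/mol throughout.  When a bundle carries both a
coordination model and a surface-density model, the density model
wins and Z = ρ_S·4πR² is derived, because the empirical calibration
parameterizes ρ_S directly.  Relativistic and basis-set effects on
the Xe shielding enter as a constant +44.7 ppm offset
(30.3 relativistic + 14.4 basis).

## Numerics

Production evaluation uses fixed-order Gauss–Legendre grids: 256
radial nodes on (0, R) (160 inside the calibration loop) and 64 nodes
(48 in the loop) for the inner shell average of the potential; shift
shell averages use their closed forms.  Boltzmann weights are
normalized by the maximum log-weight before exponentiation, so deep
wells cannot underflow the ratio.  A nested adaptive-quadrature path
(`method="adaptive"`, relative tolerance 10⁻⁸) is retained as a
reference; tests pin the two routes together to 10⁻⁸ and check the
Gauss route against an independent Monte-Carlo rejection sampler to
within three standard errors.  Radial integration runs to the shell
wall with no inner cutoff — the diverging potential suppresses the
integrand there.

The quadratic trend fits are linear least squares in a centred,
scaled polynomial basis, converted to vertex form, with standard
errors by first-order propagation of the coefficient covariance
(measurement σ used directly when supplied, residual variance
otherwise).  A scaled curvature below 10⁻¹² is reported as "no
extremum" rather than an absurd vertex; upward curvature raises an
extremum-type error.

## The six-parameter calibration

Six quantities are fitted jointly to the H₂O and D₂O series: D₁, D₂,
one temperature-independent R shared by the isotopes, and the H₂O
density triple (ρ⁰, a_S, T_S); the D₂O density and the pair potential
stay fixed, which anchors the overall scale and breaks the otherwise
exact D↔ρ_S degeneracy.  Because the Boltzmann weight involves only
the potential, the model is exactly linear in (D₁, D₂); the fit
exploits this by variable projection — the two coefficients are
solved by linear least squares (D₁ pinned at zero if the unconstrained
solution goes negative) inside every objective evaluation, and a
trust-region optimizer handles only the four nonlinear parameters.
Eight restarts over a cavity-radius grid (3.5–4.9 Å) with seeded
jitter of the density start guard against local minima; the best
solution by joint RMS wins.  This formulation recovers generating
parameters to machine precision on self-generated data, where a
six-dimensional formulation stalled in a curved valley.  The
integer-exponent scan simply reruns the fit per admissible (E₁ < E₂)
pair and ranks by RMS.  The canonical experimental inputs are
noiseless parabolas built from the published vertex parameters on a
273–360 K grid at 3 K spacing (the experiments span 0–87 °C); grid
and weighting are configurable.

## The synthetic-data generator

The raw NMR series and the MD trajectories behind the published
analysis are not public, so the generator emulates their statistical
structure: (i) parabolic shift series with i.i.d. Gaussian noise of
configurable σ (default 0.05 ppm); (ii) single solvation shells — Z
oxygens at uniform directions with radii Gaussian about the shell
radius (default spread 0.25 Å, giving a realistically broad first RDF
peak), a hard 2.4 Å O–O exclusion imposed by re-drawing directions
(radii are re-drawn only for the rare unplaceable molecule, keeping
the radial marginal Gaussian), and two hydrogens per oxygen at the
gas-phase monomer geometry (0.9572 Å, 104.52°) in random orientation,
carried for format fidelity only; (iii) multi-temperature ensembles
(default ten temperatures, 278–368 K in 10 K steps) whose per-frame
water counts are allocated deterministically around Z(T) — floor and
ceiling counts in the exact fractional proportion, shuffled across
frames — so the ensemble mean reproduces the trend by construction.

What the generator does **not** emulate: real liquid-water structure
(second shells, hydrogen-bond network), dynamics, frame-to-frame
occupation shot noise (a Poisson-like Z draw would swamp the weakly
curved Z(T) vertex with noise and, at realistic frame counts, make
trend recovery meaningless), and quantum isotope effects beyond the
distinct ρ_S parameter sets.  Passing closure tests therefore
demonstrates self-consistency of the analysis chain, not fidelity to
real water.

## Problem sizes used in the shipped tests

Closure and recovery tests run at deliberate desk scales chosen for
statistical power: 400 frames × 10 temperatures for the end-to-end
ensemble-shift closure (per-frame shift SD ≈ 15 ppm makes the ~1.5·10⁻³
ppm/K² curvature a >3σ detection at this size), 200 frames × 10
temperatures for structural-trend recovery, 500 frames for RDF-peak
closure, and 20 warm-started replicates at 0.05 ppm noise for the
calibration's noise-stability check.

## Known limitations

- The shell-averaging measure is a reconstruction; absolute K values
  (and hence the parameters recovered by the calibration) are
  measure-dependent even though the fitted curve and its maximum are
  robust.  Calibrated parameters should be compared across studies
  only together with the measure definition.
- The pairwise-additive ("force field") shift neglects beyond-binary
  electronic effects except as absorbed by effective coefficient
  sets; the 5.5 Å cutoff discards small genuine contributions.
- Hydrogen sites are carried but unused unless explicit H-site shift
  terms are supplied.
- The quadratic trend forms are local descriptions around the
  extremum, not global equations of state.
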