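# Methods

## Scope

`slbnr` models specular neutron reflectivity from a supported lipid bilayer
(SLB) at a silicon–water interface and recovers the bilayer's structure by
simultaneous ("co-refined") fitting of several solvent contrasts. It covers
four pieces of machinery: composition-based scattering-length densities (SLDs)
for mixed lipid extracts, an exact slab-stack reflectivity engine,
constraint-bound bilayer parameterizations, and a synthetic time-of-flight
data generator used to validate the whole chain by parameter recovery.

## Scattering-length densities

The SLD of a molecular fragment is ρ = Σᵢ nᵢbᵢ / V, with bound coherent
scattering lengths b(H) = −3.739, b(D) = 6.671, b(C) = 6.646, b(N) = 9.36,
b(O) = 5.803, b(P) = 5.13 fm and the fragment's partial molecular volume V in
Å³. Results are quoted in 10⁻⁶ Å⁻². Water uses V = 30.0 Å³ for both
isotopologues, giving the endpoints ρ(H₂O) = −0.558 and ρ(D₂O) = 6.382; an
H₂O/D₂O mixture interpolates linearly in the D₂O volume fraction.

A mixed extract of PE, PG and cardiolipin (CL) is treated at the lipid-class
level: each class contributes one head fragment and one tail fragment
(cardiolipin counts as a single molecule with four acyl chains and a double
glycerophosphate head), weighted by its mole fraction, so the head-region SLD
is Σxᵢbᵢ,head / ΣxᵢVᵢ,head and likewise for tails. The default class mole
fractions are 75% PE / 13% PG / 12% CL.

Two isotope effects are modelled:

* **Per-deuteration** (extracts grown on deuterated substrate) swaps all
  *non-labile* H → D in both head and tail fragments.
* **Labile-proton exchange**: hydroxyl/amine hydrogens of the headgroups
  equilibrate with the solvent, so the head SLD is a linear function of the
  solvent D₂O fraction between its H₂O and D₂O endpoints. Default
  exchangeable-H counts are PE 3, PG 3, CL 2; they are data, not code — the
  fragment library is a plain TSV (`src/slbnr/data/fragments.tsv`) that users
  can extend.

Fragment formulas follow the common head/tail split for glycerophospholipids
(backbone, phosphate and carbonyls in the head; acyl chains minus the carbonyl
in the tails) with predominantly 16:0/18:1 chains. Partial volumes default to
the POPC literature values, V_head = 319 Å³ and V_tails = 937 Å³ (doubled for
CL). These defaults give a calculated hydrogenated tail SLD of −0.28×10⁻⁶ Å⁻²
and a per-deuterated tail SLD of 6.83×10⁻⁶ Å⁻² — deliberately *not* forced
onto any particular fitted literature value; fitted SLDs in the field depend
on each study's volume conventions, which is exactly why the fit exposes a
bounded additive SLD offset (below) rather than trusting the calculation
blindly.

## Reflectivity engine

Reflectivity of a slab stack — semi-infinite Si fronting (ρ = 2.07), SiO₂ and
film slabs, semi-infinite aqueous backing — is computed with the Abeles
characteristic-matrix method. For each layer n the perpendicular wavevector is
k_n = sqrt((Q/2)² − 4π(ρ_n − ρ_fronting)), taken on the complex branch below
the critical edge; each interface contributes the Fresnel coefficient
r_n = (k_n − k_{n+1})/(k_n + k_{n+1}) damped by the Névot–Croce factor
exp(−2 k_n k_{n+1} σ²); the 2×2 layer matrices are multiplied from the
substrate outward and R = |M₁₀/M₀₀|², clipped to [0, 1] at the 10⁻¹² level.
Névot–Croce damping (rather than error-function sub-slicing) is the standard
choice for σ well below the layer thickness; when a roughness exceeds the
thinner adjoining layer the stack warns but does not fail.

Numerical conventions worth knowing:

* **Zero-thickness slabs are dropped before evaluation.** With interface-local
  roughness damping, a zero-width layer would still perturb its neighbours'
  Fresnel coefficients; treating "no thickness" as "no layer" makes insertion
  of a d = 0 slab exactly inert, which is both the physically sensible limit
  and a tested invariance.
* **Solvent penetration** φ is resolved before the optics:
  ρ_eff = φ·ρ_solvent + (1−φ)·ρ_layer.
* **Resolution smearing** convolves R(Q) with a Gaussian of FWHM dQ/Q
  (σ_Q = (dQ/Q)·Q/2.355) by 21-point quadrature over ±3.5σ, re-evaluating the
  exact model at each abscissa rather than interpolating. Default dQ/Q = 0.08,
  typical of a time-of-flight reflectometer; the instruments in question quote
  only their wavelength band and angles, so this is a package default, not a
  measured value.
* Fixed substrate SLDs: Si 2.07, SiO₂ 3.47 (×10⁻⁶ Å⁻²); the SiO₂ thickness
  (12 Å) and roughness (3 Å) stand in for a bare-substrate characterization
  and are held fixed during bilayer fits.
* No incoherent background is part of the optics; a constant additive
  background per dataset (default 10⁻⁷) is carried by the model and the
  generator symmetrically.

The engine is validated against an independently coded Parratt recursion on
random stacks (relative 10⁻¹⁰), against the analytic single-slab closed form,
the analytic critical edge, and several structural invariances.

## Bilayer parameterizations

**Three-layer model** (hydrogenated extracts): SiO₂ | water gap (φ = 1) |
head | tail | head | solvent. Free parameters: water-gap thickness, head
thickness d_h, tail thickness d_t, tail solvent fraction φ_t, one global
roughness applied to every interface including the backing, and bounded
(±0.5×10⁻⁶ Å⁻²) additive offsets on the head and tail SLDs. The two head
slabs are literal copies (symmetric bilayer). The head solvent fraction is
**never fitted**: requiring equal area per molecule in the head and tail
regions, A = 2V_tails/(d_t(1−φ_t)) and φ_h = 1 − V_head/(d_h·A), fixes it.
With the POPC default volumes and the published structure (d_t = 27 Å,
φ_t = 12%, d_h = 7 Å) this coupling gives A ≈ 78.9 Å² and φ_h ≈ 0.42 — higher
than the ~35% head hydration printed alongside that structure, which implies
the original analysis used somewhat different fragment volumes. The volumes
are therefore configurable and the discrepancy is left visible rather than
absorbed; the recovery targets never involve φ_h. If the coupling leaves
[0, 1] the model warns, clamps for stack construction, and reports the
violation magnitude, which the objective penalizes.

**One-layer model with a sparse vesicle layer** (per-deuterated extracts):
SiO₂ | water gap | bilayer slab | [vesicle water gap | dilute vesicle bilayer]
| solvent. The vesicle extension models a small population of unruptured
vesicles sitting on the SLB; only their flat bottom is optically coherent, so
they appear as a second bilayer slab whose thickness and SLD are *tied* to the
SLB's, at solvent fraction 1 − c where c is the coverage. The extension can be
switched per contrast (vesicles may be rinsed away by a solvent exchange); the
vesicle slabs carry a fixed 10 Å roughness, but the vesicle water gap's lower
interface is the SLB's own top surface and keeps the fitted SLB roughness —
this also makes R(c) continuous as c → 0, which matters for the optimizer
(a discontinuity there manufactures a spurious χ² valley).

Structural parameters are shared across contrasts by construction; only the
solvent SLD and the exchanged head SLD differ between contrasts.

## Co-refinement

The objective is χ² = Σ_contrasts Σ_Q ((R_model − R_obs)/dR)², with 5%
relative weights where a dataset carries no dR, plus a penalty residual
(scale 10³) for area-coupling violations. Optimization is bounded
least squares (scipy trust-region reflective, Jacobian column scaling) from
n_starts = 8 initializations jittered uniformly by ±20% around the starting
values and clipped to bounds; the lowest-χ² result wins, with exact ties
broken by lexicographic parameter order so a (data, seed) pair maps to one
result. Parameter uncertainties use a residual bootstrap by default (resample
weighted residuals with replacement around the best-fit curves, refit, take
central 68% percentiles; 100 resamples by default) — the original study's
uncertainty procedure is not specified beyond fit quality, so a standard,
reproducible choice is documented instead. A coarse 1-d Δχ² = 1 profile is
available as an alternative. Model variants are compared by reduced χ²; the
richer model is flagged "necessary" when it improves reduced χ² by ≥1.3×
(configurable).

## Synthetic data generator

The generator emulates time-of-flight solid–liquid reflectometry with a
2–30 Å wavelength band at two incidence angles (0.624°/3.78°, or 0.8°/3.2°
for the second instrument geometry), i.e. Q ≈ 0.0046–0.41 Å⁻¹, on a
logarithmic grid (60 points/decade by default) with dQ = (dQ/Q)·Q. The
recovery studies trim to Q = 0.005–0.3 Å⁻¹. Noise is multiplicative Gaussian,
R·(1 + ε) with ε ~ N(0, σ_rel), σ_rel = 0.03 by default, plus a 10⁻⁷
background; the quoted uncertainty is dR = σ_rel·R + background. One child
random stream per contrast keeps series seeded and reproducible.

What it does **not** emulate: Poisson counting statistics (so dR is smooth in
Q rather than flux-shaped), wavelength-dependent flux and detector efficiency,
inter-contrast normalization errors, sample misalignment, or imperfect
substrate characterization (the SiO₂ layer is assumed known). Passing
recovery tests therefore demonstrate that the estimator is unbiased and
well-conditioned under idealized counting conditions with a correctly
specified model family — not that real instrument systematics are harmless.

The three bundled ground-truth structures are the published fits for the
hydrogenated extract deposited at 50 °C (three-layer: 8 Å gap, 7/27/7 Å at
12% tail solvent, σ = 4 Å, head SLD 1.55/2.16, tail −0.55) and the
per-deuterated extract deposited at 50 °C (9 Å gap, 41 Å slab at 6% solvent,
SLD 6.66, σ = 7 Å, 4% vesicle coverage behind a 14 Å gap, vesicles in the
H₂O contrast only) and at 25 °C (6 Å gap, 42 Å at 3%, SLD 6.60, σ = 7 Å, 3%
vesicle coverage in all three contrasts). For the 50 °C deuterated structure
the source's table and prose disagree on the SLB roughness (10 vs 7 Å); the
preset follows the prose value, consistent with the water-gap roughness in
the same table. In the recovery protocol the generator and the fitter share
the preset's SLD anchors (the truth offsets are zero but the offsets remain
fitted): the re-enacted question is whether multi-contrast co-refinement
recovers the *structure*, with the SLD calculation validated separately
against its own windows, because composition-calculated anchors depend on
volume conventions that the original analysis did not publish.

## Problem sizes

The bundled studies use 108 points per contrast (four contrasts, 432 points)
per fit, 8 multistart optimizations per co-refinement, 50–100 bootstrap
resamples for intervals, and 20 noise replicates per structure in the
replicate study; a co-refinement takes a few seconds on one core.

## Known limitations

* Slab models only: no asymmetric leaflets, no LPS-specific headgroup layer,
  no off-specular or magnetic scattering.
* The composition calculator works at lipid-class resolution; acyl-chain
  speciation (cyclopropane chains etc.) enters only through the chosen
  default fragment formulas.
* The vesicle layer is a two-slab effective model; real bound vesicles are
  polydisperse and curved, and only their SLB-aligned flat region is captured.
* Multistart local least squares is not a global optimizer; for deliberately
  degenerate setups (single contrast, strongly correlated SLD/φ parameters)
  the multistart spread should be inspected (`FitResult.start_params`).
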