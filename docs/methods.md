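# Methods

This note records the models implemented in `protonpath`, their
assumptions, the numerical choices behind them, and what the synthetic
fixtures do and do not establish.

## Unit system

Fixed globally and not configurable: lengths in Å, charges in e, energies
in kcal/mol, potentials in kcal/(mol·e), temperatures in K.  The
electrostatic constant is k_e = 332.0636 kcal·Å/(mol·e²); the gas constant
R = 1.9872×10⁻³ kcal/(mol·K).  A single unit system removes a whole class
of silent conversion errors at the cost of flexibility nobody using these
estimators needs.

## Continuum electrostatics (`protonpath.pb`)

### Model

The solute (protein plus any bound substrate) is one dielectric medium with
ε_in = 2; solvent is another with ε_out = 80.  The boundary between them is
the molecular (solvent-excluded) surface traced by a 1.4 Å probe.  Mobile
monovalent ions at 0.15 M screen the potential linearly
(linearized Poisson–Boltzmann), except inside an ion-exclusion (Stern)
shell of 2.0 Å around the solute where κ̄² = 0.  The low interior dielectric
is appropriate when conformational relaxation upon (de)protonation is
modelled explicitly by separate end-state ensembles rather than folded into
the dielectric response.

The discrete operator is the flux-conserving 7-point stencil

    Σ_f ε_f (φ_nb − φ_c) − κ̄² h² φ_c = −4π k_e q_c / h

with κ̄² carrying the ε_out factor (κ̄² = 4π k_e Σcᵢzᵢ²/RT in the package
units, so the bulk screening length is κ = √(κ̄²/ε_out); at 0.15 M and
300 K this gives a Debye length of 7.9 Å).

### Numerical choices

* **Grid.**  Default spacing 0.4 Å (0.6–0.8 Å are useful for quick scans);
  the auto grid pads the solute bounding box by max(30 %, 10 Å) per side.
  Single level, no focusing.
* **Surface construction.**  Inflate-by-probe / erode-by-probe on a signed
  distance field.  The erosion distance is evaluated with sub-grid
  accuracy: every near-boundary solvent-accessible node carries its exact
  continuum clearance F ≥ 0 to the inflated surface, a ball of radius F
  around it is provably accessible, and dist(x, accessible) =
  min_y (|x−y| − F(y)).  Node-lattice-only erosion overestimates this
  distance by up to half a grid diagonal and biases the cavity ~0.07 Å
  outward — enough to spoil a 3 % Born benchmark at 0.4 Å.
* **Face dielectrics.**  Harmonic average of the media along each edge,
  weighted by the edge's interior fraction under linear interpolation of
  the signed surface distance.  This reduces to the plain two-node harmonic
  mean when the interface crosses mid-edge and is the standard second-order
  smoothing of the dielectric jump.  With it, the Born-ion benchmark
  (q = 1 e, a = 2 Å, ε 2/80, closed form −40.47 kcal/mol) converges
  2.0 % → 0.97 % → 0.39 % at 0.8/0.6/0.4 Å, monotonically.
* **Charges.**  Trilinear (cloud-in-cell) spreading; no atom ever divides
  by zero regardless of where it sits relative to the nodes.
* **Boundary condition.**  Dirichlet Debye–Hückel superposition
  Σ_j k_e q_j exp(−κ r_j)/(ε_out r_j) on the six outer faces.
* **Solver.**  Red–black successive over-relaxation, ω from the largest
  grid dimension; iteration stops when the max-norm update falls below the
  tolerance *and* the diagonally scaled residual confirms it (update-only
  stopping can fire early on slow modes).  Default tolerance 10⁻⁶
  kcal/(mol·e); non-convergence raises with the final residual.
* **Reaction-field energies.**  ½ Σ q_i (φ_solv(i) − φ_ref(i)) with the
  reference solve on the *identical grid* using ε_in everywhere and κ = 0,
  so the grid self-energy of the spread charges cancels exactly.  The
  remaining discretization sensitivity to sub-grid placement is below 1 %
  for 0.2 Å solute translations.

### Known limitations

No nonlinear PB, no multigrid or focusing, no analytic SES triangulation.
The solver is designed for ≲130³ nodes — active-site models and benchmark
fixtures, not whole-protein production runs.

## Protonation free energies and pKa shifts (`protonpath.lra`)

The linear-response estimate ΔG = Σ δq_i (⟨V_i⟩_A + ⟨V_i⟩_B)/2 is exact
when the potential on each site atom fluctuates as a Gaussian with
state-independent variance; that is precisely the regime the synthetic
generator realises, which makes it a sharp oracle rather than a soft
regression test.  Conventions:

* δq is **protonated minus deprotonated**, so Σδq = +1 per site, and a
  positive ΔG means the environment stabilises the protonated form.
* The pKa shift uses deprotonation free energies in both media:
  pKa(prot) − pKa(solv) = (ΔG_prot − ΔG_solv)/(2.303 R T).  The solvent
  side must be computed with the *same* procedure on the bare model
  compound over matching conformations — with ΔG_solv simply set to zero
  the grid and close-neighbour self-terms do not cancel and the shift is
  meaningless (see `analysis/02`).
* Default T = 300 K.  Uncertainties by 5-block averaging over snapshots;
  with fewer snapshots than blocks the standard error is reported as 0
  rather than extrapolated.
* Combining a relative ΔΔG with a model pKa into an "absolute" free energy
  at a reference pH uses ΔG_abs = ΔΔG + 2.303 R T (pKa_model − pH).  This
  is a package convention; other sign/reference choices exist in the
  literature and none is canonical.

Ranking protonation states re-references to the minimum and breaks ties
lexicographically, so the output is deterministic for degenerate inputs.

## Chain-of-states paths (`protonpath.neb`)

* 20 images by default; endpoints are bitwise-fixed throughout.
* Energy-weighted upwind ("improved") tangents prevent the kinks the naive
  bisector tangent produces on ridges.
* The band relaxes under perpendicular true force plus tangential spring
  force (spring constant 1.0 by default) with FIRE; every `reparam_every`
  (10) iterations the images are redistributed to equal arc length along a
  cubic spline through the current band.  Linear redistribution is not
  good enough: it re-injects O(Δs²) positional error each cycle, which on
  the Müller–Brown surface permanently floors the perpendicular force above
  any tight tolerance.  The spline's O(Δs⁴) error removes that floor, and
  the FIRE velocity survives reparameterization.
* Convergence is judged on the RMS *perpendicular true force* over interior
  images, the quantity that actually vanishes on a minimum-energy path.
  Reaching `max_iter` is reported on the returned path, not raised.
* Climbing-image refinement runs only on an already-optimized band: the
  highest image feels the true force with the tangential component
  inverted, relaxed by FIRE until |∇E| ≤ 10⁻⁶.  If the path maximum is an
  endpoint (barrier-less profile) the endpoint is returned unchanged.
* Force tolerances are surface-scale-relative.  The packaged two-channel
  surfaces (energy scale ~1–5) converge at 10⁻⁴; Müller–Brown (forces of
  order 10²) uses 0.5 in the analysis scripts — the saddle accuracy is set
  by the climbing image, which refines to 10⁻⁶ regardless.

Validation: the 1-D quartic double well gives the 1.000 barrier to better
than 1 % with 20 images; the Müller–Brown saddle matches a brute-force
2000×2000 sublevel-set-connectivity oracle to 0.005 %, and the
finite-difference Hessian at the refined saddle has exactly one negative
eigenvalue.

## Path FEP and harmonic corrections (`protonpath.fep`)

The one-sided Zwanzig form is implemented exactly as defined — no BAR/MBAR
— because the estimator itself is the object of study; both-direction
consistency is available as a diagnostic by running the reversed path.
The exponential average is evaluated with a log-sum-exp shift, so finite
perturbation energies can never overflow.  Standard errors by 5-block
averaging.  Default ensemble size in the drivers is 10³–10⁵ samples per
image pair — enough for the Gaussian oracles' 3-standard-error bands at
desk scale; production molecular ensembles would be far larger.

Two properties are asserted unconditionally: Jensen's inequality
(ΔA ≤ ⟨ΔE⟩, exact for every sample set) and permutation invariance of the
estimate.

On the analytically solvable linear-coupling bath E(c, s) = c·s two
regimes matter and are easy to conflate: with a state-independent N(0, 1)
bath every increment is −β(Δc)²/2 (the per-increment closed form), while
sampling each image's own equilibrium bath N(−βc_i, 1) makes every
increment unbiased for the true A(c) = −βc²/2 difference, so only then do
profiles telescope and reversed paths negate.

The harmonic (RRHO) vibrational free energy uses mass-weighted normal-mode
analysis of a Cartesian Hessian in kcal/mol/Å² with masses in amu;
frequencies convert via √(kcal/mol/Å²/amu) = 108.59 cm⁻¹.  Imaginary modes
are counted and excluded; near-zero (roto-translational) modes are excluded
without being counted as imaginary.

## Synthetic fixtures (`protonpath.synth`) — what they do and do not show

Every generator is a pure function of its arguments and seed (one
`numpy.random.default_rng` stream), so fixtures are bitwise-reproducible.

* **Born ions** validate the full dielectric-boundary/solver/energy chain
  against a closed form.  They do not exercise irregular surfaces; the
  two-sphere re-entrant-neck test covers that qualitatively.
* **The linear-response ensemble** draws per-atom potentials from
  equal-variance Gaussians, where LRA is exact — a correctness oracle for
  the estimator, *not* evidence that real protein ensembles are in the
  linear-response regime.
* **The toy titratable site** (two disjoint δq sets on a ~20-atom scaffold)
  exercises the four-state bookkeeping and the full PB/LRA pipeline.  Its
  pKa shifts are large because bare ±0.9 e neighbours sit a few Å away at
  ε = 2 with no dielectric relaxation — physically coherent for the model,
  not representative of a real active site's magnitudes.
* **The two-channel proton-transfer pair** shares both wells (at (±1, 0),
  reaction energy −0.2) between the direct and relay surfaces by
  construction: the barrier hump W(x) = (1−x²)² has zero value and slope at
  the wells, so modulating it along the relay coordinate cannot move or
  tilt the endpoints.  The direct surface's channel lies on the transfer
  axis; the relay surface reduces the hump near relay coordinate y = 1, and
  the band discovers the detour on its own (the y-force on the axis is
  nonzero).  Default scales 5.0/1.0 give activation energies 5.15 and 1.52
  (ratio 3.4).  The pair demonstrates that the *pipeline* resolves a
  relay-vs-direct barrier ordering; it encodes no quantitative claim about
  any real enzyme's barriers.
* **Müller–Brown** is the standard 2-D transition-state benchmark; its
  `seed`-free construction and the unused `seed` argument of the surface
  pair exist only for generator-API uniformity.

## Problem sizes used by the shipped drivers

Chosen as the package's own desk-scale defaults: PB benchmarks on 61³–81³
grids (0.4 Å) with coarse 0.8 Å grids in the ensemble demos; 4–5 snapshot
frames per state in `analysis/02`; 10⁴ samples for the LRA oracle, 10⁵ for
the FEP oracle, 2×10³ per image in the profile driver; 20 images per band.
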