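# Methods

## The problem

Collagen fibrils give the cornea its mechanical stiffness, and their
angular distribution is not static: under sustained changes in the
strain regime — after injury, refractive surgery or keratoplasty —
fibril density redistributes towards the directions of higher strain.
X-ray scattering measurements on ex-vivo corneal strips under stepwise
uniaxial tension (0, 1.4, 2.8, 5 and 8 % axial strain) quantify this
redistribution.  `fibreo` implements the full chain from those angular
scattering profiles to a strain-coupled anisotropic constitutive model:
data reduction, trend fitting, the reorientation algorithm, and the
displacement-driven mechanical drivers used to exercise and validate
it.

## Angular conventions

A scan yields 256 azimuthal fibril-density readings at a uniform
spacing of 360/256 = 1.40625° (stored exactly; "1.4°" is a rounding).
Reading *j* (0-based) is taken at azimuth (j + 0.5)·1.40625°, a
half-bin offset chosen so that after point-symmetric folding the eight
fine axes aggregated into each of the 16 model orientations are centred
exactly on the bin centres θᵢ = π/32 + (i−1)·π/16.  With this
convention the loading axis (local angle 90°) falls precisely on the
boundary between orientation bins 8 and 9 and the transverse axis
between bins 16 and 1, matching the pairing (1,16), (2,15), …, (8,9)
used for symmetry averaging.

## Data reduction

1. **Normalisation.**  Ex-vivo tissue cannot synthesise collagen, so
   the total content at a point is constant; repeat-scan totals vary
   within about 12.7 % of their average from measurement noise.  Each
   profile is rescaled to total 1.0 (`total_one`), with a `mean_one`
   rescale (average density 1.0 across orientations) used for
   plotting-style comparisons and as the unit convention for trends.
2. **Folding.**  Fibril orientations are axial, so readings at θ and
   θ + 180° are averaged, leaving 128 unique axes.  Asymmetry beyond a
   tolerance (default 25 % relative) raises a warning but the mean is
   still taken.
3. **Reduction to 16 orientations.**  Groups of 8 consecutive axes sum
   into the 16 orientation bins (total content conserved exactly).
4. **Changes and symmetry.**  ΔK per orientation is the difference from
   the unloaded distribution; orientation pairs symmetric about the
   loading axis are averaged, leaving 8 unique pairs.
5. **Regions.**  The 40 scan points of a strip specimen form 5
   longitudinal groups of 8; mid-length symmetry pairs groups 1↔5 and
   2↔4, collapsing the strip to regions A (outer), B (intermediate) and
   C (central).

## Reorientation trend

Per orientation pair, the measured ΔK(ε) is simplified to a continuous
piecewise-linear function: zero below a 1 % strain threshold, a
constant slope up to the 5 % knee, and a reduced slope beyond (the
measured reduction averages about 64 %, i.e. a slope ratio of 0.36).
`fit_trend` performs a linear least-squares fit on the two-ramp basis,
expresses slopes in mean-one units (dividing by the mean unloaded
density so the trend is normalisation-independent) and projects the
result onto the conserving subspace (zero sum over orientations), which
absorbs residual noise.  Between sampled strains ΔK varies linearly by
construction; beyond 8 % (the data limit) the reduced slope is
extrapolated.

## Constitutive model

The strain energy is split isochorically:

    W = (J−1)²/D  +  C10 (I3^(−1/3) I1 − 3)
        + (1/16) Σᵢ Kᵢ [ W_f(I4ᵢ; μ1, γ1) + ½ W_f(I6ᵢ⁺; μ2, γ2) + ½ W_f(I6ᵢ⁻; μ2, γ2) ]

with W_f(I) = (μ/γ)((I3^(−1/3) I)^(γ/2) − 1) − μ ln (I3^(−1/3) I)^(1/2),
which vanishes with zero slope at the stress-free state.  Each fibril
term is active only when its own squared-stretch invariant exceeds 1
(tension gate, per orientation and per family); at the gate boundary
derivatives are evaluated one-sidedly from the tension side.

Two modelling choices deserve comment:

* **Balanced out-of-plane families.**  Interweaving lamellae are
  inclined about 15° to the tangent plane, crossing it both upwards and
  downwards with no chirality.  A single-sided +15° family carries a
  net through-thickness shear polarisation (Σ b⊗b has an xz moment):
  a homogeneous sheet under pure in-plane tension would then shear out
  of plane, and in a thin strip that spurious shear moment acts on
  near-zero-stiffness bending modes, making the equilibrium landscape
  unstable.  The out-of-plane energy therefore averages the two
  mirrored sub-families at ±15°, each gated on its own invariant
  (I6⁺, I6⁻).  The material is orthotropic in the loading frame, as the
  tissue is.
* **Placeholder stiffness constants.**  C10, μ1, γ1, μ2, γ2 (defaults
  0.03 MPa, 0.02 MPa, 40, 0.008 MPa, 30) are illustrative values of
  plausible corneal magnitude, NOT fitted to experiment; supply
  calibrated values for quantitative stress work.  Every bundled
  simulation is displacement-controlled, so the reorientation results
  do not depend on them.
* **Volumetric penalty.**  The penalty coefficient D defaults to
  1e-5 MPa⁻¹ (effectively incompressible), appropriate for hybrid
  (mixed) elements.  For the pure-displacement FE kernel the strip
  driver defaults to D = 1e-2: the incompressibility error stays below
  |J−1| ≈ 2e-4 — three orders of magnitude beneath the 1 % strain
  threshold that drives reorientation — while the tangent conditioning
  improves by three orders of magnitude and the solve is ~10× faster.

The Cauchy stress σ = (2/J) F (∂W/∂C) Fᵀ and the consistent tangent
dP/dF are implemented analytically and are cross-checked in the test
suite against central finite differences of the energy (1e-6 relative
on random tension states kept clear of the gate boundary).

## Reorientation algorithm

K is a *state function* of the current strain relative to the unloaded
reference — recomputed at every evaluation, never accumulated — because
the measured ΔK is interpolated linearly in strain with no history
variable (unloading retraces loading; no hysteresis is modelled).

1. Directional strains εᵢ = √I4ᵢ − 1 along the 16 in-plane directions.
2. For every direction j with εⱼ above the 1 % threshold, the trend
   table (gain lobe at the pair (8,9) around the loading axis) is
   rotated so the gain pair lands on bins (j, j+1) — 0-based entry k
   receives the table value at offset (k − j + 7) mod 16 — and
   evaluated at εⱼ.  Negative strains contribute nothing.
3. The 16 contributions are summed.
4. The conservation correction scales the sum by C1 = mean(K) (which
   converts the trend's mean-one units to the local normalisation) and
   removes its mean, so the corrected change sums to exactly zero.
5. K_new = K_ref + ΔK, clamped to non-negative and proportionally
   rebalanced so the total equals the reference total exactly; a
   warning is raised when clamping removes more than half of the
   transferred content (trend too large for the distribution).

Because the two-bin gain lobe is centred on the boundary between bins
j and j+1 rather than on the bin centre θⱼ, the superposed pattern
under a general strain state is symmetric about the loading axis only
to within half a bin (11.25°/2); the identity rotation at j = 8 and
exact one-bin equivariance are preserved.  Under any in-plane isotropic
strain the rotated copies cancel exactly and the update is the identity
map.

A structural property worth knowing: the uniaxial trend is *measured*
as the total observed change, but the algorithm *applies* it as a
per-direction kernel and superposes it over all directions.  Under a
uniaxial state roughly eight directions exceed the threshold, so the
superposed change is larger than the raw trend evaluated at the axial
strain.  This tension is intrinsic to the method; the validation metric
(below) absorbs it, and the synthetic generator exposes both
conventions (`mode="direct"` for emulating the uniaxial experiment and
recovering fitted trends exactly, `mode="superposed"` for observations
consistent with the numerical model).

## Mechanical drivers

* **Single element.**  A 10 mm cube under forced face displacements:
  case 1 (0.8/0.8 mm in X/Y), case 2 (0.8/0.4 mm), case 3 (0.8 mm in X
  only).  The deformation is homogeneous and diagonal, with the
  unprescribed stretches from a 1-or-2 variable zero-traction root
  find; reorientation is iterated to a fixed point per increment.
  Equibiaxial loading produces exactly zero reorientation; gains in
  bins 8/9 and losses in bins 1/16 increase strictly with strain
  anisotropy.
* **Strip model.**  14 × 3.5 × 0.5 mm, 20×2×2 8-node hexahedra (80
  elements, two layers through thickness), element regions A/B/C from
  the 5-group symmetric collapse.  Boundary conditions: axial restraint
  on the fixed end plus a minimal 3-2-1 lateral restraint, axial
  displacement (8 % nominal strain) on the far end with lateral
  contraction free; a fully clamped variant is available
  (`clamped=True`).  The free-lateral default makes the solution
  homogeneous away from the 3-2-1 constraints, so the mid-region axial
  strain equals the nominal strain essentially exactly.
* **FE kernel.**  Total-Lagrangian, analytic internal force and
  consistent tangent, mean-dilatation volumetric treatment
  (element-constant pressure at the volume-averaged J — the deviatoric
  terms depend only on isochoric invariants, so they integrate at the
  full 2×2×2 quadrature without locking; affine states give uniform J,
  hence an exact patch test).  Newton iterations are globalised by an
  energy Armijo line search with adaptive Levenberg regularisation
  (valid because the pure-Dirichlet problem minimises stored energy),
  with Jacobi-equilibrated, iteratively-refined direct solves; load
  steps bisect on failure.  Convergence requires the equilibrium
  residual to fall below 1e-8 of the gross nodal force scale (the
  magnitude of the element forces that cancel at equilibrium), floored
  by the material force scale C10·V^(2/3) so that near-zero-load
  increments terminate at round-off.  Reorientation couples in a
  staggered loop iterated to a fixed point within each increment.
* **Biaxial sweep.**  A material point under circumferential strain
  (default 5 %, along the bins-8/9 axis) and radial strain reduced by
  the requested circumferential/radial ratio, thickness traction free —
  a compact stand-in for the strain states next to a surgical
  tissue-removal boundary.  The near-axis density gain is zero at ratio
  1 and strictly increasing in the ratio.  It is monotone in the strain
  level only while both principal strains sit in the same trend
  segment: crossing the 5 % knee, the gain can dip, because the
  near-axis contributions slow to the reduced slope while the
  radial-side losses (at strain/ratio, still below the knee) keep
  growing at the full rate — a direct consequence of the piecewise
  linear kernel.

## Validation metric

`strip_validation` compares FE-predicted region distributions against
per-point observations at 1.4/2.8/5/8 % strain with the error
mean(|K_pred − K_obs| / K_obs) over orientations and strain levels.
Two flavours are exercised:

* the *round trip* (`strip_self_consistency`): observations generated
  from the identical trend at the FE's own region-mean strain states —
  errors are a few thousandths of a percent, showing the pipeline adds
  essentially no internal error;
* the *fixture validation*: observations generated independently at
  nominal strains with default repeat-scan noise — errors of roughly
  1.5–3 % per region, reflecting regional strain redistribution from
  heterogeneous stiffness and the finite-noise data, and guarded by an
  8 % regression gate.

## Synthetic data

The generator emulates the statistical structure of the real scans;
the raw experimental data are not publicly deposited, so all fixtures
are synthetic and labelled as such.

* **Profiles**: π-periodic wrapped-lobe mixtures (two orthogonal lobes
  on an isotropic background emulate the central cornea's preferred
  orientations), point symmetric by construction; noise is a uniform
  multiplicative total factor of half-width 0.127 (the reported
  repeat-scan variation; removed again by normalisation) plus
  independent 2 % per-bin jitter.  The per-bin amplitude is not
  reported experimentally and is a documented generator parameter.
* **Series**: nine specimen replicates (as in the experimental
  protocol) per strain level, averaged.
* **Trend fixture**: an approximate, non-authoritative digitisation of
  the measured behaviour — gains at pairs (8,9) and (7,10), losses
  growing towards (1,16), conserving, 1 % threshold, 0.36 slope ratio.
  Magnitudes are sized so that the superposed update keeps all
  densities positive up to 8 % strain for central-cornea-like
  distributions.
* **Strip dataset**: 40 points whose base anatomy varies smoothly and
  mid-length-symmetrically along the specimen.

What passing tests on these data do *not* show: recovery of the actual
experimental trend values (not published numerically), behaviour under
depth-dependent or peripheral-cornea anatomies, fibril-content growth
after keratoplasty (total content is conserved by construction), or
any viscoelastic/hysteretic response.

## Numerical choices and problem sizes

* Tolerances: normalisation and reduction conserve content to 1e-12;
  the update conserves totals to 1e-10 (including after clamping);
  stress/tangent vs finite differences 1e-6 relative; FE residual
  1e-8 relative; patch test 1e-8.
* Root finds use scipy's hybrid Powell method on D-scaled traction
  residuals with the previous increment as the initial guess.
* Default load schedules place increments on the measurement strains
  (1.4/2.8/5/8 %); increments are a numerical aid only, since K is a
  state function of strain.
* Bundled problem sizes: the strip runs 80 elements (20×2×2) by
  default with a 40×4×4 (640-element) density-doubled mesh in the
  refinement study; the trend-recovery study uses 50 seeded replicates
  of 9-specimen series.  The full-eye geometry constants (corneal
  radius 7.8 mm, CCT 0.545 mm, etc.) are not modelled: whole-globe
  simulation is out of scope, and the biaxial strain-ratio sweep serves
  as the material-point surrogate for the tissue-removal scenarios.

## Known limitations

* The half-bin skew of the rotated gain lobe (above) breaks exact
  mirror symmetry of the superposed pattern about an arbitrary
  principal axis; all conservation and equivariance properties are
  exact.
* The tension gate switches on the raw invariant (I4, I6), so at
  J ≠ 1 the energy has an O((J−1)²) discontinuity at the gate; with
  near-incompressibility this is numerically negligible but makes the
  energy only piecewise smooth.
* The exact functional form of the conservation coefficient in the
  source method is ambiguous; the mean-density scaling with
  mean-removal (a projection that preserves the change pattern) is
  implemented.
* Only in-plane strains (I4) drive reorientation; out-of-plane
  stretches contribute stiffness but no density transfer.
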