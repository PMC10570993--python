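# Methods

This note documents the model npcsim implements, the defaults it ships,
the numerical choices behind them, and what the synthetic study
conditions do and do not show about real data.

## Model structure

A *reference unit* holds the fluorophore attachment sites of one of the
`s` rotationally symmetric spokes of an NPC: per site an axial position
z (nm), a radius r (nm) from the central axis, an angle α (rad) relative
to the unit's other sites, and a subcomplex tag (CR, BRCR, IR, BRNR,
NR).  Tables derived from pseudoatomic structural models use exactly
this schema (lengths may be declared in Å and are converted to nm on
load, ×0.1).  Up to six (nucleoporin, terminus) channels can be
selected; the band angles are offset so the single-channel mean α, the
reference channel's mean α, or the pooled mean α is zero.  Assembly
reflects the selected sites `s` times around the axis at x = y = 0 with
angular offset 2π/s, producing m = g·s nodes.

Angle convention: α is counter-clockwise in the x–y plane viewed from
the cytoplasmic side; the cytoplasmic side is +z.  Subcomplex
membership is an input column, never inferred from z, which avoids
silent misassignment for unusual label sets.

The shipped `default_two_ring_ru()` (also available as the synthetic
stand-in table `data/synthetic_two_ring.csv`) is a two-band geometry
emulating a C-terminally tagged Nup96 label set: lateral radius
53.7 nm, one band in the CR at z = +25 nm, one in the NR at −25 nm.
All tests and default experiments run on synthetic units like this one;
tables for real depositions can be generated with the optional
`scripts/extract_reference_unit.py` helper (gemmi-based) and drop into
the same loader.

## Geometric variability

Any continuous parameter X may carry an SD; each simulated NPC then
draws X′ ~ N(X, σ²).  The discrete symmetry is never resampled.  Axial
operations act on *sides*: the subcomplex with the greatest mean z is
the CS, the least the NS; sandwiched subcomplexes follow with a weight
linear in their mean z (NS → 0, CS → 1).  With all labels on one
subcomplex, axial operations warn and no-op (measurements raise).

* **Height** (d, nm): z is affinely rescaled about the model mean z so
  that z̄_C − z̄_N = d.  The affine form realizes linear-in-z
  interpolation of sandwiched bands exactly and keeps the model
  centred; translating a single side would shift the model instead.
* **Twist** (θ, rad): the CS is rotated about z relative to the NS so
  the per-spoke difference of circular-mean angles equals θ; sandwiched
  bands rotate by the interpolated angle.  Circular means avoid wrap
  artefacts near ±π.
* **Tilt** (κ): each side's normal is drawn from a von Mises–Fisher
  distribution about +z (inversion sampling of the polar cosine;
  smaller κ = more tilt) and the side rotates rigidly about its own
  centroid.  Rotating about the centroid rather than the central axis
  keeps tilt decoupled from lateral shift; this was a genuinely open
  choice and is a documented convention of this package.  Sandwiched
  subcomplexes rotate by the weight-interpolated rotation vector.
* **Shift** (SD, nm): per side one (Δx, Δy) ~ N(0, SD²) translation;
  z untouched.
* **Radius** (r̄, nm): isotropic lateral scaling, so node spacing grows
  in dilated NPCs.
* **Elongation** (q ∈ (0,1]): nodes receive radial forces
  f_e,i = k_e · (ρ_ellipse(φ_i − φ₀) − r_i) toward an ellipse of the
  circle's area (semi-axes r̄/√q, r̄√q) at uniform random orientation
  φ₀; the forces join the stochastic forces before radialization.  The
  gain k_e = 1.0 was calibrated once against the default spring system:
  relaxation under elongation forces alone reproduces the requested
  axis ratio within 5% at q = 0.8 (measured 0.800 on 20-NPC means).
* **Symmetry** (s): the geodesic (arc) distance between adjacent spokes
  is held constant — r̄ scales by s_new/s_old — and each band keeps its
  absolute offset from r̄, so 9- and 10-fold pores come out wider.  The
  chord-length interpretation (scaling by sin(π/8)/sin(π/9)) would give
  nearly the same factor; the arc is the geodesic on a circle, so it is
  the reading used.

Order of application per NPC: symmetry → radius → height → twist →
tilt → shift → (elongation + stochastic forces via springs) → axial
offsets.  Discrete/scaling first, rigid motions next, force-based last;
the order affects results and is fixed as part of the contract.

## Spring systems and irregular deformation

Each band is an independent spring system: radial springs anchor the s
nodes to the central axis (representing the nuclear envelope),
circumferential springs connect every node to its 2h nearest same-band
neighbours (protein–protein contacts).  h = 2 by default: larger h
costs compute, h = 1 gives overly jagged shapes.  Stiffnesses follow
k = K/ℓ₀ per circumferential spring (shorter springs are stiffer, as
required) with k_r = half the weakest circumferential stiffness, so
radial springs are softer than any circumferential one.  The scale
K = 106.0 is calibrated so a uniform radial force of 10 dilates the
default ring by 2 nm: the analytic ring stiffness is
k_eff = K/r · [1/(4 sin(πh/s)) + 2 Σ_{h'=1..h} sin(πh'/s)], giving
K = 5·53.7/2.53313.  Forces are therefore expressed in units of
(stiffness · nm); only ratios of force to stiffness matter for the
resulting displacements.

Scalar forces over all m nodes are one draw from N(0, cov′) with
cov′ = (Dmag/3)² · exp(−d²/2σ²), σ = 0.5·r̄ by default, distances taken
after replacing every node's lateral radius by the global mean r̄
(radius equalization keeps adjacent bands concentric and correlated
even when their radii differ).  Sampling one joint field across all
bands keeps deformations continuous between bands.  The scalars are
radialized — f⃗ᵢ = fᵢ · x̂ᵢ, z-component 0 — which exerts no net torque
and hence cannot rotate or flip the model.

Equilibrium is found by direct minimization of
U = Σ ½k(ℓ−ℓ₀)² − Σ f⃗·x⃗ over the lateral coordinates (z frozen):
damped Newton with the analytic spring Hessian, falling back to
L-BFGS + Newton if a step fails.  The per-node residual force must fall
below 1e−6 or the run aborts with a convergence error.  Minimization is
an equivalent, tolerance-controlled replacement for integrating damped
oscillations to their static fixed point.

Axial offsets are drawn exactly like scalar forces (same kernel,
magnitude Omag, default Dmag/2) from an independent stream and added to
z with no spring interaction — lateral and axial deformation are
deliberately decoupled.

## Feature extraction

Band, subcomplex (pooled bands), and whole-NPC features come from 3D
circle and ellipse fits: a total-least-squares plane (normal = least
variance direction, oriented toward +z), an in-plane algebraic fit
(Kåsa circle; direct conic ellipse fit), and geometric Gauss–Newton
refinement in-plane.  RSS is the sum of squared shortest 3D distances
(in-plane gap plus out-of-plane offset), so out-of-plane irregularity
counts.  The ellipse orientation is reported against the projected
global +x axis; the SVD basis itself aligns with the data's principal
axes and would degenerate to ~0.  In-plane point-to-ellipse distances
use a clamped Newton iteration on the parametric angle of the nearest
point.  Whole-NPC circle radii average the g band circle fits (not
ellipse-derived radii).  Twist and height mirror their setters; tilt is
the angle between each side's fit normal and +z.

Degenerate inputs: fits need ≥ 3 non-collinear (circle) or ≥ 5
(ellipse) points; bands thinned below that by labelling efficiency
yield NaN records rather than failing the run.

## Randomness and reproducibility

One master seed derives named, independent streams (parameter draws,
forces, axial offsets, tilt, shift, elongation orientation, labelling),
each additionally keyed by NPC index.  Toggling one variability type
never perturbs another's draws; identical config + seed gives
byte-identical CSVs (the metadata timestamp is the only varying field).
Experiment cells derive sub-seeds from the master seed through a
dedicated spawn key, kept below 2³¹.

## Study conditions and problem sizes

The radius sweep runs 3 × 3 cells (model radius SD 0/1/2 nm × Dmag
1/10/20 nm) with 1000 NPCs per cell on the default two-ring unit, and
its dataset mean radius moves by well under 0.5 nm across cells
(measured spread ≈ 0.1 nm).  The class datasets cover eight presets:
unmodified reference, smaller radius (−5 nm), smaller CR–NR distance
(−10 nm), elongated (q = 0.8), 14° twist, 9-fold symmetry, shifted
sides (SD 3 nm), and independently tilted sides (κ = 50).  The 14°
twist and the 9-fold symmetry are literature-reported magnitudes; the
other preset magnitudes are this package's documented defaults, chosen
to be clearly visible without node overlap, and are plain YAML for
editing.  The two-mode twist scenario (9.6° vs 14°) ships as a worked
acceptance computation.  Monte-Carlo checks in the test suite use
10⁴–10⁵ draws with 4–5 standard-error tolerances.

## What the synthetic conditions do not show

The generator emulates label-site geometry, parametric variability, and
coherent irregularity — not photophysics (blinking, localization error,
background), non-specific labelling, nuclear-envelope curvature, or
inter-pore interactions.  Passing tests therefore validate the
simulator's contracts and the feature extractors on known ground truth;
they do not certify performance on real SMLM images, and comparisons
with real radius variability enter only through a user-supplied real
SD in the ratio sd_sim/sd_real − 1.  The spring model is a light-weight
phenomenological device for generating plausible irregular shapes, not
a predictive mechanical model of the pore; stiffness values are
calibrated conventions, not measured constants.

## Known limitations

* Bands are deformed laterally only; axial irregularity is additive
  offset without spring coupling.
* Whole-model or inter-band spring coupling is deliberately absent;
  band continuity relies on force correlation alone.
* The per-NPC elongation gain is calibrated at the default geometry;
  strongly different radii or stiffness configurations change the
  achieved axis ratio (the q-monotonicity is unaffected).
* `change_symmetry` assumes the reference tables describe an 8-fold
  pore.
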