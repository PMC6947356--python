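# Methods

## Scope and intent

`pfjsim` is a desk-scale surrogate for a volumetric finite-element study of
the patellofemoral joint: rigid bones, thin deformable cartilage layers,
and a tension-only ligament apparatus, solved quasi-statically. It is built
to compare MPFL reconstruction techniques against the intact knee on a
*common synthetic geometry*, not to predict patient-specific magnitudes.
Contact-pressure results should therefore be read ordinally (which
technique loads the cartilage more), while graft stresses are quantitative
within the stated tolerances.

## Joint geometry

The femoral trochlea is a surface of revolution about the flexion axis
(x = lateral, y = anterior, z = proximal; origin on the axis): radius
profile `R(x) = R_c + w(|x|)` where `w` is a V-rise of wall angle
`(180° − sulcus)/2` with a 3 mm parabolic blend at the sulcus and a cap at
the groove depth (the condylar crests). The patellar articular surface is
the congruent wedge with its median ridge seated in the sulcus; the Wiberg
ratio sets the medial/lateral facet extents. Two deliberate mismatches
produce a centre-weighted contact patch instead of degenerate full-face
contact: the patellar facets are 1° steeper than the groove walls, and the
patellar sagittal radius exceeds the condylar radius by 2 mm. With the
default 0.3 mm approach this engages roughly the central two-thirds of the
facets.

The patella travels along the condylar arc by rotation about the flexion
axis at 0.7 patellar/knee flexion (a standard in vivo tracking ratio), with
the patellar station at −15° (from anterior) at full extension; 40° of
knee flexion is the reference pose. Defaults: sulcus 138°, groove depth
5.5 mm, condylar radius 32 mm, patella 42 × 32 mm, Wiberg ratio 0.4,
cartilage 3 mm per layer, 5000 faces per surface. Anchor positions are
anatomically motivated: the MPFL femoral point sits essentially on the
flexion axis at the medial epicondyle (near-isometry), the AMT pulley
12 mm proximal and slightly posterior of it, the MQTFL attachment on the
medial third of the quadriceps tendon 14 mm above the patellar centre, the
patellar MPFL points on the superomedial border. These were fixed once,
before any result comparison, and are not fitted quantities.

Penetration is evaluated analytically: the signed, slope-corrected radial
distance of patellar face centroids to the revolved profile — exact for
this surface family and smooth, which the Newton solver relies on. The
triangulated meshes exist for integration weights (face areas), pressure
reporting, and export (legacy VTK and OBJ).

## Ligament apparatus

All elements are straight tension-only springs between one femur-fixed and
one patella-fixed anchor. Study kinematic inputs come from measured
attachment-distance tables per technique (anatomic, AMT superior/inferior,
MQTFL columns at 0/30/40/60/90/120°), **not** from the synthetic geometry;
the geometry contributes only force directions and moment arms. Pretension
at angle θ is `ΔL(θ)·K` with `ΔL = L(θ) − L(40°)`, implemented by
presetting each element's slack length at the baseline-seated pose so its
initial tension equals the pretension; during the equilibrium solve the
tension relaxes (or grows) as the patella displaces.

The distance tables carry per-angle tension/slack markers which are not
fully consistent with the length differences for the AMT inferior bundle
(marked under tension at 0/30° though shorter than reference, marked slack
at 60/90° though longer). Where the marker and the sign disagree the
implementation takes whichever predicts *no* tension: the inferior bundle
is slack at all study angles. This keeps the slack pattern — graft tension
at exactly {0°, 30°} in every configuration — which the source asserts
explicitly.

Bundle bookkeeping: the native MPFL is one fan-shaped ligament whose
measured stiffness (12 N/mm) describes the whole structure, so its two
bundles carry K/2 and A/2 each; a reconstruction graft is a discrete
tendon strand whose measured stiffness describes the strand, so each limb
of a looped graft (static technique, AMT pulley) carries the full K and
full A. Either way the per-bundle pretension stress is `ΔL·K/A`. The
lateral retinaculum (K = 2 N/mm) uses the active technique's elongation
profile (superior bundle for AMT), per the source's equal-length
assumption. The four quadriceps and two patellar-tendon tethers carry zero
pretension at each study pose and act purely as displacement restraints;
no quadriceps muscle force is applied.

The graft cross-section is unreported in the source; it is closed by
calibrating `A = ΔL·K/σ = 2.5·12/8.85 ≈ 3.390 mm²` on the intact-knee 0°
row and shared by all MPFL-type and LR elements. Reported stress is axial,
`σ = F/A`; beam bending of the MPFL/LR is neglected (no section geometry
is available), and the recorded Poisson ratio of the tendons is unused by
axial elements.

## Contact and equilibrium

Cartilage is an elastic foundation: `p = M δ/(t_f + t_p)` with the
confined-layer modulus `M = E(1−ν)/((1+ν)(1−2ν)) = 37.93 MPa` for
E = 10 MPa, ν = 0.45, and the two 3 mm layers in series. Tangential
traction is regularized Coulomb friction, `|τ| ≤ μ p` with
`tanh(|s|/s₀)` smoothing (μ = 0.02, s₀ = 0.01 mm, slip measured from the
seated pose); at this μ the solution is friction-insensitive (< 5 % effect
on peak relative pressure, verified in the suite).

Protocol per case and angle:

1. **Seat**: translate the patella 0.3 mm along the inward radial at its
   centre. This approach DOF is *held* for the rest of the solve — it
   stands in for the unmodelled muscle/capsular compression, and the
   baseline pressures it generates are what the relative fields subtract.
2. **Baseline**: zero the QT/PT tether tensions at the seated pose, then
   equilibrate the remaining 5 DOFs (2 in-surface translations + 3
   rotations) under contact + tethers. This field is the subtraction
   baseline and is identical across techniques.
3. **Pretension**: assemble the technique's elements with slack lengths
   set at the baseline pose, ramp the pretension in 10 increments, and at
   each increment solve the residual wrench to |F| < 1e-4 N and
   |T| < 1e-3 N·mm by damped Newton (forward-difference Jacobian,
   truncated-SVD step for unresisted directions, 0.25 mm trust region,
   backtracking line search, ≤ 200 iterations, warm-started between
   increments). Non-convergence flags the case row; it never aborts a
   study.
4. **Report**: per-face relative pressure `max(p_after − p_baseline, 0)`,
   its maximum, and max MPFL/LR stress from the relaxed element forces.

Because the held-approach reaction is large (~0.7 kN), torque balance is
reference-point dependent; the constraint point fixed at the seating step
is reused verbatim by the pretension solve, which makes "no added
elements → baseline solution" exact.

One numerical caveat: the generalized residual is only C⁰ at contact-patch
edges and slack/taut transitions; the trust region plus line search handle
the kinks, and every shipped configuration converges to tolerance.

## Study pipeline

Seven configurations (intact native; static anatomic × {semitendinosus,
gracilis}; AMT pulley × {semitendinosus, gracilis}; MQTFL ×
{semitendinosus, tibialis-posterior allograft}) × five angles = 35 rows,
deterministic for a given config (byte-identical CSV on rerun, provenance
block with config hash / seed / version). Technique comparisons use the
semitendinosus rows as the per-technique representatives — it is the one
graft tested with all three reconstructions, and the allograft's stiffness
(513 N/mm) would otherwise dominate the MQTFL technique value; the "like
the native knee" wording is quantified as a ±20 % band on peak relative
pressure (configurable).

The cohort generator perturbs every length/angle parameter with an
independent normal of coefficient of variation `cv` (default 0.05, a
realistic anthropometric spread), truncated to the family's valid ranges,
seeded; it emulates between-knee geometric variability only — not
cartilage thickness/property variation, not shape-feature correlations,
and not dysplastic morphologies. Passing cohort tests therefore
demonstrates robustness of the technique *ordering* to moderate geometric
variation, nothing more.

## What the synthetic data can and cannot show

The generator reproduces the study *conditions* (materials, stiffnesses,
measured elongations, flexion protocol) on an idealized groove/wedge pair.
It cannot reproduce the reference study's CT-averaged articular shapes, so
absolute pressures and the finer per-angle pressure ratios depend on our
patch geometry. Two documented consequences, measured with the default
geometry:

- At 30° flexion the static (2 × 20 N) and MQTFL (30 N) pretensions are
  within ~25 % of each other, and the predicted peak relative pressures
  tie to within ~3 % (0.168 vs 0.173 MPa) — the static > MQTFL ordering
  reported at extension is not resolved at 30° on this geometry.
- The AMT-pulley graft tension at 30° is ~4× the native ligament's by the
  input tables themselves (0.1 mm × 100 N/mm vs 0.2 mm × 12 N/mm), so its
  peak relative pressure (0.045 MPa) cannot sit within ±20 % of the
  intact knee's (0.010 MPa); both are near zero on the absolute scale of
  the 0° fields (~2 MPa), which is the sense in which the dynamic
  technique tracks the native knee through flexion.

## Known limitations

- Linear-elastic, homogeneous foundation cartilage; no poroelasticity,
  depth-dependence, or volumetric stress output.
- No quadriceps loading or tibiofemoral joint; quasi-static, no dynamics.
- Straight-line elements: no wrapping of the AMT loop or quadriceps
  tendon; the MQTFL attachment transmits force rigidly to the patella.
- The shared calibrated cross-section makes all graft stresses exact
  multiples of their pretension forces; it is a closure, not a
  measurement.
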