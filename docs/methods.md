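# Methods

## Model and assumptions

`vertrom` treats a vertebral column as a chain of rigid bodies.  Each
vertebra is a set of labelled triangle surfaces (centrum, neural spine,
paired pre/postzygapophyses, paired cervical ribs) with three landmarks
(anterior and posterior centrum-face centroids, a dorsal reference) and an
orthonormal anatomical frame (anterior, left-lateral, dorsal).  The working
assumptions are:

* **Rigid, pairwise articulation.**  Joints rotate; they do not translate or
  twist.  By default each joint is manipulated pairwise — the anterior
  vertebra fixed in world space, only its posterior neighbour moving — which
  mirrors how such manipulations are done two models at a time on screen.  A
  `chain=True` mode propagates rotations down the column for whole-neck
  visual sweeps; it is not used for measurement.
* **Pivot placement.**  The centre of rotation is the midpoint of the
  segment joining the facing centrum-face centroids, an operational stand-in
  for the centre of the intervertebral disc in an amphicoelous joint.  It is
  computed from surface data only (no disc is modelled) and is held at the
  same relative location along the whole column.  In minimum-spacing mode
  the pivot is recomputed after gap collapse, so manipulation starts from
  the contacted configuration.
* **Contact as termination.**  Motion ends at bone-on-bone contact, defined
  as minimum inter-surface distance ≤ ε over the allowed part pairs, not as
  triangle intersection.  This emulates rigid bodies that cannot pass
  through one another while staying robust to mesh noise.  The resulting
  maxima are osteological bounds: soft tissue could make true mobility
  either smaller (capsules, ligaments) or larger (compliant discs).
* **One-sided lateral reporting.**  Lateral ROM is reported as a bend to one
  side (the right, by convention).  On bilaterally symmetric geometry the
  bilateral total is exactly twice this and is not reported separately.

## The search

`max_displacement` brackets the first contact with a coarse pre-sweep
(default 1° steps from 0°, taking the *first* contacted step so contact that
appears and then disappears cannot be skipped), then bisects the bracketing
interval to `tol_deg`.  The returned angle is the largest contact-free
rotation; the contact report just beyond it names the stopping part pair.
Conventions and edge cases:

* already in contact at neutral → 0° (the minimum-spacing trial starts in
  centrum contact, so this is a result, not an error);
* no contact up to the bracket (default 90°) → the bracket value with an
  explicit `bracket_limited` flag;
* angle of record is the commanded joint rotation.  `measure_line_angle`
  re-measures it the way screen captures are measured (lines along the
  centrum axes projected to the median or frontal plane, acute intersection
  angle, optional jittered triplicates) and serves to validate that
  protocol, not as the primary output.

Contact queries are exact vertex-to-surface distances (vectorized
point–triangle closest-point computation, both directions), with a KD-tree
vertex prescreen that discards triangles provably unable to attain the
minimum and a bounding-sphere sort that skips part pairs that cannot beat
the current best.  Interpenetration is detected by a fixed-direction
ray-parity test on the candidate vertices and reported as a negative
distance.  The only approximation relative to true surface–surface distance
is the mesh discretization itself; on icosphere fixtures the inward sag is
computed analytically and folded into every oracle tolerance.

## Trials

* **PCVM** (paired cervical vertebral mobility): neutral pose at the
  preserved spacing; all part pairs may stop the search.
* **MISM** (minimum intervertebral space mobility): each posterior vertebra
  is translated along the chain axis until the centrum–centrum distance lies
  in [0, ε_reduce] (bisection on the translation; default ε_reduce = 1e-3 mm),
  with the applied translations recorded so the preserved pose is
  recoverable.  Centrum–centrum contact is then excluded from the stopping
  rule.  Excluded-pair interpenetration at the accepted angle is measured
  and reported against `penetration_cap` (default 1 mm); it never terminates
  the search, it only flags entries where the rigid-body idealization is
  being stretched.

Joints touching damage-masked vertebrae are computed but flagged; joints for
which the rule leaves no part pair at all (e.g. MISM on centra-only
material) are marked missing, so group sizes vary exactly as they do with
incomplete specimens.  Bracket-limited entries are censored observations and
are excluded from the statistical groups (they stay in the ROM tables,
flagged).

## Statistics

Descriptive rows (n, mean, s.d., min, max, sum) are ordinary arithmetic on
degrees; intervertebral angles are small, and this keeps `sum = n · mean`,
i.e. the summed column is total neck mobility.  Hypothesis tests treat
angles as directions in radians.  The Watson–Williams test uses the
textbook construction: per-group resultant lengths R_i, pooled resultant R,

    F = K (N − k)(ΣR_i − R) / [(k − 1)(N − ΣR_i)],   K = 1 + 3/(8κ̂),

κ̂ obtained from the weighted mean resultant length r̄ = ΣR_i/N by the
standard three-branch inversion (with κ̂ → ∞, K → 1 at zero dispersion), and
p from F(k−1, N−k).  Results carry assumption flags: low concentration
(r̄ < 0.45) and widely unequal per-group resultant lengths.  Pairwise
comparisons are emitted as an upper-triangular p-value matrix with
significance marked at p ≤ 0.05.  No multiplicity correction is applied, by
design, to keep the table semantics of the original protocol.

Validation of the test: F ≈ 0 / p ≈ 1 on identical groups; exact agreement
with a hand-computed F from the explicit resultant formula; agreement within
0.02 with a 20 000-permutation test of the mean-direction difference on
frozen 10-angle samples; type-I error within [0.035, 0.065] under an
equal-mean von Mises null (κ = 4, n = 20 per group, 2000 replicates,
seeded); power non-decreasing in mean separation.

## The synthetic generator

No vertebral dimensions are published for the target material, so the
generator's defaults are an arbitrary but proportioned stylization (all mm):
centrum radius 10, length 20, cup depth 2, neural spine height 25 with a 10°
posterior inclination, zygapophyseal facets 6 mm off the midline inclined
20° from horizontal, cervical ribs 35 mm long, intervertebral gap 2.  The
proportions were chosen once so that the neutral chain reproduces the stop
inventory reported for real material — cervical ribs stop lateral flexion,
zygapophyses stop dorsal extension (the prezygapophysis tip runs into a
raised buttress on the postzygapophysis whose clearance is `0.06 R + g`, so
gap collapse narrows but never closes it), centrum faces stop ventral
flexion — and per-index gradients can raise and incline the neural spines
caudally.  Geometry is deterministic for fixed parameters; optional surface
jitter is the only stochastic element and is off by default.

What the generator does **not** emulate: real cortical-surface roughness,
asymmetry, taphonomic distortion, non-planar facet surfaces, and any actual
taxon's proportions.  Passing tests therefore demonstrate correctness of
the machinery (posing, search, statistics) on idealized geometry, not that
any particular fossil's ROM is reproduced — for that, scan-derived meshes
must be supplied via the manifest route.

Sphere-pair fixtures give the search a closed-form oracle: two spheres of
radius r with gap g, pivot at the gap midpoint, first contact at
`arccos(2r²/(r + g/2)² − 1)`.  Icosphere vertices lie exactly on the ideal
sphere and faces sag inward by a computable bound δ, so the admissible
contact band is the closed-form angle evaluated at centre distances
2r + ε and 2(r − δ); all oracle assertions use that band plus 2·tol.

The raw per-joint angle data behind the published trial tables are not
redistributable, so `standin_angle_table` builds a deterministic synthetic
surrogate whose groups exactly match the published per-group n, mean and
standard deviation (gamma quantiles, affinely corrected to the exact
moments; angles stay non-negative).  Summary rows and the broad
between-trial significance pattern are reproduced through it; exact
published p-values are not, since those depend on the full raw samples.

## Numerical choices

* contact tolerance ε = 0.1 mm by default (1e-3 mm for sphere oracles);
  chosen small against the 10 mm centrum radius but large against float
  noise.  ε is an artifact parameter: the original on-screen judgement of
  contact had no published numeric equivalent.
* bisection `tol_deg` = 0.01° by default; large batch runs in the tests and
  the acceptance script use 0.05–0.1° with a 2° pre-sweep, the package's
  chosen problem sizes for routine validation.
* spacing reduction: bisection on the translation with an expanding upper
  bracket, failing with a reduction error if contact cannot be reached
  within the available gap plus the parts' bounding radii.
* ties between simultaneously contacting symmetric pairs (left vs right) are
  broken by float noise; the choice is deterministic for fixed inputs.
* degenerate inputs: empty meshes, non-finite vertices, coincident
  landmarks, non-orthonormal frames, empty contact rules and undersized
  groups all raise typed errors rather than propagating NaNs.

## Limitations

* No soft tissue, no translation/shear, no axial torsion: the three rotary
  profiles are the model.
* Vertex-to-surface distance slightly overestimates true surface distance
  between coarse meshes; refine the mesh (or the generator's
  `mesh_resolution`) when sub-degree absolute accuracy matters.
* The pairwise protocol measures joints independently; whole-chain coupling
  (e.g. rib–rib contact across non-adjacent vertebrae) is only visible in
  `chain=True` sweeps, which are not part of the measured tables.
* Missing morphology is never reconstructed; damaged joints are flagged and
  their absence propagates into group sizes.
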