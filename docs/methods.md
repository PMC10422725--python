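# Methods

## Problem and measurement model

External root resorption (ERR) after rapid maxillary expansion is
measured here as longitudinal surface change of individual tooth roots.
The unit of analysis is a *tooth pair*: two closed triangle meshes (mm)
of the same tooth, segmented from imaging at T0 (pre-treatment) and T1
(post-retention), each in its own scanner coordinate frame, plus named
anatomical landmarks (cusp tips; buccal/lingual cemento-enamel junction
points CEJB/CEJL; per-root apices; five registration points on the
buccal, lingual, mesial, distal and occlusal crown aspects).

The measurement chain assumes: (i) the crown is metrically stable
between timepoints, so a rigid transform maps T1 onto T0; (ii) change
is confined to the radicular surface; (iii) meshes are watertight, so
enclosed volume is well defined. Units are millimetres throughout
(STL carries no unit metadata; mm is declared, matching CBCT-scale
anatomy with ~0.3 mm voxels).

## Registration

1. *Pre-alignment*: orthogonal Procrustes (Kabsch, SVD with the
   det-correction, no scaling, no reflection) on the five matched
   registration points. With 0.2 mm Gaussian picking noise at crown
   scale this lands within a few degrees of truth — coarse, but inside
   the best-fit basin.
2. *Best fit*: point-to-point ICP of sampled T1 vertices (default 5000,
   all if fewer) against nearest T0 vertices via a KD-tree.
   Correspondences beyond 3× the median distance are rejected each
   iteration, so the resorbed apical region acts as a partial outlier
   rather than a bias. An update is accepted only if the RMS does not
   increase; iteration stops when the RMS change drops below 1e-5 mm or
   after 100 iterations. The report carries initial/final RMS, the
   (non-increasing) RMS history, and a convergence flag; a registration
   that cannot find ≥3 usable correspondences raises, never silently
   misaligns.

On identical shapes under arbitrary perturbations ≤30°/≤10 mm, the
composed landmark+ICP transform recovers truth to <0.1° and <0.01 mm
(tested over dozens of random frames); vertex-to-vertex correspondence
makes the optimum exact. Nearest-*vertex* (rather than nearest-point-
on-triangle) correspondences are a deliberate simplification; at the
mesh resolutions used they are equivalent at convergence.

## Root isolation and measurement

*CEJ plane.* Two landmarks underdetermine a plane, so the cervical cut
plane is defined to contain CEJB and CEJL with normal equal to the
component of the tooth long axis (cusp centroid minus apex centroid)
orthogonal to the CEJB–CEJL chord — a near-transverse cervical cut,
oriented so the crown is on the positive side. The same plane cuts the
T0 model (making the radicular template) and the registered T1 model,
so the crowns are removed at exactly the same level and the cut itself
contributes no T0–T1 volume difference. Cut boundaries are closed by a
centroid fan per boundary loop (one loop per root when cutting through
a furcation), keeping outputs watertight; capped half-volumes sum to
the original volume to 1e-6 relative.

*Volume.* Divergence-theorem signed volume; positive for outward
orientation; non-watertight input is rejected with the open-edge count.
ΔV = V(T0 root) − V(T1 root), ΔV% = 100·ΔV/V(T0 root).

*Root length.* Euclidean distance from the assigned cusp tip
(mesiobuccal/distobuccal/mesiolingual cusps for molar mesial/distal/
palatal roots; the buccal cusp for premolars) to the most apical point
of that root's surface. The apex is re-detected as the mesh vertex
lowest along the tooth axis within the root's region (vertices below
the CEJ, assigned to the laterally nearest root axis); ties within a
0.1 mm band — a truncated, flat apex — resolve to the most central
candidate, which makes the measurement stable under small registration
rotations. A `landmark` mode that trusts the apex landmark is provided.

*Deviation field.* For every T0 root vertex ("all points of the
shell", no decimation), the distance to the nearest point on the T1
triangle surface (exact point-triangle projection over KD-tree
candidates by triangle centroid plus all triangles incident to the two
nearest vertices), signed by a generalized winding-number inside test
(negative = T0 point outside T1 = material loss). The matching
percentage is the share of samples with |d| ≤ tolerance; tolerance
defaults to 0.3 mm (the scan voxel scale) and is configurable. The
colour map is green inside the band, ramping to saturated blue (loss)
or red (gain) at ±0.5 mm; deviations export as PLY vertex colours. A
ray-parity oracle (`sign_convention_check`) verifies the sign
convention independently in tests. T0→T1 (not symmetric) distance is
used, with T0 as the reference anatomy.

## Synthetic cohorts

The generator emulates the study design the statistics layer expects:
two appliance groups (tooth-borne vs bone-borne), upper posterior teeth
as the test arch, lower teeth as controls, both sides, two timepoints
in independent frames.

*Teeth* are stylized: a rounded crown frustum plus one tapered,
slightly tilted tube per root (three roots for upper first molars, two
for lower, one for premolars), closed and concatenated; landmarks are
placed analytically. Root radial profiles are calibrated in closed form
so below-CEJ volumes hit per-class targets (~120/130 mm³ premolars,
~315 mm³ molar root complex) chosen so the configured absolute volume
losses translate into percentage losses of realistic magnitude. Shapes
are plausible in topology and scale, not anatomical atlases — passing
recovery tests shows the *measurement chain* is unbiased, not that
segmentation of real CBCT would be.

*Resorption.* Per-root length loss is realized as a capped apical cut
(the cut height solves the cusp–apex distance change exactly, including
root tilt); negative control draws become smooth apical extension.
Volume loss beyond the truncation is realized by lacunae — Gaussian
inward displacements (radius 1.4–2.4 mm, clamped at 85 % of the local
tube radius) at sites drawn on the buccal sector (±40° about +x) of
the apical-to-mid root — and a bisection on the global depth scale
makes the mesh-measured radicular loss hit the per-tooth target
(outward displacement for negative control targets). Ground truth
(V0, ΔV below the actual CEJ plane, per-root length changes) is
*measured on the generated meshes*, never assumed.

*Effect distributions.* Per-tooth (ΔV, Δlength) pairs are drawn from
normal distributions via a latent Gaussian with correlation 0.5
(an assumption — no empirical per-tooth correlation is available;
exposed as `volume_length_corr`), roots within a tooth sharing a
further latent (0.7). Test-arch draws are truncated at zero; control
draws keep their sign. Defaults are the configured group effect tables
(e.g. TB first-molar ΔV 26.21 ± 10.03 mm³, BB 4.62 ± 3.12 mm³; TB
palatal-root Δlength 0.56 ± 0.19 mm, BB 0.15 ± 0.04 mm; near-zero
control means). Arch-width changes (PWE/DAE, negative under expansion)
are drawn per patient and level; one printed default (BB P2 DAE) lacks
a sign in its source table and is taken as −3.99 mm like its
neighbours. Scanner frames differ by random rigid transforms (≤15°,
≤8 mm); T1 registration landmarks get 0.2 mm Gaussian picking noise —
an assumed precision. Per-tooth crown scale varies by 3 % SD. All
randomness derives from one integer seed through `SeedSequence`
spawning, so cohorts are byte-reproducible.

What the generator does **not** emulate: voxelization/partial-volume
noise, segmentation error, enamel/dentin structure, crown wear,
patient-level clustering of effects. Recovery results therefore bound
the pipeline's intrinsic error, not the error of a full clinical
workflow. One visible consequence: matching percentages in the
low-effect (bone-borne) group approach 100 % on synthetic data, where
clinical shells — noisier surfaces at equal true change — sit in the
high 80s/low 90s; the matching statistic responds to *all* surface
differences, simulated or instrumental.

## Statistics

Standard tests are delegated to scipy/statsmodels behind the module
surface: Shapiro–Wilk per group plus Levene (mean-centred), one-way
ANOVA with pairwise Student t post-hocs (Bonferroni = raw p × number of
pairs, clamped at 1), pooled-variance unpaired t-tests (Welch by flag;
the design assumes homogeneous variance, which Levene checks), Pearson
chi-square without continuity correction (flag available), OLS with
intercept reporting unstandardized B, SE, standardized β
(B·sd(x)/sd(y)), t, p, 95 % CI and R², fitted separately per tooth
class. ICC is the two-way random-effects, absolute-agreement,
single-measurement form ICC(2,1) from the ANOVA mean squares (the form
is stated in the output metadata since conventions differ). Sample size
for a two-group mean comparison iterates the exact noncentral-t power
to the smallest n per group (d = 1 → n = 17 at 80 % power, α = 0.05).
A right-vs-left equivalence pre-test is run and logged before sides are
pooled. The observation unit is the tooth; within-patient correlation
is not modelled — a documented limitation shared with the reporting
conventions this layer mirrors.

## Numerical choices and problem sizes

* Vertex merge tolerance on read: 1e-6 mm (STL duplicates vertices per
  facet). Degenerate faces dropped at area ≤1e-12 mm².
* Plane membership/normal tolerances: 1e-9.
* Winding-number inside threshold 0.5; the kernel is numba-jitted with
  a pure-numpy fallback.
* Mesh resolution defaults: 0.7 mm ring spacing, 20 points per ring
  (~1.5–2.5 k vertices per tooth) — chosen so that per-tooth ΔV%
  recovery error stays well under 1 percentage point while a
  120-tooth-pair cohort analyzes in about a minute.
* Validation cohorts: 10 patients/group × 2 sides (20 teeth per class
  and group, the design's cell size) for recovery checks; smaller
  cohorts for smoke/determinism tests. Statistical calibration uses
  2000 null replicates (type-I) and 200 effect replicates (power).
* Empty cut results are legal (plane missing the mesh); coincident CEJ
  landmarks, collinear plane/landmark configurations, non-watertight
  volume requests and degenerate-variance groups raise typed
  validation errors.

## Known limitations

* Stylized tooth geometry; no open-source anatomical atlas is bundled.
* Nearest-vertex ICP correspondences (see above).
* The exact nearest-surface distance is exact only within its candidate
  set (KD-tree centroid + vertex-incidence candidates); adversarial
  meshes with extremely nonuniform triangle sizes could in principle
  evade it, ours do not.
* Per-root volume decomposition of multi-rooted teeth is out of scope
  (volumes are per tooth, lengths per root).
* The statistics layer intentionally ignores tooth-within-patient
  clustering.
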