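# Methods

This note documents the models, numerical choices and limitations of
mirrorsim: a headless re-implementation of a VR dental mirror-technique
evaluation as a geometric simulator plus a screenshot-scoring pipeline.

## Mirror optics

The virtual mirror follows the symmetric mirror-image-camera construction:
what the operator sees on the mirror face is the pinhole projection of each
object's *virtual image*, i.e. the object reflected through the mirror
plane (`reflect_point`: p′ = p − 2((p−q)·n)n). Reflection is an isometry,
so a circular lesion disc has a circular virtual image of equal diameter.
By construction, geometry lying between the mirror surface and the virtual
image never occludes the mirror content; the only clipping is by the mirror
rim, and it is applied at the raster stage so the analytic ellipses stay
exact.

`project_disc` samples K = 256 disc-boundary points, projects them through
an ideal pinhole (square pixels, principal point at the image centre,
y down) and fits the exact conic by a normalized least-squares SVD solve.
A disc fully in front of the camera projects to an exact ellipse, so the
fit residual is at numerical-noise level; tests verify the closed forms
(face-on image radius f·r/d to 0.1%, axis ratio → cos(tilt) within 1% for
distance/radius ≥ 50). Discs partially behind the camera raise an error —
there is no frustum clipping at the analytic level. Camera defaults are
vfov 60°, 1000×1000 px; the HMD's true optics are not modelled.
Two deliberate non-features: no lens distortion, no stereo.

## Scene

The dentition is a parameterized stand-in for the scanned typodont used in
the original apparatus (whose meshes are not distributed): capsules for
teeth on a parabolic arch (anterior teeth 12, 21, 31, 42 plus neighbours),
an ellipsoidal tongue lingual to the mandibular arch, and an axis-aligned
"frame" box enclosing the dentition. Coordinates are millimetres, y up,
ground plane y = 0; the occlusal plane is vertical (z = 0, horizontal
normal), matching the mounted posture with the operator at the 12 o'clock
position. The skill metrics depend only on viewer/mirror/lesion geometry,
so the exact arch dimensions (width 40 mm, anterior depth 10 mm, tooth
radius 3.5 mm by default, all configurable) are convenience choices.

The lesion is anchored on the surface facing the mirror in the 12 o'clock
posture — lingual for maxillary 12/21, labial for mandibular 31/42. The
source material does not state the carrying surface; it is configurable.

Validity criteria per task: (1) the entire mirror inside the viewport and
unoccluded — tested with 32 eye→boundary rays against all primitives,
tangency counting as occluded (conservative); (2) no penetration of
tongue/teeth — the disc sampled at its centre plus three concentric rings
of 64 boundary points, touching counting as penetration (validated against
a dense polar-grid oracle in tests); (3) Trial 2 only: handpiece tip inside
the frame box and its projection outside the lesion-image ellipse. Failing
records are kept and flagged; statistics use valid records by default.

## Raster measurement

Screenshots are label rasters (background 0, mirror 1, lesion 2) on a
half-open viewport with pixel-centre sampling: a pixel belongs to an
ellipse iff its centre does. Lesion pixels are clipped to the mirror
region. An optional salt-and-pepper label-flip augmentation exists
(default rate 0); the synthetic pipeline otherwise controls segmentation
exactly, which real screenshot analysis does not.

`fit_ellipse_moments` computes the centroid and second-order central
moments of a pixel set, takes axis directions and ratio from the
eigen-decomposition, and rescales both axes so the ellipse area equals the
pixel count — the same-area convention of ImageJ's *Fit Ellipse*, which is
how the original screenshots were measured. Fits require ≥ 16 pixels and
non-degenerate spread; no 1/12 pixel-variance correction is applied (its
effect is ≈ 0.1% at the ≥ 10 px semi-axes the pipeline produces).

Pixel→mm calibration uses the mirror's known 20 mm diameter along the
fitted major axis: `mm_per_px = 20 / (2 a_DM)`. The major axis is the
tilt-robust reference because a tilted circle preserves its true diameter
along the tilt axis. The mirror inclination is θ = arccos(b_DM/a_DM).

## Synthetic cohorts

The generator parameterizes *apparent in-mirror-image quantities* directly
rather than simulating hand kinematics, because the published group-level
statistics are apparent-image statistics and this makes them exactly
encodable as calibration targets. Per record it samples:

- radial offset of the lesion image from the mirror centre:
  Gamma(shape 4, mean per profile) — non-negative, mean-parameterizable;
  shape 4 (CV 0.5) is consistent with the reported effect sizes
  (|d| ≈ 0.5 for ≈ 0.4 mm mean differences implies SD near 0.8 mm);
- apparent ellipticity: Beta with profile mean (default SD 0.05), mapped
  to a disc tilt;
- apparent area ratio: truncated normal (default SD 0.35 percentage
  points);
- manipulation time: log-normal with σ_log 0.35, location chosen so the
  arithmetic mean matches the profile; task ① gets a ×1.3 mean factor to
  represent the first-task acclimatization effect.

The mirror is held on the line of sight to the task tooth at 250–280 mm
from the eye, roughly facing the viewer with a half-normal 4° cant and
3 mm lateral jitter. The capture camera uses a 16° vertical field of view
at 800×800 px so the mirror fills the frame, emulating a capture tuned to
fit the mirror in view. The lesion's virtual-image disc sits 1–5 mm behind
the mirror plane; the physical lesion is its reflection.

Because perspective makes the naive mapping (offset → distance,
arccos(ellipticity) → tilt, diameter → ratio) biased at the 0.1–0.5%
level — which matters when recovery is asserted within 3 standard errors
at n ≥ 500 — the generator solves each pose so the *analytic* measured
metrics equal the sampled targets exactly: the in-plane centre is driven
by Newton steps on a numerical 2×2 projection Jacobian toward the desired
pixel-space position, and tilt and diameter are rescaled by
target/measured ratios (4 iterations). Remaining end-to-end error is
rasterization only, which is mean-zero under the continuous pose
distribution (measured bias ≲ 1e-4 on ellipticity, ≲ 1e-3 percentage
points on ratio). Two consequences worth noting: the lesion diameter is a
free parameter (apparent ratios above the coplanar (3/20)² = 2.25% bound,
as published values up to 3.46% require, are reachable), and the lesion
disc floats at the solved pose rather than being glued to the tooth
surface — the tooth label is a task tag.

The packaged `calibrated_cohort.yaml` encodes the published per-tooth ×
per-trial group means for distance, ratio and time and per-trial means for
ellipticity, with group sizes 25/24/17/21. Cells whose means were not
printed (only significant contrasts were reported) are filled with
order-consistent interpolations and marked in the YAML. Randomness is keyed
per (seed, group, participant, task), so records are reproducible under
reordering and subsetting.

What passing recovery tests show: the render → segment → measure → convert
chain is unbiased and correctly scaled. What they do not show: anything
about human operators — the generator has no hand kinematics, no learning
dynamics beyond the task-① factor, no tissue deformation, and its
dispersion parameters are design choices, not fitted quantities.

## Statistics

- **KS normality screen**: one-sample KS with estimated mean/SD; since
  parameters are estimated, the null distribution is Lilliefors', obtained
  by seeded Monte Carlo (default 10⁴ replicates; 2×10³ in the CLI).
- **Friedman test**: tie-corrected statistic
  χ²_F = (k−1)·Σ_j (R_j − n(k+1)/2)² / (Σ r² − nk(k+1)²/4) with average
  ranks; p by exact enumeration of all (k!)ⁿ within-block arrangements when
  that count ≤ 10⁵, else the χ²(k−1) asymptote. Used for within-participant
  factors: the four tooth conditions per group × trial, and tasks ①–④ for
  time. The original analysis describes Friedman tests "among groups", but
  the blocked design does not support independent groups of unequal size;
  between-group contrasts here use rank-sum tests instead, reproducing the
  same comparison families.
- **Pairwise contrasts**: two-sided rank-sum (independent groups) or
  signed-rank (paired trials), Bonferroni-adjusted with m = 6 per four-group
  family per tooth × trial (families are not pooled across teeth, matching
  the per-tooth reporting) and m = 1 for the Trial-1 vs Trial-2 contrast on
  participant means. Significance markers: * p < 0.05, ** p < 0.001.
- **Effect size**: Cohen's d on raw metric values — pooled-SD form for
  independent contrasts, mean-difference/SD-of-differences for paired; the
  source does not state its formula, so the conventional one is used.

## Numerical conventions and degenerate inputs

Conic fits normalize points before the SVD solve; ellipse orientation is
reported in [0, 180) from the +x image axis. Ellipse fits reject < 16
pixels or collinear pixel sets. `measure` raises a named error when a label
class is missing. Constant samples are rejected by the KS screen and zero
variance by Cohen's d. Tangency counts as occlusion/penetration
(conservative). Problem sizes in the test-suite recovery checks (6 seed
replicates at the study's cohort sizes) and the acceptance script (20 seed
replicates) were chosen so the Monte-Carlo standard errors are a few
percent of the targets.

## Known limitations

- No real-time rendering, haptics, or HMD capture; screenshots are
  synthetic label rasters, not photometric images.
- No soft-tissue deformation or rigid-body collision response (the original
  apparatus also omitted both), and no molar targets.
- The statistics module's between-group design deviates deliberately from
  the source's stated (but unsupported) blocked design, as described above.
- Questionnaire analysis is out of scope.
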