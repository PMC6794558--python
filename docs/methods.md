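# Methods

`gazetess` implements a bottom-up workflow for screen-based eye-tracking
studies in which the areas of interest (AOIs) are derived *a posteriori*
from where participants actually looked, instead of being drawn by hand
before the analysis. The chain is

```
raw binocular samples
  -> cyclopean fusion            (events.fuse_eyes)
  -> adaptive velocity classification into fixations/saccades
  -> pooling fixations across participants per stimulus
  -> mean-shift density modes    (clustering.mean_shift)
  -> Voronoi tessellation        (tessellation.build_voronoi)
  -> experimenter labels per cell
  -> relative fixation duration  (metrics.compute_rfd)
```

This note documents the model behind each stage, the parameters that
matter, what the synthetic generator does and does not emulate, and the
design choices that were genuinely open.

## Coordinates and visual angle

The raster convention is origin top-left, x rightward, y downward, units
pixels, half-open bounds `[0, W) x [0, H)`. A `ScreenGeometry` carries the
raster size, physical size and viewing distance; thresholds naturally
expressed in degrees (noise, merge radii) are converted with
`pixels_per_degree = d * tan(1 deg) / pitch`. For the default geometry
(1280x1024 px, 34.7x25.9 cm, 60 cm) this is 38.6 px/deg horizontally and
41.4 px/deg vertically; isotropic radii use the mean of the two.

All time arithmetic uses the recorded timestamps, never the nominal rate,
so irregular sampling and dropped samples are handled by construction.

## Event detection

**Cyclopean fusion.** When both eyes are valid the coordinates are
averaged; when one eye is missing the other substitutes (and the sample is
tagged with its provenance); when both are missing the sample stays
missing. Nothing is interpolated across time: a gap in both eyes is a gap
in the record.

**Velocity.** Point-to-point Euclidean speed, `v = sqrt(dx^2 + dy^2)/dt`
in px/s, between consecutive valid samples; pairs spanning a gap are
omitted. For classification the positions are first smoothed with a short
centred moving average (`smooth_window`, default 3 samples = 12 ms at
250 Hz). At realistic noise (0.3 deg per eye) raw pairwise speeds have a
noise floor near 3600 px/s, overlapping the slowest saccades; the 3-sample
average lowers the floor roughly threefold while blurring event boundaries
by at most one sample. `compute_velocity` itself is the raw pairwise
operation, so the unsmoothed record remains available.

**Adaptive threshold.** Estimated per participant and per trial from the
trace's own velocity distribution, so noisy recordings get conservative
thresholds automatically. A Gaussian KDE of log10 velocity (fixed
bandwidth `kde_bw_log` = 0.12 log-units; a Scott-factor bandwidth on the
full mixture smooths away the saccade mode, which holds only ~10% of the
samples) is scanned for modes. The fast (saccade) mode is the rightmost
peak with relative prominence >= `peak_prominence` (0.03); the slow
(fixation) mode is the most prominent peak left of it. The threshold is
placed at the slow edge of the low-density region adjacent to the fast
mode (`valley_position` = 0; the raw density argmin is ill-posed because
the inter-mode density is typically a near-zero plateau). Anchoring at the
slow edge keeps intermediate artifacts — e.g. the small velocity bump
produced when one eye drops out and the cyclopean point jumps by half the
interocular disparity — inside the fixation population, and keeps slow
saccades above the cut. If no second mode qualifies, a robust fallback
`median + 5*MAD` is used, and the `VelocityThreshold.method` tag records
which branch fired.

**Classification, merging, noise filter.** Maximal runs of sub-threshold
sample pairs become candidate fixations; the fixation position is the
dwell-time-weighted centroid of the run. Successive fixations separated by
<= `merge_max_gap_ms` (75 ms) and <= `merge_max_dist_deg` (0.7 deg) are
merged (duration-weighted centroid, span from first onset to last offset;
the operation runs to a fixpoint and is idempotent). Candidates shorter
than `min_fixation_ms` (60 ms, a conservative noise floor: 15 samples at
250 Hz) are then discarded. The order — merge first, then the duration
filter — matters: single-pair velocity breaks inside a genuine dwell
produce fragments that merging must be allowed to reassemble before any
fragment is judged too short. Every input sample ends up in exactly one
bucket (fixation / saccade / discarded / missing), retained on the
`FixationSet` for audit.

## Mean-shift fixation-density centroids

Fixations of all participants watching a stimulus are pooled into one
point cloud (`pool_fixations`; off-screen fixations excluded, groups
pooled so all groups share the same AOIs; `per_group` scoping is available
for sensitivity analyses). Each point then climbs the Gaussian-kernel
density estimate by moving repeatedly to the kernel-weighted local mean of
all points (tolerance 1e-3 px, max 500 iterations). Converged locations
within `bandwidth/2` are merged into one centroid; each fixation is
assigned to exactly one centroid. The iteration is vectorised over points
and mode merging orders candidates by density (ties by coordinates), so
the result is deterministic and independent of input order.

**Bandwidth.** The data-driven default is a local-spacing estimator: 1.5x
the median distance to the ceil(sqrt(n))-th nearest neighbour. A global
rule-of-thumb on pooled deviations (Scott/Silverman) is inflated by the
distance *between* fixation hotspots on a multimodal gaze map and
over-smooths until separate hotspots merge; the nearest-neighbour scale
reflects within-hotspot spread only, is scale-equivariant, and reduces to
the usual n^(-1/6)-type shrinkage on unimodal clouds. A fixed bandwidth
can be forced through `ClusterConfig.fixed_bandwidth`.

**Weights.** Fixation durations are carried on every point but weighting
is off by default: each fixation counts once. `weight_by_duration=True`
switches the density to dwell-time weighting. Clusters are not pruned by
default (`min_cluster_size=1`).

## Voronoi AOIs

Each centroid generates the cell of screen locations closer to it than to
any other centroid. Cells are built by intersecting the screen rectangle
with the bisector half-planes against all other sites, so outer regions
are clipped and the cells tile the frame exactly: polygon areas sum to the
raster area to floating-point precision, and point membership by polygon
containment coincides with nearest-centroid assignment (both facts are
tested, the latter on 10^4 random points). Boundary ties break to the
lowest centroid index; boundaries carry zero measure.

Labels ("Face", "Target", ...) are attached by an explicit index->name
mapping in the experiment config, mirroring the manual naming step of the
workflow; unnamed cells become "Background". No automatic semantic
labeling is attempted on real data. Several cells may share one label;
metrics pool them.

## Relative fixation duration

For each participant x stimulus, `rfd(label)` = time fixating cells with
that label / total on-screen fixation time. Off-screen fixations enter
neither numerator nor denominator; participants with zero on-screen time
get explicit rows with missing rfd. Because the cells tile the screen, the
rfd values over all labels (Background included) sum to 1 exactly — the
partition property restated at the metric level. The long-format table
(participant, group, stimulus, condition, aoi_label, rfd, total_ms) is the
hand-off to group statistics; ANOVAs, post-hoc tests and effect sizes are
deliberately out of scope, as they are commodity routines downstream.
`summarize_by_group` provides descriptive mean/SD/n (SD with the n-1
denominator; singleton cells yield missing SD unless configured to 0).

## Synthetic generator

`generate_trace` renders a planned scanpath — dwell positions and
durations joined by constant-velocity linear sweeps of 30-60 ms — at
250 Hz, adds independent isotropic Gaussian noise per eye (specified in
degrees, default 0.3, converted per axis), offsets the eyes horizontally
by a small disparity (8 px), and drops samples independently per eye
(default 2%). Planted events are returned as ground truth. Noise is drawn
once at unit scale and multiplied by sigma, so the same seed produces the
identical noise pattern at every noise level — noise ladders are strictly
comparable, which makes the monotonicity test meaningful.

`generate_experiment` builds a cohort: groups x participants x stimuli,
with per-participant dwell-time fractions drawn from a Dirichlet around
the group's mean propensities (concentration 60; residual mass goes to
Background dwells at dedicated background positions). The fixation plan
discretises those fractions into 150-400 ms dwells near the labeled
anchor positions (20 px jitter), and the *realized* per-label durations —
not the drawn fractions — define the truth RFD, so plan discretisation
introduces no bias into recovery tests.

What the generator does **not** emulate: smooth pursuit (a study's
dynamic stimuli move), saccadic main-sequence kinematics, vergence and
pupil dynamics, calibration drift, and blink-shaped (correlated) dropout.
Passing recovery tests therefore demonstrate correctness of the pipeline's
logic under the stated noise model, not detector performance on infant
clinical recordings.

## Problem sizes and numerical choices

The bundled benchmarks use: 50 traces x 8 dwells for event recovery
(errors within 2 samples at 250 Hz); 10 two-mode mixtures of 1400
velocities for threshold validity; 100 replicates of K in 1..5 planted
clusters (100 points each, sigma 20 px, >= 8 sigma separation) for mode
counting; 10^5 uniform points for the partition check; and 100 replicates
of a 3-group x 30-participant x 2-stimulus experiment (2.4 s per
stimulus) for end-to-end propensity recovery. These sizes give stable
percentages while keeping the whole benchmark suite in the minutes range
on one core.

Degenerate inputs are handled explicitly: all-equal velocity series fall
back to a threshold strictly above every sample (zero saccades); identical
cluster points raise "zero dispersion"; duplicate Voronoi sites raise
"degenerate sites"; empty trial windows and empty fixation pools raise
with the trace/stimulus named.

## Known limitations

- The threshold estimator assumes the trace contains both fixations and
  saccades; traces consisting of a single dwell are handled by the robust
  fallback but with a necessarily arbitrary cut.
- Mean shift is O(n^2) per iteration; pooled clouds beyond ~10^4 fixations
  would need a truncated-kernel neighbour structure.
- `derive_label_map` (anchor-based labeling) is for synthetic experiments
  only, where the generator's anchors are known; real studies must label
  cells by inspection, and that mapping is part of the experiment config.
- Cells are clipped at the full screen rectangle; if a stimulus has an
  inactive border band, pass a geometry describing the active area.
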