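# gazetess

Bottom-up gaze analysis for screen-based eye tracking: from raw binocular
samples to *a posteriori* areas of interest (AOIs) and relative fixation
durations.

## The problem

Most eye-tracking studies aggregate gaze over AOIs drawn by the
experimenters *before* seeing the data. That top-down choice — where the
boxes go and how big they are — silently shapes every downstream statistic,
and it is especially fragile for young children or clinical groups whose
fixations are dispersed. `gazetess` implements the complementary bottom-up
workflow: the AOIs are derived from the participants' own fixation
densities, so "where people looked" defines the regions over which looking
is then measured.

The pipeline, per stimulus:

1. **Event detection.** Binocular samples are fused into a cyclopean trace
   (coordinates averaged; a missing eye is substituted by the other),
   point-to-point Euclidean velocity is computed, and a velocity threshold
   is estimated *per participant and per trial* from the two modes of the
   trace's own log-velocity density — noisy recordings automatically get
   conservative thresholds. Sub-threshold runs become fixations; nearby
   fixations are merged and sub-60 ms candidates are discarded as noise.
2. **Density centroids.** Fixations of all participants are pooled and the
   modes of their spatial density are found by Gaussian-kernel mean shift:
   every point climbs to the kernel-weighted local mean until it converges
   on a density peak; points converging to the same peak form a cluster.
3. **Voronoi AOIs.** Each density centroid generates the Voronoi cell of
   screen locations closer to it than to any other centroid, clipped to the
   screen rectangle. The cells tile the screen exactly, are named by the
   experimenter (unnamed cells are "Background"), and are large enough to
   be robust to typical tracker error.
4. **Metrics.** Relative fixation duration per AOI label — the time
   fixating a label divided by the participant's total on-screen fixation
   time, so the values over all labels sum to 1 — exported as a tidy
   long-format table ready for mixed-design group statistics.

A fully seeded synthetic generator (binocular 250 Hz sampling, per-eye
noise in degrees, sample dropout, planted dwells and sweeps, multi-group
designs with planted AOI dwell propensities) makes every stage testable
against ground truth without any recordings.

## Worked example

Simulate a three-group cohort (an ASD-like group with a planted Face
dwell propensity of 0.35 vs 0.50 for the two control-like groups, 28
children each, one dynamic and one static stimulus), then run the full
pipeline on the generated traces:

```python
import pandas as pd
from gazetess import (ScreenGeometry, ExperimentSpec, generate_experiment,
                      detect_fixations, pool_fixations, select_bandwidth,
                      mean_shift, build_voronoi, label_cells,
                      assign_fixations, compute_rfd, summarize_by_group)
from gazetess.simulate import derive_label_map

geometry = ScreenGeometry(1280, 1024, 34.7, 25.9, 60.0)
spec = ExperimentSpec(
    groups=(("ASD", 28), ("TD", 28), ("TC", 28)),
    stimuli=(("V4", "dynamic", 2400.0), ("P4", "static", 2400.0)),
    propensities={"ASD": {"Face": 0.35, "Target": 0.25},
                  "TD": {"Face": 0.50, "Target": 0.25},
                  "TC": {"Face": 0.50, "Target": 0.25}},
    anchors={"Face": (420.0, 300.0), "Target": (950.0, 520.0)},
    background_anchors=((150.0, 850.0), (1100.0, 150.0)),
    seed=7,
)
data = generate_experiment(spec, geometry)

fixsets = [detect_fixations(trace) for trace in data.traces]
parts = []
for stim in ("V4", "P4"):
    points = pool_fixations(fixsets, stim)          # all groups share AOIs
    h = select_bandwidth(points)
    modes = mean_shift(points, h, stimulus_id=stim)
    aoi = label_cells(build_voronoi(modes, geometry),
                      derive_label_map(modes, spec.anchors))
    print(f"{stim}: {len(points)} fixations, bandwidth {h:.1f} px, "
          f"{modes.n_clusters} centroids -> cells {aoi.labels}")
    parts += [assign_fixations(fs, aoi) for fs in fixsets
              if fs.stimulus_id == stim]

rfd = compute_rfd(pd.concat(parts, ignore_index=True),
                  ["Background", "Face", "Target"],
                  conditions={"V4": "dynamic", "P4": "static"})
print(summarize_by_group(rfd, ["group", "aoi_label"]).round(3))
```

which prints:

```
V4: 557 fixations, bandwidth 24.9 px, 4 centroids -> cells ['Face', 'Target', 'Background', 'Background']
P4: 537 fixations, bandwidth 26.4 px, 4 centroids -> cells ['Face', 'Target', 'Background', 'Background']
  group   aoi_label   mean     sd   n
0   ASD  Background  0.382  0.058  56
1   ASD        Face  0.376  0.065  56
2   ASD      Target  0.242  0.052  56
3    TC  Background  0.235  0.052  56
4    TC        Face  0.511  0.060  56
5    TC      Target  0.254  0.060  56
6    TD  Background  0.243  0.050  56
7    TD        Face  0.510  0.070  56
8    TD      Target  0.248  0.057  56
```

The clustering found four density hotspots per stimulus — the face, the
pointing target and two background loci — and tessellated the screen
around them; the recovered group means of relative fixation duration sit
close to the planted propensities (Face 0.376 vs planted 0.35 for the
ASD-like group; 0.51 vs 0.50 for the others; n = 56 is 28 participants x 2
stimuli). The `rfd` table is the long-format export a mixed ANOVA would
consume.

The same workflow is scriptable from the shell: `gazetess simulate` writes
a ground-truthed gaze log, and `gazetess run-all --config experiment.yaml`
runs read → detect → cluster → tessellate → label → RFD, writing fixation,
centroid, cell and RFD tables plus per-stimulus overlay figures and a
manifest. See `gazetess --help`.

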