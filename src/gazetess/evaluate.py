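"""Recovery benchmarks against synthetic ground truth.

Scores each pipeline stage against planted truth through an independent
route: an exhaustive threshold sweep for the velocity classifier, a
brute-force grid-KDE hill climb for mean-shift modes, and planted dwell
propensities for the full chain.  Used by the test suite and the
reproduction script; none of these functions participate in the analysis
pipeline itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clustering import kde_density, mean_shift, pool_fixations, select_bandwidth
from .events import DetectionConfig, detect_fixations
from .geometry import ScreenGeometry
from .metrics import compute_rfd, summarize_by_group
from .simulate import (
    ExperimentSpec,
    ScanpathSpec,
    derive_label_map,
    generate_experiment,
    generate_trace,
    random_fixation_plan,
)
from .tessellation import assign_fixations, build_voronoi, label_cells

__all__ = [
    "recovery_rate",
    "sweep_oracle_threshold",
    "planted_clusters",
    "grid_kde_hillclimb",
    "run_group_experiment",
]


def recovery_rate(
    geometry: ScreenGeometry,
    n_traces: int = 50,
    seed: int = 0,
    noise_sd_deg: float = 0.3,
    tol_samples: int = 2,
    config: DetectionConfig | None = None,
):
    """Fraction of planted fixations recovered with onset/offset errors
    within ``tol_samples`` at 250 Hz; also returns the matched boundary
    errors (ms) for diagnostics."""
    root = np.random.default_rng(seed)
    total = 0
    recovered = 0
    errors = []
    for _ in range(n_traces):
        plan = random_fixation_plan(np.random.default_rng(root.integers(2**31 - 1)), geometry)
        spec = ScanpathSpec(
            fixation_plan=plan,
            noise_sd_deg=noise_sd_deg,
            missing_rate=0.02,
            seed=int(root.integers(2**31 - 1)),
        )
        trace, truth = generate_trace(spec, geometry)
        fs = detect_fixations(trace, config)
        tol_ms = tol_samples * 1000.0 / spec.rate
        for tf in truth.fixations:
            total += 1
            err = min(
                (
                    max(abs(f.onset - tf.onset), abs(f.offset - tf.offset))
                    for f in fs.fixations
                ),
                default=np.inf,
            )
            errors.append(err)
            recovered += err <= tol_ms + 1e-9
    return recovered / total, np.array(errors)


def sweep_oracle_threshold(v: np.ndarray, truth_fast: np.ndarray) -> float:
    """Exhaustive-sweep oracle: the velocity cut maximising agreement with
    the planted slow/fast labels (midpoints of the sorted velocities)."""
    order = np.argsort(v)
    vs = v[order]
    cuts = np.concatenate([[vs[0] * 0.5], 0.5 * (vs[1:] + vs[:-1]), [vs[-1] * 2.0]])
    best_cut, best_acc = cuts[0], -1.0
    for c in cuts:
        acc = np.mean((v >= c) == truth_fast)
        if acc > best_acc:
            best_cut, best_acc = c, acc
    return float(best_cut)


def planted_clusters(
    rng: np.random.Generator,
    geometry: ScreenGeometry,
    k: int,
    n_per: int = 100,
    sigma: float = 20.0,
    min_sep_sigmas: float = 8.0,
):
    """K well-separated isotropic Gaussian clusters on the screen."""
    margin = 6.0 * sigma
    lo = np.array([margin, margin])
    hi = np.array([geometry.raster_width - margin, geometry.raster_height - margin])
    centers: list = []
    while len(centers) < k:
        c = rng.uniform(lo, hi)
        if all(np.linalg.norm(c - o) >= min_sep_sigmas * sigma for o in centers):
            centers.append(c)
    centers = np.array(centers)
    pts = np.vstack([rng.normal(c, sigma, size=(n_per, 2)) for c in centers])
    return centers, pts


def grid_kde_hillclimb(start, pts, bandwidth) -> np.ndarray:
    """Greedy 8-neighbour ascent on the 1-px-grid Gaussian KDE, evaluated
    lazily and memoised.  Independent route to the density maximum."""
    cache: dict = {}

    def dens(ix, iy):
        if (ix, iy) not in cache:
            cache[(ix, iy)] = kde_density(
                np.array([[ix, iy]], dtype=float), pts, bandwidth
            )[0]
        return cache[(ix, iy)]

    cx, cy = int(round(start[0])), int(round(start[1]))
    while True:
        best = (dens(cx, cy), cx, cy)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                d = dens(cx + dx, cy + dy)
                if d > best[0]:
                    best = (d, cx + dx, cy + dy)
        if (best[1], best[2]) == (cx, cy):
            return np.array([cx, cy], dtype=float)
        cx, cy = best[1], best[2]


EXP_ANCHORS = {"Face": (420.0, 300.0), "Target": (950.0, 520.0)}
EXP_BACKGROUND = ((150.0, 850.0), (1100.0, 150.0))


def run_group_experiment(
    geometry: ScreenGeometry,
    seed: int = 0,
    n_per_group: int = 30,
    face_propensities: dict | None = None,
):
    """Full-chain recovery benchmark on a 3-group x 2-condition experiment.

    Generates a synthetic cohort with planted per-group Face propensities
    (default 0.35 for the ASD-like group vs 0.50 for both comparison
    groups), runs detection -> pooled clustering -> tessellation ->
    anchor-derived labeling -> RFD, and returns ``(estimated, truth)`` Face
    summaries by group (participant-level means first, then group mean, SD,
    n).
    """
    face = face_propensities or {"ASD": 0.35, "TD": 0.50, "TC": 0.50}
    spec = ExperimentSpec(
        groups=tuple((g, n_per_group) for g in face),
        stimuli=(("V1", "dynamic", 2400.0), ("P1", "static", 2400.0)),
        propensities={g: {"Face": f, "Target": 0.25} for g, f in face.items()},
        anchors=EXP_ANCHORS,
        background_anchors=EXP_BACKGROUND,
        seed=seed,
    )
    data = generate_experiment(spec, geometry)
    fixsets = [detect_fixations(tr) for tr in data.traces]
    parts = []
    for stim, _, _ in spec.stimuli:
        pts = pool_fixations(fixsets, stim)
        h = select_bandwidth(pts)
        cs = mean_shift(pts, h, stimulus_id=stim)
        aoi = label_cells(build_voronoi(cs, geometry), derive_label_map(cs, EXP_ANCHORS))
        for fs in fixsets:
            if fs.stimulus_id == stim:
                parts.append(assign_fixations(fs, aoi))
    labeled = pd.concat(parts, ignore_index=True)
    rfd = compute_rfd(labeled, ["Background", "Face", "Target"])

    def face_by_group(table):
        per_part = (
            table.query("aoi_label == 'Face'")
            .groupby(["group", "participant"], sort=True)["rfd"]
            .mean()
            .reset_index()
        )
        return summarize_by_group(per_part, ["group"])

    return face_by_group(rfd), face_by_group(data.truth_rfd)
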