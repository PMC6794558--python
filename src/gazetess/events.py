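"""Fixation/saccade event detection from binocular gaze traces.

The detector follows the classic velocity-threshold family but estimates its
threshold adaptively, per participant and per trial, from the trace's own
velocity distribution:

1. the two eyes are fused into a cyclopean trace (coordinates averaged;
   when one eye is missing the other substitutes; nothing is fabricated
   across time),
2. point-to-point Euclidean velocity is computed from actual timestamps,
3. a smoothed density of log10 velocity is inspected: if the slow
   (fixation) and fast (saccade) modes are both visible, the threshold is
   placed at the density minimum between them; otherwise a robust fallback
   (median + 5*MAD) is used,
4. maximal sub-threshold runs become candidate fixations; nearby candidates
   are merged, and candidates shorter than a noise floor are discarded.

Each threshold records which branch produced it, so the provenance of every
classification is auditable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal, stats

from .geometry import ScreenGeometry, pixels_per_degree
from .trace import GazeTrace

__all__ = [
    "DetectionConfig",
    "CyclopeanTrace",
    "VelocitySeries",
    "VelocityThreshold",
    "Fixation",
    "FixationSet",
    "fuse_eyes",
    "smooth_positions",
    "compute_velocity",
    "estimate_threshold",
    "classify_events",
    "merge_fixations",
    "detect_fixations",
]

log = logging.getLogger(__name__)

SOURCE_BOTH = "both_eyes"
SOURCE_LEFT = "left_only"
SOURCE_RIGHT = "right_only"
SOURCE_MISSING = "missing"


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable parameters of the event detector.

    min_fixation_ms
        Noise floor: candidate fixations shorter than this are discarded.
    merge_max_gap_ms / merge_max_dist_deg
        Successive fixations closer than both bounds are merged into one.
    smooth_window
        Width (samples, odd) of the centred moving average applied to
        cyclopean positions before velocity computation; 1 disables it.
    fixed_threshold
        Optional fixed velocity threshold (px/s) bypassing estimation.
    kde_grid / kde_bw_log / peak_prominence
        Resolution and bandwidth (log10 px/s units) of the log-velocity
        density estimate, and the relative prominence a mode must have to
        count as a velocity population.
    valley_position
        Where in the low-density region between the two velocity modes the
        threshold sits: 0 = at the slow edge (just above the fixation-noise
        population), 1 = at the fast edge.
    mad_mult
        Multiplier of the MAD in the robust fallback threshold.
    """

    min_fixation_ms: float = 60.0
    merge_max_gap_ms: float = 75.0
    merge_max_dist_deg: float = 0.7
    merge_max_dist_px: float | None = None
    smooth_window: int = 3
    fixed_threshold: float | None = None
    kde_grid: int = 512
    kde_bw_log: float = 0.12
    peak_prominence: float = 0.03
    valley_position: float = 0.0
    mad_mult: float = 5.0

    def merge_radius_px(self, geometry: ScreenGeometry | None) -> float:
        if self.merge_max_dist_px is not None:
            return self.merge_max_dist_px
        if geometry is None:
            raise ValueError("merge radius in degrees requires a ScreenGeometry")
        return self.merge_max_dist_deg * pixels_per_degree(geometry, axis="mean")


@dataclass
class CyclopeanTrace:
    """Single fused gaze coordinate per sample, with per-sample provenance."""

    participant_id: str
    group: str
    stimulus_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    source: np.ndarray  # one of the SOURCE_* strings per sample
    geometry: ScreenGeometry
    nominal_rate: float = 250.0

    @property
    def trace_id(self) -> str:
        return f"{self.participant_id}:{self.stimulus_id}"

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.x)

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass
class VelocitySeries:
    """Pairwise Euclidean speeds between consecutive valid samples.

    ``t`` is the midpoint of each contributing sample pair and ``pair_index``
    the index of the pair's first sample in the source trace.
    """

    t: np.ndarray
    v: np.ndarray  # px/s, >= 0
    pair_index: np.ndarray
    trace_id: str = ""

    def __len__(self) -> int:
        return int(self.v.size)


@dataclass(frozen=True)
class VelocityThreshold:
    """Velocity cut separating fixation from saccade samples (px/s)."""

    value: float
    method: str  # adaptive_bimodal | fallback_robust | fixed
    trace_id: str = ""

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("threshold must be positive")


@dataclass
class Fixation:
    x: float
    y: float
    onset: float
    offset: float
    duration: float
    n_samples: int
    merged_from: int = 1
    label: str | None = None  # planted semantic label (synthetic truth only)


@dataclass
class FixationSet:
    """Classified fixations of one trace, with classifier provenance."""

    trace_id: str
    participant_id: str
    group: str
    stimulus_id: str
    fixations: list
    threshold: VelocityThreshold
    total_on_screen_duration: float
    geometry: ScreenGeometry | None = None
    sample_labels: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.fixations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": self.participant_id,
                "group": self.group,
                "stimulus": self.stimulus_id,
                "x": [f.x for f in self.fixations],
                "y": [f.y for f in self.fixations],
                "onset_ms": [f.onset for f in self.fixations],
                "offset_ms": [f.offset for f in self.fixations],
                "duration_ms": [f.duration for f in self.fixations],
                "n_samples": [f.n_samples for f in self.fixations],
                "merged_from": [f.merged_from for f in self.fixations],
            }
        )


def fuse_eyes(trace: GazeTrace) -> CyclopeanTrace:
    """Fuse binocular samples into one cyclopean coordinate per sample.

    Both eyes valid -> arithmetic mean of the two; one eye valid -> that
    eye's coordinates (cross-eye substitution); both missing -> the sample
    stays missing.  No interpolation across time is performed.
    """
    both = trace.valid_left & trace.valid_right
    left_only = trace.valid_left & ~trace.valid_right
    right_only = trace.valid_right & ~trace.valid_left
    x = np.full(len(trace), np.nan)
    y = np.full(len(trace), np.nan)
    x[both] = 0.5 * (trace.left_x[both] + trace.right_x[both])
    y[both] = 0.5 * (trace.left_y[both] + trace.right_y[both])
    x[left_only] = trace.left_x[left_only]
    y[left_only] = trace.left_y[left_only]
    x[right_only] = trace.right_x[right_only]
    y[right_only] = trace.right_y[right_only]
    source = np.full(len(trace), SOURCE_MISSING, dtype=object)
    source[both] = SOURCE_BOTH
    source[left_only] = SOURCE_LEFT
    source[right_only] = SOURCE_RIGHT
    return CyclopeanTrace(
        participant_id=trace.participant_id,
        group=trace.group,
        stimulus_id=trace.stimulus_id,
        t=trace.t.copy(),
        x=x,
        y=y,
        source=source,
        geometry=trace.geometry,
        nominal_rate=trace.nominal_rate,
    )


def smooth_positions(ct: CyclopeanTrace, window: int) -> CyclopeanTrace:
    """Centred moving average of the cyclopean positions.

    Missing samples stay missing; valid samples average over the valid
    members of their window.  ``window <= 1`` is the identity.
    """
    if window <= 1:
        return ct
    if window % 2 == 0:
        raise ValueError("smooth_window must be odd")
    xs = pd.Series(ct.x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    ys = pd.Series(ct.y).rolling(window, center=True, min_periods=1).mean().to_numpy()
    valid = ct.valid
    x = np.where(valid, xs, np.nan)
    y = np.where(valid, ys, np.nan)
    return replace(ct, x=x, y=y, t=ct.t.copy(), source=ct.source.copy())


def compute_velocity(ct: CyclopeanTrace) -> VelocitySeries:
    """Euclidean point-to-point velocity between consecutive valid samples.

    ``v = sqrt(dx^2 + dy^2) / dt`` in px/s using actual timestamps; pairs
    that span a missing sample are omitted.
    """
    valid = ct.valid
    if int(valid.sum()) < 2:
        raise ValueError(f"insufficient data for velocity in trace {ct.trace_id!r}")
    pair = valid[:-1] & valid[1:]
    idx = np.flatnonzero(pair)
    dt = (ct.t[idx + 1] - ct.t[idx]) / 1000.0  # s
    dx = ct.x[idx + 1] - ct.x[idx]
    dy = ct.y[idx + 1] - ct.y[idx]
    v = np.hypot(dx, dy) / dt
    tmid = 0.5 * (ct.t[idx + 1] + ct.t[idx])
    return VelocitySeries(t=tmid, v=v, pair_index=idx, trace_id=ct.trace_id)


def _robust_fallback(v: np.ndarray, mad_mult: float) -> float:
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    # degenerate series (mad == 0) still needs a cut above every sample
    return max(med + mad_mult * mad, med * 1.05 + 1e-9)


def estimate_threshold(
    vs: VelocitySeries | np.ndarray, config: DetectionConfig | None = None
) -> VelocityThreshold:
    """Adaptive per-trace velocity threshold.

    Estimates a Gaussian KDE of log10 velocity.  If at least two modes with
    relative prominence ``config.peak_prominence`` are present, the threshold
    is the density minimum between the two most prominent modes (slow =
    fixation population, fast = saccade population).  Degenerate or unimodal
    series fall back to median + ``mad_mult``*MAD, and the method tag records
    which branch fired.  Deterministic given the series and config.
    """
    config = config or DetectionConfig()
    if isinstance(vs, np.ndarray):
        vs = VelocitySeries(t=np.arange(vs.size, dtype=float), v=np.asarray(vs, float),
                            pair_index=np.arange(vs.size), trace_id="")
    if len(vs) == 0:
        raise ValueError("cannot estimate a threshold from an empty velocity series")
    if config.fixed_threshold is not None:
        return VelocityThreshold(config.fixed_threshold, "fixed", vs.trace_id)
    v = np.asarray(vs.v, dtype=float)
    positive = v[v > 0]
    if positive.size < 10 or np.ptp(positive) == 0:
        thr = _robust_fallback(v, config.mad_mult)
        log.warning("trace %s: degenerate velocity series, robust fallback threshold %.3g",
                    vs.trace_id, thr)
        return VelocityThreshold(thr, "fallback_robust", vs.trace_id)
    floor = positive.min() * 0.1
    logv = np.log10(np.maximum(v, floor))
    try:
        # fixed bandwidth in log10-velocity units: the saccade mode holds only
        # a small fraction of the samples and a Scott-factor bandwidth on the
        # full mixture smooths it away
        kde = stats.gaussian_kde(logv, bw_method=config.kde_bw_log / max(logv.std(), 1e-12))
    except np.linalg.LinAlgError:
        thr = _robust_fallback(v, config.mad_mult)
        return VelocityThreshold(thr, "fallback_robust", vs.trace_id)
    pad = 0.1
    grid = np.linspace(logv.min() - pad, logv.max() + pad, config.kde_grid)
    dens = kde(grid)
    peaks, props = signal.find_peaks(dens, prominence=config.peak_prominence * dens.max())
    if peaks.size >= 2:
        # fast (saccade) mode: the rightmost qualifying peak.  Slow
        # (fixation) mode: the most prominent peak left of it.  Intermediate
        # bumps (e.g. eye-switch jitter) are neither.
        hi = int(peaks[-1])
        left = np.argmax(props["prominences"][:-1])
        lo = int(peaks[left])
        seg = dens[lo : hi + 1]
        vmin = seg.min()
        # the inter-mode density is often a wide near-zero plateau and the raw
        # argmin sits arbitrarily within it.  Low-density indices may also be
        # split by secondary slow bumps (e.g. eye-switch jitter when one eye
        # drops out), which belong to the fixation population: anchor the cut
        # at the slow edge of the low-density segment adjacent to the fast
        # mode, so everything slower stays classified as fixation and slow
        # saccades stay above the cut.
        low = np.flatnonzero(seg <= vmin + 0.05 * (seg.max() - vmin))
        breaks = np.flatnonzero(np.diff(low) > 1)
        start = low[breaks[-1] + 1] if breaks.size else low[0]
        end = low[-1]
        valley = lo + int(round(start + config.valley_position * (end - start)))
        thr = float(10.0 ** grid[valley])
        return VelocityThreshold(thr, "adaptive_bimodal", vs.trace_id)
    thr = _robust_fallback(v, config.mad_mult)
    log.info("trace %s: unimodal velocity density, robust fallback threshold %.3g",
             vs.trace_id, thr)
    return VelocityThreshold(thr, "fallback_robust", vs.trace_id)


def _run_bounds(mask: np.ndarray) -> list[tuple[int, int]]:
    """Start/end (inclusive) indices of maximal True runs."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size - 1)
    return list(zip(starts, ends))


def _dwell_weights(t: np.ndarray) -> np.ndarray:
    """Per-sample dwell time (trapezoid rule) within a run of samples."""
    if t.size == 1:
        return np.ones(1)
    w = np.empty(t.size)
    w[0] = (t[1] - t[0]) / 2.0
    w[-1] = (t[-1] - t[-2]) / 2.0
    if t.size > 2:
        w[1:-1] = (t[2:] - t[:-2]) / 2.0
    return w


def _total_on_screen(ct: CyclopeanTrace) -> float:
    valid = ct.valid
    on = valid.copy()
    on[valid] &= (
        (ct.x[valid] >= 0)
        & (ct.x[valid] < ct.geometry.raster_width)
        & (ct.y[valid] >= 0)
        & (ct.y[valid] < ct.geometry.raster_height)
    )
    if not np.any(on):
        return 0.0
    w = np.zeros(len(ct))
    if len(ct) > 1:
        w = _dwell_weights(ct.t)
    return float(w[on].sum())


def classify_events(
    ct: CyclopeanTrace,
    thr: VelocityThreshold,
    config: DetectionConfig | None = None,
    min_fixation_ms: float | None = None,
) -> FixationSet:
    """Partition a cyclopean trace into fixations and saccades.

    Maximal runs of consecutive sample pairs with sub-threshold velocity
    become candidate fixations; candidates shorter than ``min_fixation_ms``
    (default from config) are discarded as noise.  Fixation position is the
    dwell-time-weighted centroid of the run's samples.  The per-sample
    partition (fixation / saccade / discarded / missing) is retained on the
    returned set for audit.
    """
    config = config or DetectionConfig()
    if min_fixation_ms is None:
        min_fixation_ms = config.min_fixation_ms
    n = len(ct)
    labels = np.full(n, "missing", dtype=object)
    valid = ct.valid
    labels[valid] = "discarded"
    fixations: list[Fixation] = []
    if int(valid.sum()) >= 2:
        vs = compute_velocity(ct)
        pair_fix = np.zeros(n - 1, dtype=bool)
        pair_sac = np.zeros(n - 1, dtype=bool)
        pair_fix[vs.pair_index] = vs.v < thr.value
        pair_sac[vs.pair_index] = vs.v >= thr.value
        # samples strictly interior to saccade runs (and their endpoints not
        # shared with a fixation run) are saccade samples
        for s, e in _run_bounds(pair_sac):
            labels[s : e + 2] = "saccade"
        for s, e in _run_bounds(pair_fix):
            t_run = ct.t[s : e + 2]
            duration = float(t_run[-1] - t_run[0])
            if duration < min_fixation_ms:
                # boundary samples shared with a saccade run keep that label
                seg = labels[s : e + 2]
                seg[seg != "saccade"] = "discarded"
                labels[s : e + 2] = seg
                continue
            labels[s : e + 2] = "fixation"
            w = _dwell_weights(t_run)
            cx = float(np.average(ct.x[s : e + 2], weights=w))
            cy = float(np.average(ct.y[s : e + 2], weights=w))
            fixations.append(
                Fixation(
                    x=cx,
                    y=cy,
                    onset=float(t_run[0]),
                    offset=float(t_run[-1]),
                    duration=duration,
                    n_samples=int(e - s + 2),
                )
            )
    fixations.sort(key=lambda f: f.onset)
    return FixationSet(
        trace_id=ct.trace_id,
        participant_id=ct.participant_id,
        group=ct.group,
        stimulus_id=ct.stimulus_id,
        fixations=fixations,
        threshold=thr,
        total_on_screen_duration=_total_on_screen(ct),
        geometry=ct.geometry,
        sample_labels=labels,
    )


def _merge_pair(a: Fixation, b: Fixation) -> Fixation:
    dur = a.duration + b.duration
    if dur <= 0:
        wa = wb = 0.5
    else:
        wa, wb = a.duration / dur, b.duration / dur
    return Fixation(
        x=a.x * wa + b.x * wb,
        y=a.y * wa + b.y * wb,
        onset=a.onset,
        offset=b.offset,
        duration=b.offset - a.onset,
        n_samples=a.n_samples + b.n_samples,
        merged_from=a.merged_from + b.merged_from,
    )


def merge_fixations(fs: FixationSet, config: DetectionConfig | None = None) -> FixationSet:
    """Merge successive fixations separated by a short gap and a small
    displacement into one.

    Consecutive fixations with inter-fixation gap <= ``merge_max_gap_ms`` and
    centroid distance <= the merge radius (``merge_max_dist_deg`` converted
    to px, or ``merge_max_dist_px``) are combined; the merged event spans the
    first onset to the last offset and its centroid is duration-weighted.
    Runs to a fixpoint, so the operation is idempotent.
    """
    config = config or DetectionConfig()
    radius = config.merge_radius_px(fs.geometry)
    fixations = sorted(fs.fixations, key=lambda f: f.onset)
    changed = True
    while changed:
        changed = False
        merged: list[Fixation] = []
        for f in fixations:
            if merged:
                prev = merged[-1]
                gap = f.onset - prev.offset
                dist = float(np.hypot(f.x - prev.x, f.y - prev.y))
                if gap <= config.merge_max_gap_ms and dist <= radius:
                    merged[-1] = _merge_pair(prev, f)
                    changed = True
                    continue
            merged.append(f)
        fixations = merged
    return replace(fs, fixations=fixations)


def detect_fixations(trace: GazeTrace, config: DetectionConfig | None = None) -> FixationSet:
    """Full adaptive event-detection chain for one trace.

    fuse -> smooth -> velocity -> per-trace threshold -> classify -> merge ->
    noise-duration filter.  The minimum-duration filter runs after merging so
    that single-sample velocity breaks inside a dwell cannot strand
    sub-minimum fragments.
    """
    config = config or DetectionConfig()
    ct = fuse_eyes(trace)
    cts = smooth_positions(ct, config.smooth_window)
    if int(cts.valid.sum()) < 2:
        warnings.warn(f"trace {ct.trace_id!r}: fewer than 2 valid samples, no events")
        return FixationSet(
            trace_id=ct.trace_id,
            participant_id=ct.participant_id,
            group=ct.group,
            stimulus_id=ct.stimulus_id,
            fixations=[],
            threshold=VelocityThreshold(1.0, "fallback_robust", ct.trace_id),
            total_on_screen_duration=_total_on_screen(ct),
            geometry=ct.geometry,
        )
    vs = compute_velocity(cts)
    thr = estimate_threshold(vs, config)
    fs = classify_events(cts, thr, config, min_fixation_ms=0.0)
    fs = merge_fixations(fs, config)
    kept = [f for f in fs.fixations if f.duration >= config.min_fixation_ms]
    return replace(fs, fixations=kept)
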