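"""Mean-shift identification of fixation-density centroids.

Fixations pooled across participants form a 2-D point cloud on the screen;
its density peaks are the places the audience actually looked.  Mean shift
seeks those peaks nonparametrically: every point climbs the Gaussian-kernel
density estimate by repeatedly moving to the kernel-weighted local mean of
its neighbourhood, and points that converge to the same peak form a cluster.
The converged peak locations (modes) become the sites of the Voronoi
tessellation downstream.

The implementation is deterministic and permutation-invariant: iterating is
vectorised over all points simultaneously, and mode merging orders candidate
modes by their density (ties broken by coordinates), never by input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .events import FixationSet

__all__ = [
    "ClusterConfig",
    "CentroidSet",
    "pool_fixations",
    "select_bandwidth",
    "mean_shift",
    "kde_density",
]


@dataclass(frozen=True)
class ClusterConfig:
    """Mean-shift parameters.

    fixed_bandwidth
        Overrides the data-driven bandwidth when set (px).
    bandwidth_scale
        Multiplier on the k-nearest-neighbour scale estimate.
    tol / max_iter
        Convergence tolerance (px) and iteration cap of the uphill walk.
    merge_radius_factor
        Converged locations within ``factor * bandwidth`` of an accepted
        mode are merged into it (0.5 => bandwidth/2).
    weight_by_duration
        When True, fixation durations weight the density; by default each
        fixation counts once.
    min_cluster_size
        Clusters with fewer assigned points are dissolved into their nearest
        surviving mode; 1 disables pruning.
    """

    fixed_bandwidth: float | None = None
    bandwidth_scale: float = 1.5
    tol: float = 1e-3
    max_iter: int = 500
    merge_radius_factor: float = 0.5
    weight_by_duration: bool = False
    min_cluster_size: int = 1


@dataclass
class CentroidSet:
    """Mean-shift modes and per-point cluster assignments."""

    stimulus_id: str
    centroids: np.ndarray  # (K, 2) px
    assignments: np.ndarray  # (N,) centroid index per input point
    bandwidth: float
    iterations: np.ndarray = field(default=None, repr=False)  # per-point counts
    points: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_clusters(self) -> int:
        return int(self.centroids.shape[0])

    def counts(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.n_clusters)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stimulus": self.stimulus_id,
                "centroid": np.arange(self.n_clusters),
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "n_assigned": self.counts(),
            }
        )


def pool_fixations(
    fixsets: list[FixationSet], stimulus_id: str, scope: str = "all_groups"
) -> pd.DataFrame:
    """Flatten fixation sets into weighted on-screen fixation points.

    ``scope="all_groups"`` pools every participant watching the stimulus
    into one cloud (shared AOIs for all groups); ``scope="per_group"``
    returns the same rows with the group column intact so callers can split.
    Off-screen fixations are excluded here.
    """
    if scope not in ("all_groups", "per_group"):
        raise ValueError(f"unknown pooling scope {scope!r}")
    rows = []
    geometry = None
    for fs in fixsets:
        if fs.stimulus_id != stimulus_id:
            continue
        if geometry is None:
            geometry = fs.geometry
        elif fs.geometry != geometry:
            raise ValueError("pooled fixation sets must share one screen geometry")
        for f in fs.fixations:
            if geometry is not None and not geometry.contains(f.x, f.y):
                continue
            rows.append(
                {
                    "x": f.x,
                    "y": f.y,
                    "weight": f.duration,
                    "participant": fs.participant_id,
                    "group": fs.group,
                    "stimulus": fs.stimulus_id,
                }
            )
    if not rows:
        raise ValueError(f"no on-screen fixations pooled for stimulus {stimulus_id!r}")
    return pd.DataFrame(rows)


def _as_xy(points) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        return points[["x", "y"]].to_numpy(dtype=float)
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array or a DataFrame with x, y")
    return arr


def select_bandwidth(points, config: ClusterConfig | None = None) -> float:
    """Data-driven kernel bandwidth for the fixation cloud (px).

    Scale is estimated from local interpoint spacing: the median distance to
    the ceil(sqrt(n))-th nearest neighbour, times ``bandwidth_scale``.  Being
    local, the estimate is not inflated by the distance *between* density
    peaks, so multimodal fixation maps keep their modes.  Scale-equivariant
    and overridable via ``fixed_bandwidth``.
    """
    config = config or ClusterConfig()
    if config.fixed_bandwidth is not None:
        return float(config.fixed_bandwidth)
    xy = _as_xy(points)
    n = xy.shape[0]
    if n < 2:
        raise ValueError("bandwidth selection needs at least 2 points")
    k = int(np.ceil(np.sqrt(n)))
    k = min(k, n - 1)
    tree = cKDTree(xy)
    dist, _ = tree.query(xy, k=k + 1)  # column 0 is the point itself
    h = float(np.median(dist[:, k])) * config.bandwidth_scale
    if h == 0.0:
        raise ValueError("zero dispersion: all points identical")
    return h


def kde_density(at: np.ndarray, xy: np.ndarray, bandwidth: float,
                weights: np.ndarray | None = None) -> np.ndarray:
    """Unnormalised Gaussian KDE evaluated at the given locations."""
    at = np.atleast_2d(np.asarray(at, dtype=float))
    d2 = ((at[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    k = np.exp(-d2 / (2.0 * bandwidth**2))
    if weights is not None:
        k = k * weights[None, :]
    return k.sum(axis=1)


def mean_shift(
    points,
    bandwidth: float,
    config: ClusterConfig | None = None,
    stimulus_id: str = "",
) -> CentroidSet:
    """Gaussian-kernel mean-shift mode seeking.

    Every point iterates uphill to the kernel-weighted local mean until the
    step falls below ``config.tol`` or ``config.max_iter`` is reached
    (non-converged points are attached to the nearest accepted mode with a
    warning).  Converged locations within ``bandwidth/2`` of one another are
    merged into a single centroid; each input point is assigned to exactly
    one centroid.  Deterministic and independent of input point order.
    """
    import warnings

    config = config or ClusterConfig()
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    df = points if isinstance(points, pd.DataFrame) else None
    xy = _as_xy(points)
    n = xy.shape[0]
    if n == 0:
        raise ValueError("mean_shift requires at least one point")
    w = None
    if config.weight_by_duration and df is not None and "weight" in df:
        w = df["weight"].to_numpy(dtype=float)
    h2 = 2.0 * bandwidth**2
    y = xy.copy()
    iters = np.zeros(n, dtype=int)
    active = np.ones(n, dtype=bool)
    for _ in range(config.max_iter):
        if not active.any():
            break
        ya = y[active]
        d2 = ((ya[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        k = np.exp(-d2 / h2)
        if w is not None:
            k = k * w[None, :]
        new = (k @ xy) / k.sum(axis=1, keepdims=True)
        step = np.linalg.norm(new - ya, axis=1)
        y[active] = new
        iters[active] += 1
        still = step >= config.tol
        idx = np.flatnonzero(active)
        active[idx[~still]] = False
    if active.any():
        warnings.warn(
            f"mean_shift: {int(active.sum())} point(s) not converged after "
            f"{config.max_iter} iterations; assigned to nearest mode"
        )

    # merge converged locations into modes, densest first (permutation-invariant)
    dens = kde_density(y, xy, bandwidth, w)
    order = np.lexsort((y[:, 1], y[:, 0], -dens))
    merge_r = config.merge_radius_factor * bandwidth
    modes: list[np.ndarray] = []
    assign = np.full(n, -1, dtype=int)
    for i in order:
        placed = False
        for m, loc in enumerate(modes):
            if np.hypot(*(y[i] - loc)) <= merge_r:
                assign[i] = m
                placed = True
                break
        if not placed:
            modes.append(y[i].copy())
            assign[i] = len(modes) - 1
    centroids = np.array(modes)

    if config.min_cluster_size > 1 and centroids.shape[0] > 1:
        counts = np.bincount(assign, minlength=centroids.shape[0])
        keep = counts >= config.min_cluster_size
        if keep.any() and not keep.all():
            kept_idx = np.flatnonzero(keep)
            remap = {old: new for new, old in enumerate(kept_idx)}
            kept_modes = centroids[keep]
            for i in range(n):
                if keep[assign[i]]:
                    assign[i] = remap[assign[i]]
                else:
                    d = np.linalg.norm(kept_modes - y[i], axis=1)
                    assign[i] = int(np.argmin(d))
            centroids = kept_modes

    # stable ordering: by density at the mode, descending (ties by position)
    mode_dens = kde_density(centroids, xy, bandwidth, w)
    order = np.lexsort((centroids[:, 1], centroids[:, 0], -mode_dens))
    remap = np.empty(len(order), dtype=int)
    remap[order] = np.arange(len(order))
    centroids = centroids[order]
    assign = remap[assign]
    return CentroidSet(
        stimulus_id=stimulus_id,
        centroids=centroids,
        assignments=assign,
        bandwidth=float(bandwidth),
        iterations=iters,
        points=df,
    )
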