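"""Box-level quantification of pathology activation heatmaps.

A classifier attention heatmap over an annotated sampling box is reduced to a
scalar burden measure in three steps: the box mask is partitioned into
contiguous, approximately equal-area segments (~200 x 200 um by default), the
activation is averaged within each segment, and a summary statistic (by
default the 99th percentile) is taken across segment averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label

__all__ = [
    "ANATOMICAL_LABELS",
    "INCLUSION_CLASSES",
    "SUMMARY_STATISTICS",
    "HeatMap",
    "SamplingBox",
    "SegmentPartition",
    "partition_roi",
    "segment_averages",
    "box_summary",
]

#: Anatomical sampling-box vocabulary (hippocampal subfields and MTL cortex).
ANATOMICAL_LABELS = (
    "CA1", "CA2", "CA3", "DG-GCL", "DG-H", "CA1-SUB", "SUB-PrS",
    "EC-med", "EC-ctr", "EC-lat", "BA35", "BA36",
)

#: Activation-map classes produced by the upstream patch classifier.
INCLUSION_CLASSES = (
    "tangles", "threads", "neuronal_glial", "neuritic", "other", "background",
)

#: Candidate summary statistics over segment averages.
SUMMARY_STATISTICS = ("mean", "median", "max", "q25", "q75", "q90", "q95", "q99")

#: Default segment target area: 200 x 200 um.
DEFAULT_TARGET_AREA_UM2 = 200.0 * 200.0


@dataclass
class HeatMap:
    """Gridded activation values in [0, 1] for one inclusion class.

    Parameters
    ----------
    values : ndarray of shape (H, W)
        Per-pixel activation, finite and in [0, 1].
    pixel_size_um : float
        Physical pixel size in micrometres.
    inclusion_class : str
        One of :data:`INCLUSION_CLASSES`.
    """

    values: np.ndarray
    pixel_size_um: float
    inclusion_class: str = "tangles"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("heatmap values must be a 2D grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("heatmap contains non-finite activations")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("activations must lie in [0, 1]")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        if self.inclusion_class not in INCLUSION_CLASSES:
            raise ValueError(f"unknown inclusion class {self.inclusion_class!r}")


@dataclass
class SamplingBox:
    """Annotated sampling region: a binary mask aligned to a heatmap grid."""

    box_id: str
    slide_id: str
    anatomical_label: str
    mask: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.mask.any():
            raise ValueError("sampling-box mask is empty")
        if self.anatomical_label not in ANATOMICAL_LABELS:
            raise ValueError(f"unknown anatomical label {self.anatomical_label!r}")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")


@dataclass
class SegmentPartition:
    """Disjoint contiguous segments covering a sampling-box mask.

    ``labels`` is an int grid the shape of the mask: -1 outside the mask,
    segment index (0-based) inside.
    """

    labels: np.ndarray
    target_area_um2: float = DEFAULT_TARGET_AREA_UM2
    segments: list = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.labels.max() + 1
        self.segments = [np.flatnonzero(self.labels.ravel() == i) for i in range(n)]

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def sizes(self) -> np.ndarray:
        return np.array([s.size for s in self.segments])


def _subset_components(coords: np.ndarray, shape: tuple) -> list[np.ndarray]:
    """4-connected components of a pixel subset, as index arrays into coords."""
    grid = np.zeros(shape, dtype=bool)
    grid[coords[:, 0], coords[:, 1]] = True
    lab = cc_label(grid, connectivity=1)
    vals = lab[coords[:, 0], coords[:, 1]]
    return [np.flatnonzero(vals == v) for v in np.unique(vals)]


def _principal_order(coords: np.ndarray) -> np.ndarray:
    """Stable ordering of pixels along the principal axis of the point cloud."""
    c = coords - coords.mean(axis=0)
    cov = c.T @ c
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis  # sign convention for determinism
    t = c @ axis
    return np.lexsort((coords[:, 1], coords[:, 0], t))


def _geodesic_order(coords: np.ndarray, shape: tuple) -> np.ndarray:
    """Order pixels by 4-connected BFS distance from an extremal pixel.

    The start pixel is found by a double BFS sweep (an approximate graph
    diameter endpoint), so the ordering peels the set from one end; any
    distance prefix is a connected set."""
    grid = np.zeros(shape, dtype=bool)
    grid[coords[:, 0], coords[:, 1]] = True

    def bfs_dist(start_rc):
        dist = np.full(shape, -1, dtype=int)
        frontier = np.zeros(shape, dtype=bool)
        frontier[start_rc] = True
        d = 0
        while frontier.any():
            dist[frontier] = d
            grown = np.zeros(shape, dtype=bool)
            grown[1:, :] |= frontier[:-1, :]
            grown[:-1, :] |= frontier[1:, :]
            grown[:, 1:] |= frontier[:, :-1]
            grown[:, :-1] |= frontier[:, 1:]
            frontier = grown & grid & (dist < 0)
            d += 1
        return dist

    d0 = bfs_dist((coords[0, 0], coords[0, 1]))
    dvals = d0[coords[:, 0], coords[:, 1]]
    far = coords[np.argmax(dvals)]
    d1 = bfs_dist((far[0], far[1]))
    key = d1[coords[:, 0], coords[:, 1]]
    return np.lexsort((coords[:, 1], coords[:, 0], key))


def _is_connected(grid: np.ndarray) -> bool:
    return cc_label(grid, connectivity=1).max() <= 1


def _rebalance(coords: np.ndarray, in_a: np.ndarray, n_a: int, shape: tuple) -> None:
    """Move boundary pixels across the cut until side A holds ~n_a pixels.

    Only moves that keep both sides 4-connected are made; stops when the quota
    is met (within 1 pixel) or no admissible move remains. Mutates ``in_a``.
    """
    grid_a = np.zeros(shape, dtype=bool)
    grid_b = np.zeros(shape, dtype=bool)
    grid_a[coords[in_a, 0], coords[in_a, 1]] = True
    grid_b[coords[~in_a, 0], coords[~in_a, 1]] = True
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(coords)}

    for _ in range(2 * len(coords)):
        excess = int(in_a.sum()) - n_a
        if abs(excess) <= 1:
            break
        donor, recv = (grid_a, grid_b) if excess > 0 else (grid_b, grid_a)
        # candidate donor pixels adjacent to the receiving side
        near = np.zeros_like(recv)
        near[1:, :] |= recv[:-1, :]
        near[:-1, :] |= recv[1:, :]
        near[:, 1:] |= recv[:, :-1]
        near[:, :-1] |= recv[:, 1:]
        cand = donor & near
        moved = False
        for r, c in np.argwhere(cand):
            donor[r, c] = False
            if _is_connected(donor):
                recv[r, c] = True
                in_a[index[(int(r), int(c))]] = donor is grid_b
                moved = True
                break
            donor[r, c] = True
        if not moved:
            break


def _bisect(coords: np.ndarray, k: int, shape: tuple) -> list[np.ndarray]:
    """Recursively split a connected pixel set into k connected, balanced parts.

    The set is cut at the balanced position along its principal axis; stray
    components created by the cut are reassigned across the cut until both
    sides are connected (each stray piece is adjacent to the other side by
    construction, so reassignment can only merge components).  A boundary-move
    pass then restores the size quota lost during repair.
    """
    if k <= 1:
        return [coords]
    k1 = k // 2
    n_a = int(round(len(coords) * k1 / k))

    best = None
    for order_fn in (_principal_order, _geodesic_order):
        order = order_fn(coords, shape) if order_fn is _geodesic_order \
            else order_fn(coords)
        in_a = np.zeros(len(coords), dtype=bool)
        in_a[order[:n_a]] = True

        for _ in range(50):
            moved = False
            for side in (True, False):
                idx = np.flatnonzero(in_a == side)
                if idx.size == 0:
                    continue
                comps = _subset_components(coords[idx], shape)
                if len(comps) > 1:
                    comps.sort(key=len)
                    for comp in comps[:-1]:  # keep largest piece on this side
                        in_a[idx[comp]] = not side
                    moved = True
            if not moved:
                break

        if in_a.any() and not in_a.all():
            _rebalance(coords, in_a, n_a, shape)
        imbalance = abs(int(in_a.sum()) - n_a)
        if best is None or imbalance < best[0]:
            best = (imbalance, in_a)
        if imbalance <= 1:
            break

    in_a = best[1]
    a, b = coords[in_a], coords[~in_a]
    if a.size == 0 or b.size == 0:  # degenerate cut; give up on splitting
        return [coords]
    return _bisect(a, k1, shape) + _bisect(b, k - k1, shape)


def partition_roi(
    box: SamplingBox,
    target_area_um2: float = DEFAULT_TARGET_AREA_UM2,
    seed: int = 0,
) -> SegmentPartition:
    """Partition a sampling-box mask into contiguous ~equal-area segments.

    The number of segments is ``max(1, round(mask_area / target_area))``;
    disconnected mask components are partitioned separately.  A mask smaller
    than one target segment yields a single segment.  The procedure is
    deterministic; ``seed`` is accepted for interface uniformity (the
    recursive bisection has no random tie-breaks).

    Returns
    -------
    SegmentPartition
    """
    del seed  # deterministic algorithm
    if not (target_area_um2 > 0):
        raise ValueError("target_area_um2 must be positive")
    mask = box.mask
    if not mask.any():
        raise ValueError("zero-area mask")
    target_px = target_area_um2 / box.pixel_size_um**2

    labels = np.full(mask.shape, -1, dtype=int)
    lab = cc_label(mask, connectivity=1)
    next_id = 0
    for comp_val in np.unique(lab[mask]):
        coords = np.argwhere(lab == comp_val)
        k = max(1, int(round(coords.shape[0] / target_px)))
        for part in _bisect(coords, k, mask.shape):
            labels[part[:, 0], part[:, 1]] = next_id
            next_id += 1
    return SegmentPartition(labels=labels, target_area_um2=target_area_um2)


def segment_averages(heatmap: HeatMap, partition: SegmentPartition) -> np.ndarray:
    """Arithmetic mean of the activation over each segment's pixels."""
    if heatmap.values.shape != partition.labels.shape:
        raise ValueError(
            f"heatmap shape {heatmap.values.shape} does not match "
            f"partition shape {partition.labels.shape}"
        )
    lab = partition.labels
    inside = lab >= 0
    sums = np.bincount(lab[inside], weights=heatmap.values[inside],
                       minlength=partition.n_segments)
    counts = np.bincount(lab[inside], minlength=partition.n_segments)
    return sums / counts


_QUANTILES = {"q25": 0.25, "q75": 0.75, "q90": 0.90, "q95": 0.95, "q99": 0.99}


def box_summary(segment_values: np.ndarray, statistic: str = "q99") -> float:
    """Summary statistic across segment averages.

    Quantiles interpolate linearly between closest order statistics (position
    ``p * (n - 1)``, the default convention of mainstream numeric stacks).
    An empty input yields NaN (missing), never zero.
    """
    if statistic not in SUMMARY_STATISTICS:
        raise ValueError(f"unknown summary statistic {statistic!r}")
    v = np.asarray(segment_values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return float("nan")
    if statistic == "mean":
        return float(np.mean(v))
    if statistic == "median":
        return float(np.median(v))
    if statistic == "max":
        return float(np.max(v))
    return float(np.quantile(v, _QUANTILES[statistic]))


def check_partition(partition: SegmentPartition, box: SamplingBox,
                    tolerance: float = 0.2) -> None:
    """Validate partition invariants (coverage, disjointness, connectivity,
    balance); raises ValueError with a diagnostic, warns on balance only."""
    lab = partition.labels
    if not np.array_equal(lab >= 0, box.mask):
        raise ValueError("segments do not exactly cover the mask")
    target_px = partition.target_area_um2 / box.pixel_size_um**2
    for i, seg in enumerate(partition.segments):
        grid = np.zeros(lab.shape, dtype=bool)
        grid.ravel()[seg] = True
        if cc_label(grid, connectivity=1).max() != 1:
            raise ValueError(f"segment {i} is not edge-connected")
    if partition.n_segments > 1:
        sizes = partition.sizes()
        rel = np.abs(sizes - target_px) / target_px
        if rel.max() > tolerance:
            warnings.warn(
                f"segment sizes deviate from target by up to {rel.max():.0%}",
                stacklevel=2,
            )
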