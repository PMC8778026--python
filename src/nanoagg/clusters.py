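"""Aggregate detection and kinetics extraction.

Clusters are connected components of the graph whose edges join particle
pairs closer (center-to-center, minimum image) than 3R.  The criterion
needs no a-priori cluster count, and the minimum-image convention makes
aggregates that straddle the periodic boundary come out as single
clusters.  Two particles within 3R are necessarily inside the attractive
region of their interaction well, and a third particle cannot fit
between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "ClusterAssignment",
    "KineticsTrace",
    "pbc_displacement",
    "pair_distance",
    "find_clusters",
    "trace_from_trajectory",
]


def _round_half_away(x):
    """Round half away from zero (0.5 -> 1, -0.5 -> -1).

    np.round rounds half to even, which is not what the minimum-image
    round operator uses here; the tie at exactly half a box length is
    physically measure-zero but the convention is documented and tested.
    """
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def pbc_displacement(xi, xj, h_box: float):
    """Minimum-image displacement component xi - xj in a periodic box.

    Returns xi - xj - h_box * round((xi - xj)/h_box), in
    [-h_box/2, h_box/2]; the half-box tie maps +h_box/2 to -h_box/2
    (round half away from zero).
    """
    if h_box <= 0:
        raise ValueError("h_box must be positive")
    dx = np.asarray(xi, dtype=float) - np.asarray(xj, dtype=float)
    out = dx - h_box * _round_half_away(dx / h_box)
    return float(out) if out.ndim == 0 else out


def pair_distance(pi, pj, h_box: float) -> float:
    """Minimum-image Euclidean distance between two positions (nm)."""
    d = pbc_displacement(np.asarray(pi, float), np.asarray(pj, float), h_box)
    return float(np.sqrt(np.sum(np.atleast_1d(d) ** 2)))


@dataclass
class ClusterAssignment:
    """Partition of particles into aggregates."""

    labels: np.ndarray  # cluster id per particle, 0..n_clusters-1
    sizes: np.ndarray  # particle count per cluster id

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.labels.size and self.sizes.sum() != self.labels.size:
            raise ValueError("cluster sizes do not partition the particles")

    @property
    def n_clusters(self) -> int:
        return int(self.sizes.size)

    @property
    def mean_size(self) -> float:
        return float(self.labels.size / self.sizes.size) if self.sizes.size else 0.0


def find_clusters(positions, radius: float, h_box: float) -> ClusterAssignment:
    """Cluster particles whose minimum-image distance is < 3R.

    Uses a periodic k-d tree for candidate pairs (strict inequality is
    re-checked explicitly) and sparse connected components for the
    partition.  Monodisperse radius assumed; the threshold is on
    center-to-center distance.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        return ClusterAssignment(np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("positions must be an (N, 3) array")
    n = pos.shape[0]
    threshold = 3.0 * radius
    if threshold > h_box / 2.0:
        raise ValueError("3R threshold exceeds half the box: clustering ill-defined")
    tree = cKDTree(np.mod(pos, h_box), boxsize=h_box)
    pairs = tree.query_pairs(threshold * (1.0 + 1e-12), output_type="ndarray")
    if pairs.size:
        # enforce the strict < 3R criterion exactly
        delta = pbc_displacement(pos[pairs[:, 0]], pos[pairs[:, 1]], h_box)
        dist = np.sqrt((delta**2).sum(axis=1))
        pairs = pairs[dist < threshold]
    if pairs.size:
        adj = sparse.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        n_comp, labels = sparse.csgraph.connected_components(adj, directed=False)
    else:
        n_comp, labels = n, np.arange(n)
    sizes = np.bincount(labels, minlength=n_comp)
    return ClusterAssignment(labels, sizes)


@dataclass
class KineticsTrace:
    """Time series of aggregation state: cluster count and mean size.

    times are in microseconds; mean_size is the number-averaged particle
    count per aggregate; n_clusters may be fractional for model-derived
    traces (n_total / mean_size).
    """

    times: np.ndarray
    n_clusters: np.ndarray
    mean_size: np.ndarray
    n_total: float
    histograms: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.n_clusters = np.asarray(self.n_clusters, dtype=float)
        self.mean_size = np.asarray(self.mean_size, dtype=float)
        if not (self.times.size == self.n_clusters.size == self.mean_size.size):
            raise ValueError("trace columns differ in length")
        if self.times.size:
            cons = self.n_clusters * self.mean_size
            if not np.allclose(cons, self.n_total, rtol=1e-6):
                raise ValueError(
                    "conservation violated: n_clusters * mean_size != n_total"
                )

    def __len__(self) -> int:
        return self.times.size


def trace_from_trajectory(trajectory, radius: float, h_box: float) -> KineticsTrace:
    """Cluster every frame of a trajectory into a kinetics trace.

    ``trajectory`` is an iterable of (time_ps, positions) pairs as
    produced by the BD engine.  Times are converted to microseconds.
    """
    times, counts, means, hists = [], [], [], []
    n_total = None
    for t_ps, pos in trajectory:
        pos = np.asarray(pos, float)
        if n_total is None:
            n_total = pos.shape[0]
        elif pos.shape[0] != n_total:
            raise ValueError("inconsistent particle count across frames")
        ca = find_clusters(pos, radius, h_box)
        times.append(t_ps * 1e-6)
        counts.append(ca.n_clusters)
        means.append(ca.mean_size)
        hists.append(np.bincount(ca.sizes))
    return KineticsTrace(
        times=np.array(times),
        n_clusters=np.array(counts, dtype=float),
        mean_size=np.array(means),
        n_total=float(n_total if n_total is not None else 0),
        histograms=hists,
    )
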