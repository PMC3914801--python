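"""Shared geometric and rank machinery for map analysis.

A *sampled map* is a set of n units (neurons, multi-unit sites, voxels) with
2-D anatomical coordinates (map space) and a scalar functional label
(feature space), e.g. characteristic frequency or preferred azimuth.  The
feature space may be periodic (angle-like labels), in which case all feature
distances are circular.

This module provides the primitives every measure is built from: pairwise
distances in both spaces, tie-corrected ranks, Delaunay neighbor graphs and
graph geodesics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .exceptions import (
    ConfigurationError,
    DegenerateGeometryError,
    DisconnectedGraphError,
    InvalidInputError,
)

# Relative spread below which a point set is treated as collinear/coincident.
# scipy's Qhull usually raises on exactly degenerate input; this tolerance
# additionally catches near-degenerate sets whose triangulations are
# numerically meaningless.
DEGENERACY_RTOL = 1e-10


def philox_rng(seed: Optional[int]) -> np.random.Generator:
    """Counter-based random generator: deterministic, cheaply splittable."""
    return np.random.Generator(np.random.Philox(key=seed))


def wrap_periodic(values: np.ndarray, period: float) -> np.ndarray:
    """Wrap values into the canonical symmetric interval (-period/2, period/2]."""
    values = np.asarray(values, dtype=float)
    wrapped = values - period * np.floor(values / period + 0.5)
    # floor maps the upper boundary to -period/2; move it to +period/2
    wrapped = np.where(wrapped <= -period / 2, wrapped + period, wrapped)
    return wrapped


def circular_difference(a, b, period: float):
    """Shortest signed circular difference a - b, in (-period/2, period/2]."""
    return wrap_periodic(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), period)


@dataclass
class SampledMap:
    """Positions and feature labels of n sampled units.

    Parameters
    ----------
    positions : (n, 2) array
        Map-space (anatomical) coordinates, any consistent length unit.
    labels : (n,) array
        Feature-space coordinates (characteristic stimuli).
    periodic : bool
        Whether the feature space is circular (e.g. preferred angle).
    period : float, optional
        Full span of the circular feature space (e.g. 2*pi or 360).
        Required iff ``periodic``.
    subject_id : str, optional
        Tag identifying the subject the units were recorded from.
    """

    positions: np.ndarray
    labels: np.ndarray
    periodic: bool = False
    period: Optional[float] = None
    subject_id: Optional[str] = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.labels = np.asarray(self.labels, dtype=float).ravel()
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise InvalidInputError("positions must be an (n, 2) array")
        if self.positions.shape[0] != self.labels.shape[0]:
            raise InvalidInputError("positions and labels must have equal length")
        if self.positions.shape[0] < 2:
            raise InvalidInputError("a map needs at least 2 units")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidInputError("non-finite map-space coordinates")
        if not np.all(np.isfinite(self.labels)):
            raise InvalidInputError("non-finite feature labels")
        if self.periodic:
            if self.period is None or not self.period > 0:
                raise ConfigurationError("periodic maps require a positive period")
            self.labels = wrap_periodic(self.labels, self.period)
        elif self.period is not None:
            raise ConfigurationError("period given for a non-periodic map")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def with_labels(self, labels: np.ndarray) -> "SampledMap":
        """Copy of this map with the labels replaced (used by permutation tests)."""
        return SampledMap(
            positions=self.positions,
            labels=labels,
            periodic=self.periodic,
            period=self.period,
            subject_id=self.subject_id,
        )


@dataclass
class NeighborGraph:
    """Undirected neighbor graph over unit indices (no self-loops)."""

    edges: np.ndarray  # (m, 2) int array, each row i < j
    n: int

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if self.edges.size:
            self.edges = np.sort(self.edges, axis=1)
            self.edges = np.unique(self.edges, axis=0)
            if self.edges.min() < 0 or self.edges.max() >= self.n:
                raise InvalidInputError("edge index out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise InvalidInputError("self-loops not allowed")

    def adjacency(self) -> sparse.csr_matrix:
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * len(self.edges))
        return sparse.csr_matrix(
            (data, (np.r_[i, j], np.r_[j, i])), shape=(self.n, self.n)
        )


def pairwise_map_distance(smap: SampledMap) -> np.ndarray:
    """n x n matrix of Euclidean map-space (anatomical) distances."""
    return squareform(pdist(smap.positions))


def pairwise_feature_distance(smap: SampledMap) -> np.ndarray:
    """n x n matrix of feature-space distances (circular if periodic)."""
    diff = np.abs(smap.labels[:, None] - smap.labels[None, :])
    if smap.periodic:
        diff = np.minimum(diff, smap.period - diff)
    return diff


def condensed_pairs(n: int):
    """Index arrays (i, j) of the n(n-1)/2 unordered pairs, pdist ordering."""
    return np.triu_indices(n, k=1)


def tie_corrected_ranks(values) -> np.ndarray:
    """Average (mid) ranks; tied values share the mean of their rank positions."""
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise InvalidInputError("cannot rank an empty sequence")
    if not np.all(np.isfinite(values)):
        raise InvalidInputError("non-finite values cannot be ranked")
    return rankdata(values, method="average")


def _check_degenerate(positions: np.ndarray):
    span = positions.max(axis=0) - positions.min(axis=0)
    scale = max(span.max(), 1.0)
    centered = positions - positions.mean(axis=0)
    # second singular value ~ extent perpendicular to the best-fit line
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] <= DEGENERACY_RTOL * scale:
        raise DegenerateGeometryError(
            "positions are (near-)collinear or coincident; no valid triangulation"
        )


def delaunay_neighbors(
    positions: np.ndarray,
    *,
    jitter: bool = False,
    jitter_seed: Optional[int] = None,
) -> NeighborGraph:
    """Delaunay triangulation edges of 2-D unit positions.

    Degenerate (collinear/coincident) inputs raise by default.  With
    ``jitter=True`` a deterministic jitter of magnitude 1e-9 x position range
    (seeded by ``jitter_seed``) is applied first, trading exactness for
    robustness; results then depend on the seed.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] < 3:
        raise InvalidInputError("Delaunay triangulation needs at least 3 points")
    if jitter:
        if jitter_seed is None:
            raise ConfigurationError("jitter requires an explicit jitter_seed")
        rng = np.random.default_rng(jitter_seed)
        scale = max(np.ptp(positions, axis=0).max(), 1.0)
        positions = positions + rng.normal(0.0, 1e-9 * scale, size=positions.shape)
    _check_degenerate(positions)
    try:
        tri = Delaunay(positions)
    except QhullError as exc:  # pragma: no cover - caught by tolerance above in practice
        raise DegenerateGeometryError(str(exc)) from exc
    simplices = tri.simplices
    edges = np.vstack(
        [simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [0, 2]]]
    )
    return NeighborGraph(edges=edges, n=positions.shape[0])


def geodesic_distances(graph: NeighborGraph) -> np.ndarray:
    """All-pairs shortest-path edge counts on a connected neighbor graph."""
    adj = graph.adjacency()
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise DisconnectedGraphError("neighbor graph is not connected")
    dist = shortest_path(adj, method="D", directed=False, unweighted=True)
    return dist
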