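"""The seven topography measures.

Each measure compares distances (or neighborhood relations) in anatomical
map space against distances in feature space, returning a scalar whose
*polarity* states whether larger or smaller values indicate stronger
topography:

========  ==========================  ==========  =========================
name      measure                     polarity    range
========  ==========================  ==========  =========================
PC        Pearson distance corr.      ascending   [-1, 1]
SC        Spearman distance corr.     ascending   [-1, 1]
TC        topological correlation     ascending   [-1, 1]
WL        wiring length               descending  > 0
PL        path length                 descending  >= 0
ZM        Zrehen measure              descending  >= 0
TP        topographic product         descending  >= 0
========  ==========================  ==========  =========================

PC, SC and WL need only pairwise distances and therefore tolerate duplicate
positions; TC, PL and ZM define anatomical neighbors through the Delaunay
triangulation and require non-degenerate geometry.  TP resolves equidistant
neighbor orderings by Monte-Carlo averaging.

All measures are invariant under rigid motions and uniform scaling of the
positions and under adding a constant to all labels (label rotation for
periodic maps).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Dict, List, Optional

import numpy as np

from .core import (
    NeighborGraph,
    SampledMap,
    circular_difference,
    condensed_pairs,
    delaunay_neighbors,
    geodesic_distances,
    pairwise_feature_distance,
    pairwise_map_distance,
    tie_corrected_ranks,
)
from .exceptions import ConfigurationError, InvalidInputError, UndefinedMeasureError

ASCENDING = "ascending"  # larger value = more topographic
DESCENDING = "descending"  # smaller value = more topographic

POLARITY: Dict[str, str] = {
    "PC": ASCENDING,
    "SC": ASCENDING,
    "TC": ASCENDING,
    "WL": DESCENDING,
    "PL": DESCENDING,
    "ZM": DESCENDING,
    "TP": DESCENDING,
}

MEASURE_NAMES = tuple(POLARITY)


@dataclass
class MeasureResult:
    """Value of a named topography measure plus its orderliness polarity."""

    name: str
    value: float
    polarity: str
    extras: dict = dc_field(default_factory=dict)

    def more_ordered_than(self, other_value: float) -> bool:
        """True if ``other_value`` is at least as ordered as this result."""
        if self.polarity == ASCENDING:
            return other_value >= self.value
        return other_value <= self.value


def generic_product_sum(d_feature: np.ndarray, d_map: np.ndarray) -> float:
    """Generic topography functional: sum over all unordered pairs of the
    product of the feature-space and map-space distance terms."""
    n = d_feature.shape[0]
    iu, ju = condensed_pairs(n)
    return float(np.sum(d_feature[iu, ju] * d_map[iu, ju]))


def _pair_vectors(smap: SampledMap):
    iu, ju = condensed_pairs(smap.n)
    d_m = pairwise_map_distance(smap)[iu, ju]
    d_f = pairwise_feature_distance(smap)[iu, ju]
    return d_f, d_m


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        raise UndefinedMeasureError("zero variance in a distance set")
    return float(np.dot(xc, yc) / (sx * sy))


def pearson_distance_correlation(smap: SampledMap) -> MeasureResult:
    """Pearson correlation between feature- and map-space pairwise distances."""
    if smap.n < 3:
        raise InvalidInputError("PC requires n >= 3")
    d_f, d_m = _pair_vectors(smap)
    return MeasureResult("PC", _pearson(d_f, d_m), ASCENDING)


def pearson_multi_subject(maps: List[SampledMap]) -> MeasureResult:
    """Pearson distance correlation pooled over several subjects.

    Anatomical coordinate frames are not comparable between subjects, so
    only within-subject pairs enter; the correlation (and its means) is
    computed over the union of all subjects' pair lists.
    """
    if len(maps) < 1:
        raise InvalidInputError("need at least one subject")
    periodic_flags = {(m.periodic, m.period) for m in maps}
    if len(periodic_flags) > 1:
        raise ConfigurationError("subjects disagree on feature-space periodicity")
    d_f_all, d_m_all = [], []
    for m in maps:
        d_f, d_m = _pair_vectors(m)
        d_f_all.append(d_f)
        d_m_all.append(d_m)
    return MeasureResult(
        "PC", _pearson(np.concatenate(d_f_all), np.concatenate(d_m_all)), ASCENDING
    )


def spearman_distance_correlation(smap: SampledMap) -> MeasureResult:
    """Pearson correlation of tie-corrected ranks of the pairwise distances."""
    if smap.n < 3:
        raise InvalidInputError("SC requires n >= 3")
    d_f, d_m = _pair_vectors(smap)
    return MeasureResult(
        "SC",
        _pearson(tie_corrected_ranks(d_f), tie_corrected_ranks(d_m)),
        ASCENDING,
    )


def feature_rank_difference(smap: SampledMap) -> np.ndarray:
    """n x n matrix of tie-corrected rank differences of the labels.

    For periodic feature spaces ranks live on a circle and the difference is
    the circular one: min(|dR|, n - |dR|).
    """
    ranks = tie_corrected_ranks(smap.labels)
    diff = np.abs(ranks[:, None] - ranks[None, :])
    if smap.periodic:
        diff = np.minimum(diff, smap.n - diff)
    return diff


def topological_correlation(smap: SampledMap) -> MeasureResult:
    """Correlation between Delaunay-graph geodesics and feature rank differences.

    Map-space distance is the number of edges in the shortest Delaunay-graph
    path; since a 1-D feature space has no triangulation, the feature-space
    distance is the label rank difference.
    """
    graph = delaunay_neighbors(smap.positions)
    geo = geodesic_distances(graph)
    iu, ju = condensed_pairs(smap.n)
    d_rank = feature_rank_difference(smap)[iu, ju]
    return MeasureResult("TC", _pearson(d_rank, geo[iu, ju]), ASCENDING)


def feature_adjacency_edges(smap: SampledMap) -> np.ndarray:
    """Edges between units adjacent in feature space.

    Units with identical labels are mutually adjacent, and every unit is
    adjacent to all units carrying the nearest distinct label on either side
    (with wrap-around for periodic labels).
    """
    uniq, inv = np.unique(smap.labels, return_inverse=True)
    groups = [np.flatnonzero(inv == g) for g in range(len(uniq))]
    edges = []
    for g, members in enumerate(groups):
        # ties: all pairs within a label group
        if len(members) > 1:
            ii, jj = np.triu_indices(len(members), k=1)
            edges.append(np.column_stack([members[ii], members[jj]]))
        # adjacent distinct label (ascending side; descending covered by symmetry)
        g_next = g + 1
        if g_next == len(groups):
            if not smap.periodic or len(groups) < 3:
                continue
            g_next = 0
        nxt = groups[g_next]
        edges.append(
            np.column_stack(
                [np.repeat(members, len(nxt)), np.tile(nxt, len(members))]
            )
        )
    if not edges:
        return np.empty((0, 2), dtype=int)
    out = np.sort(np.vstack(edges), axis=1)
    return np.unique(out, axis=0)


def wiring_length(smap: SampledMap) -> MeasureResult:
    """Normalized anatomical length of connections between feature neighbors.

    Mean map-space distance over feature-adjacent pairs, divided by the mean
    map-space distance over all pairs, making the value independent of map
    size and units.  Smaller = shorter 'wiring' = more ordered.
    """
    if smap.n < 3:
        raise InvalidInputError("WL requires n >= 3")
    d_m = pairwise_map_distance(smap)
    iu, ju = condensed_pairs(smap.n)
    mean_all = d_m[iu, ju].mean()
    if mean_all == 0:
        raise UndefinedMeasureError("all positions coincide")
    edges = feature_adjacency_edges(smap)
    mean_wire = d_m[edges[:, 0], edges[:, 1]].mean()
    return MeasureResult("WL", float(mean_wire / mean_all), DESCENDING)


def path_length(smap: SampledMap) -> MeasureResult:
    """Normalized feature-space distance along anatomical (Delaunay) edges.

    The mirror image of wiring length with the two spaces' roles reversed:
    mean feature distance over Delaunay-neighbor pairs divided by the mean
    feature distance over all pairs.  Identical labels everywhere give 0/0,
    which is reported as 0 (a constant map has no feature structure to
    disorder).
    """
    graph = delaunay_neighbors(smap.positions)
    d_f = pairwise_feature_distance(smap)
    iu, ju = condensed_pairs(smap.n)
    mean_all = d_f[iu, ju].mean()
    edges = graph.edges
    mean_edge = d_f[edges[:, 0], edges[:, 1]].mean()
    if mean_all == 0:
        value = 0.0
    else:
        value = float(mean_edge / mean_all)
    return MeasureResult("PL", value, DESCENDING)


def _intruder_counts(smap: SampledMap, edges: np.ndarray) -> np.ndarray:
    """Per-edge count of units whose label lies strictly between the labels
    of the two anatomical neighbors (along the shorter arc if periodic)."""
    s = smap.labels
    counts = np.empty(len(edges), dtype=int)
    if not smap.periodic:
        lo = np.minimum(s[edges[:, 0]], s[edges[:, 1]])
        hi = np.maximum(s[edges[:, 0]], s[edges[:, 1]])
        inside = (s[None, :] > lo[:, None]) & (s[None, :] < hi[:, None])
        counts = inside.sum(axis=1)
    else:
        p = smap.period
        si, sj = s[edges[:, 0]], s[edges[:, 1]]
        delta = circular_difference(sj, si, p)  # in (-p/2, p/2]
        # shorter arc runs ascending from the arc start; antipodal pairs
        # (delta == p/2 exactly) ascend from s_i by convention
        start = np.where(delta >= 0, si, sj)
        end = np.where(delta >= 0, sj, si)
        # measure the arc with the same mod expression used for candidate
        # units so that endpoint equality is float-exact
        arclen = np.mod(end - start, p)
        t = np.mod(s[None, :] - start[:, None], p)
        inside = (t > 0) & (t < arclen[:, None])
        # an edge's own endpoints are never intruders
        rows = np.arange(len(edges))
        inside[rows, edges[:, 0]] = False
        inside[rows, edges[:, 1]] = False
        counts = inside.sum(axis=1)
    return counts


def zrehen_measure(smap: SampledMap) -> MeasureResult:
    """Mean number of feature-space 'intruders' per anatomical neighbor pair.

    For each Delaunay-neighbor pair, counts units whose label falls strictly
    between the pair's labels (shorter circular arc for periodic labels); a
    unit exactly equal to an endpoint label is not an intruder.  The raw
    total is normalized by the number of Delaunay edges.
    """
    graph = delaunay_neighbors(smap.positions)
    counts = _intruder_counts(smap, graph.edges)
    total = int(counts.sum())
    return MeasureResult(
        "ZM",
        float(total / len(graph.edges)),
        DESCENDING,
        extras={"raw_intruder_count": total, "n_edges": len(graph.edges)},
    )


# distances are clamped to this relative floor before taking logs so that
# duplicate positions/labels yield large-but-finite neighborhood distortions
_TP_DISTANCE_FLOOR = 1e-12


def _tp_from_orders(d_m, d_f, order_m, order_f) -> float:
    """Topographic product given explicit neighbor orderings per unit."""
    n = d_m.shape[0]
    rows = np.arange(n)[:, None]
    dm_floor = max(d_m.max(), 1.0) * _TP_DISTANCE_FLOOR
    df_floor = max(d_f.max(), 1.0) * _TP_DISTANCE_FLOOR
    dM_m = np.maximum(d_m[rows, order_m], dm_floor)  # d_M to k-th map-space nbr
    dM_f = np.maximum(d_m[rows, order_f], dm_floor)  # d_M to k-th feature-space nbr
    dF_m = np.maximum(d_f[rows, order_m], df_floor)
    dF_f = np.maximum(d_f[rows, order_f], df_floor)
    log_q = np.log(dF_m) - np.log(dF_f) + np.log(dM_m) - np.log(dM_f)
    k = np.arange(1, n)
    log_p3 = np.cumsum(log_q, axis=1) / (2.0 * k)
    return float(np.abs(log_p3).sum() / (n * (n - 1)))


def _neighbor_order(dist_row_matrix: np.ndarray, rng: Optional[np.random.Generator]):
    """Per-row neighbor orderings by distance, excluding self; ties broken
    randomly when an rng is supplied, by index otherwise."""
    n = dist_row_matrix.shape[0]
    d = dist_row_matrix.copy()
    np.fill_diagonal(d, np.inf)
    if rng is None:
        order = np.argsort(d, axis=1, kind="stable")[:, : n - 1]
    else:
        noise = rng.random(d.shape)
        order = np.lexsort((noise, d), axis=1)[:, : n - 1]
    return order


def _has_neighbor_ties(dist: np.ndarray) -> bool:
    n = dist.shape[0]
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    s = np.sort(d, axis=1)[:, : n - 1]
    return bool(np.any(np.diff(s, axis=1) == 0))


def topographic_product(
    smap: SampledMap, tie_mc: int = 1000, seed: Optional[int] = None
) -> MeasureResult:
    """Topographic product: distortion of k-nearest-neighbor orderings.

    For every unit the k-th nearest neighbors in map space and in feature
    space are compared through distance ratios; the absolute log of their
    geometric mean, averaged over units and neighborhood sizes, is 0 iff
    every neighborhood ordering is preserved.  When equidistant neighbors
    make the ordering ambiguous, the value is the mean over ``tie_mc``
    random tie-break permutations (seeded).
    """
    if smap.n < 3:
        raise InvalidInputError("TP requires n >= 3")
    d_m = pairwise_map_distance(smap)
    d_f = pairwise_feature_distance(smap)
    has_ties = _has_neighbor_ties(d_m) or _has_neighbor_ties(d_f)
    if not has_ties:
        order_m = _neighbor_order(d_m, None)
        order_f = _neighbor_order(d_f, None)
        value = _tp_from_orders(d_m, d_f, order_m, order_f)
        return MeasureResult("TP", value, DESCENDING, extras={"tie_mc": 0})
    rng = np.random.default_rng(seed)
    samples = np.empty(tie_mc)
    for it in range(tie_mc):
        order_m = _neighbor_order(d_m, rng)
        order_f = _neighbor_order(d_f, rng)
        samples[it] = _tp_from_orders(d_m, d_f, order_m, order_f)
    return MeasureResult(
        "TP",
        float(samples.mean()),
        DESCENDING,
        extras={
            "tie_mc": tie_mc,
            "tie_mc_std": float(samples.std(ddof=1)) if tie_mc > 1 else 0.0,
        },
    )


MEASURES: Dict[str, Callable[[SampledMap], MeasureResult]] = {
    "PC": pearson_distance_correlation,
    "SC": spearman_distance_correlation,
    "TC": topological_correlation,
    "WL": wiring_length,
    "PL": path_length,
    "ZM": zrehen_measure,
    "TP": topographic_product,
}


def compute_measure(smap: SampledMap, name: str, **kwargs) -> MeasureResult:
    """Compute one of the seven measures by name (PC, SC, TC, WL, PL, ZM, TP)."""
    try:
        fn = MEASURES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown measure {name!r}; choose from {', '.join(MEASURES)}"
        ) from None
    return fn(smap, **kwargs)
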