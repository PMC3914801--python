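"""Naive, loop-based reference implementations used as oracles.

Everything here is written for clarity and independence from the package's
vectorized code paths: explicit double/triple loops, no shared helpers
beyond basic numpy, graph work delegated to networkx.
"""

import itertools
import math

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay


def circ_dist(a, b, period):
    d = abs(a - b) % period
    return min(d, period - d)


def feat_dist(si, sj, periodic, period):
    return circ_dist(si, sj, period) if periodic else abs(si - sj)


def pair_lists(smap):
    n = smap.n
    d_f, d_m = [], []
    for i in range(n):
        for j in range(i + 1, n):
            d_m.append(math.dist(smap.positions[i], smap.positions[j]))
            d_f.append(feat_dist(smap.labels[i], smap.labels[j], smap.periodic, smap.period))
    return np.array(d_f), np.array(d_m)


def naive_ranks(values):
    values = list(values)
    order = sorted(range(len(values)), key=lambda k: values[k])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return np.array(ranks)


def pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def ref_pc(smap):
    d_f, d_m = pair_lists(smap)
    return pearson(d_f, d_m)


def ref_pc_multi(maps):
    d_f, d_m = [], []
    for m in maps:
        f, d = pair_lists(m)
        d_f.extend(f)
        d_m.extend(d)
    return pearson(d_f, d_m)


def ref_sc(smap):
    d_f, d_m = pair_lists(smap)
    return pearson(naive_ranks(d_f), naive_ranks(d_m))


def delaunay_graph(smap):
    tri = Delaunay(smap.positions)
    g = nx.Graph()
    g.add_nodes_from(range(smap.n))
    for simplex in tri.simplices:
        for a, b in itertools.combinations(simplex, 2):
            g.add_edge(int(a), int(b))
    return g


def ref_tc(smap):
    g = delaunay_graph(smap)
    geo = dict(nx.all_pairs_shortest_path_length(g))
    ranks = naive_ranks(smap.labels)
    xs, ys = [], []
    for i in range(smap.n):
        for j in range(i + 1, smap.n):
            d = abs(ranks[i] - ranks[j])
            if smap.periodic:
                d = min(d, smap.n - d)
            xs.append(d)
            ys.append(geo[i][j])
    return pearson(xs, ys)


def feature_neighbor_pairs(smap):
    """Unordered pairs adjacent in feature space: same label, or nearest
    distinct label on either side (wrapping for periodic labels)."""
    labels = smap.labels
    uniq = sorted(set(labels))
    pairs = set()
    for i in range(smap.n):
        for j in range(i + 1, smap.n):
            if labels[i] == labels[j]:
                pairs.add((i, j))
    for a in range(len(uniq)):
        b = a + 1
        if b == len(uniq):
            if not smap.periodic or len(uniq) < 3:
                break
            b = 0
        for i in range(smap.n):
            for j in range(smap.n):
                if labels[i] == uniq[a] and labels[j] == uniq[b]:
                    pairs.add((min(i, j), max(i, j)))
    return sorted(pairs)


def ref_wl(smap):
    pairs = feature_neighbor_pairs(smap)
    wire = [math.dist(smap.positions[i], smap.positions[j]) for i, j in pairs]
    _, d_m = pair_lists(smap)
    return float(np.mean(wire) / np.mean(d_m))


def ref_pl(smap):
    g = delaunay_graph(smap)
    edge = [
        feat_dist(smap.labels[i], smap.labels[j], smap.periodic, smap.period)
        for i, j in g.edges
    ]
    d_f, _ = pair_lists(smap)
    if np.mean(d_f) == 0:
        return 0.0
    return float(np.mean(edge) / np.mean(d_f))


def ref_zm_raw(smap):
    g = delaunay_graph(smap)
    count = 0
    for i, j in g.edges:
        si, sj = smap.labels[i], smap.labels[j]
        for k in range(smap.n):
            if k == i or k == j:
                continue
            sk = smap.labels[k]
            if not smap.periodic:
                if min(si, sj) < sk < max(si, sj):
                    count += 1
            else:
                p = smap.period
                delta = (sj - si) % p
                if delta > p / 2:
                    start, end = sj, si
                else:
                    start, end = si, sj
                length = (end - start) % p
                t = (sk - start) % p
                if 0 < t < length:
                    count += 1
    return count, g.number_of_edges()


def ref_zm(smap):
    count, n_edges = ref_zm_raw(smap)
    return count / n_edges


def ref_tp(smap):
    """Topographic product for maps without any neighbor-distance ties."""
    n = smap.n
    d_m = np.zeros((n, n))
    d_f = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d_m[i, j] = math.dist(smap.positions[i], smap.positions[j])
            d_f[i, j] = feat_dist(smap.labels[i], smap.labels[j], smap.periodic, smap.period)
    total = 0.0
    for j in range(n):
        others = [i for i in range(n) if i != j]
        nbr_m = sorted(others, key=lambda i: d_m[j, i])
        nbr_f = sorted(others, key=lambda i: d_f[j, i])
        log_prod = 0.0
        for k in range(1, n):
            q1 = d_f[j, nbr_m[k - 1]] / d_f[j, nbr_f[k - 1]]
            q2 = d_m[j, nbr_m[k - 1]] / d_m[j, nbr_f[k - 1]]
            log_prod += math.log(q1) + math.log(q2)
            total += abs(log_prod / (2 * k))
    return total / (n * (n - 1))


REFERENCES = {
    "PC": ref_pc,
    "SC": ref_sc,
    "TC": ref_tc,
    "WL": ref_wl,
    "PL": ref_pl,
    "ZM": ref_zm,
    "TP": ref_tp,
}


def brute_force_exact_p(smap, measure_fn, more_ordered_is_larger):
    """Enumerate every permutation of the labels (n! of them) and count
    those at least as ordered as the observed arrangement."""
    observed = measure_fn(smap)
    count = 0
    total = 0
    for perm in itertools.permutations(range(smap.n)):
        total += 1
        value = measure_fn(smap.with_labels(smap.labels[list(perm)]))
        if more_ordered_is_larger:
            if value >= observed - 1e-12:
                count += 1
        elif value <= observed + 1e-12:
            count += 1
    return count / total, count, total
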