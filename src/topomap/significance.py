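"""Permutation tests for topography and multiple-test corrections.

The null hypothesis of "no topography" is that the assignment of feature
labels to anatomical positions is exchangeable: shuffling the labels over
the positions should not systematically change a topography measure.  The
test statistic is any of the seven measures, oriented by its polarity.

Monte-Carlo mode draws ``m`` random label shuffles and reports

    p = (b* + 1) / (m + 1)

where b* counts shuffles at least as ordered as the observed map.  The
add-one convention counts the observed map among the samples, which keeps
the test exact (valid) and makes the minimum attainable p equal to
1/(m+1).  When the number of distinct arrangements of the label multiset is
<= m, the full permutation distribution is enumerated instead and
p = b*/N with the identity arrangement included in b*.

Each measure has a vectorized permutation kernel that evaluates, for a
whole batch of shuffles at once, a statistic that is a strictly monotone
transform of the measure under label permutation (pair-distance multisets
are permutation-invariant, so additive/multiplicative normalization terms
drop out).  The observed map is pushed through the same kernel, so the
ordering comparison is internally consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .core import (
    SampledMap,
    condensed_pairs,
    delaunay_neighbors,
    geodesic_distances,
    pairwise_map_distance,
    philox_rng,
    tie_corrected_ranks,
    wrap_periodic,
)
from .exceptions import ConfigurationError, InvalidInputError, UndefinedMeasureError
from .measures import (
    ASCENDING,
    MEASURES,
    POLARITY,
    MeasureResult,
    compute_measure,
    pearson_multi_subject,
)

DEFAULT_M = 10_000

# relative slack when comparing shuffled statistics against the observed
# one: summation order differs between samples, so exact symmetric
# rearrangements (e.g. a label reversal on a symmetric map) must not lose
# their tie to the observed value through last-ulp rounding
_TIE_RTOL = 1e-9


@dataclass
class PermutationTestResult:
    """Outcome of a topography permutation test."""

    measure: MeasureResult
    p: float
    n_samples: int
    n_more_ordered: int
    mode: str  # "monte_carlo" or "exact"
    seed: Optional[int] = None

    def __post_init__(self):
        assert 0 < self.p <= 1


_rng = philox_rng


def _random_permutations(rng, m: int, n: int) -> np.ndarray:
    return np.argsort(rng.random((m, n)), axis=1)


def _n_distinct_permutations(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    total = math.factorial(len(labels))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _multiset_permutations(values: Sequence[float]):
    """Yield all distinct arrangements of a multiset of label values."""
    uniq, counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
    n = len(values)
    out = np.empty(n)

    def rec(pos, counts):
        if pos == n:
            yield out.copy()
            return
        for k in range(len(uniq)):
            if counts[k]:
                counts[k] -= 1
                out[pos] = uniq[k]
                yield from rec(pos + 1, counts)
                counts[k] += 1

    yield from rec(0, list(counts))


def _row_ranks(L: np.ndarray) -> np.ndarray:
    return rankdata(L, axis=1, method="average")


def _circ_abs_diff(a: np.ndarray, b: np.ndarray, period: float) -> np.ndarray:
    d = np.abs(a - b)
    return np.minimum(d, period - d)


class _Kernel:
    """Vectorized permutation kernel for one measure on one map.

    ``stat(L)`` maps a (S, n) batch of label rows to S statistic values that
    order samples identically to the measure itself.
    """

    def __init__(self, smap: SampledMap, name: str, tie_rng=None):
        self.smap = smap
        self.name = name
        self.polarity = POLARITY[name]
        self.tie_rng = tie_rng
        n = smap.n
        self._iu, self._ju = condensed_pairs(n)
        self._setup()

    # -- per-measure precomputation ------------------------------------
    def _setup(self):
        smap, name = self.smap, self.name
        has_label_ties = len(np.unique(smap.labels)) < smap.n
        if name in ("PC", "SC"):
            dm = pairwise_map_distance(smap)[self._iu, self._ju]
            if np.ptp(dm) == 0:
                raise UndefinedMeasureError("zero variance of map-space distances")
            self._dm = tie_corrected_ranks(dm) if name == "SC" else dm
        elif name == "TC":
            geo = geodesic_distances(delaunay_neighbors(smap.positions))
            geo = geo[self._iu, self._ju]
            if np.ptp(geo) == 0:
                raise UndefinedMeasureError("zero variance of geodesic distances")
            self._dm = geo
        elif name == "WL":
            self._dmat = pairwise_map_distance(smap)
            self._slow = has_label_ties
        elif name == "PL":
            self._edges = delaunay_neighbors(smap.positions).edges
        elif name == "ZM":
            self._edges = delaunay_neighbors(smap.positions).edges
            self._slow = has_label_ties
        elif name == "TP":
            self._dmat = pairwise_map_distance(smap)
            dmat = self._dmat.copy()
            np.fill_diagonal(dmat, np.inf)
            self._order_m = np.argsort(dmat, axis=1, kind="stable")[:, : smap.n - 1]
            self._slow = has_label_ties or self._map_ties(dmat)
        else:  # pragma: no cover
            raise ConfigurationError(f"unknown measure {name}")

    @staticmethod
    def _map_ties(dmat_inf_diag) -> bool:
        s = np.sort(dmat_inf_diag, axis=1)[:, :-1]
        return bool(np.any(np.diff(s, axis=1) == 0))

    # -- statistic batches ---------------------------------------------
    def stat(self, L: np.ndarray) -> np.ndarray:
        L = np.atleast_2d(L)
        fn = getattr(self, f"_stat_{self.name.lower()}")
        # chunk to bound memory for pair/tensor expansions
        n = self.smap.n
        per_row = max(n * n, len(self._iu))
        chunk = max(1, int(4e6 // per_row))
        return np.concatenate(
            [fn(L[k : k + chunk]) for k in range(0, len(L), chunk)]
        )

    def _pair_dF(self, L):
        a, b = L[:, self._iu], L[:, self._ju]
        if self.smap.periodic:
            return _circ_abs_diff(a, b, self.smap.period)
        return np.abs(a - b)

    def _stat_pc(self, L):
        # Pearson r is monotone in sum(dF*dM): the dF multiset (hence its
        # mean/variance) is invariant under label permutation
        return self._pair_dF(L) @ self._dm

    def _stat_sc(self, L):
        return _row_ranks(self._pair_dF(L)) @ self._dm

    def _stat_tc(self, L):
        R = _row_ranks(L)
        d = np.abs(R[:, self._iu] - R[:, self._ju])
        if self.smap.periodic:
            d = np.minimum(d, self.smap.n - d)
        return d @ self._dm

    def _stat_wl(self, L):
        if self._slow:
            return self._slow_stat(L)
        order = np.argsort(L, axis=1)
        a, b = order[:, :-1], order[:, 1:]
        total = self._dmat[a, b].sum(axis=1)
        edge_count = self.smap.n - 1
        if self.smap.periodic and self.smap.n >= 3:
            total = total + self._dmat[order[:, -1], order[:, 0]]
            edge_count += 1
        return total / edge_count

    def _stat_pl(self, L):
        i, j = self._edges[:, 0], self._edges[:, 1]
        a, b = L[:, i], L[:, j]
        if self.smap.periodic:
            d = _circ_abs_diff(a, b, self.smap.period)
        else:
            d = np.abs(a - b)
        return d.sum(axis=1)

    def _stat_zm(self, L):
        if self._slow:
            return self._slow_stat(L)
        i, j = self._edges[:, 0], self._edges[:, 1]
        R = _row_ranks(L)
        if not self.smap.periodic:
            return (np.abs(R[:, i] - R[:, j]) - 1).sum(axis=1)
        n = self.smap.n
        delta = wrap_periodic(L[:, j] - L[:, i], self.smap.period)
        up = np.mod(R[:, j] - R[:, i], n) - 1  # intruders ascending i -> j
        down = np.mod(R[:, i] - R[:, j], n) - 1
        return np.where(delta >= 0, up, down).sum(axis=1)

    def _stat_tp(self, L):
        if self._slow:
            return self._slow_stat(L)
        n = self.smap.n
        S = len(L)
        dF = np.abs(L[:, :, None] - L[:, None, :])
        if self.smap.periodic:
            dF = np.minimum(dF, self.smap.period - dF)
        diag = np.arange(n)
        dFi = dF.copy()
        dFi[:, diag, diag] = np.inf
        order_f = np.argsort(dFi, axis=2, kind="stable")[:, :, : n - 1]
        dF_f = np.sort(dFi, axis=2)[:, :, : n - 1]  # dist to k-th feature nbr
        del dFi
        rows = diag[None, :, None]
        samp = np.arange(S)[:, None, None]
        dm = self._dmat
        dm_floor = max(dm.max(), 1.0) * 1e-12
        df_floor = max(dF.max(), 1.0) * 1e-12
        log_dM_m = np.log(np.maximum(dm[diag[:, None], self._order_m], dm_floor))
        dM_f = np.maximum(dm[rows, order_f], dm_floor)  # (S, n, n-1)
        dF_m = np.maximum(dF[samp, rows, self._order_m[None]], df_floor)
        dF_f = np.maximum(dF_f, df_floor)
        log_q = (
            np.log(dF_m) - np.log(dF_f) + log_dM_m[None] - np.log(dM_f)
        )
        k = np.arange(1, n)
        log_p3 = np.cumsum(log_q, axis=2) / (2.0 * k)
        return np.abs(log_p3).sum(axis=(1, 2)) / (n * (n - 1))

    def _slow_stat(self, L):
        # generic fallback: evaluate the plain measure per row (ties present)
        out = np.empty(len(L))
        for r, row in enumerate(L):
            kwargs = {}
            if self.name == "TP":
                kwargs = {
                    "tie_mc": 1,
                    "seed": int(self.tie_rng.integers(2**31))
                    if self.tie_rng is not None
                    else 0,
                }
            out[r] = compute_measure(self.smap.with_labels(row), self.name, **kwargs).value
        return out


def _count_at_least_as_ordered(stats, observed, polarity) -> int:
    scale = max(np.max(np.abs(stats)), abs(observed), 1e-300)
    tol = _TIE_RTOL * scale
    if polarity == ASCENDING:
        return int(np.sum(stats >= observed - tol))
    return int(np.sum(stats <= observed + tol))


def permutation_test(
    smap: SampledMap,
    measure_name: str,
    m: int = DEFAULT_M,
    seed: Optional[int] = None,
    tie_mc: int = 1000,
    mode: str = "auto",
) -> PermutationTestResult:
    """Label-shuffling permutation test for one measure on one map.

    ``mode='auto'`` switches to exact enumeration when the label multiset
    has no more than ``m`` distinct arrangements; ``'exact'`` and
    ``'monte_carlo'`` force the respective mode.
    """
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    if mode not in ("auto", "exact", "monte_carlo"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    kwargs = {"tie_mc": tie_mc, "seed": seed} if measure_name == "TP" else {}
    observed = compute_measure(smap, measure_name, **kwargs)
    rng = _rng(seed)
    kernel = _Kernel(smap, measure_name, tie_rng=rng)
    obs_stat = float(kernel.stat(smap.labels[None, :])[0])

    n_exact = _n_distinct_permutations(smap.labels)
    if mode == "exact" or (mode == "auto" and n_exact <= m):
        L = np.array(list(_multiset_permutations(smap.labels)))
        stats = kernel.stat(L)
        b = _count_at_least_as_ordered(stats, obs_stat, kernel.polarity)
        return PermutationTestResult(
            measure=observed,
            p=b / n_exact,
            n_samples=int(n_exact),
            n_more_ordered=b,
            mode="exact",
            seed=seed,
        )

    perms = _random_permutations(rng, m, smap.n)
    stats = kernel.stat(smap.labels[perms])
    b = _count_at_least_as_ordered(stats, obs_stat, kernel.polarity)
    return PermutationTestResult(
        measure=observed,
        p=(b + 1) / (m + 1),
        n_samples=m,
        n_more_ordered=b,
        mode="monte_carlo",
        seed=seed,
    )


def pooled_permutation_test(
    maps: List[SampledMap],
    m: int = DEFAULT_M,
    seed: Optional[int] = None,
) -> PermutationTestResult:
    """Multi-subject topography test on the pooled Pearson distance correlation.

    Labels are pooled across subjects, shuffled as one vector, and dealt
    back to the subjects preserving each subject's unit count; the statistic
    is the multi-subject Pearson distance correlation over within-subject
    pairs.
    """
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    if not maps:
        raise InvalidInputError("need at least one subject")
    observed = pearson_multi_subject(maps)
    sizes = [mp.n for mp in maps]
    offsets = np.cumsum([0] + sizes)
    pooled = np.concatenate([mp.labels for mp in maps])
    periodic, period = maps[0].periodic, maps[0].period

    # global pair index lists (into the pooled label vector), within subjects
    I, J, dm = [], [], []
    for k, mp in enumerate(maps):
        iu, ju = condensed_pairs(mp.n)
        I.append(iu + offsets[k])
        J.append(ju + offsets[k])
        dm.append(pairwise_map_distance(mp)[iu, ju])
    I, J, dm = np.concatenate(I), np.concatenate(J), np.concatenate(dm)
    P = len(dm)
    dm_c = dm - dm.mean()
    s_m = np.sqrt(np.sum(dm_c**2))
    if s_m == 0:
        raise UndefinedMeasureError("zero variance of map-space distances")

    def stat(L):
        a, b = L[:, I], L[:, J]
        dF = _circ_abs_diff(a, b, period) if periodic else np.abs(a - b)
        num = dF @ dm_c
        ss = np.sum(dF**2, axis=1) - np.sum(dF, axis=1) ** 2 / P
        with np.errstate(invalid="ignore", divide="ignore"):
            return num / (np.sqrt(ss) * s_m)

    obs_stat = float(stat(pooled[None, :])[0])
    rng = _rng(seed)
    n_exact = _n_distinct_permutations(pooled)
    if n_exact <= m:
        L = np.array(list(_multiset_permutations(pooled)))
        stats = stat(L)
        b = _count_at_least_as_ordered(stats, obs_stat, ASCENDING)
        return PermutationTestResult(
            observed, b / n_exact, int(n_exact), b, "exact", seed
        )
    perms = _random_permutations(rng, m, len(pooled))
    stats = stat(pooled[perms])
    b = _count_at_least_as_ordered(stats, obs_stat, ASCENDING)
    return PermutationTestResult(observed, (b + 1) / (m + 1), m, b, "monte_carlo", seed)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR-adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def bonferroni(pvalues: Sequence[float], k: Optional[int] = None) -> np.ndarray:
    """Bonferroni correction: multiply each p by k, deliberately NOT capped
    at 1 so that weak results are visibly non-significant."""
    p = np.asarray(pvalues, dtype=float)
    if k is None:
        k = len(p)
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    return p * k
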