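"""Statistical power and N80 estimation for topography detection.

For a given map model, SNR and sample size, the detection power of a
measure is the probability that its permutation test rejects at level
alpha on a freshly generated, freshly sampled noisy map.  N80 is the
smallest number of sampled units at which that power reaches 80%; it is
the natural sample-size currency for comparing measures, and the ratio
N80(measure) / N80(best measure) expresses how much more data a weaker
measure needs.

Every replicate draws a fresh ground-truth field, a fresh Halton skip and
fresh label noise, so the power estimate marginalizes over the model's map
ensemble rather than conditioning on a single map.  Estimates carry
binomial standard errors; N80 searches use a geometric grid followed by
bisection, with a bootstrap standard error from the bracketing replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, OutOfRangeError
from .models import SamplingConfig, generate_field, sample_map
from .significance import permutation_test

N80_GRID = (5, 8, 12, 18, 27, 40, 60, 90, 135, 200, 300)
DEFAULT_REPS = 200
DEFAULT_M_PERMS = 999


@dataclass
class ModelSpec:
    """A generative map model plus its scale parameter (if any)."""

    model: str  # "linear" | "angle" | "clusters"
    scale_s: Optional[float] = None
    grid_size: int = 512


@dataclass
class PowerEstimate:
    measure_name: str
    model: ModelSpec
    n_points: int
    snr: float
    reps: int
    alpha: float
    power: float
    rejections: np.ndarray  # per-rep booleans (kept for bootstrapping)

    @property
    def se(self) -> float:
        return float(np.sqrt(self.power * (1 - self.power) / self.reps))


@dataclass
class N80Result:
    measure_name: str
    model: ModelSpec
    snr: float
    target_power: float
    alpha: float
    reps: int
    n80: int
    se: float
    trace: List[Tuple[int, float]] = field(default_factory=list)


def estimate_power(
    model: ModelSpec,
    measure_name: str,
    n_points: int,
    snr: float,
    reps: int = DEFAULT_REPS,
    alpha: float = 0.05,
    m_perms: int = DEFAULT_M_PERMS,
    seed: Optional[int] = None,
    shuffle_null: bool = False,
) -> PowerEstimate:
    """Fraction of replicates whose permutation p-value is <= alpha.

    ``shuffle_null=True`` destroys the map by shuffling labels after
    sampling (used for calibration checks: power should then equal alpha).
    """
    if reps < 20:
        raise ConfigurationError("reps must be >= 20 for a usable estimate")
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    root = np.random.SeedSequence(seed)
    rejections = np.zeros(reps, dtype=bool)
    for r, child in enumerate(root.spawn(reps)):
        s_field, s_sample, s_test, s_null = child.generate_state(4) >> 1  # < 2**31
        fld = generate_field(
            model.model, model.scale_s, grid_size=model.grid_size, seed=int(s_field)
        )
        smap = sample_map(
            fld, SamplingConfig(n_points=n_points, snr=snr, seed=int(s_sample))
        )
        if shuffle_null:
            rng = np.random.default_rng(int(s_null))
            smap = smap.with_labels(rng.permutation(smap.labels))
        res = permutation_test(smap, measure_name, m=m_perms, seed=int(s_test))
        rejections[r] = res.p <= alpha
    return PowerEstimate(
        measure_name=measure_name,
        model=model,
        n_points=n_points,
        snr=snr,
        reps=reps,
        alpha=alpha,
        power=float(rejections.mean()),
        rejections=rejections,
    )


def _bootstrap_n80_se(
    lo_est: Optional[PowerEstimate],
    hi_est: PowerEstimate,
    target: float,
    n_boot: int = 200,
    seed: int = 0,
) -> float:
    """Bootstrap SE of the target-power crossing point, log-interpolated
    between the bracketing sample sizes."""
    if lo_est is None:
        return 0.0
    rng = np.random.default_rng(seed)
    n_lo, n_hi = lo_est.n_points, hi_est.n_points
    crossings = np.empty(n_boot)
    for b in range(n_boot):
        p_lo = rng.choice(lo_est.rejections, size=lo_est.reps).mean()
        p_hi = rng.choice(hi_est.rejections, size=hi_est.reps).mean()
        if p_hi <= p_lo:
            crossings[b] = n_hi
            continue
        frac = np.clip((target - p_lo) / (p_hi - p_lo), 0.0, 1.0)
        crossings[b] = np.exp(np.log(n_lo) + frac * (np.log(n_hi) - np.log(n_lo)))
    return float(crossings.std(ddof=1))


def find_n80(
    model: ModelSpec,
    measure_name: str,
    snr: float,
    target_power: float = 0.8,
    alpha: float = 0.05,
    reps: int = DEFAULT_REPS,
    m_perms: int = DEFAULT_M_PERMS,
    seed: Optional[int] = None,
    n_grid: Sequence[int] = N80_GRID,
) -> N80Result:
    """Smallest sample size reaching the target detection power.

    Scans a geometric grid of sample sizes until the estimated power
    reaches ``target_power``, then bisects between the bracketing grid
    points.  Raises :class:`OutOfRangeError` when even the largest grid
    size falls short (the map is effectively undetectable at this SNR).
    """
    if not snr > 0:
        raise ConfigurationError("snr must be > 0")
    root = np.random.SeedSequence(seed)
    trace: List[Tuple[int, float]] = []
    estimates = {}

    def power_at(n: int) -> PowerEstimate:
        if n not in estimates:
            sub = np.random.SeedSequence(entropy=root.entropy or 0, spawn_key=(n,))
            est = estimate_power(
                model, measure_name, n, snr,
                reps=reps, alpha=alpha, m_perms=m_perms,
                seed=int(sub.generate_state(1)[0] >> 1),
            )
            estimates[n] = est
            trace.append((n, est.power))
        return estimates[n]

    lo, hi = None, None
    for n in n_grid:
        est = power_at(n)
        if est.power >= target_power:
            hi = n
            break
        lo = n
    if hi is None:
        raise OutOfRangeError(
            f"N80 for {measure_name} exceeds the search range "
            f"(power {est.power:.2f} at n={n_grid[-1]})"
        )
    # bisection refinement of the smallest n with power >= target
    while lo is not None and hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(mid).power >= target_power:
            hi = mid
        else:
            lo = mid
    se = _bootstrap_n80_se(
        estimates.get(lo), estimates[hi], target_power,
        seed=int(root.generate_state(1)[0] >> 1),
    )
    return N80Result(
        measure_name=measure_name,
        model=model,
        snr=snr,
        target_power=target_power,
        alpha=alpha,
        reps=reps,
        n80=hi,
        se=se,
        trace=sorted(trace),
    )


def compare_measures(
    model: ModelSpec,
    snr: float,
    measure_list: Sequence[str],
    target_power: float = 0.8,
    alpha: float = 0.05,
    reps: int = DEFAULT_REPS,
    m_perms: int = DEFAULT_M_PERMS,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """N80 per measure plus the ratio to the most powerful measure.

    Returns a tidy frame with one row per requested measure; measures whose
    N80 lies outside the search range appear with missing (NaN) entries.
    The most powerful measure has ratio 1 exactly.
    """
    if len(measure_list) < 2:
        raise ConfigurationError("need at least 2 measures to compare")
    root = np.random.SeedSequence(seed)
    rows = []
    for k, name in enumerate(measure_list):
        sub = np.random.SeedSequence(entropy=root.entropy or 0, spawn_key=(k,))
        try:
            res = find_n80(
                model, name, snr,
                target_power=target_power, alpha=alpha,
                reps=reps, m_perms=m_perms,
                seed=int(sub.generate_state(1)[0] >> 1),
            )
            rows.append({"measure": name, "n80": res.n80, "se": res.se})
        except OutOfRangeError:
            rows.append({"measure": name, "n80": np.nan, "se": np.nan})
    df = pd.DataFrame(rows)
    best = df["n80"].min()
    df["ratio_to_best"] = df["n80"] / best
    df["model"] = model.model
    df["scale_s"] = model.scale_s
    df["snr"] = snr
    return df
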