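"""Generative map models, quasi-random sampling and SNR-controlled noise.

Three phenomenological ground-truth models over the unit square:

* **linear** — a smooth large-scale gradient ``F(x, y) = a*x + b*y`` with
  random direction, the simplest topographic arrangement (e.g. tonotopy).
* **angle** — a convoluted periodic map, like orientation maps in V1,
  obtained as the argument of two independent Gaussian white-noise fields
  bandpass-filtered with a mexican-hat (difference-of-Gaussians) kernel of
  characteristic scale ``scale_s``.
* **clusters** — locally homogeneous patches with no large-scale order: a
  Voronoi tessellation of quasi-random (Halton) seed points, each cell
  colored with an i.i.d. uniform circular label; the seed density is tied
  to ``scale_s`` so that cluster size matches the angle map's feature size.

Observation is modeled as quasi-random (Halton, bases 2 and 3) sampling of
locations inside the unit disc, nearest-grid-node readout of the field, and
additive Gaussian label noise whose standard deviation is the field's
(circular) standard deviation divided by the signal-to-noise ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from scipy.stats import qmc

from .core import SampledMap, philox_rng as _rng, wrap_periodic
from .exceptions import ConfigurationError, InvalidInputError

DEFAULT_GRID = 512
HALTON_SKIP_MAX = 10_000

# surround/center width ratio of the difference-of-Gaussians bandpass kernel
DOG_SURROUND_RATIO = 1.5
# center Gaussian sigma in pixels = scale_s * grid_size / DOG_SCALE_DIVISOR;
# scale_s thus expresses the feature size as a fraction of the field width
DOG_SCALE_DIVISOR = 8.0

# Cluster seed count n_c = round(CLUSTER_DENSITY / scale_s**2), calibrated
# once by simulation so that the half-autocorrelation feature size of the
# colored tessellation matches the angle map's at equal scale_s (see
# docs/methods.md), then frozen.
CLUSTER_DENSITY = 12.0


@dataclass
class MapField:
    """Dense ground-truth feature field over the unit square."""

    grid: np.ndarray  # (H, W), grid[i, j] = F(x=j/(W-1), y=i/(H-1))
    model: str  # "linear" | "angle" | "clusters"
    scale_s: Optional[float] = None
    periodic: bool = False
    period: Optional[float] = None
    params: dict = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if not np.all(np.isfinite(self.grid)):
            raise InvalidInputError("non-finite field values")
        if self.params is None:
            self.params = {}
        if self.periodic:
            self.grid = wrap_periodic(self.grid, self.period)

    def value_at(self, positions: np.ndarray) -> np.ndarray:
        """Field value at (x, y) points in [0,1]^2, nearest grid node."""
        positions = np.asarray(positions, dtype=float)
        h, w = self.grid.shape
        j = np.clip(np.rint(positions[:, 0] * (w - 1)).astype(int), 0, w - 1)
        i = np.clip(np.rint(positions[:, 1] * (h - 1)).astype(int), 0, h - 1)
        return self.grid[i, j]

    def sigma(self) -> float:
        """(Circular) standard deviation of the whole-map feature values."""
        if not self.periodic:
            return float(self.grid.std())
        theta = self.grid * (2 * np.pi / self.period)
        r = np.abs(np.mean(np.exp(1j * theta)))
        return float(np.sqrt(max(0.0, 2 * (1 - r))) * self.period / (2 * np.pi))


@dataclass
class SamplingConfig:
    """How a ground-truth field is observed."""

    n_points: int
    snr: float = np.inf
    halton_skip: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_points < 3:
            raise InvalidInputError("n_points must be >= 3")
        if not self.snr > 0:
            raise ConfigurationError("snr must be > 0 (use inf for noiseless)")


def _grid_xy(grid_size: int):
    ax = np.linspace(0.0, 1.0, grid_size)
    return np.meshgrid(ax, ax)


def generate_linear_map(
    seed: Optional[int] = None,
    grid_size: int = DEFAULT_GRID,
    coeffs: Optional[tuple] = None,
) -> MapField:
    """Linear gradient field F(x, y) = a*x + b*y, a, b ~ U(-1, 1).

    Only the gradient direction matters for detection (label noise scales
    with the field's own standard deviation), so near-zero draws of (a, b)
    are rejected and redrawn to keep the SNR well defined.  ``coeffs``
    fixes (a, b) explicitly for testing.
    """
    if coeffs is None:
        rng = _rng(seed)
        a = b = 0.0
        while a * a + b * b < 1e-4:
            a, b = rng.uniform(-1.0, 1.0, size=2)
    else:
        a, b = coeffs
    X, Y = _grid_xy(grid_size)
    return MapField(grid=a * X + b * Y, model="linear", params={"a": a, "b": b})


def generate_angle_map(
    scale_s: float,
    grid_size: int = DEFAULT_GRID,
    seed: Optional[int] = None,
) -> MapField:
    """Random periodic angle map from bandpass-filtered white noise.

    Two independent Gaussian white-noise fields are filtered with a
    zero-sum difference-of-Gaussians kernel (center sigma
    ``scale_s * grid_size / 8``, surround 1.5x wider, wrap-around
    boundaries) and treated as the real and imaginary parts of a complex
    field; the map is its argument, periodic with period 2*pi.
    """
    if scale_s <= 0:
        raise ConfigurationError("scale_s must be > 0")
    if grid_size < 64:
        raise ConfigurationError("grid_size must be >= 64")
    sigma_c = scale_s * grid_size / DOG_SCALE_DIVISOR
    sigma_s = DOG_SURROUND_RATIO * sigma_c
    if 4 * sigma_s > grid_size:
        raise ConfigurationError(
            f"scale_s={scale_s} too large for grid_size={grid_size}: "
            "kernel support exceeds the field"
        )
    rng = _rng(seed)
    z = np.empty((grid_size, grid_size), dtype=complex)
    re = rng.standard_normal((grid_size, grid_size))
    im = rng.standard_normal((grid_size, grid_size))
    z.real = gaussian_filter(re, sigma_c, mode="wrap") - gaussian_filter(
        re, sigma_s, mode="wrap"
    )
    z.imag = gaussian_filter(im, sigma_c, mode="wrap") - gaussian_filter(
        im, sigma_s, mode="wrap"
    )
    return MapField(
        grid=np.angle(z),
        model="angle",
        scale_s=scale_s,
        periodic=True,
        period=2 * np.pi,
        params={"sigma_center_px": sigma_c, "sigma_surround_px": sigma_s},
    )


def halton_points(
    n: int, skip: int = 0, *, in_disc: bool = False
) -> np.ndarray:
    """First ``n`` Halton points (bases 2, 3) after ``skip``, optionally
    rejection-filtered to the disc inscribed in the unit square."""
    sampler = qmc.Halton(d=2, scramble=False)
    if skip:
        sampler.fast_forward(skip)
    if not in_disc:
        return sampler.random(n)
    pts = np.empty((0, 2))
    while len(pts) < n:
        batch = sampler.random(2 * (n - len(pts)) + 8)
        keep = np.sum((batch - 0.5) ** 2, axis=1) <= 0.25
        pts = np.vstack([pts, batch[keep]])
    return pts[:n]


def generate_cluster_map(
    scale_s: float,
    grid_size: int = DEFAULT_GRID,
    seed: Optional[int] = None,
    halton_skip: Optional[int] = None,
) -> MapField:
    """Clustered arrangement: a Voronoi tessellation of Halton seed points,
    each cell colored with an i.i.d. uniform circular label.

    The number of seed points scales as ``CLUSTER_DENSITY / scale_s**2`` so
    the characteristic cell size tracks the angle-map feature size for the
    same ``scale_s``.  ``halton_skip`` randomizes the tessellation (drawn
    from the seed if not given).
    """
    if scale_s <= 0:
        raise ConfigurationError("scale_s must be > 0")
    rng = _rng(seed)
    if halton_skip is None:
        halton_skip = int(rng.integers(0, HALTON_SKIP_MAX))
    n_c = max(2, int(round(CLUSTER_DENSITY / scale_s**2)))
    seeds = halton_points(n_c, skip=halton_skip)
    labels = rng.uniform(-np.pi, np.pi, size=n_c)
    X, Y = _grid_xy(grid_size)
    tree = cKDTree(seeds)
    _, nearest = tree.query(np.column_stack([X.ravel(), Y.ravel()]))
    return MapField(
        grid=labels[nearest].reshape(grid_size, grid_size),
        model="clusters",
        scale_s=scale_s,
        periodic=True,
        period=2 * np.pi,
        params={"n_seeds": n_c, "halton_skip": halton_skip,
                "seed_points": seeds, "seed_labels": labels},
    )


def add_noise(
    labels: np.ndarray,
    snr: float,
    sigma_field: float,
    *,
    periodic: bool = False,
    period: Optional[float] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Additive Gaussian label noise at a given signal-to-noise ratio.

    ``sigma_noise = sigma_field / snr`` where ``sigma_field`` is the
    (circular) standard deviation of the whole ground-truth field.
    Periodic labels are re-wrapped after noising.
    """
    labels = np.asarray(labels, dtype=float)
    if not snr > 0:
        raise ConfigurationError("snr must be > 0")
    if np.isinf(snr):
        return labels.copy()
    if sigma_field <= 0:
        raise InvalidInputError("zero-variance field: SNR undefined")
    rng = _rng(seed)
    noisy = labels + rng.normal(0.0, sigma_field / snr, size=labels.shape)
    if periodic:
        noisy = wrap_periodic(noisy, period)
    return noisy


def sample_map(field: MapField, cfg: SamplingConfig) -> SampledMap:
    """Observe a ground-truth field: Halton locations inside the unit disc,
    nearest-node readout, then label noise at ``cfg.snr``."""
    rng = _rng(cfg.seed)
    skip = cfg.halton_skip
    if skip is None:
        skip = int(rng.integers(0, HALTON_SKIP_MAX))
    positions = halton_points(cfg.n_points, skip=skip, in_disc=True)
    labels = field.value_at(positions)
    labels = add_noise(
        labels,
        cfg.snr,
        field.sigma(),
        periodic=field.periodic,
        period=field.period,
        seed=int(rng.integers(2**31)),
    )
    return SampledMap(
        positions=positions,
        labels=labels,
        periodic=field.periodic,
        period=field.period,
    )


def generate_field(
    model: str,
    scale_s: Optional[float] = None,
    grid_size: int = DEFAULT_GRID,
    seed: Optional[int] = None,
) -> MapField:
    """Dispatch to one of the three generators by model name."""
    if model == "linear":
        return generate_linear_map(seed=seed, grid_size=grid_size)
    if model == "angle":
        return generate_angle_map(scale_s, grid_size=grid_size, seed=seed)
    if model == "clusters":
        return generate_cluster_map(scale_s, grid_size=grid_size, seed=seed)
    raise ConfigurationError(f"unknown model {model!r}")
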