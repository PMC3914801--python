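"""Characteristic-stimulus extraction from tuning curves, and map-SNR
estimation under a linear-map assumption.

Binaural-inhibition (EI) cells have monotonic, sigmoid-like azimuth/IID
tuning with no distinct peak; 'peaked' cells have bell-shaped tuning.  A
single characteristic stimulus summarizes each curve: the peak location
for peaked cells, and the steep-slope point (sigmoid transition, or the
50%-of-maximum up-crossing of a Gaussian fit) for EI cells.  These labels
are the feature-space coordinates fed to the topography measures.

Fitted families (x = stimulus, response normalized spike count):

* Gaussian:  ``A * exp(-(x - center)**2 / (2 * width**2))``
* sigmoid:   ``A / (1 + exp(-(x - center) / width))``

Widths are bounded below (defaults: 5 deg for azimuth, 2 dB for IID) to
prevent overfitting single-point peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .core import SampledMap
from .exceptions import FitFailureError, InvalidInputError

AZIMUTH_WIDTH_MIN = 5.0  # degrees
IID_WIDTH_MIN = 2.0  # dB

HALF_MAX_SIGMA = np.sqrt(2.0 * np.log(2.0))  # half-max offset in width units


def gaussian_tuning(x, amplitude, center, width):
    return amplitude * np.exp(-((x - center) ** 2) / (2.0 * width**2))


def sigmoid_tuning(x, amplitude, center, width):
    return amplitude / (1.0 + np.exp(-(x - center) / width))


_FAMILIES = {"gaussian": gaussian_tuning, "sigmoid": sigmoid_tuning}


@dataclass
class TuningCurve:
    """Measured responses of one cell over a 1-D stimulus axis."""

    stimulus: np.ndarray
    response: np.ndarray
    cell_class: str = "EI"  # "EI" | "peaked"

    def __post_init__(self):
        self.stimulus = np.asarray(self.stimulus, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.stimulus.shape != self.response.shape or self.stimulus.size < 4:
            raise InvalidInputError("need >= 4 matched stimulus/response samples")
        if np.any(np.diff(self.stimulus) <= 0):
            raise InvalidInputError("stimuli must be strictly increasing")
        if not (np.all(np.isfinite(self.stimulus)) and np.all(np.isfinite(self.response))):
            raise InvalidInputError("non-finite tuning data")
        if np.any(self.response < 0):
            raise InvalidInputError("responses must be >= 0")
        if self.cell_class not in ("EI", "peaked"):
            raise InvalidInputError("cell_class must be 'EI' or 'peaked'")


@dataclass
class TuningFit:
    """A fitted parametric tuning function."""

    family: str  # "gaussian" | "sigmoid"
    amplitude: float
    center: float
    width: float
    sse: float

    def __call__(self, x):
        return _FAMILIES[self.family](np.asarray(x, dtype=float),
                                      self.amplitude, self.center, self.width)


def _initial_guesses(curve: TuningCurve, family: str, width_min: float):
    x, y = curve.stimulus, curve.response
    span = x[-1] - x[0]
    amp = max(y.max(), 1e-6)
    w0 = max(span / 2.0, width_min)
    if family == "gaussian":
        c0 = x[np.argmax(y)]
    else:
        grad = np.abs(np.diff(y))
        c0 = 0.5 * (x[np.argmax(grad)] + x[np.argmax(grad) + 1])
    yield amp, c0, w0
    # jittered restarts used only if the first attempt fails
    for frac in (0.25, -0.25, 0.5):
        yield amp, c0 + frac * span, max(span / 4.0, width_min)


def fit_tuning(
    curve: TuningCurve, family: str, width_min: float = AZIMUTH_WIDTH_MIN
) -> TuningFit:
    """Least-squares fit of one tuning family, width bounded below.

    Peaked cells admit only the Gaussian family.  Raises
    :class:`FitFailureError` with diagnostics if no start converges.
    """
    if family not in _FAMILIES:
        raise InvalidInputError(f"unknown family {family!r}")
    if curve.cell_class == "peaked" and family != "gaussian":
        raise InvalidInputError("peaked cells are fitted with Gaussians only")
    fn = _FAMILIES[family]
    x, y = curve.stimulus, curve.response
    span = x[-1] - x[0]
    bounds = (
        [0.0, x[0] - span, width_min],
        [np.inf, x[-1] + span, np.inf],
    )
    last_err = None
    for p0 in _initial_guesses(curve, family, width_min):
        try:
            popt, _ = curve_fit(
                fn, x, y, p0=np.clip(p0, bounds[0], bounds[1]),
                bounds=bounds, maxfev=5000,
            )
        except (RuntimeError, ValueError) as exc:
            last_err = exc
            continue
        sse = float(np.sum((fn(x, *popt) - y) ** 2))
        return TuningFit(family, float(popt[0]), float(popt[1]), float(popt[2]), sse)
    raise FitFailureError(
        f"{family} fit failed for all starts on {curve.cell_class} cell: {last_err}"
    )


def select_better_fit(
    curve: TuningCurve, width_min: float = AZIMUTH_WIDTH_MIN
) -> TuningFit:
    """Fit both families to an EI cell and keep the lower-SSE one.

    Both families have three parameters, so raw SSE comparison is fair;
    exact ties go to the sigmoid (the canonical EI shape).
    """
    if curve.cell_class != "EI":
        raise InvalidInputError("select_better_fit applies to EI cells")
    fits = []
    errors = []
    for family in ("sigmoid", "gaussian"):
        try:
            fits.append(fit_tuning(curve, family, width_min=width_min))
        except FitFailureError as exc:
            errors.append(exc)
    if not fits:
        raise FitFailureError(f"both families failed: {errors}")
    # stable min: sigmoid listed first wins SSE ties
    return min(fits, key=lambda f: f.sse)


def characteristic_label(
    fit: TuningFit, cell_class: str, ipsi_sign: int = -1
) -> float:
    """Characteristic stimulus of a fitted curve.

    Peaked cells: the Gaussian center (response maximum).  EI cells: the
    sigmoid transition point, or for Gaussian fits the 50%-of-maximum
    crossing on the ipsilateral flank (``center + ipsi_sign * width *
    sqrt(2 ln 2)``; the recording hemisphere fixes ``ipsi_sign``).
    """
    if cell_class == "peaked":
        return fit.center
    if fit.family == "sigmoid":
        return fit.center
    return fit.center + ipsi_sign * fit.width * HALF_MAX_SIGMA


def bilinear_snr_estimate(smap: SampledMap) -> float:
    """Map SNR under a linear-map assumption.

    Fits the plane ``label ~ c0 + c1*x + c2*y`` by least squares and
    returns sd(fitted) / sd(residual).  A perfectly planar map returns
    ``inf``; values well below 1 indicate the labels are mostly noise
    around any plane.
    """
    if smap.n < 4:
        raise InvalidInputError("bilinear SNR needs n >= 4")
    X = np.column_stack([np.ones(smap.n), smap.positions])
    if np.linalg.matrix_rank(X) < 3:
        raise InvalidInputError("positions are collinear; plane fit degenerate")
    coef, *_ = np.linalg.lstsq(X, smap.labels, rcond=None)
    fitted = X @ coef
    resid = smap.labels - fitted
    sd_fit = fitted.std()
    sd_resid = resid.std()
    if sd_resid <= 1e-12 * max(sd_fit, np.abs(smap.labels).max(), 1.0):
        return float("inf")  # numerically perfect plane
    return float(sd_fit / sd_resid)
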