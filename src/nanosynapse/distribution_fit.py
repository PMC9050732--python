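"""Two-component Gaussian fits to distance/size histograms.

The model is

    f(x) = a1*exp(-((x - b1)/c1)**2) + a2*exp(-((x - b2)/c2)**2)

implemented exactly in this parameterization.  Note the exponent omits the
conventional factor 2, so a width ``c`` relates to a standard deviation by
``c = sigma * sqrt(2)``.  Fitting is bounded nonlinear least squares
(amplitudes >= 0, widths > 0) on binned counts, with components canonically
ordered so that ``b1 <= b2`` after the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares

from .errors import DegenerateInputError


@dataclass(frozen=True)
class HistogramData:
    x: np.ndarray  # bin centers, nm, strictly increasing
    counts: np.ndarray  # non-negative

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        if self.x.shape != self.counts.shape or self.x.ndim != 1:
            raise ValueError("x and counts must be 1D arrays of equal length")
        if len(self.x) >= 2 and not (np.diff(self.x) > 0).all():
            raise ValueError("bin centers must be strictly increasing")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class GaussianFit:
    a1: float
    b1: float
    c1: float
    a2: float
    b2: float
    c2: float
    rss: float = float("nan")
    converged: bool = False


def evaluate(fit: GaussianFit, x) -> np.ndarray | float:
    """Evaluate the two-component model at x (scalar or array)."""
    x = np.asarray(x, dtype=float)
    val = fit.a1 * np.exp(-(((x - fit.b1) / fit.c1) ** 2)) + fit.a2 * np.exp(
        -(((x - fit.b2) / fit.c2) ** 2)
    )
    return float(val) if val.ndim == 0 else val


def _default_init(h: HistogramData) -> GaussianFit:
    """Peaks of a lightly smoothed histogram seed the two centers."""
    y = gaussian_filter1d(h.counts, sigma=1.0, mode="nearest")
    interior = np.arange(1, len(y) - 1)
    is_peak = (y[interior] >= y[interior - 1]) & (y[interior] >= y[interior + 1])
    peaks = interior[is_peak]
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(y))])
    peaks = peaks[np.argsort(y[peaks])[::-1]][:2]  # two highest
    span = h.x[-1] - h.x[0]
    if len(peaks) == 1:
        b1 = float(h.x[peaks[0]])
        b2 = b1 + span / 4 if b1 < h.x.mean() else b1 - span / 4
        a1 = a2 = float(y[peaks[0]])
    else:
        b1, b2 = (float(h.x[p]) for p in peaks)
        a1, a2 = (float(y[p]) for p in peaks)
    width = max(abs(b2 - b1) / 2.0, span / 10.0, np.diff(h.x).mean())
    return GaussianFit(a1=a1, b1=b1, c1=width, a2=a2, b2=b2, c2=width)


def fit_two_gaussians(
    h: HistogramData,
    init: GaussianFit | None = None,
    max_nfev: int = 2000,
) -> GaussianFit:
    """Bounded least-squares fit of the two-component model to a histogram."""
    if len(h.x) < 6:
        raise DegenerateInputError("need at least 6 bins for a 6-parameter fit")
    if h.counts.sum() <= 0:
        raise DegenerateInputError("all-zero counts cannot constrain the model")
    p0 = init if init is not None else _default_init(h)
    theta0 = np.array([p0.a1, p0.b1, p0.c1, p0.a2, p0.b2, p0.c2], dtype=float)

    span = h.x[-1] - h.x[0]
    step = float(np.diff(h.x).mean()) if len(h.x) > 1 else 1.0
    lo = np.array([0.0, h.x[0] - span, step / 10.0, 0.0, h.x[0] - span, step / 10.0])
    hi = np.array(
        [np.inf, h.x[-1] + span, 10.0 * span + step, np.inf, h.x[-1] + span, 10.0 * span + step]
    )
    theta0 = np.clip(theta0, lo + 1e-12, hi - 1e-12)

    def residuals(theta):
        fit = GaussianFit(*theta)
        return evaluate(fit, h.x) - h.counts

    res = least_squares(
        residuals,
        theta0,
        bounds=(lo, hi),
        max_nfev=max_nfev,
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    a1, b1, c1, a2, b2, c2 = res.x
    fit = GaussianFit(a1, b1, c1, a2, b2, c2, rss=float(np.sum(res.fun**2)), converged=res.status > 0)
    if fit.b2 < fit.b1:  # canonical ordering
        fit = replace(fit, a1=fit.a2, b1=fit.b2, c1=fit.c2, a2=fit.a1, b2=fit.b1, c2=fit.c1)
    return fit


def histogram_from_samples(samples, bins: int = 40) -> HistogramData:
    """Bin raw samples into a HistogramData (bin centers at midpoints)."""
    counts, edges = np.histogram(np.asarray(samples, dtype=float), bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return HistogramData(x=centers, counts=counts.astype(float))
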