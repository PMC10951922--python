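"""Gaussian random field (GRF) model of parametric maps.

A parametric map (e.g. a fiber length map) is modeled, after
gaussianization of its intensity histogram, as a realization of a
zero-mean stationary 2D Gaussian random field.  The field is summarized
by three numbers learned from a reference ("normal") population:

* ``sigma`` -- the standard deviation of the field,
* ``lambda_det`` -- the determinant of the 2x2 covariance matrix of the
  field's partial derivatives (a roughness measure), and
* ``n_pixels`` -- the image area S in pixels.

From these, random-field theory gives closed forms for the expected
number of suprathreshold clusters (the expected Euler characteristic of
the excursion set, valid at large thresholds), the expected
suprathreshold area, and hence the expected cluster extent.  Two
per-cluster null probabilities follow: the probability of a cluster
formed at threshold ``t`` having an intensity peak at least ``x``, and
the probability of it having a spatial extent of at least ``s0`` (the
extent is approximately exponentially distributed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ParametricMap",
    "GRFModel",
    "FlatFieldError",
    "gaussianize",
    "estimate_field_params",
    "learn_model",
    "expected_cluster_count",
    "expected_suprathreshold_area",
    "expected_cluster_extent",
    "p_intensity",
    "p_surface",
]

_MIN_SIDE = 8  # gradient covariance needs interior pixels


class FlatFieldError(ValueError):
    """Raised when a map is too flat for gradient covariance estimation."""


@dataclass
class ParametricMap:
    """A 2D real-valued image carrying one parameter value per pixel.

    Parameters
    ----------
    values : ndarray, shape (H, W)
        Map values (e.g. pixels for a fiber length map, inverse degrees
        for a pore directionality map).
    pixel_size : float, optional
        Physical pixel size in micrometers per pixel (metadata only).
    """

    values: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("a parametric map must be a 2D array")
        if min(self.values.shape) < _MIN_SIDE:
            raise ValueError(
                f"map must be at least {_MIN_SIDE}x{_MIN_SIDE} pixels, "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_pixels(self) -> int:
        return int(self.values.size)


@dataclass
class GRFModel:
    """Learned GRF parameters (training-set averages).

    Attributes
    ----------
    lambda_det : float
        Determinant of the 2x2 covariance matrix of the per-pixel
        gradient vectors, in (map units)^4 / pixel^4.
    sigma : float
        Standard deviation of the field, in map units.
    n_pixels : float
        Image area S (pixel count); averaged over the training set.
    n_training_maps : int
        Number of maps the model was averaged over.
    """

    lambda_det: float
    sigma: float
    n_pixels: float
    n_training_maps: int = 1

    def __post_init__(self) -> None:
        if not self.lambda_det > 0:
            raise ValueError("lambda_det must be positive")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if self.n_pixels < 64:
            raise ValueError("n_pixels must be at least 64")


# ---------------------------------------------------------------------------
# Gaussianization (1-D optimal transport of the intensity histogram)
# ---------------------------------------------------------------------------

def gaussianize(pmap: ParametricMap) -> ParametricMap:
    """Make the intensity histogram Gaussian, preserving pixel ranks.

    The monotone (1-D optimal transport) map from the empirical CDF to a
    Gaussian CDF sends the pixel of rank ``i`` (stable sort, ties kept in
    array order) to the quantile ``Phi^-1((i - 0.5)/N)``, rescaled so the
    output has zero mean and *exactly* the input's sample variance.
    Rescaling to the empirical variance (rather than to the variance of
    the ideal quantile grid) makes the transform exactly idempotent.

    Raises
    ------
    ValueError
        If the map is constant (degenerate histogram: no transport map).
    """
    v = pmap.values.ravel()
    n = v.size
    sd = v.std()
    if sd == 0 or np.ptp(v) == 0:
        raise ValueError("cannot gaussianize a constant map")
    order = np.argsort(v, kind="stable")
    grid = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    grid *= sd / grid.std()
    out = np.empty(n, dtype=float)
    out[order] = grid
    return ParametricMap(out.reshape(pmap.shape), pixel_size=pmap.pixel_size)


# ---------------------------------------------------------------------------
# Per-image field parameter estimation and training-set averaging
# ---------------------------------------------------------------------------

def estimate_field_params(pmap: ParametricMap) -> tuple[float, float]:
    """Estimate (lambda_det, sigma) of a (gaussianized) map.

    The gradient is estimated with one-pixel forward differences on
    interior pixels (the one-pixel border is excluded from the
    covariance estimate).  Unit-lattice increments are the roughness
    the excursion-set cluster counts of the *sampled* field respond to;
    a wider stencil (e.g. central differences over two pixels)
    low-passes the field and systematically underestimates the expected
    cluster count.  ``sigma`` is the sample standard deviation of all
    pixel intensities.

    Raises
    ------
    FlatFieldError
        If the gradient covariance determinant is (near) zero, e.g. for
        a constant map or a perfect ramp.
    """
    v = pmap.values
    gx = v[1:-1, 2:] - v[1:-1, 1:-1]   # d/dcol
    gy = v[2:, 1:-1] - v[1:-1, 1:-1]   # d/drow
    cov = np.cov(np.vstack([gx.ravel(), gy.ravel()]))
    lambda_det = float(np.linalg.det(cov))
    sigma = float(v.std(ddof=1))
    scale = max(sigma, np.finfo(float).tiny)
    if not np.isfinite(lambda_det) or lambda_det <= 1e-12 * scale**4:
        raise FlatFieldError(
            "gradient covariance is degenerate; map is unsuitable for GRF "
            "modeling (constant or ramp-like field)"
        )
    return lambda_det, sigma


def learn_model(training_maps: list[ParametricMap]) -> GRFModel:
    """Average per-map field parameters over a (gaussianized) training set.

    Stores the arithmetic mean of ``lambda_det``, ``sigma`` and the pixel
    count over the training maps.  A single map is accepted (the model
    then equals the single-map estimate).
    """
    if len(training_maps) == 0:
        raise ValueError("learn_model requires at least one training map")
    dets, sigmas, sizes = [], [], []
    for m in training_maps:
        d, s = estimate_field_params(m)
        dets.append(d)
        sigmas.append(s)
        sizes.append(m.n_pixels)
    return GRFModel(
        lambda_det=float(np.mean(dets)),
        sigma=float(np.mean(sigmas)),
        n_pixels=float(np.mean(sizes)),
        n_training_maps=len(training_maps),
    )


# ---------------------------------------------------------------------------
# Random-field-theoretic expectations and per-cluster probabilities
# ---------------------------------------------------------------------------

def expected_cluster_count(model: GRFModel, t: float) -> float:
    """Expected number of clusters E[m_t] at threshold ``t``.

    Equals the expected Euler characteristic of the excursion set of a
    2D zero-mean stationary GRF (valid at large thresholds):

        E[m_t] = S (2 pi)^{-3/2} |Lambda|^{1/2} sigma^{-3} t exp(-t^2 / 2 sigma^2)
    """
    if not t > 0:
        raise ValueError("threshold t must be positive (large-threshold formula)")
    s, sig = model.n_pixels, model.sigma
    return float(
        s
        * (2.0 * np.pi) ** -1.5
        * np.sqrt(model.lambda_det)
        * sig**-3
        * t
        * np.exp(-(t**2) / (2.0 * sig**2))
    )


def expected_suprathreshold_area(model: GRFModel, t: float) -> float:
    """Expected number of pixels above ``t``: E[N_t] = S * Phi_bar(t / sigma)."""
    return float(model.n_pixels * stats.norm.sf(t / model.sigma))


def expected_cluster_extent(model: GRFModel, t: float) -> float:
    """Expected cluster extent E[S_t] = E[N_t] / E[m_t] at threshold ``t``."""
    return expected_suprathreshold_area(model, t) / expected_cluster_count(model, t)


def p_intensity(model: GRFModel, t: float, x: float) -> float:
    """Probability that a cluster formed at ``t`` peaks at or above ``x``.

    Computed as the ratio of expected cluster counts E[m_x] / E[m_t],
    which algebraically reduces to ``(x/t) exp(-(x^2 - t^2)/(2 sigma^2))``
    (the image area and roughness cancel).  Clipped to [0, 1].
    """
    if not t > 0:
        raise ValueError("threshold t must be positive")
    if x < t:
        raise ValueError("peak x must be >= threshold t")
    sig2 = model.sigma**2
    ratio = (x / t) * np.exp(-(x**2 - t**2) / (2.0 * sig2))
    return float(min(1.0, ratio))


def p_surface(model: GRFModel, t: float, s0: float) -> float:
    """Probability that a cluster formed at ``t`` has extent >= ``s0``.

    The cluster extent approximately follows an exponential law whose
    rate is the inverse of the expected extent:  P = exp(-s0 / E[S_t]).
    """
    if s0 < 0:
        raise ValueError("spatial extent s0 must be non-negative")
    p = np.exp(-s0 / expected_cluster_extent(model, t))
    return float(min(1.0, max(0.0, p)))
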