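"""Mono-exponential ADC / R2 mapping and coupling-slope metrics.

Voxel-wise apparent diffusion coefficients are estimated at each TE from the
signal decay over b, and apparent R2 rates at each b from the decay over TE,
both by bounded nonlinear least squares on the mono-exponential model
``A * exp(-rate * x)``.  ROI means of the resulting maps are regressed
against TE (in seconds) and b to yield the coupling slopes k_ADC/TE and
k_R2/b (both in mm^2/s^2), and the ROI-mean R2 of the b = 0 series is
reported (in 1/ms) as the iron surrogate R2_b=0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .acquisition import AcquisitionGrid

__all__ = [
    "MonoExpFit", "ParamMaps", "CouplingMetrics",
    "fit_mono_adc", "fit_mono_r2", "fit_parameter_maps",
    "roi_mean_series", "coupling_slopes", "estimate_snr",
]

#: physiological fit bounds
ADC_BOUNDS = (0.0, 0.01)   # mm^2/s
R2_BOUNDS = (0.0, 100.0)   # 1/s

#: Rayleigh correction: SD of |N(0,s) + i N(0,s)| equals s * sqrt(2 - pi/2)
RAYLEIGH_SD_FACTOR = float(np.sqrt(2.0 - np.pi / 2.0))


@dataclass(frozen=True)
class MonoExpFit:
    """Result of one mono-exponential least-squares fit."""

    rate: float          # decay rate: ADC (mm^2/s) or R2 (1/s)
    amplitude: float     # extrapolated signal at x = 0
    resid_norm: float    # sqrt(sum of squared residuals)
    converged: bool
    n_points: int


def _fit_monoexp(x: np.ndarray, y: np.ndarray, rate_bounds) -> MonoExpFit:
    """Least-squares fit of ``A * exp(-k x)`` with ``k`` in ``rate_bounds``.

    Initialized from the ordinary least-squares fit of ln(y) on x; with
    exactly two points the exact log-ratio solution is returned directly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct sample points")
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if np.any(y <= 0):
        raise ValueError("all signals must be > 0 for a decay fit")

    lo, hi = rate_bounds
    if np.ptp(y) == 0.0:
        # flat series: the zero-rate model fits exactly
        return MonoExpFit(0.0, float(y[0]), 0.0, True, int(x.size))
    slope, intercept = np.polyfit(x, np.log(y), 1)
    k0 = float(np.clip(-slope, lo, hi))
    a0 = float(np.exp(intercept))

    if x.size == 2:
        # exact two-point solution: the model interpolates both samples
        k = float(np.clip(np.log(y[0] / y[1]) / (x[1] - x[0]), lo, hi))
        a = float(y[0] * np.exp(k * x[0]))
        resid = float(np.linalg.norm(y - a * np.exp(-k * x)))
        return MonoExpFit(k, a, resid, True, 2)

    def residuals(p):
        return p[0] * np.exp(-p[1] * x) - y

    sol = optimize.least_squares(
        residuals, x0=[a0, k0],
        bounds=([0.0, lo], [np.inf, hi]),
        method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    return MonoExpFit(
        rate=float(sol.x[1]),
        amplitude=float(sol.x[0]),
        resid_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
        n_points=int(x.size),
    )


def fit_mono_adc(signals, bvals) -> MonoExpFit:
    """Apparent ADC from the signal decay over b at a fixed TE.

    Minimizes sum (S_i - A exp(-ADC b_i))^2 over A > 0 and
    ADC in [0, 0.01] mm^2/s.  Returns the fit with ``rate`` = ADC and
    ``amplitude`` = extrapolated b = 0 signal.
    """
    return _fit_monoexp(np.asarray(bvals, dtype=float), signals, ADC_BOUNDS)


def fit_mono_r2(signals, tes_ms) -> MonoExpFit:
    """Apparent R2 from the signal decay over TE at a fixed b.

    TE is supplied in milliseconds and converted to seconds, so ``rate`` is
    R2 in 1/s, bounded to [0, 100]; ``amplitude`` is the TE = 0 extrapolation.
    """
    te_s = np.asarray(tes_ms, dtype=float) / 1000.0
    return _fit_monoexp(te_s, signals, R2_BOUNDS)


@dataclass
class ParamMaps:
    """Voxel-wise parameter maps on the (x, y, z) grid of the input volume.

    ``adc_per_te[..., i]`` is the ADC map fitted at ``grid.tes[i]``;
    ``r2_per_b[..., j]`` the R2 map at ``grid.bvals[j]``.  ``valid`` flags
    voxels where every fit converged on positive data; all other in-mask
    voxels carry NaN and are excluded from ROI statistics.
    """

    adc_per_te: np.ndarray
    r2_per_b: np.ndarray
    valid: np.ndarray
    resid_adc: np.ndarray
    resid_r2: np.ndarray
    grid: AcquisitionGrid = field(repr=False, default=None)


def fit_parameter_maps(volume5d: np.ndarray, grid: AcquisitionGrid,
                       mask: np.ndarray | None = None) -> ParamMaps:
    """Fit ADC (per TE) and R2 (per b) for every in-mask voxel.

    Parameters
    ----------
    volume5d : ndarray, shape (x, y, z, n_te, n_b)
        Magnitude signal volume on the acquisition grid.
    grid : AcquisitionGrid
    mask : ndarray of bool, shape (x, y, z), optional
        Restrict fitting to these voxels (default: all).

    Voxels with any non-positive sample, or any non-converged fit, are
    flagged invalid rather than raising.
    """
    volume5d = np.asarray(volume5d, dtype=float)
    n_te, n_b = grid.shape
    if volume5d.ndim != 5 or volume5d.shape[3:] != (n_te, n_b):
        raise ValueError(f"volume shape {volume5d.shape} does not match grid "
                         f"(expected (..., {n_te}, {n_b}))")
    spatial = volume5d.shape[:3]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != spatial:
        raise ValueError(f"mask shape {mask.shape} does not match volume {spatial}")

    adc = np.full(spatial + (n_te,), np.nan)
    r2 = np.full(spatial + (n_b,), np.nan)
    resid_adc = np.full(spatial + (n_te,), np.nan)
    resid_r2 = np.full(spatial + (n_b,), np.nan)
    valid = np.zeros(spatial, dtype=bool)

    tes = grid.te_array
    bvals = grid.b_array
    for idx in zip(*np.nonzero(mask)):
        series = volume5d[idx]  # (n_te, n_b)
        if np.any(series <= 0):
            continue
        ok = True
        for i in range(n_te):
            fit = fit_mono_adc(series[i, :], bvals)
            adc[idx + (i,)] = fit.rate
            resid_adc[idx + (i,)] = fit.resid_norm
            ok &= fit.converged
        for j in range(n_b):
            fit = fit_mono_r2(series[:, j], tes)
            r2[idx + (j,)] = fit.rate
            resid_r2[idx + (j,)] = fit.resid_norm
            ok &= fit.converged
        valid[idx] = ok
    return ParamMaps(adc, r2, valid, resid_adc, resid_r2, grid)


def roi_mean_series(maps: ParamMaps, roi_mask: np.ndarray):
    """ROI-mean ADC per TE and R2 per b, averaging valid voxels only.

    Returns ``(mean_adc_per_te, mean_r2_per_b, n_voxels)`` where ``n_voxels``
    counts the voxels contributing to the means.  Raises if the ROI is empty
    after excluding flagged voxels.
    """
    roi_mask = np.asarray(roi_mask).astype(bool)
    use = roi_mask & maps.valid
    n = int(use.sum())
    if n == 0:
        raise ValueError("ROI contains no valid voxels")
    return maps.adc_per_te[use].mean(axis=0), maps.r2_per_b[use].mean(axis=0), n


@dataclass(frozen=True)
class CouplingMetrics:
    """Per-ROI coupling slopes and the iron surrogate.

    ``k_adc_te``: OLS slope of ROI-mean ADC against TE *in seconds*
    (mm^2/s^2); ``k_r2_b``: slope of ROI-mean R2 against b (mm^2/s^2;
    (1/s) per (s/mm^2)).  ``r2_b0``: the measured ROI-mean R2 of the b = 0
    series, reported in 1/ms.  Positive coupling corresponds to
    ``k_adc_te > 0`` and ``k_r2_b > 0``.
    """

    k_adc_te: float
    k_r2_b: float
    r2_b0: float
    adc_intercept: float
    r2_intercept: float
    k_adc_te_r: float
    k_r2_b_r: float


def coupling_slopes(mean_adc_per_te, tes_ms, mean_r2_per_b, bvals) -> CouplingMetrics:
    """Coupling-slope metrics from the ROI-mean series.

    Unweighted ordinary least squares of ADC on TE (seconds) and of R2 on b.
    ``r2_b0`` is taken directly from the measured b = 0 entry of
    ``mean_r2_per_b`` (not a regression intercept) and converted to 1/ms.
    """
    tes_ms = np.asarray(tes_ms, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    mean_adc_per_te = np.asarray(mean_adc_per_te, dtype=float)
    mean_r2_per_b = np.asarray(mean_r2_per_b, dtype=float)
    if tes_ms.size < 2 or bvals.size < 2:
        raise ValueError("need >= 2 TE and >= 2 b levels for coupling slopes")
    if bvals[0] != 0:
        raise ValueError("bvals[0] must be 0 to define r2_b0")

    adc_fit = stats.linregress(tes_ms / 1000.0, mean_adc_per_te)
    r2_fit = stats.linregress(bvals, mean_r2_per_b)
    return CouplingMetrics(
        k_adc_te=float(adc_fit.slope),
        k_r2_b=float(r2_fit.slope),
        r2_b0=float(mean_r2_per_b[0]) / 1000.0,
        adc_intercept=float(adc_fit.intercept),
        r2_intercept=float(r2_fit.intercept),
        k_adc_te_r=float(adc_fit.rvalue),
        k_r2_b_r=float(r2_fit.rvalue),
    )


def estimate_snr(image: np.ndarray, signal_mask: np.ndarray,
                 noise_mask: np.ndarray) -> float:
    """Signal-to-noise ratio from a signal ROI and a background region.

    SNR = mean(signal) / sigma_g, with the Gaussian channel noise SD
    recovered from the background magnitude via the Rayleigh relation
    sigma_g = SD(background) / sqrt(2 - pi/2).  By convention evaluated on
    the most attenuated image of the grid (max b, max TE).

    A zero-variance background (noiseless data) returns ``inf`` with a
    warning rather than raising.
    """
    image = np.asarray(image, dtype=float)
    signal_mask = np.asarray(signal_mask).astype(bool)
    noise_mask = np.asarray(noise_mask).astype(bool)
    if not signal_mask.any() or not noise_mask.any():
        raise ValueError("signal and noise masks must be non-empty")
    if (signal_mask & noise_mask).any():
        raise ValueError("signal and noise masks must be disjoint")
    sigma_g = float(image[noise_mask].std(ddof=1)) / RAYLEIGH_SD_FACTOR
    if sigma_g == 0.0:
        warnings.warn("background has zero variance; SNR is infinite", stacklevel=2)
        return float("inf")
    return float(image[signal_mask].mean()) / sigma_g
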