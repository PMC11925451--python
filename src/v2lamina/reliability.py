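"""Test-retest pattern reliability with a Monte-Carlo FWE null.

The observed statistic is the Pearson correlation between two sessions'
columnar selectivity maps over an ROI.  Its family-wise-error-corrected
p-value comes from a Monte-Carlo null: the spatial autocorrelation function
(ACF) of the first session's GLM residuals is estimated on the cortical
sheet, fitted with the standard Gaussian+exponential mixture

    ACF(r) = a * exp(-r^2 / (2 b^2)) + (1 - a) * exp(-r / c),

and null second-session maps with exactly that ACF are simulated (white
noise shaped in the Fourier domain) and correlated with the fixed
first-session map.  The procedure is asymmetric by design: the reference
map is held fixed and only the second session is simulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .exceptions import FitError, InputError


def pattern_correlation(map1, map2):
    """Pearson correlation between two maps over matched ROI voxels."""
    x = np.asarray(map1, dtype=float).ravel()
    y = np.asarray(map2, dtype=float).ravel()
    if x.size != y.size:
        raise InputError("maps differ in size")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise InputError("need at least 3 voxels for a pattern correlation")
    if x.std() == 0 or y.std() == 0:
        raise InputError("zero variance in one of the maps")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class ACFModel:
    """Fitted spatial ACF: a*exp(-r^2/(2 b^2)) + (1-a)*exp(-r/c)."""

    a: float
    b: float  # Gaussian scale, mm
    c: float  # exponential scale, mm
    lags_mm: np.ndarray = field(default=None, repr=False)
    empirical: np.ndarray = field(default=None, repr=False)
    degenerate: bool = False

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        return self.a * np.exp(-(r**2) / (2.0 * self.b**2)) + (1.0 - self.a) * np.exp(
            -r / self.c
        )


def _radial_average(acov, spacing_mm, max_lag_mm):
    """Radially bin a 2D autocovariance image (origin at [0, 0], wrap-around)."""
    nv, nu = acov.shape
    dv = np.minimum(np.arange(nv), nv - np.arange(nv))[:, None]
    du = np.minimum(np.arange(nu), nu - np.arange(nu))[None, :]
    r = np.hypot(dv, du) * spacing_mm
    nbins = int(max_lag_mm / spacing_mm)
    lags = np.arange(nbins + 1) * spacing_mm
    idx = np.clip(np.round(r / spacing_mm).astype(int), 0, nbins)
    keep = (r <= max_lag_mm + 0.5 * spacing_mm).ravel()
    sums = np.bincount(idx.ravel()[keep], weights=acov.ravel()[keep], minlength=nbins + 1)
    counts = np.bincount(idx.ravel()[keep], minlength=nbins + 1)
    return lags, sums / np.maximum(counts, 1)


def estimate_acf(residual_maps, spacing_mm=1.0, max_lag_mm=8.0) -> ACFModel:
    """Fit the mixture ACF to the spatial autocorrelation of residual maps.

    Parameters
    ----------
    residual_maps : ndarray, shape (T, nv, nu)
        GLM residual maps on the sheet grid (e.g. column-averaged residuals
        over timepoints).  NaNs are not allowed.
    spacing_mm : float
        Grid spacing.
    max_lag_mm : float
        Largest lag used in the radial average and fit.

    Raises
    ------
    FitError
        If the least-squares fit fails; the error payload carries the
        empirical (lag, ACF) curve.
    """
    maps = np.asarray(residual_maps, dtype=float)
    if maps.ndim != 3 or maps.shape[0] < 2:
        raise InputError("need a (T, nv, nu) stack with T >= 2")
    maps = maps - maps.mean(axis=(1, 2), keepdims=True)
    f = np.fft.rfft2(maps, axes=(1, 2))
    power = (f * np.conj(f)).real.mean(axis=0)
    acov = np.fft.irfft2(power, s=maps.shape[1:], axes=(0, 1))
    acov /= acov[0, 0]
    lags, emp = _radial_average(acov, spacing_mm, max_lag_mm)

    degenerate = bool(emp[1] < 0.05) if emp.size > 1 else True
    if degenerate:
        warnings.warn("residuals look spatially white; ACF fit is degenerate")

    def model(r, a, b, c):
        return a * np.exp(-(r**2) / (2.0 * b**2)) + (1.0 - a) * np.exp(-r / c)

    try:
        popt, _ = optimize.curve_fit(
            model,
            lags,
            emp,
            p0=(0.9, max(spacing_mm, 1.0), 2.0),
            bounds=([0.0, 1e-3, 1e-3], [1.0, 50.0, 50.0]),
            maxfev=20000,
        )
    except Exception as exc:  # pragma: no cover - fit failure path
        raise FitError("ACF fit failed", payload=(lags, emp)) from exc
    return ACFModel(*popt, lags_mm=lags, empirical=emp, degenerate=degenerate)


@dataclass
class NullDistribution:
    """Monte-Carlo null correlations."""

    samples: np.ndarray
    n_iter: int
    seed: int | None = None

    def critical_value(self, alpha=0.05):
        """One-sided upper critical value at level ``alpha``."""
        return float(np.quantile(self.samples, 1.0 - alpha))


def simulate_smooth_maps(acf: ACFModel, shape, n_maps, rng):
    """Draw smooth null maps with the fitted ACF via spectral shaping.

    The target ACF image is laid out on the (periodic) grid, its FFT gives
    the power spectrum, and white-noise fields are filtered by its square
    root -- white noise convolved with the kernel whose autocorrelation
    matches the fitted ACF.
    """
    nv, nu = shape
    dv = np.minimum(np.arange(nv), nv - np.arange(nv))[:, None]
    du = np.minimum(np.arange(nu), nu - np.arange(nu))[None, :]
    r = np.hypot(dv, du)
    spec = np.fft.rfft2(acf(r)).real
    spec = np.sqrt(np.clip(spec, 0.0, None))
    white = rng.standard_normal((n_maps, nv, nu))
    return np.fft.irfft2(np.fft.rfft2(white, axes=(1, 2)) * spec, s=(nv, nu), axes=(1, 2))


def simulate_null_correlations(
    acf: ACFModel, reference_map, n_iter=10000, seed=0, roi_mask=None
) -> NullDistribution:
    """Null distribution of pattern correlations against a fixed reference.

    Each iteration draws one smooth null map with the fitted ACF on the
    reference map's grid and correlates it with the reference over the ROI.
    """
    if n_iter < 100:
        raise InputError("n_iter must be >= 100")
    ref = np.asarray(reference_map, dtype=float)
    if roi_mask is None:
        roi_mask = np.isfinite(ref)
    roi_mask = np.asarray(roi_mask, dtype=bool) & np.isfinite(ref)
    refv = ref[roi_mask]
    refv = (refv - refv.mean()) / refv.std()
    rng = np.random.default_rng([int(seed) % (2**31), 57])
    samples = np.empty(n_iter)
    batch = 500
    done = 0
    while done < n_iter:
        k = min(batch, n_iter - done)
        maps = simulate_smooth_maps(acf, ref.shape, k, rng)
        sims = maps[:, roi_mask]
        sims = sims - sims.mean(axis=1, keepdims=True)
        sims /= sims.std(axis=1, keepdims=True)
        samples[done : done + k] = sims @ refv / refv.size
        done += k
    return NullDistribution(samples, n_iter, seed)


def fwe_corrected_p(observed_r, null: NullDistribution):
    """One-sided FWE-corrected p with add-one smoothing: (1 + #{null >= r}) / (1 + n)."""
    if null.samples.size == 0:
        raise InputError("empty null distribution")
    return float((1 + np.sum(null.samples >= observed_r)) / (1 + null.n_iter))


def critical_r(null: NullDistribution, alpha=0.05):
    return null.critical_value(alpha)
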