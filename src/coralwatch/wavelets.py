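"""Morlet continuous wavelet analysis of observatory time series.

Unlike a Fourier spectrum, the continuous wavelet transform (CWT) keeps both
time and scale information, which is what makes it possible to see, e.g., a
diel (24 h) rhythm in polyp activity that is present only during part of a
seven-month record.  The implementation follows the standard geophysical
formulation of the Morlet CWT:

- complex Morlet mother wavelet with nondimensional frequency ``omega0 = 6``,
  evaluated in the Fourier domain over a dyadic scale ladder (default 12
  voices per octave);
- *bias-corrected* power ``|W(s, t)|^2 / s``, so equal-amplitude oscillations
  at different periods attain equal spectral peaks;
- pointwise chi-square significance of power against a theoretical AR(1)
  ("red noise") background spectrum;
- squared wavelet coherence of two series from the smoothed cross-spectrum
  normalised by the smoothed individual spectra, with phase, and Monte Carlo
  significance from AR(1) surrogate pairs.

Series entering the transform must be gapless on their grid; gap handling is
the job of the interpolation stage upstream (:mod:`coralwatch.align`).  Edges
are zero-padded to the next power of two and the cone of influence (COI) marks
the region where edge effects contaminate the coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from coralwatch.align import IrregularSeries, RegularSeries

__all__ = [
    "NoiseModel",
    "WaveletSpectrum",
    "CoherenceResult",
    "morlet_fourier_factor",
    "save_spectrum",
    "cwt_morlet",
    "bias_corrected_power",
    "global_spectrum",
    "fit_ar1",
    "ar1_surrogate",
    "power_significance",
    "wavelet_coherence",
    "coherence_significance",
    "scale_averaged_coherence",
]

#: Reconstruction constant C_delta for the Morlet wavelet with omega0 = 6.
_C_DELTA_MORLET6 = 0.776


def save_spectrum(spectrum: "WaveletSpectrum", basepath) -> None:
    """Write a spectrum as a CSV grid plus a JSON header.

    ``<basepath>.csv`` holds the bias-corrected power grid (rows = scales,
    columns = times); ``<basepath>.json`` the axes, COI and parameters.
    """
    import json
    from pathlib import Path

    basepath = Path(basepath)
    np.savetxt(basepath.with_suffix(".csv"), spectrum.corrected_power,
               delimiter=",", fmt="%.6g")
    header = {
        "periods_h": spectrum.periods.tolist(),
        "scales_h": spectrum.scales.tolist(),
        "times": [t.isoformat() for t in spectrum.times],
        "coi_periods_h": spectrum.coi_periods.tolist(),
        "dt_hours": spectrum.dt_hours,
        "omega0": spectrum.omega0,
        "power": "bias-corrected (|W|^2 / scale)",
    }
    basepath.with_suffix(".json").write_text(json.dumps(header, indent=2))


def morlet_fourier_factor(omega0: float = 6.0) -> float:
    """Ratio of equivalent Fourier period to wavelet scale for the Morlet."""
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0 ** 2))


@dataclass
class NoiseModel:
    """First-order autoregressive ("red noise") background model."""

    ar1: float
    variance: float

    def __post_init__(self) -> None:
        if not abs(self.ar1) < 1:
            raise ValueError("|AR1 coefficient| must be < 1")
        if self.variance < 0:
            raise ValueError("variance must be non-negative")

    def spectrum(self, period: np.ndarray, dt: float) -> np.ndarray:
        """Normalised theoretical Fourier spectrum at the given periods.

        ``period`` and ``dt`` share a unit; the result integrates to 1 over
        frequency, i.e. it multiplies the process variance.
        """
        freq = dt / np.asarray(period, dtype=float)  # cycles per sample
        a = self.ar1
        return (1.0 - a ** 2) / (1.0 + a ** 2 - 2.0 * a * np.cos(2.0 * np.pi * freq))


@dataclass
class WaveletSpectrum:
    """Morlet CWT of one series: coefficients, power and cone of influence.

    Attributes
    ----------
    scales, periods
        Wavelet scales and the equivalent Fourier periods (hours); the two
        differ by the constant Morlet Fourier factor (~1.033 for omega0=6).
    coeffs
        Complex coefficient grid, shape ``(n_scales, n_times)``.
    coi_periods
        Per time point, the period above which edge effects contaminate the
        transform (the cone of influence boundary).
    """

    scales: np.ndarray
    periods: np.ndarray
    times: pd.DatetimeIndex
    coeffs: np.ndarray
    dt_hours: float
    omega0: float
    series_variance: float
    coi_periods: np.ndarray
    significance: np.ndarray | None = None

    @property
    def power(self) -> np.ndarray:
        """Raw wavelet power ``|W|^2``."""
        return np.abs(self.coeffs) ** 2

    @property
    def corrected_power(self) -> np.ndarray:
        """Bias-corrected power ``|W|^2 / s``."""
        return self.power / self.scales[:, None]

    def inside_coi(self) -> np.ndarray:
        """Boolean grid, True where the point is unaffected by edges."""
        return self.periods[:, None] <= self.coi_periods[None, :]

    def variance_estimate(self) -> float:
        """Variance recovered from the transform (a Parseval-type check)."""
        dj = np.log2(self.scales[1] / self.scales[0])
        n = self.coeffs.shape[1]
        return float(dj * self.dt_hours / (_C_DELTA_MORLET6 * n)
                     * np.sum(self.power / self.scales[:, None]))


@dataclass
class CoherenceResult:
    """Squared wavelet coherence, phase and significance of a series pair."""

    scales: np.ndarray
    periods: np.ndarray
    times: pd.DatetimeIndex
    coherence: np.ndarray
    phase: np.ndarray
    dt_hours: float
    coi_periods: np.ndarray
    significance: np.ndarray | None = None
    thresholds: np.ndarray | None = None

    def inside_coi(self) -> np.ndarray:
        return self.periods[:, None] <= self.coi_periods[None, :]


def _values_and_grid(series) -> tuple[np.ndarray, float, pd.DatetimeIndex]:
    if isinstance(series, RegularSeries):
        if not series.is_gapless:
            raise ValueError(
                "series has missing grid points; interpolate gaps upstream "
                "before the wavelet transform")
        return series.values.astype(float), float(series.step_hours), series.timestamps
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be gapless (finite values)")
    times = pd.date_range("2000-01-01", periods=len(x), freq="h")
    return x, 1.0, times


def _scale_ladder(n: int, dt: float, s0: float | None, dj: float,
                  max_period: float | None, omega0: float) -> np.ndarray:
    ff = morlet_fourier_factor(omega0)
    if s0 is None:
        s0 = 2.0 * dt
    if max_period is None:
        max_scale = n * dt / 2.0
    else:
        max_scale = max_period / ff
    if max_scale < s0:
        raise ValueError("series too short for the requested smallest scale")
    J = int(np.floor(np.log2(max_scale / s0) / dj))
    return s0 * 2.0 ** (dj * np.arange(J + 1))


def cwt_morlet(series, s0: float | None = None, dj: float = 1.0 / 12.0,
               max_period: float | None = None, omega0: float = 6.0,
               detrend: bool = True) -> WaveletSpectrum:
    """Continuous Morlet wavelet transform of a gapless regular series.

    Parameters
    ----------
    series
        A :class:`~coralwatch.align.RegularSeries` without missing values, or a
        plain 1-D array (then the grid step is taken as 1 hour).
    s0
        Smallest scale (hours); default twice the grid step.
    dj
        Scale resolution in octaves; the default 1/12 gives 12 voices/octave.
    max_period
        Largest equivalent Fourier period (hours) on the ladder; default half
        the record length.
    omega0
        Morlet nondimensional frequency (the conventional 6 balances time and
        frequency localisation).
    detrend
        Remove the series mean before transforming (the mean is a zero-
        frequency offset the Morlet cannot represent).
    """
    x, dt, times = _values_and_grid(series)
    n = len(x)
    scales = _scale_ladder(n, dt, s0, dj, max_period, omega0)
    if n * dt < 2 * scales[0]:
        raise ValueError("series shorter than the smallest scale")
    if detrend:
        x = x - x.mean()
    variance = float(np.var(x))

    n_pad = int(2 ** np.ceil(np.log2(n)))
    xf = np.fft.fft(x, n_pad)
    omega = 2.0 * np.pi * np.fft.fftfreq(n_pad, d=dt)

    # Morlet daughters in the Fourier domain (positive frequencies only),
    # normalised so every scale has unit energy.
    pos = omega > 0
    coeffs = np.empty((len(scales), n), dtype=complex)
    norm_const = np.pi ** -0.25 * np.sqrt(2.0 * np.pi / dt)
    for j, s in enumerate(scales):
        psi_hat = np.zeros(n_pad)
        psi_hat[pos] = norm_const * np.sqrt(s) * np.exp(
            -0.5 * (s * omega[pos] - omega0) ** 2)
        coeffs[j] = np.fft.ifft(xf * psi_hat)[:n]

    ff = morlet_fourier_factor(omega0)
    # e-folding time of the Morlet envelope is sqrt(2)*s
    edge = np.minimum(np.arange(n), np.arange(n)[::-1]).astype(float)
    coi = ff * np.sqrt(2.0) * dt * np.maximum(edge, 1e-12)

    return WaveletSpectrum(scales=scales, periods=ff * scales, times=times,
                           coeffs=coeffs, dt_hours=dt, omega0=omega0,
                           series_variance=variance, coi_periods=coi)


def bias_corrected_power(spectrum: WaveletSpectrum) -> np.ndarray:
    """Bias-corrected power grid ``|W|^2 / s`` (see the module docstring)."""
    return spectrum.corrected_power


def global_spectrum(spectrum: WaveletSpectrum,
                    coi_only: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Scale-indexed, time-averaged (global) bias-corrected power.

    Returns ``(periods, power)``.  With ``coi_only`` the average is restricted
    to points inside the cone of influence; scales with no such points come
    back as NaN.
    """
    p = spectrum.corrected_power
    if coi_only:
        mask = spectrum.inside_coi()
        with np.errstate(invalid="ignore"):
            curve = np.where(mask.any(axis=1),
                             np.nansum(np.where(mask, p, 0.0), axis=1)
                             / np.maximum(mask.sum(axis=1), 1),
                             np.nan)
    else:
        curve = p.mean(axis=1)
    return spectrum.periods, curve


def fit_ar1(series) -> NoiseModel:
    """Fit a red-noise background: lag-1 autocorrelation and variance."""
    if isinstance(series, (RegularSeries,)):
        x = series.values
    else:
        x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise ValueError("need at least 10 points to fit an AR(1) model")
    if np.ptp(x) == 0:
        raise ValueError("AR(1) fit undefined for a constant series")
    x = x - x.mean()
    r1 = float(np.dot(x[1:], x[:-1]) / np.dot(x, x))
    r1 = float(np.clip(r1, -0.999, 0.999))
    return NoiseModel(ar1=r1, variance=float(np.var(x)))


def ar1_surrogate(n: int, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """Simulate an AR(1) series with the model's stationary variance."""
    a = noise.ar1
    sd = np.sqrt(noise.variance) if noise.variance > 0 else 1.0
    innov_sd = sd * np.sqrt(1.0 - a ** 2)
    # seeding the recursion with eps[0] ~ N(0, sd) starts it in stationarity
    eps = rng.normal(0.0, innov_sd, n)
    eps[0] = rng.normal(0.0, sd)
    return signal.lfilter([1.0], [1.0, -a], eps)


def power_significance(spectrum: WaveletSpectrum, noise: NoiseModel | None = None,
                       level: float = 0.95) -> np.ndarray:
    """Pointwise chi-square significance mask for wavelet power.

    Each point's power is compared against the theoretical AR(1) background
    spectrum at that scale, scaled by the ``level`` quantile of a chi-square
    distribution with 2 degrees of freedom (the distribution of the squared
    modulus of a complex coefficient under Gaussian noise).  The returned
    boolean grid is True where power exceeds the background — ready to be
    drawn as significance contours.
    """
    if not 0 <= level < 1:
        raise ValueError("significance level must be in [0, 1)")
    if noise is None:
        raise ValueError("a NoiseModel is required (fit one with fit_ar1)")
    pk = noise.spectrum(spectrum.periods, spectrum.dt_hours)
    q = stats.chi2.ppf(level, df=2) / 2.0
    threshold = noise.variance * pk * q
    mask = spectrum.power > threshold[:, None]
    spectrum.significance = mask
    return mask


# ---------------------------------------------------------------------------
# coherence


def _smooth(grid: np.ndarray, scales: np.ndarray, dt: float, dj: float,
            scale_window_octaves: float = 0.6) -> np.ndarray:
    """Time-then-scale smoothing operator used in the coherence estimate.

    Time smoothing is a Gaussian of width proportional to the scale (matching
    the Morlet envelope at that scale); scale smoothing is a boxcar spanning
    ``scale_window_octaves`` octaves.  The Gaussian runs as an FFT
    convolution with symmetric edge padding — at the largest scales the
    kernel spans the whole record and direct convolution would dominate the
    Monte Carlo significance cost.
    """
    out = np.empty_like(grid)
    n = grid.shape[1]
    for j, s in enumerate(scales):
        sigma = s / dt
        half = min(int(4.0 * sigma + 0.5), n)
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
        k /= k.sum()
        padded = np.pad(grid[j], half, mode="symmetric")
        out[j] = signal.fftconvolve(padded, k, mode="same")[half:half + n]
    win = max(1, int(round(scale_window_octaves / dj)))
    if win > 1:
        if np.iscomplexobj(out):
            out = (ndimage.uniform_filter1d(out.real, win, axis=0, mode="nearest")
                   + 1j * ndimage.uniform_filter1d(out.imag, win, axis=0, mode="nearest"))
        else:
            out = ndimage.uniform_filter1d(out, win, axis=0, mode="nearest")
    return out


def wavelet_coherence(x, y, s0: float | None = None, dj: float = 1.0 / 12.0,
                      max_period: float | None = None, omega0: float = 6.0,
                      scale_window_octaves: float = 0.6) -> CoherenceResult:
    """Squared wavelet coherence and phase between two series on one grid.

    The squared coherence is ``|S(W_xy / s)|^2 / (S(|W_x|^2 / s) ·
    S(|W_y|^2 / s))`` with ``S`` the time-then-scale smoothing operator and
    ``W_xy = W_x · conj(W_y)`` the cross-spectrum.  Phase is the argument of
    the smoothed cross-spectrum: 0 means in phase, ±pi counter-phase, and
    +pi/2 means ``y`` lags ``x`` by a quarter period at that scale.
    """
    xv, dtx, tx = _values_and_grid(x)
    yv, dty, _ = _values_and_grid(y)
    if len(xv) != len(yv) or dtx != dty:
        raise ValueError("series must share one grid (length and step)")
    wx = cwt_morlet(x, s0=s0, dj=dj, max_period=max_period, omega0=omega0)
    wy = cwt_morlet(y, s0=s0, dj=dj, max_period=max_period, omega0=omega0)
    sinv = 1.0 / wx.scales[:, None]
    sx = _smooth(sinv * np.abs(wx.coeffs) ** 2, wx.scales, dtx, dj, scale_window_octaves)
    sy = _smooth(sinv * np.abs(wy.coeffs) ** 2, wx.scales, dtx, dj, scale_window_octaves)
    sxy = _smooth(sinv * (wx.coeffs * np.conj(wy.coeffs)), wx.scales, dtx, dj,
                  scale_window_octaves)
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(sxy) ** 2 / (sx * sy)
    coh = np.clip(np.nan_to_num(coh), 0.0, 1.0)
    phase = np.angle(sxy)
    return CoherenceResult(scales=wx.scales, periods=wx.periods, times=tx,
                           coherence=coh, phase=phase, dt_hours=dtx,
                           coi_periods=wx.coi_periods)


def coherence_significance(x, y, n_surrogates: int = 300, seed: int = 0,
                           level: float = 0.95, s0: float | None = None,
                           dj: float = 1.0 / 12.0, max_period: float | None = None,
                           omega0: float = 6.0,
                           result: CoherenceResult | None = None) -> np.ndarray:
    """Monte Carlo significance mask for wavelet coherence.

    AR(1) models are fitted to both series; ``n_surrogates`` independent
    surrogate pairs are drawn and their coherence computed with identical
    parameters.  The per-scale ``level`` quantile of surrogate coherence
    (pooled over inside-COI times) is the threshold; the mask is True where
    the observed coherence exceeds it.
    """
    if n_surrogates < 100:
        raise ValueError("need at least 100 surrogate pairs")
    xv, dt, _ = _values_and_grid(x)
    yv, _, _ = _values_and_grid(y)
    if result is None:
        result = wavelet_coherence(x, y, s0=s0, dj=dj, max_period=max_period,
                                   omega0=omega0)
    nx_model = fit_ar1(xv)
    ny_model = fit_ar1(yv)
    rng = np.random.default_rng(seed)
    n = len(xv)
    inside = result.inside_coi()
    samples: list[list[np.ndarray]] = [[] for _ in result.scales]
    for _ in range(n_surrogates):
        sx = ar1_surrogate(n, nx_model, rng)
        sy = ar1_surrogate(n, ny_model, rng)
        c = wavelet_coherence(sx, sy, s0=s0 if s0 is not None else 2.0 * dt,
                              dj=dj, max_period=max_period, omega0=omega0)
        for j in range(len(result.scales)):
            row = c.coherence[j][inside[j]]
            if len(row):
                samples[j].append(row.astype(np.float32))
    thresholds = np.full(len(result.scales), np.nan)
    for j, rows in enumerate(samples):
        if rows:
            thresholds[j] = np.quantile(np.concatenate(rows), level)
    mask = result.coherence > np.where(np.isfinite(thresholds),
                                       thresholds, np.inf)[:, None]
    result.significance = mask
    result.thresholds = thresholds
    return mask


def scale_averaged_coherence(result: CoherenceResult,
                             band: tuple[float, float] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Time-mean squared coherence per scale, restricted to inside-COI points.

    ``band`` optionally restricts the output to periods within ``(lo, hi)``
    hours.  Returns ``(periods, curve)``; scales with no inside-COI points are
    NaN.
    """
    inside = result.inside_coi()
    keep = np.ones(len(result.periods), dtype=bool)
    if band is not None:
        lo, hi = band
        keep = (result.periods >= lo) & (result.periods <= hi)
        if not keep.any():
            raise ValueError("no scales in the requested band")
    with np.errstate(invalid="ignore"):
        curve = np.where(inside.any(axis=1),
                         np.where(inside, result.coherence, 0.0).sum(axis=1)
                         / np.maximum(inside.sum(axis=1), 1),
                         np.nan)
    return result.periods[keep], curve[keep]
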