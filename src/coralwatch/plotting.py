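"""Figure-level views of wavelet spectra and coherence.

The layouts mirror the conventional presentation for observatory records: a
time x period heat map with significance contours and the cone of influence
shaded, plus a right-hand panel with the scale-averaged (global) curve;
coherence plots add phase arrows (right = in phase, left = counter-phase).
"""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.dates as mdates
import matplotlib.pyplot as plt

from coralwatch.wavelets import (CoherenceResult, WaveletSpectrum,
                                 global_spectrum, scale_averaged_coherence)

__all__ = ["plot_power_spectrum", "plot_coherence"]


def _heatmap_panel(ax, times, periods, grid, coi, cmap, vmax=None):
    t = mdates.date2num(times.to_pydatetime())
    pc = ax.pcolormesh(t, periods, grid, cmap=cmap, shading="auto",
                       vmax=vmax, rasterized=True)
    ax.plot(t, np.clip(coi, periods.min(), periods.max()), "k--", lw=1)
    ax.fill_between(t, np.clip(coi, periods.min(), periods.max()),
                    periods.max(), color="white", alpha=0.4, hatch="x",
                    edgecolor="gray", linewidth=0)
    ax.set_yscale("log", base=2)
    ax.set_ylim(periods.max(), periods.min())  # short periods on top
    ax.xaxis.set_major_locator(mdates.AutoDateLocator())
    ax.xaxis.set_major_formatter(mdates.ConciseDateFormatter(
        mdates.AutoDateLocator()))
    ax.set_ylabel("period (h)")
    return pc


def plot_power_spectrum(spectrum: WaveletSpectrum, title: str = "",
                        reference_periods=(12.4, 24.0, 707.0)):
    """Bias-corrected power heat map + significance contours + global panel."""
    fig, (ax, axg) = plt.subplots(
        1, 2, figsize=(10, 4), sharey=True,
        gridspec_kw={"width_ratios": [4, 1], "wspace": 0.05})
    power = spectrum.corrected_power
    pc = _heatmap_panel(ax, spectrum.times, spectrum.periods, power,
                        spectrum.coi_periods, "viridis",
                        vmax=np.quantile(power, 0.98))
    if spectrum.significance is not None:
        ax.contour(mdates.date2num(spectrum.times.to_pydatetime()),
                   spectrum.periods, spectrum.significance.astype(float),
                   levels=[0.5], colors="k", linewidths=1)
    fig.colorbar(pc, ax=ax, pad=0.02, label="power / scale")
    periods, curve = global_spectrum(spectrum)
    axg.plot(curve, periods)
    for p in reference_periods:
        if periods.min() <= p <= periods.max():
            axg.axhline(p, color="gray", ls=":", lw=1)
    axg.set_xlabel("global power")
    if title:
        ax.set_title(title)
    return fig


def plot_coherence(result: CoherenceResult, title: str = "",
                   arrow_decimation: tuple[int, int] = (6, 32)):
    """Squared-coherence heat map with phase arrows and global panel."""
    fig, (ax, axg) = plt.subplots(
        1, 2, figsize=(10, 4), sharey=True,
        gridspec_kw={"width_ratios": [4, 1], "wspace": 0.05})
    pc = _heatmap_panel(ax, result.times, result.periods, result.coherence,
                        result.coi_periods, "magma", vmax=1.0)
    if result.significance is not None:
        ax.contour(mdates.date2num(result.times.to_pydatetime()),
                   result.periods, result.significance.astype(float),
                   levels=[0.5], colors="k", linewidths=1)
    ds, dt_ = arrow_decimation
    t = mdates.date2num(result.times.to_pydatetime())
    js = np.arange(0, len(result.periods), ds)
    ts = np.arange(0, len(t), dt_)
    ph = result.phase[np.ix_(js, ts)]
    strong = result.coherence[np.ix_(js, ts)] > 0.5
    ax.quiver(t[ts][None, :].repeat(len(js), 0)[strong],
              result.periods[js][:, None].repeat(len(ts), 1)[strong],
              np.cos(ph)[strong], np.sin(ph)[strong],
              pivot="mid", scale=35, width=0.002, color="w")
    fig.colorbar(pc, ax=ax, pad=0.02, label="squared coherence")
    periods, curve = scale_averaged_coherence(result)
    axg.plot(curve, periods)
    axg.set_xlim(0, 1)
    axg.set_xlabel("mean coherence")
    if title:
        ax.set_title(title)
    return fig
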