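"""Thin plotting helpers: HRTF/ILD colour maps, cue curves, canal overlay."""

from __future__ import annotations

import numpy as np

from .canal import CanalPrediction
from .cues import ITDCurve
from .hrtf import TransferMap
from .pll import PLLCurve


def plot_transfer_map(transfer_map: TransferMap,
                      prediction: CanalPrediction | None = None,
                      ax=None, vmin: float | None = None,
                      vmax: float | None = None):
    """Frequency x azimuth colour map of a dB cue map, log-frequency axis.

    When a :class:`CanalPrediction` is given, its fundamental interference
    frequency f_ic(theta) is overlaid as a white line.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    mesh = ax.pcolormesh(transfer_map.azimuths, transfer_map.frequencies,
                         transfer_map.values, shading="auto",
                         cmap="viridis", vmin=vmin, vmax=vmax)
    if prediction is not None:
        ax.plot(prediction.azimuths, prediction.f_ic, color="white", lw=2)
    ax.set_yscale("log")
    ax.set_xlabel("azimuth (deg)")
    ax.set_ylabel("frequency (Hz)")
    ax.figure.colorbar(mesh, ax=ax, label="gain (dB)")
    return ax


def plot_itd_curves(curves: list[ITDCurve], ax=None):
    """Overlaid ITD-vs-azimuth curves (microseconds), one line per stimulus."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        ax.plot(curve.azimuths, curve.delays * 1e6,
                label=f"{curve.stimulus} ({curve.canal_state})")
    ax.set_xlabel("azimuth (deg)")
    ax.set_ylabel("ITD (us)")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.legend(fontsize="small")
    return ax


def plot_pll(curves: list[PLLCurve], ax=None):
    """PLL curves against log2 frequency; undefined points are skipped."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        keep = curve.defined
        ax.plot(curve.frequencies[keep], curve.values[keep],
                label=curve.source)
    ax.set_xscale("log", base=2)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("PLL (dB)")
    ax.legend()
    return ax
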