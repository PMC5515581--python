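"""Small plotting helpers for pipeline artifacts (FSC, spectra, histograms)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .fsc import FSCCurve
from .symmetry import AngularPowerSpectrum

__all__ = ["plot_fsc", "plot_angular_spectrum", "plot_volume_histogram"]


def plot_fsc(curve: FSCCurve, path=None, ax=None):
    """FSC curve with the 0.5 and 0.143 threshold lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.shell_freq_inv_nm, curve.correlation, lw=1.5)
    for thr, style in ((0.5, "--"), (0.143, ":")):
        ax.axhline(thr, color="grey", ls=style, lw=1, label=f"FSC = {thr}")
    ax.set_xlabel("spatial frequency (1/nm)")
    ax.set_ylabel("FSC")
    ax.set_ylim(-0.1, 1.05)
    ax.legend(frameon=False)
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_angular_spectrum(spectrum: AngularPowerSpectrum, path=None, ax=None, max_component=30):
    """Mean rotational Fourier power per component."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    hi = min(max_component, len(spectrum.mean_power) - 1)
    ax.bar(spectrum.component[1 : hi + 1], spectrum.mean_power[1 : hi + 1], width=0.8)
    ax.set_xlabel("rotational Fourier component")
    ax.set_ylabel("mean power")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_volume_histogram(volumes, path=None, ax=None, bins=40):
    """Spherule volume distribution."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(np.asarray(volumes) / 1000.0, bins=bins)
    ax.set_xlabel("spherule volume (1000 nm$^3$)")
    ax.set_ylabel("count")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
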