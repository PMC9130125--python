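"""Basic scalogram / coherence plots (log2 period axis, cone shading)."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .spectral import CoherenceSpectrum, WaveletSpectrum

__all__ = ["plot_scalogram", "plot_coherence"]


def _setup(ax, spec, mat, cmap, vmax=None):
    mesh = ax.pcolormesh(spec.times, spec.fourier_periods, mat,
                         shading="auto", cmap=cmap, vmax=vmax)
    ax.plot(spec.times, spec.coi, "k--", lw=1)
    ax.fill_between(spec.times, spec.coi, spec.fourier_periods[-1],
                    color="w", alpha=0.4, hatch="x", lw=0)
    ax.set_yscale("log", base=2)
    ax.set_ylim(spec.fourier_periods[0], spec.fourier_periods[-1])
    ax.invert_yaxis()
    ax.set_xlabel("relative year")
    ax.set_ylabel("Fourier period (yr)")
    return mesh


def plot_scalogram(spec: WaveletSpectrum, path: str | Path,
                   title: str | None = None) -> None:
    """Wavelet power with the 5%-significance contour and cone shading."""
    fig, ax = plt.subplots(figsize=(8, 4))
    mesh = _setup(ax, spec, spec.power, "viridis")
    if spec.signif_mask is not None and spec.signif_mask.any():
        ax.contour(spec.times, spec.fourier_periods,
                   spec.signif_mask.astype(float), levels=[0.5],
                   colors="k", linewidths=1.2)
    fig.colorbar(mesh, ax=ax, label="power (sigma^2)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_coherence(coh: CoherenceSpectrum, path: str | Path,
                   title: str | None = None) -> None:
    """Squared wavelet coherence with its significance contour."""
    fig, ax = plt.subplots(figsize=(8, 4))
    mesh = _setup(ax, coh, coh.coherence, "magma", vmax=1.0)
    if coh.signif_mask is not None and coh.signif_mask.any():
        ax.contour(coh.times, coh.fourier_periods,
                   coh.signif_mask.astype(float), levels=[0.5],
                   colors="w", linewidths=1.2)
    fig.colorbar(mesh, ax=ax, label="coherence")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
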