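"""Phasor-plot figures: universal semicircle, point density, fingerprints."""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np

from .fingerprint import FingerprintLibrary
from .phasor import PhasorImage, single_exp_phasor

__all__ = ["plot_phasor"]


def plot_phasor(
    images: Optional[Mapping[str, PhasorImage]] = None,
    library: Optional[FingerprintLibrary] = None,
    repetition_rate: float = 8.0e7,
    harmonic: int = 2,
    ax=None,
    tau_ticks=(0.5, 1, 2, 3, 5, 10),
):
    """Draw the universal semicircle with optional data and fingerprints.

    ``tau_ticks`` (ns) are marked on the semicircle for orientation.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    phi = np.linspace(0, np.pi, 400)
    ax.plot(0.5 + 0.5 * np.cos(phi), 0.5 * np.sin(phi), "k-", lw=1)
    for tau in tau_ticks:
        g, s = single_exp_phasor(tau, repetition_rate, harmonic)
        ax.plot([g], [s], "k.", ms=3)
        ax.annotate(f"{tau:g}", (g, s), textcoords="offset points",
                    xytext=(3, 3), fontsize=7)
    if images:
        for name, img in images.items():
            ax.plot(img.G[img.mask], img.S[img.mask], ".", ms=1, alpha=0.25, label=name)
    if library is not None:
        theta = np.linspace(0, 2 * np.pi, 100)
        for fp in library.entries:
            cg, cs = fp.centroid
            ax.plot(cg + fp.radius * np.cos(theta), cs + fp.radius * np.sin(theta),
                    "-", color=fp.color, lw=1.2)
            ax.annotate(fp.species, (cg, cs), fontsize=8, ha="center",
                        textcoords="offset points", xytext=(0, 6))
    ax.set_xlabel("G")
    ax.set_ylabel("S")
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 0.65)
    ax.set_aspect("equal")
    if images:
        ax.legend(fontsize=7, markerscale=8, loc="upper right")
    return ax
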