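"""Basic density / cumulative plot helpers (no figure styling ambitions)."""

from __future__ import annotations

import numpy as np

from .modality import kde_density


def plot_marker_density(ax, markers, bandwidth, weights=None, label=None,
                        modes=None, **kwargs):
    """Gaussian-KDE density of marker wavelengths on [300, 700] nm, with
    optional vertical lines at the mode positions."""
    grid, dens = kde_density(markers, bandwidth, weights=weights)
    line, = ax.plot(grid, dens, label=label, **kwargs)
    if modes is not None:
        for m in modes:
            ax.axvline(m, color=line.get_color(), linestyle=":", alpha=0.6)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("marker density")
    return ax


def plot_cumulative(ax, markers, weights=None, label=None, reference=None,
                    **kwargs):
    """Empirical cumulative distribution of marker wavelengths."""
    x = np.asarray(markers, dtype=float).ravel()
    w = np.ones_like(x) if weights is None else \
        np.asarray(weights, dtype=float).ravel()
    order = np.argsort(x)
    x, w = x[order], w[order]
    cum = np.cumsum(w) / w.sum()
    ax.step(x, cum, where="post", label=label, **kwargs)
    if reference is not None:
        ax.axvline(reference, color="k", linestyle="--", alpha=0.5)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("cumulative fraction")
    return ax
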