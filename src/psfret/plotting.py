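"""Quick-look plots for rate maps, histograms and decay fits."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .decayfit import DecayTrace, ExpFitResult, RateMap

__all__ = ["plot_rate_map", "plot_rate_histogram", "plot_decay_fit"]


def plot_rate_map(rmap: RateMap, path: str | Path) -> Path:
    """Four-panel figure: A0, rate, offset and chi-square images."""
    fig, axes = plt.subplots(2, 2, figsize=(8, 7))
    panels = [
        (rmap.a0_img, "A0 (e-)"),
        (rmap.rate_img, "rate (s$^{-1}$)"),
        (rmap.offset_img, "offset (e-)"),
        (rmap.chi2_img, r"$\chi^2_\nu$"),
    ]
    for ax, (img, title) in zip(axes.ravel(), panels):
        im = ax.imshow(img, interpolation="nearest")
        ax.set_title(title)
        ax.set_xticks([])
        ax.set_yticks([])
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_rate_histogram(rmap: RateMap, path: str | Path, bins: int = 50) -> Path:
    vals = rmap.rate_img[rmap.mask]
    vals = vals[np.isfinite(vals)]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(vals, bins=bins, color="seagreen")
    ax.set_xlabel("photoswitching rate constant (s$^{-1}$)")
    ax.set_ylabel("pixels")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_decay_fit(trace: DecayTrace, fit: ExpFitResult, path: str | Path) -> Path:
    """Data, fitted curve and residuals for one trace."""
    fig, (ax1, ax2) = plt.subplots(
        2, 1, figsize=(6, 5), sharex=True, height_ratios=[3, 1]
    )
    ax1.plot(trace.times, trace.values, "o", ms=3, label="data")
    if np.isfinite(fit.b):
        tt = np.linspace(trace.times[0], trace.times[-1], 200)
        ax1.plot(tt, fit.fitted(tt), "-", label="fit")
    ax1.set_ylabel("signal (e-)")
    ax1.legend()
    ax2.plot(trace.times, fit.residuals, "o", ms=3)
    ax2.axhline(0, color="k", lw=0.5)
    ax2.set_xlabel("time (s)")
    ax2.set_ylabel("residual")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
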