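"""Optional figure artifacts: chronogram, histogram, ACF and Poincare plots.

Numerical pipeline outputs never depend on anything in this module.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .descriptors import DescriptorSet
from .io import Chronogram


def _axes(path):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    return plt, fig, ax


def plot_chronogram(mean: Chronogram, sd: Chronogram | None, path: str | Path) -> None:
    """Mean chronogram with a +/- SD band."""
    plt, fig, ax = _axes(path)
    ax.plot(mean.times, mean.intensities, lw=1.0, label="biological mean")
    if sd is not None:
        band = np.nan_to_num(sd.intensities)
        ax.fill_between(mean.times, mean.intensities - band, mean.intensities + band,
                        alpha=0.3, label="+/- SD")
    ax.set_xlabel("time since inoculation (h)")
    ax.set_ylabel("relative intensity")
    ax.set_title(mean.condition)
    ax.legend()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_histogram(d: DescriptorSet, path: str | Path) -> None:
    plt, fig, ax = _axes(path)
    if d.histogram_edges is not None:
        widths = np.diff(d.histogram_edges)
        ax.bar(d.histogram_edges[:-1], d.histogram_counts, width=widths, align="edge")
    ax.set_xlabel("relative intensity")
    ax.set_ylabel("count")
    ax.set_title(d.condition)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_acf(d: DescriptorSet, path: str | Path) -> None:
    plt, fig, ax = _axes(path)
    if d.acf is not None:
        lags = np.arange(len(d.acf))
        ax.stem(lags, d.acf)
        n = max(d.n_points, 1)
        ax.axhline(2 / np.sqrt(n), ls="--", c="grey", lw=0.8)
        ax.axhline(-2 / np.sqrt(n), ls="--", c="grey", lw=0.8)
    ax.set_xlabel("lag (samples)")
    ax.set_ylabel("autocorrelation")
    ax.set_title(d.condition)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_poincare(c: Chronogram, d: DescriptorSet, path: str | Path) -> None:
    """Successive-point scatter with the SD1/SD2 ellipse on the identity line."""
    plt, fig, ax = _axes(path)
    x = c.intensities
    a, b = x[1:], x[:-1]
    ax.scatter(b, a, s=6, alpha=0.5)
    if np.isfinite(d.sd1) and np.isfinite(d.sd2):
        theta = np.linspace(0, 2 * np.pi, 200)
        cx = cy = float(np.mean(x))
        ex = d.sd2 * np.cos(theta) / np.sqrt(2) - d.sd1 * np.sin(theta) / np.sqrt(2)
        ey = d.sd2 * np.cos(theta) / np.sqrt(2) + d.sd1 * np.sin(theta) / np.sqrt(2)
        ax.plot(cx + ex, cy + ey, c="C1", lw=1.2)
    ax.set_xlabel(r"$x_t$")
    ax.set_ylabel(r"$x_{t+1}$")
    ax.set_title(f"{d.condition}  SD1={d.sd1:.3g} SD2={d.sd2:.3g}")
    ax.set_aspect("equal", adjustable="datalim")
    fig.savefig(path, dpi=120)
    plt.close(fig)
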