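"""Figure helpers: STM heatmaps with marginal histograms, scan curves, rasters.

Layout conventions follow the analysis figures: in an STM panel the
horizontal axis is the current state (ascending left to right) and the
vertical axis the next state (ascending top to bottom); the marginal
visitation histogram sits on top.  Large (m = 10) STMs are drawn on a log
color scale with a pseudo-probability floor of 1e−6 used for color mapping
only — never for statistics.  Scan panels draw entropy solid and mutual
information dashed, one color per weight scaling factor; transfer-entropy
panels shade mean ± 1 SD.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LogNorm

from .attractors import TransitionModel
from .infometrics import ScanResult

__all__ = ["plot_stm", "plot_scan", "plot_te_comparison", "plot_raster", "plot_classification"]

_COLOR_FLOOR = 1e-6


def plot_stm(model: TransitionModel, ax_pair=None, log_scale: bool | None = None,
             inset: tuple[int, int] | None = None, title: str = ""):
    """STM heatmap with its marginal histogram on top; returns the figure."""
    if log_scale is None:
        log_scale = model.m >= 10
    if ax_pair is None:
        fig, (ax_top, ax) = plt.subplots(
            2, 1, figsize=(5, 6), height_ratios=[1, 4], sharex=True,
            constrained_layout=True,
        )
    else:
        ax_top, ax = ax_pair
        fig = ax.figure
    ax_top.bar(np.arange(model.n_states), model.marginal, width=1.0, color="#444444")
    ax_top.set_ylabel("P(x)")
    mat = model.stm.T  # rows = next state, columns = current state
    if log_scale:
        ax.imshow(np.maximum(mat, _COLOR_FLOOR), norm=LogNorm(vmin=_COLOR_FLOOR, vmax=1.0),
                  cmap="Blues", aspect="auto", origin="upper")
    else:
        ax.imshow(mat, vmin=0.0, vmax=1.0, cmap="Blues", aspect="auto", origin="upper")
    if inset is not None:
        lo, hi = inset
        ax.add_patch(plt.Rectangle((lo, lo), hi - lo, hi - lo, fill=False, edgecolor="red"))
    ax.set_xlabel("current state x")
    ax.set_ylabel("next state y")
    if title:
        ax_top.set_title(title)
    return fig


def plot_scan(scans: Sequence[ScanResult], path=None, observables=("entropy", "mi"), title: str = ""):
    """Entropy (solid) and MI (dashed) vs noise strength, one color per W."""
    fig, ax = plt.subplots(figsize=(6, 4), constrained_layout=True)
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for i, scan in enumerate(scans):
        summ = scan.summary()
        for obs, style in zip(observables, ("-", "--")):
            sub = summ[summ["observable"] == obs]
            ax.plot(sub["r"], sub["mean"], style, color=colors[i % len(colors)],
                    label=f"{obs} W={scan.W:g}")
    ax.set_xlabel("noise strength r")
    ax.set_ylabel("bits")
    ax.legend(fontsize=7)
    if title:
        ax.set_title(title)
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_te_comparison(scans: dict[str, ScanResult], path=None, observable: str = "te_AB", title: str = ""):
    """Mean TE curves with ±1 SD bands, one per connectivity condition."""
    fig, ax = plt.subplots(figsize=(6, 4), constrained_layout=True)
    for name, scan in scans.items():
        summ = scan.summary()
        sub = summ[summ["observable"] == observable]
        r, mean, sd = sub["r"].to_numpy(), sub["mean"].to_numpy(), sub["sd"].to_numpy()
        ax.plot(r, mean, "-o", ms=3, label=name)
        ax.fill_between(r, mean - sd, mean + sd, alpha=0.3)
    ax.set_xlabel("noise strength r")
    ax.set_ylabel(r"TE$_{A \to B}$ (bits)")
    ax.legend()
    if title:
        ax.set_title(title)
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_raster(binary: np.ndarray, path=None, title: str = ""):
    """Binary activity: time horizontal, neuron index vertical."""
    fig, ax = plt.subplots(figsize=(8, 2.5), constrained_layout=True)
    ax.imshow(binary.T, cmap="binary", aspect="auto", interpolation="nearest", origin="lower")
    ax.set_xlabel("time step (subsampled)")
    ax.set_ylabel("neuron")
    if title:
        ax.set_title(title)
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_classification(model: TransitionModel, cls, path=None, title: str = ""):
    """Scatter of diagonal stability vs gain, colored by attractor class."""
    fig, ax = plt.subplots(figsize=(5, 4), constrained_layout=True)
    palette = {"strong": "red", "weak": "blue", "transient": "green"}
    s = cls.states
    g = np.maximum(model.gain[s], 1e-3)
    for label, color in palette.items():
        sel = cls.labels[s] == label
        ax.scatter(g[sel], model.diag[s][sel], s=8, c=color, label=label, alpha=0.6)
    ax.axvline(1.0, color="gray", ls=":", lw=1)
    ax.axhline(cls.baseline, color="gray", ls="--", lw=1)
    ax.set_xscale("log")
    ax.set_xlabel("gain G(x)")
    ax.set_ylabel(r"stability $T_{xx}$")
    ax.legend()
    if title:
        ax.set_title(title)
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
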