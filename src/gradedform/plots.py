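"""Deterministic matplotlib figures: trace lines, group overlays, test
information.  Fixed grids and orderings keep regenerated images stable."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .grm import ItemBank, ItemParameters, ThetaGrid, icc_curve, test_information

__all__ = ["plot_icc", "plot_group_overlay", "plot_tif"]

_SAVE_KW = {"dpi": 120, "metadata": {"Date": None}}


def plot_icc(item: ItemParameters, grid: ThetaGrid | None = None, path=None):
    """Category trace lines for one item."""
    grid = grid or ThetaGrid.normal(121, -4, 4)
    probs = icc_curve(item, grid)
    fig, ax = plt.subplots(figsize=(6, 4))
    for j in range(item.n_categories):
        ax.plot(grid.points, probs[:, j], label=f"category {j}")
    ax.set_xlabel(r"$\theta$")
    ax.set_ylabel("probability")
    ax.set_title(item.item_id)
    ax.legend(fontsize=8)
    if path:
        fig.savefig(path, **_SAVE_KW)
        plt.close(fig)
    return fig


def plot_group_overlay(overlay: dict, item_id: str = "", path=None):
    """Reference vs focal trace lines from :func:`gradedform.dif.group_icc_overlay`."""
    fig, ax = plt.subplots(figsize=(6, 4))
    theta = overlay["theta"]
    C = overlay["reference_icc"].shape[1]
    for j in range(C):
        ax.plot(theta, overlay["reference_icc"][:, j], color=f"C{j}")
        ax.plot(theta, overlay["focal_icc"][:, j], color=f"C{j}", linestyle=":")
    ax.set_xlabel(r"$\theta$")
    ax.set_ylabel("probability")
    ax.set_title(f"{item_id} (solid: reference, dotted: focal; "
                 f"area={overlay['area_between_curves']:.3f})")
    if path:
        fig.savefig(path, **_SAVE_KW)
        plt.close(fig)
    return fig


def plot_tif(banks: dict, grid: ThetaGrid | None = None, path=None):
    """Test information curves for one or more named banks/forms, with the
    information-10 (reliability 0.90) guide line."""
    grid = grid or ThetaGrid.normal(121, -4, 4)
    fig, ax = plt.subplots(figsize=(6, 4))
    for name in sorted(banks):
        info, _ = test_information(banks[name], grid.points)
        ax.plot(grid.points, info, label=name)
    ax.axhline(10.0, color="grey", linestyle="--", linewidth=1,
               label="information 10 (reliability 0.90)")
    ax.set_xlabel(r"$\theta$")
    ax.set_ylabel("test information")
    ax.legend(fontsize=8)
    if path:
        fig.savefig(path, **_SAVE_KW)
        plt.close(fig)
    return fig
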