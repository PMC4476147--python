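"""Functional rendering of chevron maps and edge overlays."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cooccurrence import ChevronMap
from .sparse import EdgeList

__all__ = ["plot_chevron_map", "plot_edges"]


def plot_chevron_map(
    cm: ChevronMap,
    path: Optional[str | Path] = None,
    ax: Optional[plt.Axes] = None,
    cmap: str = "coolwarm",
):
    """Draw a chevron map: cells colored by probability (or log-ratio),
    each overlaid with the two-segment glyph of its (psi, theta) edge
    configuration (reference segment horizontal, second segment at
    relative orientation theta placed at azimuth phi = psi + theta/2)."""
    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 6))
    pc, tc = cm.psi_edges, cm.theta_edges
    vals = cm.values
    if cm.mode == "ratio":
        shown = np.log2(vals)
        vmax = np.abs(shown).max() or 1.0
        norm = dict(vmin=-vmax, vmax=vmax)
        label = "log2 ratio vs reference"
    else:
        shown = vals
        norm = dict(vmin=0, vmax=vals.max() or 1.0)
        label = "probability"
    mesh = ax.pcolormesh(tc, pc, shown, cmap=cmap, **norm)
    plt.colorbar(mesh, ax=ax, label=label)

    pmid = 0.5 * (pc[:-1] + pc[1:])
    tmid = 0.5 * (tc[:-1] + tc[1:])
    cell = 0.30 * min(np.diff(tc).min(), np.diff(pc).min())
    for psi in pmid:
        for theta in tmid:
            phi = psi + theta / 2  # azimuth of the second segment's center
            # reference segment (horizontal) at the cell center
            ax.plot([theta - cell, theta + cell], [psi, psi], color="k", lw=0.6, alpha=0.6)
            cx = theta + 1.6 * cell * np.cos(phi)
            cy = psi + 1.6 * cell * np.sin(phi)
            dx = cell * np.cos(theta)
            dy = cell * np.sin(theta)
            ax.plot([cx - dx, cx + dx], [cy - dy, cy + dy], color="k", lw=0.6, alpha=0.9)
    ax.set_xlabel(r"relative orientation $\theta$ (rad)")
    ax.set_ylabel(r"symmetrized azimuth $\psi$ (rad)")
    if path is not None:
        plt.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_edges(
    edges: EdgeList,
    image: Optional[np.ndarray] = None,
    path: Optional[str | Path] = None,
    scale_to_length: float = 4.0,
):
    """Overlay extracted edges as oriented segments (length ~ scale)."""
    _fig, ax = plt.subplots(figsize=(6, 6))
    if image is not None:
        ax.imshow(image, cmap="gray")
    lengths = scale_to_length * 2.0 ** edges.scale_index
    for i in range(len(edges)):
        dx = lengths[i] / 2 * np.cos(edges.theta[i])
        dy = lengths[i] / 2 * np.sin(edges.theta[i])
        ax.plot(
            [edges.x[i] - dx, edges.x[i] + dx],
            [edges.y[i] - dy, edges.y[i] + dy],
            color="r", lw=0.8, alpha=0.7,
        )
    ax.set_xlim(0, edges.image_shape[1])
    ax.set_ylim(edges.image_shape[0], 0)
    ax.set_aspect("equal")
    if path is not None:
        plt.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
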