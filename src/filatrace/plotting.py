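"""Overlay and polar-histogram rendering.

The overlay draws the detected feature graph over the grayscale image:
straight parts as red lines, endpoints/bends/branch points as circular
markers. The polar plot shows the length-weighted histogram of axial
angles, mirrored at the origin, with the fitted von Mises density on the
half circle.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .graph import FilamentGraph, FilamentTrail
from .image import RasterImage
from .orientation import OrientationStats


def save_overlay(image: RasterImage, graph: FilamentGraph,
                 trails: list[FilamentTrail], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(image.pixels, cmap="gray", interpolation="nearest")
    for t in trails:
        pts = np.array([graph.pos(n) for n in t.nodes])
        ax.plot(pts[:, 1], pts[:, 0], "-", color="red", lw=1.2)
        ax.plot(pts[:, 1], pts[:, 0], "o", color="yellow", ms=2.5, mew=0)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_polar_histogram(stats: OrientationStats, path: str | Path) -> None:
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="polar")
    centers = np.radians(0.5 * (stats.bin_edges_deg[:-1] + stats.bin_edges_deg[1:]))
    width = np.radians(np.diff(stats.bin_edges_deg))
    # axial data: mirror the half-circle histogram at the origin
    ax.bar(np.concatenate([centers, centers + np.pi]),
           np.tile(stats.histogram, 2),
           width=np.concatenate([width, width]), color="red", alpha=0.7)
    if stats.histogram.sum() > 0 and stats.kappa > 0:
        theta = np.linspace(0, np.pi, 361)
        dens = np.exp(stats.kappa * np.cos(2 * (theta - np.radians(stats.mu_deg))))
        dens *= stats.histogram.max() / dens.max()
        ax.plot(np.concatenate([theta, theta + np.pi]),
                np.tile(dens, 2), color="black", lw=1.5)
    ax.set_yticklabels([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
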