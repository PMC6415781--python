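"""Dendrogram rendering: 45-degree branches, axes in merit (z) units.

Branch pairs leave each split at +/-45 degrees, so both the horizontal and
vertical extent of a branch equal its z-unit length; pass-through branches
drop vertically.  Line width is proportional to the fraction of states the
branch contains; each branch can be annotated with its bit code (black)
and member count (red).
"""

from __future__ import annotations

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .coding import DendrogramNode, DendrogramTree

__all__ = ["dendrogram_segments", "plot_dendrogram"]


def dendrogram_segments(tree: DendrogramTree) -> list[dict]:
    """Line segments of the dendrogram in z-unit coordinates.

    Each record holds ``(x0, y0) -> (x1, y1)``, the child node it leads to,
    and the width fraction.  Split branches satisfy ``|dx| == |dy|``
    (45-degree geometry); pass-through branches have ``dx == 0``.
    """
    segments: list[dict] = []

    def place(node: DendrogramNode, x: float, y: float) -> None:
        pair = len(node.children) == 2
        for child in node.children:
            ln = child.branch_length
            if pair:
                dx = -ln if child.prefix[-1] == "0" else ln
            else:
                dx = 0.0
            cx, cy = x + dx, y - ln
            segments.append(
                {
                    "x0": x,
                    "y0": y,
                    "x1": cx,
                    "y1": cy,
                    "node": child,
                    "width": child.width,
                }
            )
            place(child, cx, cy)

    place(tree.root, 0.0, 0.0)
    return segments


def plot_dendrogram(
    tree: DendrogramTree,
    path=None,
    *,
    labels: bool = True,
    counts: bool = True,
    min_label_frac: float = 0.0,
    max_label_level: int | None = None,
    linewidth_scale: float = 12.0,
    figsize: tuple[float, float] = (8.0, 6.0),
) -> Figure:
    """Render the dendrogram; returns the figure, optionally saved to ``path``.

    ``labels`` / ``counts`` toggle the black bit-code and red member-count
    annotations; ``min_label_frac`` and ``max_label_level`` suppress labels
    on thin or deep branches for clarity.
    """
    fig = Figure(figsize=figsize)
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    segs = dendrogram_segments(tree)
    for s in segs:
        ax.plot(
            [s["x0"], s["x1"]],
            [s["y0"], s["y1"]],
            color="black",
            linewidth=max(0.4, linewidth_scale * s["width"]),
            solid_capstyle="round",
        )
        nd = s["node"]
        deep = max_label_level is not None and nd.level > max_label_level
        if nd.width < min_label_frac or deep:
            continue
        if labels:
            ax.annotate(
                nd.prefix,
                (s["x1"], s["y1"]),
                textcoords="offset points",
                xytext=(2, -10),
                fontsize=7,
                color="black",
            )
        if counts:
            ax.annotate(
                str(nd.count),
                (s["x1"], s["y1"]),
                textcoords="offset points",
                xytext=(2, -20),
                fontsize=7,
                color="red",
            )
    ax.set_xlabel("z")
    ax.set_ylabel("z")
    ax.set_aspect("equal", adjustable="datalim")
    ax.spines[["top", "right"]].set_visible(False)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig
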