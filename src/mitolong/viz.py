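"""Circos-style circular visualization of the mitochondrial genome.

Three rings, outside in: gene/origin annotations, per-base coverage, and
deletion chords connecting each call's breakpoints with line width
proportional to supporting-read count.  Angular origin is 12 o'clock with
positions increasing clockwise, matching common mtDNA maps.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

# stable SVG element ids so identical inputs give identical files
matplotlib.rcParams["svg.hashsalt"] = "mitolong"

from .quantify import CoverageProfile
from .svcall import DeletionCall

__all__ = ["circular_plot"]

_DEFAULT_STYLE = {
    "annotation_color": "#4878A8",
    "coverage_color": "#666666",
    "chord_color": "#222222",
    "r_annotation": 1.08,
    "r_coverage_base": 0.80,
    "r_coverage_height": 0.22,
    "r_chord": 0.74,
    "figsize": 6.0,
}

_MIN_CHORD_PT = 0.5
_MAX_CHORD_PT = 6.0


def _xy(pos: float, L: int, r: float) -> tuple[float, float]:
    """Cartesian point for 1-based position ``pos`` at radius ``r``
    (12 o'clock origin, clockwise)."""
    theta = 2.0 * math.pi * (pos - 1.0) / L
    return r * math.sin(theta), r * math.cos(theta)


def _chord_width(support: int, max_support: int) -> float:
    if max_support <= 0:
        return _MIN_CHORD_PT
    w = _MIN_CHORD_PT + (_MAX_CHORD_PT - _MIN_CHORD_PT) * support / max_support
    return float(min(_MAX_CHORD_PT, max(_MIN_CHORD_PT, w)))


def circular_plot(
    profile: CoverageProfile,
    calls: Sequence[DeletionCall],
    annotations: Sequence[tuple[str, int, int]],
    out_path: str | Path,
    style_file: str | Path | None = None,
    max_depth: float | None = None,
) -> Path:
    """Render the circular genome figure to SVG or PNG (by extension)."""
    out_path = Path(out_path)
    if out_path.suffix.lower() not in (".svg", ".png"):
        raise ValueError(f"unknown image extension {out_path.suffix!r}")
    style = dict(_DEFAULT_STYLE)
    if style_file is not None:
        style.update(json.loads(Path(style_file).read_text()))

    L = profile.length
    fig, ax = plt.subplots(figsize=(style["figsize"], style["figsize"]))
    ax.set_aspect("equal")
    ax.axis("off")

    # backbone circle
    ring = np.linspace(0, 2 * math.pi, 720)
    r0 = style["r_coverage_base"]
    ax.plot(r0 * np.sin(ring), r0 * np.cos(ring), color="black", lw=0.8)

    # coverage ring
    depth = profile.depth
    top = max_depth if max_depth is not None else max(1.0, float(depth.max()))
    step = max(1, L // 2048)
    pos = np.arange(1, L + 1, step)
    theta = 2 * math.pi * (pos - 1) / L
    r = r0 + style["r_coverage_height"] * np.minimum(1.0, depth[pos - 1] / top)
    ax.fill(
        np.concatenate([r * np.sin(theta), r0 * np.sin(theta[::-1])]),
        np.concatenate([r * np.cos(theta), r0 * np.cos(theta[::-1])]),
        color=style["coverage_color"],
        alpha=0.6,
        lw=0,
    )

    # annotation ring
    for label, s, e in annotations:
        span = (e - s) % L or L
        arc = np.linspace(0, span, max(2, span // 20))
        th = 2 * math.pi * ((s - 1 + arc) % L) / L
        ra = style["r_annotation"]
        ax.plot(ra * np.sin(th), ra * np.cos(th), color=style["annotation_color"], lw=4,
                solid_capstyle="butt")
        mid = 2 * math.pi * ((s - 1 + span / 2) % L) / L
        ax.text(
            (ra + 0.08) * math.sin(mid), (ra + 0.08) * math.cos(mid), label,
            ha="center", va="center", fontsize=6,
        )

    # deletion chords
    max_support = max((c.support for c in calls), default=0)
    rc = style["r_chord"]
    for call in calls:
        x1, y1 = _xy(call.start, L, rc)
        x2, y2 = _xy(call.end, L, rc)
        ax.plot(
            [x1, x2], [y1, y2],
            color=style["chord_color"],
            lw=_chord_width(call.support, max_support),
            alpha=0.8,
            solid_capstyle="round",
        )

    ax.set_xlim(-1.35, 1.35)
    ax.set_ylim(-1.35, 1.35)
    metadata = {"Date": None} if out_path.suffix.lower() == ".svg" else None
    fig.savefig(out_path, dpi=150, metadata=metadata)
    plt.close(fig)
    return out_path
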