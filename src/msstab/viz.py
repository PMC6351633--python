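"""Similarity-matrix heatmaps and TIC diagnostics.

The heatmap is the method's primary visual: scans are ordered by
measurement and then by time along both axes (origin top-left, time
running left→right and top→bottom), one pixel per scan pair, with one
fixed value→color scale across every plot of a report so that panels are
comparable.  Artifact scans appear as full low-similarity rows+columns —
pale bands cutting through the blocks.  Negative Pearson values are
clamped to 0 for display only; stored matrices are never modified.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .io import Measurement, tic_trace
from .qc import ScanQCResult
from .similarity import SimilarityMatrix

__all__ = ["PlotStyle", "value_to_color", "plot_similarity_matrix", "plot_tic"]


@dataclasses.dataclass(frozen=True)
class PlotStyle:
    """Fixed rendering parameters shared by all plots of one report."""

    colormap: str = "viridis"
    vmin: float = 0.0
    vmax: float = 1.0
    separator_color: str = "white"
    separator_width: float = 1.2
    dpi: int = 150

    def __post_init__(self) -> None:
        if not self.vmin < self.vmax:
            raise ValueError("vmin must be < vmax")


def value_to_color(values, style: PlotStyle | None = None) -> np.ndarray:
    """Pure value→RGBA mapping used by the heatmap.

    Values are clipped into [vmin, vmax] (this is where negative Pearson
    values get clamped to 0 for display) and mapped through the style's
    colormap.  Exposed separately so the mapping is testable without
    rendering.
    """
    style = style or PlotStyle()
    vals = np.clip(np.asarray(values, dtype=float), style.vmin, style.vmax)
    norm = (vals - style.vmin) / (style.vmax - style.vmin)
    return plt.get_cmap(style.colormap)(norm)


def plot_similarity_matrix(
    m: SimilarityMatrix,
    style: PlotStyle | None = None,
    path: str | Path | None = None,
):
    """Render a grouped similarity matrix as a heatmap.

    Group boundaries from ``m.group_labels`` are drawn as separator lines
    and group labels placed at block centers.  Returns the figure; writes
    it to ``path`` (PNG/SVG by extension) when given.
    """
    style = style or PlotStyle()
    fig, ax = plt.subplots(figsize=(6, 5))
    shown = np.clip(m.values, style.vmin, style.vmax)
    im = ax.imshow(
        shown,
        cmap=style.colormap,
        vmin=style.vmin,
        vmax=style.vmax,
        origin="upper",
        interpolation="nearest",
    )
    boundaries = [b for _, _, b in m.group_labels[:-1]]
    for b in boundaries:
        ax.axhline(b - 0.5, color=style.separator_color, lw=style.separator_width)
        ax.axvline(b - 0.5, color=style.separator_color, lw=style.separator_width)
    centers = [(a + b) / 2 for _, a, b in m.group_labels]
    labels = [lab for lab, _, _ in m.group_labels]
    ax.set_xticks(centers, labels, rotation=90)
    ax.set_yticks(centers, labels)
    ax.set_xlabel("scan (by measurement, then time)")
    ax.set_ylabel("scan (by measurement, then time)")
    fig.colorbar(im, ax=ax, label=f"{m.metric} similarity")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=style.dpi)
        plt.close(fig)
    return fig


def plot_tic(
    m: Measurement,
    qc: ScanQCResult | None = None,
    path: str | Path | None = None,
    style: PlotStyle | None = None,
):
    """Plot the total ion current against scan index; when a QC result is
    given, rejected scans are marked.  Returns the figure."""
    style = style or PlotStyle()
    trace = tic_trace(m)
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(trace["scan_index"], trace["tic"], lw=1.0, marker="." if len(m) < 30 else None)
    if qc is not None and qc.keep_mask is not None:
        rej = qc.rejected_indices
        if rej.size:
            ax.plot(
                trace["scan_index"].to_numpy()[rej],
                trace["tic"].to_numpy()[rej],
                "rx",
                label=f"rejected ({rej.size})",
            )
            ax.legend()
    ax.set_xlabel("scan index")
    ax.set_ylabel("TIC")
    ax.set_title(m.label)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=style.dpi)
        plt.close(fig)
    return fig
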