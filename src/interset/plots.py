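"""Figure rendering: classical Venn diagrams (2-6 sets), UpSet plots, and
clustered pairwise heat maps.

All figures are written through one save path that fixes the SVG hash salt
and strips the date stamp, so repeated runs on identical inputs produce
byte-identical SVG; text is kept as real ``<text>`` elements (not paths) so
that counts and labels survive text extraction.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Any

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Polygon as MplPolygon

from ._venn_templates import region_anchor, venn_shapes
from .pairwise import PairwiseMatrix, hierarchical_order
from .setalgebra import CombinationTable, sort_key

__all__ = ["FigureSpec", "DEFAULT_COLORS", "FORMATS", "plot_venn", "plot_upset", "plot_heatmap"]

FORMATS = ("pdf", "svg", "png", "tiff")

# Wong's colorblind-safe palette
DEFAULT_COLORS = ("#0072B2", "#E69F00", "#009E73", "#CC79A7", "#56B4E9", "#D55E00")

_RC = {
    "svg.fonttype": "none",  # keep text as text for extraction and determinism
    "svg.hashsalt": "interset",
    "pdf.fonttype": 42,
}


@dataclass
class FigureSpec:
    """Rendering options shared by all figure families."""

    figure_type: str
    output_path: str
    format: str = "svg"
    dpi: int = 300
    colors: tuple[str, ...] | None = None
    fontsize: float = 12.0
    title: str | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.format not in FORMATS:
            raise ValueError(f"format must be one of {FORMATS}, got {self.format!r}")
        if self.dpi < 72:
            raise ValueError("dpi must be >= 72")

    def palette(self, n: int) -> list[str]:
        colors = list(self.colors) if self.colors else list(DEFAULT_COLORS)
        if len(colors) < n:
            colors = (colors * (n // len(colors) + 1))[:n]
        return colors[:n]


def _save(fig, spec: FigureSpec) -> str:
    out = os.fspath(spec.output_path)
    os.makedirs(os.path.dirname(out) or ".", exist_ok=True)
    kwargs: dict[str, Any] = {"format": spec.format, "dpi": spec.dpi}
    if spec.format == "svg":
        kwargs["metadata"] = {"Date": None}
    fig.savefig(out, **kwargs)
    plt.close(fig)
    return out


def plot_venn(table: CombinationTable, spec: FigureSpec) -> str:
    """Classical Venn diagram with every category count placed inside its
    exclusive region (zero counts printed as 0)."""
    n = table.n_sets
    if not 2 <= n <= 6:
        raise ValueError(
            f"venn diagrams support 2-6 sets, got {n}; use an UpSet plot instead"
        )
    shapes = venn_shapes(n)
    colors = spec.palette(n)
    with plt.rc_context(_RC):
        fig, ax = plt.subplots(figsize=(7, 7))
        all_x, all_y = [], []
        for shape, color in zip(shapes, colors):
            xy = np.asarray(shape.exterior.coords)
            ax.add_patch(MplPolygon(xy, closed=True, facecolor=color, alpha=0.35,
                                    edgecolor=color, linewidth=1.5))
            all_x.extend(xy[:, 0])
            all_y.extend(xy[:, 1])
        # count labels at shapely-derived interior anchors
        for mask in table.all_masks():
            x, y = region_anchor(n, mask)
            ax.text(x, y, str(table.get(mask)), ha="center", va="center",
                    fontsize=spec.fontsize)
        # set labels just outside each shape, pushed outward from the overall center
        cx, cy = float(np.mean(all_x)), float(np.mean(all_y))
        for shape, label, color in zip(shapes, table.labels, colors):
            sx, sy = shape.centroid.x, shape.centroid.y
            dx, dy = sx - cx, sy - cy
            norm = math.hypot(dx, dy) or 1.0
            ux, uy = dx / norm, dy / norm
            coords = np.asarray(shape.exterior.coords)
            reach = float(np.max((coords[:, 0] - cx) * ux + (coords[:, 1] - cy) * uy))
            ax.text(cx + ux * (reach + 0.07), cy + uy * (reach + 0.07),
                    label, ha="center", va="center", fontsize=spec.fontsize,
                    color=color, fontweight="bold")
        pad = 0.18
        ax.set_xlim(min(all_x) - pad, max(all_x) + pad)
        ax.set_ylim(min(all_y) - pad, max(all_y) + pad)
        ax.set_aspect("equal")
        ax.axis("off")
        if spec.title:
            ax.set_title(spec.title, fontsize=spec.fontsize + 2)
        return _save(fig, spec)


def _set_totals(table: CombinationTable) -> list[int]:
    """Marginal size of each set: sum of counts over categories containing it."""
    totals = [0] * table.n_sets
    for mask, count in table.counts.items():
        for i in range(table.n_sets):
            if mask >> i & 1:
                totals[i] += count
    return totals


def plot_upset(table: CombinationTable, spec: FigureSpec) -> str:
    """UpSet plot: intersection-size bars, membership dot matrix, and
    per-set size bars; categories ranked by frequency (default) or degree,
    empty categories hidden unless ``extra['show_empty']``."""
    sort_by = spec.extra.get("sort", "frequency")
    show_empty = bool(spec.extra.get("show_empty", False))
    rows = [(mask, table.get(mask)) for mask in table.all_masks()]
    if not show_empty:
        rows = [(m, c) for m, c in rows if c > 0]
    if not rows:
        raise ValueError("empty combination table: nothing to plot")
    rows.sort(key=lambda mc: sort_key(mc[0], mc[1], table.labels, by=sort_by))
    n = table.n_sets
    k = len(rows)
    totals = _set_totals(table)
    with plt.rc_context(_RC):
        fig = plt.figure(figsize=(max(6.0, 1.8 + 0.42 * k), 3.2 + 0.45 * n))
        gs = fig.add_gridspec(
            2, 2, width_ratios=[1.2, max(2.0, 0.3 * k)], height_ratios=[2.2, 1.0],
            hspace=0.06, wspace=0.45,  # gap hosts the set labels of the dot matrix
        )
        ax_bars = fig.add_subplot(gs[0, 1])
        ax_mat = fig.add_subplot(gs[1, 1], sharex=ax_bars)
        ax_sizes = fig.add_subplot(gs[1, 0], sharey=ax_mat)

        xs = np.arange(k)
        counts = [c for _, c in rows]
        ax_bars.bar(xs, counts, color="#333333", width=0.6)
        for x, c in zip(xs, counts):
            ax_bars.text(x, c, str(c), ha="center", va="bottom",
                         fontsize=spec.fontsize * 0.85)
        ax_bars.set_ylabel("Intersection size", fontsize=spec.fontsize)
        ax_bars.spines[["top", "right"]].set_visible(False)
        # counts are annotated on the bars; numeric ticks would only duplicate them
        ax_bars.tick_params(labelbottom=False, bottom=False, labelleft=False, left=False)
        ax_bars.margins(y=0.12)

        ys = np.arange(n)
        for y in ys:
            ax_mat.scatter(xs, [y] * k, s=60, color="#dddddd", zorder=1)
        for x, (mask, _) in zip(xs, rows):
            members = [i for i in range(n) if mask >> i & 1]
            ax_mat.scatter([x] * len(members), members, s=60, color="#333333", zorder=2)
            if len(members) > 1:
                ax_mat.plot([x, x], [members[0], members[-1]], color="#333333",
                            linewidth=1.8, zorder=1.5)
        ax_mat.set_yticks(ys)
        ax_mat.set_yticklabels(table.labels, fontsize=spec.fontsize)
        ax_mat.set_ylim(-0.6, n - 0.4)
        ax_mat.invert_yaxis()
        ax_mat.tick_params(bottom=False, labelbottom=False, left=False)
        for side in ("top", "right", "bottom", "left"):
            ax_mat.spines[side].set_visible(False)

        ax_sizes.barh(ys, totals, color=spec.palette(n), height=0.55)
        ax_sizes.invert_xaxis()
        ax_sizes.set_xlabel("Set size", fontsize=spec.fontsize)
        ax_sizes.tick_params(labelleft=False, left=False, labelbottom=False, bottom=False)
        ax_sizes.spines[["top", "left"]].set_visible(False)

        if spec.title:
            fig.suptitle(spec.title, fontsize=spec.fontsize + 2)
        return _save(fig, spec)


def plot_heatmap(
    m: PairwiseMatrix,
    spec: FigureSpec,
    cluster: dict[str, str] | None = None,
) -> str:
    """Pairwise heat map in two styles.

    ``square`` (default): full matrix, optionally reordered by hierarchical
    clustering with a dendrogram.  ``tribar``: lower triangle of a symmetric
    matrix with a marginal bar plot of per-set interval counts; asymmetric
    matrices are rejected with a pointer to the square style.
    """
    style = spec.extra.get("style", "square")
    if style not in ("square", "tribar"):
        raise ValueError(f"unknown heat-map style {style!r}")
    if style == "tribar" and not m.symmetric:
        raise ValueError(
            f"metric {m.metric!r} gives an asymmetric matrix; "
            "use the square heat-map style"
        )
    values = m.values.copy()
    labels = list(m.labels)
    sizes = list(m.set_sizes) if m.set_sizes else None
    Z = None
    if cluster:
        order, Z = hierarchical_order(
            m,
            linkage=cluster.get("linkage", "average"),
            distance=cluster.get("distance", "euclidean"),
        )
        idx = [labels.index(lab) for lab in order]
        values = values[np.ix_(idx, idx)]
        labels = [labels[i] for i in idx]
        if sizes:
            sizes = [sizes[i] for i in idx]

    if m.metric == "correlation":
        cmap, vmin, vmax = "RdBu_r", -1.0, 1.0
    else:
        cmap = "Blues"
        finite = values[np.isfinite(values)]
        vmin = float(finite.min()) if finite.size else 0.0
        vmax = float(finite.max()) if finite.size else 1.0
        if vmin == vmax:
            vmin, vmax = vmin - 0.5, vmax + 0.5

    n = len(labels)
    annot = bool(spec.extra.get("annot", False))
    with plt.rc_context(_RC):
        if style == "tribar":
            fig, (ax_bar, ax) = plt.subplots(
                2, 1, figsize=(1.0 + 0.6 * n, 2.2 + 0.72 * n),
                gridspec_kw={"height_ratios": [1.0, 4.0], "hspace": 0.05},
                layout="constrained",
            )
            shown = np.where(np.tril(np.ones_like(values, dtype=bool)), values, np.nan)
            im = ax.imshow(shown, cmap=cmap, vmin=vmin, vmax=vmax)
            if sizes:
                ax_bar.bar(np.arange(n), sizes, color="#555555", width=0.7)
                ax_bar.set_xlim(-0.5, n - 0.5)
                ax_bar.set_ylabel("Regions", fontsize=spec.fontsize * 0.9)
                ax_bar.tick_params(labelbottom=False, bottom=False)
                ax_bar.spines[["top", "right"]].set_visible(False)
            else:
                ax_bar.axis("off")
        else:
            width = 2.2 + 0.62 * n + (1.2 if Z is not None else 0.0)
            fig = plt.figure(figsize=(width, 1.8 + 0.62 * n), layout="constrained")
            if Z is not None:
                gs = fig.add_gridspec(1, 2, width_ratios=[1.0, 4.0], wspace=0.02)
                ax_dend = fig.add_subplot(gs[0, 0])
                from scipy.cluster import hierarchy as sch

                with plt.rc_context({"lines.linewidth": 1.0}):
                    sch.dendrogram(
                        Z, ax=ax_dend, orientation="left", no_labels=True,
                        color_threshold=0, above_threshold_color="#555555",
                    )
                ax_dend.invert_yaxis()
                ax_dend.axis("off")
                ax = fig.add_subplot(gs[0, 1])
            else:
                ax = fig.add_subplot(111)
            im = ax.imshow(values, cmap=cmap, vmin=vmin, vmax=vmax)
        ax.set_xticks(np.arange(n))
        ax.set_xticklabels(labels, rotation=90, fontsize=spec.fontsize)
        ax.set_yticks(np.arange(n))
        ax.set_yticklabels(labels, fontsize=spec.fontsize)
        if annot:
            for i in range(n):
                for j in range(n):
                    if style == "tribar" and j > i:
                        continue
                    v = values[i, j]
                    txt = "NA" if not np.isfinite(v) else f"{v:.2f}"
                    ax.text(j, i, txt, ha="center", va="center",
                            fontsize=spec.fontsize * 0.7)
        cbar_hosts = [ax_bar, ax] if style == "tribar" else [ax]
        cbar = fig.colorbar(im, ax=cbar_hosts, shrink=0.75)
        cbar.set_label(m.metric, fontsize=spec.fontsize)
        if spec.title:
            ax.set_title(spec.title, fontsize=spec.fontsize + 2)
        return _save(fig, spec)
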