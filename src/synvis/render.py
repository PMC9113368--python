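"""Deterministic figure rendering with matplotlib.

Ribbons are drawn as one PolyCollection (one SVG path per ribbon) tagged
with the group id ``ribbons``; chromosome axis lines as one LineCollection
tagged ``segments``. SVG output is byte-reproducible: the SVG id hash salt
is pinned and the date metadata suppressed, so identical layouts yield
identical files. PDF and PNG are supported as opaque outputs.
"""
from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.collections import LineCollection, PolyCollection  # noqa: E402
from matplotlib.lines import Line2D  # noqa: E402
from matplotlib.patches import Patch  # noqa: E402

from .exceptions import RenderError  # noqa: E402
from .layout import DEFAULT_COLORS, Layout  # noqa: E402

log = logging.getLogger(__name__)

SUPPORTED_FORMATS = ("pdf", "png", "svg")
_SVG_NS = "http://www.w3.org/2000/svg"
_HASHSALT = "synvis"


@dataclass
class RenderConfig:
    """Figure-level output settings."""

    width: float = 10.0
    height: float = 6.0
    dpi: int = 300
    format: str | None = None  # inferred from the output extension if None
    font_size: float = 8.0
    vertical: bool = False
    legend: bool = True
    style: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise RenderError("figure width and height must be positive")
        if self.dpi < 50:
            raise RenderError("dpi must be >= 50")


def _resolve_format(config: RenderConfig, out_path: str | Path) -> str:
    fmt = config.format or Path(out_path).suffix.lstrip(".").lower()
    if fmt not in SUPPORTED_FORMATS:
        raise RenderError(
            f"unsupported output format {fmt!r}; supported: "
            + ", ".join(SUPPORTED_FORMATS)
        )
    return fmt


def _pt(x: float, y: float, vertical: bool) -> tuple[float, float]:
    return (y, x) if vertical else (x, y)


def render_legend(layout: Layout, genome_names, config: RenderConfig, fig) -> int:
    """Add a legend with one entry per block type present plus the genome
    row labels drawn by :func:`render_figure`. Returns the entry count."""
    present = sorted({r.btype for r in layout.ribbons})
    handles = [
        Patch(facecolor=DEFAULT_COLORS.get(t, "#000000"), label=t)
        for t in present
    ]
    if handles:
        fig.legend(
            handles=handles, loc="lower center",
            ncol=max(len(handles), 1), frameon=False,
            fontsize=config.font_size,
        )
    return len(handles)


def render_figure(
    layout: Layout,
    config: RenderConfig,
    out_path: str | Path,
    genome_display: dict | None = None,
) -> Path:
    """Render a computed layout to ``out_path`` (pdf, png or svg).

    Raises :class:`RenderError` for an unknown extension or when the layout
    contains no ribbon primitives (nothing to draw).
    """
    fmt = _resolve_format(config, out_path)
    if not layout.ribbons:
        raise RenderError("nothing to draw: layout contains no ribbons")
    genome_display = genome_display or {}
    vertical = config.vertical

    with plt.rc_context({"svg.hashsalt": _HASHSALT,
                         "font.size": config.font_size}):
        fig, ax = plt.subplots(figsize=(config.width, config.height))

        polys = [
            [_pt(x, y, vertical) for x, y in ribbon.corners()]
            for ribbon in layout.ribbons
        ]
        pc = PolyCollection(
            polys,
            facecolors=[r.style.get("color", "#000000") for r in layout.ribbons],
            edgecolors="none",
            alpha=None,
        )
        pc.set_alpha(None)
        # per-ribbon alpha via RGBA facecolors keeps one collection
        rgba = [
            matplotlib.colors.to_rgba(
                r.style.get("color", "#000000"), r.style.get("alpha", 0.8)
            )
            for r in layout.ribbons
        ]
        pc.set_facecolor(rgba)
        pc.set_gid("ribbons")
        ax.add_collection(pc)

        seg_lines = [
            [_pt(s.x0, s.y, vertical), _pt(s.x1, s.y, vertical)]
            for s in layout.segments
        ]
        seg_colors = [
            genome_display.get(s.genome, {}).get("lc", "#000000")
            for s in layout.segments
        ]
        seg_widths = [
            float(genome_display.get(s.genome, {}).get("lw", 1.5))
            for s in layout.segments
        ]
        lc = LineCollection(seg_lines, colors=seg_colors,
                            linewidths=seg_widths, capstyle="butt")
        lc.set_gid("segments")
        ax.add_collection(lc)

        for glyph in layout.glyphs:
            gx, gy = _pt(glyph.x, glyph.y, vertical)
            ax.plot(
                [gx], [gy],
                marker=glyph.attributes.get("mt", "v"),
                color=glyph.attributes.get("mc", "black"),
                markersize=float(glyph.attributes.get("ms", 6)),
                linestyle="none",
                gid="marker",
            )
            if glyph.label:
                above = glyph.attributes.get("tp", "top") != "bottom"
                offset = 0.12 if above else -0.18
                tx, ty = _pt(glyph.x, glyph.y + offset, vertical)
                ax.text(
                    tx, ty, glyph.label,
                    ha="center",
                    va="bottom" if above else "top",
                    fontsize=config.font_size,
                    gid="marker-label",
                )

        for hist in layout.histograms:
            bars = []
            for xl, h in zip(hist.x_left, hist.bar_height):
                if h <= 0:
                    continue
                x0, x1 = xl, xl + hist.bar_width
                y0, y1 = hist.y0, hist.y0 + h
                bars.append(
                    [_pt(x0, y0, vertical), _pt(x1, y0, vertical),
                     _pt(x1, y1, vertical), _pt(x0, y1, vertical)]
                )
            if bars:
                hc = PolyCollection(
                    bars,
                    facecolors=hist.style.get("lc", "#2f4f4f"),
                    edgecolors="none",
                )
                hc.set_gid(f"track-{hist.track}")
                ax.add_collection(hc)
            # track baseline label once per (track, leftmost chrom) handled below

        # genome row labels on the left margin
        if layout.segments:
            min_x = min(s.x0 for s in layout.segments)
            for genome, y in layout.row_y.items():
                label = genome_display.get(genome, {}).get("label", genome)
                tx, ty = _pt(min_x, y, vertical)
                ax.annotate(
                    label, (tx, ty), textcoords="offset points",
                    xytext=(-8, 0) if not vertical else (0, 10),
                    ha="right" if not vertical else "center",
                    va="center" if not vertical else "bottom",
                    fontsize=config.font_size, gid="row-label",
                )
            seen_tracks = set()
            for hist in layout.histograms:
                if hist.track in seen_tracks:
                    continue
                seen_tracks.add(hist.track)
                tx, ty = _pt(min_x, hist.y0 + hist.height / 2, vertical)
                ax.annotate(
                    hist.track, (tx, ty), textcoords="offset points",
                    xytext=(-8, 0) if not vertical else (0, 10),
                    ha="right" if not vertical else "center",
                    va="center" if not vertical else "bottom",
                    fontsize=config.font_size, gid="track-label",
                )

        ax.autoscale_view()
        ax.margins(0.05)
        ax.set_axis_off()
        if config.legend:
            render_legend(layout, list(layout.row_y), config, fig)

        out_path = Path(out_path)
        metadata = {"Date": None} if fmt == "svg" else (
            {"CreationDate": None} if fmt == "pdf" else None
        )
        fig.savefig(out_path, format=fmt, dpi=config.dpi, metadata=metadata)
        plt.close(fig)
    log.info("wrote %s (%s, %d ribbons, %d segments)",
             out_path, fmt, len(layout.ribbons), len(layout.segments))
    return out_path


def svg_census(path: str | Path) -> dict[str, int]:
    """Count the figure's structural elements in an SVG file.

    Returns the number of ribbon paths (children of the ``ribbons`` group)
    and segment paths (children of the ``segments`` group) — the figure's
    full account of drawn blocks and chromosomes.
    """
    root = ET.parse(path).getroot()
    counts = {"ribbons": 0, "segments": 0}
    for g in root.iter(f"{{{_SVG_NS}}}g"):
        gid = g.get("id")
        if gid in counts:
            counts[gid] = sum(
                1
                for el in g.iter()
                if el is not g
                and el.tag.split("}")[-1] in ("path", "use", "line", "rect",
                                              "polygon")
            )
    return counts
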