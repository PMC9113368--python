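"""Figure geometry: axis segments, ribbons, marker glyphs, track histograms.

Two modes are provided. Stacked mode gives each genome one horizontal row
(first genome on top) and aligns homologous chromosomes vertically in
left-aligned columns; only intra-group ribbons are drawn, which favours
synteny and intra-chromosomal rearrangements. itx mode concatenates each
genome's chromosomes on a single row so inter-chromosomal translocations
and duplications become drawable ribbons.

Everything here is pure computation in abstract figure units (1 unit per
megabase horizontally, 1 unit per genome row vertically); rendering to a
file happens in :mod:`synvis.render`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import LayoutError
from .formats_io import INVERTED_TYPES, AlignmentBlock, MarkerRecord, TrackSpec
from .homology import HomologyGroup, group_lookup
from .model import ComparisonChain
from .zoom import ZoomSelection

log = logging.getLogger(__name__)

#: Horizontal scale: figure units per base pair.
BP_SCALE = 1e-6
#: Vertical distance between adjacent genome rows.
ROW_SPACING = 1.0
#: Ribbons stop short of the chromosome lines by this margin.
RIBBON_MARGIN = 0.08
#: Height of one track histogram row, and spacing between track rows.
TRACK_HEIGHT = 0.55
TRACK_SPACING = 0.85
#: Gap between concatenated chromosomes (itx) / group columns (stacked),
#: as a fraction of the longest genome's drawn length.
GAP_FRACTION = 0.02

DEFAULT_COLORS = {
    "SYN": "#a9a9a9",
    "INV": "#ffa500",
    "TRANS": "#228b22",
    "INVTR": "#228b22",
    "DUP": "#4682b4",
    "INVDP": "#4682b4",
}
DEFAULT_ALPHA = {"SYN": 0.6, "INV": 0.8, "TRANS": 0.8, "INVTR": 0.8,
                 "DUP": 0.8, "INVDP": 0.8}


@dataclass
class AxisSegment:
    """One drawn chromosome: a horizontal line plus an affine base-pair to
    figure-x map over the drawn interval [bp0, bp1]."""

    genome: str
    chrom: str
    x0: float
    x1: float
    y: float
    bp0: int
    bp1: int

    def x_of(self, bp: int) -> float:
        if self.bp1 == self.bp0:
            return self.x0
        frac = (bp - self.bp0) / (self.bp1 - self.bp0)
        return self.x0 + frac * (self.x1 - self.x0)

    def bp_of(self, x: float) -> int:
        if self.x1 == self.x0:
            return self.bp0
        frac = (x - self.x0) / (self.x1 - self.x0)
        return round(self.bp0 + frac * (self.bp1 - self.bp0))


@dataclass
class RibbonPrimitive:
    """A quadrilateral linking a block's two intervals on adjacent rows;
    ``crossed`` swaps the bottom corners to draw an inversion bow-tie."""

    btype: str
    top: tuple[float, float, float]      # (x_start, x_end, y)
    bottom: tuple[float, float, float]
    crossed: bool
    style: dict = field(default_factory=dict)
    source: AlignmentBlock | None = None

    def corners(self) -> list[tuple[float, float]]:
        tx0, tx1, ty = self.top
        bx0, bx1, by = self.bottom
        if self.crossed:
            bx0, bx1 = bx1, bx0
        return [(tx0, ty), (tx1, ty), (bx1, by), (bx0, by)]


@dataclass
class MarkerGlyph:
    genome: str
    x: float
    y: float
    attributes: dict
    label: str = ""


@dataclass
class TrackHistogram:
    """Pre-normalized histogram bars for one track on one chromosome."""

    track: str
    chrom: str
    y0: float
    height: float
    x_left: np.ndarray
    bar_width: float
    bar_height: np.ndarray
    style: dict = field(default_factory=dict)


@dataclass
class Layout:
    mode: str
    segments: list[AxisSegment] = field(default_factory=list)
    ribbons: list[RibbonPrimitive] = field(default_factory=list)
    glyphs: list[MarkerGlyph] = field(default_factory=list)
    histograms: list[TrackHistogram] = field(default_factory=list)
    row_y: dict = field(default_factory=dict)      # genome name -> y
    stats: dict = field(default_factory=dict)

    def segment_for(self, genome: str, chrom: str) -> AxisSegment | None:
        return self._index.get((genome, chrom))

    def reindex(self) -> None:
        self._index = {(s.genome, s.chrom): s for s in self.segments}


def _style_for(btype: str, overrides: dict | None) -> dict:
    style = {
        "color": DEFAULT_COLORS.get(btype, "#000000"),
        "alpha": DEFAULT_ALPHA.get(btype, 0.8),
    }
    if overrides and btype in overrides:
        style.update(overrides[btype])
    return style


def _make_ribbons(
    chain: ComparisonChain,
    layout: Layout,
    suppress: frozenset,
    intra_only: bool,
    lookup: dict | None,
    style_overrides: dict | None,
) -> None:
    skipped_inter = 0
    skipped_notal = 0
    suppressed = 0
    for comp in chain.comparisons:
        for block in comp.blocks:
            if block.btype in suppress:
                suppressed += 1
                continue
            if block.btype == "NOTAL":
                skipped_notal += 1  # drawn as axis gaps, not ribbons
                continue
            if intra_only and lookup is not None:
                g_ref = lookup.get((comp.ref_genome, block.ref_chrom))
                g_qry = lookup.get((comp.qry_genome, block.qry_chrom))
                if g_ref is None or g_ref != g_qry:
                    skipped_inter += 1
                    continue
            top_seg = layout.segment_for(comp.ref_genome, block.ref_chrom)
            bot_seg = layout.segment_for(comp.qry_genome, block.qry_chrom)
            if top_seg is None or bot_seg is None:
                skipped_inter += 1
                continue
            ty = top_seg.y - RIBBON_MARGIN
            by = bot_seg.y + RIBBON_MARGIN
            layout.ribbons.append(
                RibbonPrimitive(
                    btype=block.btype,
                    top=(top_seg.x_of(block.ref_start),
                         top_seg.x_of(block.ref_end), ty),
                    bottom=(bot_seg.x_of(block.qry_start),
                            bot_seg.x_of(block.qry_end), by),
                    crossed=block.btype in INVERTED_TYPES,
                    style=_style_for(block.btype, style_overrides),
                    source=block,
                )
            )
    layout.stats.update(
        skipped_inter_chromosomal=skipped_inter,
        notal_gaps=skipped_notal,
        suppressed=suppressed,
        ribbons=len(layout.ribbons),
    )
    if skipped_inter:
        log.info(
            "stacked layout skipped %d inter-chromosomal block(s); use itx "
            "mode to draw them", skipped_inter,
        )


def layout_stacked(
    chain: ComparisonChain,
    groups: list[HomologyGroup],
    selection: ZoomSelection | None = None,
    suppress: frozenset = frozenset(),
    style_overrides: dict | None = None,
) -> Layout:
    """Stacked mode: one row per genome, homology groups as left-aligned
    columns; only intra-group ribbons are drawn (inter-chromosomal blocks
    are counted and logged). With a zoom selection each genome's row is its
    selected window, all left-aligned at x = 0."""
    layout = Layout(mode="stacked")
    n = len(chain.genomes)
    for i, genome in enumerate(chain.genomes):
        layout.row_y[genome.name] = (n - 1 - i) * ROW_SPACING

    lookup = group_lookup(groups)
    if selection is not None:
        for genome in chain.genomes:
            chrom, lo, hi = selection.intervals[genome.name]
            layout.segments.append(
                AxisSegment(
                    genome.name, chrom,
                    0.0, max((hi - lo) * BP_SCALE, 1e-9),
                    layout.row_y[genome.name], lo, hi,
                )
            )
    else:
        # column width per group = longest member chromosome
        widths = []
        for g in groups:
            lengths = [
                chain.genome(gn).chrom_lengths[cn]
                for gn, cn in g.members.items()
            ]
            widths.append(max(lengths))
        gap_bp = GAP_FRACTION * max(
            (g.total_length for g in chain.genomes), default=1
        )
        origins: dict[int, float] = {}
        cursor = 0.0
        for g, width in zip(groups, widths):
            origins[g.order_index] = cursor
            cursor += (width + gap_bp) * BP_SCALE
        for g in groups:
            for gn, cn in g.members.items():
                length = chain.genome(gn).chrom_lengths[cn]
                x0 = origins[g.order_index]
                layout.segments.append(
                    AxisSegment(
                        gn, cn, x0, x0 + length * BP_SCALE,
                        layout.row_y[gn], 1, length,
                    )
                )
    layout.reindex()
    _make_ribbons(chain, layout, suppress, True, lookup, style_overrides)
    return layout


def layout_itx(
    chain: ComparisonChain,
    groups: list[HomologyGroup],
    selection: ZoomSelection | None = None,
    suppress: frozenset = frozenset(),
    style_overrides: dict | None = None,
) -> Layout:
    """itx mode: each genome's chromosomes concatenated on one row in
    homology-group order, separated by a fixed gap; every block type draws
    a ribbon, including inter-chromosomal ones."""
    if selection is not None:
        raise LayoutError("zooming cannot be combined with itx mode")
    layout = Layout(mode="itx")
    n = len(chain.genomes)
    for i, genome in enumerate(chain.genomes):
        layout.row_y[genome.name] = (n - 1 - i) * ROW_SPACING

    gap_bp = GAP_FRACTION * max(g.total_length for g in chain.genomes)
    ordered_groups = sorted(groups, key=lambda g: g.order_index)
    for genome in chain.genomes:
        cursor = 0.0
        lengths = genome.chrom_lengths
        drawn: set[str] = set()
        members = [
            g.members[genome.name]
            for g in ordered_groups
            if genome.name in g.members
        ]
        for chrom in members:
            length = lengths[chrom]
            layout.segments.append(
                AxisSegment(
                    genome.name, chrom, cursor, cursor + length * BP_SCALE,
                    layout.row_y[genome.name], 1, length,
                )
            )
            cursor += (length + gap_bp) * BP_SCALE
            drawn.add(chrom)
    layout.reindex()
    _make_ribbons(chain, layout, suppress, False, None, style_overrides)
    return layout


def place_tracks_and_markers(
    markers: list[MarkerRecord],
    track_values: list[tuple[TrackSpec, dict]],
    layout: Layout,
) -> Layout:
    """Attach marker glyphs and track histograms to a computed layout.

    Tracks occupy dedicated rows above the first (top) genome row, one row
    per track in file order; bar heights are normalized to each track's
    maximum within the drawn window. Markers outside every drawn segment
    warn and are skipped.
    """
    for m in markers:
        seg = layout.segment_for(m.genome, m.chrom)
        pos = m.midpoint
        if seg is None or not (seg.bp0 <= pos <= seg.bp1):
            log.warning(
                "marker %s:%s:%d-%d lies outside the drawn segments; skipped",
                m.genome, m.chrom, m.start, m.end,
            )
            continue
        layout.glyphs.append(
            MarkerGlyph(m.genome, seg.x_of(pos), layout.row_y[m.genome],
                        dict(m.attributes), m.label)
        )

    if track_values:
        top_y = max(layout.row_y.values()) if layout.row_y else 0.0
        # first track sits closest to the top genome; later tracks above it
        for t, (spec, values) in enumerate(track_values):
            y0 = top_y + TRACK_SPACING * (t + 1) - TRACK_HEIGHT / 2
            drawn_max = 0.0
            usable: list[tuple[AxisSegment, np.ndarray]] = []
            for chrom, vec in values.items():
                seg = next(
                    (s for s in layout.segments if s.chrom == chrom), None
                )
                if seg is None:
                    continue
                usable.append((seg, vec))
                if len(vec):
                    drawn_max = max(drawn_max, float(np.max(vec)))
            for seg, vec in usable:
                nbins = len(vec)
                if nbins == 0:
                    continue
                span_x = seg.x1 - seg.x0
                bar_w = span_x / nbins
                heights = (
                    vec / drawn_max * TRACK_HEIGHT
                    if drawn_max > 0
                    else np.zeros_like(vec, dtype=float)
                )
                layout.histograms.append(
                    TrackHistogram(
                        track=spec.name,
                        chrom=seg.chrom,
                        y0=y0,
                        height=TRACK_HEIGHT,
                        x_left=seg.x0 + np.arange(nbins) * bar_w,
                        bar_width=bar_w,
                        bar_height=np.asarray(heights, dtype=float),
                        style=dict(spec.attributes),
                    )
                )
    layout.stats.update(glyphs=len(layout.glyphs),
                        track_rows=len(track_values))
    return layout
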