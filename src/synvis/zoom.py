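"""Region zoom: lift a user-selected interval through the syntenic backbone.

Only SYN blocks participate in coordinate propagation; rearranged blocks
are passengers that get filtered against the propagated windows afterwards.
Each propagation step maps the two region endpoints through the pairwise
SYN blocks by within-block linear interpolation (floor rounding); an
endpoint falling between blocks snaps to the nearest edge, among the
region-overlapping blocks, of that block's counterpart interval. The
result per genome is the single span (min, max) of the mapped endpoints,
which stays a contiguous axis window even when local inversions scramble
block order.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .exceptions import ZoomError
from .formats_io import AlignmentBlock, MarkerRecord, TrackSpec, load_track_values
from .homology import pair_homology
from .model import ComparisonChain, PairwiseComparison

log = logging.getLogger(__name__)

REF_TO_QRY = "ref2qry"
QRY_TO_REF = "qry2ref"


@dataclass(frozen=True)
class RegionRequest:
    """A user-requested window: genome, chromosome, 1-based inclusive span."""

    genome: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ZoomError(
                f"invalid region {self.start}-{self.end}: need 1 <= start <= end"
            )


@dataclass(frozen=True)
class ZoomSelection:
    """One homologous (chrom, start, end) window per genome in the chain."""

    intervals: dict  # genome name -> (chrom, start, end)
    origin: RegionRequest


def interpolate(x: int, s0: int, s1: int, t0: int, t1: int, inverted: bool = False) -> int:
    """Map base ``x`` of source interval [s0, s1] into target [t0, t1] by
    linear interpolation with floor rounding; ``inverted`` reverses the
    target direction. This is the per-base definition of the block-level
    coordinate correspondence, shared with the test oracle."""
    if s1 == s0:
        return t1 if inverted else t0
    offset = (x - s0) * (t1 - t0) // (s1 - s0)
    return (t1 - offset) if inverted else (t0 + offset)


def _sides(block: AlignmentBlock, direction: str):
    """Source and target (chrom, start, end) of a block for a direction."""
    ref = (block.ref_chrom, block.ref_start, block.ref_end)
    qry = (block.qry_chrom, block.qry_start, block.qry_end)
    return (ref, qry) if direction == REF_TO_QRY else (qry, ref)


def map_region_step(
    region: tuple[str, int, int],
    comparison: PairwiseComparison,
    direction: str = REF_TO_QRY,
    chrom_length: int | None = None,
) -> tuple[str, int, int]:
    """Map one (chrom, start, end) region across one pairwise comparison.

    Uses the SYN blocks linking the region's chromosome to its homolog
    (per the pairwise synteny matching). Endpoints inside a block are
    interpolated; endpoints in an inter-block gap snap to the nearest
    source edge among the overlapping blocks. Raises :class:`ZoomError`
    when no SYN block overlaps the region.
    """
    if direction not in (REF_TO_QRY, QRY_TO_REF):
        raise ValueError(f"unknown direction {direction!r}")
    chrom, start, end = region
    matching = pair_homology(comparison)
    if direction == REF_TO_QRY:
        partner = matching.get(chrom)
        target_genome = comparison.qry_genome
    else:
        inverse = {q: r for r, q in matching.items()}
        partner = inverse.get(chrom)
        target_genome = comparison.ref_genome
    if partner is None:
        raise ZoomError(
            f"chromosome {chrom!r} has no syntenic homolog in genome "
            f"{target_genome!r}"
        )

    candidates = []
    for block in comparison.blocks:
        if block.btype != "SYN":
            continue
        (sc, s0, s1), (tc, t0, t1) = _sides(block, direction)
        if sc == chrom and tc == partner and s0 <= end and s1 >= start:
            candidates.append((s0, s1, t0, t1, block.qry_inverted))
    if not candidates:
        raise ZoomError(
            f"region {chrom}:{start}-{end} overlaps no syntenic block toward "
            f"genome {target_genome!r}; propagation dead-ends"
        )
    candidates.sort()

    def map_endpoint(x: int) -> int:
        best = None  # (gap distance, s0, mapped position)
        for s0, s1, t0, t1, inv in candidates:
            if s0 <= x <= s1:
                return interpolate(x, s0, s1, t0, t1, inv)
            edge = s0 if x < s0 else s1
            dist = abs(x - edge)
            if best is None or (dist, s0) < best[:2]:
                best = (dist, s0, interpolate(edge, s0, s1, t0, t1, inv))
        return best[2]

    a, b = map_endpoint(start), map_endpoint(end)
    lo, hi = min(a, b), max(a, b)
    lo = max(lo, 1)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return (partner, lo, hi)


def propagate_region(request: RegionRequest, chain: ComparisonChain) -> ZoomSelection:
    """Propagate a region outward along the chain until every genome has a
    homologous window, applying :func:`map_region_step` pairwise."""
    origin_idx = chain.genome_index(request.genome)
    genome = chain.genomes[origin_idx]
    lengths = genome.chrom_lengths
    if request.chrom not in lengths:
        raise ZoomError(
            f"genome {request.genome!r} has no chromosome {request.chrom!r}"
        )
    if request.end > lengths[request.chrom]:
        raise ZoomError(
            f"region end {request.end} exceeds {request.chrom!r} length "
            f"{lengths[request.chrom]}"
        )

    intervals = {request.genome: (request.chrom, request.start, request.end)}
    # forward: origin -> ... -> last genome
    current = intervals[request.genome]
    for k in range(origin_idx, len(chain.comparisons)):
        target = chain.genomes[k + 1]
        current = map_region_step(current, chain.comparisons[k], REF_TO_QRY)
        chrom, lo, hi = current
        limit = target.chrom_lengths.get(chrom)
        if limit is not None:
            current = (chrom, lo, min(hi, limit))
        intervals[target.name] = current
    # backward: origin -> ... -> first genome
    current = intervals[request.genome]
    for k in range(origin_idx - 1, -1, -1):
        target = chain.genomes[k]
        current = map_region_step(current, chain.comparisons[k], QRY_TO_REF)
        chrom, lo, hi = current
        limit = target.chrom_lengths.get(chrom)
        if limit is not None:
            current = (chrom, lo, min(hi, limit))
        intervals[target.name] = current

    selection = ZoomSelection(intervals, request)
    for name, (chrom, lo, hi) in intervals.items():
        log.info("zoom window %s: %s:%d-%d", name, chrom, lo, hi)
    return selection


def _overlaps(start: int, end: int, lo: int, hi: int) -> bool:
    return start <= hi and end >= lo


def _clip_block(block: AlignmentBlock, ref_win, qry_win) -> AlignmentBlock:
    changes = {}
    if block.ref_chrom:
        _, lo, hi = ref_win
        changes["ref_start"] = max(block.ref_start, lo)
        changes["ref_end"] = min(block.ref_end, hi)
    if block.qry_chrom:
        _, lo, hi = qry_win
        changes["qry_start"] = max(block.qry_start, lo)
        changes["qry_end"] = min(block.qry_end, hi)
    return replace(block, **changes)


def clip_to_selection(
    chain: ComparisonChain,
    markers: list[MarkerRecord],
    tracks: list[TrackSpec],
    selection: ZoomSelection,
):
    """Restrict all drawable content to a zoom selection.

    A block survives only if both its sides overlap their genomes' selected
    windows (a single-sided NOTAL block: its one side must overlap);
    survivors are coordinate-clipped to the windows. Markers must fall
    inside their genome's window. Track vectors are re-binned over the
    first genome's selected interval. Returns
    (clipped chain, clipped markers, track value vectors).
    """
    new_comparisons = []
    for comp in chain.comparisons:
        ref_win = selection.intervals[comp.ref_genome]
        qry_win = selection.intervals[comp.qry_genome]
        kept = []
        for block in comp.blocks:
            ok = True
            if block.ref_chrom:
                wc, lo, hi = ref_win
                ok = block.ref_chrom == wc and _overlaps(
                    block.ref_start, block.ref_end, lo, hi
                )
            if ok and block.qry_chrom:
                wc, lo, hi = qry_win
                ok = block.qry_chrom == wc and _overlaps(
                    block.qry_start, block.qry_end, lo, hi
                )
            if ok:
                kept.append(_clip_block(block, ref_win, qry_win))
        log.info(
            "zoom filter %s vs %s: kept %d of %d blocks",
            comp.ref_genome, comp.qry_genome, len(kept), len(comp.blocks),
        )
        new_comparisons.append(
            PairwiseComparison(comp.ref_genome, comp.qry_genome, tuple(kept))
        )
    clipped_chain = ComparisonChain(chain.genomes, tuple(new_comparisons))

    kept_markers = []
    for m in markers:
        wc, lo, hi = selection.intervals[m.genome]
        if m.chrom == wc and _overlaps(m.start, m.end, lo, hi):
            kept_markers.append(m)
    if markers:
        log.info("zoom filter markers: kept %d of %d", len(kept_markers), len(markers))

    first = chain.genomes[0]
    window = selection.intervals[first.name]
    track_values = [
        (spec, load_track_values(spec, list(first.chromosomes), window=window))
        for spec in tracks
    ]
    return clipped_chain, kept_markers, track_values
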