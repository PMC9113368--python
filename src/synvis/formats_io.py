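"""Readers for every external file the tool consumes.

All coordinates are normalized at the parser boundary to the internal
convention: 1-based, inclusive on both ends, matching the SyRI dialect.
BEDPE, BED and bedGraph inputs (0-based, half-open) are shifted on read.

Nothing here writes output except :func:`filter_small_variants`, which
copies an annotation file minus its SNP/indel records.
"""
from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .exceptions import InputError

log = logging.getLogger(__name__)

#: Structural annotation vocabulary. NOTAL marks an unaligned stretch and is
#: single-sided: one side of the block has an empty chromosome name.
BLOCK_TYPES = frozenset({"SYN", "INV", "TRANS", "INVTR", "DUP", "INVDP", "NOTAL"})

#: Inverted-orientation annotation classes (drawn as crossed ribbons).
INVERTED_TYPES = frozenset({"INV", "INVTR", "INVDP"})

#: Small-variant record types removed by :func:`filter_small_variants`.
SMALL_VARIANT_TYPES = frozenset({"SNP", "INS", "DEL"})

#: SyRI record types describing local (non-structural) variation; these and
#: every record with a non-"-" parent are dropped on parse.
_LOCAL_TYPES = frozenset({"SNP", "INS", "DEL", "HDR", "CPG", "CPL", "TDM"})

MARKER_DEFAULTS = {"mt": "v", "mc": "black", "ms": "6", "tt": "", "tp": "top"}
_MARKER_KEYS = frozenset(MARKER_DEFAULTS)

DEFAULT_BIN_SIZE = 100_000


@dataclass(frozen=True)
class ChromosomeRecord:
    """One chromosome of one genome: a name and a length in base pairs."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if not self.name:
            raise InputError("chromosome name must be non-empty")
        if self.length < 1:
            raise InputError(
                f"chromosome {self.name!r} has non-positive length {self.length}"
            )


@dataclass(frozen=True)
class AlignmentBlock:
    """One pairwise record: an interval in a reference genome linked to an
    interval in a query genome, carrying a structural annotation type.

    Coordinates are 1-based inclusive. A NOTAL block has exactly one side;
    the missing side has an empty chromosome name and zero coordinates.
    ``qry_inverted`` records that the source file gave the query interval in
    descending order (it is stored normalized, start <= end).
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    btype: str
    source_id: str = ""
    qry_inverted: bool = False

    def __post_init__(self) -> None:
        if self.btype not in BLOCK_TYPES:
            raise InputError(
                f"unknown block type {self.btype!r}; expected one of "
                + ", ".join(sorted(BLOCK_TYPES))
            )
        if self.btype == "NOTAL":
            if bool(self.ref_chrom) == bool(self.qry_chrom):
                raise InputError("NOTAL block must have exactly one aligned side")
        else:
            if not self.ref_chrom or not self.qry_chrom:
                raise InputError(
                    f"{self.btype} block must name chromosomes on both sides"
                )
        for chrom, start, end, side in (
            (self.ref_chrom, self.ref_start, self.ref_end, "ref"),
            (self.qry_chrom, self.qry_start, self.qry_end, "qry"),
        ):
            if chrom and not (1 <= start <= end):
                raise InputError(
                    f"invalid {side} interval {start}-{end} on {chrom!r}"
                )

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start + 1 if self.ref_chrom else 0

    @property
    def qry_span(self) -> int:
        return self.qry_end - self.qry_start + 1 if self.qry_chrom else 0


@dataclass(frozen=True)
class MarkerRecord:
    """A labelled locus to highlight on one genome's row."""

    genome: str
    chrom: str
    start: int
    end: int
    label: str = ""
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(
                f"marker interval {self.start}-{self.end} on {self.chrom!r} reversed"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class TrackSpec:
    """A feature track bound to the first genome's coordinates.

    ``bed_density`` counts feature midpoints per bin; ``bedgraph_value``
    averages interval values per bin, weighted by overlap length.
    """

    name: str
    path: str
    ttype: str = "bed_density"
    bin_size: int = DEFAULT_BIN_SIZE
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ttype not in ("bed_density", "bedgraph_value"):
            raise InputError(f"unknown track type {self.ttype!r}")
        if self.bin_size < 1:
            raise InputError(f"bin size must be >= 1, got {self.bin_size}")


# ---------------------------------------------------------------------------
# chromosome lengths


def _open_text(path: str | Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_chromosome_lengths(
    path: str | Path, format_hint: str = "auto"
) -> list[ChromosomeRecord]:
    """Read chromosome names and lengths from a FASTA (plain or gzipped)
    or a two-column name<TAB>length table, preserving file order."""
    if format_hint not in ("fasta", "table", "auto"):
        raise InputError(f"unknown format hint {format_hint!r}")
    if format_hint == "auto":
        with _open_text(path) as fh:
            first = fh.read(1)
        format_hint = "fasta" if first == ">" else "table"
    records: list[ChromosomeRecord] = []
    seen: set[str] = set()
    if format_hint == "fasta":
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                if rec.id in seen:
                    raise InputError(
                        f"duplicate chromosome {rec.id!r} in {path}"
                    )
                seen.add(rec.id)
                records.append(ChromosomeRecord(rec.id, len(rec.seq)))
    else:
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 2:
                    raise InputError(
                        f"{path}:{lineno}: expected name<TAB>length, got {line!r}"
                    )
                name = cols[0]
                try:
                    length = int(cols[1])
                except ValueError:
                    raise InputError(
                        f"{path}:{lineno}: non-integer length {cols[1]!r}"
                    ) from None
                if name in seen:
                    raise InputError(f"duplicate chromosome {name!r} in {path}")
                seen.add(name)
                records.append(ChromosomeRecord(name, length))
    if not records:
        raise InputError(f"no chromosomes found in {path}")
    return records


# ---------------------------------------------------------------------------
# structural annotations


def _parse_coord(token: str, path, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise InputError(
            f"{path}:{lineno}: non-numeric coordinate {token!r}"
        ) from None


def parse_syri_tsv(path: str | Path) -> list[AlignmentBlock]:
    """Parse the 12-column SyRI annotation dialect.

    Columns: ref_chrom, ref_start, ref_end, ref_seq, qry_seq, qry_chrom,
    qry_start, qry_end, id, parent, type, copy_status; the sequence columns
    are ignored. Only top-level structural records (SYN, INV, TRANS, INVTR,
    DUP, INVDP, NOTAL with parent "-") are retained; alignment children and
    local-variant records are dropped. Query intervals given in descending
    order are normalized and flagged inverted.
    """
    blocks: list[AlignmentBlock] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise InputError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            btype, parent = cols[10], cols[9]
            if btype not in BLOCK_TYPES or parent != "-":
                continue  # alignment child or local variant
            rc, qc = cols[0], cols[5]
            rc = "" if rc == "-" else rc
            qc = "" if qc == "-" else qc
            rs = re = qs = qe = 0
            if rc:
                rs = _parse_coord(cols[1], path, lineno)
                re = _parse_coord(cols[2], path, lineno)
            if qc:
                qs = _parse_coord(cols[6], path, lineno)
                qe = _parse_coord(cols[7], path, lineno)
            inverted = False
            if qc and qs > qe:
                qs, qe = qe, qs
                inverted = True
            blocks.append(
                AlignmentBlock(rc, rs, re, qc, qs, qe, btype, cols[8], inverted)
            )
    return blocks


def parse_bedpe(path: str | Path) -> list[AlignmentBlock]:
    """Parse a >=7-column BEDPE annotation file.

    Columns: chrom1, start1, end1, chrom2, start2, end2, type[, id]. Starts
    are 0-based half-open and are shifted to the internal 1-based inclusive
    convention; the type token is matched case-insensitively.
    """
    blocks: list[AlignmentBlock] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 7:
                raise InputError(
                    f"{path}:{lineno}: expected >=7 tab-separated columns, "
                    f"got {len(cols)}"
                )
            btype = cols[6].upper()
            if btype not in BLOCK_TYPES:
                raise InputError(
                    f"{path}:{lineno}: unknown type {cols[6]!r}; allowed: "
                    + ", ".join(sorted(BLOCK_TYPES))
                )
            rc = "" if cols[0] in (".", "-", "") else cols[0]
            qc = "" if cols[3] in (".", "-", "") else cols[3]
            rs = re = qs = qe = 0
            if rc:
                s = _parse_coord(cols[1], path, lineno)
                e = _parse_coord(cols[2], path, lineno)
                if e <= s:
                    raise InputError(
                        f"{path}:{lineno}: half-open interval requires end > "
                        f"start, got {s}-{e}"
                    )
                rs, re = s + 1, e
            if qc:
                s = _parse_coord(cols[4], path, lineno)
                e = _parse_coord(cols[5], path, lineno)
                if e <= s:
                    raise InputError(
                        f"{path}:{lineno}: half-open interval requires end > "
                        f"start, got {s}-{e}"
                    )
                qs, qe = s + 1, e
            source_id = cols[7] if len(cols) > 7 else ""
            blocks.append(AlignmentBlock(rc, rs, re, qc, qs, qe, btype, source_id))
    return blocks


def filter_small_variants(path_in: str | Path, path_out: str | Path) -> int:
    """Copy a SyRI-dialect file dropping SNP/INS/DEL rows; return the number
    of rows removed. Kept lines are copied verbatim, order preserved."""
    removed = 0
    with _open_text(path_in) as fin, open(path_out, "wt") as fout:
        for lineno, line in enumerate(fin, 1):
            stripped = line.rstrip("\n")
            if stripped and not stripped.startswith("#"):
                cols = stripped.split("\t")
                if len(cols) < 12:
                    raise InputError(
                        f"{path_in}:{lineno}: expected 12 tab-separated "
                        f"columns, got {len(cols)}"
                    )
                if cols[10] in SMALL_VARIANT_TYPES:
                    removed += 1
                    continue
            fout.write(line)
    return removed


# ---------------------------------------------------------------------------
# markers


def _parse_tag_string(tags: str) -> dict:
    out: dict = {}
    for item in tags.split(";"):
        item = item.strip()
        if not item:
            continue
        if ":" not in item:
            raise InputError(f"malformed attribute {item!r}; expected key:value")
        key, value = item.split(":", 1)
        out[key] = value
    return out


def parse_markers(path: str | Path, genome_names) -> list[MarkerRecord]:
    """Parse a marker BED file: chrom, start, end, genome[, attributes].

    The attribute column is a semicolon-separated key:value string with keys
    mt (glyph), mc (colour), ms (size), tt (label text), tp (label position).
    Unrecognized keys warn and are ignored; missing keys take defaults.
    """
    genome_names = set(genome_names)
    markers: list[MarkerRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise InputError(
                    f"{path}:{lineno}: marker rows need chrom, start, end, genome"
                )
            chrom = cols[0]
            start = _parse_coord(cols[1], path, lineno) + 1
            end = _parse_coord(cols[2], path, lineno)
            genome = cols[3]
            if genome not in genome_names:
                raise InputError(
                    f"{path}:{lineno}: genome {genome!r} is not configured"
                )
            attrs = dict(MARKER_DEFAULTS)
            if len(cols) > 4 and cols[4]:
                for key, value in _parse_tag_string(cols[4]).items():
                    if key not in _MARKER_KEYS:
                        log.warning(
                            "%s:%d: ignoring unknown marker attribute %r",
                            path, lineno, key,
                        )
                        continue
                    attrs[key] = value
            markers.append(
                MarkerRecord(genome, chrom, start, end, attrs["tt"], attrs)
            )
    return markers


# ---------------------------------------------------------------------------
# feature tracks


def load_track_values(
    spec: TrackSpec,
    chromosomes: list[ChromosomeRecord],
    window: tuple[str, int, int] | None = None,
) -> dict[str, np.ndarray]:
    """Bin a track file over the given chromosomes.

    Returns one value vector per chromosome with ceil(span / bin_size) bins.
    ``window`` restricts binning to one (chrom, start, end) interval, used by
    zoomed views; bin 0 then starts at the window start. Features on
    chromosomes absent from ``chromosomes`` are skipped with a warning.
    """
    spans: dict[str, tuple[int, int]] = {}
    if window is not None:
        wc, ws, we = window
        spans[wc] = (ws, we)
    else:
        for rec in chromosomes:
            spans[rec.name] = (1, rec.length)

    nbins = {
        c: math.ceil((e - s + 1) / spec.bin_size) for c, (s, e) in spans.items()
    }
    counts = {c: np.zeros(n) for c, n in nbins.items()}
    weights = {c: np.zeros(n) for c, n in nbins.items()}
    known = {rec.name for rec in chromosomes}
    warned: set[str] = set()

    with _open_text(spec.path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise InputError(
                    f"{spec.path}:{lineno}: expected at least chrom, start, end"
                )
            chrom = cols[0]
            if chrom not in known and chrom not in warned:
                log.warning(
                    "%s: chromosome %r not in the coordinate genome; skipped",
                    spec.path, chrom,
                )
                warned.add(chrom)
            if chrom not in spans:
                continue
            origin, limit = spans[chrom]
            start = _parse_coord(cols[1], spec.path, lineno) + 1
            end = _parse_coord(cols[2], spec.path, lineno)
            if spec.ttype == "bed_density":
                mid = (start + end) // 2
                if origin <= mid <= limit:
                    counts[chrom][(mid - origin) // spec.bin_size] += 1
            else:
                if len(cols) < 4:
                    raise InputError(
                        f"{spec.path}:{lineno}: bedGraph rows need a value column"
                    )
                value = float(cols[3])
                lo, hi = max(start, origin), min(end, limit)
                if lo > hi:
                    continue
                b0 = (lo - origin) // spec.bin_size
                b1 = (hi - origin) // spec.bin_size
                for b in range(b0, b1 + 1):
                    bin_lo = origin + b * spec.bin_size
                    bin_hi = min(bin_lo + spec.bin_size - 1, limit)
                    overlap = min(hi, bin_hi) - max(lo, bin_lo) + 1
                    if overlap > 0:
                        counts[chrom][b] += value * overlap
                        weights[chrom][b] += overlap

    if spec.ttype == "bedgraph_value":
        out = {}
        for chrom in counts:
            w = weights[chrom]
            vals = np.divide(
                counts[chrom], w, out=np.zeros_like(w), where=w > 0
            )
            out[chrom] = vals
        return out
    return counts


# ---------------------------------------------------------------------------
# config tables


def read_genomes_config(path: str | Path) -> list[tuple[str, str, dict]]:
    """Read the genomes table: path<TAB>name<TAB>tags, tags being a
    semicolon-separated key:value display map (may be absent)."""
    entries: list[tuple[str, str, dict]] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise InputError(
                    f"{path}:{lineno}: expected path<TAB>name[<TAB>tags]"
                )
            name = cols[1]
            if name in seen:
                raise InputError(f"{path}:{lineno}: duplicate genome {name!r}")
            seen.add(name)
            tags = _parse_tag_string(cols[2]) if len(cols) > 2 else {}
            entries.append((cols[0], name, tags))
    if len(entries) < 2:
        raise InputError(f"{path}: need at least two genomes, got {len(entries)}")
    return entries


def read_tracks_config(path: str | Path) -> list[TrackSpec]:
    """Read the tracks table: path<TAB>name<TAB>tags.

    Recognized tags: bw (bin width, bp), ty (bed | bedgraph); any others are
    kept as display attributes. The track type defaults to bed density unless
    the file ends in .bedgraph/.bg or ty:bedgraph is given.
    """
    specs: list[TrackSpec] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise InputError(
                    f"{path}:{lineno}: expected path<TAB>name[<TAB>tags]"
                )
            fpath, name = cols[0], cols[1]
            tags = _parse_tag_string(cols[2]) if len(cols) > 2 else {}
            bin_size = DEFAULT_BIN_SIZE
            if "bw" in tags:
                try:
                    bin_size = int(tags.pop("bw"))
                except ValueError:
                    raise InputError(
                        f"{path}:{lineno}: non-integer bin width"
                    ) from None
            ty = tags.pop("ty", None)
            if ty is None:
                lower = fpath.lower()
                ty = (
                    "bedgraph"
                    if lower.endswith((".bedgraph", ".bg"))
                    else "bed"
                )
            ttype = "bedgraph_value" if ty == "bedgraph" else "bed_density"
            specs.append(TrackSpec(name, fpath, ttype, bin_size, tags))
    return specs


def read_chromosome_order(path: str | Path) -> list[str]:
    """Read the optional chromosome-order file: one group-leader chromosome
    name (first genome's namespace) per line."""
    names: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                names.append(line)
    return names
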