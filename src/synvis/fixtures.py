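"""Synthetic multi-genome fixtures with planted ground truth.

The generator emits everything the tool reads — per-genome length tables
(optionally tiny FASTAs), per-pair annotation files in both the SyRI
dialect and BEDPE, a marker BED, a density-track BED and the config
tables — for a chain of genomes carrying planted inversions,
translocations and duplications. Alongside the files it returns the exact
truth: the block list per pair, the planted chromosome-homology mapping,
and per-pair SYN backbones for zoom oracles.

Construction walks each reference chromosome left to right, alternating
SYN tiles and planted events; query coordinates accumulate with an
optional per-step dilation factor, so SYN blocks are collinear and
disjoint on both sides (the property the zoom oracle relies on).
Translocated segments leave an unaligned slot at their original query
position and reappear at a seeded-random location (another chromosome for
inter-chromosomal translocations). Sequences in emitted FASTAs are all
"A": only lengths matter downstream.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .exceptions import InputError
from .formats_io import AlignmentBlock, ChromosomeRecord
from .model import GenomeSpec, PairwiseComparison
from .zoom import interpolate

#: Planted event sizes are drawn uniformly from this fraction range of the
#: chromosome length: visible at figure scale, small enough to tile many.
DEFAULT_EVENT_SIZE_FRAC = (0.01, 0.05)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture."""

    n_genomes: int = 3
    chroms_per_genome: int = 2
    chrom_length: int = 100_000
    n_inversions: int = 1
    n_translocations: int = 1
    n_duplications: int = 1
    n_inter_translocations: int = 0
    n_small_variants: int = 0
    rename_chromosomes: bool = False
    dilation: float = 1.0
    event_size_frac: tuple[float, float] = DEFAULT_EVENT_SIZE_FRAC
    write_fasta: bool = False
    n_markers: int = 2
    n_track_features: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise InputError("fixture needs >= 2 genomes")
        if self.chroms_per_genome < 1 or self.chrom_length < 100:
            raise InputError("fixture needs >= 1 chromosome of >= 100 bp")
        for n in (self.n_inversions, self.n_translocations,
                  self.n_duplications, self.n_inter_translocations,
                  self.n_small_variants):
            if n < 0:
                raise InputError("event counts must be >= 0")
        if self.n_inter_translocations and self.chroms_per_genome < 2:
            raise InputError(
                "inter-chromosomal translocations need >= 2 chromosomes"
            )


@dataclass
class FixtureTruth:
    """Ground truth of one generated fixture."""

    genomes: list[GenomeSpec]
    blocks: list[list[AlignmentBlock]]          # one list per adjacent pair
    homology: list[dict]                        # genome name -> chrom, per group
    event_counts: list[dict]                    # per pair: type -> planted count
    inter_events: list[int]                     # per pair: inter-chromosomal count


@dataclass
class FixtureBundle:
    """Paths of every emitted file."""

    root: Path
    genomes_config: Path
    length_tables: list[Path] = field(default_factory=list)
    fastas: list[Path] = field(default_factory=list)
    syri_files: list[Path] = field(default_factory=list)
    bedpe_files: list[Path] = field(default_factory=list)
    markers_bed: Path | None = None
    track_bed: Path | None = None
    tracks_config: Path | None = None


def _place_events(
    rng: random.Random, length: int, sizes: list[int]
) -> list[tuple[int, int]]:
    """Place events of the given sizes non-overlapping on [1, length],
    keeping at least 1 bp of SYN tile between and around events."""
    n = len(sizes)
    needed = sum(sizes) + (n + 1)  # 1 bp minimum gap around every event
    if needed > length:
        raise InputError(
            f"planted events ({sum(sizes)} bp in {n} events) do not fit on a "
            f"{length} bp chromosome"
        )
    free = length - sum(sizes) - (n + 1)
    cuts = sorted(rng.randint(0, free) for _ in range(n))
    # each event starts after a gap of 1 bp plus its share of the slack
    placements = []
    prev_cut = 0
    cursor = 1
    for size, cut in zip(sizes, cuts):
        gap = 1 + (cut - prev_cut)
        start = cursor + gap
        placements.append((start, start + size - 1))
        cursor = start + size
        prev_cut = cut
    return placements


def _build_pair(
    rng: random.Random,
    spec: FixtureSpec,
    ref_chroms: list[ChromosomeRecord],
    qry_names: list[str],
    pair_idx: int,
) -> tuple[list[AlignmentBlock], list[ChromosomeRecord], dict, int]:
    """Plant one pair's blocks. Returns (blocks, qry chromosomes,
    ref->qry chromosome homology, inter-chromosomal event count)."""
    n_chrom = len(ref_chroms)
    events: list[tuple[str, int]] = (
        [("INV", i) for i in range(spec.n_inversions)]
        + [("TRANS", i) for i in range(spec.n_translocations)]
        + [("ITX", i) for i in range(spec.n_inter_translocations)]
        + [("DUP", i) for i in range(spec.n_duplications)]
    )
    per_chrom: list[list[str]] = [[] for _ in range(n_chrom)]
    for etype, _ in events:
        per_chrom[rng.randrange(n_chrom)].append(etype)

    blocks: list[AlignmentBlock] = []
    qry_lengths: list[int] = []
    deferred: list[tuple[str, int, str, int, int, int, str]] = []
    # (etype, ref_chrom_idx, ref_chrom, rs, re, qlen, block_id)
    counter = 0

    for ci, ref_rec in enumerate(ref_chroms):
        etypes = per_chrom[ci]
        lo_f, hi_f = spec.event_size_frac
        sizes = [
            max(2, int(rng.uniform(lo_f, hi_f) * ref_rec.length))
            for _ in etypes
        ]
        placements = _place_events(rng, ref_rec.length, sizes)
        # walk: alternating SYN tiles and events, accumulating qry coords
        boundaries = []
        cursor = 1
        for (es, ee), etype in zip(placements, etypes):
            if es > cursor:
                boundaries.append(("SYN", cursor, es - 1))
            boundaries.append((etype, es, ee))
            cursor = ee + 1
        if cursor <= ref_rec.length:
            boundaries.append(("SYN", cursor, ref_rec.length))

        qcursor = 1
        for etype, a, b in boundaries:
            seg_len = b - a + 1
            qlen = max(1, round(seg_len * spec.dilation))
            qa, qb = qcursor, qcursor + qlen - 1
            counter += 1
            bid = f"P{pair_idx}_{etype}{counter}"
            if etype == "SYN":
                blocks.append(AlignmentBlock(
                    ref_rec.name, a, b, qry_names[ci], qa, qb, "SYN", bid))
            elif etype == "INV":
                blocks.append(AlignmentBlock(
                    ref_rec.name, a, b, qry_names[ci], qa, qb, "INV", bid))
            elif etype == "DUP":
                blocks.append(AlignmentBlock(
                    ref_rec.name, a, b, qry_names[ci], qa, qb, "DUP", bid))
            else:  # TRANS / ITX: destination chosen after lengths are known
                deferred.append((etype, ci, ref_rec.name, a, b, qlen, bid))
            qcursor = qb + 1
        qry_lengths.append(qcursor - 1)

    for etype, ci, ref_chrom, a, b, qlen, bid in deferred:
        if etype == "ITX":
            choices = [j for j in range(n_chrom) if j != ci]
            tj = rng.choice(choices)
        else:
            tj = ci
        limit = qry_lengths[tj] - qlen
        qs = rng.randint(1, max(1, limit))
        blocks.append(AlignmentBlock(
            ref_chrom, a, b, qry_names[tj], qs, qs + qlen - 1, "TRANS", bid))

    qry_chroms = [
        ChromosomeRecord(qry_names[i], qry_lengths[i]) for i in range(n_chrom)
    ]
    homology = {ref_chroms[i].name: qry_names[i] for i in range(n_chrom)}
    n_inter = sum(1 for e in deferred if e[0] == "ITX")
    return blocks, qry_chroms, homology, n_inter


def build_truth(spec: FixtureSpec) -> FixtureTruth:
    """Construct the in-memory fixture (genomes, blocks, homology) without
    touching the filesystem."""
    rng = random.Random(spec.seed)
    first_chroms = [
        ChromosomeRecord(f"chr{j + 1:02d}", spec.chrom_length)
        for j in range(spec.chroms_per_genome)
    ]
    genomes = [GenomeSpec("g1", tuple(first_chroms))]
    blocks_per_pair: list[list[AlignmentBlock]] = []
    homology_maps: list[dict] = []
    event_counts: list[dict] = []
    inter_events: list[int] = []

    ref_chroms = first_chroms
    for k in range(spec.n_genomes - 1):
        qname = f"g{k + 2}"
        if spec.rename_chromosomes:
            qry_names = [
                f"{qname}_c{j + 1:02d}" for j in range(spec.chroms_per_genome)
            ]
        else:
            qry_names = [c.name for c in ref_chroms]
        blocks, qry_chroms, homology, n_inter = _build_pair(
            rng, spec, ref_chroms, qry_names, k
        )
        if spec.rename_chromosomes:
            # scramble the query genome's declared chromosome order so the
            # grouping cannot succeed by position alone
            order = list(range(len(qry_chroms)))
            rng.shuffle(order)
            declared = [qry_chroms[i] for i in order]
        else:
            declared = qry_chroms
        genomes.append(GenomeSpec(qname, tuple(declared)))
        blocks_per_pair.append(blocks)
        homology_maps.append(homology)
        counts: dict = {}
        for b in blocks:
            counts[b.btype] = counts.get(b.btype, 0) + 1
        event_counts.append(counts)
        inter_events.append(n_inter)
        ref_chroms = qry_chroms

    # compose per-pair homologies into groups anchored at genome 1
    groups = []
    for chrom in first_chroms:
        members = {"g1": chrom.name}
        current = chrom.name
        for k, hmap in enumerate(homology_maps):
            current = hmap[current]
            members[f"g{k + 2}"] = current
        groups.append(members)

    return FixtureTruth(genomes, blocks_per_pair, groups,
                        event_counts, inter_events)


def comparisons_from_truth(truth: FixtureTruth) -> list[PairwiseComparison]:
    return [
        PairwiseComparison(
            truth.genomes[k].name, truth.genomes[k + 1].name,
            tuple(truth.blocks[k]),
        )
        for k in range(len(truth.blocks))
    ]


# ---------------------------------------------------------------------------
# file emission


def _write_syri(path: Path, blocks, rng: random.Random, n_small: int) -> None:
    lines = []
    for b in blocks:
        rc = b.ref_chrom or "-"
        qc = b.qry_chrom or "-"
        lines.append("\t".join([
            rc, str(b.ref_start) if b.ref_chrom else "-",
            str(b.ref_end) if b.ref_chrom else "-", "-", "-",
            qc, str(b.qry_start) if b.qry_chrom else "-",
            str(b.qry_end) if b.qry_chrom else "-",
            b.source_id or "-", "-", b.btype, "-",
        ]))
    syn_blocks = [b for b in blocks if b.btype == "SYN"]
    for i in range(n_small):
        host = rng.choice(syn_blocks)
        pos = rng.randint(host.ref_start, host.ref_end)
        qpos = interpolate(pos, host.ref_start, host.ref_end,
                           host.qry_start, host.qry_end)
        vtype = rng.choice(("SNP", "INS", "DEL"))
        lines.insert(rng.randint(0, len(lines)), "\t".join([
            host.ref_chrom, str(pos), str(pos), "A", "T",
            host.qry_chrom, str(qpos), str(qpos),
            f"{vtype}{i}", host.source_id or "SYN0", vtype, "-",
        ]))
    path.write_text("\n".join(lines) + "\n")


def _write_bedpe(path: Path, blocks) -> None:
    lines = []
    for b in blocks:
        rc = b.ref_chrom or "."
        qc = b.qry_chrom or "."
        lines.append("\t".join([
            rc, str(b.ref_start - 1) if b.ref_chrom else "0",
            str(b.ref_end) if b.ref_chrom else "0",
            qc, str(b.qry_start - 1) if b.qry_chrom else "0",
            str(b.qry_end) if b.qry_chrom else "0",
            b.btype, b.source_id or ".",
        ]))
    path.write_text("\n".join(lines) + "\n")


def generate_fixture(
    spec: FixtureSpec, outdir: str | Path
) -> tuple[FixtureBundle, FixtureTruth]:
    """Emit the full file bundle for a fixture and return it with its truth.

    Running twice with the same spec produces byte-identical files.
    """
    truth = build_truth(spec)
    rng = random.Random(spec.seed + 1)  # file-salt stream, separate from truth
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    bundle = FixtureBundle(root=outdir, genomes_config=outdir / "genomes.tsv")
    config_rows = []
    for genome in truth.genomes:
        table = outdir / f"{genome.name}.chrlen.tsv"
        table.write_text(
            "".join(f"{c.name}\t{c.length}\n" for c in genome.chromosomes)
        )
        bundle.length_tables.append(table)
        listed = table
        if spec.write_fasta:
            fasta = outdir / f"{genome.name}.fa"
            with open(fasta, "w") as fh:
                for c in genome.chromosomes:
                    fh.write(f">{c.name}\n")
                    seq = "A" * c.length
                    for i in range(0, len(seq), 60):
                        fh.write(seq[i:i + 60] + "\n")
            bundle.fastas.append(fasta)
            listed = fasta
        # paths relative to the config file keep bundles byte-reproducible
        config_rows.append(f"{listed.name}\t{genome.name}\tlw:1.5;lc:#000000")
    bundle.genomes_config.write_text("\n".join(config_rows) + "\n")

    for k, blocks in enumerate(truth.blocks):
        pair = f"{truth.genomes[k].name}_{truth.genomes[k + 1].name}"
        syri = outdir / f"{pair}.syri.tsv"
        bedpe = outdir / f"{pair}.bedpe"
        _write_syri(syri, blocks, rng, spec.n_small_variants)
        _write_bedpe(bedpe, blocks)
        bundle.syri_files.append(syri)
        bundle.bedpe_files.append(bedpe)

    if spec.n_markers:
        rows = []
        for i in range(spec.n_markers):
            genome = truth.genomes[rng.randrange(len(truth.genomes))]
            chrom = genome.chromosomes[rng.randrange(len(genome.chromosomes))]
            pos = rng.randint(1, chrom.length)
            rows.append(
                f"{chrom.name}\t{pos - 1}\t{pos}\t{genome.name}"
                f"\tmt:v;mc:black;ms:6;tt:M{i + 1}"
            )
        bundle.markers_bed = outdir / "markers.bed"
        bundle.markers_bed.write_text("\n".join(rows) + "\n")

    if spec.n_track_features:
        g1 = truth.genomes[0]
        rows = []
        for _ in range(spec.n_track_features):
            chrom = g1.chromosomes[rng.randrange(len(g1.chromosomes))]
            pos = rng.randint(1, chrom.length - 1)
            rows.append(f"{chrom.name}\t{pos - 1}\t{pos + 1}")
        bundle.track_bed = outdir / "features.bed"
        bundle.track_bed.write_text("\n".join(rows) + "\n")
        bundle.tracks_config = outdir / "tracks.tsv"
        bin_size = max(1, spec.chrom_length // 20)
        bundle.tracks_config.write_text(
            f"{bundle.track_bed.name}\tfeatures\tbw:{bin_size}\n"
        )
    return bundle, truth


# ---------------------------------------------------------------------------
# test oracle for zoom


def oracle_map_region(
    region: tuple[str, int, int],
    blocks,
    direction: str = "ref2qry",
) -> tuple[str, int, int] | None:
    """Definitional per-base zoom oracle.

    Builds the explicit base-to-base correspondence from the SYN blocks,
    maps every base of the region that any block covers, and returns the
    target chromosome with the (min, max) of the images — or None when no
    base of the region is covered. Intended for small comparisons only.
    """
    chrom, start, end = region
    images: list[int] = []
    target_chrom = None
    for b in blocks:
        if b.btype != "SYN":
            continue
        if direction == "ref2qry":
            sc, s0, s1 = b.ref_chrom, b.ref_start, b.ref_end
            tc, t0, t1 = b.qry_chrom, b.qry_start, b.qry_end
        else:
            sc, s0, s1 = b.qry_chrom, b.qry_start, b.qry_end
            tc, t0, t1 = b.ref_chrom, b.ref_start, b.ref_end
        if sc != chrom:
            continue
        lo, hi = max(start, s0), min(end, s1)
        for x in range(lo, hi + 1):
            images.append(interpolate(x, s0, s1, t0, t1, b.qry_inverted))
            target_chrom = tc
    if not images:
        return None
    return (target_chrom, min(images), max(images))
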