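"""Genomes, pairwise comparisons and the comparison chain.

The only comparison topology supported is a path: to draw genomes A, B, C
in that order the caller supplies A-vs-B and B-vs-C. Validation is
exhaustive-then-fail: every inconsistency found in one pass is reported in
a single error so input files can be fixed in one iteration.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .exceptions import ValidationError
from .formats_io import BLOCK_TYPES, AlignmentBlock, ChromosomeRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomeSpec:
    """A named genome: ordered chromosomes plus display attributes."""

    name: str
    chromosomes: tuple[ChromosomeRecord, ...]
    display: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("genome name must be non-empty")
        if not self.chromosomes:
            raise ValidationError(f"genome {self.name!r} has no chromosomes")
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)


@dataclass(frozen=True)
class PairwiseComparison:
    """All structural annotation blocks linking one reference genome to one
    query genome (the adjacent pair in the chain)."""

    ref_genome: str
    qry_genome: str
    blocks: tuple[AlignmentBlock, ...]

    def __post_init__(self) -> None:
        if self.ref_genome == self.qry_genome:
            raise ValidationError(
                f"comparison maps genome {self.ref_genome!r} onto itself"
            )
        object.__setattr__(self, "blocks", tuple(self.blocks))


@dataclass(frozen=True)
class ComparisonChain:
    """An ordered list of N genomes plus one comparison per adjacent pair."""

    genomes: tuple[GenomeSpec, ...]
    comparisons: tuple[PairwiseComparison, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genomes", tuple(self.genomes))
        object.__setattr__(self, "comparisons", tuple(self.comparisons))

    @property
    def genome_names(self) -> list[str]:
        return [g.name for g in self.genomes]

    def genome(self, name: str) -> GenomeSpec:
        for g in self.genomes:
            if g.name == name:
                return g
        raise ValidationError(f"no genome named {name!r} in the chain")

    def genome_index(self, name: str) -> int:
        for i, g in enumerate(self.genomes):
            if g.name == name:
                return i
        raise ValidationError(f"no genome named {name!r} in the chain")


def _check_side(
    genome: GenomeSpec,
    chrom: str,
    start: int,
    end: int,
    source_id: str,
    problems: list[str],
) -> None:
    if not chrom:
        return
    lengths = genome.chrom_lengths
    if chrom not in lengths:
        problems.append(
            f"genome {genome.name!r}: chromosome {chrom!r} named in "
            f"record {source_id or '<unnamed>'} is absent from the genome"
        )
    elif end > lengths[chrom]:
        problems.append(
            f"genome {genome.name!r}: record {source_id or '<unnamed>'} "
            f"interval {start}-{end} exceeds {chrom!r} length {lengths[chrom]}"
        )


def build_chain(genomes, comparisons) -> ComparisonChain:
    """Assemble and validate a comparison chain.

    Checks: N >= 2 genomes with unique names; exactly N-1 comparisons, each
    linking the adjacent genome pair by name; every block's chromosomes exist
    in the respective genome and its intervals fit within the declared
    chromosome lengths. All violations are collected and reported together.
    """
    genomes = tuple(genomes)
    comparisons = tuple(comparisons)
    if len(genomes) < 2:
        raise ValidationError(f"need at least 2 genomes, got {len(genomes)}")
    names = [g.name for g in genomes]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate genome names: {', '.join(dupes)}")
    if len(comparisons) != len(genomes) - 1:
        raise ValidationError(
            f"{len(genomes)} genomes require {len(genomes) - 1} pairwise "
            f"comparisons, got {len(comparisons)}"
        )

    problems: list[str] = []
    for k, comp in enumerate(comparisons):
        ref, qry = genomes[k], genomes[k + 1]
        if comp.ref_genome != ref.name or comp.qry_genome != qry.name:
            problems.append(
                f"comparison {k} links {comp.ref_genome!r}->{comp.qry_genome!r} "
                f"but the chain expects {ref.name!r}->{qry.name!r}"
            )
            continue
        for block in comp.blocks:
            _check_side(
                ref, block.ref_chrom, block.ref_start, block.ref_end,
                block.source_id, problems,
            )
            _check_side(
                qry, block.qry_chrom, block.qry_start, block.qry_end,
                block.source_id, problems,
            )
    if problems:
        raise ValidationError(
            f"{len(problems)} validation problem(s):\n  "
            + "\n  ".join(problems)
        )
    chain = ComparisonChain(genomes, comparisons)
    log.info(
        "validated chain of %d genomes (%s)",
        len(genomes), " -> ".join(names),
    )
    return chain


def summarize_chain(chain: ComparisonChain) -> list[dict[str, int]]:
    """Count blocks by annotation type for every comparison; the counts of
    each comparison partition its block list."""
    summaries: list[dict[str, int]] = []
    for comp in chain.comparisons:
        counts = Counter(b.btype for b in comp.blocks)
        summary = {t: counts.get(t, 0) for t in sorted(BLOCK_TYPES)}
        summaries.append(summary)
        log.info(
            "%s vs %s: %s",
            comp.ref_genome, comp.qry_genome,
            ", ".join(f"{t}={n}" for t, n in summary.items() if n),
        )
    return summaries
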