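"""Chromosome homology grouping.

Homology between the chromosomes of adjacent genomes is inferred from
shared syntenic length: chromosome r of the reference and q of the query
are candidate homologs weighted by the total SYN base pairs (reference
side) aligning them. A greedy one-to-one assignment on descending weight
resolves the matching — chromosome-scale synteny matrices are strongly
diagonal-dominant, where greedy coincides with the optimal assignment.
Per-pair matchings are then composed along the chain into groups.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .exceptions import ValidationError
from .model import ComparisonChain, PairwiseComparison

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HomologyGroup:
    """One set of homologous chromosomes: at most one per genome."""

    members: dict  # genome name -> chromosome name
    order_index: int

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("homology group must have >= 1 member")


def synteny_weights(comparison: PairwiseComparison) -> dict[tuple[str, str], int]:
    """Total SYN base pairs (reference side) per (ref chrom, qry chrom)."""
    weights: dict[tuple[str, str], int] = defaultdict(int)
    for block in comparison.blocks:
        if block.btype == "SYN":
            weights[(block.ref_chrom, block.qry_chrom)] += block.ref_span
    return dict(weights)


def pair_homology(comparison: PairwiseComparison) -> dict[str, str]:
    """One-to-one map of reference chromosomes to their query homologs.

    Greedy assignment on descending syntenic weight, ties broken by
    lexicographic (ref, qry) chromosome name. Chromosomes with zero
    syntenic bases stay unmatched (reported at DEBUG level).
    """
    weights = synteny_weights(comparison)
    if not weights:
        raise ValidationError(
            f"no syntenic backbone between {comparison.ref_genome!r} and "
            f"{comparison.qry_genome!r}: comparison has no SYN blocks"
        )
    matching: dict[str, str] = {}
    used_qry: set[str] = set()
    for (r, q), _w in sorted(weights.items(), key=lambda kv: (-kv[1], kv[0])):
        if r not in matching and q not in used_qry:
            matching[r] = q
            used_qry.add(q)
    unmatched_r = {r for r, _ in weights} - set(matching)
    unmatched_q = {q for _, q in weights} - used_qry
    if unmatched_r or unmatched_q:
        log.debug(
            "%s vs %s: unmatched chromosomes ref=%s qry=%s",
            comparison.ref_genome, comparison.qry_genome,
            sorted(unmatched_r), sorted(unmatched_q),
        )
    return matching


def chain_homology(
    chain: ComparisonChain, order: list[str] | None = None
) -> list[HomologyGroup]:
    """Group homologous chromosomes across the whole chain.

    Each chromosome of the first genome seeds one group, extended through
    the composed per-pair matchings; a broken link truncates the group with
    a warning. Chromosomes of later genomes never reached by any matching
    become singleton groups so that every chromosome of every genome lands
    in exactly one group. Group order follows the first genome's chromosome
    order, or the explicit ``order`` list of leader chromosome names.
    """
    matchings = [pair_homology(c) for c in chain.comparisons]
    names = chain.genome_names

    leaders = [c.name for c in chain.genomes[0].chromosomes]
    if order is not None:
        unknown = [c for c in order if c not in leaders]
        if unknown:
            raise ValidationError(
                "chromosome-order file names unknown chromosome(s) of "
                f"{names[0]!r}: {', '.join(unknown)}"
            )
        leaders = list(order) + [c for c in leaders if c not in order]

    groups: list[HomologyGroup] = []
    placed: set[tuple[str, str]] = set()
    for leader in leaders:
        members = {names[0]: leader}
        current = leader
        for k, matching in enumerate(matchings):
            nxt = matching.get(current)
            if nxt is None:
                log.warning(
                    "homology group of %s:%s truncated: no syntenic match "
                    "beyond genome %s", names[0], leader, names[k],
                )
                break
            members[names[k + 1]] = nxt
            current = nxt
        groups.append(HomologyGroup(members, len(groups)))
        placed.update(members.items())

    # every chromosome not reached from genome 1 becomes a singleton group
    for genome in chain.genomes[1:]:
        for chrom in genome.chromosomes:
            if (genome.name, chrom.name) not in placed:
                log.warning(
                    "chromosome %s:%s has no homolog chain back to %s; "
                    "drawn as a bare chromosome line",
                    genome.name, chrom.name, names[0],
                )
                groups.append(
                    HomologyGroup({genome.name: chrom.name}, len(groups))
                )
                placed.add((genome.name, chrom.name))
    return groups


def group_lookup(groups: list[HomologyGroup]) -> dict[tuple[str, str], int]:
    """Map (genome, chromosome) to its group's order index."""
    lookup: dict[tuple[str, str], int] = {}
    for g in groups:
        for genome, chrom in g.members.items():
            lookup[(genome, chrom)] = g.order_index
    return lookup
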