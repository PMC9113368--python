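# synvis

Visualize structural similarities and rearrangements between multiple
genome assemblies.

Chromosome-level, haplotype-resolved assemblies make it possible to
compare several genomes of one species directly. Between any two such
genomes most of the sequence is **syntenic** — conserved in content,
order and orientation — and everything else is a structural
rearrangement (SR): an inversion, a translocation (intra- or
inter-chromosomal) or a duplication. `synvis` turns the pairwise
synteny/SR annotations produced by tools such as SyRI, MUM&Co or
assemblytics into a multi-genome ribbon figure, and can zoom in on any
region of any genome.

## The model

To draw genomes `G1, G2, …, GN` in that order, `synvis` needs only the
N−1 **adjacent pairwise comparisons** `G1 vs G2`, `G2 vs G3`, … — a path
topology, not an all-vs-all matrix. Every computation is built from the
atom of those files, the *alignment block*: an interval on a reference
chromosome linked to an interval on a query chromosome with an
annotation type in `{SYN, INV, TRANS, INVTR, DUP, INVDP, NOTAL}`.

Three algorithms operate on the blocks:

- **Homology grouping.** For each adjacent pair, the weight
  `M[r][q] = Σ SYN base pairs` aligning ref chromosome `r` to query
  chromosome `q` is assigned greedily (descending weight, one-to-one).
  The per-pair matchings are composed along the chain, so each
  chromosome of `G1` seeds one homology group drawn as a vertically
  aligned column.
- **Region lift-over (zoom).** A requested window `g:chrom:start-end`
  is propagated outward through the chain using only the SYN blocks
  (the *syntenic backbone*). Each endpoint is mapped by within-block
  linear interpolation with floor rounding; an endpoint in a gap
  between blocks snaps to the nearest overlapping block edge. The
  result per genome is the span `(min, max)` of the two mapped
  endpoints. Blocks, markers and tracks are then filtered to the
  selected windows (a ribbon survives only if *both* of its anchors
  overlap their windows).
- **Layout.** *Stacked mode* places one genome per row with homology
  groups as left-aligned columns (best for synteny and
  intra-chromosomal SRs; inter-chromosomal blocks are skipped with a
  logged count). *itx mode* concatenates each genome's chromosomes on
  one row so inter-chromosomal translocations and duplications become
  drawable ribbons. Inverted classes (`INV`, `INVTR`, `INVDP`) draw as
  crossed ribbons; `NOTAL` stretches are gaps, not ribbons.

Output is PDF, PNG or SVG; SVG rendering is byte-deterministic.

## Worked example

The package ships a fixture generator that emits every input format with
planted, known rearrangements:

```python
from synvis.fixtures import FixtureSpec, generate_fixture
generate_fixture(FixtureSpec(n_genomes=3, chroms_per_genome=2,
                             chrom_length=2_000_000, n_inversions=2,
                             n_translocations=1, n_duplications=1,
                             n_inter_translocations=1, seed=7), "demo")
```

```sh
synvis --genomes demo/genomes.tsv \
       --sr demo/g1_g2.syri.tsv --sr demo/g2_g3.syri.tsv \
       --markers demo/markers.bed --tracks demo/tracks.tsv -o demo.svg
```

prints

```
INFO parsed 12 blocks from demo/g1_g2.syri.tsv
INFO parsed 12 blocks from demo/g2_g3.syri.tsv
INFO validated chain of 3 genomes (g1 -> g2 -> g3)
INFO g1 vs g2: DUP=1, INV=2, SYN=7, TRANS=2
INFO g2 vs g3: DUP=1, INV=2, SYN=7, TRANS=2
INFO stacked layout skipped 2 inter-chromosomal block(s); use itx mode to draw them
INFO layout: 6 segments, 22 ribbons
INFO wrote demo.svg (svg, 22 ribbons, 6 segments)
```

Each pair carries 7 syntenic tiles plus the 5 planted events (the one
inter-chromosomal translocation is skipped per row in stacked mode —
rerun with `--itx` to draw those 2 ribbons too). The 6 segments are the
2 chromosomes × 3 genomes; markers and the feature-density track are
drawn above the top genome.

Zooming propagates a window of the *middle* genome to both neighbours
through the syntenic backbone and filters everything to the result:

```sh
synvis --genomes demo/genomes.tsv \
       --sr demo/g1_g2.syri.tsv --sr demo/g2_g3.syri.tsv \
       --reg g2:chr01:250000-1250000 -o zoom.svg
```

```
INFO zoom window g2: chr01:250000-1250000
INFO zoom window g3: chr01:345130-1250000
INFO zoom window g1: chr01:250000-1250000
INFO zoom filter g1 vs g2: kept 4 of 12 blocks
INFO zoom filter g2 vs g3: kept 3 of 12 blocks
INFO layout: 3 segments, 7 ribbons
INFO wrote zoom.svg (svg, 7 ribbons, 3 segments)
```

(`g3`'s window starts at 345 130 rather than 250 000 because a planted
translocation removed part of the region from `g3`'s syntenic backbone,
so the window snaps to the nearest syntenic edge.)

Useful flags: `--bedpe` (BEDPE instead of SyRI dialect, mixable
per pair), `--itx`, `--chrord FILE` (group order), `-v` (vertical),
`--nosyn/--noinv/--notr/--nodup` (hide a ribbon class), `-W/-H/-d`
(figure size/resolution), `-f pdf|png|svg`.

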