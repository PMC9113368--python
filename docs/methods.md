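# Methods

This note documents the models, conventions and numerical choices behind
`synvis`, and what the synthetic fixtures do and do not demonstrate.

## Input model and coordinate conventions

All computation operates on *alignment blocks*: one interval in a
reference-side genome linked to one interval in a query-side genome,
typed as `SYN`, `INV`, `TRANS`, `INVTR`, `DUP`, `INVDP` or `NOTAL`.
Internally every coordinate is **1-based, inclusive on both ends**,
matching the SyRI annotation dialect; BEDPE, BED and bedGraph inputs
(0-based half-open) are converted once, at the parser boundary. The SyRI
dialect is fixed at 12 columns (ref chrom/start/end, two ignored
sequence columns, qry chrom/start/end, id, parent, type, copy status);
only top-level structural records (parent `-`) are kept, so alignment
children (`SYNAL`, …) and local variants (`SNP`, `INS`, `DEL`, `HDR`,
`CPG`, `CPL`, `TDM`) are dropped on read. Query intervals supplied in
descending order are normalized (start ≤ end) with an orientation flag
rather than rejected, since both sign conventions occur in the wild.
`NOTAL` records are retained single-sided and drawn as axis gaps, never
ribbons.

Because parsing already ignores small variants, pre-filtering a file
with `filter_small_variants` changes runtime and file size only: the
parsed structural block list is provably identical before and after
(asserted by tests on files salted with 10,000 SNP/indel rows).

The only supported topology is a path: genomes in plotting order with
one comparison per adjacent pair. Reversed comparisons (B-vs-A supplied
for the A→B slot) are rejected, not silently flipped — flipping would
have to guess which file was reversed. Validation collects *all*
violations (unknown chromosomes, out-of-range intervals, pair/name
mismatches) in one pass before aborting, so input files can be fixed in
one iteration. Chromosome-name matching is exact and case-sensitive;
case-folding would mask real FASTA/annotation mismatches.

## Homology grouping

The matching weight between ref chromosome `r` and qry chromosome `q`
is the total SYN base pairs on the reference side (the two sides differ
only by indel content, so one side suffices). Assignment is greedy on
descending weight with lexicographic `(r, q)` tie-breaks, one-to-one.
Greedy rather than Hungarian-optimal is deliberate: chromosome-scale
synteny matrices are strongly diagonal-dominant, a regime where greedy
provably attains the optimum, and greedy decisions are trivially
auditable from the log. The test suite carries a brute-force
max-weight-assignment oracle over all 5! permutations of 5×5
row/column-dominant matrices documenting the agreement.

Groups are seeded by genome 1's chromosomes (in file order, or the
order given by an explicit one-name-per-line order file) and extended by
composing the per-pair matchings. A broken link truncates the group with
a warning; chromosomes never reached from genome 1 become singleton
groups so every chromosome of every genome lands in exactly one group —
they are drawn as bare lines instead of being silently dropped, since a
chromosome without a homolog usually indicates an assembly problem worth
seeing. No auto-flip is attempted for chromosomes that are mostly
inverted relative to their homolog; they simply draw as large crossed
ribbons.

## Region lift-over (zoom)

Only `SYN` blocks participate in propagation; rearranged blocks are
passengers. A window is propagated outward from its origin genome, one
adjacent comparison at a time, until the chain ends. In one step, the
two window endpoints are mapped through the SYN blocks that link the
window's chromosome to its matched homolog:

- an endpoint inside a block maps by linear interpolation with **floor
  rounding**: `t = t0 + ⌊(x − s0)(t1 − t0)/(s1 − s0)⌋` (reversed for
  inverted blocks). Floor interpolation makes the per-base map integer,
  monotone within a block, and exactly reproducible by an independent
  per-base oracle;
- an endpoint in an inter-block gap snaps to the nearest source edge
  among the blocks overlapping the window, and takes that edge's
  counterpart. Restricting to overlapping blocks yields the minimal
  homologous span and keeps endpoint mapping equal to the min/max of
  the per-base image on collinear backbones;
- the step result is the single span `(min, max)` of the two mapped
  endpoints, clipped to the chromosome. One contiguous span per genome
  (rather than a multi-interval set) is a deliberate simplification:
  each genome is drawn as one axis window, and local inversions inside
  the window are still drawn faithfully as crossed ribbons within it.

A window overlapping no SYN block is a hard error naming the genome
reached and the dead region — including the unaddressed corner case of
a request entirely inside an unaligned (`NOTAL`) stretch.

After propagation, a block is retained iff **both** its intervals
overlap their genomes' selected windows (a one-sided ribbon would exit
the canvas); survivors are coordinate-clipped to the windows, which
makes clipping idempotent. Markers are kept iff they overlap their
genome's window; track vectors are re-binned over the first genome's
window only.

## Layout and rendering

Geometry is computed in abstract figure units: 1 unit per megabase
horizontally, 1 unit per genome row vertically, genome 1 on top. Each
drawn chromosome is an `AxisSegment` carrying an affine base-pair → x
map; ribbon anchors are produced by that map, so inverting it recovers
the source block coordinates exactly (asserted by tests). Ribbons are
straight-sided quadrilaterals; the inverted classes swap the bottom
corners into a bow-tie. In stacked mode homology groups form
left-aligned columns and inter-chromosomal blocks are skipped with a
logged count; itx mode concatenates chromosomes per row (gap: 2% of the
longest genome) and draws every block type. Zoom combined with itx is
rejected rather than guessed — the two features answer different
questions and their composition has no obvious semantics. The vertical
flag is a draw-time coordinate swap of the same layout, keeping a
single layout code path.

Default ribbon colours: SYN grey, inversions orange, translocations
green, duplications steel blue, all overridable; NOTAL draws as an axis
interruption. Track histograms occupy one row each above genome 1, bar
heights normalized per track to the maximum inside the drawn window
(an all-zero track draws flat, no division by zero). Default track bin:
100 kb, appropriate for chromosome-scale figures and overridable per
track (`bw:` tag).

Rendering uses matplotlib's Agg/SVG backends. Ribbons are one
`PolyCollection` (one SVG path per ribbon, group id `ribbons`), axis
lines one `LineCollection` (group id `segments`), which makes the SVG
fully auditable: element census equals primitive census. Determinism is
by construction — no jitter, fixed colour tables, a pinned SVG id hash
salt and suppressed date metadata — so identical inputs give
byte-identical SVG. PDF/PNG are treated as opaque (existence and
non-emptiness only).

## Synthetic fixtures

The generator builds each pair by walking the reference chromosome left
to right, alternating SYN tiles with planted events placed
non-overlapping at seeded-random positions; query coordinates
accumulate with an optional per-step dilation factor. Consequently SYN
blocks are collinear and disjoint on both sides — the regime the zoom
oracle equivalence is stated for. Inversions and duplications sit in
their slots; translocations vacate their query slot and reappear at a
random position (another chromosome when inter-chromosomal). Event
sizes default to 1–5% of the chromosome so a handful of events stays
visible at figure scale; the full-scale fixture shrinks that fraction
to pack thousands of events per pair. Renaming mode gives each later
genome fresh, order-scrambled chromosome names so homology grouping
cannot succeed positionally. Emitted FASTAs are all-`A`: only lengths
matter downstream.

What the fixtures do **not** emulate: alignment noise and spurious
micro-blocks, unbalanced rearrangements, nested/overlapping events,
inverted SYN annotations, or NOTAL records. Passing tests therefore
demonstrate the correctness of the geometry, grouping, lift-over and
filtering machinery on clean annotations — not robustness to noisy
aligner output.

## Problem sizes used in checks

The automated checks run at sizes chosen to exercise every code path
while staying desk-scale: 50 seeded fixtures × 100 probe regions for
the zoom oracle (≤ 9 kb chromosomes, so the per-base oracle is cheap);
50 renamed fixtures for homology recovery; 50 random 200-block
comparisons for clip filtering; and one six-genome chain with ~10,000
blocks per pair (50,025 ribbons) taken from parsing through SVG
rendering, which completes in a few seconds.
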