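# Methods

`fgm` builds a BAC physical map from pooled-clone short-read sequencing and
integrates assembled sequence contigs onto it. This note records the models
behind each stage, the parameters that matter, and the design choices made
where the problem left room.

## The mapping model

The landmark of the map is the *feature sequence* (FS): the fixed-length
window (default 31 bp) immediately 5′ of a chosen prefix motif on either
strand. The default motifs are the palindromic restriction sites `GGATCC`
(BamHI) and `GAATTC` (EcoRI), giving an expected FS density of about one
per kb of random sequence; any motif set can be configured, and adding
motifs (e.g. `TCTAGA`, `CTCGAG`) raises landmark density proportionally —
useful when clones are small. Unlike restriction fingerprint bands, an FS
is an exact string: two clones share a landmark if and only if they share
the 31-mer, so overlap scoring runs at tolerance 0.

Clones are never sequenced individually. A library of `n` clones is placed
into `d` pool dimensions of `p` pools each; each clone's *signature* is the
set of `d` pools containing it. Two strategies:

* **solid** — clone index written as 3 digits base `p` over GF(p); each
  dimension is a linear form drawn from a planar arc (the moment curve
  `(1, t, t²)` plus `(0,0,1)`, plus the nucleus `(0,1,0)` in even
  characteristic). Any three arc forms are linearly independent, so two
  distinct clones share at most 2 pools and all signatures are distinct for
  `n ≤ p³`. The arc bounds the dimension count at `p+1` (odd `p`) or `p+2`
  (even `p`).
* **random** — `d` independent uniform partitions; no sharing bound.

Each pool is sequenced to a per-pool fold depth; pool reads are screened
into a pool FS-set and a pool K-set (canonical 31-mers). A clone's
*intersected* F-set is the intersection of its signature pools' filtered
F-sets; a *refinement* pass then inspects each element's full pool pattern:
the element is kept only if its *candidate* clones (those whose whole
signature it covers) number at most `m_max` and jointly explain every pool
it occurs in. Unexplained pools indicate error- or repeat-derived elements.

`m_max` guards against repeats shared by many clones, but it also bounds
the legitimate local clone multiplicity: in a library of coverage `c`,
around `c` clones overlap any locus, and all of them are candidates for the
locus's elements. `m_max` must therefore exceed the library coverage with
margin (default 4, suiting the sub-1X libraries used for parameter studies;
the end-to-end example at 4X uses 14).

## Simulator

The simulator generates every input with ground truth.

* **Genome** — i.i.d. uniform ACGT of requested length; a repeat fraction
  is realized by pasting copies of a fixed random unit (default 5 kb), so
  exact self-matches exist to stress landmark uniqueness.
* **Clone library** — insert sizes are truncated normal with mean 137.42 kb,
  sd 20.434 kb (variance 417.54 kb²) on [60, 300] kb, matching a real
  large-insert maize library; start positions are uniform. For megabase
  test genomes the whole law is rescaled proportionally (e.g. mean 50 kb),
  preserving the coefficient of variation and relative truncation.
* **Reads** — 100 bp paired-end reads from ~500 bp fragments (sd 30 bp).
  Fragments are drawn on the *circularized* insert: a BAC is a circular
  molecule, so coverage is uniform across the insert with no edge deficit.
  (A linear-interval model loses landmarks near insert ends, and the loss
  compounds across `d` pools; the circular model trades this for a handful
  of clone-specific junction landmarks, the analogue of real vector-insert
  junction sequences.) The per-pool pair count is
  `depth × pool_bases / (2R)`; fragments land in a clone with probability
  proportional to insert size.
* **Errors** — substitutions only (the dominant Illumina mode; for exact
  31-mer landmarks any error is equally destructive, so indels would add
  nothing). The per-cycle curve is `e(i) = exp(u + v·(i/(R−1))^g)` with
  `u, v` pinning `e(0) = 0.10%` and `e(R−1) = 16.91%` exactly and the warp
  exponent `g` solved numerically so the positional mean is exactly 2.46%
  (`g ≈ 1.50` at R = 100). The curve is monotone by construction and every
  read shares it; FASTQ qualities are `Q = −10·log₁₀ e`. What this model
  does *not* capture is read-to-read quality variability: real quality
  matrices mix near-perfect and poor reads at the same positional mean, and
  because the error-free-window probability is convex in the error rate,
  such variability *raises* mean window survival. Only the three printed
  statistics are reproduced here, so per-pool element retention after
  frequency filtering is a little lower than a full quality matrix would
  give (this is visible in the 20X intersected-detection check, which lands
  near 98–99% rather than above 99.6% at 9 dimensions).
* **Markers / assembled contigs** — markers are dropped every ~`spacing` bp
  (jittered ±30%) and hit every clone whose interval contains them.
  Assembler output is emulated by cutting the true genome at random
  breakpoints (configurable mean piece length) and discarding pieces under
  100 bp; this "fragmented truth" has no misassemblies or consensus errors,
  so anchoring tests measure placement logic, not assembly quality.

Every stochastic operation takes an explicit seed; the pipeline spawns
per-stage and per-pool seeds from one root seed, so pools and sweep cells
are reproducible in any execution order.

## Frequency filter

Pool F-sets are filtered by element count before intersection: elements
occurring at most `f` times (default 1) are removed. A substitution almost
always creates a never-seen-again window, so singletons are overwhelmingly
false; at 20X about 99% of false elements go while true elements (expected
count ≈ 13 per pool) are filtered with probability well under 1%. The
surviving false elements are identical substitutions recurring at the same
genomic site. The filter is a precision device for error-bearing data: on
error-free simulations it is disabled (`filter_freq: 0`), and depth-sweep
detection rates are likewise measured unfiltered, since the filter would
only discard once-seen true elements there.

## Physical map

FS strings are indexed to dense integer bands (lexicographic order, so
band files are reproducible byte-for-byte). Overlap between two clones
with `nL ≤ nH` bands sharing `m` of them is scored by the Sulston
coincidence probability at tolerance 0,

    q = 1 − (1 − 1/gellen)^nH,   score = Σ_{i=m}^{nL} C(nL, i) q^i (1−q)^(nL−i),

with `gellen` the number of indexed band types (the tolerance-0 chance of
two bands coinciding is exactly 1/gellen). The binomial upper tail is
`scipy.stats.binom.sf`; scores below double-precision underflow compare as
0, which is on the accept side of any practical cutoff. Contigs are
single-linkage components over pairs with score ≤ cutoff (default 1e-12;
clones under `min_bands` bands are excluded first). Within a component,
clones are ordered by spectral seriation — the Fiedler vector of the graph
Laplacian on shared-band counts — which recovers genomic order up to whole
reversal for interval-derived band data; the eigenvector sign is
canonicalized by clone id, and the order is cut wherever adjacent clones
hold no overlap edge. Nested clones have no band evidence of relative
order; their local order is id-deterministic but arbitrary.

A DQ-style pass then flags *Q-clones* — members sharing less than half
their bands with their overlapping neighbors — and any contig with more
than `max_q` (default 5) Q-clones is rebuilt at cutoffs tightened one
decade per step (up to 9 steps), detaching clones that no longer link.
This reproduces the intent of fingerprint-contig DQ splitting without its
exact internals, so contig counts are not expected to match any particular
historical run. Band lists round-trip through FPC-compatible `.size` files
(`<clone> <n>`, one band per line, `-1` terminator).

## Integration and anchoring

Every k-mer in a contig's member K-sets carries a *membership signature* —
the subset of members containing it. Maximal constant-coverage segments
have constant signatures, so grouping k-mers by signature yields the
contig's *bins* directly as intersections-minus-differences of overlapping
clones' K-sets; bins are ordered by the mean seriation rank of their
covering clones, and signature groups under `min_kmers` (default 5, noise
from residual false elements) are dropped.

Sequence contigs (≥100 bp) are allocated to the bin containing the largest
fraction of their k-mers, provided the fraction reaches `min_frac`; exact
ties stay unallocated — unplaced is preferred over misplaced. `min_frac`
defaults to 0.5; when bins are narrower than the sequences being placed
(desk-scale simulations with small clones) a lower threshold such as 0.3
is appropriate, since the argmax bin is still correct and only the margin
shrinks.

Paired-end links come from an exact-k-mer mapper: a mate maps to a
sequence contig when ≥90% of its strand-resolved k-mers hit that contig's
k-mer index uniquely (k-mers occurring in more than one contig are
excluded). Mates mapping to different contigs record a link with mapped
strands. A proper innie pair reads opposite strands of one fragment, so
mates with *opposite* mapped strands imply the two contigs already face
the same way; equal strands imply a flip. Links are honored only between
members of the same or adjacent bins, orientation is assigned by majority
strand pattern along edges in decreasing weight, strand-contradictory ties
drop the pair, and cycle-inconsistent lighter edges are ignored. Members
are joined in bin order with 100 N spacers (the inter-contig 50 kb gap
rule applies only on chromosomes). An externally produced link table can
be supplied in place of the internal mapper.

Physical contigs are placed on chromosomes by majority vote of their
member clones' marker hits; position is the median marker position, and
orientation is called only when at least two markers with distinct contig
ranks agree on a direction — single-marker contigs are placed with unknown
orientation, the classic source of whole-contig inversions. Contigs with
no markers stay unplaced. Pseudomolecules concatenate placed contigs in
position order with exactly 50 kb of N between them, described by an AGP
v2.1 file (gap type `contig`, linkage `no`).

Evaluation against simulator truth reports the anchored non-N fraction of
the genome, scaffold N50 (largest L with sequences ≥ L summing to half the
total), misplacements (assigned chromosome differs from the members' true
majority chromosome) and inversions (called orientation against the true
direction of the clone order).

## Desk-scale study conditions

Parameter studies run on 1 Mb genomes with a <0.5X library of eight clones
(insert law rescaled to a 50 kb mean) in solid pools of 16 per dimension —
16 pools per dimension matches the designs used throughout the source
experiments, and small pool counts (2–4 per dimension) are avoided because
overlapping clones' signature unions then saturate the pool space and make
every clone a refinement candidate. Depth sweeps use 3 replicate seeds.
The end-to-end worked example uses a 300 kb genome, 48 × 25 kb clones
(4X library), 6D × 16 pools at 10X error-free depth, four prefix motifs,
`m_max = 14`, `min_frac = 0.3`, markers every ~12 kb and 5 kb assembled
pieces; it anchors ≥80% of the genome with zero misplacements and zero
inversions. These sizes keep any single simulation under about a minute on
one core.

## Known limitations

* The error model is positionally exact but homogeneous across reads (see
  above); cloning bias, GC bias, chimeras and vector contamination are not
  modeled, and organellar sequences are out of scope.
* Refinement treats FS-sets and K-sets independently; neither rescues the
  other.
* The correct rate is implemented as precision (true elements over
  resolved elements) — the reading under which "many elements were false,
  as reflected by the correct rate" makes sense.
* Contig counts after DQ splitting are heuristic-dependent; only the
  Q-clone bound is guaranteed.
* The internal exact-match paired-end mapper assumes low divergence
  between reads and contigs (adequate for simulation); real data should
  use an external aligner and the link-table hook.
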