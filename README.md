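# fgm — feature-set genome mapping from pooled-clone NGS reads

`fgm` builds a BAC physical map and a draft genome scaffold *simultaneously*
from short-read sequencing of clone pools, without restriction digestion,
individual clone fingerprinting, or whole-genome shotgun assembly of the
final map. It is aimed at groups constructing clone-based physical maps of
plant and other complex genomes who want sequence-defined landmarks instead
of gel bands, and at methodologists studying pooled-sample deconvolution.

The package contains the full method — pool design, landmark screening,
clone deconvolution, contiging, sequence integration, marker anchoring —
plus a complete simulator (genomes, BAC libraries, position-dependent
sequencing errors, markers, assembler-like contigs) so every stage can be
exercised and scored against ground truth on a desktop.

## The method in brief

A *feature sequence* (FS) is the 31 bp window immediately 5′ of a prefix
motif (defaults `GGATCC`, `GAATTC`) on either strand — an exact-string
landmark. Clones are pooled in d dimensions of p pools each (the *solid*
design assigns clone index (a,b,c) ∈ GF(p)³ to pool αa+βb+γc per dimension,
with the coefficient triples on a planar arc so any two clones share ≤ 2
pools). After sequencing each pool to depth ~20X:

1. pool reads are screened into FS-sets and canonical k-mer sets, and
   elements seen ≤ f times (default f = 1) are filtered out as
   error-derived;
2. each clone's F-set is resolved by intersecting its d signature pools'
   F-sets, then refined by demanding that every pool an element occurs in
   is explained by ≤ m_max candidate clones;
3. clones become physical contigs via the Sulston coincidence score at
   tolerance 0,
   `score = Σ_{i=m}^{nL} C(nL,i) q^i (1−q)^(nL−i)`, `q = 1 − (1 − 1/G)^{nH}`,
   with G the number of indexed band types and cutoff 1e-12, ordered by
   spectral seriation and cleaned by stepwise Q-clone splitting;
4. contigs are cut into bins by k-mer membership signatures; assembled
   sequence contigs are allocated to best bins, connected and oriented by
   paired-end links, anchored to chromosomes by markers, and emitted as
   pseudomolecules with 50 kb N gaps (AGP v2.1 + FASTA).

Detection rate (recall of a clone's true elements) and correct rate
(precision of the resolved set) are computed against simulator truth at
every stage. See `docs/methods.md` for models, parameters and limitations.

## Worked example

A truth-checked end-to-end run on a 300 kb synthetic genome: a 4X library
of 48 × 25 kb clones in 6D × 16 solid pools, 10X error-free reads, four
prefix motifs, markers every ~12 kb:

```yaml
# toy.yaml
genome_length: 300000
n_clones: 48
mean_insert: 25000
dimension: 6
pools_per_dim: 16
depth: 10
with_errors: false
filter_freq: 0      # error-free reads create no false elements
m_max: 14           # candidate bound above the 4X local clone multiplicity
marker_spacing: 12000
seq_mean_len: 5000
min_frac: 0.3
prefixes: [GGATCC, GAATTC, TCTAGA, CTCGAG]
seed: 3
```

```console
$ fgm run --config toy.yaml --out runs/toy
contigs=4 clone_usage=100.00% mapped=80.51% N50=144718 misplaced=0 inverted=0
```

Reading: all 48 clones assembled into 4 physical contigs (clone usage
100%); the anchored pseudomolecule covers 80.5% of the genome in non-N
bases with a scaffold N50 of 144.7 kb; every contig landed on the right
chromosome in the right orientation. The run directory holds the genome,
clone/pool/marker tables, per-clone final F-sets, the FPC-compatible
`clones.size` band file, `contigs.tsv`, and the pseudomolecule AGP/FASTA:

```console
$ head -3 runs/toy/pseudomolecules.agp
##agp-version 2.1
chr1	1	144718	1	W	ctg0001	1	144718	+
chr1	144719	194718	2	N	50000	contig	no	na
```

The same stages are available as separate verbs (`fgm simulate | screen |
deconvolve | contig | anchor | sweep`) operating on plain-text files, and
as library functions (`fgm.run_pipeline`, `fgm.sweep_depth`, …).

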