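"""Synthetic data: genomes, BAC libraries, read errors, pooled paired-end reads.

This module generates every input the mapping pipeline consumes, together
with the ground truth needed to score the downstream stages:

* random genomes with controllable internal repeat content;
* BAC clone libraries with truncated-normal insert sizes (default model:
  mean 137.42 kb, variance 417.54 kb², range 60-300 kb);
* a position-dependent substitution-error model for 100 bp short reads
  (0.10 % at the first cycle rising to 16.91 % at the last, 2.46 % mean);
* per-pool paired-end reads (~500 bp fragments) at a requested fold depth;
* molecular markers and "fragmented truth" sequence contigs that stand in
  for an external assembler's output when exercising the anchoring stage.

Every stochastic operation takes an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from . import dna

# ---------------------------------------------------------------------------
# Genome


@dataclass
class Genome:
    """A nuclear genome held as 2-bit code arrays, one per chromosome."""

    sequences: dict[str, np.ndarray]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def sequence(self, chrom: str, start: int | None = None, end: int | None = None) -> str:
        return dna.decode(self.sequences[chrom][start:end])

    def codes(self, chrom: str) -> np.ndarray:
        return self.sequences[chrom]

    @classmethod
    def from_strings(cls, seqs: dict[str, str]) -> "Genome":
        return cls({name: dna.encode(s) for name, s in seqs.items()})


def generate_genome(
    length: int,
    repeat_fraction: float = 0.0,
    seed: int = 0,
    *,
    n_chromosomes: int = 1,
    repeat_unit: int = 5000,
    max_insert: int | None = None,
) -> Genome:
    """Generate a random genome, optionally salted with internal repeats.

    ``repeat_fraction`` of the bases consist of repeated copies of segments
    drawn once and pasted at random positions (so exact self-matches of
    length ``repeat_unit`` exist, to stress landmark uniqueness).  If
    ``max_insert`` is given, genomes shorter than 10x that insert are
    rejected as unsamplable by the clone-library simulator.
    """
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not 0.0 <= repeat_fraction < 1.0:
        raise ValueError("repeat_fraction must be in [0, 1)")
    if max_insert is not None and length < 10 * max_insert:
        raise ValueError(
            f"genome length {length} < 10 x max clone insert {max_insert}: "
            "library would be unsamplable"
        )
    rng = np.random.default_rng(seed)
    per_chrom = [length // n_chromosomes] * n_chromosomes
    per_chrom[-1] += length - sum(per_chrom)
    seqs: dict[str, np.ndarray] = {}
    for ci, clen in enumerate(per_chrom):
        n_rep = int(round(clen * repeat_fraction))
        if n_rep > 0:
            unit_len = min(repeat_unit, max(1, n_rep // 2))
            n_copies = max(2, n_rep // unit_len)
            unit = rng.integers(0, 4, size=unit_len, dtype=np.uint8)
            backbone_len = clen - n_copies * unit_len
            if backbone_len < 0:
                n_copies = clen // unit_len
                backbone_len = clen - n_copies * unit_len
            backbone = rng.integers(0, 4, size=backbone_len, dtype=np.uint8)
            cuts = np.sort(rng.integers(0, backbone_len + 1, size=n_copies))
            parts: list[np.ndarray] = []
            prev = 0
            for cut in cuts:
                parts.append(backbone[prev:cut])
                parts.append(unit)
                prev = cut
            parts.append(backbone[prev:])
            seqs[f"chr{ci + 1}"] = np.concatenate(parts)
        else:
            seqs[f"chr{ci + 1}"] = rng.integers(0, 4, size=clen, dtype=np.uint8)
    return Genome(seqs)


# ---------------------------------------------------------------------------
# Clone library


@dataclass
class Clone:
    """A BAC clone: a genomic interval (0-based, half-open)."""

    id: str
    chrom: str
    start: int
    end: int

    @property
    def insert_size(self) -> int:
        return self.end - self.start


@dataclass
class LibraryModel:
    """Truncated-normal BAC insert-size law.

    Defaults reproduce a maize-style large-insert library: mean 137.42 kb,
    sd 20.434 kb (variance 417.54 kb²), inserts confined to [60, 300] kb.
    """

    mean_insert: float = 137_420.0
    sd_insert: float = 20_434.0
    min_insert: int = 60_000
    max_insert: int = 300_000
    n_clones: int = 10_000

    def scaled(self, mean_target: float, n_clones: int | None = None) -> "LibraryModel":
        """Proportionally rescale the law to a smaller mean insert.

        Used for desk-scale simulations on megabase genomes where full-size
        BAC inserts would not fit; the shape (cv, relative truncation) is
        preserved.
        """
        f = mean_target / self.mean_insert
        return LibraryModel(
            mean_insert=self.mean_insert * f,
            sd_insert=self.sd_insert * f,
            min_insert=int(round(self.min_insert * f)),
            max_insert=int(round(self.max_insert * f)),
            n_clones=self.n_clones if n_clones is None else n_clones,
        )


def sample_insert_sizes(model: LibraryModel, n: int, rng: np.random.Generator) -> np.ndarray:
    if model.min_insert == model.max_insert:
        return np.full(n, model.min_insert, dtype=np.int64)
    a = (model.min_insert - model.mean_insert) / model.sd_insert
    b = (model.max_insert - model.mean_insert) / model.sd_insert
    sizes = stats.truncnorm.rvs(
        a, b, loc=model.mean_insert, scale=model.sd_insert, size=n, random_state=rng
    )
    return np.round(sizes).astype(np.int64)


def simulate_library(genome: Genome, model: LibraryModel, seed: int = 0) -> list[Clone]:
    """Draw clones with uniform start positions and truncated-normal inserts."""
    longest = max(len(s) for s in genome.sequences.values())
    if longest < model.max_insert:
        raise ValueError(
            f"longest chromosome ({longest} bp) shorter than the maximum "
            f"insert ({model.max_insert} bp)"
        )
    rng = np.random.default_rng(seed)
    sizes = sample_insert_sizes(model, model.n_clones, rng)
    names = list(genome.sequences)
    lens = np.array([len(genome.sequences[c]) for c in names], dtype=np.float64)
    chrom_idx = rng.choice(len(names), size=model.n_clones, p=lens / lens.sum())
    clones = []
    width = len(str(model.n_clones))
    for i in range(model.n_clones):
        chrom = names[chrom_idx[i]]
        L = len(genome.sequences[chrom])
        size = int(min(sizes[i], L))
        start = int(rng.integers(0, L - size + 1))
        clones.append(Clone(f"c{i:0{width}d}", chrom, start, start + size))
    return clones


# ---------------------------------------------------------------------------
# Error model


@dataclass
class ErrorModel:
    """Per-cycle substitution probabilities along a read."""

    per_position: np.ndarray

    @property
    def read_length(self) -> int:
        return len(self.per_position)

    @property
    def min_error(self) -> float:
        return float(self.per_position[0])

    @property
    def max_error(self) -> float:
        return float(self.per_position[-1])

    @property
    def mean_error(self) -> float:
        return float(self.per_position.mean())

    def phred_qualities(self) -> np.ndarray:
        """Sanger Phred qualities Q = -10 log10(e), rounded, capped at 40."""
        q = np.clip(np.round(-10 * np.log10(self.per_position)), 2, 40)
        return q.astype(np.int8)


def default_error_model(
    read_length: int = 100,
    *,
    min_error: float = 0.0010,
    max_error: float = 0.1691,
    mean_error: float = 0.0246,
) -> ErrorModel:
    """Calibrated position-dependent substitution curve.

    The curve is log-linear in a warped coordinate,
    ``e(i) = exp(u + v * (i/(R-1))**g)``, with ``u``/``v`` pinning the first
    and last cycle to ``min_error``/``max_error`` exactly and the warp
    exponent ``g`` solved so the positional mean equals ``mean_error``.
    Monotone by construction.
    """
    R = read_length
    if R < 4:
        raise ValueError("error-model calibration needs read length >= 4")
    if not 0 < min_error < mean_error < max_error < 1:
        raise ValueError("need 0 < min_error < mean_error < max_error < 1")
    u = np.log(min_error)
    v = np.log(max_error / min_error)
    x = np.arange(R) / (R - 1)

    def mean_at(g: float) -> float:
        return float(np.exp(u + v * x**g).mean())

    lo, hi = 0.05, 50.0
    if not mean_at(hi) <= mean_error <= mean_at(lo):
        raise ValueError("mean_error not achievable with the given endpoints")
    g = optimize.brentq(lambda gg: mean_at(gg) - mean_error, lo, hi)
    return ErrorModel(np.exp(u + v * x**g))


# ---------------------------------------------------------------------------
# Pooled paired-end reads


@dataclass
class ReadBatch:
    """All read pairs of one pool, with per-read ground truth.

    ``mate1``/``mate2`` are (n, R) 2-bit code arrays as sequenced (mate2 is
    the reverse-complement end of the fragment).  Truth columns give the
    source clone index, the fragment interval on the clone's chromosome and
    whether mate1 reads the forward genome strand.
    """

    pool_id: str
    mate1: np.ndarray
    mate2: np.ndarray
    clone_index: np.ndarray
    frag_start: np.ndarray  # relative to the clone insert, circular coordinates
    frag_len: np.ndarray
    mate1_forward: np.ndarray  # bool

    @property
    def n_pairs(self) -> int:
        return len(self.mate1)

    @property
    def read_length(self) -> int:
        return self.mate1.shape[1]


def _gather_reads(genome: "Genome", clones: list[Clone], clone_index: np.ndarray,
                  rel_start: np.ndarray, frag_len: np.ndarray, R: int,
                  from_end: bool) -> np.ndarray:
    """Extract (n, R) forward-strand read windows from circular clones.

    ``rel_start`` is the fragment start relative to the clone's insert;
    coordinates wrap at the insert length (a BAC is a circular molecule, so
    the two ends of the insert are adjacent through the vector backbone —
    coverage is uniform with no edge deficit).
    """
    n = len(clone_index)
    out = np.empty((n, R), dtype=np.uint8)
    offset = rel_start if not from_end else rel_start + frag_len - R
    by_chrom: dict[str, list[int]] = {}
    for i, ci in enumerate(clone_index):
        by_chrom.setdefault(clones[ci].chrom, []).append(i)
    lens = np.array([clones[ci].insert_size for ci in clone_index], dtype=np.int64)
    starts = np.array([clones[ci].start for ci in clone_index], dtype=np.int64)
    for chrom, idx in by_chrom.items():
        idx = np.asarray(idx)
        pos = (offset[idx, None] + np.arange(R)) % lens[idx, None] + starts[idx, None]
        out[idx] = genome.sequences[chrom][pos]
    return out


def apply_errors(reads: np.ndarray, model: ErrorModel, rng: np.random.Generator) -> np.ndarray:
    """Substitute bases in place according to the per-cycle error vector."""
    n, R = reads.shape
    hit = rng.random((n, R)) < model.per_position[None, :]
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit, dtype=np.uint8)
        reads[hit] = (reads[hit] + shift) % 4
    return reads


def simulate_pool_reads(
    design,
    clones: list[Clone],
    genome: Genome,
    depth: float,
    error_model: ErrorModel | None = None,
    *,
    read_length: int = 100,
    fragment_mean: int = 500,
    fragment_sd: int = 30,
    seed: int = 0,
    pool_ids=None,
):
    """Yield a :class:`ReadBatch` per pool at the requested fold depth.

    The pair count per pool is ``depth * (total clone bases in pool) /
    (2 * read_length)``.  Fragments start uniformly within a clone chosen
    with probability proportional to insert size; mate1 reads the forward
    genome strand for half the pairs (coin flip).  Pool streams are
    seed-isolated so pools can be simulated in any order.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    clone_by_id = {c.id: i for i, c in enumerate(clones)}
    ids = list(design.membership) if pool_ids is None else list(pool_ids)
    root = np.random.SeedSequence(seed)
    pool_seeds = {pid: s for pid, s in zip(sorted(design.membership), root.spawn(len(design.membership)))}
    R = read_length
    for pid in ids:
        rng = np.random.default_rng(pool_seeds[pid])
        members = sorted(design.membership[pid])
        cidx = np.array([clone_by_id[m] for m in members], dtype=np.int64)
        sizes = np.array([clones[i].insert_size for i in cidx], dtype=np.float64)
        total = sizes.sum()
        n_pairs = int(round(depth * total / (2 * R)))
        if total == 0 or n_pairs == 0:
            yield ReadBatch(pid, np.empty((0, R), np.uint8), np.empty((0, R), np.uint8),
                            np.empty(0, np.int64), np.empty(0, np.int64),
                            np.empty(0, np.int64), np.empty(0, bool))
            continue
        pick = rng.choice(len(cidx), size=n_pairs, p=sizes / total)
        clone_index = cidx[pick]
        ins = sizes[pick].astype(np.int64)
        flen = np.round(rng.normal(fragment_mean, fragment_sd, size=n_pairs)).astype(np.int64)
        flen = np.clip(flen, 2 * R, ins)
        rel = (rng.random(n_pairs) * ins).astype(np.int64)  # circular: any start
        left = _gather_reads(genome, clones, clone_index, rel, flen, R, False)
        right = _gather_reads(genome, clones, clone_index, rel, flen, R, True)
        right_rc = (3 - right[:, ::-1])
        fwd = rng.random(n_pairs) < 0.5
        mate1 = np.where(fwd[:, None], left, right_rc).astype(np.uint8)
        mate2 = np.where(fwd[:, None], right_rc, left).astype(np.uint8)
        if error_model is not None:
            if error_model.read_length != R:
                raise ValueError("error model read length mismatch")
            apply_errors(mate1, error_model, rng)
            apply_errors(mate2, error_model, rng)
        yield ReadBatch(pid, mate1, mate2, clone_index, rel, flen, fwd)


def batch_mismatches(batch: ReadBatch, clones: list[Clone], genome: Genome) -> int:
    """Count substituted bases in a batch against its recorded origins."""
    R = batch.read_length
    left = _gather_reads(genome, clones, batch.clone_index,
                         batch.frag_start, batch.frag_len, R, False)
    right = _gather_reads(genome, clones, batch.clone_index,
                          batch.frag_start, batch.frag_len, R, True)
    right_rc = (3 - right[:, ::-1]).astype(np.uint8)
    fwd = batch.mate1_forward[:, None]
    true1 = np.where(fwd, left, right_rc)
    true2 = np.where(fwd, right_rc, left)
    return int((batch.mate1 != true1).sum() + (batch.mate2 != true2).sum())


# ---------------------------------------------------------------------------
# Markers and fragmented-truth sequence contigs


@dataclass
class Marker:
    id: str
    chrom: str
    position: int
    clone_hits: set = field(default_factory=set)


def generate_markers(genome: Genome, clones: list[Clone], spacing: int = 50_000,
                     seed: int = 0) -> list[Marker]:
    """Drop markers every ~``spacing`` bp (jittered) and record clone hits.

    A marker hits a clone when its locus lies inside the clone interval.
    """
    rng = np.random.default_rng(seed)
    markers = []
    k = 0
    for chrom, codes in genome.sequences.items():
        L = len(codes)
        pos = spacing // 2
        while pos < L:
            m = Marker(f"m{k:05d}", chrom, int(pos))
            for c in clones:
                if c.chrom == chrom and c.start <= pos < c.end:
                    m.clone_hits.add(c.id)
            markers.append(m)
            k += 1
            pos += int(spacing * (0.7 + 0.6 * rng.random()))
    return markers


def fragment_truth_contigs(genome: Genome, mean_len: int = 10_000, seed: int = 0,
                           min_len: int = 100):
    """Cut the true genome at random breakpoints into assembler-like contigs.

    Stands in for an external short-read assembler's output when testing
    sequence allocation and anchoring; pieces shorter than ``min_len`` bp
    are discarded (mirroring the pipeline's 100 bp length filter).

    Returns ``(contigs, truth)`` where ``contigs`` maps contig id to DNA
    string and ``truth`` maps contig id to (chrom, start, end).
    """
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    truth: dict[str, tuple[str, int, int]] = {}
    k = 0
    for chrom, codes in genome.sequences.items():
        L = len(codes)
        n_cuts = max(0, int(round(L / mean_len)) - 1)
        cuts = np.sort(rng.integers(1, L, size=n_cuts)) if n_cuts else np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [L]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            if e - s < min_len:
                continue
            cid = f"seq{k:05d}"
            contigs[cid] = dna.decode(codes[s:e])
            truth[cid] = (chrom, int(s), int(e))
            k += 1
    return contigs, truth
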