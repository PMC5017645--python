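"""Integrate assembled sequence contigs onto the physical map.

Stages, mirroring the map-integration workflow:

1. each physical contig is split into *bins* — maximal segments covered by
   a constant subset of its clones along the seriation; a bin's k-mer set
   is the intersection of its covering clones' K-sets minus the union of
   the other members' K-sets;
2. sequence contigs are allocated to the bin holding the largest fraction
   of their k-mers (ties are left unallocated);
3. paired-end reads whose mates map to different sequence contigs link
   contigs in the same or adjacent bins; majority strand patterns orient
   them, contradictions are dropped by weight, and members are joined into
   one scaffold per physical contig with short N spacers;
4. molecular markers vote each physical contig onto a chromosome (median
   marker position; orientation only with >= 2 concordant markers), and
   pseudomolecules are emitted with fixed 50 kb N gaps.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import dna
from .features import FSet
from .physmap import PhysContig

GAP_BETWEEN_CONTIGS = 50_000
SPACER_WITHIN_CONTIG = 100


# ---------------------------------------------------------------------------
# Bins


@dataclass
class Bin:
    contig_id: str
    rank: int
    clones: list[str]
    words: np.ndarray  # sorted canonical k-mers

    @property
    def n_kmers(self) -> int:
        return len(self.words)


def split_into_bins(contig: PhysContig, ksets: dict[str, FSet], *,
                    min_kmers: int = 5) -> list[Bin]:
    """Cut a seriated contig into constant-coverage bins.

    Every k-mer of the members' K-sets carries a *signature* — the subset
    of member clones whose K-set contains it.  Maximal segments covered by
    a constant clone subset have constant signatures, so grouping k-mers by
    signature recovers the bins directly as intersections-minus-differences
    of the overlapping clones' K-sets; each group's k-mer set is exactly
    (∩ covering) ∖ (∪ non-covering members).  Bins are ordered along the
    contig by the mean seriation rank of their covering clones.  Signature
    groups below ``min_kmers`` (noise from residual false elements) are
    dropped.
    """
    order = contig.clones
    n = len(order)
    parts = [ksets[c].words for c in order if ksets[c].n_elements]
    if not parts:
        return []
    union = np.unique(np.concatenate(parts))
    W = (n + 63) // 64
    masks = np.zeros((len(union), W), dtype=np.uint64)
    for r, cid in enumerate(order):
        hit = np.isin(union, ksets[cid].words, assume_unique=True)
        masks[hit, r // 64] |= np.uint64(1 << (r % 64))
    uniq_masks, inverse, counts = np.unique(masks, axis=0, return_inverse=True,
                                            return_counts=True)
    bins: list[Bin] = []
    for gi in range(len(uniq_masks)):
        if counts[gi] < min_kmers:
            continue
        ranks = [r for r in range(n)
                 if uniq_masks[gi, r // 64] & np.uint64(1 << (r % 64))]
        if not ranks:
            continue
        words = union[inverse == gi]
        bins.append(Bin(contig.id, -1, [order[r] for r in ranks], words))
    rank_of = {cid: r for r, cid in enumerate(order)}
    bins.sort(key=lambda b: (float(np.mean([rank_of[c] for c in b.clones])),
                             min(rank_of[c] for c in b.clones), b.clones[0]))
    for i, b in enumerate(bins):
        b.rank = i
    return bins


# ---------------------------------------------------------------------------
# Sequence contigs and allocation


@dataclass
class SeqContig:
    """An externally assembled sequence contig (>= 100 bp)."""

    id: str
    sequence: str
    k: int = 31
    words: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.words is None:
            codes = dna.encode(self.sequence)
            if len(codes) >= self.k:
                w = dna.canonical(dna.window_codes(codes, self.k), self.k)
                if np.any(codes > 3):
                    w = w[dna.valid_windows(codes, self.k)]
                self.words = np.unique(w)
            else:
                self.words = np.empty(0, np.uint64)

    def __len__(self) -> int:
        return len(self.sequence)


MIN_SEQ_LEN = 100


@dataclass
class Allocation:
    seq_id: str
    contig_id: str
    bin_rank: int
    score: float


def allocate(seq: SeqContig, bins: list[Bin], min_frac: float = 0.5) -> Allocation | None:
    """Assign a sequence to the bin sharing the largest k-mer fraction.

    Returns ``None`` below ``min_frac`` or on an exact tie (ambiguous
    placements are preferred unplaced over misplaced).
    """
    if len(seq.words) == 0:
        return None
    best: Allocation | None = None
    best_score, tie = -1.0, False
    for b in bins:
        if b.n_kmers == 0:
            continue
        m = len(np.intersect1d(seq.words, b.words, assume_unique=True))
        s = m / len(seq.words)
        if s > best_score:
            best, best_score, tie = Allocation(seq.id, b.contig_id, b.rank, s), s, False
        elif s == best_score and s > 0:
            tie = True
    if best is None or best_score < min_frac or tie:
        return None
    return best


# ---------------------------------------------------------------------------
# Paired-end mapping


def _contig_kmer_index(contigs: dict[str, str], k: int):
    """Forward (strand-resolved) k-mer -> contig index, cross-contig dupes dropped."""
    ids = sorted(contigs)
    words_all, owner = [], []
    for i, cid in enumerate(ids):
        codes = dna.encode(contigs[cid])
        if len(codes) < k:
            continue
        w = np.unique(dna.window_codes(codes, k))
        words_all.append(w)
        owner.append(np.full(len(w), i, dtype=np.int32))
    if not words_all:
        return ids, np.empty(0, np.uint64), np.empty(0, np.int32)
    words = np.concatenate(words_all)
    owner = np.concatenate(owner)
    order = np.argsort(words, kind="stable")
    words, owner = words[order], owner[order]
    # a k-mer and its revcomp may both occur; uniqueness is per exact word
    first = np.ones(len(words), bool)
    first[1:] = words[1:] != words[:-1]
    last = np.ones(len(words), bool)
    last[:-1] = words[1:] != words[:-1]
    uniq = first & last
    return ids, words[uniq], owner[uniq]


def _map_mates(mates: np.ndarray, index, k: int, t: float):
    """Map each read row to (contig_index, strand) or (-1, 0)."""
    ids, U, C = index
    n, R = mates.shape
    W = R - k + 1
    out_c = np.full(n, -1, dtype=np.int64)
    out_s = np.zeros(n, dtype=np.int8)
    if len(U) == 0 or W <= 0:
        return out_c, out_s
    need = t * W
    n_ctg = len(ids)
    for rc in (False, True):
        words = dna.window_codes(mates, k, rc=rc)
        idx = np.searchsorted(U, words)
        idx_c = np.minimum(idx, len(U) - 1)
        hit = U[idx_c] == words
        flat = hit.ravel()
        if not flat.any():
            continue
        rows = np.repeat(np.arange(n, dtype=np.int64), W)[flat]
        ctgs = C[idx_c].ravel()[flat].astype(np.int64)
        keys, counts = np.unique(rows * n_ctg + ctgs, return_counts=True)
        # per row, keep the contig with the most hits (keys are row-sorted)
        krows = keys // n_ctg
        order = np.lexsort((counts, krows))
        krows_o, counts_o, keys_o = krows[order], counts[order], keys[order]
        last = np.ones(len(keys_o), bool)
        last[:-1] = krows_o[1:] != krows_o[:-1]
        sel_rows = krows_o[last]
        sel_ctgs = keys_o[last] % n_ctg
        ok = (counts_o[last] >= need) & (out_c[sel_rows] == -1)
        out_c[sel_rows[ok]] = sel_ctgs[ok]
        out_s[sel_rows[ok]] = -1 if rc else 1
    return out_c, out_s


def map_pairs(batches, contigs: dict[str, str], *, k: int = 31, t: float = 0.9) -> pd.DataFrame:
    """Exact-k-mer paired-end mapper producing an inter-contig link table.

    A mate maps to a contig when >= ``t`` of its k-mers hit that contig's
    strand-resolved k-mer index uniquely; a link is recorded when the two
    mates map to different contigs.  Columns: contig_a, contig_b, strand_a,
    strand_b, n (aggregated link count), with contig_a < contig_b.
    """
    index = _contig_kmer_index(contigs, k)
    ids = index[0]
    rows = []
    for batch in batches:
        c1, s1 = _map_mates(batch.mate1, index, k, t)
        c2, s2 = _map_mates(batch.mate2, index, k, t)
        ok = (c1 >= 0) & (c2 >= 0) & (c1 != c2)
        for a, b, sa, sb in zip(c1[ok], c2[ok], s1[ok], s2[ok]):
            ca, cb = ids[a], ids[b]
            if ca > cb:
                ca, cb, sa, sb = cb, ca, sb, sa
            rows.append((ca, cb, int(sa), int(sb)))
    if not rows:
        return pd.DataFrame(columns=["contig_a", "contig_b", "strand_a", "strand_b", "n"])
    df = pd.DataFrame(rows, columns=["contig_a", "contig_b", "strand_a", "strand_b"])
    return (df.groupby(["contig_a", "contig_b", "strand_a", "strand_b"])
              .size().rename("n").reset_index())


# ---------------------------------------------------------------------------
# Connect and orient within physical contigs


@dataclass
class Scaffold:
    """Ordered, oriented sequence members of one physical contig."""

    contig_id: str
    members: list[tuple[str, str]]  # (seq_id, "+"/"-")
    sequence: str


def _relative_orientation(group: pd.DataFrame) -> tuple[str | None, int]:
    """Majority relation between two linked contigs: 'same', 'opposite' or None.

    Proper innie pairs read opposite strands of one fragment, so mates with
    opposite mapped strands imply the contigs already face the same way.
    """
    same = int(group.loc[group.strand_a != group.strand_b, "n"].sum())
    opp = int(group.loc[group.strand_a == group.strand_b, "n"].sum())
    if same == opp:
        return None, same + opp
    return ("same" if same > opp else "opposite"), same + opp


def connect_and_orient(allocations: dict[str, Allocation], links: pd.DataFrame,
                       bins_by_contig: dict[str, list[Bin]],
                       seqs: dict[str, SeqContig], *,
                       spacer: int = SPACER_WITHIN_CONTIG) -> dict[str, Scaffold]:
    """Order and orient allocated sequences inside each physical contig.

    Order is primarily by bin rank; links are honored only between members
    of the same or adjacent bins and orient members by majority strand
    pattern (conflicts dropped by link weight, ties drop both).  Members
    are joined with ``spacer`` N characters.
    """
    by_contig: dict[str, list[Allocation]] = {}
    for a in allocations.values():
        if a is not None:
            by_contig.setdefault(a.contig_id, []).append(a)
    scaffolds: dict[str, Scaffold] = {}
    for ctg_id, allocs in by_contig.items():
        allocs.sort(key=lambda a: (a.bin_rank, a.seq_id))
        members = [a.seq_id for a in allocs]
        rank = {a.seq_id: a.bin_rank for a in allocs}
        mset = set(members)
        # candidate edges: links between members in the same or adjacent bins
        edges = []
        if len(links):
            sub = links[links.contig_a.isin(mset) & links.contig_b.isin(mset)]
            for (a, b), grp in sub.groupby(["contig_a", "contig_b"]):
                if abs(rank[a] - rank[b]) > 1:
                    continue
                rel, weight = _relative_orientation(grp)
                if rel is None:
                    continue  # strand-contradictory tie: drop both directions
                edges.append((weight, a, b, rel))
        edges.sort(key=lambda e: (-e[0], e[1], e[2]))
        orient: dict[str, int] = {}
        g = nx.Graph()
        for w, a, b, rel in edges:
            sign = 1 if rel == "same" else -1
            if a in orient and b in orient:
                if orient[a] * orient[b] != sign:
                    continue  # cycle conflict: heavier edges already applied
                g.add_edge(a, b)
            elif a in orient:
                orient[b] = orient[a] * sign
                g.add_edge(a, b)
            elif b in orient:
                orient[a] = orient[b] * sign
                g.add_edge(a, b)
            else:
                orient[a] = 1
                orient[b] = sign
                g.add_edge(a, b)
        for m in members:
            orient.setdefault(m, 1)
        # normalize: first member faces +
        if orient[members[0]] < 0:
            orient = {m: -o for m, o in orient.items()}
        # within-bin ordering refinement: chain same-bin members along links
        ordered: list[str] = []
        for r in sorted({rank[m] for m in members}):
            group = [m for m in members if rank[m] == r]
            if len(group) > 2 and g.number_of_edges() and all(m in g for m in group):
                sub = g.subgraph(group)
                deg1 = sorted(n for n in sub if sub.degree(n) <= 1)
                if deg1 and nx.is_connected(sub):
                    path = list(nx.dfs_preorder_nodes(sub, deg1[0]))
                    if len(path) == len(group):
                        group = path
            ordered.extend(group)
        parts = []
        for m in ordered:
            s = seqs[m].sequence
            parts.append(s if orient[m] > 0 else dna.revcomp(s))
        scaffolds[ctg_id] = Scaffold(
            ctg_id,
            [(m, "+" if orient[m] > 0 else "-") for m in ordered],
            ("N" * spacer).join(parts),
        )
    return scaffolds


# ---------------------------------------------------------------------------
# Marker anchoring and pseudomolecules


@dataclass
class ContigPlacement:
    contig_id: str
    chrom: str
    position: float
    orientation: str  # "+", "-" or "?"
    n_markers: int


@dataclass
class Pseudomolecule:
    chrom: str
    placements: list[ContigPlacement]
    sequence: str


@dataclass
class AnchoredAssembly:
    pseudomolecules: dict[str, Pseudomolecule]
    placements: dict[str, ContigPlacement]
    unplaced: list[str]
    scaffolds: dict[str, Scaffold]


def anchor_contigs(contigs: list[PhysContig], scaffolds: dict[str, Scaffold],
                   markers, *, gap: int = GAP_BETWEEN_CONTIGS) -> AnchoredAssembly:
    """Place physical contigs on chromosomes by marker majority vote.

    Position is the median marker position on the winning chromosome;
    orientation requires >= 2 markers with a consistent order against the
    clone seriation (single-marker contigs stay orientation "?", the
    classic source of whole-contig inversions).  Contigs without markers
    are left unplaced.
    """
    placements: dict[str, ContigPlacement] = {}
    unplaced: list[str] = []
    for contig in contigs:
        if contig.id not in scaffolds:
            unplaced.append(contig.id)
            continue
        rank = {cid: i for i, cid in enumerate(contig.clones)}
        hits = []  # (chrom, position, clone rank)
        for m in markers:
            ranks = [rank[c] for c in m.clone_hits if c in rank]
            if ranks:
                hits.append((m.chrom, m.position, float(np.mean(ranks))))
        if not hits:
            unplaced.append(contig.id)
            continue
        chrom = Counter(h[0] for h in hits).most_common(1)[0][0]
        on = sorted((h[2], h[1]) for h in hits if h[0] == chrom)
        pos = float(np.median([p for _, p in on]))
        orientation = "?"
        if len({r for r, _ in on}) >= 2:
            conc = disc = 0
            for i in range(len(on)):
                for j in range(i + 1, len(on)):
                    if on[i][0] == on[j][0]:
                        continue
                    if on[i][1] < on[j][1]:
                        conc += 1
                    elif on[i][1] > on[j][1]:
                        disc += 1
            if conc != disc:
                orientation = "+" if conc > disc else "-"
        placements[contig.id] = ContigPlacement(contig.id, chrom, pos, orientation,
                                                len(hits))
    pseudos: dict[str, Pseudomolecule] = {}
    by_chrom: dict[str, list[ContigPlacement]] = {}
    for pl in placements.values():
        by_chrom.setdefault(pl.chrom, []).append(pl)
    for chrom, pls in sorted(by_chrom.items()):
        pls.sort(key=lambda p: (p.position, p.contig_id))
        parts = []
        for pl in pls:
            s = scaffolds[pl.contig_id].sequence
            parts.append(dna.revcomp(s) if pl.orientation == "-" else s)
        pseudos[chrom] = Pseudomolecule(chrom, pls, ("N" * gap).join(parts))
    return AnchoredAssembly(pseudos, placements, unplaced, scaffolds)


# ---------------------------------------------------------------------------
# Evaluation


def n50(lengths) -> int:
    """Largest L with total length of sequences >= L at least half the sum."""
    lengths = sorted((int(x) for x in lengths), reverse=True)
    if not lengths:
        return 0
    half = sum(lengths) / 2
    acc = 0
    for L in lengths:
        acc += L
        if acc >= half:
            return L
    return lengths[-1]


@dataclass
class EvaluationReport:
    mapped_fraction: float
    n50: int
    n_misplaced: int
    n_inverted: int
    n_placed: int
    n_unplaced: int


def evaluate(assembly: AnchoredAssembly, genome, clones,
             contigs: list[PhysContig]) -> EvaluationReport:
    """Score an anchored assembly against simulator truth.

    Misplacement: a placed contig whose assigned chromosome differs from
    the majority chromosome of its member clones.  Inversion: a placed
    contig whose effective direction (clone seriation vs. genomic order,
    combined with the applied orientation flip) runs against the genome.
    """
    clone_by_id = {c.id: c for c in clones}
    contig_by_id = {c.id: c for c in contigs}
    mapped = sum(len(p.sequence) - p.sequence.count("N")
                 for p in assembly.pseudomolecules.values())
    n_mis = n_inv = 0
    for pl in assembly.placements.values():
        members = [clone_by_id[c] for c in contig_by_id[pl.contig_id].clones]
        true_chrom = Counter(c.chrom for c in members).most_common(1)[0][0]
        if pl.chrom != true_chrom:
            n_mis += 1
            continue
        starts = [c.start for c in members if c.chrom == true_chrom]
        if len(starts) >= 2 and pl.orientation != "?":
            ascending = starts[-1] >= starts[0]
            true_or = "+" if ascending else "-"
            if pl.orientation != true_or:
                n_inv += 1
    lengths = [len(s.sequence) for s in assembly.scaffolds.values()]
    return EvaluationReport(
        mapped_fraction=mapped / genome.total_length,
        n50=n50(lengths),
        n_misplaced=n_mis,
        n_inverted=n_inv,
        n_placed=len(assembly.placements),
        n_unplaced=len(assembly.unplaced),
    )
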