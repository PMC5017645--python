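"""Physical-map contiging from clones' final FS-sets.

Feature sequences are indexed to dense integer *bands*; clone overlap is
judged by the Sulston coincidence score at tolerance 0 (every band value
is exactly distinguishable, so the per-band chance-match probability is
derived from the total number of indexed band types).  Contigs are
single-linkage components over pairs scoring at or below the cutoff
(default 1e-12), ordered by a greedy seriation that maximizes adjacent
shared-band counts.  A DQ-style pass then splits contigs carrying too many
questionable (Q) clones by rebuilding them at stepwise-tightened cutoffs.
Band lists round-trip through FPC-compatible ``.size`` files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from . import dna
from .features import FSet


@dataclass
class BandIndex:
    """Dense 1-based integer ids for FS band types (lexicographic order)."""

    words: np.ndarray  # sorted uint64; band id = position + 1
    klen: int

    @classmethod
    def from_fsets(cls, fsets: dict[str, FSet]) -> "BandIndex":
        parts = [fs.words for fs in fsets.values() if fs.n_elements]
        klens = {fs.klen for fs in fsets.values()}
        if len(klens) != 1:
            raise ValueError("FS-sets must share one element length")
        union = np.unique(np.concatenate(parts)) if parts else np.empty(0, np.uint64)
        return cls(union, klens.pop())

    def __len__(self) -> int:
        return len(self.words)

    def band_ids(self, fset: FSet) -> np.ndarray:
        """Strictly increasing band ids of an FS-set's elements."""
        idx = np.searchsorted(self.words, fset.words)
        ok = (idx < len(self.words)) & (self.words[np.minimum(idx, len(self.words) - 1)] == fset.words)
        if not np.all(ok):
            raise KeyError("FS-set contains elements absent from the band index")
        return (idx + 1).astype(np.int64)

    def band_string(self, band_id: int) -> str:
        return dna.word_to_string(self.words[band_id - 1], self.klen)


def clone_bands(fsets: dict[str, FSet], index: BandIndex | None = None,
                min_bands: int = 0):
    """Map clones to sorted band-id arrays, dropping clones with too few bands.

    Returns ``(bands, index, n_dropped)``.
    """
    index = index or BandIndex.from_fsets(fsets)
    bands: dict[str, np.ndarray] = {}
    dropped = 0
    for cid, fs in fsets.items():
        b = index.band_ids(fs)
        if len(b) < min_bands:
            dropped += 1
            continue
        bands[cid] = b
    return bands, index, dropped


@dataclass
class SulstonParams:
    """Overlap-score parameters; tolerance is fixed at 0 for exact bands."""

    cutoff: float = 1e-12
    gellen: int = 0  # number of possible band values; 0 = set from the index
    min_bands: int = 40


def sulston_score(b1: np.ndarray, b2: np.ndarray, gellen: int) -> float:
    """P(two random clones share >= m of their bands), tolerance 0.

    With nH = max(|b1|,|b2|), nL = min, per-band coincidence probability
    q = 1 - (1 - 1/gellen)**nH and m observed shared bands, the score is
    the binomial upper tail sum_{i=m}^{nL} C(nL,i) q^i (1-q)^(nL-i).
    """
    if len(b1) == 0 or len(b2) == 0:
        raise ValueError("band lists must be non-empty")
    hi = int(max(b1.max(), b2.max()))
    if gellen < hi:
        raise ValueError(f"gellen {gellen} < largest band id {hi}")
    nH, nL = max(len(b1), len(b2)), min(len(b1), len(b2))
    m = len(np.intersect1d(b1, b2, assume_unique=True))
    if m == 0:
        return 1.0
    q = 1.0 - (1.0 - 1.0 / gellen) ** nH
    return float(stats.binom.sf(m - 1, nL, q))


@dataclass
class PhysContig:
    """An ordered run of overlapping clones."""

    id: str
    clones: list[str]
    q_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def n_q(self) -> int:
        return sum(self.q_flags.values())


def _pairwise(bands: dict[str, np.ndarray], gellen: int):
    ids = sorted(bands)
    shared = {}
    score = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            m = len(np.intersect1d(bands[a], bands[b], assume_unique=True))
            shared[(a, b)] = shared[(b, a)] = m
            s = sulston_score(bands[a], bands[b], gellen)
            score[(a, b)] = score[(b, a)] = s
    return ids, shared, score


def _seriate(members: list[str], edges: set, shared) -> list[list[str]]:
    """Spectral seriation of one linkage component.

    Orders clones by the Fiedler vector of the graph Laplacian built on
    shared-band counts — for band data from intervals on a line this
    recovers the genomic order up to full reversal.  The order is then cut
    wherever adjacent clones do not actually overlap (no edge), which keeps
    the adjacency invariant and splits accidental chimeras.
    """
    members = sorted(members)
    n = len(members)
    if n <= 2:
        return [members]
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = shared[(members[i], members[j])]
    L = np.diag(S.sum(axis=1)) - S
    vals, vecs = np.linalg.eigh(L)
    f = vecs[:, np.argsort(vals)[1]]
    order = sorted(range(n), key=lambda i: (f[i], members[i]))
    if members[order[0]] > members[order[-1]]:
        order = order[::-1]  # deterministic direction (eigenvector sign is not)
    path = [members[i] for i in order]
    out, cur = [], [path[0]]
    for prev, nxt in zip(path, path[1:]):
        if (prev, nxt) in edges:
            cur.append(nxt)
        else:
            out.append(cur)
            cur = [nxt]
    out.append(cur)
    return out


def build_contigs(bands: dict[str, np.ndarray], params: SulstonParams):
    """Single-linkage contiging + greedy seriation.

    Returns ``(contigs, singletons, score_table)`` where ``score_table``
    carries the pairwise scores/shared counts for downstream stages.
    """
    gellen = params.gellen or int(max((b.max() for b in bands.values()), default=0))
    ids, shared, score = _pairwise(bands, gellen)
    edges = {pair for pair, s in score.items() if s <= params.cutoff}
    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_edges_from(pair for pair in edges if pair[0] < pair[1])
    contigs: list[PhysContig] = []
    singletons: list[str] = []
    comps = sorted(nx.connected_components(g), key=lambda c: min(c))
    k = 0
    for comp in comps:
        if len(comp) == 1:
            singletons.extend(comp)
            continue
        for path in _seriate(sorted(comp), edges, shared):
            if len(path) == 1:
                singletons.extend(path)
            else:
                contigs.append(PhysContig(f"ctg{k:04d}", path))
                k += 1
    table = {"shared": shared, "score": score, "gellen": gellen}
    return contigs, singletons, table


def flag_q_clones(contig: PhysContig, bands: dict[str, np.ndarray], table,
                  cutoff: float, q_frac: float = 0.5) -> None:
    """Mark members sharing less than ``1 - q_frac`` of their bands with neighbors."""
    for cid in contig.clones:
        nbrs = [o for o in contig.clones
                if o != cid and table["score"][(cid, o)] <= cutoff]
        if not nbrs:
            contig.q_flags[cid] = True
            continue
        nbr_bands = np.unique(np.concatenate([bands[o] for o in nbrs]))
        mine = bands[cid]
        unshared = 1.0 - len(np.intersect1d(mine, nbr_bands, assume_unique=True)) / len(mine)
        contig.q_flags[cid] = unshared > q_frac


def q_analysis(contigs: list[PhysContig], bands: dict[str, np.ndarray], table,
               params: SulstonParams, *, max_q: int = 5, steps: int = 9,
               q_frac: float = 0.5):
    """Split contigs with more than ``max_q`` Q-clones at tightened cutoffs.

    Each step divides the cutoff by 10 (exponent -13, -14, ... from a 1e-12
    start) and rebuilds only the offending contig's members; clones that no
    longer link detach as singletons.  Mirrors the stepwise DQ pass of
    fingerprint contiging without reproducing its exact internals.

    Returns ``(contigs, singletons)``.
    """
    out: list[PhysContig] = []
    singles: list[str] = []
    work = list(contigs)
    for contig in work:
        flag_q_clones(contig, bands, table, params.cutoff, q_frac)
        if contig.n_q <= max_q:
            out.append(contig)
            continue
        resolved = False
        for s in range(1, steps + 1):
            cut = params.cutoff * 10.0 ** (-s)
            sub_bands = {c: bands[c] for c in contig.clones}
            sub_params = SulstonParams(cut, table["gellen"], params.min_bands)
            subs, sub_singles, sub_table = build_contigs(sub_bands, sub_params)
            ok = True
            for sc in subs:
                flag_q_clones(sc, sub_bands, sub_table, cut, q_frac)
                if sc.n_q > max_q:
                    ok = False
            if ok:
                singles.extend(sub_singles)
                out.extend(subs)
                resolved = True
                break
        if not resolved:
            out.append(contig)  # reported as-is; caller sees the Q count
    for i, c in enumerate(out):
        c.id = f"ctg{i:04d}"
    return out, singles


def clone_usage(contigs: list[PhysContig], n_imported: int) -> float:
    """Clones placed in (multi-clone) contigs over clones imported."""
    placed = sum(len(c.clones) for c in contigs)
    return placed / n_imported if n_imported else float("nan")


# ---------------------------------------------------------------------------
# FPC-compatible ".size" files


def write_size_file(bands: dict[str, np.ndarray], path) -> None:
    """Write band lists in the FPC ``.size`` dialect.

    Per clone: ``<name> <n_bands>`` then one band integer per line, block
    terminated by ``-1``; the file ends with a newline.
    """
    with open(path, "w") as fh:
        for cid in bands:
            b = np.asarray(bands[cid])
            if len(b) and b.min() <= 0:
                raise ValueError(f"clone {cid}: band ids must be positive")
            fh.write(f"{cid} {len(b)}\n")
            for v in b:
                fh.write(f"{int(v)}\n")
            fh.write("-1\n")


def read_size_file(path) -> dict[str, np.ndarray]:
    """Read a ``.size`` file back into clone -> band-id arrays."""
    out: dict[str, np.ndarray] = {}
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        name, n = lines[i].rsplit(" ", 1)
        n = int(n)
        vals = [int(v) for v in lines[i + 1 : i + 1 + n]]
        if len(vals) != n or lines[i + 1 + n] != "-1":
            raise ValueError(f"malformed .size block for clone {name}")
        out[name] = np.array(vals, dtype=np.int64)
        i += n + 2
    return out
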