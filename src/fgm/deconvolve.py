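"""Resolve per-clone F-sets from pool F-sets by signature intersection + refinement.

A clone's *intersected* F-set holds every element present in all ``d``
pools of its signature (count = the minimum across those pools).  Pool
collisions and repeats still leak false elements through the intersection,
so a *refinement* pass re-examines each element's full pool-occurrence
pattern: an element is kept only if the set of clones whose signatures it
contains (its *candidates*) is small (``<= m_max``) and jointly explains
every pool the element occurs in.  Elements whose pool pattern includes
pools no candidate clone accounts for are error- or repeat-derived and are
dropped.

Detection rate (|resolved ∩ true| / |true|) and correct rate — precision,
|resolved ∩ true| / |resolved| — are computed against simulator truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .features import FSet
from .pooling import PoolDesign


def intersect_clone(clone_id: str, design: PoolDesign,
                    pool_fsets: dict[str, FSet]) -> FSet:
    """Intersect the (filtered) F-sets of the clone's signature pools."""
    sig = design.signature_of(clone_id)
    missing = [p for p in sig if p not in pool_fsets]
    if missing:
        raise KeyError(f"missing F-set for pool(s) {', '.join(missing)}")
    first = pool_fsets[sig[0]]
    words, counts = first.words, first.counts
    for pid in sig[1:]:
        fs = pool_fsets[pid]
        words, ia, ib = np.intersect1d(words, fs.words, assume_unique=True,
                                       return_indices=True)
        counts = np.minimum(counts[ia], fs.counts[ib])
    return FSet(first.kind, first.klen, words, counts,
                owner=clone_id, stage="intersected")


def intersect_all(design: PoolDesign, pool_fsets: dict[str, FSet]) -> dict[str, FSet]:
    return {cid: intersect_clone(cid, design, pool_fsets) for cid in design.clone_ids}


def _pool_bitmasks(union_words: np.ndarray, pool_fsets: dict[str, FSet],
                   pool_order: list[str]) -> np.ndarray:
    """(n_elements, n_words) uint64 bitmask of pools containing each element."""
    n_pools = len(pool_order)
    W = (n_pools + 63) // 64
    masks = np.zeros((len(union_words), W), dtype=np.uint64)
    for b, pid in enumerate(pool_order):
        fs = pool_fsets.get(pid)
        if fs is None or fs.n_elements == 0:
            continue
        hit = np.isin(union_words, fs.words, assume_unique=True)
        masks[hit, b // 64] |= np.uint64(1 << (b % 64))
    return masks


def refine_all(intersected: dict[str, FSet], design: PoolDesign,
               pool_fsets: dict[str, FSet], m_max: int = 4) -> dict[str, FSet]:
    """Refinement pass over all clones' intersected F-sets.

    Element ``e`` survives (for every candidate clone) iff its candidate
    clones number at most ``m_max`` and the union of their signatures
    covers every pool whose F-set contains ``e``.
    """
    pool_order = design.pool_ids
    pool_bit = {pid: b for b, pid in enumerate(pool_order)}
    W = (len(pool_order) + 63) // 64
    sig_mask = {}
    for cid in design.clone_ids:
        m = np.zeros(W, dtype=np.uint64)
        for pid in design.signature_of(cid):
            b = pool_bit[pid]
            m[b // 64] |= np.uint64(1 << (b % 64))
        sig_mask[cid] = m

    all_words = [fs.words for fs in intersected.values() if fs.n_elements]
    if not all_words:
        return {cid: replace(fs, stage="final") for cid, fs in intersected.items()}
    union = np.unique(np.concatenate(all_words))
    pools_of = _pool_bitmasks(union, pool_fsets, pool_order)

    cand_count = np.zeros(len(union), dtype=np.int64)
    cand_cover = np.zeros((len(union), W), dtype=np.uint64)
    for cid, fs in intersected.items():
        if fs.n_elements == 0:
            continue
        idx = np.searchsorted(union, fs.words)
        cand_count[idx] += 1
        cand_cover[idx] |= sig_mask[cid][None, :]

    uncovered = (pools_of & ~cand_cover).any(axis=1)
    keep = (cand_count <= m_max) & ~uncovered

    final: dict[str, FSet] = {}
    for cid, fs in intersected.items():
        if fs.n_elements == 0:
            final[cid] = replace(fs, stage="final")
            continue
        idx = np.searchsorted(union, fs.words)
        sel = keep[idx]
        final[cid] = FSet(fs.kind, fs.klen, fs.words[sel], fs.counts[sel],
                          owner=cid, stage="final")
    return final


@dataclass
class RateReport:
    """Detection (recall of true elements) and correct rate (precision)."""

    n_true: int
    n_resolved: int
    n_shared: int

    @property
    def detection_rate(self) -> float:
        return self.n_shared / self.n_true if self.n_true else float("nan")

    @property
    def correct_rate(self) -> float | None:
        if self.n_resolved == 0:
            return None  # undefined on an empty resolved set
        return self.n_shared / self.n_resolved


def rates(resolved: FSet, true_words: np.ndarray | FSet) -> RateReport:
    tw = true_words.words if isinstance(true_words, FSet) else np.asarray(true_words, dtype=np.uint64)
    tw = np.unique(tw)
    shared = np.intersect1d(resolved.words, tw, assume_unique=True)
    return RateReport(len(tw), resolved.n_elements, len(shared))


def pool_coverage(design: PoolDesign, clones, genome) -> dict[str, float]:
    """Per-pool ratio of total member insert size to genome length."""
    size = {c.id: c.insert_size for c in clones}
    total = genome.total_length if hasattr(genome, "total_length") else int(genome)
    return {pid: sum(size[c] for c in members) / total
            for pid, members in design.membership.items()}


def detection_probability(depth: float, d: int, *, read_length: int = 100,
                          k: int = 31, error: float = 0.0,
                          prefix_len: int = 0) -> float:
    """Closed-form detection probability oracle for one true element.

    A window of ``k + prefix_len`` bases must fall error-free inside a read
    in each of the clone's ``d`` pools; copies arrive with Poisson rate
    ``depth * (R - w + 1)/R * (1 - e)^w`` per pool.
    """
    w = k + prefix_len
    lam = depth * (read_length - w + 1) / read_length * (1.0 - error) ** w
    return float((1.0 - np.exp(-lam)) ** d)
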