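"""Feature sequences (FS) and canonical k-mers: extraction, screening, filtering.

A *feature sequence* is the fixed-length window (default 31 bp) lying
immediately 5' of a chosen prefix motif (defaults: the palindromic
restriction sites GGATCC and GAATTC) on either strand.  FSs are stored
strand-resolved — the window read 5'->3' on the strand bearing the prefix —
so genome and read scans agree without canonicalization.  K-mers, which
arrive from both strands of random fragments, are canonicalized as
``min(kmer, revcomp(kmer))``.

Per-pool F-sets (an FS-set and a K-set) accumulate element counts over all
reads of both mates; a frequency filter then discards elements seen no more
than ``f`` times (default 1), which removes most error-derived elements
because a substitution almost always creates a never-seen-again window.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import numpy as np

from . import dna

DEFAULT_PREFIXES = ("GGATCC", "GAATTC")


@dataclass(frozen=True)
class FeatureParams:
    """Extraction parameters: prefix motifs, FS window length, k-mer length."""

    prefixes: tuple[str, ...] = DEFAULT_PREFIXES
    fs_len: int = 31
    k: int = 31

    def __post_init__(self):
        if not self.prefixes:
            raise ValueError("at least one prefix motif is required")
        for p in self.prefixes:
            if not p or any(ch not in "ACGT" for ch in p):
                raise ValueError(f"prefix {p!r} must be non-empty uppercase ACGT")
        if not 1 <= self.fs_len <= dna.MAX_K or not 1 <= self.k <= dna.MAX_K:
            raise ValueError(f"fs_len and k must be in [1, {dna.MAX_K}]")


@dataclass
class FSet:
    """A multiset of feature elements (FS strings or canonical k-mers).

    Elements are packed uint64 words kept sorted; ``counts`` aligns with
    ``words``.  ``kind`` is "FS" or "KMER"; ``stage`` tracks provenance
    (pool, intersected, final).
    """

    kind: str
    klen: int
    words: np.ndarray
    counts: np.ndarray
    owner: str = ""
    stage: str = "pool"

    def __post_init__(self):
        self.words = np.asarray(self.words, dtype=np.uint64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.words.shape != self.counts.shape:
            raise ValueError("words and counts must align")

    @property
    def n_elements(self) -> int:
        return len(self.words)

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_words(cls, kind: str, klen: int, words: np.ndarray, *,
                   owner: str = "", stage: str = "pool") -> "FSet":
        """Aggregate raw occurrence words (with multiplicity) into an FSet."""
        words = np.asarray(words, dtype=np.uint64)
        uniq, counts = np.unique(words, return_counts=True)
        return cls(kind, klen, uniq, counts.astype(np.int64), owner=owner, stage=stage)

    @classmethod
    def from_dict(cls, kind: str, klen: int, elements: dict[str, int], *,
                  owner: str = "", stage: str = "pool") -> "FSet":
        items = sorted(elements.items())
        words = dna.strings_to_words([s for s, _ in items])
        order = np.argsort(words)
        counts = np.array([c for _, c in items], dtype=np.int64)
        return cls(kind, klen, words[order], counts[order], owner=owner, stage=stage)

    def to_dict(self) -> dict[str, int]:
        return dict(zip(dna.words_to_strings(self.words, self.klen),
                        self.counts.tolist()))

    def element_set(self) -> set[str]:
        return set(dna.words_to_strings(self.words, self.klen))

    def subset_of(self, other: "FSet") -> bool:
        return bool(np.all(np.isin(self.words, other.words)))

    def count_of(self, element: str) -> int:
        w = np.uint64(dna.string_to_word(element))
        i = np.searchsorted(self.words, w)
        if i < len(self.words) and self.words[i] == w:
            return int(self.counts[i])
        return 0


# ---------------------------------------------------------------------------
# Extraction


def _fs_words_2d(codes: np.ndarray, params: FeatureParams) -> np.ndarray:
    """All strand-resolved FS occurrence words in rows of a 2-bit code array."""
    c2 = codes[None, :] if codes.ndim == 1 else codes
    n, L = c2.shape
    fl = params.fs_len
    out: list[np.ndarray] = []
    fs_fwd = fs_rc = None
    any_bad = bool(np.any(c2 > 3))
    if L >= fl + min(len(p) for p in params.prefixes):
        if L >= fl:
            fs_fwd = dna.window_codes(c2, fl)
            fs_rc = dna.window_codes(c2, fl, rc=True)
            fs_ok = dna.valid_windows(c2, fl) if any_bad else None
    if fs_fwd is None:
        return np.empty(0, dtype=np.uint64)
    for prefix in params.prefixes:
        w = len(prefix)
        if L < w:
            continue
        pwords = dna.window_codes(c2, w)
        p_ok = dna.valid_windows(c2, w) if any_bad else None
        pcode = np.uint64(dna.string_to_word(prefix))
        rc_code = np.uint64(dna.string_to_word(dna.revcomp(prefix)))
        # forward strand: prefix at column q, FS = fs_len bases upstream
        hits = pwords == pcode
        if p_ok is not None:
            hits &= p_ok
        rows, cols = np.nonzero(hits)
        keep = cols >= fl
        r, q = rows[keep], cols[keep]
        if len(r):
            vals = fs_fwd[r, q - fl]
            if fs_ok is not None:
                vals = vals[fs_ok[r, q - fl]]
            out.append(vals)
        # reverse strand: revcomp(prefix) at column q; the prefix sits on the
        # reverse strand and its upstream window is the revcomp of the
        # fs_len bases 3' of the match on the forward row
        hits = pwords == rc_code
        if p_ok is not None:
            hits &= p_ok
        rows, cols = np.nonzero(hits)
        keep = cols + w + fl <= L
        r, q = rows[keep], cols[keep]
        if len(r):
            vals = fs_rc[r, q + w]
            if fs_ok is not None:
                vals = vals[fs_ok[r, q + w]]
            out.append(vals)
    if not out:
        return np.empty(0, dtype=np.uint64)
    return np.concatenate(out)


def _kmer_words_2d(codes: np.ndarray, k: int) -> np.ndarray:
    """All canonical k-mer occurrence words in rows of a 2-bit code array."""
    c2 = codes[None, :] if codes.ndim == 1 else codes
    if c2.shape[1] < k:
        return np.empty(0, dtype=np.uint64)
    words = dna.canonical(dna.window_codes(c2, k), k)
    if np.any(c2 > 3):
        words = words[dna.valid_windows(c2, k)]
    return words.ravel()


def extract_feature_sequences(seq: str, params: FeatureParams | None = None) -> Counter:
    """FS multiset of one sequence, scanning both strands.

    Occurrences with fewer than ``fs_len`` upstream bases on their strand,
    or whose window contains a non-ACGT base, are skipped.
    """
    params = params or FeatureParams()
    words = _fs_words_2d(dna.encode(seq), params)
    return Counter(dna.words_to_strings(words, params.fs_len))


def extract_kmers(seq: str, k: int = 31) -> set[str]:
    """Set of canonical k-mers of one sequence (non-ACGT windows skipped)."""
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    words = _kmer_words_2d(dna.encode(seq), k)
    return set(dna.words_to_strings(np.unique(words), k))


def fset_of_sequence(seq_codes: np.ndarray, params: FeatureParams, kind: str, *,
                     owner: str = "", stage: str = "pool") -> FSet:
    """FSet of a raw sequence (e.g. a clone interval) — the truth oracle path."""
    if kind == "FS":
        return FSet.from_words("FS", params.fs_len, _fs_words_2d(seq_codes, params),
                               owner=owner, stage=stage)
    return FSet.from_words("KMER", params.k, _kmer_words_2d(seq_codes, params.k),
                           owner=owner, stage=stage)


# ---------------------------------------------------------------------------
# Pool screening


@dataclass
class ScreenStats:
    n_reads: int = 0
    n_fs_occurrences: int = 0
    n_kmer_occurrences: int = 0


def screen_pool(reads, params: FeatureParams | None = None, *,
                kinds: tuple[str, ...] = ("FS", "KMER"), owner: str = "",
                stats: ScreenStats | None = None):
    """Screen all reads of a pool into its FS-set and/or K-set.

    ``reads`` may be a :class:`~fgm.simulate.ReadBatch`, a 2-D uint8 code
    array, or an iterable of DNA strings.  Returns a dict
    ``{"FS": FSet, "KMER": FSet}`` restricted to the requested kinds.
    """
    from .simulate import ReadBatch  # local import to avoid a cycle

    params = params or FeatureParams()
    if isinstance(reads, ReadBatch):
        mats = [reads.mate1, reads.mate2]
        owner = owner or reads.pool_id
    elif isinstance(reads, np.ndarray):
        mats = [reads]
    else:
        strings = list(reads)
        mats = []
        if strings:
            by_len: dict[int, list[str]] = {}
            for s in strings:
                by_len.setdefault(len(s), []).append(s)
            for same in by_len.values():
                mats.append(np.stack([dna.encode(s) for s in same]))
    fs_parts, km_parts, n_reads = [], [], 0
    for m in mats:
        if m.size == 0:
            continue
        n_reads += len(m)
        if "FS" in kinds:
            fs_parts.append(_fs_words_2d(m, params))
        if "KMER" in kinds:
            km_parts.append(_kmer_words_2d(m, params.k))
    out: dict[str, FSet] = {}
    if "FS" in kinds:
        words = np.concatenate(fs_parts) if fs_parts else np.empty(0, np.uint64)
        out["FS"] = FSet.from_words("FS", params.fs_len, words, owner=owner, stage="pool")
    if "KMER" in kinds:
        words = np.concatenate(km_parts) if km_parts else np.empty(0, np.uint64)
        out["KMER"] = FSet.from_words("KMER", params.k, words, owner=owner, stage="pool")
    if stats is not None:
        stats.n_reads += n_reads
        stats.n_fs_occurrences += int(out["FS"].total_count) if "FS" in out else 0
        stats.n_kmer_occurrences += int(out["KMER"].total_count) if "KMER" in out else 0
    return out


def filter_by_frequency(fset: FSet, f: int = 1) -> FSet:
    """Drop elements whose pool count is <= f (counts preserved for the rest).

    Defined on pool-stage sets only; f=0 is the identity.
    """
    if f < 0:
        raise ValueError("filtering frequency must be >= 0")
    if fset.stage != "pool":
        raise ValueError("frequency filtering applies to pool-stage F-sets")
    keep = fset.counts > f
    return replace(fset, words=fset.words[keep], counts=fset.counts[keep])
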