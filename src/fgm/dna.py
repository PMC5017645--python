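"""Low-level DNA machinery: 2-bit codes and vectorized k-mer windows.

All sequence-heavy operations in the package run on numpy ``uint8`` code
arrays (A=0, C=1, G=2, T=3; 255 marks any other character) and pack k-mers
into ``uint64`` words, base-4 big-endian, so that numeric order on packed
k-mers equals lexicographic order on the strings.  k ≤ 31 fits in a word.
"""

from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

MAX_K = 31


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string into a uint8 code array (255 for non-ACGT)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an uppercase DNA string."""
    if np.any(codes > 3):
        out = np.full(codes.shape, ord("N"), dtype=np.uint8)
        ok = codes <= 3
        out[ok] = _DECODE[codes[ok]]
        return out.tobytes().decode("ascii")
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array (non-ACGT stays invalid)."""
    out = (3 - codes[::-1].astype(np.int16)).astype(np.uint8)
    out[codes[::-1] > 3] = 255
    return out


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def _as2d(codes: np.ndarray) -> np.ndarray:
    return codes[None, :] if codes.ndim == 1 else codes


def window_codes(codes: np.ndarray, k: int, rc: bool = False) -> np.ndarray:
    """Pack every length-k window of each row into a uint64.

    Parameters
    ----------
    codes : (n, L) or (L,) uint8 array of 2-bit base codes.
    k : window length, 1..31.
    rc : if True, return the code of the reverse complement of each window
        (still indexed by the window's position on the forward row).

    Returns
    -------
    (n, L-k+1) uint64 array (or 1-D if the input was 1-D).  Windows that
    contain a non-ACGT base are undefined; use :func:`valid_windows` to
    mask them.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    c2 = _as2d(codes)
    n, L = c2.shape
    if L < k:
        raise ValueError(f"sequence length {L} < k={k}")
    W = L - k + 1
    out = np.zeros((n, W), dtype=np.uint64)
    clean = np.where(c2 > 3, 0, c2).astype(np.uint64)
    if rc:
        for t in range(k):
            out |= (np.uint64(3) - clean[:, t : t + W]) << np.uint64(2 * t)
    else:
        for t in range(k):
            out |= clean[:, t : t + W] << np.uint64(2 * (k - 1 - t))
    return out[0] if codes.ndim == 1 else out


def valid_windows(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of length-k windows made entirely of ACGT."""
    c2 = _as2d(codes)
    bad = (c2 > 3).astype(np.int32)
    cs = np.cumsum(bad, axis=1)
    W = c2.shape[1] - k + 1
    tot = cs[:, k - 1 :].copy()
    tot[:, 1:] -= cs[:, : W - 1]
    mask = tot == 0
    return mask[0] if codes.ndim == 1 else mask


def revcomp_words(words: np.ndarray, k: int) -> np.ndarray:
    """Reverse complement of packed k-mer words (vectorized)."""
    x = np.asarray(words, dtype=np.uint64)
    m2 = np.uint64(0x3333333333333333)
    m4 = np.uint64(0x0F0F0F0F0F0F0F0F)
    # complement every base: XOR all 2k payload bits with 1s
    x = x ^ np.uint64((1 << (2 * k)) - 1)
    # reverse the 32 2-bit groups of the word, then shift payload down
    x = ((x & m2) << np.uint64(2)) | ((x >> np.uint64(2)) & m2)
    x = ((x & m4) << np.uint64(4)) | ((x >> np.uint64(4)) & m4)
    x = x.byteswap()
    return x >> np.uint64(64 - 2 * k)


def canonical(words: np.ndarray, k: int) -> np.ndarray:
    """Canonical form: min(word, revcomp(word)) elementwise."""
    return np.minimum(np.asarray(words, dtype=np.uint64), revcomp_words(words, k))


def word_to_string(word: int, k: int) -> str:
    out = bytearray(k)
    w = int(word)
    for i in range(k - 1, -1, -1):
        out[i] = b"ACGT"[w & 3]
        w >>= 2
    return out.decode("ascii")


def words_to_strings(words: np.ndarray, k: int) -> list[str]:
    return [word_to_string(w, k) for w in np.asarray(words).ravel()]


def string_to_word(s: str) -> int:
    w = 0
    for ch in s:
        code = int(_ENCODE[ord(ch)])
        if code > 3:
            raise ValueError(f"non-ACGT character {ch!r} in k-mer {s!r}")
        w = (w << 2) | code
    return w


def strings_to_words(strings) -> np.ndarray:
    return np.array([string_to_word(s) for s in strings], dtype=np.uint64)
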