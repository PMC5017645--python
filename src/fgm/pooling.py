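"""Combinatorial pool designs for clone deconvolution.

A design places each of ``n`` clones into exactly ``d`` pools, one per
dimension, with ``p`` pools per dimension.  Two strategies:

* ``solid`` — clones are indexed as 3-digit base-``p`` vectors over GF(p)
  and each dimension is a linear form drawn from a planar arc (moment
  curve, plus the nucleus for even characteristic), so any three forms are
  linearly independent.  Consequence: two distinct clones share at most 2
  pools, and all signatures are distinct whenever n <= p**3.
* ``random`` — d independent uniform partitions into p near-equal pools;
  no pair-sharing guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Primitive polynomials for the supported non-prime orders, as coefficient
# lists over the base prime (constant term first).
_PRIMITIVE = {
    4: (2, [1, 1, 1]),        # x^2 + x + 1 over GF(2)
    8: (2, [1, 1, 0, 1]),     # x^3 + x + 1
    9: (3, [1, 0, 1]),        # x^2 + 1 over GF(3)
    16: (2, [1, 1, 0, 0, 1]), # x^4 + x + 1
}

_PRIMES = {2, 3, 5, 7, 11, 13}


class GF:
    """Arithmetic tables for a small finite field of order q.

    Supports prime q in {2,3,5,7,11,13} and prime powers {4,8,9,16} —
    enough for pool designs up to 16 pools per dimension.
    """

    def __init__(self, q: int):
        if q in _PRIMES:
            a = np.arange(q)
            self.add = (a[:, None] + a[None, :]) % q
            self.mul = (a[:, None] * a[None, :]) % q
        elif q in _PRIMITIVE:
            p, poly = _PRIMITIVE[q]
            deg = len(poly) - 1
            elems = [tuple(int(d) for d in np.base_repr(i, p).zfill(deg)[::-1]) for i in range(q)]
            index = {e: i for i, e in enumerate(elems)}

            def padd(x, y):
                return tuple((a + b) % p for a, b in zip(x, y))

            def pmul(x, y):
                prod = [0] * (2 * deg - 1)
                for i, a in enumerate(x):
                    for j, b in enumerate(y):
                        prod[i + j] = (prod[i + j] + a * b) % p
                for k in range(len(prod) - 1, deg - 1, -1):
                    c = prod[k]
                    if c:
                        prod[k] = 0
                        for t in range(deg):
                            prod[k - deg + t] = (prod[k - deg + t] - c * poly[t]) % p
                return tuple(prod[:deg])

            self.add = np.array([[index[padd(x, y)] for y in elems] for x in elems])
            self.mul = np.array([[index[pmul(x, y)] for y in elems] for x in elems])
        else:
            raise ValueError(f"unsupported pool count per dimension: {q}")
        self.q = q

    @property
    def even(self) -> bool:
        return self.q % 2 == 0


def arc_forms(gf: GF) -> list[tuple[int, int, int]]:
    """Linear forms with every 3 linearly independent (a planar arc).

    Moment-curve points (1, t, t*t) for t in GF(q) plus (0, 0, 1); for even
    q the nucleus (0, 1, 0) extends the conic to a hyperoval.  Size q+1
    (odd q) or q+2 (even q) — the maximum number of dimensions a solid
    design over GF(q) can support.
    """
    forms = [(1, t, int(gf.mul[t, t])) for t in range(gf.q)]
    forms.append((0, 0, 1))
    if gf.even:
        forms.append((0, 1, 0))
    return forms


@dataclass
class PoolDesign:
    """Pool membership and per-clone signatures for one design."""

    d: int
    p: int
    strategy: str
    membership: dict[str, set]          # pool id -> clone ids
    signature: dict[str, tuple]         # clone id -> d pool ids (dim order)
    clone_ids: list[str]

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    @property
    def pool_ids(self) -> list[str]:
        return sorted(self.membership)

    def signature_of(self, clone_id: str) -> tuple:
        return self.signature[clone_id]


def _pool_id(dim: int, pool: int) -> str:
    return f"d{dim}p{pool:02d}"


def _clone_id_list(clones) -> list[str]:
    return [c if isinstance(c, str) else c.id for c in clones]


def max_dimensions(p: int) -> int:
    """Largest d a solid design with p pools per dimension supports."""
    return p + 2 if p % 2 == 0 else p + 1


def build_solid_pools(clones, d: int, p: int, seed: int | None = None) -> PoolDesign:
    """GF(p) linear-form ("solid") pooling.

    Clone i is the base-p vector (a, b, c) of its index; dimension j with
    form (alpha, beta, gamma) puts it in pool alpha*a + beta*b + gamma*c of
    that dimension.  Any two clones share at most 2 pools and signatures
    are distinct.  ``seed``, if given, randomizes the clone -> index
    assignment (pool sizes and guarantees are unaffected).
    """
    ids = _clone_id_list(clones)
    n = len(ids)
    if d < 1:
        raise ValueError("d must be >= 1")
    gf = GF(p)
    if n > p**3:
        raise ValueError(f"{n} clones exceed p^3 = {p ** 3} addressable indices")
    forms = arc_forms(gf)
    if d > len(forms):
        raise ValueError(
            f"d={d} exceeds the {len(forms)} independent forms available for p={p}"
        )
    order = np.arange(n)
    if seed is not None:
        order = np.random.default_rng(seed).permutation(n)
    membership: dict[str, set] = {
        _pool_id(j, v): set() for j in range(d) for v in range(p)
    }
    signature: dict[str, tuple] = {}
    add, mul = gf.add, gf.mul
    for i, cid in zip(order, ids):
        a, b, c = (int(i) // (p * p)) % p, (int(i) // p) % p, int(i) % p
        sig = []
        for j, (al, be, ga) in enumerate(forms[:d]):
            v = add[add[mul[al, a], mul[be, b]], mul[ga, c]]
            pid = _pool_id(j, int(v))
            membership[pid].add(cid)
            sig.append(pid)
        signature[cid] = tuple(sig)
    return PoolDesign(d, p, "solid", membership, signature, ids)


def build_random_pools(clones, d: int, p: int, seed: int = 0) -> PoolDesign:
    """d independent uniform partitions into p pools of near-equal size."""
    ids = _clone_id_list(clones)
    n = len(ids)
    if d < 1:
        raise ValueError("d must be >= 1")
    rng = np.random.default_rng(seed)
    membership = {_pool_id(j, v): set() for j in range(d) for v in range(p)}
    sigs = [[] for _ in range(n)]
    for j in range(d):
        perm = rng.permutation(n)
        for slot, i in enumerate(perm):
            v = slot % p
            pid = _pool_id(j, v)
            membership[pid].add(ids[i])
            sigs[i].append(pid)
    signature = {ids[i]: tuple(sigs[i]) for i in range(n)}
    return PoolDesign(d, p, "random", membership, signature, ids)


def max_shared_pools(design: PoolDesign) -> int:
    """Exhaustive max over clone pairs of shared pool count (O(n^2))."""
    sigs = [set(design.signature[c]) for c in design.clone_ids]
    best = 0
    for i in range(len(sigs)):
        for j in range(i + 1, len(sigs)):
            best = max(best, len(sigs[i] & sigs[j]))
    return best
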