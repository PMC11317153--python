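"""Substitution-tolerant k-mer encoding and the fixed-size hash tables.

The encoder maps every DNA k-mer to ``ell`` integer indices in ``[0, 2**k)``
using hash functions built from three complementary base-partition maps:

* ``F1`` sends {A,T} to 0 and {C,G} to 1,
* ``F2`` sends {A,C} to 0 and {T,G} to 1,
* ``F3`` sends {A,G} to 0 and {T,C} to 1.

For every unordered pair of distinct bases exactly one map assigns the two
bases the same bit, so a single hash function built from one map per k-mer
locus tolerates four of the twelve substitution types at that locus.  When
the per-locus map assignments of the ``ell`` functions form permutations of
(F1, F2, F3), every possible single-base substitution is tolerated by at
least one of the functions: the substituted k-mer collides with the
original in at least one table index.

Indices are canonicalized over strands: the encoded value is the minimum of
the code of the k-mer and the code of its reverse complement, so a k-mer
and its reverse complement always index the same table slots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# base codes: A=0 C=1 G=2 T=3; 4 marks any non-ACGT character
A, C, G, T = 0, 1, 2, 3
INVALID = 4

#: bit assigned to each base code by the three partition maps, row = map id
BASE_MAP_BITS = np.array(
    [
        [0, 1, 1, 0],  # F1: {A,T}->0 {C,G}->1
        [0, 0, 1, 1],  # F2: {A,C}->0 {T,G}->1
        [0, 1, 0, 1],  # F3: {A,G}->0 {T,C}->1
    ],
    dtype=np.uint8,
)

BASE_MAP_NAMES = ("F1", "F2", "F3")

_CODE_LUT = np.full(256, INVALID, dtype=np.uint8)
for _b, _c in zip(b"ACGT", (A, C, G, T)):
    _CODE_LUT[_b] = _c
for _b, _c in zip(b"acgt", (A, C, G, T)):
    _CODE_LUT[_b] = _c

_COMPLEMENT = np.array([T, G, C, A, INVALID], dtype=np.uint8)


def seq_to_codes(seq: str | bytes) -> np.ndarray:
    """Convert a DNA string to the internal base-code array (non-ACGT -> 4)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE_LUT[np.frombuffer(seq, dtype=np.uint8)]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes][::-1]


def revcomp(seq: str) -> str:
    tbl = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(tbl)[::-1]


class ParameterError(ValueError):
    """Invalid encoder or table parameter."""


@dataclass(frozen=True)
class HashFunctionSet:
    """The per-locus base-map assignment shared by all pipeline stages.

    ``assignment[i, j]`` is the id (0..2) of the partition map used by hash
    function ``i`` at k-mer locus ``j``.  At every locus the column of ids is
    a prefix of a concatenation of ceil(ell/3) random permutations of
    (F1, F2, F3); in particular for ``ell == 3`` each locus uses each map
    exactly once, which is what yields single-substitution tolerance.
    """

    k: int
    ell: int
    seed: int
    assignment: np.ndarray  # shape (ell, k), uint8 map ids

    #: per-function bit lookup, shape (ell, k, 5); the extra column absorbs
    #: INVALID codes so bulk lookups never index out of range
    _bits: np.ndarray = field(init=False, repr=False, compare=False)
    _weights: np.ndarray = field(init=False, repr=False, compare=False)

    _packed: np.ndarray | None = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        bits = np.zeros((self.ell, self.k, 5), dtype=np.uint8)
        bits[:, :, :4] = BASE_MAP_BITS[self.assignment]
        object.__setattr__(self, "_bits", bits)
        pow2 = (1 << np.arange(self.k, dtype=np.uint64)).astype(np.int64)
        weights = bits.astype(np.int64) * pow2[None, :, None]
        object.__setattr__(self, "_weights", weights)
        # all ell per-function weights packed into one int64 (k-bit fields)
        # when they fit: one table lookup per locus instead of ell
        if self.ell * self.k <= 63:
            shifts = (np.arange(self.ell, dtype=np.int64) * self.k)[:, None, None]
            packed = (weights << shifts).sum(axis=0)
            object.__setattr__(self, "_packed", packed)
        else:
            object.__setattr__(self, "_packed", None)

    @property
    def table_size(self) -> int:
        return 1 << self.k


def build_hash_functions(k: int = 32, ell: int = 3, seed: int = 1) -> HashFunctionSet:
    """Randomly assign base maps to the ``ell`` hash functions at each locus.

    At each of the ``k`` loci, ceil(ell/3) of the 3! = 6 permutations of
    (F1, F2, F3) are drawn and concatenated; function ``i`` uses entry ``i``
    of the concatenation.  Deterministic for a fixed ``seed``.
    """
    if k < 4:
        raise ParameterError(f"k must be >= 4, got {k}")
    if ell < 1:
        raise ParameterError(f"ell must be >= 1, got {ell}")
    perms = np.array(list(_all_permutations()), dtype=np.uint8)  # (6, 3)
    n_perm = -(-ell // 3)  # ceil
    rng = np.random.default_rng(seed)
    choice = rng.integers(0, 6, size=(n_perm, k))
    concat = perms[choice]  # (n_perm, k, 3)
    assignment = np.ascontiguousarray(
        concat.transpose(0, 2, 1).reshape(n_perm * 3, k)[:ell]
    )
    return HashFunctionSet(k=k, ell=ell, seed=seed, assignment=assignment)


def _all_permutations():
    from itertools import permutations

    return permutations(range(3))


@dataclass(frozen=True)
class EncodedKmer:
    """Canonical table indices of one k-mer under every hash function."""

    indices: tuple[int, ...]
    canonical: bool = True


def encode_codes(hfs: HashFunctionSet, codes: np.ndarray) -> np.ndarray | None:
    """Encode a single k-mer given as a code array; None if it has non-ACGT."""
    if codes.shape[0] != hfs.k or np.any(codes >= INVALID):
        return None
    idx, valid = encode_sequence(hfs, codes)
    return idx[:, 0]


def encode_kmer(hfs: HashFunctionSet, kmer: str) -> EncodedKmer | None:
    """Canonical indices of ``kmer``; None for k-mers with ambiguous bases.

    The per-function code is delta = sum_j bit_j * 2**(j-1) (1-based j), and
    the canonical index is min(delta(kmer), delta(revcomp(kmer))).
    """
    if len(kmer) != hfs.k:
        raise ParameterError(f"k-mer length {len(kmer)} != k={hfs.k}")
    idx = encode_codes(hfs, seq_to_codes(kmer))
    if idx is None:
        return None
    return EncodedKmer(indices=tuple(int(v) for v in idx))


def encode_sequence(hfs: HashFunctionSet, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Canonical indices for every k-mer window of a code array.

    Returns ``(indices, valid)`` where ``indices`` has shape
    ``(ell, n_windows)`` with ``n_windows = len(codes) - k + 1`` and
    ``valid[w]`` is False for windows containing a non-ACGT code (their
    indices are meaningless and must be skipped by callers).

    Windows are scanned in a handful of vectorized passes: the weight of
    locus j under function i is ``bit * 2**j``, accumulated over the k
    offsets, which avoids materializing an (n, k) window matrix.
    """
    n = codes.shape[0] - hfs.k + 1
    if n <= 0:
        return np.zeros((hfs.ell, 0), dtype=np.int64), np.zeros(0, dtype=bool)
    fwd = _raw_deltas(hfs, codes, n)
    rc = _raw_deltas(hfs, revcomp_codes(codes), n)[:, ::-1]
    indices = np.minimum(fwd, rc)
    bad = (codes >= INVALID).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[hfs.k:] - cs[:n]) == 0
    return indices, valid


def forward_deltas(hfs: HashFunctionSet, codes: np.ndarray) -> np.ndarray:
    """Per-function codes of every window on the given strand only (no
    reverse-complement canonicalization); shape (ell, n_windows)."""
    n = codes.shape[0] - hfs.k + 1
    if n <= 0:
        return np.zeros((hfs.ell, 0), dtype=np.int64)
    return _raw_deltas(hfs, codes, n)


def _raw_deltas(hfs: HashFunctionSet, codes: np.ndarray, n: int) -> np.ndarray:
    if hfs._packed is not None:
        acc = np.zeros(n, dtype=np.int64)
        for j in range(hfs.k):
            acc += hfs._packed[j][codes[j : j + n]]
        mask = (1 << hfs.k) - 1
        out = np.empty((hfs.ell, n), dtype=np.int64)
        for i in range(hfs.ell):
            out[i] = (acc >> (i * hfs.k)) & mask
        return out
    out = np.zeros((hfs.ell, n), dtype=np.int64)
    w = hfs._weights  # (ell, k, 5)
    for j in range(hfs.k):
        col = codes[j : j + n]
        for i in range(hfs.ell):
            out[i] += w[i, j][col]
    return out


@dataclass
class KmerCountTable:
    """Byte-counter array Q of size 2**k with exact/fuzzy query semantics.

    Counters saturate at 255 instead of wrapping, so the per-locus count
    signal D = max(q_1..q_ell) stays monotone under repeated increments.
    """

    k: int
    ell: int
    hit_threshold: int = 3
    counters: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counters is None:
            self.counters = np.zeros(1 << self.k, dtype=np.uint8)

    @property
    def size(self) -> int:
        return self.counters.shape[0]


def new_count_table(hfs: HashFunctionSet, hit_threshold: int = 3) -> KmerCountTable:
    return KmerCountTable(k=hfs.k, ell=hfs.ell, hit_threshold=hit_threshold)


def increment_counts(table: KmerCountTable, enc: EncodedKmer) -> KmerCountTable:
    """Increment the ell slots indexed by one encoded k-mer, saturating at 255."""
    idx = np.asarray(enc.indices, dtype=np.int64)
    cur = table.counters[idx].astype(np.uint16)
    table.counters[idx] = np.minimum(cur + 1, 255).astype(np.uint8)
    return table


def bulk_increment(table: KmerCountTable, indices: np.ndarray) -> None:
    """Add one count per index (flat array, duplicates allowed), saturating.

    Uses a bincount per batch so saturated slots never wrap.
    """
    if indices.size == 0:
        return
    add = np.bincount(indices, minlength=table.size)
    touched = add.nonzero()[0]
    cur = table.counters[touched].astype(np.int64)
    table.counters[touched] = np.minimum(cur + add[touched], 255).astype(np.uint8)


def query_hit_flags(table: KmerCountTable, enc: EncodedKmer) -> tuple[int, int, int]:
    """Exact-hit flag E, fuzzy-hit flag Z and count signal D for one k-mer.

    E = 1 iff min(q_1..q_ell) >= t (all functions agree the k-mer was seen),
    Z = 1 iff max(q_1..q_ell) >= t (some function saw it, possibly via a
    substituted variant), and D = max(q_1..q_ell).  E <= Z always.
    """
    q = table.counters[np.asarray(enc.indices, dtype=np.int64)]
    if q.shape[0] != table.ell:
        raise ParameterError("encoded k-mer and table disagree on ell")
    t = table.hit_threshold
    mx = int(q.max())
    return int(q.min() >= t), int(mx >= t), mx


def scan_reference(
    table: KmerCountTable, hfs: HashFunctionSet, codes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (E, Z, D) arrays over every k-mer window of a sequence.

    Windows containing ambiguous bases get E = Z = D = 0.
    """
    if table.k != hfs.k:
        raise ParameterError("table and hash functions disagree on k")
    idx, valid = encode_sequence(hfs, codes)
    n = idx.shape[1]
    if n == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z.copy(), z.copy()
    safe = np.where(valid[None, :], idx, 0)
    q = table.counters[safe].astype(np.int64)  # (ell, n)
    qmin = q.min(axis=0)
    qmax = q.max(axis=0)
    t = table.hit_threshold
    E = ((qmin >= t) & valid).astype(np.int64)
    Z = ((qmax >= t) & valid).astype(np.int64)
    D = np.where(valid, qmax, 0)
    return E, Z, D


@dataclass
class MarkerTable:
    """Array B mapping encoded marker k-mers to global candidate-breakpoint ids.

    Slots hold -1 when empty.  Four-byte signed slots, 2**k of them.
    """

    k: int
    ell: int
    loci: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.loci is None:
            self.loci = np.full(1 << self.k, -1, dtype=np.int32)

    @property
    def size(self) -> int:
        return self.loci.shape[0]
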