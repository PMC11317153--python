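"""From reads + reference to candidate HGT-related segments.

Stages, in pipeline order:

1. ``downsample_and_count`` — sample read pairs at rate M/A and accumulate
   their k-mers into the count table Q.
2. ``screen_present_fragments`` — tile each reference sequence into windows
   of w bp and keep windows whose exact / fuzzy hit ratios reach m1 / m2;
   only genomes actually present in the sample survive this screen.
3. ``detect_cbkps`` — inside present windows, find loci where the binned
   k-mer count signal D jumps by more than theta: candidate breakpoints.
   A read set drawn from a rearranged genome leaves exactly such steps at
   junction loci of the clean reference (a coverage dip on the recipient
   where no read supports the pre-insertion k-mers, a coverage step on the
   donor at the transferred interval's ends).
4. ``build_marker_table`` / ``pair_hgt_cbkps`` — recognize candidate loci
   inside raw read pairs via their marker k-mers; two candidates from
   different species retrieved by one read pair are HGT-derived.
5. ``extract_segments`` — cut +-500 bp of reference around HGT-derived
   candidates; these small segments are the alignment target downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core_encoding import (
    INVALID,
    HashFunctionSet,
    KmerCountTable,
    MarkerTable,
    bulk_increment,
    encode_sequence,
    new_count_table,
    scan_reference,
    seq_to_codes,
)
from .reference_io import ReferenceDatabase

DEFAULT_M = 2_000_000_000  # target base budget for downsampling
DEFAULT_WINDOW = 500
DEFAULT_M1 = 0.08
DEFAULT_M2 = 0.1
DEFAULT_BIN = 5
DEFAULT_THETA = 3.0
SEGMENT_FLANK = 500


class EmptyInputError(ValueError):
    pass


@dataclass(frozen=True)
class SamplingPlan:
    """Per-read-pair Bernoulli downsampling at rate min(1, M/A)."""

    M: float
    A: int
    rate: float
    seed: int


def make_sampling_plan(M: float, A: int, seed: int) -> SamplingPlan:
    if A <= 0:
        raise EmptyInputError("no input bases (A = 0)")
    return SamplingPlan(M=M, A=A, rate=min(1.0, M / A), seed=seed)


ReadPair = tuple[str, str, str]  # (id, seq1, seq2)


@dataclass
class KmerScanCache:
    """Packed canonical indices of the selected reads' k-mers, per batch.

    Each batch holds (packed, valid, owner): the ell canonical indices of a
    window packed into one int64 (k-bit fields), a validity mask, and the
    read-pair index owning each window.  Lets the marker-pairing step skip
    re-encoding; only built when ell * k fits the packing (<= 63 bits).
    """

    k: int
    ell: int
    batch_pairs: int = 20_000
    n_pairs: int = 0
    batches: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=list)

    def unpack(self, packed: np.ndarray) -> np.ndarray:
        mask = (1 << self.k) - 1
        return np.stack([(packed >> (i * self.k)) & mask for i in range(self.ell)])


def downsample_and_count(
    pairs: Sequence[ReadPair],
    hfs: HashFunctionSet,
    M: float = DEFAULT_M,
    seed: int = 1,
    hit_threshold: int = 3,
    batch_pairs: int = 20_000,
) -> tuple[KmerCountTable, list[ReadPair], SamplingPlan, KmerScanCache | None]:
    """Select read pairs at rate M/A and count their k-mers into Q.

    Returns the filled table, the selected pairs (re-used verbatim by the
    marker-pairing step), the sampling plan, and a scan cache of the
    encoded indices.  Deterministic under seed.
    """
    pairs = list(pairs)
    A = sum(len(s1) + len(s2) for _, s1, s2 in pairs)
    plan = make_sampling_plan(M, A, seed)
    rng = np.random.default_rng(seed)
    if plan.rate >= 1.0:
        selected = pairs
        rng.random(len(pairs))  # keep the stream position independent of rate
    else:
        keep = rng.random(len(pairs)) < plan.rate
        selected = [p for p, k in zip(pairs, keep) if k]
    table = new_count_table(hfs, hit_threshold=hit_threshold)
    cache = None
    if hfs.ell * hfs.k <= 63:
        cache = KmerScanCache(
            k=hfs.k, ell=hfs.ell, batch_pairs=batch_pairs, n_pairs=len(selected)
        )
    for start in range(0, len(selected), batch_pairs):
        batch = selected[start : start + batch_pairs]
        codes = _join_codes([s for _, s1, s2 in batch for s in (s1, s2)])
        idx, valid = encode_sequence(hfs, codes)
        flat = idx[:, valid].ravel()
        bulk_increment(table, flat)
        if cache is not None:
            packed = idx[0].copy()
            for i in range(1, hfs.ell):
                packed |= idx[i] << (i * hfs.k)
            own = _batch_owners(batch, idx.shape[1])
            cache.batches.append((packed, valid, own))
    return table, selected, plan, cache


def _batch_owners(batch: Sequence[ReadPair], n_windows: int) -> np.ndarray:
    """Read-pair index owning each window of the joined batch code array."""
    owner: list[int] = []
    length: list[int] = []
    for pi, (_, s1, s2) in enumerate(batch):
        for s in (s1, s2):
            owner.append(pi)
            length.append(len(s) + 1)  # + joining separator
    if not owner:
        return np.zeros(0, dtype=np.int64)
    length[-1] -= 1
    return np.repeat(np.asarray(owner), np.asarray(length))[:n_windows]


def _join_codes(seqs: list[str]) -> np.ndarray:
    """Concatenate sequences with an invalid-code separator so k-mer windows
    never straddle two reads."""
    if not seqs:
        return np.zeros(0, dtype=np.uint8)
    return seq_to_codes("N".join(seqs))


# ---------------------------------------------------------------------------
# window screening

@dataclass(frozen=True)
class WindowVerdict:
    sequence: str
    window_start: int
    window_len: int
    u: int          # number of k-mers in the window
    kappa: float    # exact hit ratio
    mu: float       # fuzzy hit ratio
    present: bool


def hit_ratios(E: np.ndarray, Z: np.ndarray) -> tuple[float, float]:
    """Exact and fuzzy hit ratios kappa and mu of one window's flag arrays."""
    u = len(E)
    if u == 0:
        return 0.0, 0.0
    return float(np.sum(E) / u), float(np.sum(Z) / u)


def screen_present_fragments(
    ref: ReferenceDatabase,
    table: KmerCountTable,
    hfs: HashFunctionSet,
    w: int = DEFAULT_WINDOW,
    m1: float = DEFAULT_M1,
    m2: float = DEFAULT_M2,
) -> list[WindowVerdict]:
    """Tile every reference sequence into windows of w bp and score each.

    A window is *present* iff kappa >= m1 and mu >= m2.  Sequences shorter
    than w form a single truncated window.  Windows step by w (tiles).
    """
    if w <= hfs.k:
        raise ValueError(f"window {w} must exceed k={hfs.k}")
    verdicts: list[WindowVerdict] = []
    for name, seq in ref.sequences.items():
        E, Z, _ = scan_reference(table, hfs, seq_to_codes(seq))
        L = len(seq)
        for start in range(0, max(1, L), w):
            end = min(start + w, L)
            if end - start < hfs.k and start > 0:
                continue  # tail shorter than one k-mer merges into nothing
            kE = E[start : max(start, end - hfs.k + 1)]
            kZ = Z[start : max(start, end - hfs.k + 1)]
            kappa, mu = hit_ratios(kE, kZ)
            verdicts.append(
                WindowVerdict(
                    sequence=name, window_start=start, window_len=end - start,
                    u=len(kE), kappa=kappa, mu=mu,
                    present=(kappa >= m1 and mu >= m2),
                )
            )
    return verdicts


def present_regions(verdicts: Iterable[WindowVerdict]) -> dict[str, list[tuple[int, int]]]:
    """Merge adjacent present windows into half-open regions per sequence."""
    regions: dict[str, list[tuple[int, int]]] = {}
    for v in verdicts:
        if not v.present:
            continue
        lst = regions.setdefault(v.sequence, [])
        start, end = v.window_start, v.window_start + v.window_len
        if lst and lst[-1][1] >= start:
            lst[-1] = (lst[-1][0], max(lst[-1][1], end))
        else:
            lst.append((start, end))
    return regions


# ---------------------------------------------------------------------------
# candidate breakpoints

@dataclass
class CandidateBreakpoint:
    """A reference locus with an abrupt k-mer count change (cBKP)."""

    genome: str
    locus: int          # 0-based
    marker: str         # reference k-mer starting at locus
    id: int = -1        # global id, assigned by build_marker_table callers
    hgt_derived: bool = False


def cbkp_loci_from_counts(D: np.ndarray, e: int, k: int, theta: float) -> np.ndarray:
    """Bin-difference scan of one count profile; returns sorted unique loci.

    xi_z is the mean of D over [z, z+e).  Each bin start z is compared with
    bins starting at z+e .. z+e+k; a difference above theta selects z, a
    difference below -theta selects the later bin's start.
    """
    n = D.shape[0]
    if n < 2 * e:
        return np.zeros(0, dtype=np.int64)
    cs = np.concatenate(([0.0], np.cumsum(D, dtype=np.float64)))
    nbins = n - e + 1
    xi = (cs[e:] - cs[:-e]) / e  # xi[z], z in [0, nbins)
    hits: list[np.ndarray] = []
    for off in range(e, e + k + 1):
        m = nbins - off
        if m <= 0:
            break
        eps = xi[:m] - xi[off : off + m]
        z = np.nonzero(eps > theta)[0]
        d = np.nonzero(eps < -theta)[0] + off
        if z.size:
            hits.append(z)
        if d.size:
            hits.append(d)
    if not hits:
        return np.zeros(0, dtype=np.int64)
    return np.unique(np.concatenate(hits))


def detect_cbkps(
    ref: ReferenceDatabase,
    table: KmerCountTable,
    hfs: HashFunctionSet,
    e: int = DEFAULT_BIN,
    theta: float = DEFAULT_THETA,
    regions: dict[str, list[tuple[int, int]]] | None = None,
) -> list[CandidateBreakpoint]:
    """Candidate breakpoints inside present regions of every sequence.

    ``regions`` restricts the scan (pass ``present_regions(verdicts)``);
    when None the whole of every sequence is scanned.
    """
    out: list[CandidateBreakpoint] = []
    for name, seq in ref.sequences.items():
        seq_regions = regions.get(name, []) if regions is not None else [(0, len(seq))]
        if not seq_regions:
            continue
        _, _, D = scan_reference(table, hfs, seq_to_codes(seq))
        for start, end in seq_regions:
            hi = min(end - hfs.k + 1, D.shape[0])
            if hi <= start:
                continue
            loci = cbkp_loci_from_counts(D[start:hi], e, hfs.k, theta) + start
            for z in loci:
                marker = seq[z : z + hfs.k]
                if len(marker) < hfs.k:
                    continue
                out.append(CandidateBreakpoint(genome=name, locus=int(z), marker=marker))
    for i, c in enumerate(out):
        c.id = i
    return out


def build_marker_table(
    cbkps: list[CandidateBreakpoint],
    ref: ReferenceDatabase,
    table: KmerCountTable,
    hfs: HashFunctionSet,
) -> MarkerTable:
    """Store each candidate's marker k-mer indices -> its global id in B.

    Markers whose count in Q is zero everywhere are omitted (their locus is
    unsupported by any read).  Colliding slots: last writer wins, in
    candidate-id order.
    """
    B = MarkerTable(k=hfs.k, ell=hfs.ell)
    if not cbkps:
        return B
    by_seq: dict[str, list[CandidateBreakpoint]] = {}
    for c in cbkps:
        by_seq.setdefault(c.genome, []).append(c)
    for name, cs in by_seq.items():
        idx, valid = encode_sequence(hfs, seq_to_codes(ref.sequences[name]))
        loci = np.array([c.locus for c in cs], dtype=np.int64)
        ids = np.array([c.id for c in cs], dtype=np.int32)
        inside = loci < idx.shape[1]
        loci, ids = loci[inside], ids[inside]
        midx = idx[:, loci]                  # (ell, n_markers)
        ok = valid[loci] & (table.counters[midx].max(axis=0) > 0)
        order = np.argsort(ids[ok], kind="stable")
        sel = midx[:, ok][:, order]
        B.loci[sel.ravel(order="F")] = np.repeat(ids[ok][order], hfs.ell)
    return B


def pair_hgt_cbkps(
    selected_pairs: Sequence[ReadPair],
    B: MarkerTable,
    hfs: HashFunctionSet,
    species_of: dict[str, str],
    cbkps: list[CandidateBreakpoint],
    batch_pairs: int = 20_000,
    cache: KmerScanCache | None = None,
) -> list[tuple[int, int]]:
    """Flag HGT-derived candidates via cross-species read-pair co-retrieval.

    Re-enumerates the k-mers of the selected read pairs, retrieves candidate
    ids from B, and whenever one read pair retrieves two candidates from
    different species, marks both ``hgt_derived`` and emits the id pairing.
    """
    by_id = {c.id: c for c in cbkps}
    max_id = max(by_id) if by_id else -1
    # integer species codes per cBKP id, for vectorized group tests
    species_names = sorted({species_of[c.genome] for c in cbkps}) if cbkps else []
    sp_code = {s: i for i, s in enumerate(species_names)}
    id_species = np.full(max_id + 1, -1, dtype=np.int64)
    for c in cbkps:
        id_species[c.id] = sp_code[species_of[c.genome]]
    pairings: set[tuple[int, int]] = set()
    if cache is not None and (
        cache.k != hfs.k
        or cache.ell != hfs.ell
        or cache.batch_pairs != batch_pairs
        or cache.n_pairs != len(selected_pairs)
    ):
        cache = None
    n_batches = -(-len(selected_pairs) // batch_pairs) if selected_pairs else 0
    for bi in range(n_batches):
        start = bi * batch_pairs
        batch = selected_pairs[start : start + batch_pairs]
        if cache is not None and bi < len(cache.batches):
            packed, valid, own = cache.batches[bi]
            idx = cache.unpack(packed)
        else:
            codes = _join_codes([s for _, s1, s2 in batch for s in (s1, s2)])
            idx, valid = encode_sequence(hfs, codes)
            own = _batch_owners(batch, idx.shape[1])
        ids = B.loci[idx]              # (ell, n)
        ids[:, ~valid] = -1
        mask = ids >= 0
        if not mask.any():
            continue
        flat_ids = ids[mask]
        flat_own = np.broadcast_to(own, ids.shape)[mask]
        # unique (read pair, id) combos, sorted by pair then id
        combo = flat_own * np.int64(max_id + 1) + flat_ids
        combo = np.sort(combo)
        if combo.shape[0] > 1:
            combo = combo[np.concatenate(([True], np.diff(combo) != 0))]
        grp_pair = combo // (max_id + 1)
        grp_id = combo % (max_id + 1)
        grp_sp = id_species[grp_id]
        starts = np.concatenate(([0], np.nonzero(np.diff(grp_pair))[0] + 1))
        # a read pair retrieving ids of >= 2 species flags every retrieved
        # id: each then has a partner of a different species in that pair
        sp_bits = np.left_shift(np.int64(1), grp_sp)
        group_mask = np.bitwise_or.reduceat(sp_bits, starts)
        multi = (group_mask & (group_mask - 1)) != 0  # >= 2 bits set
        sizes = np.diff(np.concatenate((starts, [grp_pair.shape[0]])))
        row_multi = np.repeat(multi, sizes)
        hgt_flag = np.zeros(max_id + 1, dtype=bool)
        hgt_flag[grp_id[row_multi]] = True
        for i in np.nonzero(hgt_flag)[0]:
            c = by_id.get(int(i))
            if c is not None and not c.hgt_derived:
                c.hgt_derived = True
        # record explicit id pairings for small groups (test-scale fixtures)
        small = np.nonzero(multi & (sizes <= 8))[0]
        for gi in small:
            ids_here = grp_id[starts[gi] : starts[gi] + sizes[gi]]
            for x in range(len(ids_here)):
                for y in range(x + 1, len(ids_here)):
                    a, b = int(ids_here[x]), int(ids_here[y])
                    if id_species[a] != id_species[b]:
                        pairings.add((min(a, b), max(a, b)))
    return sorted(pairings)


# ---------------------------------------------------------------------------
# segment extraction

@dataclass
class SegmentSet:
    """Extracted reference segments plus the coordinate-lift table.

    Segment names are ``<source>|<offset>`` so any alignment position lifts
    back to the reference with one addition.
    """

    sequences: dict[str, str] = field(default_factory=dict)
    source: dict[str, tuple[str, int]] = field(default_factory=dict)

    def lift(self, segment_name: str, pos: int) -> tuple[str, int]:
        src, off = self.source[segment_name]
        return src, off + pos

    def write_fasta(self, path: str | Path) -> None:
        from .reference_io import write_fasta

        write_fasta(path, self.sequences)

    def write_sidecar(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            [(n, s, o) for n, (s, o) in self.source.items()],
            columns=["segment", "source_sequence", "source_offset"],
        ).to_csv(path, sep="\t", index=False)


def extract_segments(
    ref: ReferenceDatabase,
    cbkps: list[CandidateBreakpoint],
    flank: int = SEGMENT_FLANK,
) -> SegmentSet:
    """+-flank bp of reference around every HGT-derived candidate, merged.

    Overlapping or adjacent intervals on one sequence fuse into a single
    segment to avoid duplicate alignment targets.
    """
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for c in cbkps:
        if not c.hgt_derived:
            continue
        L = ref.lengths[c.genome]
        by_seq.setdefault(c.genome, []).append(
            (max(0, c.locus - flank), min(L, c.locus + flank))
        )
    segs = SegmentSet()
    for name, ivals in sorted(by_seq.items()):
        ivals.sort()
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            seg_name = f"{name}|{s}"
            segs.sequences[seg_name] = ref.sequences[name][s:e]
            segs.source[seg_name] = (name, s)
    return segs
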