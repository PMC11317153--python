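"""Post-hoc junction analyses: microhomology and between-sample similarity.

Microhomology — a short identical sequence present on both sides of a
junction — is the signature of end-joining repair.  For each breakpoint
pair we take the 10 bp of reference retained on each side of the joint
(in fused-molecule orientation) and measure the longest identical run
spanning the junction.  Enrichment over chance is assessed against
hypothetical pairs built by re-pairing breakpoints at random.

Between-sample similarity uses Spearman correlation over breakpoint-pair
presence/absence arrays and the Jaccard coefficient
J(A, B) = |A n B| / |A u B| over event sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .reference_io import ReferenceDatabase

DEFAULT_FLANK = 10

#: a breakpoint as (genome, 0-based position, retained side 'L'/'R')
Breakpoint = tuple[str, int, str]


def needleman_wunsch(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -1) -> tuple[str, str]:
    """Global alignment of two short strings; ties prefer diagonal moves."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    H[:, 0] = gap * np.arange(n + 1)
    H[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(H[i - 1, j - 1] + s, H[i - 1, j] + gap, H[i, j - 1] + gap)
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                out_a.append(a[i - 1]); out_b.append(b[j - 1])
                i, j = i - 1, j - 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] + gap:
            out_a.append(a[i - 1]); out_b.append("-")
            i -= 1
        else:
            out_b.append(b[j - 1]); out_a.append("-")
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def microhomology_length(flank_up: str, flank_down: str) -> int:
    """Longest junction-spanning identical run between the two flanks.

    ``flank_up`` ends at the junction and ``flank_down`` starts at it, so
    the run is the maximal L with flank_up[-L:] == flank_down[:L] — the run
    a global overlap alignment of the two flanks places across the joint.
    """
    best = 0
    for L in range(1, min(len(flank_up), len(flank_down)) + 1):
        if flank_up[-L:] == flank_down[:L]:
            best = L
    return best


@dataclass(frozen=True)
class MicrohomologyResult:
    flank_a: str
    flank_b: str
    homology_len: int
    truncated: bool


def _retained_flank(ref: ReferenceDatabase, bkp: Breakpoint, flank: int, role: str) -> tuple[str, bool]:
    """Flank of the retained sequence in fused-molecule orientation.

    ``role`` 'up' yields the ``flank`` bases ending at the junction,
    'down' the bases starting at it; a retained-right side contributes its
    reverse complement when it plays the upstream role (and vice versa).
    """
    from .core_encoding import revcomp

    genome, pos, side = bkp
    seq = ref.sequences[genome]
    if side == "?":
        side = "L" if role == "up" else "R"
    if side == "L":
        lo = max(0, pos - flank)
        piece, trunc = seq[lo:pos], pos - flank < 0
        if role == "down":
            piece = revcomp(piece)
    else:
        hi = min(len(seq), pos + flank)
        piece, trunc = seq[pos:hi], pos + flank > len(seq)
        if role == "up":
            piece = revcomp(piece)
    return piece, trunc


def microhomology(
    ref: ReferenceDatabase,
    bkp_a: Breakpoint,
    bkp_b: Breakpoint,
    flank: int = DEFAULT_FLANK,
) -> MicrohomologyResult:
    """Microhomology of one breakpoint pair from the reference flanks."""
    fa, ta = _retained_flank(ref, bkp_a, flank, "up")
    fb, tb = _retained_flank(ref, bkp_b, flank, "down")
    return MicrohomologyResult(
        flank_a=fa, flank_b=fb,
        homology_len=microhomology_length(fa, fb),
        truncated=ta or tb,
    )


@dataclass(frozen=True)
class BackgroundReport:
    observed_lengths: np.ndarray
    background_lengths: np.ndarray
    ranksum_stat: float
    ranksum_p: float
    observed_frac_gt5: float
    background_frac_gt5: float
    degenerate: bool


def microhomology_background(
    ref: ReferenceDatabase,
    observed_pairs: list[tuple[Breakpoint, Breakpoint]],
    n: int = 10_000,
    seed: int = 1,
    flank: int = DEFAULT_FLANK,
) -> BackgroundReport:
    """Observed vs re-paired background microhomology distributions.

    Samples up to ``n`` observed pairs and builds ``n`` hypothetical pairs
    by drawing two breakpoints (without replacement within a pair) from the
    pooled breakpoint set, then compares the two length distributions with
    the Wilcoxon rank-sum test and reports the > 5 bp fractions.
    """
    pool: list[Breakpoint] = []
    for a, b in observed_pairs:
        pool.extend((a, b))
    if len(pool) < 2:
        raise ValueError("need at least 2 breakpoints")
    rng = np.random.default_rng(seed)
    if len(observed_pairs) >= n:
        chosen = [observed_pairs[i] for i in rng.choice(len(observed_pairs), n, replace=False)]
    else:
        warnings.warn("fewer observed pairs than requested; sampling with replacement")
        chosen = [observed_pairs[i] for i in rng.choice(len(observed_pairs), n, replace=True)]
    obs = np.array([microhomology(ref, a, b, flank).homology_len for a, b in chosen])
    bg = np.empty(n, dtype=np.int64)
    for i in range(n):
        ia, ib = rng.choice(len(pool), 2, replace=False)
        bg[i] = microhomology(ref, pool[ia], pool[ib], flank).homology_len
    degenerate = n < 2 or obs.std() == 0 and bg.std() == 0
    if degenerate:
        stat, p = float("nan"), float("nan")
    else:
        stat, p = stats.ranksums(obs, bg)
    return BackgroundReport(
        observed_lengths=obs, background_lengths=bg,
        ranksum_stat=float(stat), ranksum_p=float(p),
        observed_frac_gt5=float(np.mean(obs > 5)),
        background_frac_gt5=float(np.mean(bg > 5)),
        degenerate=bool(degenerate),
    )


# ---------------------------------------------------------------------------
# similarity between samples

@dataclass
class SimilarityMatrix:
    samples: list[str]
    spearman: np.ndarray   # NaN where a presence array is constant
    jaccard: np.ndarray


def jaccard(a: set, b: set) -> float:
    """|A n B| / |A u B|; 1.0 for two empty sets by convention."""
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def hgt_similarity(
    breakpoint_sets: dict[str, set],
    event_sets: dict[str, set],
) -> SimilarityMatrix:
    """Pairwise Spearman (breakpoint presence) and Jaccard (event sets).

    The breakpoint-pair catalog is the union over samples; each sample's
    presence array X has X_i = 1 iff catalog entry i occurs in the sample.
    """
    samples = sorted(set(breakpoint_sets) | set(event_sets))
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    catalog = sorted(set().union(*(breakpoint_sets.get(s, set()) for s in samples)))
    X = np.array(
        [[1 if c in breakpoint_sets.get(s, set()) else 0 for c in catalog] for s in samples],
        dtype=float,
    )
    k = len(samples)
    sp = np.full((k, k), np.nan)
    jc = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            ei = event_sets.get(samples[i], set())
            ej = event_sets.get(samples[j], set())
            jc[i, j] = jaccard(ei, ej)
            if X.shape[1] >= 2 and X[i].std() > 0 and X[j].std() > 0:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sp[i, j] = stats.spearmanr(X[i], X[j]).statistic
    return SimilarityMatrix(samples=samples, spearman=sp, jaccard=jc)
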