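"""Precise breakpoint calling from alignments to the HGT-related segments.

A junction between two genomes leaves two footprints in a short-read
alignment against the extracted segments:

* discordant pairs — the two mates map to segments of different genomes,
  giving a rough breakpoint pair;
* split reads — one mate crosses the junction and is soft-clipped; the
  clip realigns on the partner genome and pins the junction to the base.

Observations are clustered per genome pair with DBSCAN (epsilon 200 bp,
minPoints 1, Euclidean distance over the two genome axes), then each
cluster is refined by realigning every member clip between the cluster's
position bounds.  Junction geometry is tracked in reference coordinates:
``side`` says on which side of the breakpoint the retained sequence lies,
``orientation`` whether the two genomes join on the same strand (forward)
or opposite strands (reverse).
"""

from __future__ import annotations

import shutil
import subprocess
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.cluster import DBSCAN

from .core_encoding import seq_to_codes
from .reference_io import ReferenceDatabase
from .segment_extraction import SegmentSet

DEFAULT_MAPQ_MIN = 20
DEFAULT_DBSCAN_EPS = 200.0
DEFAULT_SW_CUTOFF = 0.8
DEFAULT_SPLIT_RATIO = 1e-7
MIN_CLIP_LEN = 10
REFINE_PAD = 300


class AlignerNotFoundError(RuntimeError):
    pass


def run_aligner(
    segments_fasta: str | Path,
    fq1: str | Path,
    fq2: str | Path,
    workdir: str | Path,
    threads: int = 1,
) -> Path:
    """Index the segments and align the reads with bwa mem; returns a SAM path.

    The aligner backend is pluggable: any coordinate-addressable SAM/BAM over
    the same segment names can be passed to ``extract_junction_observations``
    instead (``--bam`` on the CLI).
    """
    if shutil.which("bwa") is None:
        raise AlignerNotFoundError(
            "bwa not found on PATH; supply a pre-made alignment with --bam"
        )
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    idx = workdir / "segments.fa"
    if Path(segments_fasta).resolve() != idx.resolve():
        shutil.copy(segments_fasta, idx)
    subprocess.run(["bwa", "index", str(idx)], check=True, capture_output=True)
    sam = workdir / "aligned.sam"
    with open(sam, "w") as out:
        subprocess.run(
            ["bwa", "mem", "-t", str(threads), str(idx), str(fq1), str(fq2)],
            check=True, stdout=out, stderr=subprocess.DEVNULL,
        )
    return sam


@dataclass(frozen=True)
class JunctionObservation:
    """One read-pair's evidence for a junction between two genomes.

    Positions are lifted reference coordinates (0-based).  ``side_*`` is
    'L' when the retained sequence lies left of the breakpoint on that
    genome; ``orientation`` is 'forward' for a same-strand join.  For split
    observations ``anchor`` names the genome carrying the clipped alignment
    and ``clip_seq`` the soft-clipped bases (reference-forward orientation).
    """

    genome_a: str
    pos_a: int
    genome_b: str
    pos_b: int
    kind: str                    # 'discordant' | 'split'
    orientation: str             # 'forward' | 'reverse'
    side_a: str = "?"
    side_b: str = "?"
    anchor: str = ""             # genome name of the anchor side ('' = none)
    clip_seq: str = ""
    anchor_pos: int = -1         # precise clip boundary on the anchor genome
    anchor_side: str = "?"


def _junction_end(aln: pysam.AlignedSegment) -> tuple[int, str]:
    """Rough junction-proximal end of a mate: (segment pos, side flag)."""
    if aln.is_reverse:
        return aln.reference_start, "R"
    return aln.reference_end, "L"


def _long_clips(aln: pysam.AlignedSegment, min_clip: int) -> list[tuple[str, int]]:
    """(end, length) of soft clips >= min_clip; end is 'left' or 'right'."""
    cig = aln.cigartuples or []
    out = []
    if cig and cig[0][0] == 4 and cig[0][1] >= min_clip:
        out.append(("left", cig[0][1]))
    if cig and cig[-1][0] == 4 and cig[-1][1] >= min_clip:
        out.append(("right", cig[-1][1]))
    return out


def extract_junction_observations(
    sam_path: str | Path,
    segments: SegmentSet,
    species_of: dict[str, str] | None = None,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    min_clip: int = MIN_CLIP_LEN,
) -> list[JunctionObservation]:
    """Collect discordant-pair and split-read junction evidence from a SAM.

    Only primary alignments with MAPQ >= ``mapq_min`` contribute.  A split
    observation needs exactly one soft clip >= ``min_clip`` (reads clipped
    long at both ends are ambiguous and skipped) and a mate on a different
    genome that supplies the partner locus.
    """
    by_name: dict[str, dict[int, pysam.AlignedSegment]] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            slot = 1 if aln.is_read1 else 2
            by_name.setdefault(aln.query_name, {})[slot] = aln

    obs: list[JunctionObservation] = []
    for name, mates in by_name.items():
        if len(mates) != 2:
            continue
        a1, a2 = mates[1], mates[2]
        if a1.mapping_quality < mapq_min or a2.mapping_quality < mapq_min:
            continue
        g1, off1 = segments.source[a1.reference_name]
        g2, off2 = segments.source[a2.reference_name]
        if g1 == g2:
            continue
        p1, s1 = _junction_end(a1)
        p2, s2 = _junction_end(a2)
        orient = "forward" if a1.is_reverse != a2.is_reverse else "reverse"
        first = (g1, off1 + p1, s1, a1)
        second = (g2, off2 + p2, s2, a2)
        if first[0] > second[0]:
            first, second = second, first
        ga, pa, sa, alna = first
        gb, pb, sb, alnb = second
        obs.append(
            JunctionObservation(
                genome_a=ga, pos_a=pa, genome_b=gb, pos_b=pb,
                kind="discordant", orientation=orient, side_a=sa, side_b=sb,
            )
        )
        # split-read evidence from either mate
        for aln, g, partner_pos, partner_g in (
            (alna, ga, pb, gb),
            (alnb, gb, pa, ga),
        ):
            off = segments.source[aln.reference_name][1]
            clips = _long_clips(aln, min_clip)
            if len(clips) != 1:
                continue
            end, clen = clips[0]
            seq = aln.query_sequence
            if seq is None:
                continue
            if end == "left":
                clip_seq = seq[:clen]
                anchor_pos = off + aln.reference_start
                anchor_side = "R"
            else:
                clip_seq = seq[-clen:]
                anchor_pos = off + aln.reference_end
                anchor_side = "L"
            if g <= partner_g:
                rec = dict(genome_a=g, pos_a=anchor_pos, genome_b=partner_g,
                           pos_b=partner_pos, side_a=anchor_side, side_b="?")
            else:
                rec = dict(genome_a=partner_g, pos_a=partner_pos, genome_b=g,
                           pos_b=anchor_pos, side_a="?", side_b=anchor_side)
            obs.append(
                JunctionObservation(
                    kind="split", orientation=orient, anchor=g,
                    clip_seq=clip_seq, anchor_pos=anchor_pos,
                    anchor_side=anchor_side, **rec,
                )
            )
    return obs


# ---------------------------------------------------------------------------
# clustering

@dataclass
class BreakpointCluster:
    genome_a: str
    genome_b: str
    members: list[JunctionObservation]
    lower_a: int = 0
    upper_a: int = 0
    lower_b: int = 0
    upper_b: int = 0

    def __post_init__(self) -> None:
        xs = [m.pos_a for m in self.members]
        ys = [m.pos_b for m in self.members]
        self.lower_a, self.upper_a = min(xs), max(xs)
        self.lower_b, self.upper_b = min(ys), max(ys)


def cluster_breakpoint_pairs(
    observations: list[JunctionObservation],
    eps: float = DEFAULT_DBSCAN_EPS,
) -> list[BreakpointCluster]:
    """DBSCAN (eps, minPoints=1) over (pos_a, pos_b) per genome pair.

    With minPoints 1 the clustering is a partition: every observation lands
    in exactly one cluster, never in noise.
    """
    groups: dict[tuple[str, str], list[JunctionObservation]] = {}
    for o in observations:
        groups.setdefault((o.genome_a, o.genome_b), []).append(o)
    clusters: list[BreakpointCluster] = []
    for (ga, gb), members in sorted(groups.items()):
        pts = np.array([[m.pos_a, m.pos_b] for m in members], dtype=float)
        labels = DBSCAN(eps=eps, min_samples=1).fit_predict(pts)
        for lab in sorted(set(labels)):
            sub = [m for m, l in zip(members, labels) if l == lab]
            clusters.append(BreakpointCluster(genome_a=ga, genome_b=gb, members=sub))
    return clusters


# ---------------------------------------------------------------------------
# refinement

@dataclass
class RefinedBreakpointPair:
    """Base-precise junction between two genomes with split-read support."""

    genome_a: str
    pos_a: int
    genome_b: str
    pos_b: int
    split_reads: int
    junction_reads: int
    orientation: str
    side_a: str
    side_b: str
    precise: bool
    passed_ratio_filter: bool = True


def realign_clip(
    clip: str,
    ref_seq: str,
    lower: int,
    upper: int,
    orientation: str,
    partner_side: str,
    cutoff: float = DEFAULT_SW_CUTOFF,
    pad: int = REFINE_PAD,
) -> tuple[int, float] | None:
    """Find the junction position of a soft clip on the partner genome.

    Candidate stop positions run from ``lower - pad`` to ``upper + pad``;
    at each position the clip (oriented per ``orientation``/``partner_side``)
    is compared base-by-base against the reference and scored match +1 /
    mismatch -1, normalized by clip length.  The first position whose
    normalized score exceeds ``cutoff`` wins; if none does, the best-scoring
    position is returned only if it passes the cutoff (else None).
    """
    from .core_encoding import revcomp

    m = len(clip)
    if m == 0:
        return None
    if orientation == "reverse":
        # opposite-strand join: the clip's reference-forward image is its
        # reverse complement, still on the retained side of the stop position
        clip = revcomp(clip)
    lo = max(0, lower - pad)
    hi = min(len(ref_seq), upper + pad)
    if partner_side == "R":
        # retained sequence right of p: clip matches ref[p : p+m]
        start_lo, start_hi = lo, min(hi, len(ref_seq) - m)
        if start_hi < start_lo:
            return None
        region = seq_to_codes(ref_seq[start_lo : start_hi + m])
        stops = np.arange(start_lo, start_hi + 1)
        win0 = 0
    else:
        # retained sequence left of p: clip matches ref[p-m : p]
        start_lo, start_hi = max(lo, m), hi
        if start_hi < start_lo:
            return None
        region = seq_to_codes(ref_seq[start_lo - m : start_hi])
        stops = np.arange(start_lo, start_hi + 1)
        win0 = 0
    cl = seq_to_codes(clip)
    wins = sliding_window_view(region, m)
    n = min(len(stops), wins.shape[0] - win0)
    if n <= 0:
        return None
    matches = (wins[win0 : win0 + n] == cl).sum(axis=1)
    norm = (2 * matches - m) / m
    passing = np.nonzero(norm > cutoff)[0]
    if passing.size == 0:
        return None
    first = int(passing[0])
    return int(stops[first]), float(norm[first])


def refine_breakpoint(
    cluster: BreakpointCluster,
    ref: ReferenceDatabase,
    cutoff: float = DEFAULT_SW_CUTOFF,
) -> RefinedBreakpointPair:
    """Precise breakpoint pair of one cluster via clip realignment voting.

    Every split-read member realigns its clip on the partner genome between
    the cluster bounds; each success votes for one position on each genome.
    The modal position per genome wins; ``split_reads`` counts reads whose
    two votes both match the modal positions.  Clusters without any passing
    clip fall back to the modal rough positions, flagged imprecise.
    """
    votes: list[tuple[int, int, str, str, str]] = []  # (pa, pb, orient, side_a, side_b)
    for o in cluster.members:
        if o.kind != "split" or not o.clip_seq:
            continue
        if o.anchor == cluster.genome_a:
            partner, plo, phi = cluster.genome_b, cluster.lower_b, cluster.upper_b
        else:
            partner, plo, phi = cluster.genome_a, cluster.lower_a, cluster.upper_a
        # expected partner side: a junction joins an L side to an R side on
        # a same-strand fusion and equal sides on an opposite-strand fusion
        if o.orientation == "forward":
            pside = "R" if o.anchor_side == "L" else "L"
        else:
            pside = o.anchor_side
        hit = realign_clip(
            o.clip_seq, ref.sequences[partner], plo, phi,
            o.orientation, pside, cutoff=cutoff,
        )
        if hit is None:
            continue
        p, _score = hit
        if o.anchor == cluster.genome_a:
            votes.append((o.anchor_pos, p, o.orientation, o.anchor_side, pside))
        else:
            votes.append((p, o.anchor_pos, o.orientation, pside, o.anchor_side))

    junction_reads = len(cluster.members)
    if votes:
        pa = Counter(v[0] for v in votes).most_common(1)[0][0]
        pb = Counter(v[1] for v in votes).most_common(1)[0][0]
        support = sum(1 for v in votes if v[0] == pa and v[1] == pb)
        orient = Counter(v[2] for v in votes).most_common(1)[0][0]
        side_a = Counter(v[3] for v in votes).most_common(1)[0][0]
        side_b = Counter(v[4] for v in votes).most_common(1)[0][0]
        return RefinedBreakpointPair(
            genome_a=cluster.genome_a, pos_a=int(pa),
            genome_b=cluster.genome_b, pos_b=int(pb),
            split_reads=support, junction_reads=junction_reads,
            orientation=orient, side_a=side_a, side_b=side_b, precise=True,
        )
    pa = Counter(m.pos_a for m in cluster.members).most_common(1)[0][0]
    pb = Counter(m.pos_b for m in cluster.members).most_common(1)[0][0]
    orient = Counter(m.orientation for m in cluster.members).most_common(1)[0][0]
    side_a = Counter(m.side_a for m in cluster.members).most_common(1)[0][0]
    side_b = Counter(m.side_b for m in cluster.members).most_common(1)[0][0]
    return RefinedBreakpointPair(
        genome_a=cluster.genome_a, pos_a=int(pa),
        genome_b=cluster.genome_b, pos_b=int(pb),
        split_reads=0, junction_reads=junction_reads,
        orientation=orient, side_a=side_a, side_b=side_b, precise=False,
    )


def filter_by_split_ratio(
    pairs: list[RefinedBreakpointPair],
    total_read_pairs: int,
    min_ratio: float = DEFAULT_SPLIT_RATIO,
) -> list[RefinedBreakpointPair]:
    """Flag pairs whose split-read fraction of the sample passes ``min_ratio``."""
    if total_read_pairs <= 0:
        raise ValueError("total_read_pairs must be positive")
    for p in pairs:
        p.passed_ratio_filter = (p.split_reads / total_read_pairs) >= min_ratio
    return pairs


def detect_breakpoints(
    sam_path: str | Path,
    segments: SegmentSet,
    ref: ReferenceDatabase,
    total_read_pairs: int,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    eps: float = DEFAULT_DBSCAN_EPS,
    cutoff: float = DEFAULT_SW_CUTOFF,
    min_ratio: float = DEFAULT_SPLIT_RATIO,
) -> list[RefinedBreakpointPair]:
    """Full breakpoint stage: observations -> clusters -> refinement -> filter."""
    obs = extract_junction_observations(sam_path, segments, mapq_min=mapq_min)
    clusters = cluster_breakpoint_pairs(obs, eps=eps)
    pairs = [refine_breakpoint(c, ref, cutoff=cutoff) for c in clusters]
    pairs = filter_by_split_ratio(pairs, total_read_pairs, min_ratio=min_ratio)
    return [p for p in pairs if p.passed_ratio_filter]
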