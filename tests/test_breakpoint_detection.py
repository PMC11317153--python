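"""Junction observation extraction, DBSCAN clustering and clip refinement."""

import numpy as np
import pysam
import pytest

from hgtscan import breakpoint_detection as bd
from hgtscan.reference_io import ReferenceDatabase
from hgtscan.segment_extraction import SegmentSet


def _segments(ref: ReferenceDatabase) -> SegmentSet:
    segs = SegmentSet()
    for name, seq in ref.sequences.items():
        segs.sequences[f"{name}|0"] = seq
        segs.source[f"{name}|0"] = (name, 0)
    return segs


def _write_sam(path, segs: SegmentSet, records):
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in segs.sequences.items()],
    }
    names = list(segs.sequences)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec["name"]
            a.reference_id = names.index(rec["ref"])
            a.reference_start = rec["pos"]
            a.mapping_quality = rec.get("mapq", 60)
            a.cigarstring = rec["cigar"]
            a.query_sequence = rec["seq"]
            a.flag = rec["flag"]
            out.write(a)


# flag helpers: paired + mapped mates
F_R1, F_R2, F_REV, F_MREV = 0x1 | 0x40, 0x1 | 0x80, 0x10, 0x20


class TestObservationExtraction:
    @pytest.fixture()
    def junction_sam(self, tmp_path, two_genome_ref):
        """One true junction gA:1000 | gB:500 (forward join) plus chaff."""
        A = two_genome_ref.sequences["gA"]
        B = two_genome_ref.sequences["gB"]
        segs = _segments(two_genome_ref)
        recs = [
            # discordant pair across the junction, split mate on gA
            dict(name="jr1", ref="gA|0", pos=900, cigar="100M50S",
                 seq=A[900:1000] + B[500:550], flag=F_R1 | F_MREV),
            dict(name="jr1", ref="gB|0", pos=650, cigar="150M",
                 seq=B[650:800], flag=F_R2 | F_REV),
            # low-MAPQ mate: whole pair discarded
            dict(name="lowq", ref="gA|0", pos=400, cigar="150M",
                 seq=A[400:550], flag=F_R1 | F_MREV),
            dict(name="lowq", ref="gB|0", pos=900, cigar="150M",
                 seq=B[900:1050], flag=F_R2 | F_REV, mapq=15),
            # concordant same-genome pair: no observation
            dict(name="conc", ref="gA|0", pos=100, cigar="150M",
                 seq=A[100:250], flag=F_R1 | F_MREV),
            dict(name="conc", ref="gA|0", pos=350, cigar="150M",
                 seq=A[350:500], flag=F_R2 | F_REV),
        ]
        sam = tmp_path / "fix.sam"
        _write_sam(sam, segs, recs)
        return sam, segs

    def test_discordant_and_split_extracted(self, junction_sam):
        sam, segs = junction_sam
        obs = bd.extract_junction_observations(sam, segs)
        kinds = sorted(o.kind for o in obs)
        assert kinds == ["discordant", "split"]
        disc = next(o for o in obs if o.kind == "discordant")
        assert (disc.genome_a, disc.pos_a) == ("gA", 1000)
        assert (disc.genome_b, disc.pos_b) == ("gB", 650)
        assert disc.orientation == "forward"
        split = next(o for o in obs if o.kind == "split")
        assert split.anchor == "gA"
        assert split.anchor_pos == 1000 and split.anchor_side == "L"
        assert len(split.clip_seq) == 50

    def test_mapq_threshold_is_monotone(self, junction_sam):
        sam, segs = junction_sam
        counts = [
            len(bd.extract_junction_observations(sam, segs, mapq_min=q))
            for q in (0, 20, 61)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0


def _brute_force_dbscan(points: np.ndarray, eps: float) -> list[set[int]]:
    """minPoints=1 DBSCAN == connected components of the eps-ball graph."""
    n = len(points)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) <= eps:
                parent[find(i)] = find(j)
    comps: dict[int, set[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return sorted(comps.values(), key=min)


def _obs_at(x, y):
    return bd.JunctionObservation(
        genome_a="gA", pos_a=int(x), genome_b="gB", pos_b=int(y),
        kind="discordant", orientation="forward",
    )


class TestClustering:
    @pytest.mark.parametrize(
        "pts,n_clusters",
        [
            ([(100, 100), (150, 160)], 1),   # rho ~ 78.1 < 200
            ([(0, 0), (3, 4)], 1),            # rho = 5
            ([(0, 0), (1000, 1000)], 2),      # rho ~ 1414 > 200
        ],
    )
    def test_small_examples(self, pts, n_clusters):
        clusters = bd.cluster_breakpoint_pairs([_obs_at(x, y) for x, y in pts])
        assert len(clusters) == n_clusters

    def test_partition_matches_brute_force_oracle(self, rng):
        for trial in range(10):
            n = int(rng.integers(2, 50))
            pts = rng.integers(0, 2000, size=(n, 2)).astype(float)
            obs = [_obs_at(x, y) for x, y in pts]
            clusters = bd.cluster_breakpoint_pairs(obs)
            # every observation in exactly one cluster
            assert sum(len(c.members) for c in clusters) == n
            got = sorted(
                (sorted(obs.index(m) for m in c.members) for c in clusters),
                key=lambda s: s[0],
            )
            want = sorted(
                (sorted(s) for s in _brute_force_dbscan(pts, 200.0)),
                key=lambda s: s[0],
            )
            assert got == want


class TestRefinement:
    def test_exact_clip_realigns_at_junction(self, two_genome_ref):
        B = two_genome_ref.sequences["gB"]
        clip = B[500:510]
        hit = bd.realign_clip(clip, B, lower=450, upper=700, orientation="forward",
                              partner_side="R")
        assert hit is not None
        pos, score = hit
        assert pos == 500 and score == pytest.approx(1.0)

    def test_three_mismatches_in_ten_fail_cutoff(self):
        # score (7 - 3) / 10 = 0.4 < 0.8: no refinement from this clip
        ref = "A" * 300
        clip = "AAAAAAA" + "CCC"
        hit = bd.realign_clip(clip, ref, lower=100, upper=120,
                              orientation="forward", partner_side="R")
        assert hit is None

    def test_unanimous_votes_give_precise_pair(self, two_genome_ref):
        A = two_genome_ref.sequences["gA"]
        B = two_genome_ref.sequences["gB"]
        members = []
        for i in range(2):
            members.append(
                bd.JunctionObservation(
                    genome_a="gA", pos_a=1000, genome_b="gB", pos_b=650,
                    kind="split", orientation="forward", anchor="gA",
                    clip_seq=B[500:520 + 5 * i], anchor_pos=1000, anchor_side="L",
                )
            )
        cluster = bd.BreakpointCluster("gA", "gB", members)
        pair = bd.refine_breakpoint(cluster, two_genome_ref)
        assert pair.precise
        assert (pair.pos_a, pair.pos_b) == (1000, 500)
        assert pair.split_reads == 2

    def test_cluster_without_splits_reports_rough_modal(self, two_genome_ref):
        members = [_obs_at(1000, 650), _obs_at(1000, 660), _obs_at(990, 650)]
        pair = bd.refine_breakpoint(
            bd.BreakpointCluster("gA", "gB", members), two_genome_ref
        )
        assert not pair.precise
        assert (pair.pos_a, pair.pos_b) == (1000, 650)
        assert pair.split_reads == 0

    def test_reverse_orientation_clip(self, two_genome_ref):
        # opposite-strand join gA:1000 | revcomp(gB[..800]): the clip is the
        # reverse complement of the sequence retained left of gB:800
        from hgtscan.core_encoding import revcomp

        B = two_genome_ref.sequences["gB"]
        clip = revcomp(B[785:800])
        hit = bd.realign_clip(clip, B, lower=700, upper=900,
                              orientation="reverse", partner_side="L")
        assert hit is not None
        assert hit[0] == 800


class TestSplitRatioFilter:
    def _pair(self, split_reads):
        return bd.RefinedBreakpointPair(
            genome_a="gA", pos_a=1, genome_b="gB", pos_b=2,
            split_reads=split_reads, junction_reads=split_reads,
            orientation="forward", side_a="L", side_b="R", precise=True,
        )

    @pytest.mark.parametrize(
        "split,total,passes",
        [(5, 10**7, True), (1, 10**8, False), (0, 10**7, False)],
    )
    def test_threshold(self, split, total, passes):
        (pair,) = bd.filter_by_split_ratio([self._pair(split)], total)
        assert pair.passed_ratio_filter is passes

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            bd.filter_by_split_ratio([self._pair(1)], 0)
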