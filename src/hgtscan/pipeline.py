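"""End-to-end detection: reads + reference in, breakpoints + events out."""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from . import breakpoint_detection as bkp
from . import event_inference as evi
from . import segment_extraction as seg
from .core_encoding import build_hash_functions
from .reference_io import (
    BreakpointRecord,
    EventRecord,
    ReferenceDatabase,
    iter_read_pairs,
    load_reference,
    to_external,
    write_breakpoints,
    write_events,
)


@dataclass
class DetectionResult:
    breakpoint_pairs: list[bkp.RefinedBreakpointPair] = field(default_factory=list)
    events: list[evi.HgtEvent] = field(default_factory=list)
    total_read_pairs: int = 0
    n_cbkps: int = 0
    n_hgt_cbkps: int = 0
    n_segments: int = 0
    status: str = "ok"   # ok | no-candidate-segments | no-reads

    def breakpoint_records(self) -> list[BreakpointRecord]:
        return [
            BreakpointRecord(
                genome_a=p.genome_a, pos_a=to_external(p.pos_a),
                genome_b=p.genome_b, pos_b=to_external(p.pos_b),
                split_reads=p.split_reads, junction_reads=p.junction_reads,
            )
            for p in self.breakpoint_pairs
        ]

    def event_records(self) -> list[EventRecord]:
        return [
            EventRecord(
                recipient_genome=e.recipient_genome,
                insertion_pos=to_external(e.insertion_pos),
                donor_genome=e.donor_genome,
                transfer_start=to_external(e.transfer_start),
                transfer_end=e.transfer_end,  # exclusive 0-based == inclusive 1-based
                direction=e.direction,
                support=e.support,
            )
            for e in self.events
        ]


def detect(
    ref: ReferenceDatabase,
    read_pairs: list[tuple[str, str, str]],
    k: int = 32,
    ell: int = 3,
    seed: int = 1,
    M: float = seg.DEFAULT_M,
    hit_threshold: int = 3,
    w: int = seg.DEFAULT_WINDOW,
    m1: float = seg.DEFAULT_M1,
    m2: float = seg.DEFAULT_M2,
    bin_len: int = seg.DEFAULT_BIN,
    theta: float = seg.DEFAULT_THETA,
    mapq_min: int = bkp.DEFAULT_MAPQ_MIN,
    dbscan_eps: float = bkp.DEFAULT_DBSCAN_EPS,
    sw_cutoff: float = bkp.DEFAULT_SW_CUTOFF,
    split_ratio: float = bkp.DEFAULT_SPLIT_RATIO,
    min_transfer_len: int = evi.DEFAULT_MIN_TRANSFER_LEN,
    share_tol: int = evi.DEFAULT_SHARE_TOL,
    population_pairs: list[bkp.RefinedBreakpointPair] | None = None,
    workdir: str | Path | None = None,
    sam_path: str | Path | None = None,
    threads: int = 1,
) -> DetectionResult:
    """Run the whole detection pipeline on in-memory read pairs.

    ``sam_path`` injects a pre-made alignment (the aligner backend contract
    used by the test suite); otherwise bwa mem runs on the extracted
    segments in ``workdir`` (a temporary directory by default).
    """
    res = DetectionResult(total_read_pairs=len(read_pairs))
    if not read_pairs:
        res.status = "no-reads"
        return res

    hfs = build_hash_functions(k=k, ell=ell, seed=seed)
    table, selected, _plan, cache = seg.downsample_and_count(
        read_pairs, hfs, M=M, seed=seed, hit_threshold=hit_threshold
    )
    verdicts = seg.screen_present_fragments(ref, table, hfs, w=w, m1=m1, m2=m2)
    regions = seg.present_regions(verdicts)
    cbkps = seg.detect_cbkps(ref, table, hfs, e=bin_len, theta=theta, regions=regions)
    res.n_cbkps = len(cbkps)
    B = seg.build_marker_table(cbkps, ref, table, hfs)
    seg.pair_hgt_cbkps(selected, B, hfs, ref.species_of, cbkps, cache=cache)
    res.n_hgt_cbkps = sum(1 for c in cbkps if c.hgt_derived)
    segments = seg.extract_segments(ref, cbkps)
    res.n_segments = len(segments.sequences)
    if not segments.sequences:
        res.status = "no-candidate-segments"
        return res

    with tempfile.TemporaryDirectory() as tmp:
        wd = Path(workdir) if workdir is not None else Path(tmp)
        wd.mkdir(parents=True, exist_ok=True)
        if sam_path is None:
            seg_fa = wd / "segments.fa"
            segments.write_fasta(seg_fa)
            fq1, fq2 = wd / "reads_1.fq", wd / "reads_2.fq"
            from .reference_io import write_fastq_pair

            write_fastq_pair(fq1, fq2, read_pairs)
            sam_path = bkp.run_aligner(seg_fa, fq1, fq2, wd, threads=threads)
        res.breakpoint_pairs = bkp.detect_breakpoints(
            sam_path, segments, ref, total_read_pairs=len(read_pairs),
            mapq_min=mapq_min, eps=dbscan_eps, cutoff=sw_cutoff,
            min_ratio=split_ratio,
        )
    res.events = evi.infer_events(
        res.breakpoint_pairs, population_pairs,
        min_transfer_len=min_transfer_len, tolerance=share_tol,
    )
    return res


def detect_files(
    ref_fasta: str | Path,
    species_map: str | Path,
    fq1: str | Path,
    fq2: str | Path,
    outdir: str | Path,
    **kwargs,
) -> DetectionResult:
    """File-level entry point: writes breakpoints.tsv and events.tsv."""
    ref = load_reference(ref_fasta, species_map)
    pairs = list(iter_read_pairs(fq1, fq2))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = detect(ref, pairs, workdir=outdir / "work", **kwargs)
    write_breakpoints(outdir / "breakpoints.tsv", res.breakpoint_records())
    write_events(outdir / "events.tsv", res.event_records())
    return res
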