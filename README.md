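# hgtscan

Detection of **complete horizontal gene transfer (HGT) events** — the
transferred donor sequence, its two donor-genome breakpoints, and the
recipient-genome insertion site — from paired-end shotgun metagenomic reads
aligned against a multi-genome reference collection.

It is aimed at microbiome researchers who want base-precise transfer calls
between species in a community sample without paying the cost of aligning
every read against a full reference database: the reads are first matched to
the reference with a substitution-tolerant k-mer scheme that narrows the
alignment target down to small candidate segments around putative junctions.

## Method

1. **Fuzzy k-mer matching.** Three base-partition maps encode bases to bits
   (`F1`: {A,T}/{C,G}, `F2`: {A,C}/{T,G}, `F3`: {A,G}/{T,C}); for every
   unordered base pair exactly one map assigns both the same bit.  Each
   k-mer is encoded by ℓ = 3 hash functions whose per-locus maps form random
   permutations of (F1, F2, F3), into indices
   δ = Σⱼ βⱼ 2^(j−1) ∈ [0, 2^k), canonicalized over strands as
   min(δ, δ̄).  Any single-base substitution collides with the original in
   at least one function.  Read k-mers are counted (after downsampling at
   rate M/A) into a byte array Q of size 2^k.
2. **Segment extraction.** Reference windows (w = 500 bp) are screened by
   exact/fuzzy hit ratios κ ≥ 0.08, μ ≥ 0.1; inside present windows, loci
   where the binned count signal D = max(q₁..q₃) jumps by more than θ = 3
   become candidate breakpoints (cBKPs).  Their marker k-mers are looked up
   inside the raw read pairs; two candidates of different species retrieved
   by one read pair are HGT-derived, and ±500 bp of reference around them
   becomes the alignment target.
3. **Breakpoint refinement.** Reads are aligned to the segments with
   `bwa mem`; discordant pairs and soft-clipped split reads (MAPQ ≥ 20)
   yield junction observations, clustered per genome pair with DBSCAN
   (ε = 200 bp, minPoints = 1).  Each clip realigns on the partner genome
   between the cluster bounds until its normalized score exceeds 0.8; the
   stop position is the precise breakpoint.  Pairs with split-read fraction
   below 1e-7 of the sample are dropped.
4. **Event inference.** Breakpoint pairs are nodes of a graph; two pairs
   that share a breakpoint (the insertion site) and place their remaining
   breakpoints on one donor genome are linked, subject to read-geometry,
   orientation-consistency, ≥ 500 bp transfer length, and
   exactly-two-donor-cluster constraints.  A maximum-weight matching
   (weight = average split reads) resolves events.

A synthetic-community simulator plus evaluator (precision/recall/F1 against
planted events) make the whole pipeline testable offline, and
post-hoc analyses cover junction microhomology (with a randomized
background) and between-sample HGT similarity (Spearman over breakpoint
presence, Jaccard `J(A,B) = |A∩B| / |A∪B|` over event sets).

## Worked example

```bash
hgtscan simulate --outdir demo --n-species 3 --genome-length 20000 \
    --n-events 1 --depth 40 --seed 8
hgtscan detect --ref demo/reference.fa --species-map demo/species_map.tsv \
    --fq1 demo/reads_1.fq --fq2 demo/reads_2.fq --outdir demo/out --k 20 --seed 8
hgtscan evaluate --pred demo/out/events.tsv --truth demo/truth.tsv
```

which prints (simulation, detection, then scoring):

```
wrote 8164 read pairs, 1 planted events
status=ok candidates=54775 hgt_candidates=54631 segments=3 breakpoint_pairs=2 events=1
{"tp": 1, "fp": 0, "fn": 0, "precision": 1.0, "recall": 1.0, "f1": 1.0}
```

The detect line says 54,775 loci showed k-mer count discontinuities (at 40×
coverage the count signal is noisy enough that most loci qualify — at this
toy scale the screen keeps nearly the whole 60 kb reference, see
`docs/methods.md`), they merged into three alignment segments, and the two
refined breakpoint pairs assemble into the one planted transfer; the
evaluator confirms donor interval, insertion site and direction all match
the truth within 50 bp.

The same objects are available as a library:

```python
from hgtscan import CommunitySpec, simulate_community, simulate_reads, detect, evaluate_events

ref, sample, truth = simulate_community(CommunitySpec(seed=1), n_events=3)
reads = simulate_reads(sample, depth=40, err_rate=0.001, seed=1)
result = detect(ref, reads, k=20, seed=1)
print(evaluate_events(result.events, truth, tolerance=50))
```

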