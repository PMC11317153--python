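# Methods

## Model

An HGT event copies an interval of a donor genome, forward or
reverse-complement, into a position on a recipient genome, creating three
breakpoints: the two ends of the transferred interval on the donor and the
insertion site on the recipient.  Against a reference that predates the
transfer, reads from the fused molecule betray the junctions twice over:
read pairs whose mates map to two different genomes (junction reads), and
reads crossing a junction whose alignment is soft-clipped, the clip mapping
on the partner genome (split reads).  hgtscan detects the junctions as
breakpoint *pairs* (one locus per genome), then reconstructs events by
pairing up breakpoint pairs that share their recipient-side breakpoint.

## Substitution-tolerant k-mer encoding

The three base-partition maps F1 ({A,T}→0, {C,G}→1), F2 ({A,C}/{T,G}) and
F3 ({A,G}/{T,C}) have the property that each unordered pair of distinct
bases is merged (assigned the same bit) by exactly one map.  A hash
function is an array of one map per k-mer locus; it turns the k-mer into k
bits and then the integer δ = Σⱼ βⱼ 2^(j−1) ∈ [0, 2^k).  Using ℓ = 3
functions whose per-locus maps are random permutations of (F1, F2, F3)
guarantees that any single-base substitution leaves at least one of the
three indices unchanged, which is what makes the matching fuzzy.  δ is
written with 0-based bit weights so the index always fits the 2^k-slot
table (1-based weights would need a table twice that size).  Indices are
canonicalized as min over the k-mer and its reverse complement, so both
strands address the same slots.

Counts live in a byte array Q of 2^k slots; counters saturate at 255 rather
than wrap, keeping the count signal monotone.  A query returns an exact hit
E = [min(q₁..q₃) ≥ t] and a fuzzy hit Z = [max(q₁..q₃) ≥ t] with t = 3;
E ≤ Z always.  k-mers containing non-ACGT characters are skipped
everywhere.  For speed, the three per-function codes of a window are packed
into one 64-bit integer (k-bit fields) whenever ℓ·k ≤ 63, so bulk encoding
costs one table lookup per locus instead of three.

## Segment extraction

Read pairs are downsampled at rate M/A (M = 2×10⁹ bases by default, A the
sample's total bases) before counting, then reference sequences are tiled
into w = 500 bp windows (non-overlapping tiles: the unit being selected is
a fragment, and tiling keeps thresholds interpretable; sequences shorter
than w form one truncated window).  Windows pass when the exact hit ratio
κ ≥ 0.08 and the fuzzy hit ratio μ ≥ 0.1.  Inside present windows the
per-locus count D = max(q₁..q₃) is averaged over e = 5 bp bins; every bin
start z is compared with bins starting z+e .. z+e+k, and a difference
beyond θ = 3 selects the higher bin's start (ε > θ selects z, ε < −θ the
later bin) as a candidate breakpoint (cBKP).

Candidate marker k-mers (the reference k-mer at the cBKP locus) are stored
in a second table B (2^k four-byte slots, id of the candidate; zero-count
markers are dropped, colliding slots keep the last writer).  The selected
read pairs are re-enumerated; when one pair retrieves markers of two
candidates from different species, both are HGT-derived.  ±500 bp of
reference around HGT-derived candidates, merged when overlapping, become
the alignment segments; segment names carry the source offset so alignment
coordinates lift back exactly.

**Behavior at desk scale.**  θ = 3 is calibrated against sparse counts.  At
the benchmark's 40× coverage the binned count signal fluctuates by more
than θ from coverage noise alone, and with tables of 2^20 slots hash
collisions add further jitter, so most loci qualify as candidates and the
cross-species pairing step flags most of them: the screen then keeps nearly
the whole (tiny) reference rather than a narrow neighborhood.  This costs
nothing at 0.5 Mb reference scale and leaves accuracy to the alignment
stages, which is where precision comes from in any case; the reduction
becomes meaningful when the reference is orders of magnitude larger than
the candidate set.  Passing tests therefore demonstrate correctness of the
detection chain, not the production-scale reduction ratio.

## Breakpoint detection

Reads are aligned to the segments with `bwa mem` (any SAM/BAM over the same
segment names can be injected instead; the test suite uses synthetic SAM
fixtures).  Primary alignments with MAPQ ≥ 20 contribute: cross-genome
mate pairs as discordant observations (rough positions: the
junction-proximal alignment ends), and alignments with exactly one soft
clip ≥ 10 bp as split observations (reads clipped long at both ends are
ambiguous and skipped).  Junction geometry is kept in reference
coordinates: a side flag per genome ('L' = retained sequence left of the
breakpoint) and an orientation ('forward' = same-strand join, inferred from
the mate strand pattern, which is invariant to which strand of the fused
molecule the fragment came from).

Observations are clustered per genome pair by DBSCAN over the two position
axes (Euclidean ε = 200 bp, minPoints = 1, so clustering is a partition).
Within a cluster, every split read's clip is realigned on the partner
genome across the cluster bounds (±300 bp padding for insert-size spread):
candidate stop positions are scanned lower → upper and scored match +1 /
mismatch −1 against the clip, normalized by clip length; the first position
exceeding 0.8 wins.  The scan is gap-free: under the package's
substitution-only error model an alignment with a gap (open −2, extend −1)
can never outscore the gapless placement at the true junction, so the
gap-free score equals the local-alignment score for the data in scope while
staying vectorizable.  Each successful clip votes for one position per
genome; modal positions become the refined pair and reads voting for both
modal positions are its split-read support.  Clusters with no passing clip
keep the modal rough positions flagged imprecise.  Junction microhomology
makes the exact cut ambiguous by its own length, so refined positions may
sit a few bases from the planted coordinates; the evaluator's 50 bp
tolerance absorbs this.  Pairs with split_reads / total_read_pairs < 1e-7
are excluded (the ratio uses read pairs; single-read accounting would
simply halve the threshold).

## Event inference

Two refined pairs are linked when one breakpoint of each coincides (same
genome, within 50 bp — refined positions coincide exactly on clean data;
the tolerance covers noise) and the remaining two breakpoints lie on one
other genome.  The shared breakpoint is the insertion site, the span
between the distinct breakpoints the transferred interval.  Four
constraints gate the edge: (1) geometry — the two pairs retain opposite
sides of the recipient at the shared breakpoint and each donor breakpoint's
retained side faces into the interval; (2) both pairs agree on strand
orientation, which becomes the event's direction; (3) interval ≥ 500 bp;
(4) DBSCAN (ε = 200, minPoints = 1) over all donor-genome breakpoints
related to the insertion site yields exactly two clusters — in
single-sample mode "all" means the sample's own pairs, in multi-sample mode
a pooled table can be supplied.  Maximum-weight matching
(networkx, weight = average split reads of the two pairs; candidate edges
are pre-sorted by node ids so ties resolve deterministically) assigns each
pair to at most one event.  Reciprocal events sharing an interval are
matched independently and all reported.

## Synthetic communities and evaluation

The generator draws i.i.d. bases at the configured GC (no repeats by
default — real genomes' repeat structure, uneven coverage and indel errors
are *not* modeled, so passing benchmarks bound performance on idealized
data only).  Events are planted with ≥ 5 kb clearance from each other and
from sequence ends so junctions are unambiguous; deletion from the
sample-local donor is available but off by default, matching the common
case where the donor population retains its copy.  Reads are uniform
fragments (normal insert, default 350 ± 30, mate 2 reverse-complemented)
with i.i.d. substitution errors; per-genome pair counts follow
depth·L/(2·read_len), scaled by relative abundance.

The evaluator matches predictions to planted events one-to-one (greedy by
distance) requiring genome identity, direction agreement and all three
coordinates within tolerance (default 50 bp, configurable).  F1 = 2PR/(P+R)
with 0 when undefined.  The desk benchmark — 10 seeds, 5 genomes × 100 kb,
3 events of 1–3 kb, 40×, 0.1% error, k = 20 — keeps one run under a minute
on one CPU; k = 20 (1 MB count table) rather than the production k = 32
(4 GB) bounds memory while leaving the chain of logic identical.  The
sequencing-budget rule of thumb 30·L/α states the total output at which a
genome of length L and relative abundance α reaches the ~30× coverage the
detector wants.

## Junction analyses

Microhomology of a breakpoint pair is measured on reference flanks in
fused-molecule orientation: the 10 bp ending at the junction on the
upstream partner and the 10 bp starting at it downstream (retained-right
sides contribute their reverse complement when playing the upstream role).
The homology length is the longest junction-spanning identical run — the
maximal L with suffix(up, L) = prefix(down, L), which is the run a global
overlap alignment places across the joint; a Needleman–Wunsch aligner
(match +1, mismatch −1, gap −1, ties toward the diagonal) is provided for
reporting the alignment itself.  Enrichment is tested against hypothetical
pairs formed by re-pairing two breakpoints drawn at random from the pooled
set (10 000 draws by default; Wilcoxon rank-sum on the length
distributions, plus the > 5 bp fractions).  Between-sample similarity uses
Spearman correlation over breakpoint-pair presence arrays built on the
union catalog (undefined and reported missing when an array is constant)
and the Jaccard coefficient over event sets (1 for two empty sets by
convention).

## Known limitations

* Substitutions only: neither the encoder nor the realignment tolerates
  indels within a k-mer/clip.
* Inter-species events only; strain-level (intra-species) transfers and
  ancient transfers already shared by the reference are out of reach.
* The candidate screen's reduction power depends on table load; at toy
  scales it degrades to a pass-through (see above).
* Mechanism classification (NHEJ / alt-EJ / TEI / …) is not performed; the
  homology length output is the hook for an external classifier.
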