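"""Synthetic community generator and pipeline evaluator.

The generator builds a small microbial community from scratch: random
genomes (i.i.d. bases at a configurable GC content, one genome per
species), a set of planted transfer events (a donor interval copied,
forward or reverse-complement, into a recipient position, optionally
deleted from the sample-local donor), and paired-end reads drawn from the
*rearranged* sample genomes.  Detection then runs against the *clean*
genomes, mirroring real usage where the reference database predates the
transfer.

The evaluator scores predicted events (and optionally breakpoint pairs)
against the planted truth with a positional tolerance, one-to-one greedy
matching, and reports precision / recall / F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_encoding import revcomp
from .event_inference import HgtEvent
from .reference_io import ReferenceDatabase

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CommunitySpec:
    """Shape of a synthetic community.

    Defaults mirror the desk-scale benchmark: five 100 kb single-contig
    species at equal abundance, GC 0.5.
    """

    n_species: int = 5
    genome_length: int = 100_000
    gc: float = 0.5
    abundances: tuple[float, ...] | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10 kb")
        ab = self.abundances
        if ab is not None:
            if len(ab) != self.n_species:
                raise ValueError("abundances length != n_species")
            if abs(sum(ab) - 1.0) > 1e-9:
                raise ValueError("abundances must sum to 1")

    def relative_abundances(self) -> np.ndarray:
        if self.abundances is None:
            return np.full(self.n_species, 1.0 / self.n_species)
        return np.asarray(self.abundances, dtype=float)


@dataclass(frozen=True)
class PlantedEvent:
    donor_genome: str
    start: int            # 0-based inclusive, on the clean donor genome
    end: int              # 0-based exclusive
    recipient_genome: str
    insertion_pos: int    # 0-based position on the clean recipient genome
    direction: str        # 'forward' | 'reverse'
    delete_from_donor: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    events: list[PlantedEvent] = field(default_factory=list)

    def breakpoint_pairs(self) -> list[tuple[str, int, str, int]]:
        """The two truth breakpoint pairs implied by each planted event."""
        out = []
        for ev in self.events:
            out.append((ev.recipient_genome, ev.insertion_pos, ev.donor_genome, ev.start))
            out.append((ev.recipient_genome, ev.insertion_pos, ev.donor_genome, ev.end))
        return out


def _random_genome(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def simulate_community(
    spec: CommunitySpec,
    n_events: int = 3,
    event_len_range: tuple[int, int] = (1000, 3000),
    delete_from_donor: bool = False,
    margin: int = 5000,
    max_tries: int = 200,
) -> tuple[ReferenceDatabase, dict[str, str], TruthSet]:
    """Clean reference + rearranged sample genomes + planted-event truth.

    Events are placed non-overlapping on both the donor and the recipient
    (with ``margin`` bp of clearance) so each junction is unambiguous;
    infeasible placement after ``max_tries`` draws raises.
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"g{i + 1}" for i in range(spec.n_species)]
    clean = {n: _random_genome(rng, spec.genome_length, spec.gc) for n in names}
    species_of = {n: f"s{i + 1}" for i, n in enumerate(names)}
    ref = ReferenceDatabase(sequences=clean, species_of=species_of)

    used: dict[str, list[tuple[int, int]]] = {n: [] for n in names}

    def free(genome: str, lo: int, hi: int) -> bool:
        return all(hi + margin <= s or e + margin <= lo for s, e in used[genome])

    events: list[PlantedEvent] = []
    for _ in range(n_events):
        for attempt in range(max_tries):
            donor, recipient = rng.choice(spec.n_species, size=2, replace=False)
            dn, rn = names[donor], names[recipient]
            L = int(rng.integers(event_len_range[0], event_len_range[1] + 1))
            start = int(rng.integers(margin, spec.genome_length - margin - L))
            ins = int(rng.integers(margin, spec.genome_length - margin))
            if not free(dn, start, start + L) or not free(rn, ins, ins):
                continue
            direction = "forward" if rng.random() < 0.5 else "reverse"
            events.append(
                PlantedEvent(
                    donor_genome=dn, start=start, end=start + L,
                    recipient_genome=rn, insertion_pos=ins,
                    direction=direction, delete_from_donor=delete_from_donor,
                )
            )
            used[dn].append((start, start + L))
            used[rn].append((ins, ins))
            break
        else:
            raise RuntimeError("could not place planted events without overlap")

    # apply events to per-genome edit lists (sorted right-to-left so earlier
    # coordinates stay valid)
    sample = dict(clean)
    inserts: dict[str, list[tuple[int, str]]] = {n: [] for n in names}
    deletions: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    for ev in events:
        payload = clean[ev.donor_genome][ev.start : ev.end]
        if ev.direction == "reverse":
            payload = revcomp(payload)
        inserts[ev.recipient_genome].append((ev.insertion_pos, payload))
        if ev.delete_from_donor:
            deletions[ev.donor_genome].append((ev.start, ev.end))
    for n in names:
        seq = sample[n]
        edits = [(pos, "ins", payload) for pos, payload in inserts[n]]
        edits += [(s, "del", e) for s, e in deletions[n]]
        for pos, kind, arg in sorted(edits, key=lambda t: t[0], reverse=True):
            if kind == "ins":
                seq = seq[:pos] + arg + seq[pos:]
            else:
                seq = seq[:pos] + seq[arg:]
        sample[n] = seq

    return ref, sample, TruthSet(events=events)


def simulate_reads(
    sample_genomes: dict[str, str],
    depth: float = 40.0,
    read_len: int = 150,
    insert_mean: float = 350.0,
    insert_sd: float = 30.0,
    err_rate: float = 0.001,
    seed: int = 1,
    abundances: dict[str, float] | None = None,
) -> list[tuple[str, str, str]]:
    """Uniform paired-end read sampling with i.i.d. substitution errors.

    Per genome, the pair count is depth x length / (2 x read_len), scaled
    by relative abundance (x species count) when abundances are given, so a
    uniform community gets ``depth`` coverage everywhere.  Mate 2 is the
    reverse complement of the fragment's far end.  Returns (id, s1, s2).
    """
    if read_len >= insert_mean:
        raise ValueError("read_len must be below insert_mean")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str, str]] = []
    n_genomes = len(sample_genomes)
    for gi, (name, seq) in enumerate(sorted(sample_genomes.items())):
        L = len(seq)
        if read_len >= L:
            raise ValueError(f"read_len >= genome length for {name}")
        scale = 1.0
        if abundances is not None:
            scale = abundances[name] * n_genomes
        n_pairs = int(round(depth * scale * L / (2 * read_len)))
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        starts = rng.integers(0, L - read_len, size=n_pairs)
        isizes = np.clip(
            rng.normal(insert_mean, insert_sd, size=n_pairs).astype(int),
            2 * read_len, None,
        )
        flip = rng.random(n_pairs) < 0.5
        for i in range(n_pairs):
            s = int(starts[i])
            e = min(L, s + int(isizes[i]))
            frag = seq[s:e]
            if len(frag) < 2 * read_len:
                frag = seq[max(0, e - 2 * read_len) : e]
            if flip[i]:
                frag = revcomp(frag)
            m1 = frag[:read_len]
            m2 = revcomp(frag[-read_len:])
            if err_rate > 0:
                m1 = _mutate(rng, m1, err_rate)
                m2 = _mutate(rng, m2, err_rate)
            pairs.append((f"{name}_{i}", m1, m2))
    return pairs


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.shape[0]) < rate)[0]
    if hit.size == 0:
        return seq
    lut = {65: "CGT", 67: "AGT", 71: "ACT", 84: "ACG"}
    for i in hit:
        alts = lut.get(int(arr[i]), "ACGT")
        arr[i] = ord(alts[rng.integers(0, len(alts))])
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# evaluation

@dataclass(frozen=True)
class EvalReport:
    tolerance: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def evaluate_events(
    predicted: list[HgtEvent],
    truth: TruthSet,
    tolerance: int = 50,
) -> EvalReport:
    """Event-level precision/recall/F1 with one-to-one greedy matching.

    A prediction matches a planted event iff recipient genome + insertion
    position, donor genome + both interval ends are each within
    ``tolerance`` bp, and the direction agrees.
    """
    unmatched = list(truth.events)
    tp = 0
    for pred in predicted:
        best_i, best_d = -1, None
        for i, t in enumerate(unmatched):
            if pred.recipient_genome != t.recipient_genome:
                continue
            if pred.donor_genome != t.donor_genome:
                continue
            if pred.direction != t.direction:
                continue
            d = max(
                abs(pred.insertion_pos - t.insertion_pos),
                abs(pred.transfer_start - t.start),
                abs(pred.transfer_end - t.end),
            )
            if d <= tolerance and (best_d is None or d < best_d):
                best_i, best_d = i, d
        if best_i >= 0:
            tp += 1
            unmatched.pop(best_i)
    fp = len(predicted) - tp
    fn = len(unmatched)
    p, r, f1 = _prf(tp, fp, fn)
    return EvalReport(tolerance=tolerance, tp=tp, fp=fp, fn=fn, precision=p, recall=r, f1=f1)


def evaluate_breakpoints(
    predicted: list[tuple[str, int, str, int]],
    truth: TruthSet,
    tolerance: int = 50,
) -> EvalReport:
    """Breakpoint-pair-level scores; pairs are genome-labelled loci duos."""
    def norm(bp):
        g1, p1, g2, p2 = bp
        return (g1, p1, g2, p2) if g1 <= g2 else (g2, p2, g1, p1)

    unmatched = [norm(b) for b in truth.breakpoint_pairs()]
    tp = 0
    for bp in predicted:
        bp = norm(bp)
        for i, t in enumerate(unmatched):
            if bp[0] == t[0] and bp[2] == t[2] and abs(bp[1] - t[1]) <= tolerance and abs(bp[3] - t[3]) <= tolerance:
                tp += 1
                unmatched.pop(i)
                break
    fp = len(predicted) - tp
    fn = len(unmatched)
    p, r, f1 = _prf(tp, fp, fn)
    return EvalReport(tolerance=tolerance, tp=tp, fp=fp, fn=fn, precision=p, recall=r, f1=f1)


def truth_as_events(truth: TruthSet) -> list[HgtEvent]:
    """Planted events in prediction form (for evaluator self-consistency)."""
    return [
        HgtEvent(
            recipient_genome=t.recipient_genome, insertion_pos=t.insertion_pos,
            donor_genome=t.donor_genome, transfer_start=t.start,
            transfer_end=t.end, direction=t.direction, support=0.0,
        )
        for t in truth.events
    ]


def run_desk_benchmark(
    seeds: list[int],
    n_species: int = 5,
    genome_length: int = 100_000,
    n_events: int = 3,
    event_len_range: tuple[int, int] = (1000, 3000),
    depth: float = 40.0,
    err_rate: float = 0.001,
    k: int = 20,
    tolerance: int = 50,
) -> list[EvalReport]:
    """Full-pipeline event-level scores over seeded synthetic communities.

    Defaults are the desk-scale benchmark conditions: five 100 kb genomes,
    three planted 1-3 kb transfers, 40x coverage with 0.1% substitution
    error, detection at k = 20, scoring at 50 bp tolerance.
    """
    from .pipeline import detect

    reports: list[EvalReport] = []
    for seed in seeds:
        spec = CommunitySpec(n_species=n_species, genome_length=genome_length, seed=seed)
        ref, sample, truth = simulate_community(
            spec, n_events=n_events, event_len_range=event_len_range
        )
        pairs = simulate_reads(sample, depth=depth, err_rate=err_rate, seed=seed)
        result = detect(ref, pairs, k=k, seed=seed)
        reports.append(evaluate_events(result.events, truth, tolerance=tolerance))
    return reports


def sequencing_budget(L: float, a_rel: float) -> float:
    """Recommended sequencing output (bases) to reach ~30x on a species of
    genome length ``L`` at relative abundance ``a_rel``: 30 * L / a_rel."""
    if a_rel <= 0 or a_rel > 1:
        raise ValueError("relative abundance must be in (0, 1]")
    if L <= 0:
        raise ValueError("genome length must be positive")
    return 30.0 * L / a_rel
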