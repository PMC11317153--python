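"""Complete HGT events from breakpoint pairs via maximum-weight matching.

A complete transfer leaves three breakpoints: two on the donor genome (the
ends of the transferred interval) and one on the recipient (the insertion
site), observed as two breakpoint pairs that share the recipient
breakpoint.  Each refined pair is a graph node; an edge joins two nodes
that could be the two halves of one event, and a maximum-weight matching
(weight = average split-read support of the two pairs) resolves which
pairs actually belong together when several assignments are possible.

Edges must pass four checks before entering the graph:

1. read geometry — at the shared breakpoint the two pairs retain opposite
   sides of the recipient, and on the donor the retained sides face into
   the transferred interval;
2. consistent strand orientation (both pairs forward, or both reverse);
3. transferred interval at least 500 bp;
4. the donor genome carries exactly two breakpoint clusters related to the
   insertion site (DBSCAN, eps 200, minPoints 1, over all related donor
   breakpoints in the population).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.cluster import DBSCAN

from .breakpoint_detection import RefinedBreakpointPair

DEFAULT_MIN_TRANSFER_LEN = 500
DEFAULT_SHARE_TOL = 50
DEFAULT_CLUSTER_EPS = 200.0


@dataclass(frozen=True)
class HgtEvent:
    """Donor interval + recipient insertion site + direction of one transfer."""

    recipient_genome: str
    insertion_pos: int
    donor_genome: str
    transfer_start: int   # 0-based inclusive
    transfer_end: int     # 0-based exclusive
    direction: str        # 'forward' | 'reverse'
    support: float        # average split reads of the two matched pairs

    @property
    def length(self) -> int:
        return self.transfer_end - self.transfer_start


@dataclass(frozen=True)
class CandidateEdge:
    i: int
    j: int
    event: HgtEvent


def _ends(p: RefinedBreakpointPair):
    return (
        (p.genome_a, p.pos_a, p.side_a),
        (p.genome_b, p.pos_b, p.side_b),
    )


def link_candidates(
    pairs: list[RefinedBreakpointPair],
    tolerance: int = DEFAULT_SHARE_TOL,
) -> list[CandidateEdge]:
    """Propose an edge for every two pairs sharing one breakpoint with the
    two remaining breakpoints on a single (donor) genome."""
    edges: list[CandidateEdge] = []
    for i in range(len(pairs)):
        for j in range(i + 1, len(pairs)):
            ev = _try_link(pairs[i], pairs[j], tolerance)
            if ev is not None:
                edges.append(CandidateEdge(i=i, j=j, event=ev))
    return edges


def _try_link(
    p1: RefinedBreakpointPair,
    p2: RefinedBreakpointPair,
    tolerance: int,
) -> HgtEvent | None:
    for a1, d1 in _orderings(p1):
        for a2, d2 in _orderings(p2):
            if a1[0] != a2[0] or abs(a1[1] - a2[1]) > tolerance:
                continue  # no shared breakpoint under this assignment
            if d1[0] != d2[0]:
                continue  # remaining breakpoints on different genomes
            if d1[0] == a1[0]:
                continue  # donor must differ from recipient
            lo, hi = sorted((d1[1], d2[1]))
            direction = "forward" if p1.orientation == "forward" else "reverse"
            support = (p1.split_reads + p2.split_reads) / 2.0
            return HgtEvent(
                recipient_genome=a1[0],
                insertion_pos=a1[1],
                donor_genome=d1[0],
                transfer_start=lo,
                transfer_end=hi,
                direction=direction,
                support=support,
            )
    return None


def _orderings(p: RefinedBreakpointPair):
    e1, e2 = _ends(p)
    return ((e1, e2), (e2, e1))


def _geometry_ok(
    p1: RefinedBreakpointPair, p2: RefinedBreakpointPair, ev: HgtEvent, tolerance: int
) -> bool:
    """Constraint 1: retained sides match the event geometry.

    The two pairs must retain opposite sides of the recipient at the shared
    breakpoint, and each donor breakpoint's retained side must face into
    the transferred interval.
    """
    sides = []
    for p in (p1, p2):
        shared_side = donor_side = None
        donor_pos = None
        for (g, pos, side), (og, opos, oside) in (_ends(p), _ends(p)[::-1]):
            if g == ev.recipient_genome and abs(pos - ev.insertion_pos) <= tolerance:
                shared_side, donor_side, donor_pos = side, oside, opos
                break
        if shared_side is None or donor_side in (None, "?"):
            return False
        sides.append((shared_side, donor_side, donor_pos))
    (s1, d1, y1), (s2, d2, y2) = sides
    if "?" in (s1, s2):
        return False
    if s1 == s2:
        return False  # both pairs retain the same recipient side
    mid = (ev.transfer_start + ev.transfer_end) / 2
    for d_side, y in ((d1, y1), (d2, y2)):
        if y <= mid and d_side != "R":
            return False  # left donor end must retain rightward (into interval)
        if y > mid and d_side != "L":
            return False
    return True


def apply_constraints(
    edges: list[CandidateEdge],
    pairs: list[RefinedBreakpointPair],
    population_pairs: list[RefinedBreakpointPair] | None = None,
    min_transfer_len: int = DEFAULT_MIN_TRANSFER_LEN,
    tolerance: int = DEFAULT_SHARE_TOL,
    eps: float = DEFAULT_CLUSTER_EPS,
) -> list[CandidateEdge]:
    """Drop candidate edges failing any of the four event constraints."""
    pop = pairs if population_pairs is None else population_pairs
    kept: list[CandidateEdge] = []
    for e in edges:
        p1, p2 = pairs[e.i], pairs[e.j]
        if p1.orientation != p2.orientation:
            continue  # constraint 2
        if e.event.length < min_transfer_len:
            continue  # constraint 3
        if not _geometry_ok(p1, p2, e.event, tolerance):
            continue  # constraint 1
        if _donor_cluster_count(e.event, pop, tolerance, eps) != 2:
            continue  # constraint 4
        kept.append(e)
    return kept


def _donor_cluster_count(
    ev: HgtEvent,
    population: list[RefinedBreakpointPair],
    tolerance: int,
    eps: float,
) -> int:
    """Number of DBSCAN clusters among donor-genome breakpoints related to
    the insertion breakpoint across the population."""
    donor_positions: list[int] = []
    for p in population:
        for (g, pos, _), (og, opos, _) in (_ends(p), _ends(p)[::-1]):
            if (
                g == ev.recipient_genome
                and abs(pos - ev.insertion_pos) <= tolerance
                and og == ev.donor_genome
            ):
                donor_positions.append(opos)
    if not donor_positions:
        return 0
    pts = np.array(donor_positions, dtype=float).reshape(-1, 1)
    labels = DBSCAN(eps=eps, min_samples=1).fit_predict(pts)
    return len(set(labels))


def match_events(
    pairs: list[RefinedBreakpointPair],
    edges: list[CandidateEdge],
) -> list[HgtEvent]:
    """Maximum-weight matching over the breakpoint graph; one event per
    matched edge.  Ties resolve toward lexicographically smaller node ids."""
    if not edges:
        return []
    G = nx.Graph()
    G.add_nodes_from(range(len(pairs)))
    best: dict[tuple[int, int], CandidateEdge] = {}
    for e in sorted(edges, key=lambda e: (e.i, e.j)):
        key = (e.i, e.j)
        if key not in best or e.event.support > best[key].event.support:
            best[key] = e
    for (i, j), e in best.items():
        G.add_edge(i, j, weight=e.event.support, edge=e)
    mate = nx.max_weight_matching(G)
    events = []
    for i, j in sorted(tuple(sorted(m)) for m in mate):
        events.append(best[(i, j)].event)
    return events


def infer_events(
    pairs: list[RefinedBreakpointPair],
    population_pairs: list[RefinedBreakpointPair] | None = None,
    min_transfer_len: int = DEFAULT_MIN_TRANSFER_LEN,
    tolerance: int = DEFAULT_SHARE_TOL,
) -> list[HgtEvent]:
    """Link -> constrain -> match; the complete event-inference stage."""
    edges = link_candidates(pairs, tolerance=tolerance)
    edges = apply_constraints(
        edges, pairs, population_pairs,
        min_transfer_len=min_transfer_len, tolerance=tolerance,
    )
    return match_events(pairs, edges)
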