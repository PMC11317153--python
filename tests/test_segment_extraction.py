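"""Downsampling, window screening, cBKP calling, markers and segments."""

import numpy as np
import pytest

from hgtscan import benchmark_sim as sim
from hgtscan import segment_extraction as seg
from hgtscan.core_encoding import build_hash_functions, new_count_table, seq_to_codes
from hgtscan.reference_io import ReferenceDatabase


class TestSampling:
    def test_rate_is_budget_over_bases(self):
        plan = seg.make_sampling_plan(M=2e9, A=4_000_000_000, seed=1)
        assert plan.rate == pytest.approx(0.5)

    def test_rate_capped_at_one_counts_everything(self, hfs16):
        pairs = [("r1", "ACGT" * 10, "TTTA" * 10)]
        table, selected, plan, _ = seg.downsample_and_count(pairs, hfs16, M=1e9, seed=1)
        assert plan.rate == 1.0
        assert selected == pairs
        assert table.counters.sum() > 0

    def test_zero_bases_rejected(self):
        with pytest.raises(seg.EmptyInputError):
            seg.make_sampling_plan(M=1e9, A=0, seed=1)

    def test_deterministic_under_seed(self, hfs16, rng):
        bases = np.array(list("ACGT"))
        pairs = [
            (f"r{i}", "".join(bases[rng.integers(0, 4, 60)]), "".join(bases[rng.integers(0, 4, 60)]))
            for i in range(200)
        ]
        t1, s1, _, _ = seg.downsample_and_count(pairs, hfs16, M=10_000, seed=5)
        t2, s2, _, _ = seg.downsample_and_count(pairs, hfs16, M=10_000, seed=5)
        assert s1 == s2 and len(s1) < len(pairs)
        assert np.array_equal(t1.counters, t2.counters)


class TestWindowScreening:
    def test_toy_hit_ratios(self):
        kappa, mu = seg.hit_ratios(np.array([1, 0, 1, 0]), np.array([1, 1, 1, 0]))
        assert kappa == pytest.approx(0.5)
        assert mu == pytest.approx(0.75)

    def test_kmers_per_window_with_default_w(self, rng):
        # w = 500, k = 32 -> u = w - k + 1 = 469
        hfs = build_hash_functions(k=32, ell=3, seed=1)
        bases = np.array(list("ACGT"))
        ref = ReferenceDatabase(
            sequences={"g": "".join(bases[rng.integers(0, 4, 500)])},
            species_of={"g": "s"},
        )
        table = new_count_table(hfs)
        (v,) = seg.screen_present_fragments(ref, table, hfs, w=500)
        assert v.u == 469

    def test_empty_table_screens_everything_out(self, hfs16, two_genome_ref):
        table = new_count_table(hfs16)
        verdicts = seg.screen_present_fragments(two_genome_ref, table, hfs16)
        assert all(not v.present for v in verdicts)
        assert seg.present_regions(verdicts) == {}

    def test_kappa_never_exceeds_mu(self, hfs16, two_genome_ref, rng):
        table = new_count_table(hfs16)
        table.counters[:] = rng.integers(0, 6, size=table.size)
        for v in seg.screen_present_fragments(two_genome_ref, table, hfs16):
            assert v.kappa <= v.mu

    def test_short_sequence_forms_truncated_window(self, hfs16):
        ref = ReferenceDatabase(sequences={"g": "ACGT" * 30}, species_of={"g": "s"})
        table = new_count_table(hfs16)
        verdicts = seg.screen_present_fragments(ref, table, hfs16, w=500)
        assert len(verdicts) == 1
        assert verdicts[0].window_len == 120
        assert verdicts[0].u == 120 - 16 + 1


class TestCbkpDetection:
    def test_hand_worked_step_profile(self):
        # D drops 4 -> 0 at index 4; bin 0 vs bin 4 differs by 4 > theta=3
        loci = seg.cbkp_loci_from_counts(
            np.array([4, 4, 4, 4, 0, 0, 0, 0]), e=2, k=2, theta=3
        )
        assert 0 in loci
        assert set(loci) <= {0, 1, 2}

    def test_flat_profile_yields_nothing(self):
        assert len(seg.cbkp_loci_from_counts(np.full(50, 7), e=5, k=4, theta=3)) == 0

    def test_mirrored_profile_selects_far_bin(self):
        loci = seg.cbkp_loci_from_counts(
            np.array([0, 0, 0, 0, 4, 4, 4, 4]), e=2, k=2, theta=3
        )
        assert 4 in loci
        assert all(l >= 4 for l in loci)


class TestMarkersAndPairing:
    def _setup(self, hfs16, two_genome_ref):
        refA = two_genome_ref.sequences["gA"]
        refB = two_genome_ref.sequences["gB"]
        cbkps = [
            seg.CandidateBreakpoint("gA", 100, refA[100:116], id=0),
            seg.CandidateBreakpoint("gA", 500, refA[500:516], id=1),
            seg.CandidateBreakpoint("gB", 300, refB[300:316], id=2),
        ]
        table = new_count_table(hfs16)
        return cbkps, table

    def test_zero_count_marker_omitted(self, hfs16, two_genome_ref):
        cbkps, table = self._setup(hfs16, two_genome_ref)
        B = seg.build_marker_table(cbkps, two_genome_ref, table, hfs16)
        assert (B.loci >= 0).sum() == 0  # nothing counted in Q yet

    def test_retained_marker_retrievable(self, hfs16, two_genome_ref):
        from hgtscan.core_encoding import encode_kmer

        cbkps, table = self._setup(hfs16, two_genome_ref)
        table.counters[:] = 1  # everything supported
        B = seg.build_marker_table(cbkps, two_genome_ref, table, hfs16)
        for c in cbkps:
            idx = np.asarray(encode_kmer(hfs16, c.marker).indices)
            assert c.id in B.loci[idx]

    def test_cross_species_read_pair_flags_both(self, hfs16, two_genome_ref):
        cbkps, table = self._setup(hfs16, two_genome_ref)
        table.counters[:] = 1
        B = seg.build_marker_table(cbkps, two_genome_ref, table, hfs16)
        refA = two_genome_ref.sequences["gA"]
        refB = two_genome_ref.sequences["gB"]
        read_pairs = [("j1", refA[90:130], refB[290:330])]  # markers 0 and 2
        pairings = seg.pair_hgt_cbkps(
            read_pairs, B, hfs16, two_genome_ref.species_of, cbkps
        )
        assert (0, 2) in pairings
        assert cbkps[0].hgt_derived and cbkps[2].hgt_derived
        assert not cbkps[1].hgt_derived

    def test_same_species_pair_not_flagged(self, hfs16, two_genome_ref):
        cbkps, table = self._setup(hfs16, two_genome_ref)
        table.counters[:] = 1
        B = seg.build_marker_table(cbkps, two_genome_ref, table, hfs16)
        refA = two_genome_ref.sequences["gA"]
        read_pairs = [("p1", refA[90:130], refA[490:530])]  # markers 0 and 1: same species
        pairings = seg.pair_hgt_cbkps(
            read_pairs, B, hfs16, two_genome_ref.species_of, cbkps
        )
        assert pairings == []
        assert not any(c.hgt_derived for c in cbkps)

    def test_single_marker_read_not_flagged(self, hfs16, two_genome_ref):
        cbkps, table = self._setup(hfs16, two_genome_ref)
        table.counters[:] = 1
        B = seg.build_marker_table(cbkps, two_genome_ref, table, hfs16)
        refA = two_genome_ref.sequences["gA"]
        read_pairs = [("s1", refA[90:130], refA[1500:1540])]
        assert seg.pair_hgt_cbkps(read_pairs, B, hfs16, two_genome_ref.species_of, cbkps) == []


class TestSegments:
    def _ref(self):
        seq = "A" * 10_000
        return ReferenceDatabase(sequences={"g": seq}, species_of={"g": "s"})

    def _cbkp(self, locus, flagged=True):
        c = seg.CandidateBreakpoint("g", locus, "A" * 16, id=0)
        c.hgt_derived = flagged
        return c

    def test_interior_cbkp_spans_both_flanks(self):
        segs = seg.extract_segments(self._ref(), [self._cbkp(1000)])
        assert segs.source == {"g|500": ("g", 500)}
        assert len(segs.sequences["g|500"]) == 1000

    def test_clipped_at_sequence_start(self):
        segs = seg.extract_segments(self._ref(), [self._cbkp(200)])
        assert segs.source == {"g|0": ("g", 0)}
        assert len(segs.sequences["g|0"]) == 700

    def test_overlapping_segments_merge(self):
        segs = seg.extract_segments(self._ref(), [self._cbkp(1000), self._cbkp(1300)])
        assert list(segs.source) == ["g|500"]
        assert len(segs.sequences["g|500"]) == 1300  # 500..1800

    def test_unflagged_candidates_ignored(self):
        segs = seg.extract_segments(self._ref(), [self._cbkp(1000, flagged=False)])
        assert segs.sequences == {}

    def test_lift_roundtrip(self):
        segs = seg.extract_segments(self._ref(), [self._cbkp(1000)])
        assert segs.lift("g|500", 0) == ("g", 500)
        assert segs.lift("g|500", 999) == ("g", 1499)


class TestPlantedJunctionSensitivity:
    def test_junction_loci_among_hgt_cbkps(self):
        # error-free reads at 40x over one planted transfer: the junction
        # loci on both donor and recipient must appear among the
        # HGT-derived candidates within k bp
        k = 16
        spec = sim.CommunitySpec(n_species=3, genome_length=20_000, seed=42)
        ref, sample, truth = sim.simulate_community(
            spec, n_events=1, event_len_range=(1500, 1500), margin=3000
        )
        pairs = sim.simulate_reads(sample, depth=40, err_rate=0.0, seed=42)
        hfs = build_hash_functions(k=k, ell=3, seed=1)
        table, selected, _, cache = seg.downsample_and_count(pairs, hfs, seed=1)
        verdicts = seg.screen_present_fragments(ref, table, hfs)
        cbkps = seg.detect_cbkps(
            ref, table, hfs, regions=seg.present_regions(verdicts)
        )
        B = seg.build_marker_table(cbkps, ref, table, hfs)
        seg.pair_hgt_cbkps(selected, B, hfs, ref.species_of, cbkps, cache=cache)
        flagged = [(c.genome, c.locus) for c in cbkps if c.hgt_derived]
        ev = truth.events[0]
        for genome, locus in [
            (ev.recipient_genome, ev.insertion_pos),
            (ev.donor_genome, ev.start),
            (ev.donor_genome, ev.end),
        ]:
            assert any(
                g == genome and abs(l - locus) <= 2 * k for g, l in flagged
            ), (genome, locus, [f for f in flagged if f[0] == genome][:10])
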