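"""Rearrangement and library simulator tests."""

import collections
from fractions import Fraction

import numpy as np
import pytest

import htgts_tcr as h
from htgts_tcr.simulate import (DEFAULT_TRA_SCHEDULE, LibraryParams,
                                _molecule_for_event, fragment_and_capture,
                                load_bait_table, make_bait_table, revcomp,
                                simulate_tcra_usage_gradient, write_bait_table)


class TestJunctionModelParams:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            h.JunctionModelParams(del_v=-1)

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError, match="productivity"):
            h.JunctionModelParams(productivity="maybe")


class TestAlleleRearrangement:
    def test_vdj_event_structure(self, trb_locus):
        rng = np.random.default_rng(1)
        ev = h.simulate_allele_rearrangement(trb_locus,
                                             h.JunctionModelParams(), rng)
        assert ev.event_class == "VDJ"
        assert ev.v_id and ev.d_id and ev.j_id
        v = trb_locus[ev.v_id]
        j = trb_locus[ev.j_id]
        assert ev.coding_seq.startswith(v.sequence[: len(v.sequence) - ev.del_v])
        assert ev.coding_seq.endswith(j.sequence[ev.del_j :])

    def test_coding_seq_assembly_exact(self, trb_locus):
        rng = np.random.default_rng(2)
        for _ in range(50):
            ev = h.simulate_allele_rearrangement(trb_locus,
                                                 h.JunctionModelParams(), rng)
            v = trb_locus[ev.v_id].sequence
            d = trb_locus[ev.d_id].sequence
            j = trb_locus[ev.j_id].sequence
            expected = (v[: len(v) - ev.del_v] + ev.n1
                        + d[ev.del_d5 : len(d) - ev.del_d3] + ev.n2
                        + j[ev.del_j :])
            assert ev.coding_seq == expected

    def test_anchors_always_survive(self, trb_locus):
        """Deletions are clipped so Cys/Phe anchors always remain."""
        params = h.JunctionModelParams(del_v=50, del_j=50)
        rng = np.random.default_rng(3)
        for _ in range(200):
            ev = h.simulate_allele_rearrangement(trb_locus, params, rng)
            v = trb_locus[ev.v_id]
            j = trb_locus[ev.j_id]
            assert ev.del_v <= len(v.sequence) - (v.anchor_codon_offset + 3)
            assert ev.del_j <= j.anchor_codon_offset

    def test_frame_shift_matches_anchor_distance(self, trb_locus):
        rng = np.random.default_rng(4)
        for _ in range(100):
            ev = h.simulate_allele_rearrangement(trb_locus,
                                                 h.JunctionModelParams(), rng)
            v = trb_locus[ev.v_id]
            j = trb_locus[ev.j_id]
            j_anchor = len(ev.coding_seq) - (len(j.sequence) - j.anchor_codon_offset)
            assert ev.frame_shift == (j_anchor - v.anchor_codon_offset) % 3

    def test_frame_mode_productive_iff_in_frame(self, trb_locus):
        params = h.JunctionModelParams(productivity="frame")
        rng = np.random.default_rng(5)
        for _ in range(100):
            ev = h.simulate_allele_rearrangement(trb_locus, params, rng)
            assert ev.is_productive == (ev.frame_shift == 0)

    def test_full_mode_rejects_stop_codons(self, trb_locus):
        rng = np.random.default_rng(6)
        n_stop = 0
        for _ in range(2000):
            ev = h.simulate_allele_rearrangement(trb_locus,
                                                 h.JunctionModelParams(), rng)
            if ev.frame_shift == 0 and not ev.is_productive:
                n_stop += 1
                v = trb_locus[ev.v_id]
                j = trb_locus[ev.j_id]
                ja = len(ev.coding_seq) - (len(j.sequence) - j.anchor_codon_offset)
                cdr3 = ev.coding_seq[v.anchor_codon_offset : ja + 3]
                codons = {cdr3[p : p + 3] for p in range(0, len(cdr3) - 2, 3)}
                assert codons & {"TAA", "TAG", "TGA"}
        assert n_stop > 0  # stop codons do occur with N insertions

    def test_dj_event_has_no_v(self, trb_locus):
        rng = np.random.default_rng(7)
        ev = h.simulate_allele_rearrangement(trb_locus, h.JunctionModelParams(),
                                             rng, event_class="DJ")
        assert ev.event_class == "DJ" and ev.v_id is None
        assert not ev.is_productive

    def test_dj_respects_cluster_rule(self, trb_locus):
        """D2 (between the clusters) never joins a cluster-1 J."""
        rng = np.random.default_rng(8)
        seen_d2 = False
        for _ in range(500):
            ev = h.simulate_allele_rearrangement(
                trb_locus, h.JunctionModelParams(), rng)
            d = trb_locus[ev.d_id]
            j = trb_locus[ev.j_id]
            assert j.contig_start > d.contig_end
            if ev.d_id == "TRBD2":
                seen_d2 = True
                assert j.cluster == "Jb2"
        assert seen_d2

    def test_nonfunctional_rss_excluded(self):
        import dataclasses
        locus = h.build_toy_locus(4, 2, 6, seed=40)
        segs = [dataclasses.replace(s, functionality="nonfunctional_rss")
                if s.id == "TRBV1" else s for s in locus.segments]
        locus2 = h.Locus(name="TRB", segments=segs, contig=locus.contig)
        rng = np.random.default_rng(9)
        for _ in range(200):
            ev = h.simulate_allele_rearrangement(locus2,
                                                 h.JunctionModelParams(), rng)
            assert ev.v_id != "TRBV1"

    def test_v_weights_respected(self, trb_locus):
        ids = [v.id for v in trb_locus.v_segments]
        weights = {ids[0]: 1.0}  # everything else zero
        params = h.JunctionModelParams(v_weights=weights)
        rng = np.random.default_rng(10)
        for _ in range(50):
            ev = h.simulate_allele_rearrangement(trb_locus, params, rng)
            assert ev.v_id == ids[0]

    def test_vj_join_on_dless_locus(self, tra_locus):
        rng = np.random.default_rng(11)
        ev = h.simulate_allele_rearrangement(tra_locus,
                                             h.JunctionModelParams(), rng)
        assert ev.event_class == "VDJ" and ev.d_id is None
        assert ev.n2 == "" and ev.del_d5 == 0 and ev.del_d3 == 0


class TestCellModel:
    def test_two_events_per_cell(self, trb_locus):
        rng = np.random.default_rng(12)
        evs = h.simulate_cell(trb_locus, h.JunctionModelParams(), rng)
        assert len(evs) == 2
        assert {e.allele for e in evs} == {0, 1}

    def test_feedback_inhibition(self, trb_locus):
        """A productive allele-0 VDJ leaves allele 1 DJ-only."""
        params = h.JunctionModelParams(productivity="frame")
        rng = np.random.default_rng(13)
        for _ in range(300):
            a0, a1 = h.simulate_cell(trb_locus, params, rng)
            if a0.event_class == "VDJ" and a0.is_productive:
                assert a1.event_class == "DJ"

    def test_beta_selection_keeps_only_survivors(self, trb_locus):
        params = h.JunctionModelParams(productivity="frame")
        rng = np.random.default_rng(14)
        for _ in range(100):
            evs = h.simulate_cell(trb_locus, params, rng,
                                  selection="beta_selection")
            assert any(e.is_productive for e in evs)

    def test_bad_selection_rejected(self, trb_locus):
        with pytest.raises(ValueError, match="selection"):
            h.simulate_cell(trb_locus, h.JunctionModelParams(),
                            np.random.default_rng(0), selection="gamma")

    def test_germline_alleles_without_rearrangement(self, trb_locus):
        rng = np.random.default_rng(15)
        evs = h.simulate_cells(trb_locus, h.JunctionModelParams(), 100, rng,
                               p_rearrange=0.0)
        assert all(e.event_class == "germline" for e in evs)

    def test_exact_beta_selection_enumeration(self):
        exp = h.beta_selection_expectation()
        assert exp["survival"] == Fraction(5, 9)
        assert exp["productive_vdj_fraction"] == Fraction(5, 7)


class TestTcraGradient:
    def test_rounds_shift_usage_distal(self, tra_locus):
        params = h.JunctionModelParams()
        rng = np.random.default_rng(16)
        def distal_frac(round_count, n=800):
            hits = 0
            for _ in range(n):
                ev = simulate_tcra_usage_gradient(tra_locus, round_count, rng,
                                                  params)
                if tra_locus[ev.v_id].positional_class == "distal":
                    hits += 1
            return hits / n
        early, late = distal_frac(1), distal_frac(5)
        assert late > early + 0.3  # 0.05 -> 0.80 class weight

    def test_round_recorded_and_validated(self, tra_locus):
        rng = np.random.default_rng(17)
        ev = simulate_tcra_usage_gradient(tra_locus, 2, rng)
        assert ev.round_index == 2
        with pytest.raises(ValueError, match="round_count"):
            simulate_tcra_usage_gradient(tra_locus, 0, rng)

    def test_rejects_d_locus(self, trb_locus):
        with pytest.raises(ValueError, match="D-less"):
            simulate_tcra_usage_gradient(trb_locus, 1,
                                         np.random.default_rng(0))

    def test_rounds_past_schedule_reuse_last_row(self, tra_locus):
        rng = np.random.default_rng(18)
        ev = simulate_tcra_usage_gradient(tra_locus, 99, rng)
        assert ev.round_index == 99


class TestLibrary:
    def test_bait_table_round_trip(self, trb_locus, tmp_path):
        baits = make_bait_table(trb_locus, [trb_locus.j_segments[0].id])
        p = tmp_path / "baits.tsv"
        write_bait_table(baits, p)
        again = load_bait_table(p)
        assert again == baits

    def test_j_bait_primers_are_antisense_downstream(self, trb_locus):
        j = trb_locus.j_segments[0]
        (bait,) = make_bait_table(trb_locus, [j.id])
        assert bait.side == "J"
        down = trb_locus.downstream_flank(j.id, 250)
        assert revcomp(bait.bio_seq) in down
        assert revcomp(bait.nested_seq) in down

    def test_v_bait_primers_are_sense_within_v(self, trb_locus):
        v = trb_locus.v_segments[0]
        (bait,) = make_bait_table(trb_locus, [v.id])
        assert bait.side == "V"
        n = len(v.sequence)
        assert bait.bio_seq == v.sequence[n - 100 : n - 80]
        assert bait.nested_seq == v.sequence[n - 60 : n - 40]

    def test_molecule_contains_junction(self, trb_locus):
        rng = np.random.default_rng(19)
        ev = h.simulate_allele_rearrangement(trb_locus,
                                             h.JunctionModelParams(), rng)
        (bait,) = make_bait_table(trb_locus, [ev.j_id])
        mol, bio_pos, nested_pos = _molecule_for_event(ev, trb_locus, bait,
                                                       LibraryParams())
        assert revcomp(ev.coding_seq) in mol
        # primer sites appear verbatim at the stated positions
        assert mol[bio_pos : bio_pos + len(bait.bio_seq)] == bait.bio_seq
        assert mol[nested_pos : nested_pos + len(bait.nested_seq)] == bait.nested_seq
        # read 1 direction: outer bio primer first, nested primer closer to
        # the junction
        assert bio_pos < nested_pos

    def test_incompatible_event_not_captured(self, trb_locus):
        rng = np.random.default_rng(20)
        ev = h.simulate_allele_rearrangement(trb_locus,
                                             h.JunctionModelParams(), rng)
        other = next(j for j in trb_locus.j_segments if j.id != ev.j_id)
        (bait,) = make_bait_table(trb_locus, [other.id])
        assert _molecule_for_event(ev, trb_locus, bait, LibraryParams()) is None

    def test_size_selection_enforced(self, small_library):
        for p in small_library["pairs"]:
            assert 300 <= p.product_len <= 700

    def test_read1_starts_with_nested_primer(self, small_library):
        baits = {b.primer_id: b for b in small_library["baits"]}
        mismatched = 0
        for p in small_library["pairs"]:
            nested = baits[p.bait_id].nested_seq
            prefix = p.seq1[: len(nested)]
            d = sum(a != b for a, b in zip(prefix, nested))
            mismatched += d
            assert d <= 2  # sequencing errors only
        # error rate 0.001: a handful of mismatches at most over the library

    def test_truth_table_links_reads(self, small_library):
        truth = small_library["truth"]
        ids = {p.read_id for p in small_library["pairs"]}
        assert set(truth["read_id"]) == ids
        assert (truth["bait_id"].str.startswith("bait_")).all()

    def test_pcr_duplicates_share_breakpoints(self, trb_locus):
        rng = np.random.default_rng(22)
        params = h.JunctionModelParams()
        evs = [h.simulate_allele_rearrangement(trb_locus, params, rng)
               for _ in range(200)]
        baits = make_bait_table(trb_locus, [j.id for j in trb_locus.j_segments])
        lib = LibraryParams(mean_duplicates=1.0, error_rate=0.0)
        pairs, truth = fragment_and_capture(evs, trb_locus, baits, lib, rng)
        by_mol = collections.defaultdict(list)
        for p in pairs:
            by_mol[p.read_id.rsplit("d", 1)[0]].append(p)
        n_dup_groups = sum(1 for v in by_mol.values() if len(v) > 1)
        assert n_dup_groups > 5
        for group in by_mol.values():
            assert len({(p.seq1, p.seq2) for p in group}) == 1

    def test_fastq_round_trip(self, small_library, tmp_path):
        from htgts_tcr.preprocess import read_fastq_pairs
        from htgts_tcr.simulate import write_fastq
        pairs = small_library["pairs"][:20]
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        write_fastq(pairs, r1, r2)
        back = list(read_fastq_pairs(r1, r2))
        assert [(b[0], b[1], b[3]) for b in back] == \
            [(p.read_id, p.seq1, p.seq2) for p in pairs]

    def test_empty_library_warns(self, trb_locus):
        rng = np.random.default_rng(23)
        (bait,) = make_bait_table(trb_locus, [trb_locus.j_segments[0].id])
        with pytest.warns(UserWarning, match="empty"):
            fragment_and_capture([], trb_locus, [bait], LibraryParams(), rng)
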