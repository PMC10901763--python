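"""Scrambling classification, MDS density, alternative processing."""

import pytest

from pgrmap import classify_scrambling, compute_mpka, detect_alt_processing
from pgrmap.architecture import summarize_architecture
from pgrmap.evaluate import full_recovery
from pgrmap.model import IES, MDS, Interval, RearrangementMap


def make_map(entries, mac_id="m", ies=()):
    """entries: (mic_start, mic_end, strand[, mic_contig]) in somatic order."""
    rmap = RearrangementMap(mac_contig_id=mac_id)
    pos = 0
    for i, entry in enumerate(entries, start=1):
        s, e, strand = entry[:3]
        contig = entry[3] if len(entry) > 3 else "g"
        length = e - s
        rmap.mds_list.append(
            MDS(i, Interval(mac_id, pos, pos + length), Interval(contig, s, e), strand)
        )
        rmap.mic_contigs_used.add(contig)
        pos += length
    rmap.ies_list = list(ies)
    return rmap


def reverse_map(rmap, total_len):
    """The same chromosome annotated from the reverse-complemented somatic seq."""
    out = RearrangementMap(mac_contig_id=rmap.mac_contig_id)
    flipped = []
    for m in rmap.mds_list:
        flipped.append(
            MDS(
                0,
                Interval(m.mac.contig_id, total_len - m.mac.end, total_len - m.mac.start),
                m.mic,
                "+" if m.strand == "-" else "-",
            )
        )
    flipped.sort(key=lambda m: m.mac.start)
    for i, m in enumerate(flipped, start=1):
        m.ordinal = i
    out.mds_list = flipped
    return out


class TestClassify:
    def test_colinear_plus_is_unscrambled(self):
        call = classify_scrambling(make_map([(0, 100, "+"), (200, 300, "+"), (400, 500, "+")]))
        assert call.label == "unscrambled" and call.evidence == []

    def test_reordered_same_strand_is_insertion(self):
        call = classify_scrambling(make_map([(0, 100, "+"), (400, 500, "+"), (200, 300, "+")]))
        assert call.label == "insertion"

    def test_opposite_strand_mds_is_inversion(self):
        call = classify_scrambling(make_map([(0, 100, "+"), (200, 300, "-"), (400, 500, "+")]))
        assert call.label == "inversion"

    def test_reorder_plus_inversion_is_concurrent(self):
        call = classify_scrambling(make_map([(0, 100, "+"), (400, 500, "-"), (200, 300, "+")]))
        assert call.label == "concurrent"

    def test_second_contig_interruption_is_insertion(self):
        call = classify_scrambling(
            make_map(
                [(0, 100, "+", "g1"), (0, 100, "+", "g2"), (200, 300, "+", "g1")]
            )
        )
        assert call.label == "insertion"

    def test_single_mds_is_unscrambled(self):
        assert classify_scrambling(make_map([(0, 100, "+")])).label == "unscrambled"

    @pytest.mark.parametrize(
        "entries",
        [
            [(0, 100, "+"), (200, 300, "+"), (400, 500, "+")],
            [(0, 100, "+"), (400, 500, "+"), (200, 300, "+")],
            [(0, 100, "+"), (200, 300, "-"), (400, 500, "+")],
            [(0, 100, "+"), (400, 500, "-"), (200, 300, "+")],
        ],
    )
    def test_invariant_under_somatic_reverse_complement(self, entries):
        rmap = make_map(entries)
        total = sum(e - s for s, e, *_ in entries)
        assert classify_scrambling(rmap).label == classify_scrambling(
            reverse_map(rmap, total)
        ).label

    def test_simulated_labels_match_truth(self, default_sim, default_annotation):
        _, _, _, truth = default_sim
        for mac_id, rmap in default_annotation.maps.items():
            chrom = truth.chromosomes[mac_id]
            if chrom.kind != "primary":
                continue
            if full_recovery(truth, rmap, mac_id):
                assert classify_scrambling(rmap).label == chrom.label, mac_id


class TestMpka:
    def test_worked_examples(self):
        assert compute_mpka(make_map([(0, 500, "+")] * 4), 2000) == 2.0
        assert compute_mpka(make_map([(0, 500, "+")]), 1000) == 1.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            compute_mpka(make_map([(0, 100, "+")]), 0)

    def test_simulated_median_tracks_generative_expectation(self):
        """Mean MDS 500 bp + IES gives roughly two MDSs per somatic kb."""
        from pgrmap import SimulationParams, annotate_genomes, simulate

        params = SimulationParams(
            n_chromosomes=40,
            mds_len=(400, 600),
            scramble_frac=0,
            altproc_a_rate=0,
            altproc_b_rate=0,
            seed=9,
        )
        mac, mic, _ = simulate(params)
        res = annotate_genomes(mac, mic)
        lengths = {c.id: len(c.seq) for c in res.trimmed_mac}
        summary = summarize_architecture(list(res.maps.values()), lengths)
        assert 1.6 < summary.median_mpka < 2.4

    def test_scrambled_density_at_least_unscrambled_in_simulation(
        self, default_sim, default_annotation
    ):
        _, _, _, _ = default_sim
        lengths = {c.id: len(c.seq) for c in default_annotation.trimmed_mac}
        summary = summarize_architecture(list(default_annotation.maps.values()), lengths)
        if summary.median_mpka_scrambled is not None:
            assert summary.median_mpka_scrambled >= summary.median_mpka_unscrambled


class TestAltProcessing:
    def test_identical_footprints_give_one_a_type_event(self):
        m1 = make_map([(100, 400, "+")], mac_id="m1")
        m2 = make_map([(100, 400, "+")], mac_id="m2")
        events = detect_alt_processing([m1, m2])
        assert len(events) == 1
        e = events[0]
        assert e.type == "A" and e.members == ("m1", "m2") and e.overlap_bp == 300

    def test_a_type_is_symmetric_in_members(self):
        m1 = make_map([(100, 400, "+")], mac_id="m1")
        m2 = make_map([(100, 400, "+")], mac_id="m2")
        assert detect_alt_processing([m1, m2]) == detect_alt_processing([m2, m1])

    def test_mds_inside_foreign_ies_is_b_type(self):
        host = make_map(
            [(0, 300, "+"), (500, 800, "+")],
            mac_id="host",
            ies=[IES(mic=Interval("g", 300, 500), between=(1, 2))],
        )
        nested = make_map([(350, 430, "+")], mac_id="nested")
        events = detect_alt_processing([host, nested])
        b = [e for e in events if e.type == "B"]
        assert len(b) == 1
        assert b[0].members == ("nested", "host")  # directional

    def test_disjoint_footprints_give_no_events(self):
        m1 = make_map([(0, 300, "+")], mac_id="m1")
        m2 = make_map([(1000, 1300, "+")], mac_id="m2")
        assert detect_alt_processing([m1, m2]) == []

    def test_staggered_terminal_overlap_is_breakage_not_a_type(self):
        """A retained breakage junction's short terminal overlap is excluded."""
        up = make_map([(0, 500, "+")], mac_id="up")
        down = make_map([(470, 900, "+")], mac_id="down")
        assert detect_alt_processing([up, down], min_overlap=30) == []

    def test_simulated_events_recovered(self, default_sim, default_annotation):
        _, _, _, truth = default_sim
        events = detect_alt_processing(
            list(default_annotation.maps.values()),
            {k: v for k, v in default_annotation.scrambling.items()},
        )
        planted_a = {tuple(sorted(e.members)) for e in truth.alt_events if e.type == "A"}
        detected_a = {tuple(sorted(e.members)) for e in events if e.type == "A"}
        assert planted_a <= detected_a
        planted_b = {e.members for e in truth.alt_events if e.type == "B"}
        detected_b = {e.members for e in events if e.type == "B"}
        assert planted_b <= detected_b
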