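"""Telomere recognition, assembly filtering, dedup and the MIC screen."""

import re

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pgrmap import (
    Contig,
    GenomeSet,
    clean_mac,
    dedup_contigs,
    find_telomeres,
    revcomp,
    screen_mic_contamination,
    trim_telomeres,
)
from pgrmap.bruteforce import bruteforce_greedy_clusters
from pgrmap.cleanup import TELOMERE_3_PATTERN, TELOMERE_5_PATTERN
from pgrmap.similarity import global_identity


def rand_seq(rng, n, gc_balanced=True):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestTelomereRegex:
    def test_five_prime_literal_example(self, rng):
        seq = "CCCCAAAACCCCAAAACCAAAA" + rand_seq(rng, 300)
        ann = find_telomeres(Contig(id="c", seq=seq))
        assert ann.state == "five_prime"
        assert (ann.five_prime.start, ann.five_prime.end) == (0, 22)

    def test_balanced_random_sequence_has_no_telomere(self, rng):
        # GC-balanced random bases essentially never satisfy either motif
        seq = rand_seq(rng, 300)
        assert find_telomeres(Contig(id="c", seq=seq)).state == "none"

    def test_three_prime_minimal_12bp_match(self, rng):
        seq = rand_seq(rng, 300) + "GGGGTTTTGGGG"
        ann = find_telomeres(Contig(id="c", seq=seq))
        assert ann.state == "three_prime"
        assert len(ann.three_prime) == 12
        assert ann.three_prime.end == len(seq)

    def test_match_must_anchor_near_the_end(self, rng):
        inner = "CCCCAAAACCCCAAAACCAAAA"
        seq = rand_seq(rng, 100) + inner + rand_seq(rng, 100)
        assert find_telomeres(Contig(id="c", seq=seq), max_offset=30).state == "none"

    @given(
        st.text(alphabet="ACGT", min_size=0, max_size=40),
        st.integers(min_value=0, max_value=6),
    )
    def test_five_prime_agrees_with_reference_regex_scan(self, tail, units):
        """Anchored longest-match equals a direct per-start regex scan."""
        seq = "CCCCAAAA" * units + tail
        if not seq:
            return
        ann = find_telomeres(Contig(id="c", seq=seq), max_offset=30)
        best = None
        for start in range(min(30, len(seq)) + 1):
            m = TELOMERE_5_PATTERN.match(seq, start)
            if m and (best is None or m.end() - m.start() > best[1] - best[0]):
                best = (m.start(), m.end())
        got = (
            (ann.five_prime.start, ann.five_prime.end) if ann.five_prime else None
        )
        assert got == best

    @given(st.text(alphabet="GT", min_size=0, max_size=30))
    def test_three_prime_agrees_with_reference_regex_scan(self, head):
        seq = "ACGTACGTAC" + head + "GGGGTTTT" * 3
        ann = find_telomeres(Contig(id="c", seq=seq), max_offset=30)
        best = None
        for start in range(len(seq)):
            for m in [TELOMERE_3_PATTERN.match(seq, start)]:
                if m and m.end() >= len(seq) - 30:
                    if best is None or m.end() - m.start() > best[1] - best[0]:
                        best = (m.start(), m.end())
        got = (
            (ann.three_prime.start, ann.three_prime.end) if ann.three_prime else None
        )
        assert got == best


class TestTrim:
    def test_both_ends_trimmed_length(self, rng):
        core = rand_seq(rng, 500)
        telo5, telo3 = "CCCCAAAA" * 3, "GGGGTTTT" * 3
        contig = Contig(id="c", seq=telo5 + core + telo3)
        ann = find_telomeres(contig)
        trimmed, offset = trim_telomeres(contig, ann)
        assert len(trimmed.seq) == 500 and offset == 24

    def test_no_telomere_is_identity(self, rng):
        contig = Contig(id="c", seq=rand_seq(rng, 200))
        ann = find_telomeres(contig)
        trimmed, offset = trim_telomeres(contig, ann)
        assert trimmed.seq == contig.seq and offset == 0

    def test_simulated_trim_recovers_pre_telomere_core(self, default_sim):
        params, mac, _, truth = default_sim
        telo = params.telomere_len
        for contig in mac:
            ann = find_telomeres(contig)
            trimmed, _ = trim_telomeres(contig, ann)
            assert trimmed.seq == contig.seq[telo:-telo]


def _capped(rng, n, both=True):
    telo5, telo3 = "CCCCAAAA" * 3, "GGGGTTTT" * 3
    core = rand_seq(rng, n - len(telo5) - (len(telo3) if both else 0))
    return telo5 + core + (telo3 if both else "")


class TestCleanMac:
    def test_short_contig_kept_with_both_telomeres(self, rng):
        g = GenomeSet([Contig(id="c", seq=_capped(rng, 350))])
        report = clean_mac(g, {"c": 10.0})
        assert report.kept == ["c"]

    def test_short_one_telomere_contig_discarded(self, rng):
        g = GenomeSet([Contig(id="c", seq=_capped(rng, 350, both=False))])
        report = clean_mac(g, {"c": 10.0})
        assert report.discarded == {"c": "short_no_two_telomeres"}

    def test_low_coverage_discarded_regardless_of_telomeres(self, rng):
        g = GenomeSet([Contig(id="c", seq=_capped(rng, 2000))])
        report = clean_mac(g, {"c": 0.5})
        assert report.discarded == {"c": "low_coverage"}

    def test_no_telomere_requires_evidence(self, rng):
        seq = rand_seq(rng, 1000)
        report = clean_mac(GenomeSet([Contig(id="c", seq=seq)]), {"c": 5.0})
        assert report.discarded == {"c": "no_telomere_no_evidence"}
        report = clean_mac(
            GenomeSet([Contig(id="c", seq=seq)]), {"c": 5.0}, evidence={"c"}
        )
        assert report.kept == ["c"]

    def test_partition_and_fixed_point(self, rng):
        contigs = [
            Contig(id=f"c{i}", seq=_capped(rng, 300 + 100 * i, both=i % 2 == 0))
            for i in range(6)
        ]
        g = GenomeSet(contigs)
        cov = {c.id: (0.5 if c.id == "c3" else 5.0) for c in contigs}
        report = clean_mac(g, cov)
        assert sorted(report.kept) + sorted(report.discarded) != []
        assert set(report.kept) | set(report.discarded) == set(g.ids)
        assert sum(report.class_counts.values()) == len(contigs)
        survivors = GenomeSet([g[c] for c in report.kept])
        again = clean_mac(survivors, cov)
        assert sorted(again.kept) == sorted(report.kept)
        assert again.discarded == {}


class TestDedup:
    def test_identical_pair_keeps_one(self, rng):
        seq = rand_seq(rng, 500)
        g = GenomeSet([Contig(id="a", seq=seq), Contig(id="b", seq=seq)])
        report = dedup_contigs(g)
        assert report.kept == ["a"] and report.discarded == {"b": "redundant"}

    def test_reverse_complement_is_redundant(self, rng):
        seq = rand_seq(rng, 500)
        g = GenomeSet([Contig(id="a", seq=seq), Contig(id="b", seq=revcomp(seq))])
        report = dedup_contigs(g)
        assert len(report.kept) == 1

    def test_dissimilar_contigs_all_kept_matching_bruteforce(self, rng):
        seqs = {f"c{i}": rand_seq(rng, int(rng.integers(200, 400))) for i in range(30)}
        g = GenomeSet([Contig(id=k, seq=v) for k, v in seqs.items()])
        report = dedup_contigs(g)
        clusters = bruteforce_greedy_clusters(
            seqs, lambda a, b: global_identity(a, b) >= 0.98
        )
        assert sorted(report.kept) == sorted(clusters)
        assert len(report.discarded) == 0


class TestMicScreen:
    def test_mac_core_in_mic_is_contaminant(self, rng):
        core = rand_seq(rng, 800)
        mic = GenomeSet([Contig(id="mic1", seq=core, source="MIC")])
        mac = GenomeSet([Contig(id="mac1", seq=core)])
        report = screen_mic_contamination(mic, mac)
        assert report.discarded == {"mic1": "contaminant"}

    def test_partial_footprint_is_kept(self, rng):
        shared = rand_seq(rng, 400)
        mic = GenomeSet(
            [Contig(id="mic1", seq=shared + rand_seq(rng, 600), source="MIC")]
        )
        mac = GenomeSet([Contig(id="mac1", seq=shared)])
        report = screen_mic_contamination(mic, mac)  # qcov 40% only
        assert report.kept == ["mic1"]

    def test_spiked_simulation_removes_exactly_the_spikes(self, rng, default_sim):
        params, mac, mic, _ = default_sim
        telo = params.telomere_len
        spiked = GenomeSet(label="mic")
        for contig in mic:
            spiked.add(contig)
        mac_list = list(mac)[:10]
        for i, contig in enumerate(mac_list):
            spiked.add(
                Contig(id=f"spike_{i}", seq=contig.seq[telo:-telo], source="MIC")
            )
        trimmed_mac = GenomeSet(
            [Contig(id=c.id, seq=c.seq[telo:-telo]) for c in mac_list]
        )
        report = screen_mic_contamination(spiked, trimmed_mac)
        assert sorted(report.discarded) == sorted(f"spike_{i}" for i in range(10))
        assert all(reason == "contaminant" for reason in report.discarded.values())
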