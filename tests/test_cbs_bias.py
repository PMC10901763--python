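"""Breakage-site statistics and nucleotide-bias profiling."""

import numpy as np
import pytest

from pgrmap import Contig, GenomeSet, build_pfm, detect_cbs, profile_bins, revcomp, terminal_at_content
from pgrmap.model import MDS, Interval, RearrangementMap


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def one_mds_map(mac_id, mac_len, mic_start, mic_end, contig="g"):
    rmap = RearrangementMap(mac_contig_id=mac_id)
    rmap.mds_list = [
        MDS(1, Interval(mac_id, 0, mac_len), Interval(contig, mic_start, mic_end), "+")
    ]
    rmap.mic_contigs_used.add(contig)
    return rmap


class TestDetectCbs:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.mic_seq = rand_seq(rng, 2000)
        self.mic = GenomeSet([Contig(id="g", seq=self.mic_seq, source="MIC")])

    def run(self, up_end, down_start, down_end=1600):
        maps = [
            one_mds_map("up", up_end, 0, up_end),
            one_mds_map("down", down_end - down_start, down_start, down_end),
        ]
        lengths = {"up": up_end, "down": down_end - down_start}
        return detect_cbs(maps, self.mic, lengths)

    def test_retained_junction(self):
        (rec,) = self.run(up_end=1000, down_start=998)
        assert rec.delta == -2 and rec.mode == "retained"
        assert rec.cbs_seq == self.mic_seq[998:1000]
        assert (rec.m, rec.n) == (1000, 998)
        assert rec.flank_5 == self.mic_seq[968:998]
        assert rec.flank_3 == self.mic_seq[1000:1030]

    def test_eliminated_junction(self):
        (rec,) = self.run(up_end=1000, down_start=1005)
        assert rec.delta == 5 and rec.mode == "eliminated"
        assert rec.cbs_seq == self.mic_seq[1000:1005]

    def test_blunt_junction(self):
        (rec,) = self.run(up_end=1000, down_start=1000)
        assert rec.delta == 0 and rec.mode == "blunt" and rec.cbs_seq == ""

    def test_distant_chromosomes_not_paired(self):
        assert self.run(up_end=1000, down_start=1200) == []

    def test_non_subtelomeric_terminal_mds_excluded(self):
        maps = [
            one_mds_map("up", 1000, 0, 1000),
            one_mds_map("down", 700, 998, 1600),
        ]
        # the downstream map's MDS stops 98 bp short of its somatic end
        maps[1].mds_list[0].mac = Interval("down", 0, 602)
        lengths = {"up": 1000, "down": 700}
        records = detect_cbs(maps, self.mic, lengths)
        assert records != []  # left end of "down" is still subtelomeric
        maps[1].mds_list[0].mac = Interval("down", 98, 700)
        assert detect_cbs(maps, self.mic, lengths) == []

    def test_flank_truncation_flagged_at_contig_edge(self):
        maps = [
            one_mds_map("up", 20, 0, 20),
            one_mds_map("down", 600, 18, 618),
        ]
        (rec,) = detect_cbs(maps, self.mic, {"up": 20, "down": 600})
        assert rec.flank_truncated and len(rec.flank_5) == 18

    def test_simulated_junctions_exact(self, default_sim, default_annotation):
        _, _, mic, truth = default_sim
        lengths = {c.id: len(c.seq) for c in default_annotation.trimmed_mac}
        records = detect_cbs(list(default_annotation.maps.values()), mic, lengths)
        planted = {
            (c.mic_contig, c.upstream_mac_id, c.downstream_mac_id): c for c in truth.cbs
        }
        assert len(records) == len(planted)
        for rec in records:
            t = planted[(rec.mic_contig_id, rec.upstream_mac_id, rec.downstream_mac_id)]
            assert (rec.m, rec.n, rec.cbs_seq, rec.mode) == (t.m, t.n, t.cbs_seq, t.mode)


class TestProfileBins:
    def test_homopolymer_gives_unit_frequency(self):
        profile = profile_bins([Contig(id="c", seq="A" * 2500)])
        assert profile.freq.shape == (250, 4)
        assert np.allclose(profile.freq[:, 0], 1.0)

    def test_orientation_normalization(self, rng):
        seq = rand_seq(rng, 1000)
        fwd = profile_bins([Contig(id="c", seq=seq)], {"c": "+"})
        rev = profile_bins([Contig(id="c", seq=revcomp(seq))], {"c": "-"})
        assert np.allclose(fwd.freq, rev.freq)

    def test_bins_sum_to_one(self, rng):
        contigs = [Contig(id=f"c{i}", seq=rand_seq(rng, int(rng.integers(400, 3000)))) for i in range(5)]
        profile = profile_bins(contigs)
        assert np.allclose(profile.freq.sum(axis=1), 1.0, atol=1e-12)

    def test_short_contigs_skipped(self, rng):
        profile = profile_bins([Contig(id="c", seq=rand_seq(rng, 100))])
        assert profile.n_contigs == 0

    def test_simulated_subtelomeric_at_enrichment(self, default_sim):
        params, mac, _, _ = default_sim
        telo = params.telomere_len
        contigs = [
            Contig(id=c.id, seq=c.seq[telo:-telo])
            for c in mac
            if c.id.startswith("mac_")
        ]
        profile = profile_bins(contigs)
        at = profile.freq[:, 0] + profile.freq[:, 3]
        interior = at[50:200].mean()
        assert at[0] > interior and at[-1] > interior


class TestTerminalAt:
    def test_pure_at_and_pure_gc_windows(self):
        tracks = terminal_at_content(
            [Contig(id="a", seq="ATATATATAT" * 10), Contig(id="b", seq="GCGCGCGCGC" * 10)]
        )
        assert np.nanmax(tracks["five_prime"][0]) == 1.0
        assert np.nanmin(tracks["five_prime"][0]) == 1.0
        assert np.nanmax(tracks["five_prime"][1]) == 0.0

    def test_uniform_random_mean_near_half(self, rng):
        contigs = [Contig(id=f"c{i}", seq=rand_seq(rng, 400)) for i in range(40)]
        tracks = terminal_at_content(contigs)
        mean = np.nanmean(tracks["five_prime"])
        n = tracks["five_prime"].size * 10
        assert abs(mean - 0.5) < 3 * np.sqrt(0.25 / n) + 0.02

    def test_short_contig_uses_available_length(self):
        tracks = terminal_at_content([Contig(id="c", seq="ATATATATATAT")], terminal_len=100)
        row = tracks["five_prime"][0]
        assert np.isfinite(row[:3]).all() and np.isnan(row[50])


class TestPfm:
    def test_uniform_sequences_give_unit_columns(self):
        pfm = build_pfm(["GAA", "GAA", "GAA"])
        assert pfm.freq[0, 2] == 1.0  # G
        assert pfm.freq[1, 0] == 1.0 and pfm.freq[2, 0] == 1.0  # A, A
        assert pfm.consensus == "GAA"

    def test_two_sequences_split_half(self):
        pfm = build_pfm(["AT", "TA"])
        assert np.allclose(pfm.freq[:, [0, 3]], 0.5)

    def test_three_prime_anchor_right_aligns(self):
        pfm = build_pfm(["CGG", "GG"], anchor="three_prime")
        assert pfm.freq[1, 2] == 1.0 and pfm.freq[2, 2] == 1.0
        assert pfm.freq[0, 1] == 1.0  # the C covers only the longer sequence

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_pfm([])

    def test_planted_subtelomeric_motif_recovered(self):
        """All-chromosome GAA planting shows as unit PFM frequency at 8..10."""
        from pgrmap import SimulationParams, simulate, trim_genome

        params = SimulationParams(
            n_chromosomes=12,
            cbs_mode_probs={"retained": 0.0, "eliminated": 0.6, "blunt": 0.4},
            altproc_a_rate=0,
            altproc_b_rate=0,
            seed=13,
        )
        mac, _, truth = simulate(params)
        assert all(c.motif_planted == (True, True) for c in truth.chromosomes.values())
        trimmed, _ = trim_genome(mac)
        pfm5 = build_pfm([c.seq[:40] for c in trimmed])
        assert pfm5.freq[8, 2] == 1.0  # G
        assert pfm5.freq[9, 0] == 1.0 and pfm5.freq[10, 0] == 1.0  # A A
        pfm3 = build_pfm([c.seq[-40:] for c in trimmed], anchor="three_prime")
        assert pfm3.freq[-11, 3] == 1.0 and pfm3.freq[-10, 3] == 1.0  # T T
        assert pfm3.freq[-9, 1] == 1.0  # C
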