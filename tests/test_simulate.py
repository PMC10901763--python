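"""Simulator contracts: determinism, limits, and the planted-truth invariants."""

import numpy as np
import pytest

from pgrmap import (
    SimulationParams,
    find_telomeres,
    inject_artifacts,
    reconstruct_mac,
    revcomp,
    simulate,
    trim_telomeres,
)
from pgrmap.io import read_truth_json, write_truth_json


def small_params(**kw):
    defaults = dict(n_chromosomes=6, seed=11, altproc_a_rate=0, altproc_b_rate=0)
    defaults.update(kw)
    return SimulationParams(**defaults)


class TestDeterminism:
    def test_same_seed_same_output(self):
        mac1, mic1, t1 = simulate(small_params())
        mac2, mic2, t2 = simulate(small_params())
        assert [c.seq for c in mac1] == [c.seq for c in mac2]
        assert [c.seq for c in mic1] == [c.seq for c in mic2]
        assert t1.to_dict() == t2.to_dict()

    def test_different_seed_differs(self):
        mac1, _, _ = simulate(small_params(seed=1))
        mac2, _, _ = simulate(small_params(seed=2))
        assert [c.seq for c in mac1] != [c.seq for c in mac2]


class TestNoRearrangementLimit:
    def test_single_mds_chromosome_has_no_ies(self):
        params = small_params(
            n_chromosomes=1,
            mds_per_chromosome=(1, 1),
            scramble_frac=0.0,
            chromosomes_per_mic=(1, 1),
        )
        mac, mic, truth = simulate(params)
        chrom = truth.chromosomes["mac_0001"]
        assert chrom.ies == [] and chrom.pointers == []
        # the germline locus contains the somatic core verbatim
        mds = chrom.mds[0]
        core = mic["mic_001"].seq[mds.mic_start : mds.mic_end]
        contig = mac["mac_0001"]
        telo = params.telomere_len
        assert contig.seq[telo:-telo] == core


class TestTruthInvariants:
    def test_reconstruction_oracle(self, default_sim):
        _, mac, mic, truth = default_sim
        for contig in mac:
            ann = find_telomeres(contig)
            trimmed, _ = trim_telomeres(contig, ann)
            assert trimmed.seq == reconstruct_mac(truth, mic, contig.id), contig.id

    def test_pointer_copies_flank_each_ies(self, default_sim):
        """Each pointer sits at both germline IES flanks and once at the
        somatic junction."""
        _, mac, mic, truth = default_sim
        for chrom in truth.chromosomes.values():
            mds_by_ordinal = {m.ordinal: m for m in chrom.mds}
            contig = mac[chrom.mac_id]
            core = contig.seq[chrom.telomere_len : -chrom.telomere_len]
            for ptr in chrom.pointers:
                assert core[ptr.mac_start : ptr.mac_end] == ptr.seq
            for ies in chrom.ies:
                ptr = next(p for p in chrom.pointers if p.junction == ies.junction)
                up = mds_by_ordinal[ies.junction]
                down = mds_by_ordinal[ies.junction + 1]
                mic_seq = mic[ies.mic_contig].seq
                assert mic_seq[up.mic_end - len(ptr.seq) : up.mic_end] == ptr.seq
                assert mic_seq[down.mic_start : down.mic_start + len(ptr.seq)] == ptr.seq

    def test_retained_cbs_shared_by_both_termini(self, default_sim):
        _, mac, mic, truth = default_sim
        retained = [c for c in truth.cbs if c.mode == "retained"]
        assert retained, "default conditions should plant retained junctions"
        for c in retained:
            assert c.n - c.m == -len(c.cbs_seq) < 0
            assert mic[c.mic_contig].seq[c.n : c.m] == c.cbs_seq
            telo = truth.chromosomes[c.upstream_mac_id].telomere_len
            up_core = mac[c.upstream_mac_id].seq[telo:-telo]
            down_core = mac[c.downstream_mac_id].seq[telo:-telo]
            assert up_core.endswith(c.cbs_seq)
            assert down_core.startswith(c.cbs_seq)

    def test_eliminated_and_blunt_deltas(self, default_sim):
        params, _, _, truth = default_sim
        for c in truth.cbs:
            if c.mode == "eliminated":
                lo, hi = params.cbs_eliminated_gap
                assert lo <= c.n - c.m <= hi
            elif c.mode == "blunt":
                assert c.n == c.m and c.cbs_seq == ""

    def test_scrambled_chromosomes_follow_their_labels(self, default_sim):
        _, _, _, truth = default_sim
        for chrom in truth.chromosomes.values():
            strands = {m.strand for m in chrom.mds}
            starts = [m.mic_start for m in sorted(chrom.mds, key=lambda m: m.ordinal)]
            monotonic = all(a < b for a, b in zip(starts, starts[1:]))
            if chrom.label == "unscrambled":
                assert strands == {"+"} and monotonic
            elif chrom.label == "inversion":
                assert "-" in strands and monotonic
            elif chrom.label == "insertion":
                assert strands == {"+"} and not monotonic
            elif chrom.label == "concurrent":
                assert "-" in strands and not monotonic

    def test_truth_json_round_trip(self, tmp_path, default_sim):
        _, _, _, truth = default_sim
        write_truth_json(truth, tmp_path / "truth.json")
        back = read_truth_json(tmp_path / "truth.json")
        assert back.to_dict() == truth.to_dict()

    def test_subtelomeric_motif_planted_at_offset(self, default_sim):
        params, mac, _, truth = default_sim
        telo = params.telomere_len
        o = params.subtel_motif_offset
        for chrom in truth.chromosomes.values():
            core = mac[chrom.mac_id].seq[telo:-telo]
            if chrom.motif_planted[0]:
                assert core[o : o + 3] == params.subtel_motif
            if chrom.motif_planted[1]:
                assert core[len(core) - o - 3 : len(core) - o] == revcomp(params.subtel_motif)


class TestArtifacts:
    def test_zero_rates_leave_sequences_unchanged(self):
        params = small_params(truncation_rate=0, low_coverage_rate=0, contaminant_rate=0)
        mac, _, truth = simulate(params)
        out = inject_artifacts(mac, params, truth)
        assert out.ids == mac.ids
        assert all(out[c.id].seq == c.seq for c in mac)
        assert all(c.coverage >= 1 for c in out)

    def test_full_truncation_leaves_one_telomere(self):
        params = small_params(truncation_rate=1.0, contaminant_rate=0)
        mac, _, truth = simulate(params)
        out = inject_artifacts(mac, params, truth)
        for contig in out:
            ann = find_telomeres(contig)
            assert ann.state in ("five_prime", "three_prime")

    def test_class_counts_match_truth_labels(self):
        params = small_params(
            n_chromosomes=20,
            truncation_rate=0.4,
            low_coverage_rate=0.3,
            contaminant_rate=0.3,
            seed=5,
        )
        mac, _, truth = simulate(params)
        out = inject_artifacts(mac, params, truth)
        n_trunc = sum(1 for a in truth.artifacts.values() if a["truncated"])
        n_low = sum(1 for a in truth.artifacts.values() if a["low_coverage"])
        n_cont = sum(1 for a in truth.artifacts.values() if a["contaminant"])
        assert n_trunc == sum(
            1
            for c in out
            if not truth.artifacts[c.id]["contaminant"]
            and find_telomeres(c).state in ("five_prime", "three_prime")
        )
        assert n_low == sum(
            1 for c in out if c.coverage < 1
        )
        assert n_cont == sum(1 for cid in out.ids if cid.startswith("contam_"))


class TestParamValidation:
    def test_pointer_longer_than_mds_rejected(self):
        with pytest.raises(ValueError, match="pointer"):
            SimulationParams(mds_len=(30, 40), pointer_len=(10, 20)).validate()

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="mds_len"):
            SimulationParams(mds_len=(800, 200)).validate()

    def test_bad_probabilities_rejected(self):
        with pytest.raises(ValueError, match="cbs_mode_probs"):
            SimulationParams(
                cbs_mode_probs={"retained": 0.7, "eliminated": 0.7, "blunt": 0.1}
            ).validate()

    def test_small_mds_warns(self):
        with pytest.warns(UserWarning, match="word size"):
            SimulationParams(mds_len=(20, 80), pointer_len=(2, 2)).validate()

    def test_label_plan_length_checked(self):
        with pytest.raises(ValueError, match="label_plan"):
            SimulationParams(n_chromosomes=3, label_plan=["unscrambled"]).validate()
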