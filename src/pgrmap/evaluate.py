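"""Comparison of recovered annotation against planted simulation truth.

All metrics are exact-match by design: an IES counts as recovered only
when both germline boundaries agree to the base, a pointer only when its
sequence is reproduced verbatim, a scrambling label only conditional on
full MDS recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import GenomeSet, RearrangementMap
from .simulate import SimulationTruth


@dataclass
class RecoveryStats:
    n_planted_ies: int = 0
    n_recovered_ies: int = 0
    n_planted_pointers: int = 0
    n_recovered_pointers: int = 0
    n_pointer_mismatches: int = 0
    n_junctions_checked: int = 0
    n_excision_failures: int = 0

    @property
    def ies_recall(self) -> float:
        return self.n_recovered_ies / self.n_planted_ies if self.n_planted_ies else 1.0

    @property
    def pointer_exact_fraction(self) -> float:
        total = self.n_recovered_pointers + self.n_pointer_mismatches
        return self.n_recovered_pointers / total if total else 1.0


def score_recovery(
    truth: SimulationTruth,
    maps: dict[str, RearrangementMap],
    trimmed_mac: GenomeSet,
    mic: GenomeSet,
) -> RecoveryStats:
    """Exact-boundary IES recall, verbatim pointer recovery, excision identity."""
    stats = RecoveryStats()
    for mac_id, chrom in truth.chromosomes.items():
        rmap = maps.get(mac_id)
        found_ies = (
            {(i.mic.contig_id, i.mic.start, i.mic.end) for i in rmap.ies_list}
            if rmap
            else set()
        )
        for ies in chrom.ies:
            stats.n_planted_ies += 1
            if (ies.mic_contig, ies.mic_start, ies.mic_end) in found_ies:
                stats.n_recovered_ies += 1
        planted_ptr = {(p.mac_start, p.mac_end): p.seq for p in chrom.pointers}
        stats.n_planted_pointers += len(planted_ptr)
        if rmap:
            for p in rmap.pointers:
                if p.mac_pos is None:
                    continue
                key = (p.mac_pos.start, p.mac_pos.end)
                if key in planted_ptr:
                    if p.seq == planted_ptr[key]:
                        stats.n_recovered_pointers += 1
                    else:
                        stats.n_pointer_mismatches += 1
    stats.n_excision_failures, stats.n_junctions_checked = excision_failures(
        maps, trimmed_mac, mic
    )
    return stats


def excision_failures(
    maps: dict[str, RearrangementMap], trimmed_mac: GenomeSet, mic: GenomeSet
) -> tuple[int, int]:
    """Check excision identity at every annotated IES junction.

    Removing the IES and one pointer copy from the germline must reproduce
    the somatic junction sequence base-for-base.
    """
    failures = 0
    checked = 0
    for mac_id, rmap in maps.items():
        if mac_id not in trimmed_mac:
            continue
        mac_seq = trimmed_mac[mac_id].seq
        by_ordinal = {m.ordinal: m for m in rmap.mds_list}
        ptr_len = {p.junction: len(p.seq) for p in rmap.pointers}
        for ies in rmap.ies_list:
            k, k1 = ies.between
            up, down = by_ordinal[k], by_ordinal[k1]
            p = ptr_len.get((k, k1), 0)
            mic_seq = mic[up.mic.contig_id].seq
            from .model import revcomp

            if up.strand == "+":
                left = mic_seq[up.mic.start : up.mic.end]
                right = mic_seq[down.mic.start : down.mic.end]
            else:
                left = revcomp(mic_seq[up.mic.start : up.mic.end])
                right = revcomp(mic_seq[down.mic.start : down.mic.end])
            rebuilt = left + right[p:]
            somatic = mac_seq[up.mac.start : down.mac.end]
            checked += 1
            if rebuilt != somatic:
                failures += 1
    return failures, checked


def full_recovery(truth: SimulationTruth, rmap: RearrangementMap, mac_id: str) -> bool:
    """True when every planted MDS was recovered with exact intervals."""
    chrom = truth.chromosomes[mac_id]
    if len(rmap.mds_list) != len(chrom.mds):
        return False
    planted = {
        (m.ordinal, m.mac_start, m.mac_end, m.mic_contig, m.mic_start, m.mic_end, m.strand)
        for m in chrom.mds
    }
    found = {
        (m.ordinal, m.mac.start, m.mac.end, m.mic.contig_id, m.mic.start, m.mic.end, m.strand)
        for m in rmap.mds_list
    }
    return planted == found


def scrambling_accuracy(
    truth: SimulationTruth, maps: dict[str, RearrangementMap], labels: dict[str, str]
) -> tuple[int, int, int]:
    """(n correct, n fully recovered, n total) over primary chromosomes."""
    correct = recovered = total = 0
    for mac_id, chrom in truth.chromosomes.items():
        if chrom.kind != "primary" or mac_id not in maps:
            continue
        total += 1
        if not full_recovery(truth, maps[mac_id], mac_id):
            continue
        recovered += 1
        if labels.get(mac_id) == chrom.label:
            correct += 1
    return correct, recovered, total


def cbs_agreement(truth: SimulationTruth, records) -> dict:
    """Match detected breakage records to planted junctions.

    Returns counts of planted junctions, detected records, records whose
    delta and sequence agree exactly with the planted junction, and
    detected records with no planted counterpart.
    """
    planted = {
        (c.mic_contig, c.upstream_mac_id, c.downstream_mac_id): c for c in truth.cbs
    }
    exact = spurious = 0
    matched = set()
    for r in records:
        key = (r.mic_contig_id, r.upstream_mac_id, r.downstream_mac_id)
        t = planted.get(key)
        if t is None:
            spurious += 1
            continue
        matched.add(key)
        if r.m == t.m and r.n == t.n and r.cbs_seq == t.cbs_seq and r.mode == t.mode:
            exact += 1
    return {
        "n_planted": len(planted),
        "n_detected": len(records),
        "n_exact": exact,
        "n_matched": len(matched),
        "n_spurious": spurious,
    }


def altproc_precision_recall(truth: SimulationTruth, events) -> dict[str, dict]:
    """Per-type precision/recall of detected alternative-processing events."""
    out = {}
    for etype in ("A", "B"):
        planted = {
            tuple(sorted(e.members)) if etype == "A" else e.members
            for e in truth.alt_events
            if e.type == etype
        }
        detected = {
            tuple(sorted(e.members)) if etype == "A" else e.members
            for e in events
            if e.type == etype
        }
        tp = len(planted & detected)
        out[etype] = {
            "n_planted": len(planted),
            "n_detected": len(detected),
            "precision": tp / len(detected) if detected else 1.0,
            "recall": tp / len(planted) if planted else 1.0,
        }
    return out
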