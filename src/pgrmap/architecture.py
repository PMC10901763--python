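"""Chromosome architecture: scrambling calls, MDS density, alternative
processing.

A chromosome is scrambled when its MDSs sit in the germline in a different
order or orientation than in the somatic product. The majority strand of
its MDSs defines the reference orientation; opposite-strand MDSs are
inversion evidence, non-monotonic germline positions (or an MDS from a
second germline contig interrupting a colinear run) are insertion
evidence, and chromosomes with both kinds are "concurrent".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Optional

from .model import AltProcessingEvent, Interval, RearrangementMap, ScramblingCall


def classify_scrambling(rmap: RearrangementMap) -> ScramblingCall:
    """Label one somatic chromosome from its rearrangement map."""
    mds = rmap.mds_list
    if len(mds) <= 1:
        return ScramblingCall(mac_contig_id=rmap.mac_contig_id, label="unscrambled")

    n_plus = sum(1 for m in mds if m.strand == "+")
    frame = "+" if n_plus * 2 >= len(mds) else "-"
    evidence: list[str] = []

    for m in mds:
        if m.strand != frame:
            evidence.append(f"inversion:MDS{m.ordinal}")

    # orientation-normalized germline order; inverted MDSs keep their slot,
    # so an out-of-place inverted MDS still yields insertion evidence
    ordered = mds if frame == "+" else mds[::-1]
    by_contig_runs: list[tuple[str, list[int]]] = []
    for m in ordered:
        if by_contig_runs and by_contig_runs[-1][0] == m.mic.contig_id:
            by_contig_runs[-1][1].append(m.mic.start)
        else:
            by_contig_runs.append((m.mic.contig_id, [m.mic.start]))
    seen_contigs: set[str] = set()
    insertion = False
    for contig_id, starts in by_contig_runs:
        if contig_id in seen_contigs:
            insertion = True  # a second-contig MDS interrupted a colinear run
        seen_contigs.add(contig_id)
        if any(b <= a for a, b in zip(starts, starts[1:])):
            insertion = True
    if insertion:
        evidence.append("insertion:non-monotonic-germline-order")

    has_inv = any(e.startswith("inversion") for e in evidence)
    has_ins = any(e.startswith("insertion") for e in evidence)
    if has_inv and has_ins:
        label = "concurrent"
    elif has_inv:
        label = "inversion"
    elif has_ins:
        label = "insertion"
    else:
        label = "unscrambled"
    return ScramblingCall(mac_contig_id=rmap.mac_contig_id, label=label, evidence=evidence)


def compute_mpka(rmap: RearrangementMap, trimmed_length: int) -> float:
    """MDS count per kilobase of the telomere-trimmed somatic contig."""
    if trimmed_length <= 0:
        raise ValueError("trimmed length must be positive")
    return rmap.n_mds * 1000.0 / trimmed_length


DEFAULT_MIN_OVERLAP = 30
DEFAULT_MIN_CONTAINMENT = 0.9


def _is_breakage_overlap(
    a_iv: Interval, b_iv: Interval, a_terminal: bool, b_terminal: bool
) -> bool:
    """Staggered terminal-terminal overlap: the breakage-junction signature.

    A retained chromosome breakage site duplicates its terminal bases into
    both neighbouring chromosomes, producing a short staggered overlap
    between two subtelomeric MDSs whose chromosomes extend in opposite
    directions. Those overlaps are breakage retention, not alternative
    processing, and are excluded here. Containment is never breakage-like.
    """
    if not (a_terminal and b_terminal):
        return False
    if a_iv.contains(b_iv) or b_iv.contains(a_iv):
        return False
    return True  # staggered partial overlap of two terminal MDSs


def detect_alt_processing(
    maps: list[RearrangementMap],
    scrambling: Optional[dict[str, ScramblingCall]] = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_containment: float = DEFAULT_MIN_CONTAINMENT,
) -> list[AltProcessingEvent]:
    """Find A-type (shared germline MDS) and B-type (MDS-in-IES) events.

    A-type: MDS footprints of two different somatic contigs overlap by at
    least ``min_overlap`` bases on the germline. B-type: one contig's MDS
    lies within another contig's IES at ``min_containment`` or better; only
    IESs of unscrambled chromosomes are consulted. Events are deduplicated
    per contig pair, keeping the largest overlap.
    """
    scrambling = scrambling or {}
    mds_by_contig: dict[str, list[tuple[str, Interval, bool]]] = {}
    for m in maps:
        for i, mds in enumerate(m.mds_list):
            terminal = i == 0 or i == len(m.mds_list) - 1
            mds_by_contig.setdefault(mds.mic.contig_id, []).append(
                (m.mac_contig_id, mds.mic, terminal)
            )

    best_a: dict[tuple[str, str], AltProcessingEvent] = {}
    for entries in mds_by_contig.values():
        entries.sort(key=lambda e: e[1].start)
        for i, (mac_a, iv_a, term_a) in enumerate(entries):
            for mac_b, iv_b, term_b in entries[i + 1 :]:
                if iv_b.start >= iv_a.end:
                    break
                if mac_a == mac_b:
                    continue
                ov = iv_a.overlap(iv_b)
                if ov < min_overlap:
                    continue
                if _is_breakage_overlap(iv_a, iv_b, term_a, term_b):
                    continue
                pair = tuple(sorted((mac_a, mac_b)))
                region = Interval(
                    iv_a.contig_id,
                    max(iv_a.start, iv_b.start),
                    min(iv_a.end, iv_b.end),
                )
                prev = best_a.get(pair)
                if prev is None or ov > prev.overlap_bp:
                    best_a[pair] = AltProcessingEvent(
                        type="A", members=pair, mic_region=region, overlap_bp=ov
                    )

    best_b: dict[tuple[str, str], AltProcessingEvent] = {}
    ies_by_contig: dict[str, list[tuple[str, Interval]]] = {}
    for m in maps:
        call = scrambling.get(m.mac_contig_id)
        if call is not None and call.label != "unscrambled":
            continue
        for ies in m.ies_list:
            ies_by_contig.setdefault(ies.mic.contig_id, []).append(
                (m.mac_contig_id, ies.mic)
            )
    for contig_id, ies_entries in ies_by_contig.items():
        for mac_mds, iv_mds, _ in mds_by_contig.get(contig_id, []):
            for mac_ies, iv_ies in ies_entries:
                if mac_mds == mac_ies:
                    continue
                ov = iv_mds.overlap(iv_ies)
                if len(iv_mds) == 0 or ov / len(iv_mds) < min_containment:
                    continue
                pair = (mac_mds, mac_ies)  # directional: MDS owner, IES owner
                region = Interval(
                    contig_id, max(iv_mds.start, iv_ies.start), min(iv_mds.end, iv_ies.end)
                )
                prev = best_b.get(pair)
                if prev is None or ov > prev.overlap_bp:
                    best_b[pair] = AltProcessingEvent(
                        type="B", members=pair, mic_region=region, overlap_bp=ov
                    )

    events = list(best_a.values()) + list(best_b.values())
    events.sort(key=lambda e: (e.type, e.members))
    return events


@dataclass
class ArchitectureSummary:
    """Per-assembly architecture statistics."""

    mpka: dict[str, float] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)
    scrambled_fraction: float = 0.0
    label_counts: dict[str, int] = field(default_factory=dict)
    median_mpka: float = 0.0
    median_mpka_scrambled: Optional[float] = None
    median_mpka_unscrambled: Optional[float] = None


def summarize_architecture(
    maps: list[RearrangementMap], trimmed_lengths: dict[str, int]
) -> ArchitectureSummary:
    out = ArchitectureSummary()
    for m in maps:
        if m.n_mds == 0:
            continue
        call = classify_scrambling(m)
        out.labels[m.mac_contig_id] = call.label
        out.mpka[m.mac_contig_id] = compute_mpka(m, trimmed_lengths[m.mac_contig_id])
    for label in ("unscrambled", "inversion", "insertion", "concurrent"):
        out.label_counts[label] = sum(1 for v in out.labels.values() if v == label)
    n = len(out.labels)
    if n:
        out.scrambled_fraction = 1.0 - out.label_counts["unscrambled"] / n
        out.median_mpka = median(out.mpka.values())
        scr = [v for k, v in out.mpka.items() if out.labels[k] != "unscrambled"]
        uns = [v for k, v in out.mpka.items() if out.labels[k] == "unscrambled"]
        out.median_mpka_scrambled = median(scr) if scr else None
        out.median_mpka_unscrambled = median(uns) if uns else None
    return out
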