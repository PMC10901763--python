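"""Chaining HSPs into MDS/pointer/IES annotation per somatic contig.

The chaining procedure mirrors the junction-first logic of somatic/germline
comparison in spirotrichs: (1) pairs of HSPs realizing the canonical
"MDS–pointer–MDS" structure (somatic overlap of 0..max_pointer bases,
disjoint germline footprints) validate both members as MDSs; (2) members
sharing an identical pointer are temporarily connected into longer units;
(3) HSPs whose somatic interval is contained in another surviving unit are
discarded as nested; (4) the temporary merges are undone and survivors are
numbered along the somatic contig. IESs are recorded only between
consecutive MDSs that are colinear on the germline (same contig, same
orientation, germline order matching somatic order); pointers are the
somatic overlaps of consecutive MDSs.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Optional

import numpy as np

from .model import HSP, IES, MDS, Interval, Pointer, RearrangementMap

logger = logging.getLogger(__name__)

DEFAULT_MAX_POINTER = 50
DEFAULT_MIN_IES = 10


def _is_junction(a: HSP, b: HSP, max_pointer: int, min_ies: int) -> bool:
    """Can ``a`` (left) and ``b`` (right) form an MDS-pointer-MDS junction?"""
    overlap = a.mac.end - b.mac.start
    if overlap < 0 or overlap > max_pointer:
        return False
    if b.mac.end <= a.mac.end:  # containment is not a junction
        return False
    if a.mic.contig_id != b.mic.contig_id:
        return True  # different germline loci: junction without an IES
    if a.mic.overlap(b.mic) > 0:
        return False
    gap = _colinear_gap(a, b)
    if gap is None:
        return True  # non-colinear arrangement (scrambled junction)
    return gap >= min_ies


def _colinear_gap(a: HSP, b: HSP) -> Optional[int]:
    """Germline gap between colinear neighbours, else None.

    Colinear means: same germline contig and strand, with the germline
    order of the footprints matching somatic order under that strand.
    """
    if a.mic.contig_id != b.mic.contig_id or a.strand != b.strand:
        return None
    if a.strand == "+":
        gap = b.mic.start - a.mic.end
    else:
        gap = a.mic.start - b.mic.end
    return gap if gap >= 0 else None


def _pointer_key(a: HSP, b: HSP, mac_seq: str) -> tuple:
    overlap = a.mac.end - b.mac.start
    return (b.mac.start, a.mac.end, mac_seq[b.mac.start : a.mac.end]) if overlap > 0 else None


def chain_mds(
    hsps: list[HSP],
    mac_contig_id: str,
    mac_seq: str,
    max_pointer: int = DEFAULT_MAX_POINTER,
    min_ies: int = DEFAULT_MIN_IES,
) -> RearrangementMap:
    """Chain the HSPs of one somatic contig into a rearrangement map.

    ``mac_seq`` is the telomere-trimmed somatic sequence (pointer sequences
    are read from it).
    """
    rmap = RearrangementMap(mac_contig_id=mac_contig_id)
    if not hsps:
        return rmap
    order = sorted(
        hsps,
        key=lambda h: (h.mac.start, -h.score, len(h.mac), h.mic.contig_id, h.mic.start),
    )

    # (b) validate junction pairs and collect shared-pointer connections
    junction_partners: dict[int, set[int]] = {i: set() for i in range(len(order))}
    shared_pointer: dict[tuple, list[tuple[int, int]]] = {}
    for i, a in enumerate(order):
        for j in range(i + 1, len(order)):
            b = order[j]
            if b.mac.start > a.mac.end:  # sorted: no later HSP can touch a
                break
            if _is_junction(a, b, max_pointer, min_ies):
                junction_partners[i].add(j)
                junction_partners[j].add(i)
                key = _pointer_key(a, b, mac_seq)
                if key is not None:
                    shared_pointer.setdefault(key, []).append((i, j))

    # (c) temporarily connect members sharing an identical pointer into units
    parent = list(range(len(order)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for pairs in shared_pointer.values():
        for i, j in pairs:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj

    units: dict[int, list[int]] = {}
    for i in range(len(order)):
        units.setdefault(find(i), []).append(i)

    # (d) nesting test on unit spans, strongest first; ties: longer span,
    # then earlier germline coordinate
    def unit_span(members: list[int]) -> tuple[int, int]:
        return (
            min(order[i].mac.start for i in members),
            max(order[i].mac.end for i in members),
        )

    def unit_rank(members: list[int]) -> tuple:
        span = unit_span(members)
        score = sum(order[i].score for i in members)
        first = min(members, key=lambda i: (order[i].mic.contig_id, order[i].mic.start))
        return (-score, -(span[1] - span[0]), order[first].mic.contig_id, order[first].mic.start)

    ranked = sorted(units.values(), key=unit_rank)
    kept_spans: list[tuple[int, int]] = []
    survivors: list[int] = []
    for members in ranked:
        s, e = unit_span(members)
        nested = any(ks <= s and e <= ke for ks, ke in kept_spans)
        if nested:
            dup = any(ks == s and e == ke for ks, ke in kept_spans)
            if dup:
                logger.warning(
                    "discarding duplicate-span unit on %s at [%d, %d)", mac_contig_id, s, e
                )
            continue
        kept_spans.append((s, e))
        survivors.extend(members)

    # (e) merges undone: survivors are individual HSPs again, but an HSP
    # nested inside another surviving HSP must still go
    survivors_sorted = sorted(
        survivors, key=lambda i: (-order[i].score, -len(order[i].mac), order[i].mic.contig_id, order[i].mic.start)
    )
    final: list[int] = []
    for i in survivors_sorted:
        if any(order[j].mac.contains(order[i].mac) for j in final if j != i):
            continue
        final.append(i)
    final.sort(key=lambda i: (order[i].mac.start, order[i].mac.end))

    for ordinal, i in enumerate(final, start=1):
        h = order[i]
        rmap.mds_list.append(
            MDS(
                ordinal=ordinal,
                mac=h.mac,
                mic=h.mic,
                strand=h.strand,
                source_pass=h.source_pass,
            )
        )
        rmap.mic_contigs_used.add(h.mic.contig_id)

    # pointers for every consecutive pair; IESs for colinear pairs
    for k in range(len(rmap.mds_list) - 1):
        up, down = rmap.mds_list[k], rmap.mds_list[k + 1]
        ptr = call_pointer(up, down, mac_seq, max_pointer)
        if ptr is not None:
            rmap.pointers.append(ptr)
        hsp_up = order[final[k]]
        hsp_down = order[final[k + 1]]
        gap = _colinear_gap(hsp_up, hsp_down)
        if gap is not None and gap >= min_ies:
            if up.strand == "+":
                iv = Interval(up.mic.contig_id, up.mic.end, down.mic.start)
            else:
                iv = Interval(up.mic.contig_id, down.mic.end, up.mic.start)
            rmap.ies_list.append(IES(mic=iv, between=(up.ordinal, down.ordinal)))

    covered = 0
    prev_end = 0
    for mds in rmap.mds_list:
        s = max(mds.mac.start, prev_end)
        if mds.mac.end > s:
            covered += mds.mac.end - s
        prev_end = max(prev_end, mds.mac.end)
    rmap.mac_coverage_frac = covered / len(mac_seq) if mac_seq else 0.0
    return rmap


def call_pointer(
    upstream: MDS, downstream: MDS, mac_seq: str, max_pointer: int = DEFAULT_MAX_POINTER
) -> Optional[Pointer]:
    """Pointer of a consecutive MDS pair: their somatic overlap.

    Abutting MDSs give a zero-length pointer with empty sequence; a somatic
    gap between the two MDSs means no pointer (the gap stays uncovered);
    an overlap beyond ``max_pointer`` is a chaining artifact and yields no
    pointer either (junctions that long are rejected upstream).
    """
    if downstream.ordinal != upstream.ordinal + 1:
        raise ValueError("pointer requires consecutive MDS ordinals")
    overlap = upstream.mac.end - downstream.mac.start
    if overlap < 0:
        return None
    if overlap > max_pointer:
        logger.warning(
            "somatic overlap %d exceeds max_pointer at junction (%d, %d)",
            overlap,
            upstream.ordinal,
            downstream.ordinal,
        )
        return None
    junction = (upstream.ordinal, downstream.ordinal)
    if overlap == 0:
        return Pointer(junction=junction, seq="", mac_pos=None)
    iv = Interval(upstream.mac.contig_id, downstream.mac.start, upstream.mac.end)
    return Pointer(junction=junction, seq=mac_seq[iv.start : iv.end], mac_pos=iv)


def summarize_pointers(maps: list[RearrangementMap]) -> dict:
    """Pointer length histogram, modal-length PFM, and ANT-motif fraction.

    The position-frequency matrix is computed over all pointers of the
    modal length; the ANT fraction counts pointers (of any length >= 3)
    containing at least one A-N-T triple, plus TA dinucleotide pointers
    among length-2 cases are not counted (the motif needs three bases).
    """
    seqs = [p.seq for m in maps for p in m.pointers if p.seq]
    if not seqs:
        return {"histogram": {}, "modal_length": None, "pfm": None, "ant_fraction": None}
    hist = Counter(len(s) for s in seqs)
    modal = max(hist, key=lambda L: (hist[L], -L))
    modal_seqs = [s for s in seqs if len(s) == modal]
    pfm = np.zeros((modal, 4))
    index = {b: i for i, b in enumerate("ACGT")}
    for s in modal_seqs:
        for pos, c in enumerate(s):
            if c in index:
                pfm[pos, index[c]] += 1
    pfm /= len(modal_seqs)
    has_ant = [
        any(s[i] == "A" and s[i + 2] == "T" for i in range(len(s) - 2)) for s in seqs
    ]
    return {
        "histogram": dict(sorted(hist.items())),
        "modal_length": modal,
        "pfm": pfm,
        "ant_fraction": sum(has_ant) / len(seqs),
    }
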