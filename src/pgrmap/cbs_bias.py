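"""Chromosome breakage sites and nucleotide-bias profiling.

A chromosome breakage site (CBS) is the germline region between the
subtelomeric MDSs of two different somatic chromosomes that map to
adjacent positions on a germline contig. With ``m`` the germline
coordinate where the upstream chromosome ends and ``n`` where the
downstream one starts, ``delta = n - m`` is negative when the site is
duplicated and retained in both somatic products, positive when it is
eliminated, and zero for blunt breakage.

Bias profiling follows the standard nanochromosome treatment: two-telomere
contigs are orientation-normalized by gene direction, sliced into 250
bins for composition profiles, and their terminal 100 bp are scanned with
a 10 bp sliding window (step 1) for AT content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import CBSRecord, Contig, GenomeSet, RearrangementMap, revcomp

DEFAULT_MAX_GAP = 100
DEFAULT_SUBTEL_WINDOW = 5
FLANK = 30

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def detect_cbs(
    maps: list[RearrangementMap],
    mic: GenomeSet,
    trimmed_lengths: dict[str, int],
    max_gap: int = DEFAULT_MAX_GAP,
    subtel_window: int = DEFAULT_SUBTEL_WINDOW,
) -> list[CBSRecord]:
    """Pair terminal MDS endpoints of different chromosomes into CBSs.

    A chromosome contributes a right endpoint (the end of its germline
    footprint) and/or a left endpoint when the corresponding terminal MDS
    is subtelomeric — its somatic interval reaches within
    ``subtel_window`` of the trimmed contig end. Endpoints of two
    chromosomes extending in opposite directions pair when
    ``|n - m| <= max_gap``.
    """
    # per (mic contig, mac contig): footprint span and subtelomeric endpoints
    right_ends: set[tuple[str, str, int, int]] = set()  # (mic, mac, m, span_lo)
    left_ends: set[tuple[str, str, int, int]] = set()  # (mic, mac, n, span_hi)
    for m in maps:
        if not m.mds_list:
            continue
        L = trimmed_lengths[m.mac_contig_id]
        spans: dict[str, tuple[int, int]] = {}
        for mds in m.mds_list:
            lo, hi = spans.get(mds.mic.contig_id, (mds.mic.start, mds.mic.end))
            spans[mds.mic.contig_id] = (min(lo, mds.mic.start), max(hi, mds.mic.end))
        first, last = m.mds_list[0], m.mds_list[-1]
        for terminal, is_first in ((first, True), (last, False)):
            subtel = (
                terminal.mac.start <= subtel_window
                if is_first
                else L - terminal.mac.end <= subtel_window
            )
            if not subtel:
                continue
            span = spans[terminal.mic.contig_id]
            # the somatic 5' terminal MDS marks where the chromosome starts
            # on the germline (its left edge on plus, right edge on minus)
            contributes_left = is_first == (terminal.strand == "+")
            if contributes_left and terminal.mic.start == span[0]:
                left_ends.add(
                    (terminal.mic.contig_id, m.mac_contig_id, span[0], span[1])
                )
            if not contributes_left and terminal.mic.end == span[1]:
                right_ends.add(
                    (terminal.mic.contig_id, m.mac_contig_id, span[1], span[0])
                )

    records: list[CBSRecord] = []
    for mic_id, up_mac, m_pos, up_lo in sorted(right_ends):
        seq = mic[mic_id].seq
        for mic_id2, down_mac, n_pos, down_hi in sorted(left_ends):
            if mic_id2 != mic_id or down_mac == up_mac:
                continue
            delta = n_pos - m_pos
            if abs(delta) > max_gap:
                continue
            # opposite extension directions from the junction
            if not (up_lo < min(m_pos, n_pos) and down_hi > max(m_pos, n_pos)):
                continue
            lo, hi = min(m_pos, n_pos), max(m_pos, n_pos)
            flank5 = seq[max(0, lo - FLANK) : lo]
            flank3 = seq[hi : hi + FLANK]
            records.append(
                CBSRecord(
                    mic_contig_id=mic_id,
                    upstream_mac_id=up_mac,
                    downstream_mac_id=down_mac,
                    m=m_pos,
                    n=n_pos,
                    mode="retained" if delta < 0 else ("eliminated" if delta > 0 else "blunt"),
                    cbs_seq=seq[lo:hi],
                    flank_5=flank5,
                    flank_3=flank3,
                    flank_truncated=len(flank5) < FLANK or len(flank3) < FLANK,
                )
            )
    records.sort(key=lambda r: (r.mic_contig_id, min(r.m, r.n)))
    return records


@dataclass
class NucleotideProfile:
    """Averaged per-bin base frequencies across contigs (A, C, G, T)."""

    n_bins: int
    freq: np.ndarray  # (n_bins, 4)
    n_contigs: int


def profile_bins(
    contigs: list[Contig],
    orientation: Optional[dict[str, str]] = None,
    n_bins: int = 250,
) -> NucleotideProfile:
    """Composition profile of orientation-normalized two-telomere contigs.

    Each telomere-trimmed contig is reverse-complemented when its gene is
    on the minus strand, sliced into ``n_bins`` near-equal bins (the first
    ``L mod n_bins`` bins take one extra base), and per-bin frequencies are
    averaged across contigs. Contigs shorter than ``n_bins`` are skipped.
    """
    orientation = orientation or {}
    acc = np.zeros((n_bins, 4))
    used = 0
    for contig in contigs:
        seq = contig.seq
        if len(seq) < n_bins:
            continue
        if orientation.get(contig.id, "+") == "-":
            seq = revcomp(seq)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for b, chunk in enumerate(np.array_split(arr, n_bins)):
            counts = np.array(
                [
                    (chunk == ord("A")).sum(),
                    (chunk == ord("C")).sum(),
                    (chunk == ord("G")).sum(),
                    (chunk == ord("T")).sum(),
                ],
                dtype=float,
            )
            total = counts.sum()
            if total:
                acc[b] += counts / total
        used += 1
    if used:
        acc /= used
    return NucleotideProfile(n_bins=n_bins, freq=acc, n_contigs=used)


def terminal_at_content(
    contigs: list[Contig],
    terminal_len: int = 100,
    window: int = 10,
    step: int = 1,
) -> dict[str, np.ndarray]:
    """Sliding-window AT content over both terminal regions.

    Returns matrices (one per end, rows = contigs, columns = window
    starts); contigs shorter than ``terminal_len`` use what they have, and
    missing windows are NaN.
    """
    n_windows = max(0, (terminal_len - window) // step + 1)
    out = {
        "five_prime": np.full((len(contigs), n_windows), np.nan),
        "three_prime": np.full((len(contigs), n_windows), np.nan),
    }
    for row, contig in enumerate(contigs):
        for key, region in (
            ("five_prime", contig.seq[:terminal_len]),
            ("three_prime", contig.seq[-terminal_len:]),
        ):
            for w in range(n_windows):
                s = w * step
                chunk = region[s : s + window]
                if len(chunk) < window:
                    break
                at = sum(1 for c in chunk if c in "AT")
                out[key][row, w] = at / window
    return out


@dataclass
class PositionFrequencyMatrix:
    """Per-position base counts/frequencies of anchored sequences."""

    length: int
    counts: np.ndarray  # (length, 4)
    freq: np.ndarray  # (length, 4); columns with no coverage are zero
    n_sequences: int
    consensus: str = field(default="")


def build_pfm(seqs: list[str], anchor: str = "five_prime") -> PositionFrequencyMatrix:
    """Position-frequency matrix of sequences aligned at one end.

    ``anchor`` five_prime left-aligns the sequences, three_prime
    right-aligns them; each column is normalized by the number of
    sequences covering it.
    """
    if not seqs:
        raise ValueError("build_pfm requires at least one sequence")
    if anchor not in ("five_prime", "three_prime"):
        raise ValueError("anchor must be five_prime or three_prime")
    L = max(len(s) for s in seqs)
    counts = np.zeros((L, 4))
    cover = np.zeros(L)
    for s in seqs:
        offset = 0 if anchor == "five_prime" else L - len(s)
        for j, c in enumerate(s):
            if c in _BASE_INDEX:
                counts[offset + j, _BASE_INDEX[c]] += 1
            cover[offset + j] += 1
    freq = np.zeros_like(counts)
    nonzero = cover > 0
    freq[nonzero] = counts[nonzero] / cover[nonzero, None]
    consensus = "".join(
        "ACGT"[int(np.argmax(freq[i]))] if cover[i] else "-" for i in range(L)
    )
    return PositionFrequencyMatrix(
        length=L, counts=counts, freq=freq, n_sequences=len(seqs), consensus=consensus
    )
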