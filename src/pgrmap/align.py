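"""Ungapped seed-and-extend local alignment between somatic and germline contigs.

Semantics: exact ``word_size``-mer seeds locate diagonals; every seeded
diagonal is scanned once, yielding the maximal-scoring ungapped segments
delimited by (a) the running score falling to zero or below, (b) the score
dropping more than ``xdrop`` below the running maximum, or (c) an N or a
sequence end. Each emitted segment runs from its delimiter-defined start to
its running-maximum position, must contain at least one full seed word
(a run of ``word_size`` matches with no N) and must pass the E-value
cutoff. Segments on one diagonal are disjoint by construction, so
same-diagonal merging is inherent.

E-values use the Karlin-Altschul formula for ungapped scoring,
``E = K * m * n * exp(-lambda * S)``, with lambda solved at uniform base
frequencies and K taken from the published ungapped values for the two
scoring regimes in use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Optional

import numpy as np
from scipy.optimize import brentq

from .model import HSP, Contig, GenomeSet, Interval, revcomp

# published ungapped K for nucleotide scoring at uniform base composition
_K_TABLE = {(1, -2): 0.621, (1, -3): 0.711}
_K_DEFAULT = 0.621


@dataclass
class AlignParams:
    word_size: int
    match: int = 1
    mismatch: int = -2
    xdrop: int = 10
    evalue_max: float = 1e-5
    strand: Literal["both", "plus"] = "both"

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be at least 4")
        if self.mismatch >= 0:
            raise ValueError("mismatch score must be negative")
        if self.match <= 0 or self.xdrop <= 0 or self.evalue_max <= 0:
            raise ValueError("match, xdrop and evalue_max must be positive")


@lru_cache(maxsize=None)
def karlin_altschul_lambda(match: int, mismatch: int) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 at uniform frequencies."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-6, 10.0))


def karlin_altschul_evalue(
    score: int, m: int, n: int, match: int, mismatch: int
) -> float:
    lam = karlin_altschul_lambda(match, mismatch)
    k = _K_TABLE.get((match, mismatch), _K_DEFAULT)
    return k * m * n * math.exp(-lam * score)


def _encode(seq: str) -> np.ndarray:
    """Bytes view of a sequence for vectorized comparison; N encodes as 0."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    arr[arr == ord("N")] = 0
    return arr


def xdrop_segments(
    steps: np.ndarray, nmask: np.ndarray, xdrop: int
) -> list[tuple[int, int, int]]:
    """Maximal X-drop segments of one diagonal.

    ``steps`` holds the per-position score increments, ``nmask`` marks
    positions where either base is N (hard breaks). Returns
    ``(start, end, score)`` triples with 0-based half-open offsets.
    """
    segs: list[tuple[int, int, int]] = []
    s = 0
    best = 0
    best_end = -1
    seg_start = 0

    def flush(reset_to: int) -> None:
        nonlocal s, best, best_end, seg_start
        if best > 0:
            segs.append((seg_start, best_end, best))
        s = 0
        best = 0
        best_end = -1
        seg_start = reset_to

    for t in range(len(steps)):
        if nmask[t]:
            flush(t + 1)
            continue
        s += int(steps[t])
        if s > best:
            best = s
            best_end = t + 1
        if s <= 0 or best - s > xdrop:
            flush(t + 1)
    flush(len(steps))
    return segs


def _max_match_run(match_mask: np.ndarray) -> int:
    """Length of the longest run of True values."""
    best = run = 0
    for v in match_mask:
        run = run + 1 if v else 0
        if run > best:
            best = run
    return best


@lru_cache(maxsize=64)
def _subject_index(subject: str, w: int) -> dict[str, list[int]]:
    """Word -> positions index of a subject sequence (N-words skipped)."""
    positions: dict[str, list[int]] = {}
    for j in range(len(subject) - w + 1):
        word = subject[j : j + w]
        if "N" not in word:
            positions.setdefault(word, []).append(j)
    return positions


def _seeded_diagonals(query: str, subject: str, w: int) -> set[int]:
    """Diagonals (subject_pos - query_pos) carrying at least one exact seed."""
    if len(query) < w or len(subject) < w:
        return set()
    positions = _subject_index(subject, w)
    diagonals: set[int] = set()
    for i in range(len(query) - w + 1):
        word = query[i : i + w]
        hits = positions.get(word)
        if hits:
            for j in hits:
                diagonals.add(j - i)
    return diagonals


def _scan_strand(
    query: str,
    subject: str,
    qarr: np.ndarray,
    sarr: np.ndarray,
    params: AlignParams,
    m_eff: int,
    n_eff: int,
) -> list[tuple[int, int, int, int]]:
    """All passing segments of query vs subject (given orientation).

    Returns ``(qstart, qend, sstart, score, identities, evalue)`` tuples in
    the coordinates of the two sequences as supplied.
    """
    out = []
    for diag in sorted(_seeded_diagonals(query, subject, params.word_size)):
        qlo = max(0, -diag)
        qhi = min(len(query), len(subject) - diag)
        if qhi - qlo < params.word_size:
            continue
        q = qarr[qlo:qhi]
        s = sarr[qlo + diag : qhi + diag]
        nmask = (q == 0) | (s == 0)
        match = (q == s) & ~nmask
        steps = np.where(match, params.match, params.mismatch)
        for st, en, score in xdrop_segments(steps, nmask, params.xdrop):
            if en - st < params.word_size:
                continue
            if _max_match_run(match[st:en]) < params.word_size:
                continue
            ev = karlin_altschul_evalue(score, m_eff, n_eff, params.match, params.mismatch)
            if ev > params.evalue_max:
                continue
            ident = int(match[st:en].sum())
            out.append((qlo + st, qlo + en, qlo + diag + st, score, ident, ev))
    return out


def seed_extend(
    query: Contig,
    subject: Contig,
    params: AlignParams,
    m_override: Optional[int] = None,
    n_override: Optional[int] = None,
    source_pass: str = "long_seed",
) -> list[HSP]:
    """Ungapped local alignment of a MAC query against a MIC subject.

    Both sequences are expected telomere-trimmed. Output is sorted by query
    start, then score descending.
    """
    m_eff = m_override or len(query.seq)
    n_eff = n_override or len(subject.seq)
    qarr = _encode(query.seq)
    hsps: list[HSP] = []

    def collect(subject_seq: str, strand: str) -> None:
        sarr = _encode(subject_seq)
        for qs, qe, ss, score, ident, ev in _scan_strand(
            query.seq, subject_seq, qarr, sarr, params, m_eff, n_eff
        ):
            length = qe - qs
            if strand == "+":
                mic_iv = Interval(subject.id, ss, ss + length)
            else:
                mic_iv = Interval(
                    subject.id, len(subject.seq) - (ss + length), len(subject.seq) - ss
                )
            hsps.append(
                HSP(
                    mac=Interval(query.id, qs, qe),
                    mic=mic_iv,
                    strand=strand,  # type: ignore[arg-type]
                    score=score,
                    identities=ident,
                    evalue=ev,
                    source_pass=source_pass,  # type: ignore[arg-type]
                )
            )

    collect(subject.seq, "+")
    if params.strand == "both":
        collect(revcomp(subject.seq), "-")
    hsps.sort(key=lambda h: (h.mac.start, -h.score, h.mic.contig_id, h.mic.start))
    return hsps


def _uncovered(hsps: list[HSP], length: int) -> list[tuple[int, int]]:
    """Maximal query intervals not covered by any HSP footprint."""
    covered: list[tuple[int, int]] = []
    for h in sorted(hsps, key=lambda h: h.mac.start):
        if covered and h.mac.start <= covered[-1][1]:
            covered[-1] = (covered[-1][0], max(covered[-1][1], h.mac.end))
        else:
            covered.append((h.mac.start, h.mac.end))
    gaps = []
    prev = 0
    for s, e in covered:
        if s > prev:
            gaps.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        gaps.append((prev, length))
    return gaps


def two_pass_align(
    mac: GenomeSet,
    mic: GenomeSet,
    pass1: AlignParams,
    pass2: AlignParams,
    max_pointer: int = 50,
) -> dict[str, list[HSP]]:
    """Long-seed pass over full contigs, short-seed pass over the gaps.

    The second pass re-queries every maximal uncovered MAC interval (padded
    by ``max_pointer`` on each side) against the MIC contigs hit by the
    flanking first-pass HSPs — or all MIC contigs when the first pass found
    nothing there.
    """
    if pass1.word_size <= pass2.word_size:
        pass  # callers normally supply 28/12; equal word sizes are legal but useless
    result: dict[str, list[HSP]] = {}
    mic_list = list(mic)
    for q in mac:
        hsps: list[HSP] = []
        for s in mic_list:
            hsps.extend(seed_extend(q, s, pass1))
        gaps = _uncovered(hsps, len(q.seq))
        for gs, ge in gaps:
            lo = max(0, gs - max_pointer)
            hi = min(len(q.seq), ge + max_pointer)
            if hi - lo < pass2.word_size:
                continue
            flank_ids = {
                h.mic.contig_id for h in hsps if h.mac.end >= lo and h.mac.start <= hi
            }
            subjects = [s for s in mic_list if s.id in flank_ids] if flank_ids else mic_list
            window = Contig(id=q.id, seq=q.seq[lo:hi], source="MAC")
            for s in subjects:
                for h in seed_extend(
                    window,
                    s,
                    pass2,
                    m_override=len(q.seq),
                    source_pass="short_seed",
                ):
                    h.mac = Interval(q.id, h.mac.start + lo, h.mac.end + lo)
                    hsps.append(h)
        # drop exact duplicates re-found by the second pass
        seen: set[tuple] = set()
        unique: list[HSP] = []
        for h in sorted(hsps, key=lambda h: (h.mac.start, -h.score, h.source_pass)):
            key = (h.mac.start, h.mac.end, h.mic.contig_id, h.mic.start, h.strand)
            if key in seen:
                continue
            seen.add(key)
            unique.append(h)
        result[q.id] = unique
    return result


def hsps_to_table(hsps: list[HSP]) -> list[str]:
    """12-column tabular dump (1-based inclusive; sstart > send on minus)."""
    rows = []
    for h in hsps:
        length = len(h.mac)
        pct = 100.0 * h.identities / length
        if h.strand == "+":
            ss, se = h.mic.start + 1, h.mic.end
        else:
            ss, se = h.mic.end, h.mic.start + 1
        rows.append(
            "\t".join(
                [
                    h.mac.contig_id,
                    h.mic.contig_id,
                    f"{pct:.2f}",
                    str(length),
                    str(length - h.identities),
                    "0",
                    str(h.mac.start + 1),
                    str(h.mac.end),
                    str(ss),
                    str(se),
                    f"{h.evalue:.2e}",
                    str(h.score),
                ]
            )
        )
    return rows
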