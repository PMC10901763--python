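"""Assembly cleanup: telomere detection/trimming, filtering, redundancy
removal and the somatic-contamination screen for germline assemblies.

Telomere recognition uses the two anchored repeat patterns of spirotrich
nanochromosomes — a C-rich 5' cap matching ``[AC]*CCCCAA[AC]*CCAAAA`` and a
G-rich 3' cap matching ``GGGGTT[GT]*TTGGGG[GT]*``. The 5' match must start
within ``max_offset`` bases of the contig start, the 3' match must end
within ``max_offset`` bases of the contig end, and the longest qualifying
match is taken.

Filtering rules, applied in order: contigs with coverage below 1 are
discarded as unsupported; contigs without any telomere and without
external (RNA-mapping) evidence are discarded; contigs shorter than 400 bp
are discarded unless they carry both telomeres.
"""

from __future__ import annotations

import re
from typing import Optional

from .align import AlignParams, seed_extend
from .model import Contig, GenomeSet, Interval, TelomereAnnotation, CleanupReport
from .similarity import global_identity

TELOMERE_5_PATTERN = re.compile(r"[AC]*CCCCAA[AC]*CCAAAA")
TELOMERE_3_PATTERN = re.compile(r"GGGGTT[GT]*TTGGGG[GT]*")
# the 3' pattern reversed literally, for anchored longest-match search on
# the reversed sequence
_TELOMERE_3_REVERSED = re.compile(r"[GT]*GGGGTT[GT]*TTGGGG")

MIN_COVERAGE = 1.0
MIN_LENGTH = 400
DEFAULT_MAX_OFFSET = 30


def _longest_anchored(pattern: re.Pattern, seq: str, max_offset: int) -> Optional[tuple[int, int]]:
    """Longest pattern match starting within ``max_offset`` of position 0."""
    best = None
    for start in range(min(max_offset, len(seq)) + 1):
        m = pattern.match(seq, start)
        if m and m.end() > m.start():
            if best is None or (m.end() - m.start()) > (best[1] - best[0]):
                best = (m.start(), m.end())
    return best


def find_telomeres(contig: Contig, max_offset: int = DEFAULT_MAX_OFFSET) -> TelomereAnnotation:
    """Anchored longest-match telomere detection at both contig ends."""
    ann = TelomereAnnotation(contig_id=contig.id)
    hit5 = _longest_anchored(TELOMERE_5_PATTERN, contig.seq, max_offset)
    if hit5:
        ann.five_prime = Interval(contig.id, hit5[0], hit5[1])
    rev = contig.seq[::-1]
    hit3 = _longest_anchored(_TELOMERE_3_REVERSED, rev, max_offset)
    if hit3:
        n = len(contig.seq)
        ann.three_prime = Interval(contig.id, n - hit3[1], n - hit3[0])
    if ann.five_prime and ann.three_prime and ann.five_prime.end > ann.three_prime.start:
        # degenerate tiny contig where both matches overlap; keep the longer
        if len(ann.five_prime) >= len(ann.three_prime):
            ann.three_prime = None
        else:
            ann.five_prime = None
    contig.telomere_state = ann.state  # type: ignore[assignment]
    return ann


def trim_telomeres(contig: Contig, annotation: TelomereAnnotation) -> tuple[Contig, int]:
    """Remove telomeric caps; returns the trimmed contig and the 5' offset.

    Everything outside the internal span (including any bases outward of
    the telomere match) is removed; the offset maps trimmed coordinates
    back to the original contig.
    """
    if annotation.contig_id != contig.id:
        raise ValueError("annotation does not refer to this contig")
    start = annotation.five_prime.end if annotation.five_prime else 0
    end = annotation.three_prime.start if annotation.three_prime else len(contig.seq)
    trimmed = Contig(
        id=contig.id,
        seq=contig.seq[start:end],
        source=contig.source,
        coverage=contig.coverage,
        telomere_state="none",
    )
    return trimmed, start


def _n_telomeres(state: str) -> int:
    return {"none": 0, "five_prime": 1, "three_prime": 1, "both": 2}[state]


def clean_mac(
    mac: GenomeSet,
    coverage: Optional[dict[str, float]] = None,
    evidence: Optional[set[str]] = None,
    max_offset: int = DEFAULT_MAX_OFFSET,
) -> CleanupReport:
    """Apply the somatic-assembly keep/discard rules.

    Telomere states are (re)annotated here. Contigs missing from the
    coverage table pass the coverage rule. ``evidence`` carries ids with
    external transcription support, exempting telomere-free contigs.
    """
    coverage = coverage or {}
    evidence = evidence or set()
    kept: list[str] = []
    discarded: dict[str, str] = {}
    class_counts = {0: 0, 1: 0, 2: 0}
    for contig in mac:
        ann = find_telomeres(contig, max_offset)
        n_tel = _n_telomeres(ann.state)
        class_counts[n_tel] += 1
        cov = coverage.get(contig.id, contig.coverage)
        if cov is not None and cov < MIN_COVERAGE:
            discarded[contig.id] = "low_coverage"
        elif n_tel == 0 and contig.id not in evidence:
            discarded[contig.id] = "no_telomere_no_evidence"
        elif len(contig.seq) < MIN_LENGTH and ann.state != "both":
            discarded[contig.id] = "short_no_two_telomeres"
        else:
            kept.append(contig.id)
    return CleanupReport(kept=kept, discarded=discarded, class_counts=class_counts)


def dedup_contigs(genome: GenomeSet, identity_min: float = 0.98) -> CleanupReport:
    """Greedy longest-first redundancy removal.

    A contig is redundant when it aligns globally (either strand, identity
    denominator = its own length) to a longer already-kept contig at
    ``identity_min`` or better. The longest member of each cluster is kept.
    Length ties break lexicographically by id.
    """
    order = sorted(genome, key=lambda c: (-len(c.seq), c.id))
    kept: list[str] = []
    discarded: dict[str, str] = {}
    class_counts = {0: 0, 1: 0, 2: 0}
    for contig in order:
        class_counts[_n_telomeres(contig.telomere_state)] += 1
        redundant = False
        for rep_id in kept:
            if global_identity(contig.seq, genome[rep_id].seq) >= identity_min:
                redundant = True
                break
        if redundant:
            discarded[contig.id] = "redundant"
        else:
            kept.append(contig.id)
    return CleanupReport(kept=kept, discarded=discarded, class_counts=class_counts)


def screen_mic_contamination(
    mic: GenomeSet,
    mac: GenomeSet,
    evalue_max: float = 1e-10,
    identity_min: float = 0.97,
    qcov_min: float = 0.95,
    word_size: int = 28,
) -> CleanupReport:
    """Flag germline contigs that are somatic carry-over.

    A MIC contig is a contaminant when HSPs against any single MAC contig
    with per-HSP identity above ``identity_min`` and E-value below
    ``evalue_max`` jointly cover more than ``qcov_min`` of the MIC contig.
    """
    params = AlignParams(word_size=word_size, match=1, mismatch=-2, evalue_max=evalue_max)
    kept: list[str] = []
    discarded: dict[str, str] = {}
    class_counts = {0: 0, 1: 0, 2: 0}
    for q in mic:
        class_counts[_n_telomeres(q.telomere_state)] += 1
        contaminant = False
        for target in mac:
            hsps = seed_extend(q, target, params)
            footprints = []
            for h in hsps:
                if h.evalue >= evalue_max:
                    continue
                if h.identities / len(h.mac) <= identity_min:
                    continue
                footprints.append((h.mac.start, h.mac.end))
            if not footprints:
                continue
            footprints.sort()
            covered = 0
            prev_end = 0
            for s, e in footprints:
                s = max(s, prev_end)
                if e > s:
                    covered += e - s
                    prev_end = e
                prev_end = max(prev_end, e)
            if covered / len(q.seq) > qcov_min:
                contaminant = True
                break
        if contaminant:
            discarded[q.id] = "contaminant"
        else:
            kept.append(q.id)
    return CleanupReport(kept=kept, discarded=discarded, class_counts=class_counts)
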