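"""End-to-end orchestration: trim, two-pass align, chain, classify.

Thin glue over the stage modules so drivers, tests and the acceptance
script run the identical path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .align import AlignParams, two_pass_align
from .annotate import DEFAULT_MAX_POINTER, DEFAULT_MIN_IES, chain_mds
from .architecture import classify_scrambling
from .cleanup import find_telomeres, trim_telomeres
from .model import Contig, GenomeSet, RearrangementMap, ScramblingCall


def default_pass1() -> AlignParams:
    """Long-seed pass: word 28, ungapped, E-value 1e-5."""
    return AlignParams(word_size=28, match=1, mismatch=-2, xdrop=10, evalue_max=1e-5)


def default_pass2() -> AlignParams:
    """Short-seed pass for small MDSs: word 12, ungapped, E-value 1e-5."""
    return AlignParams(word_size=12, match=1, mismatch=-3, xdrop=10, evalue_max=1e-5)


@dataclass
class AnnotationResult:
    trimmed_mac: GenomeSet
    trim_offsets: dict[str, int]
    maps: dict[str, RearrangementMap]
    scrambling: dict[str, ScramblingCall] = field(default_factory=dict)


def trim_genome(mac: GenomeSet) -> tuple[GenomeSet, dict[str, int]]:
    """Annotate and strip telomeres from every contig."""
    trimmed = GenomeSet(label=mac.label)
    offsets: dict[str, int] = {}
    for contig in mac:
        ann = find_telomeres(contig)
        t, offset = trim_telomeres(contig, ann)
        trimmed.add(t)
        offsets[contig.id] = offset
    return trimmed, offsets


def annotate_genomes(
    mac: GenomeSet,
    mic: GenomeSet,
    pass1: Optional[AlignParams] = None,
    pass2: Optional[AlignParams] = None,
    max_pointer: int = DEFAULT_MAX_POINTER,
    min_ies: int = DEFAULT_MIN_IES,
    trim: bool = True,
) -> AnnotationResult:
    """Full somatic-vs-germline annotation of a genome pair.

    ``mac`` may carry telomeres (``trim=True``) or be pre-trimmed.
    """
    if trim:
        trimmed, offsets = trim_genome(mac)
    else:
        trimmed, offsets = mac, {c.id: 0 for c in mac}
    p1 = pass1 or default_pass1()
    p2 = pass2 or default_pass2()
    hsps = two_pass_align(trimmed, mic, p1, p2, max_pointer=max_pointer)
    maps = {}
    calls = {}
    for contig in trimmed:
        rmap = chain_mds(
            hsps[contig.id],
            contig.id,
            contig.seq,
            max_pointer=max_pointer,
            min_ies=min_ies,
        )
        maps[contig.id] = rmap
        calls[contig.id] = classify_scrambling(rmap)
    return AnnotationResult(
        trimmed_mac=trimmed, trim_offsets=offsets, maps=maps, scrambling=calls
    )
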