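"""Domain types shared across the rearrangement pipeline.

Coordinate convention: every in-memory interval is 0-based, half-open
``[start, end)`` on the plus strand of its contig. Conversion to 1-based
inclusive (GFF3) or BED happens only at serialization boundaries in
:mod:`pgrmap.io`.

The central objects mirror the biology of ciliate programmed genome
rearrangement: a somatic (MAC) nanochromosome is stitched from
macronucleus-destined sequences (MDSs) found on germline (MIC) contigs;
the germline-limited spacers between colinear MDSs are IESs, and the short
repeat shared by two adjacent MDSs at a junction is the pointer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional

Strand = Literal["+", "-"]

VALID_BASES = frozenset("ACGTN")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMP)[::-1]


@dataclass
class Interval:
    """A 0-based half-open interval on a named contig."""

    contig_id: str
    start: int
    end: int
    strand: Strand = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        """Overlap length in bp with another interval on the same contig."""
        if self.contig_id != other.contig_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "Interval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class Contig:
    """A sequence record with telomere state, coverage and provenance."""

    id: str
    seq: str
    source: Literal["MAC", "MIC"] = "MAC"
    coverage: Optional[float] = None
    telomere_state: Literal["none", "five_prime", "three_prime", "both"] = "none"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"contig {self.id!r} has empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            offset = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(
                f"contig {self.id!r} contains invalid character "
                f"{self.seq[offset]!r} at offset {offset}"
            )

    def __len__(self) -> int:
        return len(self.seq)


class GenomeSet:
    """An ordered, id-unique collection of contigs."""

    def __init__(self, contigs: Optional[list[Contig]] = None, label: str = ""):
        self.label = label
        self._contigs: dict[str, Contig] = {}
        for c in contigs or []:
            self.add(c)

    def add(self, contig: Contig) -> None:
        if contig.id in self._contigs:
            raise ValueError(f"duplicate contig id {contig.id!r}")
        self._contigs[contig.id] = contig

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._contigs

    def __getitem__(self, contig_id: str) -> Contig:
        return self._contigs[contig_id]

    def __iter__(self) -> Iterator[Contig]:
        return iter(self._contigs.values())

    def __len__(self) -> int:
        return len(self._contigs)

    @property
    def ids(self) -> list[str]:
        return list(self._contigs)


@dataclass
class HSP:
    """An ungapped local alignment (high-scoring pair) between MAC and MIC.

    ``strand`` is the MIC strand relative to the MAC plus strand; both
    intervals are stored in plus-strand coordinates of their contigs.
    """

    mac: Interval
    mic: Interval
    strand: Strand
    score: int
    identities: int
    evalue: float
    source_pass: Literal["long_seed", "short_seed"] = "long_seed"

    def __post_init__(self) -> None:
        if len(self.mac) != len(self.mic):
            raise ValueError("ungapped HSP requires equal interval lengths")
        if self.identities > len(self.mac):
            raise ValueError("identities exceed alignment length")


@dataclass
class MDS:
    """A macronucleus-destined sequence: one retained germline segment."""

    ordinal: int  # 1-based position along the MAC contig
    mac: Interval
    mic: Interval
    strand: Strand
    source_pass: Literal["long_seed", "short_seed"] = "long_seed"


@dataclass
class Pointer:
    """Junction repeat: the MAC overlap of two adjacent MDSs."""

    junction: tuple[int, int]  # (k, k+1) MDS ordinals
    seq: str
    mac_pos: Optional[Interval]  # None for zero-length (blunt) pointers

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class IES:
    """An internal eliminated sequence between two colinear MDSs on the MIC."""

    mic: Interval
    between: tuple[int, int]

    @property
    def length(self) -> int:
        return len(self.mic)


@dataclass
class RearrangementMap:
    """Ordered MDS/IES/pointer annotation linking one MAC contig to the MIC."""

    mac_contig_id: str
    mds_list: list[MDS] = field(default_factory=list)
    pointers: list[Pointer] = field(default_factory=list)
    ies_list: list[IES] = field(default_factory=list)
    mac_coverage_frac: float = 0.0
    mic_contigs_used: set[str] = field(default_factory=set)

    @property
    def n_mds(self) -> int:
        return len(self.mds_list)


@dataclass
class ScramblingCall:
    """Per-chromosome scrambling classification with its evidence."""

    mac_contig_id: str
    label: Literal["unscrambled", "inversion", "insertion", "concurrent"]
    evidence: list[str] = field(default_factory=list)


@dataclass
class AltProcessingEvent:
    """An alternative-processing event shared between two MAC chromosomes.

    A-type: the same germline MDS region is processed into distinct somatic
    chromosomes. B-type: one chromosome's MDS lies inside another
    chromosome's IES (directional: members = (mds_owner, ies_owner)).
    """

    type: Literal["A", "B"]
    members: tuple[str, str]
    mic_region: Interval
    overlap_bp: int


@dataclass
class CBSRecord:
    """A chromosome breakage junction between two somatic chromosome precursors.

    ``m`` is the MIC coordinate where the upstream chromosome ends, ``n``
    where the downstream chromosome starts; ``delta = n - m``. A negative
    delta means the breakage-site sequence is duplicated and retained in
    both somatic products; positive means it is eliminated with the IES-like
    spacer; zero is a blunt junction.
    """

    mic_contig_id: str
    upstream_mac_id: str
    downstream_mac_id: str
    m: int
    n: int
    mode: Literal["retained", "eliminated", "blunt"]
    cbs_seq: str
    flank_5: str
    flank_3: str
    flank_truncated: bool = False

    @property
    def delta(self) -> int:
        return self.n - self.m

    def __post_init__(self) -> None:
        d = self.n - self.m
        expect = "retained" if d < 0 else ("eliminated" if d > 0 else "blunt")
        if self.mode != expect:
            raise ValueError(f"mode {self.mode!r} inconsistent with delta {d}")
        if len(self.cbs_seq) != abs(d):
            raise ValueError("cbs_seq length must equal |delta|")


@dataclass
class TelomereAnnotation:
    """Locations of the C-rich 5' and G-rich 3' telomere matches."""

    contig_id: str
    five_prime: Optional[Interval] = None
    three_prime: Optional[Interval] = None

    @property
    def state(self) -> str:
        if self.five_prime and self.three_prime:
            return "both"
        if self.five_prime:
            return "five_prime"
        if self.three_prime:
            return "three_prime"
        return "none"


@dataclass
class CleanupReport:
    """Partition of an assembly into kept and discarded contigs."""

    kept: list[str]
    discarded: dict[str, str]  # contig id -> reason
    class_counts: dict[int, int]  # telomere count (0/1/2) -> n contigs

    def __post_init__(self) -> None:
        overlap = set(self.kept) & set(self.discarded)
        if overlap:
            raise ValueError(f"contigs both kept and discarded: {sorted(overlap)}")
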