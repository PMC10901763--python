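"""Paired germline/somatic genome simulator with planted ground truth.

The generator emulates the rearrangement architecture of spirotrich
ciliates: telomere-capped somatic nanochromosomes stitched from
macronucleus-destined sequences (MDSs); germline loci in which the same
MDSs are separated by internal eliminated sequences (IESs) flanked by
repeated pointers; scrambled MDS orders and orientations; chromosome
breakage sites (CBSs) between adjacent nanochromosome precursors on a
germline contig (retained / eliminated / blunt); AT-rich subtelomeric
stretches carrying a fixed terminal motif; and alternative processing
(A-type: one germline MDS region used by two somatic chromosomes; B-type:
a short chromosome's MDS nested inside another chromosome's IES).

Design notes
------------
* The germline contig is the primary object: somatic chromosomes are
  derived from the germline blocks, so the reconstruction invariant
  (stitching the truth MDS copies back together reproduces the
  telomere-trimmed somatic sequence byte-exactly) holds by construction.
* Junction hardening: the six germline bases flanking every planted
  alignment block are sampled to mismatch the corresponding somatic
  continuation, so ungapped X-drop extension (xdrop 10 with mismatch −2 or
  −3) provably terminates at the planted boundary and every pointer is
  recoverable verbatim. This is the strong form of the rule that an IES
  may not begin or end with its pointer.
* Retained CBSs are emitted once on the germline contig and shared as the
  terminal bases of both neighbouring precursors, giving n − m = −d; an
  eliminated junction inserts a germline-limited gap of g bases (n − m =
  +g); blunt junctions abut.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import asdict, dataclass, field
from typing import Literal, Optional

import numpy as np

from .model import Contig, GenomeSet, revcomp

BASES = np.array(list("ACGT"))
_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}

# number of forced-mismatch bases flanking every planted block; 6 mismatches
# at the weakest penalty (-2) drop the running score by 12 > xdrop 10
HARDEN = 6

TELO_UNIT_5 = "CCCCAAAA"
TELO_UNIT_3 = "GGGGTTTT"

_RE_5 = re.compile(r"[AC]*CCCCAA[AC]*CCAAAA")


@dataclass
class SimulationParams:
    """Generation parameters; defaults are the package's study conditions."""

    n_chromosomes: int = 50
    mds_per_chromosome: tuple[int, int] = (3, 8)
    mds_len: tuple[int, int] = (200, 800)
    ies_len: tuple[int, int] = (30, 300)
    pointer_len: tuple[int, int] = (2, 15)
    pointer_at_bias: float = 0.8
    gc: float = 0.5
    telomere_repeats: int = 5
    scramble_frac: float = 0.2
    scramble_props: dict = field(
        default_factory=lambda: {"inversion": 0.6, "insertion": 0.25, "concurrent": 0.15}
    )
    cbs_mode_probs: dict = field(
        default_factory=lambda: {"retained": 0.7, "eliminated": 0.2, "blunt": 0.1}
    )
    cbs_retained_len: tuple[int, int] = (2, 30)
    cbs_eliminated_gap: tuple[int, int] = (1, 50)
    altproc_a_rate: float = 0.1
    altproc_b_rate: float = 0.1
    subtelomeric_at_len: tuple[int, int] = (8, 30)
    subtel_at_bias: float = 0.85
    subtel_motif: Optional[str] = "GAA"
    subtel_motif_offset: int = 8
    chromosomes_per_mic: tuple[int, int] = (3, 6)
    mic_margin: tuple[int, int] = (50, 200)
    truncation_rate: float = 0.1
    low_coverage_rate: float = 0.05
    contaminant_rate: float = 0.1
    seed: int = 0
    # explicit per-chromosome scrambling labels; overrides scramble_frac
    label_plan: Optional[list[str]] = None

    IES_FLOOR: int = 20

    def validate(self) -> None:
        for name in (
            "mds_per_chromosome",
            "mds_len",
            "ies_len",
            "pointer_len",
            "cbs_retained_len",
            "cbs_eliminated_gap",
            "subtelomeric_at_len",
            "chromosomes_per_mic",
            "mic_margin",
        ):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"empty or negative range for {name}: ({lo}, {hi})")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be positive")
        for probs, label in (
            (self.scramble_props, "scramble_props"),
            (self.cbs_mode_probs, "cbs_mode_probs"),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{label} must sum to 1")
        if not 0 <= self.scramble_frac <= 1:
            raise ValueError("scramble_frac must lie in [0, 1]")
        if self.mds_len[0] <= 2 * self.pointer_len[1] + 2 * HARDEN:
            raise ValueError(
                "minimum MDS length must exceed twice the maximum pointer "
                "length plus the junction-hardening margin"
            )
        if self.ies_len[0] < self.IES_FLOOR:
            raise ValueError(f"minimum IES length is {self.IES_FLOOR} bp")
        if self.label_plan is not None:
            if len(self.label_plan) != self.n_chromosomes:
                raise ValueError("label_plan must list one label per chromosome")
            bad = set(self.label_plan) - {"unscrambled", "inversion", "insertion", "concurrent"}
            if bad:
                raise ValueError(f"unknown scrambling labels in label_plan: {sorted(bad)}")
        if self.mds_len[0] < 28:
            warnings.warn(
                "minimum MDS length below the long-seed word size (28); "
                "small MDSs are only recoverable by the short-seed pass",
                stacklevel=2,
            )

    @property
    def telomere_len(self) -> int:
        return 8 * self.telomere_repeats


# ---------------------------------------------------------------------------
# Truth records
# ---------------------------------------------------------------------------


@dataclass
class TruthMDS:
    ordinal: int
    mac_start: int
    mac_end: int  # trimmed-chromosome coordinates
    mic_contig: str
    mic_start: int
    mic_end: int
    strand: str


@dataclass
class TruthPointer:
    junction: int  # between MDS `junction` and `junction + 1`
    seq: str
    mac_start: int
    mac_end: int


@dataclass
class TruthIES:
    junction: int
    mic_contig: str
    mic_start: int
    mic_end: int


@dataclass
class ChromosomeTruth:
    mac_id: str
    kind: str  # primary | alt_a | alt_b
    label: str  # unscrambled | inversion | insertion | concurrent
    mds: list[TruthMDS]
    pointers: list[TruthPointer]
    ies: list[TruthIES]
    telomere_len: int
    motif_planted: tuple[bool, bool] = (False, False)


@dataclass
class TruthCBS:
    mic_contig: str
    upstream_mac_id: str
    downstream_mac_id: str
    m: int
    n: int
    mode: str
    cbs_seq: str


@dataclass
class TruthAltEvent:
    type: str  # A | B
    members: tuple[str, str]
    mic_contig: str
    mic_start: int
    mic_end: int


@dataclass
class SimulationTruth:
    chromosomes: dict[str, ChromosomeTruth] = field(default_factory=dict)
    cbs: list[TruthCBS] = field(default_factory=list)
    alt_events: list[TruthAltEvent] = field(default_factory=list)
    artifacts: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "chromosomes": {k: asdict(v) for k, v in self.chromosomes.items()},
            "cbs": [asdict(c) for c in self.cbs],
            "alt_events": [asdict(a) for a in self.alt_events],
            "artifacts": self.artifacts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        truth = cls()
        for k, v in d["chromosomes"].items():
            truth.chromosomes[k] = ChromosomeTruth(
                mac_id=v["mac_id"],
                kind=v["kind"],
                label=v["label"],
                mds=[TruthMDS(**m) for m in v["mds"]],
                pointers=[TruthPointer(**p) for p in v["pointers"]],
                ies=[TruthIES(**i) for i in v["ies"]],
                telomere_len=v["telomere_len"],
                motif_planted=tuple(v["motif_planted"]),
            )
        truth.cbs = [TruthCBS(**c) for c in d["cbs"]]
        truth.alt_events = [
            TruthAltEvent(
                type=a["type"],
                members=tuple(a["members"]),
                mic_contig=a["mic_contig"],
                mic_start=a["mic_start"],
                mic_end=a["mic_end"],
            )
            for a in d["alt_events"]
        ]
        truth.artifacts = d["artifacts"]
        return truth


def reconstruct_mac(truth: SimulationTruth, mic: GenomeSet, mac_id: str) -> str:
    """Rebuild a telomere-trimmed somatic chromosome from the germline.

    Takes the truth MDS copies in somatic order, reverse-complements
    inverted ones, and stitches consecutive segments keeping a single copy
    of each pointer. Equivalent to excising every IES (and germline-limited
    spacer) and unscrambling.
    """
    chrom = truth.chromosomes[mac_id]
    ptr_len = {p.junction: len(p.seq) for p in chrom.pointers}
    parts: list[str] = []
    for mds in sorted(chrom.mds, key=lambda m: m.ordinal):
        seg = mic[mds.mic_contig].seq[mds.mic_start : mds.mic_end]
        if mds.strand == "-":
            seg = revcomp(seg)
        if parts:
            seg = seg[ptr_len.get(mds.ordinal - 1, 0) :]
        parts.append(seg)
    return "".join(parts)


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(BASES, size=n, p=p)) if n else []


def _at_seq(rng: np.random.Generator, n: int, at_bias: float) -> list[str]:
    p = [at_bias / 2, (1 - at_bias) / 2, (1 - at_bias) / 2, at_bias / 2]
    return list(rng.choice(BASES, size=n, p=p)) if n else []


def _randint(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def _match_run(seq: str, allowed: str) -> int:
    """Length of the maximal prefix of ``seq`` drawn from ``allowed``."""
    n = 0
    for c in seq:
        if c not in allowed:
            break
        n += 1
    return n


def _screen_terminal_5(body: str) -> bool:
    """True when the 5' telomere regex cannot creep past the telomere.

    The C-rich telomere match extends into the chromosome body only through
    an unbroken A/C run ending in a further ``CCAAAA``; reject bodies where
    that is possible.
    """
    run = _match_run(body, "AC")
    return "CCAAAA" not in body[: run + 6]


def _screen_terminal_3(body: str) -> bool:
    """3' mirror of :func:`_screen_terminal_5` for the G-rich telomere."""
    rev = body[::-1]
    run = _match_run(rev, "GT")
    return "TTGGGG" not in rev[: run + 6]


# ---------------------------------------------------------------------------
# Chromosome assembly
# ---------------------------------------------------------------------------


@dataclass
class _Chrom:
    """Assembly-time state for one somatic chromosome."""

    mac_id: str
    label: str
    n_mds: int
    pointers: list[str]  # K-1 pointer strings
    cores: list[list[str]]  # K mutable core parts (no pointers)
    at5: list[str]
    at3: list[str]
    x_left: Optional[list[str]]  # shared retained-CBS chars, or None
    x_right: Optional[list[str]]
    layout: list[tuple[int, str]]  # MIC order: (1-based ordinal, strand)
    motif5: bool = False
    motif3: bool = False
    # filled after part freeze
    mds_seqs: list[str] = field(default_factory=list)
    mac_core: str = ""

    def mds_string(self, k: int) -> str:
        """Full sequence of MDS ``k`` (1-based) in somatic orientation."""
        parts: list[str] = []
        if k == 1:
            if self.x_left:
                parts.append("".join(self.x_left))
            parts.append("".join(self.at5))
        else:
            parts.append(self.pointers[k - 2])
        parts.append("".join(self.cores[k - 1]))
        if k == self.n_mds:
            parts.append("".join(self.at3))
            if self.x_right:
                parts.append("".join(self.x_right))
        else:
            parts.append(self.pointers[k - 1])
        return "".join(parts)

    def freeze(self) -> None:
        self.mds_seqs = [self.mds_string(k) for k in range(1, self.n_mds + 1)]
        parts = [self.mds_seqs[0]]
        for k in range(1, self.n_mds):
            parts.append(self.mds_seqs[k][len(self.pointers[k - 1]) :])
        self.mac_core = "".join(parts)

    def mac_mds_intervals(self) -> list[tuple[int, int]]:
        """Trimmed-chromosome [start, end) of each MDS, overlapping on pointers."""
        out = []
        start = 0
        for k in range(self.n_mds):
            out.append((start, start + len(self.mds_seqs[k])))
            if k < self.n_mds - 1:
                start += len(self.mds_seqs[k]) - len(self.pointers[k])
        return out

    def terminal_parts_5(self) -> list[list[str]]:
        head = [self.x_left] if self.x_left else []
        return head + [self.at5, self.cores[0]]

    def terminal_parts_3(self) -> list[list[str]]:
        tail = [self.x_right] if self.x_right else []
        return [self.cores[-1], self.at3] + tail


def _make_layout(rng: np.random.Generator, label: str, k: int) -> list[tuple[int, str]]:
    """MIC-order layout of MDS ordinals with strands for one chromosome.

    Terminal MDSs always stay terminal and plus-stranded so that chromosome
    precursors keep well-defined boundaries on the germline contig.
    """
    order = list(range(1, k + 1))
    strands = {i: "+" for i in order}
    interior = list(range(2, k))  # 1-based ordinals strictly inside
    if label in ("insertion", "concurrent"):
        pairs = [j for j in interior if (j + 1) in interior]
        j = int(rng.choice(pairs))
        a, b = order.index(j), order.index(j + 1)
        order[a], order[b] = order[b], order[a]
        interior = [i for i in interior if i not in (j, j + 1)]
    if label in ("inversion", "concurrent"):
        inv = int(rng.choice(interior))
        strands[inv] = "-"
    return [(i, strands[i]) for i in order]


def _min_mds(label: str) -> int:
    return {"unscrambled": 1, "inversion": 3, "insertion": 4, "concurrent": 5}[label]


def _build_chromosome(
    rng: np.random.Generator,
    params: SimulationParams,
    mac_id: str,
    label: str,
    x_left: Optional[list[str]],
    x_right: Optional[list[str]],
) -> _Chrom:
    k = max(_randint(rng, params.mds_per_chromosome), _min_mds(label))
    pointers = []
    for _ in range(k - 1):
        plen = _randint(rng, params.pointer_len)
        pointers.append("".join(_at_seq(rng, plen, params.pointer_at_bias)))
    cores: list[list[str]] = []
    for i in range(k):
        total = _randint(rng, params.mds_len)
        trim = (len(pointers[i - 1]) if i > 0 else 0) + (
            len(pointers[i]) if i < k - 1 else 0
        )
        cores.append(_rand_seq(rng, max(total - trim, 2 * HARDEN), params.gc))

    # terminal AT-rich stretches, screened so the telomere regexes cannot
    # creep into the chromosome body
    for _ in range(200):
        at5 = _at_seq(rng, _randint(rng, params.subtelomeric_at_len), params.subtel_at_bias)
        body = ("".join(x_left) if x_left else "") + "".join(at5) + "".join(cores[0])
        if _screen_terminal_5(body):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not sample a clean 5' subtelomeric stretch")
    for _ in range(200):
        at3 = _at_seq(rng, _randint(rng, params.subtelomeric_at_len), params.subtel_at_bias)
        body = "".join(cores[-1]) + "".join(at3) + ("".join(x_right) if x_right else "")
        if _screen_terminal_3(body):
            break
    else:  # pragma: no cover
        raise RuntimeError("could not sample a clean 3' subtelomeric stretch")

    return _Chrom(
        mac_id=mac_id,
        label=label,
        n_mds=k,
        pointers=pointers,
        cores=cores,
        at5=at5,
        at3=at3,
        x_left=x_left,
        x_right=x_right,
        layout=_make_layout(rng, label, k),
    )


def _stamp(
    parts: list[list[str]],
    offset: int,
    motif: str,
    stamped: dict[int, set[int]],
    from_end: bool,
) -> bool:
    """Write ``motif`` at ``offset`` from a chromosome terminus.

    ``parts`` runs outward-in for the 5' end and inward-out for the 3' end
    (``from_end``). Positions inside a shared retained-CBS part may already
    carry the neighbour's stamp; in that case the whole stamp is skipped.
    Returns True when the stamp was written.
    """
    flat: list[tuple[list[str], int]] = []
    for part in parts:
        for i in range(len(part)):
            flat.append((part, i))
    if from_end:
        flat = flat[::-1]
    lo = offset
    hi = offset + len(motif)
    if hi > len(flat):
        return False
    targets = flat[lo:hi]
    if from_end:
        targets = targets[::-1]
        motif_chars = motif
    else:
        motif_chars = motif
    # conflict check against shared, already-stamped positions
    for part, i in targets:
        marks = stamped.get(id(part))
        if marks is not None and i in marks:
            return False
    for (part, i), c in zip(targets, motif_chars):
        part[i] = c
        stamped.setdefault(id(part), set()).add(i)
    return True


# ---------------------------------------------------------------------------
# Germline contig emission
# ---------------------------------------------------------------------------


class _MicBuilder:
    """Accumulates one germline contig plus a mutable-position mask."""

    def __init__(self, contig_id: str):
        self.id = contig_id
        self.chars: list[str] = []
        self.free: list[bool] = []

    @property
    def cursor(self) -> int:
        return len(self.chars)

    def emit(self, seq, free: bool) -> tuple[int, int]:
        start = self.cursor
        self.chars.extend(seq)
        self.free.extend([free] * (self.cursor - start))
        return start, self.cursor


def _emit_group(
    rng: np.random.Generator,
    params: SimulationParams,
    mic_id: str,
    chroms: list[_Chrom],
    junctions: list[dict],
    truth: SimulationTruth,
) -> _MicBuilder:
    """Lay one group of chromosome precursors onto a germline contig."""
    mb = _MicBuilder(mic_id)
    mb.emit(_rand_seq(rng, _randint(rng, params.mic_margin), params.gc), free=True)

    ends: list[tuple[int, int]] = []  # (n, m) per chromosome on this contig
    for ci, ch in enumerate(chroms):
        if ci > 0:
            jx = junctions[ci - 1]
            if jx["mode"] == "eliminated":
                gs, ge = mb.emit(
                    _rand_seq(rng, jx["gap"], params.gc), free=True
                )
                jx["gap_span"] = (gs, ge)
                n = ge
            elif jx["mode"] == "retained":
                n = mb.cursor - len(jx["x"])
            else:
                n = mb.cursor
        else:
            n = mb.cursor

        mac_ivs = ch.mac_mds_intervals()
        mds_records: dict[int, TruthMDS] = {}
        prev_entry: Optional[tuple[int, str]] = None
        spacer_after: dict[int, tuple[int, int]] = {}
        for t, (k, strand) in enumerate(ch.layout):
            seq = ch.mds_seqs[k - 1]
            if strand == "-":
                seq = revcomp(seq)
            skip = 0
            if k == 1 and ch.x_left is not None and t == 0 and ci > 0:
                skip = len(ch.x_left)  # shared CBS chars already on the contig
            s, e = mb.emit(seq[skip:], free=False)
            s -= skip
            mds_records[k] = TruthMDS(
                ordinal=k,
                mac_start=mac_ivs[k - 1][0],
                mac_end=mac_ivs[k - 1][1],
                mic_contig=mic_id,
                mic_start=s,
                mic_end=e,
                strand=strand,
            )
            if prev_entry is not None:
                pk, _ = prev_entry
                spacer_after[pk] = (spacer_after[pk][0], s)
            if t < len(ch.layout) - 1:
                length = _randint(rng, params.ies_len)
                ss, _ = mb.emit(_rand_seq(rng, length, params.gc), free=True)
                spacer_after[k] = (ss, ss)  # end fixed when next MDS lands
            prev_entry = (k, strand)

        ies_records = []
        pos = {k: t for t, (k, _) in enumerate(ch.layout)}
        for k in range(1, ch.n_mds):
            # an IES exists only where somatic neighbours are also germline
            # neighbours in order and orientation (colinear)
            if (
                pos[k + 1] == pos[k] + 1
                and ch.layout[pos[k]][1] == "+"
                and ch.layout[pos[k + 1]][1] == "+"
            ):
                span = spacer_after[ch.layout[pos[k]][0]]
                ies_records.append(
                    TruthIES(junction=k, mic_contig=mic_id, mic_start=span[0], mic_end=span[1])
                )
        pointer_records = []
        start = 0
        for k in range(1, ch.n_mds):
            start += len(ch.mds_seqs[k - 1]) - len(ch.pointers[k - 1])
            pointer_records.append(
                TruthPointer(
                    junction=k,
                    seq=ch.pointers[k - 1],
                    mac_start=start,
                    mac_end=start + len(ch.pointers[k - 1]),
                )
            )

        truth.chromosomes[ch.mac_id] = ChromosomeTruth(
            mac_id=ch.mac_id,
            kind="primary",
            label=ch.label,
            mds=sorted(mds_records.values(), key=lambda m: m.ordinal),
            pointers=pointer_records,
            ies=ies_records,
            telomere_len=params.telomere_len,
            motif_planted=(ch.motif5, ch.motif3),
        )
        ends.append((n, mb.cursor))

    mb.emit(_rand_seq(rng, _randint(rng, params.mic_margin), params.gc), free=True)

    for ci, jx in enumerate(junctions):
        m = ends[ci][1]
        n = ends[ci + 1][0]
        truth.cbs.append(
            TruthCBS(
                mic_contig=mic_id,
                upstream_mac_id=chroms[ci].mac_id,
                downstream_mac_id=chroms[ci + 1].mac_id,
                m=m,
                n=n,
                mode=jx["mode"],
                cbs_seq="",  # filled after hardening from the final sequence
            )
        )
    return mb


# ---------------------------------------------------------------------------
# Junction hardening
# ---------------------------------------------------------------------------


def _harden_block(
    rng: np.random.Generator,
    mic: _MicBuilder,
    mac_core: str,
    mac_start: int,
    mac_end: int,
    mic_start: int,
    mic_end: int,
    strand: str,
) -> None:
    """Force HARDEN mismatches at each extension direction of one block."""

    def fix(mic_pos: int, mac_char: str, complemented: bool) -> None:
        if not (0 <= mic_pos < mic.cursor) or not mic.free[mic_pos]:
            return
        want_diff = revcomp(mac_char) if complemented else mac_char
        if mic.chars[mic_pos] == want_diff:
            mic.chars[mic_pos] = str(rng.choice(_OTHER[want_diff]))

    for t in range(HARDEN):
        # rightward somatic extension
        if mac_end + t < len(mac_core):
            if strand == "+":
                fix(mic_end + t, mac_core[mac_end + t], False)
            else:
                fix(mic_start - 1 - t, mac_core[mac_end + t], True)
        # leftward somatic extension
        if mac_start - 1 - t >= 0:
            if strand == "+":
                fix(mic_start - 1 - t, mac_core[mac_start - 1 - t], False)
            else:
                fix(mic_end + t, mac_core[mac_start - 1 - t], True)


# ---------------------------------------------------------------------------
# Top-level generation
# ---------------------------------------------------------------------------


def simulate(params: SimulationParams) -> tuple[GenomeSet, GenomeSet, SimulationTruth]:
    """Generate a paired somatic/germline genome with full planted truth.

    Deterministic for a fixed seed. Somatic contigs carry telomeres; truth
    coordinates on the somatic side refer to the telomere-trimmed sequence.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    truth = SimulationTruth()

    # chromosome labels
    if params.label_plan is not None:
        labels = list(params.label_plan)
    else:
        labels = []
        for _ in range(params.n_chromosomes):
            if rng.random() < params.scramble_frac:
                kinds = list(params.scramble_props)
                probs = np.array([params.scramble_props[k] for k in kinds], dtype=float)
                labels.append(str(rng.choice(kinds, p=probs / probs.sum())))
            else:
                labels.append("unscrambled")

    # group chromosomes onto germline contigs and draw breakage junctions
    groups: list[list[int]] = []
    i = 0
    while i < params.n_chromosomes:
        g = _randint(rng, params.chromosomes_per_mic)
        groups.append(list(range(i, min(i + g, params.n_chromosomes))))
        i += g

    mic_builders: list[_MicBuilder] = []
    all_chroms: list[_Chrom] = []
    stamped: dict[int, set[int]] = {}
    mode_names = list(params.cbs_mode_probs)
    mode_probs = np.array([params.cbs_mode_probs[k] for k in mode_names], dtype=float)
    mode_probs = mode_probs / mode_probs.sum()

    for gi, group in enumerate(groups):
        mic_id = f"mic_{gi + 1:03d}"
        junctions: list[dict] = []
        for _ in range(len(group) - 1):
            mode = str(rng.choice(mode_names, p=mode_probs))
            jx: dict = {"mode": mode}
            if mode == "retained":
                d = _randint(rng, params.cbs_retained_len)
                x = _at_seq(rng, d, params.pointer_at_bias)
                if d >= 2:
                    x[0], x[-1] = "A", "T"  # the modal breakage-site signature
                jx["x"] = x
            elif mode == "eliminated":
                jx["gap"] = _randint(rng, params.cbs_eliminated_gap)
            junctions.append(jx)

        chroms: list[_Chrom] = []
        for pos, ci in enumerate(group):
            x_left = (
                junctions[pos - 1]["x"]
                if pos > 0 and junctions[pos - 1]["mode"] == "retained"
                else None
            )
            x_right = (
                junctions[pos]["x"]
                if pos < len(group) - 1 and junctions[pos]["mode"] == "retained"
                else None
            )
            chroms.append(
                _build_chromosome(
                    rng, params, f"mac_{ci + 1:04d}", labels[ci], x_left, x_right
                )
            )

        # terminal motif stamping (shared retained-CBS chars stamp at most once)
        if params.subtel_motif:
            for ch in chroms:
                ch.motif5 = _stamp(
                    ch.terminal_parts_5(),
                    params.subtel_motif_offset,
                    params.subtel_motif,
                    stamped,
                    from_end=False,
                )
                ch.motif3 = _stamp(
                    ch.terminal_parts_3(),
                    params.subtel_motif_offset,
                    revcomp(params.subtel_motif),
                    stamped,
                    from_end=True,
                )
        for ch in chroms:
            ch.freeze()
        mic_builders.append(_emit_group(rng, params, mic_id, chroms, junctions, truth))
        all_chroms.extend(chroms)

    mac_core_by_id = {ch.mac_id: ch.mac_core for ch in all_chroms}
    mic_by_id = {mb.id: mb for mb in mic_builders}

    _plant_alt_processing(rng, params, truth, all_chroms, mic_by_id, mac_core_by_id)

    # junction hardening over every planted block
    for chrom_truth in truth.chromosomes.values():
        core = mac_core_by_id[chrom_truth.mac_id]
        for mds in chrom_truth.mds:
            _harden_block(
                rng,
                mic_by_id[mds.mic_contig],
                core,
                mds.mac_start,
                mds.mac_end,
                mds.mic_start,
                mds.mic_end,
                mds.strand,
            )

    mic = GenomeSet(label="mic")
    for mb in mic_builders:
        mic.add(Contig(id=mb.id, seq="".join(mb.chars), source="MIC"))

    # breakage-site sequences come from the final germline sequence
    for cbs in truth.cbs:
        seq = mic[cbs.mic_contig].seq
        lo, hi = min(cbs.m, cbs.n), max(cbs.m, cbs.n)
        cbs.cbs_seq = seq[lo:hi]

    telo5 = TELO_UNIT_5 * params.telomere_repeats
    telo3 = TELO_UNIT_3 * params.telomere_repeats
    mac = GenomeSet(label="mac")
    for ch in all_chroms:
        mac.add(
            Contig(
                id=ch.mac_id,
                seq=telo5 + mac_core_by_id[ch.mac_id] + telo3,
                source="MAC",
                telomere_state="both",
            )
        )
    for mac_id, chrom_truth in truth.chromosomes.items():
        if chrom_truth.kind != "primary":
            mac.add(
                Contig(
                    id=mac_id,
                    seq=telo5 + mac_core_by_id[mac_id] + telo3,
                    source="MAC",
                    telomere_state="both",
                )
            )
    return mac, mic, truth


def _plant_alt_processing(
    rng: np.random.Generator,
    params: SimulationParams,
    truth: SimulationTruth,
    chroms: list[_Chrom],
    mic_by_id: dict[str, _MicBuilder],
    mac_core_by_id: dict[str, str],
) -> None:
    """Plant A-type (shared MDS) and B-type (MDS-in-IES) events."""
    n_a = round(params.altproc_a_rate * params.n_chromosomes)
    n_b = round(params.altproc_b_rate * params.n_chromosomes)

    donors = [
        c for c in chroms if truth.chromosomes[c.mac_id].label == "unscrambled" and c.n_mds >= 3
    ]
    rng.shuffle(donors)
    for idx in range(min(n_a, len(donors))):
        donor = donors[idx]
        dt = truth.chromosomes[donor.mac_id]
        mds = dt.mds[int(rng.integers(1, donor.n_mds - 1))]  # interior MDS
        alt_id = f"maca_{idx + 1:04d}"
        seg = "".join(mic_by_id[mds.mic_contig].chars[mds.mic_start : mds.mic_end])
        mac_core_by_id[alt_id] = seg
        truth.chromosomes[alt_id] = ChromosomeTruth(
            mac_id=alt_id,
            kind="alt_a",
            label="unscrambled",
            mds=[
                TruthMDS(
                    ordinal=1,
                    mac_start=0,
                    mac_end=len(seg),
                    mic_contig=mds.mic_contig,
                    mic_start=mds.mic_start,
                    mic_end=mds.mic_end,
                    strand="+",
                )
            ],
            pointers=[],
            ies=[],
            telomere_len=params.telomere_len,
        )
        truth.alt_events.append(
            TruthAltEvent(
                type="A",
                members=(alt_id, donor.mac_id),
                mic_contig=mds.mic_contig,
                mic_start=mds.mic_start,
                mic_end=mds.mic_end,
            )
        )

    margin = HARDEN + 2
    hosts = []
    for c in chroms:
        ct = truth.chromosomes[c.mac_id]
        if ct.label != "unscrambled":
            continue
        for ies in ct.ies:
            if ies.mic_end - ies.mic_start >= 60 + 2 * margin:
                hosts.append((c.mac_id, ies))
    rng.shuffle(hosts)
    for idx in range(min(n_b, len(hosts))):
        host_id, ies = hosts[idx]
        b_id = f"macb_{idx + 1:04d}"
        ies_len = ies.mic_end - ies.mic_start
        blen = int(rng.integers(60, min(120, ies_len - 2 * margin) + 1))
        off = int(rng.integers(margin, ies_len - margin - blen + 1))
        start = ies.mic_start + off
        seq = _rand_seq(rng, blen, params.gc)
        if params.subtel_motif and blen >= 2 * (params.subtel_motif_offset + 3):
            motif = params.subtel_motif
            o = params.subtel_motif_offset
            seq[o : o + len(motif)] = list(motif)
            seq[blen - o - len(motif) : blen - o] = list(revcomp(motif))
            planted = (True, True)
        else:
            planted = (False, False)
        mb = mic_by_id[ies.mic_contig]
        for i, c in enumerate(seq):
            mb.chars[start + i] = c
            mb.free[start + i] = False
        seg = "".join(seq)
        mac_core_by_id[b_id] = seg
        truth.chromosomes[b_id] = ChromosomeTruth(
            mac_id=b_id,
            kind="alt_b",
            label="unscrambled",
            mds=[
                TruthMDS(
                    ordinal=1,
                    mac_start=0,
                    mac_end=blen,
                    mic_contig=ies.mic_contig,
                    mic_start=start,
                    mic_end=start + blen,
                    strand="+",
                )
            ],
            pointers=[],
            ies=[],
            telomere_len=params.telomere_len,
            motif_planted=planted,
        )
        truth.alt_events.append(
            TruthAltEvent(
                type="B",
                members=(b_id, host_id),
                mic_contig=ies.mic_contig,
                mic_start=start,
                mic_end=start + blen,
            )
        )


# ---------------------------------------------------------------------------
# Assembly artifacts
# ---------------------------------------------------------------------------


def inject_artifacts(
    mac: GenomeSet, params: SimulationParams, truth: Optional[SimulationTruth] = None
) -> GenomeSet:
    """Degrade a simulated somatic assembly the way real ones arrive.

    With the configured rates, contigs lose one telomere (truncation),
    receive coverage values with a low-coverage subset below 1, and random
    telomere-free contaminant contigs are appended. Labels are recorded in
    the truth when one is supplied. Rates of zero leave sequences unchanged.
    """
    rng = np.random.default_rng(params.seed + 1)
    out = GenomeSet(label=mac.label)
    telo = params.telomere_len
    for contig in mac:
        seq = contig.seq
        state = contig.telomere_state
        truncated = bool(rng.random() < params.truncation_rate)
        if truncated:
            if rng.random() < 0.5:
                seq = seq[telo:]
                state = "three_prime"
            else:
                seq = seq[:-telo]
                state = "five_prime"
        low = bool(rng.random() < params.low_coverage_rate)
        coverage = float(rng.uniform(0.1, 0.9)) if low else float(rng.uniform(5, 60))
        out.add(
            Contig(
                id=contig.id,
                seq=seq,
                source="MAC",
                coverage=coverage,
                telomere_state=state,
            )
        )
        if truth is not None:
            truth.artifacts[contig.id] = {
                "truncated": truncated,
                "low_coverage": low,
                "contaminant": False,
                "coverage": coverage,
            }
    n_cont = int(rng.binomial(max(len(out), 1), params.contaminant_rate))
    for i in range(n_cont):
        cid = f"contam_{i + 1:03d}"
        coverage = float(rng.uniform(2, 20))
        out.add(
            Contig(
                id=cid,
                seq="".join(_rand_seq(rng, int(rng.integers(400, 2000)), params.gc)),
                source="MAC",
                coverage=coverage,
            )
        )
        if truth is not None:
            truth.artifacts[cid] = {
                "truncated": False,
                "low_coverage": False,
                "contaminant": True,
                "coverage": coverage,
            }
    return out


# ---------------------------------------------------------------------------
# Hand-built loci for focused tests
# ---------------------------------------------------------------------------


def make_locus(
    rng: np.random.Generator,
    mds_lens: list[int],
    pointer_seqs: list[str],
    ies_lens: list[int],
    gc: float = 0.5,
) -> tuple[str, str, dict]:
    """Build one unscrambled somatic core and its germline locus.

    Returns ``(mac_core, mic_locus, truth)`` where truth carries the planted
    MDS/IES intervals (germline coordinates) and pointer strings. Junctions
    are hardened exactly as in :func:`simulate`.
    """
    if len(pointer_seqs) != len(mds_lens) - 1 or len(ies_lens) != len(mds_lens) - 1:
        raise ValueError("need one pointer and one IES per junction")
    mds_seqs = []
    for i, total in enumerate(mds_lens):
        left = pointer_seqs[i - 1] if i > 0 else ""
        right = pointer_seqs[i] if i < len(pointer_seqs) else ""
        core = "".join(_rand_seq(rng, total - len(left) - len(right), gc))
        mds_seqs.append(left + core + right)
    mac_core = mds_seqs[0]
    for i in range(1, len(mds_seqs)):
        mac_core += mds_seqs[i][len(pointer_seqs[i - 1]) :]

    mb = _MicBuilder("mic_locus")
    mds_iv = []
    ies_iv = []
    for i, seq in enumerate(mds_seqs):
        mds_iv.append(mb.emit(seq, free=False))
        if i < len(ies_lens):
            ies_iv.append(mb.emit(_rand_seq(rng, ies_lens[i], gc), free=True))
    start = 0
    mac_iv = []
    for i, seq in enumerate(mds_seqs):
        mac_iv.append((start, start + len(seq)))
        if i < len(pointer_seqs):
            start += len(seq) - len(pointer_seqs[i])
    for (ms, me), (gs, ge) in zip(mac_iv, mds_iv):
        _harden_block(rng, mb, mac_core, ms, me, gs, ge, "+")
    return (
        mac_core,
        "".join(mb.chars),
        {"mds_mic": mds_iv, "mds_mac": mac_iv, "ies_mic": ies_iv, "pointers": pointer_seqs},
    )
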