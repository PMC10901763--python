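"""Homologous IESs: conserved excision sites, mobile-IES families, and
transposon (TBE) ORF grouping.

Conserved IES-excised sites are junction positions that map to the same
protein-alignment column across homologous genes; mobile IESs are
sequence-similar IESs at unrelated loci; telomere-bearing elements (TBEs)
are germline transposons recognized by three characteristic ORFs in
mutual proximity on one strand.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import Interval
from .similarity import global_identity

logger = logging.getLogger(__name__)


def map_site_to_column(pointer_cds_pos: int, gene_alignment_row: str) -> int:
    """Map a coding-sequence position to its protein-alignment column.

    The position is 0-based on the intron-free coding sequence; the residue
    index is ``pos // 3`` and the returned column is that residue's
    position in the gapped alignment row.
    """
    if pointer_cds_pos < 0:
        raise ValueError("coding-sequence position must be nonnegative")
    residue = pointer_cds_pos // 3
    seen = 0
    for col, c in enumerate(gene_alignment_row):
        if c == "-":
            continue
        if seen == residue:
            return col
        seen += 1
    raise ValueError(
        f"coding position {pointer_cds_pos} (residue {residue}) lies beyond "
        f"the {seen} residues of the alignment row"
    )


@dataclass
class ConservedSite:
    """An IES excision position shared across homologous genes."""

    ortholog_group_id: str
    members: list[tuple[str, str, int]]  # (gene id, IES id, alignment column)
    n_species: int
    within_species_only: bool


def find_conserved_sites(
    sites: dict[str, list[tuple[str, int]]],
    groups: dict[str, list[tuple[str, str]]],
    alignments: dict[str, dict[str, str]],
    tolerance: int = 0,
) -> list[ConservedSite]:
    """Cluster per-gene excision sites by shared alignment column.

    ``sites`` maps gene id -> [(IES id, CDS position)]; ``groups`` maps
    ortholog-group id -> [(species, gene id)]; ``alignments`` maps group id
    -> gene id -> aligned (gapped) protein row. Sites from alternative
    fragmentation must be excluded by the caller beforehand. Columns within
    ``tolerance`` of each other cluster together (chained).
    """
    out: list[ConservedSite] = []
    for group_id, members in sorted(groups.items()):
        aln = alignments.get(group_id, {})
        species_of = {gene: sp for sp, gene in members}
        mapped: list[tuple[int, str, str]] = []  # (column, gene, ies)
        for _, gene in members:
            if gene not in aln:
                if gene in sites and sites[gene]:
                    warnings.warn(f"gene {gene} missing from alignment of {group_id}")
                continue
            for ies_id, cds_pos in sites.get(gene, []):
                try:
                    col = map_site_to_column(cds_pos, aln[gene])
                except ValueError as exc:
                    warnings.warn(f"site {ies_id} of {gene} skipped: {exc}")
                    continue
                mapped.append((col, gene, ies_id))
        mapped.sort()
        cluster: list[tuple[int, str, str]] = []
        clusters: list[list[tuple[int, str, str]]] = []
        for entry in mapped:
            if cluster and entry[0] - cluster[-1][0] > tolerance:
                clusters.append(cluster)
                cluster = []
            cluster.append(entry)
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            genes = {g for _, g, _ in cl}
            if len(genes) < 2:
                continue
            species = {species_of[g] for g in genes}
            out.append(
                ConservedSite(
                    ortholog_group_id=group_id,
                    members=[(g, i, c) for c, g, i in cl],
                    n_species=len(species),
                    within_species_only=len(species) == 1,
                )
            )
    return out


@dataclass
class IESCluster:
    """A mobile-IES family: members similar to the representative."""

    representative: str
    members: list[str]  # excludes the representative
    identity_min: float
    length_ratio_min: float


def cluster_mobile_ies(
    ies_seqs: dict[str, str],
    identity_min: float = 0.9,
    length_ratio_min: float = 0.9,
) -> list[IESCluster]:
    """Greedy longest-first clustering of IES sequences.

    A sequence joins the first (longest, earliest) representative it
    matches at ``identity_min`` global identity (either strand, denominator
    = shorter length) with length ratio at least ``length_ratio_min``.
    Families of size >= 2 are reported. IESs with conserved excised sites
    should be removed by the caller first.
    """
    order = sorted(ies_seqs, key=lambda k: (-len(ies_seqs[k]), k))
    reps: list[str] = []
    members: dict[str, list[str]] = {}
    for sid in order:
        seq = ies_seqs[sid]
        home = None
        for rep in reps:
            rep_seq = ies_seqs[rep]
            ratio = min(len(seq), len(rep_seq)) / max(len(seq), len(rep_seq))
            if ratio < length_ratio_min:
                continue
            if global_identity(seq, rep_seq) >= identity_min:
                home = rep
                break
        if home is None:
            reps.append(sid)
            members[sid] = []
        else:
            members[home].append(sid)
    return [
        IESCluster(
            representative=rep,
            members=members[rep],
            identity_min=identity_min,
            length_ratio_min=length_ratio_min,
        )
        for rep in reps
        if members[rep]
    ]


@dataclass
class TBEAnnotation:
    """A grouped transposon element: complete with all three ORF classes."""

    mic_contig_id: str
    span: Interval
    status: str  # complete | partial
    orf_hits: list[tuple[str, Interval, str]] = field(default_factory=list)


ORF_CLASSES = ("orf1", "orf2", "orf3")


def group_tbe_orfs(
    hits: Iterable[tuple[str, int, int, str, str]],
    max_span_gap: int = 2000,
) -> list[TBEAnnotation]:
    """Chain transposon ORF hits into complete/partial elements.

    ``hits`` rows are (mic contig, start, end, strand, orf class).
    Overlapping hits of the same class and strand are merged first; chains
    of hits with consecutive gaps at most ``max_span_gap`` on one strand
    containing all three ORF classes are complete elements, any other
    non-empty chain is partial. Output is invariant under permutation of
    the input rows.
    """
    merged: dict[tuple[str, str, str], list[list[int]]] = {}
    for contig, start, end, strand, orf_class in hits:
        if orf_class not in ORF_CLASSES:
            raise ValueError(f"unknown ORF class {orf_class!r}")
        key = (contig, strand, orf_class)
        merged.setdefault(key, []).append([start, end])
    flat: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for (contig, strand, orf_class), ivs in merged.items():
        ivs.sort()
        fused: list[list[int]] = []
        for s, e in ivs:
            if fused and s <= fused[-1][1]:
                fused[-1][1] = max(fused[-1][1], e)
            else:
                fused.append([s, e])
        for s, e in fused:
            flat.setdefault((contig, strand), []).append((s, e, orf_class))

    out: list[TBEAnnotation] = []
    for (contig, strand), entries in sorted(flat.items()):
        entries.sort()
        chain: list[tuple[int, int, str]] = []

        def close() -> None:
            if not chain:
                return
            classes = {c for _, _, c in chain}
            out.append(
                TBEAnnotation(
                    mic_contig_id=contig,
                    span=Interval(contig, chain[0][0], max(e for _, e, _ in chain)),
                    status="complete" if classes == set(ORF_CLASSES) else "partial",
                    orf_hits=[
                        (c, Interval(contig, s, e), strand) for s, e, c in chain
                    ],
                )
            )

        for entry in entries:
            if chain and entry[0] - max(e for _, e, _ in chain) > max_span_gap:
                close()
                chain = []
            chain.append(entry)
        close()
    out.sort(key=lambda t: (t.mic_contig_id, t.span.start))
    return out
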