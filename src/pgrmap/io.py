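"""Readers and writers: FASTA, GFF3 (MIC-side), BED (MAC-side), TSV tables.

GFF3 features are written 1-based inclusive, BED features 0-based half-open;
all in-memory coordinates are 0-based half-open, so the only conversion is
``start + 1`` on the GFF3 start column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from Bio import SeqIO

from .model import IES, MDS, Contig, GenomeSet, Interval, Pointer, RearrangementMap

PathLike = Union[str, Path]


def read_fasta(path: PathLike, source: str = "MAC", label: str = "") -> GenomeSet:
    """Read a FASTA file into a :class:`GenomeSet`.

    Sequences are uppercased and U is mapped to T; characters outside
    A/C/G/T/N are rejected with the contig id and offset. A sequence line
    appearing before the first header is a parse error naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped and not stripped.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            if stripped.startswith(">"):
                break
    genome = GenomeSet(label=label or path.stem)
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        genome.add(Contig(id=rec.id, seq=seq, source=source))  # type: ignore[arg-type]
    return genome


def write_fasta(genome: Iterable[Contig], path: PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for contig in genome:
            fh.write(f">{contig.id}\n")
            for i in range(0, len(contig.seq), width):
                fh.write(contig.seq[i : i + width] + "\n")


def read_coverage_table(path: PathLike) -> dict[str, float]:
    """Read a two-column TSV ``contig_id<TAB>coverage`` (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0] in ("contig", "contig_id", "id"):
        df = df.iloc[1:]
    return {str(r[0]): float(r[1]) for r in df.itertuples(index=False)}


def write_coverage_table(coverage: dict[str, float], path: PathLike) -> None:
    pd.DataFrame(
        {"contig_id": list(coverage), "coverage": list(coverage.values())}
    ).to_csv(path, sep="\t", index=False)


def read_orientation_table(path: PathLike) -> dict[str, str]:
    """Read a two-column TSV ``contig_id<TAB>strand`` with strand in {+,-}."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0] in ("contig", "contig_id", "id"):
        df = df.iloc[1:]
    return {str(r[0]): str(r[1]) for r in df.itertuples(index=False)}


def write_orientation_table(orientation: dict[str, str], path: PathLike) -> None:
    pd.DataFrame(
        {"contig_id": list(orientation), "strand": list(orientation.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotation output: GFF3 on the MIC side, BED on the MAC side
# ---------------------------------------------------------------------------


def _gff3_escape(value: str) -> str:
    return value.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_annotations(
    maps: Iterable[RearrangementMap],
    mic_path: PathLike,
    mac_path: PathLike,
    mic: Optional[GenomeSet] = None,
    mac: Optional[GenomeSet] = None,
) -> None:
    """Write MIC-side MDS/IES features as GFF3 and MAC-side MDS/pointer BED.

    When genome sets are supplied, feature contig ids are validated against
    them. Files round-trip through :func:`read_annotations` to equal
    structures.
    """
    maps = list(maps)
    for m in maps:
        if mac is not None and m.mac_contig_id not in mac:
            raise ValueError(f"unknown MAC contig id {m.mac_contig_id!r}")
        if mic is not None:
            for mds in m.mds_list:
                if mds.mic.contig_id not in mic:
                    raise ValueError(f"unknown MIC contig id {mds.mic.contig_id!r}")

    with open(mic_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in maps:
            pointer_by_junction = {p.junction: p for p in m.pointers}
            for mds in m.mds_list:
                ptr = pointer_by_junction.get((mds.ordinal, mds.ordinal + 1))
                attrs = (
                    f"ID={_gff3_escape(m.mac_contig_id)}.MDS{mds.ordinal};"
                    f"mac_contig={_gff3_escape(m.mac_contig_id)};"
                    f"ordinal={mds.ordinal};"
                    f"pointer={_gff3_escape(ptr.seq) if ptr else '.'}"
                )
                fh.write(
                    "\t".join(
                        [
                            mds.mic.contig_id,
                            "pgrmap",
                            "MDS",
                            str(mds.mic.start + 1),
                            str(mds.mic.end),
                            ".",
                            mds.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
            for ies in m.ies_list:
                attrs = (
                    f"ID={_gff3_escape(m.mac_contig_id)}.IES{ies.between[0]};"
                    f"mac_contig={_gff3_escape(m.mac_contig_id)};"
                    f"between={ies.between[0]}-{ies.between[1]}"
                )
                fh.write(
                    "\t".join(
                        [
                            ies.mic.contig_id,
                            "pgrmap",
                            "IES",
                            str(ies.mic.start + 1),
                            str(ies.mic.end),
                            ".",
                            "+",
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )

    with open(mac_path, "w") as fh:
        fh.write('track name="pgrmap" description="MAC-side MDS and pointer features"\n')
        for m in maps:
            for mds in m.mds_list:
                fh.write(
                    "\t".join(
                        [
                            m.mac_contig_id,
                            str(mds.mac.start),
                            str(mds.mac.end),
                            f"MDS{mds.ordinal}",
                            "0",
                            mds.strand,
                        ]
                    )
                    + "\n"
                )
            for ptr in m.pointers:
                if ptr.mac_pos is None:
                    continue
                fh.write(
                    "\t".join(
                        [
                            m.mac_contig_id,
                            str(ptr.mac_pos.start),
                            str(ptr.mac_pos.end),
                            f"pointer_{ptr.junction[0]}_{ptr.junction[1]}:{ptr.seq}",
                            "0",
                            "+",
                        ]
                    )
                    + "\n"
                )


def _gff3_unescape(value: str) -> str:
    return value.replace("%3B", ";").replace("%3D", "=").replace("%2C", ",")


def read_annotations(mic_path: PathLike, mac_path: PathLike) -> list[RearrangementMap]:
    """Re-parse GFF3/BED annotation files written by :func:`write_annotations`.

    Reconstructs per-MAC-contig maps with MDS, IES and pointer features
    (coverage fraction and pass provenance are not serialized and are left
    at defaults).
    """
    maps: dict[str, RearrangementMap] = {}

    def get(mac_id: str) -> RearrangementMap:
        if mac_id not in maps:
            maps[mac_id] = RearrangementMap(mac_contig_id=mac_id)
        return maps[mac_id]

    pointer_seqs: dict[tuple[str, int], str] = {}
    with open(mic_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            contig, _, ftype, start, end, _, strand, _, attr_str = cols
            attrs = dict(kv.split("=", 1) for kv in attr_str.split(";"))
            mac_id = _gff3_unescape(attrs["mac_contig"])
            iv = Interval(contig, int(start) - 1, int(end))
            if ftype == "MDS":
                ordinal = int(attrs["ordinal"])
                get(mac_id).mds_list.append(
                    MDS(ordinal=ordinal, mac=None, mic=iv, strand=strand)  # type: ignore[arg-type]
                )
                get(mac_id).mic_contigs_used.add(contig)
                if attrs.get("pointer", ".") != ".":
                    pointer_seqs[(mac_id, ordinal)] = _gff3_unescape(attrs["pointer"])
            elif ftype == "IES":
                a, b = attrs["between"].split("-")
                get(mac_id).ies_list.append(IES(mic=iv, between=(int(a), int(b))))

    with open(mac_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            cols = line.rstrip("\n").split("\t")
            mac_id, start, end, name, _, strand = cols
            # the BED strand column carries the MDS germline orientation,
            # already held in MDS.strand; somatic intervals are plus-strand
            iv = Interval(mac_id, int(start), int(end))
            m = get(mac_id)
            if name.startswith("MDS"):
                ordinal = int(name[3:])
                for mds in m.mds_list:
                    if mds.ordinal == ordinal:
                        mds.mac = iv
            elif name.startswith("pointer_"):
                head, seq = name.split(":", 1)
                _, a, b = head.split("_")
                m.pointers.append(
                    Pointer(junction=(int(a), int(b)), seq=seq, mac_pos=iv)
                )

    # zero-length pointers have no BED record; restore them from the GFF3
    # pointer attribute (empty string) so structures round-trip
    for (mac_id, ordinal), seq in pointer_seqs.items():
        m = get(mac_id)
        if seq == "" and not any(p.junction == (ordinal, ordinal + 1) for p in m.pointers):
            m.pointers.append(Pointer(junction=(ordinal, ordinal + 1), seq="", mac_pos=None))

    for m in maps.values():
        m.mds_list.sort(key=lambda d: d.ordinal)
        m.pointers.sort(key=lambda p: p.junction)
        m.ies_list.sort(key=lambda i: i.between)
    return list(maps.values())


def write_truth_json(truth, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def read_truth_json(path: PathLike):
    from .simulate import SimulationTruth

    with open(path) as fh:
        return SimulationTruth.from_dict(json.load(fh))
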