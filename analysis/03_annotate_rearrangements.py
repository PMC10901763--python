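#!/usr/bin/env python
"""Annotate MDS/IES/pointer structure and validate against planted truth.

Runs the two-pass ungapped alignment (word 28 then word 12 over the gaps)
and the junction-first chaining on the cleaned somatic set, writes the
GFF3/BED annotation and per-contig summary, and scores exact-boundary IES
recovery, verbatim pointer recovery and excision identity against the
simulation truth.
"""

from pathlib import Path

import pandas as pd

from pgrmap import annotate_genomes, summarize_pointers, write_annotations
from pgrmap.evaluate import score_recovery
from pgrmap.io import read_fasta, read_truth_json

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main() -> None:
    mac = read_fasta(DATA / "mac.fasta", source="MAC")
    mic = read_fasta(DATA / "mic.fasta", source="MIC")
    truth = read_truth_json(DATA / "truth.json")

    res = annotate_genomes(mac, mic)
    maps = res.maps
    write_annotations(
        [m for m in maps.values() if m.n_mds],
        OUT / "mic_features.gff3",
        OUT / "mac_features.bed",
        mic=mic,
        mac=res.trimmed_mac,
    )

    rows = []
    for cid, rmap in sorted(maps.items()):
        rows.append(
            (
                cid,
                rmap.n_mds,
                len(rmap.ies_list),
                len(rmap.pointers),
                ",".join(str(len(p.seq)) for p in rmap.pointers) or ".",
                f"{rmap.mac_coverage_frac:.4f}",
            )
        )
    pd.DataFrame(
        rows,
        columns=["contig", "n_mds", "n_ies", "n_pointers", "pointer_lengths", "coverage_frac"],
    ).to_csv(OUT / "annotation_summary.tsv", sep="\t", index=False)

    stats = score_recovery(truth, maps, res.trimmed_mac, mic)
    pointers = summarize_pointers(list(maps.values()))
    print(f"contigs annotated: {sum(1 for m in maps.values() if m.n_mds)}")
    print(f"IESs: {stats.n_recovered_ies}/{stats.n_planted_ies} recovered with exact "
          f"boundaries ({100 * stats.ies_recall:.1f}%)")
    print(f"pointers: {stats.n_recovered_pointers} verbatim, "
          f"{stats.n_pointer_mismatches} mismatched")
    print(f"excision identity: {stats.n_junctions_checked - stats.n_excision_failures}"
          f"/{stats.n_junctions_checked} junctions clean")
    print(f"modal pointer length: {pointers['modal_length']} bp; "
          f"ANT-motif fraction {100 * pointers['ant_fraction']:.1f}%")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
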