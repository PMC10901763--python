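#!/usr/bin/env python
"""Clean the somatic assembly and screen the germline assembly.

Applies the telomere/coverage/length keep rules and redundancy removal to
the somatic contigs, then flags somatic carry-over in the germline set
(after spiking it with ten somatic cores to demonstrate the screen), and
compares every decision with the planted artifact labels.
"""

from pathlib import Path

import pandas as pd

from pgrmap import Contig, GenomeSet, clean_mac, dedup_contigs, screen_mic_contamination
from pgrmap.io import read_coverage_table, read_fasta, read_truth_json

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main() -> None:
    mac = read_fasta(DATA / "mac.fasta", source="MAC")
    mic = read_fasta(DATA / "mic.fasta", source="MIC")
    coverage = read_coverage_table(DATA / "coverage.tsv")
    truth = read_truth_json(DATA / "truth.json")

    report = clean_mac(mac, coverage)
    survivors = GenomeSet([mac[c] for c in report.kept])
    dedup = dedup_contigs(survivors)

    rows = []
    for contig in mac:
        art = truth.artifacts.get(contig.id, {})
        reason = report.discarded.get(contig.id) or dedup.discarded.get(contig.id) or "."
        rows.append(
            (
                contig.id,
                contig.telomere_state,
                f"{coverage.get(contig.id, float('nan')):.2f}",
                "discard" if reason != "." else "keep",
                reason,
                art.get("contaminant", False),
                art.get("low_coverage", False),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["contig", "telomeres", "coverage", "decision", "reason",
                 "planted_contaminant", "planted_low_coverage"],
    )
    df.to_csv(OUT / "mac_cleanup.tsv", sep="\t", index=False)

    # no planted contaminant or unsupported contig survives the rules
    kept = df[df.decision == "keep"]
    n_bad_kept = int((kept.planted_contaminant | kept.planted_low_coverage).sum())

    spiked = GenomeSet(label="mic_spiked")
    for contig in mic:
        spiked.add(contig)
    telo = 40
    spikes = [c for c in mac if c.id.startswith("mac_")][:10]
    for i, contig in enumerate(spikes):
        core = contig.seq[telo:-telo] if contig.telomere_state == "both" else contig.seq
        spiked.add(Contig(id=f"spike_{i}", seq=core, source="MIC"))
    trimmed = GenomeSet(
        [Contig(id=c.id, seq=c.seq[telo:-telo] if c.telomere_state == "both" else c.seq)
         for c in spikes]
    )
    screen = screen_mic_contamination(spiked, trimmed)
    pd.DataFrame(
        [(cid, "contaminant") for cid in sorted(screen.discarded)]
        + [(cid, "keep") for cid in sorted(screen.kept)],
        columns=["contig", "decision"],
    ).to_csv(OUT / "mic_screen.tsv", sep="\t", index=False)
    n_spikes_caught = sum(1 for c in screen.discarded if c.startswith("spike_"))

    print(f"somatic contigs kept: {len(kept)}/{len(mac)}")
    print(f"telomere classes (0/1/2): {report.class_counts[0]}/{report.class_counts[1]}/{report.class_counts[2]}")
    print(f"planted contaminant or unsupported contigs surviving cleanup: {n_bad_kept}")
    print(f"germline screen: {n_spikes_caught}/10 spiked somatic cores flagged, "
          f"{len(screen.discarded) - n_spikes_caught} genuine contigs lost")
    print(f"reports in {OUT}")


if __name__ == "__main__":
    main()
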