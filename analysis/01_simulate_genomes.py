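#!/usr/bin/env python
"""Generate the study's reference genome pair.

Simulates 50 somatic nanochromosomes and their germline precursors under
the default conditions (seed 42), injects realistic assembly artifacts
(truncated, low-coverage and contaminant contigs), and writes the FASTA
files, the coverage and gene-orientation tables, and the planted truth
that later steps validate against.
"""

from pathlib import Path

from pgrmap import SimulationParams, inject_artifacts, simulate
from pgrmap.io import (
    write_coverage_table,
    write_fasta,
    write_orientation_table,
    write_truth_json,
)

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = SimulationParams(n_chromosomes=50, seed=42)
    mac, mic, truth = simulate(params)
    n_clean = len(mac)
    mac = inject_artifacts(mac, params, truth)

    write_fasta(mac, OUT / "mac.fasta")
    write_fasta(mic, OUT / "mic.fasta")
    write_truth_json(truth, OUT / "truth.json")
    write_coverage_table(
        {cid: art["coverage"] for cid, art in truth.artifacts.items()},
        OUT / "coverage.tsv",
    )
    write_orientation_table({c.id: "+" for c in mac}, OUT / "orientation.tsv")

    n_scrambled = sum(
        1
        for c in truth.chromosomes.values()
        if c.kind == "primary" and c.label != "unscrambled"
    )
    n_trunc = sum(1 for a in truth.artifacts.values() if a["truncated"])
    n_cont = sum(1 for a in truth.artifacts.values() if a["contaminant"])
    print(f"somatic contigs: {len(mac)} ({n_clean} genuine, {n_cont} contaminants)")
    print(f"germline contigs: {len(mic)}")
    print(f"scrambled chromosomes planted: {n_scrambled}/50")
    print(f"breakage junctions planted: {len(truth.cbs)}")
    print(f"alternative-processing events planted: {len(truth.alt_events)}")
    print(f"artifact contigs: {n_trunc} truncated, {n_cont} contaminant")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
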