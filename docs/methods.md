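# Methods

## The annotation model

The pipeline treats somatic (MAC) nanochromosomes as concatenations of
macronucleus-destined sequences (MDSs) found, possibly reordered or
inverted, on germline (MIC) contigs. Two adjacent MDSs overlap on the
somatic side by their pointer — a short repeat present at both flanks of
the intervening germline IES and once at the somatic junction. All
internal coordinates are 0-based half-open; GFF3 (1-based inclusive) and
BED conversions happen only at serialization.

### Two-pass ungapped alignment

Somatic contigs are telomere-trimmed and aligned to the germline with an
in-house seed-and-extend aligner. Exact word seeds mark diagonals; each
seeded diagonal is scanned once, emitting maximal ungapped segments
delimited by (a) the running score reaching zero, (b) an X-drop of more
than 10 score units below the running maximum, or (c) an N or sequence
end. A segment must contain a full seed word and pass the Karlin–Altschul
E-value cutoff (1e−5), with lambda solved numerically for the scoring
pair at uniform base frequencies and K taken from the published ungapped
constants (0.621 for +1/−2, 0.711 for +1/−3). The search space is the
product of the trimmed sequence lengths. Pass 1 uses word 28 with
+1/−2; pass 2 uses word 12 with +1/−3 and queries only the maximal
somatic intervals left uncovered by pass 1, padded by the maximum pointer
length (50 bp), against the germline contigs hit by the flanking pass-1
HSPs. Scoring emulates the regimes of the two standard tools this
replaces; only word size, ungappedness and the E-value cutoff are taken
as fixed. Because each diagonal is scanned canonically, the emitted HSP
set is reproducible by an exhaustive, seed-free diagonal scan — the
equivalence is asserted in the tests over hundreds of random pairs.

### Junction-first chaining

Per somatic contig, HSP pairs whose somatic intervals overlap by
0..50 bp and whose germline footprints are disjoint realize the
MDS–pointer–MDS structure and validate both members. Validated partners
are temporarily connected (they share the junction pointer) into units;
any unit or HSP whose somatic span is contained in a stronger surviving
span is discarded as nested (total score decides, then span length, then
the earlier germline coordinate); the merges are then undone and
survivors are renumbered along the contig. Pointers are the somatic
overlaps of consecutive survivors (zero-length pointers allowed; somatic
gaps yield no pointer and stay uncovered). An IES is recorded only where
consecutive MDSs are germline-colinear — same contig, same strand,
germline order matching somatic order — with a gap of at least 10 bp
(`min_ies`); colinear gaps below that threshold are treated as alignment
fray and produce a junction without an IES. Junctions across germline
contigs are allowed but never produce an IES. Multi-mapping ties break
deterministically by score, length, then germline coordinate.

### Scrambling, density, alternative processing

The majority strand of a chromosome's MDSs defines its reference
orientation. Opposite-strand MDSs are inversion evidence. After
orientation normalization the germline start coordinates of the MDSs
(all of them — an inverted MDS occupies a position too) must increase
within each germline-contig run; violations, and any second-contig MDS
interrupting a colinear run, are insertion evidence. Both kinds anywhere
on the contig give "concurrent"; we do not require them at distinct
junctions. Single-MDS chromosomes are unscrambled by definition. MPKA is
the MDS count per somatic kilobase of the trimmed contig.

A-type alternative processing is an overlap of at least 30 bp between
germline MDS footprints of two different somatic contigs; B-type is one
contig's MDS contained (≥ 90%) in another contig's IES, consulting only
IESs of unscrambled chromosomes. Both thresholds are configurable; the
source analysis states none. One exclusion matters: a retained breakage
site duplicates its terminal bases into both neighbouring chromosomes,
so two subtelomeric terminal MDSs that overlap in a staggered fashion
while their chromosomes extend in opposite directions are breakage
retention, not alternative processing, and are skipped. Containment
overlaps are never excluded.

### Breakage sites

A chromosome's germline footprint contributes a left endpoint n (where
it starts) and a right endpoint m (where it ends) when the corresponding
somatic terminal MDS reaches within 5 bp (`subtel_window`) of the trimmed
contig end. Endpoints of different chromosomes extending in opposite
directions pair when |n − m| ≤ 100 (`max_gap`). delta = n − m; negative
deltas are retained sites (sequence `MIC[n, m)` duplicated into both
products), positive are eliminated spacers, zero is blunt — the blunt
class is ours; the source dichotomy covers only the two signs. 30 bp
flanks are reported and flagged when truncated by a contig edge.

### Nucleotide bias

Two-telomere, telomere-trimmed, orientation-normalized contigs are cut
into 250 near-equal bins (the first `L mod 250` bins take one extra
base) and per-bin base frequencies averaged across contigs. Terminal
AT-content uses the terminal 100 bp with a 10 bp window and step 1; the
source describes both 50/10/2 and 100/10/1 variants, and all three
values are parameters here with the latter as default. Position-frequency
matrices anchor sequences at either end and normalize each column by the
number of sequences covering it.

### IES homology

An excision site given as a 0-based coding-sequence position maps to
residue `pos // 3` and thence to that residue's column in the gapped
protein-alignment row. Sites of at least two genes in one ortholog group
sharing a column (tolerance 0 by default — "the same position") form a
conserved site, flagged `within_species_only` when all members come from
one species; sites involved in alternative processing must be excluded
by the caller. The junction coordinate used is the pointer's left edge
on the coding sequence; the source does not fix this choice. Mobile IES
families come from greedy longest-first clustering under global identity
≥ 0.9 (denominator: the shorter sequence, either strand, computed as an
infix edit-distance alignment via edlib) with length ratio ≥ 0.9;
families of one are not reported. TBE transposons are chains of merged
ORF hits on one strand with consecutive gaps ≤ 2 kb; a chain carrying
all three ORF classes is complete, any other is partial. "Correct
orientation" is interpreted as one-strand co-occurrence; no class order
is imposed.

## The simulator

The generator builds the germline first and derives the somatic
chromosomes from it, so the central invariant — stitching the truth MDS
copies (one pointer copy per junction, inverted copies
reverse-complemented) reproduces the telomere-trimmed somatic sequence
byte-exactly — holds by construction and is verified, not assumed.

Defaults, chosen once as the study conditions: 50 chromosomes; 3–8 MDSs
of 200–800 bp; IESs 30–300 bp (floor 20); pointers 2–15 bp with A/T
probability 0.8; background GC 0.5; telomeres of five C4A4 / G4T4 units
(40 bp); 20% scrambled chromosomes split 60/25/15 between inversion,
insertion and concurrent; breakage junctions 70% retained (2–30 bp,
flavored to start with A and end with T), 20% eliminated (1–50 bp
spacer), 10% blunt; 3–6 chromosome precursors per germline contig with
50–200 bp of flanking germline margin; AT-rich subtelomeric stretches of
8–30 bp at bias 0.85 carrying a fixed GAA motif at offset 8 from each
trimmed end (reverse-complemented at the 3' end); alternative processing
at rate 0.1 per type — an A-type event re-uses a donor's interior MDS
region as a new single-MDS chromosome, a B-type event writes a new 60–120
bp chromosome into the interior of a host IES; artifact injection then
truncates one telomere from 10% of contigs, assigns coverage with a 5%
low-coverage subset below 1, and appends ~10% telomere-free contaminant
contigs. Scrambling operates on interior MDSs only, so precursor
boundaries stay well-defined; scrambled chromosomes therefore need at
least 3 (inversion), 4 (insertion) or 5 (concurrent) MDSs and the MDS
count is raised to that minimum, which also gives scrambled chromosomes
slightly higher MDS density — mirroring the empirical pattern that
scrambled nanochromosomes carry more MDSs. An explicit `label_plan`
can replace the random scrambling draw when exact class counts are
needed.

Three deliberate constructions make the planted truth the unique correct
annotation:

* **Junction hardening.** Ungapped X-drop extension past a true boundary
  succeeds whenever a short run of chance matches follows; with random
  flanks roughly a quarter of junction ends would overshoot and no exact
  recovery target could be met. The generator therefore samples the six
  germline bases flanking every planted alignment block to mismatch the
  corresponding somatic continuation (six mismatches at the weakest
  penalty exceed the X-drop), which provably pins every HSP end to its
  planted boundary. This is the strong form of screening an IES against
  beginning or ending with its pointer. The somatic-side extensions at
  chromosome termini are pinned by the sequence ends themselves.
* **Telomere screens.** The subtelomeric stretches and retained-site
  sequences are rejection-sampled so that neither telomere regex can
  extend past the telomere into the chromosome body (no `CCAAAA`
  reachable through an unbroken A/C run at the 5' end, mirrored at the
  3' end); otherwise trimming would occasionally eat subtelomeric bases
  and break byte-exact reconstruction.
* **Single emission of shared sequence.** A retained breakage site is
  emitted once on the germline contig and referenced by both
  neighbouring precursors, so "the same d-mer at both termini and at the
  germline boundary" is structural. The terminal-motif stamp skips a
  junction whose shared bases were already stamped from the other side
  (possible for retained sites of 9–21 bp); the truth records which
  chromosome ends carry the motif.

What the simulator does **not** emulate — and hence what green tests do
not show about real data: repeats beyond the planted structures (no
paralogy, no transposon sequence models, no low-complexity expansions
other than the AT stretches), sequencing error and assembly
fragmentation beyond whole-telomere truncation, polyploid coverage
structure, scrambling of terminal MDSs, IESs between non-colinear MDSs,
and multi-gene nanochromosomes (one plus-strand gene per chromosome is
assumed, so orientation normalization is exercised only through
constructed minus-strand cases in the tests). Recovery rates on real
assemblies will be bounded by repeat resolution and assembly quality,
not by the chaining logic validated here.

## Numerical and engineering choices

* Degenerate inputs: empty HSP lists give empty maps; single-MDS maps are
  unscrambled; zero-length pointers are recorded with empty sequence;
  PFMs reject empty input; composition profiles skip contigs shorter
  than the bin count with a warning.
* Tie-breaks are deterministic everywhere (score, then length, then
  lexicographic ids / germline coordinates); duplicate-span units log a
  warning and are dropped.
* Cleanup rule order is coverage → telomere/evidence → length; the order
  affects only the recorded reason, never the kept set, and re-running
  cleanup on its own output is a fixed point.
* Greedy dedup and mobile-IES clustering are validated against
  brute-force replays of the same pairwise predicate (full matrix greedy
  for dedup; transitive closure for families — the two coincide on the
  well-separated families the tests plant).
* Problem sizes in the tests and the acceptance script (50–100
  chromosomes, pairs ≤ 500 bp for the exhaustive aligner oracle, sets of
  20–50 sequences for the clustering oracles) were chosen so each
  validation completes in seconds while exercising every code path;
  statistics at these sizes are exact-match counts, not asymptotics.
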