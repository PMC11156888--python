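# Methods

## Scope and model

`dsbtag` implements the computational side of a dsODN tag-integration assay
for genome-wide nomination of Cas9 cleavage sites. The biological model it
assumes: a blunt double-stranded oligodeoxynucleotide (dsODN, 34/39/46 nt)
is captured by NHEJ into Cas9-induced double-strand breaks; genomic DNA is
sheared (500–700 bp), adaptor-ligated with an 8-nt random molecular index
(UMI), sample-barcoded during PCR, and sequenced as 150-bp paired-end reads.
Each tag-bearing read therefore contains a genomic flank running into one
terminus of the tag; the first genomic base adjacent to the tag marks the
break junction. A blunt integration yields two junctions one base apart
(positions `c-1` and `c` for a cut between `c-1` and `c`).

The package's stages, in order: sample demultiplexing by 5' barcode
(unique best barcode within a Hamming cap, default 1; ties and N bases are
conservative failures), UMI extraction, tag detection, junction-fragment
alignment, junction consolidation into cleavage sites, protospacer+PAM
mismatch scanning, replicate confidence classification, and the off-index
summary. A separate module quantifies dsODN insertion outcomes in targeted
amplicon pools. All stages run on simulated data with planted ground truth.

## Tag detection and junction extraction

Tags are located by their junction-proximal anchors — the first and last
`anchor_length` bases (default 12) of the oligo, searched in both
orientations anywhere in either mate at up to `max_anchor_mm` (default 1)
mismatches. Twelve bases give ~2·10⁻⁶ per-position false-anchor probability
at one allowed mismatch, adequate specificity for the 10⁵-bp test genomes
the built-in aligner targets; production-scale genomes should raise
`anchor_length` or rely on the unique-alignment filter downstream, which
already removes spurious junctions. Scanning is positionally unanchored
(the tag may sit anywhere in the read); a primer-anchored variant would be
stricter but assumes a fixed library geometry we do not require.

Reads are normalised to tag-forward frame before splitting, so the side
label (`left_of_tag` / `right_of_tag`) is invariant to tag orientation. The
longer flank outside the tag span becomes the junction fragment; fragments
under `min_fragment_length` (default 25 — short enough to keep junction
yield high, long enough to map uniquely in a 100-kb genome) are discarded.
Two disjoint tag spans in one read are treated as a tandem (double)
integration: the read is trimmed at the outermost junction, the tag-to-tag
interior discarded, and the fragment flagged.

Full-length integration means the entire oligo (either orientation) occurs
in the read within `max_mm` (default 1, tolerating one sequencing error).
Note the tolerance makes truncations of fewer than ~5 terminal bases
indistinguishable from an error-bearing complete oligo; the simulator
therefore truncates by at least 5 when it needs an unambiguous non-full
molecule, and by 3–10 in discovery libraries where the flag is incidental.

## Alignment

The built-in aligner is exact-k-mer seed (k = 20) plus ungapped extension,
with Hamming mismatches counted over the whole fragment (cap default 3,
matching ~1% error over 150-bp reads with margin). Every fragment k-mer is
tried as a seed on both strands; if no seed matches at all (possible when
errors are spaced so every k-mer carries one), a vectorised full-genome
scan takes over, so placements always equal an exhaustive Hamming scan.
Ties at the best mismatch count across distinct loci are declared ambiguous
and the fragment is discarded — never randomly placed — because a random
placement could fabricate an off-target locus. The aligner is deliberately
ungapped and in-memory: it exists to place junction fragments on synthetic
test genomes. For real genomes, alignments from a production mapper are
ingested from SAM using the read-name convention `readid|UMI|side`.

Coordinates are 0-based half-open internally; BED output is 0-based
half-open; human-readable TSVs are 1-based.

## Site calling

Junctions cluster by single-linkage within `merge_window` (default 10)
bases on one contig — wide enough to join the two sides of a blunt
integration, staggered-end joins and small junction scatter, narrow enough
not to fuse sites (planted sites sit ≥1 kb apart). The site position is the
read-weighted modal junction (leftmost on ties); molecules are counted as
distinct `(UMI, junction position, side)` triples, a deterministic exact
dedup with no Hamming-1 UMI merging (error-merging is a possible
extension; at 0.5% per-base error it would change counts by a few percent).

Each site's neighbourhood (`flank` = 25 bp, covering junction scatter plus
the 23-bp frame) is scanned on both strands for the best protospacer+PAM
frame. The mismatch budget is a single combined Hamming count over the
concatenated protospacer and PAM, with pattern-N positions free; the
default cap is 7, configurable (6 for comparisons with pipelines that use a
six-mismatch rule). Ties break by (1) distance between the frame's implied
blunt-cut position — `cut_offset` = 3 bases 5' of the PAM, standard SpCas9
geometry, used only here and in simulation — and the site, (2) + strand,
(3) leftmost. Sites with no qualifying frame are dropped and counted.
Matching is strictly ungapped: DNA/RNA-bulge off-targets are out of scope.

Calls with read support below 10 carry `low_read_flag` rather than being
removed, reflecting that such sites reproduce variably but are not
artifacts. The on-target call is the zero-mismatch site at the configured
cut coordinate (±25 bp), or the best-supported zero-mismatch site when no
coordinate is given. Confidence across a biological replicate group uses
single-linkage locus grouping within `locus_tolerance` (10 bp, same contig
and target strand): detection in ≥ `min_replicates` (default 2) replicates
is high-confidence, singletons are retained as low-confidence. The
off-index is the ratio of summed off-target read counts to on-target read
counts; it is undefined (an error, not zero) without exactly one on-target
call.

## Amplicon insertion-outcome classification

For a 200–280 bp amplicon spanning a target site, reads carrying the target
anchor (≥15 bp, either strand, ≤1 mismatch) are partitioned by tag presence
and read-length excess over the reference amplicon. Tag presence means any
≥10-bp contiguous block of the oligo within 1 mismatch — the in-silico
analogue of grep-based extraction, made tolerant of truncated captures.
Inclusive length-excess windows, keyed by tag length: 34-nt tag — single
29–49, double 64–84; 39-nt tag — single 34–54, double 69–89. Windows for
other tags are configuration. Insertion frequency = (single + double) /
total target reads; edited-but-out-of-window reads form an explicit
`edited_other` class so the partition is exhaustive, and they never count
toward insertion frequency. The full-length rate divides complete-oligo
reads by all insertion-bearing reads, truncated ones included. Paired 150-bp
mates are merged by best exact-overlap (≥20 bp, ≤2 mismatches) before
length measurement; length-only classification does not distinguish
head-to-tail from inverted double insertions.

## Simulator

The simulator is the package's source of ground truth. It plants, in an
i.i.d. uniform genome (default 100 kb), one exact on-target frame and a
panel of off-target frames with exact prescribed mismatch counts
(substitutions drawn without replacement from protospacer positions; the
PAM stays pattern-valid), all ≥1 kb apart, on random strands. Default study
conditions: 20 off-targets cycling mismatch counts 1–7 with molecule counts
`max(12, 48 − 5·mm)` (weaker cleavage at more-diverged sites, read support
straddling the low-read threshold), 150 on-target molecules, fragment
lengths U[500, 700], 150-bp paired reads, 8-nt UMIs, 0.5% uniform
substitution error, 5% truncated and 5% tandem integrations (tandem capture
is capped at 10%, the upper end of its observed range), 50% untagged
background fragments, 1–3 PCR-duplicate reads per molecule sharing one UMI.
Each molecule covers one genomic flank of its junction (left → junction
`c−1`, right → `c`) with 60–110 covered bases, so the junction a read should
report is part of its truth record.

What the simulator does not model: chromatin effects on cleavage, junction
microhomology or resection, indel repair at untagged breaks, PCR chimeras,
quality-score-correlated errors, and gapped off-target geometries. Passing
tests therefore demonstrate the correctness of the computational pipeline
under its stated read model, not performance on real libraries.

Amplicon pools draw read classes from configured fractions (defaults used
in the checks: 60/25/10/5% unedited/single/double/other, 70% of single- and
double-insert reads full-length); non-full insertions truncate by ≥5 bases
(see above), and with the default windows a double insertion cannot shed 10
bases and stay in-window, so non-full doubles are emitted full-length and
the realised per-read truth is what tests compare against. `edited_other`
reads carry 10–31-bp tag remnants, below the single window.

All randomness flows from one integer seed through numpy's PCG64; fixed
seeds reproduce byte-identical FASTQ/FASTA output, and the pipeline itself
is RNG-free, so reruns are byte-identical end to end.

## Verification sizes

The shipped checks use: 500 random (window, guide) instances against the
exhaustive frame-scan oracle; 200 fragments (including planted repeats for
the ambiguity verdict) against the full-genome Hamming oracle on a 100-kb
genome; a 21-site discovery run (~3,000 read pairs) for recovery, off-index
and dedup; three simulated replicates for the confidence rule; and
2,000-read amplicon pools. These sizes keep the whole suite under a couple
of minutes on one CPU while leaving every rule's decision boundary
(mismatch 7 vs 8, read support 9 vs 10, window edges 29/49/64/84 and
34/54/69/89) explicitly exercised.
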