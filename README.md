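# dsbtag

Discovery of CRISPR-Cas9 off-target cleavage sites from dsODN-tagged
double-strand-break sequencing libraries.

In tag-integration assays, a short blunt double-stranded
oligodeoxynucleotide (dsODN) is captured by NHEJ into Cas9-induced
double-strand breaks; sequencing the tag–genome junctions reveals where the
nuclease actually cut, genome-wide and in cells. `dsbtag` implements the
full computational workflow for such libraries, for researchers profiling
sgRNA specificity (including therapeutic guide selection):

- **seqio** — paired-end FASTQ I/O, 5'-barcode demultiplexing, extraction
  of the 8-nt UMI introduced by the ligated adaptor;
- **tagscan** — dsODN detection in reads (either orientation, anywhere),
  full-length vs truncated integration assessment, tandem-insertion
  handling, and splitting of reads into junction-flanking genomic fragments;
- **alignment** — a built-in exact-seed/ungapped-extension aligner for
  synthetic test genomes, plus SAM ingestion for externally aligned runs;
- **sitecall** — junction consolidation into cleavage sites with exact
  `(UMI, position, side)` molecule deduplication, off-target nomination by
  protospacer+PAM scanning with a combined mismatch budget of
  $d_H(\text{site}, \text{protospacer{+}PAM}) \le 7$ (pattern-N positions
  free), replicate confidence classes (high ⇔ detected in ≥2 biological
  replicates; read support <10 flagged), and the off-index
  $\mathrm{OI} = \sum_i r_i^{\text{off}} / r^{\text{on}}$;
- **ampliconq** — dsODN insertion-rate quantification in targeted amplicon
  pools via read-length-excess windows (34-nt tag: single 29–49, double
  64–84; 39-nt tag: single 34–54, double 69–89; inclusive), with insertion
  frequency = (single+double)/total and full-length rate =
  complete-oligo / any-insertion reads;
- **simulate** — a fully seeded simulator that plants an on-target and a
  panel of off-target frames with exact mismatch counts in a random genome
  and emits barcoded, UMI-tagged, error-bearing read pairs with per-read
  ground truth, so every stage is testable without external data.

See `docs/methods.md` for the model, parameter defaults and limitations
(matching is ungapped: bulge/gap off-targets are out of scope).

## Worked example

Simulate a two-replicate run (one on-target plus four off-targets) and
execute the whole pipeline from one manifest:

```yaml
# manifest.yaml
reference: out/simdata/genome.fa
output_dir: out
guides:
  - name: g1
    protospacer: GACCCCCTCCACCCCGCCTC
samples:
  - id: rep1
    barcode: ACGTCA
    r1: out/simdata/reads_R1.fastq.gz
    r2: out/simdata/reads_R2.fastq.gz
    guide: g1
    dsodn: dsodn_39
    replicate_group: grpA
  - id: rep2
    barcode: TTGCAG
    r1: out/simdata/reads_R1.fastq.gz
    r2: out/simdata/reads_R2.fastq.gz
    guide: g1
    dsodn: dsodn_39
    replicate_group: grpA
simulate:
  guide: g1
  dsodn: dsodn_39
  n_offtargets: 4
  genome_length: 40000
  on_target_molecules: 40
```

```sh
$ dsbtag run -m manifest.yaml --seed 3
rep1    sites=6    calls=5    off_index=3.8026
rep2    sites=7    calls=5    off_index=3.4691
```

Each sample yields 5 calls: the on-target plus the four planted off-target
loci (spurious junction clusters with no frame within the 7-mismatch
budget are dropped and counted in the log). The off-index 3.8026 is rep1's
289 off-target reads divided by its 76 on-target reads — close to the
simulator's planted molecule ratio. The mismatch-annotated site table
(`out/rep1/site_table.txt`) shows matching bases as dots and off-target
mismatches as letters, sorted by read support, with read counts and
replicate confidence alongside:

```
GACCCCCTCCACCCCGCCTCNGG    (on-target reference)
..................C....    chr_sim:14398 -  mm=1 reads=93 high
.......................    chr_sim:8012 -  mm=0 reads=76 high
..A..G.............A...    chr_sim:26564 -  mm=3 reads=71 high
...G......G............    chr_sim:21346 -  mm=2 reads=70 high
.C.....G.....G.A.......    chr_sim:32220 +  mm=4 reads=55 high
```

All five loci were detected in both replicates (`out/confidence.tsv`), so
all grade high-confidence. Machine-readable outputs: per-sample
`calls.tsv`, `sites.bed`, `off_index.tsv`, and per-group `confidence.tsv`.
Other subcommands: `dsbtag simulate` (materialise synthetic inputs),
`dsbtag demux`, `dsbtag amplicon` (insertion-rate summaries), and
`dsbtag report` (re-render site tables as text/HTML/TSV).

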