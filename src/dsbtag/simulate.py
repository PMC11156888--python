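"""Synthetic data with ground truth for every pipeline stage.

The simulator emulates a tag-enrichment discovery library: a random genome
carries one on-target protospacer+PAM and a panel of planted off-target
frames with exact mismatch counts; Cas9-cut molecules receive a blunt dsODN
integration at the cut site (random orientation, occasional truncation or
tandem double insertion), are sheared to 500-700 bp fragments,
adaptor-ligated with an 8-nt UMI, sample-barcoded, and sequenced as 150-bp
paired-end reads with uniform substitution errors. PCR duplicates are
emulated by emitting several reads per molecule under one UMI. Untagged
background fragments exercise tag-detection specificity.

Everything is driven by one integer seed through a PCG64 generator, so a
fixed seed reproduces identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._dna import revcomp
from .seqio import ReadPair
from .sitecall import GuideSpec
from .tagscan import DsODNSpec

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    others = [b for b in "ACGT" if b != base]
    return others[rng.integers(0, 3)]


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = _mutate_base(rng, arr[i])
    return "".join(arr)


@dataclass
class PlantedSite:
    """Truth record for one planted cleavage site."""

    site_id: str
    seq_name: str
    frame_start: int
    strand: str
    planted_seq: str  # protospacer+PAM frame in guide orientation
    mismatch_count: int
    mismatch_positions: list[int]
    cut_pos: int  # tag inserted between cut_pos-1 and cut_pos
    is_on_target: bool
    molecules: int


@dataclass
class ReadTruth:
    """Truth record for one emitted read pair.

    ``junction_pos``/``side`` are the simulator's own geometric derivation
    of the junction this read should report: a molecule covering the genomic
    flank left of the insertion yields junction ``cut_pos - 1``, one covering
    the right flank yields ``cut_pos``; the side label lives in tag-forward
    frame, so it flips with tag orientation.
    """

    read_id: str
    site_id: Optional[str]  # None for untagged background
    umi: str
    cut_pos: Optional[int]
    tag_orientation: Optional[str]
    full_length: bool
    tandem: bool
    junction_pos: Optional[int] = None
    side: Optional[str] = None


def default_offtarget_plan(n_sites: int = 20) -> list[tuple[int, int]]:
    """(mismatch_count, molecules) for a panel of off-targets.

    Mismatch counts cycle 1-7; molecule counts fall with divergence,
    mimicking weaker cleavage at more-mismatched sites, but never below 12
    so every planted site is comfortably detectable.
    """
    plan = []
    for i in range(n_sites):
        mm = (i % 7) + 1
        plan.append((mm, max(12, 48 - 5 * mm)))
    return plan


@dataclass
class SimConfig:
    """Study conditions for a simulated discovery run."""

    seed: int
    guide: GuideSpec
    dsodn: DsODNSpec
    genome_length: int = 100_000
    offtarget_plan: list[tuple[int, int]] = field(default_factory=default_offtarget_plan)
    on_target_molecules: int = 150
    fragment_length_range: tuple[int, int] = (500, 700)
    read_length: int = 150
    umi_length: int = 8
    flank_range: tuple[int, int] = (60, 110)  # covered genomic bases adjacent to the junction
    reads_per_molecule_range: tuple[int, int] = (1, 3)
    tandem_insertion_prob: float = 0.05  # tandem capture is a minor species (<=10%)
    truncation_prob: float = 0.05
    substitution_error_rate: float = 0.005
    background_fraction: float = 0.5
    barcode: str = "ACGTCA"
    seq_name: str = "chr_sim"

    def __post_init__(self) -> None:
        for p in (self.tandem_insertion_prob, self.truncation_prob,
                  self.substitution_error_rate, self.background_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.tandem_insertion_prob > 0.10:
            raise ValueError("tandem_insertion_prob above the observed 0-10% range")


def _concrete_frame(rng: np.random.Generator, guide: GuideSpec) -> str:
    """A genomic sequence matching the guide frame with zero mismatches."""
    out = []
    for p in guide.frame:
        out.append("ACGT"[rng.integers(0, 4)] if p == "N" else p)
    return "".join(out)


def _mismatched_frame(
    rng: np.random.Generator, guide: GuideSpec, n_mm: int
) -> tuple[str, list[int]]:
    """Plant exactly ``n_mm`` substitutions, drawn without replacement from
    the protospacer positions (the PAM stays pattern-valid)."""
    frame = list(_concrete_frame(rng, guide))
    positions = sorted(rng.choice(len(guide.protospacer), size=n_mm, replace=False).tolist())
    for i in positions:
        frame[i] = _mutate_base(rng, frame[i])
    return "".join(frame), positions


def _cut_position(frame_start: int, strand: str, guide: GuideSpec) -> int:
    if strand == "+":
        return frame_start + len(guide.protospacer) - guide.cut_offset
    return frame_start + len(guide.pam) + guide.cut_offset


def simulate_genome(cfg: SimConfig) -> tuple[dict[str, str], list[PlantedSite]]:
    """Random uniform genome with the on-target and each planned off-target
    frame planted at non-overlapping positions at least 1 kb apart."""
    rng = np.random.default_rng(cfg.seed)
    n_sites = 1 + len(cfg.offtarget_plan)
    flen = cfg.guide.frame_length
    spacing = cfg.genome_length // (n_sites + 1)
    if spacing < 1000 + flen + 2000:
        raise ValueError(
            f"genome_length {cfg.genome_length} too small to place {n_sites} "
            f"sites 1 kb apart with shearing margins"
        )
    genome = np.frombuffer(_random_dna(rng, cfg.genome_length).encode(), dtype=np.uint8).copy()
    truth: list[PlantedSite] = []
    plans = [(0, cfg.on_target_molecules)] + list(cfg.offtarget_plan)
    for i, (n_mm, molecules) in enumerate(plans):
        jitter = int(rng.integers(-spacing // 4, spacing // 4 + 1))
        start = (i + 1) * spacing + jitter
        strand = "+" if rng.random() < 0.5 else "-"
        if n_mm == 0:
            frame, positions = _concrete_frame(rng, cfg.guide), []
        else:
            frame, positions = _mismatched_frame(rng, cfg.guide, n_mm)
        genomic = frame if strand == "+" else revcomp(frame)
        genome[start : start + flen] = np.frombuffer(genomic.encode(), dtype=np.uint8)
        truth.append(
            PlantedSite(
                site_id="on_target" if i == 0 else f"off_{i:02d}",
                seq_name=cfg.seq_name,
                frame_start=start,
                strand=strand,
                planted_seq=frame,
                mismatch_count=n_mm,
                mismatch_positions=positions,
                cut_pos=_cut_position(start, strand, cfg.guide),
                is_on_target=i == 0,
                molecules=molecules,
            )
        )
    return {cfg.seq_name: genome.tobytes().decode()}, truth


def _tag_block(
    rng: np.random.Generator, cfg: SimConfig
) -> tuple[str, str, bool, bool]:
    """One integrated tag block: (sequence, orientation, full_length, tandem)."""
    tag = cfg.dsodn.sequence
    orientation = "forward" if rng.random() < 0.5 else "reverse"
    oriented = tag if orientation == "forward" else revcomp(tag)
    tandem = rng.random() < cfg.tandem_insertion_prob
    truncated = rng.random() < cfg.truncation_prob
    if truncated:
        keep = int(rng.integers(len(tag) - 10, len(tag) - 2))  # drop 3-10 bases
        if rng.random() < 0.5:
            oriented = oriented[:keep]
        else:
            oriented = oriented[-keep:]
    block = oriented * 2 if tandem else oriented
    return block, orientation, not truncated, tandem


def simulate_discovery_library(
    genome: dict[str, str], truth: Sequence[PlantedSite], cfg: SimConfig
) -> tuple[list[ReadPair], list[ReadTruth]]:
    """Emit barcoded, UMI-tagged 150-bp read pairs for every planted site
    plus untagged background fragments, with per-read truth records."""
    rng = np.random.default_rng(cfg.seed + 1)
    seq = genome[cfg.seq_name]
    pairs: list[ReadPair] = []
    records: list[ReadTruth] = []
    mol_counter = 0
    genomic_payload = cfg.read_length - len(cfg.barcode) - cfg.umi_length

    def emit(fragment: str, umi: str, rec: ReadTruth, n_reads: int) -> None:
        for k in range(n_reads):
            rid = f"{rec.read_id}_r{k}"
            r1 = cfg.barcode + umi + fragment[: genomic_payload]
            r2 = revcomp(fragment)[: cfg.read_length]
            r1 = _apply_errors(rng, r1, cfg.substitution_error_rate)
            r2 = _apply_errors(rng, r2, cfg.substitution_error_rate)
            pairs.append(ReadPair(rid, r1, r2, "I" * len(r1), "I" * len(r2)))
            records.append(
                ReadTruth(rid, rec.site_id, umi, rec.cut_pos,
                          rec.tag_orientation, rec.full_length, rec.tandem,
                          rec.junction_pos, rec.side)
            )

    for site in truth:
        for _ in range(site.molecules):
            mol_counter += 1
            umi = _random_dna(rng, cfg.umi_length)
            block, orientation, full, tandem = _tag_block(rng, cfg)
            flank = int(rng.integers(*cfg.flank_range))
            frag_len = int(rng.integers(*cfg.fragment_length_range))
            b = max(50, frag_len - flank - len(block))
            c = site.cut_pos
            # the molecule's sequenced end covers one genomic flank of the
            # junction; the distal end (length b) stays tag-free in the reads
            if rng.random() < 0.5:  # cover the flank left of the insertion
                fragment = seq[c - flank : c] + block + seq[c : c + b]
                junction = c - 1
                side = "left_of_tag" if orientation == "forward" else "right_of_tag"
            else:  # cover the right flank: same physical molecule, other end
                fragment = revcomp(seq[c - b : c] + block + seq[c : c + flank])
                junction = c
                side = "right_of_tag" if orientation == "forward" else "left_of_tag"
            if rng.random() < 0.5:
                fragment = revcomp(fragment)
            n_reads = int(rng.integers(cfg.reads_per_molecule_range[0],
                                       cfg.reads_per_molecule_range[1] + 1))
            emit(fragment, umi,
                 ReadTruth(f"mol{mol_counter:06d}", site.site_id, umi, c,
                           orientation, full, tandem, junction, side),
                 n_reads)

    n_tagged = len(pairs)
    if cfg.background_fraction > 0:
        n_bg = int(round(n_tagged * cfg.background_fraction / (1 - cfg.background_fraction)))
        for _ in range(n_bg):
            mol_counter += 1
            umi = _random_dna(rng, cfg.umi_length)
            frag_len = int(rng.integers(*cfg.fragment_length_range))
            start = int(rng.integers(0, len(seq) - frag_len))
            fragment = seq[start : start + frag_len]
            if rng.random() < 0.5:
                fragment = revcomp(fragment)
            emit(fragment, umi,
                 ReadTruth(f"mol{mol_counter:06d}", None, umi, None, None, False, False),
                 1)

    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order], [records[i] for i in order]


# ---------------------------------------------------------------------------
# amplicon pools

@dataclass
class AmpliconReadTruth:
    read_id: str
    read_class: str
    full_length: bool


def simulate_amplicon_pool(
    spec,
    fractions: dict[str, float],
    full_length_fraction: float,
    n: int,
    seed: int,
) -> tuple[list[str], list[AmpliconReadTruth]]:
    """Amplicon reads with 0/1/2 dsODN insertions at the amplicon midpoint.

    ``fractions`` maps read classes (unedited / single_insert /
    double_insert / edited_other) to probabilities summing to 1. Non-full
    insertions are truncated by at least 5 bases so that the full-length
    assessment (whole oligo within 1 mismatch) cannot be reconstituted by
    chance from junction-adjacent bases. Non-full single insertions stay
    inside the single-insert length window; for double insertions the
    default windows leave no room to truncate both copies by 5, so
    double-insert reads are emitted full-length. ``edited_other`` reads
    carry a short truncated tag block whose excess falls below the single
    window.
    """
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    rng = np.random.default_rng(seed)
    ref = spec.reference_amplicon
    tag = spec.dsodn.sequence
    taglen = len(tag)
    s_lo, s_hi, d_lo, d_hi = spec.windows()
    cut = len(ref) // 2
    classes = list(fractions)
    probs = np.array([fractions[c] for c in classes])
    reads: list[str] = []
    records: list[AmpliconReadTruth] = []

    def oriented_tag(length: int) -> str:
        t = tag if rng.random() < 0.5 else revcomp(tag)
        if length >= taglen:
            return t
        return t[:length] if rng.random() < 0.5 else t[-length:]

    for i in range(n):
        cls = classes[rng.choice(len(classes), p=probs)]
        full = False
        if cls == "unedited":
            read = ref
        elif cls == "single_insert":
            full = rng.random() < full_length_fraction
            if full or s_lo > taglen - 5:
                full = True
                ins = oriented_tag(taglen)
            else:
                # in-window, but >=5 bases short of the complete oligo
                ins = oriented_tag(int(rng.integers(s_lo, taglen - 5 + 1)))
            read = ref[:cut] + ins + ref[cut:]
        elif cls == "double_insert":
            full = rng.random() < full_length_fraction
            max_trunc_total = 2 * taglen - d_lo
            if not full and max_trunc_total >= 10:
                budget = int(rng.integers(10, min(max_trunc_total, 2 * (taglen - 20)) + 1))
                t1 = int(rng.integers(5, budget - 4))
                ins = oriented_tag(taglen - t1) + oriented_tag(taglen - (budget - t1))
            else:
                full = True
                ins = oriented_tag(taglen) + oriented_tag(taglen)
            read = ref[:cut] + ins + ref[cut:]
        elif cls == "edited_other":
            ins = oriented_tag(int(rng.integers(10, max(11, s_lo - 3))))
            read = ref[:cut] + ins + ref[cut:]
        else:
            raise ValueError(f"unknown read class {cls!r}")
        reads.append(read)
        records.append(AmpliconReadTruth(f"amp{i:06d}", cls, full))
    return reads, records


def write_fasta(path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_truth_tsv(path, truth: Sequence[PlantedSite]) -> None:
    cols = ["site_id", "contig", "frame_start", "strand", "planted_seq",
            "mismatch_count", "mismatch_positions", "cut_pos", "is_on_target",
            "molecules"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in truth:
            fh.write("\t".join(map(str, [
                s.site_id, s.seq_name, s.frame_start, s.strand, s.planted_seq,
                s.mismatch_count, ",".join(map(str, s.mismatch_positions)) or "-",
                s.cut_pos, int(s.is_on_target), s.molecules])) + "\n")


def simulate_files(man, outdir, seed: int) -> dict[str, str]:
    """Materialise a manifest's ``simulate`` block: genome FASTA, pooled
    barcoded paired FASTQ (gzip) and truth TSV, one library per sample.

    Per-sample libraries share one genome and differ by barcode and derived
    seed; reads are pooled and deterministically shuffled so demultiplexing
    is exercised.
    """
    from dataclasses import replace
    from pathlib import Path

    from .seqio import write_fastq_pairs

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blk = dict(man.simulate or {})
    guide = man.guides[blk.pop("guide", next(iter(man.guides)))]
    dsodn = man.dsodns[blk.pop("dsodn", "dsodn_39")]
    n_off = int(blk.pop("n_offtargets", 20))
    cfg = SimConfig(
        seed=seed, guide=guide, dsodn=dsodn,
        offtarget_plan=default_offtarget_plan(n_off),
        **{k: v for k, v in blk.items()},
    )
    genome, truth = simulate_genome(cfg)
    pairs = []
    for i, s in enumerate(man.samples.samples):
        scfg = replace(cfg, seed=seed + 101 * (i + 1), barcode=s.barcode)
        spairs, _ = simulate_discovery_library(genome, truth, scfg)
        for p in spairs:
            p.read_id = f"{s.sample_id}.{p.read_id}"
        pairs.extend(spairs)
    rng = np.random.default_rng(seed + 7)
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]

    paths = {
        "reference": str(outdir / "genome.fa"),
        "r1": str(outdir / "reads_R1.fastq.gz"),
        "r2": str(outdir / "reads_R2.fastq.gz"),
        "truth": str(outdir / "truth_sites.tsv"),
    }
    write_fasta(paths["reference"], genome)
    write_fastq_pairs(paths["r1"], paths["r2"], pairs)
    write_truth_tsv(paths["truth"], truth)
    return paths
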