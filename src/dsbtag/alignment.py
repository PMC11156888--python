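"""Placement of junction fragments on the reference genome.

Two routes are supported:

* a built-in exact-seed / ungapped-extension aligner over a k-mer index —
  intended for the synthetic test genomes this package simulates (up to a
  few hundred kilobases), not for production human-genome work;
* ingestion of externally produced alignments in SAM, for runs aligned with
  a production mapper. The read-name convention ``readid|UMI|side`` carries
  the junction metadata through the external aligner.

Coordinates are 0-based half-open internally; the junction coordinate names
the first genomic base adjacent to the tag.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import pysam
from Bio import SeqIO

from ._dna import hamming_capped, revcomp, sliding_mismatches
from .tagscan import JunctionFragment


@dataclass
class AlignmentHit:
    seq_name: str
    start: int  # 0-based, half-open interval start
    strand: str  # "+" | "-"
    mismatches: int
    unique: bool = True


@dataclass
class ReferenceIndex:
    """Named reference sequences plus an exact k-mer seed table.

    The table maps each length-``k`` substring (forward strand, no N) to all
    its occurrences; reverse-strand lookups go through the reverse
    complement of the query instead of indexing both strands.
    """

    sequences: dict[str, str]
    k: int
    seeds: dict[str, list[tuple[str, int]]]


def load_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase-sequence dict."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate contig name in FASTA: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"empty or unparseable FASTA: {path}")
    return seqs


def build_index(fasta: Union[str, Path, dict], k: int = 20) -> ReferenceIndex:
    """Index every length-k substring without N of the reference."""
    sequences = fasta if isinstance(fasta, dict) else load_fasta(fasta)
    if not sequences:
        raise ValueError("empty reference")
    seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for name, seq in sequences.items():
        for off in range(len(seq) - k + 1):
            kmer = seq[off : off + k]
            if "N" not in kmer:
                seeds[kmer].append((name, off))
    return ReferenceIndex(sequences=dict(sequences), k=k, seeds=dict(seeds))


def _candidate_starts(
    seq: str, index: ReferenceIndex, proximal_first_from_end: Optional[bool]
) -> set[tuple[str, int]]:
    """Seed lookup: candidate (contig, start) placements for ``seq``.

    Tries every k-mer of the fragment; ``proximal_first_from_end`` only
    affects enumeration order (junction-proximal seeds first), the candidate
    set is order-independent.
    """
    k = index.k
    n = len(seq)
    offsets = range(n - k + 1)
    if proximal_first_from_end:
        offsets = reversed(offsets)
    out: set[tuple[str, int]] = set()
    for off in offsets:
        for name, pos in index.seeds.get(seq[off : off + k], ()):
            start = pos - off
            if start >= 0 and start + n <= len(index.sequences[name]):
                out.add((name, start))
    return out


def _brute_candidates(seq: str, index: ReferenceIndex, max_mm: int) -> set[tuple[str, int]]:
    # fallback full scan for fragments whose every k-mer carries an error
    out: set[tuple[str, int]] = set()
    for name, ref in index.sequences.items():
        mm = sliding_mismatches(ref, seq)
        for start in (mm <= max_mm).nonzero()[0]:
            out.add((name, int(start)))
    return out


def align_candidates(
    seq: str, index: ReferenceIndex, max_mm: int = 3, junction_at_end: bool = True
) -> list[AlignmentHit]:
    """All best-scoring ungapped placements of ``seq`` within ``max_mm``.

    Seeds on exact k-mers (both orientations), extends ungapped over the
    full fragment, and falls back to a vectorised full scan when seeding
    finds nothing — so fragments with unluckily spaced errors are still
    placed exactly as an exhaustive scan would place them.
    """
    rc = revcomp(seq)
    placements: list[tuple[str, int, str]] = []
    for strand, oriented, prox in (("+", seq, junction_at_end), ("-", rc, not junction_at_end)):
        cands = _candidate_starts(oriented, index, prox)
        if not cands:
            cands = _brute_candidates(oriented, index, max_mm)
        placements.extend((name, start, strand) for name, start in cands)
    best_mm = max_mm + 1
    best: list[AlignmentHit] = []
    seen: set[tuple[str, int, str]] = set()
    for name, start, strand in placements:
        if (name, start, strand) in seen:
            continue
        seen.add((name, start, strand))
        oriented = seq if strand == "+" else rc
        ref = index.sequences[name]
        mm = hamming_capped(ref[start : start + len(seq)], oriented, best_mm)
        if mm < best_mm:
            best_mm = mm
            best = [AlignmentHit(name, start, strand, mm)]
        elif mm == best_mm and mm <= max_mm:
            best.append(AlignmentHit(name, start, strand, mm))
    if best_mm > max_mm:
        return []
    return sorted(best, key=lambda h: (h.seq_name, h.start, h.strand))


def align_fragment(
    fragment: JunctionFragment, index: ReferenceIndex, max_mm: int = 3
) -> Optional[AlignmentHit]:
    """Best unique placement of a junction fragment, or None.

    Multi-mapping fragments (ties at the best mismatch count at different
    loci) are discarded rather than randomly placed, to avoid fabricating
    off-target loci; use :func:`align_candidates` to inspect the tied set.
    """
    seq = fragment.genomic_seq
    if len(seq) < index.k:
        return None
    junction_at_end = fragment.side == "left_of_tag"
    hits = align_candidates(seq, index, max_mm, junction_at_end)
    if len(hits) != 1:
        return None
    return hits[0]


def junction_position(hit: AlignmentHit, side: str, fragment_length: int) -> int:
    """Genomic coordinate of the base adjacent to the tag.

    A ``left_of_tag`` fragment ends at the junction (in tag-forward frame),
    a ``right_of_tag`` fragment starts at it; reverse-strand placements
    mirror the fragment, so the junction swaps ends.
    """
    at_fragment_end = side == "left_of_tag"
    if hit.strand == "-":
        at_fragment_end = not at_fragment_end
    return hit.start + fragment_length - 1 if at_fragment_end else hit.start


@dataclass
class SamIngest:
    hits: list[tuple[AlignmentHit, str, str, str, int]]  # hit, read_id, umi, side, length
    n_unmapped: int = 0
    n_secondary: int = 0


SIDE_CODES = {"L": "left_of_tag", "R": "right_of_tag",
              "left_of_tag": "left_of_tag", "right_of_tag": "right_of_tag"}


def load_sam(path) -> SamIngest:
    """Ingest external alignments of junction fragments from a SAM file.

    Each primary mapped record contributes one hit; the query name must
    follow the ``readid|UMI|side`` convention (side ``L``/``R``). Secondary,
    supplementary and unmapped records are skipped and counted. A record
    without the name convention is a hard error naming the record.
    """
    out = SamIngest(hits=[])
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                out.n_secondary += 1
                continue
            if rec.is_unmapped:
                out.n_unmapped += 1
                continue
            parts = rec.query_name.split("|")
            if len(parts) != 3 or parts[2] not in SIDE_CODES:
                raise ValueError(
                    f"SAM record {rec.query_name!r} does not follow the "
                    f"'readid|UMI|side' naming convention"
                )
            read_id, umi, side_code = parts
            strand = "-" if rec.is_reverse else "+"
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            hit = AlignmentHit(rec.reference_name, rec.reference_start, strand, int(nm))
            out.hits.append(
                (hit, read_id, umi, SIDE_CODES[side_code], rec.query_length)
            )
    return out
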