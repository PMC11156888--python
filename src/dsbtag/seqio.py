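"""Paired-end FASTQ I/O, sample demultiplexing and UMI extraction.

The library-preparation scheme this module assumes: genomic fragments are
adaptor-ligated with an adaptor carrying a random molecular index (UMI,
default 8 nt), then amplified with sample-barcoded forward primers, so a raw
read 1 begins ``<barcode><umi><fragment...>``. Both the barcode mate and the
UMI geometry are configurable because adaptor layouts differ between runs.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._dna import hamming_capped, validate_dna


@dataclass
class ReadPair:
    """One paired-end sequencing record (mates in lockstep order)."""

    read_id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str

    def __post_init__(self) -> None:
        self.seq1 = validate_dna(self.seq1, what=f"{self.read_id} R1")
        self.seq2 = validate_dna(self.seq2, what=f"{self.read_id} R2")
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass
class UmiTaggedRead:
    """A read pair with barcode and UMI clipped off and the UMI recorded."""

    read_id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str
    umi: str
    sample_id: Optional[str] = None


@dataclass
class Sample:
    """One entry of the run manifest."""

    sample_id: str
    barcode: str
    r1: Optional[str] = None
    r2: Optional[str] = None
    guide_name: str = ""
    dsodn_name: str = ""
    replicate_group: str = ""

    def __post_init__(self) -> None:
        self.barcode = validate_dna(self.barcode, what=f"barcode of {self.sample_id}")


@dataclass
class SampleManifest:
    """Per-run sample sheet; barcodes must be unique and equal length."""

    samples: list[Sample]

    def __post_init__(self) -> None:
        codes = [s.barcode for s in self.samples]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate barcodes in manifest")
        if len({len(c) for c in codes}) > 1:
            raise ValueError("barcodes must all have the same length")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in manifest")

    @property
    def barcode_length(self) -> int:
        return len(self.samples[0].barcode)


@dataclass
class DemuxReport:
    """Bookkeeping for the conservation identity assigned+unassigned==input."""

    n_input: int = 0
    n_assigned: dict = field(default_factory=dict)
    n_unassigned: int = 0

    @property
    def n_assigned_total(self) -> int:
        return sum(self.n_assigned.values())


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fastq_pairs(path_r1, path_r2) -> Iterator[ReadPair]:
    """Stream read pairs from two FASTQ files (gzip transparently handled).

    Raises ``ValueError`` naming the record index if the files have unequal
    record counts, and propagates Biopython's error for malformed records.
    """
    with _open_text(path_r1) as fh1, _open_text(path_r2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        idx = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            idx += 1
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                longer = "R2" if rec1 is None else "R1"
                raise ValueError(
                    f"mate-count mismatch: {longer} has a record at index {idx} "
                    f"with no partner"
                )
            id1 = rec1[0].split()[0]
            id2 = rec2[0].split()[0]
            if id1.endswith("/1"):
                id1 = id1[:-2]
            if id2.endswith("/2"):
                id2 = id2[:-2]
            if id1 != id2:
                raise ValueError(
                    f"read id mismatch at record {idx}: {id1!r} vs {id2!r}"
                )
            yield ReadPair(id1, rec1[1], rec2[1], rec1[2], rec2[2])


def write_fastq_pairs(path_r1, path_r2, pairs: Iterable[ReadPair]) -> int:
    """Write pairs to two FASTQ files; returns the number written."""
    n = 0
    opener = gzip.open if str(path_r1).endswith(".gz") else open
    opener2 = gzip.open if str(path_r2).endswith(".gz") else open
    with opener(path_r1, "wt") as fh1, opener2(path_r2, "wt") as fh2:
        for p in pairs:
            fh1.write(f"@{p.read_id}\n{p.seq1}\n+\n{p.qual1}\n")
            fh2.write(f"@{p.read_id}\n{p.seq2}\n+\n{p.qual2}\n")
            n += 1
    return n


def assign_barcode(
    seq: str, manifest: SampleManifest, max_barcode_mm: int = 1
) -> Optional[str]:
    """Assign a read prefix to a sample barcode, or None.

    Assignment requires a unique best barcode within ``max_barcode_mm``
    Hamming distance; ties and everything beyond the cap go unassigned.
    N bases count as mismatches.
    """
    blen = manifest.barcode_length
    prefix = seq[:blen]
    if len(prefix) < blen:
        return None
    best: Optional[str] = None
    best_mm = max_barcode_mm + 1
    tied = False
    for s in manifest.samples:
        mm = hamming_capped(prefix, s.barcode, max_barcode_mm)
        if mm < best_mm:
            best, best_mm, tied = s.sample_id, mm, False
        elif mm == best_mm and mm <= max_barcode_mm:
            tied = True
    if best is None or best_mm > max_barcode_mm or tied:
        return None
    return best


def demultiplex(
    pairs: Iterable[ReadPair],
    manifest: SampleManifest,
    max_barcode_mm: int = 1,
    barcode_mate: int = 1,
) -> tuple[dict[str, list[ReadPair]], list[ReadPair], DemuxReport]:
    """Split read pairs by 5' sample barcode on the designated mate.

    Returns (per-sample pairs with the barcode trimmed, unassigned pairs,
    report). Every input pair lands in exactly one output bucket.
    """
    if barcode_mate not in (1, 2):
        raise ValueError("barcode_mate must be 1 or 2")
    blen = manifest.barcode_length
    out: dict[str, list[ReadPair]] = {s.sample_id: [] for s in manifest.samples}
    unassigned: list[ReadPair] = []
    report = DemuxReport(n_assigned={s.sample_id: 0 for s in manifest.samples})
    for pair in pairs:
        report.n_input += 1
        seq = pair.seq1 if barcode_mate == 1 else pair.seq2
        sid = assign_barcode(seq, manifest, max_barcode_mm)
        if sid is None:
            report.n_unassigned += 1
            unassigned.append(pair)
            continue
        if barcode_mate == 1:
            trimmed = replace(pair, seq1=pair.seq1[blen:], qual1=pair.qual1[blen:])
        else:
            trimmed = replace(pair, seq2=pair.seq2[blen:], qual2=pair.qual2[blen:])
        out[sid].append(trimmed)
        report.n_assigned[sid] += 1
    return out, unassigned, report


def extract_umi(
    pair: ReadPair, umi_length: int = 8, umi_mate: int = 1
) -> Optional[UmiTaggedRead]:
    """Clip the UMI off the designated mate (post-barcode-trim coordinates).

    Returns None when the mate is too short to contain a UMI; callers count
    such drops rather than aborting.
    """
    seq = pair.seq1 if umi_mate == 1 else pair.seq2
    if len(seq) <= umi_length:
        return None
    umi = seq[:umi_length]
    if umi_mate == 1:
        return UmiTaggedRead(
            pair.read_id,
            pair.seq1[umi_length:],
            pair.seq2,
            pair.qual1[umi_length:],
            pair.qual2,
            umi,
        )
    return UmiTaggedRead(
        pair.read_id,
        pair.seq1,
        pair.seq2[umi_length:],
        pair.qual1,
        pair.qual2[umi_length:],
        umi,
    )


def write_demux_report(path, report: DemuxReport) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tn_assigned\n")
        for sid in sorted(report.n_assigned):
            fh.write(f"{sid}\t{report.n_assigned[sid]}\n")
        fh.write(f"__unassigned__\t{report.n_unassigned}\n")
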