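"""Detection of the dsODN tag in reads and junction fragment extraction.

A dsODN (double-stranded oligodeoxynucleotide) captured into a Cas9-induced
double-strand break by NHEJ leaves two tag-genome junctions. Reads from a
tag-enriched library contain genomic sequence running into (part of) the tag.
This module locates the tag by its junction-proximal anchors (the first and
last ``anchor_length`` bases of the tag, in either orientation), decides
whether the full-length oligo is present, and splits reads into the genomic
fragment flanking the junction.

Tag detection scans the whole read rather than requiring the tag at a fixed,
primer-anchored offset; this is the more permissive choice and is what the
simulator exercises.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ._dna import revcomp, scan_pattern, validate_dna
from .seqio import UmiTaggedRead

#: Built-in dsODN definitions. ``guideseq_34`` is the widely used 34-nt
#: GUIDE-seq oligo; ``dsodn_39`` and ``dsodn_46`` are synthetic stand-ins of
#: the published lengths (the real sequences are run configuration and should
#: be supplied in the manifest).
DEFAULT_DSODNS = {
    "guideseq_34": "GTTTAATTGAGTTGTCATATGTTAATAACGGTAT",
    "dsodn_39": "GTTTAATTGAGTTGTCATATGTTAATAACGGTATGGAGC",
    "dsodn_46": "GTTTAATTGAGTTGTCATATGTTAATAACGGTATGGAGCTCTAGAT",
}


@dataclass
class DsODNSpec:
    """The tag oligo and the anchor length used for junction detection."""

    name: str
    sequence: str
    anchor_length: int = 12

    def __post_init__(self) -> None:
        self.sequence = validate_dna(self.sequence, what=f"dsODN {self.name}", allow_n=False)
        if not 20 <= len(self.sequence) <= 60:
            raise ValueError(f"dsODN {self.name}: length {len(self.sequence)} outside [20, 60]")
        if not 10 <= self.anchor_length <= len(self.sequence):
            raise ValueError(f"dsODN {self.name}: anchor_length must be in [10, tag length]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TagHit:
    """One detected tag occurrence in a read.

    ``read_offset`` is the 0-based start of the matched anchor;
    ``tag_span`` is the (possibly read-clipped) interval the whole tag would
    occupy, which can extend past the read on either side when the read only
    covers one junction.
    """

    orientation: str  # "forward" | "reverse"
    read_offset: int
    matched_length: int
    mismatches: int
    full_length: bool
    tag_span: tuple[int, int]
    mate: int = 1


@dataclass
class JunctionFragment:
    """The genomic side of a read relative to the tag, in tag-forward frame.

    After orientation normalisation, a ``left_of_tag`` fragment's last base
    abuts the tag 5' end and a ``right_of_tag`` fragment's first base abuts
    the tag 3' end.
    """

    genomic_seq: str
    side: str  # "left_of_tag" | "right_of_tag"
    read_id: str
    umi: str
    tandem: bool = False
    full_length: bool = False


def _anchor_candidates(seq: str, spec: DsODNSpec, max_anchor_mm: int) -> list[TagHit]:
    tag = spec.sequence
    L = spec.anchor_length
    n = len(seq)
    hits: list[TagHit] = []
    for orientation, oriented in (("forward", tag), ("reverse", revcomp(tag))):
        for terminus, anchor in (("start", oriented[:L]), ("end", oriented[-L:])):
            for off, mm in scan_pattern(seq, anchor, max_anchor_mm):
                if terminus == "start":
                    span = (off, off + len(tag))
                else:
                    span = (off + L - len(tag), off + L)
                matched = min(span[1], n) - max(span[0], 0)
                hits.append(
                    TagHit(orientation, off, matched, mm, False, span)
                )
    return hits


def find_tag(seq: str, spec: DsODNSpec, max_anchor_mm: int = 1) -> Optional[TagHit]:
    """Locate the dsODN tag in ``seq`` via its junction-proximal anchors.

    Returns the lowest-mismatch hit; ties prefer forward orientation, then
    the smallest read offset. None when no anchor occurs within
    ``max_anchor_mm``.
    """
    hits = _anchor_candidates(seq, spec, max_anchor_mm)
    if not hits:
        return None
    hits.sort(key=lambda h: (h.mismatches, h.orientation != "forward", h.read_offset))
    best = hits[0]
    best.full_length = is_full_length(seq, spec, max_mm=max(1, max_anchor_mm))
    return best


def find_all_tags(seq: str, spec: DsODNSpec, max_anchor_mm: int = 1) -> list[TagHit]:
    """All anchor hits whose implied tag spans do not overlap, best first.

    Used to recognise tandem (double) integrations: two copies of the tag at
    one break yield two disjoint spans.
    """
    hits = _anchor_candidates(seq, spec, max_anchor_mm)
    hits.sort(key=lambda h: (h.mismatches, h.orientation != "forward", h.read_offset))
    kept: list[TagHit] = []
    for h in hits:
        if all(
            h.tag_span[1] <= k.tag_span[0] or h.tag_span[0] >= k.tag_span[1]
            for k in kept
        ):
            kept.append(h)
    return kept


def is_full_length(seq: str, spec: DsODNSpec, max_mm: int = 1) -> bool:
    """True iff the entire tag (either orientation) occurs within ``seq``
    at Hamming distance <= ``max_mm``."""
    for oriented in (spec.sequence, revcomp(spec.sequence)):
        for _ in scan_pattern(seq, oriented, max_mm):
            return True
    return False


def split_at_junction(
    read: UmiTaggedRead, hit: TagHit, min_fragment_length: int = 25
) -> Optional[JunctionFragment]:
    """Extract the genomic flank of the tag from a tag-bearing read.

    The read is normalised to tag-forward frame (reverse hits are
    reverse-complemented) so the side label is orientation-invariant. The
    longer of the two flanks outside the tag span is taken; fragments shorter
    than ``min_fragment_length`` are rejected (None).
    """
    seq = read.seq1 if hit.mate == 1 else read.seq2
    n = len(seq)
    start, end = hit.tag_span
    if hit.orientation == "reverse":
        seq = revcomp(seq)
        start, end = n - end, n - start
    left = seq[: max(start, 0)]
    right = seq[min(end, n):]
    if len(left) >= len(right):
        frag, side = left, "left_of_tag"
    else:
        frag, side = right, "right_of_tag"
    if len(frag) < min_fragment_length:
        return None
    return JunctionFragment(
        genomic_seq=frag,
        side=side,
        read_id=read.read_id,
        umi=read.umi,
        full_length=hit.full_length,
    )


def extract_junction_fragment(
    read: UmiTaggedRead,
    spec: DsODNSpec,
    max_anchor_mm: int = 1,
    min_fragment_length: int = 25,
) -> Optional[JunctionFragment]:
    """Scan both mates for the tag and return the junction fragment.

    Tandem integrations (two disjoint tag spans in one read) are trimmed at
    the outermost junction: the fragment is the flank outside the union of
    tag spans, flagged ``tandem``; the tag-to-tag interior is discarded.
    """
    for mate, seq in ((1, read.seq1), (2, read.seq2)):
        hits = find_all_tags(seq, spec, max_anchor_mm)
        if not hits:
            continue
        best = hits[0]
        best.mate = mate
        best.full_length = is_full_length(seq, spec, max_mm=max(1, max_anchor_mm))
        if len(hits) > 1:
            # widen the excluded span to the union of all tag copies
            lo = min(h.tag_span[0] for h in hits)
            hi = max(h.tag_span[1] for h in hits)
            best = TagHit(
                best.orientation, best.read_offset, best.matched_length,
                best.mismatches, best.full_length, (lo, hi), mate,
            )
        frag = split_at_junction(read, best, min_fragment_length)
        if frag is not None:
            frag.tandem = len(hits) > 1
            return frag
    return None
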