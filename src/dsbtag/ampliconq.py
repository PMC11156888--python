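"""Targeted-amplicon quantification of dsODN insertion outcomes.

For a PCR amplicon spanning a nuclease target site (typically 200-280 bp),
reads carrying the target sequence are partitioned into unedited reads,
reads with a single or double (tandem) dsODN insertion — recognised by
their characteristic read-length excess over the reference amplicon — and
an explicit ``edited_other`` remainder (tag-bearing reads whose length
excess fits neither window, e.g. truncated integrations), so the partition
is exhaustive.

Length-excess windows (inclusive) by tag length:

=========  =============  =============
tag (nt)   single insert  double insert
=========  =============  =============
34         29-49          64-84
39         34-54          69-89
=========  =============  =============

The insertion frequency counts only single- and double-insertion reads; the
full-length rate divides reads containing the complete oligo (either
orientation) by all insertion-bearing reads, truncated ones included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from ._dna import encode, revcomp, sliding_mismatches, validate_dna
from .tagscan import DsODNSpec, is_full_length

#: (single_lo, single_hi, double_lo, double_hi) length-excess windows, by tag length.
DEFAULT_EXCESS_WINDOWS: dict[int, tuple[int, int, int, int]] = {
    34: (29, 49, 64, 84),
    39: (34, 54, 69, 89),
}

READ_CLASSES = ("unedited", "single_insert", "double_insert", "edited_other")


@dataclass
class AmpliconSpec:
    """One targeted amplicon: reference sequence plus an on-target anchor."""

    site_name: str
    reference_amplicon: str
    target_anchor: str
    dsodn: DsODNSpec
    excess_windows: Optional[dict[int, tuple[int, int, int, int]]] = None

    def __post_init__(self) -> None:
        self.reference_amplicon = validate_dna(
            self.reference_amplicon, what=f"amplicon {self.site_name}")
        self.target_anchor = validate_dna(
            self.target_anchor, what=f"anchor of {self.site_name}")
        if not 100 <= len(self.reference_amplicon) <= 1000:
            raise ValueError(f"amplicon {self.site_name}: length outside [100, 1000]")
        if len(self.target_anchor) < 15:
            raise ValueError(f"amplicon {self.site_name}: target_anchor shorter than 15 nt")
        if self.reference_amplicon.count(self.target_anchor) != 1:
            raise ValueError(
                f"amplicon {self.site_name}: target_anchor must occur exactly once "
                f"in the reference amplicon")

    def windows(self) -> tuple[int, int, int, int]:
        table = self.excess_windows or DEFAULT_EXCESS_WINDOWS
        try:
            return table[len(self.dsodn)]
        except KeyError:
            raise ValueError(
                f"no length-excess windows configured for a {len(self.dsodn)}-nt tag"
            ) from None


@dataclass
class AmpliconSummary:
    site_name: str
    n_total_target_reads: int
    n_unedited: int
    n_single: int
    n_double: int
    n_other: int
    n_full_length: int
    n_off_amplicon: int = 0

    @property
    def n_with_insertion(self) -> int:
        return self.n_single + self.n_double + self.n_other

    @property
    def insertion_frequency(self) -> Optional[float]:
        """(single + double) / total target reads; None on an empty pool."""
        if self.n_total_target_reads == 0:
            return None
        return (self.n_single + self.n_double) / self.n_total_target_reads

    @property
    def full_length_rate(self) -> Optional[float]:
        """Complete-oligo reads / any-insertion reads; None when undefined."""
        if self.n_with_insertion == 0:
            return None
        return self.n_full_length / self.n_with_insertion


def _contains_within(seq: str, pattern: str, max_mm: int) -> bool:
    if len(pattern) > len(seq):
        return False
    if max_mm == 0:
        return pattern in seq
    mm = sliding_mismatches(seq, pattern)
    return bool((mm <= max_mm).any())


def select_target_reads(
    reads: Iterable[str], spec: AmpliconSpec, max_anchor_mm: int = 1
) -> tuple[list[str], int]:
    """Keep reads containing the target anchor (either strand) within
    ``max_anchor_mm``; returns (kept reads, off-amplicon count)."""
    anchor = spec.target_anchor
    anchor_rc = revcomp(anchor)
    kept: list[str] = []
    n_off = 0
    for seq in reads:
        seq = seq.upper()
        if (
            anchor in seq or anchor_rc in seq
            or _contains_within(seq, anchor, max_anchor_mm)
            or _contains_within(seq, anchor_rc, max_anchor_mm)
        ):
            kept.append(seq)
        else:
            n_off += 1
    return kept, n_off


def has_insertion(
    seq: str, dsodn: DsODNSpec, min_fragment: int = 10, max_mm: int = 1
) -> bool:
    """True iff any contiguous tag block of >= ``min_fragment`` bases
    (either orientation) occurs in ``seq`` within ``max_mm`` mismatches.

    Catches truncated integrations that the length windows alone would
    misread as small indels.
    """
    seq = seq.upper()
    tag = dsodn.sequence
    # fast path: intact tag present verbatim
    if tag in seq or revcomp(tag) in seq:
        return True
    if len(seq) < min_fragment:
        return False
    s = encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(s, min_fragment)
    for oriented in (tag, revcomp(tag)):
        if len(oriented) < min_fragment:
            continue
        p = encode(oriented)
        frags = np.lib.stride_tricks.sliding_window_view(p, min_fragment)
        # (n_frags, n_windows) mismatch matrix in one shot
        mm = (windows[None, :, :] != frags[:, None, :]).sum(axis=2)
        if (mm <= max_mm).any():
            return True
    return False


def classify_read(
    read_len: int,
    ref_len: int,
    dsodn_len: int,
    insertion_present: bool,
    excess_windows: Optional[dict[int, tuple[int, int, int, int]]] = None,
) -> str:
    """Classify one target read by tag presence and length excess.

    ``excess = read_len - ref_len``; window bounds are inclusive. Reads with
    a tag fragment but an excess outside both windows are ``edited_other``.
    """
    if ref_len <= 0:
        raise ValueError("ref_len must be positive")
    if not insertion_present:
        return "unedited"
    table = excess_windows or DEFAULT_EXCESS_WINDOWS
    try:
        s_lo, s_hi, d_lo, d_hi = table[dsodn_len]
    except KeyError:
        raise ValueError(
            f"no length-excess windows configured for a {dsodn_len}-nt tag"
        ) from None
    excess = read_len - ref_len
    if s_lo <= excess <= s_hi:
        return "single_insert"
    if d_lo <= excess <= d_hi:
        return "double_insert"
    return "edited_other"


def summarize(
    reads: Iterable[str],
    spec: AmpliconSpec,
    max_anchor_mm: int = 1,
    min_fragment: int = 10,
    max_tag_mm: int = 1,
) -> AmpliconSummary:
    """Full per-site tally: target selection, tag detection, length-window
    classification and full-length assessment."""
    target, n_off = select_target_reads(reads, spec, max_anchor_mm)
    counts = {c: 0 for c in READ_CLASSES}
    n_full = 0
    ref_len = len(spec.reference_amplicon)
    for seq in target:
        inserted = has_insertion(seq, spec.dsodn, min_fragment, max_tag_mm)
        cls = classify_read(len(seq), ref_len, len(spec.dsodn), inserted,
                            spec.excess_windows)
        counts[cls] += 1
        if inserted and is_full_length(seq, spec.dsodn, max_mm=max_tag_mm):
            n_full += 1
    return AmpliconSummary(
        site_name=spec.site_name,
        n_total_target_reads=len(target),
        n_unedited=counts["unedited"],
        n_single=counts["single_insert"],
        n_double=counts["double_insert"],
        n_other=counts["edited_other"],
        n_full_length=n_full,
        n_off_amplicon=n_off,
    )


def merge_pairs(
    seq1: str, seq2: str, min_overlap: int = 20, max_mm: int = 2
) -> Optional[str]:
    """Merge overlapping 150-bp mates into one amplicon-spanning sequence.

    R2 is reverse-complemented and the best 3'-overlap of R1 with it within
    ``max_mm`` mismatches (longest first) is joined; None when no acceptable
    overlap exists. R1 bases win inside the overlap.
    """
    r2 = revcomp(seq2.upper())
    r1 = seq1.upper()
    max_ov = min(len(r1), len(r2))
    for ov in range(max_ov, min_overlap - 1, -1):
        a = r1[-ov:]
        b = r2[:ov]
        if sum(x != y for x, y in zip(a, b)) <= max_mm:
            return r1 + r2[ov:]
    return None


def write_summary_tsv(path, summaries: Sequence[AmpliconSummary]) -> None:
    cols = ["site", "n_reads", "n_unedited", "n_single", "n_double", "n_other",
            "n_full_length", "insertion_frequency", "full_length_rate"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in summaries:
            fi = "NA" if s.insertion_frequency is None else f"{s.insertion_frequency:.6f}"
            fl = "NA" if s.full_length_rate is None else f"{s.full_length_rate:.6f}"
            fh.write("\t".join(map(str, [
                s.site_name, s.n_total_target_reads, s.n_unedited, s.n_single,
                s.n_double, s.n_other, s.n_full_length, fi, fl])) + "\n")
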