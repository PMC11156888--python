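"""Cleavage-site consolidation, off-target nomination and reporting.

Junctions from individual reads are clustered into cleavage sites, each site
is scanned for the best protospacer+PAM match within a configurable mismatch
budget (default: seven or fewer mismatches over the combined target and PAM
frame, with pattern-N positions free), sites are classified as high or low
confidence by replicate support, and the off-index — the ratio of summed
off-target read counts to on-target read counts — summarises per-sample
specificity.

Off-target matching here is strictly ungapped: DNA or RNA bulges between the
guide and the genomic site are not modelled.
"""

from __future__ import annotations

import html as _html
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._dna import revcomp, validate_dna

LOW_READ_THRESHOLD = 10  # read support below this is flagged as variably reproducible


@dataclass
class GuideSpec:
    """An sgRNA target: 20-nt protospacer plus PAM pattern.

    ``cut_offset`` is the blunt-cut distance 5' of the PAM (3 for SpCas9);
    it is used for simulation and scan tie-breaking only.
    """

    name: str
    protospacer: str
    pam: str = "NGG"
    cut_offset: int = 3
    on_target: Optional[tuple[str, int]] = None  # (contig, cut coordinate)

    def __post_init__(self) -> None:
        self.protospacer = validate_dna(self.protospacer, what=f"protospacer {self.name}", allow_n=False)
        self.pam = validate_dna(self.pam, what=f"PAM of {self.name}")
        if not 0 < self.cut_offset < len(self.protospacer):
            raise ValueError(f"guide {self.name}: cut_offset out of range")

    @property
    def frame(self) -> str:
        return self.protospacer + self.pam

    @property
    def frame_length(self) -> int:
        return len(self.protospacer) + len(self.pam)


@dataclass(frozen=True)
class IntegrationJunction:
    """One UMI-carrying tag-genome junction from a single read."""

    seq_name: str
    junction_pos: int
    side: str  # "left_of_tag" | "right_of_tag"
    strand: str
    umi: str
    read_id: str = ""


@dataclass
class CleavageSite:
    seq_name: str
    position: int
    window: tuple[int, int]  # half-open interval covering member junctions
    umi_count: int
    read_count: int
    side_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class OffTargetCall:
    site: CleavageSite
    matched_seq: str
    target_strand: str
    mismatch_count: int
    mismatch_positions: list[int]
    is_on_target: bool = False
    low_read_flag: bool = False
    confidence: str = ""

    @property
    def read_count(self) -> int:
        return self.site.read_count


@dataclass
class LocusGroup:
    """One locus tracked across the replicates of a biological group."""

    seq_name: str
    position: int  # representative (leftmost member) position
    target_strand: str
    n_replicates_detected: int
    confidence: str  # "high" | "low"
    read_counts: dict[str, int]  # replicate label -> read count (0 = absent)


@dataclass
class ConfidenceReport:
    min_replicates: int
    groups: list[LocusGroup]


@dataclass
class OffIndex:
    sample_id: str
    off_reads_total: int
    on_reads: int

    @property
    def value(self) -> float:
        if self.on_reads == 0:
            raise ZeroDivisionError("off-index undefined with zero on-target reads")
        return self.off_reads_total / self.on_reads


def consolidate(
    junctions: Sequence[IntegrationJunction], merge_window: int = 10
) -> list[CleavageSite]:
    """Cluster junctions into cleavage sites by single-linkage within
    ``merge_window`` bases on the same contig.

    Site position is the read-weighted modal junction (leftmost on ties);
    ``umi_count`` deduplicates PCR copies by exact (umi, position, side)
    identity.
    """
    ordered = sorted(junctions, key=lambda j: (j.seq_name, j.junction_pos))
    sites: list[CleavageSite] = []
    cluster: list[IntegrationJunction] = []

    def flush() -> None:
        if not cluster:
            return
        positions = Counter(j.junction_pos for j in cluster)
        # modal position, ties to the leftmost
        position = min(positions, key=lambda p: (-positions[p], p))
        molecules = {(j.umi, j.junction_pos, j.side) for j in cluster}
        side_counts = Counter(j.side for j in cluster)
        sites.append(
            CleavageSite(
                seq_name=cluster[0].seq_name,
                position=position,
                window=(min(positions), max(positions) + 1),
                umi_count=len(molecules),
                read_count=len(cluster),
                side_counts=dict(side_counts),
            )
        )

    for j in ordered:
        if cluster and (
            j.seq_name != cluster[0].seq_name
            or j.junction_pos - cluster[-1].junction_pos > merge_window
        ):
            flush()
            cluster = []
        cluster.append(j)
    flush()
    return sites


def _pattern_mismatches(seq: str, pattern: str) -> list[int]:
    """0-based positions where ``seq`` violates ``pattern`` (N matches all)."""
    return [i for i, (s, p) in enumerate(zip(seq, pattern)) if p != "N" and s != p]


def _implied_cut(start: int, strand: str, guide: GuideSpec) -> int:
    """Genomic coordinate of the first base on the PAM side of the blunt cut
    for a frame whose genomic interval starts at ``start``."""
    if strand == "+":
        return start + len(guide.protospacer) - guide.cut_offset
    return start + len(guide.pam) + guide.cut_offset


def scan_target(
    reference: dict[str, str],
    site: CleavageSite,
    guide: GuideSpec,
    flank: int = 25,
    max_mismatches: int = 7,
) -> Optional[tuple[str, str, int, list[int]]]:
    """Best protospacer+PAM frame near a consolidated site, or None.

    Every frame whose genomic start lies within ``flank`` bases of the site
    position is evaluated on both strands; the mismatch count is the number
    of bases differing from the protospacer plus PAM-pattern violations
    (pattern N is free). Ties break by distance of the frame's implied cut
    position to the site, then + strand, then leftmost.
    """
    contig = reference.get(site.seq_name)
    if contig is None:
        raise KeyError(f"contig {site.seq_name} not in reference")
    flen = guide.frame_length
    lo = max(0, site.position - flank)
    hi = min(len(contig) - flen, site.position + flank)
    best: Optional[tuple[tuple[int, int, int, int], tuple[str, str, int, list[int]]]] = None
    for start in range(lo, hi + 1):
        window = contig[start : start + flen]
        for strand in ("+", "-"):
            frame = window if strand == "+" else revcomp(window)
            mism = _pattern_mismatches(frame, guide.frame)
            if len(mism) > max_mismatches:
                continue
            cut_dist = abs(_implied_cut(start, strand, guide) - site.position)
            key = (len(mism), cut_dist, 0 if strand == "+" else 1, start)
            if best is None or key < best[0]:
                best = (key, (frame, strand, len(mism), mism))
    return best[1] if best else None


def call_sites(
    sites: Sequence[CleavageSite],
    guide: GuideSpec,
    reference: dict[str, str],
    flank: int = 25,
    max_mismatches: int = 7,
    on_target_tolerance: int = 25,
) -> tuple[list[OffTargetCall], int]:
    """Annotate consolidated sites with their best guide match.

    Sites with no frame within the mismatch budget are dropped (the count of
    drops is returned). The on-target call is the site matching the guide's
    configured cut coordinate within ``on_target_tolerance`` bases at zero
    mismatches, or — when no coordinate is configured — the best-supported
    zero-mismatch site.
    """
    calls: list[OffTargetCall] = []
    n_dropped = 0
    for site in sites:
        res = scan_target(reference, site, guide, flank, max_mismatches)
        if res is None:
            n_dropped += 1
            continue
        matched_seq, strand, n_mm, positions = res
        calls.append(
            OffTargetCall(
                site=site,
                matched_seq=matched_seq,
                target_strand=strand,
                mismatch_count=n_mm,
                mismatch_positions=positions,
                low_read_flag=site.read_count < LOW_READ_THRESHOLD,
            )
        )
    candidates = [c for c in calls if c.mismatch_count == 0]
    if guide.on_target is not None:
        contig, pos = guide.on_target
        candidates = [
            c for c in candidates
            if c.site.seq_name == contig and abs(c.site.position - pos) <= on_target_tolerance
        ]
    if candidates:
        on = max(candidates, key=lambda c: c.site.read_count)
        on.is_on_target = True
    return calls, n_dropped


def classify_confidence(
    call_sets: dict[str, list[OffTargetCall]],
    min_replicates: int = 2,
    locus_tolerance: int = 10,
) -> ConfidenceReport:
    """Group calls across biological replicates and grade reproducibility.

    Calls within ``locus_tolerance`` bases on the same contig and target
    strand are the same locus (single linkage). A locus seen in at least
    ``min_replicates`` replicates is high-confidence; singletons are
    retained as low-confidence, not discarded. The grouping is invariant to
    replicate order. Each call's ``confidence`` field is set in place.
    """
    entries = []  # (seq_name, strand, position, replicate, call)
    for rep in sorted(call_sets):
        for call in call_sets[rep]:
            entries.append((call.site.seq_name, call.target_strand, call.site.position, rep, call))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    groups: list[LocusGroup] = []
    cluster: list[tuple] = []

    def flush() -> None:
        if not cluster:
            return
        reps = {e[3] for e in cluster}
        conf = "high" if len(reps) >= min_replicates else "low"
        counts: dict[str, int] = {r: 0 for r in call_sets}
        for e in cluster:
            counts[e[3]] += e[4].site.read_count
            e[4].confidence = conf
        groups.append(
            LocusGroup(
                seq_name=cluster[0][0],
                position=min(e[2] for e in cluster),
                target_strand=cluster[0][1],
                n_replicates_detected=len(reps),
                confidence=conf,
                read_counts=counts,
            )
        )

    for e in entries:
        if cluster and (
            e[0] != cluster[0][0]
            or e[1] != cluster[0][1]
            or e[2] - cluster[-1][2] > locus_tolerance
        ):
            flush()
            cluster = []
        cluster.append(e)
    flush()
    return ConfidenceReport(min_replicates=min_replicates, groups=groups)


def compute_off_index(calls: Sequence[OffTargetCall], sample_id: str = "") -> OffIndex:
    """Ratio of total off-target reads to on-target reads for one sample."""
    on = [c for c in calls if c.is_on_target]
    if len(on) != 1:
        raise ValueError(
            f"off-index requires exactly one on-target call, found {len(on)}"
        )
    off_total = sum(c.site.read_count for c in calls if not c.is_on_target)
    return OffIndex(sample_id=sample_id, off_reads_total=off_total, on_reads=on[0].site.read_count)


# ---------------------------------------------------------------------------
# site-table rendering

_ANSI_RED = "\x1b[31m"
_ANSI_RESET = "\x1b[0m"


def _dotted(call: OffTargetCall, guide: GuideSpec, colorize=None) -> str:
    out = []
    for i, base in enumerate(call.matched_seq):
        if i in call.mismatch_positions:
            out.append(colorize(base) if colorize else base)
        else:
            out.append(".")
    return "".join(out)


def render_site_table(
    calls: Sequence[OffTargetCall], guide: GuideSpec, format: str = "tsv"
) -> str:
    """Render the mismatch-annotated site table.

    The on-target protospacer+PAM heads the table; each call shows matching
    bases as ``.`` and mismatched bases as the off-target letter (colourised
    in text/html). Rows sort by read count descending, ties by coordinate.
    """
    ordered = sorted(
        calls, key=lambda c: (-c.site.read_count, c.site.seq_name, c.site.position)
    )
    header = ["sequence", "contig", "position", "strand", "mismatches",
              "reads", "umis", "on_target", "confidence"]

    def row(call: OffTargetCall, colorize=None) -> list[str]:
        return [
            _dotted(call, guide, colorize),
            call.site.seq_name,
            str(call.site.position + 1),  # 1-based for human-readable output
            call.target_strand,
            str(call.mismatch_count),
            str(call.site.read_count),
            str(call.site.umi_count),
            "yes" if call.is_on_target else "no",
            call.confidence or "NA",
        ]

    if format == "tsv":
        lines = ["\t".join(header)]
        lines.append("\t".join([guide.frame, "-", "-", "-", "0", "-", "-", "reference", "-"]))
        lines.extend("\t".join(row(c)) for c in ordered)
        return "\n".join(lines) + "\n"
    if format == "text":
        color = lambda b: f"{_ANSI_RED}{b}{_ANSI_RESET}"
        lines = [guide.frame + "    (on-target reference)"]
        for c in ordered:
            r = row(c, color)
            lines.append(f"{r[0]}    {r[1]}:{r[2]} {r[3]}  mm={r[4]} reads={r[5]} {r[8]}")
        return "\n".join(lines) + "\n"
    if format == "html":
        color = lambda b: f'<span style="color:red;font-weight:bold">{_html.escape(b)}</span>'
        rows = [
            "<tr><td><code>%s</code></td>%s</tr>"
            % (_dotted(c, guide, color), "".join(f"<td>{_html.escape(v)}</td>" for v in row(c)[1:]))
            for c in ordered
        ]
        head = "".join(f"<th>{h}</th>" for h in header)
        return (
            "<table>\n<tr>%s</tr>\n<tr><td><code>%s</code></td>"
            "<td colspan=\"8\">on-target reference</td></tr>\n%s\n</table>\n"
            % (head, guide.frame, "\n".join(rows))
        )
    raise ValueError(f"unknown format: {format}")


def write_calls_tsv(path, calls: Sequence[OffTargetCall]) -> None:
    """Machine-readable call table; coordinates 1-based inclusive."""
    cols = ["contig", "start", "end", "strand", "matched_seq", "mismatch_count",
            "mismatch_positions", "read_count", "umi_count", "side_left",
            "side_right", "is_on_target", "low_read_flag", "confidence"]
    ordered = sorted(calls, key=lambda c: (c.site.seq_name, c.site.position))
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in ordered:
            w = c.site.window
            fh.write("\t".join(map(str, [
                c.site.seq_name, w[0] + 1, w[1], c.target_strand, c.matched_seq,
                c.mismatch_count, ",".join(map(str, c.mismatch_positions)) or "-",
                c.site.read_count, c.site.umi_count,
                c.site.side_counts.get("left_of_tag", 0),
                c.site.side_counts.get("right_of_tag", 0),
                int(c.is_on_target), int(c.low_read_flag), c.confidence or "NA",
            ])) + "\n")


def write_sites_bed(path, sites: Sequence[CleavageSite]) -> None:
    """BED (0-based half-open) of consolidated sites, score = read count."""
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda s: (s.seq_name, s.position)):
            fh.write(f"{s.seq_name}\t{s.window[0]}\t{s.window[1]}\t"
                     f"site_{s.position}\t{s.read_count}\t.\n")
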