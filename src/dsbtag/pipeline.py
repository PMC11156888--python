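"""Run orchestration: demultiplex -> UMI -> tag scan -> align -> consolidate
-> call -> confidence -> off-index, with per-stage TSV outputs and a log
that records the conservation identity of every stage."""

from __future__ import annotations

import logging
import sys
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import alignment, seqio, sitecall, tagscan
from .manifest import RunManifest

log = logging.getLogger("dsbtag")


@dataclass
class SampleResult:
    sample_id: str
    n_pairs: int = 0
    n_umi_dropped: int = 0
    n_tagged: int = 0
    n_aligned: int = 0
    n_ambiguous: int = 0
    n_unaligned: int = 0
    n_sites: int = 0
    n_sites_dropped: int = 0
    calls: list = field(default_factory=list)
    sites: list = field(default_factory=list)
    off_index: Optional[sitecall.OffIndex] = None


def setup_logging(logfile=None, verbose: bool = True) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile, mode="w"))
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def junctions_from_reads(
    reads,
    dsodn: tagscan.DsODNSpec,
    index: alignment.ReferenceIndex,
    max_anchor_mm: int = 1,
    min_fragment_length: int = 25,
    max_fragment_mm: int = 3,
    result: Optional[SampleResult] = None,
) -> list[sitecall.IntegrationJunction]:
    """Tag-scan and align UMI-tagged reads into integration junctions."""
    res = result or SampleResult("")
    junctions: list[sitecall.IntegrationJunction] = []
    for read in reads:
        frag = tagscan.extract_junction_fragment(
            read, dsodn, max_anchor_mm, min_fragment_length)
        if frag is None:
            continue
        res.n_tagged += 1
        hit = alignment.align_fragment(frag, index, max_fragment_mm)
        if hit is None:
            # distinguish ambiguous from unplaceable for the log
            n = len(alignment.align_candidates(
                frag.genomic_seq, index, max_fragment_mm,
                frag.side == "left_of_tag")) if len(frag.genomic_seq) >= index.k else 0
            if n > 1:
                res.n_ambiguous += 1
            else:
                res.n_unaligned += 1
            continue
        res.n_aligned += 1
        pos = alignment.junction_position(hit, frag.side, len(frag.genomic_seq))
        junctions.append(
            sitecall.IntegrationJunction(
                seq_name=hit.seq_name,
                junction_pos=pos,
                side=frag.side,
                strand=hit.strand,
                umi=frag.umi,
                read_id=frag.read_id,
            )
        )
    return junctions


def junctions_from_sam(path) -> list[sitecall.IntegrationJunction]:
    """Integration junctions from externally aligned fragments in SAM."""
    ingest = alignment.load_sam(path)
    log.info("SAM ingest %s: %d hits, %d unmapped skipped, %d secondary skipped",
             path, len(ingest.hits), ingest.n_unmapped, ingest.n_secondary)
    out = []
    for hit, read_id, umi, side, qlen in ingest.hits:
        pos = alignment.junction_position(hit, side, qlen)
        out.append(sitecall.IntegrationJunction(hit.seq_name, pos, side,
                                                hit.strand, umi, read_id))
    return out


def run_sample(
    sample_id: str,
    reads,
    guide: sitecall.GuideSpec,
    dsodn: tagscan.DsODNSpec,
    reference: dict[str, str],
    index: alignment.ReferenceIndex,
    params,
) -> SampleResult:
    res = SampleResult(sample_id)
    junctions = junctions_from_reads(
        reads, dsodn, index,
        params.max_anchor_mm, params.min_fragment_length,
        params.max_fragment_mm, res)
    sites = sitecall.consolidate(junctions, params.merge_window)
    res.sites = sites
    res.n_sites = len(sites)
    calls, n_dropped = sitecall.call_sites(
        sites, guide, reference,
        flank=params.flank, max_mismatches=params.max_mismatches)
    res.calls = calls
    res.n_sites_dropped = n_dropped
    if any(c.is_on_target for c in calls):
        res.off_index = sitecall.compute_off_index(calls, sample_id)
    else:
        log.warning("sample %s: no on-target call; off-index undefined", sample_id)
    log.info(
        "sample %s: tagged=%d aligned=%d ambiguous=%d unaligned=%d "
        "(tagged == aligned + ambiguous + unaligned) sites=%d calls=%d dropped=%d",
        sample_id, res.n_tagged, res.n_aligned, res.n_ambiguous,
        res.n_unaligned, res.n_sites, len(calls), n_dropped)
    return res


def run_all(manifest: RunManifest, outdir=None) -> dict[str, SampleResult]:
    """Execute the full discovery workflow for every sample in a manifest.

    Deterministic: identical manifest and inputs produce byte-identical
    output TSVs. Returns per-sample results; writes the output tree under
    ``manifest.output_dir`` (or ``outdir``).
    """
    out = Path(outdir or manifest.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress\n")
    if manifest.reference is None:
        raise ValueError("manifest must name a reference FASTA for `run`")
    reference = alignment.load_fasta(manifest.reference)
    index = alignment.build_index(reference, k=manifest.params.k)
    log.info("indexed %d contig(s), k=%d", len(reference), manifest.params.k)

    # samples sharing a FASTQ pair are demultiplexed together
    groups: dict[tuple, list[seqio.Sample]] = defaultdict(list)
    for s in manifest.samples.samples:
        groups[(s.r1, s.r2)].append(s)

    results: dict[str, SampleResult] = {}
    for (r1, r2), members in groups.items():
        sub = seqio.SampleManifest(members)
        pairs = seqio.read_fastq_pairs(r1, r2)
        assigned, unassigned, report = seqio.demultiplex(
            pairs, sub, manifest.params.max_barcode_mm)
        log.info("demux %s: %d pairs in = %d assigned + %d unassigned",
                 Path(r1).name, report.n_input, report.n_assigned_total,
                 report.n_unassigned)
        seqio.write_demux_report(out / f"demux_{Path(r1).stem}.tsv", report)
        for s in members:
            sdir = out / s.sample_id
            sdir.mkdir(exist_ok=True)
            tagged_reads = []
            n_umi_dropped = 0
            for p in assigned[s.sample_id]:
                u = seqio.extract_umi(p, manifest.params.umi_length)
                if u is None:
                    n_umi_dropped += 1
                else:
                    u.sample_id = s.sample_id
                    tagged_reads.append(u)
            guide = manifest.guides[s.guide_name]
            dsodn = manifest.dsodns[s.dsodn_name]
            res = run_sample(s.sample_id, tagged_reads, guide, dsodn,
                             reference, index, manifest.params)
            res.n_pairs = len(assigned[s.sample_id])
            res.n_umi_dropped = n_umi_dropped
            results[s.sample_id] = res
            sitecall.write_sites_bed(sdir / "sites.bed", res.sites)
            with open(sdir / "off_index.tsv", "w") as fh:
                fh.write("sample_id\toff_reads_total\ton_reads\toff_index\n")
                oi = res.off_index
                if oi is None:
                    fh.write(f"{s.sample_id}\tNA\tNA\tNA\n")
                else:
                    fh.write(f"{s.sample_id}\t{oi.off_reads_total}\t"
                             f"{oi.on_reads}\t{oi.value:.6f}\n")

    # replicate-group confidence classification
    by_group: dict[str, dict[str, list]] = defaultdict(dict)
    for s in manifest.samples.samples:
        by_group[s.replicate_group][s.sample_id] = results[s.sample_id].calls
    with open(out / "confidence.tsv", "w") as fh:
        fh.write("replicate_group\tcontig\tposition\tstrand\t"
                 "n_replicates_detected\tconfidence\tread_counts\n")
        for grp in sorted(by_group):
            report = sitecall.classify_confidence(
                by_group[grp], manifest.params.min_replicates,
                manifest.params.locus_tolerance)
            for g in report.groups:
                counts = ",".join(f"{r}:{g.read_counts[r]}"
                                  for r in sorted(g.read_counts))
                fh.write(f"{grp}\t{g.seq_name}\t{g.position + 1}\t"
                         f"{g.target_strand}\t{g.n_replicates_detected}\t"
                         f"{g.confidence}\t{counts}\n")
    # per-sample call tables and site tables, with confidence labels set
    for s in manifest.samples.samples:
        sitecall.write_calls_tsv(out / s.sample_id / "calls.tsv",
                                 results[s.sample_id].calls)
        with open(out / s.sample_id / "site_table.txt", "w") as fh:
            fh.write(sitecall.render_site_table(
                results[s.sample_id].calls, manifest.guides[s.guide_name], "text"))
    marker.unlink()
    return results
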