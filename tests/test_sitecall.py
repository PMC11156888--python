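"""Site consolidation, protospacer+PAM scanning, confidence and off-index."""

import numpy as np
import pytest

from dsbtag._dna import revcomp
from dsbtag.sitecall import (
    CleavageSite,
    GuideSpec,
    IntegrationJunction,
    OffTargetCall,
    call_sites,
    classify_confidence,
    compute_off_index,
    consolidate,
    render_site_table,
    scan_target,
    write_calls_tsv,
)

PROTO = "GACGTTAACCGGATCCATGC"


def _junction(pos, umi="AAAAAAAA", side="left_of_tag", contig="c1"):
    return IntegrationJunction(contig, pos, side, "+", umi)


def _site(pos, reads=20, umis=None, contig="c1"):
    return CleavageSite(contig, pos, (pos, pos + 1), umis or reads, reads,
                        {"left_of_tag": reads})


def _call(pos, reads, mm=0, on=False, strand="+", contig="c1"):
    return OffTargetCall(
        site=_site(pos, reads, contig=contig),
        matched_seq=PROTO + "AGG", target_strand=strand,
        mismatch_count=mm, mismatch_positions=list(range(mm)), is_on_target=on)


class TestConsolidate:
    def test_modal_position_read_weighted(self):
        js = [_junction(1000, umi=f"A{i:07d}".replace("0", "C")) for i in range(3)]
        js += [_junction(1004, umi=f"G{i:07d}".replace("0", "T")) for i in range(2)]
        sites = consolidate(js)
        assert len(sites) == 1
        assert sites[0].position == 1000  # 3 reads beat 2
        assert sites[0].read_count == 5

    def test_tie_goes_leftmost(self):
        js = [_junction(1002), _junction(1000)]
        assert consolidate(js)[0].position == 1000

    def test_separated_clusters_split(self):
        sites = consolidate([_junction(1000), _junction(1020)], merge_window=10)
        assert [s.position for s in sites] == [1000, 1020]

    def test_single_linkage_chains(self):
        sites = consolidate([_junction(1000), _junction(1008), _junction(1016)],
                            merge_window=10)
        assert len(sites) == 1
        assert sites[0].window == (1000, 1017)

    def test_umi_triples_deduplicate(self):
        # same molecule sequenced thrice, a second molecule at the same spot
        js = [_junction(1000, umi="ACGTACGT")] * 3 + [_junction(1000, umi="TTTTCCCC")]
        site = consolidate(js)[0]
        assert site.read_count == 4 and site.umi_count == 2

    def test_simulated_breaks_recovered_at_planted_coordinates(
            self, sim_genome, sim_cfg, umi_reads, ref_index, dsodn):
        from dsbtag.pipeline import junctions_from_reads

        genome, truth = sim_genome
        junctions = junctions_from_reads(umi_reads, dsodn, ref_index)
        sites = consolidate(junctions, merge_window=10)
        big = [s for s in sites if s.read_count >= 5]
        assert len(big) == len(truth)
        for t in truth:
            assert any(abs(s.position - t.cut_pos) <= 2 for s in big)


def oracle_scan_target(reference, site, guide, flank=25, max_mismatches=7):
    """Independent exhaustive enumeration of every frame on both strands."""
    contig = reference[site.seq_name]
    flen = len(guide.protospacer) + len(guide.pam)
    pattern = guide.protospacer + guide.pam
    rows = []
    for start in range(max(0, site.position - flank),
                       min(len(contig) - flen, site.position + flank) + 1):
        gseq = contig[start : start + flen]
        for strand in ("+", "-"):
            frame = gseq if strand == "+" else revcomp(gseq)
            mm = [i for i in range(flen)
                  if pattern[i] != "N" and frame[i] != pattern[i]]
            if len(mm) > max_mismatches:
                continue
            if strand == "+":
                cut = start + len(guide.protospacer) - guide.cut_offset
            else:
                cut = start + len(guide.pam) + guide.cut_offset
            rows.append((len(mm), abs(cut - site.position),
                         0 if strand == "+" else 1, start,
                         (frame, strand, len(mm), mm)))
    if not rows:
        return None
    return min(rows)[4]


class TestScanTarget:
    def _reference(self, rng, planted, length=600):
        seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, length)))
        for pos, frame in planted:
            seq[pos : pos + len(frame)] = frame
        return {"c1": "".join(seq)}

    def test_exact_frame_at_cut_position(self, guide, rng):
        frame = PROTO + "AGG"
        ref = self._reference(rng, [(300, frame)])
        res = scan_target(ref, _site(317), guide)
        assert res is not None
        matched, strand, n_mm, positions = res
        assert (matched, strand, n_mm, positions) == (frame, "+", 0, [])

    def test_planted_five_mismatches_found_with_positions(self, guide, rng):
        frame = list(PROTO + "TGG")
        planted_positions = [2, 7, 11, 15, 19]
        for i in planted_positions:
            frame[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frame[i]]
        ref = self._reference(rng, [(300, "".join(frame))])
        res = scan_target(ref, _site(317), guide)
        matched, strand, n_mm, positions = res
        assert n_mm == 5 and positions == planted_positions
        assert res == oracle_scan_target(ref, _site(317), guide)

    def test_frame_beyond_budget_is_none(self, guide, rng):
        frame = list(PROTO + "TGG")
        for i in range(8):
            frame[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frame[i]]
        ref = self._reference(rng, [(300, "".join(frame))])
        # the random backbone must not itself contain a <=7-mm frame
        if oracle_scan_target(ref, _site(317), guide) is not None:
            pytest.skip("random backbone happened to contain a qualifying frame")
        assert scan_target(ref, _site(317), guide) is None

    def test_oracle_equivalence_random_instances(self, guide, rng):
        """Best frame, strand, mismatch count and tie-break all agree with
        the exhaustive scan on random windows."""
        for _ in range(120):
            length = 400
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
            ref = {"c1": seq}
            site = _site(int(rng.integers(60, length - 60)))
            got = scan_target(ref, site, guide, max_mismatches=10)
            expected = oracle_scan_target(ref, site, guide, max_mismatches=10)
            assert got == expected

    def test_monotonicity_in_budget_and_flank(self, guide, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        ref = {"c1": seq}
        site = _site(200)
        for lo, hi in [(6, 8), (8, 10), (10, 12)]:
            if scan_target(ref, site, guide, max_mismatches=lo) is not None:
                assert scan_target(ref, site, guide, max_mismatches=hi) is not None
        for small, big in [(5, 25), (25, 50)]:
            if scan_target(ref, site, guide, flank=small, max_mismatches=12) is not None:
                assert scan_target(ref, site, guide, flank=big, max_mismatches=12) is not None


class TestCallSites:
    def test_composition_and_drop_counting(self, guide, rng):
        seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, 2500)))
        on = PROTO + "AGG"
        off = list(on)
        for i in (1, 5, 9, 13):
            off[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[off[i]]
        seq[300:323] = on
        seq[1300:1323] = "".join(off)
        ref = {"c1": "".join(seq)}
        sites = [_site(317, reads=100), _site(1317, reads=30), _site(2100, reads=5)]
        if oracle_scan_target(ref, sites[2], guide) is not None:
            pytest.skip("random backbone contains a qualifying frame")
        calls, n_dropped = call_sites(sites, guide, ref)
        assert len(calls) == 2 and n_dropped == 1
        assert calls[0].is_on_target and calls[0].mismatch_count == 0
        assert calls[1].mismatch_count == 4 and not calls[1].is_on_target

    @pytest.mark.parametrize("reads,flag", [(9, True), (10, False), (11, False)])
    def test_low_read_flag_boundary(self, guide, rng, reads, flag):
        seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, 400)))
        seq[200:223] = PROTO + "AGG"
        calls, _ = call_sites([_site(217, reads=reads)], guide, {"c1": "".join(seq)})
        assert calls[0].low_read_flag is flag

    def test_missing_contig_is_hard_error(self, guide):
        with pytest.raises(KeyError):
            call_sites([_site(100, contig="nope")], guide, {"c1": "ACGT" * 100})


class TestClassifyConfidence:
    def test_two_of_three_replicates_high(self):
        sets = {"r1": [_call(1000, 50)], "r2": [_call(1003, 40)], "r3": []}
        report = classify_confidence(sets)
        assert len(report.groups) == 1
        g = report.groups[0]
        assert g.confidence == "high" and g.n_replicates_detected == 2
        assert g.read_counts == {"r1": 50, "r2": 40, "r3": 0}

    def test_singleton_low_but_retained(self):
        sets = {"r1": [_call(1000, 50)], "r2": [], "r3": []}
        report = classify_confidence(sets)
        assert len(report.groups) == 1
        assert report.groups[0].confidence == "low"
        assert sets["r1"][0].confidence == "low"  # annotated in place

    def test_min_replicates_one_makes_every_call_high(self):
        report = classify_confidence({"r1": [_call(1000, 5), _call(5000, 3)]},
                                     min_replicates=1)
        assert all(g.confidence == "high" for g in report.groups)

    def test_strand_and_distance_separate_loci(self):
        sets = {"r1": [_call(1000, 10), _call(1030, 10)],
                "r2": [_call(1000, 10, strand="-")]}
        report = classify_confidence(sets, locus_tolerance=10)
        assert len(report.groups) == 3
        assert all(g.confidence == "low" for g in report.groups)

    def test_permutation_invariance(self):
        a = {"r1": [_call(1000, 50)], "r2": [_call(1004, 40), _call(3000, 7)],
             "r3": [_call(998, 20)]}
        b = {k: a[k] for k in ["r3", "r1", "r2"]}
        ga = classify_confidence(a)
        gb = classify_confidence(b)
        key = lambda g: (g.seq_name, g.position, g.target_strand)
        assert sorted((key(g), g.confidence, g.n_replicates_detected)
                      for g in ga.groups) == \
               sorted((key(g), g.confidence, g.n_replicates_detected)
                      for g in gb.groups)


class TestOffIndex:
    def test_direct_ratio(self):
        calls = [_call(100, 400, on=True), _call(500, 30), _call(900, 10)]
        oi = compute_off_index(calls, "s1")
        assert oi.value == pytest.approx(0.1)
        assert oi.off_reads_total == 40 and oi.on_reads == 400

    def test_no_off_targets_gives_zero(self):
        assert compute_off_index([_call(100, 400, on=True)]).value == 0.0

    def test_missing_on_target_is_error(self):
        with pytest.raises(ValueError, match="on-target"):
            compute_off_index([_call(100, 10)])
        with pytest.raises(ValueError, match="on-target"):
            compute_off_index([_call(100, 10, on=True), _call(300, 10, on=True)])


class TestRenderSiteTable:
    def test_zero_mismatch_row_is_all_dots(self, guide):
        out = render_site_table([_call(100, 50, on=True)], guide, "tsv")
        row = out.splitlines()[2].split("\t")
        assert row[0] == "." * 23

    def test_mismatch_letters_at_positions(self, guide):
        call = _call(100, 50)
        seq = list(PROTO + "AGG")
        seq[2] = "T" if seq[2] != "T" else "A"
        seq[7] = "G" if seq[7] != "G" else "C"
        call.matched_seq = "".join(seq)
        call.mismatch_positions = [2, 7]
        call.mismatch_count = 2
        out = render_site_table([call], guide, "tsv")
        rendered = out.splitlines()[2].split("\t")[0]
        assert rendered[2] == seq[2] and rendered[7] == seq[7]
        assert all(c == "." for i, c in enumerate(rendered) if i not in (2, 7))

    def test_sorted_by_reads_then_coordinate(self, guide):
        calls = [_call(100, 10), _call(500, 90), _call(300, 90)]
        out = render_site_table(calls, guide, "tsv")
        positions = [int(l.split("\t")[2]) for l in out.splitlines()[2:]]
        assert positions == [301, 501, 101]

    def test_tsv_roundtrip_matches_calls(self, guide, tmp_path):
        calls = [_call(100, 50, on=True), _call(500, 9, mm=2)]
        calls[1].low_read_flag = True
        path = tmp_path / "calls.tsv"
        write_calls_tsv(path, calls)
        lines = path.read_text().splitlines()
        header = lines[0].split("\t")
        rows = [dict(zip(header, l.split("\t"))) for l in lines[1:]]
        by_pos = {int(r["start"]) - 1: r for r in rows}
        for c in calls:
            r = by_pos[c.site.position]
            assert int(r["read_count"]) == c.site.read_count
            assert int(r["mismatch_count"]) == c.mismatch_count
            assert bool(int(r["is_on_target"])) == c.is_on_target
            assert bool(int(r["low_read_flag"])) == c.low_read_flag
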