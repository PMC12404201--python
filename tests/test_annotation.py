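"""Intron DB construction, circRNA collapse and flank assignment rules."""

import pytest

from circflow import annotation as ann
from circflow.quantify import CircRNA


def gene(gene_id="g", strand="+", transcripts=None, biotype="protein_coding"):
    return ann.GeneModel(
        gene_id=gene_id, chrom="chr1", strand=strand,
        transcripts=transcripts or [[(0, 100), (200, 300), (400, 500)]],
        biotype=biotype,
    )


class TestBuildIntronDb:
    def test_introns_are_complement_of_exons(self):
        introns = ann.build_intron_db([gene()])
        assert [(i.start, i.end) for i in introns] == [(100, 200), (300, 400)]

    def test_gaps_shorter_than_ten_nt_discarded(self):
        g = gene(transcripts=[[(0, 100), (108, 300)]])
        assert ann.build_intron_db([g]) == []
        g2 = gene(transcripts=[[(0, 100), (110, 300)]])  # exactly 10 nt is kept
        assert [(i.start, i.end) for i in ann.build_intron_db([g2])] == [(100, 110)]

    def test_alternative_first_exon_excluded_before_subtraction(self):
        # second transcript starts at 50 while the gene's outermost start is 0:
        # its first exon is an alternative-TSS exon and must not mask the intron
        g = gene(
            transcripts=[
                [(0, 100), (200, 300), (400, 500)],
                [(50, 100), (200, 300), (400, 500)],
            ]
        )
        introns = ann.build_intron_db([g])
        assert [(i.start, i.end) for i in introns] == [(100, 200), (300, 400)]

    def test_alternative_last_exon_excluded(self):
        g = gene(
            transcripts=[
                [(0, 100), (200, 300), (400, 500)],
                [(0, 100), (200, 290)],
            ]
        )
        introns = ann.build_intron_db([g])
        assert [(i.start, i.end) for i in introns] == [(100, 200), (300, 400)]

    def test_non_protein_coding_dropped(self):
        assert ann.build_intron_db([gene(biotype="lncRNA")]) == []

    def test_expressed_exon_whitelist(self):
        white = {("chr1", 0, 100), ("chr1", 400, 500)}
        introns = ann.build_intron_db([gene()], expressed_exons=white)
        assert [(i.start, i.end) for i in introns] == [(100, 400)]

    def test_transcript_without_exons_is_malformed(self):
        with pytest.raises(ValueError, match="no exons"):
            gene(transcripts=[[]])


def circ(start, end, cid=None, strand="+"):
    return CircRNA(
        circ_id=cid or f"c{start}-{end}", chrom="chr1", strand=strand, start=start, end=end
    )


class TestCollapse:
    def test_both_ends_within_tol_merge(self):
        clusters = ann.collapse_circrnas([circ(100, 560), circ(105, 565)])
        assert len(clusters) == 1
        assert (clusters[0].start, clusters[0].end) == (100, 565)

    def test_one_end_beyond_tol_stays_separate(self):
        clusters = ann.collapse_circrnas([circ(100, 560), circ(111, 560)])
        assert len(clusters) == 2

    def test_chain_merges_by_single_linkage(self):
        circs = [circ(100, 560), circ(109, 560), circ(118, 560)]
        clusters = ann.collapse_circrnas(circs)
        # independent oracle: brute-force transitive closure
        def linked(a, b):
            return abs(a.start - b.start) <= 10 and abs(a.end - b.end) <= 10
        comp = {c.circ_id: {c.circ_id} for c in circs}
        changed = True
        while changed:
            changed = False
            for a in circs:
                for b in circs:
                    if linked(a, b) and comp[a.circ_id] != comp[b.circ_id]:
                        merged = comp[a.circ_id] | comp[b.circ_id]
                        for m in merged:
                            comp[m] = merged
                        changed = True
        oracle = {frozenset(v) for v in comp.values()}
        got = {frozenset(cl.members) for cl in clusters}
        assert got == oracle == {frozenset(c.circ_id for c in circs)}

    def test_different_strands_never_merge(self):
        clusters = ann.collapse_circrnas([circ(100, 560, strand="+"), circ(100, 560, strand="-")])
        assert len(clusters) == 2


def make_introns(strand="+"):
    g = gene(
        gene_id="host", strand=strand,
        transcripts=[[(0, 100), (200, 300), (400, 500), (600, 700)]],
    )
    other = ann.GeneModel(
        gene_id="bystander", chrom="chr1", strand=strand,
        transcripts=[[(2000, 2100), (2200, 2300)]],
    )
    return ann.build_intron_db([g, other])


class TestAssignFlanking:
    def test_plus_strand_adjacent_introns(self):
        introns = make_introns("+")
        clusters = ann.collapse_circrnas([circ(200, 300)])
        labeled = {(i.start, i.end): i for i in ann.assign_flanking_introns(clusters, introns)}
        assert labeled[(100, 200)].klass == "flank_up"
        assert labeled[(300, 400)].klass == "flank_down"
        assert labeled[(500, 600)].klass == "nonflanking"
        assert labeled[(2100, 2200)].klass == "other_gene"

    def test_gap_of_eleven_is_nonflanking(self):
        introns = [
            ann.IntronRecord("i1", "host", "chr1", "+", 100, 189),
            ann.IntronRecord("i2", "host", "chr1", "+", 300, 400),
        ]
        clusters = ann.collapse_circrnas([circ(200, 300)])
        labeled = {i.intron_id: i.klass for i in ann.assign_flanking_introns(clusters, introns)}
        assert labeled["i1"] == "nonflanking"  # 200 - 189 = 11 > 10
        assert labeled["i2"] == "flank_down"

    def test_minus_strand_swaps_genomic_relations(self):
        introns = make_introns("-")
        clusters = ann.collapse_circrnas([circ(200, 300, strand="-")])
        labeled = {(i.start, i.end): i.klass for i in ann.assign_flanking_introns(clusters, introns)}
        # upstream in transcription direction = genomically right
        assert labeled[(300, 400)] == "flank_up"
        assert labeled[(100, 200)] == "flank_down"

    def test_strand_reflection_leaves_labels_invariant(self):
        L = 3000
        fwd_introns = make_introns("+")
        fwd = {
            i.intron_id: i.klass
            for i in ann.assign_flanking_introns(
                ann.collapse_circrnas([circ(200, 300)]), fwd_introns
            )
        }
        mirrored = [
            ann.IntronRecord(i.intron_id, i.gene_id, i.chrom, "-", L - i.end, L - i.start)
            for i in fwd_introns
        ]
        rev = {
            i.intron_id: i.klass
            for i in ann.assign_flanking_introns(
                ann.collapse_circrnas([circ(L - 300, L - 200, strand="-")]), mirrored
            )
        }
        assert fwd == rev

    def test_single_intron_circle_is_double_flanked(self):
        introns = [ann.IntronRecord("i", "host", "chr1", "+", 300, 400)]
        clusters = ann.collapse_circrnas([circ(400, 500), circ(200, 300)])
        labeled = ann.assign_flanking_introns(clusters, introns)
        assert labeled[0].double_flank
        assert len(labeled[0].circ_ids) == 2

    def test_classification_is_a_partition(self, truth):
        introns = ann.build_intron_db(truth.genes)
        clusters = ann.collapse_circrnas(truth.circrnas)
        labeled = ann.assign_flanking_introns(clusters, introns)
        for i in labeled:
            assert i.klass in {"flank_up", "flank_down", "nonflanking", "other_gene"}
            if i.klass.startswith("flank"):
                assert i.circ_ids
        # pipeline matches the planted truth classification exactly
        truth_classes = {i.intron_id: i.klass for i in truth.intron_records()}
        assert {i.intron_id: i.klass for i in labeled} == truth_classes
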