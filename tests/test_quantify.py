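"""BSJ calling, FSJ counting, junction ratio, reference filter, saturation."""

import numpy as np
import pandas as pd
import pytest

from circflow import quantify as q
from circflow._util import revcomp
from circflow.io import READS_COLUMNS


def make_genome(length=1000, canonical_at=((100, 560),), strand="+"):
    seq = list("A" * length)
    for start, end in canonical_at:
        if strand == "+":
            seq[start - 2 : start] = "AG"
            seq[end : end + 2] = "GT"
        else:
            seq[start - 2 : start] = "AC"
            seq[end : end + 2] = "CT"
    return {"chr1": "".join(seq)}


def read_row(s1, e1, s2, e2, strand="+", rid="r0", cigar="30M,30M", jt="?"):
    return (rid, "chr1", strand, s1, e1, s2, e2, cigar, jt)


def reads_frame(rows):
    return pd.DataFrame(rows, columns=READS_COLUMNS)


class TestCallBsj:
    def test_canonical_backsplice_called_at_exact_coordinates(self):
        genome = make_genome()
        reads = reads_frame([read_row(500, 560, 100, 160)])
        circs = q.call_bsj(reads, genome)
        assert len(circs) == 1
        assert (circs[0].start, circs[0].end, circs[0].bsj) == (100, 560, 1)

    def test_noncanonical_flanks_rejected(self):
        genome = {"chr1": "A" * 1000}  # AT/GC nowhere near GT/AG
        reads = reads_frame([read_row(500, 560, 100, 160)])
        assert q.call_bsj(reads, genome) == []

    def test_colinear_read_is_not_a_backsplice(self):
        genome = make_genome()
        reads = reads_frame([read_row(100, 160, 500, 560)])
        assert q.call_bsj(reads, genome) == []

    def test_minus_strand_backsplice(self):
        genome = make_genome(strand="-")
        reads = reads_frame([read_row(100, 160, 500, 560, strand="-")])
        circs = q.call_bsj(reads, genome)
        assert len(circs) == 1 and (circs[0].start, circs[0].end) == (100, 560)

    def test_unknown_chromosome_raises(self):
        reads = reads_frame([read_row(500, 560, 100, 160)])
        reads.loc[0, "chrom"] = "chrX"
        with pytest.raises(ValueError, match="unknown chromosome"):
            q.call_bsj(reads, {"chr1": "A" * 1000})

    def test_segment_beyond_chromosome_raises(self):
        reads = reads_frame([read_row(950, 1010, 100, 160)])
        with pytest.raises(ValueError, match="beyond chromosome end"):
            q.call_bsj(reads, make_genome())

    def test_count_conservation(self, truth, reads):
        accepted = q.detect_bsj_reads(reads, truth.genome)
        circs = q.call_bsj(reads, truth.genome)
        assert sum(c.bsj for c in circs) == len(accepted)
        assert len(accepted) == (reads["junction_type"] == "bsj").sum()

    def test_strand_reflection_invariance(self):
        genome = make_genome()
        reads = reads_frame([read_row(500, 560, 100, 160)])
        circs = q.call_bsj(reads, genome)
        L = 1000
        mirrored_genome = {"chr1": revcomp(genome["chr1"])}
        mreads = reads_frame(
            [read_row(L - 560, L - 500, L - 160, L - 100, strand="-")]
        )
        mcircs = q.call_bsj(mreads, mirrored_genome)
        assert len(mcircs) == len(circs) == 1
        assert (mcircs[0].start, mcircs[0].end) == (L - circs[0].end, L - circs[0].start)


class TestCountFsj:
    def circ(self):
        return q.CircRNA(circ_id="c", chrom="chr1", strand="+", start=100, end=560)

    def test_ten_reads_across_donor(self):
        rows = [
            read_row(560, 590, -1, -1, rid=f"r{k}", cigar="30M")  # junction at donor
            for k in range(0)
        ]
        rows = [read_row(530, 560, 560, 590, rid=f"r{k}") for k in range(10)]
        fsj = q.count_fsj(reads_frame(rows), [self.circ()])
        assert fsj.loc[0, "fsj"] == 10

    def test_read_spanning_both_boundaries_counted_once(self):
        small = q.CircRNA(circ_id="c", chrom="chr1", strand="+", start=100, end=130)
        rows = [read_row(90, 150, -1, -1, cigar="60M")]
        fsj = q.count_fsj(reads_frame(rows), [small])
        assert fsj.loc[0, "fsj"] == 1

    def test_backsplice_reads_never_count_as_fsj(self):
        rows = [read_row(530, 560, 100, 130)]
        fsj = q.count_fsj(reads_frame(rows), [self.circ()])
        assert fsj.loc[0, "fsj"] == 0

    def test_no_linear_reads_gives_ratio_one(self):
        fsj = q.count_fsj(reads_frame([]), [self.circ()])
        assert fsj.loc[0, "fsj"] == 0
        assert q.junction_ratio(7, 0) == 1.0


class TestJunctionRatio:
    @pytest.mark.parametrize(
        "bsj,fsj,expected", [(0, 8, 0.0), (7, 0, 1.0), (5, 10, 0.5), (10, 20, 0.5)]
    )
    def test_printed_formula(self, bsj, fsj, expected):
        assert q.junction_ratio(bsj, fsj) == pytest.approx(expected)

    def test_both_zero_is_na(self):
        assert np.isnan(q.junction_ratio(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            q.junction_ratio(-1, 5)

    def test_monotonicity(self):
        grid = range(3, 30, 3)  # strict monotonicity needs fsj > 0
        for f in grid:
            vals = [q.junction_ratio(b, f) for b in range(1, 20)]
            assert all(x < y for x, y in zip(vals, vals[1:]))
        for b in range(1, 10):
            vals = [q.junction_ratio(b, f) for f in grid]
            assert all(x > y for x, y in zip(vals, vals[1:]))


class TestFilterReference:
    def counts(self, rows):
        return pd.DataFrame(rows, columns=["circ_id", "population", "bsj"])

    def test_five_in_one_population_retained(self):
        kept = q.filter_reference(self.counts([("c1", "neuron", 5), ("c1", "other", 0)]))
        assert kept["circ_id"].tolist() == ["c1"]
        assert kept.loc[0, "populations"] == "neuron"

    def test_four_everywhere_dropped(self):
        kept = q.filter_reference(self.counts([("c1", "neuron", 4), ("c1", "other", 4)]))
        assert kept.empty

    def test_cross_population_pooling_does_not_rescue(self):
        kept = q.filter_reference(self.counts([("c1", "neuron", 3), ("c1", "other", 2)]))
        assert kept.empty

    def test_replicates_pool_within_population(self):
        kept = q.filter_reference(
            self.counts([("c1", "neuron", 3), ("c1", "neuron", 2)])
        )
        assert kept["circ_id"].tolist() == ["c1"]


class TestSaturation:
    def test_full_fraction_recovers_everything(self, truth, reads):
        accepted = q.detect_bsj_reads(reads, truth.genome)
        curve = q.saturation_curve(accepted, fractions=[100], seed=0)
        assert curve.loc[0, "recovery"] == 1.0

    def test_tiny_fraction_recovers_nothing(self, truth, reads):
        # ~50 reads per circle at 1% leaves expected counts far below 5
        accepted = q.detect_bsj_reads(reads, truth.genome)
        curve = q.saturation_curve(accepted, fractions=[1], n_reps=3, seed=0)
        assert curve.loc[0, "recovery"] <= 0.05

    def test_bad_fraction_rejected(self, truth, reads):
        accepted = q.detect_bsj_reads(reads, truth.genome)
        with pytest.raises(ValueError):
            q.saturation_curve(accepted, fractions=[0])
        with pytest.raises(ValueError):
            q.saturation_curve(accepted, fractions=[101])

    def test_determinism_under_seed(self, truth, reads):
        accepted = q.detect_bsj_reads(reads, truth.genome)
        c1 = q.saturation_curve(accepted, fractions=[10, 50], seed=3)
        c2 = q.saturation_curve(accepted, fractions=[10, 50], seed=3)
        pd.testing.assert_frame_equal(c1, c2)
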