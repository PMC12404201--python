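"""RCM detection against a brute-force oracle, plus density/GC/permutation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circflow import rcm
from circflow._util import revcomp

from oracles import brute_force_rcms


def as_tuples(pairs):
    return sorted((p.up_start, p.up_end, p.down_start, p.down_end) for p in pairs)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestExactMode:
    def test_planted_thirty_mer_recovered_at_exact_coordinates(self):
        rng = np.random.default_rng(0)
        core = random_seq(rng, 30)
        up = random_seq(rng, 100) + core + random_seq(rng, 100)
        down = random_seq(rng, 80) + revcomp(core) + random_seq(rng, 120)
        pairs = rcm.find_rcms(up, down)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.up_start <= 100 and p.up_end >= 130  # may extend by chance
        assert up[p.up_start : p.up_end] == revcomp(down[p.down_start : p.down_end])

    def test_ac_only_sequences_cannot_pair(self):
        assert rcm.find_rcms("AC" * 100, "CA" * 100) == []

    def test_short_matches_filtered(self):
        rng = np.random.default_rng(3)
        core = random_seq(rng, 15)
        up = random_seq(rng, 60) + core + random_seq(rng, 60)
        down = random_seq(rng, 60) + revcomp(core) + random_seq(rng, 60)
        # a 15-nt planted match is below the >20 nt cutoff
        assert all(p.length >= 21 for p in rcm.find_rcms(up, down))

    def test_n_never_matches(self):
        up = "N" * 50
        down = "N" * 50
        assert rcm.find_rcms(up, down) == []

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ValueError):
            rcm.find_rcms("ACGTX" * 10, "ACGT" * 10)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 400))
        up, down = random_seq(rng, n), random_seq(rng, n)
        if seed % 2:  # plant a recoverable pair half the time
            core = random_seq(rng, int(rng.integers(21, 45)))
            pos_u = int(rng.integers(0, n - len(core)))
            pos_d = int(rng.integers(0, n - len(core)))
            up = up[:pos_u] + core + up[pos_u + len(core) :]
            down = down[:pos_d] + revcomp(core) + down[pos_d + len(core) :]
        assert as_tuples(rcm.find_rcms(up, down)) == brute_force_rcms(up, down)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        up=st.text(alphabet="ACGT", min_size=25, max_size=200),
        down=st.text(alphabet="ACGT", min_size=25, max_size=200),
        core=st.text(alphabet="ACGT", min_size=21, max_size=40),
    )
    def test_property_oracle_equivalence_with_planted_core(self, up, down, core):
        up2 = up[: len(up) // 2] + core + up[len(up) // 2 :]
        down2 = down[: len(down) // 3] + revcomp(core) + down[len(down) // 3 :]
        assert as_tuples(rcm.find_rcms(up2, down2)) == brute_force_rcms(up2, down2)

    def test_symmetry_under_role_swap(self):
        rng = np.random.default_rng(11)
        core = random_seq(rng, 33)
        up = random_seq(rng, 150) + core + random_seq(rng, 50)
        down = random_seq(rng, 70) + revcomp(core) + random_seq(rng, 130)
        fwd = as_tuples(rcm.find_rcms(up, down))
        swapped = sorted(
            (p.down_start, p.down_end, p.up_start, p.up_end)
            for p in rcm.find_rcms(down, up)
        )
        assert sorted((d0, d1, u0, u1) for u0, u1, d0, d1 in fwd) == sorted(
            (u0, u1, d0, d1) for d0, d1, u0, u1 in swapped
        )

    def test_every_report_satisfies_its_invariant(self, truth):
        pairs = rcm.find_rcms_for_circs(truth.flank_pairs(), truth.genome)
        seq = truth.genome["chr1"]
        for p in pairs.itertuples(index=False):
            assert p.length > 20
            assert seq[p.up_start : p.up_end] == revcomp(seq[p.down_start : p.down_end])


class TestGreedyMode:
    def test_mismatch_tolerated(self):
        rng = np.random.default_rng(21)
        core = random_seq(rng, 40)
        mutated = core[:20] + ("A" if core[20] != "A" else "C") + core[21:]
        up = random_seq(rng, 100) + mutated + random_seq(rng, 100)
        down = random_seq(rng, 100) + revcomp(core) + random_seq(rng, 100)
        exact = rcm.find_rcms(up, down, mode="exact", min_len=21)
        greedy = rcm.find_rcms(up, down, mode="greedy", min_len=21)
        assert not any(p.length >= 40 for p in exact)  # exact mode splits at the mismatch
        assert any(p.length >= 40 and p.n_mismatches >= 1 for p in greedy)


class TestSummaries:
    def test_density_groups_rcms_of_one_circ_per_bin(self):
        rcms = pd.DataFrame(
            {"circ_id": ["c1", "c1", "c1"], "length": [25, 27, 29]}
        )
        meta = pd.DataFrame(
            {"circ_id": ["c1"], "circ_class": ["neuronal"], "flank_len": [2000]}
        )
        out = rcm.rcm_density(rcms, meta, length_bins=[20, 30, 50])
        row = out[out["length_bin"].str.contains("30")].iloc[0]
        assert row["n_circ"] == 1
        assert row["per_kb"] == pytest.approx(0.5)

    def test_density_normalizes_per_kb(self):
        rcms = pd.DataFrame({"circ_id": ["c1"], "length": [25]})
        meta1 = pd.DataFrame({"circ_id": ["c1"], "circ_class": ["x"], "flank_len": [1000]})
        meta2 = meta1.assign(flank_len=[2000])
        d1 = rcm.rcm_density(rcms, meta1, length_bins=[20, 30])["per_kb"].iloc[0]
        d2 = rcm.rcm_density(rcms, meta2, length_bins=[20, 30])["per_kb"].iloc[0]
        assert d1 == pytest.approx(2 * d2)

    @pytest.mark.parametrize(
        "seq,expected", [("ACGT", 0.5), ("AAAA", 0.0), ("GCGCN", 1.0)]
    )
    def test_gc_content(self, seq, expected):
        assert rcm.gc_content(seq) == pytest.approx(expected)

    def test_gc_all_n_is_na(self):
        assert np.isnan(rcm.gc_content("NNN"))


class TestPermutation:
    def regions(self, spans):
        return pd.DataFrame(
            [("chr1", s, e) for s, e in spans], columns=["chrom", "start", "end"]
        )

    def space(self, length=10000):
        return self.regions([(0, length)])

    def test_identical_sets_give_minimal_p(self):
        q = self.regions([(i * 500, i * 500 + 50) for i in range(8)])
        res = rcm.permutation_overlap(q, q, self.space(), ntimes=100, seed=1)
        assert res.observed == 8
        assert res.p_empirical <= 0.05

    def test_empty_repeats_give_p_one(self):
        q = self.regions([(0, 50), (100, 150)])
        res = rcm.permutation_overlap(q, self.regions([]), self.space(), ntimes=50, seed=0)
        assert res.observed == 0
        assert res.p_empirical == 1.0
        assert (res.null_overlaps == 0).all()

    def test_oversized_query_is_a_placement_error(self):
        q = self.regions([(0, 500)])
        with pytest.raises(ValueError, match="placement"):
            rcm.permutation_overlap(q, q, self.regions([(0, 100)]), ntimes=5, seed=0)

    def test_deterministic_under_seed(self):
        q = self.regions([(0, 50), (600, 640)])
        reps = self.regions([(500, 700)])
        r1 = rcm.permutation_overlap(q, reps, self.space(), ntimes=50, seed=9)
        r2 = rcm.permutation_overlap(q, reps, self.space(), ntimes=50, seed=9)
        assert (r1.null_overlaps == r2.null_overlaps).all()
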