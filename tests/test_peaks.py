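import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import iclipkit as ik
from iclipkit.annotation import FeatureInterval, Gene, GenomeAnnotation, Transcript
from iclipkit.crosslinks import empty_crosslink_table, make_crosslink_table
from iclipkit.peaks import _window_sums, benjamini_hochberg, window_score


def single_gene_annotation(length=100, strand="+", start=0, chrom="chr1", clen=None):
    gene = Gene("g1", chrom, strand, start, start + length, "ncRNA",
                [Transcript("g1.t1", [FeatureInterval("ncRNA", start, start + length)])])
    return GenomeAnnotation([gene], {chrom: clen or (start + length)})


class TestWindowScore:
    def test_isolated_site_includes_itself(self):
        t = make_crosslink_table([("chr1", 50, "+", 4, "S")])
        assert window_score(t, ("chr1", 50, "+")) == 4

    def test_sites_sixteen_apart_exclude_each_other(self):
        t = make_crosslink_table([("chr1", 50, "+", 2, "S"), ("chr1", 66, "+", 3, "S")])
        assert window_score(t, ("chr1", 50, "+")) == 2
        assert window_score(t, ("chr1", 66, "+")) == 3
        # at the boundary (15 apart) they do include each other
        t2 = make_crosslink_table([("chr1", 50, "+", 2, "S"), ("chr1", 65, "+", 3, "S")])
        assert window_score(t2, ("chr1", 50, "+")) == 5

    def test_opposite_strand_excluded(self):
        t = make_crosslink_table([("chr1", 50, "+", 2, "S"), ("chr1", 51, "-", 9, "S")])
        assert window_score(t, ("chr1", 50, "+")) == 2

    def test_dense_cluster_matches_brute_force(self):
        rng = np.random.default_rng(2)
        pos = sorted(rng.choice(np.arange(100, 130), 12, replace=False))
        rows = [("chr1", int(p), "+", int(c), "S")
                for p, c in zip(pos, rng.integers(1, 6, len(pos)))]
        t = make_crosslink_table(rows)
        for p in pos:
            brute = sum(c for q, _, c in ((r[1], r[2], r[3]) for r in rows)
                        if abs(q - p) <= 15)
            assert window_score(t, ("chr1", int(p), "+")) == brute

    def test_adding_constant_count_is_monotone(self):
        rng = np.random.default_rng(3)
        rows = [("chr1", int(p), "+", int(c), "S")
                for p, c in zip(rng.choice(200, 20, replace=False),
                                rng.integers(1, 5, 20))]
        t = make_crosslink_table(rows)
        boosted_rows = [(c0, p, s, c + 1, sm) for c0, p, s, c, sm in rows]
        # every position occupied in the boosted table
        extra = [("chr1", int(p), "+", 1, "S") for p in range(200)
                 if p not in {r[1] for r in rows}]
        t2 = make_crosslink_table(boosted_rows + extra)
        for p in (r[1] for r in rows):
            assert window_score(t2, ("chr1", p, "+")) >= window_score(t, ("chr1", p, "+"))


class TestBenjaminiHochberg:
    def test_single_p_identity(self):
        assert benjamini_hochberg([0.01]) == pytest.approx([0.01])

    def test_ties(self):
        assert benjamini_hochberg([0.5, 0.5]) == pytest.approx([0.5, 0.5])

    def test_hand_computed_step_up(self):
        # m=4: m*p/i = [.04, .04, .04, .9]; cumulative min from the back
        out = benjamini_hochberg([0.01, 0.02, 0.03, 0.9])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.9])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_independent_step_up_oracle(self, pvals):
        out = benjamini_hochberg(pvals)
        p = np.asarray(pvals)
        order = np.argsort(p, kind="stable")
        m = len(p)
        adj = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj, 1.0)
        assert out == pytest.approx(expected)


class TestCallPeaks:
    def test_empty_table(self):
        ann = single_gene_annotation()
        out = ik.call_peaks(empty_crosslink_table(), ann)
        assert len(out) == 0

    def test_determinism(self, sim_run):
        _, annotation, _, _, _, table = sim_run
        a = ik.call_peaks(table, annotation, seed=42)
        b = ik.call_peaks(table, annotation, seed=42)
        assert a.equals(b)

    def test_short_gene_flagged(self):
        ann = single_gene_annotation(length=20)
        t = make_crosslink_table([("chr1", 10, "+", 3, "S")])
        out = ik.call_peaks(t, ann)
        assert bool(out["flagged_short"].iloc[0])

    def test_p_value_matches_high_replication_monte_carlo(self):
        """Stacked cDNAs in a 100-nt gene: the 100-permutation p-value agrees
        with an independent 10,000-permutation rerun of the null definition
        within 3 binomial standard deviations."""
        ann = single_gene_annotation(length=100)
        t = make_crosslink_table([("chr1", 50, "+", 5, "S")])
        out = ik.call_peaks(t, ann, n_perm=100, seed=1)
        p_hat = float(out["p_value"].iloc[0])
        observed_score = int(out["window_score"].iloc[0])
        assert observed_score == 5

        rng = np.random.default_rng(999)
        null = []
        for _ in range(10_000):
            occ = np.bincount(rng.integers(0, 100, 5), minlength=100)
            sums = _window_sums(occ, 15)
            null.extend(sums[occ > 0])
        null = np.asarray(null)
        p_true = (1 + (null >= observed_score).sum()) / (1 + null.size)
        # the 100-perm estimate pools ~n_pool null scores
        n_pool = 100 * 5
        sd = np.sqrt(p_true * (1 - p_true) / n_pool)
        assert abs(p_hat - p_true) <= 3 * sd + 1.0 / n_pool

    def test_intergenic_sites_use_pseudo_gene(self):
        ann = single_gene_annotation(length=100, clen=5000)
        t = make_crosslink_table([("chr1", 3000, "+", 5, "S")])
        out = ik.call_peaks(t, ann, seed=0)
        assert out["gene_id"].iloc[0].startswith("intergenic:")
        assert 0 < out["p_value"].iloc[0] <= 1

    def test_stacked_cluster_is_significant_among_noise(self):
        rng = np.random.default_rng(8)
        noise_pos = rng.choice(np.arange(0, 2000), 40, replace=False)
        rows = [("chr1", int(p), "+", 1, "S") for p in noise_pos if p != 1000]
        rows.append(("chr1", 1000, "+", 30, "S"))
        t = make_crosslink_table(rows)
        ann = single_gene_annotation(length=2000)
        out = ik.call_peaks(t, ann, seed=0)
        big = out[out["position"] == 1000]
        assert bool(big["significant"].iloc[0])
        assert out["significant"].sum() <= 3  # noise stays out

    def test_summits_pick_maximum_count_position(self):
        rows = [("chr1", 1000, "+", 30, "S"), ("chr1", 1005, "+", 2, "S"),
                ("chr1", 1010, "+", 1, "S")]
        t = make_crosslink_table(rows)
        ann = single_gene_annotation(length=2000)
        out = ik.call_peaks(t, ann, seed=0)
        summits = ik.peak_summits(out)
        assert list(summits["position"]) == [1000]
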