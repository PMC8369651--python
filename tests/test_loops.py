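"""Loop signal change, APA, differential loops, stripes."""

import numpy as np
import pandas as pd
import pytest

from hexasense.core import GenomeBinning
from hexasense.hic import BalancedView, kr_balance
from hexasense.loops import (
    apa,
    classify_loops_by_stripe,
    differential_loops,
    loop_signal_change,
    stripe_aggregate,
)
from hexasense.synthetic import make_hic_truth, simulate_hic_pair
from conftest import dense_matrix


RES = 10


def unbalanced_view(dense):
    m = dense_matrix(dense, res=RES)
    n = m.n_bins
    return BalancedView(m, np.ones(n), np.zeros(n, dtype=bool))


def loop_frame(pixels, chrom="chr1"):
    return pd.DataFrame(
        [
            {
                "chrom1": chrom,
                "start1": i * RES,
                "end1": (i + 1) * RES,
                "chrom2": chrom,
                "start2": j * RES,
                "end2": (j + 1) * RES,
            }
            for i, j in pixels
        ]
    )


class TestLoopSignalChange:
    def test_identity(self):
        bv = unbalanced_view(np.ones((40, 40)))
        out = loop_signal_change(bv, bv, loop_frame([(5, 20), (10, 30)]))
        np.testing.assert_allclose(out["ratio"], 1.0)
        assert out.attrs["mean_ratio"] == pytest.approx(1.0)

    def test_scaled_pixels_exact(self):
        d = np.ones((40, 40))
        d2 = d.copy()
        pixels = [(5, 20), (10, 30), (8, 25)]
        for i, j in pixels:
            d2[i, j] = d2[j, i] = 0.4
        b1, b2 = unbalanced_view(d), unbalanced_view(d2)
        out = loop_signal_change(b1, b2, loop_frame(pixels))
        total_factor = np.triu(d2).sum() / np.triu(d).sum()
        np.testing.assert_allclose(out["ratio"], 0.4 / total_factor)

    def test_depth_rescaling_invariance(self):
        d = np.ones((40, 40))
        d2 = d.copy()
        d2[5, 20] = d2[20, 5] = 0.5
        out1 = loop_signal_change(
            unbalanced_view(d), unbalanced_view(d2), loop_frame([(5, 20)])
        )
        out2 = loop_signal_change(
            unbalanced_view(d * 3), unbalanced_view(d2 * 11), loop_frame([(5, 20)])
        )
        np.testing.assert_allclose(out1["ratio"], out2["ratio"])

    def test_masked_loop_flagged(self):
        d = np.ones((40, 40))
        m = dense_matrix(d, res=RES)
        mask = np.zeros(40, dtype=bool)
        mask[5] = True
        bv = BalancedView(m, np.where(mask, np.nan, 1.0), mask)
        out = loop_signal_change(bv, bv, loop_frame([(5, 20), (10, 30)]))
        assert not out["defined"].iloc[0] and out["defined"].iloc[1]
        assert out.attrs["mean_ratio"] == pytest.approx(1.0)


class TestAPA:
    def test_uniform_oe_enrichment_one(self):
        n = 80
        toeplitz = 1.0 / (np.abs(np.subtract.outer(np.arange(n), np.arange(n))) + 1)
        bv = unbalanced_view(toeplitz)
        out = apa(bv, loop_frame([(15, 50), (20, 60)]), half_window=5)
        assert out.center_enrichment == pytest.approx(1.0, abs=1e-9)

    def test_planted_loops_recovered(self):
        res = 5000
        nb = 300
        binning = GenomeBinning({"c": nb * res}, res)
        truth = make_hic_truth(
            n_bins=nb, block_size=nb, delta=0.0, tad_size=nb, n_loops=30,
            loop_factor=10.0, depth=2e6, seed=0,
        )
        before, _, truth = simulate_hic_pair(binning, "c", truth)
        loops = pd.DataFrame(
            [
                {
                    "chrom1": "c", "start1": i * res, "end1": (i + 1) * res,
                    "chrom2": "c", "start2": j * res, "end2": (j + 1) * res,
                }
                for i, j, _, _ in truth.loops
            ]
        )
        out = apa(kr_balance(before), loops, half_window=10)
        assert out.center_enrichment == pytest.approx(10.0, rel=0.3)

    def test_grouping_independent(self):
        n = 80
        d = np.ones((n, n))
        d[15, 50] = d[50, 15] = 9.0
        bv = unbalanced_view(d)
        loops = loop_frame([(15, 50), (20, 60)])
        loops["subcomp"] = ["A1", "B2"]
        grouped = apa(bv, loops, half_window=5, group_col="subcomp")
        assert set(grouped) == {"A1", "B2"}
        assert grouped["A1"].n_loops == 1 and grouped["B2"].n_loops == 1
        assert grouped["A1"].center_enrichment > grouped["B2"].center_enrichment

    def test_edge_and_diagonal_loops_dropped(self):
        bv = unbalanced_view(np.ones((40, 40)))
        with pytest.raises(ValueError):
            apa(bv, loop_frame([(2, 38), (10, 15)]), half_window=5)


class TestDifferentialLoops:
    def brute_force(self, before, after, slop):
        def overlap(s1, e1, s2, e2):
            return s1 - slop < e2 + slop and s2 - slop < e1 + slop

        kept = []
        for _, r in before.iterrows():
            ok = False
            for _, o in after.iterrows():
                if (
                    r["chrom1"] == o["chrom1"] and r["chrom2"] == o["chrom2"]
                    and overlap(r["start1"], r["end1"], o["start1"], o["end1"])
                    and overlap(r["start2"], r["end2"], o["start2"], o["end2"])
                ):
                    ok = True
            kept.append(ok)
        return kept

    def test_identical_nothing_lost(self):
        loops = loop_frame([(5, 20), (10, 30)])
        out = differential_loops(loops, loops)
        assert out["lost_fraction"] == 0.0 and len(out["gained"]) == 0

    def test_slop_reach(self):
        before = loop_frame([(100, 200)])
        after = before.copy()
        after[["start1", "end1", "start2", "end2"]] += 15  # 15 bp shift, slop 10 both
        out = differential_loops(before, after, slop=10)
        assert out["lost_fraction"] == 0.0
        out2 = differential_loops(before, after, slop=2)
        assert out2["lost_fraction"] == 1.0

    def test_other_chromosome_never_matched(self):
        before = loop_frame([(5, 20)])
        after = loop_frame([(5, 20)], chrom="chr2")
        out = differential_loops(before, after)
        assert out["lost_fraction"] == 1.0 and len(out["gained"]) == 1

    def test_random_fixtures_match_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            def rand_loops(k):
                recs = []
                for _ in range(k):
                    s1 = int(rng.integers(0, 500))
                    s2 = s1 + int(rng.integers(50, 300))
                    recs.append(
                        {
                            "chrom1": "chr1", "start1": s1, "end1": s1 + 20,
                            "chrom2": "chr1", "start2": s2, "end2": s2 + 20,
                        }
                    )
                return pd.DataFrame(recs)

            before, after = rand_loops(6), rand_loops(6)
            slop = int(rng.integers(0, 40))
            out = differential_loops(before, after, slop=slop)
            kept = self.brute_force(before, after, slop)
            assert len(out["kept"]) == sum(kept)
            assert out["lost_fraction"] == pytest.approx(1 - np.mean(kept))
            # symmetry: lost(b, a) == gained(a, b)
            rev = differential_loops(after, before, slop=slop)
            assert len(out["gained"]) == len(rev["lost"])


class TestStripes:
    def test_planted_stripe_detected(self):
        res = 5000
        nb = 300
        binning = GenomeBinning({"c": nb * res}, res)
        truth = make_hic_truth(
            n_bins=nb, block_size=nb, delta=0.0, tad_size=nb, depth=2e6, seed=0
        )
        truth.stripes = [(80, "left", 15, 3.0, 3.0), (220, "right", 15, 3.0, 3.0)]
        before, _, _ = simulate_hic_pair(binning, "c", truth)
        out = stripe_aggregate(kr_balance(before), pd.DataFrame(
            [{"anchor_bin": 80, "orientation": "left"},
             {"anchor_bin": 220, "orientation": "right"}]
        ), extent=15)
        # balancing absorbs part of the planted factor 3; detection must
        # still be strong and a null must stay near 1
        assert out["ratio"] > 1.8
        null = stripe_aggregate(kr_balance(before), pd.DataFrame(
            [{"anchor_bin": 150, "orientation": "left"}]
        ), extent=15)
        assert null["ratio"] == pytest.approx(1.0, abs=0.25)

    def test_mirror_symmetry(self):
        n = 60
        d = np.ones((n, n))
        for k in range(1, 11):
            d[20, 20 + k] = d[20 + k, 20] = 4.0  # left stripe at 20
            d[40 - k, 40] = d[40, 40 - k] = 4.0  # right stripe at 40
        bv = unbalanced_view(d)
        left = stripe_aggregate(bv, pd.DataFrame([{"anchor_bin": 20, "orientation": "left"}]), extent=10)
        right = stripe_aggregate(bv, pd.DataFrame([{"anchor_bin": 40, "orientation": "right"}]), extent=10)
        np.testing.assert_allclose(left["profile"], right["profile"], rtol=1e-9)

    def test_truncation_and_empty(self):
        bv = unbalanced_view(np.ones((30, 30)))
        out = stripe_aggregate(bv, pd.DataFrame([{"anchor_bin": 25, "orientation": "left"}]), extent=10)
        assert np.isnan(out["profile"][-1])  # truncated past the edge
        with pytest.raises(ValueError):
            stripe_aggregate(bv, pd.DataFrame(columns=["anchor_bin", "orientation"]), extent=5)


class TestClassifyByStripe:
    def anchors(self):
        return pd.DataFrame(
            [
                {"chrom": "chr1", "start": 40, "end": 70},
                {"chrom": "chr1", "start": 290, "end": 320},
            ]
        )

    def test_both_one_none(self):
        loops = loop_frame([(5, 30), (5, 20), (10, 15)])
        # loop anchors: (50,60)&(300,310) -> both; (50,60)&(200,210) -> one;
        # (100,110)&(150,160) -> none
        cls = classify_loops_by_stripe(loops, self.anchors())
        assert list(cls) == ["both", "one", "none"]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        anchors = pd.DataFrame(
            [
                {"chrom": "chr1", "start": int(s), "end": int(s) + 25}
                for s in rng.integers(0, 600, size=8)
            ]
        )
        loops = loop_frame(
            [(int(i), int(i) + int(g)) for i, g in zip(rng.integers(0, 40, 25), rng.integers(5, 20, 25))]
        )
        cls = classify_loops_by_stripe(loops, anchors)

        def hit(s, e):
            return any((a["start"] < e) and (s < a["end"]) for _, a in anchors.iterrows())

        for k, (_, row) in enumerate(loops.iterrows()):
            n = hit(row["start1"], row["end1"]) + hit(row["start2"], row["end2"])
            assert cls.iloc[k] == {2: "both", 1: "one", 0: "none"}[n]
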