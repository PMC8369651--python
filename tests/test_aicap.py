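"""Proteomics pipeline: FOT, imputation, quantile normalization, AICAP,
grouping, enrichment and residue-composition correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hexasense.core import QuantTable
from hexasense.aicap import (
    aicap_pipeline,
    assign_aicap_group,
    compute_aicap,
    ibaq_to_fot,
    impute_missing,
    preranked_enrichment,
    quantile_normalize,
    residue_composition_correlation,
)


def make_table(columns: dict, conditions: dict, kind="iBAQ"):
    data = pd.DataFrame(columns, index=[f"p{i}" for i in range(len(next(iter(columns.values()))))], dtype=float)
    cond = pd.Series({s: conditions[s] for s in data.columns})
    batch = pd.Series({s: "b1" for s in data.columns})
    return QuantTable(data, cond, batch, kind=kind)


class TestFOT:
    def test_forced_by_definition(self):
        t = make_table({"s": [2, 3, 5]}, {"s": "control"})
        out = ibaq_to_fot(t)
        np.testing.assert_allclose(out.data["s"], [2e5, 3e5, 5e5])
        assert out.kind == "FOT"

    def test_missing_stays_missing(self):
        t = make_table({"s": [1, np.nan]}, {"s": "control"})
        out = ibaq_to_fot(t)
        assert out.data["s"].iloc[0] == 1e6 and np.isnan(out.data["s"].iloc[1])

    def test_columns_sum_to_1e6(self, quant_table):
        out = ibaq_to_fot(quant_table)
        np.testing.assert_allclose(out.data.sum(axis=0, skipna=True), 1e6)

    def test_all_missing_sample_rejected(self):
        t = make_table({"s": [np.nan, np.nan]}, {"s": "control"})
        with pytest.raises(ValueError):
            ibaq_to_fot(t)


class TestImpute:
    def test_per_column_minimum(self):
        t = make_table({"s": [4, np.nan, 2]}, {"s": "control"}, kind="FOT")
        out = impute_missing(t)
        np.testing.assert_array_equal(out.data["s"], [4, 2, 2])

    def test_identity_when_complete(self):
        t = make_table({"s": [4.0, 2.0]}, {"s": "control"}, kind="FOT")
        pd.testing.assert_frame_equal(impute_missing(t).data, t.data)

    def test_two_missing_share_minimum(self):
        t = make_table({"s": [np.nan, 5, np.nan, 3]}, {"s": "control"}, kind="FOT")
        out = impute_missing(t)
        assert list(out.data["s"]) == [3, 5, 3, 3]


class TestQuantileNormalize:
    def test_rank_mean_forced(self):
        t = make_table(
            {"a": [1, 2, 3], "b": [4, 5, 6]},
            {"a": "control", "b": "treated"},
            kind="FOT",
        )
        out = quantile_normalize(t)
        np.testing.assert_allclose(out.data["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out.data["b"], [2.5, 3.5, 4.5])

    def test_single_column_unchanged(self):
        t = make_table({"a": [3, 1, 2]}, {"a": "control"}, kind="FOT")
        np.testing.assert_allclose(quantile_normalize(t).data["a"], [3, 1, 2])

    def test_ties_share_average_target(self):
        # brute-force oracle: ranks of [1,1,2] are {1,2} tied then 3;
        # reference = mean of sorted columns = [(1+3)/2,(1+4)/2,(2+5)/2] = [2,2.5,3.5]
        t = make_table(
            {"a": [1, 1, 2], "b": [3, 4, 5]},
            {"a": "control", "b": "treated"},
            kind="FOT",
        )
        out = quantile_normalize(t)
        np.testing.assert_allclose(out.data["a"], [2.25, 2.25, 3.5])
        np.testing.assert_allclose(out.data["b"], [2.0, 2.5, 3.5])

    def test_sorted_columns_identical(self):
        rng = np.random.default_rng(0)
        cols = {f"s{i}": rng.lognormal(size=40) for i in range(4)}
        t = make_table(cols, {f"s{i}": "control" for i in range(4)}, kind="FOT")
        out = quantile_normalize(t).data.to_numpy()
        sorted_cols = np.sort(out, axis=0)
        for c in range(1, 4):
            np.testing.assert_array_equal(sorted_cols[:, c], sorted_cols[:, 0])

    def test_missing_rejected(self):
        t = make_table({"a": [1, np.nan]}, {"a": "control"}, kind="FOT")
        with pytest.raises(ValueError):
            quantile_normalize(t)


class TestComputeAICAP:
    def test_ratio_of_means(self):
        t = make_table(
            {"c1": [100.0], "c2": [100.0], "t1": [50.0], "t2": [50.0]},
            {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"},
            kind="FOT_normalized",
        )
        res = compute_aicap(t)
        assert res["aicap"].iloc[0] == pytest.approx(0.5)

    def test_symmetric_null(self):
        t = make_table(
            {"c1": [100.0, 7], "c2": [120.0, 8], "t1": [100.0, 7], "t2": [120.0, 8]},
            {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"},
            kind="FOT_normalized",
        )
        res = compute_aicap(t)
        assert res["aicap"].iloc[0] == pytest.approx(1.0)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_welch_matches_textbook(self):
        """Welch t-test p-values agree with the closed-form implementation."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(10, 2, size=(1, 3))
            y = rng.normal(8, 1, size=(1, 4))
            cols = {f"c{i}": x[:, i] for i in range(3)}
            cols.update({f"t{i}": y[:, i] for i in range(4)})
            conds = {f"c{i}": "control" for i in range(3)}
            conds.update({f"t{i}": "treated" for i in range(4)})
            t = make_table(cols, conds, kind="FOT_normalized")
            res = compute_aicap(t)
            m1, m2 = y.mean(), x.mean()
            v1, v2 = y.var(ddof=1) / 4, x.var(ddof=1) / 3
            tstat = (m1 - m2) / np.sqrt(v1 + v2)
            df = (v1 + v2) ** 2 / (v1**2 / 3 + v2**2 / 2)
            p = 2 * stats.t.sf(abs(tstat), df)
            assert res["p_value"].iloc[0] == pytest.approx(p, rel=1e-10)

    def test_zero_control_flagged_undefined(self):
        t = make_table(
            {"c1": [0.0], "c2": [0.0], "t1": [5.0], "t2": [6.0]},
            {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"},
            kind="FOT_normalized",
        )
        res = compute_aicap(t)
        assert not res["defined"].iloc[0]
        assert np.isnan(res["aicap"].iloc[0])

    def test_replicate_minimum_enforced(self):
        t = make_table(
            {"c1": [1.0], "t1": [2.0], "t2": [3.0]},
            {"c1": "control", "t1": "treated", "t2": "treated"},
            kind="FOT_normalized",
        )
        with pytest.raises(ValueError):
            compute_aicap(t)

    def test_pipeline_scale_invariance(self):
        """Multiplying any sample column by a positive constant leaves AICAP
        unchanged (FOT removes per-sample scale)."""
        from hexasense.synthetic import simulate_quant_experiment

        table, _ = simulate_quant_experiment(n_proteins=80, seed=9)
        res1 = aicap_pipeline(table)
        scaled = table.data.copy()
        rng = np.random.default_rng(1)
        for c in scaled.columns:
            scaled[c] = scaled[c] * rng.uniform(0.1, 10)
        table2 = QuantTable(scaled, table.condition, table.batch, "iBAQ")
        res2 = aicap_pipeline(table2)
        np.testing.assert_allclose(res1["aicap"], res2["aicap"], rtol=1e-9)


class TestGroups:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.072, "0-0.3"),  # MED1's reported index
            (0.537, "0.5-0.7"),  # BRD4's reported index
            (0.401, "0.3-0.5"),  # RNAPII's reported index
            (1.1, "1.1+"),  # left-closed boundary
            (0.3, "0.3-0.5"),
            (0.0, "0-0.3"),
        ],
    )
    def test_bin_assignment(self, value, label):
        assert assign_aicap_group(value) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assign_aicap_group(-0.1)


class TestEnrichment:
    RANK = pd.Series(
        [0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 0.9, 1.1, 1.3, 1.5],
        index=[f"p{i}" for i in range(10)],
    )

    def test_top_loaded_minimal_p(self):
        er = preranked_enrichment(self.RANK, ["p0", "p1", "p2"], n_perm=200, seed=1)
        assert er.es > 0
        assert er.p_value == pytest.approx(1 / 201)

    def test_all_proteins_degenerate(self):
        er = preranked_enrichment(self.RANK, list(self.RANK.index), n_perm=100, seed=1)
        assert er.es == 0.0

    def test_brute_force_running_sum(self):
        """ES equals direct enumeration of the weighted KS running sum."""
        members = ["p1", "p4", "p7"]
        er = preranked_enrichment(self.RANK, members, n_perm=100, seed=2)
        metric = np.clip(1 - self.RANK.to_numpy(), 0, None)
        hits = np.array([p in members for p in self.RANK.index])
        steps = np.where(hits, metric / metric[hits].sum(), -1 / 7)
        rs = np.cumsum(steps)
        expected = rs[np.argmax(np.abs(rs))]
        assert er.es == pytest.approx(expected)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            preranked_enrichment(self.RANK, ["zz"], n_perm=100, seed=0)


class TestResidueComposition:
    def make_results(self, aicaps):
        return pd.DataFrame(
            {
                "aicap": aicaps,
                "defined": [True] * len(aicaps),
            },
            index=[f"p{i}" for i in range(len(aicaps))],
        )

    def test_perfect_monotone(self):
        # leucine fraction strictly decreasing as AICAP increases -> rho = -1
        res = self.make_results([0.1, 0.3, 0.5, 0.7])
        seqs = {
            "p0": "LLLLLLAAAA",
            "p1": "LLLLAAAAAA",
            "p2": "LLAAAAAAAA",
            "p3": "LAAAAAAAAA",
        }
        regions = pd.DataFrame(columns=["protein", "start", "end", "kind"])
        out = residue_composition_correlation(res, seqs, regions)
        rho = out[(out["residue"] == "L") & (out["region"] == "whole")]["rho"].iloc[0]
        assert rho == pytest.approx(-1.0)

    def test_absent_residue_missing(self):
        res = self.make_results([0.1, 0.3, 0.5])
        seqs = {"p0": "AAAA", "p1": "AALL", "p2": "ALLL"}
        regions = pd.DataFrame(columns=["protein", "start", "end", "kind"])
        out = residue_composition_correlation(res, seqs, regions)
        rho_w = out[(out["residue"] == "W") & (out["region"] == "whole")]["rho"].iloc[0]
        assert np.isnan(rho_w)

    def test_aicap_above_one_excluded(self):
        res = self.make_results([0.1, 0.5, 1.4])
        seqs = {f"p{i}": "LLAA" for i in range(3)}
        regions = pd.DataFrame(columns=["protein", "start", "end", "kind"])
        out = residue_composition_correlation(res, seqs, regions)
        assert out["n_proteins"].max() == 2

    def test_region_classes(self):
        res = self.make_results([0.2, 0.4, 0.6])
        seqs = {"p0": "LLLLAAAA", "p1": "LLAAAAAA", "p2": "LAAAAAAL"}
        regions = pd.DataFrame(
            [
                {"protein": p, "start": 0, "end": 4, "kind": "IDR"}
                for p in ("p0", "p1", "p2")
            ]
        )
        out = residue_composition_correlation(res, seqs, regions)
        rho_idr = out[(out["residue"] == "L") & (out["region"] == "idr")]["rho"].iloc[0]
        assert rho_idr == pytest.approx(-1.0)  # IDR L-fractions 1, .5, .25
        # PLD class empty for every protein -> zero proteins retained
        assert out[out["region"] == "pld"]["n_proteins"].max() == 0
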