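"""Expression grouping, DEG filter, terciles, DMR-DEG association."""

import numpy as np
import pandas as pd
import pytest

from methylscape.expression import (
    associate_dmr_deg,
    compare_time_points,
    electrolyte_leakage,
    filter_degs,
    gene_region_levels,
    group_by_expression,
    methdeg_crosstab,
    methylation_terciles,
)


class TestExpressionGroups:
    @pytest.mark.parametrize(
        "rpkm,expected",
        [
            (10.0, "highest"),   # boundary: >= 10
            (25.0, "highest"),
            (9.99, "medium"),    # 1 < x < 10
            (1.0, "lowest"),     # boundary: 0 < x <= 1
            (0.5, "lowest"),
            (0.0, "silent"),
        ],
    )
    def test_boundary_semantics(self, rpkm, expected):
        expr = pd.DataFrame({"gene_id": ["g"], "rpkm_ctrl": [rpkm]})
        assert group_by_expression(expr).iloc[0] == expected

    def test_negative_rpkm_rejected(self):
        expr = pd.DataFrame({"gene_id": ["g"], "rpkm_ctrl": [-1.0]})
        with pytest.raises(ValueError):
            group_by_expression(expr)

    def test_groups_partition_gene_set(self, rng):
        expr = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(100)],
             "rpkm_ctrl": rng.exponential(5, size=100).round(2)}
        )
        groups = group_by_expression(expr)
        assert len(groups) == 100
        assert groups.value_counts().sum() == 100


class TestTerciles:
    def test_nine_genes_split_evenly(self):
        levels = {f"g{i}": i / 10 for i in range(9)}
        t = methylation_terciles(levels)
        assert (len(t.low), len(t.mid), len(t.high)) == (3, 3, 3)
        assert t.low == ["g0", "g1", "g2"] and t.high == ["g6", "g7", "g8"]

    def test_ten_genes_low_absorbs_extra(self):
        levels = {f"g{i}": i / 10 for i in range(10)}
        t = methylation_terciles(levels)
        assert (len(t.low), len(t.mid), len(t.high)) == (4, 3, 3)

    def test_rank_split_matches_sorting_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 60))
            levels = {f"g{i:03d}": float(rng.random()) for i in range(n)}
            t = methylation_terciles(levels)
            ordered = sorted(levels, key=lambda g: (levels[g], g))
            assert t.low + t.mid + t.high == ordered
            assert max(len(t.low), len(t.mid), len(t.high)) - \
                min(len(t.low), len(t.mid), len(t.high)) <= 1

    def test_degenerate_all_equal_flagged(self):
        t = methylation_terciles({f"g{i}": 0.5 for i in range(6)})
        assert t.degenerate
        assert len(t.low) == len(t.mid) == len(t.high) == 2

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            methylation_terciles({"a": 0.1, "b": 0.2})


class TestDegFilter:
    def _expr(self, fc, q):
        return pd.DataFrame(
            {"gene_id": ["g"], "rpkm_ctrl": [5.0], "rpkm_trt": [5.0 * fc],
             "fold_change": [fc], "q_value": [q]}
        )

    def test_both_boundaries_inclusive(self):
        out = filter_degs(self._expr(2.0, 0.01))
        assert len(out) == 1 and out.iloc[0]["deg_status"] == "up"

    def test_below_fold_threshold_fails(self):
        assert len(filter_degs(self._expr(1.9, 0.001))) == 0

    def test_downregulation_by_magnitude(self):
        out = filter_degs(self._expr(0.5, 0.001))
        assert len(out) == 1 and out.iloc[0]["deg_status"] == "down"
        assert len(filter_degs(self._expr(0.6, 0.001))) == 0

    def test_q_above_threshold_fails(self):
        assert len(filter_degs(self._expr(4.0, 0.02))) == 0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="fold_change"):
            filter_degs(pd.DataFrame({"gene_id": ["g"], "q_value": [0.001]}))

    def test_silent_genes_with_nan_fold_never_pass(self):
        expr = self._expr(np.nan, 0.001)
        assert len(filter_degs(expr)) == 0


class TestAssociation:
    def _degs(self, *genes, status="up"):
        return pd.DataFrame({"gene_id": list(genes), "deg_status": status})

    def _dmr(self, start, end, direction="hyper", context="CG"):
        return pd.DataFrame(
            {"chrom": ["chrA"], "start": [start], "end": [end],
             "context": [context], "direction": [direction]}
        )

    def test_dmr_in_non_deg_body_yields_nothing(self, toy_index):
        md = associate_dmr_deg(self._dmr(5100, 5300), self._degs("other"), toy_index)
        assert len(md) == 0

    def test_hyper_upstream_of_up_deg_is_pro_methdeg(self, toy_index):
        # upstream window of gplus is [3000, 5000)
        md = associate_dmr_deg(self._dmr(3400, 3600), self._degs("gplus"), toy_index)
        assert len(md) == 1
        rec = md.iloc[0]
        assert rec["region"] == "upstream"
        assert (rec["dmr_direction"], rec["deg_direction"], rec["context"]) == \
            ("hyper", "up", "CG")

    def test_body_overlap_is_gb_methdeg(self, toy_index):
        md = associate_dmr_deg(self._dmr(7900, 8100), self._degs("gplus"), toy_index)
        assert set(md["region"]) == {"gene_body"}

    def test_gene_can_be_both_pro_and_gb(self, toy_index):
        dmrs = pd.concat(
            [self._dmr(3400, 3600), self._dmr(5100, 5300)], ignore_index=True
        )
        md = associate_dmr_deg(dmrs, self._degs("gplus"), toy_index)
        assert set(md["region"]) == {"upstream", "gene_body"}
        assert md["gene_id"].nunique() == 1

    def test_removing_a_dmr_never_adds_records(self, toy_index):
        dmrs = pd.concat(
            [self._dmr(3400, 3600), self._dmr(5100, 5300)], ignore_index=True
        )
        full = associate_dmr_deg(dmrs, self._degs("gplus"), toy_index)
        reduced = associate_dmr_deg(dmrs.iloc[:1], self._degs("gplus"), toy_index)
        keys = ["gene_id", "region", "dmr_start"]
        assert set(map(tuple, reduced[keys].values)) <= set(map(tuple, full[keys].values))

    def test_crosstab_counts_unique_genes(self, toy_index):
        dmrs = pd.concat(
            [self._dmr(3400, 3600), self._dmr(3700, 3900)], ignore_index=True
        )
        md = associate_dmr_deg(dmrs, self._degs("gplus"), toy_index)
        ct = methdeg_crosstab(md)
        assert ct["n_genes"].tolist() == [1]


class TestCompareTimePoints:
    def test_identical_sets_all_shared(self):
        out = compare_time_points({"a", "b"}, {"a", "b"})
        assert out["shared"] == {"a", "b"}
        assert not out["unique_t1"] and not out["unique_t2"]

    def test_disjoint_sets_no_shared(self):
        out = compare_time_points({"a"}, {"b"})
        assert out["shared"] == set()

    def test_cardinality_identity(self, rng):
        for _ in range(20):
            s1 = {f"g{i}" for i in rng.integers(0, 50, size=rng.integers(0, 30))}
            s2 = {f"g{i}" for i in rng.integers(0, 50, size=rng.integers(0, 30))}
            out = compare_time_points(s1, s2)
            assert (len(out["unique_t1"]) + len(out["unique_t2"])
                    + 2 * len(out["shared"])) == len(s1) + len(s2)


class TestElectrolyteLeakage:
    def test_basic_ratio(self):
        assert electrolyte_leakage(3, 30) == 10.0

    def test_extremes(self):
        assert electrolyte_leakage(5, 5) == 100.0
        assert electrolyte_leakage(0, 5) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            electrolyte_leakage(1, 0)
        with pytest.raises(ValueError):
            electrolyte_leakage(6, 5)


def test_gene_region_levels_direct_average(toy_index):
    calls = pd.DataFrame(
        {
            "chrom": "chrA",
            "pos": [5100, 5200, 6100, 3500],
            "strand": "+",
            "context": "CG",
            "meth_reads": [2, 8, 5, 10],
            "total_reads": [10, 10, 10, 10],
        }
    )
    calls["level"] = calls["meth_reads"] / calls["total_reads"]
    exon = gene_region_levels(calls, toy_index, "exon", "CG")
    assert exon["gplus"] == pytest.approx((0.2 + 0.8) / 2)
    intron = gene_region_levels(calls, toy_index, "intron", "CG")
    assert intron["gplus"] == pytest.approx(0.5)
    up = gene_region_levels(calls, toy_index, "upstream", "CG")
    assert up["gplus"] == pytest.approx(1.0)
    assert "gminus" not in exon
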