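import json

import numpy as np
import pandas as pd
import pytest

from allometh._errors import ConfigError, ParameterError
from allometh import integration as ig
from allometh.dmr import tile_windows

from conftest import make_calls


GENES = pd.DataFrame(
    [
        {"genome": "At", "gene_id": "gA", "chrom": "At_c", "start": 3000, "end": 4000,
         "strand": "+", "length": 1000},
        {"genome": "Bt", "gene_id": "gB", "chrom": "Bt_c", "start": 3000, "end": 4000,
         "strand": "+", "length": 1000},
    ]
)
QUARTETS = pd.DataFrame(
    [{"ad_gene": "x", "ai_gene": "y", "at_gene": "gA", "bt_gene": "gB"}],
    index=pd.RangeIndex(1, name="quartet"),
)


def _uniform_calls(chrom, level, start=0, end=8000, step=25, context="CG"):
    c = int(level * 10)
    return make_calls([(chrom, p, "+", context, c, 10) for p in range(start + 1, end, step)])


class TestHomoeologMethDiff:
    def test_identical_methylomes_give_zero(self):
        calls = {
            "At": _uniform_calls("At_c", 0.5),
            "Bt": _uniform_calls("Bt_c", 0.5),
        }
        diff = ig.homoeolog_meth_diff(calls, GENES, QUARTETS, contexts=("CG",))
        assert np.allclose(diff["delta_m"], 0.0)

    def test_body_difference_recovered(self):
        calls = {
            "At": _uniform_calls("At_c", 0.8),
            "Bt": _uniform_calls("Bt_c", 0.1),
        }
        diff = ig.homoeolog_meth_diff(calls, GENES, QUARTETS, contexts=("CG",))
        body = diff[(diff["region"] == "body")].iloc[0]
        assert body["delta_m"] == pytest.approx(0.7)

    def test_missing_side_flagged_nan(self):
        calls = {
            "At": _uniform_calls("At_c", 0.8),
            "Bt": make_calls([]),  # no coverage on the B side
        }
        diff = ig.homoeolog_meth_diff(calls, GENES, QUARTETS, contexts=("CG",))
        assert diff["delta_m"].isna().all()


class TestClassifyAssociations:
    def _diff(self, delta, context="CHG", region="body"):
        return pd.DataFrame(
            [{"quartet": 0, "region": region, "context": context,
              "level_a": np.nan, "level_b": np.nan, "delta_m": delta}]
        )

    def test_negative_association(self):
        rec = ig.classify_associations(self._diff(0.6), pd.Series({0: -3.0})).iloc[0]
        assert rec["classified"] and rec["direction"] == "negative"

    def test_positive_association(self):
        rec = ig.classify_associations(self._diff(0.5, "CG"), pd.Series({0: 2.0})).iloc[0]
        assert rec["classified"] and rec["direction"] == "positive"

    def test_chh_cutoff_strict(self):
        rec = ig.classify_associations(self._diff(0.08, "CHH"), pd.Series({0: -3.0})).iloc[0]
        assert not rec["classified"]

    def test_missing_delta_never_classified(self):
        rec = ig.classify_associations(self._diff(np.nan), pd.Series({0: -3.0})).iloc[0]
        assert not rec["classified"]


class TestAssociationSignTest:
    def _assoc(self, n_neg, n_pos):
        rows = [
            {"quartet": i, "region": "body", "context": "CHG", "classified": True,
             "direction": "negative" if i < n_neg else "positive"}
            for i in range(n_neg + n_pos)
        ]
        return pd.DataFrame(rows)

    def test_balanced_is_one(self):
        res = ig.association_sign_test(self._assoc(30, 30))
        assert res.iloc[0]["p"] == 1.0

    def test_onesided_extreme_matches_closed_form(self):
        res = ig.association_sign_test(self._assoc(60, 0))
        assert res.iloc[0]["p"] == pytest.approx(2 * 0.5**60, rel=1e-12)

    def test_counts_conserved(self):
        res = ig.association_sign_test(self._assoc(13, 7))
        assert res.iloc[0]["n_negative"] + res.iloc[0]["n_positive"] == 20


class TestDegDmgEnrichment:
    def test_independent_table_chi2_zero(self):
        universe = {f"g{i}" for i in range(200)}
        dmgs = {f"g{i}" for i in range(100)}
        degs = {f"g{i}" for i in range(0, 200, 2)}  # half in each stratum
        res = ig.deg_dmg_enrichment(degs, dmgs, universe)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_chi2(self):
        # 2x2 table (30,10 / 10,30): Pearson chi2 = 20, p ~ 7.7e-6
        universe = {f"g{i}" for i in range(80)}
        dmgs = {f"g{i}" for i in range(40)}
        degs = {f"g{i}" for i in range(30)} | {f"g{i}" for i in range(40, 50)}
        res = ig.deg_dmg_enrichment(degs, dmgs, universe)
        assert res.chi2 == pytest.approx(20.0)
        assert res.p == pytest.approx(7.744e-6, rel=1e-3)
        assert res.prop_deg_in_dmg == pytest.approx(30 / 40)
        assert res.prop_deg_universe == pytest.approx(40 / 80)

    def test_small_expected_falls_back_to_fisher(self):
        universe = {f"g{i}" for i in range(10)}
        with pytest.warns(UserWarning, match="Fisher"):
            res = ig.deg_dmg_enrichment({"g0"}, {"g0", "g1"}, universe)
        assert res.method == "fisher"

    def test_subset_violation_rejected(self):
        with pytest.raises(ParameterError):
            ig.deg_dmg_enrichment({"zz"}, set(), {"g0"})


class TestCorrelateMethExpr:
    def test_antimonotone_is_minus_one(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [9, 7, 5, 3, 2, 1]
        rho, _ = ig.correlate_meth_expr(x, y)
        assert rho == pytest.approx(-1.0)

    def test_null_simulation_small_rho(self, rng):
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        rho, _ = ig.correlate_meth_expr(x, y)
        assert abs(rho) < 0.1

    def test_constant_vector_is_missing(self):
        rho, p = ig.correlate_meth_expr([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ParameterError):
            ig.correlate_meth_expr([1, 2, np.nan], [1, 2, 3])

    def test_pearson_flag(self):
        rho, _ = ig.correlate_meth_expr([1, 2, 3, 4, 5], [2, 4, 6, 8, 10], "pearson")
        assert rho == pytest.approx(1.0)


def _stage_fixture(rng, plant=False):
    """Two stages on one genome; optionally plant coupled CHH + expression shifts."""
    genes = pd.DataFrame(
        [
            {"gene_id": f"g{i}", "chrom": "c", "start": 5000 * i + 2000,
             "end": 5000 * i + 3000, "strand": "+", "length": 1000}
            for i in range(20)
        ]
    )
    windows = tile_windows([("c", 0, 100_000)], 100)
    base_rows = []
    for p in range(1, 100_000, 20):
        base_rows.append(("c", p, "+", "CHH", 1, 10))
        base_rows.append(("c", p + 7, "+", "CG", 5, 10))
    base = make_calls(base_rows)
    shifted = base.copy()
    if plant:
        # CHH hypermethylation over the bodies of the first 4 genes
        for i in range(4):
            lo, hi = 5000 * i + 2000, 5000 * i + 3000
            sel = (shifted["pos"] > lo) & (shifted["pos"] <= hi) & (shifted["context"] == "CHH")
            shifted.loc[sel, "c_count"] = 9
    meth_samples = {
        "s20_1": base, "s20_2": base.copy(),
        "s40_1": shifted, "s40_2": shifted.copy(),
    }
    meth_stages = {"s20_1": "20DAP", "s20_2": "20DAP", "s40_1": "40DAP", "s40_2": "40DAP"}
    mu = np.full(20, 200.0)
    mat = {f"e20_{r}": rng.poisson(mu) for r in range(3)}
    mu2 = mu.copy()
    if plant:
        mu2[:4] *= 8  # the CHH-hyper genes are the differentially expressed ones
    mat.update({f"e40_{r}": rng.poisson(mu2) for r in range(3)})
    counts = pd.DataFrame(mat, index=genes["gene_id"])
    expr_stages = {s: ("20DAP" if s.startswith("e20") else "40DAP") for s in mat}
    lengths = genes.set_index("gene_id")["length"]
    return windows, meth_samples, meth_stages, counts, lengths, expr_stages, genes


class TestStageComparison:
    def test_identical_stages_produce_nothing(self, rng):
        windows, ms, mstg, counts, lengths, estg, genes = _stage_fixture(rng, plant=False)
        # make expression identical across stages too
        for r in range(3):
            counts[f"e40_{r}"] = counts[f"e20_{r}"]
        rep = ig.stage_comparison(windows, ms, mstg, counts, lengths, estg, genes, "20DAP")
        assert rep["40DAP"]["dmr_counts"].empty
        assert rep["40DAP"]["n_deg"] == 0

    def test_planted_chh_hyper_dominates_association(self, rng):
        windows, ms, mstg, counts, lengths, estg, genes = _stage_fixture(rng, plant=True)
        rep = ig.stage_comparison(windows, ms, mstg, counts, lengths, estg, genes, "20DAP")
        stage = rep["40DAP"]
        dmrc = stage["dmr_counts"].set_index(["context", "direction"])["count"]
        assert dmrc.idxmax() == ("CHH", "hyper")
        assoc = stage["deg_dmr_association"]
        top = assoc.sort_values("n_deg_associated", ascending=False).iloc[0]
        assert (top["context"], top["direction"]) == ("CHH", "hyper")
        assert top["n_deg_associated"] == 4
        assert stage["enrichment"].p < 0.05

    def test_unknown_baseline_rejected(self, rng):
        windows, ms, mstg, counts, lengths, estg, genes = _stage_fixture(rng)
        with pytest.raises(ConfigError):
            ig.stage_comparison(windows, ms, mstg, counts, lengths, estg, genes, "nope")


class TestLiftCalls:
    def test_identity_block_relabel(self):
        from allometh.dmr import CollinearBlock
        calls = make_calls([("t", 10, "+", "CG", 1, 2)])
        blocks = [CollinearBlock("q", 0, 100, "t", 0, 100, 9000, "same")]
        out = ig.lift_calls_to_query(calls, blocks)
        assert out.iloc[0]["chrom"] == "q" and out.iloc[0]["pos"] == 10

    def test_inverted_block_flips_strand_and_coordinate(self):
        from allometh.dmr import CollinearBlock
        calls = make_calls([("t", 1, "+", "CG", 1, 2), ("t", 100, "-", "CG", 1, 2)])
        blocks = [CollinearBlock("q", 0, 100, "t", 0, 100, 9000, "inverted")]
        out = ig.lift_calls_to_query(calls, blocks).sort_values("pos").reset_index(drop=True)
        # 1-based pos 1 maps to pos 100 and vice versa
        assert list(out["pos"]) == [1, 100]
        assert list(out["strand"]) == ["+", "-"]

    def test_sites_outside_blocks_dropped(self):
        from allometh.dmr import CollinearBlock
        calls = make_calls([("t", 500, "+", "CG", 1, 2)])
        blocks = [CollinearBlock("q", 0, 100, "t", 0, 100, 9000, "same")]
        assert ig.lift_calls_to_query(calls, blocks).empty


class TestRunPipeline:
    CFG = {"sim": {"n_quartets": 12, "chrom_length_bp": 60_000, "seed": 17}}

    def test_summary_is_deterministic(self, tmp_path):
        s1 = ig.run_pipeline(self.CFG, tmp_path / "run1")
        s2 = ig.run_pipeline(self.CFG)
        assert json.dumps(s1, sort_keys=True, default=float) == json.dumps(
            s2, sort_keys=True, default=float
        )
        assert (tmp_path / "run1" / "summary.json").exists()

    def test_bias_partition_consistency(self):
        s = ig.run_pipeline(self.CFG)
        assert sum(s["bias_counts"].values()) == self.CFG["sim"]["n_quartets"]
        assert sum(s["eld_counts"].values()) == self.CFG["sim"]["n_quartets"]
        for sid, rate in s["conversion_rate"].items():
            assert 0.98 < rate <= 1.0
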