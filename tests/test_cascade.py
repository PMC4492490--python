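"""Consensus targets, the two association levels, selection, prioritisation."""

import numpy as np
import pandas as pd
import pytest

import mirdosage as md

TOOLS = ("targetscan", "pita", "microcosm", "mirtarbase")


def catalog(tool, pairs):
    return md.TargetPredictionCatalog(tool, frozenset(pairs))


class TestConsensusTargets:
    def _catalogs(self):
        # engineered overlaps for miRNA "m": g1 in 4 tools, g2 in 3,
        # g3 in 2, g4 in 1, g5 in 3
        presence = {"g1": 4, "g2": 3, "g3": 2, "g4": 1, "g5": 3}
        cats = []
        for i, tool in enumerate(TOOLS):
            pairs = {("m", g) for g, k in presence.items() if i < k}
            cats.append(catalog(tool, pairs))
        return cats

    def test_support_counts_match_hand_tally(self):
        cs = md.consensus_targets(self._catalogs(), "m", min_tools=3)
        assert cs.genes == {"g1", "g2", "g5"}
        assert cs.support == {"g1": 4, "g2": 3, "g5": 3}

    def test_gene_in_all_four_included(self):
        cs = md.consensus_targets(self._catalogs(), "m", min_tools=4)
        assert cs.genes == {"g1"}

    def test_two_of_four_excluded_at_min_three(self):
        cs = md.consensus_targets(self._catalogs(), "m", min_tools=3)
        assert "g3" not in cs.genes

    def test_absent_mirna_empty_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="mirdosage"):
            cs = md.consensus_targets(self._catalogs(), "nope", min_tools=3)
        assert cs.genes == set()
        assert "absent" in caplog.text

    def test_too_few_catalogs_rejected(self):
        with pytest.raises(ValueError, match="min_tools"):
            md.consensus_targets(self._catalogs()[:2], "m", min_tools=3)


class TestSelectCandidates:
    def test_printed_fdr_columns_joint(self, table1):
        cn, tg = table1
        selected = md.select_candidates(cn, tg, 0.05)
        assert set(selected) == {"hsa-mir-15a", "hsa-mir-17", "hsa-mir-20a"}

    def test_printed_copy_number_column_alone(self, table1):
        cn, _ = table1
        assert (cn["fdr"] < 0.05).sum() == 6

    def test_not_determined_never_selected(self, table1):
        cn, tg = table1
        # give every n.d. miRNA a perfect copy-number FDR: still unselectable
        cn = cn.assign(fdr=0.0)
        selected = md.select_candidates(cn, tg, 0.05)
        nd = set(tg.loc[~tg["determined"], "mirna"])
        assert not nd & set(selected)

    def test_empty_input_empty_output(self):
        empty = pd.DataFrame(columns=["mirna", "fdr", "determined"])
        assert md.select_candidates(empty, empty, 0.05) == []

    def test_monotone_in_alpha(self, table1):
        cn, tg = table1
        small = set(md.select_candidates(cn, tg, 0.005))
        large = set(md.select_candidates(cn, tg, 0.10))
        assert small <= large


class TestPrintedTargetFilter:
    def test_five_genes_four_negative_one_positive(self, table2):
        kept = md.filter_printed_targets(table2, p_cut=0.01)
        assert len(kept) == 5
        assert (kept["sign"] == "negative").sum() == 4
        assert (kept["sign"] == "positive").sum() == 1

    def test_strictly_larger_p_still_excluded(self, table2):
        extra = pd.concat([table2, pd.DataFrame(
            [("NOPE", "1q", 0.011, "negative")], columns=table2.columns)])
        kept = md.filter_printed_targets(extra, p_cut=0.01)
        assert "NOPE" not in set(kept["gene"])


def _expr(values, samples, annotation=None):
    return md.ExpressionMatrix(pd.DataFrame(values, columns=samples), annotation)


class TestAssociateCN:
    def _setup(self, seed=0, n=60, planted_slope=2.0):
        rng = np.random.default_rng(seed)
        genome = {"chr13": 100_000_000}
        samples = [f"S{i}" for i in range(n)]
        gain = rng.random(n) < 0.5
        cn_level = np.where(gain, rng.normal(0.4, 0.05, n), rng.normal(0, 0.05, n))
        profiles = [
            md.SegmentedCNProfile(s, pd.DataFrame(
                [("chr13", 0, 100_000_000, v)],
                columns=["chrom", "start", "end", "value"]))
            for s, v in zip(samples, cn_level)
        ]
        gridcn = md.segments_to_grid(profiles, md.build_grid(genome, 500))
        ids = [f"mir-{i}" for i in range(11)]
        vals = rng.normal(6, 0.5, size=(11, n))
        vals[0] += planted_slope * cn_level  # mir-0 is the dosage miRNA
        ann = pd.DataFrame({"chrom": "chr13",
                            "start": np.linspace(5e6, 95e6, 11).astype(int)},
                           index=ids)
        mirnas = md.ExpressionMatrix(
            pd.DataFrame(vals, index=ids, columns=samples), ann)
        cfg = md.AnalysisConfig(seed=seed, permutations=999, grid_points=500)
        return mirnas, gridcn, cfg

    def test_planted_dosage_mirna_has_smallest_fdr(self):
        mirnas, gridcn, cfg = self._setup()
        res = md.associate_cn(mirnas, gridcn, cfg)
        best = res.loc[res["fdr"].idxmin(), "mirna"]
        assert best == "mir-0"
        assert res.set_index("mirna").loc["mir-0", "fdr"] < 0.05

    def test_constant_cn_gives_p_one(self):
        mirnas, _, cfg = self._setup()
        samples = mirnas.sample_ids
        profiles = [
            md.SegmentedCNProfile(s, pd.DataFrame(
                [("chr13", 0, 100_000_000, 0.0)],
                columns=["chrom", "start", "end", "value"]))
            for s in samples
        ]
        gridcn = md.segments_to_grid(profiles, md.build_grid({"chr13": 100_000_000}, 500))
        res = md.associate_cn(mirnas, gridcn, cfg)
        assert (res["p"] == 1.0).all()
        assert (res["statistic"] == 0.0).all()

    def test_duplicated_mirna_row_identical_p(self):
        mirnas, gridcn, cfg = self._setup()
        dup_vals = pd.concat([mirnas.values,
                              mirnas.values.loc[["mir-0"]].rename(index={"mir-0": "dup"})])
        dup_ann = pd.concat([mirnas.annotation,
                             mirnas.annotation.loc[["mir-0"]].rename(index={"mir-0": "dup"})])
        dup = md.ExpressionMatrix(dup_vals, dup_ann)
        res = md.associate_cn(dup, gridcn, cfg).set_index("mirna")
        assert res.loc["dup", "p"] == res.loc["mir-0", "p"]

    def test_unannotated_mirna_skipped_with_warning(self, caplog):
        mirnas, gridcn, cfg = self._setup()
        ann = mirnas.annotation.drop(index="mir-5")
        m2 = md.ExpressionMatrix(mirnas.values, ann)
        with caplog.at_level("WARNING", logger="mirdosage"):
            res = md.associate_cn(m2, gridcn, cfg)
        assert "mir-5" not in set(res["mirna"]) and "mir-5" in caplog.text


class TestAssociateTargets:
    def _setup(self, seed=1, n=60, coupled=5, n_targets=20, slope=-0.7):
        rng = np.random.default_rng(seed)
        samples = [f"S{i}" for i in range(n)]
        y = rng.normal(6, 1, size=n)
        mirnas = md.ExpressionMatrix(
            pd.DataFrame([y], index=["mir-a"], columns=samples))
        genes = [f"g{i}" for i in range(n_targets)]
        vals = rng.normal(7, 0.5, size=(n_targets, n))
        for i in range(coupled):
            vals[i] += slope * (y - y.mean())
        mrnas = md.ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples))
        cset = md.ConsensusTargetSet("mir-a", set(genes), {g: 3 for g in genes})
        cfg = md.AnalysisConfig(seed=seed, permutations=999)
        return mirnas, mrnas, cset, cfg

    def test_planted_repression_detected(self):
        mirnas, mrnas, cset, cfg = self._setup()
        res = md.associate_targets(mirnas, mrnas, {"mir-a": cset}, cfg)
        row = res.set_index("mirna").loc["mir-a"]
        assert bool(row["determined"]) and row["fdr"] < 0.05

    def test_empty_consensus_not_determined(self):
        mirnas, mrnas, _, cfg = self._setup()
        empty = md.ConsensusTargetSet("mir-a", set(), {})
        res = md.associate_targets(mirnas, mrnas, {"mir-a": empty}, cfg)
        row = res.set_index("mirna").loc["mir-a"]
        assert not row["determined"] and np.isnan(row["fdr"])

    def test_independent_targets_null_p(self):
        # pooled p across replicates of a null coupling is roughly uniform
        ps = []
        for seed in range(40):
            mirnas, mrnas, cset, cfg = self._setup(seed=seed + 100, coupled=0)
            res = md.associate_targets(mirnas, mrnas, {"mir-a": cset}, cfg)
            ps.append(float(res["p"].iloc[0]))
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01


class TestPrioritizeTargets:
    def test_self_target_minimal_p_positive(self):
        rng = np.random.default_rng(3)
        n = 30
        samples = [f"S{i}" for i in range(n)]
        y = rng.normal(size=n)
        mirnas = md.ExpressionMatrix(pd.DataFrame([y], index=["m"], columns=samples))
        vals = pd.DataFrame([y, rng.normal(size=n)], index=["self", "noise"],
                            columns=samples)
        mrnas = md.ExpressionMatrix(vals)
        cset = md.ConsensusTargetSet("m", {"self", "noise"}, {"self": 4, "noise": 4})
        cfg = md.AnalysisConfig(seed=3, permutations=999)
        res = md.prioritize_targets("m", mirnas, mrnas, cset, cfg)
        assert res["gene"].iloc[0] == "self"
        assert res["sign"].iloc[0] == "positive"
        assert res["p"].iloc[0] == pytest.approx(1 / 1000)

    def test_planted_repressed_gene_retained_negative(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 60
            samples = [f"S{i}" for i in range(n)]
            y = rng.normal(size=n)
            t = -0.8 * y + rng.normal(0, 0.5, size=n)
            mirnas = md.ExpressionMatrix(
                pd.DataFrame([y], index=["m"], columns=samples))
            mrnas = md.ExpressionMatrix(
                pd.DataFrame([t], index=["g"], columns=samples))
            cset = md.ConsensusTargetSet("m", {"g"}, {"g": 3})
            cfg = md.AnalysisConfig(seed=seed, permutations=999)
            res = md.prioritize_targets("m", mirnas, mrnas, cset, cfg)
            hits += len(res) == 1 and res["sign"].iloc[0] == "negative"
        assert hits >= 95

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(4)
        n = 40
        samples = [f"S{i}" for i in range(n)]
        y = rng.normal(size=n)
        genes = [f"g{i}" for i in range(6)]
        vals = -0.5 * y + rng.normal(0, 0.4, size=(6, n))
        mrnas = md.ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples))
        mirnas = md.ExpressionMatrix(pd.DataFrame([y], index=["m"], columns=samples))
        cfg = md.AnalysisConfig(seed=4, permutations=999)
        a = md.prioritize_targets("m", mirnas, mrnas,
                                  md.ConsensusTargetSet("m", set(genes), {}), cfg)
        b = md.prioritize_targets("m", mirnas, mrnas,
                                  md.ConsensusTargetSet("m", set(reversed(genes)), {}), cfg)
        pd.testing.assert_frame_equal(a, b)


class TestRunCascade:
    def test_small_cohort_end_to_end(self, small_cohort, small_gridcn, small_config):
        res = md.run_cascade(small_cohort.mirna, small_cohort.mrna, small_gridcn,
                             small_cohort.catalogs, small_config)
        assert len(res.summary) == 14
        assert set(res.summary.columns) >= {"mirna", "cn_p", "cn_fdr",
                                            "target_fdr", "selected"}
        assert set(res.selected) == set(res.summary.loc[res.summary["selected"],
                                                        "mirna"])
        # every prioritised target row respects the raw-p cut
        if len(res.targets):
            assert (res.targets["p"] < small_config.target_p_cut).all()
            assert set(res.targets["mirna"]) <= set(res.selected)
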