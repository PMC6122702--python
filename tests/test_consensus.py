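import itertools

import numpy as np
import pandas as pd
import pytest

from mimicmap.concordance import (aggregate_by_process, assign_hmg_mimicry,
                                  average_z_rank, classify_concordance,
                                  consensus_pair, consensus_select,
                                  top_core_genes, zscore_fold)
from mimicmap.diffexpr import DiffExprTable
from mimicmap.io_formats import HMGList


def make_table(dataset_id, rows, contrast=("poorly_diff", "well_diff")):
    """rows: list of (symbol, logFC, p) or (symbol, logFC, p, adj_p)."""
    recs = []
    for r in rows:
        symbol, logfc, p = r[0], r[1], r[2]
        adj = r[3] if len(r) > 3 else min(1.0, p * 2)
        recs.append((symbol, logfc, np.sign(logfc) * 2.0, p, adj, 1, False))
    frame = pd.DataFrame(recs, columns=["symbol", "logFC", "t", "p", "adj_p",
                                        "n_probes", "ambiguous"])
    return DiffExprTable(dataset_id=dataset_id, contrast=contrast, rows=frame)


# status -> (logFC, p) per dataset; "absent" omits the gene
STATUS = {"up": (1.0, 0.01), "down": (-1.0, 0.01), "ns": (0.5, 0.5)}


class TestConsensusSelect:
    def test_two_of_three_supporters(self):
        tables = [make_table("D1", [("GLS", 1.0, 0.01)]),
                  make_table("D2", [("GLS", 0.8, 0.02)]),
                  make_table("D3", [("OTHER", 1.0, 0.01)])]
        cs = consensus_select(tables, "up", k_min=2, alpha=0.05)
        assert cs.members == {"GLS": frozenset({"D1", "D2"})}

    def test_opposite_direction_qualifiers_excluded_from_both(self):
        tables = [make_table("D1", [("G", 1.0, 0.01)]),
                  make_table("D2", [("G", -1.0, 0.01)])]
        up, down, excluded = consensus_pair(tables, k_min=1, alpha=0.05)
        assert "G" not in up and "G" not in down and excluded == {"G"}

    def test_k_min_exceeding_tables_rejected(self):
        tables = [make_table("D1", [("G", 1.0, 0.01)])]
        with pytest.raises(ValueError, match="k_min"):
            consensus_select(tables, "up", k_min=2)

    def test_all_27_status_patterns_match_brute_force(self):
        """Exhaustive check of the k-of-n rule with exclusivity over every
        (up-sig / down-sig / ns) pattern across three datasets."""
        k_min = 2
        patterns = list(itertools.product(STATUS, repeat=3))
        genes = [f"G{i:02d}" for i in range(len(patterns))]
        tables = []
        for d in range(3):
            rows = [(g, *STATUS[pat[d]]) for g, pat in zip(genes, patterns)]
            tables.append(make_table(f"D{d}", rows))
        up = consensus_select(tables, "up", k_min=k_min, alpha=0.05)
        down = consensus_select(tables, "down", k_min=k_min, alpha=0.05)
        for g, pat in zip(genes, patterns):
            n_up = sum(s == "up" for s in pat)
            n_down = sum(s == "down" for s in pat)
            expect_up = n_up >= k_min and not n_down >= k_min
            expect_down = n_down >= k_min and not n_up >= k_min
            assert (g in up) == expect_up, (g, pat)
            assert (g in down) == expect_down, (g, pat)

    def test_membership_monotone_in_alpha_and_k_min(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(40)]
        tables = [make_table(f"D{d}", [(g, rng.normal(), rng.uniform())
                                       for g in genes]) for d in range(3)]
        base = consensus_select(tables, "up", k_min=2, alpha=0.05).genes
        looser_alpha = consensus_select(tables, "up", k_min=2, alpha=0.2).genes
        lower_k = consensus_select(tables, "up", k_min=1, alpha=0.05).genes
        # raising alpha or lowering k_min may move genes into the exclusion
        # zone only if they also qualify down; restrict to one-signed genes
        one_signed = {g for g in genes if all(
            t.rows.set_index("symbol").loc[g, "logFC"] > 0 for t in tables)}
        assert base & one_signed <= looser_alpha
        assert base & one_signed <= lower_k

    def test_ambiguous_rows_ignored(self):
        t1 = make_table("D1", [("G", 1.0, 0.01)])
        t1.rows.loc[0, "ambiguous"] = True
        t2 = make_table("D2", [("G", 1.0, 0.01)])
        cs = consensus_select([t1, t2], "up", k_min=2)
        assert "G" not in cs


class TestTopCoreGenes:
    def test_identical_tables_give_their_own_top_n(self):
        rows = [(f"G{i:02d}", 1.0 + i * 0.1, 1e-6, 1e-6 * (i + 1))
                for i in range(10)]
        tables = [make_table(f"D{d}", rows) for d in range(3)]
        core = top_core_genes(tables, "up", n=5, alpha_adj=1e-4)
        assert core == [f"G{i:02d}" for i in range(5)]

    def test_disjoint_top_lists_give_empty_result(self):
        t1 = make_table("D1", [("A", 1.0, 1e-6, 1e-6)])
        t2 = make_table("D2", [("B", 1.0, 1e-6, 1e-6)])
        assert top_core_genes([t1, t2], "up", n=1) == []

    def test_random_instance_matches_brute_force_sets(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i:02d}" for i in range(30)]
        tables = []
        for d in range(3):
            rows = [(g, float(rng.choice([-1, 1])) * rng.uniform(0.5, 2),
                     rng.uniform(0, 1e-3), rng.uniform(0, 2e-4))
                    for g in genes]
            tables.append(make_table(f"D{d}", rows))
        n, alpha_adj = 8, 1e-4
        core = set(top_core_genes(tables, "up", n=n, alpha_adj=alpha_adj))
        expected = None
        for t in tables:
            r = t.rows[t.rows["logFC"] > 0].copy()
            r["_a"] = r["logFC"].abs()
            top = set(r.sort_values(["adj_p", "_a", "symbol"],
                                    ascending=[True, False, True]).head(n)["symbol"])
            expected = top if expected is None else expected & top
        adj = {t.dataset_id: t.rows.set_index("symbol")["adj_p"] for t in tables}
        expected = {g for g in expected
                    if all(a.loc[g] < alpha_adj for a in adj.values())}
        assert core == expected


class TestZScore:
    def test_hand_computed_z(self):
        t = make_table("D", [("A", 1.0, 0.01), ("B", 2.0, 0.01),
                             ("C", 3.0, 0.01)])
        z = zscore_fold(t)
        np.testing.assert_allclose(z.loc[["A", "B", "C"]], [-1, 0, 1])

    def test_all_equal_fold_changes_give_zero(self):
        t = make_table("D", [("A", 1.0, 0.01), ("B", 1.0, 0.01)])
        assert (zscore_fold(t) == 0).all()

    def test_normalization_property(self):
        rng = np.random.default_rng(8)
        rows = [(f"G{i}", rng.normal(), 0.01) for i in range(50)]
        z = zscore_fold(make_table("D", rows))
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1, rel=1e-12)

    def test_only_significant_genes_used(self):
        t = make_table("D", [("A", 1.0, 0.01), ("B", 3.0, 0.01),
                             ("C", 100.0, 0.9)])
        assert set(zscore_fold(t).index) == {"A", "B"}

    def test_fewer_than_two_genes_rejected(self):
        t = make_table("D", [("A", 1.0, 0.01)])
        with pytest.raises(ValueError, match=">=2 genes"):
            zscore_fold(t)


class TestAverageZRank:
    def test_single_dataset_preserves_order(self):
        z = pd.Series([2.0, -1.0, 0.5], index=["A", "B", "C"])
        out = average_z_rank({"T1": z}, ["A", "B", "C"])
        assert list(out["symbol"]) == ["A", "C", "B"]
        assert list(out["rank"]) == [1, 2, 3]

    def test_average_over_available_datasets(self):
        z1 = pd.Series([1.0], index=["G"])
        z2 = pd.Series([2.0], index=["G"])
        out = average_z_rank({"T1": z1, "T2": z2}, ["G"])
        assert out.loc[0, "avg_z"] == pytest.approx(1.5)

    def test_invariant_to_dataset_order_and_affine_rescaling(self):
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(20)]
        rows = {d: [(g, rng.normal(), 0.01) for g in genes] for d in "XY"}
        tables = {d: make_table(d, rows[d]) for d in "XY"}
        profiles = {d: zscore_fold(tables[d]) for d in "XY"}
        base = average_z_rank(profiles, genes)
        flipped = average_z_rank(dict(reversed(list(profiles.items()))), genes)
        assert list(base["symbol"]) == list(flipped["symbol"])
        # positive affine rescale of logFC leaves z, hence ranks, unchanged
        scaled = {d: [(g, 3.0 * lf + 7.0, p) for g, lf, p in rows[d]]
                  for d in "XY"}
        rescaled = {d: zscore_fold(make_table(d, scaled[d])) for d in "XY"}
        out = average_z_rank(rescaled, genes)
        assert list(out["symbol"]) == list(base["symbol"])

    def test_missing_everywhere_sorts_last(self):
        z = pd.Series([1.0], index=["A"])
        out = average_z_rank({"T1": z}, ["A", "MISSING"])
        assert list(out["symbol"]) == ["A", "MISSING"]
        assert np.isnan(out.loc[1, "avg_z"])


class TestClassifyConcordance:
    def tumours(self, gene_sign_p):
        """gene_sign_p: per dataset list of (gene, logFC, p)."""
        return [make_table(f"T{i}", rows, contrast=("tumour", "non_tumour"))
                for i, rows in enumerate(gene_sign_p)]

    def consensus_of(self, direction, genes):
        from mimicmap.concordance import ConsensusGeneSet
        return ConsensusGeneSet(direction, 1, 0.05,
                                {g: frozenset({"D1"}) for g in genes})

    def test_down_in_cells_up_in_tumours_is_discordant(self):
        # the AFP/GPC3 pattern: low in poorly differentiated lines yet
        # consistently upregulated in liver tumour datasets
        tumours = self.tumours([[("AFP", 2.0, 0.001)]] * 3)
        calls = classify_concordance(self.consensus_of("down", ["AFP"]), tumours)
        assert calls[0].call == "discordant"
        assert calls[0].tumour_direction == "up"

    def test_down_in_both_settings_is_concordant(self):
        tumours = self.tumours([[("FABP1", -2.0, 0.001)]] * 4)
        calls = classify_concordance(self.consensus_of("down", ["FABP1"]), tumours)
        assert calls[0].call == "concordant"

    def test_no_significant_tumour_evidence_is_unclassified(self):
        tumours = self.tumours([[("G", 1.0, 0.4)], [("G", -1.0, 0.6)]])
        calls = classify_concordance(self.consensus_of("up", ["G"]), tumours)
        assert calls[0].call == "unclassified"
        assert calls[0].tumour_direction == "none"

    def test_exact_sign_tie_is_unclassified(self):
        tumours = self.tumours([[("G", 1.0, 0.01)], [("G", -1.0, 0.01)]])
        calls = classify_concordance(self.consensus_of("up", ["G"]), tumours)
        assert calls[0].call == "unclassified"

    def test_every_gene_gets_exactly_one_call(self):
        rng = np.random.default_rng(9)
        genes = [f"G{i}" for i in range(30)]
        tumours = self.tumours([
            [(g, rng.normal(), rng.uniform()) for g in genes]
            for _ in range(4)])
        calls = classify_concordance(self.consensus_of("up", genes), tumours)
        assert sorted(c.gene for c in calls) == sorted(genes)
        assert all(c.call in {"concordant", "discordant", "unclassified"}
                   for c in calls)


class TestMimicry:
    UP = HMGList("up", frozenset({"GLS", "HK2"}))
    DOWN = HMGList("down", frozenset({"FABP1", "CPS1"}))

    def test_upregulated_gene_higher_in_hle_assigned_hle(self):
        deltas = {"DELTA_A": {"GLS": 2.0}, "DELTA_B": {"GLS": 1.5}}
        out = assign_hmg_mimicry(self.UP, HMGList("down", frozenset({"X"})),
                                 deltas)
        gls = [a for a in out if a.gene == "GLS"][0]
        assert gls.assigned_to == "HLE"

    def test_upregulated_gene_lower_in_hle_assigned_huh7(self):
        deltas = {"DELTA_A": {"HK2": -2.0}, "DELTA_B": {"HK2": -1.0}}
        out = assign_hmg_mimicry(self.UP, HMGList("down", frozenset({"X"})),
                                 deltas)
        hk2 = [a for a in out if a.gene == "HK2"][0]
        assert hk2.assigned_to == "HUH7"

    def test_downregulated_gene_lower_in_hle_assigned_hle(self):
        deltas = {"DELTA_A": {"FABP1": -1.0}, "DELTA_B": {"FABP1": -2.0}}
        out = assign_hmg_mimicry(HMGList("up", frozenset({"X"})), self.DOWN,
                                 deltas)
        fabp1 = [a for a in out if a.gene == "FABP1"][0]
        assert fabp1.assigned_to == "HLE"

    def test_disagreeing_delta_signs_are_ambiguous(self):
        deltas = {"DELTA_A": {"GLS": 2.0}, "DELTA_B": {"GLS": -1.0}}
        out = assign_hmg_mimicry(self.UP, HMGList("down", frozenset({"X"})),
                                 deltas)
        gls = [a for a in out if a.gene == "GLS"][0]
        assert gls.assigned_to == "ambiguous"

    def test_gene_absent_from_one_table_excluded(self):
        deltas = {"DELTA_A": {"GLS": 2.0, "HK2": 1.0}, "DELTA_B": {"HK2": 1.0}}
        out = assign_hmg_mimicry(self.UP, HMGList("down", frozenset({"X"})),
                                 deltas)
        assert {a.gene for a in out} == {"HK2"}

    def test_requires_exactly_two_delta_tables(self):
        with pytest.raises(ValueError, match="exactly 2"):
            assign_hmg_mimicry(self.UP, self.DOWN, {"A": {"GLS": 1.0}})

    def test_protein_support_and_veto(self):
        deltas = {"DELTA_A": {"GLS": 2.0}, "DELTA_B": {"GLS": 1.0}}
        down = HMGList("down", frozenset({"X"}))
        agree = assign_hmg_mimicry(self.UP, down, deltas,
                                   protein_folds={"GLS": 3.0})
        assert agree[0].protein_support == "agrees"
        disagree = assign_hmg_mimicry(self.UP, down, deltas,
                                      protein_folds={"GLS": 0.4})
        assert disagree[0].protein_support == "disagrees"
        assert disagree[0].assigned_to == "HLE"  # advisory by default
        vetoed = assign_hmg_mimicry(self.UP, down, deltas,
                                    protein_folds={"GLS": 0.4},
                                    protein_veto=True)
        assert vetoed[0].assigned_to == "ambiguous"


class TestAggregateByProcess:
    def make_assignments(self, specs):
        from mimicmap.concordance import MimicryAssignment
        return [MimicryAssignment(g, d, (("DELTA_A", "+"), ("DELTA_B", "+")),
                                  a) for g, d, a in specs]

    def test_counting(self):
        assignments = self.make_assignments(
            [(f"G{i}", "down", "HLE") for i in range(3)])
        out = aggregate_by_process(assignments,
                                   {f"G{i}": "urea cycle" for i in range(3)})
        row = out.iloc[0]
        assert (row["process"], row["cell_line"], row["direction"],
                row["count"]) == ("urea cycle", "HLE", "down", 3)

    def test_empty_assignments(self):
        assert len(aggregate_by_process([], {"G": "x"})) == 0

    def test_totals_conserved_and_unmapped_in_others(self):
        rng = np.random.default_rng(2)
        specs = [(f"G{i}", rng.choice(["up", "down"]),
                  rng.choice(["HLE", "HUH7", "ambiguous"])) for i in range(50)]
        assignments = self.make_assignments(specs)
        pmap = {f"G{i}": "glycolysis" for i in range(0, 50, 2)}
        out = aggregate_by_process(assignments, pmap)
        n_assigned = sum(1 for _, _, a in specs if a in ("HLE", "HUH7"))
        assert out["count"].sum() == n_assigned
        assert "Others" in set(out["process"])
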