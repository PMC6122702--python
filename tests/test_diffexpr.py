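import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mimicmap.diffexpr import (ShrinkageParams, bh_adjust, collapse_probes,
                               diffexpr_table, estimate_shrinkage,
                               moderated_t_test, read_geo2r_table)
from mimicmap.io_formats import ExpressionDataset

from conftest import make_dataset

UNMODERATED = ShrinkageParams(d0=0.0, s0_sq=1.0)


def one_probe_dataset(a_values, b_values):
    values = pd.DataFrame([list(a_values) + list(b_values)], index=["p1"],
                          columns=[f"A{i}" for i in range(len(a_values))]
                          + [f"B{i}" for i in range(len(b_values))])
    return ExpressionDataset(
        "ONE", "", values, {"p1": "GENE1"},
        {c: c[0] for c in values.columns})


class TestModeratedT:
    def test_identical_constant_groups_are_null(self):
        ds = one_probe_dataset([5, 5, 5], [5, 5, 5])
        out = moderated_t_test(ds, ("A", "B"), UNMODERATED)
        assert out.loc["p1", "logFC"] == 0
        assert out.loc["p1", "t"] == 0
        assert out.loc["p1", "p"] == 1

    def test_hand_computed_pooled_t(self):
        # A={1,2,3}, B={4,5,6}: s^2 = 1, se = sqrt(2/3), t = -3/se
        ds = one_probe_dataset([1, 2, 3], [4, 5, 6])
        out = moderated_t_test(ds, ("A", "B"), ShrinkageParams(0.0, 1.0))
        assert out.loc["p1", "logFC"] == pytest.approx(-3.0)
        assert abs(out.loc["p1", "t"]) == pytest.approx(3.0 / math.sqrt(2 / 3),
                                                        rel=1e-12)

    def test_d0_zero_equals_pooled_t(self, rng):
        ds = make_dataset(rng, n_probes=100, n_per_group=5)
        out = moderated_t_test(ds, ("A", "B"), ShrinkageParams(0.0, 1.0))
        a = ds.values.iloc[:, :5].to_numpy()
        b = ds.values.iloc[:, 5:].to_numpy()
        ref = stats.ttest_ind(a, b, axis=1)
        np.testing.assert_allclose(out["t"], ref.statistic, atol=1e-12)
        np.testing.assert_allclose(out["p"], ref.pvalue, atol=1e-12)

    def test_d0_infinite_limit_uses_prior_variance(self, rng):
        ds = make_dataset(rng, n_probes=20, n_per_group=4)
        s0 = 2.5
        out = moderated_t_test(ds, ("A", "B"),
                               ShrinkageParams(math.inf, s0))
        expected = out["logFC"] / math.sqrt(s0 * (1 / 4 + 1 / 4))
        np.testing.assert_allclose(out["t"], expected, rtol=1e-12)

    def test_welch_matches_scipy(self, rng):
        ds = make_dataset(rng, n_probes=50, n_per_group=6)
        out = moderated_t_test(ds, ("A", "B"), statistic="welch")
        a = ds.values.iloc[:, :6].to_numpy()
        b = ds.values.iloc[:, 6:].to_numpy()
        ref = stats.ttest_ind(a, b, axis=1, equal_var=False)
        np.testing.assert_allclose(out["t"], ref.statistic, atol=1e-12)
        np.testing.assert_allclose(out["p"], ref.pvalue, atol=1e-12)

    def test_small_group_rejected(self, rng):
        ds = make_dataset(rng, n_probes=5, n_per_group=1)
        with pytest.raises(ValueError, match=">=2 samples"):
            moderated_t_test(ds, ("A", "B"), UNMODERATED)

    def test_probes_with_missing_values_dropped(self, rng):
        ds = make_dataset(rng, n_probes=10, n_per_group=3)
        ds.values.iloc[0, :2] = np.nan  # only 1 finite value in group A
        out = moderated_t_test(ds, ("A", "B"), UNMODERATED)
        assert len(out) == 9 and "p000" not in out.index

    def test_matches_limma_reference(self, tmp_path, rng):
        """Independent cross-check of the whole engine against limma."""
        n, k = 200, 4
        values = (rng.normal(8, 1, (n, 2 * k))
                  * rng.uniform(0.5, 2.0, n)[:, None])
        frame = pd.DataFrame(values, index=[f"p{i}" for i in range(n)],
                             columns=[f"A{i}" for i in range(k)]
                             + [f"B{i}" for i in range(k)])
        matrix = tmp_path / "m.tsv"
        frame.to_csv(matrix, sep="\t")
        script = tmp_path / "ref.R"
        script.write_text(f"""
suppressMessages(library(limma))
x <- as.matrix(read.delim("{matrix}", row.names=1))
design <- model.matrix(~0 + factor(rep(c("A","B"), each={k})))
colnames(design) <- c("A","B")
fit <- eBayes(contrasts.fit(lmFit(x, design),
                            makeContrasts(A-B, levels=design)))
write.table(data.frame(t=fit$t[,1], p=fit$p.value[,1]),
            "{tmp_path}/ref.tsv", sep="\\t", quote=FALSE)
""")
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t")
        ds = ExpressionDataset("LIM", "", frame,
                               {p: p for p in frame.index},
                               {c: c[0] for c in frame.columns})
        out = moderated_t_test(ds, ("A", "B"), "estimate")
        np.testing.assert_allclose(out["t"], ref["t"], rtol=1e-8)
        np.testing.assert_allclose(out["p"], ref["p"], rtol=1e-8, atol=1e-12)


class TestShrinkageEstimation:
    def test_all_equal_variances_give_infinite_prior_df(self):
        params = estimate_shrinkage(np.full(100, 2.0), d=4)
        assert math.isinf(params.d0) and params.s0_sq == 2.0

    def test_recovers_true_prior_df(self, rng):
        d0_true, s0_true, d = 4.0, 1.0, 6
        n = 10_000
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, n)
        s2 = sigma2 * rng.chisquare(d, n) / d
        params = estimate_shrinkage(s2, d=d)
        assert 3.0 <= params.d0 <= 5.0          # within 25%
        assert 0.8 <= params.s0_sq <= 1.25

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError, match=">= 10 probes"):
            estimate_shrinkage(np.ones(5) + np.arange(5), d=4)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=50))
    def test_adjusted_at_least_raw_and_capped(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0).all()
        # monotone in the p-ordering
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestCollapseProbes:
    def make_probe_table(self, rows):
        frame = pd.DataFrame(rows, columns=["probe", "logFC", "t", "p", "adj_p"])
        return frame.set_index("probe")

    def test_single_probe_per_gene_is_identity(self):
        tbl = self.make_probe_table([("p1", 1.0, 2.0, 0.01, 0.02),
                                     ("p2", -1.0, -2.0, 0.03, 0.04)])
        out = collapse_probes(tbl, {"p1": "G1", "p2": "G2"})
        assert list(out["symbol"]) == ["G1", "G2"]
        assert list(out["n_probes"]) == [1, 1]
        np.testing.assert_allclose(out["logFC"], [1.0, -1.0])

    def test_best_p_probe_kept(self):
        tbl = self.make_probe_table([("p1", 1.0, 2.5, 0.01, 0.02),
                                     ("p2", 2.0, 2.2, 0.04, 0.05)])
        out = collapse_probes(tbl, {"p1": "GENE1", "p2": "GENE1"})
        assert len(out) == 1
        assert out.loc[0, "p"] == 0.01
        assert out.loc[0, "n_probes"] == 2
        assert not out.loc[0, "ambiguous"]

    def test_sign_conflicting_significant_probes_flagged_ambiguous(self):
        tbl = self.make_probe_table([("p1", 1.0, 2.5, 0.01, 0.02),
                                     ("p2", -1.0, -2.6, 0.009, 0.02)])
        out = collapse_probes(tbl, {"p1": "GENE1", "p2": "GENE1"})
        assert bool(out.loc[0, "ambiguous"])

    def test_unannotated_probes_dropped_and_rows_never_grow(self, rng):
        ds = make_dataset(rng, n_probes=40)
        probe_map = dict(ds.probe_to_gene)
        probe_map["p000"] = ""
        stats_tbl = moderated_t_test(ds, ("A", "B"), UNMODERATED)
        out = collapse_probes(stats_tbl, probe_map)
        assert len(out) <= len(stats_tbl)
        assert set(out["symbol"]) <= set(probe_map.values())


def test_geo2r_export_dialect(tmp_path):
    p = tmp_path / "geo2r.tsv"
    p.write_text(
        "ID\tadj.P.Val\tP.Value\tt\tlogFC\tGene.symbol\n"
        "p1\t0.02\t0.001\t5.0\t2.0\tGls\n"
        "p2\t0.50\t0.200\t1.0\t0.5\tGls\n"
        "p3\t0.03\t0.002\t-4.0\t-1.5\tFABP1\n"
        "p4\t0.90\t0.800\t0.1\t0.1\t\n")
    table = read_geo2r_table(p, "GSE0", ("poorly_diff", "well_diff"))
    assert set(table.rows["symbol"]) == {"GLS", "FABP1"}
    gls = table.rows.set_index("symbol").loc["GLS"]
    assert gls["p"] == 0.001 and gls["n_probes"] == 2


def test_pvalues_uniform_under_global_null(rng):
    ds = make_dataset(rng, n_probes=5000, n_per_group=5)
    out = moderated_t_test(ds, ("A", "B"), "estimate")
    ks = stats.kstest(out["p"], "uniform").statistic
    assert ks < 0.03
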