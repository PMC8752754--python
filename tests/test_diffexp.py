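"""Moderated-t differential expression, BH adjustment and the panel rule."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from glycocode.diffexp import (
    DesignSpec,
    bh_adjust,
    design_from_metadata,
    moderated_t,
    one_vs_rest_de,
    select_panel,
)
from glycocode.io import ExpressionMatrix


def unpaired_design(n1, n2):
    samples = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    groups = {s: s[0] for s in samples}
    return samples, DesignSpec("two_group_unpaired", groups, ("a", "b"))


class TestModeratedT:
    def test_null_gene_zero_statistic(self):
        samples, design = unpaired_design(4, 4)
        rng = np.random.default_rng(0)
        values = rng.normal(size=(5, 8))
        values[0] = np.tile([1.0, 2.0, 3.0, 4.0], 2)  # identical in both groups
        m = ExpressionMatrix([f"g{i}" for i in range(5)], samples, values)
        res = moderated_t(m, design)
        assert res.table.loc["g0", "log2fc"] == 0
        assert res.table.loc["g0", "t"] == 0
        assert res.table.loc["g0", "p"] == 1

    def test_d0_zero_recovers_ordinary_pooled_t(self):
        """With the prior switched off the statistic is the textbook
        two-sample pooled t, checked against a direct computation."""
        samples, design = unpaired_design(4, 4)
        rng = np.random.default_rng(1)
        values = rng.normal(size=(5, 8))
        m = ExpressionMatrix([f"g{i}" for i in range(5)], samples, values)
        res = moderated_t(m, design, prior_df=0)
        x1, x2 = values[:, :4], values[:, 4:]
        sp = np.sqrt((x1.var(axis=1, ddof=1) * 3 + x2.var(axis=1, ddof=1) * 3) / 6)
        expected_t = (x1.mean(axis=1) - x2.mean(axis=1)) / (sp * np.sqrt(0.5))
        np.testing.assert_allclose(res.table["t"].to_numpy(), expected_t, atol=1e-10)
        expected_p = 2 * stats.t.sf(np.abs(expected_t), 6)
        np.testing.assert_allclose(res.table["p"].to_numpy(), expected_p, atol=1e-10)

    def test_matches_limma_on_heterogeneous_fixture(self, tmp_path):
        """Independent oracle: R limma's eBayes on the same matrix."""
        rng = np.random.default_rng(7)
        sd = np.sqrt(rng.chisquare(4, 60) / 4)
        values = rng.normal(0, 1, (60, 10)) * sd[:, None]
        genes = [f"g{i}" for i in range(60)]
        frame = pd.DataFrame(values, index=genes, columns=[f"s{j}" for j in range(10)])
        expr = tmp_path / "expr.tsv"
        frame.to_csv(expr, sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"x <- as.matrix(read.delim('{expr}', row.names=1))\n"
            "design <- cbind(Intercept=1, Group=c(rep(1,5), rep(0,5)))\n"
            "fit <- eBayes(lmFit(x, design))\n"
            "out <- data.frame(t=fit$t[,'Group'], p=fit$p.value[,'Group'], d0=fit$df.prior)\n"
            f"write.table(out, '{tmp_path / 'out.tsv'}', sep='\\t', quote=FALSE, row.names=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")

        samples, design = unpaired_design(5, 5)
        m = ExpressionMatrix(genes, samples, values)
        res = moderated_t(m, design)
        assert res.prior_df == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        np.testing.assert_allclose(res.table["t"].to_numpy(), ref["t"].to_numpy(), atol=1e-8)
        np.testing.assert_allclose(res.table["p"].to_numpy(), ref["p"].to_numpy(), atol=1e-8)

    def test_paired_identical_copies_give_p_one(self):
        """Pairs that are exact copies carry no signal: every zero-variance
        gene comes out with p = 1 (one varying gene anchors the prior)."""
        n_pairs = 4
        rng = np.random.default_rng(3)
        base = rng.normal(size=(6, n_pairs))
        values = np.empty((6, 2 * n_pairs))
        values[:, :n_pairs] = base
        values[:, n_pairs:] = base
        values[5, :n_pairs] += rng.normal(0, 1, n_pairs)  # one real gene
        samples = [f"t{i}" for i in range(n_pairs)] + [f"n{i}" for i in range(n_pairs)]
        groups = {s: ("tumour" if s[0] == "t" else "normal") for s in samples}
        pairs = {s: f"p{s[1:]}" for s in samples}
        design = DesignSpec("paired", groups, ("tumour", "normal"), pairs)
        m = ExpressionMatrix([f"g{i}" for i in range(6)], samples, values)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = moderated_t(m, design)
        assert (res.table["p"].iloc[:5] == 1.0).all()

    def test_all_zero_variance_is_error(self):
        samples, design = unpaired_design(3, 3)
        values = np.tile(np.arange(6.0), (3, 1))
        values = np.tile([[1.0]], (3, 6))
        m = ExpressionMatrix(["a", "b", "c"], samples, values)
        with pytest.raises(ValueError, match="zero variance"):
            moderated_t(m, design)

    def test_small_group_rejected(self):
        samples, design = unpaired_design(1, 5)
        m = ExpressionMatrix(["g"], samples, np.arange(6.0)[None, :])
        with pytest.raises(ValueError, match=">= 2"):
            moderated_t(m, design)

    def test_affine_invariance(self, small_matrix):
        """Adding per-gene constants leaves t unchanged; a global positive
        scale leaves t and p unchanged while the fold change scales."""
        samples = small_matrix.sample_ids
        groups = {s: ("a" if i < 3 else "b") for i, s in enumerate(samples)}
        design = DesignSpec("two_group_unpaired", groups, ("a", "b"))
        res = moderated_t(small_matrix, design)

        shifted = ExpressionMatrix(
            small_matrix.gene_ids,
            samples,
            small_matrix.values + np.arange(10.0)[:, None],
        )
        res_shift = moderated_t(shifted, design)
        np.testing.assert_allclose(res_shift.table["t"], res.table["t"], atol=1e-10)

        scaled = ExpressionMatrix(small_matrix.gene_ids, samples, 3.5 * small_matrix.values)
        res_scale = moderated_t(scaled, design)
        np.testing.assert_allclose(res_scale.table["t"], res.table["t"], atol=1e-9)
        np.testing.assert_allclose(res_scale.table["p"], res.table["p"], atol=1e-9)
        np.testing.assert_allclose(
            res_scale.table["log2fc"], 3.5 * res.table["log2fc"], atol=1e-10
        )


class TestBH:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_tied_inputs(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_against_brute_force_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            q = bh_adjust(p)
            # brute force: sorted p, cumulative min from the right
            order = np.argsort(p, kind="stable")
            m = p.size
            brute = np.empty(m)
            running = np.inf
            for i in range(m - 1, -1, -1):
                running = min(running, p[order[i]] * m / (i + 1))
                brute[order[i]] = min(running, 1.0)
            np.testing.assert_allclose(q, brute, atol=1e-12)
            np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_and_bounded(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestPanel:
    def fake_result(self, genes, pvals):
        table = pd.DataFrame({"p": pvals, "q": bh_adjust(pvals)}, index=genes)
        from glycocode.diffexp import DEResult

        return DEResult(table=table, prior_df=np.inf, prior_var=1.0)

    def test_two_of_four_rule(self):
        genes = ["g1"]
        results = {
            f"c{i}": self.fake_result(genes, [p]) for i, p in enumerate([0.005, 0.009, 0.5, 0.5])
        }
        sel = select_panel(results)
        assert sel.selected_genes == ["g1"]
        assert sel.table.loc["g1", "n_significant"] == 2

    def test_single_cohort_hit_not_selected(self):
        results = {
            "c1": self.fake_result(["g1"], [0.001]),
            "c2": self.fake_result(["g1"], [0.5]),
            "c3": self.fake_result(["g1"], [0.9]),
        }
        assert select_panel(results).selected_genes == []

    def test_gene_measured_in_one_cohort_only(self):
        results = {
            "c1": self.fake_result(["g1"], [0.001]),
            "c2": self.fake_result(["g2"], [0.001]),
        }
        sel = select_panel(results)
        assert sel.selected_genes == []
        assert sel.table.loc["g1", "n_significant"] == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_panel({})


class TestOneVsRest:
    def test_identical_clusters_null(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(6, 4))
        values = np.concatenate([base, base], axis=1)
        samples = [f"s{i}" for i in range(8)]
        m = ExpressionMatrix([f"g{i}" for i in range(6)], samples, values)
        # clusters are identical sample sets: A = first copy, B = second
        labels = {s: ("A" if i < 4 else "B") for i, s in enumerate(samples)}
        results = one_vs_rest_de(m, labels)
        np.testing.assert_allclose(results["A"].table["t"], 0.0, atol=1e-12)

    def test_three_clusters_three_tables(self, small_matrix):
        labels = {s: "ABC"[i % 3] for i, s in enumerate(small_matrix.sample_ids)}
        results = one_vs_rest_de(small_matrix, labels)
        assert sorted(results) == ["A", "B", "C"]
        for res in results.values():
            assert list(res.table.index) == small_matrix.gene_ids

    def test_small_cluster_rejected(self, small_matrix):
        labels = {s: ("A" if i == 0 else "B") for i, s in enumerate(small_matrix.sample_ids)}
        with pytest.raises(ValueError, match="need >= 2"):
            one_vs_rest_de(small_matrix, labels)

    def test_planted_basal_gene_positive_in_basal_cluster(self, discovery_tumours):
        matrix, tumours, _ = discovery_tumours
        labels = {m.sample_id: m.true_subtype for m in tumours}
        results = one_vs_rest_de(matrix, labels)
        row = results["basal"].table.loc["MUC16"]
        assert row["t"] > 0
        assert row["q"] <= 0.05


class TestDesignFromMetadata:
    def test_paired_uses_pairs_only(self, bulk_default):
        _, cohorts = bulk_default
        _, metadata = cohorts[0]
        design = design_from_metadata(metadata, paired=True)
        assert design.kind == "paired"
        assert len(design.pairs) == 2 * 30
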