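"""Post-count RNA-seq operations: QC, filtering, TMM, DE, clustering."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist

from trem2quant import synthdata as sd
from trem2quant import transcript as tr
from trem2quant.transcript import CountMatrix


def cm_from(array, genotypes=None, **meta_cols):
    counts = pd.DataFrame(np.asarray(array),
                          columns=[f"S{j}" for j in range(np.asarray(array).shape[1])])
    counts.index = [f"g{i}" for i in range(counts.shape[0])]
    n = counts.shape[1]
    meta = pd.DataFrame({"genotype": genotypes or ["WT"] * n, **meta_cols},
                        index=counts.columns)
    return CountMatrix(counts, meta)


class TestSampleQC:
    def base(self, gene_count_pct, strandness):
        return cm_from(np.ones((5, len(gene_count_pct)), dtype=int) * 20,
                       gene_count_pct=gene_count_pct, strandness=strandness)

    def test_all_within_bands_none_excluded(self):
        cm = self.base([80, 85, 82], [0.95, 0.97, 0.99])
        kept, report = tr.sample_qc(cm)
        assert kept.counts.shape[1] == 3 and report.empty

    def test_low_gene_count_sample_excluded_with_reason(self):
        cm = self.base([80, 39, 82], [0.95, 0.97, 0.99])
        kept, report = tr.sample_qc(cm, min_gene_count_pct=50)
        assert kept.counts.shape[1] == 2
        assert report.loc[0, "sample"] == "S1"
        assert "39" in report.loc[0, "reason"]

    def test_ambiguous_strandness_excluded(self):
        cm = self.base([80, 85, 82], [0.95, 0.5009, 0.99])
        kept, report = tr.sample_qc(cm)
        assert "strandness" in report.loc[0, "reason"]

    def test_report_rows_equal_inputs_minus_outputs(self):
        cm = self.base([30, 39, 82, 90], [0.95, 0.97, 0.5, 0.99])
        kept, report = tr.sample_qc(cm, min_gene_count_pct=50)
        assert len(report) == 4 - kept.counts.shape[1]

    def test_excluding_everything_errors(self):
        cm = self.base([10, 20], [0.9, 0.9])
        with pytest.raises(ValueError):
            tr.sample_qc(cm, min_gene_count_pct=50)


class TestFilterGenes:
    def test_boundary_four_samples_at_ten_kept(self):
        rows = [[10, 10, 10, 10, 0, 0],   # exactly 4 samples at 10 -> kept
                [10, 10, 10, 9, 0, 0],    # only 3 -> dropped
                [9, 9, 9, 9, 9, 9]]       # never reaches 10 -> dropped
        cm = cm_from(rows, ["WT"] * 3 + ["Hom"] * 3)
        kept = tr.filter_genes(cm)
        assert list(kept.counts.index) == ["g0"]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_row_scan(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.integers(0, 30, size=(40, 8))
        cm = cm_from(mat, ["WT"] * 4 + ["Hom"] * 4)
        kept = set(tr.filter_genes(cm).counts.index)
        brute = {f"g{i}" for i, row in enumerate(mat)
                 if sum(1 for c in row if c >= 10) >= 4}
        assert kept == brute


class TestBHAdjust:
    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(tr.bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_hand_computed_step_up(self):
        # p=(0.01,0.02,0.03), m=3: adjusted = min over j>=i of p_j * m/j
        np.testing.assert_allclose(tr.bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_matches_brute_force_definition(self, ps):
        adj = tr.bh_adjust(ps)
        m = len(ps)
        order = np.argsort(ps, kind="stable")
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, ps[i] * m / rank)
            brute[i] = running
        np.testing.assert_allclose(adj, brute, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tr.bh_adjust([0.5, 1.5])


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 500, 300)
        counts = pd.DataFrame({f"S{j}": col for j in range(4)})
        np.testing.assert_allclose(tr.tmm_factors(counts), 1.0, atol=1e-9)

    def test_pure_depth_difference_gives_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.integers(10, 500, 400)
        counts = pd.DataFrame({"A": col, "B": 2 * col, "C": col})
        np.testing.assert_allclose(tr.tmm_factors(counts), 1.0, atol=1e-9)

    def test_geometric_mean_is_one(self):
        cm, _ = sd.gen_counts(500, ["WT"] * 4 + ["Hom"] * 4,
                              de_genes={i: 2.0 for i in range(50)}, seed=2)
        f = tr.tmm_factors(cm.counts)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-12)

    def test_matches_independent_rederivation(self):
        """Against a naive second implementation of the doubly-trimmed,
        precision-weighted mean of M-values written from the definition."""
        cm, _ = sd.gen_counts(800, ["WT"] * 4 + ["Hom"] * 4,
                              de_genes={i: 2.5 for i in range(40)}, seed=5)
        y = cm.counts.to_numpy(float)
        lib = y.sum(axis=0)
        f75 = np.array([np.quantile(y[:, j] / lib[j], 0.75)
                        for j in range(y.shape[1])])
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
        naive = np.ones(y.shape[1])
        for j in range(y.shape[1]):
            if j == ref:
                continue
            o, r = y[:, j], y[:, ref]
            keepg = (o > 0) & (r > 0)
            o, r = o[keepg], r[keepg]
            M = np.log2((o / lib[j]) / (r / lib[ref]))
            A = 0.5 * np.log2((o / lib[j]) * (r / lib[ref]))
            w = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
            mlo, mhi = np.quantile(M, [0.3, 0.7])
            alo, ahi = np.quantile(A, [0.05, 0.95])
            sel = (M >= mlo) & (M <= mhi) & (A >= alo) & (A <= ahi)
            naive[j] = 2 ** (np.sum(w[sel] * M[sel]) / np.sum(w[sel]))
        naive /= np.exp(np.mean(np.log(naive)))
        np.testing.assert_allclose(tr.tmm_factors(cm.counts), naive, rtol=0.02)

    def test_matches_edger_reference_implementation(self, tmp_path):
        """Cross-check against edgeR's calcNormFactors on planted-DE data."""
        cm, _ = sd.gen_counts(2000, ["WT"] * 5 + ["Hom"] * 5,
                              de_genes={i: 2.0 for i in range(100)}, seed=3)
        path = tmp_path / "counts.tsv"
        cm.counts.to_csv(path, sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR))\n'
            'y <- as.matrix(read.delim(commandArgs(trailingOnly=TRUE)[1], '
            'row.names=1))\n'
            'cat(calcNormFactors(DGEList(counts=y), method="TMM")$samples'
            '$norm.factors, sep=",")\n')
        out = subprocess.run(["Rscript", str(script), str(path)],
                             capture_output=True, text=True, check=True)
        edger = np.array([float(v) for v in out.stdout.strip().split(",")])
        np.testing.assert_allclose(tr.tmm_factors(cm.counts), edger, rtol=0.02)

    def test_no_shared_expression_errors(self):
        counts = pd.DataFrame({"A": [5, 0, 0], "B": [0, 3, 4]})
        with pytest.raises(ValueError, match="no expressed genes"):
            tr.tmm_factors(counts)


class TestDE:
    def test_null_pvalues_uniform(self):
        from scipy import stats as sps

        ks = []
        for rep in range(10):
            cm, _ = sd.gen_counts(400, ["WT"] * 5 + ["Hom"] * 5, seed=900 + rep)
            de = tr.genewise_de_test(tr.filter_genes(cm))
            ks.append(sps.kstest(de["p_value"], "uniform").pvalue)
        assert np.median(ks) > 0.05
        assert min(ks) > 0.001

    def test_planted_fold_change_recovered(self):
        cm, gt = sd.gen_counts(400, ["WT"] * 5 + ["Hom"] * 5,
                               de_genes={i: 2.0 for i in range(20)}, seed=13)
        de = tr.genewise_de_test(tr.filter_genes(cm))
        planted = [g for g in gt.params["de_gene_names"] if g in de.index]
        assert abs(de.loc[planted, "log2FC"].median() - 2.0) < 0.2

    def test_fdr_controls_null_discoveries(self):
        counts = []
        for rep in range(10):
            cm, _ = sd.gen_counts(400, ["WT"] * 5 + ["Hom"] * 5, seed=300 + rep)
            de = tr.classify_deg(tr.genewise_de_test(tr.filter_genes(cm)))
            counts.append((de["status"] != "ns").mean())
        assert np.mean(counts) <= 0.05

    def test_groups_need_two_samples(self):
        cm, _ = sd.gen_counts(50, ["WT"] * 2 + ["Hom"] * 2, seed=0)
        cm2 = CountMatrix(cm.counts.iloc[:, :3], cm.meta.iloc[:3])
        with pytest.raises(ValueError):
            tr.genewise_de_test(cm2)


class TestClassifyDeg:
    @pytest.mark.parametrize("fdr,lfc,expected", [
        (0.01, 0.30, "up"),
        (0.01, 0.25, "ns"),     # strict inequality at the fold-change cut
        (0.05, 0.30, "ns"),     # strict inequality at the FDR cut
        (0.01, -0.30, "down"),
        (0.01, -0.25, "ns"),
        (0.2, 1.0, "ns"),
    ])
    def test_threshold_boundaries(self, fdr, lfc, expected):
        de = pd.DataFrame({"log2FC": [lfc], "p_value": [fdr], "fdr": [fdr]})
        out = tr.classify_deg(de)
        assert out["status"].iloc[0] == expected

    def test_fold_change_cut_matches_legend_rounding(self):
        # |log2FC| > 0.25 <=> |FC| > 2^0.25 = 1.189..., i.e. the 1.2 of
        # the figure legends after rounding
        assert 2 ** 0.25 == pytest.approx(1.19, abs=0.01)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(0, 1), st.floats(-3, 3))
    def test_pure_function_of_fdr_and_lfc(self, fdr, lfc):
        de = pd.DataFrame({"log2FC": [lfc], "p_value": [fdr], "fdr": [fdr]})
        status = tr.classify_deg(de)["status"].iloc[0]
        if fdr < 0.05 and lfc > 0.25:
            assert status == "up"
        elif fdr < 0.05 and lfc < -0.25:
            assert status == "down"
        else:
            assert status == "ns"


class TestHierCluster:
    def test_distances_match_brute_force_standardized_euclidean(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(12, 6)))
        out = tr.hier_cluster(X)
        V = X.to_numpy()
        sd_ = V.std(axis=0, ddof=1)
        brute = pdist(V / sd_ - (V.mean(axis=0) / sd_), metric="euclidean")
        np.testing.assert_allclose(out["distances"], brute, rtol=1e-9)
        np.testing.assert_allclose(out["distances"],
                                   pdist(V, metric="seuclidean"), rtol=1e-9)

    def test_identical_rows_merge_first(self):
        X = pd.DataFrame([[1.0, 2.0, 3.0],
                          [1.0, 2.0, 3.0],
                          [9.0, -4.0, 2.0]], index=["a", "b", "c"])
        out = tr.hier_cluster(X)
        first = out["linkage"][0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_outlier_joins_last(self):
        X = pd.DataFrame([[0.0, 0.1], [0.1, 0.0], [5.0, 5.0], [0.05, 0.05]])
        out = tr.hier_cluster(X)
        assert int(out["linkage"][-1, 1]) >= 4 or 2 in out["linkage"][-1, :2]

    def test_zero_variance_feature_warns(self):
        X = pd.DataFrame([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            tr.hier_cluster(X)


class TestResidualize:
    def covariates(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"sex": rng.integers(0, 2, n),
                             "strand": rng.normal(0.95, 0.02, n),
                             "exonic": rng.normal(0.7, 0.05, n)},
                            index=[f"S{j}" for j in range(n)])

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(1)
        cov = self.covariates(10)
        expr = pd.DataFrame(rng.normal(size=(30, 10)), columns=cov.index)
        resid = tr.residualize(expr, cov)
        X = np.column_stack([np.ones(10), cov.to_numpy(float)])
        assert np.abs(resid.to_numpy() @ X).max() < 1e-8

    def test_expression_linear_in_sex_residualizes_to_zero(self):
        cov = self.covariates(8)
        expr = pd.DataFrame(np.outer(np.arange(1, 6),
                                     cov["sex"].to_numpy(float) * 2 + 1),
                            columns=cov.index)
        resid = tr.residualize(expr, cov)
        assert np.abs(resid.to_numpy()).max() < 1e-8

    def test_collinear_design_rejected(self):
        cov = self.covariates(6)
        cov["dup"] = cov["sex"]
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 6)),
                            columns=cov.index)
        with pytest.raises(ValueError, match="collinear"):
            tr.residualize(expr, cov)
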