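import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from corestress.preprocessing import (
    ComBat,
    combat_adjust,
    filter_zero_variance,
    log_transform,
    pca,
    treatment_dendrogram,
    zscore_genes,
)


def _frame(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestLogTransform:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (1.0, 1.0), (7.0, 3.0)])
    def test_reference_values(self, x, expected):
        m = _frame([[x, x]])
        assert log_transform(m).iloc[0, 0] == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            log_transform(_frame([[-0.5, 1.0]]))

    def test_monotone_per_gene(self, toy_matrix):
        logged = log_transform(toy_matrix)
        for g in toy_matrix.index:
            order_raw = np.argsort(toy_matrix.loc[g].to_numpy())
            order_log = np.argsort(logged.loc[g].to_numpy())
            assert np.array_equal(order_raw, order_log)


class TestZeroVarianceFilter:
    def test_constant_gene_removed_varying_kept(self):
        m = _frame([[3.2, 3.2, 3.2], [1.0, 1.0, 2.0]])
        out = filter_zero_variance(m)
        assert list(out.index) == ["g1"]

    def test_all_constant_warns_and_empties(self):
        m = _frame([[1.0, 1.0], [2.0, 2.0]])
        with pytest.warns(UserWarning, match="zero variance"):
            out = filter_zero_variance(m)
        assert out.shape[0] == 0

    def test_order_preserved(self, toy_matrix):
        out = filter_zero_variance(toy_matrix)
        assert list(out.index) == [g for g in toy_matrix.index if g in out.index]


class TestZScore:
    def test_population_sd_convention(self):
        # population sd of (1,2,3) is sqrt(2/3); the package convention
        out = zscore_genes(_frame([[1.0, 2.0, 3.0]]))
        expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(out.to_numpy()[0], expected, atol=1e-12)

    def test_row_means_zero_and_idempotent(self, toy_matrix):
        z = zscore_genes(toy_matrix)
        assert np.abs(z.mean(axis=1)).max() < 1e-10
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(zscore_genes(z).to_numpy(), z.to_numpy(), atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            zscore_genes(_frame([[2.0, 2.0, 2.0]]))


class TestComBat:
    def test_single_batch_is_identity(self, toy_matrix):
        out = combat_adjust(toy_matrix, np.array(["A"] * toy_matrix.shape[1]))
        np.testing.assert_allclose(out.to_numpy(), toy_matrix.to_numpy(), atol=1e-8)

    def test_shape_and_ids_preserved(self, toy_matrix):
        batch = np.array(["A", "A", "A", "B", "B", "B"])
        out = combat_adjust(toy_matrix, batch)
        assert out.shape == toy_matrix.shape
        assert list(out.index) == list(toy_matrix.index)
        assert list(out.columns) == list(toy_matrix.columns)

    def test_singleton_batch_error_names_batch(self, toy_matrix):
        batch = np.array(["A"] * 5 + ["LONER"])
        with pytest.raises(ValueError, match="LONER"):
            combat_adjust(toy_matrix, batch)

    def test_planted_shift_removed(self):
        rng = np.random.default_rng(1)
        n_genes, n = 150, 50
        base = rng.normal(6, 2, size=(n_genes, 1))
        X = base + rng.normal(0, 0.5, size=(n_genes, 2 * n))
        X[:, n:] += 5.0
        m = _frame(X)
        batch = np.array(["A"] * n + ["B"] * n)
        adj = combat_adjust(m, batch).to_numpy()
        diff_before = np.abs(X[:, :n].mean(1) - X[:, n:].mean(1))
        diff_after = np.abs(adj[:, :n].mean(1) - adj[:, n:].mean(1))
        assert diff_before.mean() > 4.5
        assert diff_after.mean() < 0.1

    def test_planted_variance_ratio_equalized(self):
        # planted 3x between-batch variance ratio, n=50/batch: after EB
        # correction the ratio is centred on 1; shrinkage toward the batch
        # prior leaves gene-level residual spread, so the band is checked
        # at a width consistent with the reference implementation
        rng = np.random.default_rng(2)
        n_genes, n = 200, 50
        base = rng.normal(6, 2, size=(n_genes, 1))
        X = np.hstack(
            [
                base + rng.normal(0, 1, size=(n_genes, n)),
                base + rng.normal(0, np.sqrt(3), size=(n_genes, n)),
            ]
        )
        m = _frame(X)
        adj = combat_adjust(m, np.array(["A"] * n + ["B"] * n)).to_numpy()
        before = X[:, n:].var(axis=1, ddof=1) / X[:, :n].var(axis=1, ddof=1)
        ratio = adj[:, n:].var(axis=1, ddof=1) / adj[:, :n].var(axis=1, ddof=1)
        assert np.median(before) > 2.5
        assert 0.9 <= np.median(ratio) <= 1.1
        assert np.mean((ratio >= 0.6) & (ratio <= 1.67)) >= 0.95
        assert np.mean((ratio >= 0.8) & (ratio <= 1.25)) > np.mean(
            (before >= 0.8) & (before <= 1.25)
        )

    def test_gene_constant_within_batch_handled(self):
        X = np.array([[1.0, 1.0, 1.0, 4.0, 5.0, 6.0], [2.0, 3.0, 4.0, 7.0, 8.0, 9.0]])
        out = combat_adjust(_frame(X), np.array(["A"] * 3 + ["B"] * 3))
        assert np.isfinite(out.to_numpy()).all()

    def test_batch_variance_on_pc1_decreases(self):
        # planted batch shifts, no treatment structure: the share of PC1
        # variance explained by batch must drop after adjustment
        rng = np.random.default_rng(3)
        n_genes, n = 120, 15
        base = rng.normal(5, 2, size=(n_genes, 1))
        X = base + rng.normal(0, 1, size=(n_genes, 3 * n))
        shifts = [0.0, 2.5, -2.0]
        for b in range(3):
            X[:, b * n : (b + 1) * n] += shifts[b]
        batch = np.repeat(["A", "B", "C"], n)
        m = _frame(X)

        def batch_r2(frame):
            pc1 = pca(frame, 1).scores["PC1"].to_numpy()
            design = pd.get_dummies(batch).to_numpy(dtype=float)
            beta, *_ = np.linalg.lstsq(design, pc1, rcond=None)
            resid = pc1 - design @ beta
            return 1 - resid.var() / pc1.var()

        adj = combat_adjust(m, batch)
        assert batch_r2(adj) < batch_r2(m)

    def test_matches_bioconductor_sva(self, tmp_path):
        """Cross-check against the reference empirical-Bayes implementation."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the sva cross-check")
        rng = np.random.default_rng(5)
        base = rng.normal(6, 2, size=(30, 1))
        X = base + rng.normal(0, 1, size=(30, 24))
        X[:, 10:] += rng.normal(2.0, 0.5)
        m = _frame(X)
        batch = np.array(["A"] * 10 + ["B"] * 14)
        ours = combat_adjust(m, batch)
        m.to_csv(tmp_path / "in.tsv", sep="\t")
        ours.to_csv(tmp_path / "py.tsv", sep="\t")
        (tmp_path / "batch.txt").write_text("\n".join(batch) + "\n")
        script = f"""
        suppressMessages(library(sva))
        m <- as.matrix(read.delim("{tmp_path}/in.tsv", row.names=1))
        batch <- scan("{tmp_path}/batch.txt", what="character", quiet=TRUE)
        ref <- ComBat(dat=m, batch=batch)
        py <- as.matrix(read.delim("{tmp_path}/py.tsv", row.names=1))
        cat(max(abs(ref - py)), "\\n")
        """
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        max_diff = float(out.stdout.strip().splitlines()[-1])
        assert max_diff < 1e-8

    def test_estimator_api(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 30))
        batch = np.repeat(["A", "B"], 6)
        est = ComBat()
        adjusted = est.fit_transform(X, batch=batch)
        assert adjusted.shape == X.shape
        assert est.gamma_star_.shape == (2, 30)
        assert est.get_params()["conv"] == 1e-4


class TestPCA:
    def test_duplicated_samples_same_variance_fractions(self, toy_matrix):
        dup = pd.concat([toy_matrix, toy_matrix.add_suffix("_r")], axis=1)
        v1 = pca(toy_matrix, 2).variance_explained
        v2 = pca(dup, 2).variance_explained
        np.testing.assert_allclose(v1, v2, atol=1e-10)

    def test_rank_one_signal_dominates(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(40, 1))
        v = rng.normal(size=(1, 12))
        m = _frame(u @ v + rng.normal(0, 1e-6, size=(40, 12)))
        res = pca(m, 2)
        assert res.variance_explained[0] > 0.99

    def test_variance_fractions_sum_below_one_and_ordered(self, toy_matrix):
        res = pca(toy_matrix, 3)
        assert res.variance_explained.sum() <= 1 + 1e-12
        assert np.all(np.diff(res.variance_explained) <= 1e-12)

    def test_sign_convention(self, toy_matrix):
        res = pca(toy_matrix, 2)
        for pc in res.components.index:
            loadings = res.components.loc[pc].to_numpy()
            assert loadings[np.argmax(np.abs(loadings))] > 0

    def test_too_many_components_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            pca(toy_matrix, 7)


class TestTreatmentDendrogram:
    @staticmethod
    def _meta(treatments):
        return pd.DataFrame(
            {"treatment": treatments, "bioproject": "P1"},
            index=[f"s{j}" for j in range(len(treatments))],
        )

    def test_identical_profiles_merge_first_at_zero(self):
        m = _frame(
            np.column_stack([[1.0, 2.0, 3.0]] * 2 + [[9.0, -4.0, 0.5]]),
            genes=["g0", "g1", "g2"],
            samples=["s0", "s1", "s2"],
        )
        meta = self._meta(["heat", "cold", "salt"])
        tree = treatment_dendrogram(m, meta)
        first = tree.linkage_matrix[0]
        merged = {tree.labels[int(first[0])], tree.labels[int(first[1])]}
        assert merged == {"heat", "cold"}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_merge_count(self, corrected_small):
        m, meta = corrected_small
        from corestress.preprocessing import zscore_genes

        tree = treatment_dendrogram(zscore_genes(m), meta)
        assert tree.n_merges == len(tree.labels) - 1
        assert np.all(np.diff(tree.linkage_matrix[:, 2]) >= -1e-12)

    def test_absent_treatment_warns(self):
        m = _frame(np.random.default_rng(0).normal(size=(5, 4)))
        meta = pd.DataFrame(
            {
                "treatment": ["heat", "heat", "cold", "cold", "salt"],
                "bioproject": "P1",
            },
            index=[f"s{j}" for j in range(4)] + ["missing_sample"],
        )
        with pytest.warns(UserWarning, match="salt"):
            tree = treatment_dendrogram(m, meta)
        assert set(tree.labels) == {"heat", "cold"}
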