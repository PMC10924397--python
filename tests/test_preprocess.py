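"""Gene filtering and the normalize/log/standardize transform."""

import numpy as np
import pytest

from scfsnn import apply_normalize, filter_genes, fit_normalize
from scfsnn.preprocess import CountMatrix

from conftest import toy_counts


class TestFilterGenes:
    def test_gene_with_81pct_zeros_removed_at_080_threshold(self, rng):
        values = rng.integers(1, 10, size=(100, 2))
        values[:81, 0] = 0  # zero fraction 0.81 > 0.8
        out = filter_genes(toy_counts(values), 0.8)
        assert out.gene_ids.tolist() == ["g1"]

    def test_threshold_one_is_a_no_op(self, small_counts):
        out = filter_genes(small_counts, 1.0)
        assert np.array_equal(out.values, small_counts.values)

    def test_three_gene_toy_keeps_expected_columns(self):
        # zero fractions 0.0, 0.5, 0.9 -> at threshold 0.8 genes 0 and 1 stay
        values = np.ones((10, 3), dtype=int)
        values[:5, 1] = 0
        values[:9, 2] = 0
        out = filter_genes(toy_counts(values), 0.8)
        assert out.gene_ids.tolist() == ["g0", "g1"]

    def test_idempotent(self, small_counts):
        once = filter_genes(small_counts, 0.3)
        twice = filter_genes(once, 0.3)
        assert np.array_equal(once.values, twice.values)

    def test_all_removed_raises(self):
        values = np.zeros((10, 2), dtype=int)
        values[0, :] = 1  # zero fraction 0.9 in both genes
        with pytest.raises(ValueError, match="empty-after-filter"):
            filter_genes(toy_counts(values), 0.5)


class TestFitNormalize:
    def test_constant_gene_with_equal_totals_is_dropped_as_zero_variance(self):
        # cells have equal totals, so gene 0 (counts 3, 3) is constant after
        # log-normalization and cannot be standardized
        counts = toy_counts([[3, 1, 6], [3, 5, 2]])
        with pytest.warns(UserWarning, match="zero-variance"):
            proc = fit_normalize(counts)
        assert proc.gene_ids.tolist() == ["g1", "g2"]
        assert proc.values.shape == (2, 2)

    def test_hand_computed_2x2(self):
        proc = fit_normalize(toy_counts([[10, 0], [0, 10]]))
        assert proc.d0 == 10.0
        # log-normalized matrix is [[log 11, 0], [0, log 11]]; each column has
        # mean log(11)/2 and sample sd log(11)/sqrt(2) -> entries +-1/sqrt(2)
        expected = np.array([[1, -1], [-1, 1]]) / np.sqrt(2)
        np.testing.assert_allclose(proc.values, expected, atol=1e-12)

    def test_columns_standardized_on_fit_data(self, small_counts):
        proc = fit_normalize(small_counts)
        np.testing.assert_allclose(proc.values.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(proc.values.std(axis=0, ddof=1), 1.0, atol=1e-6)

    def test_zero_total_cell_named_in_error(self):
        values = np.array([[0, 0], [1, 2], [3, 4]])
        with pytest.raises(ValueError, match="c0"):
            fit_normalize(toy_counts(values))


class TestApplyNormalize:
    def test_idempotent_on_fitting_data(self, small_counts):
        proc = fit_normalize(small_counts)
        out = apply_normalize(small_counts, proc)
        np.testing.assert_allclose(out, proc.values, atol=1e-12)

    def test_scale_invariance_per_cell(self, small_counts):
        """Multiplying one cell's raw counts by a constant leaves its row unchanged."""
        proc = fit_normalize(small_counts)
        scaled = small_counts.values.copy()
        scaled[3] *= 7
        out = apply_normalize(toy_counts(scaled), proc)
        np.testing.assert_allclose(out[3], proc.values[3], atol=1e-9)

    def test_gene_mismatch_raises(self, small_counts):
        proc = fit_normalize(small_counts)
        other = CountMatrix(
            small_counts.values[:, :5],
            small_counts.gene_ids[:5],
            small_counts.cell_ids,
        )
        with pytest.raises(ValueError, match="gene_ids"):
            apply_normalize(other, proc)


class TestValidation:
    def test_non_integer_count_rejected(self):
        with pytest.raises(ValueError, match="non-integer"):
            toy_counts([[1.0, 2.5], [3.0, 4.0]])

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CountMatrix(
                np.ones((3, 2), dtype=int),
                np.array(["g", "g"], dtype=object),
                np.array(["a", "b", "c"], dtype=object),
            )
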