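"""Normalization, detection filtering, imputation, batch centering and PCA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from propde.preprocess import (
    aggregate_peptides,
    filter_by_detection,
    impute_missing,
    log2_z_rescale,
    pca_scores,
    remove_batch_means,
)
from propde.simulate import SynthConfig, generate_experiment, generate_network

from conftest import make_design, peptide_table_from_array, protein_table_from_array


class TestLog2ZRescale:
    def test_hand_computed_two_row_example(self):
        # rows [0,2] and [4,6] on log2 scale: M_global=3, SD_global=sqrt(20/3)
        table = peptide_table_from_array([[0.0, 2.0], [4.0, 6.0]], scale="log2")
        out, record = log2_z_rescale(table)
        assert record.global_mean == pytest.approx(3.0)
        assert record.global_sd == pytest.approx(math.sqrt(20 / 3))
        expected = np.array([3 - math.sqrt(20 / 3) / math.sqrt(2), 3 + math.sqrt(20 / 3) / math.sqrt(2)])
        np.testing.assert_allclose(out.values.to_numpy()[0], expected, rtol=1e-12)
        np.testing.assert_allclose(out.values.to_numpy()[1], expected, rtol=1e-12)
        np.testing.assert_allclose(out.values.to_numpy()[0], [1.174, 4.826], atol=1e-3)

    def test_row_at_global_moments_is_fixed_point(self):
        # for a single row the global moments are the row moments, so the
        # rescaling must return the row unchanged
        rng = np.random.default_rng(1)
        x = rng.normal(10, 2, size=(1, 8))
        out, _ = log2_z_rescale(peptide_table_from_array(x, scale="log2"))
        np.testing.assert_allclose(out.values.to_numpy(), x, atol=1e-9)

    def test_constant_row_dropped_and_counted(self):
        table = peptide_table_from_array([[5.0, 5.0, 5.0, 5.0], [1.0, 2.0, 3.0, 4.0]], scale="log2")
        out, record = log2_z_rescale(table)
        assert record.dropped_constant_rows == 1
        assert list(out.values.index) == ["pep1"]

    def test_missing_entries_stay_missing(self):
        table = peptide_table_from_array([[1.0, 2.0, np.nan, 4.0], [2.0, 1.0, 5.0, 3.0]], scale="log2")
        out, _ = log2_z_rescale(table)
        assert np.isnan(out.values.to_numpy()[0, 2])
        assert out.n_missing == 1

    def test_raw_scale_log2_transformed_first(self):
        table = peptide_table_from_array([[1.0, 4.0], [16.0, 64.0]], scale="raw")
        out, record = log2_z_rescale(table)
        # log2 -> rows [0,2], [4,6]: same as the hand-computed example
        assert record.global_mean == pytest.approx(3.0)

    def test_nonpositive_raw_intensity_errors(self):
        table = peptide_table_from_array([[0.0, 4.0], [2.0, 8.0]], scale="raw")
        with pytest.raises(ValueError, match="positive"):
            log2_z_rescale(table)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_every_retained_row_has_global_moments(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(12, 3, size=(40, 6))
        out, record = log2_z_rescale(peptide_table_from_array(x, scale="log2"))
        vals = out.values.to_numpy()
        np.testing.assert_allclose(vals.mean(axis=1), record.global_mean, atol=1e-9)
        np.testing.assert_allclose(vals.std(axis=1, ddof=1), record.global_sd, atol=1e-9)


class TestAggregate:
    def test_median_is_robust_to_outlier_peptide(self):
        table = peptide_table_from_array(
            [[1.0], [3.0], [100.0]], proteins=["A", "A", "A"], scale="log2"
        )
        out = aggregate_peptides(table, method="median")
        assert out.values.loc["A"].iloc[0] == 3.0

    def test_single_peptide_protein_identity(self):
        table = peptide_table_from_array([[1.5, 2.5]], proteins=["A"], scale="log2")
        out = aggregate_peptides(table)
        np.testing.assert_array_equal(out.values.loc["A"], [1.5, 2.5])

    def test_missing_peptide_ignored_cell_missing_iff_all_missing(self):
        table = peptide_table_from_array(
            [[np.nan, 1.0], [4.0, np.nan]], proteins=["A", "A"], scale="log2"
        )
        out = aggregate_peptides(table)
        np.testing.assert_array_equal(out.values.loc["A"], [4.0, 1.0])
        table2 = peptide_table_from_array(
            [[np.nan, 1.0], [np.nan, 3.0]], proteins=["A", "A"], scale="log2"
        )
        assert np.isnan(aggregate_peptides(table2).values.loc["A"].iloc[0])


class TestDetectionFilter:
    def design(self):
        return make_design(n_replicates=4, ages=("young",), drugs=("EtOH", "Rapa"),
                           inductions=("ctrl",))

    def table(self, row):
        return protein_table_from_array([row], sample_ids=[f"S{i:02d}" for i in range(8)])

    def test_three_of_four_rule(self):
        # group EtOH = S00..S03, Rapa = S04..S07
        kept = self.table([1, 1, 1, 1, 1, 1, 1, np.nan])
        out = filter_by_detection(kept, self.design(), min_detected=3)
        assert len(out.values) == 1
        dropped = self.table([1, 1, 1, 1, 1, 1, np.nan, np.nan])
        out = filter_by_detection(dropped, self.design(), min_detected=3)
        assert len(out.values) == 0

    def test_min_detected_zero_keeps_all(self):
        t = self.table([np.nan] * 4 + [1, 1, 1, 1])
        out = filter_by_detection(t, self.design(), min_detected=0)
        assert len(out.values) == 1

    def test_absent_in_one_group_drops_protein(self):
        t = self.table([np.nan] * 4 + [1, 1, 1, 1])
        out = filter_by_detection(t, self.design(), min_detected=3)
        assert len(out.values) == 0

    def test_group_smaller_than_threshold_errors_naming_group(self):
        design = make_design(n_replicates=2, ages=("young",), drugs=("EtOH", "Rapa"),
                             inductions=("ctrl",))
        t = protein_table_from_array([[1, 1, 1, 1]], sample_ids=[f"S{i:02d}" for i in range(4)])
        with pytest.raises(ValueError, match=r"only 2 sample"):
            filter_by_detection(t, design, min_detected=3)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_monotone_in_min_detected(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(30, 8))
        x[rng.random(x.shape) < 0.3] = np.nan
        x = x[~np.isnan(x).all(axis=1)]
        t = protein_table_from_array(x, sample_ids=[f"S{i:02d}" for i in range(8)])
        design = self.design()
        kept = [
            set(filter_by_detection(t, design, min_detected=k).values.index)
            for k in range(5)
        ]
        for lower, higher in zip(kept, kept[1:]):
            assert higher <= lower


class TestImpute:
    def test_identical_complete_neighbor_k1(self):
        x = np.array([
            [1.0, 2.0, 3.0, np.nan],
            [1.0, 2.0, 3.0, 7.0],
            [9.0, 9.0, 9.0, 9.0],
        ])
        out = impute_missing(protein_table_from_array(x), k=1)
        assert out.values.iloc[0, 3] == 7.0

    def test_no_missing_is_identity(self):
        x = np.arange(12, dtype=float).reshape(3, 4)
        t = protein_table_from_array(x)
        out = impute_missing(t, k=2)
        assert out.values.equals(t.values)

    def test_equidistant_neighbors_averaged(self):
        # three complete neighbors all at the same distance from the target
        x = np.array([
            [0.0, 0.0, np.nan],
            [1.0, 1.0, 10.0],
            [1.0, 1.0, 20.0],
            [1.0, 1.0, 30.0],
        ])
        out = impute_missing(protein_table_from_array(x), k=3)
        assert out.values.iloc[0, 2] == pytest.approx((10 + 20 + 30) / 3)

    def test_observed_entries_preserved_bit_exactly(self, rng):
        x = rng.normal(size=(40, 8))
        miss = rng.random(x.shape) < 0.1
        x[miss] = np.nan
        t = protein_table_from_array(x)
        out = impute_missing(t, k=5)
        observed = ~np.isnan(x)
        assert (out.values.to_numpy()[observed] == x[observed]).all()
        assert not out.values.isna().any().any()

    def test_mostly_missing_row_falls_back_to_row_mean(self):
        x = np.array([
            [2.0, np.nan, np.nan, np.nan, np.nan, 4.0],
            [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
            [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
        ])
        out = impute_missing(protein_table_from_array(x), k=1)
        np.testing.assert_allclose(out.values.iloc[0, 1:5], 3.0)

    def test_all_missing_row_errors(self):
        x = np.array([[np.nan, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError, match="zero present"):
            impute_missing(protein_table_from_array(x), k=1)


class TestBatchRemoval:
    def test_two_batches_centered_to_grand_mean(self):
        design = make_design(n_replicates=2, ages=("young",), drugs=("EtOH",),
                             inductions=("ctrl",), n_batches=2)
        # batches alternate: S00 -> b1, S01 -> b2
        t = protein_table_from_array([[5.0, 7.0]], sample_ids=["S00", "S01"])
        out = remove_batch_means(t, design)
        np.testing.assert_allclose(out.values.to_numpy()[0], [6.0, 6.0])

    def test_grand_mean_unchanged(self, rng):
        design = make_design()
        x = rng.normal(size=(25, 32))
        t = protein_table_from_array(x, sample_ids=list(design.sample_ids))
        out = remove_batch_means(t, design)
        np.testing.assert_allclose(
            out.values.mean(axis=1), t.values.mean(axis=1), atol=1e-9
        )

    def test_single_batch_identity_with_warning(self):
        design = make_design(n_batches=1)
        t = protein_table_from_array(
            np.arange(64, dtype=float).reshape(2, 32), sample_ids=list(design.sample_ids)
        )
        with pytest.warns(UserWarning, match="single batch"):
            out = remove_batch_means(t, design)
        assert out.values.equals(t.values)

    def test_orthogonal_batch_leaves_planted_effect_estimate_unchanged(self):
        # batch orthogonal to condition: removing batch means must not bias
        # the group difference
        config = SynthConfig(
            n_proteins=40, n_modules=2, module_size=10, n_terms=5,
            peptides_per_protein=1.0, noise_sd=0.0, peptide_offset_sd=0.0,
            baseline_sd=0.0, batch_sd=0.8, mcar_rate=0.0, mnar_slope=0.0,
            effect_map={"rapa_vs_etoh_uninduced": (("P0000",), 1.0)}, seed=9,
        )
        graph, modules = generate_network(config)
        peptides, design, truth = generate_experiment(config, graph, modules)
        log2 = np.log2(peptides.values)
        t = protein_table_from_array(
            log2.to_numpy(), sample_ids=list(log2.columns),
            protein_ids=list(peptides.proteins),
        )
        cells = design.cells()
        pos = [s for s, c in cells.items() if c in {("young", "Rapa", "ctrl"), ("old", "Rapa", "ctrl")}]
        neg = [s for s, c in cells.items() if c in {("young", "EtOH", "ctrl"), ("old", "EtOH", "ctrl")}]
        before = t.values.loc["P0000", pos].mean() - t.values.loc["P0000", neg].mean()
        out = remove_batch_means(t, design)
        after = out.values.loc["P0000", pos].mean() - out.values.loc["P0000", neg].mean()
        assert after == pytest.approx(before, abs=1e-9)
        assert after == pytest.approx(1.0, abs=1e-9)


class TestPCA:
    def test_two_cluster_data_separated_on_pc1(self, rng):
        base = rng.normal(size=(30, 1))
        left = base + rng.normal(scale=0.01, size=(30, 4))
        right = base + 5.0 + rng.normal(scale=0.01, size=(30, 4))
        t = protein_table_from_array(np.hstack([left, right]))
        scores, var = pca_scores(t, n_components=2)
        assert var[0] > 0.99
        pc1 = scores["PC1"]
        assert (pc1.iloc[:4] * pc1.iloc[4:].to_numpy() < 0).all()

    def test_variance_explained_nonincreasing_and_orthogonal_scores(self, rng):
        t = protein_table_from_array(rng.normal(size=(50, 10)))
        scores, var = pca_scores(t, n_components=5)
        assert (np.diff(var) <= 1e-12).all()
        assert var.sum() <= 1 + 1e-12
        gram = scores.to_numpy().T @ scores.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_too_many_components_errors(self, rng):
        t = protein_table_from_array(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError, match="n_components"):
            pca_scores(t, n_components=6)

    def test_incomplete_table_rejected(self):
        t = protein_table_from_array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="complete"):
            pca_scores(t, n_components=1)
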