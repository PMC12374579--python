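import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depselect.preprocess import (
    batch_qc,
    binomial_transform,
    completeness_filter,
    filter_batches,
    impute_missing,
    log2_transform,
    mean_normalize,
    ratio_normalize,
)

from conftest import make_matrix, make_samples

finite_row = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False, width=32),
    min_size=3,
    max_size=8,
)


class TestImputation:
    def test_imputed_value_is_row_minimum_minus_offset(self):
        m = make_matrix([[2.0, None, 3.0]])
        out, dropped = impute_missing(m, epsilon=0.05)
        assert dropped == []
        assert out.values.loc["P1"].tolist() == [2.0, 1.95, 3.0]

    def test_complete_row_unchanged(self):
        m = make_matrix([[1.0, 2.0, 3.0]])
        out, _ = impute_missing(m)
        assert out.values.loc["P1"].tolist() == [1.0, 2.0, 3.0]

    def test_all_missing_protein_dropped_and_reported(self):
        m = make_matrix([[None, None], [1.0, 2.0]])
        out, dropped = impute_missing(m)
        assert dropped == ["P1"]
        assert out.protein_ids == ["P2"]

    def test_mask_retained_as_provenance(self, toy_matrix):
        out, _ = impute_missing(toy_matrix)
        assert out.missing_mask.to_numpy().sum() == 3
        assert not out.values.isna().to_numpy().any()

    def test_epsilon_must_be_positive(self, toy_matrix):
        with pytest.raises(ValueError, match="epsilon"):
            impute_missing(toy_matrix, epsilon=0.0)

    @settings(max_examples=50, deadline=None)
    @given(row=finite_row, miss_at=st.integers(min_value=0, max_value=7))
    def test_observed_unchanged_and_imputed_below_minimum(self, row, miss_at):
        miss_at = miss_at % len(row)
        if len(row) < 2:
            return
        cells = [None if j == miss_at else v for j, v in enumerate(row)]
        if all(c is None for c in cells):
            return
        m = make_matrix([cells])
        out, _ = impute_missing(m, epsilon=0.05)
        observed = [v for v in cells if v is not None]
        for j, v in enumerate(cells):
            got = out.values.iloc[0, j]
            if v is None:
                assert got == pytest.approx(min(observed) - 0.05)
                assert got < min(observed)
            else:
                assert got == v


class TestMeanNormalize:
    def test_identical_columns_unchanged(self):
        m = make_matrix([[1.0, 1.0], [3.0, 3.0]])
        out = mean_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_hand_computed_2x2(self):
        # columns [1,1] and [3,3]: grand mean 2, both columns centered to it
        m = make_matrix([[1.0, 3.0], [1.0, 3.0]])
        out = mean_normalize(m)
        np.testing.assert_allclose(out.values.mean(axis=0), [2.0, 2.0])
        np.testing.assert_allclose(out.values.to_numpy(), [[2.0, 2.0], [2.0, 2.0]])

    @settings(max_examples=30, deadline=None)
    @given(
        rows=st.lists(
            st.lists(
                st.floats(min_value=-100, max_value=100, allow_nan=False, width=32),
                min_size=3,
                max_size=3,
            ),
            min_size=2,
            max_size=6,
        )
    )
    def test_column_means_equal_grand_mean(self, rows):
        m = make_matrix(rows)
        out = mean_normalize(m)
        grand = m.values.to_numpy().mean()
        np.testing.assert_allclose(
            out.values.mean(axis=0), np.full(3, grand), atol=1e-9
        )
        assert out.values.to_numpy().mean() == pytest.approx(grand, abs=1e-9)


class TestRatioNormalize:
    def test_grand_mean_reference_hand_computed(self):
        m = make_matrix([[10.0, 12.0]])
        out = ratio_normalize(m, "grand_mean")
        assert out.values.loc["P1"].tolist() == [-1.0, 1.0]

    def test_single_sample_self_reference_is_zero(self):
        m = make_matrix([[7.0], [3.0]])
        out = ratio_normalize(m, "grand_mean")
        np.testing.assert_allclose(out.values.to_numpy(), 0.0)

    def test_reference_sample_column_becomes_zero(self):
        m = make_matrix([[1.0, 5.0], [2.0, 9.0]], samples=["S1", "S2"])
        out = ratio_normalize(m, "reference_sample:S1")
        np.testing.assert_allclose(out.values["S1"], 0.0)

    def test_reference_group(self, two_group_labels):
        m = make_matrix(
            [[1.0, 3.0, 10.0, 20.0]], samples=["A1", "A2", "B1", "B2"]
        )
        samples = make_samples(2)
        out = ratio_normalize(m, "reference_group:A", samples)
        np.testing.assert_allclose(out.values.loc["P1"], [-1.0, 1.0, 8.0, 18.0])

    def test_unknown_reference_errors(self):
        m = make_matrix([[1.0, 2.0]])
        with pytest.raises(ValueError, match="unknown ratio reference"):
            ratio_normalize(m, "bogus")


class TestBinomialTransform:
    def test_median_split(self):
        m = make_matrix([[1.0, 2.0, 3.0, 4.0]])
        out = binomial_transform(m)
        assert out.codes.loc["P1"].tolist() == [0, 0, 1, 1]

    def test_constant_row_all_under(self):
        m = make_matrix([[5.0, 5.0, 5.0]])
        out = binomial_transform(m)
        assert out.codes.loc["P1"].tolist() == [0, 0, 0]

    @settings(max_examples=40, deadline=None)
    @given(row=finite_row)
    def test_over_count_bounded_and_monotone_invariant(self, row):
        row = [round(v, 2) for v in row]  # keep near-ties away from float eps
        n = len(row)
        m = make_matrix([row])
        codes = binomial_transform(m).codes.to_numpy()
        assert codes.sum() <= np.ceil(n / 2)
        # strictly monotone transform leaves the categorization unchanged
        m2 = make_matrix([[np.exp(v / 25.0) for v in row]])
        codes2 = binomial_transform(m2).codes.to_numpy()
        np.testing.assert_array_equal(codes, codes2)


class TestBatches:
    def _setup(self):
        batches = [1, 2, 3, 1, 2, 1, 2, 3, 1, 2]
        samples = make_samples(5, batches=batches)
        rng = np.random.default_rng(0)
        m = make_matrix(
            rng.lognormal(3, 1, size=(4, 10)).tolist(), samples=samples.samples
        )
        return m, samples

    def test_keep_subset(self):
        m, samples = self._setup()
        out, sub = filter_batches(m, samples, {"1", "3"})
        assert out.n_samples == 6
        assert set(sub.table["batch"]) == {"1", "3"}
        # sample order preserved
        assert out.samples == [
            s for s in m.samples if samples.batches[s] in {"1", "3"}
        ]

    def test_keep_all_is_identity_and_idempotent(self):
        m, samples = self._setup()
        out, sub = filter_batches(m, samples, {"1", "2", "3"})
        assert out.samples == m.samples
        again, _ = filter_batches(out, sub, {"1", "2", "3"})
        assert again.samples == out.samples

    def test_emptied_group_errors(self):
        batches = [1, 1, 1, 1, 2, 2]
        samples = make_samples(3, batches=batches)  # group B entirely batch 2
        m = make_matrix(np.ones((2, 6)).tolist(), samples=samples.samples)
        with pytest.raises(ValueError):
            filter_batches(m, samples, {"1"})

    def test_unknown_batch_errors(self):
        m, samples = self._setup()
        with pytest.raises(ValueError, match="unknown batch"):
            filter_batches(m, samples, {"9"})

    def test_qc_flags_high_missingness_batch(self):
        batches = [1, 2, 3, 1, 2, 1, 2, 3, 1, 2]
        samples = make_samples(5, batches=batches)
        rng = np.random.default_rng(1)
        vals = rng.lognormal(3, 1, size=(50, 10))
        m = make_matrix(vals.tolist(), samples=samples.samples)
        batch2 = [s for s in m.samples if samples.batches[s] == "2"]
        miss = m.missing_mask.copy()
        miss.loc[:, batch2] = rng.random((50, len(batch2))) < 0.5
        other = [s for s in m.samples if s not in batch2]
        miss.loc[:, other] = rng.random((50, len(other))) < 0.05
        m2 = make_matrix(
            m.values.mask(miss).to_numpy().tolist(), samples=m.samples, mask=miss
        )
        qc = batch_qc(m2, samples)
        flagged = qc.loc[qc["flagged"], "batch"].tolist()
        assert flagged == ["2"]

    def test_qc_identical_batches_unflagged(self):
        m, samples = self._setup()
        qc = batch_qc(m, samples)
        assert not qc["flagged"].any()

    def test_qc_requires_two_batches(self):
        samples = make_samples(3)
        m = make_matrix(np.ones((2, 6)).tolist(), samples=samples.samples)
        with pytest.raises(ValueError, match="2 batches"):
            batch_qc(m, samples)


class TestCompletenessAndLog2:
    def test_log2_requires_positive(self):
        m = make_matrix([[0.0, 1.0]])
        with pytest.raises(ValueError, match="positive"):
            log2_transform(m)

    def test_completeness_keeps_one_sided_proteins(self):
        samples = make_samples(3)
        # P1 fully observed in A, absent in B -> kept (one group suffices);
        # P2 observed once per group (1/3 < 0.5 in both) -> dropped
        m = make_matrix(
            [
                [1.0, 2.0, 3.0, None, None, None],
                [None, 1.0, None, None, 1.0, None],
            ],
            samples=samples.samples,
        )
        out, dropped = completeness_filter(m, samples, 0.5)
        assert out.protein_ids == ["P1"]
        assert dropped == ["P2"]
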