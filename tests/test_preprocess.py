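"""Tests for the count-table -> SRP preprocessing chain."""

import numpy as np
import pytest

from rmnet.preprocess import (
    AbundanceTable,
    ProportionTable,
    counts_to_srp,
    filter_otus_abundance,
    filter_otus_prevalence,
    filter_timepoints,
    impute_missing,
    relative_abundance,
    standardize_srp,
)


def table(counts, missing=None, **kw):
    counts = np.asarray(counts, dtype=float)
    return AbundanceTable(
        counts=counts,
        otu_ids=kw.get("otu_ids", [f"OTU{i}" for i in range(counts.shape[0])]),
        time_labels=kw.get("time_labels", [f"t{j}" for j in range(counts.shape[1])]),
        missing_mask=missing,
    )


def props(values, missing=None):
    values = np.asarray(values, dtype=float)
    return ProportionTable(
        values=values,
        otu_ids=[f"OTU{i}" for i in range(values.shape[0])],
        time_labels=[f"t{j}" for j in range(values.shape[1])],
        missing_mask=missing,
    )


class TestRelativeAbundance:
    def test_column_proportions(self):
        out = relative_abundance(table([[2], [3], [5]]))
        assert out.values[:, 0] == pytest.approx([0.2, 0.3, 0.5])

    def test_single_taxon_column(self):
        out = relative_abundance(table([[7], [0], [0]]))
        assert out.values[:, 0] == pytest.approx([1, 0, 0])

    def test_two_by_two(self):
        out = relative_abundance(table([[1, 9], [3, 1]]))
        assert out.values == pytest.approx(np.array([[0.25, 0.9], [0.75, 0.1]]))

    def test_columns_sum_to_one(self, rng):
        out = relative_abundance(table(rng.integers(1, 100, (6, 8))))
        assert out.values.sum(axis=0) == pytest.approx(np.ones(8), abs=1e-9)

    def test_zero_column_names_time_point(self):
        with pytest.raises(ValueError, match="t1"):
            relative_abundance(table([[1, 0], [2, 0]]))

    def test_missing_entries_excluded_from_sums(self):
        missing = np.array([[False, True], [False, False]])
        out = relative_abundance(table([[1, 5], [3, 2]], missing=missing))
        assert out.values[1, 1] == pytest.approx(1.0)
        assert out.missing_mask[0, 1]


class TestPrevalenceFilter:
    def test_boundary_is_kept(self):
        counts = np.zeros((1, 10))
        counts[0, :5] = 3  # present at exactly half the time points
        assert filter_otus_prevalence(table(counts)).shape[0] == 1

    def test_below_boundary_removed(self):
        counts = np.zeros((1, 10))
        counts[0, :4] = 3
        assert filter_otus_prevalence(table(counts)).shape[0] == 0

    def test_survivor_order_preserved(self):
        counts = np.array([[1] * 10, [0] * 10, [2] * 10], dtype=float)
        out = filter_otus_prevalence(table(counts))
        assert out.otu_ids == ["OTU0", "OTU2"]

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning):
            filter_otus_prevalence(table(np.zeros((2, 4))))

    def test_idempotent(self, rng):
        t = table(rng.integers(0, 3, (8, 10)))
        once = filter_otus_prevalence(t)
        twice = filter_otus_prevalence(once)
        assert once.otu_ids == twice.otu_ids


class TestAbundanceFilter:
    def test_low_but_steady_kept(self):
        out = filter_otus_abundance(props([[0.05, 0.06, 0.04]]))
        assert out.shape[0] == 1  # CV ~ 0.16 <= 3.4

    def test_high_max_always_kept(self):
        out = filter_otus_abundance(props([[0.5, 0.0, 0.0]]))
        assert out.shape[0] == 1

    def test_all_zero_row_removed(self):
        out = filter_otus_abundance(props([[0.0, 0.0, 0.0], [0.5, 0.2, 0.3]]))
        assert out.otu_ids == ["OTU1"]

    def test_idempotent(self, rng):
        p = props(rng.uniform(0, 0.2, (8, 6)))
        once = filter_otus_abundance(p)
        assert filter_otus_abundance(once).otu_ids == once.otu_ids


class TestTimepointFilter:
    def test_high_max_column_kept(self):
        vals = np.full((10, 2), 0.01)
        vals[0, 0] = 0.4
        vals[:, 1] = 0.1  # second column safe on both clauses
        out = filter_timepoints(props(vals))
        assert out.shape[1] == 2

    def test_sparse_low_column_removed(self):
        vals = np.zeros((10, 2))
        vals[:3, 0] = 0.05  # max 0.05, 3/10 non-zero -> removed
        vals[:, 1] = 0.1
        out = filter_timepoints(props(vals))
        assert out.time_labels == ["t1"]

    def test_populated_low_column_kept(self):
        vals = np.zeros((10, 1))
        vals[:7, 0] = 0.05  # max 0.05 but 7/10 non-zero -> kept
        assert filter_timepoints(props(vals)).shape[1] == 1

    def test_removing_all_errors(self):
        vals = np.zeros((10, 2))
        vals[:3, :] = 0.001  # all columns low-signal and sparse
        with pytest.raises(ValueError):
            filter_timepoints(props(vals))


class TestImputation:
    def test_identity_without_missing(self, rng):
        p = props(rng.uniform(0, 1, (6, 5)))
        out = impute_missing(p)
        assert np.array_equal(out.values, p.values)

    def test_rank_one_entry_recovered(self):
        u = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        v = np.array([0.1, 0.3, 0.5, 0.7, 0.9, 0.2])
        full = np.outer(u, v)
        missing = np.zeros_like(full, dtype=bool)
        missing[2, 3] = True
        out = impute_missing(props(full, missing=missing), n_components=1)
        assert out.values[2, 3] == pytest.approx(full[2, 3], abs=1e-6)

    def test_observed_entries_untouched(self, rng):
        vals = rng.uniform(0, 1, (8, 7))
        missing = np.zeros_like(vals, dtype=bool)
        missing[1, 2] = missing[5, 0] = True
        out = impute_missing(props(vals, missing=missing), n_components=3)
        assert np.array_equal(out.values[~missing], vals[~missing])
        assert not out.missing_mask.any()

    def test_matches_em_pca_oracle(self, rng):
        # independent EM-PCA: alternate rank-1 SVD reconstruction to convergence
        vals = rng.uniform(0, 1, (7, 6))
        missing = np.zeros_like(vals, dtype=bool)
        missing[3, 4] = True
        expect = vals.copy()
        expect[3, 4] = np.delete(vals[:, 4], 3).mean()
        for _ in range(2000):
            mu = expect.mean(axis=0)
            u, s, vt = np.linalg.svd(expect - mu, full_matrices=False)
            recon = s[0] * np.outer(u[:, 0], vt[0]) + mu
            new = np.where(missing, recon, vals)
            if abs(new[3, 4] - expect[3, 4]) < 1e-12:
                break
            expect = new
        out = impute_missing(props(vals, missing=missing), n_components=1, tol=1e-12)
        assert out.values[3, 4] == pytest.approx(expect[3, 4], abs=1e-8)

    def test_too_many_missing_rejected(self):
        vals = np.full((4, 4), 0.5)
        missing = np.ones_like(vals, dtype=bool)
        missing[:, 0] = False
        with pytest.raises(ValueError):
            impute_missing(props(vals, missing=missing))


class TestStandardize:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([0.2, 0.5, 0.8], [0.0, 0.5, 1.0]),
            ([0.0, 1.0], [0.0, 1.0]),
            ([0.1, 0.1, 0.4], [0.0, 0.0, 1.0]),
        ],
    )
    def test_min_max_rows(self, row, expected):
        out = standardize_srp(props([row]))
        assert out.values[0] == pytest.approx(expected)

    def test_rows_span_unit_interval(self, rng):
        out = standardize_srp(props(rng.uniform(0, 1, (6, 9))))
        assert out.values.min(axis=1) == pytest.approx(np.zeros(6))
        assert out.values.max(axis=1) == pytest.approx(np.ones(6))

    def test_constant_row_is_an_error(self):
        with pytest.raises(ValueError, match="OTU1"):
            standardize_srp(props([[0.1, 0.9], [0.3, 0.3]]))

    def test_missing_values_rejected(self):
        missing = np.array([[True, False]])
        with pytest.raises(ValueError):
            standardize_srp(props([[0.1, 0.9]], missing=missing))


def test_full_chain_produces_srp(rng):
    counts = rng.integers(1, 200, (8, 12)).astype(float)
    missing = rng.uniform(size=counts.shape) < 0.05
    t = table(counts, missing=missing)
    srp = counts_to_srp(t)
    assert srp.values.shape[1] == 12
    assert np.all((srp.values >= 0) & (srp.values <= 1))
    assert srp.values.min(axis=1) == pytest.approx(np.zeros(srp.values.shape[0]))
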