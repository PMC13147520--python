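"""Correlation matrix: coefficients, p-values, pairwise deletion."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from biochromtox.correlations import (
    build_matrix,
    exclusion_subsets,
    pearson,
    pearson_pvalue,
    spearman,
)
from biochromtox.tables import DESCRIPTOR_COLUMNS, ENDPOINT_COLUMNS


def midrank_spearman_oracle(x, y):
    """Brute-force Spearman: midranks by counting, then the definitional
    Pearson formula on the rank vectors."""
    def midranks(v):
        v = list(v)
        return [
            1 + sum(1 for w in v if w < vi) + (sum(1 for w in v if w == vi) - 1) / 2
            for vi in v
        ]

    rx, ry = midranks(x), midranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestCoefficients:
    def test_pearson_self_correlation(self):
        assert pearson([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]) == pytest.approx(1.0)

    def test_pearson_hand_computed_triple(self):
        # covariance formula by hand: r((1,2,3),(6,4,5)) = -0.5
        assert pearson([1, 2, 3], [6, 4, 5]) == pytest.approx(-0.5)

    def test_spearman_rank_invariance_under_monotone_transform(self):
        x = [0.3, 1.1, 2.2, 3.9, 7.4]
        y = [math.exp(v) for v in x]
        assert spearman(x, y) == pytest.approx(1.0)

    def test_spearman_midranks_with_ties(self):
        # midranks of y are (1.5, 1.5, 3, 4); Pearson on ranks = 0.949
        assert spearman([1, 2, 3, 4], [1, 1, 2, 3]) == pytest.approx(0.949, abs=5e-4)

    def test_too_few_pairs_is_missing(self):
        assert math.isnan(pearson([1.0, 2.0], [3.0, 4.0]))

    def test_zero_variance_is_missing(self):
        assert math.isnan(pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
        assert math.isnan(spearman([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]))

    @given(
        xy=st.lists(
            st.tuples(st.integers(-5, 5), st.integers(-5, 5)),
            min_size=3,
            max_size=8,
        ),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_spearman_equals_bruteforce_midrank_oracle(self, xy):
        """Tie-rich integer pairs of length <= 8 against the enumeration
        oracle; degenerate inputs are missing on both routes."""
        x = [float(a) for a, _ in xy]
        y = [float(b) for _, b in xy]
        if len(set(x)) == 1 or len(set(y)) == 1:
            assert math.isnan(spearman(x, y))
            return
        assert spearman(x, y) == pytest.approx(midrank_spearman_oracle(x, y), abs=1e-12)

    @given(
        data=st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
            ),
            min_size=4,
            max_size=12,
        ),
        a=st.floats(0.1, 10.0),
        b=st.floats(-5.0, 5.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_pearson_affine_invariance_and_sign_flip(self, data, a, b):
        x = np.array([p[0] for p in data])
        y = np.array([p[1] for p in data])
        r = pearson(x, y)
        if math.isnan(r):
            return
        assert pearson(a * x + b, y) == pytest.approx(r, abs=1e-8)
        assert pearson(-a * x + b, y) == pytest.approx(-r, abs=1e-8)


class TestPValue:
    def test_zero_correlation_has_p_one(self):
        assert pearson_pvalue(0.0, 10) == pytest.approx(1.0)

    def test_perfect_correlation_reports_zero(self):
        assert pearson_pvalue(1.0, 5) == 0.0

    def test_matches_t_distribution_oracle(self):
        # r = 0.5, n = 20 -> t = 0.5*sqrt(18)/sqrt(0.75) = 2.449, df = 18
        t = 0.5 * math.sqrt(18) / math.sqrt(1 - 0.25)
        expected = 2 * stats.t.sf(t, 18)
        assert pearson_pvalue(0.5, 20) == pytest.approx(expected, rel=1e-12)
        assert t == pytest.approx(2.449, abs=5e-4)


class TestBuildMatrix:
    def test_pairwise_deletion_counts_match_direct_counting(
        self, descriptors, endpoints, reference_subsets
    ):
        matrix = build_matrix(descriptors, endpoints, subsets=reference_subsets)
        desc = descriptors.descriptors
        for cell in matrix.cells:
            include = reference_subsets.get(cell.endpoint, endpoints.compound_ids)
            expected_n = sum(
                1
                for c in include
                if not np.isnan(desc.loc[c, cell.descriptor])
                and not np.isnan(endpoints.values.loc[c, cell.endpoint])
            )
            assert cell.n == expected_n

    def test_injected_missing_drops_n_by_exactly_one(self, descriptors, endpoints):
        matrix_full = build_matrix(descriptors, endpoints)
        damaged = descriptors.frame.copy()
        damaged.loc["BPA", "chi_iam"] = np.nan
        from biochromtox.tables import DescriptorTable

        matrix_damaged = build_matrix(DescriptorTable(damaged), endpoints)
        for endpoint in ENDPOINT_COLUMNS:
            before = matrix_full.cell(endpoint, "chi_iam").n
            after = matrix_damaged.cell(endpoint, "chi_iam").n
            has_bpa = not np.isnan(endpoints.values.loc["BPA", endpoint])
            assert after == before - (1 if has_bpa else 0)

    def test_vasodilation_subset_row(self, descriptors, endpoints, reference_subsets):
        matrix = build_matrix(descriptors, endpoints, subsets=reference_subsets)
        cell = matrix.cell("vasodilation_pct", "chi_iam")
        assert cell.n == 8
        assert cell.r == pytest.approx(0.9907, abs=5e-4)
        assert cell.rho == pytest.approx(1.0)

    def test_row_max_flags_largest_abs_r(self, descriptors, endpoints):
        matrix = build_matrix(descriptors, endpoints)
        for endpoint in ENDPOINT_COLUMNS:
            row = [c for c in matrix.cells if c.endpoint == endpoint and not c.missing]
            if not row:
                continue
            best = max(abs(c.r) for c in row)
            for c in row:
                if abs(c.r) == best:
                    assert c.is_row_max

    def test_disjoint_tables_raise(self, descriptors, endpoints):
        from biochromtox.tables import DescriptorTable

        other = descriptors.frame.copy()
        other.index = ["X" + c for c in other.index]
        with pytest.raises(ValueError, match="share no compound_id"):
            build_matrix(DescriptorTable(other), endpoints)
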