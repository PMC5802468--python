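import numpy as np
import pandas as pd
import pytest

from pleiopace.analysis import (
    classify_pleiotropy,
    classify_table,
    correlation_matrix,
    mean_rate,
    outcome_table,
)
from pleiopace.protocols import FICurve


def _fi(amps, freqs):
    return FICurve(np.asarray(amps, float), np.asarray(freqs, float), 1000.0)


class TestMeanRate:
    def test_constant_curve(self):
        fi = _fi([0.3, 0.6, 0.9], [10.0, 10.0, 10.0])
        assert mean_rate(fi, (0.2, 1.0)) == 10.0

    def test_simple_average(self):
        fi = _fi([0.3, 0.6, 0.9], [0.0, 5.0, 10.0])
        assert mean_rate(fi, (0.2, 1.0)) == 5.0

    def test_range_restriction_drops_points(self):
        fi = _fi([0.3, 0.6, 0.9], [0.0, 5.0, 10.0])
        assert mean_rate(fi, (0.5, 1.0)) == 7.5

    def test_empty_intersection_is_error(self):
        fi = _fi([0.3, 0.6], [1.0, 2.0])
        with pytest.raises(ValueError):
            mean_rate(fi, (1.5, 2.0))


def _table(neuron, san, genes=None):
    n = len(neuron)
    genes = genes or ["CACNA1C"] * n
    return outcome_table([
        {"variant_id": f"V{i}", "gene": genes[i],
         "neuron": neuron[i], "san": san[i]} for i in range(n)
    ])


class TestCorrelationMatrix:
    def test_identical_columns_correlate_to_one(self):
        tab = _table([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        mat = correlation_matrix(tab, ["neuron", "san"])
        assert mat.loc["neuron", "san"] == pytest.approx(1.0)
        assert np.allclose(np.diag(mat), 1.0)
        assert mat.equals(mat.T)

    def test_negated_columns_correlate_to_minus_one(self):
        tab = _table([1.0, 2.0, 3.0], [-1.0, -2.0, -3.0])
        mat = correlation_matrix(tab, ["neuron", "san"])
        assert mat.loc["neuron", "san"] == pytest.approx(-1.0)

    def test_four_row_example_matches_textbook_formula(self):
        x = np.array([2.0, 4.0, 5.0, 9.0])
        y = np.array([1.0, 3.0, 2.0, 7.0])
        # independent route: raw-sums Pearson formula
        n = 4
        num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
        den = np.sqrt(n * np.sum(x * x) - np.sum(x) ** 2) * np.sqrt(
            n * np.sum(y * y) - np.sum(y) ** 2)
        expected = num / den
        mat = correlation_matrix(_table(x, y), ["neuron", "san"])
        assert mat.loc["neuron", "san"] == pytest.approx(expected, rel=1e-12)

    def test_row_order_and_affine_invariance(self):
        x = [2.0, 4.0, 5.0, 9.0]
        y = [1.0, 3.0, 2.0, 7.0]
        base = correlation_matrix(_table(x, y), ["neuron", "san"])
        shuffled = correlation_matrix(_table(x[::-1], y[::-1]),
                                      ["neuron", "san"])
        scaled = correlation_matrix(_table([3 * v + 1 for v in x], y),
                                    ["neuron", "san"])
        r = base.loc["neuron", "san"]
        assert shuffled.loc["neuron", "san"] == pytest.approx(r)
        assert scaled.loc["neuron", "san"] == pytest.approx(r)

    def test_missing_rows_dropped_and_minimum_enforced(self):
        tab = _table([1.0, 2.0, np.nan, 4.0], [1.0, 2.0, 3.0, 4.0])
        mat = correlation_matrix(tab, ["neuron", "san"])
        assert mat.loc["neuron", "san"] == pytest.approx(1.0)
        small = _table([1.0, np.nan, np.nan, 4.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            correlation_matrix(small, ["neuron", "san"])

    def test_zero_variance_flagged_as_nan(self):
        tab = _table([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        mat = correlation_matrix(tab, ["neuron", "san"])
        assert np.isnan(mat.loc["neuron", "san"])

    def test_gene_class_filter(self):
        tab = _table([1, 2, 3, 1, 2, 3], [1, 2, 3, 3, 2, 1],
                     genes=["CACNA1C"] * 3 + ["SCN1A"] * 3)
        ca = correlation_matrix(tab, ["neuron", "san"], "ca")
        na = correlation_matrix(tab, ["neuron", "san"], "na_hcn")
        assert ca.loc["neuron", "san"] == pytest.approx(1.0)
        assert na.loc["neuron", "san"] == pytest.approx(-1.0)


class TestClassifyPleiotropy:
    def test_same_sign_is_analogous(self):
        assert classify_pleiotropy(0.05, 0.04) == "analogous"

    def test_opposite_sign_is_non_analogous(self):
        assert classify_pleiotropy(0.05, -0.04) == "non-analogous"

    def test_dead_band_gives_neutral(self):
        assert classify_pleiotropy(0.001, -0.08, dead_band=0.01) == "neutral"

    def test_table_classification_counts(self):
        tab = _table([0.05, -0.03, 0.001], [0.04, 0.05, -0.06],
                     genes=["CACNA1C", "CACNA1C", "SCN1A"])
        tab = tab.rename(columns={"neuron": "neuron_rel", "san": "san_rel"})
        out = classify_table(tab, "neuron_rel", "san_rel")
        assert list(out["classification"]) == [
            "analogous", "non-analogous", "neutral"]
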