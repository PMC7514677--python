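import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import grpspace as g
from grpspace.mi import bin_codes


def gaussian_pair(rho, n, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = rho * x + math.sqrt(1 - rho**2) * rng.standard_normal(n)
    return x, y


class TestEstimateMI:
    def test_independent_gaussians_near_zero(self):
        rng = np.random.default_rng(0)
        est = g.estimate_mi(rng.standard_normal(5000), rng.standard_normal(5000))
        assert est <= 0.02

    def test_gaussian_closed_form(self):
        """At rho=0.9 the estimate tracks -0.5*ln(1-rho^2) within 10%."""
        x, y = gaussian_pair(0.9, 10_000, seed=1)
        true = -0.5 * math.log(1 - 0.81)
        assert abs(g.estimate_mi(x, y) - true) / true < 0.10

    def test_deterministic_monotone_relation_saturates(self):
        """y = f(x) strictly monotone: plug-in MI equals the binned entropy ln(B)."""
        x = np.random.default_rng(1).standard_normal(400)
        cfg = g.EstimatorConfig(n_bins=8, bias_correction="none")
        assert g.estimate_mi(x, np.exp(x), cfg) == pytest.approx(math.log(8), abs=1e-12)

    def test_symmetry_exact(self):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal(123), rng.standard_normal(123)
        assert g.estimate_mi(x, y) == g.estimate_mi(y, x)

    @pytest.mark.parametrize("transform", [np.exp, lambda v: v**3, lambda v: 1 / (1 + np.exp(-v))])
    def test_monotone_transform_invariance(self, transform):
        """Equal-frequency binning acts on ranks only (strictly increasing maps)."""
        x, y = gaussian_pair(0.6, 500, seed=3)
        assert g.estimate_mi(x, y) == g.estimate_mi(transform(x), y)
        assert g.estimate_mi(x, y) == g.estimate_mi(x, transform(y))

    def test_constant_vector_degenerate(self, caplog):
        x = np.random.default_rng(0).standard_normal(100)
        with caplog.at_level("WARNING"):
            assert g.estimate_mi(x, np.full(100, 3.14)) == 0.0
        assert "degenerate" in caplog.text

    def test_length_mismatch_rejected(self):
        with pytest.raises(g.ContractError, match="mismatch"):
            g.estimate_mi(np.arange(10.0), np.arange(11.0))

    def test_too_few_samples_rejected(self):
        with pytest.raises(g.ContractError):
            g.estimate_mi(np.arange(6.0), np.arange(6.0), g.EstimatorConfig(n_bins=4))

    def test_bias_shrinks_with_sample_size(self):
        """Mean absolute error on Gaussian pairs decreases from n=200 to n=5000."""
        true = -0.5 * math.log(1 - 0.36)
        errs = {}
        for n in (200, 1000, 5000):
            ests = [g.estimate_mi(*gaussian_pair(0.6, n, seed=s)) for s in range(5)]
            errs[n] = abs(np.mean(ests) - true)
        assert errs[5000] < errs[200]


class TestMIMatrix:
    def test_three_genes_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        expr = g.ExpressionMatrix(
            ["a", "b", "c"], [f"s{i}" for i in range(30)], np.abs(rng.standard_normal((3, 30)))
        )
        m = g.compute_mi_matrix(expr)
        np.testing.assert_array_equal(m.values, m.values.T)
        np.testing.assert_array_equal(np.diagonal(m.values), 0.0)

    def test_identical_genes_maximize_row(self):
        rng = np.random.default_rng(2)
        vals = np.abs(rng.standard_normal((5, 60)))
        vals[1] = vals[0]
        expr = g.ExpressionMatrix([f"a{i}" for i in range(5)], [f"s{j}" for j in range(60)], vals)
        m = g.compute_mi_matrix(expr)
        assert m.values[0, 1] == m.values[0].max()

    def test_worker_count_is_bit_identical(self, random_expression):
        m1 = g.compute_mi_matrix(random_expression, n_workers=1)
        m4 = g.compute_mi_matrix(random_expression, n_workers=4)
        np.testing.assert_array_equal(m1.values, m4.values)

    def test_single_gene_rejected(self):
        expr = g.ExpressionMatrix(["a"], [f"s{j}" for j in range(20)], np.ones((1, 20)))
        with pytest.raises(g.ContractError):
            g.compute_mi_matrix(expr)

    def test_meta_records_estimator(self, random_expression):
        m = g.compute_mi_matrix(random_expression)
        assert m.estimator_meta["estimator"] == "equal_frequency_bins"
        assert m.estimator_meta["n_samples"] == random_expression.n_samples


class TestPermutationNull:
    def test_seeded_reproducibility(self):
        x, y = gaussian_pair(0.5, 200, seed=0)
        a = g.permutation_null_mi(x, y, n_permutations=20, seed=5)
        b = g.permutation_null_mi(x, y, n_permutations=20, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_null_quantile_shrinks_with_n(self):
        qs = {}
        for n in (100, 1000):
            rng = np.random.default_rng(1)
            x, y = rng.standard_normal(n), rng.standard_normal(n)
            qs[n] = np.quantile(g.permutation_null_mi(x, y, n_permutations=200, seed=0), 0.95)
        assert qs[1000] < qs[100]

    def test_strong_dependence_beats_null(self):
        x, y = gaussian_pair(0.9, 500, seed=4)
        null = g.permutation_null_mi(x, y, n_permutations=1000, seed=0)
        assert g.estimate_mi(x, y) > null.max()


@settings(deadline=None, max_examples=30)
@given(st.integers(min_value=0, max_value=10**6))
def test_equal_frequency_bins_balanced(seed):
    """Distinct values spread (near-)evenly over bins; ties share a bin."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(120)
    codes = bin_codes(x, 6)
    counts = np.bincount(codes, minlength=6)
    assert counts.min() >= 1 and counts.max() - counts.min() <= 1
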