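import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import grpspace as g
from tests.conftest import make_symmetric_mi


def brute_force_ks(a, b):
    """Literal sup over pooled points of |ECDF_a - ECDF_b|."""
    best = 0.0
    for x in list(a) + list(b):
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        best = max(best, abs(fa - fb))
    return best


class TestKS:
    def test_identical_samples(self):
        assert g.ks_statistic([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_disjoint_supports(self):
        assert g.ks_statistic([1.0, 2.0], [3.0, 4.0]) == 1.0

    def test_interleaved_example(self):
        assert g.ks_statistic([1.0, 3.0], [2.0, 4.0]) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(g.ContractError):
            g.ks_statistic([], [1.0])

    def test_p_value_identical_is_one(self):
        x = np.arange(100.0)
        assert g.ks_p_value(x, x) == 1.0

    def test_p_value_disjoint_is_tiny(self):
        assert g.ks_p_value(np.arange(100.0), np.arange(100.0) + 1000) < 1e-10


class TestNeglog:
    @pytest.mark.parametrize("d,expected", [(1.0, 0.0), (math.exp(-1), 1.0), (0.1, 2.302585)])
    def test_values(self, d, expected):
        assert g.neglog_transform(d) == pytest.approx(expected, abs=1e-6)

    def test_zero_capped_by_pooled_size(self, caplog):
        with caplog.at_level("WARNING"):
            assert g.neglog_transform(0.0, pooled_n=99) == pytest.approx(math.log(100))
        with pytest.raises(g.ContractError):
            g.neglog_transform(0.0)


class TestHistogramPDF:
    def test_identical_values_single_bin(self):
        pdf = g.estimate_pdf(np.full(100, 2.5), n_bins=10, shared_range=(0, 5))
        assert np.count_nonzero(pdf.masses) == 1
        assert pdf.masses.sum() == pytest.approx(1.0)

    def test_uniform_masses(self):
        vals = np.random.default_rng(0).uniform(0, 1, size=10**6)
        pdf = g.estimate_pdf(vals, n_bins=10, shared_range=(0, 1))
        np.testing.assert_allclose(pdf.masses, 0.1, atol=0.005)

    def test_zero_width_range_rejected(self):
        with pytest.raises(g.ContractError):
            g.estimate_pdf(np.ones(5), n_bins=4, shared_range=(1.0, 1.0))


class TestHellinger:
    def test_identity(self):
        p = g.estimate_pdf(np.random.default_rng(0).uniform(size=100), 10, (0, 1))
        assert g.hellinger_distance(p, p) == 0.0

    def test_disjoint_supports_maximal(self):
        p = g.HistogramPDF([0, 1, 2], [1.0, 0.0])
        q = g.HistogramPDF([0, 1, 2], [0.0, 1.0])
        assert g.hellinger_distance(p, q) == 1.0

    def test_closed_form(self):
        p = g.HistogramPDF([0, 1, 2], [1.0, 0.0])
        q = g.HistogramPDF([0, 1, 2], [0.5, 0.5])
        assert g.hellinger_distance(p, q) == pytest.approx(math.sqrt(1 - math.sqrt(0.5)))

    def test_euclidean_sq_variant(self):
        p = g.HistogramPDF([0, 1, 2], [1.0, 0.0])
        q = g.HistogramPDF([0, 1, 2], [0.5, 0.5])
        assert g.hellinger_distance(p, q, form="euclidean_sq") == pytest.approx(0.25)

    def test_mismatched_bins_rejected(self):
        p = g.HistogramPDF([0, 1, 2], [0.5, 0.5])
        q = g.HistogramPDF([0, 2, 4], [0.5, 0.5])
        with pytest.raises(g.ContractError):
            g.hellinger_distance(p, q)


class TestComparisons:
    @pytest.fixture
    def aligned_collections(self, three_chrom_annotation):
        ids = ["g1", "g2", "g3", "g4", "g5", "g6"]
        a = g.partition_grp(make_symmetric_mi(ids, 0), three_chrom_annotation)
        a.condition = "tumor"
        b = g.partition_grp(make_symmetric_mi(ids, 1), three_chrom_annotation)
        b.condition = "control"
        return a, b

    def test_identical_inputs_give_zero_distances(self, aligned_collections):
        a, _ = aligned_collections
        for r in g.condition_comparison(a, a):
            assert r.value == 0.0

    def test_one_record_per_nonempty_key(self, aligned_collections):
        a, b = aligned_collections
        records = g.condition_comparison(a, b)
        assert len(records) == 5  # ("X","X") empty, skipped
        assert all(0.0 <= r.value <= 1.0 for r in records)

    def test_anchored_record_count(self):
        """10 populated chromosomes -> 90 directed cis-vs-trans records."""
        import pandas as pd

        chroms = [str(i) for i in range(1, 11)]
        rows, gid = [], 0
        for c in chroms:
            for k in range(3):
                rows.append({"chrom": c, "start": k * 10, "end": k * 10 + 5, "gene_id": f"g{gid:02d}"})
                gid += 1
        annot = g.GeneAnnotation(pd.DataFrame(rows))
        col = g.partition_grp(make_symmetric_mi([f"g{i:02d}" for i in range(30)]), annot)
        for metric in ("ks", "hellinger"):
            assert len(g.cis_trans_comparison(col, metric)) == 90

    def test_empty_cis_anchor_skipped(self, aligned_collections, caplog):
        a, _ = aligned_collections
        with caplog.at_level("WARNING"):
            records = g.cis_trans_comparison(a, "ks")
        anchors = {r.program_a[0][0] for r in records}
        assert "X" not in anchors  # single-gene chromosome has no cis program
        assert "empty cis program" in caplog.text


class TestOracle:
    def test_ks_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n, m = rng.integers(1, 12, size=2)
            a = np.round(rng.normal(size=n), 1)  # rounding forces ties
            b = np.round(rng.normal(size=m), 1)
            assert g.ks_statistic(a, b) == pytest.approx(brute_force_ks(a, b), abs=1e-14)


@settings(deadline=None, max_examples=200)
@given(st.data())
def test_hellinger_metric_axioms(data):
    """Symmetry, identity and triangle inequality on random densities."""
    n_bins = data.draw(st.integers(2, 8))
    edges = np.arange(n_bins + 1, dtype=float)

    def density():
        raw = np.array(data.draw(
            st.lists(st.floats(0.001, 1, allow_nan=False), min_size=n_bins, max_size=n_bins)
        ))
        masses = raw / raw.sum()
        masses[-1] = 1.0 - masses[:-1].sum()  # exact normalization
        return g.HistogramPDF(edges, masses)

    p, q, r = density(), density(), density()
    dpq = g.hellinger_distance(p, q)
    assert dpq == pytest.approx(g.hellinger_distance(q, p), abs=1e-14)
    assert g.hellinger_distance(p, p) == 0.0
    assert 0.0 <= dpq <= 1.0
    assert dpq <= g.hellinger_distance(p, r) + g.hellinger_distance(r, q) + 1e-12
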