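import numpy as np
import pytest

import grpspace as g
from grpspace.simulate import apportion


class TestApportionment:
    def test_exact_proportional_split(self):
        assert apportion(100, {"1": 3, "2": 1}) == {"1": 75, "2": 25}

    def test_largest_remainder_with_lexicographic_ties(self):
        assert apportion(5, {"1": 1, "2": 1, "X": 1}) == {"1": 2, "2": 2, "X": 1}

    def test_conserves_total_and_guarantees_minimum(self):
        weights = {"1": 1000, "2": 500, "3": 1, "X": 1}
        counts = apportion(10, weights)
        assert sum(counts.values()) == 10
        assert all(c >= 1 for c in counts.values())

    def test_empty_weights_rejected(self):
        with pytest.raises(g.ConfigurationError):
            apportion(10, {})


class TestAnnotationGeneration:
    def test_deterministic(self):
        cfg = g.SimulationConfig(seed=3)
        a1, a2 = g.generate_annotation(cfg), g.generate_annotation(cfg)
        assert a1.table.equals(a2.table)
        assert a1.digest() == a2.digest()

    def test_counts_and_coordinates(self):
        cfg = g.SimulationConfig(n_genes=100, chromosome_weights={"1": 3, "2": 1})
        annot = g.generate_annotation(cfg)
        chrom_of = annot.chromosome_of()
        assert sum(1 for c in chrom_of.values() if c == "1") == 75
        for chrom in ("1", "2"):
            starts = annot.table.loc[annot.table["chrom"] == chrom, "start"].to_numpy()
            assert (np.diff(starts) > 0).all()

    def test_every_weighted_chromosome_populated(self):
        cfg = g.SimulationConfig(n_genes=30)
        annot = g.generate_annotation(cfg)
        assert set(annot.chromosomes()) == set(g.DEFAULT_CHROMOSOME_WEIGHTS)


class TestExpressionGeneration:
    def test_deterministic(self):
        cfg = g.SimulationConfig(n_genes=40, chromosome_weights={"1": 1, "2": 1}, seed=9)
        annot = g.generate_annotation(cfg)
        c1, t1 = g.generate_expression_pair(annot, cfg)
        c2, t2 = g.generate_expression_pair(annot, cfg)
        np.testing.assert_array_equal(c1.values, c2.values)
        np.testing.assert_array_equal(t1.values, t2.values)
        assert c1.sample_ids == c2.sample_ids

    def test_non_negative_and_shared_gene_set(self):
        cfg = g.SimulationConfig(seed=0)
        annot = g.generate_annotation(cfg)
        control, tumor = g.generate_expression_pair(annot, cfg)
        assert control.values.min() >= 0 and tumor.values.min() >= 0
        assert control.gene_ids == tumor.gene_ids == annot.gene_ids
        assert control.n_samples == cfg.n_samples_control
        assert tumor.n_samples == cfg.n_samples_tumor

    def test_unit_marginal_variance(self):
        """Per-gene variance of the latent signal approaches 1 at large n."""
        cfg = g.SimulationConfig(
            n_genes=60,
            chromosome_weights={"1": 1, "2": 1, "3": 1},
            n_samples_control=2000,
            n_samples_tumor=2000,
            seed=4,
        )
        annot = g.generate_annotation(cfg)
        control, _ = g.generate_expression_pair(annot, cfg)
        variances = np.var(control.values / 10.0, axis=1, ddof=1)
        # sd of a normal sample variance is sqrt(2/(n-1)) ~ 0.032 at n=2000
        assert abs(variances.mean() - 1.0) < 0.05

    def test_zero_couplings_give_independent_genes(self):
        cfg = g.SimulationConfig(
            n_genes=50,
            chromosome_weights={"1": 1, "2": 1},
            cis_coupling_control=0.0,
            cis_coupling_tumor=0.0,
            trans_coupling_control=0.0,
            trans_coupling_tumor=0.0,
            n_samples_control=400,
            n_samples_tumor=400,
            seed=8,
        )
        annot = g.generate_annotation(cfg)
        control, _ = g.generate_expression_pair(annot, cfg)
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(100):
            i, j = rng.choice(50, size=2, replace=False)
            r = np.corrcoef(control.values[i], control.values[j])[0, 1]
            worst = max(worst, abs(r))
        assert worst < 4 / np.sqrt(400)

    def test_cis_and_trans_correlations_match_couplings(self):
        """Within-chromosome pairs correlate at cis, across at trans."""
        cfg = g.SimulationConfig(
            n_genes=40,
            chromosome_weights={"1": 1, "2": 1},
            cis_coupling_control=0.6,
            trans_coupling_control=0.3,
            cis_coupling_tumor=0.6,
            trans_coupling_tumor=0.3,
            n_samples_control=4000,
            n_samples_tumor=10,
            seed=2,
        )
        annot = g.generate_annotation(cfg)
        control, _ = g.generate_expression_pair(annot, cfg)
        chrom_of = control.gene_ids  # genes 0..19 on chr1, 20..39 on chr2
        cis_r = np.corrcoef(control.values[0], control.values[1])[0, 1]
        trans_r = np.corrcoef(control.values[0], control.values[25])[0, 1]
        assert cis_r == pytest.approx(0.6, abs=0.06)
        assert trans_r == pytest.approx(0.3, abs=0.06)

    def test_annotation_config_mismatch_rejected(self):
        cfg = g.SimulationConfig(n_genes=40, chromosome_weights={"1": 1, "2": 1})
        other = g.SimulationConfig(n_genes=40, chromosome_weights={"1": 1, "3": 1})
        annot = g.generate_annotation(other)
        with pytest.raises(g.ContractError):
            g.generate_expression_pair(annot, cfg)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"chromosome_weights": {}},
            {"chromosome_weights": {"Y": 1}},
            {"chromosome_weights": {"1": -2}},
            {"cis_coupling_control": 1.0},
            {"trans_coupling_control": -0.1},
            {"cis_coupling_tumor": 0.2, "trans_coupling_tumor": 0.5},
            {"noise_sd": 0.0},
            {"n_genes": 3, "chromosome_weights": {"1": 1, "2": 1, "3": 1, "4": 1}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(g.ConfigurationError):
            g.SimulationConfig(**kwargs)
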