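"""Ground-truth invariants and recoverable planted structure of the generators."""

import numpy as np
import pandas as pd
import pytest

from braintx.association import spearman_rho
from braintx.simulate import (
    GroundTruth,
    default_effect_maps,
    gen_dev_expression,
    gen_expression_matrix,
    gen_interaction_network,
    gen_reference_lists,
    latent_pattern,
    make_ground_truth,
)
from braintx.sexdiff import sex_de_genes
from braintx.types import DEFAULT_PERIODS, DEFAULT_REGIONS, STRUCTURAL_INDEX


class TestGroundTruth:
    def test_classes_must_be_disjoint(self):
        with pytest.raises(ValueError):
            GroundTruth(class1_genes={"a"}, class2_genes={"a"}, genes=["a", "b"])

    def test_planted_genes_must_exist(self):
        with pytest.raises(ValueError):
            GroundTruth(class1_genes={"ghost"}, genes=["a", "b"])

    def test_make_ground_truth_sizes_and_roundtrip(self):
        truth = make_ground_truth(n_genes=300, n_class1=20, n_class2=30, seed=2)
        assert len(truth.class1_genes) == 20 and len(truth.class2_genes) == 30
        assert len(truth.control_genes) == 250
        again = GroundTruth.from_json(truth.to_json())
        assert again.class1_genes == truth.class1_genes
        assert again.specific_genes == truth.specific_genes


class TestExpressionMatrix:
    def test_determinism(self, small_truth):
        sites = [f"v{i}" for i in range(30)]
        a = gen_expression_matrix(20, sites, small_truth, seed=9)
        b = gen_expression_matrix(20, sites, small_truth, seed=9)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_parameter_validation(self, small_truth):
        sites = [f"v{i}" for i in range(10)]
        with pytest.raises(ValueError):
            gen_expression_matrix(20, sites, small_truth, corr_strength=1.0)
        with pytest.raises(ValueError):
            gen_expression_matrix(20, ["a", "b"], small_truth)

    def test_class_signs_against_effect_maps(self, small_truth):
        # Class-2 gene vs GMD effect map: positive Spearman in >=99% of seeds.
        sites = [f"v{i}" for i in range(200)]
        g2 = sorted(small_truth.class2_genes)[0]
        g1 = sorted(small_truth.class1_genes)[0]
        hits_g2 = hits_g1 = 0
        n_seeds = 60
        for seed in range(n_seeds):
            maps = default_effect_maps(200, seed=seed)
            expr = gen_expression_matrix(
                20, sites, small_truth, corr_strength=0.8, seed=seed,
                coupling=latent_pattern(200, seed),
            )
            rho2 = spearman_rho(expr.values.loc[g2], maps[STRUCTURAL_INDEX])
            rho1 = spearman_rho(expr.values.loc[g1], maps["ALFF"])
            hits_g2 += rho2 > 0
            hits_g1 += rho1 > 0
        assert hits_g2 == n_seeds
        assert hits_g1 == n_seeds

    def test_nonplanted_genes_uncorrelated(self, small_truth):
        sites = [f"v{i}" for i in range(50)]
        null_gene = "g10"
        rhos = []
        for seed in range(100):
            maps = default_effect_maps(50, seed=seed)
            expr = gen_expression_matrix(20, sites, small_truth, seed=seed,
                                         coupling=latent_pattern(50, seed))
            rhos.append(spearman_rho(expr.values.loc[null_gene], maps["ALFF"]))
        assert abs(np.mean(rhos)) < 0.05

    def test_strong_coupling_limit(self, small_truth):
        # corr_strength -> 1 with negligible noise: Spearman of a Class-1
        # gene vs the coupling pattern approaches +1.
        sites = [f"v{i}" for i in range(100)]
        b = latent_pattern(100, 0)
        expr = gen_expression_matrix(20, sites, small_truth, corr_strength=0.999,
                                     seed=0, coupling=b)
        g1 = sorted(small_truth.class1_genes)[0]
        assert spearman_rho(expr.values.loc[g1], b) > 0.99


class TestDevExpression:
    def test_label_length_validation(self, small_truth):
        with pytest.raises(ValueError):
            gen_dev_expression(small_truth, periods=("a", "b"))
        with pytest.raises(ValueError):
            gen_dev_expression(small_truth, regions=DEFAULT_REGIONS[:5])

    def test_nonnegative_and_deterministic(self, small_truth):
        a = gen_dev_expression(small_truth, seed=4)
        b = gen_dev_expression(small_truth, seed=4)
        assert (a.expression.to_numpy() >= 0).all()
        pd.testing.assert_frame_equal(a.expression, b.expression)

    def test_both_sexes_in_every_cell(self, small_truth):
        dev = gen_dev_expression(small_truth, n_per_cell=2, seed=0)
        sexes = dev.samples.groupby(["period", "region"], observed=True)["sex"].nunique()
        assert (sexes == 2).all()

    def test_region_specific_gene_elevated_in_target_across_periods(self, small_truth):
        dev = gen_dev_expression(small_truth, seed=1)
        gene, (_, region) = "g00", small_truth.specific_genes["g00"]
        in_region = dev.samples["region"] == region
        by_period = dev.expression[gene].groupby(
            [dev.samples["period"], in_region], observed=True
        ).mean().unstack()
        assert (by_period[True] > by_period[False]).all()

    def test_sex_biased_gene_detection_power(self, small_truth):
        # 1-SD shift, 64 samples per sex: detected at p<0.01 in >=80% of seeds
        detected = 0
        for seed in range(20):
            dev = gen_dev_expression(small_truth, n_per_cell=1, seed=seed)
            rec = sex_de_genes(dev, genes=["g01"], alpha=0.01)
            detected += ("g01" in rec.index and rec.loc["g01", "direction"] == "female_high")
        assert detected >= 16


class TestNetworkGenerator:
    def test_validation(self, small_truth):
        with pytest.raises(ValueError):
            gen_interaction_network(1, 0.1, small_truth)
        with pytest.raises(ValueError):
            gen_interaction_network(10, 0.0, small_truth)

    def test_score_range_and_determinism(self, small_truth):
        a = gen_interaction_network(20, 0.1, small_truth, seed=6)
        b = gen_interaction_network(20, 0.1, small_truth, seed=6)
        pd.testing.assert_frame_equal(a, b)
        assert a["combined_score"].between(0, 1000).all()

    def test_class1_peripheral_in_expectation(self):
        diffs = []
        for seed in range(5):
            truth = make_ground_truth(n_genes=400, n_class1=40, n_class2=40, seed=seed)
            edges = gen_interaction_network(400, 0.05, truth, seed=seed)
            deg = pd.concat([edges["protein_a"], edges["protein_b"]]).value_counts()
            d1 = deg.reindex(sorted(truth.class1_genes)).fillna(0).mean()
            dc = deg.reindex(sorted(truth.control_genes)).fillna(0).mean()
            diffs.append(dc - d1)
        assert np.mean(diffs) > 0


class TestReferenceLists:
    def test_rate_zero_and_one(self, small_truth):
        lists0 = gen_reference_lists(
            small_truth, {"class1": 0.0, "class2": 0.0, "control": 0.0}, seed=0
        )
        assert not lists0["risk"] & (small_truth.class1_genes | small_truth.class2_genes)
        lists1 = gen_reference_lists(
            small_truth, {"class1": 1.0, "class2": 0.0, "control": 0.0}, seed=0
        )
        assert small_truth.class1_genes <= lists1["risk"]

    def test_rate_validation(self, small_truth):
        with pytest.raises(ValueError):
            gen_reference_lists(small_truth, {"class1": 1.5, "class2": 0.1, "control": 0.0})

    def test_configured_rates_recovered(self):
        truth = make_ground_truth(n_genes=2000, seed=3)
        lists = gen_reference_lists(truth, {"class1": 0.2, "class2": 0.1, "control": 0.05},
                                    seed=3)
        risk = lists["risk"]
        r1 = len(risk & truth.class1_genes) / len(truth.class1_genes)
        r2 = len(risk & truth.class2_genes) / len(truth.class2_genes)
        rc = len(risk & truth.control_genes) / len(truth.control_genes)
        assert abs(r1 - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 150)
        assert abs(r2 - 0.1) < 3 * np.sqrt(0.1 * 0.9 / 200)
        assert abs(rc - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1650)
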