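"""Spearman association, permutation p-values, selection and classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from braintx.association import (
    AssociationRecord,
    classify_directional,
    class_counts,
    identify_depression_genes,
    permutation_pvalue,
    spearman_rho,
)
from braintx.types import DifferenceMap, ExpressionMatrix, INDICES


def _brute_rank(v):
    """Average ranks, computed by direct definition."""
    v = np.asarray(v, float)
    ranks = np.empty(len(v))
    for i, x in enumerate(v):
        less = np.sum(v < x)
        equal = np.sum(v == x)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [30, 20, 10]) == pytest.approx(-1.0)

    def test_ties_equal_pearson_of_average_ranks(self):
        x, y = [1, 2, 2, 3], [1, 2, 3, 4]
        rx, ry = _brute_rank(x), _brute_rank(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(expected)

    def test_constant_vector_flagged_missing(self):
        assert np.isnan(spearman_rho([1.0, 1.0, 1.0], [1, 2, 3]))

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [3, 4])


class TestPermutationPvalue:
    def test_monotone_pair_attains_minimum(self):
        x = np.arange(200.0)
        rec = permutation_pvalue(x, x, n_perm=10_000, seed=0)
        assert rec.rho == pytest.approx(1.0)
        assert rec.p_perm == pytest.approx(1.0 / 10_001)

    def test_brute_force_count_of_rho_preserving_permutations(self):
        # On 6 distinct sites only the identity and the full reversal give
        # |rho| = 1; exhaustive enumeration over all 720 permutations.
        x = np.arange(6.0)
        count = sum(
            1
            for perm in itertools.permutations(range(6))
            if abs(spearman_rho(x, x[list(perm)])) >= 1.0 - 1e-12
        )
        assert count == 2

    def test_single_permutation_attainable_values(self):
        rng = np.random.default_rng(5)
        for seed in range(20):
            rec = permutation_pvalue(rng.normal(size=9), rng.normal(size=9), n_perm=1, seed=seed)
            assert rec.p_perm in (0.5, 1.0)

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        a = permutation_pvalue(x, y, n_perm=500, seed=3)
        b = permutation_pvalue(np.exp(x), y, n_perm=500, seed=3)
        assert a.p_perm == b.p_perm and a.rho == pytest.approx(b.rho)

    def test_null_pvalues_roughly_uniform(self, rng):
        ps = [
            permutation_pvalue(rng.normal(size=40), rng.normal(size=40), n_perm=199, seed=s).p_perm
            for s in range(200)
        ]
        ps = np.asarray(ps)
        assert abs(ps.mean() - 0.5) < 0.08
        assert abs((ps < 0.2).mean() - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 200)

    def test_record_invariant(self):
        with pytest.raises(ValueError):
            AssociationRecord("g", "ALFF", rho=0.5, p_perm=1e-9, n_perm=100)


def _maps_from_vectors(vectors):
    maps = {}
    for name, t in vectors.items():
        n = len(t)
        table = pd.DataFrame(
            {"t": t, "p": np.full(n, 0.5), "p_adj": np.full(n, 0.5),
             "significant": np.zeros(n, bool)},
            index=[f"v{i}" for i in range(n)],
        )
        maps[name] = DifferenceMap(index_name=name, table=table)
    return maps


class TestIdentifyAndClassify:
    def _setup(self, rng, n=60):
        base = rng.normal(size=n)
        maps = _maps_from_vectors(
            {
                "ALFF": base + 0.05 * rng.normal(size=n),
                "fALFF": rng.normal(size=n),
                "ReHo": base + 0.05 * rng.normal(size=n),
                "GMD": -base + 0.05 * rng.normal(size=n),
            }
        )
        sites = [f"v{i}" for i in range(n)]
        expr = pd.DataFrame(
            {
                "gmd_only": -base + 0.6 * rng.normal(size=n),
                "reho_and_gmd": base + 0.1 * rng.normal(size=n),
                "null_gene": rng.normal(size=n),
            },
            index=sites,
        ).T
        return ExpressionMatrix(values=pd.DataFrame(expr, columns=sites)), maps, base

    def test_and_rule_requires_gmd_plus_one_functional(self, rng):
        expr, maps, _ = self._setup(rng)
        records, selected = identify_depression_genes(
            expr, maps, alpha=0.01, n_perm=999, seed=0
        )
        assert "reho_and_gmd" in selected
        assert "null_gene" not in selected
        # gmd_only correlates with GMD but with no functional index at alpha
        assert records.loc["gmd_only", "p_GMD"] < 0.01

    def test_site_misalignment_reported(self, rng):
        expr, maps, _ = self._setup(rng)
        bad = expr.values.copy()
        bad.columns = [f"w{i}" for i in range(bad.shape[1])]
        with pytest.raises(ValueError, match="site mismatch"):
            identify_depression_genes(ExpressionMatrix(values=bad), maps, n_perm=10)

    @staticmethod
    def _records(rows):
        cols = {}
        for name in INDICES:
            cols[f"rho_{name}"] = [r[0][name] for r in rows.values()]
            cols[f"p_{name}"] = [r[1][name] for r in rows.values()]
        return pd.DataFrame(cols, index=list(rows))

    def test_class1_sign_pattern(self):
        records = self._records(
            {"g1": ({"ALFF": 0.5, "fALFF": 0.4, "ReHo": 0.6, "GMD": -0.5},
                    {"ALFF": 1e-4, "fALFF": 1e-4, "ReHo": 1e-4, "GMD": 1e-4})}
        )
        out = classify_directional(records, ["g1"], alpha=0.001)
        assert out.loc["g1", "class"] == "Class1"

    def test_mixed_significant_signs_unclassified(self):
        records = self._records(
            {"g1": ({"ALFF": -0.5, "fALFF": 0.1, "ReHo": 0.6, "GMD": -0.5},
                    {"ALFF": 1e-4, "fALFF": 0.5, "ReHo": 1e-4, "GMD": 1e-4})}
        )
        out = classify_directional(records, ["g1"], alpha=0.001)
        assert out.loc["g1", "class"] == "unclassified"

    def test_insignificant_functional_sign_ignored(self):
        # negative but non-significant ALFF does not block Class1
        records = self._records(
            {"g1": ({"ALFF": -0.1, "fALFF": 0.2, "ReHo": 0.6, "GMD": -0.5},
                    {"ALFF": 0.8, "fALFF": 0.3, "ReHo": 1e-4, "GMD": 1e-4})}
        )
        out = classify_directional(records, ["g1"], alpha=0.001)
        assert out.loc["g1", "class"] == "Class1"

    def test_class2_is_mirror_image_and_partition(self):
        records = self._records(
            {
                "a": ({"ALFF": -0.5, "fALFF": -0.4, "ReHo": -0.6, "GMD": 0.5},
                      {"ALFF": 1e-4, "fALFF": 1e-4, "ReHo": 1e-4, "GMD": 1e-4}),
                "b": ({"ALFF": 0.5, "fALFF": 0.4, "ReHo": 0.6, "GMD": -0.5},
                      {"ALFF": 1e-4, "fALFF": 1e-4, "ReHo": 1e-4, "GMD": 1e-4}),
                "c": ({"ALFF": 0.0, "fALFF": 0.0, "ReHo": 0.0, "GMD": 0.0},
                      {"ALFF": 0.9, "fALFF": 0.9, "ReHo": 0.9, "GMD": 0.9}),
            }
        )
        out = classify_directional(records, ["a", "b"], alpha=0.001)
        assert out.loc["a", "class"] == "Class2"
        assert out.loc["b", "class"] == "Class1"
        assert out.loc["c", "class"] == "control"
        counts = class_counts(out)
        assert counts["depression_related"] == 2

    def test_missing_record_errors(self):
        records = self._records(
            {"g1": ({"ALFF": 0.5, "fALFF": 0.4, "ReHo": 0.6, "GMD": -0.5},
                    {"ALFF": 1e-4, "fALFF": 1e-4, "ReHo": 1e-4, "GMD": 1e-4})}
        )
        with pytest.raises(ValueError):
            classify_directional(records, ["ghost"])
        with pytest.raises(ValueError):
            classify_directional(records.drop(columns=["rho_GMD"]), ["g1"])
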