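"""Aging screen: Pearson inference, calling rules, signatures, intersections."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import agingscreen as ag
from agingscreen import SimulationConfig
from agingscreen.errors import ConfigError, DegenerateDataError
from agingscreen.screen import called_genes, linkage_to_newick

from conftest import make_call_table


class TestPearsonWithP:
    def test_perfect_linearity(self):
        r, p, n = ag.pearson_with_p([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)
        assert n == 3

    def test_perfect_anti_linearity(self):
        r, p, n = ag.pearson_with_p([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_constant_vector_raises_not_silent_zero(self):
        with pytest.raises(DegenerateDataError, match="constant"):
            ag.pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_pairs(self):
        with pytest.raises(DegenerateDataError):
            ag.pearson_with_p([1, 2], [3, 4])

    def test_nan_pairs_removed_pairwise(self):
        r_full, p_full, _ = ag.pearson_with_p([1, 2, 3, 4], [1, 3, 2, 5])
        r, p, n = ag.pearson_with_p([1, 2, 3, 4, np.nan],
                                    [1, 3, 2, 5, 100.0])
        assert n == 4
        assert r == pytest.approx(r_full)
        assert p == pytest.approx(p_full)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_negating_y_negates_r_preserves_p(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        r1, p1, _ = ag.pearson_with_p(x, y)
        r2, p2, _ = ag.pearson_with_p(x, -y)
        assert r2 == pytest.approx(-r1)
        assert p2 == pytest.approx(p1)

    def test_agrees_with_permutation_null(self, rng):
        """The two-sided t-transform p is calibrated against the empirical
        permutation distribution (aggregate over vectors; per-vector
        agreement is limited by conditioning at n=8)."""
        B = 5000
        diffs = []
        for _ in range(30):
            x = rng.standard_normal(8)
            y = rng.standard_normal(8)
            r, p, _ = ag.pearson_with_p(x, y)
            xc = x - x.mean()
            xc /= np.linalg.norm(xc)
            perms = rng.permuted(np.tile(y, (B, 1)), axis=1)
            pc = perms - perms.mean(axis=1, keepdims=True)
            pc /= np.linalg.norm(pc, axis=1, keepdims=True)
            p_perm = np.mean(np.abs(pc @ xc) >= abs(r) - 1e-12)
            diffs.append(p - p_perm)
        diffs = np.asarray(diffs)
        sem = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * sem + 1e-3


class TestScreenTissue:
    def test_noise_free_down_gene_called(self):
        cfg = SimulationConfig(n_genes=5, n_samples_per_tissue=150,
                               tissues={"hippocampus": "i"}, frac_down=0.2,
                               frac_up=0.0, slope_down=-0.05, noise_sd=1e-9,
                               seed=2)
        matrices, samples, truth = ag.simulate_aging_cohort(cfg)
        table = ag.screen_tissue(matrices["hippocampus"], samples)
        down = truth.planted_genes("i", "down")
        assert set(table.loc[down, "call"]) == {"down"}

    def test_call_thresholds_respected(self, planted_cohort):
        expr, samples, _ = planted_cohort
        table = ag.screen_tissue(expr, samples)
        up = table[table["call"] == "up"]
        down = table[table["call"] == "down"]
        assert ((up["r"] > 0) & (up["p"] < 0.05)).all()
        assert ((down["r"] < 0) & (down["p"] < 0.01)).all()

    def test_lowering_alpha_down_shrinks_down_set(self, planted_cohort):
        expr, samples, _ = planted_cohort
        loose = ag.screen_tissue(expr, samples, alpha_down=0.01)
        strict = ag.screen_tissue(expr, samples, alpha_down=0.001)
        assert called_genes(strict, "down") <= called_genes(loose, "down")

    def test_constant_gene_skipped_with_count(self, small_expr):
        meta = pd.DataFrame({"sample_id": ["s1", "s2", "s3", "s4"],
                             "age": [41.0, 48.0, 55.0, 62.0]})
        table = ag.screen_tissue(small_expr, meta, age_window=None,
                                 min_samples=3)
        assert "GC" not in table.index  # constant gene
        assert table.attrs["n_skipped"] == 1

    def test_age_window_restricts_donors(self, small_expr):
        meta = pd.DataFrame({"sample_id": ["s1", "s2", "s3", "s4"],
                             "age": [30.0, 48.0, 55.0, 62.0]})
        table = ag.screen_tissue(small_expr, meta, age_window=(40, 69),
                                 min_samples=3)
        assert (table["n"] == 3).all()

    def test_too_few_samples_is_tissue_level_error(self, small_expr):
        meta = pd.DataFrame({"sample_id": ["s1"], "age": [50.0]})
        with pytest.raises(DegenerateDataError):
            ag.screen_tissue(small_expr, meta)

    def test_matches_scalar_pearson(self, planted_cohort):
        """Vectorized screen r/p equal the scalar Pearson path."""
        expr, samples, _ = planted_cohort
        table = ag.screen_tissue(expr, samples)
        ages = samples.set_index("sample_id").loc[expr.sample_ids, "age"]
        for gene in table.index[:5]:
            r, p, n = ag.pearson_with_p(expr.values.loc[gene], ages)
            assert table.loc[gene, "r"] == pytest.approx(r, abs=1e-12)
            assert table.loc[gene, "p"] == pytest.approx(p, rel=1e-9)


class TestTissueSimilarity:
    def _tables(self, r_vec, genes):
        return make_call_table(genes, r_vec, 0.5, "none")

    def test_identical_signatures_correlate_at_one(self, rng):
        genes = [f"G{i}" for i in range(150)]
        r = rng.uniform(-0.5, 0.5, 150)
        tables = {"a": self._tables(r, genes), "b": self._tables(r, genes)}
        sim = ag.tissue_signature_similarity(tables, n_groups=1)
        assert sim.similarity.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(np.diag(sim.similarity), 1.0)

    def test_negated_signature_correlates_at_minus_one(self, rng):
        genes = [f"G{i}" for i in range(150)]
        r = rng.uniform(-0.5, 0.5, 150)
        tables = {"a": self._tables(r, genes), "b": self._tables(-r, genes)}
        sim = ag.tissue_signature_similarity(tables, n_groups=2)
        assert sim.similarity.loc["a", "b"] == pytest.approx(-1.0)

    def test_small_common_gene_set_rejected(self, rng):
        genes = [f"G{i}" for i in range(50)]
        r = rng.uniform(-0.5, 0.5, 50)
        tables = {"a": self._tables(r, genes), "b": self._tables(r, genes)}
        with pytest.raises(DegenerateDataError, match="shared"):
            ag.tissue_signature_similarity(tables, n_groups=1)

    def test_fixed_grouping_overrides_clustering(self, rng):
        genes = [f"G{i}" for i in range(120)]
        tables = {t: self._tables(rng.uniform(-0.5, 0.5, 120), genes)
                  for t in ("a", "b", "c")}
        sim = ag.tissue_signature_similarity(
            tables, fixed_groups={"a": "x", "b": "x", "c": "y"})
        assert sim.group_members() == {"x": ["a", "b"], "y": ["c"]}

    def test_newick_export_contains_all_tissues(self, rng):
        genes = [f"G{i}" for i in range(120)]
        tables = {t: self._tables(rng.uniform(-0.5, 0.5, 120), genes)
                  for t in ("a", "b", "c", "d")}
        sim = ag.tissue_signature_similarity(tables, n_groups=2)
        nwk = linkage_to_newick(sim.linkage, list(sim.similarity.index))
        assert nwk.endswith(";")
        for t in "abcd":
            assert t in nwk


class TestGroupIntersection:
    def _table_from_calls(self, genes, down):
        call = ["down" if g in down else "none" for g in genes]
        r = [-0.5 if g in down else 0.0 for g in genes]
        p = [0.001 if g in down else 0.9 for g in genes]
        return make_call_table(genes, r, p, call)

    def test_identical_sets_intersect_to_themselves(self):
        genes = [f"G{i}" for i in range(20)]
        S = {"G1", "G5", "G9"}
        tables = {t: self._table_from_calls(genes, S) for t in ("a", "b", "c")}
        gi = ag.group_intersection(tables, ["a", "b", "c"], "down")
        assert gi.genes == frozenset(S)
        assert gi.venn_counts[("a", "b", "c")] == 3

    def test_disjoint_sets_give_empty_intersection(self):
        genes = [f"G{i}" for i in range(9)]
        tables = {
            "a": self._table_from_calls(genes, {"G0", "G1"}),
            "b": self._table_from_calls(genes, {"G2", "G3"}),
            "c": self._table_from_calls(genes, {"G4"}),
        }
        gi = ag.group_intersection(tables, ["a", "b", "c"], "down")
        assert gi.genes == frozenset()

    def test_venn_counts_match_set_algebra(self, rng):
        """Exhaustive set-algebra oracle: for every region, the count of
        genes in exactly that subset of tissues."""
        genes = [f"G{i}" for i in range(60)]
        tissues = ["a", "b", "c"]
        sets = {t: set(rng.choice(genes, size=25, replace=False))
                for t in tissues}
        tables = {t: self._table_from_calls(genes, sets[t]) for t in tissues}
        gi = ag.group_intersection(tables, tissues, "down")
        import itertools
        for k in range(1, 4):
            for combo in itertools.combinations(tissues, k):
                inside = set.intersection(*(sets[t] for t in combo))
                outside = set.union(*(sets[t] for t in tissues
                                      if t not in combo), set())
                expected = len(inside - outside)
                assert gi.venn_counts[combo] == expected
        assert gi.genes == frozenset(set.intersection(*sets.values()))

    def test_order_independent(self, rng):
        genes = [f"G{i}" for i in range(30)]
        sets = {t: set(rng.choice(genes, size=12, replace=False))
                for t in ("a", "b")}
        tables = {t: self._table_from_calls(genes, sets[t]) for t in sets}
        g1 = ag.group_intersection(tables, ["a", "b"], "down")
        g2 = ag.group_intersection(tables, ["b", "a"], "down")
        assert g1.genes == g2.genes

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigError, match="empty"):
            ag.group_intersection({}, [], "down")


class TestCrossValidate:
    def _table(self, genes, down_genes):
        call = ["down" if g in down_genes else "none" for g in genes]
        return make_call_table(genes,
                               [-0.4 if g in down_genes else 0.0 for g in genes],
                               [0.001 if g in down_genes else 0.8 for g in genes],
                               call)

    def test_gene_down_everywhere_is_validated(self):
        genes = ["G1", "G2"]
        disc = {t: self._table(genes, {"G1"}) for t in ("a", "b", "c")}
        val = [self._table(genes, {"G1"}), self._table(genes, set())]
        assert ag.cross_validate(disc, val, k_min=3, direction="down") == {"G1"}

    def test_gene_missing_from_validation_excluded(self):
        genes = ["G1"]
        disc = {t: self._table(genes, {"G1"}) for t in ("a", "b", "c")}
        val = [self._table(genes, set())]
        assert ag.cross_validate(disc, val, k_min=3, direction="down") == frozenset()

    def test_k_min_exceeding_tissue_count_rejected(self):
        genes = ["G1"]
        disc = {"a": self._table(genes, {"G1"})}
        with pytest.raises(ConfigError):
            ag.cross_validate(disc, [self._table(genes, {"G1"})], k_min=2,
                              direction="down")

    def test_planted_recovery_with_shared_truth(self):
        cfg = SimulationConfig(
            n_genes=1000, n_samples_per_tissue=150,
            tissues={"a": "i", "b": "i", "c": "i"},
            frac_down=0.1, frac_up=0.0, slope_down=-0.06, noise_sd=1.0,
            seed=21,
        )
        matrices, samples, truth = ag.simulate_aging_cohort(cfg)
        disc = {t: ag.screen_tissue(matrices[t],
                                    samples[samples["tissue"] == t])
                for t in matrices}
        vexpr, vsamples = ag.simulate_validation_cohort(truth, group="i",
                                                        n_samples=150, seed=22)
        val = [ag.screen_tissue(vexpr, vsamples, log_age=True, age_window=None)]
        validated = ag.cross_validate(disc, val, k_min=3, direction="down")
        planted = set(truth.planted_genes("i", "down"))
        assert len(validated & planted) / len(planted) >= 0.9
        false_in = validated - planted
        nulls = set(truth.aging["gene"]) - planted
        assert len(false_in) / len(nulls) < 0.05
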