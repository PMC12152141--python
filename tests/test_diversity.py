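"""Diversity statistics against closed forms, brute-force oracles, and an
independent PERMANOVA implementation."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from ecoassembly.containers import DistanceMatrix, FeatureTable
from ecoassembly.diversity import (
    OrdinationResult,
    bray_curtis,
    pairwise_permanova,
    parametric_ok,
    pcoa,
    permanova,
    procrustes_test,
    rarefy,
    richness,
    shannon,
    within_group_turnover,
)
from conftest import random_table


class TestRarefy:
    def test_sample_at_depth_returned_unchanged(self):
        t = FeatureTable(counts=[[3, 7], [50, 50]], sample_ids=["a", "b"], taxon_ids=["x", "y"])
        out = rarefy(t, 10, seed=0)
        assert out.counts[0].tolist() == [3, 7]
        assert out.counts[1].sum() == 10

    def test_all_samples_below_depth_yields_empty_with_warning(self):
        t = FeatureTable(counts=[[1, 1], [2, 0]], sample_ids=["a", "b"], taxon_ids=["x", "y"])
        with pytest.warns(UserWarning, match="dropped 2"):
            out = rarefy(t, 100, seed=0)
        assert out.n_samples == 0

    def test_totals_exactly_depth(self, rng):
        t = random_table(rng, 6, 20, max_count=60)
        out = rarefy(t, 50, seed=1)
        assert (out.sample_totals() == 50).all()

    def test_hypergeometric_expectation(self):
        # counts [10, 10] subsampled to 10: taxon 1 expectation is 5
        t = FeatureTable(counts=[[10, 10]], sample_ids=["s"], taxon_ids=["a", "b"])
        draws = [rarefy(t, 10, seed=s).counts[0, 0] for s in range(2000)]
        # sd of the mean of 2000 hypergeometric(20,10,10) draws ~ 0.036
        assert np.mean(draws) == pytest.approx(5.0, abs=0.15)


class TestAlphaDiversity:
    def test_richness_counts_positive_taxa(self):
        t = FeatureTable(counts=[[5, 0, 2], [0, 0, 0]], sample_ids=["a", "b"],
                         taxon_ids=["x", "y", "z"])
        assert richness(t).tolist() == [2, 0]

    def test_shannon_uniform_and_single(self):
        t = FeatureTable(counts=[[5, 5, 5, 5], [9, 0, 0, 0]],
                         sample_ids=["a", "b"], taxon_ids=list("wxyz"))
        h = shannon(t)
        assert h["a"] == pytest.approx(np.log(4), abs=1e-12)
        assert h["b"] == pytest.approx(0.0, abs=1e-12)

    def test_shannon_base_two(self):
        t = FeatureTable(counts=[[1, 1]], sample_ids=["a"], taxon_ids=["x", "y"])
        assert shannon(t, base=2)["a"] == pytest.approx(1.0)

    def test_shannon_all_zero_sample_rejected(self):
        t = FeatureTable(counts=[[0, 0]], sample_ids=["a"], taxon_ids=["x", "y"])
        with pytest.raises(ValueError, match="all-zero"):
            shannon(t)

    def test_brute_force_oracle_on_random_fixtures(self, rng):
        for _ in range(100):
            t = random_table(rng, 3, rng.integers(2, 50))
            h = shannon(t)
            s = richness(t)
            for i in range(3):
                row = t.counts[i]
                assert s.iloc[i] == sum(1 for c in row if c > 0)
                p = row[row > 0] / row.sum()
                assert h.iloc[i] == pytest.approx(-sum(x * np.log(x) for x in p), abs=1e-12)


class TestBrayCurtis:
    def test_identical_disjoint_and_worked_example(self):
        t = FeatureTable(
            counts=[[6, 4, 0], [6, 4, 0], [0, 4, 6], [0, 0, 9]],
            sample_ids=list("abcd"), taxon_ids=["x", "y", "z"],
        )
        bc = bray_curtis(t)
        assert bc["a", "b"] == pytest.approx(0.0)
        assert bc["a", "c"] == pytest.approx(0.6)  # 1 - 2*4/20
        assert bc["a", "d"] == pytest.approx(1.0)

    def test_range_and_symmetry(self, rng):
        for _ in range(25):
            t = random_table(rng, 5, 12)
            bc = bray_curtis(t).values
            assert (bc >= 0).all() and (bc <= 1 + 1e-12).all()
            assert np.allclose(bc, bc.T)
            assert np.allclose(np.diag(bc), 0)

    def test_zero_total_sample_rejected(self):
        t = FeatureTable(counts=[[1, 1], [0, 0]], sample_ids=["a", "b"], taxon_ids=["x", "y"])
        with pytest.raises(ValueError, match="zero total"):
            bray_curtis(t)


class TestPcoa:
    def test_three_equidistant_points(self):
        dm = DistanceMatrix(list("abc"), 1 - np.eye(3))
        res = pcoa(dm)
        pos = res.eigenvalues[res.eigenvalues > 1e-9]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])
        rec = squareform(pdist(res.coordinates))
        assert np.allclose(rec, dm.values, atol=1e-8)

    def test_line_reconstruction(self):
        pts = np.array([[0.0], [1.0], [3.0], [7.0]])
        dm = DistanceMatrix(list("abcd"), squareform(pdist(pts)))
        res = pcoa(dm)
        assert (res.eigenvalues > 1e-9).sum() == 1
        assert np.allclose(squareform(pdist(res.coordinates)), dm.values, atol=1e-8)

    def test_duplicated_sample_collocates(self):
        pts = np.array([[0, 0], [1, 2], [1, 2], [4, 1]], dtype=float)
        dm = DistanceMatrix(list("abcd"), squareform(pdist(pts)))
        res = pcoa(dm)
        assert np.allclose(res.coordinates[1], res.coordinates[2], atol=1e-8)

    def test_proportion_explained_over_positive_axes(self, rng):
        t = random_table(rng, 8, 20)
        res = pcoa(bray_curtis(t))
        pos = res.proportion_explained[res.eigenvalues > 0]
        assert pos.sum() == pytest.approx(1.0)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_matches_skbio(self, rng):
        import skbio.stats.ordination

        t = random_table(rng, 7, 15)
        dm = bray_curtis(t)
        ours = pcoa(dm)
        theirs = skbio.stats.ordination.pcoa(dm.to_skbio())
        k = (ours.eigenvalues > 1e-9).sum()
        assert np.allclose(
            np.abs(ours.coordinates[:, :k]),
            np.abs(theirs.samples.to_numpy()[:, :k]),
            atol=1e-6,
        )


class TestPermanova:
    def test_perfect_separation_hits_p_floor(self):
        # duplicated identical samples per group, far apart between groups:
        # only label permutations reproducing the exact partition tie the
        # observed F, which is vanishingly rare with 8 samples per group
        n = 16
        vals = np.zeros((n, n))
        vals[:8, 8:] = vals[8:, :8] = 10.0
        dm = DistanceMatrix([f"s{i}" for i in range(n)], vals)
        res = permanova(dm, ["a"] * 8 + ["b"] * 8, n_permutations=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)
        assert res.effect_size > 0.9

    def test_r_squared_in_unit_interval(self, rng):
        for _ in range(10):
            t = random_table(rng, 9, 15)
            dm = bray_curtis(t)
            res = permanova(dm, ["a", "b", "c"] * 3, n_permutations=49, seed=1)
            assert 0.0 <= res.effect_size <= 1.0

    def test_statistic_matches_skbio(self, rng):
        import skbio.stats.distance

        t = random_table(rng, 10, 20)
        dm = bray_curtis(t)
        groups = ["a"] * 5 + ["b"] * 5
        ours = permanova(dm, groups, n_permutations=9, seed=0)
        theirs = skbio.stats.distance.permanova(dm.to_skbio(), groups, permutations=9)
        assert ours.statistic == pytest.approx(theirs["test statistic"], abs=1e-8)

    def test_undersized_group_rejected(self):
        dm = DistanceMatrix(list("abc"), 1 - np.eye(3))
        with pytest.raises(ValueError, match=">= 2 samples"):
            permanova(dm, ["x", "x", "y"], n_permutations=9, seed=0)


class TestPairwisePermanova:
    def test_two_groups_match_single_test(self, rng):
        t = random_table(rng, 8, 12)
        dm = bray_curtis(t)
        groups = ["a"] * 4 + ["b"] * 4
        single = permanova(dm, groups, n_permutations=99, seed=7)
        pair = pairwise_permanova(dm, groups, n_permutations=99, seed=7)
        assert len(pair) == 1
        assert pair[0].statistic == pytest.approx(single.statistic)
        assert pair[0].extra["p_adjusted"] == pytest.approx(pair[0].p_value)

    def test_bh_adjustment_never_decreases_p(self, rng):
        t = random_table(rng, 12, 15)
        dm = bray_curtis(t)
        groups = ["a", "b", "c"] * 4
        results = pairwise_permanova(dm, groups, n_permutations=49, seed=3)
        assert len(results) == 3
        for r in results:
            assert r.extra["p_adjusted"] >= r.p_value - 1e-12


class TestTurnover:
    def test_no_variation_flagged(self):
        dm = DistanceMatrix(list("abcd"), 0.4 * (1 - np.eye(4)))
        res = within_group_turnover(dm, ["g1", "g1", "g2", "g2"])
        assert res.anova_p == 1.0
        assert "no variation" in res.note

    def test_shifted_group_detected(self, rng):
        # one group's within distances uniformly higher -> Tukey flags it
        hits = 0
        for rep in range(10):
            r = np.random.default_rng(rep)
            n = 20
            base = r.uniform(0.2, 0.4, size=(n, n))
            vals = (base + base.T) / 2
            np.fill_diagonal(vals, 0)
            vals[:10, :10] += 0.3  # group A internally more dissimilar
            np.fill_diagonal(vals, 0)
            dm = DistanceMatrix([f"s{i}" for i in range(n)], vals)
            res = within_group_turnover(dm, ["A"] * 10 + ["B"] * 10)
            row = res.tukey.iloc[0]
            hits += (row["difference"] > 0) and (row["p_value"] < 0.05)
        assert hits >= 9

    def test_homogenizing_regime_has_lower_turnover_than_dispersal_limited(self):
        from ecoassembly.synthetic import RegimeSpec, simulate_metacommunity

        means = {}
        for regime in ("homogenizing_dispersal", "dispersal_limitation"):
            spec = RegimeSpec(regime=regime, n_taxa=80, depth=400,
                              n_samples_per_group=3, seed=21)
            table, _, _, _ = simulate_metacommunity(spec)
            means[regime] = bray_curtis(table).condensed().mean()
        assert means["homogenizing_dispersal"] < means["dispersal_limitation"]

    def test_centroid_method_runs(self, rng):
        t = random_table(rng, 10, 15)
        res = within_group_turnover(bray_curtis(t), ["a"] * 5 + ["b"] * 5,
                                    method="centroid")
        assert set(res.per_group) == {"a", "b"}
        assert all(len(v) == 5 for v in res.per_group.values())


class TestParametricSwitch:
    def test_normal_homoscedastic_passes(self, rng):
        groups = [rng.normal(0, 1, 30) for _ in range(3)]
        assert parametric_ok(groups)

    def test_heavy_tails_fail(self, rng):
        groups = [rng.standard_cauchy(60) for _ in range(3)]
        assert not parametric_ok(groups)


class TestProcrustes:
    def _ordination(self, coords):
        n, k = coords.shape
        return OrdinationResult([f"s{i}" for i in range(n)], coords,
                                np.ones(k), np.ones(k) / k)

    def test_identity_gives_correlation_one(self, rng):
        x = rng.standard_normal((10, 3))
        res = procrustes_test(self._ordination(x), self._ordination(x.copy()),
                              n_permutations=49, seed=0)
        assert res.statistic == pytest.approx(1.0, abs=1e-10)
        assert res.extra["m2"] == pytest.approx(0.0, abs=1e-10)

    def test_rotation_and_scaling_invariance(self, rng):
        x = rng.standard_normal((12, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        y = 3.5 * x @ rot + 2.0
        res = procrustes_test(self._ordination(x), self._ordination(y),
                              n_permutations=49, seed=0)
        assert res.extra["m2"] == pytest.approx(0.0, abs=1e-10)

    def test_column_padding_handles_unequal_dimensionality(self, rng):
        x = rng.standard_normal((10, 4))
        y = rng.standard_normal((10, 2))
        res = procrustes_test(self._ordination(x), self._ordination(y),
                              n_permutations=19, seed=1)
        assert 0.0 <= res.statistic <= 1.0

    def test_mismatched_samples_rejected(self, rng):
        a = self._ordination(rng.standard_normal((5, 2)))
        b = OrdinationResult([f"x{i}" for i in range(5)],
                             rng.standard_normal((5, 2)), np.ones(2), np.ones(2) / 2)
        with pytest.raises(ValueError, match="different sample sets"):
            procrustes_test(a, b, n_permutations=9, seed=0)
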