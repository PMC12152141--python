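"""Null models of community assembly: brute-force oracles, forced
degeneracies, equivariance, and the five-way classification rules."""

from itertools import combinations

import numpy as np
import pytest
import skbio

from ecoassembly.containers import FeatureTable, SampleMetadata
from ecoassembly.assembly import (
    AssemblyProfile,
    NullModelConfig,
    assembly_profile,
    bmntd,
    bnti,
    classify_pair,
    modal_process,
    raup_crick_bray,
    rc_score,
)
from ecoassembly.synthetic import simulate_tree
from conftest import random_table


def brute_force_bmntd(table, tree, abundance_weighted):
    """Independent double-loop implementation over patristic distances."""
    tipd = tree.tip_tip_distances()
    n = table.n_samples
    out = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        taxa_i = [t for t, c in zip(table.taxon_ids, table.counts[i]) if c > 0]
        taxa_j = [t for t, c in zip(table.taxon_ids, table.counts[j]) if c > 0]

        def one_way(src_taxa, src_counts, dst_taxa):
            total = 0.0
            csum = sum(src_counts[table.taxon_ids.index(t)] for t in src_taxa)
            for t in src_taxa:
                w = (
                    src_counts[table.taxon_ids.index(t)] / csum
                    if abundance_weighted
                    else 1.0 / len(src_taxa)
                )
                total += w * min(tipd[t, u] for u in dst_taxa)
            return total

        v = 0.5 * (one_way(taxa_i, table.counts[i], taxa_j)
                   + one_way(taxa_j, table.counts[j], taxa_i))
        out[i, j] = out[j, i] = v
    return out


class TestBmntd:
    def test_identical_samples_have_zero_turnover(self, small_tree):
        taxa = [t.name for t in small_tree.tips()]
        counts = np.tile([3, 0, 5, 0, 1, 0, 2, 0, 0, 4, 0, 1], (2, 1))
        table = FeatureTable(counts=counts, sample_ids=["a", "b"], taxon_ids=taxa)
        assert bmntd(table, small_tree)["a", "b"] == pytest.approx(0.0)

    def test_two_singleton_samples_equal_patristic_distance(self):
        tree = skbio.TreeNode.read(["(A:1,B:1);"])
        table = FeatureTable(counts=[[4, 0], [0, 9]], sample_ids=["a", "b"],
                             taxon_ids=["A", "B"])
        assert bmntd(table, tree)["a", "b"] == pytest.approx(2.0)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_brute_force_oracle(self, weighted, rng):
        # 100 random small instances against the independent double loop
        for rep in range(100):
            tree = simulate_tree(int(rng.integers(4, 13)), seed=rep)
            taxa = [t.name for t in tree.tips()]
            table = random_table(rng, int(rng.integers(2, 7)), len(taxa), max_count=8)
            table = FeatureTable(counts=table.counts, sample_ids=table.sample_ids,
                                 taxon_ids=taxa)
            got = bmntd(table, tree, abundance_weighted=weighted).values
            want = brute_force_bmntd(table, tree, weighted)
            assert np.allclose(got, want, atol=1e-12)

    def test_taxa_missing_from_tree_dropped_with_report(self, small_tree, caplog):
        taxa = [t.name for t in small_tree.tips()] + ["ghost"]
        counts = np.ones((2, len(taxa)), dtype=int)
        table = FeatureTable(counts=counts, sample_ids=["a", "b"], taxon_ids=taxa)
        with caplog.at_level("WARNING"):
            bmntd(table, small_tree)
        assert "dropped" in caplog.text

    def test_sample_with_no_tree_taxa_rejected(self, small_tree):
        taxa = [t.name for t in small_tree.tips()] + ["ghost"]
        counts = np.zeros((2, len(taxa)), dtype=int)
        counts[0, 0] = 5
        counts[1, -1] = 5  # only the off-tree taxon
        table = FeatureTable(counts=counts, sample_ids=["a", "b"], taxon_ids=taxa)
        with pytest.raises(ValueError, match="no taxa on the tree"):
            bmntd(table, small_tree)


class TestBnti:
    def test_equivariant_under_joint_taxon_relabeling(self, rng):
        tree = simulate_tree(10, seed=3)
        taxa = [t.name for t in tree.tips()]
        table = random_table(rng, 4, 10, max_count=6)
        table = FeatureTable(counts=table.counts, sample_ids=table.sample_ids,
                             taxon_ids=taxa)
        config = NullModelConfig(n_null=199, seed=11)
        z1 = bnti(table, tree, config).values
        # permute the column order of the table (same taxon -> tip mapping)
        perm = rng.permutation(10)
        table2 = FeatureTable(counts=table.counts[:, perm],
                              sample_ids=table.sample_ids,
                              taxon_ids=[taxa[k] for k in perm])
        z2 = bnti(table2, tree, config).values
        assert np.allclose(z1, z2, equal_nan=True)

    def test_star_tree_degeneracy_flags_all_pairs_undefined(self, rng):
        # equal-length star phylogeny: betaMNTD is shuffle-invariant
        newick = "(" + ",".join(f"t{i}:1" for i in range(8)) + ");"
        tree = skbio.TreeNode.read([newick])
        table = random_table(rng, 3, 8, max_count=5)
        with pytest.warns(UserWarning):
            z = bnti(table, tree, NullModelConfig(n_null=50, seed=1))
        off = z.values[np.triu_indices(3, k=1)]
        assert np.isnan(off).all()

    def test_deterministic_given_seed(self, rng, small_tree):
        taxa = [t.name for t in small_tree.tips()]
        table = random_table(rng, 4, len(taxa), max_count=9)
        table = FeatureTable(counts=table.counts, sample_ids=table.sample_ids,
                             taxon_ids=taxa)
        config = NullModelConfig(n_null=99, seed=5)
        assert np.allclose(
            bnti(table, small_tree, config).values,
            bnti(table, small_tree, config).values,
            equal_nan=True,
        )


class TestRaupCrick:
    def test_rank_score_bounds_and_antisymmetry(self):
        # reversing the comparison direction negates the score exactly
        for n_null in (10, 99, 1000):
            for less in range(0, n_null + 1, max(1, n_null // 7)):
                for equal in range(0, n_null - less + 1, max(1, n_null // 5)):
                    greater = n_null - less - equal
                    s = rc_score(less, equal, n_null)
                    assert -1.0 <= s <= 1.0
                    assert rc_score(greater, equal, n_null) == pytest.approx(-s)

    def test_identical_samples_score_minus_one(self, rng):
        pool = rng.lognormal(0, 1, 40)
        row = rng.multinomial(300, pool / pool.sum())
        table = FeatureTable(counts=np.tile(row, (3, 1)),
                             sample_ids=["a", "b", "c"],
                             taxon_ids=[f"t{j}" for j in range(40)])
        with pytest.warns(UserWarning):  # low n_null for speed
            rc = raup_crick_bray(table, NullModelConfig(n_null=60, seed=2))
        assert rc["a", "b"] == pytest.approx(-1.0)

    def test_disjoint_samples_from_shared_rare_pool_score_plus_one(self):
        # two communities splitting a shared pool of equally rare taxa into
        # disjoint halves: null pairs of richness 6 from 12 taxa almost
        # always overlap, so the observed disjoint pair ranks above them
        rng = np.random.default_rng(0)
        n_taxa = 12
        counts = np.zeros((8, n_taxa), dtype=int)
        for i in range(6):  # background samples keep occupancy near-uniform
            counts[i] = rng.integers(1, 4, n_taxa)
        counts[6, :6] = 5
        counts[7, 6:] = 5
        table = FeatureTable(counts=counts,
                             sample_ids=[f"s{i}" for i in range(8)],
                             taxon_ids=[f"t{j}" for j in range(n_taxa)])
        rc = raup_crick_bray(table, NullModelConfig(n_null=1000, seed=3))
        assert rc["s6", "s7"] > 0.9

    def test_deterministic_given_seed(self, rng):
        table = random_table(rng, 4, 25)
        config = NullModelConfig(n_null=100, seed=9)
        assert np.allclose(
            raup_crick_bray(table, config).values,
            raup_crick_bray(table, config).values,
            equal_nan=True,
        )

    def test_reference_table_must_cover_taxa(self, rng):
        table = random_table(rng, 3, 10)
        ref = random_table(rng, 5, 4)
        with pytest.raises(ValueError, match="lacks taxa"):
            raup_crick_bray(table, NullModelConfig(n_null=100, seed=0), reference=ref)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "bnti_value,rc_value,expected",
        [
            (-3.1, 0.2, "homogeneous_selection"),
            (3.1, 0.2, "heterogeneous_selection"),
            (0.5, 0.99, "dispersal_limitation"),
            (0.5, -0.99, "homogenizing_dispersal"),
            (0.5, 0.2, "undominated"),
            # boundaries fall to the stochastic / undominated side
            (2.0, 0.99, "dispersal_limitation"),
            (-2.0, -0.99, "homogenizing_dispersal"),
            (2.0, 0.95, "undominated"),
            (-2.0, -0.95, "undominated"),
            (float("nan"), 0.2, "undefined"),
            (0.5, float("nan"), "undefined"),
        ],
    )
    def test_decision_rules(self, bnti_value, rc_value, expected):
        assert classify_pair(bnti_value, rc_value) == expected


class TestAssemblyProfile:
    def _matrices(self, z_vals, rc_vals, ids):
        n = len(ids)
        z = np.full((n, n), np.nan)
        rc = np.full((n, n), np.nan)
        k = 0
        for i, j in combinations(range(n), 2):
            z[i, j] = z[j, i] = z_vals[k]
            rc[i, j] = rc[j, i] = rc_vals[k]
            k += 1
        from ecoassembly.containers import DistanceMatrix

        return DistanceMatrix(ids, z), DistanceMatrix(ids, rc)

    def test_counted_fractions(self):
        # 5 samples in one group: 10 pairs, 4 dispersal limitation, 6 undominated
        ids = [f"s{i}" for i in range(5)]
        z_vals = [0.0] * 10
        rc_vals = [0.99] * 4 + [0.0] * 6
        z, rc = self._matrices(z_vals, rc_vals, ids)
        meta = SampleMetadata.from_mapping({s: "g" for s in ids})
        prof = assembly_profile(z, rc, meta, grouping="within")[0]
        assert prof.fractions["dispersal_limitation"] == pytest.approx(0.4)
        assert prof.fractions["undominated"] == pytest.approx(0.6)
        assert prof.n_pairs == 10

    def test_fractions_sum_to_one_and_undefined_excluded(self):
        ids = [f"s{i}" for i in range(4)]
        z_vals = [0.0, np.nan, -3.0, 0.0, 3.0, 0.0]
        rc_vals = [0.0, 0.5, 0.0, -0.99, 0.2, 0.99]
        z, rc = self._matrices(z_vals, rc_vals, ids)
        meta = SampleMetadata.from_mapping({s: "g" for s in ids})
        prof = assembly_profile(z, rc, meta, grouping="within")[0]
        assert sum(prof.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert prof.n_undefined == 1
        assert prof.n_pairs == 5

    def test_profile_invariant_rejects_bad_fractions(self):
        with pytest.raises(ValueError, match="sum"):
            AssemblyProfile(group="g", fractions={"undominated": 0.5}, n_pairs=2)

    def test_grouping_modes(self):
        ids = [f"s{i}" for i in range(4)]
        z_vals = [0.0] * 6
        rc_vals = [0.0] * 6
        z, rc = self._matrices(z_vals, rc_vals, ids)
        meta = SampleMetadata.from_mapping(
            {"s0": "a", "s1": "a", "s2": "b", "s3": "b"}
        )
        within = assembly_profile(z, rc, meta, grouping="within")
        assert sorted(p.group for p in within) == ["a", "b"]
        assert all(p.n_pairs == 1 for p in within)
        involving = assembly_profile(z, rc, meta, grouping="involving")
        assert all(p.n_pairs == 5 for p in involving)  # all pairs touch each group
        everything = assembly_profile(z, rc, meta, grouping="all")
        assert everything[0].n_pairs == 6
        assert modal_process(everything[0]) == "undominated"

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NullModelConfig(n_null=1)
        with pytest.warns(UserWarning, match="noisy"):
            NullModelConfig(n_null=50)
        with pytest.raises(ValueError):
            NullModelConfig(bnti_threshold=-1)
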