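import numpy as np
import pytest

from kappaclust.annotation_io import AnnotationMatrix
from kappaclust.clustering import (
    ClusteringParams,
    cluster,
    find_seeds,
    merge_seeds,
    subcluster,
)
from kappaclust.kappa import KappaMatrix, kappa_matrix
from kappaclust.simulate import FixtureSpec, generate, nested_block_matrix, two_block_spec


def kmat_from(scores, genes):
    s = np.array(scores, dtype=float)
    np.fill_diagonal(s, 1.0)
    return KappaMatrix(tuple(genes), s)


class TestParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"kappa_threshold": 1.5},
            {"kappa_threshold": -0.1},
            {"membership_fraction": 0.0},
            {"linkage_fraction": 1.2},
            {"initial_group_membership": 1},
            {"final_group_membership": 0},
            {"linkage_denominator": "median"},
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            ClusteringParams(**kw)

    def test_with_kappa_keeps_other_fields(self):
        p = ClusteringParams(membership_fraction=0.7)
        q = p.with_kappa(0.6)
        assert q.kappa_threshold == 0.6 and q.membership_fraction == 0.7


class TestFindSeeds:
    def test_complete_graph_single_seed(self):
        n = 4
        km = kmat_from(np.full((n, n), 0.9), [f"g{i}" for i in range(n)])
        seeds = find_seeds(km, ClusteringParams(kappa_threshold=0.5))
        assert seeds == [frozenset({"g0", "g1", "g2", "g3"})]

    def test_no_qualifying_pairs_no_seeds(self):
        km = kmat_from(np.full((5, 5), 0.1), [f"g{i}" for i in range(5)])
        assert find_seeds(km, ClusteringParams(kappa_threshold=0.5)) == []

    def test_majority_rule_boundary(self):
        # g0 close to g1,g2,g3; pairs (g1,g3) and (g2,g3) below threshold:
        # candidate {g0..g3} has 4/6 qualifying pairs = 0.667
        s = np.array(
            [
                [1.0, 0.9, 0.9, 0.9],
                [0.9, 1.0, 0.9, 0.1],
                [0.9, 0.9, 1.0, 0.1],
                [0.9, 0.1, 0.1, 1.0],
            ]
        )
        km = kmat_from(s, ["g0", "g1", "g2", "g3"])
        lenient = find_seeds(km, ClusteringParams(kappa_threshold=0.5))
        assert frozenset({"g0", "g1", "g2", "g3"}) in lenient
        strict = find_seeds(
            km, ClusteringParams(kappa_threshold=0.5, membership_fraction=0.7)
        )
        assert frozenset({"g0", "g1", "g2", "g3"}) not in strict

    def test_size_filter(self):
        km = kmat_from(np.full((3, 3), 0.9), ["g0", "g1", "g2"])
        assert find_seeds(km, ClusteringParams(initial_group_membership=4)) == []
        assert (
            find_seeds(km, ClusteringParams(initial_group_membership=3))
            == [frozenset({"g0", "g1", "g2"})]
        )


class TestMergeSeeds:
    def test_min_denominator_majority_merge(self):
        # shared 2 / min 3 = 0.667 under the min rule
        mods = merge_seeds(
            [frozenset("ABCD"), frozenset("CDE")],
            ClusteringParams(linkage_denominator="min"),
        )
        assert [sorted(m.members) for m in mods] == [["A", "B", "C", "D", "E"]]
        assert mods[0].origin == "merged"

    def test_union_denominator_keeps_weakly_overlapping(self):
        # shared 2 / union 5 = 0.4 under the union rule: no merge; the
        # 3-gene group then falls below the final size filter
        mods = merge_seeds(
            [frozenset("ABCD"), frozenset("CDE")],
            ClusteringParams(linkage_denominator="union"),
        )
        assert [sorted(m.members) for m in mods] == [["A", "B", "C", "D"]]
        assert mods[0].origin == "seed"

    def test_disjoint_seeds_untouched(self):
        mods = merge_seeds([frozenset("ABCD"), frozenset("EFGH")], ClusteringParams())
        assert len(mods) == 2
        assert all(m.origin == "seed" for m in mods)

    def test_identical_seeds_collapse(self):
        mods = merge_seeds([frozenset("ABCD"), frozenset("ABCD")], ClusteringParams())
        assert len(mods) == 1

    def test_chained_transitive_merge(self):
        mods = merge_seeds(
            [frozenset("ABCDE"), frozenset("CDEFG"), frozenset("EFGHI")],
            ClusteringParams(linkage_denominator="min", linkage_fraction=0.5),
        )
        assert [sorted(m.members) for m in mods] == [list("ABCDEFGHI")]

    def test_numbering_by_size_then_member(self):
        mods = merge_seeds(
            [frozenset("WXYZ"), frozenset("ABCD"), frozenset("MNOPQ")],
            ClusteringParams(),
        )
        assert [m.module_id for m in mods] == [1, 2, 3]
        assert sorted(mods[0].members) == list("MNOPQ")  # largest first
        assert sorted(mods[1].members) == list("ABCD")  # tie broken by member

    def test_final_size_filter(self):
        mods = merge_seeds([frozenset("AB"), frozenset("CDEF")],
                           ClusteringParams(final_group_membership=4))
        assert [sorted(m.members) for m in mods] == [["C", "D", "E", "F"]]


class TestCluster:
    def test_identical_profiles_single_module(self):
        inc = np.tile(np.array([1, 1, 0, 0], dtype=np.uint8), (5, 1))
        m = AnnotationMatrix(tuple(f"g{i}" for i in range(5)), tuple("abcd"), inc)
        res = cluster(m, ClusteringParams(kappa_threshold=0.5))
        assert res.n_modules == 1
        assert res.modules[0].members == frozenset(m.gene_ids)
        assert not res.unclustered

    def test_all_pairs_below_threshold_all_unclustered(self):
        inc = np.eye(4, 5, dtype=np.uint8)  # pairwise disjoint profiles
        m = AnnotationMatrix(tuple(f"g{i}" for i in range(4)), tuple("abcde"), inc)
        res = cluster(m, ClusteringParams(kappa_threshold=0.5))
        assert res.n_modules == 0
        assert res.unclustered == frozenset(m.gene_ids)

    def test_planted_two_blocks_recovered(self):
        m, truth = generate(two_block_spec())
        res = cluster(m, ClusteringParams(kappa_threshold=0.5))
        recovered = sorted((frozenset(mod.members) for mod in res.modules), key=sorted)
        assert recovered == sorted(truth.group_members, key=sorted)

    def test_union_and_unclustered_partition_genes(self):
        m, _ = generate(FixtureSpec(seed=3))
        res = cluster(m)
        assert res.clustered_genes | res.unclustered == set(m.gene_ids)
        assert not res.clustered_genes & res.unclustered

    def test_determinism(self):
        m, _ = generate(FixtureSpec(seed=5))
        r1 = cluster(m)
        r2 = cluster(m)
        assert [mod.members for mod in r1.modules] == [mod.members for mod in r2.modules]
        assert r1.unclustered == r2.unclustered

    def test_modules_pairwise_distinct(self):
        m, _ = generate(FixtureSpec(seed=7))
        res = cluster(m, ClusteringParams(kappa_threshold=0.3))
        sets = [mod.members for mod in res.modules]
        assert len(sets) == len(set(sets))

    def test_seed_subset_relationship_across_thresholds(self):
        # every seed at a stricter threshold sits inside some candidate
        # neighbourhood at the looser one
        m, _ = generate(FixtureSpec(seed=11))
        km = kappa_matrix(m)
        hi = find_seeds(km, ClusteringParams(kappa_threshold=0.6))
        assert km.qualifying_pair_count(0.6) <= km.qualifying_pair_count(0.3)
        for s in hi:
            assert any(s <= km.neighbors_at(g, 0.3) | {g} for g in s)


class TestSubcluster:
    def test_nested_blocks_split_at_higher_kappa(self):
        m, (a_genes, b_genes) = nested_block_matrix()
        res = cluster(m, ClusteringParams(kappa_threshold=0.35))
        assert res.modules[0].members == a_genes | b_genes
        sub = subcluster(res, 1, m, ClusteringParams(kappa_threshold=0.6))
        assert {mod.members for mod in sub.modules} == {a_genes, b_genes}
        assert all(mod.size < res.modules[0].size for mod in sub.modules)
        assert all(mod.origin == "submodule" and mod.lineage == 1 for mod in sub.modules)

    def test_identical_profiles_single_submodule(self):
        inc = np.tile(np.array([1, 1, 0, 0, 0], dtype=np.uint8), (6, 1))
        m = AnnotationMatrix(tuple(f"g{i}" for i in range(6)), tuple("abcde"), inc)
        res = cluster(m, ClusteringParams(kappa_threshold=0.3))
        sub = subcluster(res, 1, m, ClusteringParams(kappa_threshold=0.9))
        assert sub.n_modules == 1
        assert sub.modules[0].members == res.modules[0].members

    def test_higher_kappa_above_all_pairs_no_submodules(self):
        m, _ = generate(FixtureSpec(seed=2, p_within=0.7))
        res = cluster(m, ClusteringParams(kappa_threshold=0.3))
        sub = subcluster(res, 1, m, ClusteringParams(kappa_threshold=0.999))
        assert sub.n_modules == 0

    def test_non_increasing_kappa_rejected(self):
        m, _ = generate(two_block_spec())
        res = cluster(m, ClusteringParams(kappa_threshold=0.5))
        with pytest.raises(ValueError):
            subcluster(res, 1, m, ClusteringParams(kappa_threshold=0.5))

    def test_unknown_module_id(self):
        m, _ = generate(two_block_spec())
        res = cluster(m, ClusteringParams(kappa_threshold=0.5))
        with pytest.raises(KeyError):
            subcluster(res, 99, m, ClusteringParams(kappa_threshold=0.8))
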