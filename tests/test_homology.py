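"""Domain-homology statistics: shuffles, co-occurrence, FDR, coherence."""

import itertools
from collections import Counter

import numpy as np
import pytest

from complexevo import (
    ComplexDataset,
    DomainAnnotation,
    WeightedNetwork,
    bh_fdr,
    cocomplex_pair_count,
    complexes_with_homolog_pairs,
    pair_interaction_enrichment,
    shuffle_complexes,
    spread_regression,
    superfamily_distribution_test,
    superfamily_function_coherence,
)
from complexevo.homology import read_domains_tsv, write_domains_tsv
from complexevo.ontology import GOResource
from complexevo.synthetic import generate_world


class TestDomainAnnotation:
    def test_tandem_repeats_collapse_in_mda(self):
        da = DomainAnnotation({"p": ["A", "A", "B", "A"]})
        assert da.mda["p"] == ("A", "B", "A")

    def test_superfamily_index_consistent(self):
        da = DomainAnnotation({"p": ["A", "B"], "q": ["B"], "r": []})
        assert da.superfamily_index == {"A": {"p"}, "B": {"p", "q"}}
        assert da.superfamilies_of("r") == frozenset()

    def test_architecture_homology_requires_identical_order(self):
        da = DomainAnnotation({"p": ["A", "B"], "q": ["B", "A"], "r": ["A", "B"]})
        assert not da.share_architecture("p", "q")
        assert da.share_architecture("p", "r")
        assert da.share_domain("p", "q")

    def test_round_trip_tsv(self, tmp_path):
        da = DomainAnnotation({"p": ["A", "B"], "q": ["C"]})
        path = tmp_path / "domains.tsv"
        write_domains_tsv(da, path)
        assert read_domains_tsv(path).mda == da.mda


class TestShuffle:
    def test_single_complex_unchanged(self):
        ds = ComplexDataset.from_lists([{"a", "b", "c"}])
        assert shuffle_complexes(ds, 0).complexes == ds.complexes

    def test_size_and_protein_multisets_preserved(self):
        ds = ComplexDataset.from_lists([{"a", "b"}, {"c", "d", "e"}, {"f", "g"}])
        for seed in range(20):
            out = shuffle_complexes(ds, seed)
            assert sorted(out.sizes) == sorted(ds.sizes)
            assert out.proteins == ds.proteins
            assert out.provenance == "randomised"

    def test_pairing_frequencies_match_enumeration(self):
        # with {a,b},{c,d} exactly 3 distinct pairings exist, so a shares a
        # complex with each of b, c, d one third of the time
        ds = ComplexDataset.from_lists([{"a", "b"}, {"c", "d"}])
        partner = Counter()
        n = 6000
        for seed in range(n):
            out = shuffle_complexes(ds, seed)
            for c in out:
                if "a" in c:
                    partner[next(iter(c - {"a"}))] += 1
        for other in "bcd":
            assert partner[other] / n == pytest.approx(1 / 3, abs=3 * 0.006)


class TestCocomplexPairCount:
    def test_triangle_in_one_complex(self):
        da = DomainAnnotation({p: ["S"] for p in "abc"})
        ds = ComplexDataset.from_lists([{"a", "b", "c"}])
        assert cocomplex_pair_count("S", ds, da) == 3

    def test_spread_members_give_zero(self):
        da = DomainAnnotation({p: ["S"] for p in "abc"})
        ds = ComplexDataset.from_lists([{"a"}, {"b"}, {"c"}])
        assert cocomplex_pair_count("S", ds, da) == 0

    def test_two_complexes_two_members_each(self):
        da = DomainAnnotation({p: ["S"] for p in "abcd"})
        ds = ComplexDataset.from_lists([{"a", "b"}, {"c", "d"}])
        assert cocomplex_pair_count("S", ds, da) == 2

    def test_unknown_superfamily_counts_zero(self):
        da = DomainAnnotation({"a": ["S"]})
        ds = ComplexDataset.from_lists([{"a"}])
        assert cocomplex_pair_count("missing", ds, da) == 0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            proteins = [f"P{i}" for i in range(15)]
            da = DomainAnnotation(
                {
                    p: list(rng.choice(["A", "B", "C"], size=rng.integers(0, 3)))
                    for p in proteins
                }
            )
            perm = list(rng.permutation(proteins))
            ds = ComplexDataset.from_lists([set(perm[:5]), set(perm[5:9]), set(perm[9:])])
            for sfam in "ABC":
                brute = sum(
                    1
                    for c in ds
                    for p, q in itertools.combinations(sorted(c), 2)
                    if sfam in da.superfamilies_of(p) and sfam in da.superfamilies_of(q)
                )
                assert cocomplex_pair_count(sfam, ds, da) == brute


class TestBHFDR:
    def test_step_up_hand_cases(self):
        assert bh_fdr([0.001, 0.02, 0.9], 0.05) == {0, 1}
        assert bh_fdr([0.001, 0.02, 0.9], 0.01) == {0}

    def test_all_ones_and_empty(self):
        assert bh_fdr([1.0, 1.0], 0.05) == set()
        assert bh_fdr([], 0.05) == set()

    def test_step_up_rescues_interior_pvalue(self):
        # 0.030 fails its own rank-2 threshold (0.025) but rank 3 passes
        # (0.032 <= 0.0375), so the step-up keeps the first three
        assert bh_fdr([0.01, 0.030, 0.032, 0.9], 0.05) == {0, 1, 2}


class TestDistributionTest:
    def test_small_superfamilies_excluded(self):
        da = DomainAnnotation({p: ["S"] for p in "abcd"})  # 4 members < 5
        ds = ComplexDataset.from_lists([{"a", "b"}, {"c", "d"}])
        results, sig = superfamily_distribution_test(ds, da, n_rand=50, seed=0)
        assert results == {} and sig == set()

    def test_concentrated_superfamily_detected(self):
        # one superfamily fills a whole complex; background is unannotated
        members = {f"m{i}" for i in range(6)}
        others = [{f"x{i}", f"y{i}"} for i in range(10)]
        ds = ComplexDataset.from_lists([members, *others])
        da = DomainAnnotation({p: ["S"] for p in members})
        n_rand = 1000
        results, sig = superfamily_distribution_test(ds, da, n_rand=n_rand, seed=3)
        assert results["S"].observed == 15  # C(6,2)
        assert results["S"].p_value <= 1 / (n_rand + 1) + 1e-12
        assert sig == {"S"}


class TestHomologPairs:
    def test_no_shared_superfamily_counts_zero(self):
        da = DomainAnnotation({"a": ["A"], "b": ["B"], "c": ["C"], "d": ["D"]})
        ds = ComplexDataset.from_lists([{"a", "b"}, {"c", "d"}])
        res = complexes_with_homolog_pairs(ds, da, n_rand=50, seed=0)
        assert res.count == 0 and res.pairs == []

    def test_domain_count_at_least_architecture_count(self):
        world = generate_world(seed=8, planted_homolog_complex_fraction=0.4)
        dom = complexes_with_homolog_pairs(
            world.true_complexes, world.domain_annotation, "domain", n_rand=50, seed=0
        )
        arch = complexes_with_homolog_pairs(
            world.true_complexes, world.domain_annotation, "architecture",
            n_rand=50, seed=0,
        )
        assert dom.count >= arch.count
        arch_pairs = set(map(frozenset, arch.pairs))
        assert arch_pairs <= set(map(frozenset, dom.pairs))

    def test_unannotated_proteins_never_pair(self):
        da = DomainAnnotation({"a": ["S"], "b": ["S"]})
        ds = ComplexDataset.from_lists([{"a", "b"}, {"x", "y"}])
        res = complexes_with_homolog_pairs(ds, da, n_rand=200, seed=0)
        assert res.count == 1
        assert res.pairs == [("a", "b")]


class TestNullPValueDistribution:
    def test_discrete_count_pvalues_are_super_uniform(self):
        """Under the null the empirical p of a discrete count statistic is
        valid: P(p <= alpha) <= alpha (conservative) at every level."""
        world = generate_world(seed=101, n_complexes=60, n_superfamilies=60)
        results, _ = superfamily_distribution_test(
            world.true_complexes, world.domain_annotation, n_rand=1000, seed=1
        )
        ps = np.array([r.p_value for r in results.values()])
        assert len(ps) >= 30
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
            se = np.sqrt(alpha * (1 - alpha) / len(ps))
            assert np.mean(ps <= alpha) <= alpha + 3 * se

    def test_continuous_statistic_pvalues_uniform_by_ks(self):
        """Where the permutation statistic is effectively continuous (mean
        GOSS of sampled pairs) null p-values pass a KS uniformity check."""
        from scipy import stats

        from complexevo.complexes import cocomplex_pairs
        from complexevo.correlated import (
            CorrelatedPair,
            correlated_pair_enrichment,
        )

        world = generate_world(seed=300, n_complexes=15)
        ds, net, go = world.true_complexes, world.pin, world.go
        pool = sorted(tuple(sorted(p)) for p in cocomplex_pairs(ds))
        rng = np.random.default_rng(7)
        ps = []
        for r in range(200):
            idx = rng.choice(len(pool), size=20, replace=False)
            witnesses = [
                CorrelatedPair("A", "B", 2, 0.5, [(0, a, b)])
                for a, b in (pool[i] for i in idx)
            ]
            _, p_goss = correlated_pair_enrichment(
                witnesses, ds, net, go, n_rand=1000, seed=r
            )
            ps.append(p_goss)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestInteractionEnrichment:
    def test_no_edge_pairs_give_p_one(self):
        ds = ComplexDataset.from_lists([{"a", "b"}, {"c", "d"}])
        net = WeightedNetwork.from_edges([("x", "y")])
        p = pair_interaction_enrichment([("a", "b")], ds, net, n_rand=100, seed=0)
        assert p == 1.0

    def test_all_edges_on_sparse_background_significant(self):
        members = [f"p{i}" for i in range(12)]
        ds = ComplexDataset.from_lists([set(members)])
        pairs = [("p0", "p1"), ("p2", "p3"), ("p4", "p5")]
        net = WeightedNetwork.from_edges(pairs)
        n_rand = 1000
        p = pair_interaction_enrichment(pairs, ds, net, n_rand=n_rand, seed=1)
        assert p <= 0.01

    def test_requires_enough_candidate_pairs(self):
        ds = ComplexDataset.from_lists([{"a", "b"}])
        net = WeightedNetwork.from_edges([("a", "b")])
        with pytest.raises(ValueError):
            pair_interaction_enrichment(
                [("a", "b"), ("a", "b")], ds, net, n_rand=10, seed=0
            )


class TestSpreadRegression:
    def test_one_member_per_complex_lies_on_diagonal(self):
        # superfamily sizes 1..4, every member alone in its own complex
        mda, pid = {}, 0
        for size in (1, 2, 3, 4):
            for _ in range(size):
                mda[f"p{pid}"] = [f"S{size}"]
                pid += 1
        da = DomainAnnotation(mda)
        ds = ComplexDataset.from_lists([{p} for p in mda])
        points, r2 = spread_regression(da, ds)
        assert all(x == y for x, y in points)
        assert r2 == pytest.approx(1.0)

    def test_five_point_fixture_matches_closed_form(self):
        mda = {}
        placements = {"S1": 2, "S2": 3, "S3": 5, "S4": 7, "S5": 11}
        ds_lists, pid = [], 0
        for sfam, k in placements.items():
            for _ in range(k):
                mda[f"p{pid}"] = [sfam]
                ds_lists.append({f"p{pid}"})
                pid += 1
        # remove one complex for S5 so its members split 11 -> 10 complexes
        ds_lists[-2] = ds_lists[-2] | ds_lists[-1]
        ds_lists.pop()
        da = DomainAnnotation(mda)
        ds = ComplexDataset.from_lists(ds_lists)
        points, r2 = spread_regression(da, ds)
        x = np.array([p[0] for p in points], dtype=float)
        y = np.array([p[1] for p in points], dtype=float)
        assert r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)

    def test_degenerate_x_variance_reports_none(self):
        da = DomainAnnotation({"a": ["S1"], "b": ["S2"]})
        ds = ComplexDataset.from_lists([{"a"}, {"b"}])
        points, r2 = spread_regression(da, ds)
        assert r2 is None


class TestFunctionCoherence:
    @pytest.fixture()
    def deep_go(self):
        # root -> mid -> deep; 2 coherent proteins on deep, 18 diverse
        parents = {"root": set(), "mid": {"root"}, "deep": {"mid"}}
        for i in range(18):
            parents[f"leaf{i}"] = {"root"}
        annotations = {"m1": {"deep"}, "m2": {"deep"}, "m3": {"deep"}}
        for i in range(18):
            annotations[f"bg{i}"] = {f"leaf{i}"}  # unique leaf each
        return GOResource(parents=parents, annotations=annotations)

    def test_coherent_members_significant(self, deep_go):
        da = DomainAnnotation({"m1": ["S"], "m2": ["S"], "m3": ["S"]})
        p = superfamily_function_coherence(
            "S", da, deep_go, n_rand=500, seed=0, mode="members"
        )
        assert p <= 0.01

    def test_single_annotated_member_skipped(self, deep_go):
        da = DomainAnnotation({"m1": ["S"], "zzz": ["S"]})
        assert (
            superfamily_function_coherence("S", da, deep_go, n_rand=50, seed=0)
            is None
        )

    def test_interactor_mode_runs_and_detects_shared_context(self, deep_go):
        # two members whose interactors are the coherent deep proteins
        da = DomainAnnotation({"u": ["S"], "v": ["S"]})
        edges = [("u", "m1"), ("u", "m2"), ("v", "m2"), ("v", "m3")]
        edges += [(f"bg{i}", f"bg{i + 1}") for i in range(0, 16, 2)]
        net = WeightedNetwork.from_edges(edges)
        p = superfamily_function_coherence(
            "S", da, deep_go, n_rand=300, seed=0, mode="interactors", net=net
        )
        assert p is not None and p <= 0.05
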