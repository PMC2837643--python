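"""Planted-world generators: determinism, planted structure, calibration."""

import numpy as np
import pytest

from complexevo import (
    ComplexDataset,
    generate_domain_annotations,
    generate_go,
    generate_planted_pin,
    generate_tap_records,
    generate_world,
    protein_goss,
    write_world,
)
from complexevo.synthetic import TruncatedGeometric


class TestPlantedPin:
    def test_forced_probabilities_give_disjoint_triangles(self):
        net, truth = generate_planted_pin(
            2, size_sampler=TruncatedGeometric(lo=3, hi=3), p_within=1.0,
            p_between=0.0, seed=0,
        )
        assert net.n_edges == 6
        assert len(truth) == 2
        for c in truth:
            members = sorted(c)
            assert all(
                net.has_edge(a, b)
                for i, a in enumerate(members)
                for b in members[i + 1 :]
            )

    def test_undetectable_configuration_rejected(self):
        with pytest.raises(ValueError):
            generate_planted_pin(2, p_within=0.0, p_between=0.0, seed=0)
        with pytest.raises(ValueError):
            generate_planted_pin(2, p_within=0.3, p_between=0.5, seed=0)

    def test_intra_density_matches_binomial_expectation(self):
        net, truth = generate_planted_pin(
            20, size_sampler=TruncatedGeometric(lo=3, hi=15),
            p_within=0.9, p_between=0.01, seed=42,
        )
        n_pairs = sum(len(c) * (len(c) - 1) // 2 for c in truth)
        n_intra = sum(
            1
            for c in truth
            for i, a in enumerate(sorted(c))
            for b in sorted(c)[i + 1 :]
            if net.has_edge(a, b)
        )
        se = np.sqrt(0.9 * 0.1 / n_pairs)
        assert n_intra / n_pairs == pytest.approx(0.9, abs=3 * se)

    def test_all_weights_start_at_one(self):
        net, _ = generate_planted_pin(3, p_within=0.8, p_between=0.05, seed=1)
        assert all(net.weight(a, b) == 1.0 for a, b in net.edges())


class TestTapRecords:
    def test_exhaustive_baits_no_noise(self):
        truth = ComplexDataset.from_lists([{"a", "b", "c"}], provenance="gold")
        records = generate_tap_records(truth, 1.0, 0.0, 0, seed=0)
        by_bait = {r.bait: set(r.preys) for r in records}
        assert by_bait == {"a": {"b", "c"}, "b": {"a", "c"}, "c": {"a", "b"}}

    def test_total_false_negative_rate_empties_preys(self):
        truth = ComplexDataset.from_lists([{"a", "b", "c"}], provenance="gold")
        records = generate_tap_records(truth, 1.0, 1.0, 0, seed=0)
        assert all(r.preys == [] for r in records)

    def test_false_positives_come_from_non_members(self):
        truth = ComplexDataset.from_lists(
            [{"a", "b"}, {"x", "y"}], provenance="gold"
        )
        records = generate_tap_records(truth, 1.0, 1.0, 1, seed=0)
        for r in records:
            complex_of_bait = next(c for c in truth if r.bait in c)
            assert all(p not in complex_of_bait for p in r.preys)

    def test_mean_prey_count_matches_binomial(self):
        truth = ComplexDataset.from_lists(
            [{f"c{i}_{j}" for j in range(5)} for i in range(1000)],
            provenance="gold",
        )
        records = generate_tap_records(truth, 1.0, 0.5, 0, seed=9)
        lengths = [len(r.preys) for r in records]
        se = np.sqrt(4 * 0.5 * 0.5 / len(lengths))
        assert np.mean(lengths) == pytest.approx(2.0, abs=3 * se)

    def test_empty_complex_set_rejected(self):
        with pytest.raises(ValueError):
            generate_tap_records(
                ComplexDataset.from_lists([], provenance="gold"), 1.0, 0.0, 0, 0
            )


class TestDomainGenerator:
    def test_full_planting_gives_every_complex_a_homolog_pair(self):
        _, truth = generate_planted_pin(10, p_within=0.9, p_between=0.01, seed=2)
        da = generate_domain_annotations(
            sorted(truth.proteins), truth,
            planted_homolog_complex_fraction=1.0, seed=2,
        )
        for c in truth:
            members = sorted(c)
            assert any(
                da.share_domain(a, b)
                for i, a in enumerate(members)
                for b in members[i + 1 :]
            )

    def test_null_world_has_no_planted_markers(self):
        _, truth = generate_planted_pin(10, p_within=0.9, p_between=0.01, seed=2)
        da = generate_domain_annotations(sorted(truth.proteins), truth, seed=2)
        assert all(not s.startswith(("HOM", "COR")) for s in da.superfamilies)

    def test_correlated_pairs_planted_in_enough_complexes(self):
        _, truth = generate_planted_pin(12, p_within=0.9, p_between=0.01, seed=3)
        da = generate_domain_annotations(
            sorted(truth.proteins), truth, planted_correlated_pairs=2,
            complexes_per_correlated_pair=4, seed=3,
        )
        from complexevo import pair_complex_count

        for k in (1, 2):
            assert (
                pair_complex_count(f"COR{k:04d}A", f"COR{k:04d}B", truth, da) >= 4
            )

    def test_capacity_overflow_rejected(self):
        truth = ComplexDataset.from_lists([{"a", "b"}], provenance="gold")
        with pytest.raises(ValueError):
            generate_domain_annotations(
                ["a", "b"], truth, planted_correlated_pairs=1,
                complexes_per_correlated_pair=3, seed=0,
            )


class TestGoGenerator:
    def test_root_only_dag_scores_zero_everywhere(self):
        proteins = [f"p{i}" for i in range(5)]
        go = generate_go(proteins, depth=1, branching=3, n_annotations=10, seed=0)
        assert go.terms == {"GO:0000001"}
        for p in proteins:
            for q in proteins:
                assert protein_goss(go, p, q) == 0.0

    def test_sibling_leaves_share_only_root(self):
        from complexevo.ontology import GOResource, resnik_similarity

        go = GOResource(
            parents={"r": set(), "l1": {"r"}, "l2": {"r"}},
            annotations={"p1": {"l1"}, "p2": {"l2"}},
        )
        assert resnik_similarity(go, "l1", "l2") == 0.0
        assert resnik_similarity(go, "l1", "l1") == go.ic["l1"] > 0

    def test_generated_dag_has_propagation_closure(self):
        proteins = [f"p{i}" for i in range(30)]
        go = generate_go(proteins, depth=3, branching=2, n_annotations=60, seed=4)
        for p, terms in go.propagated.items():
            for t in terms:
                assert go.ancestors(t) <= terms


class TestWorldDeterminism:
    def test_regeneration_is_byte_identical(self, tmp_path):
        kwargs = dict(
            seed=21, n_complexes=8, planted_homolog_complex_fraction=0.5,
            planted_correlated_pairs=1, core_fraction=0.2,
        )
        p1 = write_world(generate_world(**kwargs), tmp_path / "w1")
        p2 = write_world(generate_world(**kwargs), tmp_path / "w2")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes(), name

    def test_different_seeds_differ(self, tmp_path):
        w1 = generate_world(seed=1, n_complexes=8)
        w2 = generate_world(seed=2, n_complexes=8)
        assert w1.pin.edge_set() != w2.pin.edge_set()

    def test_truth_members_subset_of_proteins(self):
        w = generate_world(seed=5, n_complexes=6)
        assert w.true_complexes.proteins <= set(w.proteins)
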