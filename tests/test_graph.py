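import numpy as np
import pytest

from mitocircles.datasets import CP_DERIVED_CONTIG, table1_contigs, table1_graph
from mitocircles.graph import (
    ChromosomePath,
    ConnectionGraph,
    ResolutionError,
    StitchError,
    assign_multiplicities,
    prune_graph,
    resolve_circles,
    stitch_sequences,
)
from mitocircles.io import revcomp
from mitocircles.screen import DepthModel, estimate_modal_depth
from mitocircles.synth import fragment_to_contigs, generate_genome, scaled_study_config
from oracles import enumerate_decompositions, random_seq


def cycle_graph(n, depth=70.0, length=1000, prefix="c"):
    g = ConnectionGraph()
    ids = [f"{prefix}{i}" for i in range(n)]
    for cid in ids:
        g.add_contig(cid, length=length, depth=depth)
    for i, cid in enumerate(ids):
        g.add_link(cid, "e", ids[(i + 1) % n], "b")
    return g, ids


class TestPrune:
    def test_cp_node_and_its_edge_removed_cycle_intact(self):
        g, ids = cycle_graph(3)
        g.add_contig("cp", length=300, depth=1000.0)
        g.add_link(ids[0], "e", "cp", "b")
        labels = {cid: "mt" for cid in ids} | {"cp": "cp_derived"}
        pruned = prune_graph(g, labels, DepthModel(70.0))
        assert "cp" not in pruned.nodes
        assert pruned.link_set() == g.link_set() - {
            tuple(sorted([(ids[0], "e"), ("cp", "b")]))
        }

    def test_fork_resolved_by_depth_difference(self):
        g = ConnectionGraph()
        g.add_contig("A", length=1000, depth=71.0)
        g.add_contig("B", length=1000, depth=70.0)
        g.add_contig("C", length=1000, depth=250.0)
        g.add_link("A", "e", "B", "b")
        g.add_link("A", "e", "C", "b")
        labels = {"A": "mt", "B": "mt", "C": "mt"}
        pruned = prune_graph(g, labels, DepthModel(70.0))
        assert pruned.link_set() == {(("A", "e"), ("B", "b"))}

    def test_spurious_links_pruned_to_exact_truth_adjacency(self):
        cfg = scaled_study_config(0.03, seed=8)
        truth = generate_genome(cfg)
        contigs, graph = fragment_to_contigs(truth, n_spurious_links=2)
        model = estimate_modal_depth(contigs)
        labels = {c.id: "mt" for c in contigs}
        keep = {
            c.id for c in contigs if truth.expected_depth[c.id] > 3 * cfg.mt_depth
        }
        for cid in keep:
            labels[cid] = "cp_derived"
        pruned = prune_graph(graph, labels, model, keep=keep)
        assert pruned.link_set() == truth.adjacency_set()

    def test_idempotent(self):
        g, ids = cycle_graph(4)
        g.add_contig("x", length=100, depth=400.0)
        g.add_link(ids[1], "e", "x", "b")
        labels = {cid: "mt" for cid in ids} | {"x": "non_organellar"}
        model = DepthModel(70.0)
        once = prune_graph(g, labels, model)
        twice = prune_graph(once, labels, model)
        assert once == twice


class TestMultiplicities:
    def test_simple_ratios(self):
        g = ConnectionGraph()
        g.add_contig("a", length=100, depth=70.0)
        g.add_contig("b", length=100, depth=140.0)
        g.add_link("a", "e", "b", "b")
        g.add_link("a", "e", "b", "b")
        g.add_link("a", "b", "b", "e")
        g.add_link("a", "b", "b", "e")
        mult = assign_multiplicities(g, DepthModel(70.0))
        assert mult["a"] == 1
        assert mult["b"] == 2

    def test_ambiguous_ratio_resolved_to_smallest_feasible(self):
        # the 113.7x contig over modal 72.6 (ratio 1.57) sits in a plain
        # cycle: copy number 1 admits a decomposition, so 1 wins
        contigs = table1_contigs()
        graph = table1_graph(contigs)
        model = estimate_modal_depth(contigs)
        labels = {c.id: "mt" for c in contigs} | {CP_DERIVED_CONTIG: "cp_derived"}
        pruned = prune_graph(graph, labels, model, keep={CP_DERIVED_CONTIG})
        mult = assign_multiplicities(pruned, model)
        assert "Contig69702" in mult.ambiguous
        assert mult["Contig69702"] == 1


class TestResolve:
    def test_single_contig_self_circle(self):
        g = ConnectionGraph()
        g.add_contig("a", length=500, depth=70.0)
        g.add_link("a", "e", "a", "b")
        paths = resolve_circles(g)
        assert len(paths) == 1
        assert paths[0].members == [("a", "+")]
        assert paths[0].circular

    def test_study_profile_three_circles_1_7_6(self):
        contigs = table1_contigs()
        graph = table1_graph(contigs)
        model = estimate_modal_depth(contigs)
        labels = {c.id: "mt" for c in contigs} | {CP_DERIVED_CONTIG: "cp_derived"}
        pruned = prune_graph(graph, labels, model, keep={CP_DERIVED_CONTIG})
        paths = resolve_circles(pruned, assign_multiplicities(pruned, model))
        assert sorted(len(p.members) for p in paths) == [1, 6, 7]

    def test_multiplicity_two_decomposition_matches_enumeration_oracle(self):
        g = ConnectionGraph()
        for cid, depth in [("A", 140.0), ("B", 70.0), ("C", 70.0), ("D", 70.0)]:
            g.add_contig(cid, length=100, depth=depth)
        g.add_link("A", "e", "B", "b")
        g.add_link("B", "e", "A", "b")
        g.add_link("A", "e", "C", "b")
        g.add_link("C", "e", "D", "b")
        g.add_link("D", "e", "A", "b")
        copy_number = {"A": 2, "B": 1, "C": 1, "D": 1}
        valid = enumerate_decompositions(g, copy_number)
        assert valid, "fixture must admit at least one decomposition"
        runs = []
        for _ in range(3):
            paths = resolve_circles(g, copy_number)
            key = frozenset(
                (tuple(p.members), sum(1 for q in paths if q.members == p.members))
                for p in paths
            )
            runs.append(key)
        assert runs[0] == runs[1] == runs[2]  # same decomposition every run
        assert runs[0] in valid

    def test_dangling_end_names_offender(self):
        g = ConnectionGraph()
        g.add_contig("a", length=100, depth=70.0)
        g.add_contig("b", length=100, depth=70.0)
        g.add_link("a", "e", "b", "b")
        with pytest.raises(ResolutionError, match="a:b"):
            resolve_circles(g)

    def test_canonical_rotation_and_ordering(self):
        g, ids = cycle_graph(3, prefix="m")
        paths = resolve_circles(g)
        assert paths[0].members[0] == ("m0", "+")

    def test_conservation_of_length(self):
        g, ids = cycle_graph(5, length=123)
        paths = resolve_circles(g)
        assert sum(p.total_length for p in paths) == 5 * 123

    def test_roundtrip_many_seeds(self):
        for seed in range(6):
            cfg = scaled_study_config(0.02, seed=100 + seed)
            truth = generate_genome(cfg)
            contigs, graph = fragment_to_contigs(truth)
            model = estimate_modal_depth(contigs)
            labels = {c.id: "mt" for c in contigs}
            pruned = prune_graph(graph, labels, model)
            paths = resolve_circles(pruned, assign_multiplicities(pruned, model))
            chroms = stitch_sequences(
                paths, {cid: n.sequence for cid, n in pruned.nodes.items()}
            )
            recovered = 0
            for rec in chroms:
                for planted in truth.chromosomes:
                    doubled = planted.sequence * 2
                    if len(rec.sequence) == len(planted.sequence) and (
                        rec.sequence in doubled or revcomp(rec.sequence) in doubled
                    ):
                        recovered += 1
                        break
            assert recovered == len(truth.chromosomes)


class TestStitch:
    def test_two_contigs_no_overlap(self):
        rng = np.random.default_rng(0)
        a, b = random_seq(rng, 100), random_seq(rng, 100)
        path = ChromosomePath([("a", "+"), ("b", "+")], circular=True, total_length=200)
        (rec,) = stitch_sequences([path], {"a": a, "b": b})
        assert len(rec.sequence) == 200
        assert rec.topology == "circular"

    def test_published_draft_lengths(self):
        contigs = table1_contigs(with_sequences=True)
        graph = table1_graph(contigs)
        model = estimate_modal_depth(contigs)
        labels = {c.id: "mt" for c in contigs} | {CP_DERIVED_CONTIG: "cp_derived"}
        pruned = prune_graph(graph, labels, model, keep={CP_DERIVED_CONTIG})
        paths = resolve_circles(pruned, assign_multiplicities(pruned, model))
        chroms = stitch_sequences(
            paths, {cid: n.sequence for cid, n in pruned.nodes.items()}
        )
        lengths = sorted(len(r.sequence) for r in chroms)
        assert lengths == [185_980, 282_737, 312_303]

    def test_overlap_trimmed_and_verified(self):
        rng = np.random.default_rng(1)
        a = random_seq(rng, 100)
        b = a[-10:] + random_seq(rng, 90)
        path = ChromosomePath([("a", "+"), ("b", "+")], circular=False)
        overlaps = {tuple(sorted([("a", "e"), ("b", "b")])): 10}
        (rec,) = stitch_sequences([path], {"a": a, "b": b}, overlaps)
        assert len(rec.sequence) == 190

    def test_overlap_mismatch_raises(self):
        rng = np.random.default_rng(2)
        a, b = random_seq(rng, 100), random_seq(rng, 100)
        path = ChromosomePath([("a", "+"), ("b", "+")], circular=False)
        overlaps = {tuple(sorted([("a", "e"), ("b", "b")])): 10}
        with pytest.raises(StitchError):
            stitch_sequences([path], {"a": a, "b": b}, overlaps)
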