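"""Newick I/O, the rooted-tree model, and metric-preserving rerooting."""

import logging

import numpy as np
import pytest

import tiptempo as tt
from tiptempo.errors import (
    DuplicateTipLabelError,
    NegativeBranchLengthError,
    NewickParseError,
)

from conftest import dendropy_tip_distances, parent_chain_distances


class TestReadNewick:
    def test_distances_sum_printed_lengths(self, three_tip_tree):
        assert tt.root_to_tip_distances(three_tip_tree) == {
            "A": 1.5, "B": 2.5, "C": 3.0,
        }

    def test_polytomy_accepted(self, star_tree):
        assert star_tree.n_tips == 3
        assert len(star_tree.root.children) == 3
        assert tt.root_to_tip_distances(star_tree) == {
            "A": 1.0, "B": 1.0, "C": 1.0,
        }

    def test_missing_semicolon_is_parse_error(self):
        with pytest.raises(NewickParseError):
            tt.read_newick("((A:1,B:2):0.5,C:3)")

    def test_malformed_reports_position(self):
        with pytest.raises(NewickParseError, match=r"column"):
            tt.read_newick("((A:1,B:2:0.5,C:3);")

    def test_duplicate_tip_label_named(self):
        with pytest.raises(DuplicateTipLabelError, match="A"):
            tt.read_newick("((A:1,A:2):0.5,C:3);")

    def test_negative_length_rejected_then_clamped(self):
        with pytest.raises(NegativeBranchLengthError, match="A"):
            tt.read_newick("((A:-1,B:2):0.5,C:3);")
        tree = tt.read_newick("((A:-1,B:2):0.5,C:3);", clamp_negative=True)
        assert tt.root_to_tip_distances(tree)["A"] == 0.5

    def test_missing_length_zero_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="tiptempo.tree"):
            tree = tt.read_newick("((A:1,B),C:3);")
        assert tt.root_to_tip_distances(tree)["B"] == 0.0
        assert any("missing branch length" in r.message for r in caplog.records)

    def test_scientific_notation_and_internal_labels(self):
        tree = tt.read_newick("((A:1e-3,B:2.5E-2)support95:0.5,C:3);")
        d = tt.root_to_tip_distances(tree)
        assert d["A"] == pytest.approx(0.501, abs=1e-15)
        internal = [n.label for n in tree.preorder()
                    if not n.is_leaf and n.label]
        assert internal == ["support95"]


class TestWriteNewick:
    @pytest.mark.parametrize("text", [
        "((A:1,B:2):0.5,C:3);",
        "(A:1,B:1,C:1);",
        "((A:1e-3,B:2.5E-2)n1:0.5,C:3);",
    ])
    def test_round_trip_preserves_metric(self, text):
        t1 = tt.read_newick(text)
        t2 = tt.read_newick(tt.write_newick(t1))
        assert tt.root_to_tip_distances(t1) == tt.root_to_tip_distances(t2)
        assert t1.tip_tip_distances() == t2.tip_tip_distances()

    def test_round_trip_idempotent_text(self, noisefree_sim):
        tree, _, _ = noisefree_sim
        once = tt.write_newick(tree)
        again = tt.write_newick(tt.read_newick(once))
        assert once == again

    def test_quoted_label_preserved(self):
        tree = tt.read_newick("('A b':1,C:2,D:3);")
        out = tt.write_newick(tree)
        assert "'A b'" in out
        back = tt.read_newick(out)
        assert sorted(back.tip_labels) == ["A b", "C", "D"]

    def test_simulated_round_trip_matrix_identical(self):
        cfg = tt.SimulationConfig(n_tips=100, rate_noise=0.2, seed=5)
        tree, _, _ = tt.simulate_clock_tree(cfg)
        m1 = dendropy_tip_distances(tt.write_newick(tree))
        m2 = dendropy_tip_distances(
            tt.write_newick(tt.read_newick(tt.write_newick(tree))))
        for key in m1:
            assert m2[key] == pytest.approx(m1[key], abs=1e-12)


class TestReroot:
    def test_reroot_midpoint_of_terminal_edge(self, three_tip_tree):
        c = next(n for n in three_tip_tree.edges() if n.label == "C")
        out = tt.reroot(three_tip_tree, tt.RootPlacement(c, 0.5))
        assert tt.root_to_tip_distances(out) == {
            "C": 1.5, "A": 3.0, "B": 4.0,
        }

    def test_fraction_zero_on_root_child_is_identity(self, three_tip_tree):
        child = three_tip_tree.root.children[0]
        out = tt.reroot(three_tip_tree, tt.RootPlacement(child, 0.0))
        assert (tt.root_to_tip_distances(out)
                == tt.root_to_tip_distances(three_tip_tree))

    def test_input_not_mutated(self, three_tip_tree):
        before = tt.write_newick(three_tip_tree)
        c = next(n for n in three_tip_tree.edges() if n.label == "C")
        tt.reroot(three_tip_tree, tt.RootPlacement(c, 0.7))
        assert tt.write_newick(three_tip_tree) == before

    def test_no_degree_two_nodes_remain(self, noisefree_sim):
        tree, _, _ = noisefree_sim
        rng = np.random.default_rng(0)
        edges = tree.edges()
        child = edges[int(rng.integers(len(edges)))]
        out = tt.reroot(tree, tt.RootPlacement(child, 0.3))
        for node in out.preorder():
            if node is not out.root and not node.is_leaf:
                assert len(node.children) >= 2

    def test_fraction_one_internal_places_root_at_node(self, three_tip_tree):
        ab = next(n for n in three_tip_tree.edges()
                  if not n.is_leaf)
        out = tt.reroot(three_tip_tree, tt.RootPlacement(ab, 1.0))
        d = tt.root_to_tip_distances(out)
        assert d == {"A": 1.0, "B": 2.0, "C": 3.5}
        # no zero-length root edge was introduced
        assert all(ch.length > 0 for ch in out.root.children)

    def test_metric_invariance_under_random_placements(self):
        cfg = tt.SimulationConfig(n_tips=30, rate_noise=0.1, seed=42)
        tree, _, _ = tt.simulate_clock_tree(cfg)
        reference = dendropy_tip_distances(tt.write_newick(tree))
        rng = np.random.default_rng(7)
        edges = tree.edges()
        for _ in range(50):
            child = edges[int(rng.integers(len(edges)))]
            frac = float(rng.uniform())
            out = tt.reroot(tree, tt.RootPlacement(child, frac))
            got = dendropy_tip_distances(tt.write_newick(out))
            for key, val in reference.items():
                assert got[key] == pytest.approx(val, abs=1e-12)


class TestDistances:
    def test_matches_independent_upward_walk(self):
        cfg = tt.SimulationConfig(n_tips=100, rate_noise=0.3, seed=17)
        tree, _, _ = tt.simulate_clock_tree(cfg)
        walked = parent_chain_distances(tree)
        for label, dist in tt.root_to_tip_distances(tree).items():
            assert dist == pytest.approx(walked[label], abs=1e-12)

    def test_additivity_bound(self, noisy_sim):
        tree, _, _ = noisy_sim
        depths = tt.root_to_tip_distances(tree)
        pair = tree.tip_tip_distances()
        for key, dist in pair.items():
            x, y = sorted(key)
            assert depths[x] + depths[y] >= dist - 1e-12

    def test_additivity_equality_when_root_on_path(self, three_tip_tree):
        depths = tt.root_to_tip_distances(three_tip_tree)
        pair = three_tip_tree.tip_tip_distances()
        # the root lies on every path to C
        for other in ("A", "B"):
            assert depths[other] + depths["C"] == pytest.approx(
                pair[frozenset((other, "C"))], abs=1e-15)
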