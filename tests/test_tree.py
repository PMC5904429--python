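import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcodelim.distance import DistanceMatrix, distance_matrix
from barcodelim.seqio import newick_string, write_newick
from barcodelim.synthetic import SimulationConfig, simulate_dataset
from barcodelim.tree import (
    NON_MONOPHYLETIC,
    TRIVIALLY_MONOPHYLETIC,
    PhyloTree,
    bootstrap_support,
    clade_support_by_species,
    nj,
    root_with_outgroup,
)
from conftest import make_alignment


def _matrix(ids, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(ids, d, np.full(d.shape, 100, dtype=int))


def random_additive_tree(rng: np.random.Generator, n: int) -> np.ndarray:
    """Path-length matrix of a random binary tree with random branch lengths.

    Components are merged pairwise until three remain, then joined at a
    central vertex; ``D`` accumulates every leaf-to-leaf path as it closes.
    Serves as the independent oracle: NJ must invert the matrix exactly.
    """
    D = np.zeros((n, n))
    comps = [{i: 0.0} for i in range(n)]  # leaf -> distance to component root
    while len(comps) > 3:
        i, j = sorted(rng.choice(len(comps), size=2, replace=False))
        a, b = comps[i], comps[j]
        la, lb = rng.uniform(0.005, 0.06, size=2)
        for x, dx in a.items():
            for y, dy in b.items():
                D[x, y] = D[y, x] = dx + la + dy + lb
        merged = {**{x: dx + la for x, dx in a.items()},
                  **{y: dy + lb for y, dy in b.items()}}
        comps = [comps[k] for k in range(len(comps)) if k not in (i, j)] + [merged]
    stems = rng.uniform(0.005, 0.06, size=len(comps))
    for ia in range(len(comps)):
        for ib in range(ia + 1, len(comps)):
            for x, dx in comps[ia].items():
                for y, dy in comps[ib].items():
                    D[x, y] = D[y, x] = dx + stems[ia] + dy + stems[ib]
    return D


class TestNJ:
    def test_three_taxon_exact_lengths(self):
        m = _matrix(["A", "B", "C"], [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        t = nj(m)
        s = newick_string(t, 0)
        assert "A:0.050000" in s and "B:0.150000" in s and "C:0.250000" in s

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) scaled by /20
        ids = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        ) / 20.0
        t = nj(_matrix(ids, d))
        assert t.splits() == {frozenset({"C", "D"})}
        # path lengths reproduce the input distances
        pdm = t.tree.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in pdm.taxon_iter()}
        for i, a in enumerate(ids):
            for j in range(i + 1, 4):
                assert pdm.patristic_distance(taxa[a], taxa[ids[j]]) == pytest.approx(
                    d[i, j], abs=1e-9
                )

    def test_all_zero_matrix_zero_branches(self):
        t = nj(_matrix(list("ABCD"), np.zeros((4, 4))))
        lengths = [e.length for e in t.tree.edges() if e.length is not None]
        assert all(l == 0 for l in lengths)

    def test_fewer_than_three_taxa_errors(self):
        with pytest.raises(ValueError):
            nj(_matrix(["A", "B"], [[0, 0.1], [0.1, 0]]))

    def test_leaf_set_preserved(self):
        rng = np.random.default_rng(0)
        n = 7
        D = random_additive_tree(rng, n)
        t = nj(_matrix([f"t{i}" for i in range(n)], D))
        assert sorted(t.leaf_names()) == [f"t{i}" for i in range(n)]

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.integers(4, 8))
    def test_additive_matrix_recovery(self, seed, n):
        """NJ is exact on additive matrices: path lengths match to 1e-9."""
        rng = np.random.default_rng(seed)
        D = random_additive_tree(rng, n)
        ids = [f"t{i}" for i in range(n)]
        t = nj(_matrix(ids, D))
        pdm = t.tree.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in pdm.taxon_iter()}
        for i in range(n):
            for j in range(i + 1, n):
                assert pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]]) == pytest.approx(
                    D[i, j], abs=1e-9
                )

    def test_matches_dendropy_nj_topology(self):
        """Independent cross-check against dendropy's own NJ on synthetic data."""
        aln, _ = simulate_dataset(
            SimulationConfig(n_species=5, specimens_per_species=(3, 2, 2, 3, 2),
                             seq_length=400, seed=7, missing_block=(0.0, 0))
        )
        m = distance_matrix(aln)
        ours = nj(m).splits()
        pdm_csv = ["," + ",".join(m.ids)]
        for i, sid in enumerate(m.ids):
            pdm_csv.append(sid + "," + ",".join(str(v) for v in m.d[i]))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO("\n".join(pdm_csv)), delimiter=","
        )
        ref = pdm.nj_tree()
        ref_splits = set()
        leaves = frozenset(m.ids)
        refmin = min(leaves)
        for node in ref.preorder_node_iter():
            if node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 2 <= len(side) <= len(leaves) - 2:
                ref_splits.add(side if refmin not in side else leaves - side)
        assert ours == ref_splits


class TestBootstrap:
    def test_fixed_differences_give_full_support(self):
        aln = make_alignment(
            {"x1": "AAAATTTTCCCC", "x2": "AAAATTTTCCCC",
             "y1": "GGGGTTTTAAAA", "y2": "GGGGTTTTAAAA"},
            {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"},
        )
        t = bootstrap_support(aln, replicates=50, seed=0)
        assert set(t.split_support.values()) == {100}

    def test_single_replicate_quantised(self):
        rng = np.random.default_rng(2)
        from conftest import random_alignment
        aln, _, _ = random_alignment(rng, 8, 60, 4, missing_frac=0.0)
        t = bootstrap_support(aln, replicates=1, seed=3)
        assert set(t.split_support.values()) <= {0, 100}

    def test_determinism_and_seed_sensitivity(self):
        rng = np.random.default_rng(4)
        from conftest import random_alignment
        aln, _, _ = random_alignment(rng, 10, 80, 4, missing_frac=0.0)
        a = bootstrap_support(aln, replicates=100, seed=5).split_support
        b = bootstrap_support(aln, replicates=100, seed=5).split_support
        assert a == b
        c = bootstrap_support(aln, replicates=100, seed=6).split_support
        assert set(a) == set(c)  # same reference tree, possibly different %

    def test_supports_within_range(self):
        aln, _ = simulate_dataset(
            SimulationConfig(n_species=4, specimens_per_species=(2, 2, 2, 2),
                             seq_length=300, seed=1)
        )
        t = bootstrap_support(aln, replicates=100, seed=1)
        assert all(0 <= v <= 100 for v in t.split_support.values())


class TestRooting:
    def _tree_with_outgroup(self):
        aln = make_alignment(
            {"o1": "GGGGGGGGAAAA", "a1": "AAAATTTTCCCC", "a2": "AAAATTTTCCCC",
             "b1": "AAAACCCCCCCC", "b2": "AAAACCCCCCCC"},
            {"o1": "OG", "a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        return aln, bootstrap_support(aln, replicates=20, seed=0)

    def test_root_on_pendant_edge(self):
        aln, t = self._tree_with_outgroup()
        r = root_with_outgroup(t, ["o1"])
        children = r.tree.seed_node.child_nodes()
        sides = [
            {lf.taxon.label for lf in c.leaf_iter()} for c in children
        ]
        assert {"o1"} in sides

    def test_unknown_outgroup_errors(self):
        _, t = self._tree_with_outgroup()
        with pytest.raises(KeyError):
            root_with_outgroup(t, ["nope"])

    def test_all_leaves_as_outgroup_errors(self):
        _, t = self._tree_with_outgroup()
        with pytest.raises(ValueError):
            root_with_outgroup(t, t.leaf_names())

    def test_supports_survive_rerooting(self):
        _, t = self._tree_with_outgroup()
        r = root_with_outgroup(t, ["o1"])
        assert r.split_support == t.split_support
        assert r.splits() >= set(t.split_support)  # rooting adds no new non-trivial splits beyond canon set

    def test_original_tree_untouched(self):
        _, t = self._tree_with_outgroup()
        before = newick_string(t, 0)
        root_with_outgroup(t, ["o1"])
        assert newick_string(t, 0) == before


class TestCladeSupport:
    def test_species_clade_lookup_and_verdicts(self):
        aln = make_alignment(
            {"a1": "AAAATTTT", "a2": "AAAATTTA", "b1": "CCCCTTTT",
             "b2": "CCCCTTTA", "s1": "GGGGTTTT", "x1": "AATTTTTT", "x2": "CCGGTTTT"},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "s1": "S",
             "x1": "X", "x2": "X"},
        )
        t = bootstrap_support(aln, replicates=50, seed=0)
        out = clade_support_by_species(t, aln.species_labels)
        assert isinstance(out["A"], int) and isinstance(out["B"], int)
        assert out["S"] == TRIVIALLY_MONOPHYLETIC
        # x1 sits with A-like sequences, x2 with B-like: interleaved
        assert out["X"] == NON_MONOPHYLETIC


class TestNewickDisplay:
    def test_low_supports_hidden_only_in_rendering(self):
        aln = make_alignment(
            {"x1": "AAAATTTTCCCC", "x2": "AAAATTTTCCCC",
             "y1": "GGGGTTTTAAAA", "y2": "GGGGTTTTAAAA"},
            {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"},
        )
        t = bootstrap_support(aln, replicates=10, seed=0)
        (split,) = list(t.split_support)
        t.split_support[split] = 42
        assert "42" not in newick_string(t, 50)
        assert "42" in newick_string(t, 0)
        assert t.split_support[split] == 42  # in-memory value untouched

    def test_round_trip_branch_lengths(self, tmp_path):
        rng = np.random.default_rng(9)
        n = 6
        D = random_additive_tree(rng, n)
        t = nj(_matrix([f"t{i}" for i in range(n)], D))
        path = tmp_path / "t.nwk"
        write_newick(t, path, 0)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        orig = {
            frozenset(lf.taxon.label for lf in node.leaf_iter()): node.edge.length
            for node in t.tree.preorder_node_iter() if node.parent_node is not None
        }
        new = {
            frozenset(lf.taxon.label for lf in node.leaf_iter()): node.edge.length
            for node in parsed.preorder_node_iter() if node.parent_node is not None
        }
        assert set(orig) == set(new)
        for k in orig:
            assert new[k] == pytest.approx(orig[k], abs=1e-6)
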