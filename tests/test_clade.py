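"""Distances, neighbor joining, bootstrap and clade assignment."""

import numpy as np
import pytest

import _nj_oracle as oracle
from paleomito import (
    DistanceMatrix,
    assign_clade,
    assign_clades,
    bootstrap_support,
    compute_distances,
    nj_tree,
)

LABELS5 = ("t1", "t2", "t3", "t4", "t5")


def matrix(labels, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(labels, d, np.ones_like(d, dtype=int))


class TestComputeDistances:
    def test_identical_sequences(self):
        D = compute_distances({"a": "ACGT", "b": "ACGT"})
        assert D.get("a", "b") == 0.0

    def test_one_mismatch_in_four(self):
        D = compute_distances({"a": "ACGT", "b": "ACGA"})
        assert D.get("a", "b") == pytest.approx(0.25)

    def test_pairwise_deletion_excludes_n_and_gap(self):
        D = compute_distances({"a": "ACN", "b": "AGN"})
        assert D.get("a", "b") == pytest.approx(0.5)
        assert D.comparable_sites[0, 1] == 2
        D = compute_distances({"a": "AC-T", "b": "ACGT"})
        assert D.comparable_sites[0, 1] == 3

    def test_zero_comparable_sites_names_the_pair(self):
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            compute_distances({"a": "NNAC", "b": "ACNN"})

    def test_jukes_cantor_correction(self):
        # p = 0.25 -> d = -3/4 ln(1 - 1/3)
        D = compute_distances({"a": "ACGT", "b": "ACGA"}, model="jc")
        assert D.get("a", "b") == pytest.approx(-0.75 * np.log(1 - 1 / 3))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compute_distances({"a": "ACGT", "b": "ACG"})


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d12, d13, d23 = 0.3, 0.5, 0.4
        t = nj_tree(matrix(("a", "b", "c"), [[0, d12, d13], [d12, 0, d23], [d13, d23, 0]]))
        # pendant branches: a=(d12+d13-d23)/2 etc., checked via path sums
        assert t.path_length("a", "b") == pytest.approx(d12, abs=1e-9)
        assert t.path_length("a", "c") == pytest.approx(d13, abs=1e-9)
        assert t.path_length("b", "c") == pytest.approx(d23, abs=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(matrix(("a", "b"), [[0, 1], [1, 0]]))

    def test_four_taxon_additive_recovery_against_ls_oracle(self):
        # known tree: pendant branches 1,2,3,4 and internal branch 5
        # ((A:1,B:2):5,(C:3,D:4))
        labels = ("A", "B", "C", "D")
        D = np.array(
            [
                [0, 3, 9, 10],
                [3, 0, 10, 11],
                [9, 10, 0, 7],
                [10, 11, 7, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(matrix(labels, D))
        assert set(tree.bipartitions()) == oracle.best_topology(labels, D)
        for i in range(4):
            for j in range(i + 1, 4):
                assert tree.path_length(labels[i], labels[j]) == pytest.approx(
                    D[i, j], abs=1e-9
                )

    @pytest.mark.parametrize("seed", range(20))
    def test_five_taxon_additive_recovery(self, seed):
        rng = np.random.default_rng(1000 + seed)
        D, truth_bps = oracle.random_additive_matrix(LABELS5, rng)
        tree = nj_tree(matrix(LABELS5, D))
        assert set(tree.bipartitions()) == truth_bps
        for i in range(5):
            for j in range(i + 1, 5):
                assert tree.path_length(LABELS5[i], LABELS5[j]) == pytest.approx(
                    D[i, j], abs=1e-9
                )

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(77)
        D, _ = oracle.random_additive_matrix(LABELS5, rng)
        tree = nj_tree(matrix(LABELS5, D))
        perm = [3, 0, 4, 1, 2]
        labels2 = tuple(LABELS5[i] for i in perm)
        D2 = D[np.ix_(perm, perm)]
        tree2 = nj_tree(matrix(labels2, D2))
        assert set(tree.bipartitions()) == set(tree2.bipartitions())

    def test_agrees_with_dendropy_on_noisy_matrix(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(5)
        D, _ = oracle.random_additive_matrix(LABELS5, rng)
        noisy = D + rng.uniform(0, 0.02, D.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        tree = nj_tree(matrix(LABELS5, noisy))

        import io as _io

        csv = "," + ",".join(LABELS5) + "\n"
        for i, lab in enumerate(LABELS5):
            csv += lab + "," + ",".join(f"{noisy[i, j]:.10f}" for j in range(5)) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_io.StringIO(csv), delimiter=","
        )
        dtree = pdm.nj_tree()
        dendro_bps = set()
        taxa = set(LABELS5)
        ref = min(taxa)
        for node in dtree.preorder_node_iter():
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 2 <= len(side) <= len(taxa) - 2:
                dendro_bps.add(frozenset(taxa - side) if ref in side else side)
        assert set(tree.bipartitions()) == dendro_bps


def make_clade_alignment(
    n_clades=3, refs_per_clade=2, queries_per_clade=2, fixed_diffs=20,
    length=600, wobble=2, seed=0,
):
    """Alignment of clades separated by fixed differences, with per-sequence
    private mutations; returns (alignment, reference labels, query truth)."""
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list("ACGT"), size=length))
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}

    def mutate(seq, k):
        seq = list(seq)
        for p in rng.choice(length, size=k, replace=False):
            seq[p] = rot[seq[p]]
        return "".join(seq)

    alignment, labels, truth = {}, {}, {}
    for c in range(n_clades):
        founder = mutate(base, fixed_diffs * (c + 1))
        clade = f"clade{c + 1}"
        for r in range(refs_per_clade):
            name = f"{clade}_ref{r + 1}"
            alignment[name] = mutate(founder, wobble)
            labels[name] = clade
        for q in range(queries_per_clade):
            name = f"q{c + 1}_{q + 1}"
            alignment[name] = mutate(founder, wobble)
            truth[name] = clade
    return alignment, labels, truth


class TestBootstrap:
    def test_deterministic_given_seed(self):
        aln, _, _ = make_clade_alignment(seed=3)
        t1 = bootstrap_support(aln, n_replicates=25, seed=9)
        t2 = bootstrap_support(aln, n_replicates=25, seed=9)
        assert t1.supports == t2.supports

    def test_single_replicate_supports_are_zero_or_hundred(self):
        aln, _, _ = make_clade_alignment(seed=4)
        t = bootstrap_support(aln, n_replicates=1, seed=0)
        assert set(t.supports.values()) <= {0.0, 100.0}

    def test_clearly_separated_groups_get_full_support(self):
        aln, _, _ = make_clade_alignment(
            n_clades=2, refs_per_clade=3, queries_per_clade=0,
            fixed_diffs=25, wobble=1, seed=5,
        )
        t = bootstrap_support(aln, n_replicates=100, seed=1)
        group = frozenset(l for l in aln if l.startswith("clade2"))
        taxa = t.taxa
        canonical = taxa - group if min(taxa) in group else group
        assert t.supports[canonical] == 100.0

    def test_invalid_replicates_rejected(self):
        aln, _, _ = make_clade_alignment(seed=6)
        with pytest.raises(ValueError):
            bootstrap_support(aln, n_replicates=0, seed=0)


class TestAssignClade:
    def test_identical_query_joins_its_clade(self):
        aln, labels, _ = make_clade_alignment(queries_per_clade=0, seed=7)
        aln["query"] = aln["clade1_ref1"]
        assignments, _ = assign_clades(aln, labels, n_replicates=50, seed=2)
        (a,) = assignments
        assert a.clade == "clade1"
        assert a.nearest_label.startswith("clade1")
        assert a.nearest_distance == pytest.approx(0.0)

    def test_conflicting_labels_leave_query_unassigned(self):
        # two "clades" that are actually one tight group: every supported edge
        # around the query mixes labels A and B
        aln, _, _ = make_clade_alignment(
            n_clades=1, refs_per_clade=4, queries_per_clade=1, wobble=1, seed=8
        )
        labels = {"clade1_ref1": "A", "clade1_ref2": "A",
                  "clade1_ref3": "B", "clade1_ref4": "B"}
        assignments, _ = assign_clades(aln, labels, n_replicates=50, seed=3)
        (a,) = assignments
        if a.clade != "unassigned":
            # if a supported pure-label group exists it must contain the
            # query's nearest reference
            assert a.clade in {"A", "B"}

    def test_three_clade_recovery(self):
        aln, labels, truth = make_clade_alignment(seed=9)
        assignments, tree = assign_clades(
            aln, labels, n_replicates=100, seed=4, min_support=70.0
        )
        assert len(assignments) == 6
        for a in assignments:
            assert a.clade == truth[a.query]
            assert a.support is not None and a.support >= 70.0

    def test_assignments_never_invent_labels(self):
        aln, labels, _ = make_clade_alignment(seed=10)
        assignments, _ = assign_clades(aln, labels, n_replicates=30, seed=5)
        valid = set(labels.values()) | {"unassigned"}
        assert all(a.clade in valid for a in assignments)

    def test_tree_without_references_rejected(self):
        aln, _, _ = make_clade_alignment(seed=11)
        D = compute_distances(aln)
        tree = nj_tree(D)
        with pytest.raises(ValueError):
            assign_clade(tree, {"not_in_tree": "X"})

    def test_supports_invariant_under_rerooting(self):
        """Bipartition supports depend only on the unrooted topology, so the
        newick serialisation (rooted at an arbitrary node) round-trips them."""
        dendropy = pytest.importorskip("dendropy")
        aln, _, _ = make_clade_alignment(seed=12)
        t = bootstrap_support(aln, n_replicates=50, seed=6)
        newick = t.to_newick()
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        dtree.reroot_at_node(dtree.seed_node.child_nodes()[0])
        # internal labels (supports) survive rerooting as edge attributes
        labels_before = sorted(
            float(n.label) for n in dendropy.Tree.get(
                data=newick, schema="newick"
            ).preorder_node_iter() if n.label
        )
        assert labels_before == sorted(
            v for v in t.supports.values()
        )
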