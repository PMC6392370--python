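import itertools
import math

import dendropy
import numpy as np
import pytest

from barcodeval.distances import DistanceMatrix, distance_matrix
from barcodeval.seqio import tree_to_newick
from barcodeval.synth import RegionSimProfile, evolve_sequences
from barcodeval.trees import (
    _k80_pmatrix,
    fitch_score,
    k2p_log_likelihood,
    ml_search,
    mp_search,
    nj_tree,
    root_at_outgroup,
    species_monophyly,
)
from tests.conftest import aln_from, make_taxa, parse_tree


# ---------------------------------------------------------------------------
# oracles


def random_binary_tree(labels, rng, bl_range=(0.1, 1.0)):
    """Random unrooted binary topology with uniform branch lengths."""
    tns = dendropy.TaxonNamespace()
    nodes = [dendropy.Node(taxon=tns.require_taxon(label=l)) for l in labels]
    rng.shuffle(nodes)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = rng.uniform(*bl_range)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    center = dendropy.Node()
    for child in nodes:
        center.add_child(child)
        child.edge.length = rng.uniform(*bl_range)
    t = dendropy.Tree(taxon_namespace=tns)
    t.seed_node = center
    t.is_rooted = False
    return t


def patristic_matrix(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda x: x.label)
    labels = [t.label for t in taxa]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels, d)


def splits(tree):
    tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        key = min(below, tips - below, key=sorted)
        out[key] = out.get(key, 0.0) + (node.edge.length or 0.0)
    return out


def exhaustive_parsimony(tree, aln):
    """Minimum substitutions by brute force over internal state assignments."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = list(tree.leaf_node_iter())
    masks = {
        "A": {0}, "C": {1}, "G": {2}, "T": {3},
        "N": {0, 1, 2, 3}, "-": {0, 1, 2, 3},
        "R": {0, 2}, "Y": {1, 3},
    }
    total = 0
    for col in range(aln.length):
        best = math.inf
        leaf_states = {
            id(l): masks[aln[l.taxon.label].sequence[col]] for l in leaves
        }
        for assign in itertools.product(range(4), repeat=len(internals)):
            states = {id(n): {s} for n, s in zip(internals, assign)}
            states.update(leaf_states)
            cost = 0
            for node in tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                ps = next(iter(states[id(node.parent_node)]))
                # leaf may take its cheapest compatible state
                cost += 0 if ps in states[id(node)] else 1
            best = min(best, cost)
        total += best
    return total


# ---------------------------------------------------------------------------
# NJ


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]]),
        )
        t = nj_tree(d)
        lengths = {
            l.taxon.label: l.edge.length for l in t.leaf_node_iter()
        }
        # three-point equations: la = (ab+ac-bc)/2 etc.
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_exact_on_additive_four_taxon(self):
        truth = parse_tree("((a:0.1,b:0.2):0.15,(c:0.3,d:0.4):0.05);")
        truth.is_rooted = False
        rec = nj_tree(patristic_matrix(truth))
        assert splits(rec).keys() == splits(truth).keys()
        for k, v in splits(truth).items():
            assert splits(rec)[k] == pytest.approx(v, abs=1e-12)

    def test_exact_on_random_additive_matrices(self):
        rng = np.random.default_rng(11)
        for rep in range(10):
            truth = random_binary_tree([f"t{i}" for i in range(8)], rng)
            rec = nj_tree(patristic_matrix(truth))
            st, sr = splits(truth), splits(rec)
            assert st.keys() == sr.keys()
            for k in st:
                assert sr[k] == pytest.approx(st[k], abs=1e-9)

    def test_deterministic_tie_breaking(self):
        # four equidistant taxa: every Q is tied; lowest index pair joins
        d = DistanceMatrix(["a", "b", "c", "d"], np.ones((4, 4)) - np.eye(4))
        t1 = tree_to_newick(nj_tree(d))
        t2 = tree_to_newick(nj_tree(d))
        assert t1 == t2
        assert "(a:" in t1 or ",a:" in t1

    def test_undefined_pairs_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(DistanceMatrix(["a", "b", "c"], d, [("a", "b")]))


# ---------------------------------------------------------------------------
# parsimony


class TestFitch:
    def test_single_change_column(self):
        t = parse_tree("((a:1,b:1):1,(c:1,d:1):1);")
        aln = aln_from({"a": "A", "b": "A", "c": "G", "d": "G"})
        assert fitch_score(t, aln).value == 1

    def test_constant_and_missing_columns(self):
        t = parse_tree("((a:1,b:1):1,(c:1,d:1):1);")
        # missing data (gap/N) is compatible with any state at no cost
        aln = aln_from({"a": "AA-", "b": "AAN", "c": "AAA", "d": "AAA"})
        assert fitch_score(t, aln).value == 0

    def test_root_invariance(self):
        rng = np.random.default_rng(5)
        t = random_binary_tree(list("abcdef"), rng)
        aln = aln_from(
            {l: "".join(rng.choice(list("ACGT-"), size=12)) for l in "abcdef"}
        )
        base = fitch_score(t, aln).value
        for leaf in list(t.leaf_node_iter())[:3]:
            t2 = t.clone(depth=1)
            target = next(
                l for l in t2.leaf_node_iter()
                if l.taxon.label == leaf.taxon.label
            )
            t2.reroot_at_edge(target.edge, length1=0.1, length2=0.1)
            assert fitch_score(t2, aln).value == base

    def test_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(9)
        for rep in range(10):
            n = int(rng.integers(4, 7))
            labels = [f"x{i}" for i in range(n)]
            t = random_binary_tree(labels, rng)
            aln = aln_from(
                {
                    l: "".join(rng.choice(list("ACGTN-RY"), size=6,
                                          p=[.2, .2, .2, .2, .06, .06, .04, .04]))
                    for l in labels
                }
            )
            assert fitch_score(t, aln).value == exhaustive_parsimony(t, aln)

    def test_missing_tip_sequence(self):
        t = parse_tree("((a:1,b:1):1,(c:1,q:1):1);")
        with pytest.raises(ValueError, match="q"):
            fitch_score(t, aln_from({"a": "A", "b": "A", "c": "A", "d": "A"}))


class TestMPSearch:
    @pytest.fixture()
    def strong_signal(self):
        truth = parse_tree(
            "(((a:0.04,b:0.04):0.04,(c:0.04,d:0.04):0.04):0.02,"
            "((e:0.04,f:0.04):0.04,(g:0.04,h:0.04):0.04):0.02);"
        )
        truth.is_rooted = False
        prof = RegionSimProfile("sim", 2000, 0, 0.1, 0.0, kappa=2.0)
        aln, _ = evolve_sequences(truth, prof, seed=21)
        return truth, aln

    def test_recovers_true_topology(self, strong_signal):
        truth, aln = strong_signal
        tree, score = mp_search(aln, restarts=1, seed=0)
        assert splits(tree).keys() == splits(truth).keys()

    def test_monotone_in_restarts(self, strong_signal):
        _, aln = strong_signal
        s1 = mp_search(aln, restarts=1, seed=3)[1].value
        s5 = mp_search(aln, restarts=5, seed=3)[1].value
        assert s5 <= s1

    def test_four_taxa_equals_exhaustive(self):
        rng = np.random.default_rng(17)
        labels = list("abcd")
        aln = aln_from(
            {l: "".join(rng.choice(list("ACGT"), size=20)) for l in labels}
        )
        _, score = mp_search(aln, restarts=3, seed=0)
        best = min(
            fitch_score(parse_tree(nwk), aln).value
            for nwk in (
                "((a:1,b:1):1,(c:1,d:1):1);",
                "((a:1,c:1):1,(b:1,d:1):1);",
                "((a:1,d:1):1,(b:1,c:1):1);",
            )
        )
        assert score.value == best


# ---------------------------------------------------------------------------
# likelihood


class TestK80Likelihood:
    def test_pmatrix_rows_sum_to_one_and_match_expm(self):
        from scipy.linalg import expm

        kappa, t = 3.1, 0.37
        a, b = kappa / (kappa + 2), 1 / (kappa + 2)
        Q = np.full((4, 4), b)
        Q[0, 2] = Q[2, 0] = Q[1, 3] = Q[3, 1] = a
        np.fill_diagonal(Q, 0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        assert np.allclose(_k80_pmatrix(t, kappa), expm(Q * t), atol=1e-12)

    def test_star_tree_identical_sequences(self):
        t = parse_tree("(a:0,b:0,c:0);")
        L = 17
        aln = aln_from({l: "A" * L for l in "abc"})
        lnl = k2p_log_likelihood(t, aln, kappa=2.0).value
        assert lnl == pytest.approx(L * math.log(0.25), abs=1e-9)

    def test_two_tip_closed_form(self):
        t = parse_tree("(a:0.07,b:0.05);")
        aln = aln_from({"a": "ACGTACGTAA", "b": "ACGTGCTTAA"})
        lnl = k2p_log_likelihood(t, aln, kappa=1.7).value
        P = _k80_pmatrix(0.12, 1.7)  # reversibility: only the sum matters
        code = {"A": 0, "C": 1, "G": 2, "T": 3}
        expected = sum(
            math.log(0.25 * P[code[x], code[y]])
            for x, y in zip("ACGTACGTAA", "ACGTGCTTAA")
        )
        assert lnl == pytest.approx(expected, abs=1e-9)

    def test_rerooting_invariance(self):
        rng = np.random.default_rng(2)
        t = random_binary_tree(list("abcdef"), rng, bl_range=(0.01, 0.3))
        aln = aln_from(
            {l: "".join(rng.choice(list("ACGT"), size=60)) for l in "abcdef"}
        )
        base = k2p_log_likelihood(t, aln, 2.0).value
        t2 = t.clone(depth=1)
        leaf = next(t2.leaf_node_iter())
        t2.reroot_at_edge(leaf.edge, length1=leaf.edge.length / 2,
                          length2=leaf.edge.length / 2)
        assert k2p_log_likelihood(t2, aln, 2.0).value == pytest.approx(
            base, abs=1e-9
        )

    def test_pair_likelihood_maximized_at_k2p_distance(self):
        from scipy.optimize import minimize_scalar

        rng = np.random.default_rng(8)
        truth = parse_tree("(a:0.04,b:0.04);")
        prof = RegionSimProfile("sim", 3000, 0, 0.1, 0.0, kappa=2.0)
        aln, _ = evolve_sequences(truth, prof, seed=13)
        d_hat = distance_matrix(aln).get("a", "b")
        # profile the pair likelihood in the total path length; the K2P
        # distance estimate should be its argmax (it is the K80 pair MLE
        # jointly with kappa; use the kappa implied by the observed P/Q)
        from barcodeval.distances import pair_counts

        pc = pair_counts(aln["a"].sequence, aln["b"].sequence)

        def neg(params_t, kappa):
            t = parse_tree(f"(a:{params_t / 2},b:{params_t / 2});")
            return -k2p_log_likelihood(t, aln, kappa).value

        # optimize kappa at the analytic distance first
        ka = minimize_scalar(
            lambda k: neg(d_hat, k), bounds=(0.1, 50), method="bounded",
            options={"xatol": 1e-8},
        ).x
        res = minimize_scalar(
            lambda t: neg(t, ka), bounds=(1e-6, 1.0), method="bounded",
            options={"xatol": 1e-8},
        )
        assert res.x == pytest.approx(d_hat, abs=1e-4)


class TestMLSearch:
    def test_recovers_true_topology_and_improves_lnl(self):
        truth = parse_tree(
            "(((a:0.05,b:0.05):0.05,(c:0.05,d:0.05):0.05):0.02,"
            "((e:0.05,f:0.05):0.05,(g:0.05,h:0.05):0.05):0.02);"
        )
        truth.is_rooted = False
        prof = RegionSimProfile("sim", 1500, 0, 0.1, 0.0, kappa=2.0)
        aln, _ = evolve_sequences(truth, prof, seed=5)
        start = nj_tree(distance_matrix(aln))
        start_lnl = k2p_log_likelihood(start, aln, 2.0).value
        tree, score, kappa = ml_search(aln, seed=1)
        assert splits(tree).keys() == splits(truth).keys()
        assert score.value >= start_lnl
        assert 0.5 < kappa < 10


# ---------------------------------------------------------------------------
# rooting and monophyly


class TestRooting:
    def test_root_on_single_outgroup(self):
        t = parse_tree("((og1_1:1,(spA_1:1,spA_2:1):1):1,(spB_1:1,spB_2:1):1);")
        taxa = make_taxa({"spA": 2, "spB": 2}, outgroups=1)
        rooted = root_at_outgroup(t, taxa)
        children = rooted.seed_node.child_nodes()
        sides = [
            frozenset(l.taxon.label for l in c.leaf_iter()) for c in children
        ]
        assert frozenset(["og1_1"]) in sides

    def test_root_on_outgroup_clade_stem(self):
        t = parse_tree(
            "(((og1_1:1,og2_1:1):1,spA_1:1):1,(spA_2:1,spB_1:1):1,spB_2:1);"
        )
        taxa = make_taxa({"spA": 2, "spB": 2}, outgroups=2)
        rooted = root_at_outgroup(t, taxa)
        sides = [
            frozenset(l.taxon.label for l in c.leaf_iter())
            for c in rooted.seed_node.child_nodes()
        ]
        assert frozenset(["og1_1", "og2_1"]) in sides

    def test_non_monophyletic_outgroup_warns_and_roots(self, caplog):
        t = parse_tree(
            "((og1_1:1,spA_1:1):1,(og2_1:1,spA_2:1):1,(spB_1:1,spB_2:1):1);"
        )
        taxa = make_taxa({"spA": 2, "spB": 2}, outgroups=2)
        import logging

        with caplog.at_level(logging.WARNING, logger="barcodeval.trees"):
            rooted = root_at_outgroup(t, taxa)
        assert rooted.is_rooted
        assert any("separable" in r.message for r in caplog.records)

    def test_no_outgroup_tips_error(self):
        t = parse_tree("((spA_1:1,spA_2:1):1,(spB_1:1,spB_2:1):1);")
        with pytest.raises(ValueError, match="outgroup"):
            root_at_outgroup(t, make_taxa({"spA": 2, "spB": 2}))


class TestMonophyly:
    def test_both_pass(self):
        t = parse_tree("((spA_1:1,spA_2:1):1,(spB_1:1,spB_2:1):1);")
        t.is_rooted = True
        df = species_monophyly(t, make_taxa({"spA": 2, "spB": 2}))
        assert df["passes"].all()

    def test_interleaved_fail(self):
        t = parse_tree("((spA_1:1,spB_1:1):1,(spA_2:1,spB_2:1):1);")
        t.is_rooted = True
        df = species_monophyly(t, make_taxa({"spA": 2, "spB": 2}))
        assert not df["passes"].any()

    def test_singleton_not_evaluable_and_outgroup_ignored(self):
        t = parse_tree(
            "(og1_1:1,((spA_1:1,spA_2:1):1,spB_1:1):1);"
        )
        t.is_rooted = True
        taxa = make_taxa({"spA": 2, "spB": 1}, outgroups=1)
        df = species_monophyly(t, taxa).set_index("species")
        assert df.loc["spA", "passes"]
        assert not df.loc["spB", "evaluable"]
        assert "og1" not in df.index

    def test_unmapped_tip_error(self):
        t = parse_tree("((spA_1:1,spA_2:1):1,(zzz:1,spB_1:1):1);")
        with pytest.raises(ValueError, match="zzz"):
            species_monophyly(t, make_taxa({"spA": 2, "spB": 2}))

    def test_agrees_with_mrca_oracle_on_random_trees(self):
        rng = np.random.default_rng(23)
        species = {f"sp{c}": 4 for c in "ABCDE"}
        taxa = make_taxa(species)
        labels = [e.sequence_id for e in taxa.entries]
        for rep in range(20):
            t = random_binary_tree(labels, rng)
            t.is_rooted = True
            df = species_monophyly(t, taxa).set_index("species")
            for sp in species:
                tips = [f"{sp}_{i}" for i in range(1, 5)]
                mrca = t.mrca(taxon_labels=tips)
                oracle = (
                    sum(1 for _ in mrca.leaf_iter()) == len(tips)
                )
                assert df.loc[sp, "passes"] == oracle

    def test_rotation_invariance(self):
        t = parse_tree("((spA_1:1,spA_2:1):1,(spB_1:1,spB_2:1):1);")
        t.is_rooted = True
        rot = parse_tree("((spB_2:1,spB_1:1):1,(spA_2:1,spA_1:1):1);")
        rot.is_rooted = True
        taxa = make_taxa({"spA": 2, "spB": 2})
        assert species_monophyly(t, taxa).equals(species_monophyly(rot, taxa))
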