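"""Tree inference (NJ, MP, ML) and the tree-based identification criterion.

Neighbor-joining is the exact Saitou–Nei agglomeration and recovers
additive matrices perfectly. Parsimony and likelihood trees are found by
nearest-neighbor-interchange (NNI) hill-climbing from the NJ starting
topology, accepting strict improvements only, with seeded random-restart
sweep orders; this trades the black-box heuristics of desktop phylogenetics
suites for a deterministic, testable search. The likelihood model is the
equal-frequency Kimura 2-parameter (K80) model, matching the distance
model, with a single transition/transversion rate ratio kappa.

Trees are dendropy objects throughout, so newick I/O, rerooting and
bipartition machinery come for free.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from barcodeval.distances import DistanceMatrix, distance_matrix
from barcodeval.seqio import Alignment, TaxonMap

logger = logging.getLogger(__name__)

# state bitmasks over (A, C, G, T); gap and N are fully missing
_MASK = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001,
    "K": 0b1100, "M": 0b0011, "B": 0b1110, "D": 0b1101,
    "H": 0b1011, "V": 0b0111, "N": 0b1111, "-": 0b1111,
}


@dataclass(frozen=True)
class TreeScore:
    """Objective value of a tree: parsimony steps or log-likelihood (nats)."""

    kind: str  # "parsimony_steps" | "log_likelihood"
    value: float

    def __post_init__(self):
        if self.kind not in ("parsimony_steps", "log_likelihood"):
            raise ValueError(f"unknown score kind {self.kind!r}")
        if self.kind == "parsimony_steps" and self.value < 0:
            raise ValueError("parsimony steps cannot be negative")


# ---------------------------------------------------------------------------
# site-pattern compression


def compress_patterns(aln: Alignment) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Unique column patterns with multiplicities.

    Returns (tip id -> uint8 bitmask vector over patterns, pattern weights).
    """
    mat = np.zeros((len(aln), aln.length), dtype=np.uint8)
    for i, rec in enumerate(aln):
        mat[i] = [_MASK[c] for c in rec.sequence]
    patterns, weights = np.unique(mat, axis=1, return_counts=True)
    masks = {rec.id: patterns[i] for i, rec in enumerate(aln)}
    return masks, weights.astype(float)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(m: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Joins the Q-minimizing pair at each step; exact ties resolve to the
    lowest (row, column) index pair in the current agglomeration order, so
    results are stable across runs. Negative branch-length estimates are
    clamped to zero. The result is unrooted (seed node of degree 3).
    """
    if len(m.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    if np.isnan(m.d).any():
        raise ValueError(
            "distance matrix contains undefined pairs; exclude or impute "
            "them before tree building"
        )
    tns = dendropy.TaxonNamespace()
    nodes = [
        dendropy.Node(taxon=tns.require_taxon(label=lab)) for lab in m.labels
    ]
    D = m.d.astype(float).copy()

    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)  # row-major: lowest pair
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        parent = dendropy.Node()
        ci, cj = nodes[i], nodes[j]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = max(li, 0.0)
        cj.edge.length = max(lj, 0.0)
        dnew = 0.5 * (D[i] + D[j] - dij)
        keep = [x for x in range(k) if x not in (i, j)]
        D = np.pad(D[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        D[-1, :-1] = D[:-1, -1] = dnew[keep]
        nodes = [nodes[x] for x in keep] + [parent]

    # final three-point solve: exact lengths for the remaining star
    (x, y, z) = nodes
    dxy, dxz, dyz = D[0, 1], D[0, 2], D[1, 2]
    center = dendropy.Node()
    for node, length in (
        (x, (dxy + dxz - dyz) / 2.0),
        (y, (dxy + dyz - dxz) / 2.0),
        (z, (dxz + dyz - dxy) / 2.0),
    ):
        center.add_child(node)
        node.edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# parsimony


def _fitch_cost(tree: dendropy.Tree, masks: dict[str, np.ndarray],
                weights: np.ndarray) -> float:
    n_pat = len(weights)
    changes = np.zeros(n_pat)
    store: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            store[id(node)] = masks[node.taxon.label]
            continue
        acc = None
        for child in node.child_nodes():
            cm = store.pop(id(child))
            if acc is None:
                acc = cm
            else:
                inter = acc & cm
                empty = inter == 0
                acc = np.where(empty, acc | cm, inter)
                changes += empty
        store[id(node)] = acc
    return float(changes @ weights)


def fitch_score(t: dendropy.Tree, aln: Alignment) -> TreeScore:
    """Fitch small-parsimony score (minimum substitutions over all columns).

    Gaps, N and ambiguity codes are missing data: a tip may take any state
    compatible with its code at no cost. The score is a property of the
    unrooted topology — independent of root placement. Polytomies are folded
    child-by-child, i.e. scored as an arbitrary resolution.
    """
    tips = {leaf.taxon.label for leaf in t.leaf_node_iter()}
    missing = tips - set(aln.ids)
    if missing:
        raise ValueError(f"tree tips without sequences: {sorted(missing)}")
    masks, weights = compress_patterns(aln)
    return TreeScore("parsimony_steps", _fitch_cost(t, masks, weights))


# ---------------------------------------------------------------------------
# NNI machinery (operates on the unrooted representation: seed of degree 3)


def _nni_edges(tree: dendropy.Tree) -> list[dendropy.Node]:
    """Internal edges as their child nodes (both endpoints internal)."""
    return [
        node
        for node in tree.preorder_node_iter()
        if node.parent_node is not None and not node.is_leaf()
    ]


def _nni_swap(v: dendropy.Node, child_index: int) -> tuple:
    """Swap child ``child_index`` of v with one sibling subtree of v.

    Returns a token that :func:`_nni_undo` uses to revert the move.
    """
    u = v.parent_node
    s = next(c for c in u.child_nodes() if c is not v)
    c = v.child_nodes()[child_index]
    u.remove_child(s, suppress_unifurcations=False)
    v.remove_child(c, suppress_unifurcations=False)
    u.add_child(c)
    v.add_child(s)
    return (u, v, s, c)


def _nni_undo(token: tuple) -> None:
    u, v, s, c = token
    u.remove_child(c, suppress_unifurcations=False)
    v.remove_child(s, suppress_unifurcations=False)
    u.add_child(s)
    v.add_child(c)


def _hill_climb(tree: dendropy.Tree, score_fn, rng: np.random.Generator | None,
                max_sweeps: int = 60) -> float:
    """Greedy NNI: accept strictly improving moves until a sweep is quiet."""
    best = score_fn(tree)
    for _ in range(max_sweeps):
        improved = False
        edges = _nni_edges(tree)
        if rng is not None:
            rng.shuffle(edges)
        for v in edges:
            if v.parent_node is None or v.is_leaf():
                continue  # may have been restructured earlier in the sweep
            for ci in range(len(v.child_nodes())):
                token = _nni_swap(v, ci)
                cand = score_fn(tree)
                if cand < best - 1e-12:
                    best = cand
                    improved = True
                else:
                    _nni_undo(token)
        if not improved:
            break
    return best


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return tree.clone(depth=1)


def _parsimony_start_tree(aln: Alignment) -> dendropy.Tree:
    """NJ start topology; falls back to p-distances if K2P is saturated."""
    m = distance_matrix(aln)
    if np.isnan(m.d).any():
        from barcodeval.distances import encode_alignment

        codes = encode_alignment(aln)
        valid = codes >= 0
        n = len(aln)
        p = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mask = valid[i] & valid[j]
                tot = int(mask.sum())
                p[i, j] = p[j, i] = (
                    float((mask & (codes[i] != codes[j])).sum()) / tot
                    if tot else 0.75
                )
        m = DistanceMatrix(aln.ids, p)
    return nj_tree(m)


def mp_search(aln: Alignment, restarts: int = 1, seed: int = 0
              ) -> tuple[dendropy.Tree, TreeScore]:
    """Maximum-parsimony search: NJ start + NNI hill-climbing.

    ``restarts`` independent hill-climbs are run; the first uses the
    canonical edge order, later ones seeded random sweep orders and random
    initial NNI perturbations. The best-scoring tree is returned; the score
    is monotonically non-increasing in ``restarts``.
    """
    if len(aln) < 4:
        raise ValueError("parsimony search needs at least 4 sequences")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    masks, weights = compress_patterns(aln)
    start = _parsimony_start_tree(aln)

    def score_fn(t):
        return _fitch_cost(t, masks, weights)

    best_tree, best_score = None, math.inf
    rng = np.random.default_rng(seed)
    for r in range(restarts):
        tree = _clone(start)
        sweep_rng = None
        if r > 0:
            sweep_rng = np.random.default_rng(rng.integers(2**31))
            for _ in range(r):  # light perturbation away from the NJ start
                edges = _nni_edges(tree)
                if not edges:
                    break
                v = edges[int(sweep_rng.integers(len(edges)))]
                _nni_swap(v, int(sweep_rng.integers(2)))
        sc = _hill_climb(tree, score_fn, sweep_rng)
        if sc < best_score:
            best_tree, best_score = tree, sc
    return best_tree, TreeScore("parsimony_steps", best_score)


# ---------------------------------------------------------------------------
# likelihood under K80


def _k80_pmatrix(t: float, kappa: float) -> np.ndarray:
    """K80 transition-probability matrix at branch length t (subs/site).

    The rate matrix is normalized to one expected substitution per site per
    unit length: transition rate alpha = kappa/(kappa+2), each transversion
    rate beta = 1/(kappa+2).
    """
    alpha = kappa / (kappa + 2.0)
    beta = 1.0 / (kappa + 2.0)
    e1 = math.exp(-2.0 * (alpha + beta) * t)
    e2 = math.exp(-4.0 * beta * t)
    p_same = 0.25 + 0.25 * e2 + 0.5 * e1
    p_ts = 0.25 + 0.25 * e2 - 0.5 * e1
    p_tv = 0.25 - 0.25 * e2
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    P[0, 2] = P[2, 0] = P[1, 3] = P[3, 1] = p_ts  # A<->G, C<->T
    return P


_TIP_PARTIALS = np.array(
    [[(m >> s) & 1 for s in range(4)] for m in range(16)], dtype=float
)


def _pruning_lnl(tree: dendropy.Tree, masks: dict[str, np.ndarray],
                 weights: np.ndarray, kappa: float) -> float:
    store: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            part = _TIP_PARTIALS[masks[node.taxon.label]]
        else:
            part = None
            for child in node.child_nodes():
                cp = store.pop(id(child))
                t = child.edge.length or 0.0
                lifted = cp @ _k80_pmatrix(t, kappa).T
                part = lifted if part is None else part * lifted
        store[id(node)] = part
    root_part = store[id(tree.seed_node)]
    site = 0.25 * root_part.sum(axis=1)
    if np.any(site <= 0) or not np.all(np.isfinite(site)):
        raise ValueError("non-finite site likelihood")
    return float(weights @ np.log(site))


def k2p_log_likelihood(t: dendropy.Tree, aln: Alignment,
                       kappa: float = 2.0) -> TreeScore:
    """Log-likelihood (nats) of the alignment on the tree under K80.

    Felsenstein pruning with stationary frequencies 1/4; gaps/N contribute a
    partial likelihood of 1 for every state. The model is time-reversible,
    so the value is invariant to root placement.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    for node in t.preorder_node_iter():
        if node.edge.length is not None and node.edge.length < 0:
            raise ValueError("negative branch length")
    masks, weights = compress_patterns(aln)
    return TreeScore("log_likelihood", _pruning_lnl(t, masks, weights, kappa))


_BL_BOUNDS = (1e-9, 10.0)
_KAPPA_BOUNDS = (0.05, 100.0)


def _optimize_branches(tree, masks, weights, kappa) -> float:
    lnl = -math.inf
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            continue

        def neg(t, node=node):
            node.edge.length = t
            return -_pruning_lnl(tree, masks, weights, kappa)

        res = minimize_scalar(
            neg, bounds=_BL_BOUNDS, method="bounded",
            options={"xatol": 1e-6},
        )
        node.edge.length = float(res.x)
        lnl = -res.fun
    return lnl


def ml_search(aln: Alignment, seed: int = 0, kappa0: float = 2.0,
              max_cycles: int = 20) -> tuple[dendropy.Tree, TreeScore, float]:
    """Maximum-likelihood tree search under K80.

    Starts from the NJ topology and branch lengths, then cycles (i) kappa
    optimization by bounded scalar search, (ii) per-branch length
    optimization (tolerance 1e-6), (iii) an NNI sweep accepting strict
    log-likelihood improvements, until a full cycle gains < 1e-4 nats.
    Returns (tree, score, kappa estimate); the final likelihood can never be
    below the starting tree's.
    """
    if len(aln) < 4:
        raise ValueError("likelihood search needs at least 4 sequences")
    masks, weights = compress_patterns(aln)
    tree = _parsimony_start_tree(aln)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and (node.edge.length or 0.0) <= 0:
            node.edge.length = _BL_BOUNDS[0]
    kappa = kappa0
    rng = np.random.default_rng(seed)
    lnl = _pruning_lnl(tree, masks, weights, kappa)
    for _ in range(max_cycles):
        prev = lnl

        def neg_kappa(k):
            return -_pruning_lnl(tree, masks, weights, k)

        res = minimize_scalar(
            neg_kappa, bounds=_KAPPA_BOUNDS, method="bounded",
            options={"xatol": 1e-6},
        )
        kappa = float(res.x)
        lnl = _optimize_branches(tree, masks, weights, kappa)

        def score_fn(t):
            return -_pruning_lnl(t, masks, weights, kappa)

        lnl = -_hill_climb(tree, score_fn, rng, max_sweeps=5)
        if lnl - prev < 1e-4:
            break
    return tree, TreeScore("log_likelihood", lnl), kappa


# ---------------------------------------------------------------------------
# rooting and monophyly


def _leafsets(tree: dendropy.Tree) -> dict[int, frozenset[str]]:
    sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[id(node)] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= sets[id(child)]
            sets[id(node)] = frozenset(acc)
    return sets


def root_at_outgroup(t: dendropy.Tree, taxa: TaxonMap) -> dendropy.Tree:
    """Root on the branch separating outgroup tips from ingroup tips.

    If no branch achieves a perfect separation (non-monophyletic outgroups),
    the branch maximizing the separation count is used and a warning logged.
    """
    t = _clone(t)
    tips = {leaf.taxon.label for leaf in t.leaf_node_iter()}
    og = {lab for lab in tips if lab in taxa and taxa.is_outgroup(lab)}
    if not og:
        raise ValueError("no outgroup tips present in the tree")
    ingroup = tips - og
    sets = _leafsets(t)
    best_node, best_score = None, -1
    perfect = len(og) + len(ingroup)
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = sets[id(node)]
        score = max(
            len(below & og) + len(ingroup - below),   # outgroup below
            len(below & ingroup) + len(og - below),   # outgroup above
        )
        if score > best_score:
            best_node, best_score = node, score
    if best_score < perfect:
        logger.warning(
            "outgroup is not separable by a single branch; rooting at the "
            "best-separating branch (%d/%d tips on the right side)",
            best_score, perfect,
        )
    edge = best_node.edge
    half = (edge.length or 0.0) / 2.0
    t.reroot_at_edge(edge, length1=half, length2=half,
                     update_bipartitions=False)
    t.is_rooted = True
    return t


def species_monophyly(t: dendropy.Tree, taxa: TaxonMap) -> pd.DataFrame:
    """Per-species conspecific-monophyly outcome on a (rooted) tree.

    A species passes when some node's descendant tip set equals exactly the
    species' tip set; on unrooted input the complement side of a branch
    counts too. Species sampled once are flagged not evaluable; outgroup
    tips are ignored.
    """
    tips = {leaf.taxon.label for leaf in t.leaf_node_iter()}
    unmapped = [lab for lab in tips if lab not in taxa]
    if unmapped:
        raise ValueError(f"tree tips missing from taxon map: {sorted(unmapped)}")
    sets = _leafsets(t)
    clusters = set(sets.values())
    og = {lab for lab in tips if taxa.is_outgroup(lab)}
    non_og_tips = tips - og
    rows = []
    members = taxa.restricted_to(tips).species_members(include_outgroups=False)
    for species in sorted(members):
        sp_tips = frozenset(members[species])
        evaluable = len(sp_tips) >= 2
        passes = False
        if evaluable:
            passes = sp_tips in clusters
            if not passes and not t.is_rooted:
                passes = frozenset(tips - sp_tips) in clusters
        rows.append(
            {
                "species": species,
                "n_tips": len(sp_tips),
                "evaluable": evaluable,
                "passes": bool(passes),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# optional bootstrap annotation


def bootstrap_support(aln: Alignment, n_replicates: int = 100, seed: int = 0
                      ) -> dendropy.Tree:
    """NJ tree annotated with column-resampling bootstrap support (percent).

    Support is informational only — the identification criterion depends on
    clade membership, never on support values.
    """
    rng = np.random.default_rng(seed)
    base = nj_tree(distance_matrix(aln))
    base.encode_bipartitions()
    counts: dict = {}
    cols = [
        ["".join(rec.sequence[j] for j in idx) for rec in aln]
        for idx in (
            rng.integers(0, aln.length, size=aln.length)
            for _ in range(n_replicates)
        )
    ]
    from barcodeval.seqio import SequenceRecord

    for rows in cols:
        rep = Alignment(
            [SequenceRecord(rec.id, s) for rec, s in zip(aln.records, rows)]
        )
        try:
            rep_tree = nj_tree(distance_matrix(rep))
        except ValueError:
            continue
        rep_tree.migrate_taxon_namespace(base.taxon_namespace)
        rep_tree.encode_bipartitions()
        for bip in rep_tree.bipartition_encoding:
            counts[bip.split_bitmask] = counts.get(bip.split_bitmask, 0) + 1
    for edge in base.preorder_edge_iter():
        if edge.bipartition is None or edge.head_node.is_leaf():
            continue
        n = counts.get(edge.bipartition.split_bitmask, 0)
        edge.head_node.label = str(round(100.0 * n / n_replicates))
    return base
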