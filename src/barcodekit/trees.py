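"""Phylogenetic trees for barcode evaluation.

Distance side: Saitou–Nei neighbour joining on the K2P matrix (negative
branch lengths clamped to zero), delegated to scikit-bio and returned as a
dendropy tree.  Character side: equal-weights Fitch parsimony with exact
branch-and-bound search for small taxon sets and random-addition + TBR
hill-climbing otherwise, with tree length and the homoplasy indices

    CI = M / L        (consistency index)
    RI = (G - L) / (G - M)   (retention index)
    RC = CI * RI      (rescaled consistency index)

where per character m = (distinct observed states - 1), g = (taxa with data -
frequency of the commonest state), and L is the realised tree length.  Gaps
and ambiguity codes are treated as missing data (no cost).

Strict consensus, column-resampling bootstrap supports and species-monophyly
tests operate on dendropy trees throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np
import skbio

from .distances import DistanceMatrix, distance_matrix
from .seqio import LocusAlignment

__all__ = [
    "ParsimonyResult",
    "nj_tree",
    "fitch_length",
    "mp_search",
    "consistency_indices",
    "strict_consensus",
    "bootstrap_support",
    "is_monophyletic",
]

_STATE_MASK = {"A": 1, "C": 2, "G": 4, "T": 8}
_MISSING = 15  # gaps/ambiguity: full state set, no cost


@dataclass
class ParsimonyResult:
    """Outcome of a maximum-parsimony search."""

    best_trees: list[dendropy.Tree]
    length: int
    ci: float
    ri: float
    rc: float
    ci_informative: float
    ri_informative: float
    rc_informative: float
    n_characters: int
    n_informative: int
    strategy: str

    @property
    def consensus(self) -> dendropy.Tree:
        return strict_consensus(self.best_trees)


# ---------------------------------------------------------------------------
# character encoding

def _encode(aln: LocusAlignment) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Alignment -> (pattern matrix, weights, taxon ids).

    Columns are compressed to unique site patterns; the matrix holds state
    bitmasks of shape (n_taxa, n_patterns).
    """
    ids = aln.ids
    n = len(ids)
    cols = np.empty((aln.length, n), dtype=np.uint8)
    for i, rec in enumerate(aln.records):
        cols[:, i] = [_STATE_MASK.get(c, _MISSING) for c in rec.seq]
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    return patterns.T.copy(), counts.astype(np.int64), ids


def _pattern_min_steps(patterns: np.ndarray) -> np.ndarray:
    """Per-pattern minimum steps m = distinct unambiguous states - 1."""
    present = np.zeros(patterns.shape[1], dtype=np.int64)
    for mask in (1, 2, 4, 8):
        present += np.any((patterns == mask), axis=0)
    return np.maximum(present - 1, 0)


def _pattern_max_steps(patterns: np.ndarray) -> np.ndarray:
    """Per-pattern star-tree (maximum) steps g = n_with_data - max state freq."""
    freqs = np.stack(
        [np.sum(patterns == mask, axis=0) for mask in (1, 2, 4, 8)]
    )
    with_data = freqs.sum(axis=0)
    gmax = np.where(with_data > 0, with_data - freqs.max(axis=0), 0)
    return gmax


def _pattern_informative(patterns: np.ndarray) -> np.ndarray:
    freqs = np.stack(
        [np.sum(patterns == mask, axis=0) for mask in (1, 2, 4, 8)]
    )
    return (freqs >= 2).sum(axis=0) >= 2


# ---------------------------------------------------------------------------
# unrooted tree scaffolding for search (adjacency over integer nodes; leaves
# are 0..n-1, internal nodes count upward)

def _postorder(adj: dict[int, list[int]], root: int) -> list[tuple[int, int]]:
    """(node, parent) pairs in postorder from an arbitrary root."""
    order = []
    stack = [(root, -1)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    return order[::-1]


def _fitch_score(
    adj: dict[int, list[int]],
    patterns: np.ndarray,
    weights: np.ndarray,
    per_pattern: bool = False,
):
    """Fitch length of an unrooted tree over all site patterns at once."""
    # root at leaf 0 so every internal node has exactly two children
    root = 0 if 0 in adj else next(iter(adj))
    steps = np.zeros(patterns.shape[1], dtype=np.int64)
    states: dict[int, np.ndarray] = {}
    for node, parent in _postorder(adj, root):
        children = [nb for nb in adj[node] if nb != parent]
        if not children:
            states[node] = patterns[node]
            continue
        acc = None
        for ch in children:
            s = states.pop(ch)
            if acc is None:
                acc = s
                continue
            inter = acc & s
            union = acc | s
            empty = inter == 0
            steps += empty
            acc = np.where(empty, union, inter)
        if node < patterns.shape[0]:  # rooted at a leaf: include its state
            inter = acc & patterns[node]
            empty = inter == 0
            steps += empty
            acc = np.where(empty, acc | patterns[node], inter)
        states[node] = acc
    if per_pattern:
        return steps
    return int(np.dot(steps, weights))


def _edges(adj: dict[int, list[int]]) -> list[tuple[int, int]]:
    return [(u, v) for u in adj for v in adj[u] if u < v]


def _insert_on_edge(
    adj: dict[int, list[int]], edge: tuple[int, int], leaf: int, new_node: int
) -> None:
    u, v = edge
    adj[u].remove(v)
    adj[v].remove(u)
    adj[new_node] = [u, v, leaf]
    adj[u].append(new_node)
    adj[v].append(new_node)
    adj[leaf] = [new_node]


def _remove_leaf(adj: dict[int, list[int]], leaf: int) -> None:
    hub = adj.pop(leaf)[0]
    nbs = [nb for nb in adj.pop(hub) if nb != leaf]
    u, v = nbs
    adj[u] = [x if x != hub else v for x in adj[u]]
    adj[v] = [x if x != hub else u for x in adj[v]]


def _copy(adj: dict[int, list[int]]) -> dict[int, list[int]]:
    return {k: list(v) for k, v in adj.items()}


def _bipartitions(adj: dict[int, list[int]], n_leaves: int) -> frozenset:
    """Non-trivial leaf bipartitions, each as the frozenset not containing leaf 0."""
    out = set()
    for u, v in _edges(adj):
        # leaves on v's side when edge (u,v) removed
        side = set()
        stack = [(v, u)]
        while stack:
            node, parent = stack.pop()
            if node < n_leaves:
                side.add(node)
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node))
        if 0 in side:
            side = set(range(n_leaves)) - side
        if 1 < len(side) < n_leaves - 1:
            out.add(frozenset(side))
    return frozenset(out)


def _adj_to_newick(adj: dict[int, list[int]], ids: Sequence[str]) -> str:
    n = len(ids)
    root = adj[0][0]  # internal node adjacent to leaf 0

    def sub(node: int, parent: int) -> str:
        if node < n:
            return ids[node].replace(" ", "_")
        parts = [sub(nb, node) for nb in adj[node] if nb != parent]
        return "(" + ",".join(parts) + ")"

    parts = [sub(nb, root) for nb in adj[root]]
    return "(" + ",".join(parts) + ");"


def _adj_to_tree(
    adj: dict[int, list[int]],
    ids: Sequence[str],
    taxon_namespace: dendropy.TaxonNamespace,
) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=_adj_to_newick(adj, ids),
        schema="newick",
        taxon_namespace=taxon_namespace,
        preserve_underscores=True,
    )


def _tree_to_adj(
    tree: dendropy.Tree, ids: Sequence[str]
) -> dict[int, list[int]]:
    """Dendropy tree -> adjacency with leaves renumbered per ``ids``."""
    index = {name: i for i, name in enumerate(ids)}
    tree = tree.clone(depth=1)
    counter = itertools.count(len(ids))
    node_id: dict = {}
    adj: dict[int, list[int]] = {}

    def nid(nd) -> int:
        if nd not in node_id:
            if nd.is_leaf():
                label = nd.taxon.label.replace(" ", "_")
                if label not in index:
                    label = nd.taxon.label
                node_id[nd] = index[label]
            else:
                node_id[nd] = next(counter)
        return node_id[nd]

    for edge in tree.preorder_edge_iter():
        if edge.head_node is None or edge.tail_node is None:
            continue
        a, b = nid(edge.tail_node), nid(edge.head_node)
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    # suppress degree-2 nodes (rooted seed node)
    for node in [k for k, v in adj.items() if len(v) == 2]:
        u, v = adj.pop(node)
        adj[u] = [x if x != node else v for x in adj[u]]
        adj[v] = [x if x != node else u for x in adj[v]]
    return adj


# ---------------------------------------------------------------------------
# public operations

def fitch_length(tree: dendropy.Tree, aln: LocusAlignment) -> int:
    """Fitch small-parsimony length of ``tree`` on ``aln``.

    Gaps and ambiguity codes are missing data.  The score is independent of
    rooting.
    """
    patterns, weights, ids = _encode(aln)
    labels = {
        lf.taxon.label.replace(" ", "_") for lf in tree.leaf_node_iter()
    }
    expected = {i.replace(" ", "_") for i in ids}
    if labels != expected:
        raise ValueError(
            f"taxa mismatch: tree has {sorted(labels)}, alignment has "
            f"{sorted(expected)}"
        )
    adj = _tree_to_adj(tree, [i.replace(" ", "_") for i in ids])
    return _fitch_score(adj, patterns, weights)


def _greedy_addition(
    order: Sequence[int],
    patterns: np.ndarray,
    weights: np.ndarray,
    n_leaves: int,
) -> dict[int, list[int]]:
    a, b, c = order[0], order[1], order[2]
    hub = n_leaves
    adj = {hub: [a, b, c], a: [hub], b: [hub], c: [hub]}
    next_internal = n_leaves + 1
    for leaf in order[3:]:
        best_edge, best_len = None, None
        for edge in _edges(adj):
            _insert_on_edge(adj, edge, leaf, next_internal)
            ln = _fitch_score(adj, patterns, weights)
            _remove_leaf(adj, leaf)
            if best_len is None or ln < best_len:
                best_edge, best_len = edge, ln
        _insert_on_edge(adj, best_edge, leaf, next_internal)
        next_internal += 1
    return adj


def _tbr_neighbors(adj: dict[int, list[int]], n_leaves: int):
    """Yield trees reachable by one tree-bisection-reconnection move."""
    for u, v in _edges(adj):
        work = _copy(adj)
        work[u].remove(v)
        work[v].remove(u)

        def component(start: int) -> list[int]:
            seen = {start}
            stack = [start]
            while stack:
                node = stack.pop()
                for nb in work[node]:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            return list(seen)

        def suppress(node: int) -> None:
            if node in work and len(work[node]) == 2:
                x, y = work[node]
                del work[node]
                work[x] = [z if z != node else y for z in work[x]]
                work[y] = [z if z != node else x for z in work[y]]

        comp_u = component(u)
        comp_v = component(v)
        # a single-leaf component is a leaf prune + regraft; both singleton
        # is impossible for n >= 4
        su, sv = u, v
        suppress(u)
        suppress(v)
        edges_u = [(a, b) for a in comp_u if a in work for b in work[a] if a < b]
        edges_v = [(a, b) for a in comp_v if a in work for b in work[a] if a < b]
        cand_u = edges_u if edges_u else [None]
        cand_v = edges_v if edges_v else [None]
        spare = [n for n in (su, sv) if n not in work]
        for eu in cand_u:
            for ev in cand_v:
                t = {k: list(vv) for k, vv in work.items()}
                fresh = iter(spare + [max(t) + 10, max(t) + 11])
                # attachment point in each component
                def attach(component_nodes, edge, t=t, fresh=fresh):
                    if edge is None:  # component is a single node or leaf edge
                        # find its sole free node: a node of degree <3 is fine;
                        # for a leaf-only component use the leaf itself
                        nodes = [n for n in component_nodes if n in t]
                        return nodes[0] if nodes else component_nodes[0]
                    a, b = edge
                    mid = next(fresh)
                    t[a] = [z if z != b else mid for z in t[a]]
                    t[b] = [z if z != a else mid for z in t[b]]
                    t[mid] = [a, b]
                    return mid

                pu = attach(comp_u, eu)
                pv = attach(comp_v, ev)
                for n in (pu, pv):
                    t.setdefault(n, [])
                t[pu].append(pv)
                t[pv].append(pu)
                yield t


def mp_search(
    aln: LocusAlignment,
    strategy: str = "auto",
    seed: int | None = None,
    max_trees: int = 100,
    replicates: int = 10,
    force: bool = False,
) -> ParsimonyResult:
    """Maximum-parsimony tree search.

    ``bnb`` is exact branch-and-bound (default for <= 12 taxa; refused above
    16 without ``force``); ``hillclimb`` runs ``replicates`` random-addition
    starts each followed by TBR branch swapping to a local optimum.  All
    equally best trees (up to ``max_trees``, deduplicated by bipartition set)
    are retained.
    """
    n = len(aln.records)
    if n < 4:
        raise ValueError("need at least 4 taxa for a parsimony search")
    if strategy == "auto":
        strategy = "bnb" if n <= 12 else "hillclimb"
    if strategy == "bnb" and n > 16 and not force:
        raise ValueError(
            f"branch-and-bound on {n} taxa is infeasible; pass force=True or "
            "use strategy='hillclimb'"
        )
    patterns, weights, ids = _encode(aln)
    rng = np.random.default_rng(seed)

    best_len = math.inf
    best: list[dict[int, list[int]]] = []
    seen: set[frozenset] = set()

    def record(adj: dict[int, list[int]], ln: int) -> None:
        nonlocal best_len
        if ln < best_len:
            best_len = ln
            best.clear()
            seen.clear()
        if ln == best_len and len(best) < max_trees:
            bp = _bipartitions(adj, n)
            if bp not in seen:
                seen.add(bp)
                best.append(_copy(adj))

    if strategy == "bnb":
        # upper bound from one greedy addition
        ub_adj = _greedy_addition(list(range(n)), patterns, weights, n)
        record(ub_adj, _fitch_score(ub_adj, patterns, weights))

        hub = n
        base = {hub: [0, 1, 2], 0: [hub], 1: [hub], 2: [hub]}

        def grow(adj: dict[int, list[int]], next_leaf: int, next_internal: int):
            if next_leaf == n:
                record(adj, _fitch_score(adj, patterns, weights))
                return
            for edge in list(_edges(adj)):
                _insert_on_edge(adj, edge, next_leaf, next_internal)
                ln = _fitch_score(adj, patterns, weights)
                if ln <= best_len:  # length never decreases as taxa are added
                    grow(adj, next_leaf + 1, next_internal + 1)
                _remove_leaf(adj, next_leaf)

        grow(base, 3, n + 1)
    elif strategy == "hillclimb":
        for _rep in range(replicates):
            order = list(rng.permutation(n))
            adj = _greedy_addition(order, patterns, weights, n)
            ln = _fitch_score(adj, patterns, weights)
            improved = True
            while improved:
                improved = False
                for cand in _tbr_neighbors(adj, n):
                    cl = _fitch_score(cand, patterns, weights)
                    if cl < ln:
                        adj, ln = cand, cl
                        improved = True
                        break
            record(adj, ln)
            # collect equal-length TBR neighbours of the local optimum
            if ln == best_len:
                for cand in _tbr_neighbors(adj, n):
                    if len(best) >= max_trees:
                        break
                    if _fitch_score(cand, patterns, weights) == best_len:
                        record(cand, best_len)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    tns = dendropy.TaxonNamespace([i.replace(" ", "_") for i in ids])
    trees = [_adj_to_tree(adj, ids, tns) for adj in best]
    m = _pattern_min_steps(patterns)
    g = _pattern_max_steps(patterns)
    info = _pattern_informative(patterns)
    per_pat = _fitch_score(best[0], patterns, weights, per_pattern=True)
    ci, ri, rc = _indices(m, g, per_pat, weights, np.ones_like(info, dtype=bool))
    cii, rii, rci = _indices(m, g, per_pat, weights, info)
    return ParsimonyResult(
        best_trees=trees,
        length=int(best_len),
        ci=ci,
        ri=ri,
        rc=rc,
        ci_informative=cii,
        ri_informative=rii,
        rc_informative=rci,
        n_characters=int(weights.sum()),
        n_informative=int(weights[info].sum()),
        strategy=strategy,
    )


def _indices(m, g, l, weights, mask) -> tuple[float, float, float]:
    M = float(np.dot(m[mask], weights[mask]))
    G = float(np.dot(g[mask], weights[mask]))
    L = float(np.dot(l[mask], weights[mask]))
    if L == 0 or G == M:
        return float("nan"), float("nan"), float("nan")
    ci = M / L
    ri = (G - L) / (G - M)
    return ci, ri, ci * ri


def consistency_indices(
    tree: dendropy.Tree, aln: LocusAlignment, informative_only: bool = False
) -> tuple[float, float, float]:
    """(CI, RI, RC) of a tree on an alignment.

    ``informative_only`` restricts the sums to parsimony-informative
    characters (both conventions appear in the literature).  Undefined
    indices (no homoplasy-capable characters, G = M) come back as NaN.
    """
    patterns, weights, ids = _encode(aln)
    adj = _tree_to_adj(tree, [i.replace(" ", "_") for i in ids])
    per_pat = _fitch_score(adj, patterns, weights, per_pattern=True)
    m = _pattern_min_steps(patterns)
    g = _pattern_max_steps(patterns)
    mask = (
        _pattern_informative(patterns)
        if informative_only
        else np.ones(patterns.shape[1], dtype=bool)
    )
    return _indices(m, g, per_pat, weights, mask)


def nj_tree(
    m: DistanceMatrix,
    outgroup_ids: Sequence[str] | None = None,
) -> dendropy.Tree:
    """Saitou–Nei neighbour-joining tree from a distance matrix.

    Negative branch lengths are clamped to zero; the tree is rooted on the
    outgroup when given, otherwise left unrooted.  Undefined (saturated)
    distance entries are an error.
    """
    if not np.all(np.isfinite(m.d)):
        bad = np.argwhere(~np.isfinite(m.d))
        i, j = bad[0]
        raise ValueError(
            f"distance matrix has undefined entries (e.g. {m.ids[i]!r} vs "
            f"{m.ids[j]!r}); NJ needs a fully defined matrix"
        )
    labels = [i.replace(" ", "_") for i in m.ids]
    sk_dm = skbio.DistanceMatrix(m.d, ids=labels)
    sk_tree = skbio.tree.nj(sk_dm)
    tree = dendropy.Tree.get(
        data=str(sk_tree), schema="newick", preserve_underscores=True
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    if outgroup_ids:
        _root_on_outgroup(tree, [i.replace(" ", "_") for i in outgroup_ids])
    return tree


def _root_on_outgroup(tree: dendropy.Tree, outgroup_labels: Sequence[str]) -> None:
    tree.is_rooted = True
    taxa = [tree.taxon_namespace.get_taxon(l) for l in outgroup_labels]
    if any(t is None for t in taxa):
        missing = [l for l, t in zip(outgroup_labels, taxa) if t is None]
        raise KeyError(f"outgroup ids not on tree: {missing}")
    if len(taxa) == 1:
        node = tree.find_node_with_taxon_label(taxa[0].label)
    else:
        node = tree.mrca(taxa=taxa)
        if node is tree.seed_node:
            # outgroup spans the current root; root on the first member's edge
            node = tree.find_node_with_taxon_label(taxa[0].label)
    if node.edge.length is not None:
        tree.reroot_at_edge(
            node.edge, length1=node.edge.length / 2, length2=node.edge.length / 2
        )
    else:
        tree.reroot_at_edge(node.edge)


def strict_consensus(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Tree retaining exactly the bipartitions present in every input tree."""
    if not trees:
        raise ValueError("no trees")
    tns = trees[0].taxon_namespace
    leafsets = {
        frozenset(lf.taxon.label for lf in t.leaf_node_iter()) for t in trees
    }
    if len(leafsets) != 1:
        raise ValueError("trees have different leaf sets")
    tl = dendropy.TreeList(trees, taxon_namespace=tns)
    cons = tl.consensus(min_freq=1.0)
    cons.is_rooted = False
    return cons


def bootstrap_support(
    aln: LocusAlignment,
    builder: Callable[[LocusAlignment], dendropy.Tree] | str = "nj",
    n_replicates: int = 1000,
    seed: int | None = None,
    tree: dendropy.Tree | None = None,
) -> dendropy.Tree:
    """Column-resampling bootstrap supports on a reference tree.

    ``builder`` maps an alignment to a tree ("nj", "mp" or a callable); the
    reference tree defaults to the builder's tree on the original alignment.
    Supports (percent of replicates containing each internal bipartition) are
    written to ``node.label``/``edge.bipartition`` of the reference tree.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)

    if builder == "nj":
        build = lambda a: nj_tree(distance_matrix(a))
    elif builder == "mp":
        build = lambda a: mp_search(
            a,
            strategy="hillclimb",
            seed=int(rng.integers(2**31)),
            replicates=2,
            max_trees=1,
        ).best_trees[0]
    elif callable(builder):
        build = builder
    else:
        raise ValueError(f"unknown builder {builder!r}")

    if tree is None:
        reference = build(aln)
    else:
        reference = tree.clone(depth=1)
    ids = aln.ids
    n_index = {i: k for k, i in enumerate(ids)}
    ref_adj_bips = _dendropy_bipartitions(reference, n_index)

    counts = {bp: 0 for bp in ref_adj_bips}
    seqs = [r.seq for r in aln.records]
    for _ in range(n_replicates):
        cols = rng.integers(0, aln.length, size=aln.length)
        resampled = LocusAlignment(
            aln.locus,
            [
                type(r)(r.individual_id, r.species, r.locus,
                        "".join(r.seq[c] for c in cols))
                for r in aln.records
            ],
        )
        rep_tree = build(resampled)
        rep_bips = _dendropy_bipartitions(rep_tree, n_index)
        for bp in counts:
            if bp in rep_bips:
                counts[bp] += 1

    for node, bp in _iter_internal_bipartitions(reference, n_index):
        node.label = f"{100.0 * counts[bp] / n_replicates:.0f}"
    return reference


def _iter_internal_bipartitions(tree: dendropy.Tree, n_index: Mapping[str, int]):
    n = len(n_index)
    lookup = {k.replace(" ", "_"): v for k, v in n_index.items()}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(
            lookup[lf.taxon.label.replace(" ", "_")]
            for lf in node.leaf_iter()
        )
        if 0 in side:
            side = frozenset(range(n)) - side
        if 1 < len(side) < n - 1:
            yield node, side


def _dendropy_bipartitions(
    tree: dendropy.Tree, n_index: Mapping[str, int]
) -> set[frozenset]:
    return {bp for _node, bp in _iter_internal_bipartitions(tree, n_index)}


def is_monophyletic(
    tree: dendropy.Tree,
    species_map: Mapping[str, str],
    species: str,
    outgroup_ids: Sequence[str],
) -> bool:
    """Whether a species' individuals form a clade on the outgroup-rooted tree.

    Singleton species are monophyletic by definition.
    """
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    _root_on_outgroup(tree, [i.replace(" ", "_") for i in outgroup_ids])
    members = {
        i.replace(" ", "_") for i, sp in species_map.items() if sp == species
    }
    if not members:
        raise KeyError(f"species {species!r} has no individuals on the tree")
    tree_labels = {lf.taxon.label.replace(" ", "_") for lf in tree.leaf_node_iter()}
    if not members <= tree_labels:
        raise KeyError(f"individuals missing from tree: {sorted(members - tree_labels)}")
    if len(members) == 1:
        return True
    taxa = [
        t for t in tree.taxon_namespace if t.label.replace(" ", "_") in members
    ]
    mrca = tree.mrca(taxa=taxa)
    clade = {lf.taxon.label.replace(" ", "_") for lf in mrca.leaf_iter()}
    return clade == members
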