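import itertools

import dendropy
import numpy as np
import pytest

from barcodekit.distances import DistanceMatrix, distance_matrix
from barcodekit.seqio import LocusAlignment, SequenceRecord
from barcodekit.synthetic import LocusSpec, simulate_dataset, study_like_config
from barcodekit.trees import (
    consistency_indices,
    fitch_length,
    is_monophyletic,
    mp_search,
    nj_tree,
    strict_consensus,
    bootstrap_support,
)
from conftest import make_alignment


def _tree(newick, tns=None):
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        taxon_namespace=tns,
    )


def _aln(seqs, species=None):
    rows = [
        (f"t{i}", (species or {}).get(i, f"sp{i}"), s) for i, s in enumerate(seqs)
    ]
    return make_alignment("L", rows)


# --- independent oracles ----------------------------------------------------

def all_topologies(n):
    """Every unrooted binary topology over leaves 0..n-1 (adjacency maps)."""
    out = [{n: [0, 1, 2], 0: [n], 1: [n], 2: [n]}]
    for leaf in range(3, n):
        new = []
        for adj in out:
            for u, v in [(a, b) for a in adj for b in adj[a] if a < b]:
                a = {k: list(w) for k, w in adj.items()}
                m = max(a) + 1
                a[u].remove(v)
                a[v].remove(u)
                a[m] = [u, v, leaf]
                a[u].append(m)
                a[v].append(m)
                a[leaf] = [m]
                new.append(a)
        out = new
    return out


def brute_fitch(adj, seqs):
    """Minimum mutations by exhaustive enumeration of internal states."""
    n = len(seqs)
    internal = [k for k in adj if k >= n]
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    total = 0
    for col in range(len(seqs[0])):
        obs = {i: seqs[i][col] for i in range(n)}
        free = [i for i in obs if obs[i] not in "ACGT"]
        best = 10**9
        for assign in itertools.product("ACGT", repeat=len(internal) + len(free)):
            it = iter(assign)
            state = {k: next(it) for k in internal}
            for i, o in obs.items():
                state[i] = o if o in "ACGT" else next(it)
            best = min(best, sum(1 for u, v in edges if state[u] != state[v]))
        total += best
    return total


def adj_to_newick(adj, n):
    def sub(node, parent):
        if node < n:
            return f"t{node}"
        return "(" + ",".join(
            sub(nb, node) for nb in adj[node] if nb != parent
        ) + ")"

    root = adj[0][0]
    return "(" + ",".join(sub(nb, root) for nb in adj[root]) + ");"


# --- Fitch length -----------------------------------------------------------

def test_single_column_two_state():
    aln = _aln(["A", "A", "G", "G"])
    tree = _tree("((t0,t1),(t2,t3));")
    assert fitch_length(tree, aln) == 1


def test_invariant_column_zero_steps():
    aln = _aln(["A", "A", "A", "A"])
    assert fitch_length(_tree("((t0,t1),(t2,t3));"), aln) == 0


def test_score_independent_of_rooting():
    aln = _aln(["ACGT", "ACGA", "GCTT", "GCTA"])
    t1 = _tree("((t0,t1),(t2,t3));")
    t2 = _tree("(t0,(t1,(t2,t3)));")  # same unrooted topology
    assert fitch_length(t1, aln) == fitch_length(t2, aln)


def test_fitch_matches_exhaustive_state_enumeration():
    rng = np.random.default_rng(5)
    for _ in range(5):
        n = 5
        seqs = [
            "".join(rng.choice(list("ACGT-"), size=6)) for _ in range(n)
        ]
        aln = _aln(seqs)
        for adj in all_topologies(n)[:7]:
            tree = _tree(adj_to_newick(adj, n))
            assert fitch_length(tree, aln) == brute_fitch(adj, seqs)


def test_taxa_mismatch_rejected():
    aln = _aln(["A", "A", "G", "G"])
    with pytest.raises(ValueError, match="mismatch"):
        fitch_length(_tree("((t0,t1),(t2,tX));"), aln)


# --- MP search --------------------------------------------------------------

def test_bnb_equals_all_topology_enumeration():
    rng = np.random.default_rng(11)
    for trial in range(3):
        n = 6
        seqs = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(n)]
        aln = _aln(seqs)
        oracle = min(brute_fitch(adj, seqs) for adj in all_topologies(n))
        res = mp_search(aln, strategy="bnb")
        assert res.length == oracle


def test_hillclimb_matches_bnb():
    rng = np.random.default_rng(3)
    seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(7)]
    aln = _aln(seqs)
    bnb = mp_search(aln, strategy="bnb")
    hc = mp_search(aln, strategy="hillclimb", seed=0, replicates=5)
    assert hc.length == bnb.length


def test_no_variable_sites_zero_length():
    aln = _aln(["ACGT"] * 5)
    res = mp_search(aln, strategy="bnb")
    assert res.length == 0


def test_bnb_refused_for_large_trees():
    aln = _aln(["ACGT"] * 17)
    with pytest.raises(ValueError, match="force"):
        mp_search(aln, strategy="bnb")


def test_search_determinism():
    rng = np.random.default_rng(8)
    seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(8)]
    aln = _aln(seqs)
    r1 = mp_search(aln, strategy="hillclimb", seed=4, replicates=3)
    r2 = mp_search(aln, strategy="hillclimb", seed=4, replicates=3)
    assert r1.length == r2.length
    assert [t.as_string(schema="newick") for t in r1.best_trees] == [
        t.as_string(schema="newick") for t in r2.best_trees
    ]


# --- consistency indices ----------------------------------------------------

def test_perfect_data_ci_one():
    seqs = ["AAAA", "AAAA", "TTAA", "TTAA"]
    aln = _aln(seqs)
    res = mp_search(aln, strategy="bnb")
    assert res.ci == pytest.approx(1.0)
    assert res.rc == pytest.approx(res.ci * res.ri)


def test_indices_against_hand_computed_example():
    # 5 taxa, 1 character A,A,A,G,G on a tree forcing homoplasy:
    # ((t0,t3),(t1,(t2,t4))) separates the two G taxa -> L=2, m=1, g=2
    # CI = 1/2, RI = (2-2)/(2-1) = 0
    aln = _aln(["A", "A", "A", "G", "G"])
    tree = _tree("((t0,t3),(t1,(t2,t4)));")
    ci, ri, rc = consistency_indices(tree, aln)
    assert ci == pytest.approx(0.5)
    assert ri == pytest.approx(0.0)
    assert rc == pytest.approx(0.0)


def test_indices_bounds_and_identity(study_dataset):
    ds, _ = study_dataset
    from barcodekit.seqio import concatenate

    aln = concatenate(ds, ["rbcL", "matK", "ITS"])
    res = mp_search(aln, strategy="hillclimb", seed=1, replicates=2)
    assert 0 < res.ci <= 1
    assert 0 <= res.ri <= 1
    assert res.rc == pytest.approx(res.ci * res.ri)
    # L between min and max possible steps: CI = M/L <= 1 guarantees L >= M
    # and RI >= 0 guarantees L <= G
    ci2, ri2, rc2 = consistency_indices(res.best_trees[0], aln)
    assert ci2 == pytest.approx(res.ci)


def test_indices_undefined_without_variation():
    aln = _aln(["ACGT"] * 4)
    res = mp_search(aln, strategy="bnb")
    assert np.isnan(res.ci)


# --- NJ ---------------------------------------------------------------------

def test_nj_recovers_additive_tree_exactly():
    # ((a:1,b:2):1,(c:3,d:4)) pairwise path lengths
    ids = ["a", "b", "c", "d"]
    d = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        dtype=float,
    )
    m = DistanceMatrix(ids=ids, d=d, sites=np.full((4, 4), 10))
    tree = nj_tree(m)
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    for i, j in itertools.combinations(range(4), 2):
        got = pdm.patristic_distance(
            tns.get_taxon(ids[i]), tns.get_taxon(ids[j])
        )
        assert got == pytest.approx(d[i, j])


def test_nj_no_negative_branch_lengths():
    rng = np.random.default_rng(0)
    raw = rng.uniform(0, 0.2, size=(6, 6))
    d = (raw + raw.T) / 2
    np.fill_diagonal(d, 0)
    m = DistanceMatrix(
        ids=[f"x{i}" for i in range(6)], d=d, sites=np.full((6, 6), 10)
    )
    tree = nj_tree(m)
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            assert e.length >= 0


def test_nj_rejects_undefined_entries():
    d = np.array([[0, np.inf], [np.inf, 0]])
    m = DistanceMatrix(ids=["a", "b"], d=d, sites=np.full((2, 2), 5))
    with pytest.raises(ValueError, match="undefined"):
        nj_tree(m)


# --- consensus --------------------------------------------------------------

def test_consensus_of_identical_trees():
    tns = dendropy.TaxonNamespace()
    t1 = _tree("((t0,t1),(t2,t3),t4);", tns)
    t2 = _tree("((t0,t1),(t2,t3),t4);", tns)
    cons = strict_consensus([t1, t2])
    leaves = frozenset(f"t{i}" for i in range(5))
    bip = set()
    for nd in cons.preorder_internal_node_iter():
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        if "t0" in side:  # normalise unrooted bipartitions by complement
            side = leaves - side
        bip.add(side)
    assert frozenset(["t2", "t3", "t4"]) in bip  # == {t0,t1} unrooted
    assert frozenset(["t2", "t3"]) in bip


def test_consensus_of_conflicting_trees_is_star():
    tns = dendropy.TaxonNamespace()
    t1 = _tree("((t0,t1),(t2,t3),t4);", tns)
    t2 = _tree("((t0,t2),(t1,t3),t4);", tns)
    cons = strict_consensus([t1, t2])
    internal = [
        nd
        for nd in cons.preorder_internal_node_iter()
        if nd.parent_node is not None
    ]
    assert internal == []


def test_consensus_bipartitions_equal_brute_intersection():
    rng = np.random.default_rng(2)
    seqs = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(6)]
    aln = _aln(seqs)
    res = mp_search(aln, strategy="bnb", max_trees=50)
    cons = res.consensus
    n = 6

    def bips(tree):
        all_leaves = frozenset(f"t{i}" for i in range(n))
        out = set()
        for nd in tree.preorder_internal_node_iter():
            if nd.parent_node is None:
                continue
            side = frozenset(l.taxon.label for l in nd.leaf_iter())
            if "t0" in side:
                side = all_leaves - side
            if 1 < len(side) < n - 1:
                out.add(side)
        return out

    expected = None
    for t in res.best_trees:
        b = bips(t)
        expected = b if expected is None else expected & b
    assert bips(cons) == expected


def test_consensus_leafset_mismatch_rejected():
    tns = dendropy.TaxonNamespace()
    t1 = _tree("((t0,t1),(t2,t3));", tns)
    t2 = _tree("((t0,t1),(t2,t9));", tns)
    with pytest.raises(ValueError):
        strict_consensus([t1, t2])


# --- bootstrap --------------------------------------------------------------

def _supports(tree):
    return [
        int(nd.label)
        for nd in tree.preorder_internal_node_iter()
        if nd.parent_node is not None and nd.label is not None
    ]


def test_bootstrap_single_replicate_supports_are_0_or_100():
    cfg = study_like_config(seed=31, loci=(LocusSpec("x", 300, 0.0),))
    ds, _ = simulate_dataset(cfg)
    tree = bootstrap_support(ds.loci["x"], builder="nj", n_replicates=1, seed=0)
    assert set(_supports(tree)) <= {0, 100}


def test_bootstrap_deterministic_under_seed():
    cfg = study_like_config(seed=32, loci=(LocusSpec("x", 300, 0.0),))
    ds, _ = simulate_dataset(cfg)
    t1 = bootstrap_support(ds.loci["x"], builder="nj", n_replicates=10, seed=5)
    t2 = bootstrap_support(ds.loci["x"], builder="nj", n_replicates=10, seed=5)
    assert _supports(t1) == _supports(t2)


def test_bootstrap_high_support_for_deep_divergence():
    cfg = study_like_config(
        seed=33,
        loci=(LocusSpec("x", 800, 0.0),),
        inter_divergence=0.08,
        intra_divergence=0.001,
    )
    ds, _ = simulate_dataset(cfg)
    tree = bootstrap_support(ds.loci["x"], builder="nj", n_replicates=50, seed=2)
    smap = ds.species_map
    # every species clade on the reference tree should be near-unanimous
    for nd in tree.preorder_internal_node_iter():
        if nd.parent_node is None or nd.label is None:
            continue
        leaves = {l.taxon.label for l in nd.leaf_iter()}
        clade_species = {smap[l] for l in leaves}
        if len(clade_species) == 1 and len(leaves) == sum(
            1 for v in smap.values() if v in clade_species
        ):
            assert int(nd.label) >= 95


# --- monophyly --------------------------------------------------------------

def test_monophyly_on_clean_separation():
    tree = _tree("((a1,a2),(b1,b2),(o1));")
    smap = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "o1": "O"}
    assert is_monophyletic(tree, smap, "A", ["o1"])
    assert is_monophyletic(tree, smap, "B", ["o1"])


def test_interleaved_species_not_monophyletic():
    tree = _tree("(((a1,b1),a2),b2,o1);")
    smap = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "o1": "O"}
    assert not is_monophyletic(tree, smap, "A", ["o1"])


def test_singleton_species_monophyletic_by_definition():
    tree = _tree("((a1,b1),b2,o1);")
    smap = {"a1": "A", "b1": "B", "b2": "B", "o1": "O"}
    assert is_monophyletic(tree, smap, "A", ["o1"])


def test_missing_outgroup_rejected():
    tree = _tree("((a1,a2),b1,b2);")
    smap = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    with pytest.raises(KeyError):
        is_monophyletic(tree, smap, "A", ["zz"])
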