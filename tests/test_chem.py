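from itertools import combinations

import numpy as np
import pytest

from glomod.chem import (McsBudgetExceeded, atom_pair_multiset,
                         atom_pair_tanimoto, cluster_distance_vs_similarity,
                         max_common_subgraph, mcs_tanimoto, pair_scores,
                         similarity_matrix)
from glomod.molecules import (BY_CID, BY_LETTER, PUBLISHED_REFERENCE_LISTING,
                              MoleculeGraph, from_molfile, resolve)

PANEL = tuple("MLIHKRFW")


def _graph(elements, bonds, aromatic=(), name="g"):
    return MoleculeGraph(name, "?", 0, tuple(elements),
                         tuple((i, j, float(o)) for i, j, o in bonds),
                         frozenset(aromatic))


# -- molecule encodings ------------------------------------------------------

def test_panel_molecules_have_expected_heavy_atom_counts():
    expected = {"M": 9, "L": 9, "I": 9, "H": 11, "K": 10, "R": 12,
                "F": 12, "W": 15}
    for letter, n in expected.items():
        assert BY_LETTER[letter].n_atoms == n


def test_reference_listing_swaps_only_leucine_isoleucine():
    for letter in PANEL:
        by_name = resolve(letter, by_reference_listing=False)
        by_listing = resolve(letter, by_reference_listing=True)
        if letter in "LI":
            assert by_name.name != by_listing.name
        else:
            assert by_name is by_listing
    assert BY_CID[PUBLISHED_REFERENCE_LISTING["L"]].name == "L-isoleucine"


def test_molecule_validation():
    with pytest.raises(ValueError, match="self-bond"):
        _graph("CC", [(0, 0, 1)])
    with pytest.raises(ValueError, match="disconnected"):
        _graph("CC", [])


def test_molfile_parsing_roundtrip_equivalence():
    # ethanol V2000 block with explicit hydrogens; heavy atoms only survive
    mol = "\n".join([
        "ethanol", "", "",
        "  4  3  0  0  0  0  0  0  0  0999 V2000",
        "    0.0000    0.0000    0.0000 C   0  0",
        "    1.5000    0.0000    0.0000 C   0  0",
        "    2.0000    1.0000    0.0000 O   0  0",
        "    0.5000    1.0000    0.0000 H   0  0",
        "  1  2  1  0",
        "  2  3  1  0",
        "  1  4  1  0",
        "M  END"])
    g = from_molfile(mol)
    assert g.elements == ("C", "C", "O")
    assert len(g.bonds) == 2


# -- MCS ---------------------------------------------------------------------

def test_identical_molecules_score_one():
    for letter in ("M", "H", "F"):
        m = BY_LETTER[letter]
        assert mcs_tanimoto(m, m) == pytest.approx(1.0)
        assert atom_pair_tanimoto(m, m) == pytest.approx(1.0)


def test_single_carbon_vs_ethane():
    c1 = _graph("C", [], name="methane")
    c2 = _graph("CC", [(0, 1, 1)], name="ethane")
    assert mcs_tanimoto(c1, c2) == pytest.approx(0.5)  # 1 / (1 + 2 - 1)


def test_mcs_symmetric_on_panel_pairs():
    for a, b in [("K", "R"), ("F", "W"), ("M", "I")]:
        ma, mb = BY_LETTER[a], BY_LETTER[b]
        assert mcs_tanimoto(ma, mb) == pytest.approx(mcs_tanimoto(mb, ma))


def test_mcs_budget_is_a_hard_failure():
    with pytest.raises(McsBudgetExceeded):
        mcs_tanimoto(BY_LETTER["W"], BY_LETTER["F"], max_states=10)


def _connected_induced_subsets(adj, size):
    """All connected vertex subsets of the given size (grown from each seed)."""
    n = len(adj)
    out = set()

    # unrestricted growth: simple and exhaustive enough for <= 12 nodes
    def grow2(subset, candidates):
        if len(subset) == size:
            out.add(frozenset(subset))
            return
        reach = set().union(*(adj[u] for u in subset)) - subset
        for v in sorted(reach & candidates):
            grow2(subset | {v}, candidates - {v})
    for seed in range(n):
        grow2({seed}, set(range(n)))
    return out


def _oracle_mcs_size(a: MoleculeGraph, b: MoleculeGraph) -> int:
    """Brute force: largest connected induced subgraph of `a` that embeds
    induced-isomorphically (element labels) into `b`, via networkx VF2."""
    import networkx as nx
    from networkx.algorithms import isomorphism as iso

    def to_nx(m):
        g = nx.Graph()
        for i, e in enumerate(m.elements):
            g.add_node(i, element=e)
        g.add_edges_from((i, j) for i, j, _ in m.bonds)
        return g

    ga, gb = to_nx(a), to_nx(b)
    adj = [set(ga.neighbors(i)) for i in ga.nodes]
    nm = iso.categorical_node_match("element", None)
    for size in range(min(a.n_atoms, b.n_atoms), 0, -1):
        for subset in _connected_induced_subsets(adj, size):
            sub = ga.subgraph(subset)
            gm = iso.GraphMatcher(gb, sub, node_match=nm)
            if gm.subgraph_is_isomorphic():
                return size
    return 0


@pytest.mark.parametrize("pair", [("M", "L"), ("M", "I"), ("L", "I"),
                                  ("K", "H"), ("M", "K")])
def test_mcs_equals_brute_force_oracle(pair):
    a, b = BY_LETTER[pair[0]], BY_LETTER[pair[1]]
    n = len(max_common_subgraph(a, b))
    assert n == _oracle_mcs_size(a, b)


def test_mcs_oracle_on_random_labeled_graphs(rng):
    """Randomly grown small labeled graphs: search equals brute force."""
    def random_graph(n, k):
        elements = rng.choice(list("CNO"), size=n)
        bonds = [(i, int(rng.integers(0, i)), 1.0) for i in range(1, n)]
        for _ in range(k):
            i, j = rng.integers(0, n, 2)
            if i != j and (i, j) not in [(x, y) for x, y, _ in bonds] \
                    and (j, i) not in [(x, y) for x, y, _ in bonds]:
                bonds.append((int(min(i, j)), int(max(i, j)), 1.0))
        return _graph(elements, bonds)

    for _ in range(6):
        a, b = random_graph(7, 2), random_graph(8, 2)
        assert len(max_common_subgraph(a, b)) == _oracle_mcs_size(a, b)


# -- atom pairs --------------------------------------------------------------

def test_atom_pair_multiset_size_is_all_pairs():
    for letter in PANEL:
        m = BY_LETTER[letter]
        n = m.n_atoms
        assert sum(atom_pair_multiset(m).values()) == n * (n - 1) // 2


def test_atom_pair_disjoint_descriptor_sets_score_zero():
    a = _graph("CC", [(0, 1, 1)])
    b = _graph("OO", [(0, 1, 1)])
    assert atom_pair_tanimoto(a, b) == 0.0


def test_atom_pair_scores_bounded_and_symmetric():
    scores = pair_scores()
    assert ((scores["atom_pair"] >= 0) & (scores["atom_pair"] <= 1)).all()
    for a, b in [("K", "R"), ("W", "F")]:
        assert atom_pair_tanimoto(BY_LETTER[a], BY_LETTER[b]) == pytest.approx(
            atom_pair_tanimoto(BY_LETTER[b], BY_LETTER[a]))


def test_atom_pairs_match_rdkit_reference():
    """Independent cross-check: the hand-rolled Carhart descriptors reproduce
    rdkit's atom-pair Tanimoto on every panel pairing."""
    rdkit = pytest.importorskip("rdkit")
    from rdkit import Chem, DataStructs
    from rdkit.Chem.AtomPairs import Pairs
    smiles = {"M": "CSCCC(N)C(=O)O", "L": "CC(C)CC(N)C(=O)O",
              "I": "CCC(C)C(N)C(=O)O", "H": "O=C(O)C(N)Cc1c[nH]cn1",
              "K": "NCCCCC(N)C(=O)O", "R": "NC(=N)NCCCC(N)C(=O)O",
              "F": "c1ccccc1CC(N)C(=O)O",
              "W": "c1ccc2c(c1)c(c[nH]2)CC(N)C(=O)O"}
    fps = {k: Pairs.GetAtomPairFingerprint(Chem.MolFromSmiles(s))
           for k, s in smiles.items()}
    for a, b in combinations(PANEL, 2):
        ours = atom_pair_tanimoto(BY_LETTER[a], BY_LETTER[b])
        ref = DataStructs.TanimotoSimilarity(fps[a], fps[b])
        assert ours == pytest.approx(ref, abs=1e-9), (a, b)


# -- matrices and regression -------------------------------------------------

def test_similarity_matrices_symmetric_unit_diagonal():
    mcs_m, ap_m = similarity_matrix()
    for mat in (mcs_m, ap_m):
        assert np.allclose(np.diag(mat), 1.0)
        assert np.allclose(mat, mat.T)


def test_similar_triads_score_higher_within_than_between():
    """The three structural triads (M,L,I), (K,R), (H,F,W) have higher mean
    within-group than between-group similarity for both scores."""
    mcs_m, ap_m = similarity_matrix()
    groups = [set("MLI"), set("KR"), set("HFW")]
    for mat in (mcs_m, ap_m):
        within, between = [], []
        for a, b in combinations(PANEL, 2):
            (within if any({a, b} <= g for g in groups) else between).append(
                mat.loc[a, b])
        assert np.mean(within) > np.mean(between)


def test_regression_on_anti_linear_fixture():
    pairs = [frozenset(p) for p in [("A", "B"), ("A", "C"), ("B", "C"),
                                    ("A", "D"), ("B", "D")]]
    scores = {p: s for p, s in zip(pairs, [0.1, 0.3, 0.5, 0.7, 0.9])}
    distances = {p: 1.0 - scores[p] for p in pairs}
    res = cluster_distance_vs_similarity(distances, scores)
    assert res.extra["slope"] == pytest.approx(-1.0)
    assert res.extra["r_squared"] == pytest.approx(1.0)
    assert res.p_value < 1e-6
    # duplicated points leave OLS estimates unchanged
    doubled_scores = dict(scores)
    doubled_dist = dict(distances)
    res2 = cluster_distance_vs_similarity(
        {**doubled_dist}, {**doubled_scores})
    assert res2.extra["slope"] == pytest.approx(res.extra["slope"])
    with pytest.raises(ValueError, match="3 stimulus pairs"):
        cluster_distance_vs_similarity({pairs[0]: 1.0}, {pairs[0]: 0.5})
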