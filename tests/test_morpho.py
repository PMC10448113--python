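import numpy as np
import pandas as pd
import pytest

from glomod.morpho import (NeuronTree, classify_tuft_count_distribution,
                           critical_points, detect_tufts, extract_features,
                           feature_table, population_pca, read_swc,
                           tuft_distances, tuft_volume, write_swc)
from glomod.synthetic import generate_tree


def _tree(rows):
    rows = np.asarray(rows, dtype=float)
    return NeuronTree(rows[:, 0].astype(int), rows[:, 6].astype(int),
                      rows[:, 2:5], rows[:, 5], rows[:, 1].astype(int))


def _chain(n, step=10.0):
    return _tree([[i + 1, 3 if i else 1, i * step, 0, 0, 1, i if i else -1]
                  for i in range(n)])


# -- SWC IO and validation ---------------------------------------------------

def test_swc_roundtrip(tmp_path):
    tree, _ = generate_tree(2, seed=4)
    path = tmp_path / "cell.swc"
    write_swc(tree, path)
    back = read_swc(path)
    assert np.array_equal(back.ids, tree.ids)
    assert np.array_equal(back.parents, tree.parents)
    assert np.allclose(back.xyz, tree.xyz)
    # writing the reread tree reproduces the file byte for byte
    path2 = tmp_path / "cell2.swc"
    write_swc(back, path2)
    assert path.read_text() == path2.read_text()


def test_three_node_chain_depth():
    tree = _chain(3)
    assert tree.root == 1
    assert tree.path_distance(3) == pytest.approx(20.0)


def test_structural_errors_rejected(tmp_path):
    with pytest.raises(ValueError, match="exactly one root"):
        _tree([[1, 1, 0, 0, 0, 1, -1], [2, 3, 1, 0, 0, 1, -1]])
    with pytest.raises(ValueError, match="dangling"):
        _tree([[1, 1, 0, 0, 0, 1, -1], [2, 3, 1, 0, 0, 1, 9]])
    with pytest.raises(ValueError, match="exactly one root"):
        _tree([[1, 1, 0, 0, 0, 1, 2], [2, 3, 1, 0, 0, 1, 1]])
    bad = tmp_path / "bad.swc"
    bad.write_text("1 1 0 0 0 1 -1\n2 3 a b c 1 1\n")
    with pytest.raises(ValueError):
        read_swc(bad)


# -- critical points ---------------------------------------------------------

def test_unbranched_chain_has_one_end_no_branches():
    ends, branches = critical_points(_chain(5))
    assert ends == [5] and branches == []


def test_binary_tree_critical_points():
    # soma 1 -> 2; 2 branches into 3,4; each branches into two leaves
    rows = [[1, 1, 0, 0, 0, 1, -1], [2, 3, 10, 0, 0, 1, 1],
            [3, 3, 20, 10, 0, 1, 2], [4, 3, 20, -10, 0, 1, 2],
            [5, 3, 30, 15, 0, 1, 3], [6, 3, 30, 5, 0, 1, 3],
            [7, 3, 30, -5, 0, 1, 4], [8, 3, 30, -15, 0, 1, 4]]
    ends, branches = critical_points(_tree(rows))
    assert ends == [5, 6, 7, 8]
    assert branches == [2, 3, 4]


# -- DBSCAN tuft detection ---------------------------------------------------

def _brute_force_dbscan(points, eps, min_points):
    """Density-reachability oracle: core points (>= min_points neighbors
    within eps, self included) joined into components; border points attach
    to any reachable core cluster (lowest cluster id wins)."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    neighbors = [set(np.nonzero(d[i] <= eps)[0]) for i in range(n)]
    core = [i for i in range(n) if len(neighbors[i]) >= min_points]
    labels = {}
    cluster = 0
    for c in core:
        if c in labels:
            continue
        stack = [c]
        while stack:
            u = stack.pop()
            if u in labels:
                continue
            labels[u] = cluster
            if u in core:
                stack.extend(v for v in neighbors[u] if v not in labels)
        cluster += 1
    for i in range(n):
        if i not in labels:
            reachable = sorted(labels[c] for c in core if i in neighbors[c])
            if reachable:
                labels[i] = reachable[0]
    member_sets = {}
    for i, lab in labels.items():
        member_sets.setdefault(lab, set()).add(i)
    noise = set(range(n)) - set(labels)
    return set(map(frozenset, member_sets.values())), noise


def _tree_from_points(points):
    """Star tree: every point is a leaf hanging off the soma, so the critical
    points are exactly the input points."""
    rows = [[1, 1, 500, 500, 500, 1, -1]]
    for k, p in enumerate(points):
        rows.append([k + 2, 3, p[0], p[1], p[2], 1, 1])
    return _tree(rows)


def test_dbscan_matches_density_reachability_oracle(rng):
    for trial in range(20):
        points = rng.uniform(0, 60, size=(int(rng.integers(5, 30)), 3))
        tree = _tree_from_points(points)
        clusters, blunt = detect_tufts(tree, eps=15.0, min_points=5)
        got = {frozenset(np.array(c.member_ids) - 2) for c in clusters}
        want, noise = _brute_force_dbscan(points, 15.0, 5)
        assert got == want, f"trial {trial}"
        assert {n - 2 for n in blunt} == noise


def test_six_points_in_small_ball_form_one_cluster(rng):
    pts = rng.uniform(-5, 5, size=(6, 3))
    clusters, blunt = detect_tufts(_tree_from_points(pts))
    assert len(clusters) == 1 and blunt == []


def test_four_points_never_cluster(rng):
    pts = rng.uniform(-1, 1, size=(4, 3))
    clusters, blunt = detect_tufts(_tree_from_points(pts))
    assert clusters == [] and len(blunt) == 4


def test_two_distant_balls_stay_separate(rng):
    a = rng.uniform(-5, 5, size=(6, 3))
    b = rng.uniform(95, 105, size=(6, 3))
    clusters, _ = detect_tufts(_tree_from_points(np.vstack([a, b])))
    assert len(clusters) == 2


def test_planted_tuft_counts_recovered_on_200_random_trees():
    recovered = 0
    for k in range(200):
        n_tufts = k % 4          # 0..3 planted tufts
        tree, truth = generate_tree(n_tufts, nodes_per_tuft=5 + k % 4,
                                    seed=3000 + k)
        clusters, _ = detect_tufts(tree)
        recovered += len(clusters) == truth["n_tufts"]
    assert recovered == 200


# -- volumes and distances ---------------------------------------------------

def test_hull_volume_closed_forms():
    cube = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                    dtype=float)
    vol, degenerate = tuft_volume(cube)
    assert vol == pytest.approx(1.0, rel=1e-9) and not degenerate
    tetra = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    vol, degenerate = tuft_volume(tetra)
    assert vol == pytest.approx(1 / 6, rel=1e-9) and not degenerate
    coplanar = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 2, 0]],
                        dtype=float)
    vol, degenerate = tuft_volume(coplanar)
    assert vol == 0.0 and degenerate


def test_path_distance_bounds_euclidean():
    tree, _ = generate_tree(2, seed=6)
    clusters, _ = detect_tufts(tree)
    soma_xyz = tree.coords(tree.root)
    for c in clusters:
        euclid = min(np.linalg.norm(tree.coords(m) - soma_xyz)
                     for m in c.member_ids)
        assert c.soma_path_distance >= euclid - 1e-9


def test_straight_dendrite_path_distance():
    # soma at 0, chain to a 5-leaf tuft at 50 um
    rows = [[1, 1, 0, 0, 0, 1, -1]]
    for i in range(1, 6):
        rows.append([i + 1, 3, i * 10.0, 0, 0, 1, i])
    hub = 6
    for k in range(5):
        rows.append([7 + k, 3, 50.0 + 2.0, 2.0 * k - 4.0, 0, 1, hub])
    tree = _tree(rows)
    clusters, _ = detect_tufts(tree)
    assert len(clusters) == 1
    assert clusters[0].soma_path_distance == pytest.approx(50.0)
    soma, inter = tuft_distances(tree, clusters)
    assert soma == [clusters[0].soma_path_distance]
    assert inter.shape == (1, 1)


# -- features and PCA --------------------------------------------------------

def test_feature_vector_of_planted_cells():
    tree1, _ = generate_tree(1, seed=7)
    f1 = extract_features(tree1)
    assert f1["n_tufts"] == 1
    assert f1["n_primary_dendritic_stems"] == 1
    assert f1["n_primary_basal_neurites"] == 2
    assert f1["mean_intertuft_distance"] == 0.0
    tree3, truth3 = generate_tree(3, seed=8)
    f3 = extract_features(tree3)
    assert f3["n_tufts"] == 3
    assert f3["mean_tuft_volume"] > 0
    assert f3["mean_intertuft_distance"] > 30.0


def test_bare_chain_has_zero_tuft_features():
    feats = extract_features(_chain(6))
    assert feats["n_tufts"] == 0
    assert feats["mean_tuft_volume"] == 0.0
    assert not feats["has_tufts"]


def test_population_pca_properties():
    trees = {f"c{k}": generate_tree(1 + k % 3, seed=40 + k)[0] for k in range(9)}
    feats = feature_table(trees)
    scores, loadings, evr, dropped = population_pca(feats)
    assert evr.sum() == pytest.approx(1.0)
    # duplicated cells land on identical scores
    dup = pd.concat([feats, feats.iloc[[0]].rename(index={feats.index[0]: "dup"})])
    scores2, *_ = population_pca(dup)
    assert np.allclose(scores2.loc["dup"], scores2.loc[feats.index[0]])
    with pytest.raises(ValueError, match="3 cells"):
        population_pca(feats.iloc[:2])


def test_two_latent_factors_dominate_pca(rng):
    """Features built from two latent factors: PC1+PC2 carry ~all variance."""
    n = 30
    u, v = rng.normal(size=n), rng.normal(size=n)
    base = pd.DataFrame({"f1": u, "f2": v, "f3": u + v + 1e-6 * rng.normal(size=n),
                         "f4": u - 2 * v + 1e-6 * rng.normal(size=n)})
    _, _, evr, _ = population_pca(base)
    assert evr[:2].sum() > 0.99


def test_tuft_count_distribution():
    dist = classify_tuft_count_distribution([1, 1, 1, 2, 2, 3])
    assert dist[1] == pytest.approx(0.5)
    assert dist.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        classify_tuft_count_distribution([])
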