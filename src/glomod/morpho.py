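"""Mitral/tufted-cell morphometry on reconstructed neuron trees.

Reconstructions arrive as SWC trees with the soma as root. End points and
branch points ("critical points") are clustered with DBSCAN (eps = 15 μm,
at least 5 points) into dendritic tufts; end points outside any cluster are
blunt neurite endings. Per cell the module derives tuft volumes (convex
hulls), soma-to-tuft path distances along the dendrite, inter-tuft
Euclidean distances, and a nine-feature morphometric vector fed to a
standardized PCA across the cell population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

#: Clustering defaults for tuft detection.
TUFT_EPS_UM = 15.0
TUFT_MIN_POINTS = 5

#: The nine morphometric features, in canonical order.
FEATURE_NAMES = (
    "n_tufts",
    "n_primary_dendritic_stems",
    "mean_tuft_volume",
    "mean_branch_points_per_tuft",
    "n_secondary_dendrites",
    "n_primary_basal_neurites",
    "n_secondary_basal_neurites",
    "mean_soma_tuft_path_distance",
    "mean_intertuft_distance",
)


@dataclass
class NeuronTree:
    """Rooted tree of 3D nodes; the root is the soma."""

    ids: np.ndarray          # node ids as stored in the SWC file
    parents: np.ndarray      # parent ids; -1 for the root
    xyz: np.ndarray          # (n, 3) μm
    radius: np.ndarray
    types: np.ndarray

    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=int)
        self.parents = np.asarray(self.parents, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        if len(self._index) != self.ids.size:
            raise ValueError("duplicate node ids")
        roots = np.nonzero(self.parents == -1)[0]
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite node coordinates")
        for pid in self.parents:
            if pid != -1 and int(pid) not in self._index:
                raise ValueError(f"dangling parent id {pid}")
        self._check_acyclic()

    def _check_acyclic(self):
        state = {}
        for nid in self.ids:
            path = []
            cur = int(nid)
            while cur != -1 and state.get(cur) is None:
                state[cur] = "visiting"
                path.append(cur)
                cur = int(self.parents[self._index[cur]])
            if cur != -1 and state.get(cur) == "visiting":
                raise ValueError("cycle detected in parent links")
            for p in path:
                state[p] = "done"

    @property
    def n_nodes(self) -> int:
        return self.ids.size

    @property
    def root(self) -> int:
        return int(self.ids[np.nonzero(self.parents == -1)[0][0]])

    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {int(i): [] for i in self.ids}
        for nid, pid in zip(self.ids, self.parents):
            if pid != -1:
                ch[int(pid)].append(int(nid))
        return ch

    def coords(self, node_id: int) -> np.ndarray:
        return self.xyz[self._index[int(node_id)]]

    def path_to_root(self, node_id: int) -> list[int]:
        path = [int(node_id)]
        while True:
            pid = int(self.parents[self._index[path[-1]]])
            if pid == -1:
                return path
            path.append(pid)

    def path_distance(self, node_id: int) -> float:
        """Distance from the soma to ``node_id`` along the dendrite (μm)."""
        path = self.path_to_root(node_id)
        pts = np.vstack([self.coords(n) for n in path])
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# SWC IO
# ---------------------------------------------------------------------------

def read_swc(path) -> NeuronTree:
    """Parse an SWC file (id, type, x, y, z, radius, parent per line)."""
    ids, types, xyz, radius, parents = [], [], [], [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        ids.append(int(parts[0]))
        types.append(int(parts[1]))
        xyz.append([float(parts[2]), float(parts[3]), float(parts[4])])
        radius.append(float(parts[5]))
        parents.append(int(parts[6]))
    if not ids:
        raise ValueError(f"{path}: no nodes")
    return NeuronTree(np.array(ids), np.array(parents), np.array(xyz),
                      np.array(radius), np.array(types))


def write_swc(tree: NeuronTree, path) -> None:
    lines = ["# id type x y z radius parent"]
    for k in range(tree.n_nodes):
        x, y, z = tree.xyz[k]
        lines.append(f"{tree.ids[k]} {tree.types[k]} {x:.6g} {y:.6g} {z:.6g} "
                     f"{tree.radius[k]:.6g} {tree.parents[k]}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# critical points and tuft clustering
# ---------------------------------------------------------------------------

def critical_points(tree: NeuronTree) -> tuple[list[int], list[int]]:
    """End points (no children) and branch points (>= 2 children), soma
    excluded from both sets."""
    ch = tree.children()
    root = tree.root
    ends = [n for n, c in ch.items() if not c and n != root]
    branches = [n for n, c in ch.items() if len(c) >= 2 and n != root]
    return sorted(ends), sorted(branches)


@dataclass
class TuftCluster:
    member_ids: tuple[int, ...]
    center: np.ndarray
    volume: float = 0.0
    degenerate_hull: bool = False
    soma_path_distance: float = 0.0


def detect_tufts(tree: NeuronTree, eps: float = TUFT_EPS_UM,
                 min_points: int = TUFT_MIN_POINTS
                 ) -> tuple[list[TuftCluster], list[int]]:
    """DBSCAN tuft detection on the end/branch points of a tree.

    Clusters of at least ``min_points`` critical points within ``eps`` μm
    become tufts; end points labeled as noise are blunt neurite endings.
    Points are fed to DBSCAN sorted by node id so border-point assignment is
    deterministic. Returns (clusters, blunt ending node ids).
    """
    ends, branches = critical_points(tree)
    nodes = sorted(ends + branches)
    if not nodes:
        return [], []
    pts = np.vstack([tree.coords(n) for n in nodes])
    labels = DBSCAN(eps=eps, min_samples=min_points).fit_predict(pts)
    clusters = []
    for lab in sorted(set(labels) - {-1}):
        members = tuple(n for n, l in zip(nodes, labels) if l == lab)
        coords = np.vstack([tree.coords(n) for n in members])
        volume, degenerate = tuft_volume(coords)
        cluster = TuftCluster(
            member_ids=members, center=coords.mean(axis=0), volume=volume,
            degenerate_hull=degenerate,
            soma_path_distance=min(tree.path_distance(n) for n in members))
        clusters.append(cluster)
    blunt = [n for n, l in zip(nodes, labels) if l == -1 and n in set(ends)]
    return clusters, sorted(blunt)


def tuft_volume(points: np.ndarray) -> tuple[float, bool]:
    """Convex-hull volume (μm³) of a tuft's critical points.

    Coplanar/collinear point sets have no 3D hull; they yield volume 0 with
    the degeneracy flag set."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 4:
        return 0.0, True
    try:
        return float(ConvexHull(points).volume), False
    except QhullError:
        return 0.0, True


def tuft_distances(tree: NeuronTree, clusters: list[TuftCluster]):
    """Soma-to-tuft path distances (along the dendrite, to the closest
    member) and pairwise Euclidean distances between tuft centers."""
    soma = [c.soma_path_distance for c in clusters]
    n = len(clusters)
    inter = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(clusters[i].center - clusters[j].center))
            inter[i, j] = inter[j, i] = d
    return soma, inter


# ---------------------------------------------------------------------------
# feature extraction and population PCA
# ---------------------------------------------------------------------------

def extract_features(tree: NeuronTree, eps: float = TUFT_EPS_UM,
                     min_points: int = TUFT_MIN_POINTS) -> dict[str, float]:
    """The nine-feature morphometric vector of one cell.

    Primary dendritic stems are root children whose subtree contains at
    least one tuft member; root children without any become primary basal
    neurites; their children are the secondary counts. Tuft means are 0 when
    the cell has no (or a single) tuft; ``has_tufts`` flags that case.
    """
    clusters, _ = detect_tufts(tree, eps, min_points)
    ch = tree.children()
    root = tree.root
    _, branch_nodes = critical_points(tree)
    branch_set = set(branch_nodes)
    tuft_members = set().union(*(c.member_ids for c in clusters)) if clusters else set()

    def subtree_nodes(start: int) -> set[int]:
        out, stack = set(), [start]
        while stack:
            n = stack.pop()
            out.add(n)
            stack.extend(ch[n])
        return out

    primary_stems, primary_basal = [], []
    for child in ch[root]:
        (primary_stems if subtree_nodes(child) & tuft_members
         else primary_basal).append(child)
    n_secondary_dendrites = sum(len(ch[s]) for s in primary_stems)
    n_secondary_basal = sum(len(ch[s]) for s in primary_basal)

    soma_dists, inter = tuft_distances(tree, clusters)
    iu = np.triu_indices(len(clusters), k=1)
    inter_vals = inter[iu]
    features = {
        "n_tufts": float(len(clusters)),
        "n_primary_dendritic_stems": float(len(primary_stems)),
        "mean_tuft_volume": float(np.mean([c.volume for c in clusters])) if clusters else 0.0,
        "mean_branch_points_per_tuft":
            float(np.mean([len(set(c.member_ids) & branch_set) for c in clusters]))
            if clusters else 0.0,
        "n_secondary_dendrites": float(n_secondary_dendrites),
        "n_primary_basal_neurites": float(len(primary_basal)),
        "n_secondary_basal_neurites": float(n_secondary_basal),
        "mean_soma_tuft_path_distance": float(np.mean(soma_dists)) if soma_dists else 0.0,
        "mean_intertuft_distance": float(inter_vals.mean()) if inter_vals.size else 0.0,
        "has_tufts": bool(clusters),
    }
    return features


def feature_table(trees: dict[str, NeuronTree], eps: float = TUFT_EPS_UM,
                  min_points: int = TUFT_MIN_POINTS) -> pd.DataFrame:
    rows = {}
    for name, tree in trees.items():
        feats = extract_features(tree, eps, min_points)
        rows[name] = {k: feats[k] for k in FEATURE_NAMES}
    return pd.DataFrame(rows).T[list(FEATURE_NAMES)]


def population_pca(features: pd.DataFrame):
    """PCA of standardized morphometric features across cells.

    Constant features are dropped (and reported); each remaining feature is
    standardized to mean 0 / variance 1. Returns (scores DataFrame, loadings
    DataFrame, explained variance ratios, dropped feature names)."""
    if features.shape[0] < 3:
        raise ValueError("population PCA needs at least 3 cells")
    constant = [c for c in features.columns if features[c].nunique() <= 1]
    kept = features.drop(columns=constant)
    standardized = StandardScaler().fit_transform(kept.to_numpy(dtype=float))
    pca = PCA()
    scores = pca.fit_transform(standardized)
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    scores_df = pd.DataFrame(scores, index=features.index, columns=comp_names)
    loadings_df = pd.DataFrame(pca.components_.T, index=kept.columns,
                               columns=comp_names)
    return scores_df, loadings_df, pca.explained_variance_ratio_, constant


def classify_tuft_count_distribution(tuft_counts) -> pd.Series:
    """Fraction of cells per tuft count, summing to 1."""
    counts = pd.Series(list(tuft_counts), dtype=int)
    if counts.empty:
        raise ValueError("empty population")
    return counts.value_counts(normalize=True).sort_index()
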