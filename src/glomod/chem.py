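"""Structural similarity between odor molecules, from first principles.

Two Tanimoto scores are computed on heavy-atom graphs:

* **MCS Tanimoto** — exhaustive search for the largest *connected induced*
  common subgraph under element-label-preserving isomorphism (bond orders
  ignored, adjacency and non-adjacency both preserved); score =
  |MCS| / (|A| + |B| - |MCS|), counted in atoms. The induced reading keeps
  rings intact: a benzene ring may not "unroll" onto an open carbon chain of
  the partner molecule.
* **Atom-pair Tanimoto** — Carhart atom pairs: every unordered pair of heavy
  atoms typed as (element, heavy-neighbor count, pi-electron count) together
  with their topological (shortest-path) distance, scored as a multiset
  Tanimoto |intersection| / |union|.

Both searches are exact; the panel molecules have at most 15 heavy atoms, so
exhaustive MCS enumeration with a simple element-count bound is fast.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .molecules import BY_LETTER, MoleculeGraph, resolve


class McsBudgetExceeded(RuntimeError):
    """Raised when the exhaustive MCS search exceeds its state budget.

    The search never falls back to an approximation; callers must raise the
    budget explicitly."""


# ---------------------------------------------------------------------------
# maximum common substructure
# ---------------------------------------------------------------------------

def max_common_subgraph(a: MoleculeGraph, b: MoleculeGraph,
                        max_states: int = 20_000_000) -> dict[int, int]:
    """Largest connected induced common subgraph of two element-labeled graphs.

    Returns one optimal atom mapping {index in a -> index in b}. The search
    grows a partial mapping one atom pair at a time, always attaching the new
    pair through a bond present in both molecules and requiring the new pair
    to agree with every mapped pair on adjacency (induced isomorphism), so
    every enumerated mapping is a connected induced common subgraph; a
    branch-and-bound cut on the per-element count of remaining atoms prunes
    hopeless branches.
    """
    if a.n_atoms == 0 or b.n_atoms == 0:
        raise ValueError("empty molecule")
    adj_a, adj_b = a.adjacency, b.adjacency
    el_a, el_b = a.elements, b.elements

    best: dict[int, int] = {}
    states = 0
    seen: set[frozenset[tuple[int, int]]] = set()

    def element_bound(used_a: set[int], used_b: set[int]) -> int:
        rem_a = Counter(el_a[i] for i in range(a.n_atoms) if i not in used_a)
        rem_b = Counter(el_b[j] for j in range(b.n_atoms) if j not in used_b)
        return sum(min(rem_a[e], rem_b[e]) for e in rem_a)

    def extend(mapping: dict[int, int], seed_a: int):
        nonlocal best, states
        states += 1
        if states > max_states:
            raise McsBudgetExceeded(
                f"MCS search between {a.name} and {b.name} exceeded "
                f"{max_states} states")
        if len(mapping) > len(best):
            best = dict(mapping)
        used_a, used_b = set(mapping), set(mapping.values())
        if len(mapping) + element_bound(used_a, used_b) <= len(best):
            return
        # candidate pairs adjacent to the mapped core in both molecules and
        # consistent (adjacency iff adjacency) with every mapped pair
        candidates = set()
        for ma, mb in mapping.items():
            for na in adj_a[ma]:
                if na in used_a or na < seed_a:
                    continue
                for nb in adj_b[mb]:
                    if nb in used_b or el_a[na] != el_b[nb]:
                        continue
                    if all((pa in adj_a[na]) == (pb in adj_b[nb])
                           for pa, pb in mapping.items()):
                        candidates.add((na, nb))
        for na, nb in sorted(candidates):
            mapping[na] = nb
            key = frozenset(mapping.items())
            if key not in seen:
                seen.add(key)
                extend(mapping, seed_a)
            del mapping[na]

    # seed with every compatible pair; dedupe by requiring the seed to be the
    # smallest a-index of the final mapping
    for i in range(a.n_atoms):
        for j in range(b.n_atoms):
            if el_a[i] == el_b[j]:
                extend({i: j}, seed_a=i)
    return best


def mcs_tanimoto(a: MoleculeGraph, b: MoleculeGraph,
                 max_states: int = 20_000_000) -> float:
    """Atom-counted Tanimoto similarity on the maximum common substructure."""
    mcs = max_common_subgraph(a, b, max_states=max_states)
    n = len(mcs)
    return n / (a.n_atoms + b.n_atoms - n)


# ---------------------------------------------------------------------------
# Carhart atom pairs
# ---------------------------------------------------------------------------

def atom_types(mol: MoleculeGraph) -> tuple[tuple[str, int, int], ...]:
    """Carhart atom type per atom: (element, heavy-neighbor count, pi electrons)."""
    deg = mol.degrees()
    pi = mol.pi_electrons()
    return tuple((mol.elements[i], deg[i], pi[i]) for i in range(mol.n_atoms))


def atom_pair_multiset(mol: MoleculeGraph) -> Counter:
    """Multiset of (type, type, topological distance) descriptors, endpoint
    types unordered; one descriptor per unordered heavy-atom pair."""
    types = atom_types(mol)
    pairs: Counter = Counter()
    for (i, j), d in mol.shortest_path_lengths().items():
        t1, t2 = sorted((types[i], types[j]))
        pairs[(t1, t2, d)] += 1
    return pairs


def atom_pair_tanimoto(a: MoleculeGraph, b: MoleculeGraph) -> float:
    """Multiset Tanimoto on Carhart atom-pair descriptors."""
    if a.n_atoms == 0 or b.n_atoms == 0:
        raise ValueError("empty molecule")
    pa, pb = atom_pair_multiset(a), atom_pair_multiset(b)
    inter = sum(min(pa[k], pb[k]) for k in pa.keys() & pb.keys())
    union = sum((pa | pb).values())
    return inter / union if union else 1.0


# ---------------------------------------------------------------------------
# panel matrices and the structure-tuning regression
# ---------------------------------------------------------------------------

def pair_scores(letters=("M", "L", "I", "H", "K", "R", "F", "W"),
                by_reference_listing: bool = False) -> pd.DataFrame:
    """MCS and atom-pair Tanimoto for every unordered panel pair."""
    rows = []
    for i, la in enumerate(letters):
        for lb in letters[i + 1:]:
            ma = resolve(la, by_reference_listing)
            mb = resolve(lb, by_reference_listing)
            rows.append({"pair": f"{la}/{lb}", "a": la, "b": lb,
                         "mcs": mcs_tanimoto(ma, mb),
                         "atom_pair": atom_pair_tanimoto(ma, mb)})
    return pd.DataFrame(rows)


def similarity_matrix(letters=("M", "L", "I", "H", "K", "R", "F", "W"),
                      by_reference_listing: bool = False
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric unit-diagonal MCS and atom-pair similarity matrices."""
    n = len(letters)
    mcs = np.eye(n)
    ap = np.eye(n)
    scores = pair_scores(letters, by_reference_listing)
    index = {l: i for i, l in enumerate(letters)}
    for _, row in scores.iterrows():
        i, j = index[row["a"]], index[row["b"]]
        mcs[i, j] = mcs[j, i] = row["mcs"]
        ap[i, j] = ap[j, i] = row["atom_pair"]
    mcs_df = pd.DataFrame(mcs, index=list(letters), columns=list(letters))
    ap_df = pd.DataFrame(ap, index=list(letters), columns=list(letters))
    return mcs_df, ap_df


def cluster_distance_vs_similarity(cluster_distances: dict[frozenset, float],
                                   scores: dict[frozenset, float]):
    """Regress tuning-derived cluster distances on structural similarity.

    Both inputs are keyed by unordered stimulus pairs; returns the OLS slope,
    R-squared and two-sided p-value of the slope-equals-zero test. A negative
    significant slope means structurally similar stimuli sit close in tuning
    space.
    """
    from .stats import ols_slope_test
    keys = sorted(cluster_distances.keys() & scores.keys(),
                  key=lambda k: sorted(k))
    if len(keys) < 3:
        raise ValueError("need at least 3 stimulus pairs for the regression")
    x = np.array([scores[k] for k in keys], dtype=float)
    y = np.array([cluster_distances[k] for k in keys], dtype=float)
    return ols_slope_test(x, y)
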