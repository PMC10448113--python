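"""Morphometry of a synthetic cohort of 61 mitral/tufted cells: density-based
tuft detection, convex-hull tuft volumes, the nine-feature morphometric
vector, the tuft-count distribution and the standardized population PCA.

Writes the feature and PCA tables to results/morpho/ and the per-cell SWC
reconstructions to scratch/morpho_swc/.
"""

from pathlib import Path

import numpy as np

from glomod.morpho import (classify_tuft_count_distribution, feature_table,
                           population_pca, write_swc)
from glomod.synthetic import generate_tree

OUT = Path("results/morpho")
SWC_OUT = Path("scratch/morpho_swc")
N_CELLS = 61
#: Planted tuft-count proportions: mostly uni- and bi-tufted cells.
TUFT_WEIGHTS = {1: 0.45, 2: 0.35, 3: 0.15, 4: 0.05}


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    SWC_OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(11)
    trees, planted = {}, {}
    counts = list(TUFT_WEIGHTS)
    probs = np.array(list(TUFT_WEIGHTS.values()))
    for k in range(N_CELLS):
        n_tufts = int(rng.choice(counts, p=probs))
        tree, truth = generate_tree(n_tufts, nodes_per_tuft=int(rng.integers(5, 10)),
                                    n_basal=int(rng.integers(1, 4)),
                                    seed=int(rng.integers(2**31)))
        name = f"cell{k:03d}"
        trees[name] = tree
        planted[name] = truth["n_tufts"]
        write_swc(tree, SWC_OUT / f"{name}.swc")

    feats = feature_table(trees)
    feats.to_csv(OUT / "features.csv")
    exact = sum(int(feats.loc[n, "n_tufts"]) == planted[n] for n in trees)
    print(f"planted tuft counts recovered for {exact}/{N_CELLS} cells")

    dist = classify_tuft_count_distribution(feats["n_tufts"].astype(int))
    print("tuft-count distribution (fraction of cells):")
    print((dist * 100).round(1).to_string())

    scores, loadings, evr, dropped = population_pca(feats)
    scores.to_csv(OUT / "pca_scores.csv")
    loadings.to_csv(OUT / "pca_loadings.csv")
    print(f"PCA: PC1 {evr[0]:.1%}, PC2 {evr[1]:.1%} of variance"
          + (f"; dropped constant features {dropped}" if dropped else ""))
    print("PC1 loadings (trade-off between tuft number and per-tuft size):")
    print(loadings["PC1"].round(2).to_string())


if __name__ == "__main__":
    main()
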