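"""Compute the Tanimoto similarity matrices of the eight amino-acid stimuli
(exhaustive connected MCS and Carhart atom pairs) and regress the
tuning-derived normalized cluster distances on structural similarity: a
negative slope means structurally similar stimuli evoke similar tuning.

Reads results/tuning/cluster_distances.csv; writes results/chemsim/.
"""

from pathlib import Path

import pandas as pd

from glomod.chem import cluster_distance_vs_similarity, similarity_matrix
from glomod.protocol import PANEL
from glomod.tuning import cluster_distance_map

IN, OUT = Path("results/tuning"), Path("results/chemsim")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    mcs_m, ap_m = similarity_matrix(PANEL, by_reference_listing=True)
    mcs_m.to_csv(OUT / "tanimoto_mcs.csv")
    ap_m.to_csv(OUT / "tanimoto_atom_pair.csv")
    print("MCS Tanimoto matrix:")
    print(mcs_m.round(2).to_string())
    print("key published pairs: "
          f"K/R {mcs_m.loc['K', 'R']:.2f} (MCS) {ap_m.loc['K', 'R']:.2f} (AP), "
          f"W/F {mcs_m.loc['W', 'F']:.2f} / {ap_m.loc['W', 'F']:.2f}, "
          f"M/L {mcs_m.loc['M', 'L']:.2f} / {ap_m.loc['M', 'L']:.2f}")

    cluster_csv = IN / "cluster_distances.csv"
    if not cluster_csv.exists():
        print("no cluster distances yet - run 03_tuning_analysis.py first")
        return
    distances = cluster_distance_map(pd.read_csv(cluster_csv))
    for name, mat in (("mcs", mcs_m), ("atom_pair", ap_m)):
        scores = {frozenset((a, b)): mat.loc[a, b]
                  for a in PANEL for b in PANEL if a < b}
        res = cluster_distance_vs_similarity(distances, scores)
        print(f"cluster distance vs {name} similarity: "
              f"slope {res.extra['slope']:.3f}, R2 {res.extra['r_squared']:.3f}, "
              f"p {res.p_value:.4f} {res.stars}")
        pd.Series(res.to_dict()).to_json(OUT / f"regression_{name}.json")


if __name__ == "__main__":
    main()
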