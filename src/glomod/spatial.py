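"""Spatial organization of glomerular species: territories and chemotopy.

Positions are normalized to the manually defined boundaries of the
glomerular cluster along the medio-lateral, caudo-rostral and ventro-dorsal
axes, so every coordinate lies in [0, 1]. On top of the normalized map the
module computes species territories (centroid + per-axis SD ellipsoid),
inter-centroid distances split by structural similarity of the preferred
stimuli, the centroid deviation of compound-profile species, and the two
juxtaposition analyses (distance vs. trace correlation; distance by shared
dominant tuning).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .stats import TestResult, ols_slope_test, omnibus_kw, posthoc_dunn, two_group
from .tuning import TuningClassification

#: Stimulus groups with similar molecular receptive range.
SIMILAR_GROUPS = (frozenset("HFW"), frozenset("KR"), frozenset("MLI"))


def normalize_positions(centroids: np.ndarray, boundaries, tolerance: float = 0.0,
                        roi_ids=None) -> np.ndarray:
    """Affine map of μm coordinates to the unit cube given per-axis (min, max)
    boundary coordinates. Points outside the boundaries beyond ``tolerance``
    (in μm) are rejected with the offending ROI named."""
    pts = np.atleast_2d(np.asarray(centroids, dtype=float))
    bounds = np.asarray(boundaries, dtype=float)
    if bounds.shape != (3, 2) or np.any(bounds[:, 1] <= bounds[:, 0]):
        raise ValueError("boundaries must be three (min, max) pairs with max > min")
    lo, hi = bounds[:, 0], bounds[:, 1]
    bad = np.nonzero(np.any((pts < lo - tolerance) | (pts > hi + tolerance), axis=1))[0]
    if bad.size:
        ident = roi_ids[bad[0]] if roi_ids is not None else f"index {bad[0]}"
        raise ValueError(f"position of ROI {ident} outside the declared boundaries")
    return np.clip((pts - lo) / (hi - lo), 0.0, 1.0)


def denormalize_positions(normalized: np.ndarray, boundaries) -> np.ndarray:
    """Inverse of :func:`normalize_positions`."""
    bounds = np.asarray(boundaries, dtype=float)
    return np.atleast_2d(normalized) * (bounds[:, 1] - bounds[:, 0]) + bounds[:, 0]


@dataclass(frozen=True)
class SpeciesTerritory:
    label: str
    centroid: np.ndarray     # normalized (x, y, z)
    sd: np.ndarray           # per-axis SD (1x SD ellipsoid semi-axes)
    n_members: int


def species_territories(positions: dict[str, np.ndarray],
                        classifications: dict[str, TuningClassification],
                        tuning_kind: str = "dominant") -> dict[str, SpeciesTerritory]:
    """One territory per observed tuning label: per-axis centroid and SD."""
    members: dict[str, list[np.ndarray]] = {}
    for roi_id, cls in classifications.items():
        label = cls.label if tuning_kind == "dominant" else cls.default_label
        if not label:
            continue
        members.setdefault(label, []).append(np.asarray(positions[roi_id], dtype=float))
    out = {}
    for label, pts in members.items():
        arr = np.vstack(pts)
        sd = arr.std(axis=0) if len(pts) > 1 else np.zeros(3)
        out[label] = SpeciesTerritory(label, arr.mean(axis=0), sd, len(pts))
    return out


def territories_to_frame(territories: dict[str, SpeciesTerritory]) -> pd.DataFrame:
    rows = [{"label": t.label, "n": t.n_members,
             "cx": t.centroid[0], "cy": t.centroid[1], "cz": t.centroid[2],
             "sdx": t.sd[0], "sdy": t.sd[1], "sdz": t.sd[2]}
            for t in territories.values()]
    return pd.DataFrame(rows).set_index("label")


def _is_similar_pair(label_a: str, label_b: str,
                     groups=SIMILAR_GROUPS) -> bool:
    """True when both labels' stimuli fall within one similar-group."""
    stimuli = set(label_a) | set(label_b)
    return any(stimuli <= g for g in groups)


def intercentroid_distances(territories: dict[str, SpeciesTerritory],
                            similar_groups=SIMILAR_GROUPS
                            ) -> tuple[pd.DataFrame, TestResult]:
    """Euclidean distances between species-pair centroids, partitioned into
    pairs of structurally similar vs. dissimilar stimuli, with a Mann-Whitney
    comparison of the two distance populations."""
    if len(territories) < 2:
        raise ValueError("need at least 2 territories")
    rows = []
    for a, b in combinations(sorted(territories), 2):
        d = float(np.linalg.norm(territories[a].centroid - territories[b].centroid))
        rows.append({"a": a, "b": b, "distance": d,
                     "similar": _is_similar_pair(a, b, similar_groups)})
    table = pd.DataFrame(rows)
    similar = table.loc[table["similar"], "distance"].to_numpy()
    dissimilar = table.loc[~table["similar"], "distance"].to_numpy()
    if similar.size and dissimilar.size:
        test = two_group(similar, dissimilar, names=("similar", "dissimilar"))
    else:
        test = TestResult("mann-whitney-u", np.nan, np.nan,
                          (similar.size, dissimilar.size),
                          groups=("similar", "dissimilar"),
                          extra={"skipped": "one partition empty"})
    return table, test


def compound_centroid_deviation(territories: dict[str, SpeciesTerritory],
                                similar_groups=SIMILAR_GROUPS):
    """Positional deviation of compound-profile species from their
    constituents' hypothetical centroid.

    For every 2-3 letter species (e.g. "HFW") whose constituent single-letter
    species all exist, the deviation is the Euclidean distance between the
    compound species' centroid and the unweighted mean of the constituent
    single-species centroids. Compounds of structurally similar stimuli are
    compared against all remaining compounds (Mann-Whitney). Compounds with a
    missing constituent are skipped and logged.
    """
    rows, skipped = [], []
    for label, terr in territories.items():
        if not 2 <= len(label) <= 3:
            continue
        constituents = list(label)
        missing = [c for c in constituents if c not in territories]
        if missing:
            skipped.append({"label": label, "missing": "".join(missing)})
            continue
        hypothetical = np.mean([territories[c].centroid for c in constituents], axis=0)
        deviation = float(np.linalg.norm(terr.centroid - hypothetical))
        similar = any(set(label) <= g for g in similar_groups)
        rows.append({"label": label, "deviation": deviation, "similar": similar})
    table = pd.DataFrame(rows, columns=["label", "deviation", "similar"])
    sim = table.loc[table["similar"], "deviation"].to_numpy()
    rest = table.loc[~table["similar"], "deviation"].to_numpy()
    if sim.size and rest.size:
        test = two_group(sim, rest, names=("similar_compounds", "other_compounds"))
    else:
        test = TestResult("mann-whitney-u", np.nan, np.nan, (sim.size, rest.size),
                          groups=("similar_compounds", "other_compounds"),
                          extra={"skipped": "one cohort empty"})
    return table, test, skipped


def distance_vs_trace_correlation(positions: dict[str, np.ndarray],
                                  traces: dict[str, np.ndarray]
                                  ) -> tuple[pd.DataFrame, TestResult]:
    """Interglomerular distance vs. Pearson correlation of raw traces.

    All unordered ROI pairs; degenerate (constant) traces are excluded
    pairwise. Returns the scatter table and the OLS slope test of
    correlation on distance."""
    ids = [i for i in positions if i in traces]
    if len(ids) < 3:
        raise ValueError("need at least 3 ROIs with both position and trace")
    rows = []
    for a, b in combinations(ids, 2):
        ta, tb = np.asarray(traces[a], float), np.asarray(traces[b], float)
        if np.ptp(ta) == 0 or np.ptp(tb) == 0:
            continue
        rows.append({
            "a": a, "b": b,
            "distance": float(np.linalg.norm(np.asarray(positions[a], float)
                                             - np.asarray(positions[b], float))),
            "correlation": float(np.corrcoef(ta, tb)[0, 1]),
        })
    table = pd.DataFrame(rows)
    test = ols_slope_test(table["distance"], table["correlation"])
    return table, test


def shared_tuning_distance(positions: dict[str, np.ndarray],
                           classifications: dict[str, TuningClassification]):
    """Pairwise distances binned by dominant-tuning overlap.

    Categories: no common stimulus / at least one common / all stimuli in
    common; compared by Kruskal-Wallis with Dunn/Bonferroni post-hocs over
    the non-empty categories."""
    ids = [i for i, c in classifications.items() if c.dominant_set]
    rows = []
    for a, b in combinations(ids, 2):
        sa, sb = set(classifications[a].dominant_set), set(classifications[b].dominant_set)
        common = sa & sb
        if not common:
            cat = "none_common"
        elif common == sa == sb:
            cat = "all_common"
        else:
            cat = "some_common"
        rows.append({"a": a, "b": b, "category": cat,
                     "distance": float(np.linalg.norm(
                         np.asarray(positions[a], float) - np.asarray(positions[b], float)))})
    table = pd.DataFrame(rows, columns=["a", "b", "category", "distance"])
    groups, names, empty = [], [], []
    for cat in ("none_common", "some_common", "all_common"):
        vals = table.loc[table["category"] == cat, "distance"].to_numpy()
        if vals.size:
            groups.append(vals)
            names.append(cat)
        else:
            empty.append(cat)
    if len(groups) < 2:
        raise ValueError("fewer than 2 non-empty tuning-overlap categories")
    omnibus = omnibus_kw(groups, names)
    posthoc = posthoc_dunn(groups, names) if len(groups) > 2 else []
    return table, omnibus, posthoc, empty
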