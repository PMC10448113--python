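"""Odor-tuning classification and tuning-space statistics.

A region's *default* odor tuning is the set of stimuli whose response peak
exceeds 2x the SD of the averaged baseline fluorescence; the *dominant*
tuning uses 3x. Tuning labels concatenate single-letter codes in the fixed
panel order (e.g. "HFW"). On top of the classification this module computes
lifetime sparseness, Pearson correlation matrices, average-linkage
hierarchical clustering with normalized cluster distances, tuning-broadness
histograms, glomerular-species frequency tables, odor-space coordinates and
cross-population correlation-distribution comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .protocol import PANEL
from .traces import ResponseProfile

_PANEL_RANK = {c: i for i, c in enumerate(PANEL)}


@dataclass(frozen=True)
class TuningClassification:
    roi_id: str
    default_set: tuple[str, ...]
    dominant_set: tuple[str, ...]

    def __post_init__(self):
        if not set(self.dominant_set) <= set(self.default_set):
            raise ValueError("dominant tuning must be a subset of default tuning")

    @property
    def label(self) -> str:
        """Dominant tuning label in fixed panel order, e.g. 'HFW'."""
        return "".join(sorted(self.dominant_set, key=_PANEL_RANK.get))

    @property
    def default_label(self) -> str:
        return "".join(sorted(self.default_set, key=_PANEL_RANK.get))


def classify_tuning(profile: ResponseProfile, default_factor: float = 2.0,
                    dominant_factor: float = 3.0, panel=PANEL) -> TuningClassification:
    """Threshold the single-stimulus peaks at 2x/3x the baseline SD."""
    sd = profile.baseline_sd
    default = tuple(c for c in panel
                    if profile.amplitudes.get(c, 0.0) > default_factor * sd
                    and profile.amplitudes.get(c, 0.0) > 0)
    dominant = tuple(c for c in default
                     if profile.amplitudes[c] > dominant_factor * sd)
    return TuningClassification(profile.roi_id, default, dominant)


def lifetime_sparseness(r, n_stimuli: int | None = None) -> float:
    """Lifetime sparseness of a non-negative response vector.

    sparseness = [1 - (Σr_n/N)² / (Σr_n²/N)] / (1 - 1/N): 0 for a region
    responding equally strongly to all stimuli, 1 for one responding to
    exactly one.
    """
    r = np.asarray(r, dtype=float)
    n = n_stimuli if n_stimuli is not None else r.size
    if n < 2:
        raise ValueError("sparseness needs at least 2 stimuli")
    if np.any(r < 0):
        raise ValueError("response amplitudes must be non-negative")
    sum_sq = float(np.sum(r**2))
    if sum_sq == 0:
        raise ValueError("sparseness undefined for an all-zero response vector")
    value = (1.0 - (np.sum(r) / n) ** 2 / (sum_sq / n)) / (1.0 - 1.0 / n)
    # clamp the tiny negative round-off a uniform vector can produce
    return float(min(1.0, max(0.0, value)))


# ---------------------------------------------------------------------------
# correlation structure
# ---------------------------------------------------------------------------

def amplitude_matrix(profiles: list[ResponseProfile], panel=PANEL) -> pd.DataFrame:
    """ROIs x stimuli matrix of panel-normalized response peak amplitudes."""
    data = {p.roi_id: p.single_stimulus_vector(panel) for p in profiles}
    return pd.DataFrame(data, index=list(panel)).T


def correlation_matrix(vectors: pd.DataFrame, by: str = "stimulus") -> pd.DataFrame:
    """Pearson correlation matrix of pooled amplitude vectors.

    ``by='stimulus'`` correlates the pooled per-stimulus columns across ROIs;
    ``by='roi'`` correlates the per-ROI tuning vectors. Zero-variance vectors
    yield NaN entries (flagged by pandas semantics).
    """
    if by not in ("stimulus", "roi"):
        raise ValueError("by must be 'stimulus' or 'roi'")
    mat = vectors if by == "stimulus" else vectors.T
    if mat.shape[1] < 2 or mat.shape[0] < 2:
        raise ValueError("need at least 2 vectors of length >= 2")
    return mat.corr(method="pearson")


def hierarchical_cluster(vectors: pd.DataFrame):
    """Average-linkage clustering of stimuli on correlation distance.

    Distance d = 1 - Pearson r between pooled per-stimulus amplitude
    columns. Returns (scipy linkage matrix, normalized cluster-distance
    table): per stimulus pair the cophenetic merge height divided by the
    maximum merge height, so the most distant pair scores 1.
    """
    if vectors.shape[1] < 3:
        raise ValueError("hierarchical clustering needs at least 3 stimuli")
    corr = vectors.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    cophenetic = squareform(hierarchy.cophenet(linkage))
    max_height = cophenetic.max()
    labels = list(vectors.columns)
    rows = []
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            h = cophenetic[i, j]
            rows.append({"a": a, "b": labels[j], "cophenetic": h,
                         "cluster_distance": h / max_height if max_height > 0 else 0.0})
    return linkage, pd.DataFrame(rows)


def cluster_distance_map(table: pd.DataFrame) -> dict[frozenset, float]:
    """Normalized cluster distances keyed by unordered stimulus pair."""
    return {frozenset((r["a"], r["b"])): r["cluster_distance"]
            for _, r in table.iterrows()}


# ---------------------------------------------------------------------------
# population summaries
# ---------------------------------------------------------------------------

def tuning_broadness(classifications: list[TuningClassification],
                     kind: str = "dominant", panel=PANEL) -> pd.Series:
    """Histogram of tuning breadth (number of supra-threshold stimuli)."""
    if not classifications:
        raise ValueError("no classifications")
    attr = "dominant_set" if kind == "dominant" else "default_set"
    sizes = [len(getattr(c, attr)) for c in classifications]
    counts = pd.Series(0, index=range(len(panel) + 1), name=kind)
    for s in sizes:
        counts[s] += 1
    return counts


def species_table(labels_per_animal: dict[str, list[str]]) -> pd.DataFrame:
    """Glomerular-species frequencies across animals.

    Input: per animal, the list of tuning labels of its classified ROIs.
    Output: one row per species with per-animal counts, mean ± SD across
    animals, and the fraction of animals lacking the species, ranked by mean
    occurrence.
    """
    if not labels_per_animal:
        raise ValueError("need at least one animal")
    animals = list(labels_per_animal)
    species = sorted({lbl for labels in labels_per_animal.values() for lbl in labels})
    counts = pd.DataFrame(0, index=species, columns=animals)
    for animal, labels in labels_per_animal.items():
        for lbl in labels:
            counts.loc[lbl, animal] += 1
    out = pd.DataFrame({
        "mean": counts.mean(axis=1),
        "sd": counts.std(axis=1, ddof=1) if len(animals) > 1 else 0.0,
        "lacking_ratio": (counts == 0).mean(axis=1),
    })
    out = pd.concat([out, counts], axis=1)
    return out.sort_values("mean", ascending=False)


def odor_space_coordinates(profile: ResponseProfile,
                           axis_pairs=(("R", "W"), ("K", "H"), ("M", "I")),
                           panel=PANEL) -> np.ndarray:
    """Coordinates of one ROI in the amplitude-difference odor space.

    coordinate_k = r_a - r_b for each configured pair, each in [-1, 1] for
    panel-normalized amplitudes."""
    r = dict(zip(panel, profile.single_stimulus_vector(panel)))
    coords = []
    for a, b in axis_pairs:
        if a not in r or b not in r:
            raise KeyError(f"axis pair ({a},{b}) not covered by the panel")
        coords.append(r[a] - r[b])
    return np.array(coords)


def correlation_distribution_compare(groups: dict[str, np.ndarray],
                                     threshold: float = 0.7):
    """All-pairs Pearson correlations within each named group of amplitude
    vectors (rows), ranked, with the fraction above ``threshold`` and
    pairwise Mann-Whitney comparisons between groups."""
    from .stats import two_group
    ranked: dict[str, np.ndarray] = {}
    fractions: dict[str, float] = {}
    for name, mat in groups.items():
        mat = np.asarray(mat, dtype=float)
        if mat.shape[0] < 2:
            raise ValueError(f"group {name!r} needs at least 2 vectors")
        degenerate = np.ptp(mat, axis=1) == 0
        mat = mat[~degenerate]
        corr = np.corrcoef(mat)
        iu = np.triu_indices_from(corr, k=1)
        coeffs = np.sort(corr[iu])[::-1]
        ranked[name] = coeffs
        fractions[name] = float(np.mean(coeffs > threshold)) if coeffs.size else np.nan
    names = list(ranked)
    tests = [two_group(ranked[a], ranked[b], names=(a, b))
             for i, a in enumerate(names) for b in names[i + 1:]]
    return ranked, fractions, tests
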