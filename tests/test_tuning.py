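from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glomod.protocol import PANEL
from glomod.traces import ResponseProfile
from glomod.tuning import (TuningClassification, amplitude_matrix,
                           classify_tuning, correlation_distribution_compare,
                           correlation_matrix, hierarchical_cluster,
                           lifetime_sparseness, odor_space_coordinates,
                           species_table, tuning_broadness)


def _profile(amplitudes, sd=0.1, roi_id="r"):
    return ResponseProfile(roi_id, amplitudes, sd)


# -- classification ----------------------------------------------------------

def test_classification_thresholds():
    amps = {"H": 0.9, "F": 0.5, "W": 0.4, "M": 0.05, "L": 0.05, "I": 0.05,
            "K": 0.05, "R": 0.05}
    cls = classify_tuning(_profile(amps, sd=0.1))
    assert set(cls.default_set) == {"H", "F", "W"}
    assert set(cls.dominant_set) == {"H", "F", "W"}
    assert cls.label == "HFW"  # panel order M,L,I,H,K,R,F,W


def test_all_zero_amplitudes_give_empty_sets():
    cls = classify_tuning(_profile({c: 0.0 for c in PANEL}, sd=0.0))
    assert cls.default_set == () and cls.dominant_set == () and cls.label == ""


def test_zero_sd_includes_every_positive_response():
    amps = {c: (0.2 if c in "KW" else 0.0) for c in PANEL}
    cls = classify_tuning(_profile(amps, sd=0.0))
    assert set(cls.default_set) == set(cls.dominant_set) == {"K", "W"}


def test_dominant_subset_of_default_enforced():
    amps = {"H": 0.25, **{c: 0.0 for c in PANEL if c != "H"}}
    cls = classify_tuning(_profile(amps, sd=0.1))
    assert cls.default_set == ("H",) and cls.dominant_set == ()
    with pytest.raises(ValueError):
        TuningClassification("x", ("H",), ("H", "W"))


# -- sparseness --------------------------------------------------------------

def test_sparseness_reference_values():
    assert lifetime_sparseness(np.full(8, 0.3)) == 0.0
    one_hot = np.zeros(8)
    one_hot[2] = 0.7
    assert lifetime_sparseness(one_hot) == 1.0
    assert lifetime_sparseness([1.0, 0.5]) == pytest.approx(0.2)


def test_sparseness_errors():
    with pytest.raises(ValueError, match="all-zero"):
        lifetime_sparseness(np.zeros(8))
    with pytest.raises(ValueError, match="at least 2"):
        lifetime_sparseness([1.0])
    with pytest.raises(ValueError, match="non-negative"):
        lifetime_sparseness([1.0, -0.1])


@settings(deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=8).filter(
    lambda r: sum(r) > 0.01))
def test_sparseness_bounded_and_scale_invariant(r):
    s = lifetime_sparseness(r)
    assert 0.0 <= s <= 1.0
    assert lifetime_sparseness(np.array(r) * 7.3) == pytest.approx(s, abs=1e-9)


def test_sparseness_decreases_from_one_hot_toward_uniform():
    """Along the convex path (1-t) * one_hot + t * uniform the statistic
    falls monotonically from 1 to 0."""
    one_hot = np.zeros(8)
    one_hot[0] = 1.0
    uniform = np.full(8, 1.0)
    values = [lifetime_sparseness((1 - t) * one_hot + t * uniform)
              for t in np.linspace(0.0, 1.0, 11)]
    assert values[0] == 1.0 and values[-1] == 0.0
    assert all(a > b for a, b in zip(values, values[1:]))


# -- correlation and clustering ---------------------------------------------

def test_correlation_matrix_reference_cases():
    mat = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0],
                        "b": [1.0, 2.0, 3.0, 4.0],
                        "c": [4.0, 3.0, 2.0, 1.0]})
    corr = correlation_matrix(mat, by="stimulus")
    assert corr.loc["a", "b"] == pytest.approx(1.0)
    assert corr.loc["a", "c"] == pytest.approx(-1.0)
    assert np.allclose(np.diag(corr), 1.0)
    assert np.allclose(corr, corr.T)


def test_independent_long_vectors_nearly_uncorrelated(rng):
    n = 4000
    mat = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
    corr = correlation_matrix(mat)
    assert abs(corr.loc["a", "b"]) < 3.0 / np.sqrt(n)


def _brute_force_average_linkage(dist: np.ndarray):
    """Exhaustive average-linkage agglomeration; returns merge heights per
    leaf pair (cophenetic matrix)."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph


def test_average_linkage_matches_brute_force_oracle(rng):
    for _ in range(5):
        mat = pd.DataFrame(rng.normal(size=(30, 4)),
                           columns=["a", "b", "c", "d"])
        _, table = hierarchical_cluster(mat)
        corr = mat.corr().to_numpy()
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        coph = _brute_force_average_linkage(dist)
        labels = list(mat.columns)
        for _, row in table.iterrows():
            i, j = labels.index(row["a"]), labels.index(row["b"])
            assert row["cophenetic"] == pytest.approx(coph[i, j])
        assert table["cluster_distance"].max() == pytest.approx(1.0)


def test_identical_columns_merge_first_at_zero():
    mat = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0],
                        "c": [3.0, 1.0, 2.0]})
    linkage, table = hierarchical_cluster(mat)
    # a and b are perfectly correlated -> merge height 0, first merge
    pair = table.set_index(["a", "b"])
    assert pair.loc[("a", "b"), "cophenetic"] == pytest.approx(0.0, abs=1e-12)
    assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="3 stimuli"):
        hierarchical_cluster(mat[["a", "b"]])


# -- population summaries ----------------------------------------------------

def test_tuning_broadness_histogram():
    cls = [TuningClassification("a", ("W",), ("W",)),
           TuningClassification("b", ("K",), ("K",)),
           TuningClassification("c", ("H", "F", "W"), ("H", "F", "W"))]
    hist = tuning_broadness(cls, "dominant")
    assert hist[1] == 2 and hist[3] == 1 and hist.sum() == 3
    default = tuning_broadness(cls, "default")
    assert default.sum() == hist.sum()


def test_species_table_counts_and_lacking_ratio():
    table = species_table({"an1": ["W", "W", "R"], "an2": ["W"],
                           "an3": [], "an4": ["R"]})
    assert table.loc["W", "an1"] == 2
    assert table.loc["W", "mean"] == pytest.approx(3 / 4)
    assert table.loc["R", "lacking_ratio"] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        species_table({})


def test_species_frequencies_recovered_on_synthetic_cohort(protocol):
    """Planted species frequencies come back within binomial error across a
    simulated cohort of animals."""
    from glomod.synthetic import generate_roi_dataset
    spec = {"W": 0.6, "KR": 0.4}
    labels = {}
    for animal in range(4):
        _, gt = generate_roi_dataset(60, protocol, tuning_spec=spec,
                                     seed=100 + animal)
        labels[f"an{animal}"] = [e["label"] for e in gt.rois.values()]
    table = species_table(labels)
    p_hat = table.loc["W", "mean"] / 60.0
    assert p_hat == pytest.approx(0.6, abs=3 * np.sqrt(0.6 * 0.4 / 240))


def test_odor_space_coordinates():
    amps = {c: 0.0 for c in PANEL}
    amps["R"] = 1.0
    point = odor_space_coordinates(_profile(amps))
    assert point[0] == pytest.approx(1.0)          # R - W axis
    equal = _profile({c: 0.5 for c in PANEL})
    assert np.allclose(odor_space_coordinates(equal), 0.0)
    assert np.all(np.abs(point) <= 1.0)
    with pytest.raises(KeyError):
        odor_space_coordinates(_profile(amps), axis_pairs=(("R", "Z"),))


def test_correlation_distribution_compare(rng):
    archetype = rng.uniform(size=8)
    coherent = archetype + rng.normal(0, 0.05, size=(12, 8))
    independent = rng.uniform(size=(12, 8))
    ranked, fractions, tests = correlation_distribution_compare(
        {"coherent": coherent, "independent": independent})
    assert fractions["coherent"] > fractions["independent"]
    assert np.median(ranked["coherent"]) > np.median(ranked["independent"])
    assert tests[0].p_value < 0.01
    identical = np.tile(archetype, (3, 1)) + 1e-12 * rng.normal(size=(3, 8))
    ranked_i, fractions_i, _ = correlation_distribution_compare(
        {"same": identical, "other": independent})
    assert fractions_i["same"] == 1.0
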