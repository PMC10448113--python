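"""End-to-end orchestration of the synthetic odor-map analysis.

``run_pipeline`` executes the stages in dependency order — simulate,
process, tuning, chemical similarity, spatial statistics, morphometry,
projection color — and writes CSV/JSON artifacts plus a JSON report into
the output directory. Every stage draws its seed deterministically from the
single root seed, so a rerun with the same configuration reproduces the
report byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem, colorproj, morpho, spatial, synthetic, traces, tuning
from .protocol import PANEL, make_protocol

#: Fixed per-stage seed offsets below 2**31.
_STAGE_SEEDS = {"simulate": 11, "trees": 23, "volume": 37}


@dataclass
class RunConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    n_rois: int = 200
    n_trees: int = 12
    snr: float = 10.0
    repeats: int = 4
    frame_rate: float = 1.0
    layout: str = "random"
    min_area: float = 25.0
    response_sd_factor: float = 3.0
    min_responses: int = 2
    default_factor: float = 2.0
    dominant_factor: float = 3.0
    als_lambda: float = 1e4
    als_p: float = 0.01
    tuft_eps: float = 15.0
    tuft_min_points: int = 5
    color_ratio: float = 2.0
    stages: tuple[str, ...] = ("simulate", "process", "tuning", "chemsim",
                               "spatial", "morpho", "color")

    def stage_seed(self, name: str) -> int:
        return (self.seed * 1009 + _STAGE_SEEDS.get(name, 0)) % (2**31)


def validate_inputs(dataset_dir) -> dict:
    """Schema validation of a saved ROI dataset; returns a report dict."""
    report = {"ok": True, "errors": []}
    try:
        records, protocol, _ = synthetic.load_roi_dataset(dataset_dir)
    except Exception as exc:  # noqa: BLE001 - reported, not raised
        return {"ok": False, "errors": [f"unreadable dataset: {exc}"]}
    for rec in records:
        if rec.raw_trace.size != protocol.n_frames:
            report["ok"] = False
            report["errors"].append(
                f"{rec.roi_id}: trace length {rec.raw_trace.size} != "
                f"protocol n_frames {protocol.n_frames}")
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns the report dict (also written
    to ``outdir/report.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config)}
    state: dict = {}

    for stage in config.stages:
        runner = _STAGE_RUNNERS.get(stage)
        if runner is None:
            raise ValueError(f"unknown stage {stage!r}")
        missing = [dep for dep in _STAGE_DEPS.get(stage, ()) if dep not in report]
        if missing:
            raise RuntimeError(f"stage {stage!r} requires earlier stage(s) "
                               f"{missing}; add them to config.stages")
        report[stage] = runner(config, state, out)

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True,
                                                default=_jsonable))
    (out / "config.json").write_text(json.dumps(asdict(config), indent=1))
    return report


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, state: dict, out: Path) -> dict:
    protocol = make_protocol(repeats=config.repeats, frame_rate=config.frame_rate,
                             seed=config.stage_seed("simulate"))
    records, gt = synthetic.generate_roi_dataset(
        config.n_rois, protocol, snr=config.snr,
        seed=config.stage_seed("simulate"), layout=config.layout)
    synthetic.save_roi_dataset(out / "dataset", records, protocol, gt)
    state.update(records=records, protocol=protocol, ground_truth=gt)
    return {"n_rois": len(records), "n_events": len(protocol.events),
            "n_frames": protocol.n_frames}


def _stage_process(config: RunConfig, state: dict, out: Path) -> dict:
    kept, profiles, processed, log = traces.process_dataset(
        state["records"], state["protocol"],
        smoothness=config.als_lambda, asymmetry=config.als_p,
        min_area=config.min_area, response_sd_factor=config.response_sd_factor,
        min_responses=config.min_responses)
    traces.profiles_to_frame(profiles).to_csv(out / "profiles.csv")
    (out / "exclusions.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    state.update(kept=kept, profiles=profiles, processed=processed)
    rule_tally: dict[str, int] = {}
    for rules in log.values():
        for r in rules:
            key = r.split(":")[0] if r.startswith("manual") else r
            rule_tally[key] = rule_tally.get(key, 0) + 1
    return {"n_in": len(state["records"]), "n_kept": len(kept),
            "n_excluded": len(log), "rule_tally": rule_tally}


def _stage_tuning(config: RunConfig, state: dict, out: Path) -> dict:
    kept_profiles = [state["profiles"][r.roi_id] for r in state["kept"]]
    classifications = {p.roi_id: tuning.classify_tuning(
        p, config.default_factor, config.dominant_factor) for p in kept_profiles}
    sparseness = {p.roi_id: tuning.lifetime_sparseness(p.single_stimulus_vector())
                  for p in kept_profiles
                  if p.single_stimulus_vector().sum() > 0}
    amp = tuning.amplitude_matrix(kept_profiles)
    corr = tuning.correlation_matrix(amp, by="stimulus")
    linkage, cluster_table = tuning.hierarchical_cluster(amp)
    broadness = {kind: tuning.tuning_broadness(list(classifications.values()), kind)
                 for kind in ("default", "dominant")}
    pd.DataFrame({"label": {i: c.label for i, c in classifications.items()},
                  "default_label": {i: c.default_label
                                    for i, c in classifications.items()}}
                 ).to_csv(out / "classifications.csv", index_label="roi_id")
    corr.to_csv(out / "stimulus_correlation.csv")
    cluster_table.to_csv(out / "cluster_distances.csv", index=False)
    state.update(classifications=classifications, cluster_table=cluster_table,
                 amplitude_matrix=amp)
    return {"n_classified": len(classifications),
            "median_sparseness": float(np.median(list(sparseness.values())))
            if sparseness else None,
            "broadness_dominant": broadness["dominant"].to_dict()}


def _stage_chemsim(config: RunConfig, state: dict, out: Path) -> dict:
    mcs_m, ap_m = chem.similarity_matrix(PANEL, by_reference_listing=True)
    mcs_m.to_csv(out / "tanimoto_mcs.csv")
    ap_m.to_csv(out / "tanimoto_atom_pair.csv")
    result = {"mcs_matrix": "tanimoto_mcs.csv", "ap_matrix": "tanimoto_atom_pair.csv"}
    if "cluster_table" in state:
        distances = tuning.cluster_distance_map(state["cluster_table"])
        scores = {frozenset((a, b)): mcs_m.loc[a, b]
                  for a in PANEL for b in PANEL if a < b}
        reg = chem.cluster_distance_vs_similarity(distances, scores)
        result["regression"] = reg.to_dict()
    return result


def _stage_spatial(config: RunConfig, state: dict, out: Path) -> dict:
    positions = {r.roi_id: np.asarray(r.centroid) for r in state["kept"]}
    classifications = state["classifications"]
    territories = spatial.species_territories(positions, classifications)
    spatial.territories_to_frame(territories).to_csv(out / "territories.csv")
    result: dict = {"n_territories": len(territories)}
    if len(territories) >= 2:
        table, test = spatial.intercentroid_distances(territories)
        table.to_csv(out / "intercentroid.csv", index=False)
        result["intercentroid_test"] = test.to_dict()
        dev_table, dev_test, skipped = spatial.compound_centroid_deviation(territories)
        dev_table.to_csv(out / "compound_deviation.csv", index=False)
        result["compound_deviation_test"] = dev_test.to_dict()
        result["compound_skipped"] = skipped
    raw = {r.roi_id: r.raw_trace for r in state["kept"]}
    if len(raw) >= 3:
        scatter, slope = spatial.distance_vs_trace_correlation(positions, raw)
        scatter.to_csv(out / "distance_vs_correlation.csv", index=False)
        result["distance_correlation_test"] = slope.to_dict()
    return result


def _stage_morpho(config: RunConfig, state: dict, out: Path) -> dict:
    rng = np.random.default_rng(config.stage_seed("trees"))
    trees, planted = {}, {}
    for k in range(config.n_trees):
        n_tufts = int(rng.integers(1, 4))
        tree, truth = synthetic.generate_tree(
            n_tufts, seed=int(rng.integers(2**31)))
        name = f"cell{k:03d}"
        trees[name] = tree
        planted[name] = truth["n_tufts"]
        morpho.write_swc(tree, out / f"{name}.swc")
    feats = morpho.feature_table(trees, config.tuft_eps, config.tuft_min_points)
    feats.to_csv(out / "morpho_features.csv")
    scores, loadings, evr, dropped = morpho.population_pca(feats)
    scores.to_csv(out / "morpho_pca_scores.csv")
    loadings.to_csv(out / "morpho_pca_loadings.csv")
    dist = morpho.classify_tuft_count_distribution(feats["n_tufts"].astype(int))
    recovered = all(int(feats.loc[n, "n_tufts"]) == planted[n] for n in trees)
    return {"n_cells": len(trees), "tuft_count_distribution": dist.to_dict(),
            "explained_variance": list(map(float, evr)),
            "dropped_features": dropped, "planted_tufts_recovered": recovered}


def _stage_color(config: RunConfig, state: dict, out: Path) -> dict:
    rng = np.random.default_rng(config.stage_seed("volume"))
    shape = (48, 48, 24)
    blobs = []
    for c in range(3):
        xy = rng.uniform(8, 40, size=2)
        blobs.append(((xy[0], xy[1], 6.0), c, 100.0))    # GL blob
        blobs.append(((xy[0], xy[1], 18.0), c, 100.0))   # matching MCL blob
    volume, truth = synthetic.generate_channel_volume(
        shape, blobs, seed=config.stage_seed("volume"), noise_sd=1.0)
    categories = colorproj.classify_voxels(volume, ratio=config.color_ratio,
                                           min_intensity=5.0)
    dists = colorproj.layer_distributions(volume, categories)
    dists.to_csv(out / "color_distributions.csv", index=False)
    same, cross, test, skipped = colorproj.layer_correspondence(volume, categories)
    return {"n_classified": int(np.sum(categories >= 0)),
            "same_color_offsets": same,
            "correspondence_test": test.to_dict(), "skipped_colors": skipped}


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "process": _stage_process,
    "tuning": _stage_tuning,
    "chemsim": _stage_chemsim,
    "spatial": _stage_spatial,
    "morpho": _stage_morpho,
    "color": _stage_color,
}

_STAGE_DEPS = {
    "process": ("simulate",),
    "tuning": ("process",),
    "spatial": ("tuning",),
}
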