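"""Synthetic inputs with exported ground truth.

Real recordings of this kind — multiphoton calcium imaging of glomeruli and
mitral/tufted cells in the larval *Xenopus* olfactory bulb — are not
redistributable, so every input the pipeline consumes is generated here
with known ground truth: stimulus-locked ROI traces with planted odor
tuning, neuron trees with planted dendritic tufts, species position layouts
(random or chemotopic), and 3-channel volumes with planted color blobs.

Traces are modeled as a constant baseline with slow polynomial drift plus
stimulus-locked transients (instantaneous rise, single-exponential decay
with a GCaMP6s-order time constant of 4 s) and white Gaussian noise whose
SD is peak_scale / SNR. The generators make no attempt at biophysical
realism beyond what the downstream analyses need to be exercised honestly;
all randomness flows from explicit seeds and equal seeds give bit-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .colorproj import ChannelVolume
from .morpho import NeuronTree
from .protocol import PANEL, AcquisitionProtocol, make_protocol
from .traces import RoiRecord

#: Default species mix: narrow single-letter species, compound profiles of
#: structurally similar and dissimilar stimuli, and untuned ROIs ("") that
#: only the filtering stage should remove.
DEFAULT_TUNING_SPEC = {
    "W": 0.10, "I": 0.08, "K": 0.08, "H": 0.07, "R": 0.07, "M": 0.06,
    "L": 0.06, "F": 0.06, "KR": 0.08, "HFW": 0.07, "HW": 0.06, "MLI": 0.06,
    "LI": 0.05, "KW": 0.03, "MH": 0.02, "": 0.05,
}

#: Decay time constant of the calcium transient kernel (s), GCaMP6s order.
DEFAULT_TAU_S = 4.0


@dataclass
class GroundTruth:
    """Planted parameters serialized beside every synthetic dataset."""

    rois: dict[str, dict] = field(default_factory=dict)
    trees: dict[str, dict] = field(default_factory=dict)
    volumes: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"rois": self.rois, "trees": self.trees,
                           "volumes": self.volumes}, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(rois=d.get("rois", {}), trees=d.get("trees", {}),
                   volumes=d.get("volumes", {}))


def transient_kernel(times: np.ndarray, onset: float, tau: float = DEFAULT_TAU_S
                     ) -> np.ndarray:
    """Instantaneous rise at ``onset``, exponential decay with ``tau``."""
    dt = times - onset
    return np.where(dt >= 0, np.exp(-np.maximum(dt, 0.0) / tau), 0.0)


# ---------------------------------------------------------------------------
# ROI datasets
# ---------------------------------------------------------------------------

def generate_roi_dataset(n_rois: int, protocol: AcquisitionProtocol,
                         tuning_spec: dict[str, float] | None = None,
                         snr: float = 10.0, seed: int = 0,
                         layout: str = "random",
                         baseline_f: float = 100.0,
                         drift_amplitude: float = 0.05,
                         tau: float = DEFAULT_TAU_S,
                         small_area_fraction: float = 0.1,
                         area_floor: float = 8.0,
                         repeat_jitter: float = 0.05,
                         ) -> tuple[list[RoiRecord], GroundTruth]:
    """Synthesize ROI records with planted odor tuning.

    Each ROI draws a species label from ``tuning_spec`` (label ->
    frequency); every stimulus in the label gets a true amplitude from
    U(0.6, 1.0) (peak ΔF/F), the odorant mixture responds with the maximum
    of the single amplitudes, and all other stimuli are silent. The raw
    trace is baseline_f x (1 + drift + transients + noise) with noise SD =
    1 / snr in ΔF/F units. ``small_area_fraction`` of footprints fall below
    25 μm² to exercise the area filter. Positions are uniform in the unit
    cluster box unless ``layout='chemotopic'``, which arranges species
    territories by structural similarity (see
    :func:`generate_species_positions`).
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    if snr <= 0:
        raise ValueError("snr must be positive")
    spec = dict(tuning_spec if tuning_spec is not None else DEFAULT_TUNING_SPEC)
    total = sum(spec.values())
    labels_pool = list(spec)
    probs = np.array([spec[l] / total for l in labels_pool])
    rng = np.random.default_rng(seed)

    labels = rng.choice(labels_pool, size=n_rois, p=probs)
    if layout == "random":
        positions = rng.uniform(0.0, 1.0, size=(n_rois, 3))
    elif layout == "chemotopic":
        positions = _chemotopic_member_positions(labels, rng)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    times = protocol.times
    noise_sd = 1.0 / snr
    records, gt = [], GroundTruth()
    n_small = int(round(small_area_fraction * n_rois))
    small = np.zeros(n_rois, dtype=bool)
    small[:n_small] = True
    rng.shuffle(small)

    for k in range(n_rois):
        roi_id = f"roi{k:04d}"
        label = str(labels[k])
        amps = {c: float(rng.uniform(0.6, 1.0)) for c in label}
        mix_amp = max(amps.values()) if amps else 0.0
        signal = np.zeros_like(times)
        for e in protocol.events:
            a = amps.get(e.code, mix_amp if e.code.islower() and amps else 0.0)
            if a > 0:
                # trial-to-trial variability of the response amplitude
                a = a * float(1.0 + repeat_jitter * rng.standard_normal())
                signal += max(a, 0.0) * transient_kernel(times, e.onset, tau)
        coeffs = rng.uniform(-drift_amplitude, drift_amplitude, size=2)
        tt = times / times[-1]
        drift = coeffs[0] * tt + coeffs[1] * tt**2
        dff_true = signal + drift + rng.normal(0.0, noise_sd, size=times.size)
        raw = baseline_f * (1.0 + dff_true)
        area = float(rng.uniform(area_floor, 24.9)) if small[k] \
            else float(rng.uniform(25.0, 150.0))
        records.append(RoiRecord(roi_id=roi_id, footprint_area=area,
                                 centroid=tuple(positions[k]), raw_trace=raw))
        gt.rois[roi_id] = {
            "label": label, "amplitudes": amps, "mix_amplitude": mix_amp,
            "noise_sd": noise_sd, "position": [float(v) for v in positions[k]],
            "area": area, "responder": bool(amps),
        }
    return records, gt


# ---------------------------------------------------------------------------
# species position layouts (for chemotopy analyses)
# ---------------------------------------------------------------------------

#: Anchors of the three similar-stimulus groups, far apart in the unit cube.
_GROUP_ANCHORS = {
    frozenset("HFW"): np.array([0.2, 0.2, 0.25]),
    frozenset("KR"): np.array([0.8, 0.25, 0.6]),
    frozenset("MLI"): np.array([0.25, 0.8, 0.8]),
}


def _species_centers(species: list[str], layout: str, rng,
                     center_jitter: float = 0.04) -> dict[str, np.ndarray]:
    """Planted territory center per species label.

    ``random``: uniform in the unit cube (spatially null). ``chemotopic``:
    single-letter and similar-compound species sit near their group anchor,
    with similar compounds at the mean of their constituents; compounds
    spanning groups are placed uniformly (their deviation carries no
    chemotopic signal).
    """
    centers: dict[str, np.ndarray] = {}
    singles = [s for s in species if len(s) == 1]
    compounds = [s for s in species if len(s) > 1]
    for s in singles + compounds:
        if layout == "random":
            centers[s] = rng.uniform(0.0, 1.0, size=3)
            continue
        group = next((g for g in _GROUP_ANCHORS if set(s) <= g), None)
        if group is None:
            centers[s] = rng.uniform(0.0, 1.0, size=3)
        elif len(s) == 1 or not all(c in centers for c in s):
            centers[s] = np.clip(
                _GROUP_ANCHORS[group] + rng.uniform(-0.08, 0.08, size=3), 0, 1)
        else:
            constituent = np.mean([centers[c] for c in s], axis=0)
            centers[s] = np.clip(
                constituent + rng.uniform(-center_jitter, center_jitter, size=3), 0, 1)
    return centers


def _chemotopic_member_positions(labels, rng, member_spread: float = 0.05
                                 ) -> np.ndarray:
    species = sorted({str(l) for l in labels if l})
    centers = _species_centers(species, "chemotopic", rng)
    out = np.empty((len(labels), 3))
    for k, label in enumerate(labels):
        label = str(label)
        if not label:
            out[k] = rng.uniform(0.0, 1.0, size=3)
        else:
            out[k] = np.clip(centers[label]
                             + rng.normal(0.0, member_spread, size=3), 0, 1)
    return out


def generate_species_positions(species_counts: dict[str, int],
                               layout: str = "random", seed: int = 0,
                               member_spread: float = 0.05):
    """Member positions for a set of species, under a null (random) or
    planted chemotopic layout.

    Returns (positions dict roi_id -> xyz, labels dict roi_id -> label,
    centers dict label -> planted center)."""
    if layout not in ("random", "chemotopic"):
        raise ValueError(f"unknown layout {layout!r}")
    rng = np.random.default_rng(seed)
    centers = _species_centers(sorted(species_counts), layout, rng)
    positions, labels = {}, {}
    k = 0
    for label in sorted(species_counts):
        for _ in range(species_counts[label]):
            roi_id = f"roi{k:04d}"
            positions[roi_id] = np.clip(
                centers[label] + rng.normal(0.0, member_spread, size=3), 0, 1)
            labels[roi_id] = label
            k += 1
    return positions, labels, centers


# ---------------------------------------------------------------------------
# neuron trees
# ---------------------------------------------------------------------------

#: Well-separated stem directions; consecutive tufts use consecutive entries.
_STEM_DIRECTIONS = np.array([
    [1, 0, 0], [0, 1, 0], [0, 0, 1], [-1, 0, 0], [0, -1, 0], [0, 0, -1],
    [1, 1, 0], [-1, 1, 0],
], dtype=float)
_STEM_DIRECTIONS /= np.linalg.norm(_STEM_DIRECTIONS, axis=1, keepdims=True)


def generate_tree(n_tufts: int, nodes_per_tuft: int = 8,
                  tuft_spread: float = 6.0, seed: int = 0,
                  n_basal: int = 2, eps: float = 15.0) -> tuple[NeuronTree, dict]:
    """Synthetic MTC reconstruction with ``n_tufts`` planted tuft clusters.

    Each tuft is a branch node at the tuft center plus ``nodes_per_tuft - 1``
    leaf nodes within ``tuft_spread`` μm of it, reached from the soma by an
    unbranched dendritic stem of 50-90 μm. Spread below eps/2 and stem
    directions at least 45 degrees apart guarantee that the planted clusters
    are exactly what density clustering with (eps, 5 points) recovers.
    ``n_basal`` short basal neurites contribute blunt endings. Returns the
    tree and its ground-truth record (tuft count, member ids, centers).
    """
    if n_tufts < 0:
        raise ValueError("n_tufts must be >= 0")
    if n_tufts > len(_STEM_DIRECTIONS):
        raise ValueError(f"at most {len(_STEM_DIRECTIONS)} tufts supported")
    if n_tufts and nodes_per_tuft < 5:
        raise ValueError("a detectable tuft needs at least 5 critical points")
    if tuft_spread >= eps / 2:
        raise ValueError(f"tuft_spread {tuft_spread} must stay below eps/2 = {eps / 2}"
                         " for planted clusters to be unambiguous")
    rng = np.random.default_rng(seed)
    ids, parents, xyz = [1], [-1], [np.zeros(3)]
    types = [1]

    def add_node(parent_id: int, pos: np.ndarray, node_type: int = 3) -> int:
        nid = len(ids) + 1
        ids.append(nid)
        parents.append(parent_id)
        xyz.append(pos)
        types.append(node_type)
        return nid

    truth = {"n_tufts": n_tufts, "tufts": []}
    for t in range(n_tufts):
        direction = _STEM_DIRECTIONS[t]
        center = direction * rng.uniform(50.0, 90.0)
        # unbranched stem from the soma toward the tuft center
        n_stem = 4
        prev = 1
        for s in range(1, n_stem + 1):
            prev = add_node(prev, center * s / (n_stem + 1))
        hub = add_node(prev, center)              # tuft branch node
        members = [hub]
        n_leaves = nodes_per_tuft - 1
        parents_pool = [hub]
        if n_leaves >= 7:
            # larger tufts get a second-order branch node inside the spread
            offset = rng.normal(size=3)
            offset *= 0.4 * tuft_spread / np.linalg.norm(offset)
            hub2 = add_node(hub, center + offset)
            members.append(hub2)
            n_leaves -= 1
            parents_pool = [hub, hub, hub2, hub2]  # >= 2 children each
        for leaf in range(n_leaves):
            offset = rng.normal(size=3)
            offset *= rng.uniform(0.3, 0.9) * tuft_spread / np.linalg.norm(offset)
            members.append(add_node(parents_pool[leaf % len(parents_pool)],
                                    center + offset))
        truth["tufts"].append({"center": [float(v) for v in center],
                               "member_ids": members})
    for b in range(n_basal):
        direction = -_STEM_DIRECTIONS[(b + n_tufts) % len(_STEM_DIRECTIONS)]
        prev = 1
        for s in range(1, 4):
            prev = add_node(prev, direction * 8.0 * s, node_type=4)
    tree = NeuronTree(np.array(ids), np.array(parents), np.vstack(xyz),
                      np.ones(len(ids)), np.array(types))
    return tree, truth


# ---------------------------------------------------------------------------
# channel volumes
# ---------------------------------------------------------------------------

def generate_channel_volume(shape=(48, 48, 24), blobs=(), seed: int = 0,
                            noise_sd: float = 0.0, blob_sigma: float = 2.5,
                            gl_z_fraction: float = 0.5
                            ) -> tuple[ChannelVolume, dict]:
    """3-channel volume of Gaussian blobs on a zero background.

    ``blobs`` is a sequence of (center, channel, intensity[, sigma]) with
    channel in {0, 1, 2}. The region mask splits the grid along z: the first
    ``gl_z_fraction`` of slices are the glomerular layer, the rest the
    mitral-cell layer. Ground truth records each blob's dominant channel and
    region.
    """
    rng = np.random.default_rng(seed)
    grid = np.indices(shape, dtype=float)
    intensities = np.zeros((3, *shape))
    truth = {"blobs": []}
    for blob in blobs:
        center, channel, intensity = blob[0], int(blob[1]), float(blob[2])
        sigma = float(blob[3]) if len(blob) > 3 else blob_sigma
        if channel not in (0, 1, 2):
            raise ValueError(f"channel index {channel} outside 0-2")
        if intensity < 0:
            raise ValueError("blob intensity must be >= 0")
        sq = sum((grid[d] - center[d]) ** 2 for d in range(len(shape)))
        intensities[channel] += intensity * np.exp(-sq / (2.0 * sigma**2))
        region = "GL" if center[-1] < shape[-1] * gl_z_fraction else "MCL"
        truth["blobs"].append({"center": [float(c) for c in center],
                               "channel": channel, "intensity": intensity,
                               "region": region})
    if noise_sd > 0:
        intensities = np.maximum(intensities
                                 + rng.normal(0.0, noise_sd, intensities.shape), 0.0)
    z = np.arange(shape[-1])
    regions = np.broadcast_to(np.where(z < shape[-1] * gl_z_fraction, 1, 2),
                              shape).copy()
    return ChannelVolume(intensities, regions), truth


# ---------------------------------------------------------------------------
# dataset IO
# ---------------------------------------------------------------------------

def save_roi_dataset(outdir, records: list[RoiRecord],
                     protocol: AcquisitionProtocol, gt: GroundTruth) -> None:
    """Write traces (wide CSV), ROI metadata (CSV), protocol and ground
    truth (JSON) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traces = pd.DataFrame({r.roi_id: r.raw_trace for r in records})
    traces.to_csv(outdir / "traces.csv", index_label="frame")
    meta = pd.DataFrame([{"roi_id": r.roi_id, "footprint_area": r.footprint_area,
                          "x": r.centroid[0], "y": r.centroid[1], "z": r.centroid[2],
                          "level": r.level, "manual_flag": r.manual_flag or ""}
                         for r in records])
    meta.to_csv(outdir / "rois.csv", index=False)
    (outdir / "protocol.json").write_text(protocol.to_json())
    (outdir / "ground_truth.json").write_text(gt.to_json())


def load_roi_dataset(outdir):
    """Inverse of :func:`save_roi_dataset` (ground truth optional)."""
    outdir = Path(outdir)
    traces = pd.read_csv(outdir / "traces.csv", index_col="frame")
    meta = pd.read_csv(outdir / "rois.csv", keep_default_na=False)
    protocol = AcquisitionProtocol.from_dict(
        json.loads((outdir / "protocol.json").read_text()))
    records = []
    for _, row in meta.iterrows():
        records.append(RoiRecord(
            roi_id=row["roi_id"], footprint_area=float(row["footprint_area"]),
            centroid=(float(row["x"]), float(row["y"]), float(row["z"])),
            raw_trace=traces[row["roi_id"]].to_numpy(),
            level=row["level"], manual_flag=row["manual_flag"] or None))
    gt_path = outdir / "ground_truth.json"
    gt = GroundTruth.from_json(gt_path.read_text()) if gt_path.exists() else None
    return records, protocol, gt
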