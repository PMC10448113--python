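"""Multicolor projection analysis: 2:1 color-ratio voxel classification.

Three-channel volumes from multicolor dye fills are classified voxel-wise:
a voxel belongs to a primary color category when that channel's intensity is
at least ``ratio`` (default 2:1) times both other channels and above an
intensity floor. Categories are compared between the mitral-cell layer
(MCL) and the glomerular layer (GL) to test whether somata and tufts of the
same color population occupy corresponding territories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .stats import TestResult, two_group

CHANNEL_NAMES = ("red", "green", "blue")
#: Region labels in the mask volume.
REGION_OTHER, REGION_GL, REGION_MCL = 0, 1, 2
REGION_NAMES = {REGION_GL: "GL", REGION_MCL: "MCL"}


@dataclass
class ChannelVolume:
    """3-channel intensity grid with a per-voxel region mask."""

    intensities: np.ndarray          # (3, *grid)
    regions: np.ndarray              # (*grid,) of {0 other, 1 GL, 2 MCL}
    voxel_size_um: float = 1.0

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.regions = np.asarray(self.regions, dtype=int)
        if self.intensities.shape[0] != 3:
            raise ValueError("volume must have exactly 3 channels")
        if self.intensities.shape[1:] != self.regions.shape:
            raise ValueError("region mask shape does not match the intensity grid")
        if np.any(self.intensities < 0):
            raise ValueError("negative intensities")


def classify_voxels(volume: ChannelVolume, ratio: float = 2.0,
                    min_intensity: float = 0.0) -> np.ndarray:
    """Per-voxel color category.

    Category c (0 red, 1 green, 2 blue) iff I_c >= ratio * I_other for both
    other channels (a tie at exactly ratio:1 counts) and I_c >
    ``min_intensity``; -1 otherwise. For ratio >= 1 at most one channel can
    satisfy the rule, so the classification is exclusive.
    """
    if ratio < 1.0:
        raise ValueError("ratio below 1 makes the rule non-exclusive")
    I = volume.intensities
    out = np.full(volume.regions.shape, -1, dtype=int)
    for c in range(3):
        others = [o for o in range(3) if o != c]
        dominant = ((I[c] >= ratio * I[others[0]]) & (I[c] >= ratio * I[others[1]])
                    & (I[c] > min_intensity))
        out[dominant] = c
    return out


def category_coordinates(volume: ChannelVolume, categories: np.ndarray
                         ) -> dict[tuple[str, str], np.ndarray]:
    """Voxel coordinates (μm) per (color, region) category."""
    out = {}
    for region_code, region in REGION_NAMES.items():
        for c, color in enumerate(CHANNEL_NAMES):
            mask = (categories == c) & (volume.regions == region_code)
            coords = np.argwhere(mask) * volume.voxel_size_um
            out[(color, region)] = coords
    return out


def layer_distributions(volume: ChannelVolume, categories: np.ndarray
                        ) -> pd.DataFrame:
    """Per (color, region): voxel count and per-axis quartiles.

    Empty categories appear with count 0 and NaN summaries, so absent colors
    are visible rather than silently dropped."""
    coords = category_coordinates(volume, categories)
    axes = "xyz"[:volume.regions.ndim]
    rows = []
    for (color, region), pts in coords.items():
        row = {"color": color, "region": region, "n_voxels": len(pts)}
        for k, axis in enumerate(axes):
            if len(pts):
                q1, med, q3 = np.percentile(pts[:, k], [25, 50, 75])
            else:
                q1 = med = q3 = np.nan
            row.update({f"{axis}_q1": q1, f"{axis}_median": med, f"{axis}_q3": q3})
        rows.append(row)
    return pd.DataFrame(rows)


def kde_summary(points: np.ndarray, grid_shape=(32, 32), extent=None) -> np.ndarray:
    """2D density summary of voxel positions projected on the first two axes
    (simple histogram density; adequate for territory comparison)."""
    if len(points) == 0:
        return np.zeros(grid_shape)
    xy = points[:, :2]
    rng = extent or ((xy[:, 0].min(), xy[:, 0].max() + 1e-9),
                     (xy[:, 1].min(), xy[:, 1].max() + 1e-9))
    hist, *_ = np.histogram2d(xy[:, 0], xy[:, 1], bins=grid_shape, range=rng,
                              density=True)
    return hist


def layer_correspondence(volume: ChannelVolume, categories: np.ndarray):
    """Same-color vs. cross-color GL-MCL centroid offsets.

    For every color present in both layers, the offset between its GL and
    MCL centroids (projected on the in-layer x-y axes, since the layers are
    separated along z); cross-color offsets pair the GL centroid of one
    color with the MCL centroid of another. A topological soma-tuft link
    shows as same-color offsets smaller than cross-color ones (Mann-Whitney).
    Colors missing a layer are skipped and reported.
    """
    coords = category_coordinates(volume, categories)
    centroids = {key: pts[:, :2].mean(axis=0) if len(pts) else None
                 for key, pts in coords.items()}
    present = [c for c in CHANNEL_NAMES
               if centroids[(c, "GL")] is not None and centroids[(c, "MCL")] is not None]
    skipped = [c for c in CHANNEL_NAMES if c not in present]
    same = {c: float(np.linalg.norm(centroids[(c, "GL")] - centroids[(c, "MCL")]))
            for c in present}
    cross = {}
    for a, b in combinations(present, 2):
        cross[(a, b)] = float(np.linalg.norm(centroids[(a, "GL")] - centroids[(b, "MCL")]))
        cross[(b, a)] = float(np.linalg.norm(centroids[(b, "GL")] - centroids[(a, "MCL")]))
    if len(present) >= 2:
        test = two_group(list(same.values()), list(cross.values()),
                         names=("same_color", "cross_color"))
    else:
        test = TestResult("mann-whitney-u", np.nan, np.nan,
                          (len(same), len(cross)), groups=("same_color", "cross_color"),
                          extra={"skipped": "fewer than 2 colors in both layers"})
    return same, cross, test, skipped
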