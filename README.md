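# glomod

Quantification of functional odor maps in the larval *Xenopus laevis*
olfactory bulb, from ROI-level calcium traces to odor-tuning
classification, sparseness and chemotopy statistics, molecular similarity
scoring, and mitral/tufted-cell (MTC) morphometry.

Amino acids are the dominant odor class for the larval lateral olfactory
bulb. Given multiphoton recordings of glomeruli, juxtaglomerular cells or
MTC somata responding to a panel of eight amino acids (M, L, I, H, K, R, F,
W), the package answers, with explicit statistics:

* which stimuli each region is tuned to, and how selectively;
* whether glomeruli preferring structurally similar amino acids sit close
  to each other (chemotopy) or not;
* how structural similarity of the stimuli relates to similarity of the
  evoked tuning;
* how MTC dendritic morphology (tuft number, volume, projection pattern)
  is organized across the cell population.

Because such recordings are not freely redistributable, the package ships a
first-class synthetic-data generator that emulates every input with known
ground truth — stimulus-locked calcium transients, neuron trees with
planted dendritic tufts, 3-channel projection volumes — so the whole
pipeline is testable end to end against planted parameters.

## The quantities at the core

**ΔF/F and response peaks.** Raw fluorescence is baseline-corrected with
asymmetric least squares smoothing, converted to ΔF/F = (F − F₀)/F₀,
normalized to the maximum response amplitude of the series, and reduced to
per-stimulus peak amplitudes (maximum within 15 s of stimulus onset,
averaged over repeats). ROIs are excluded automatically when the footprint
is below 25 μm², no peak exceeds 3× the SD of the non-stimulus intervals,
or fewer than two supra-threshold responses are present.

**Odor tuning.** The *default* (2× baseline SD) and *dominant* (3×)
tuning are the stimulus sets with supra-threshold peaks; a region with
dominant tuning "HFW" responds supra-threshold to H, F and W. Tuning
selectivity is summarized by lifetime sparseness

S = [1 − (Σ rₙ/N)² / (Σ rₙ²/N)] / (1 − 1/N),

which is 0 for a region responding equally to all N stimuli and 1 for one
responding to exactly one.

**Molecular similarity.** Two Tanimoto scores are computed from first
principles on heavy-atom graphs of the amino acids: the maximum common
substructure score |MCS| / (|A| + |B| − |MCS|) via exhaustive search for
the largest connected induced common subgraph, and the Carhart atom-pair
score (multiset Tanimoto over (atom type, atom type, topological distance)
descriptors). Tuning-derived cluster distances are regressed on these
scores (OLS slope test) to quantify structure–tuning coupling.

**Chemotopy and juxtaposition.** ROI positions are normalized to the
cluster boundaries; glomerular species (sets of ROIs sharing a tuning
label) get centroid + SD-ellipsoid territories. Inter-centroid distances
are compared between structurally similar and dissimilar species pairs,
and compound-profile species (e.g. "HFW") are tested for sitting at the
centroid of their constituent single-stimulus species.

**Morphometry.** SWC-reconstructed MTCs are reduced to end and branch
points; DBSCAN (eps 15 μm, ≥ 5 points) detects dendritic tufts, convex
hulls give tuft volumes, and nine morphometric features per cell feed a
standardized PCA.

## Worked example

```python
import numpy as np
from glomod import make_protocol, process_dataset, classify_tuning, lifetime_sparseness
from glomod.synthetic import generate_roi_dataset

protocol = make_protocol(repeats=4, frame_rate=1.0, seed=1)
records, truth = generate_roi_dataset(500, protocol, snr=10.0, seed=1)
kept, profiles, traces, log = process_dataset(records, protocol)
cls = classify_tuning(profiles[kept[0].roi_id])
print(len(kept), cls.label, round(lifetime_sparseness(
    profiles[kept[0].roi_id].single_stimulus_vector()), 3))
```

prints

```
429 L 0.349
```

— 429 of 500 simulated ROIs survive the three exclusion rules (the planted
dataset contains 10% sub-25 μm² footprints and 5% untuned ROIs), and the
first kept ROI is dominantly tuned to leucine; its moderate lifetime
sparseness of 0.35 reflects measurable sub-threshold responses to the
other stimuli at SNR 10. Across this dataset the dominant
tuning matches the planted species label for better than 99% of
responders.

The molecular similarity scores:

```python
from glomod import similarity_matrix
mcs, ap = similarity_matrix(by_reference_listing=True)
print(mcs.loc["K", "R"], ap.loc["K", "R"])   # 0.571..., 0.405...
```

The numbered scripts under `analysis/` run the full study on synthetic
data — simulation, trace processing, tuning, chemical similarity,
chemotopy, morphometry, projection color — each printing what it found and
writing its tables under `results/`. The `glomod` command-line tool exposes
the same stages (`glomod simulate | process | tuning | chemsim | morpho |
run`).

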