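# Methods

This note documents the models, conventions and numerical choices behind
`glomod`: what each stage computes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## Stimulus protocol

A recording applies odorants for 5 s each at 1 min inter-stimulus
intervals with a 15 s pre-stimulus lead-in, at 0.5–1 Hz frame rates
(default 1 Hz). Each sequence opens with the odorant mixture followed by
the eight single amino acids (M, L, I, H, K, R, F, W, the fixed panel
order used for labels and matrices); a full experiment consists of four
such sequences (`repeats=4`), the configuration used for somatic
recordings; glomerular recordings use one pair. All analysis windows
derive from the stored onsets: response peaks are read from
[onset, onset + 15 s], baseline statistics from the non-stimulus intervals
[onset + 25 s, onset + 40 s].

## Baseline correction and ΔF/F

Baselines are estimated by asymmetric least squares smoothing: minimize
Σ wᵢ (yᵢ − zᵢ)² + λ Σ (Δ²z)² with stiffness λ = 10⁴ frames² and
asymmetry p = 0.01 (both exposed). The classic weighting scheme
(w = p above the baseline, 1 − p below) converges to the p-expectile of
the noise — about 1.6 noise-SD *below* the true baseline for Gaussian
noise at p = 0.01 — which would add the same margin to every ΔF/F
amplitude and push the window maxima of untuned stimuli near the 3σ
dominant-tuning threshold at any SNR. The default weighting is therefore
noise-aware: each iteration estimates the noise SD from the negative
residuals (1.4826 × MAD) and applies the asymmetric weight p only to
points more than 2 SD above the running baseline, weighting sub-noise
points symmetrically. The baseline then sits in the middle of the noise
band while still ignoring calcium transients; the classic scheme is
available via `noise_aware=False`. ΔF/F = (F − z)/z; a non-positive
baseline anywhere is an error, not a clamp.

Two normalizations coexist deliberately: the trace normalization (ΔF/F
divided by the maximum response amplitude of the whole series, mixtures
included) feeds the threshold classification, while amplitude-vector
analyses (correlation, clustering, sparseness, odor-space coordinates)
re-normalize the eight single-stimulus peaks to their own maximum.
Mixtures are used only for filtering and trace normalization; they never
enter a tuning vector.

## Peaks, filtering, SBR

The per-stimulus amplitude is the mean over repeats of the window maximum
(ties broken by the earliest frame). Automatic exclusion applies three
rules — footprint < 25 μm²; no peak above 3× the SD of the pooled
non-stimulus intervals; fewer than 2 supra-threshold responses — and logs
every violated rule per ROI; manual exclusion flags are applied last and
logged separately. The exclusion SD (non-stimulus intervals of the
normalized trace) and the classification baseline SD are computed from the
same interval set but kept as two separately computed statistics, matching
their two separate definitions.

SBR = (mean ΔF/F over the 15 s post-stimulus windows − mean over
non-stimulus intervals) / sqrt(0.5 (σ_s² + σ_ns²)). The radical follows
the standard discriminability denominator; `pooled_sd=False` selects the
literal non-radical reading. SBR is invariant under gain rescaling and
zero when the window means agree.

Intensity-difference maps average, per pixel, the peak frame within 8 s of
onset and its two neighbors (neighbors truncated at the window edge, so a
peak on the first frame never averages in pre-stimulus fluorescence) minus
the mean of the 5 pre-stimulus frames.

## Tuning classification and tuning-space statistics

Default/dominant tuning: stimuli whose amplitude exceeds 2×/3× the
baseline SD; dominant ⊆ default by construction; labels concatenate
letters in panel order. Lifetime sparseness uses the normalized vector
(scale-invariant by construction); an all-zero vector is undefined and
signalled. Hierarchical clustering is average linkage on correlation
distance d = 1 − r between pooled per-stimulus amplitude columns; the
cluster distance of a stimulus pair is its cophenetic merge height divided
by the maximum merge height (the divisor the 0–1 normalization leaves
open). Species tables count ROIs per tuning label per animal and report
mean ± SD and the fraction of animals lacking each species. Odor-space
coordinates are pairwise amplitude differences (default axes R−W, K−H,
M−I, configurable).

## Molecular similarity

Molecules are the eight amino acids in neutral form, heavy atoms only,
encoded as hand-written connection tables with bond orders and aromatic
flags; each records its public registry number. The published
reference-number listing transposes leucine (6106) and isoleucine (6306);
scoring is available both by molecule identity and by that listing
(`by_reference_listing=True`), which reproduces the published scores —
the two differ only for pairs involving L or I (the published "M/L"
atom-pair score is reproduced by methionine vs the structure registered
under 6306, i.e. isoleucine; the MCS score is identical either way).

*MCS*: exhaustive branch-and-bound search for the largest connected
**induced** common subgraph under element-label matching, bond orders
ignored. The induced reading keeps rings intact — a benzene ring may not
unroll onto an open chain of the partner molecule — and is what reproduces
the published W/F score (11/16 = 0.69); the non-induced reading would give
12/15 = 0.80. Score = |MCS| / (|A| + |B| − |MCS|), atom-counted. The
search grows mappings through shared bonds with an element-count bound and
an explicit state budget; exceeding the budget raises, never
approximates.

*Atom pairs*: Carhart descriptors — atom type (element, heavy-neighbor
count, π-electron count), unordered type pair plus shortest-path bond
distance, one descriptor per heavy-atom pair — scored as multiset Tanimoto
Σmin/Σmax. π electrons: aromatic atoms count 1; otherwise the sum of
(bond order − 1) over incident bonds. This typing reproduces the reference
implementations (rdkit, ChemmineR) exactly on the full panel; the typing
scheme is isolated in one function because atom-pair scores are
convention-sensitive.

The structure–tuning regression fits OLS of normalized cluster distance on
similarity score over the 28 stimulus pairs and tests H₀: slope = 0.

## Spatial maps and chemotopy

Positions are affinely normalized to declared per-axis boundaries
(medio-lateral, caudo-rostral, ventro-dorsal); distances are computed in
normalized space (a μm-space flag exists for the juxtaposition regression,
where the convention is ambiguous). Species territories are per-axis
centroid and SD (descriptive ellipsoids only). Inter-centroid distances
are partitioned by whether both labels fall inside one structural triad
{H,F,W}, {K,R}, {M,L,I} and compared by Mann-Whitney. Compound-profile
deviation uses the unweighted mean of the constituent single-species
centroids (member counts ignored, per the definition of a hypothetical
centroid of species); compounds with missing constituents are skipped and
logged. Juxtaposition: OLS of raw-trace correlation on pairwise distance,
and Kruskal-Wallis with Dunn/Bonferroni post-hocs of distances binned by
dominant-set overlap (none / some / all).

## Morphometry

Trees are SWC files validated for a single root (the soma), acyclic parent
links and finite coordinates. Critical points are end points (no
children) and branch points (≥ 2 children), the soma excluded from both
(a root with several children is a stem junction, not a dendritic branch
point). DBSCAN with eps = 15 μm and min 5 points on the critical points
yields tufts; noise end points are blunt neurite endings; points are fed
in node-id order so border-point assignment is deterministic. Tuft volume
is the 3D convex hull of the cluster's critical points; coplanar or
collinear clusters get volume 0 with an explicit degeneracy flag. The
soma-tuft distance is the dendritic path length to the cluster member with
the minimal path distance (a cluster-center projection is ill-defined off
the tree); inter-tuft distances are Euclidean between cluster centers.

The nine PCA features are: tuft count; primary dendritic stems (root
children whose subtree contains a tuft member); mean tuft volume; mean
branch points per tuft; secondary dendrites (children of primary stems);
primary basal neurites (root children without tufts); secondary basal
neurites; mean soma-tuft path distance; mean inter-tuft distance. Seven
of these are named explicitly in the source analyses; the two mean
distances complete the list from the quantities that analysis computes —
documented here as an assumption. Features are standardized to mean 0 /
variance 1; constant features are dropped with a report, since they carry
no variance direction.

## Projection color analysis

A voxel joins color category c when I_c ≥ 2 × I_other for both other
channels (a tie at exactly 2:1 counts) and I_c exceeds an intensity floor
(default 0, i.e. any positive intensity; the floor keeps pure-noise voxels
out and is exposed because the original procedure does not state one).
For ratio ≥ 1 the rule is exclusive. Region masks (GL vs MCL) are inputs;
the synthetic generator emits a z-split mask. Layer correspondence
compares same-color vs cross-color GL–MCL centroid offsets (projected on
the in-layer x–y axes) by Mann-Whitney.

## Statistics

Shapiro-Wilk for normality screening; Kruskal-Wallis omnibus for > 2
groups; Dunn's pairwise z-tests on pooled ranks with tie-corrected
variance and Bonferroni adjustment (adjusted p = min(1, raw × m),
monotone in raw p); Mann-Whitney U for two groups (exact null for group
sizes ≤ 8 without cross-group ties, tie-corrected normal approximation
otherwise); OLS slope test via statsmodels. Significance markers follow
the usual figure convention (* ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001). Null
calibration of all tests is asserted in the test suite (empirical type-I
error within [α/2, 2α] at α = 0.05 over 1000 replicates).

## Synthetic data: what it emulates and what it does not

ROI traces are baseline × (1 + drift + transients + noise): constant
baseline fluorescence (100 a.u.), a low-order polynomial drift (±5% over
the recording, so ALS correction is genuinely exercised), stimulus-locked
transients with instantaneous rise and single-exponential decay (τ = 4 s,
the order of GCaMP6s kinetics; configurable — no biophysical calcium
model), and white Gaussian noise with SD = 1/SNR in ΔF/F units (default
SNR 10). Each ROI draws a species label from a frequency table mixing
narrow, compound and untuned profiles; labeled stimuli get true amplitudes
from U(0.6, 1.0) with 5% trial-to-trial jitter, the mixture responds with
the maximum single amplitude, 10% of footprints fall below 25 μm². The
magnitudes of noise, drift and the species mix are package choices made
for honest test coverage — the source experiments publish no quantitative
values for them — so passing tests demonstrate correctness of the
computations on data of this structure, not performance on real
recordings: no motion artifacts, no CNMF demixing residuals, no correlated
noise, no z-drift.

Synthetic trees plant tufts as a hub (plus a second-order hub in larger
tufts) with leaves inside a spread radius < eps/2, reached by unbranched
stems along directions ≥ 45° apart at 50–90 μm, so planted clusters are
mathematically guaranteed to be exactly what DBSCAN(15 μm, 5) recovers;
basal neurites contribute blunt endings. Channel volumes are Gaussian
blobs on zero background with optional white noise and a z-split region
mask.

Species position layouts: `random` places every species center uniformly
(the spatial null); `chemotopic` anchors the three structural triads far
apart, scatters single-letter species near their triad anchor, and places
similar-compound species at the mean of their constituents. Members
scatter with SD 0.05 around their center. The planted effect size makes
the chemotopy tests reject with power ≥ 0.8 while the random layout keeps
their empirical type-I error at the nominal level — both asserted in the
acceptance tests (500 null / 100 planted replicates).

All generators are driven by explicit seeds; equal seeds give
bit-identical outputs, and the pipeline derives per-stage seeds
deterministically from one root seed.

## Problem sizes

The shipped analyses and tests run at desk scale: 300–500 ROIs per
simulated dataset, four stimulus sequences (~2200 frames at 1 Hz), a
61-cell morphometric cohort, 200 random trees for exact tuft-count
recovery, 500 null and 100 planted chemotopy layouts, and 1000 null
replicates for the statistical calibration. These sizes were chosen to
match the magnitude of the original cohorts while keeping every check
cheap to re-run.

## Known limitations

* The pipeline starts at extracted ROI traces; motion correction and
  source extraction are out of scope.
* Atom-pair scores depend on the atom-typing convention; agreement with
  other tools is expected only under Carhart typing as specified above.
* The exhaustive MCS search is exponential in the worst case; it is fast
  for molecules of this size (≤ 15 heavy atoms) and guarded by a hard
  state budget for anything larger.
* Ellipsoid territories are descriptive; no overlap statistics are
  computed.
* The Mann-Whitney comparisons of pairwise distance sets inherit the usual
  caveat that pairwise distances sharing endpoints are not independent;
  the null calibration asserted in the tests shows the practical size
  distortion is small at these problem sizes.
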