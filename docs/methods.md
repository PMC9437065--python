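# Methods

`svscore` quantifies immune-cell infiltration in highly multiplexed tissue
images (imaging mass cytometry and similar modalities, ~1 µm/px) as a set
of spatially variant, per-region scores between composite cell types, and
stratifies each region of interest (ROI) on the immune continuum:
**inflamed** (CD8/M1-rich), **suppressed** (M2-dominated), **cold**
(immune-poor).

## Model and procedure

### Inputs

One ROI is a C×H×W stack of non-negative marker intensities (one plane per
metal-tagged antibody), a label mask of segmented cells (0 = background),
and a marker panel with composite type rules. The shipped rules are

| type | member markers | weight |
|---|---|---|
| Tumor | ECadherin, PanKeratin | 0.6 |
| Stroma | Col1, SMA | 1.0 |
| CD8 | CD8a | 1.0 |
| M1 | CD68, HLA-DR | 1.0 |
| M2 | CD68, CD163, CD206 | 1.0 |

The Tumor weight of 0.6 compensates for epithelial overstaining. A
composite score is `weight × mean expression over member markers`; the
mean (not the sum) keeps 1-marker and 3-marker rules on the same scale,
which matters because they compete in an argmax. Ties resolve to the first
rule in config order, so typing is deterministic.

### Preprocessing

* Intensity scaling maps a percentile window linearly onto [0, 1] with
  clipping: per-image (each channel's [0th, 99.9th] percentile window) for
  processing, or per-ROI (the pooled [20th, 99th] window over all
  channels) when comparing across ROIs with uneven background staining.
  Percentiles use linear interpolation between order statistics. A
  constant channel maps to zeros with a logged warning.
* The CD8a plane is median-filtered over a radius-1 disk (the 5-pixel
  cross) before feature extraction; per-cell CD8 staining is weak in cold
  tissue and single hot pixels would otherwise dominate small cell means.
* The fallback segmenter (Otsu → distance-transform watershed → components
  filtered to equivalent diameter 5–20 px, then nearest-label Euclidean
  expansion by 2 px, 3 px optional) is a deterministic classical stand-in
  for users without an external mask. External masks — including
  deep-learning ones — are accepted anywhere a mask is needed and are the
  better choice on real tissue.

### Cell-level scoring

Per-cell features are the unweighted centroid and per-channel mean over
the label's pixels. Typed centroids become nodes of an undirected radius
graph: edge iff centroid distance ≤ 30 µm (boundary inclusive — "within"
is read as ≤). The ROI is tiled into 25 µm patches (half-open bins, the
last patch absorbing the far edge). For patch *i*:

* density `P_i,type = n_i,type / n_i,cell` when the patch is non-empty,
  else 0; densities over types sum to exactly 1 on non-empty patches;
* directed link count `L_i,A→B` = over type-A cells in patch *i*, the
  number of their type-B graph neighbors *anywhere* — summing over patches
  recovers the graph-wide directed count exactly (a tested conservation
  law);
* pair score(A, B) = realized A–B edges touching patch *i* through a
  qualifying endpoint, divided by `n_i,A · n_i,B` (or `n(n−1)/2` for
  self-pairs), clipped to 1, and 0 when the denominator is 0. The
  numerator counts each edge once per patch; because neighbors may lie
  outside the patch the ratio can exceed 1 before clipping.

The per-ROI raw score for a pair is the mean patch score over non-empty
patches; the scaled score is `10 × raw`, clipped to [0, 10]. Fixed bins on
the scaled CD8–Tumor score, applied half-open as (lo, hi], give the
stratum: (−0.001, 2.255] → cold, (6.695, 10] → inflamed, and the medium
bin (2.255, 6.695] resolves by macrophage balance — suppressed when
Tumor–M2 ≥ Tumor–M1, else inflamed. The secondary rule is the minimal
deterministic realization of validating the bins against the macrophage
score distributions. The M2/M1 ratio (counts or densities) is reported
alongside; a zero M1 component returns +inf with a warning rather than
raising.

A monotonicity caveat worth knowing: adding a CD8 cell to a patch
increases the pair-score denominator, so an added cell with *few* tumor
neighbors can lower that patch's CD8–Tumor score. The guarantee that holds
(and is property-tested) is: a CD8 cell adjacent to **all** tumor cells of
its patch never decreases the ROI CD8–Tumor raw score.

### Pixel-level scoring

The scaled stack is tiled with n×n pixel patches (n = 5 default; grids are
ceil(H/n) × ceil(W/n), edge patches averaging only their own pixels — a
1500×1500 µm ROI at 1 µm/px gives exactly 300×300 = 90,000 patches). Each
patch takes the composite type with the highest weighted mean intensity;
if every composite mean is below 0.1 the patch is background. The
threshold applies to all five types. Densities divide by the total patch
count (background included); the pixel immunoscore of {A, B} is the
fraction of adjacent patch pairs realizing that type pair, under
4-connectivity ("direct neighbors"; 8-connectivity and a
background-excluding denominator are config options).

### Clustering

Phenotype discovery (as opposed to rule-based typing) z-scores the
selected marker columns (zero-variance columns become zeros rather than
poisoning the scale), builds a k-nearest-neighbor graph (k = 15), and runs
Leiden community detection (RB modularity) at a given resolution and seed;
results are deterministic for a fixed seed. The default resolution of 1.0
is a standard exploratory setting and deliberately fine-grained; when the
goal is to recover a handful of major phenotypes (as in the calibration
tests, which seek exactly the five composite types), a coarse resolution
of ~0.1 is appropriate — at 1.0 Leiden subdivides large homogeneous
phenotype blobs into subcommunities, which is not an error but a
granularity choice. Cluster count is data- and resolution-dependent and is
never asserted against a fixed number.

Pixel clustering prepends downsampling by block-mean (factor 2), per-channel
min-max normalization, and a background drop (pixels with every marker
< 0.3), and appends an average-linkage merge of cluster mean-expression
vectors at cosine distance, cut at 0.25 × the maximum pairwise distance;
the merge never increases the cluster count. Per-channel (not global)
min-max was chosen and documented; the merge treats all-zero mean vectors
as maximally distant since cosine distance is undefined at zero.

### Pseudo-H&E

The nuclei layer averages the nuclear-role channels (chromatin/nuclear
factors plus the Ir DNA intercalators) and maps them through the upper
half of a blue-red diverging colormap (`bwr_r`) with alpha linear 0→1; the
cytosol layer averages the cytosolic channels through the upper half of a
pink-green diverging colormap (`PiYG_r`, the pink half) with alpha
0.5→1; nuclei composite over cytosol as
`out = α_n·c_n + (1−α_n)·α_c·c_c`. Exact RGB tables are shipped
constants; visual identity with any particular stain is not claimed.

## Synthetic tissue generator

The generator exists so every downstream stage is testable with known
ground truth; it emulates exactly the features the pipeline consumes and
nothing more:

* cells are disks (diameter 10 px — the typical segmented cell diameter at
  1 µm/px) placed by dart-throwing with a minimum center spacing (12 px
  default; 11 px at high density) inside a 500×500 px ROI (kept below full
  acquisition size for test speed; full-size geometry is checked
  analytically);
* per-pixel background is Poisson(λ = 0.5) in every channel — mass
  cytometry counts are low-count and Poisson-like — and a cell adds
  lognormal(µ = 3, σ = 0.3) signal on the member markers of its true type;
  nuclear-role markers light up in every cell so the fallback segmenter
  has a target;
* archetypes fix the type composition (inflamed .45/.25/.15/.10/.05 for
  Tumor/Stroma/CD8/M1/M2; suppressed .45/.25/.05/.05/.20; cold
  .55/.38/.03/.02/.02) and, per immune type, the probability of being
  placed within the 30 µm interaction radius of a tumor cell (inflamed:
  CD8 .9 / M1 .8 / M2 .3; suppressed: .35/.3/.85; cold: .2/.2/.2). Only
  the rank order of resulting scores is meaningful.

The default of 400 cells per ROI is a fast test setting; cohort-level
checks of the archetype ordering use the density typical of the imaged
tissue, ~4,500 cells/mm² (1,125 cells per 500×500 µm ROI), at which
small-count noise in the rarer macrophage types averages out. All
randomness flows from a single seed; identical calls are bitwise
identical.

What the generator does **not** emulate: tissue morphology (glands,
vessels, fibrous stroma), cell shape variation, marker spillover between
channels, spatial background gradients, or segmentation errors. Passing
tests therefore demonstrate the correctness and calibration of the
*scoring machinery*, not robustness to real-tissue artifacts — on real
data, segmentation quality and panel normalization dominate.

## Numerical choices

* Downsampling averages trailing partial blocks over the pixels they
  contain (no padding bias).
* Label expansion resolves collisions to the nearest label with exact
  Euclidean distances; ties go to the lower label id (implemented by
  ascending-id claims with strict-inequality overrides, verified against
  an all-pairs oracle).
* Patch binning, argmax tie-breaks, Leiden seeding, and rendering are all
  deterministic; renders are pure functions of their inputs.
* Scores are clipped, never renormalized: raw ∈ [0, 1], scaled ∈ [0, 10]
  by construction.

## Known limitations

* The pair-score denominator counts only in-patch cells while the
  numerator admits out-of-patch neighbors; this makes sparse patches
  saturate at 1 easily. The clip is documented and the alternative
  (windowed denominators) is not implemented.
* The stratification bins are shipped constants on the 0–10 scale; they
  are meaningful only under the `10 × raw` scaling (a cohort min–max
  alternative is available via `scale_factor`).
* The fallback segmenter is not a substitute for modern segmentation on
  real tissue; it is calibrated only on the generator's well-separated
  disks.
* Proprietary acquisition formats are not parsed; export to TIFF first.
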