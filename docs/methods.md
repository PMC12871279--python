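# Methods

This note records the models and procedures spotkit implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic fixtures do and do not establish about
real data.

## Density stain

Cytoplasmic segmentation needs a cytosol channel; PolyT stains are unreliable
at somatic boundaries, so a stain-like image is synthesized from the decoded
transcripts themselves. Transcripts are counted into the imaging voxel grid
(half-open bins, 0-based indices, micrometer coordinates in a section-local
frame) and smoothed with a 3D Gaussian (σ_z = 1, σ_xy = 3) followed by a 3D
median filter (windows z = 2, xy = 10). Units for σ and the windows are
voxels at the binning resolution; the source description does not fix the
units, and voxels are the only choice that keeps the operation
resolution-independent at the stated numbers. The published window sizes are
even; a centered median filter needs odd windows, so even values are rounded
up to the next odd integer (3 and 11) while the stated numbers are stored
verbatim in the run parameters, and a radius interpretation (5 and 21) is
available via `DensityParams(windows_are_radii=True)`. Both filters use
reflect padding. The Gaussian stage is linear and mass-conserving away from
boundaries; the median stage is not, which is intended — it suppresses
isolated bright voxels that are noise, not cytosol.

## Tiling, stitching, transcript assignment

Sections are tiled into 350 × 350 μm tiles. The overlap width is not fixed by
the source; the default is 50 μm, enough that a soma (≲ 30 μm) split by a tile
boundary appears whole in at least one tile. Tiles are ordered row-major from
the minimum corner, and that order defines "newer" in the stitching rule.
Transcripts take the integer label of their containing voxel; label 0 and
out-of-volume positions stay unassigned.

Stitching reconciles cells that share transcripts in overlap regions. For
each pair, with s = |shared| / |smaller cell's transcripts| (size measured in
transcripts, ties broken by lexicographic cell id): s > 0.5 (strict) merges
the smaller cell into the larger; otherwise each contested transcript is
reassigned to the newer tile's cell. The strictness at exactly 50% matters
and is tested. After stitching every transcript belongs to at most one cell,
and the counts matrix plus per-gene unsegmented tallies conserve the non-blank
input exactly.

The per-tile segmenter is pluggable. The built-in backend (Otsu threshold on
the density stain, peaks as markers, watershed on the negated density) exists
so the full pipeline runs and is testable end to end; it is not a
state-of-the-art segmenter and is not meant to replace a trained deep model
on real tissue.

## Alpha-shape boundaries

Cell boundaries are 2D alpha shapes of each cell's transcript positions per
z-plane, stacked into a pseudo-3D representation. We use the inverse-radius
convention: the alpha shape at radius threshold r is the union of Delaunay
triangles with circumradius ≤ r, and alpha = 1/r. The boundary alpha is the
maximum alpha (tightest shape) whose alpha shape is a single closed polygon,
found by binary search over the sorted circumradius values — the predicate
can only change there, so the search is exact rather than approximate — and
then multiplied by 0.75, relaxing the shape slightly away from the critical
point. If the scaled shape is somehow multi-component the largest-area
component is kept (unreachable under this parameterization; kept as a
guard). Planes with fewer than three non-collinear points get a null
boundary; a cell with a null boundary on every plane keeps its transcripts
but reports zero volume and area.

Geometry: volume = Σ plane areas × z-spacing; the reported 2D area is the
maximum single-plane area; the polygon centroid is the area-weighted mean of
per-plane centroids. Cell volumes from 7–10 μm sections underestimate true
somatic volumes because most cells exceed the section thickness; the numbers
are comparable within a dataset, not absolute.

## Quality filters

Per-cell metrics use non-blank counts only; blanks are carried per cell and
enter the blank fraction blanks / (blanks + transcripts). Removal thresholds:
fewer than 6 genes, fewer than 30 transcripts, or blank fraction ≥ 2% (the
source states the 2% line without inclusivity; we remove at the boundary).
No volume floor is applied — the volume distribution under 3D segmentation
shows no clear lower mode — and no upper transcript cutoff, which the doublet
stage replaces. Density is reported as transcripts/μm³, the only
dimensionally consistent reading of a per-volume density.

Division markers are derived by one-vs-rest Wilcoxon rank-sum tests on a
cluster-median expression matrix (clusters are the observations, which keeps
the test cheap and stable); the top genes per division, ties broken by name.
Incongruent pairs are all cross-division marker combinations; the incongruent
percentage of a cell of division D counts transcripts of foreign markers
paired against any D marker, over the cell's non-blank transcripts.

## Doublet thresholding

The doublet stage separates scoring (pluggable) from thresholding (the
contribution). The built-in scorer simulates artificial doublets by summing
2n random distinct cell pairs' count profiles, embeds observed plus simulated
profiles by PCA of log1p counts, and scores each observed cell by the
fraction of simulated doublets among its k = 25 nearest training profiles.
Counts are deliberately not depth-normalized: a doublet's doubled library
size is its strongest signature, and normalizing it away collapses same-type
artificial doublets onto the singlet clusters and destroys the vote's
separation.

Thresholding: dif = doublet_p − singlet_p, so doublet-like cells sit high;
the sign convention is configurable since the source phrasing admits either.
Predicted doublets are cells with dif > 0 (an explicit mask can be passed);
the threshold is q0.9 − q0.1 of their dif values, quantiles by linear
interpolation at p·(n−1), and all cells with dif strictly above the threshold
are flagged. With no predicted doublets the threshold is undefined (NaN),
nothing is flagged, and a warning is emitted. The quantile-spread formula
presumes a scorer whose probabilities saturate; a weakly separating scorer
makes it erratic, which is a property of the formula worth knowing before
applying it to a new platform.

## DoubleMAD filtering of mapping scores

For each supertype's correlation distribution: median m, MAD_low = median of
|x − m| over x ≤ m, MAD_high analogous over x ≥ m (the median belongs to both
sides, which stabilizes heavily tied data); removal below m − 3·MAD_low. The
removal comparison carries a 1e-9 relative tolerance purely to absorb
floating-point rounding in the median arithmetic.

Bimodality is assessed on a Gaussian KDE (Silverman bandwidth, 512-point grid
over the data range — a fixed, reproducible recipe). A distribution is
bimodal iff the KDE has exactly two modes, the minor mode carries ≥ 10% of
total density (mass split at the local minimum between modes), the local
minimum lies within ±0.05 of the median, and the normalized peak-height
difference is < 0.05. The height reading of "difference between the two mode
peaks" is used because a location reading (< 0.05 apart) would preclude a
resolvable minimum. These criteria only fire for near-balanced modes: a
70/30 mixture with modes 0.25 apart fails both the median-window and
peak-height conditions and is handled by the ordinary unimodal path — which
still removes such a contaminant mode, since it falls below m − 3·MAD_low.
When a distribution is bimodal, the filter recomputes the median and MAD_low
on the values above the local minimum only, so a biologically plausible lower
mode is not double-penalized; if that subset has fewer than three values the
full distribution is used with a warning. Supertypes with fewer than three
cells are kept unfiltered and flagged.

The nearest-neighbor diagnostic (`ann_distance`) reports, per supertype, the
mean distance from each cell to its nearest same-supertype neighbor;
well-mapped cell types are spatially coherent, so removed cells with large
values corroborate the filter.

## Spatial domains

Transcripts are aggregated into 30 μm half-open grids from the section
origin, blanks tallied separately; grids pass QC with ≥ 60 genes, ≥ 300
transcripts and < 3% blanks. The spatial k-NN graph uses k = 8 with exact
ties broken toward the lower node index and union symmetrization. The
production embedding comes from an external spatially aware model; a PCA of
log-normalized grid counts is the built-in stand-in so the stage runs end to
end.

Stability: 25 subsamples of 80% of nodes, Leiden (RB configuration modularity,
k = 15 embedding graph) across a resolution sweep (default 0.2–2.0 in 0.1
steps; the source states both 0.6–2.0 and 0.2–2.0, and the wider sweep is the
default), all C(25,2) subsample pairs scored by ARI and AMI on shared nodes.
A structural caveat: under the configuration-model null, any community of m
nodes — even a perfect clique — is split once the resolution exceeds roughly
m/(m−1), regardless of how well separated it is. Exact stability (ARI = AMI
= 1) on a two-domain fixture is therefore only a meaningful expectation at
the low end of the sweep; the separable-fixture checks run at resolutions
0.2–0.5, where the property holds exactly across seeds.

Domain/region concordance is the Jaccard coefficient between the set of cell
types observed in a domain and each region's region-specific type set, with
raw overlap counts reported alongside.

## Atlas registration

Alignment files carry, per section, a linear anchoring — vectors o, u, v such
that atlas = o + x_norm·u + y_norm·v with coordinates normalized by image
width and height — and landmark pairs for the non-linear correction. The
warp is barycentric: Delaunay triangulation of the source markers, each cell
expressed in barycentric coordinates of its containing triangle, weights
applied to the paired target markers. Cells outside the triangulation use the
affine extension of the nearest triangle (by centroid distance); dropping
them is the configurable alternative. Collinear or missing markers degrade to
the identity warp with a warning rather than failing the section. Region
lookup floors coordinates to 25 μm voxel indices; out-of-volume cells get
label 0 ("outside"). The annotation volume's axis order is (x, y, z) with an
explicit permutation hook for real atlas volumes. The warp is exact on the
markers themselves and reproduces any affine warp exactly, which the fixtures
exploit.

## COVET and MSSI

The niche covariance of a cell is the mean of (e_j − ē)(e_j − ē)ᵀ over its
k = 8 nearest spatial neighbors, with ē the global dataset mean — the shift
makes matrices comparable across niches. The focal cell is excluded from its
own niche (configurable). Matrices are symmetric PSD by construction.

MSSI compares two spatial expression patterns over a 5-scale hierarchy. Each
dataset gets its own k = 8 spatial graph (inverse-distance weights) and its
own coarsening: greedy heavy-edge matching (edges by decreasing weight, index
tie-breaks), matched pairs pooled by mean, unmatched nodes carried as
singletons — ⌈n/2⌉ supernodes on well-structured graphs, possibly a few more
on irregular ones — followed by a graph blur (half own value, half neighbor
mean). At each scale, luminance l = (2μ_r μ_q + C1)/(μ_r² + μ_q² + C1) and
contrast c = (2σ_r σ_q + C2)/(σ_r² + σ_q² + C2) follow standard
structural-similarity practice with C1 = (0.01·L)², C2 = (0.03·L)²; L is the
pooled dynamic range of both inputs, chosen over a reference-only range so
the score is exactly symmetric. The structure term is the Pearson correlation
of the two 64-bin normalized expression histograms over the pooled value
range — distribution-based, so datasets need not share cells or coordinates.
The final score is the mean of the per-scale l·c·s products. Self-comparison
is exactly 1; at the original scale a permutation of the same values also
scores 1 (identical histograms), and the penalty appears after coarsening,
where pooling mixes values by spatial position.

## Synthetic fixtures

`generate_section` emulates: cells as 3D Gaussian transcript blobs (radius
6 ± 1 μm, ~150–200 transcripts each, Dirichlet-weighted gene use) on discrete
imaging planes; division-specific mutually exclusive marker blocks so
incongruent-gene logic has signal; uniform extracellular noise; blank
codewords at 0.2% of spots (realistic rates are a fraction of a percent,
leaving typical cells far below the 2% QC line); doublet partners planted
2–4.5 μm from a host cell of a different division; low-quality plants with
either 8–19 transcripts from ≤ 4 genes or an 8% blank rate. Non-doublet cells
are separated by ≥ 2.5× the mean radius. Every generator is a pure function
of its seed.

What the fixtures do not emulate: instrument optics, codebook decoding
errors, z-anisotropy of real point-spread functions, tissue morphology,
cell-type-dependent density, or detached-tissue artifacts. Passing tests
establish the correctness of the rules and the algebra — conservation,
thresholds, merges, transforms — not segmentation quality on real tissue.

`generate_mapping_scores` plants per-supertype Normal(μ, 0.03²) main modes
with μ ∈ [0.45, 0.8] and optional contaminant modes 0.25 lower.
`generate_alignment_fixture` plants an affine warp (shear/scale of strength
`warp_amplitude`) sampled at grid landmarks, so the barycentric warp
reproduces the analytic truth to machine precision — a deliberate choice that
turns the round-trip test into an exact one instead of an
interpolation-accuracy test.

## Problem sizes and defaults

The test suite and the acceptance script run on desk-scale fixtures chosen as
the smallest sizes at which each property is stably exercised: 60-cell
sections (~9,000 transcripts), 200 + 30-cell doublet fixtures, n = 2000 score
mixtures, 80-node embeddings with 25 bootstrap subsamples, 1000-point
region-lookup checks. Dataset-scale quantities (median volumes, per-dataset
retention counts) depend on tissue and panel and are not reproduced by these
fixtures.

## Known limitations

- The built-in segmenter is a test stand-in; real use should plug in a
  trained volumetric model and feed its label volumes to
  `assign_transcripts`.
- The quantile-spread doublet threshold assumes saturating scores (see
  above); with a weak scorer it under-flags.
- The bimodality criteria only detect near-balanced modes; imbalanced
  contaminant modes are handled by the unimodal DoubleMAD path.
- Grid QC defaults (60 genes / 300 transcripts) assume a ~500-gene panel;
  small panels need lower floors (exposed as options).
- MSSI values depend on the coarsening operator; the heavy-edge-matching
  choice is validated by the self-similarity, symmetry and permutation
  properties, not against an external reference implementation.
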