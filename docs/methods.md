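# Methods

This note documents the models and procedures implemented in `spotmap`,
the parameters that matter, the numerical choices made where the design
was open, and what the synthetic fixtures do and do not emulate.

## Data model and conventions

All coordinates are continuous pixels in the image convention: origin at
the top-left, x right, y down. This matches the nuclear-stain raster
without any flip; readers expose `flip_y` for data recorded the other way.
ROI boxes are half-open `[min, max)` on both axes so a tiling of boxes
partitions reads exactly. Gene matching is case-sensitive exact string
comparison throughout. A missing sample column means a single implicit
sample (`sample_1`).

Counts are integers everywhere; any real-valued matrix downstream is
explicitly a *normalized* matrix carrying its normalization record.

## Density estimation

Expression density maps are isotropic Gaussian KDEs of a gene's read
positions, computed with scikit-learn's `KernelDensity`. The bandwidth is
the kernel sd in pixels; when not given it defaults to Silverman's
rule-of-thumb on that gene's reads (`σ·n^(−1/6)` with σ the mean per-axis
sd, the d = 2 case) and is always recorded in the output, since there is
no single correct smoothing scale for tissue data. The evaluation grid
covers the reads' bounding box plus three bandwidths of margin at a
default step of bandwidth/2 (finer grids change the integrated mass by
< 0.5%). Maps are true probability densities (integral ≈ 1 over the
plane); per-map max-scaling happens only at render time so maps of
different genes stay comparable. Overlays rescale each channel by its own
max, which shows *where* each gene concentrates, not relative abundance.

## Colocalization

The neighborhood-enrichment test builds one exact k-nearest-neighbor
graph (Euclidean; no self-links) and keeps it fixed while gene labels are
shuffled, because positions never change under the null — rebuilding the
graph per permutation would be a no-op. Distance ties break toward the
lower read index so the graph is deterministic; below 4,000 reads a
brute-force stable sort implements that rule exactly, above it a k-d tree
is used (ties between distinct points have measure zero there).

Directed links are symmetrized by summation (count[g,h] + count[h,g] for
g ≠ h), so an off-diagonal entry counts each unordered neighbor relation
from both sides and the total directed count is always n·k. The diagonal
(self-colocalization, a measure of a gene's spatial clustering) is
computed and reported. Null mean and sd are the empirical moments over
permutations from a single seeded RNG stream, making results
bit-reproducible and independent of threading. Defaults: k = 5,
500 permutations; both are logged in the result. Pairs with zero null sd
get a NaN Z and a warning rather than an arbitrary value.

Interpretation caveat: the test conditions on the *global* graph, so
strong coincidence between two genes necessarily *depletes* their
connections to everything else (each read has only k slots). Negative Z
against an unrelated gene is therefore expected next to a strongly
enriched pair, most visibly at k = 1.

## Gradients

De novo discovery evaluates, on a regular lattice spanning the data
bounding box, the per-axis summed absolute KDE variation
G_x(p) = Σ_g |d_g(p − (b,0)) − d_g(p + (b,0))| (G_y analogously). KDE
values at offset points are exact Gaussian sums — defined everywhere,
never clipped or extrapolated from a grid. Because of the absolute value
the field measures gradient intensity per axis but not its sign; the
quiver rendering therefore shows unsigned axis magnitudes, and a
`signed=True` variant drops the absolute value for users who need true
direction. Defaults: b = bandwidth/2 and lattice step 2b, which samples
the smoothed field near its resolution limit. Lattice points within three
bandwidths of the bounding-box edge are flagged (`boundary_mask`); KDE
edge bias is not corrected, so interior points are the reliable ones.

Supervised profiling computes each read's minimum Euclidean distance to an
origin point set (poly-lines are densified to ≤ 1 px spacing first, then
the minimum is exact to that resolution) via a k-d tree; it matches an
all-pairs brute force to 1e-9. The 1D gene profiles along that distance
are Gaussian KDEs *reflected about d = 0*, so each profile integrates to 1
over d ≥ 0 instead of leaking mass to negative distances near the origin.
1D bandwidth defaults to Silverman's rule per gene on its distances.
Extracting a single dominant axis from the 2D field is left to the user.

## Segmentation

**Watershed cells.** Pipeline: white top-hat with a disk structuring
element (radius default 15 px; must exceed the nucleus radius) to flatten
background, global intensity threshold (Otsu when not given), hole
filling, removal of specks below 30 px², distance-transform watershed
(markers from distance-transform peaks at ≥ 7 px separation) to split
touching nuclei, then `expand_labels` grows each nucleus outward by the
expansion distance (default 10 px), with collisions resolved by the
nearest-nucleus rule. Pixels beyond the expansion stay 0: space between
cells is deliberately unassigned, and reads landing there are tallied but
not attributed. All structuring sizes are parameters with logged defaults
because nuclear size varies across tissues and magnifications. Because the
top-hat subtracts a morphological opening, a constant intensity offset
below the threshold margin does not change the result.

**Bins.** Bin "radius" means the half-width of an axis-aligned square
(squares make the tiling-conservation property exact on a pixel grid); a
`circular` flag switches to discs. Centers form a lattice starting at the
data minimum, extended so the last bin reaches past the data maximum.
Membership is closed (|x − cx| ≤ radius), so only reads exactly on shared
bin edges are double-counted in a tiling. Empty bins are dropped.

**Spot environments.** One unit per read: the gene composition of all
reads within the radius of the focal read, focal read included.

**QC.** Units outside [min, max] total reads are dropped first, then
genes below the per-gene minimum; the filter is idempotent and refuses to
return an empty matrix, printing the count distribution instead.

## Normalization, embedding, clustering

The default normalization divides each gene column by its total count
across units, removing the dominance of highly expressed genes; columns
then sum to 1 and two genes with proportional spatial profiles become
identical. This leaves per-unit totals uncontrolled, so a per-unit total
normalization is available behind a flag but is not the default. A
zero-total gene is a hard error directing to QC first.

PCA is centered, with a sign convention (largest-magnitude loading per
component made positive, scores flipped to match) for run-to-run
reproducibility. RGB maps keep three dimensions — the top-3 PCs, or
t-SNE/UMAP run directly at 3 output dimensions (an optional `pca_init`
pre-reduction is off by default) — and min-max scale each dimension to
[0, 1] independently over units, so every channel spans the full range by
construction. Clustering offers k-means (seeded, 10 restarts), Ward
hierarchical on Euclidean distance (the standard linkage for expression
matrices), and DBSCAN (which may emit a noise label, −1). Graph-based
community detection (Leiden/Louvain) is intentionally not included.

## Probabilistic cell typing

Cells are classified against scRNA-seq class mean profiles μ_kg by a
cell-level Poisson-Bayes rule: s_c = (Σ_g n_cg) / median_k(Σ_g μ_kg)
absorbs depth differences (the median over class totals resists outlier
classes); the log-likelihood is Σ_g [n_cg log(s_c μ_kg + ε) − (s_c μ_kg +
ε)] with pseudo-expression ε = 0.1 reads guarding log 0; posteriors are
prior · exp(L) normalized per cell via log-sum-exp. Priors default to
uniform (only ratios matter); an abundance-weighted prior can be passed.
Zero-read cells get a uniform posterior and are flagged. This is a
deliberate reduction of the full pciSeq model family: spot-level cell
reassignment, misread/background spot modeling, and gene-efficiency
re-estimation are out of scope, and the interface returns exactly what
downstream analysis needs — per-cell posteriors, hard assignments
(argmax, ties toward reference order) and the gene-count echo.

Domain composition assigns each cell to the spatial domain of its nearest
clustered-bin centroid, then tabulates class frequencies per domain.

## Synthetic fixtures

The generators are pure functions of their parameters and a seed, and
always return ground truth. They emulate: layered tissue (uniform bands
with per-band gene multinomials), smooth gradients (Gaussian-concentrated
x, uniform y), coincident pairs (partner placed at an exact offset in a
random direction), background genes (uniform), nuclei (Gaussian bumps plus
optional noise and offset, with close pairs flagged), and typed cells
(non-overlapping disc footprints, uniform class labels, per-gene Poisson
counts at a depth factor, reads placed ≥ 2 px inside the footprint so
pixel-floor lookup cannot cross the boundary). They do **not** simulate
optical crowding, decoding errors, autofluorescence, irregular cell
shapes, or spatial correlation between cells — so passing tests
demonstrate correctness of the statistics under their stated models, not
robustness to those real-data artifacts.

Test and acceptance problem sizes are chosen to exercise each property at
meaningful statistical power while keeping the default suite fast: 3,000
reads × 500 permutations × 50 seeds for the null-calibration study, 500
reads for the O(n²) oracle comparisons, 1,000 cells for typing recovery,
10,000 product-grid reads for the gradient separability check.

## Known limitations

- KDE edge bias at tissue borders is flagged, not corrected.
- The colocalization null conditions on the global graph (see caveat
  above); no analytic null is provided.
- Watershed marker detection can over-split very elongated nuclei; tune
  `peak_min_distance`.
- t-SNE/UMAP determinism holds for a fixed seed and library version, not
  across versions.
- No batch correction across samples; samples are analyzed jointly only
  through their shared gene panel.
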