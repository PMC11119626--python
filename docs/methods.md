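# Methods

## Data model and preprocessing

The pipeline operates on a genes × spots matrix that moves through explicit
stages: `raw_counts → normalized → log → centralized`. Preprocessing
(`spotsom.preprocess`) is deliberately simple and fully deterministic:

1. **Gene filter** — keep genes detected (count > 0) in at least
   `min_spots_expressed` spots (default 3) and with nonzero variance.
   All-zero and constant profiles carry no portrait information and
   destabilize map training; a threshold of 3 removes them without biasing
   module content.
2. **Library-size normalization** — each spot column is scaled to a common
   total, by default the median library size (keeping values on a
   count-like scale); counts-per-10k is available. Normalization target is
   a free choice in the field; both options are exposed and the default is
   documented rather than claimed canonical.
3. **Log transform** — `log2(x + 1)` by default (base e and other
   pseudocounts configurable).
4. **Centralization** — subtraction of each gene's mean across spots. This
   is per gene, not per spot: it converts profiles to signed over/under-
   expression relative to the gene's own average, which is what makes the
   red/blue portrait coloring meaningful. Row means of the output are zero
   to float precision.

Batch correction, deconvolution and imputation are out of scope; spot
cluster or cell-type labels are always user-supplied inputs, never computed
here.

## SOM portrayal

Genes are the training samples: gene g contributes its expression profile
x_g ∈ R^(n_spots). A Kohonen map with a rectangular grid (default 50 × 50 =
2500 units) is trained by classical online learning:

- **Best-matching unit (BMU)**: argmin over units of the Euclidean distance
  ‖x − w‖₂, computed by exhaustive scan; exact ties resolve to the lowest
  row, then lowest column, making every query deterministic.
- **Update**: for each sample, all units move toward it,
  w ← w + α(t) · h(t) · (x − w), with a Gaussian neighborhood
  h = exp(−d²_grid/2σ²) evaluated on squared grid distance to the BMU.
- **Schedule**: learning rate decays exponentially 0.5 → 0.01 and the
  radius from max(rows, cols)/2 → 1 over `n_epochs` passes (default 20).
  These are standard Kohonen defaults; all are estimator parameters.
- **Initialization**: by default units are spaced on a regular grid spanning
  ±2 SD along the top two principal axes of the gene profiles (SVD with a
  deterministic sign convention), which makes runs reproducible up to the
  shuffling seed; pure random initialization is available. A fixed
  `random_state` yields bit-identical models.

The fitted estimator stores the weight tensor (rows × cols × n_spots), the
gene → unit assignment (re-derived from final weights, hence re-checkable
against a brute-force scan), and quantization errors before and after
training. The training contract asserted in the tests is weak monotonicity:
final mean gene-to-BMU distance never exceeds the initial one.

**Portraits.** Spot j's portrait is the grid of j-th weight components —
since the gene layout is fixed, portraits of different spots are directly
comparable, and stacking all spot portraits reconstructs the weight tensor
exactly. Group portraits are element-wise means over member spots.

## Module segmentation

Six modes produce labeled unit regions with attached gene lists:

- **Overexpression spots** (single-spot, group, and underexpression
  variants): per portrait, units above a threshold are marked; masks are
  unioned over portraits; 8-connected components with ≥ `min_units`
  (default 4) units become modules. The default threshold is **half of the
  portrait's peak value** — a full-width-at-half-maximum criterion. The
  rationale: an activation spot is a local structure whose extent varies
  with data composition, so the cut must adapt to the portrait's own
  dynamic range. A fixed value-quantile cut (also available via
  `threshold_quantile`) marks a fixed fraction of the grid regardless of
  how large the true spot is; on synthetic data with 500 diffuse background
  genes on a 400-unit grid, a 0.9-quantile cut marks 40 units around an
  ~11–15-unit spot and dilutes the recovered gene list with background
  genes (capping Jaccard overlap with the planted module near 0.6), whereas
  the half-maximum rule tracks the spot extent and recovers planted modules
  essentially exactly. The behavior is flat across peak fractions 0.3–0.6,
  so the default 0.5 is not a tuned edge.
- **K-means** on metagene weight vectors (a partition of the grid, via
  scikit-learn, seeded).
- **Correlation clustering**: grid-adjacent units are linked when their
  weight vectors' Pearson correlation exceeds a threshold; connected
  components are modules. Identical vectors count as correlation 1, and a
  constant vector correlates 0 with anything else (the degenerate case has
  no direction).
- **Distance map (U-matrix)**: each unit's mean Euclidean distance to its
  grid neighbors; units above a boundary quantile form ridges, and
  components of the remaining units are modules.

Labels A, B, C, … are assigned by decreasing unit count, then by
top-left-most unit, purely for determinism; they are analysis-specific. A
module's **spatial score** for spot j is the mean of the module's metagene
components at j — equivalently the mean of the module region in spot j's
portrait — and is the value used to color the tissue image.

## Gene sets and enrichment

A gene-set map counts the set's members per SOM unit (members absent from
the trained model are excluded; the map is additive over disjoint sets).
Per-spot signature scores are means of centralized expression over member
genes. Module enrichment uses the one-sided hypergeometric (Fisher) test on
the overlap of each module gene list with each set, restricted to a
universe that defaults to the genes retained after filtering (using the
full annotation as universe would inflate enrichment with never-detected
genes). Benjamini–Hochberg FDR is applied across all module × set pairs.
The p-value is discrete; its calibration is checked in the tests via the
randomized probability integral transform, which is exactly uniform under
the null and makes a standard KS test applicable.

## Receptor–ligand calls

A pair's per-spot state is decided on normalized **log** expression *before*
centralization: centralized values are signed relative levels, whereas
"expressed vs not expressed" is a detection statement, so the default
threshold 0 on log-normalized values means "any signal". Values exactly at
the threshold count as not expressed (strict inequality — a deterministic
edge rule). States: coexpressed (both above), receptor-only, ligand-only,
none; the joint score of a coexpressed spot is the mean of the two values.
Color saturation scales the call's expression level by the matrix-wide 95th
percentile of the two genes' values, clipped to [0, 1]. Pathway-wide maps
fold per-pair calls with the precedence coexpressed > receptor-only >
ligand-only > none, keeping the best coexpressed pair's score. Only
same-spot co-occurrence is scored; ligand diffusion to neighboring spots is
not modeled. Spot neighborhoods use hex distance on Visium array
coordinates (column parity alternates with row parity; in axial coordinates
q = (col − row)/2, r = row, the distance is (|Δq| + |Δr| + |Δq + Δr|)/2).
A neighborhood query returns the center spot plus all in-tissue spots
within the ring.

## Pathway signal flow

Each pathway node receives a positive, fold-change-like value: the
preprocessing log base raised to the mean centralized expression of the
node's genes over the cluster's spots (nodes with no matched gene are
neutral at 1). Signals propagate in topological order: a source's signal is
its own value; any other node multiplies its value by the combined input,
where an activating edge contributes the parent's signal, an inhibiting
edge the parent's reciprocal, and multiple inputs combine by geometric
mean. Consequences used as test oracles: a linear activation chain yields
the product of node values at the sink; all-neutral input yields all-ones;
activation-only graphs are monotone in upstream values. Cycles are either
rejected or, when condensation is enabled (default), each strongly
connected component collapses to one node valued at the geometric mean of
its members — a documented approximation, not a steady-state solution.
The propagation rule itself is this package's declared choice; no claim of
numerical equivalence to any published pathway-flow tool is made.

## Rendering

Portraits use a diverging blue–white–red scale (red = overexpressed)
normalized symmetrically about zero with limits at the 99th percentile of
|values| (outlier-stable); spatial maps use a sequential blue–beige–brown
scale (brown = high) with per-image quantile limits; global limits can be
supplied for cross-image comparability. Receptor–ligand maps use one fixed
palette constant (apricot/blue/green) with per-spot saturation blending
toward white. Rendering is a pure function — identical inputs give
byte-identical uint8 images — and color mapping is rank-preserving within
an image. Spots outside the tissue are never drawn. No H&E underlay or
registration is performed; pixel coordinates are taken as read, with an
optional scale factor.

## Synthetic data generator

The generator emulates the structure the pipeline is designed to detect,
at desk scale:

- **Lattice**: an n_rows × n_cols Visium-style hex lattice (default
  20 × 20 = 400 spots, all in-tissue).
- **Domains**: `n_domains` (default 4) contiguous regions grown by
  multi-source breadth-first search from randomly chosen centers on the hex
  adjacency graph — a lattice Voronoi under hex graph distance that is
  connected by construction.
- **Modules**: one gene module per domain (default 50 genes each) with
  negative-binomial mean `base_mean × fold_change` (defaults 2.0 × 4)
  inside the home domain and `base_mean` elsewhere; 500 background genes
  are flat. Dispersion is the NB size parameter (default 2.0, i.e.
  var = μ + μ²/2, a moderately overdispersed count model typical of
  spot-level data).
- **Library sizes**: log-normal around 2000 counts (σ = 0.25), applied as a
  per-spot scale of the mean matrix against the dataset-average expected
  total — scaling against each spot's own expected total would shrink the
  realized in/out-domain fold ratio below the nominal fold change.

What the generator does **not** emulate: cell-type mixtures within spots,
smooth spatial gradients, spot-to-spot bleed-over, zero-inflation beyond
NB, or chemistry artifacts. Passing the recovery tests therefore shows the
pipeline identifies well-separated co-expression programs under realistic
count noise; it does not certify performance on gradual transitions or
heavily mixed spots.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at the
generator's default conditions (700 genes × 400 spots, 20 × 20 SOM, 20
epochs) across ten seeds, and the default 50 × 50 configuration on a
smaller fixture; these sizes keep a complete run in the minutes range on a
single core while leaving the method's behavior unchanged. Other choices:
strict inequalities at all thresholds (expression, portrait cuts); row-major
tie-breaking for BMUs; module labels ordered by size then position;
centralized row means asserted to 1e−12; PSF closed forms asserted to
relative 1e−12; model archives round-trip bit-exactly.

## Known limitations

- The online SOM is O(epochs × genes × units × spots); the default 50 × 50
  grid on ten-thousand-gene datasets takes correspondingly longer (no
  batch/parallel variant is provided).
- Overexpression module extraction assumes activation spots are connected
  regions; interleaved programs that share units are split or merged by the
  connectivity rule.
- Enrichment is overlap-based (hypergeometric); no ranked GSEA or
  SOM-specific set statistics.
- PSF condensation of cycles is an approximation; feedback dynamics are not
  modeled.
- Gene identifiers are matched case-sensitively after whitespace stripping;
  mixing symbol and Ensembl spaces requires caller-side mapping.
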