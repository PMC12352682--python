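# Methods

## Data model

Spot-level data enter as a `SpotTable`: spot ids, non-negative integer
array coordinates, a genes×spots expression matrix, and a lattice dialect.
Two dialects are supported. The classic ST square grid populates every
(row, col) pair under tissue. The Visium honeycomb obeys a parity
constraint — `array_row` and `array_col` of every spot have equal parity —
and is stored *unchanged* on the rectangular index grid: the structurally
empty half of the cells is carried in the tissue mask rather than
compressed away. This keeps the geometry the even-odd down-sampling rule
needs and makes the two dialects share one code path.

`to_grid` shifts coordinates so the minimum row/col maps to (0, 0)
(recorded in `origin_offset`), producing a dense G×H×W tensor plus an H×W
binary mask; `from_grid` inverts it exactly on occupied positions. All
coordinates are 0-based, grids row-major with row as the first spatial
axis.

QC filtering drops genes expressed (value > 0) in fewer than
`min_spots_per_gene` spots, then spots with fewer than `min_genes_per_spot`
detected genes — a single pass each, genes first. We deliberately do not
iterate to a fixed point; as a consequence a second application can, in
borderline cases, remove a gene whose supporting spots were discarded by
the spot filter (the filter is idempotent on typical data but not by
construction). Thresholds of (20, 10) and (10, 200) are the conventional
choices for ST melanoma-scale and Visium brain-scale sections respectively.

Raw counts are heavy-tailed, so `normalize_log1p_minmax` (log1p followed by
per-gene min–max scaling over tissue positions) is provided as an explicit,
separately invoked step that puts every gene on the loss's natural [0, 1]
scale. It is a choice, not a law; the network itself accepts any finite
non-negative grid.

## Down-sampling protocol and training scheme

Evaluation needs ground truth at unmeasured positions, which only exists by
construction: the full grid is down-sampled on the lattice and the removed
tissue positions become the held-out test set.

* **square_step2** — retain positions with row ≡ 0 and col ≡ 0 (mod 2);
  the retained set re-indexed by half-coordinates is a ⌈H/2⌉×⌈W/2⌉ grid.
* **visium_even_odd** — retain occupied positions with both array
  coordinates even. On the honeycomb this is the parity rule whose
  retained set, re-indexed by half-coordinates, is again a regular lattice;
  alternative parities would leave a set that no longer tiles.

Retained ∪ masked = tissue and the two sets are disjoint, for any mask;
the partition is purely geometric and independent of expression values.

Training is self-supervised and transductive: the grid to be enhanced is
itself down-sampled once more, and the network learns the 2× mapping from
that down-sample back to the grid. At evaluation time the trained network
maps the low-resolution grid to 2× and is scored at the masked positions
of the original; at application time it maps the full grid to 2×. Odd
dimensions are handled by placing the target in a 2⌈H/2⌉×2⌈W/2⌉ canvas
whose mask is zero outside the real extent.

## Network

Genes are the batch axis (each gene a one-channel image); all parameters
are shared across genes. Components and defaults:

| parameter | default | meaning |
|---|---|---|
| `cnn_channels` | (32, 32) | output channels of the two 3×3 convolutions |
| `patch_size` p | 2 | token = p×p block of the grid |
| `embed_dim` D | 128 | token width; divisible by `n_heads` |
| `n_heads` | 4 | attention heads |
| `n_blocks` | 4 | transformer blocks |
| `mlp_ratio` | 2 | hidden width of the block MLP, in units of D |
| `gnn_sigma` σ | 1.0 | Gaussian kernel width, in patch-index units |
| `gnn_k` | 4 | neighbors retained per patch |
| `gnn_epsilon` ε | 1e−8 | row-normalization guard |

Block composition is pre-norm residual: z ← z + MHSA(LN z); then
z ← z + (Ã · LN z) W_g + b_g; then z ← z + MLP(LN z). The graph update is
one aggregation per block — no multi-hop propagation, no learned edge
weights. Patch coordinates are the patch's (row, col) indices; self-edges
are excluded from the kNN set (a distance-0 self edge would dominate the
Gaussian kernel and wash out the neighbor signal), and kNN ties — common on
integer lattices where four neighbors are equidistant — break toward the
smaller linear index so the graph is deterministic. The graph is built once
per input shape and cached across epochs. For very small inputs, where
N − 1 < k patches exist, the effective k is clamped to N − 1 (the graph
builder itself refuses k ≥ N).

Positional encoding follows the sinusoidal formula over the flattened
row-major patch index. A flattened index is width-dependent: token 5 of a
3-wide patch grid and token 5 of a 6-wide grid are different 2-D positions,
so the raw table does not transfer between the training resolution and the
2×-larger inference resolution. We therefore resize the table: the
encoding is generated at the training patch-grid shape (recorded in the
network state) and bilinearly interpolated over the 2-D patch layout for
any other shape — the standard treatment of position embeddings when a
vision transformer changes input resolution. Without this, the model's
held-out accuracy drops below the nearest-neighbor baseline; with it, the
encoding keeps its spatial meaning across scales.

The head projects each token to 4p² values, unfolded to four channels per
grid cell. Channel k addresses high-resolution position
(2i + ⌊k/2⌋, 2j + k mod 2); interleaving is an exact index permutation
(bit-exact inverse pair, no float arithmetic). By default
(`global_residual="nearest"`) the channels predict deviations from the
low-resolution cell value — residual learning against the trivial nearest
upsample, the standard formulation in image super-resolution, which starts
training from a sensible interpolant instead of from zero.
`global_residual="none"` restores the pure projection head. Inputs are
zero-padded to patch-divisible dimensions (mask extended with zeros) and
the output cropped back, so padding never reaches the loss.

Initialization is seeded: He-scaled convolutions, truncated-normal (σ =
0.02, clipped at 2σ) projections, unit/zero LayerNorm, zero head bias. All
arithmetic is float64 numpy with reverse-mode autodiff
(`spavgn._autodiff`), so initialization, forward and training are
bit-reproducible from the seed on any machine.

## Loss and optimization

The masked multi-channel MSE has the form
L = 1/(4N) Σ_k Σ_ij M^(k)(Ŷ^(k) − Y^(k))² with N = Σ_k Σ_ij M^(k), where
M^(k) is the sub-sampled tissue mask. Note that N already counts valid
pixels across all four channels, so the 1/(4N) prefactor is a factor 4
smaller than a per-valid-pixel mean; `loss_norm="per_pixel"` (1/N) is
offered for convenience. The two differ by a constant, so gradients and
minimizers are identical up to the learning-rate scale.

Optimization is full-batch Adam (lr 1e−3, no weight decay, no scheduler,
no early stopping) for a fixed number of epochs — 500 by default; the
tests and the acceptance script use 300 on their benchmark size. An
all-zero mask raises rather than dividing by zero; a non-finite loss
aborts with the epoch index.

`enhance` interleaves the four predicted channels into the 2H×2W map,
masks it with the nearest-neighbor 2× expansion of the tissue mask, and
doubles the origin offset so the output lives on the doubled lattice.
Observed spots map to even-even output coordinates. For honeycomb inputs
the 2× output occupies positions that no longer satisfy the Visium parity
constraint; the enhanced grid is therefore consumed as a grid (evaluation
indexes it directly), and `from_grid` accepts a lattice override when a
spot table is needed.

## Baselines

Nearest, (bi)linear and (bi)cubic interpolate the retained spots as
scattered data (Delaunay-based); nearest breaks distance ties toward the
smaller linear index of the retained enumeration. Masked positions outside
the convex hull of the retained spots — the odd border rows/columns of an
even-sized grid — are filled by nearest neighbor and flagged. NEDI is
implemented in its canonical covariance-based two-pass 2× form: 4-tap
blending weights are re-estimated per pixel by ridge-regularized least
squares on the surrounding low-resolution window (diagonal neighborhoods
for the odd-odd pass, axial for the remaining pass), degrading to the
uniform average when the local system is ill-conditioned. Reflect padding
is used at borders in pass 2 because it preserves pixel-class parity and
therefore always references an already-known pixel. Because a retained
low-resolution index (i, j) corresponds to original position (2i, 2j) on
both dialects, NEDI's 2× output aligns with original coordinates directly.

## Metrics

Gene-wise PCC is computed across evaluated spots; genes with zero variance
in either the truth or the prediction are undefined, excluded from the
median, and counted separately. The summary statistic is the median.
Silhouette uses Euclidean distances with singleton clusters scoring 0
(delegated to scikit-learn behind the module surface); Davies–Bouldin is
computed directly — mean over clusters of max_{j≠i}(S_i+S_j)/D_ij — with a
guard that raises on coincident centroids. The cluster metrics accept any
embedding; the pipeline's documented default is PCA of the imputed
full-resolution expression (retained positions keep their observed
values), scored against the generator's true domain labels.

## Synthetic data

The generator emulates the structure of spot-level data, not its
biology: per-gene smooth fields on either lattice — affine gradients
(min–max scaled, hence exactly linear in (row, col)), isotropic Gaussian
blobs with σ between 0.15 and 0.35 of the short grid side, or
piecewise-constant levels over Voronoi domains — with optional Gaussian
noise on the [0, 1] scale or Poisson noise on an exp-scaled count scale,
and a full-rectangle or disk tissue mask. Defaults (24×24, 16 genes, no
noise) match the benchmark conditions used by the end-to-end tests and the
acceptance script; that size trains in seconds per run on one CPU while
leaving 432 held-out positions, which keeps the whole suite fast without
changing what is being demonstrated. Noiseless gradients give analytically
known held-out values (bilinear recovers them exactly), which the tests
exploit as oracles.

What passing these tests shows: the geometry (partitions, interleaving,
masks), the optimization (loss decreases, gradients finite, deterministic
under seed), and the comparative behavior on smooth fields (the trained
network beats nearest-neighbor interpolation at held-out positions). What
they do not show: performance on real tissue, where counts are sparse,
noise is overdispersed, and expression fields are not smooth — the
generator makes no attempt to match real melanoma or brain expression
distributions.

## Known limitations

* Genes are processed as a full batch; very large panels should be
  mini-batched over genes (not implemented).
* Only 2× enhancement is supported — the sub-pixel head is strictly 2×2.
* The honeycomb's structurally empty cells participate as zeros in the
  convolutional front-end; a dialect-aware convolution might do better.
* No augmentation, no early stopping, no hyperparameter search; the
  defaults are sensible for desk-scale grids but untuned for large Visium
  sections.
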