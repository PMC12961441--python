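# Methods

This note documents the models and procedures implemented in `ptv2fr`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish.

## Problem setting

Multi-view reconstructions of sorghum seedling trays yield colored 3-D point
clouds in which every point belongs to a leaf, a stem, or the acrylic
cultivation tray ("pot").  The package (i) assigns one of these three labels
to every point with a point-transformer network, and (ii) turns a labeled
cloud into per-plant and per-leaf phenotypes: stem length and basal diameter,
leaf length/width/area, and the tray-level leaf area index (LAI).  Stems are
a small minority of points (< 10% after downsampling), which drives the loss
design.

## Network

The backbone is a U-shaped encoder-decoder over point sets.  Input features
are the centered coordinates concatenated with RGB scaled to [-0.5, 0.5]
(6 channels).  Each stage runs an attention block at fixed width; grid
(voxel) pooling with cell size doubling per stage (2 cm base) moves between
resolutions, with `segment-max` feature pooling, mean-pooled cell
coordinates, and skip connections on the decoder path.

### Multi-radius dual-coordinate attention (MRDCA)

The attention block projects features with Linear → PointBN → ReLU, splits
them into three branches (default 16 channels each), and builds one k-NN
graph per branch with K = 8, 16, 24.  For query i and neighbor j the score
combines four signals:

    w_ij = softmax_j( q_i·k_j / d  +  ψ_rel([Δp_ij, Δf_ij])
                      + ψ_abs(p_j^norm)  +  α · ψ_pool([Δf_ij, avg, max]) )

with q = φ(W_q f), k = φ(W_k f), v = W_v f, φ = ReLU∘PointBN, Δp and Δf the
coordinate/feature offsets, p^norm the per-cloud min-max-normalized absolute
coordinates (a degenerate axis maps to 0, never NaN), d the branch width,
and α a learnable scalar gate.  The enhanced features f_i = Σ_j w_ij v_j of
the three branches are concatenated (summation available) and fused by a
linear layer with φ.

Two details are deliberate design choices.  A score term that is constant
over the neighbor index j cancels inside the softmax and would receive
exactly zero gradient; therefore the absolute-coordinate signal is evaluated
at the neighbor (p_j^norm), and the pooled channel statistics (neighborhood
average and maximum of Δf) are concatenated with the per-pair Δf_ij before
ψ_pool rather than used alone.  The gate α is initialized at 0.1: near-silent,
so early training is dominated by the relative-geometry terms, but nonzero so
the pooled pathway is trainable from the first step.  k-NN ties break toward
the lower point index, which fixes permutation equivariance up to genuinely
tied distances.

### Point-graph involution feature refinement (PG-InvFR)

Between the decoder output and the segmentation head, each point receives a
dynamic kernel with one weight per neighbor slot of a k-NN graph (default
K = 16):

    H_i = M_k( ReLU( M_c([F_i, d_i]) ) ),   f_i^out = α_i Σ_j H_ij f_j

where d_i holds the K neighbor distances plus the unit principal direction
of the local covariance (sign fixed to non-negative z), and the gate
α_i = σ(U_i) is the logistic of the Shannon entropy U_i of an auxiliary
linear classifier's softmax — uncertain (boundary) points are refined more
strongly.  Decisions the source design left open:

- The auxiliary classifier is a single linear head on the decoder features,
  trained jointly with weight 0.4; its softmax is detached before the
  entropy, so the gate modulates magnitudes without feeding gradients back
  through the gating path (stability).
- The refinement is residual (f + f^out), and M_k is zero-initialized: the
  module starts as the identity.  With randomly initialized kernels the
  untrained refinement injects large feature noise and measurably degrades
  held-out accuracy; zero-init removes that failure mode without limiting
  capacity.
- Entropy uses pointwise probabilities by default; a neighborhood-averaged
  variant is a flag.  A single refinement pass is the default; the iteration
  count is configurable.

### Baseline block

For ablations, the attention block can be swapped for plain scaled
dot-product attention over the same k-NN graph (q·k/√d, softmax, weighted
values).  This is the package's stand-in for the original grouped vector
attention and is what "baseline" means throughout.

## Loss

The training loss is L = α·L_CE + β·L_Lovász with α = β = 1 by default.
L_CE is cross-entropy with inverse-frequency class weights
w_c = N/(C·N_c), computed on the downsampled training labels and normalized
to mean 1; the batch loss is normalized by the sum of applied weights so its
scale is stable under imbalance.  L_Lovász is the multiclass Lovász-softmax
surrogate of the Jaccard loss: per class present in the batch, errors
e_i = |1{y_i=c} − p_i(c)| are sorted descending and dotted with the gradient
of the Lovász extension of the Jaccard loss of the sorted ground truth;
classes absent from the batch are skipped (they would only contribute
noise on small batches).  Points labeled −1 are excluded everywhere.
The ignore label, the −1 convention and weighted-mean normalization make
a cloud with no valid points an error, not a silent zero.

## Training protocol

AdamW (lr 0.001, weight decay 0.05), batch size 32, 100 epochs, MultiStepLR
decaying by 0.05 after epochs 60 and 80 — these are the package defaults for
full-scale runs.  Augmentations: random scale 0.9-1.1, random x/y flip
(p = 0.5; never z — plants are gravity-oriented), clipped Gaussian jitter
(σ = 0.005, clip 0.02), elastic distortion with parameter pairs
[[0.2, 0.4], [0.8, 1.6]] (each pair applies one Gaussian-smoothed random
displacement field, trilinearly interpolated), and a sphere crop capped at
80 000 points.  Training is deterministic for a fixed seed.

The engine underneath is an in-repo reverse-mode autodiff over numpy
(float64 by default; a float32 mode, `ptv2fr.nn.set_default_dtype`, halves
memory traffic and is used for the training experiments).  When
`train_points` is set, each training cloud is furthest-point-subsampled once
per run (deterministically from the seed); fixed coordinates let the k-NN
graphs be memoized across epochs.  A per-step resampling mode exists but is
slower.

## Trait extraction

All thresholds act on real-scale coordinates in meters (`rescale_cloud`
applies the reconstruction scale first).  Stems are instanced by DBSCAN on
the xy projection (ε = 0.03 m, minPts = 80); noise points are dropped and
plants are numbered by centroid order, which makes ids permutation-stable.
Each stem's axis comes from RANSAC line consensus (120 two-point hypotheses,
inlier threshold τ = 0.01 m, largest inlier count wins, ties to the earliest
iteration) refined by SVD on the inliers, with the sign convention a_z ≥ 0.
The printed value of τ in the source description carries a unit
inconsistency (meters vs centimeters); the package defaults to meters, the
stated basis of all thresholds, and τ is configurable.

Leaf points go to the plant with the nearest stem centroid in xy (ties to
the lower plant id), then split into individual leaves by 3-D DBSCAN
(ε = 1 cm, minPts = 20); leaves closer than ε merge — a documented
limitation of density-based instancing.  Leaf length and width are the
extents along the first and second principal components (the
first-and-third variant is available behind a flag; first-and-second is the
only ordering that guarantees W ≤ L on planar leaves).  Leaf area
triangulates the projection onto the leaf's principal plane (Delaunay) and
sums 3-D triangle areas ½‖(p_j−p_i)×(p_k−p_i)‖.  Irregular sampling of
curved leaves produces sliver triangles whose facets stand nearly
perpendicular to the leaf plane and inflate the sum; each triangle's
3-D/projected area ratio is therefore capped at 5 (configurable), which
leaves flat and moderately curved surfaces untouched and holds the error on
curved test surfaces below 2%.

Stem length is the extent of the stem points projected onto the fitted axis
(reported in cm).  Stem diameter — named but not defined in the source — is
twice the median perpendicular distance to the axis among points in the
basal 20% of the axial extent (reported in mm).  LAI is the summed leaf
area divided by the 625 cm² tray footprint.

## Synthetic benchmark

The generator emulates the structure of the (unreleased) real dataset: one
25×25×5 cm tray per cloud, 15-25 seedlings on a jittered 5×5 grid, stems as
thin, slightly tilted cylinders (length 3-5 cm, radius 0.8-1.5 mm), and two
alternate leaves per seedling modeled as cylinder-section ribbons.  Ribbons
are developable, so surface area (arc × width) and chord length
(2R sin(arc/2R)) are closed-form — the generator is the analytic oracle for
the trait pipeline.  Colors are drawn from overlapping Gaussian class
distributions (deep green leaves, paler yellow-green stems, gray tray) so
color alone does not separate stem from leaf.  Reconstruction artifacts are
emulated by Gaussian surface noise (σ = 0.5 mm), a vertical density
gradient, and a thinned random angular occlusion sector.  Default clouds
are furthest-point-sampled to 4096 points with stems below 10% of points.
A dense noise-free preset (400 points per stem, 900 per leaf, no FPS)
serves trait-recovery studies; its leaves are kept short and shallow so
instances stay separable at the 1 cm clustering radius.

What the synthetic data does not emulate: real reconstruction outliers and
ghost geometry, self-occlusion coupled to viewing geometry, leaf wrinkling
and twist, soil/substrate clutter, and color calibration drift.  Passing
the synthetic benchmark therefore demonstrates that the implementation is
internally correct and that the architecture can learn the geometry-color
cues it was designed for — not that the reported headline accuracies of the
original study transfer to real trays.

## Experiment sizes used by the test suite

All experiments run single-threaded on CPU against the numpy engine, so the
suite uses reduced problem sizes, chosen once as the package's own desk
profile: a 2-stage "mini" network (24-48 channels, 8-channel branches), an
overfit sanity run (200 steps, batch 1, lr 3e-3, weight decay 0.01 on five
2048-point pots), and a generalization run (17 training / 3 held-out pots,
150 steps, 2048-point training subsamples, evaluation on the full 4096-point
clouds; medians over 3 seeds).  At these sizes the full model reaches
held-out mIoU ≈ 0.93-0.95 against ≈ 0.85-0.89 for the all-toggles-off
baseline, and trait recovery on 20 dense pots is exact on plant and leaf
counts with stem length and leaf area errors well under 5%.  The numbers
printed by `scripts/acceptance.py` are recomputed from scratch on every run.

## Known limitations

- The original backbone's stage depths/widths are undocumented; the desk
  profiles here are explicit stand-ins, and no attempt is made to reproduce
  the published accuracy tables, which require the unreleased dataset.
- DBSCAN-based instancing cannot split touching organs; ε/minPts defaults
  are matched to the synthetic geometry and will need retuning on real data.
- The uncertainty gate acts multiplicatively on refinement magnitude only;
  iterative refinement (> 1 pass) is untested beyond smoke level.
- Single-CPU numpy training limits practical problem sizes; the
  architecture, not the engine, is the object of study.
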