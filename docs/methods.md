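# Methods

## Problem

Given a set of drugs, a set of target proteins, and a list of verified
drug–target interactions, predict which of the remaining (drug, protein)
pairs interact. The package treats this as balanced binary classification:
verified pairs are positives, and an equal number of pairs drawn uniformly
from the unverified remainder serves as the negative class. This
downsampling accepts a small, quantifiable risk that true-but-unverified
interactions enter the negative set; at the benchmark scales the
non-interacting pool outnumbers the positives by more than an order of
magnitude, so the contamination is negligible.

## Protein descriptor: PHOG over the PSSM

A protein of length L is represented by its L×20 PSSM (PSI-BLAST log-odds
block; the weighted-percentage block is discarded — the descriptor is a
function of a single L×20 score matrix, and log-odds scores are the profile
representation that carries the evolutionary signal). The matrix is treated
as an image F and summarised in four steps:

1. **Edge image.** `I = sqrt((F∗Sx)² + (F∗Sy)²)` where Sx, Sy are the 3×3
   Sobel kernels (outer products of [1,0,−1] and [1,2,1]) and ∗ is true 2-D
   convolution (kernel flipped). Borders use replicate padding so the output
   keeps the input's shape and a constant input yields exactly zero edges —
   which also makes the descriptor invariant to adding a constant to all
   scores (the kernels sum to zero).
2. **Gradient field.** Central differences of I, again replicate-padded:
   g_x(r,c) = I(r+1,c) − I(r−1,c), g_y(r,c) = I(r,c+1) − I(r,c−1);
   magnitude g = √(g_x²+g_y²) and orientation θ = atan2(g_y, g_x) mapped to
   [0, 360). A two-quadrant arctangent cannot produce the full [0,360)
   range, so the four-quadrant form is used. Pixels with g = 0 carry no
   orientation; they are flagged and excluded from voting rather than
   assigned a spurious bin.
3. **Spatial pyramid.** Level ℓ tiles the matrix into 2^ℓ × 2^ℓ cells with
   floor boundaries (at level 3 the 20 PSSM columns split into widths 2 and
   3). This convention — rather than ℓ×ℓ grids — is the one under which the
   pyramid has 1 + 4 + 16 + 64 = 85 cells over levels 0–3 and the default
   descriptor 85 × 8 = 680 dimensions.
4. **Histograms.** Each cell accumulates an m-bin orientation histogram
   (bin = ⌊θ/(360/m)⌋), by default weighted by gradient magnitude (standard
   HOG practice; an unweighted count mode is available via
   `PhogConfig(magnitude_weighted=False)` — both satisfy the same
   invariants). Each histogram is normalised as V / √(‖V‖² + ε²) with
   ε = 1e−5 by default: the norm of every block is < 1, tends to 1 as
   ‖V‖/ε → ∞, and an empty histogram stays exactly zero instead of NaN.
   Blocks are concatenated level 0 first, cells in row-major order.

Defaults: 3 pyramid levels beyond the root, 8 bins, ε = 1e−5,
magnitude-weighted. The descriptor length law is m·(4^(ℓmax+1) − 1)/3. The
raw PSSM scores are used without rescaling; the constant-offset invariance
above makes a global shift irrelevant, and per-matrix rescaling would
interact with the magnitude weighting. Proteins shorter than 2^ℓmax
residues (8 at defaults) cannot host the finest grid and are rejected.

## Drug descriptor

An 881-bit binary substructure fingerprint per drug (the PubChem dictionary
size), consumed as precomputed bit strings from a two-column TSV. Computing
fingerprints from SMILES/SDF is deliberately out of scope; any external
tool that emits the TSV plugs in.

## Classifier: rotation forest

Training set X (n×m), labels y, K feature subsets, L trees, bootstrap
fraction f = 0.75. Per tree:

1. a fresh random partition of the m feature indices into K disjoint
   subsets with sizes differing by at most one (fresh per tree to maximise
   ensemble diversity);
2. per subset, a bootstrap sample of ⌊f·n⌉ rows drawn with replacement; the
   subset's columns are mean-centred on that sample and decomposed by PCA
   (SVD), keeping **all** loadings so each block contributes a square
   coefficient matrix. Rank-deficient blocks (routine for sparse binary
   features under bootstrap duplication) are padded with zero loadings; a
   block with no variance at all falls back to identity loadings with a
   warning;
3. the block loadings are placed at the rows/columns of their original
   feature indices in an m×m rotation matrix — entries linking features of
   different subsets are structurally zero;
4. an unpruned CART tree is fit on the fully rotated training set
   (X − centre)·R. The bootstrap only diversifies the loadings; the
   rotation must apply to every row (and to unseen samples at prediction
   time), so the stored per-block centring vector is reapplied then.

Prediction averages the per-tree class-probability vectors (class-frequency
leaves; hard votes would make the mean-combination confidence degenerate)
and takes the argmax, ties breaking toward the class earlier in the stored
class order. f = 1.0 is defined as "use all rows unresampled", which makes
the configuration K=1, L=1, f=1.0 collapse exactly to a single tree on the
classical PCA rotation — a useful algebraic anchor that the test suite
verifies against an independent implementation. Defaults K = 28, L = 26,
the optimum of a (K, L) grid search on the reference benchmarks;
`grid_search` reproduces that sweep on any data set.

## Evaluation

Stratified 5-fold cross-validation (per-class fold sizes differ by at most
one; a non-stratified mode exists). Reported per fold and as mean ± sample
standard deviation: accuracy, precision TP/(TP+FP), sensitivity TP/(TP+FN),
specificity TN/(TN+FP), MCC, and AUC by trapezoidal integration of the ROC
swept over the ensemble's interacting-class confidence. A zero MCC
denominator is defined as MCC = 0 with a warning; a rate with a zero
denominator is reported as NaN with a warning rather than silently 0.

## Synthetic benchmarks and what they show

`fixtures` fabricates complete benchmarks at the four reference scales
(drugs × proteins × positives): 445×664×2926, 210×204×1476, 223×95×635,
54×26×90. Every drug and protein carries a latent binary type; a pair is
*compatible* when both ends are type 1, and the type-1 prevalences are
sized so the compatible-pair count slightly exceeds the number of positives
to draw. Each positive is taken from the compatible pool with probability
`separability`, otherwise uniformly; at separability 1 essentially all
positives are compatible and almost every sampled negative is not, so the
types fully determine the labels, while at separability 0 the labels are
pure noise. Sizing the compatible pool to the positive count is what makes
the planted signal actually recoverable: with abundant compatible pairs the
uniformly sampled negatives would contain many compatible pairs and cap the
achievable accuracy well below 1 even at full separability.

Protein type is written into the PSSM as a low-frequency sinusoidal stripe
(period 8, amplitude 6) over uniform integer noise (±3) — stripes along the
sequence for type 0, along the alphabet axis for type 1 — orientations that
the PHOG histograms resolve directly. Drug type is written as a dense
(0.95) versus sparse (0.05) leading 40-bit block over background density
0.1. The signal lives in both modalities, so ablating either degrades
accuracy. Protein lengths are uniform on 50–200, a realistic range for the
smaller target families.

These fixtures demonstrate that the pipeline is wired correctly — it
recovers a planted association perfectly and stays at chance under the null
— not that it attains any particular accuracy on real data: real PSSM
texture differences between interacting and non-interacting targets are far
subtler than the planted stripes, fingerprint bits are correlated, and real
interaction networks have hub structure that uniform sampling ignores.

## Numerical and design choices

* Replicate padding everywhere a border rule is needed (Sobel convolution
  and central differences): shape-preserving and exactly zero on constants.
* True convolution (kernel flip) for the Sobel stage; with these
  antisymmetric kernels the flip only changes gradient signs, which the
  magnitude and the [0,360) orientation absorb consistently.
* Cross-validation splits at the pair level; holding out whole drugs or
  proteins (cold-start evaluation) is a different, harder protocol and is
  not implemented.
* Feature order is fingerprint block then PHOG block — irrelevant to trees
  but fixed for reproducibility.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the config/spec objects; fixed seeds give bit-identical benchmarks,
  models and predictions.
* Test and acceptance runs use the smallest (54×26×90) benchmark scale: 180
  balanced pairs × 1561 features per cross-validation keeps a full
  pipeline run in tens of seconds while exercising every stage at the
  default K = 28, L = 26.

## Limitations

* No fingerprint computation from chemical structure files and no PSI-BLAST
  execution; both inputs are consumed in their standard exchange formats.
* Negative downsampling is uniform; informative negative selection
  strategies are out of scope.
* The rotation forest supports only CART base learners and binary or
  multiclass labels with in-memory data.
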