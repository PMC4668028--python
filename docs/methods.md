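# Methods

This note records the mathematical definitions, numerical choices and study
design behind `mccad`. Coordinates are 0-based `(row, col)`; pixel spacing is
isotropic in mm/pixel and always supplied explicitly (raster formats carry no
spacing metadata).

## Breast segmentation

Empty space dominates a mammogram and is nearly uniform, so it fills the
maximum-count bin `b_max` of an `n_bins = 64` histogram over the full
bit-depth range. The threshold is placed at the *maximum declivity*: among
`k = b_max … b_max + n_examine − 1` (default `n_examine = 8`) the bin
maximizing `count(k) − count(k+1)` is found and the threshold is the left
edge of bin `k* + 1` (ties to the smallest `k`). The binary image is dilated
with a disk (default radius 5 px) to bridge low-intensity gaps, and the
largest 8-connected component is the breast. A constant-bright image has no
declivity to examine and raises a dedicated error.

## Stage 1 — Hessian features and random forest

**Features.** Second derivatives are computed by convolving with second
derivatives of a Gaussian at scale σ (`scipy.ndimage.gaussian_filter`,
kernels truncated at radius ⌈4σ⌉, reflect boundary; x = column direction).
The 2×2 Hessian eigenvalues are evaluated in closed form and ordered
|λ1| ≤ |λ2|; the per-scale feature is (λ1, λ2, ‖H‖_F, |λ1|/|λ2|), with the
ratio defined as 0 when λ2 = 0. Features across scales are concatenated
(length 4·n_scales). No γ-normalization is applied across scales — the raw
responses are left to the classifier. A bright blob yields λ1, λ2 ≪ 0 and
ratio ≈ 1; a bright ridge yields λ1 ≈ 0, λ2 ≪ 0.

**Forest.** Implemented from first principles. Each tree is grown on a
bootstrap sample of size |T|. At each node a fixed number of candidate
decisions (default 50) is drawn: feature index uniform, threshold uniform
between the node's min and max of that feature; the candidate maximizing the
information gain

I(S, θ) = H(S) − Σ_{i∈{L,R}} (|S_i|/|S|)·H(S_i),  H = Shannon entropy (bits)

is taken (left child: value < threshold). A node becomes a leaf when its
labels are homogeneous, the depth limit (30) is reached, or no candidate
leaves both children with at least 1 % of the full training-set size. Leaf
posteriors are empirical class frequencies; the forest posterior is the plain
average over trees. Setting the candidate count to `None` enumerates every
feature × midpoint split exhaustively (used by the correctness tests against
a brute-force optimum). Tree application is vectorized level-wise so a full
512×512 breast region (~170 k pixels × 20 features) classifies in ~1 s.

Pixels with posterior ≥ θ_RF are flagged; 8-connected components of the
flagged map become candidates, each reduced to the pixel maximizing
zero-normalized cross-correlation with a 2-D Gaussian template (window side
2⌈3σ⌉+1, reflect padding, σ defaulting to the middle feature scale; ties
break to the lexicographically smallest pixel; constant windows score −∞).

## Stage 2 — discriminative RBM

Energy over binary hiddens h, real-valued visibles x ∈ [0,1]^D (patch
intensities divided by the bit-depth maximum) and a one-hot class y:

E(y, x, h) = −h′Wx − b′x − c′h − d_y − h′U[:,y]

Because hiddens are conditionally independent, the conditional is exact:

F_y(x) = d_y + Σ_j softplus(c_j + U_{jy} + W_j·x),  p(y|x) = softmax_y F_y(x)

computed in log-space with max subtraction. Two trainers are implemented:

* **Contrastive divergence (default API)** on the joint (y, x): positive
  phase clamps the data with mean-field hidden activations; the negative
  phase samples hiddens, reconstructs visible *means* (no binarization) and
  resamples the class from softmax(d + U′h).
* **Exact discriminative gradient** of −Σ log p(y|x) (the same quantity used
  for finite-difference verification; note ∂/∂b ≡ 0 since b′x cancels).

The end-to-end study trains with the discriminative objective (learning rate
0.5, 300 epochs): on the small phantom patch sets (~600 patches) CD
plateaued around training AUC 0.85 while the discriminative objective —
which is what classification ultimately uses — reaches ~1.0 and carried over
to held-out candidates. CD remains the default and is verified on prototype
data in the tests. Candidates with p(μC | patch) ≥ θ_DRBM are the final
detections, so the cascade funnel |final| ≤ |candidates| ≤ |components| ≤
|flagged pixels| is monotone by construction.

**Training sets.** Stage-1 positives are the annotated μC coordinates;
negatives are uniform breast pixels outside annotated cluster regions and at
least 3 px from any truth point, balanced 1:1 with the positives. Stage-2
positives are patches at the annotated coordinates; negatives are the
trained stage-1 *false-positive peaks* (so the DRBM learns exactly the
failure modes of the forest), subsampled to the positive count and topped up
with background patches when the forest produces too few.

**θ_RF calibration.** The stage-1 threshold trades candidate recall against
candidate count, and a too-permissive threshold *merges* the flagged
components of adjacent cluster members, after which one NMS peak stands in
for several μCs. Following the per-dataset empirical-threshold practice, the
study calibrates θ_RF on the training phantoms over the grid 0.3–0.9,
maximizing candidate recall with ties broken toward fewer candidates
(selected value: 0.8).

## Cluster rules

All physical parameters convert through the spacing: a 1 cm window is
100 / 200 / 50 px at 0.1 / 0.05 / 0.2 mm per pixel.

**Rule 1 (pairwise distance).** For each detection p, N(p) collects the
detections within d_c1 = 4 mm. N(p) is a candidate cluster if it has ≥ 3
members, all *pairwise* distances stay within d_c1 (a chain-shaped
neighborhood is not a cluster), and the members fit a centroid-centered
square of area A_c1 = 1 cm². Overlapping candidates are resolved greedily by
size (ties to the smallest seed coordinate), yielding member-disjoint
clusters.

**Rule 2 (cumulative local probability).** The per-pixel sum of individual
detection probabilities over a sliding square window of area A_c2 = 1 cm²
(odd side, zero padding) is computed with an integral image — exact,
O(1)/pixel — thresholded, and 8-connected components become clusters scored
by their maximum window sum.

## Evaluation

Individual detections are matched one-to-one to truth points greedily by
ascending distance with a 0.5 mm tolerance (≈ one μC radius; tolerance is
config-exposed and scales with spacing). ROC uses breast-mask pixels minus
μC pixels as the negative count; PR omits thresholds keeping zero detections
(undefined precision); FROC plots cluster sensitivity against mean
false-positive clusters per image, counting each annotated region at most
once and letting annotation-free images contribute only false positives.
Trapezoidal AUC sorts by x, clips at x_max and normalizes by it. The
threshold-free pixel AUC uses the Mann–Whitney rank statistic with mid-rank
ties (cross-checked against scikit-learn in the tests). Stratified folds
split images with and without μCs separately into groups of near-uniform
size.

## Phantom generator: realism and limits

Each phantom is a half-ellipse "breast" (anchored at the left edge as a
chest wall) on a near-black border, filled with low-frequency tissue texture
(white noise convolved with a wide Gaussian, rescaled to amplitude 10 around
base level 30), bright isotropic Gaussian bumps for μCs (amplitude 25–60,
σ 0.8–1.6 px), Gaussian-profile ridges as vessel-like distractors, and
additive pixel noise (σ = 2), quantized to the bit depth. This reproduces the
structures the cascade must separate — blobs vs ridges vs smooth tissue on a
segmentable support — but *not* clinical appearance: no pectoral muscle,
skin line, labels, scanner artifacts, spiculated masses, or realistic noise
spectra, and μC morphology is idealized (round, not pleomorphic). Absolute
sensitivities on phantoms are therefore optimistic; the study validates the
machinery, not clinical performance.

Placement enforces annotation consistency with rule 1: cluster members lie
within a 2 mm radius (= d_c1/2, so pairwise distances satisfy the rule's
premise) and ≥ 3·max(σ) apart (resolvable as distinct blobs); scattered μCs
keep ≥ 4 mm (+2 px) from every other μC and stay beyond any cluster's radius
+ 4 mm; cluster centers stay ≥ 2·radius + 4 mm apart. Under these
constraints the annotated clusters are exactly the groupings satisfying
rule 1 — verified by a test that runs rule 1 on the ground-truth coordinates
and recovers every planted cluster with zero false positives.

## Study design and problem sizes

The study sizes are the package's own choices, picked to finish on one CPU
in well under the time budget while leaving no statistical ambiguity:
training on 6 phantoms (seeds derived from the master seed; ~300 μCs),
evaluation on 20 fixed phantoms (seeds 0–19; 1000 μCs, 124 annotated
clusters), 512×512 at 0.2 mm/pixel, scales {0.5, 1.0, 1.5, 2.0, 2.5},
9×9 patches, 100 trees, 200 hidden units. Measured results (seed 1):
pixel ROC AUC 0.993, point sensitivity 0.982 at 0.65 FP/image, rule-1
cluster sensitivity 0.984 at 0.0 FP clusters/image, zero funnel violations,
~82 s total.

## Numerical choices

* Eigenvalues via the closed-form 2×2 solution (no LAPACK per-pixel calls).
* Conditional DRBM probabilities and softplus in log-space; sigmoid split by
  sign — no overflow for any parameter magnitude.
* Integral image in float64; tests verify exactness against nested loops on
  dyadic-rational inputs (both summation orders are then exact).
* Determinism: every stochastic stage takes a seed; the master seed fans out
  to per-stage substreams (`numpy` Generator `spawn`), so reruns are
  bit-identical.
* Model files (forest, DRBM) are versioned JSON; detections/annotations are
  CSV with ≥ 9 significant digits on scores.
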