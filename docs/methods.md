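# Methods

This note records the models and procedures `glandcraft` implements, the
parameter choices that matter, what the synthetic phantoms do and do not
emulate, and the numerical conventions adopted where the underlying
procedure admits more than one reading.

## Tissue-component mapping

A patch is rescaled by 0.5 (bilinear) and three clusterings are run with
k-means (k-means++ initialisation, 10 restarts, tolerance 1e-4, fixed
seed):

* HSV saturation, k=3 — the darkest (least saturated) cluster is the
  lumen-candidate map; lumens and lumen-coloured artefacts are near-white
  and sit at S ≈ 0.
* CMYK cyan, k=3 — cluster 3 (highest cyan) is taken as cytoplasm and
  cluster 2 as stroma.  Both assignments are configuration
  (`MapConfig.cyan_cytoplasm_cluster` / `cyan_stroma_cluster`): with k=3
  the nuclei pixels cannot form their own cluster and are absorbed into
  the top-cyan cluster, so the "cytoplasm" map is really the epithelial
  cytoplasm+nuclei band.  The dedicated k=4 RGB clustering below
  re-isolates the nuclei.
* full RGB, k=4 — the darkest centroid (lowest mean intensity) is the
  nuclei map.

Cluster labels are always relabelled in ascending centroid intensity, so
binarisation is invariant to initialisation order.  Post-processing per
component: lumen — area opening (λ=20 px, 8-connectivity) then dilation
(disk r=1); cytoplasm/stroma — opening (disk r=1) then area opening;
nuclei — dilation then area opening.  Maps are restored to full
resolution by nearest-neighbour upsampling so they align with
full-resolution crops.

**Lumen-mode guard.** k-means with a fixed k will split a unimodal
distribution; on a patch with no lumens the "darkest saturation cluster"
would be an arbitrary noise tertile.  The pipeline therefore declares the
lumen map empty when the darkest saturation centroid is not well
separated from the next one (`lumen_separation_ratio`, default: the dark
centroid must be below half the next centroid).  Patches containing real
lumens pass this guard by a wide margin (centroids ≈ 0.03 vs ≈ 0.26 on
phantoms).

**Colour conventions.** CMYK cyan uses the black-key correction
C = (1−R′−K)/(1−K), defined as 0 for pure black.  Stain deconvolution
uses OD = −log₁₀((I+1)/255) (the +1 guards log 0) unmixed with the
row-normalised Ruifrok–Johnston H&E vectors, third vector the residual.
The tissue test behind the "discard patches with under 5 % tissue" rule
treats a pixel as tissue when min(R,G,B) < 220 (configurable).

## The 241-feature descriptor

Order and names are frozen in a versioned schema
(`glandcraft/data/feature_schema_v1.json`): 20 morphology, 15 fractal,
126 GLCM, 60 LBP-family, 20 context.

**Morphology.**  Standard region properties of the gland and lumen masks.
The gland mask is recovered from the masked candidate crop by Otsu
thresholding of R+G+B, area opening (4-connectivity, λ=20), hole filling,
largest component.  Conventions where the defining formulas are loose:
eccentricity is that of the second-moment ellipse; orientation is degrees
from the x-axis in (−90, 90]; roundness = (equivDiam/2)·perimeter/area,
reading the "gland radius" as half the equivalent diameter; compactness
is the literal perimeter/area (so it is not scale-free; both are kept as
defined).  An empty lumen yields zeroed lumen features plus a validity
flag.

**Fractal.**  Each grayscale channel (cyan, hematoxylin, eosin) is read
as rows of fractional Brownian motion; the first-difference increments
are fGn, whose PSD follows f^(1−2H).  The estimator averages |DFT|² of
the increments over profiles and fits log₁₀PSD against log₁₀f over all
positive frequencies to Nyquist; H = (1−slope)/2, unclamped, flagged if
outside [0,1].  Directions: 0° = rows, 90° = columns; 30/45/60° rotate
the crop by −θ (bilinear) and crop to the largest inscribed axis-aligned
rectangle before taking rows, which preserves unit sample spacing.
*Known bias:* the rotation's bilinear interpolation low-passes the
profiles and inflates H for oblique directions (≈ +0.15–0.25 on
spectrally flat images).  All candidates share the bias, so the features
remain comparable across candidates, but oblique and axial H values are
not directly comparable to each other.  Crops too short for a direction
(< 16 samples) yield the sentinel 0 with a validity flag.  Recovery on
exact fGn fixtures: mean |Ĥ−H| ≈ 0.01–0.03 at 256×512 for
H ∈ {0.2, 0.5, 0.8} (the acceptance script recomputes this).

**Texture.**  Channels are clipped to [0,1] and quantised uniformly to 8
levels over [0,255].  GLCMs at offsets (0,2) and (−2,2) are symmetrised
(M + Mᵀ) and normalised to sum 1.  The 21 scalars per matrix: homogeneity,
contrast, energy, correlation (0 when a marginal SD vanishes), entropy
(natural log, 0·ln 0 ≡ 0), and the literal column means
μⱼ = (1/N)Σᵢ p(i,j) and column SDs (ddof = 1).  LBP uses the
rotation-invariant uniform operator with P=8, R=1, circular neighbours by
bilinear interpolation and s(0)=1; uniform patterns map to their bit
count, others to 9.  VAR is the biased variance of the same neighbour
samples.  LBP and LBPV histograms are accumulated over interior pixels
and L1-normalised by the interior pixel count so candidates of different
sizes are comparable.  Texture and fractal channels are computed on the
unmasked bounding box by default (`use_masked_texture` switches to the
masked crop).

**Context.**  Nuclei "elements" are 8-connected components; an element is
inside a region only if all its pixels are.  The toroid is gland − lumen;
its cytoplasm+nuclei occupancy uses the union of the two maps (a pixel in
both counts once).  Lumen edge statistics use Euclidean distances from
the lumen centroid to its inner boundary pixels (SD with ddof = 1); a
multi-component lumen is treated as one region.  Ratios with zero
denominators are 0 with a validity flag.

## Feature selection

Columns are z-scored (constant columns flagged, set to 0 and discarded by
the class test).  A one-sample KS test against N(0,1) (gate α = 0.05,
configurable) routes each feature to one-way ANOVA (normal) or
Kruskal–Wallis; features with class-test p > 10⁻⁶ are dropped.  Pairwise
Pearson correlations of the survivors, with p-values from the t
transform, identify redundant pairs (|r| ≥ 0.95 and p ≤ α); within each
offending pair the member with the larger class-test p is dropped (ties
to the later schema position), one pair at a time in deterministic order,
until no pair offends.  The audit trail records every feature's
disposition.  Selection is refit inside each outer CV training split by
default; a global one-shot mode exists for comparison.

## Classification

**Fold plan.**  Patients are shuffled (seeded), stably sorted by
descending candidate count, and greedily assigned each to the outer fold
minimising the squared per-class count excess — a balanced bin-packing
that keeps fold class proportions within ~15 % of global when feasible.
All candidates of a patient share a fold.

**SVM cascade.**  Stage A separates artefacts from glands on all training
rows; stage B separates benign from grade 3 on the non-artefact rows.
Both are SVMs with the inhomogeneous quadratic kernel (γ⟨x,x′⟩+1)², C and
γ tuned in log₁₀-space over [10⁻², 10²] by minimising inner-CV error
(patient-wise folds when enough patients, else stratified).  The tuner is
a Gaussian-process Bayesian optimiser (Matérn 5/2, expected-improvement
acquisition over random candidate draws, default budget 30 evaluations; a
log-grid alternative is provided).  Final models are refit on the full
training split with Platt-calibrated probabilities
(`CalibratedClassifierCV`, sigmoid, non-ensemble).  Cascade probabilities
compose as p(artefact) = 1−p_A, p(benign) = p_A(1−p_B),
p(grade3) = p_A·p_B; a stage-A score of exactly 0.5 routes to "gland",
favouring recall of true glands.

**MLP.**  241→(selected)→15 logistic units→3 softmax, full-batch gradient
descent with momentum 0.9 and the classic adaptive rule: after an epoch
whose loss decreases the learning rate (initial 10⁻³) grows ×1.5; if the
tentative loss exceeds 1.04× the current loss the update is rejected, the
velocity reset, and the rate halved.  Early stop after 20 non-improving
validation epochs (10 % held-out split), cap 1000 epochs.

**Evaluation.**  Binary metrics per outer fold for artefact-vs-gland
(all rows, positive = gland) and benign-vs-grade3 (rows whose *true*
class is a gland, positive = grade 3), plus the three-class accuracy;
AUC is the trapezoidal area under the score-ranked ROC.  The
score-significance analysis treats each class's predicted probability as
a variable: z-score, KS normality gate, then ANOVA or Kruskal–Wallis
against the true class, averaged over folds (folds with under 10 rows are
skipped; constant score columns report p = 1).

**Permutation null.**  With labels permuted, the selection stage
correctly rejects every feature at α = 10⁻⁶, so the null experiment is
run with the gate open (α = 1); the cascade then scores at chance
(≈ 1/3), confirming that the patient-wise CV does not leak.

## The phantom generator

Phantoms emulate exactly the structures the descriptor keys on: near-white
lumen blobs (radially Fourier-perturbed ellipses), a cytoplasm ring of
8–13 px, an epithelial nuclei band (two staggered layers when dense),
pink-violet stroma, additive Gaussian noise (sd 5), and per-patient
offsets on both stain palette (±3 per channel) and geometry scale
(±8 %) so patient-wise and record-wise CV genuinely differ.  Class
semantics: benign lumens large and fusiform (geometric-mean radius
17–28 px, axis ratio 1.6–2.5) with dense nuclei coverage (0.75–0.95);
grade-3 lumens small and near-circular (7–12 px, ratio ≤ 1.25) with
sparse coverage (0.25–0.45); artefacts are bare lumen-coloured blobs with
no cytoplasm or nuclei.  Glands are placed on a jittered grid sized from
the worst-case gland extent, with bounded reject-and-resample.  Class
labels are dealt from exact largest-remainder pools per patient, so
cohort class counts track the requested mixture.

The study cohort used by the tests and the acceptance script is 15
patients × 7 patches × 9 glands ≈ 945 candidates on 512-px patches —
glands are drawn at their natural pixel scale, so patch size only sets
how many fit, not their statistics.

What the phantoms do **not** emulate: stain variability beyond a global
per-patient shift, out-of-focus blur, touching/fused glands, nuclear
pleomorphism, texture inside the stroma, and Gleason patterns 4–5.
Passing the recovery tests therefore demonstrates that the pipeline is
implemented correctly and that patient-wise CV is honest — not that the
reported effect sizes transfer to real slides, where class overlap is far
larger.

The fGn fixtures are exact by construction: each row's spectrum is
complex white Gaussian shaped by f^((1−2H)/2) with a nulled DC bin, so
the log–log PSD slope is 1−2H and H = 0.5 reduces to white noise.

## Numerical conventions and degenerate inputs

* All randomness flows from one root seed through named SHA-256-derived
  streams (`utils.derive_seed`); every stage is reproducible bit-for-bit.
* Area openings keep components with area ≥ λ; connectivity is 8
  everywhere except the gland-mask opening (4, as specified for that
  step).
* Non-finite feature values are mapped to 0 and flagged in the
  per-candidate validity record; ratios with empty denominators likewise.
* k-means refuses channels with fewer distinct values than k, naming the
  channel.
* Nested CV with tiny folds: score significance skips folds with under
  10 rows; stage training raises when a cascade stage lacks both classes.

## Known limitations

* The oblique-direction Hurst bias discussed above.
* The nuclei component map at the default 0.5 scale loses isolated small
  nuclei (the mandated dilation + λ=20 area opening removes sub-5-px
  clusters); dense epithelial rings survive.  Contextual features in the
  estimated-maps route are correspondingly conservative; the ground-truth
  route is unaffected.
* `compactness` and `roundness` are not dimensionless; they discriminate
  size as much as shape.
* The phantom's class separation is deliberately large; accuracy on it is
  a correctness check, not a performance claim.
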