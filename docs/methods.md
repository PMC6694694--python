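# Methods

This note documents the models, algorithms and design choices behind
`fundusdr`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, and what the synthetic test bed does and does not
demonstrate.

## Scope and overall design

`fundusdr` re-implements a classical (pre-deep-learning) automated
diabetic-retinopathy assessment pipeline for single 45° non-mydriatic
color fundus photographs: photometric normalization, vessel and optic-disc
extraction, morphological/color lesion detection with a margin-classifier
refinement, an image-quality gate, a decision-rule severity stage, and
pixel-level lesion quantification.  Alongside the pipeline it implements
the screening-evaluation statistics used to judge such systems against
clinician grading (confusion matrices, sensitivity/specificity and their
complements, Cohen's kappa with the conventional qualitative bands,
ROC/AUC, one-way ANOVA from per-group summary statistics, and Fisher-LSD
pairwise comparisons).

No clinical image corpus ships with the package.  All raster-level claims
are validated on a seeded synthetic scene generator with exact per-pixel
ground truth; the statistics layer is additionally validated against the
published summary tables bundled in `fundusdr.datasets`.

## Photometric preprocessing

*Field of view.*  The circular camera field (ROI) is separated from the
black border by adaptive luminance thresholding (local mean over a window
of 1/8 of the frame, minus a 10-gray-level offset, combined with an
absolute dark floor of 18), hole-filling of the largest connected
component, and a circularity check against the equivalent-area disc
template.  A frame with no black border falls back to the full frame
minus a 1-px margin; an image whose largest bright component covers less
than 20 % of the frame raises `NoFieldFound`.

*Normalization.*  Camera and operator variability is removed by matching
each photograph's lightness mean/SD (linear) and saturation mean
(multiplicative) inside the ROI to a standard reference image.  The
decomposition is HSV: the value channel plays the role of lightness and
hue is left untouched, so the operation is hue-preserving and exactly
invertible through `skimage`'s conversions.  The shipped reference is a
clean synthetic scene with a fixed seed; users normalizing real
photographs should measure a profile from their own reference with
`make_profile`.  Normalization is idempotent to within one gray level at
≥ 99 % of ROI pixels (clipping at the range ends accounts for the rest).

*Denoising* is a per-channel median filter, radius 1 by default.  On
piecewise-smooth structure the filter is near-idempotent (a second pass
moves ~1.6 % of pixels, all on thin vessel edges); on i.i.d. sensor noise
repeated medians keep evolving, which is expected behavior for median
filtering rather than a defect.

## Vessel map

Vessels are the darkest elongated structures on the green channel.  The
detector is a multi-orientation line operator: at every pixel, the local
background mean minus the mean along a short line segment, maximized over
12 orientations and three lengths (7, 11, 17 px at 512-px frame width).
The response is thresholded at 4 gray levels, then refined by a per-pixel
linear color classifier over (R, G, B, line response, orientation
anisotropy, green-minus-local) trained once on generator-labeled scenes
and shipped as a JSON coefficient record.  The anisotropy feature
(best-orientation minus worst-orientation response) is what separates
true line structure from isotropically dark blobs such as hemorrhages.

Two post-passes stabilize the map: a 3×3 closing bridges single-pixel
gaps left by the per-pixel decision, and rejected line-response
components that touch the accepted network on two or more disjoint arcs
are reclaimed (dark chunks at vessel crossings look isotropic pixel-wise
but are bridging pieces of the tree).  The classifier operating point is
shifted 0.5 standardized units toward vessel recall: a missed vessel
chunk becomes a red-lesion false positive downstream, while an over-called
vessel pixel is recoverable by the red detector's strip-and-requeue logic.

On the seeded 20-scene benchmark the map reaches mean Dice ≈ 0.73 against
ground truth (no scene below 0.70).  The 1-2 px boundary band of each
vessel accounts for most of the residual disagreement.

## Optic disc

Candidates are bright blobs (top 1.5 % of the smoothed luminance inside
the ROI).  Each is scored by a weighted sum of mean brightness percentile
(weight 0.45), circularity as IoU with its equivalent circle (0.25), and
vessel convergence measured as vessel density in a ring around the
candidate (0.30); ties break on the brightness term.  The best candidate
is returned with confidence equal to its normalized score — a discless
scene yields a flagged low-confidence result rather than an error, which
feeds the quality gate.  On the benchmark the center error is below half
the true disc radius in 100 % of scenes.

## Lesion detection

*Red lesions.*  Small candidates come from a dark top-hat (grey closing
minus image) on the green channel with a structuring element of
disc_radius/15; large candidates from color discrimination — darkness
relative to a field-restricted background estimate plus reddish hue.  The
background is a normalized convolution that excludes candidate and vessel
pixels, so a dense lesion load cannot drag the estimate down and mask its
own contrast.  Candidates inside 1.3× the disc radius are removed.
Candidates overlapping the vessel map by ≥ 20 % of their area are not
dropped outright: their vessel pixels are stripped and the off-vessel
remainder re-queued (minimum fragment size: half the microaneurysm area
boundary), so a lesion that merely touches the tree survives while pure
vessel segments do not.  First-pass candidates covered ≥ 60 % by a
closing of the vessel map are suppressed as embedded vessel structure.

Surviving candidates are accepted or rejected by an RBF support-vector
machine over eight shape/color/contrast features (area, eccentricity,
circularity, mean hue, mean saturation, green contrast, boundary
gradient, distance to vessel), trained on a generator-labeled candidate
corpus spanning mild, dense, large-lesion and lesion-free scenes, and
shipped as a JSON record of standardized support vectors.  An earlier
linear margin classifier proved unstable across lesion-density regimes
(its single hyperplane cannot express the hue×shape×contrast interactions
that separate vessel fragments from true lesions); the SVM removed all
clean-scene false positives while accepting essentially every true
candidate.

Accepted regions are finally fused: a vessel crossing a hemorrhage cuts
its candidate in two and the stripped band is lost, so accepted parts are
bridged across gaps of up to ~8 px (annexing only candidate or vessel
pixels), holes are filled, and the fused components become the reported
regions.  The microaneurysm/hemorrhage split is a configurable area
boundary (30 px at 512² scale, scaled by (width/512)²).

*Bright lesions.*  Candidates are pixels whose luminance exceeds the
field-restricted background estimate by 18 gray levels; the disc region
is excluded.  The exudate/cotton-wool split is a fixed two-feature rule:
mean boundary gradient ≥ 14 means a sharp-edged exudate; below it the
region is a cotton-wool spot when large (≥ 120 px), else a soft small
exudate.

*Photocoagulation scars* are round (circularity ≥ 0.55), similar-sized
pale spots in the peripheral annulus (outside 0.55 of the ROI radius,
area 20-800 px).  A scene is PRP-positive at ≥ 15 spots with area
coefficient of variation ≤ 0.6.

## Quality gate

Five measurements, each with a frozen threshold calibrated once on the
seeded degradation suite (`scripts/calibrate_quality.py` reproduces the
calibration report):

| measurement | definition | flag when |
|---|---|---|
| fuzzy_score | SD of the Laplacian of luminance over the ROI | < 1.0 |
| dark_fraction | fraction of the field hull below luminance 40 | > 0.15 |
| saturated_fraction | fraction of ROI with any channel ≥ 250 | > 0.18 |
| eyelash_score | area fraction of elongated dark intrusions crossing the field boundary | > 0.004 |
| decenter_px | distance of the field-hull center from the frame center | > 60 px |

Dark patches and eyelashes carve themselves out of the adaptively
thresholded ROI, so those two measurements (and the centering) are taken
over the convex hull of the ROI rather than the ROI itself.  An image is
qualified exactly when no flag fires; on the calibration suite all clean
scenes qualify and every degraded variant (severity 0.5) is flagged with
the correct cause.

## Staging

A first-match rule cascade, all thresholds in the config:

1. not qualified → UNGRADABLE (absorbing: no lesion evidence overrides it);
2. PRP-positive scar pattern → PRP;
3. ≥ 20 hemorrhages in every quadrant, or total red-lesion area ≥ 5,000 px
   (512² scale, ≈ 3 % of the field) → DR3;
4. any hemorrhage or bright lesion → DR2;
5. microaneurysms only → DR1;
6. otherwise DR0.

The quadrant rule adapts the clinical 4-2-1 severe-NPDR criterion to what
single photographs show; venous beading and IRMA are not assessable here,
hence the total-area fallback.  The area cut was calibrated once on the
default cohort — in the same one-shot spirit as the quality-gate
thresholds — so that severe-NPDR-level lesion loads grade DR3: it sits in
the wide gap between mild/moderate loads (≤ ~900 px planted red area) and
severe loads (≥ ~7,500 px), on both the planted and the detected scale,
which keeps the stage decision robust to the detector's conservative area
bias in dense scenes.  Quadrants partition the ROI about the
posterior pole (disc center shifted temporally by half the ROI radius).
Proliferative disease cannot be diagnosed reliably without angiography,
so the PDR rule (a confluent red region ≥ 25,000 px) is an experimental
mode, off by default; a config switch can collapse PDR into DR3 for
comparison against graders who pool them.  Staging is monotone under
lesion addition (verified as a property over random lesion subsets).

## Quantification

Six indices per image: total area, region count and maximum region area
for the hemorrhage family and the exudate family.  Areas are raw pixel
counts — no mm² calibration is attempted, matching systems that quantify
"on the basis of pixel area".  Microaneurysms count in the hemorrhage
family by default (they are red lesions); a config switch excludes them.
Group summaries report sample mean and SD with the n−1 denominator, which
is what makes the one-way ANOVA from summaries reproduce a raw-data
ANOVA exactly.

## Evaluation statistics

The summary-statistics ANOVA uses the exact decomposition
SS_between = Σ nᵢ(mᵢ − m̄)², SS_within = Σ (nᵢ−1)sᵢ², so published
(n, mean, SD) tables can be re-analyzed without raw data; equivalence
with `scipy.stats.f_oneway` on reconstructed raw data is property-tested.
The pairwise comparisons implement Fisher's LSD — pooled error term,
SE = √(MS_within(1/nᵢ + 1/nⱼ)), t on the within d.f., unadjusted
two-sided p — because that structure exactly reproduces the published
standard errors and 95 % CIs; Bonferroni is available as an option.
Kappa is unweighted with the usual qualitative bands (≤ 0.2 poor, ≤ 0.4
fair, ≤ 0.6 moderate, ≤ 0.8 good, above that excellent).  ROC curves
sweep thresholds over unique scores with trapezoid AUC, which equals the
pairwise concordance statistic (property-tested at 1e−9).

Per-stage sensitivities/specificities of the original screening program
are not reproducible from its published count table alone (the collapse
it used is not fully specified), so multi-class screening metrics here
require an explicit positive-label set.

## The synthetic test bed

`fundusdr.synthetic` renders 512×512 scenes: a circular field with radial
vignetting and Gaussian sensor noise, a recursive branching vessel walk
converging on a bright soft-edged disc, a darker macula, and planted
lesions — dark red dots (microaneurysms), irregular dark blobs
(hemorrhages), sharp yellow multi-lobed clusters (exudates), feathered
pale patches (cotton-wool spots) and regular peripheral pale spots
(photocoagulation scars).  All randomness derives from one root seed via
`SeedSequence` spawning, so any scene is reproducible in isolation, and
ground-truth region areas equal planted pixel counts exactly.
Microaneurysms are planted strictly off-vessel; hemorrhages may touch a
vessel on < 10 % of their area.  Five degradations (blur, dark patch,
eyelash, overexposure, decentering) model the disqualification causes of
community screening, with severity mapping monotonically to strength.

The default cohort has three groups of 39/29/23 scenes whose planted
loads emulate the published lesion-burden trends across severity: total
areas rise strictly with group (mild+moderate → severe → proliferative)
while lesion counts peak in the middle group, because proliferative-stage
lesions are drawn large enough to emulate fusion into fewer, bigger
regions.

What passing the synthetic benchmark does **not** show: performance on
real photographs.  The generator has flat shading, no media opacity, no
inter-eye anatomy variation, no laterality errors, and lesion photometry
far cleaner than real pathology; detection thresholds transferred to real
data would need recalibration against a labeled clinical set.  The test
bed's purpose is exact-ground-truth verification of the algorithmic
machinery, not a clinical validation.

## Benchmark definitions and problem sizes

The shipped benchmark (used by the test suite and `scripts/acceptance.py`)
runs the full pipeline on 20 scenes (14 lesion-bearing + 6 clean) plus
the 91-scene cohort.  A planted lesion counts as detected when ≥ 30 % of
its pixels are covered by the detected mask of its family — the usual
region-overlap hit criterion in lesion-detection evaluation; per-lesion
recall is scored on hemorrhages ≥ 50 px.  False positives are counted per
clean scene.  Cohort stage accuracy compares the pipeline's stage with
the stage obtained by applying the same rule cascade to the planted
ground-truth evidence, so it isolates detection fidelity from rule
choice.  The repeatability check quantifies the same images three times
and reports the agreement as a kappa (identical outputs give exactly 1).

## Known limitations

* Dense lesion fields still lose some area where lesions and vessels
  interleave; the fusion and completion steps recover vessel crossings but
  not every lesion pixel the vessel classifier claims.  The bias grows
  with lesion size (roughly 0.9 of planted area recovered for
  severe-NPDR-scale lesions, 0.7 for the largest proliferative-scale
  ones), so while the mild-vs-advanced separation and the group ANOVA are
  robust, the estimated severe-vs-proliferative ordering of mean total
  area can invert even when the planted ordering is strict.  Per-lesion
  areas in dense scenes are conservative.
* The vessel map is a binary mask: no width, tortuosity or artery/vein
  information.
* Neovascularization is not a detected class; PDR detection is an
  experimental area-based surrogate, off by default.
* "Other diseases" (non-DR pathology) is not modeled and no rule emits it.
* Grading is per-image; fusing the two fields per eye, or images per
  patient, is out of scope.
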