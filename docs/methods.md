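# Methods

## Problem setting

Dopamine-transporter (DAT) SPECT distinguishes nigrostriatal degeneration
(reduced striatal tracer binding, most pronounced in the putamen of the
more-affected hemisphere) from scans with normal striatal uptake.  A 3D
convolutional network can learn this binary discrimination directly from
stereotactically normalized volumes, but is opaque; layer-wise relevance
propagation (LRP) redistributes the network's output score backward through
the layers under a per-neuron conservation constraint, producing a signed
voxel map of how much each voxel contributed to the decision.  This package
implements the classifier, the LRP engine with a specific per-layer rule
combination, the semi-quantitative preprocessing around them, and a
synthetic striatal phantom so that the entire pipeline is testable without
clinical data.

## Preprocessing and the specific binding ratio

Volumes are assumed already resampled to a canonical grid (x: left to
right, y: posterior to anterior, z: inferior to superior).  Intensities are
divided by the 75th percentile (linear interpolation between order
statistics) of a reference region comprising the brain without the striata,
pinning nonspecific uptake at 1.  The specific binding ratio (SBR) of a
target structure is estimated by hottest-voxels analysis: the target mask
is dilated by 1 voxel (the "large" ROI), the hottest 25% of its voxels are
averaged, and the reference level 1 is subtracted.  The dilation absorbs
small localization error and partial-volume spill; the fraction and
dilation are configurable and recorded in outputs.  Scans whose right
putaminal SBR is lower than the left are mirrored about the midsagittal
grid plane x = (nx-1)/2 (an exact involution for any grid parity), so the
lower-binding ("ipsilateral") putamen is on the left in every scan the
classifier sees.  Exact SBR ties are not flipped — a measure-zero case
pinned for determinism.

## Classifier

Four 3D convolutional layers (3x3x3 kernels, stride 1, dilation 1, valid
padding, no pooling) with rectified-linear activations, a flatten, fully
connected layers of 32 and 16 rectified units with dropout 0.2 after the
first, and a 2-way softmax.  The reference width is 16 filters per
convolutional layer.  Training minimizes categorical cross-entropy with
Adam at learning rate 1e-4 and batch size 8, without class weighting, and
retains the weights of the epoch with the lowest validation loss (maximum
epochs default 30; there is no other stopping rule).  Hidden layers use He-normal
fan-in initialization; the softmax head starts at zero, so the untrained
network is exactly indifferent (logits 0, cross-entropy ln 2) and the first
gradient steps align the readout with the labels — with a random head, the
initial readout direction correlates with the label with arbitrary sign,
and unlearning an anti-correlated head at the small fixed learning rate
costs many epochs.  The network is
implemented directly on NumPy (im2col convolutions running as BLAS matrix
products, exact backpropagation validated against finite differences in the
test suite); this gives the relevance engine first-class access to every
layer's weights and activations.  All stochastic steps — initialization,
batch shuffling, dropout — are seeded, so training is reproducible on a
fixed BLAS configuration.

## Cohort splitting

Cases are stratified into the four sex-by-label subgroups.  Within each
subgroup the fractions (train 2/3; of the remainder, 1/3 validation and 2/3
test) are applied with largest-remainder rounding, which keeps every
subgroup within one case of its ideal count in every set while the global
set sizes are hit exactly (1296 cases give 864/144/288).  One hundred
candidate splits are drawn and the split minimizing the age-balance
objective — the sum over the four subgroups of the range (max minus min) of
mean ages across the three sets — is retained.  The objective is the
simplest scalarization of "minimum difference in mean age over the
subgroups" and is configurable.

## Relevance propagation

With z_ij = a_i w_ij (forward activation times trained weight), relevance
starts as the pre-softmax score of the most activated output neuron and is
redistributed one weighted layer at a time:

* **epsilon rule** (output and both fully connected layers, eps = 1e-4):
  R_i = sum_j z_ij / (sum_i z_ij + eps sign(sum_i z_ij)) R_j, sign(0) = +1.
* **alpha-beta rule** (the two convolutional layers nearest the output,
  alpha = 2, beta = alpha - 1 = 1): positive and negative parts of z are
  redistributed separately with weights alpha and -(alpha - 1), which
  conserves relevance on bias-free layers and permits negative relevance
  ("evidence against").
* **flat rule** (the two convolutional layers nearest the input): each
  neuron's relevance is split equally over its receptive field, controlling
  the resolution and semantics of the final map.  Conservation is exact.

Raw scores rather than softmax probabilities start the decomposition: the
argmax is identical (softmax is monotone) and the map keeps score units.
Biases participate in the forward pass but absorb no relevance; the
resulting leak at epsilon-rule layers is reported by the conservation
diagnostics (the sequence of layer relevance sums) rather than silently
redistributed.  Epsilon-rule dissipation is bounded by
eps * sum_j |R_j| / min_j |sum_i z_ij + eps sign(.)|.

Two degenerate cases are pinned explicitly.  First, in the alpha-beta rule
a neuron whose contributions are all of one sign redistributes its full
relevance through that single channel (coefficient 1 instead of alpha):
keeping the alpha weighting there would emit alpha times the neuron's
relevance, breaking conservation, and would prevent the rule from
collapsing onto the epsilon rule (eps -> 0) on layers without negative
weights.  The alpha/beta weighting therefore only arbitrates *between* the
two channels when both exist.  Second, maps of predicted-normal scans are
multiplied by -1 ("sign harmonization") so that positive relevance always
denotes evidence for reduced uptake; the flag is recorded and the raw-sign
map is recovered by negation.  This reconciles the observation that the
group-mean map of true negatives is the sign-flip of the true-positive one
with a single reading convention.

## Relevance analytics

Group mean maps are voxel-wise arithmetic means over true-negative and
true-positive cases; the heat map is mean(TP) - mean(TN).  (The source
descriptions of the subtraction order disagree between text and figure
caption; the caption order is used because it makes the ipsilateral putamen
the hottest region, and a flag can invert it.)  The putaminal mean
relevance of a scan applies the same hottest-voxels analysis as the SBR to
the sign-harmonized map, ranking voxels by absolute relevance (relevance is
signed; ranking by raw value would bias negative means toward zero — raw
ranking remains available) and averaging the signed values of the selected
voxels.  Dichotomizing this statistic at zero yields a second classifier
(ties declared negative); a scan whose relevance-based class contradicts
the CNN prediction is flagged as an "inconsistent map", the candidate
misclassification signal.

## The phantom

The generator emulates the appearance of normalized DAT-SPECT, not its
physics: a brain ellipsoid of uniform background 1.0 inside a 144 x 168 x
132 mm field of view; bilateral ellipsoidal putamen (semi-axes 8/15/10 mm)
and caudate (5/10/8 mm) adding specific binding background x contrast, with
the per-case contrast drawn from N(2.5, 0.3) clipped at 1; Gaussian blur of
12 mm FWHM standing in for SPECT resolution; then zero-mean Gaussian noise
with standard deviation proportional to local intensity (5% default)
standing in for reconstructed count noise.  Disease is a fractional loss
(severity) of the specific putaminal signal in a randomly drawn hemisphere;
the other hemisphere loses severity x asymmetry (default 0.5) and the
caudate loses severity x caudate_sparing (default 0.5), matching the
putamen-first, asymmetric pattern of nigrostriatal degeneration.  Positive
cases draw severity uniformly from [0.2, 1]; the floor keeps labels from
being dominated by boundary cases, and a separate borderline mode (severity
near 0.1) exists to emulate equivocal scans.  Ages are N(67.5, 11) years
and sex is Bernoulli(0.42 female); both exist only to exercise the
stratified split.

Deliberate idealizations: the putamen-caudate gap (~17 mm surface to
surface) is wider than the anatomical internal capsule so that a fully
denervated putamen with spared caudate reads SBR near 0 despite the 12 mm
PSF; structures are axis-aligned ellipsoids; noise is Gaussian and
uncorrelated; there is no attenuation, scatter, or reconstruction texture,
and no atypical (vascular) patterns.  Tests passing on phantoms therefore
demonstrate the correctness of the computational pipeline and the
qualitative behaviour of relevance maps on a controlled object — not
clinical performance.

## The end-to-end study and problem sizes

The default study simulates 450 scans (47.8% positive), splits them
300/50/100, trains and explains every test scan, and reports CNN and
relevance-based confusion metrics, the localization of peak relevance, the
CNN-vs-relevance agreement, and conservation diagnostics.  The study grid
is 28 x 32 x 26 at 5.25 mm — the same physical object as the full
48 x 56 x 44 at 3 mm grid, sampled coarser — with 8 filters per
convolutional layer and at most 20 training epochs under the
best-validation checkpoint.  These scaled-down sizes keep a complete study
at desk-scale single-CPU cost while leaving every algorithmic component
identical to the full-resolution configuration, which remains available
through the configuration.  Two scale choices matter and were set by
explicit diagnostics: the grid cannot be much coarser because the
network's receptive field (9 voxels across after four convolutions) must
stay comparable to the striatal structures — on a 6 mm grid the receptive
field spans 54 mm, the network degenerates toward a global peak-mass
readout, and the peak-relevance voxel localizes unreliably; and the epoch
budget cannot be much smaller because convergence at the fixed learning
rate 1e-4 becomes initialization-fragile (runs can stall on the
majority-class plateau).  The master seed fans out to stage seeds by fixed
offsets (cohort +0, split +1, initialization +2, training +3).

## Relevance polarity on the phantom

One qualitative property of clinical relevance maps does not reproduce on
this phantom, and the package reports it honestly rather than adjusting
the analysis.  Trained on phantom cohorts, the two output scores are
nearly antisymmetric, so the relevance of the most activated neuron has,
after sign harmonization, the *same* putaminal sign for both classes:
normal scans concentrate strong positive raw relevance on the putaminal
peaks (the uptake is the evidence for "normal"), while reduced scans
assign modest negative relevance to the residual putaminal uptake
(evidence *against* "reduced") and spread the positive evidence over the
background.  Per-layer conservation is exact and the scalar-oracle checks
pass, so this is a property of what the network learns, not of the
propagation: the effect persists and strengthens with longer training,
more filters, and finer grids.  Consequently the zero-cutoff putaminal
relevance classifier tracks the CNN prediction only for the normal class
(50-60% overall agreement), unlike the clinical finding it emulates, where
the network evidently learned absence/contrast features that place
net-positive relevance in the denervated putamen.

The same polarity drives a second consequence: in a reduced-uptake scan
the single voxel of maximum |relevance| is contested between the (negative)
putaminal cluster and the sharpest spot of the diffuse background
component, which typically sits in a ring just outside the striatum.
Which one wins depends on the particular learned solution, so the
peak-localization rate over correctly classified positives varies strongly
across training seeds (from ~100% down to a few percent in otherwise
equally accurate runs) even though the group-level structure is stable:
the absolute heat-map peak lies in the ipsilateral putamen in every probe
run, and normal scans localize their peak relevance on the putamina
essentially always.  The acceptance suite asserts the individual-scan
localization and agreement properties at their nominal thresholds and
reports them as failing on this phantom; the accuracy property holds
robustly.  The study report records signed and absolute heat-map variants
and all per-case statistics so the phenomenon can be inspected directly.

## Known limitations

* The phantom's intensity model is piecewise-constant-plus-blur; networks
  trained on it exploit simpler features than clinical scans require, and
  absolute performance numbers do not transfer.
* The 236-million-parameter count of the original full-resolution network
  depends on an input matrix size that is not public; parameter counts here
  are reported for the configured grid instead.
* Cohen's kappa is reported without a standard error (estimator variant
  unspecified in the source material).
* Relevance maps explain the trained classifier, not the disease: sign and
  localization statements are claims about the network's evidence use.
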