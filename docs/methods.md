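# Methods

`msilowsig` implements a workflow for making low-abundant, spatially
annotated signals in mass spectrometry imaging (MSI) accessible: a shallow
convolutional autoencoder (ConvAE) compresses the m/z channel axis while
preserving local spatial structure, random-forest (RF) regression ranks
latent features against a co-registered annotation (here: tumor hypoxia in
[0,1]), a perturbation probe recovers the original m/z channels behind the
top-ranked latent feature, and tolerance-window matching links those
channels to tandem-MS peptide masses. An RF-only route (no encoding)
provides the comparison baseline. Everything below is the package's own
account of the procedure, its defaults, and its limits.

## Preprocessing

Per-sample m/z axes are averaged into a common grid; peaks are picked on
each sample's mean spectrum at a required signal-to-noise ratio (default 6),
mapped back to the grid by binary search (ties to the lower index), and
same-bin peaks averaged into reference peaks. The SNR noise scale is
1.4826 x the median absolute deviation of the first-differenced spectrum — a
robust, parameter-free estimator chosen because peak pickers' internal noise
models vary. A `min_assignments` threshold on bin occupancy optionally
summarizes inter-sample mass shifts; at 1 (default) shifts are deliberately
retained as near-duplicate channels so that downstream matching can stay
close to the raw measurements. Pixel spectra are TIC-normalized (zero-TIC
tissue pixels are reclassified as background and logged); channels are then
put on a common scale across samples by equalizing per-channel tissue means
(the simplest per-m/z global factor), and finally min-max scaled to [0,1]
per channel with bounds frozen on the training samples only, so validation
samples cannot leak into the normalization.

## Autoencoder

Input patches are 3 x 3 pixels x P channels. The encoder is a 1 x 1
convolution to 1024 hidden channels, then a 2 x 2 valid convolution to the
latent size (default 64; the reference study uses 16), each followed by
batch normalization and ReLU; a 3 x 3 patch becomes a 2 x 2 x z2 code. The
decoder mirrors the encoder layer by layer (transposed convolution, batch
norm, ReLU, pointwise convolution, batch norm, ReLU), so reconstructions are
nonnegative like the input. Batch-normalization constants are momentum 0.99
and epsilon 1e-3. The layers and Adam optimizer are implemented directly on
numpy arrays (the network is two convolutions deep; gradients are exact and
covered by finite-difference tests).

The reconstruction loss is an *adjusted* mean absolute error: the absolute
error is summed over the pixels and channels of a patch and averaged over
patches only. Summing rather than averaging over channels keeps every
individual channel's error visible in the loss, which is what lets
low-abundant channels survive compression. The semi-supervised mode adds
the mean, over pixels whose annotation exceeds 0.6, of the per-pixel
channel-summed error (zero when no pixel qualifies; the normalizer is the
number of selected pixels, so the term does not shrink as annotations get
sparser). The variational mode appends pointwise mean/log-variance heads
and a sampling step and adds the KL divergence to a standard Gaussian,
averaged over patches.

Training uses Adam at learning rate 1e-4 (rates at or above 1e-3 are
accepted but warned about — they visibly degrade the learned
representations), 25 epochs unsupervised/variational and 50 semi-supervised,
on overlapping patches (step 2) from the training samples; all-background
patches are discarded. The module-level default batch size is 32. The
pipeline default is 8: on the desk-scale reference study (~1000 training
patches) this yields ~3000 optimizer steps over 25 epochs, the same
optimization regime the architecture is designed for on full-size data,
where an epoch alone has hundreds of steps. Initialization is He-style with
an explicit seed; training is deterministic given the seed.

## Feature ranking

Patches of step 1 from all annotation-usable samples are balanced by
downsampling non-hypoxic patches (annotation target exactly 0; the target
itself stays continuous) to the hypoxic count. RF regressors (1000 trees,
mtry = sqrt of feature count, squared-error impurity) are refit on each of
10 cross-validation folds; per-fold mean-decrease-in-impurity scores are
normalized to sum 1 and kept per run, so both mean rankings and
"top in k of 10 runs" statements are computable. Features are either latent
patch means (ConvAE route: mean over the 2 x 2 latent pixels) or original
channel patch means (RF-only route). RF-only channels are selected by the
union over runs of features reaching a fraction (default 1/4) of that run's
top score.

## Recovery

For one probed channel at a time, every other channel is set to the
constant 1 (the maximum of the normalized scale) in all pixels; the modified
patches are encoded, and the chosen latent feature's per-patch mean is
Spearman-correlated with the per-patch mean of the probed channel's original
ion image, per sample. A channel is associated when the aggregated
correlation exceeds 0.95; the aggregate is the minimum over samples (the
conservative reading; mean is available). Undefined correlations (constant
series) count as non-association and veto the channel under min
aggregation. Implementation note: with all other channels constant, the
first convolution is affine in the probed channel, which allows an exact
fast path that avoids the full channel contraction (tested against the
direct implementation).

Two documented policies handle known behaviors of impurity-ranked latent
features:

* **Orientation.** Impurity importance is sign-agnostic, so the top feature
  can encode the annotation with inverted polarity. The pipeline orients
  the feature by the sign of the correlation between its latent patch means
  and the annotation targets and applies the cutoff to the oriented
  correlation. With a positively oriented feature this is exactly the plain
  high-positive-correlation rule.
* **Fallback.** Some latent features are degenerate under the constant-fill
  probe (for example features that separate tissue from background, which
  saturate to zero) and recover nothing. When that happens the pipeline
  falls back to the next-ranked features (at most 2 further, logged). The
  top-ranked feature is used whenever it recovers anything.

## Evaluation

Every associated channel's ion image is compared to a reference channel's
image (default: the RF-only top-importance channel) with SSIM — 7 x 7
uniform window, K1 = 0.01, K2 = 0.03, data range 1.0, images cropped to the
tissue bounding box so the shared empty background does not inflate scores.
Score distributions are compared with two-sided Mann-Whitney U tests (exact
distribution for tie-free combined n <= 16, tie-corrected normal
approximation otherwise; two identical constant groups return p = 1),
Benjamini-Hochberg adjusted across the family at FDR 5%, and annotated with
the usual star cutpoints. Boxplot statistics follow Tukey (1.5 x IQR
whiskers, linear-interpolation quartiles). Cross-validated R2 of the
regression forests, adjusted for the latent feature count, quantifies how
well a latent configuration explains the annotation.

## Peptide matching

MALDI ions are predominantly singly charged, so peak m/z converts to mass
by subtracting 1. Each associated peak's tolerance window combines the
envelope of per-sample FWHM half-maximum points (linearly interpolated
crossings; flanks that never cross are truncated at the axis bound and
logged) with a technical window of one channel spacing (0.0487 m/z) either
side; the window is the intersection of the two, shifted by -1 (the shift
commutes with min/max). Peptides whose sequence contains "C" are excluded
beforehand (a proxy for modified peptides). A peptide mass matches a window
inclusively. Matched peaks of one protein are collapsed into mass-shift
groups: overlapping windows always merge, and near-duplicate ion images
(Pearson r > 0.975) merge only within 3 channel spacings — drift spans at
most a few channels, and distinct peptides with genuinely similar spatial
distributions must not collapse. A protein becomes a candidate when at
least 2 distinct groups remain whose exemplary ion images pairwise exceed
Spearman 0.80 over the concatenated tissue pixels of all samples; one
exemplary mass pair is reported per candidate.

## Synthetic data generator

The generator emulates a multi-sample MALDI-TOF peptide imaging study with
a co-registered hypoxia annotation. Per sample: an elliptical tissue mask;
an annotation field that is a clipped sum of Gaussian blobs (default 5
blobs, scale 3 px on a 40 x 40 grid — focal staining covering roughly a
fifth of the tissue); six smooth morphology fields. Channels fall into four
classes on a 0.0487-spaced m/z grid over [600, 3200]:

* **Signal channels** (default 4 bases, each with 1 isotope at +1.003 and 1
  mass-shift replicate at +0.03 — 12 planted channels): base intensity is
  gain x (0.3 + 0.25 x basal field + 1.0 x annotation) + Gaussian noise
  (sd 0.06). Bases are paired into synthetic "proteins" sharing the basal
  abundance field, because tryptic peptides of one protein share the
  protein's whole image — the property the candidate plausibility check
  (Spearman > 0.80 between mass-pair images) relies on. Isotopes are
  decaying copies (factor 0.6); replicates are near-copies (Pearson
  r > 0.975 by construction). The whole family is scaled so its tissue mean
  is 0.2 x the confounder mean ("low-abundant").
* **Anti-correlated channels** (default 6): high baseline minus 0.5 x
  annotation — hypoxia-depleted peptides such as proliferation markers.
  They are discriminative for a regression model but dissimilar to the
  induced signal group, which is what separates impurity-based selection
  from latent-feature recovery in the comparison.
* **Morphology confounders** (default 60): baseline + (0.4-1.0) x a
  morphology field, with intensity-proportional pixel noise (CV 0.5) —
  structured but shot-noise dominated, like real high-abundance channels.
  Their count matters: with too few of them the reconstruction objective is
  nearly indifferent to differentiating latent features and the code can
  collapse onto a single direction.
* **Speckle channels** (the remainder): low baseline, negligible structure,
  intensity-proportional noise — the majority class in real TOF peptide
  imaging.

The peptide table pairs two matchable peptides per synthetic protein at
masses (base m/z - 1) + jitter (sd 0.005 Da, the accuracy scale of modern
tandem-MS monoisotopic masses), adds decoys rejected until they are at
least 3 technical errors from every channel, and one cysteine-containing
row to exercise the exclusion rule. Everything is deterministic given the
seed.

What the generator does **not** emulate: profile spectra (channels are
picked peaks), matrix clusters, spatial instrument drift beyond the fixed
mass-shift replicates, chimeric or multiply charged species, and
co-registration error between annotation and MSI (inputs are perfectly
aligned). Passing tests therefore show that the pipeline recovers planted
linear annotation couplings under realistic noise and redundancy — not that
it is robust to misalignment or nonlinear couplings.

## Reference study and problem sizes

The bundled end-to-end study uses 5 samples (3 training, 2 validation) of
40 x 40 pixels and 300 channels, a 16-feature latent space, 25 epochs,
batch 8, 1000-tree forests with 10-fold cross-validation. A full two-route
run takes a few minutes on one CPU core. These sizes were chosen so the
whole study, including training, runs comfortably on a laptop while keeping
every structural element of the full-scale problem.

## Known limitations

* Run-to-run variability is real and mirrors the method itself: which
  latent feature ranks top, its polarity, and its behavior under the
  constant-fill probe all depend on initialization. The orientation and
  fallback policies absorb the common cases, but occasional realizations
  collapse the whole latent code onto one direction (reconstruction barely
  suffers, so training does not escape it); such runs recover nothing and
  simply report empty results. On the reference study this affects roughly
  one seed in six.
* Recovery precision is limited by smoothly structured confounders: a
  channel whose image is smooth enough and whose net learned weight is
  positive can exceed the 0.95 cutoff without being annotation-coupled.
  Shot-noise-dominated channels are reliably rejected.
* The impurity-importance cutoffs (1/4, 1/3) are scale-free only because
  per-run scores are normalized to sum 1; raw sklearn importances would
  make the fractions data-dependent.
* `adjusted_r2` requires n_obs > n_features + 1 and is reported as the mean
  over cross-validation folds; folds with constant held-out targets are
  skipped.
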