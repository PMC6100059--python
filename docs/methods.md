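# Methods

This note documents the models and procedures implemented in `seedhsi`, the
defaults and why they were chosen, what the synthetic scenes do and do not
emulate, and the numerical decisions a user reproducing or extending the
pipeline should know about.

## Problem setting

A line-scan NIR hyperspectral camera images trays of single seeds; each
pixel carries a reflectance spectrum over a few hundred contiguous bands.
Varieties of the same species differ subtly in composition (oil, water,
phenolics), which shifts the depths of shared absorption features — for
grape seeds the relevant features sit near 1100, 1200 and 1300 nm (C–H
overtones) and 1450 nm (O–H first overtone). Two of the three varieties
modelled here are compositionally similar and overlap spectrally; the third
is clearly distinct. The task is to assign every seed to a variety and to
render the assignment as an image.

## Reflectance calibration

Raw counts are converted to relative reflectance per pixel and band,
R = (I_raw − I_dark)/(I_white − I_dark), using a dark-current frame and a
near-100 % white standard. References may be full frames or per-line
references broadcast along the scan axis, as line-scan systems commonly
store them. Decisions:

- A reference pair is rejected when white ≤ dark on more than 1 % of
  elements; below that, pixels with white − dark < 10⁻⁶ are set to 0 and
  counted (division guard).
- Corrected values are clipped to [−0.05, 1.5]. Sensor noise at the range
  edges can push reflectance slightly out of [0, 1]; the band crop removes
  most of it, the clip bounds what remains. This policy is a package
  decision, not a measured property of any instrument.
- Correcting an already corrected cube is refused (cubes carry a
  raw/corrected kind tag that the pipeline stages check).
- The default working range 975–1646 nm keeps 200 of the sensor's 256 bands at
  3.36 nm spacing; the first and last ~30 bands are treated as noise.

## Segmentation

The mask band is chosen by maximising, over bands, the absolute difference
between the mean of a provisional foreground and background, split at the
per-band median (the split quantile is configurable; 0.5 is robust when
seeds cover less than half the image). Otsu's threshold on that band gives
the mask; it is parameter-free and exactly computable on two-level
histograms, which makes it testable. Connected components
(8-connectivity default) smaller than 10 px are discarded; surviving ROIs
are labelled 1..K in raster order. Seeds are laid out without touching, so
no watershed splitting is attempted. ROIs touching the image border are
kept but flagged. Ties in the contrast criterion go to the lower band
index; a flat cube or a constant grey image is an error, not a guess.

## Wavelet smoothing

Pixel spectra are smoothed by a level-3 Daubechies-7 wavelet decomposition
with symmetric boundary extension. Two reconstruction rules are available:

- `universal-soft` (default): detail coefficients at all three levels are
  soft-thresholded at σ√(2 ln n), with σ estimated per spectrum from the
  finest-level details (MAD/0.6745).
- `approximation-only`: details are discarded entirely.

Whether the original workflow thresholded details or kept only the
approximation is not knowable from its description; both are provided and
the default is the standard practice. A level-3 transform needs at least
104 samples with db7; shorter spectra are rejected with the required
length. With symmetric (non-periodic) extension the approximation-only rule
is only approximately a projection: repeating it moves the result by ~10⁻³
near the spectrum ends and ~10⁻⁴ in the interior, which is the tolerance
the idempotence test asserts.

Object spectra are arithmetic means of the smoothed foreground pixel
spectra per ROI, accumulated in float64 via label-wise bincount so the
result is independent of pixel iteration order.

## PCA and effective wavelengths

PCA is fitted on pooled foreground pixel spectra of the calibration scenes
(full SVD, deterministic), with a seeded uniform subsample cap (default
50 000 pixels) to bound memory. Each loading column's sign is fixed so its
largest-magnitude entry is positive, making score images and extremum kinds
reproducible. Requesting more components than the data's centered rank is
an error at the fitting level; the pipeline clips the requested count to
the achievable rank (noiseless scenes have rank 2: three class spectra
minus the mean), so degenerate inputs still run.

Score images place each foreground pixel's centered projection at its
location with the background exactly zero (mask multiplication).

Effective wavelengths are local maxima and minima of the loading curves
with prominence at least 10 % of that curve's maximum absolute loading;
curve endpoints never qualify. Candidates pooled over the first six
components are deduplicated: within any 10 nm neighbourhood one candidate
survives. The survivor is the candidate with the largest
**eigenvalue-scaled** loading |l|·√(explained variance fraction), i.e. the
band's contribution to overall spectral variance, with ties to the lower
wavelength. The scaling matters: components are unit-norm regardless of
importance, so a minor component's loading curve can have *larger*
pointwise magnitudes than the dominant ones, and under isotropic pixel
noise the trailing components are pure noise directions whose spurious
extrema would otherwise displace genuine absorption-feature extrema at
dedup time. Raw-|loading| ranking remains available
(`dedup_rank="loading"`). The 10 nm window is chosen so that genuinely
close informative pairs (~17 nm apart) are not merged.

## Discriminant model

The classifier is an RBF-kernel SVM, K(x, x′) = exp(−g‖x−x′‖²), on object
spectra restricted to the EW bands. No feature scaling is applied by
default (reflectance values are already commensurate). Multiclass handling
is one-vs-one voting. The grid search covers integer exponents c, g ∈
2⁻⁸…2⁸ (17 × 17); the selection score is stratified 5-fold cross-validated
accuracy on the calibration objects, seeded, with ties broken toward
smaller c then smaller g. An optional refinement pass searches
quarter-octave steps around the best coarse cell, since optimal kernel
widths rarely sit exactly on the power-of-two lattice. The winner is
refitted on all calibration objects. Models serialise to a self-contained
JSON (format `seedhsi-svm-v1`) holding (c, g), the grid record and the
training data; loading refits, which is exact because libsvm training is
deterministic.

Splitting is done at the image level — all seeds of a scene share a fold —
with a 2:1 calibration:prediction ratio and one image per stratum withheld
for external validation. Evaluation reports a 3×3 confusion matrix (rows =
true class), per-class accuracies (row-normalised diagonal) and overall
accuracy (trace/total), printed to one decimal percent. A class absent from
an evaluation set has undefined (NaN) per-class accuracy rather than being
an error, so two-class subproblems evaluate cleanly.

## Synthetic scenes

The generator emulates the statistical structure the chain relies on, not
the radiometry of a real instrument:

- **Endmembers**: a gently tilted baseline (≈0.48–0.56 reflectance) minus
  Gaussian dips (σ = 18 nm) at shared centres 1100/1200/1300/1450 nm.
  Classes 1 and 2 differ only in dip depths by `class_overlap` × a fixed
  offset (≈0.02–0.03 reflectance at default overlap 1.0); class 3 has
  clearly different depths plus a −0.08 baseline shift, so it separates on
  the first component, as the two-similar-one-distinct variety structure
  requires.
- **Layout**: non-touching ellipses (semi-axes 3.5–7 px) placed by
  rejection sampling with a 2 px minimum gap and a bounded retry budget;
  an infeasible layout is an error naming the constraint.
- **Radiometry**: dark level 40 counts, white level 4040 counts with an
  optional linear illumination gradient along the scan axis carried by the
  white frame (it cancels under calibration, which the tests exploit);
  pixel spectra are endmember + isotropic Gaussian noise (default
  σ = 0.02 reflectance, a typical NIR pixel noise level), scaled into
  counts; reference frames get small count-level noise of their own.
  Background sits at 0.03 reflectance, just above dark.
- Scenes default to 96 × 128 px, 200 bands, 4 seeds per class; a 256-band
  preset (874.3–1731.1 nm) exercises band cropping, keeping exactly its
  middle 200 bands under the default crop.

Not modelled, deliberately: within-seed spatial heterogeneity, per-seed
biological variation around the class endmember, wavelength-correlated
noise, stray light and specular effects. Consequently the synthetic
end-to-end accuracies sit at or near 100 %, well above what real seed
populations yield — between-seed biological variance, not sensor noise, is
what limits real-world accuracy. Passing the end-to-end tests therefore
shows the chain is wired correctly and recovers planted structure; it says
nothing about accuracy on real images.

## Problem sizes

The end-to-end experiments use 10 scenes (120 seeds) split 6:3:1, PCA on
~12 000 pooled foreground pixel spectra, and the full 17 × 17 SVM grid at
5 folds; the wavelength-recovery experiment uses 20 replicate scenes.
These sizes give stable statistics (recovery fractions and accuracies are
reproducible across seeds) while a complete run stays in the tens of
seconds on one core.

## Known limitations

- The ENVI dialect is minimal (BSQ written, BIL read, float32/float64,
  wavelengths in the header); vendor raw formats and BIP are out of scope.
- Otsu assumes a bimodal grey histogram; scenes whose seeds cover most of
  the field of view would need a different provisional-foreground quantile.
- The EW count on synthetic scenes (~25–30) exceeds what an analyst would
  shortlist on smooth real loading curves, because trailing noise
  components contribute isolated spurious extrema that survive dedup; they
  are harmless to the classifier here but a real campaign would cap the
  component count by inspecting the variance spectrum.
- Accuracies are reported to one decimal percent by round-half-even, which
  matches conventional reporting but can differ in the last digit from
  round-half-up for exact .05 fractions.
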