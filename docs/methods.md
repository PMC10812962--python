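# Methods

This note records the models, conventions and design choices behind
`qmapsynth`, in the spirit of a methods appendix: what is computed, under
which assumptions, and which decisions were genuinely open.

## 1. Problem setting

T1rho mapping of knee cartilage is sensitive to proteoglycan loss and
therefore to early osteoarthritis, but the acquisition is long and not part
of routine protocols; T2 mapping is far more widely available.  The package
implements and stress-tests an image-synthesis shortcut: learn a mapping
from T2 map slices to T1rho map slices with a 2D U-Net, then quantify how
trustworthy the synthetic maps are for compartment-level cartilage
analysis, including under acquisition shift (different coil/scanner).
Because suitable multi-institution MRI cohorts cannot be redistributed, the
package ships a phantom generator that reproduces the statistical structure
the task needs at desk scale; every experiment in the test-suite and the
acceptance script runs on such phantoms.

## 2. Phantom generator

One synthetic "subject" is a stylized sagittal knee volume, by default
8 slices of 64 x 64 voxels:

* a circular bone "femur", surrounded by an annular cartilage shell split
  into six equal angular sectors standing in for the six compartments of
  compartmental knee analysis (MF, LF, MT, LT, PAT, TRO);
* muscle filling an elliptical body outline, background (air) outside;
* the disc radius tapers toward the end slices so volumes are genuinely 3D.

The geometry is deliberately schematic.  What the downstream method needs
from segmentations is contiguous, disjoint, non-empty labelled regions with
realistic relaxation statistics — not anatomical shape.  Consequences are
spelled out in section 8.

Relaxation fields are generated T2-first.  Every compartment draws a
subject-level baseline `N(mean, spread)`; a smooth spatial modulation field
(Gaussian-filtered white noise, 6-voxel in-plane correlation length, 4% of
the tissue mean) and per-voxel jitter (SD 0.5 ms) are added.  T1rho then
follows deterministically within each tissue class:

    T1rho(v) = t1rho_mean + offset_c + (t1rho_spread / t2_spread) * (T2(v) - t2_mean)

so subject-to-subject variation propagates from T2 into T1rho with a fixed,
population-level affine law, and a network trained on some subjects can in
principle predict held-out subjects exactly.  The slope equals the spread
ratio so that the realized T1rho across subjects has exactly the configured
mean and spread.  `offset_c` is a systematic per-compartment shift
(defaults +3.0/-1.5/-3.0/+1.5/-2.5/+2.5 ms for MF/LF/MT/LT/PAT/TRO,
zero-sum so the cartilage-wide mean is preserved) making the law
compartment-dependent: compartment-level systematic differences of a few
ms are the rule in compartmental relaxometry, and without them a single
global rescaling of T2 would already be a near-perfect predictor and the
synthesis task would be trivial.  A network can resolve the offsets from
spatial context; a scalar rescaling cannot, which is what the
identity-baseline comparison in the tests verifies.  Default tissue values (cartilage T1rho 43 +/- 3 ms,
T2 33 +/- 2.5 ms; shorter times for muscle and bone; S0 about 100 a.u. in
cartilage) sit in the range reported for healthy-to-early-OA knee cartilage
at 3 T, with T1rho > T2 and a wider T1rho spread.

Focal OA-like lesions break the affine coupling: a Poisson number of
lesions per subject (rate 1.5) places Gaussian blobs (in-plane sigma
3 voxels) confined to one compartment, elevating T1rho by 25% of the
cartilage mean at the blob centre and T2 by half that fraction.  The 2:1
ratio encodes the premise that T1rho carries information beyond T2 — a
purely global rescaling of T2 cannot reproduce lesion contrast, which is
what makes the synthesis task non-trivial and is verified by the
identity-baseline comparison in the tests.  The ratio is configurable
(`lesion_t2_ratio`).

Echo series follow the mono-exponential decay S(t) = S0 exp(-t/T) at the
four-point preparation schedules (TSL 0/10/40/80 ms for T1rho,
TE 0/12.9/25.7/51.4 ms for T2) that are shared across the acquisition
protocols this package targets.  Noise is additive Gaussian with SD equal
to `noise_sigma` (default 1%) of the mean cartilage S0.  Additive Gaussian
was chosen over Rician as the default because quantitative maps, not
magnitude k-space images, are the working currency here, and it keeps the
fitting oracle unbiased at the SNRs used; a Rician option exists
(`rician_noise`).  Echoes are registered by construction — echo-to-echo
registration is a preprocessing concern outside this package's scope.

All randomness derives from `(spec.seed, subject_id)` through stable
hashing, so any subject can be regenerated independently, bit-identically.

### Domain-shift operator

A coil/scanner change is emulated by three knobs applied to an echo series:
one smooth, strictly positive multiplicative bias field shared by all
echoes (coil sensitivity is static across preparations; default amplitude
10%, correlation length 12 voxels), an SNR rescaling (noise SD multiplied
by `snr_scale`; 2.0 means SNR halved), and an optional additive shift of
the underlying relaxation time implemented by re-exponentiating the decay
(systematic map-value differences between coils/scanners of a few ms are
documented in the reproducibility literature; default 0).  Because the bias
field multiplies all echoes equally it cancels exactly in the decay ratio:
it corrupts S0, not T — the degradation of fitted maps under shift comes
from the SNR change and, if enabled, the offset.

## 3. Relaxometry

Maps are fitted voxelwise with the two-parameter model S(t) = S0 exp(-t/T)
by damped least squares (Levenberg-Marquardt with an analytic Jacobian),
vectorized across all voxels with a per-voxel damping factor.
Initialization is the closed-form log-linear regression of log(max(S, eps))
on t; the floor affects only initialization, the iterations see raw
intensities.  Convergence uses a relative cost tolerance of 1e-8 (plus an
absolute floor so noiseless voxels terminate at machine precision), at most
200 iterations.  Fit bounds default to (1, 300) ms — wide enough for every
physiological knee value, tight enough to stabilize flat-decay voxels; the
bound is distinct from the (0, 150) ms display/evaluation clip window.
Out-of-bound optima are clamped and flagged non-converged, never silently
filled; all-zero voxels are flagged with T at the lower bound.  Fits are
per-voxel and independent; no spatial regularization.

Optionally, voxels whose fitted S0 falls below a fraction (pipeline
default 5%) of the volume's 99th-percentile S0 are treated as signal-free
background and set to T = 0.  Air voxels contain pure noise and their
"relaxation times" are meaningless draws from the whole fit range; without
suppression they dominate whole-volume error metrics and the background
half of the training loss.

Correctness is established against two independent routes: an exhaustive
profiled grid search (T on a 0.01 ms grid, S0 profiled in closed form) and
scipy's LM on individual voxels.

## 4. Synthesis network and training protocol

The network is a 2D U-Net: `depth` encoder levels of 3x3 conv + batch norm
+ ReLU with 2x2 max pooling and channel doubling, a bottleneck block,
a mirrored decoder using nearest-neighbour upsampling and skip
concatenation, and a linear 1x1 output convolution.  With depth 3 this
gives the canonical 8-convolution configuration (3 + 1 + 3 blocks + output);
"8 convolutional layers" does not pin down widths, so channel widths are
configuration with documented defaults (base 16), not facts.  A "tiny"
preset (depth 3, base 8, ~61k parameters) exists for desk-scale
experiments and is what the tests and acceptance script train; depth 3 is
kept because the receptive field must span the phantom's femur for a
cartilage voxel's compartment to be inferable from context.  Network
arithmetic runs in float32 by default (configurable), which is standard
for CNN training and roughly halves CPU time.

The implementation is plain numpy with hand-derived backpropagation and an
Adam optimizer, verified against central finite differences in the test
suite.  This keeps the package free of deep-learning framework
dependencies and is entirely adequate at the problem sizes targeted here.

Inputs and targets are clipped to [0, 150] ms (suppressing residual
background values) and divided by `intensity_scale` (default 150, mapping
to [0, 1]).  The training objective weights cartilage above the rest of
the slice:

    loss = 1.5 * MSE(pred[cartilage], truth[cartilage])
         + MAE(pred[background], truth[background])

with "background" the complement of the cartilage mask over the whole
slice.  Two conventions had to be fixed here because weighting schemes of
this form leave them open: (i) both reductions are per-region means (not
sums), so the 1.5 weight is scale-comparable across mask sizes; (ii) the
loss is applied on the normalized intensity scale.  Slices without
cartilage contribute the MAE term only (the MSE term is defined as 0) and
are counted in the log.

The protocol is subject-wise throughout: a 65:15:20 train/validation/test
split computed by largest-remainder rounding over a seeded shuffle of
subject ids (no subject's slices ever cross subsets — asserted on every
run), early stopping when validation loss has not improved for 25 epochs
with the best-validation checkpoint returned, optional 4-fold
cross-validation over the train+validation pool, and an exhaustive grid
hyperparameter search selected by validation cartilage NMSE.  Adam is the
optimizer (learning rate 2e-3, batch 8 slices, at most 130 epochs by
default), with the learning rate halved whenever validation loss plateaus
for 6 epochs, floored at 3e-4.  The patience and floor are deliberately
generous: the validation loss is dominated by the irreducible noise of the
background L1 term, so the cartilage component improves by amounts that
are small and non-monotone against that floor, and a tight patience or a
deep learning-rate decay truncates exactly the compartment-level
refinement that the agreement statistics measure.  Batch normalization
uses running statistics at inference, so prediction is deterministic.

One consequence worth noting: the training-loop sanity check (fitting the
identity map on identical input/target pairs to far below the initial
loss) is run without batch normalization, whose running-statistics lag
bounds the achievable validation precision well above what the check
demands; this is a property of BN, not of the optimizer or gradients.

## 5. Evaluation metrics

* NMSE (percent): `100 * sum((pred-truth)^2) / sum(truth^2)` over a region.
  The normalization of "NMSE" varies across the synthesis literature (sum
  ratio vs. its square root); this package fixes the sum-of-squares ratio
  and provides the RMS variant behind a flag for sensitivity analyses.
* PSNR: `10 log10(range^2 / MSE)` with the data range fixed at the 150 ms
  clip ceiling — a per-image maximum would make values incomparable across
  subjects.  Zero-MSE voxelsets yield a logged +inf sentinel excluded from
  aggregation.
* SSIM: standard Gaussian-weighted structural similarity (sigma 1.5,
  K1 0.01, K2 0.03, data range 150) computed per whole slice (no masking)
  and averaged over the volume; SSIM is reported for the volume only,
  since windowed structure is ill-defined on scattered masked voxels.
* CORR: Pearson correlation of voxel values over the region; compartment
  agreement uses Pearson r of per-(subject x compartment) means with
  dof = n - 2 and a two-tailed p-value.
* Bland-Altman: differences pred - truth of paired unit means; bias is the
  mean difference, limits of agreement bias +/- 1.96 * sample SD (the
  conventional normal-quantile multiplier).
* Quantification error: mean over subject x compartment units of
  `100 * |mean_pred - mean_truth| / mean_truth`, judged against the 6.42%
  threshold for a clinically significant change in cartilage T1rho.  The
  unit of aggregation (subject x compartment, not voxel) is a documented
  interpretation; per-volume (not slice-averaged) NMSE is likewise the
  fixed convention, with the alternative one flag away.

Per-subject metrics are aggregated as mean +/- SD within each stratum
(e.g. in-distribution vs. shifted acquisition), and the per-subject table
is persisted so any aggregate can be recomputed.

## 6. Pipeline and reproducibility

`run_pipeline` chains simulate -> fit -> split -> train -> predict ->
evaluate.  Each stage writes its outputs plus a completion marker into its
own subdirectory of the run directory; deleting one stage's directory
re-runs exactly that stage, with later stages reading persisted files.
The exact configuration (YAML, losslessly round-tripping) and its hash are
stored in the run directory and the log.  Volumes travel as NIfTI-1
(identity orientation, voxel spacing on the affine diagonal, float32 maps,
int16 labels, 4D echo stacks with a JSON sidecar for preparation times).
The out-of-distribution stratum applies the domain-shift operator to the
held-out subjects' echo series, refits their maps, and evaluates
predictions against the shifted refits — the same maps a consumer of the
shifted acquisition would possess.  The relaxation-time offset is applied
to the T1rho acquisition only: coil/scanner changes affect the spin-lock
and T2 preparations disproportionately, and an offset common to both maps
would largely cancel (the network tracks its input).  The stress condition
used by the tests and the acceptance script is a 10% bias field, SNR
halved, and a 3 ms T1rho offset — the magnitude reported between knee
coils in multi-site reproducibility work.  Under it, synthetic maps stay
visually faithful while cartilage NMSE rises, the Bland-Altman bias grows
and the quantification error crosses the clinical-significance threshold:
the stale-synthesis failure mode the stratified evaluation exists to
expose.  Without the offset, a bias field plus noise alone leaves the
compartment-mean bias direction to sampling variability, because the
multiplicative field cancels in the decay ratio.

Problem sizes were chosen so the full pipeline (30 subjects of 8 x 64 x 64
voxels, tiny preset) completes in minutes on one CPU core; these sizes are
the package's desk-scale defaults, and everything scales up by
configuration only.

## 7. Numerical choices

* Fit: LM damping multiplied by 0.3 / 4.0 on accept/reject, lambda capped
  at 1e12 (then flagged), 2x2 normal equations solved in closed form.
* Degenerate inputs: all-zero voxels, empty compartments, zero-variance
  correlation inputs and all-zero-truth NMSE regions are flagged, logged
  or rejected explicitly — never silently imputed.
* Ties in max pooling route gradient to all tied positions (measure-zero
  for continuous inputs).
* Seeds: one root seed; per-stage and per-subject substreams via stable
  hashing, all below 2^31.

## 8. What the phantoms do and do not show

The generator reproduces: subject-wise variability of compartment
statistics, a deterministic-but-compartment-dependent T2 -> T1rho law,
focal lesions with T1rho-excess contrast, mono-exponential decay at the
correct preparation times, additive noise, and multiplicative coil fields
with SNR changes.  It does not reproduce: anatomical shape, partial-volume
and chemical-shift effects, registration error between echoes, Rician
statistics at very low SNR (unless enabled), B0/B1 inhomogeneity
interacting with the preparation pulses, or inter-site population
differences.  Passing the phantom-based checks therefore demonstrates that
the implementation of the method is correct and that the pipeline can
recover a learnable cross-relaxation mapping under noise and acquisition
shift; it does not certify clinical-grade accuracy on real knees, which
requires the corresponding MRI cohorts.
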