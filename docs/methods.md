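# Methods

`needletrack` implements and evaluates a post-processing framework for
transmission-mode ultrasonic needle tracking: a needle carries a
fibre-optic photoacoustic ultrasound transmitter; a clinical linear
probe receives each transmission on all elements simultaneously; the
received channel data are reconstructed into a tracking image whose
bright spot marks the needle tip; and a residual convolutional network,
trained purely on synthetic data, sharpens that spot. This note records
the model assumptions, parameter choices and numerical decisions.

## Acoustic forward model

The medium is homogeneous and lossless with a uniform sound speed
*c* = 1500 m/s. The probe is a linear array of 128 rectangular planar
elements distributed equidistantly across a 38.4 mm aperture
(pitch 0.3 mm; element width defaults to 0.9 × pitch), sampled at
40 MHz. Propagation is one-way (transmitter → probe), so all
time-of-flight arithmetic uses *c*, not *c*/2.

Each element's A-line is the transmit pulse delayed by the one-way time
of flight `r/c` and scaled by spherical spreading `1/r`, summed over
≥ 8 laterally distributed sub-apertures per element. The sub-element
summation captures the near-field response of the finite rectangular
element at the depths of interest without a full diffraction
simulation; the far-field sinc directivity approximation is not used.

**Transmit pulse.** The transmitter's waveform is modelled as a
Gaussian-modulated sinusoid. Photoacoustic fibre-tip transmitters are
near-monopolar (fractional bandwidth ≈ 2), and the tracking images
measured in vivo with such a system show raw resolutions of roughly
1.3 mm axially and 2.1 mm laterally at 24–38 mm depth. The default
pulse — centre frequency 0.6 MHz, −6 dB fractional bandwidth 1.7 — is
calibrated so the simulated raw point-spread function reproduces that
scale: the envelope's axial FWHM is ≈ 1.3 mm and the lateral FWHM of
the reconstructed PSF runs from ≈ 1.7 mm at 24 mm depth to ≈ 2.6 mm at
38 mm. This matters because the enhancement task is only well posed
when the raw PSF is broader than the Gaussian training target in both
axes (see below); a multi-MHz pulse would make the simulated raw PSF
*finer* than the target and turn the network into a blurring operator.

**Noise.** Zero-mean i.i.d. Gaussian noise is added to the channel
data with standard deviation `peak|samples| / SNR`, so SNR is defined
throughout as peak signal amplitude over noise standard deviation (the
same convention `measure_snr` uses). Per-image SNRs are drawn
log-uniformly from [10.5, 56.1]; the log-uniform choice spreads images
evenly across low- and high-quality regimes while reproducing the
stated range.

## Image reconstruction

The reference reconstruction is one-way frequency-wavenumber (Stolt)
migration: 2-D FFT of the channel data over (t, x); remap of temporal
frequency ω to axial wavenumber via the one-way dispersion relation
`kz = sqrt((ω/c)² − kx²)` with linear interpolation and the
amplitude-preserving Jacobian `c·kz/sqrt(kz²+kx²)`; evanescent
components (`|kx| > ω/c`) zeroed; inverse FFT onto a depth grid with
natural spacing `c/fs`, then bilinear resampling onto the requested
pixel grid. Time zero is the transmitter firing instant (available as
a hardware trigger in the real system). Arrays are zero-padded to
twice the data extent (next power of two) in both axes to suppress
wrap-around.

A brute-force delay-and-sum (DAS) reconstruction — for each pixel, sum
the element samples at the geometric one-way delay with linear
temporal interpolation, no apodization and no obliquity weighting —
serves as the independent oracle. On noise-free point sources the two
agree to within one pixel in peak position and correlate above 0.9
within a 5×5 mm box. Their box-MIP lateral FWHMs differ by ≈ 12%:
the unapodized DAS point response carries backprojection-arc arms that
the maximum-intensity projection picks up, while the migrated PSF
matches the 1.21·λz/D diffraction estimate. Axial FWHMs agree to ~2%.

**Envelope detection and normalization.** The analytic-signal
magnitude is taken along the axial (temporal) direction only, per
image column, then the image is divided by its global maximum, giving
values in [0, 1] with unit peak. Normalization is idempotent by
construction (an already-normalized image is returned unchanged) and
invariant to input scaling.

## Synthetic training corpus

Each pair couples a reconstructed, envelope-normalized image of one
noisy point-source transmission with a ground-truth image: a unit
delta at the pixel containing the source, convolved with a separable
anisotropic Gaussian of σ = [σz, σx] pixels, rescaled to unit peak.
Scaling the target to peak 1 (rather than unit integral) keeps targets
in the same [0, 1] solution space as the inputs. Sub-pixel source
positions are rounded to the nearest pixel centre before convolution.

On the native grid (dz = c/fs = 37.5 µm, dx = pitch = 0.3 mm) the
kernels elongated in axial *pixels* — [1,1], [4,2], [8,4] — compensate
the 8:1 axial/lateral sampling anisotropy; the default σ = [4,2]
corresponds to target FWHMs of 0.353 mm axially and 1.413 mm
laterally. Source positions are drawn uniformly over the configured
region; the full-scale corpus is 1000 pairs with sources at lateral
±15 mm, depth 10–42 mm, plus a 100-pair validation set generated
identically with an independent seed (the validation size is the
package's choice).

## Residual network and training

The network is a fully convolutional modified residual net: a lifting
3×3 convolution (1 → C channels), N residual blocks of
[conv 3×3 → ReLU → conv 3×3] with an additive skip around each block,
a projection 3×3 convolution (C → 1), an additive skip from the
network input, and a clamp of the output to [0, 1]. At the full scale
(N = 16, C = 64) this has 1,182,913 trainable parameters. No batch
normalization is used. The input→output skip plus clamp means the
network learns a residual correction and its predictions stay in the
normalized-image solution space.

Training minimises the L1 loss with Adam (initial step 10⁻³, no
schedule) on 64×64 patches cropped at uniformly random offsets, in
batches of 16, with `ceil(n_pairs/batch)` steps per epoch (random
patching has no natural epoch boundary). The full-image validation
loss is evaluated every epoch and the best-validation weights are
returned. The engine is pure numpy (im2col-free flat-offset GEMM
convolutions with hand-written backprop), so training is
bit-reproducible for a given seed.

**Clamp gradient.** The [0, 1] clamp is applied with a
straight-through gradient during backprop. With a hard gradient mask
the background L1 term drives pre-activations below zero everywhere,
after which every pixel — including the tip — is silenced and training
collapses to the all-zero image; the straight-through estimator keeps
the (rare, high-value) tip pixels trainable. Weight initialization is
fan-in-scaled Gaussian, seeded.

## Evaluation metrics

Resolution follows the bounding-box / maximum-intensity-projection
procedure: a 5×5 mm box is centred on the global maximum (clipped at
image edges with a warning), collapsed to axial and lateral profiles
by maxima along the orthogonal axis, and each profile's FWHM measured
between the half-maximum crossings nearest the peak. Crossings are
located sub-pixel by band-limited (polyphase 16×) upsampling followed
by linear interpolation on the fine profile: plain linear crossings on
raw samples over-estimate σ ≈ 1 px Gaussian widths by ≈ 4% (the
profile is convex at the crossing) and peak positions between pixels
bias σ = 2 px widths by ≈ 2%; the refinement keeps the estimator
within 2% over σ ∈ {1,…,8} px (verified < 0.8% in tests). If a
profile never falls below half maximum inside the box, the box extent
is reported and the result flagged.

Localization error is the Euclidean distance from the peak pixel
centre to the true source. Object counting binarizes at −6 dB below
peak (amplitude convention, i.e. 0.5) and counts 8-connected
components; ties in the global maximum break toward the smallest
depth, then the smallest lateral index.

## Desk-scale study profile

The full study conditions (1000 pairs, 16 blocks × 64 channels,
80 epochs) are impractical for routine single-CPU runs, so the test
suite and the results script use a reduced profile whose outputs the
package treats as its reference desk-scale experiment:

* grid restricted axially to the insertion depth band, 22–41.2 mm
  (512 × 128 pixels at the native spacings, so kernel pixel sizes keep
  their physical meaning);
* 200 training / 8 validation pairs with sources at lateral ±12 mm,
  depth 24–38 mm (the depth band of the needle insertions); held-out
  evaluation sources at 26–38 mm so the 5 mm measurement box fits
  inside the grid;
* a 4-block, 16-channel network trained for 20 epochs (depth and width
  reduced together; the architecture is otherwise identical).

At this scale the σ = [4,2] network reduces the mean axial FWHM of 20
held-out noisy sources from ≈ 1.6 mm to ≈ 0.75–0.85 mm and the mean
lateral FWHM from ≈ 2.4 mm to ≈ 1.6–2.0 mm (seed-dependent), with
mean localization error well under 1 mm — the same direction and
order of improvement as the full-scale system, though the axial
sharpening is less complete than with the full network and corpus. The σ = [1,1] kernel never stabilizes a
single clean tip at this scale: its target carries an order of
magnitude less intensity mass than σ = [4,2], so the all-zero
attractor of the L1 background term is much stronger, and along the
training trajectory the network alternates between fragmenting the
tip into several objects and suppressing it entirely. Both modes are
counted as degraded renderings when kernels are compared.

## What the synthetic data do and do not show

The generator emulates single point-source transmissions in a
homogeneous lossless medium with exactly one object per image. It does
not model tissue texture or reverberation clutter, acoustic
attenuation or sound-speed heterogeneity, elevation (3-D) effects,
element impulse-response/bandwidth colouring, or multi-source scenes.
Passing tests therefore demonstrate that the pipeline's geometry,
reconstruction, training and measurement machinery are correct and
that enhancement sharpens the PSF under the stated conditions; they do
not by themselves establish in vivo performance.

## Degenerate inputs and edge cases

All-zero channel data cannot be assigned an SNR and all-zero images
cannot be normalized (both raise). A trained network that outputs an
identically zero image raises at enhancement rather than fabricating a
peak. Reconstruction refuses grids coarser than the element pitch
(lateral Nyquist) and simulation refuses record lengths that would
truncate the farthest arrival. Enhanced images are rescaled to unit
peak so every image entering the evaluation stage satisfies the same
normalization contract.
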