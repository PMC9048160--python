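# Methods

This note documents the models, parameter choices and numerical decisions
behind `panev`, and what the synthetic study does and does not show.

## System geometry and coordinates

All images and maps are `[row, col] = [depth z, lateral x]`, 0-based, with
z = 0 at the transducer face and x = 0 at the aperture centre; element *i*
of the linear array sits at `(i + 0.5 − n/2) · pitch`. The default probe is
a 128-element, 0.315 mm-pitch array (aperture 40.32 mm), centre frequency
7 MHz, −6 dB fractional bandwidth 0.809, sampling 1024 samples per channel
at 40 MHz. The speed of sound defaults to 1540 m/s (a standard soft-tissue
value, consistent with the 39.4 mm axial field of view implied by
1024 samples at 40 MHz one-way); it is configurable everywhere. The optical
simulation grid is 40 × 40 mm at 0.1 mm.

## Monte Carlo fluence (2D)

Photon packets are launched uniformly over a 38.4 mm illumination stripe at
the surface, travelling straight down. Transport is confined to the imaging
plane: the images and source maps are 2D, and the quantity that matters here
is the relative fluence pattern along the needle shaft rather than
radiometric absolutes. Specular reflection from the refractive-index
mismatch (n = 1.4 vs 1.0) is applied once at launch. Scattering free paths
are sampled from μs, with direction changes drawn from the analytic inverse
CDF of the 2D Henyey–Greenstein phase function (g = 0.9 by default);
absorption is deposited continuously along each free path in half-cell
sub-steps, scored at the sub-step midpoint (depositing at end-points aliases
against the 0.1 mm cells and distorts the depth profile by up to 2×).
Fluence is the absorption estimator: deposited weight / (μₐ · cell area),
per launched photon. Packets below weight 1e−4 play Russian roulette
(survival 0.1); packets leaving the grid are terminated with their weight
logged as escaped. An energy ledger records deposited, escaped and the net
roulette weight so the audit `launched = deposited + escaped + roulette_net`
holds to floating-point accuracy; because roulette is unbiased,
deposited + escaped alone matches the launched weight to ~1e−6 relative at
1e5 packets.

With μs = 0 the simulation collapses to Beer–Lambert attenuation, which the
tests use as a closed-form oracle (≤ 2 % relative error over the first 5 mm
at 1e5 packets). Across seeds, band-averaged fluence scatters as ~1/√n.

**Absorption scale.** The three tissue absorption levels spanned by the
training sweep default to 0.10, 0.15 and 0.20 mm⁻¹ (1–2 cm⁻¹), typical of
soft tissue at 850 nm. With the reduced scattering of 1 mm⁻¹ this gives an
effective attenuation of ~0.6–0.9 mm⁻¹, so the shaft is appreciably lit down
to roughly a centimetre — matching the depth range over which LED-excited
needles are realistically visible. Substantially larger absorption values
confine the fluence (and hence the ground-truth needle) to the top ~2 mm of
the image, which is exactly the zone removed by the 150-sample early-time
zeroing; training pairs would then carry no usable correspondence. `μₐ` is a
free parameter of `OpticalMedium` for users who want other regimes.

## Needle model

The needle is an in-plane line from its surface entry point to the tip,
rasterised at half-cell resolution and dilated by one cell (shaft
half-thickness). Poses are parameterised by insertion angle (degrees above
the horizontal surface) and tip depth, with the tip's lateral position
anchored (default +5 mm): anchoring the tip rather than the entry point
keeps every sweep node's shaft inside the field of view (a 40 mm aperture
cannot contain both the entry point and a 25 mm-deep tip at 20°). The
needle-only initial pressure is the fluence sampled on the shaft mask,
max-normalised to 1.

The dataset builder additionally requires each pose's in-grid shaft to rise
above 4 mm depth (a pure geometry test): a shaft confined to larger depths
receives no appreciable fluence at any supported absorption level and would
produce an all-zero source. Infeasible jittered poses are deterministically
re-drawn, then the tip pulled shallower in 1 mm steps as a last resort.

## Acoustic forward model

Each non-zero source cell contributes an impulse at the one-way time of
flight r/c with spherical 1/r decay — a point-source superposition in place
of a full-wave solver. The 1/r (3D) response was chosen over the 2D
line-source response because the pipeline's acceptance surface is
round-trip localisation and relative image structure, not absolute
amplitude, and amplitudes are renormalised during semi-synthesis anyway.
Impulses are laid on a 120 MHz internal grid (3× the output rate) with
linear-interpolation splitting between neighbouring samples to avoid delay
quantisation stripes. The transducer is a zero-phase Gaussian band-pass
centred at 7 MHz whose amplitude is 0.5 at f₀ ± (frac_bw · f₀/2) =
7 ± 2.832 MHz; DC leakage is below −30 dB. Decimation to 40 MHz uses a
polyphase anti-aliasing FIR (in-band tones preserved within 1 %). Element
directivity and finite element width are not modelled.

## Synthetic tissue background

The background generator is an explicit stand-in for measured in vivo
finger data, which the pipeline also accepts as HDF5 stacks
(`[frame, time, channel]`). Its structure mimics what such acquisitions
show: a handful of elliptical vessel cross-sections at 3.5–30 mm depth, one
optional two-layered artery rendered as concentric rings (wall and lumen
boundary), and a thin bright skin line (default 1.5 mm). Per-frame noise is
iid Gaussian with std 0.05 × the clean-signal maximum — strong enough that a
single frame is visibly noisy, the regime in which 128-frame averaging
matters. The first 150 samples additionally carry a laterally-coherent
decaying oscillation with ~10× the white-noise RMS, mimicking LED-driver
noise; it is confined to the span the 150-sample zeroing removes. Averaging
over 128 frames (the default acquisition length) suppresses the white noise
by √128 ≈ 11.3.

What this generator does *not* emulate: physiological vessel trees, flow or
motion between frames, acoustic attenuation and heterogeneity, speckle from
unresolved absorbers, or probe-specific artefact signatures. Passing tests
therefore demonstrate that the pipeline's machinery works end to end and
that the enhancement direction holds under controlled conditions — not that
a model trained on these backgrounds transfers to clinical data.

## Semi-synthesis and dataset assembly

Needle RF is scaled so its peak equals κ × the background frame's peak
(default κ = 1; a measured needle reference amplitude can replace this), the
two frames are summed, and the first 150 of 1024 samples are zeroed. The
default dataset holds 2000 pairs: the 150 sweep nodes (5 depths × 10
angles × 3 absorptions) cycled with uniform jitter (±2 mm depth, ±2° angle)
and paired with one of 13 synthetic backgrounds, split 8:1:1 into
train/validation/test by a seeded permutation. Inputs are the reconstructed
combined frames (interpolated to 578 × 565 at 70 µm, cropped to 512 × 512,
resized bicubically to 128 × 128, max-normalised); targets are the
needle-only pressure maps projected onto the same image grid and scaled to
[0, 1]. The crop removes deep rows (bottom) and 33 columns per side,
preserving the transducer-adjacent region where needles appear; a flag
reverses the depth choice.

## Reconstruction

Fourier-domain (Stolt-style) mapping: 2D FFT of the (zero-padded ×2)
time–lateral data, resampling of the temporal-frequency axis at
ω = c·√(k_z² + k_x²) with linear interpolation, weighting by the Jacobian
|k_z|/√(k_z² + k_x²) (evanescent components are never sampled by
construction), inverse FFT, and by default the depth-axis envelope so images
are non-negative like displayed PA images. The output depth axis uses the
one-way sampling dz = c/fs; the round-trip with the forward model localises
point sources to well under 0.2 mm over 5–25 mm depth.

## Network and training

The U-Net defaults to 4 scales with (16, 32, 64, 128) encoder filters,
batch normalisation after every convolution, 2 × 2 max pooling, transposed-
convolution upsampling, channel concatenation at equal scales, and a 1 × 1
convolution + sigmoid head whose bias is initialised at −3 — the logit of
the sparse targets' foreground fraction, so early iterations are not spent
driving the output towards "mostly empty". Training minimises MSE with Adam
(initial learning rate 0.001) under cosine annealing to zero over 5000
iterations with batch 4, checkpointing at the best validation MSE. The
implementation is pure NumPy with hand-derived backpropagation (convolutions
evaluated as nine shifted BLAS contractions), float32 throughout, fully
seeded; identical seeds reproduce identical loss curves on the same
hardware.

**Desk scale.** The test suite's end-to-end experiment uses 200 pairs, 500
iterations, a 3-scale / 16-filter network and learning rate 0.01: Adam moves
each parameter by at most ~lr per step, so a 10× shorter schedule needs a
~10× larger rate to cover the same parameter distance. Under these
conditions the enhanced arm typically exceeds the conventional arm's median
SNR by two orders of magnitude and reduces the median MHD from ~90 px to
~3 px on the synthetic test split.

## Post-processing, baseline and metrics

U-Net outputs are binarised at 0.1 × max (the threshold is a configurable
invention; none is canonical), connected components are labelled with
8-connectivity, and the component with the largest boundary-pixel count
(pixels with a 4-neighbour outside) is kept — appropriate under the
single-needle, in-plane assumption. The trajectory is the mask's maximally
separated pixel pair (convex hull + pairwise scan, validated against a
brute-force O(n²) oracle), with the deeper endpoint reported as the tip.

The standard Hough transform baseline keeps the accumulator convention
r = x sin θ + y cos θ (x = column, y = row, θ ∈ [0°, 180°) at 1 px / 1°
bins) and greedy local-maxima extraction with Chebyshev-distance peak
suppression; input images are pre-binarised at 0.2 × max. These
hyperparameters are deliberately surfaced — the detector's sensitivity to
them is part of what the comparison illustrates.

SNR samples the Bresenham rasterisation of the reference segment for S and
takes σ over the largest axis-aligned rectangle (histogram-stack dynamic
programming) that avoids the needle dilated by 20 px (margin keeps
sidelobes out of σ; rectangles must be at least 32 × 32). A constant
background raises an explicit undefined-SNR signal. MHD follows the
symmetric-max of directed mean nearest-neighbour distances; KD-trees give
exact equality with the double-loop definition. Sequence evaluation counts
a true positive when a detection's MHD to the labelled segment is ≤ 10 px
(0.7 mm at 70 µm — no canonical criterion exists, so this is configurable),
and reports the false-positive rate over needle-free frames by default
(an `all`-frames denominator is available).

In the two-arm evaluation, an arm that detects nothing on a needle-present
image scores the image diagonal as its MHD; a perfectly flat background
yields an infinite SNR. Reference segments derive from the ground-truth maps
(threshold 0.3 after upsizing to the 256 × 256 evaluation resolution).

## Known limitations

* 2D optics and ray-like acoustics: no full-wave diffraction, attenuation or
  heterogeneity; quantitative fluence and amplitude values are not
  calibrated, only patterns and ratios.
* The background model's realism is limited (see above); κ, noise levels and
  vessel statistics should be matched to a real system before drawing
  system-level conclusions.
* Single straight needle per frame; curved needles, out-of-plane insertions
  and multi-needle scenes are out of scope.
* The desk-scale training demonstrates direction-of-effect on synthetic
  data, not clinical performance.
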