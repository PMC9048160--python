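# panev — needle visibility enhancement for LED-based photoacoustic imaging

Clinical metallic needles are hard to see in LED-excited photoacoustic (PA)
imaging: the low optical fluence of LED arrays yields weak needle signals
buried under tissue background, noise, and reconstruction artefacts, while
blood vessels present confusable line-like structures. `panev` implements a
complete, self-contained pipeline for training and evaluating a compact U-Net
that isolates the needle in reconstructed PA images, using **semi-synthetic
training data**: simulated needle sensor signals summed with (synthetic or
user-supplied) tissue-background RF before reconstruction.

The package is aimed at researchers in photoacoustic instrumentation and
image enhancement who want a reproducible, desk-scale testbed for the whole
chain:

1. **Optical simulation** — 2D Monte Carlo photon transport
   (Henyey–Greenstein scattering, weighted packets, Russian roulette) gives
   the fluence on the needle shaft; the needle-only initial pressure map
   p₀ ∝ μₐ·Φ is the network's ground truth.
2. **Acoustic simulation** — point-source projection to a 128-element linear
   array (0.315 mm pitch, 40.32 mm aperture) with a 7 MHz / 80.9 %
   fractional-bandwidth Gaussian transducer response, internally sampled at
   120 MHz and decimated to 40 MHz (1024 × 128 RF frames).
3. **Background synthesis** — vessel-like absorbers (including a two-layered
   artery), a skin line, per-frame white noise and strong early-time
   (LED-induced) noise; 128-frame averaging suppresses the noise by √128.
4. **Semi-synthesis** — needle RF is max-normalised against the background
   frame (ratio κ), summed, and the first 150 time samples are zeroed.
5. **Reconstruction** — Fourier-domain (k-space / Stolt) beamforming, depth
   envelope, interpolation to 578 × 565 px at 70 µm, crop to 512 × 512, and
   bicubic resize to the 128 × 128 network input.
6. **Enhancement** — a compact U-Net (two 3 × 3 convolutions + 2 × 2 max
   pooling per scale, transposed-convolution upsampling, skip connections,
   sigmoid output) trained with MSE, Adam and cosine-annealed learning rate.
7. **Evaluation** — maximum-contour post-processing and needle line fitting,
   a standard Hough transform baseline (r = x sin θ + y cos θ), and two
   metrics:
   * **SNR** = S/σ, the mean amplitude along the labelled needle segment
     over the standard deviation of the largest needle-free background
     rectangle;
   * **MHD**, the modified Hausdorff distance
     `max( mean_a min_b ‖a−b‖, mean_b min_a ‖a−b‖ )` between extracted and
     reference needle point sets (pixels; 70 µm/px);
   plus per-sequence true/false-positive detection rates.

## Worked example

The one-command demo runs the entire chain at small scale (64 semi-synthetic
pairs, 300 training iterations, a 3-scale / 16-filter network) and evaluates
the held-out test split:

```bash
panev demo --seed 5 --out demo_run/
```

which logs (numbers from this exact command):

```
demo medians: {"conventional": {"snr": 0.64, "mhd": 185.25},
               "enhanced":     {"snr": 568.36, "mhd": 2.43}}
```

Read this as: on test images the conventional reconstruction shows the
needle at roughly background level (median SNR 0.64) and thresholding it
latches onto vessels and artefacts (median MHD 185 px from the reference
needle segment), whereas the U-Net output suppresses the background almost
completely (median SNR ≈ 570) and the post-processed needle trajectory lies
within ~2.4 px (~0.17 mm) of the reference. `demo_run/metrics_report.json`
holds the per-image values; every stage also writes a `run_record.json` with
the command, seed and output digests.

Individual stages are available as subcommands (`panev simulate-fluence`,
`forward`, `make-background`, `build-dataset`, `reconstruct`, `train`,
`enhance`, `extract`, `baseline-sht`, `evaluate` — see `panev --help`).

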