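"""Fourier-domain (k-space) reconstruction and the resize/crop chain.

The reconstruction maps the 2D spectrum of the time x lateral sensor data onto
spatial wavenumbers (Stolt-style spectral remapping): for each lateral
wavenumber k_x the temporal-frequency axis omega is resampled at
``omega = c * sqrt(k_z^2 + k_x^2)`` and weighted by the mapping Jacobian
``k_z / sqrt(k_z^2 + k_x^2)``; evanescent components (|omega/c| < |k_x|) are
discarded by construction.  The output depth axis uses the one-way sampling
``dz = c / fs`` so the native image spans ``n_samples * c / fs`` axially and
the array aperture laterally.  By default the depth-axis envelope (magnitude
of the analytic signal) is taken so images are non-negative, matching
displayed photoacoustic images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from skimage.transform import resize

from .core import ConfigError, Grid2D, ProbeGeometry, ReconImage, RFFrame


@dataclass(frozen=True)
class ReconConfig:
    """Image-chain geometry: interpolated size, crop, and model input size."""

    pixel_size_um: float = 70.0
    interp_depth: int = 565
    interp_lateral: int = 578
    crop: int = 512
    model_size: int = 128
    eval_size: int = 256
    envelope: bool = True
    crop_from: str = "bottom"  # which depth rows the crop removes

    def __post_init__(self) -> None:
        if min(self.interp_depth, self.interp_lateral, self.crop,
               self.model_size, self.eval_size) <= 0 or self.pixel_size_um <= 0:
            raise ConfigError("all sizes must be positive")
        if self.crop > self.interp_depth or self.crop > self.interp_lateral:
            raise ConfigError("crop size must not exceed the interpolated size")
        if self.crop_from not in ("bottom", "top"):
            raise ConfigError("crop_from must be 'bottom' or 'top'")


def reconstruct(rf: RFFrame, probe: ProbeGeometry | None = None,
                sound_speed: float | None = None,
                envelope: bool = True) -> ReconImage:
    """Reconstruct an RF frame into a native-grid image.

    The native grid is ``(n_samples, n_elements)`` with pixel pitch
    ``(c / fs, element pitch)``.  Time is zero-padded x2 before the FFT to
    reduce wrap-around; the lateral axis likewise.
    """
    probe = probe or rf.probe
    c = sound_speed if sound_speed is not None else probe.sound_speed
    if c <= 0:
        raise ConfigError("sound speed must be positive")
    data = rf.samples
    if not np.all(np.isfinite(data)):
        raise ConfigError("RF must be finite")
    nt, nx = data.shape

    nt2, nx2 = 2 * nt, 2 * nx
    padded = np.zeros((nt2, nx2))
    padded[:nt, :nx] = data

    dt_s = 1e-6 / rf.fs_mhz
    pitch_m = probe.pitch_mm * 1e-3
    dz_m = c * dt_s  # one-way depth sampling

    spec = np.fft.fft2(padded)
    omega = 2 * np.pi * np.fft.fftfreq(nt2, d=dt_s)          # rad/s
    kx = 2 * np.pi * np.fft.fftfreq(nx2, d=pitch_m)          # rad/m
    kz = 2 * np.pi * np.fft.fftfreq(nt2, d=dz_m)             # output axis

    # sort the omega axis once for interpolation
    order = np.argsort(omega)
    omega_sorted = omega[order]
    spec_sorted = spec[order, :]

    # target temporal frequency for every (kz, kx); sign follows kz
    kmag = np.sqrt(kz[:, None] ** 2 + kx[None, :] ** 2)
    omega_map = np.sign(kz)[:, None] * c * kmag
    with np.errstate(invalid="ignore", divide="ignore"):
        jacobian = np.where(kmag > 0, np.abs(kz)[:, None] / kmag, 1.0)

    remapped = np.empty_like(spec)
    for j in range(nx2):
        col = spec_sorted[:, j]
        re = np.interp(omega_map[:, j], omega_sorted, col.real,
                       left=0.0, right=0.0)
        im = np.interp(omega_map[:, j], omega_sorted, col.imag,
                       left=0.0, right=0.0)
        remapped[:, j] = (re + 1j * im) * jacobian[:, j]

    img = np.real(np.fft.ifft2(remapped))[:nt, :nx]
    if envelope:
        img = np.abs(hilbert(img, axis=0))
    # native pixels are anisotropic (dz x pitch); record the depth pitch
    return ReconImage(pixels=img, pixel_size_um=probe.dz_mm * 1e3,
                      kind="conventional")


def native_pixel_mm(probe: ProbeGeometry) -> tuple:
    """(depth, lateral) pixel pitch of the native reconstruction grid, mm."""
    return probe.dz_mm, probe.pitch_mm


def resample_and_crop(img: ReconImage, probe: ProbeGeometry,
                      rcfg: ReconConfig | None = None) -> ReconImage:
    """Bilinear resample to the uniform-pixel interpolated size, then crop.

    At defaults: 578 (lateral) x 565 (depth) pixels of 70 um, then remove 53
    depth rows and 33 columns from each lateral side, giving 512 x 512.  The
    depth rows are removed from the bottom so the transducer-adjacent region
    where needles appear survives (``crop_from`` reverses this).
    """
    rcfg = rcfg or ReconConfig()
    interp = resize(img.pixels, (rcfg.interp_depth, rcfg.interp_lateral),
                    order=1, anti_aliasing=False, preserve_range=True)
    n_rows = rcfg.interp_depth - rcfg.crop
    n_cols = rcfg.interp_lateral - rcfg.crop
    left = n_cols // 2
    right = n_cols - left
    if rcfg.crop_from == "bottom":
        cropped = interp[:rcfg.crop, left:rcfg.interp_lateral - right]
    else:
        cropped = interp[n_rows:, left:rcfg.interp_lateral - right]
    return ReconImage(pixels=cropped, pixel_size_um=rcfg.pixel_size_um,
                      kind=img.kind)


def _resize_square(img: ReconImage, size: int) -> ReconImage:
    if img.pixels.shape[0] != img.pixels.shape[1]:
        raise ConfigError("resize expects a square image")
    lo, hi = float(img.pixels.min()), float(img.pixels.max())
    out = resize(img.pixels, (size, size), order=3, anti_aliasing=False,
                 preserve_range=True)
    out = np.clip(out, lo, hi)
    scale = img.pixels.shape[0] / size
    return ReconImage(pixels=out, pixel_size_um=img.pixel_size_um * scale,
                      kind=img.kind)


def resize_for_model(img: ReconImage, size: int = 128) -> ReconImage:
    """Bicubic downsize to the network input resolution."""
    return _resize_square(img, size)


def upsize_from_model(img: ReconImage, size: int = 256) -> ReconImage:
    """Bicubic upsize to the evaluation resolution."""
    return _resize_square(img, size)


# ----------------------------------------------------------------------
# mapping a simulation-grid map into the image chain (ground-truth targets)
# ----------------------------------------------------------------------

def project_map_to_image(values: np.ndarray, grid: Grid2D,
                         probe: ProbeGeometry,
                         rcfg: ReconConfig | None = None) -> ReconImage:
    """Sample a simulation-grid map onto the interpolated image grid and crop.

    Used to rasterise needle-only initial pressure maps as ground truths on
    the same 70 um frame as the reconstructed images.  The result is
    max-normalised to [0, 1] and tagged ``ground-truth``.
    """
    from scipy.ndimage import map_coordinates

    rcfg = rcfg or ReconConfig()
    depth_extent = probe.depth_extent_mm
    lateral_extent = probe.aperture_mm
    rows = (np.arange(rcfg.interp_depth) + 0.5) / rcfg.interp_depth * depth_extent
    cols = ((np.arange(rcfg.interp_lateral) + 0.5) / rcfg.interp_lateral
            * lateral_extent - lateral_extent / 2)
    # simulation-grid fractional indices of those physical coordinates
    zi = rows / grid.dx_mm - 0.5
    xi = (cols + grid.extent_x_mm / 2) / grid.dx_mm - 0.5
    zz, xx = np.meshgrid(zi, xi, indexing="ij")
    sampled = map_coordinates(np.asarray(values, float), [zz, xx], order=1,
                              mode="constant", cval=0.0)
    peak = sampled.max()
    if peak > 0:
        sampled = sampled / peak
    img = ReconImage(pixels=sampled, pixel_size_um=rcfg.pixel_size_um,
                     kind="ground-truth")
    return resample_and_crop_identity(img, rcfg)


def resample_and_crop_identity(img: ReconImage, rcfg: ReconConfig) -> ReconImage:
    """Crop an already-interpolated-size image with the standard crop rule."""
    if img.pixels.shape != (rcfg.interp_depth, rcfg.interp_lateral):
        raise ConfigError("image is not at the interpolated size")
    n_cols = rcfg.interp_lateral - rcfg.crop
    left = n_cols // 2
    right = n_cols - left
    if rcfg.crop_from == "bottom":
        cropped = img.pixels[:rcfg.crop, left:rcfg.interp_lateral - right]
    else:
        cropped = img.pixels[rcfg.interp_depth - rcfg.crop:,
                             left:rcfg.interp_lateral - right]
    return ReconImage(pixels=cropped, pixel_size_um=rcfg.pixel_size_um,
                      kind=img.kind)
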