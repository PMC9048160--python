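"""Acoustic forward model: initial pressure map -> sensor RF for a linear array.

Each non-zero source cell contributes an impulse to every element at the
one-way time of flight r / c with spherical 1/r amplitude decay.  The impulse
train is produced on a fine internal time grid, shaped by the transducer's
Gaussian band-pass response, and decimated to the probe's output rate.
Delays are spread over the two neighbouring internal samples by linear
interpolation to avoid quantisation stripes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import ConfigError, Grid2D, ProbeGeometry, RFFrame


@dataclass(frozen=True)
class AcousticConfig:
    """Sampling-rate plan for the forward simulation."""

    internal_fs_mhz: float = 120.0
    output_fs_mhz: float = 40.0
    decay: str = "spherical"  # 1/r point response

    def __post_init__(self) -> None:
        if self.internal_fs_mhz <= 0 or self.output_fs_mhz <= 0:
            raise ConfigError("sampling rates must be positive")
        factor = self.internal_fs_mhz / self.output_fs_mhz
        if abs(factor - round(factor)) > 1e-9:
            raise ConfigError("internal rate must be an integer multiple of the output rate")
        if self.decay != "spherical":
            raise ConfigError("only spherical (1/r) decay is supported")

    @property
    def factor(self) -> int:
        return int(round(self.internal_fs_mhz / self.output_fs_mhz))


def forward_project(p0: np.ndarray, grid: Grid2D, probe: ProbeGeometry,
                    acfg: AcousticConfig | None = None) -> RFFrame:
    """Project an initial pressure map to wideband RF at the internal rate.

    Linear in ``p0``; a zero map gives a zero frame.  Raises if any source
    cell coincides with an element position.
    """
    acfg = acfg or AcousticConfig(output_fs_mhz=probe.fs_mhz)
    p0 = np.asarray(p0, dtype=np.float64)
    if p0.shape != (grid.nz, grid.nx):
        raise ConfigError(f"p0 shape {p0.shape} does not match grid")
    if not np.all(np.isfinite(p0)):
        raise ConfigError("p0 must be finite")

    nt = probe.n_samples * acfg.factor
    nch = probe.n_elements
    rf = np.zeros(nt * nch)

    iz, ix = np.nonzero(p0)
    if iz.size:
        amp0 = p0[iz, ix]
        src_x = grid.x_mm[ix]
        src_z = grid.z_mm[iz]
        elem_x = probe.element_x_mm
        # (n_src, n_elem) geometry, vectorised
        dx = src_x[:, None] - elem_x[None, :]
        r_mm = np.hypot(dx, src_z[:, None])
        if np.any(r_mm <= 0):
            raise ConfigError("source cell coincides with an element position")
        t_us = r_mm * 1e-3 / probe.sound_speed * 1e6
        s = t_us * acfg.internal_fs_mhz          # fractional sample index
        amp = amp0[:, None] / r_mm
        i0 = np.floor(s).astype(np.int64)
        frac = s - i0
        ch = np.broadcast_to(np.arange(nch), i0.shape)
        for idx, wgt in ((i0, amp * (1 - frac)), (i0 + 1, amp * frac)):
            ok = (idx >= 0) & (idx < nt)
            np.add.at(rf, idx[ok] * nch + ch[ok], wgt[ok])

    return RFFrame(samples=rf.reshape(nt, nch), fs_mhz=acfg.internal_fs_mhz,
                   probe=probe)


def transducer_sigma_mhz(probe: ProbeGeometry) -> float:
    """Gaussian std (MHz) giving amplitude 0.5 at f0 +/- frac_bw * f0 / 2."""
    half_width = probe.frac_bw_6db * probe.center_freq_mhz / 2
    return half_width / np.sqrt(2 * np.log(2))


def apply_transducer_response(rf: RFFrame, probe: ProbeGeometry) -> RFFrame:
    """Zero-phase Gaussian band-pass in the frequency domain.

    The amplitude response is ``exp(-(f - f0)^2 / (2 sigma^2))`` with sigma set
    so the response is 0.5 at the -6 dB band edges ``f0 +/- frac_bw * f0 / 2``.
    """
    sigma = transducer_sigma_mhz(probe)
    f_edge = probe.center_freq_mhz + 3 * sigma
    if rf.fs_mhz / 2 < f_edge:
        raise ConfigError("frame rate undersamples the transducer passband")
    nt = rf.n_samples
    freqs = np.fft.rfftfreq(nt, d=1.0 / rf.fs_mhz)
    gain = np.exp(-((freqs - probe.center_freq_mhz) ** 2) / (2 * sigma ** 2))
    spectrum = np.fft.rfft(rf.samples, axis=0) * gain[:, None]
    out = np.fft.irfft(spectrum, n=nt, axis=0)
    return RFFrame(samples=out, fs_mhz=rf.fs_mhz, probe=rf.probe)


def downsample_rf(rf: RFFrame, factor: int) -> RFFrame:
    """Anti-aliased integer decimation along time (polyphase FIR, zero phase)."""
    if factor < 1 or rf.n_samples % factor:
        raise ConfigError(f"decimation factor {factor} must divide {rf.n_samples}")
    if factor == 1:
        return rf
    out = signal.resample_poly(rf.samples, up=1, down=factor, axis=0)
    return RFFrame(samples=out, fs_mhz=rf.fs_mhz / factor, probe=rf.probe)


def simulate_sensor_rf(p0: np.ndarray, grid: Grid2D, probe: ProbeGeometry,
                       acfg: AcousticConfig | None = None) -> RFFrame:
    """Full chain: project, band-limit with the transducer, decimate to 40 MHz."""
    acfg = acfg or AcousticConfig(output_fs_mhz=probe.fs_mhz)
    wide = forward_project(p0, grid, probe, acfg)
    shaped = apply_transducer_response(wide, probe)
    return downsample_rf(shaped, acfg.factor)
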