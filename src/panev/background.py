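"""Synthetic tissue-background RF frames.

The generator emulates the structure of in vivo finger acquisitions used as
the tissue background: a handful of vessel-like absorbers (optionally one
two-layered artery rendered as two concentric rings), a thin high-amplitude
skin-surface line, per-frame white noise, and strong laterally-coherent
early-time noise confined to the first ~150 samples (as produced by the LED
driver).  Frame averaging suppresses the random noise by sqrt(n).

The model is a stand-in for unavailable measured data: every knob lives in
``BackgroundSpec`` so users with real RF stacks can either match their system
or load their own frames (HDF5 stack layout ``[frame, time, channel]``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .core import ConfigError, Grid2D, ProbeGeometry, RFFrame
from .forward import AcousticConfig, simulate_sensor_rf


@dataclass(frozen=True)
class BackgroundSpec:
    """Parameters of the synthetic tissue background."""

    n_vessels: int = 5
    vessel_radius_mm: tuple = (0.3, 1.2)
    artery: bool = True                 # render one vessel as two concentric rings
    artery_wall_ratio: float = 2.0      # wall/lumen amplitude ratio
    skin_depth_mm: float = 1.5
    skin_amp: float = 1.0
    noise_std: float = 0.05             # fraction of the signal max, per frame
    early_noise_span: int = 150         # samples hit by the LED-induced noise
    early_noise_gain: float = 10.0      # early-noise RMS in units of noise_std
    n_frames: int = 128

    def __post_init__(self) -> None:
        if self.n_vessels < 0:
            raise ConfigError("n_vessels must be >= 0")
        if self.noise_std < 0:
            raise ConfigError("noise_std must be >= 0")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if self.early_noise_span < 0:
            raise ConfigError("early_noise_span must be >= 0")


def generate_background_p0(spec: BackgroundSpec, grid: Grid2D,
                           seed: int = 0) -> np.ndarray:
    """Draw a random vessel/skin initial-pressure map.  Deterministic per seed."""
    rng = np.random.default_rng(seed)
    p0 = np.zeros((grid.nz, grid.nx))
    zz, xx = np.meshgrid(grid.z_mm, grid.x_mm, indexing="ij")

    placed = []  # (x, z, r)
    margin = 2.0
    x_lo = -grid.extent_x_mm / 2 + margin
    x_hi = grid.extent_x_mm / 2 - margin
    for k in range(spec.n_vessels):
        r = rng.uniform(*spec.vessel_radius_mm)
        for _ in range(60):
            cx = rng.uniform(x_lo + r, x_hi - r)
            cz = rng.uniform(spec.skin_depth_mm + 2 + r,
                             min(grid.extent_z_mm - margin - r, 30.0))
            if all(np.hypot(cx - px, cz - pz) > r + pr + 0.5
                   for px, pz, pr in placed):
                break
        else:
            raise ConfigError("vessel placement failed after bounded retries")
        placed.append((cx, cz, r))
        amp = rng.uniform(0.3, 1.0)
        axis_ratio = rng.uniform(0.6, 1.0)
        d = np.hypot((xx - cx) / axis_ratio, zz - cz)
        if spec.artery and k == 0:
            # two-layered artery: concentric circular rings (vessel walls)
            d_circ = np.hypot(xx - cx, zz - cz)
            ring = 0.15
            wall = np.abs(d_circ - r) < ring
            lumen = np.abs(d_circ - 0.5 * r) < ring
            p0[wall] = np.maximum(p0[wall], amp * spec.artery_wall_ratio
                                  / max(spec.artery_wall_ratio, 1.0))
            p0[lumen] = np.maximum(p0[lumen],
                                   amp / max(spec.artery_wall_ratio, 1.0))
        else:
            p0[d < r] = np.maximum(p0[d < r], amp)

    if spec.skin_amp > 0:
        half_beam = grid.extent_x_mm / 2 - margin
        line = (np.abs(zz - spec.skin_depth_mm) < 0.1) & (np.abs(xx) < half_beam)
        p0[line] = np.maximum(p0[line], spec.skin_amp)
    return p0


def _frame_noise(rng: np.random.Generator, base: np.ndarray,
                 spec: BackgroundSpec, fs_mhz: float) -> np.ndarray:
    """One frame's random + structured early-time noise realisation."""
    scale = float(np.abs(base).max())
    noise = np.zeros_like(base)
    if spec.noise_std > 0 and scale > 0:
        noise += rng.normal(0.0, spec.noise_std * scale, base.shape)
        n_early = min(spec.early_noise_span, base.shape[0])
        if n_early:
            # laterally-coherent decaying oscillation, random phase per frame
            t = np.arange(n_early) / fs_mhz                        # us
            f = rng.uniform(1.0, 3.0)                              # MHz
            phase = rng.uniform(0, 2 * np.pi)
            env = np.exp(-t / (n_early / fs_mhz / 3))
            osc = env * np.sin(2 * np.pi * f * t + phase)
            rms = np.sqrt(np.mean(osc ** 2))
            amp = spec.early_noise_gain * spec.noise_std * scale / max(rms, 1e-12)
            lateral = 1.0 + 0.2 * rng.standard_normal(base.shape[1])
            noise[:n_early] += amp * osc[:, None] * lateral[None, :]
    return noise


def make_background_rf(p0: np.ndarray, grid: Grid2D, probe: ProbeGeometry,
                       acfg: AcousticConfig, spec: BackgroundSpec,
                       seed: int = 0) -> np.ndarray:
    """Simulate an ordered acquisition stack ``[frame, time, channel]``.

    Every frame shares the clean forward-projected signal and gets its own
    noise realisation.  Deterministic per seed.
    """
    base = simulate_sensor_rf(p0, grid, probe, acfg).samples
    rng = np.random.default_rng(seed)
    stack = np.empty((spec.n_frames,) + base.shape)
    for i in range(spec.n_frames):
        stack[i] = base + _frame_noise(rng, base, spec, probe.fs_mhz)
    return stack


def averaged_background_rf(p0: np.ndarray, grid: Grid2D, probe: ProbeGeometry,
                           acfg: AcousticConfig, spec: BackgroundSpec,
                           seed: int = 0) -> RFFrame:
    """Streaming mean over ``spec.n_frames`` noisy frames (memory-light)."""
    base = simulate_sensor_rf(p0, grid, probe, acfg).samples
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(base)
    for _ in range(spec.n_frames):
        acc += base + _frame_noise(rng, base, spec, probe.fs_mhz)
    return RFFrame(samples=acc / spec.n_frames, fs_mhz=probe.fs_mhz, probe=probe)


def average_frames(stack) -> RFFrame:
    """Element-wise arithmetic mean of an ordered stack of equal-shape frames."""
    if isinstance(stack, np.ndarray):
        raise TypeError("average_frames takes RFFrame objects; use average_stack "
                        "for raw [frame, time, channel] arrays")
    frames = list(stack)
    if not frames:
        raise ConfigError("cannot average an empty stack")
    shape = frames[0].samples.shape
    for f in frames:
        if f.samples.shape != shape:
            raise ConfigError("all frames in a stack must share one shape")
    mean = np.mean([f.samples for f in frames], axis=0)
    return RFFrame(samples=mean, fs_mhz=frames[0].fs_mhz, probe=frames[0].probe)


def average_stack(stack: np.ndarray, probe: ProbeGeometry,
                  fs_mhz: float) -> RFFrame:
    """Mean of a raw ``[frame, time, channel]`` array as an RFFrame."""
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ConfigError("stack must be a non-empty [frame, time, channel] array")
    return RFFrame(samples=stack.mean(axis=0), fs_mhz=fs_mhz, probe=probe)


def write_stack(path, stack: np.ndarray, probe: ProbeGeometry,
                fs_mhz: float) -> None:
    import json

    with h5py.File(path, "w") as f:
        f.create_dataset("stack", data=stack)
        f.attrs["fs_mhz"] = fs_mhz
        f.attrs["probe"] = json.dumps(probe.to_dict(), sort_keys=True)


def read_stack(path) -> tuple:
    """Load a user-supplied or synthetic RF stack: (array, probe, fs_mhz)."""
    import json

    with h5py.File(path, "r") as f:
        stack = f["stack"][()]
        fs_mhz = float(f.attrs["fs_mhz"])
        probe = ProbeGeometry(**json.loads(f.attrs["probe"]))
    return stack, probe, fs_mhz
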