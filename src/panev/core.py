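"""Shared domain types, coordinate conventions, configuration, and file I/O.

Coordinate conventions used throughout the package
--------------------------------------------------
* Images and maps are 2D arrays indexed ``[row, col]`` = ``[depth z, lateral x]``,
  0-based, row-major.
* Depth ``z`` = 0 at the transducer face and increases with row index.
* Lateral ``x`` = 0 at the centre of the array aperture.  The centre of element
  ``i`` (0-based) sits at ``(i + 0.5 - n_elements / 2) * pitch`` millimetres.
* Angles are in degrees, measured from the horizontal tissue surface.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import yaml


class FormatError(ValueError):
    """A file's payload disagrees with its declared metadata or the probe."""


class ConfigError(ValueError):
    """An invalid or unknown configuration key; the message names the key."""


# --------------------------------------------------------------------------
# probe / grid
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeGeometry:
    """Linear-array probe with its acquisition settings.

    Defaults describe a 128-element, 0.315 mm pitch array (40.32 mm aperture)
    with a 7 MHz centre frequency, 80.9% -6 dB fractional bandwidth, sampling
    1024 samples per channel at 40 MHz.
    """

    n_elements: int = 128
    pitch_mm: float = 0.315
    center_freq_mhz: float = 7.0
    frac_bw_6db: float = 0.809
    fs_mhz: float = 40.0
    n_samples: int = 1024
    sound_speed: float = 1540.0  # m/s; soft-tissue default, configurable

    def __post_init__(self) -> None:
        if self.n_elements < 2:
            raise ConfigError("n_elements must be >= 2")
        if self.pitch_mm <= 0:
            raise ConfigError("pitch_mm must be positive")
        if not 0 < self.frac_bw_6db < 2:
            raise ConfigError("frac_bw_6db must lie in (0, 2)")
        if self.fs_mhz <= 2 * self.center_freq_mhz:
            raise ConfigError("fs_mhz must exceed twice center_freq_mhz")
        if self.n_samples < 1:
            raise ConfigError("n_samples must be positive")
        if self.sound_speed <= 0:
            raise ConfigError("sound_speed must be positive")

    @property
    def aperture_mm(self) -> float:
        return self.n_elements * self.pitch_mm

    @property
    def element_x_mm(self) -> np.ndarray:
        """Lateral centre coordinate of every element, in mm."""
        i = np.arange(self.n_elements)
        return (i + 0.5 - self.n_elements / 2) * self.pitch_mm

    @property
    def dz_mm(self) -> float:
        """One-way depth sampling interval c / fs, in mm."""
        return self.sound_speed / (self.fs_mhz * 1e6) * 1e3

    @property
    def depth_extent_mm(self) -> float:
        """Axial field of view n_samples * c / fs (39.4 mm at defaults)."""
        return self.n_samples * self.dz_mm

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class Grid2D:
    """Simulation grid, laterally centred on the aperture, z = 0 at the face."""

    nx: int = 400
    nz: int = 400
    dx_mm: float = 0.1

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.nz <= 0:
            raise ConfigError("nx and nz must be positive")
        if self.dx_mm <= 0:
            raise ConfigError("dx_mm must be positive")

    @property
    def extent_x_mm(self) -> float:
        return self.nx * self.dx_mm

    @property
    def extent_z_mm(self) -> float:
        return self.nz * self.dx_mm

    @property
    def x_mm(self) -> np.ndarray:
        """Lateral cell-centre coordinates (mm), centred on x = 0."""
        return (np.arange(self.nx) + 0.5) * self.dx_mm - self.extent_x_mm / 2

    @property
    def z_mm(self) -> np.ndarray:
        """Depth cell-centre coordinates (mm)."""
        return (np.arange(self.nz) + 0.5) * self.dx_mm

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------

@dataclass
class RFFrame:
    """One frame of time x channel sensor data.

    ``samples[t, ch]`` in arbitrary pressure units.  The channel count must
    match the probe; a frame sampled at the probe's native rate must also
    carry the probe's sample count.
    """

    samples: np.ndarray
    fs_mhz: float
    probe: ProbeGeometry

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise FormatError("RF samples must be a 2D [time, channel] array")
        if self.samples.shape[1] != self.probe.n_elements:
            raise FormatError(
                f"RF frame has {self.samples.shape[1]} channels, probe declares "
                f"{self.probe.n_elements}"
            )
        if self.fs_mhz == self.probe.fs_mhz and self.samples.shape[0] != self.probe.n_samples:
            raise FormatError(
                f"RF frame at the probe rate has {self.samples.shape[0]} samples, "
                f"probe declares {self.probe.n_samples}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("RF samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


VALID_IMAGE_KINDS = ("conventional", "enhanced", "ground-truth")


@dataclass
class ReconImage:
    """A beamformed (or enhanced / ground-truth) image with pixel-size metadata."""

    pixels: np.ndarray
    pixel_size_um: float
    kind: str = "conventional"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise FormatError("image must be 2D [depth, lateral]")
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("image values must be finite")
        if self.kind not in VALID_IMAGE_KINDS:
            raise FormatError(f"unknown image kind {self.kind!r}")
        if self.kind == "ground-truth":
            if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 1):
                raise FormatError("ground-truth images must be normalised to [0, 1]")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass(frozen=True)
class LineSegment:
    """A needle label/trajectory: two (row, col) endpoints, sub-pixel allowed."""

    p0: tuple
    p1: tuple

    def __post_init__(self) -> None:
        if tuple(self.p0) == tuple(self.p1):
            raise ValueError("segment endpoints must be distinct")

    @property
    def length_px(self) -> float:
        return float(np.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]))

    def as_array(self) -> np.ndarray:
        return np.array([self.p0, self.p1], dtype=float)

    def to_json(self) -> dict:
        return {"endpoints": [list(map(float, self.p0)), list(map(float, self.p1))]}


@dataclass
class ManifestEntry:
    input_path: str
    target_path: str
    needle_pose: dict      # angle_deg, tip_depth_mm, tip_x_mm
    background_id: int
    medium_id: int         # index into the absorption-coefficient list
    split: str             # train | val | test


@dataclass
class DatasetManifest:
    entries: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def split_counts(self) -> dict:
        counts = {"train": 0, "val": 0, "test": 0}
        for e in self.entries:
            counts[e.split] += 1
        return counts

    def subset(self, split: str) -> list:
        return [e for e in self.entries if e.split == split]

    def save(self, path) -> None:
        payload = {
            "meta": self.meta,
            "entries": [dataclasses.asdict(e) for e in self.entries],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        payload = json.loads(Path(path).read_text())
        return cls(entries=[ManifestEntry(**e) for e in payload["entries"]],
                   meta=payload.get("meta", {}))


# --------------------------------------------------------------------------
# HDF5 readers / writers (bit-exact round-trips)
# --------------------------------------------------------------------------

def write_rf(path, frame: RFFrame) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=frame.samples)
        f.attrs["fs_mhz"] = frame.fs_mhz
        f.attrs["probe"] = json.dumps(frame.probe.to_dict(), sort_keys=True)


def read_rf(path, probe: ProbeGeometry | None = None) -> RFFrame:
    """Read an RF frame; if ``probe`` is given it must match the stored metadata."""
    with h5py.File(path, "r") as f:
        samples = f["samples"][()]
        fs_mhz = float(f.attrs["fs_mhz"])
        stored = ProbeGeometry(**json.loads(f.attrs["probe"]))
    if probe is not None and probe != stored:
        raise FormatError("stored probe metadata disagrees with the declared probe")
    return RFFrame(samples=samples, fs_mhz=fs_mhz, probe=stored)


def write_map(path, values: np.ndarray, grid: Grid2D, name: str = "map") -> None:
    values = np.asarray(values)
    if values.shape != (grid.nz, grid.nx):
        raise FormatError(
            f"map shape {values.shape} does not match grid ({grid.nz}, {grid.nx})")
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=values)
        f.attrs["name"] = name
        f.attrs["grid"] = json.dumps(grid.to_dict(), sort_keys=True)


def read_map(path) -> tuple:
    with h5py.File(path, "r") as f:
        values = f["values"][()]
        grid = Grid2D(**json.loads(f.attrs["grid"]))
    return values, grid


def write_image(path, img: ReconImage) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("pixels", data=img.pixels)
        f.attrs["pixel_size_um"] = img.pixel_size_um
        f.attrs["kind"] = img.kind


def read_image(path) -> ReconImage:
    with h5py.File(path, "r") as f:
        return ReconImage(pixels=f["pixels"][()],
                          pixel_size_um=float(f.attrs["pixel_size_um"]),
                          kind=str(f.attrs["kind"]))


def save_png16(path, pixels: np.ndarray) -> None:
    """Export an image as 16-bit greyscale PNG for visual inspection."""
    from PIL import Image

    pixels = np.asarray(pixels, dtype=np.float64)
    lo, hi = pixels.min(), pixels.max()
    scale = (pixels - lo) / (hi - lo) if hi > lo else np.zeros_like(pixels)
    Image.fromarray((scale * 65535).astype(np.uint16)).save(path)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

_POSITIVE_KEYS = {
    "pitch_mm", "center_freq_mhz", "frac_bw_6db", "fs_mhz", "sound_speed",
    "dx_mm", "mu_s", "mu_a", "refractive_index", "width_mm", "batch",
    "learning_rate", "iterations", "n_photons", "kappa", "size",
    "pixel_size_um", "internal_fs_mhz", "n_elements", "n_samples", "nx", "nz",
}


def _merge_section(defaults: dict, override: dict, section: str) -> dict:
    merged = dict(defaults)
    for key, value in (override or {}).items():
        if key not in defaults:
            raise ConfigError(f"unknown configuration key '{section}.{key}'")
        if key in _POSITIVE_KEYS and isinstance(value, (int, float)) and value <= 0:
            raise ConfigError(f"configuration key '{section}.{key}' must be positive")
        merged[key] = value
    return merged


DEFAULT_CONFIG = {
    "probe": ProbeGeometry().to_dict(),
    "grid": Grid2D().to_dict(),
    # absorption levels in mm^-1 (1, 1.5, 2 cm^-1): the three standard-tissue
    # levels spanned by the training sweep
    "medium": {"refractive_index": 1.4, "mu_s": 10.0, "anisotropy": 0.9,
               "mu_a_levels": [0.10, 0.15, 0.20]},
    "beam": {"width_mm": 38.4},
    "fluence": {"n_photons": 100_000},
    "needle_sweep": {"depths_mm": [5.0, 10.0, 15.0, 20.0, 25.0],
                     "angles_deg": [20.0, 25.0, 30.0, 35.0, 40.0,
                                    45.0, 50.0, 55.0, 60.0, 65.0],
                     "tip_x_mm": 5.0,
                     "jitter_depth_mm": 2.0, "jitter_angle_deg": 2.0},
    "background": {"n_backgrounds": 13, "n_vessels": 5, "artery": True,
                   "noise_std": 0.05, "n_frames": 128},
    "semisynth": {"kappa": 1.0, "zero_n": 150, "size": 2000,
                  "split": [0.8, 0.1, 0.1]},
    "recon": {"pixel_size_um": 70.0, "interp_depth": 565, "interp_lateral": 578,
              "crop": 512, "model_size": 128, "eval_size": 256,
              "envelope": True, "crop_from": "bottom"},
    "model": {"scales": 4, "base_filters": 16, "batchnorm": True},
    "train": {"iterations": 5000, "batch": 4, "learning_rate": 0.001,
              "seed": 0, "val_every": 50},
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML configuration, fill defaults, and validate.

    Unknown keys and non-positive physical quantities are rejected with the
    offending key named.  ``path=None`` (or an empty file) yields the full
    default record.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration root must be a mapping")
    if overrides:
        for section, values in overrides.items():
            raw.setdefault(section, {}).update(values)

    cfg = {}
    for section, defaults in DEFAULT_CONFIG.items():
        cfg[section] = _merge_section(defaults, raw.get(section, {}), section)
    unknown = set(raw) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown configuration section '{sorted(unknown)[0]}'")

    # cross-field checks routed through the dataclass validators
    probe = ProbeGeometry(**cfg["probe"])
    grid = Grid2D(**cfg["grid"])
    if not 0 < cfg["beam"]["width_mm"] <= grid.extent_x_mm:
        raise ConfigError("configuration key 'beam.width_mm' must fit inside the grid")
    return cfg


def probe_from_config(cfg: dict) -> ProbeGeometry:
    return ProbeGeometry(**cfg["probe"])


def grid_from_config(cfg: dict) -> Grid2D:
    return Grid2D(**cfg["grid"])
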