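"""Semi-synthetic dataset assembly.

A training pair is built by (1) simulating needle-only RF from a fluence-
weighted initial pressure map, (2) scaling it against a reference background
frame with the amplitude ratio kappa, (3) summing it with that background
frame and zeroing the first 150 time samples, (4) reconstructing the combined
frame and passing it through the interpolate/crop/resize chain, and (5)
rasterising the needle-only pressure map onto the same image grid as the
[0, 1] ground truth.  Needle poses are the depth/angle sweep nodes with small
uniform jitter (default +/-2 mm, +/-2 deg) so a large dataset can be filled
from the 150 nodal configurations; entries are split 8:1:1 by a seeded
permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .background import BackgroundSpec, averaged_background_rf, generate_background_p0
from .core import (ConfigError, DatasetManifest, Grid2D, ManifestEntry,
                   ProbeGeometry, RFFrame, write_image)
from .fluence import BeamSpec, FluenceMap, NeedleSpec, OpticalMedium, needle_initial_pressure, simulate_fluence
from .forward import AcousticConfig, simulate_sensor_rf
from .recon import ReconConfig, project_map_to_image, reconstruct, resample_and_crop, resize_for_model


@dataclass(frozen=True)
class SemisynthConfig:
    """Dataset-level settings."""

    kappa: float = 1.0            # needle-to-background max-amplitude ratio
    zero_n: int = 150             # leading samples zeroed (LED noise removal)
    size: int = 2000
    split: tuple = (0.8, 0.1, 0.1)
    jitter_depth_mm: float = 2.0
    jitter_angle_deg: float = 2.0
    n_backgrounds: int = 13

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ConfigError("kappa must be positive")
        if self.size < 1:
            raise ConfigError("size must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ConfigError("split fractions must sum to 1")


def normalize_needle_rf(rf_needle: RFFrame, rf_reference: RFFrame,
                        kappa: float = 1.0) -> RFFrame:
    """Scale the simulated needle RF so max|needle| = kappa * max|reference|."""
    peak_n = float(np.abs(rf_needle.samples).max())
    peak_r = float(np.abs(rf_reference.samples).max())
    if peak_n == 0:
        raise ConfigError("needle RF is identically zero")
    if peak_r == 0:
        raise ConfigError("reference RF is identically zero")
    scale = kappa * peak_r / peak_n
    return RFFrame(samples=rf_needle.samples * scale, fs_mhz=rf_needle.fs_mhz,
                   probe=rf_needle.probe)


def combine_rf(rf_a: RFFrame, rf_b: RFFrame, zero_n: int = 150) -> RFFrame:
    """Element-wise sum with the first ``zero_n`` time rows zeroed."""
    if rf_a.samples.shape != rf_b.samples.shape or rf_a.fs_mhz != rf_b.fs_mhz:
        raise ConfigError("frames must share shape and sampling rate")
    if zero_n >= rf_a.n_samples:
        raise ConfigError("zero_n must be smaller than the sample count")
    out = rf_a.samples + rf_b.samples
    out[:zero_n] = 0.0
    return RFFrame(samples=out, fs_mhz=rf_a.fs_mhz, probe=rf_a.probe)


def shaft_reaches_light(depth_mm: float, angle_deg: float, tip_x_mm: float,
                        grid: Grid2D, illum_depth_mm: float = 4.0) -> bool:
    """Whether the in-grid part of the shaft rises above ``illum_depth_mm``.

    The shaft runs from its surface entry point (possibly outside the grid
    laterally) down to the tip; the portion inside the grid must reach the
    shallow illuminated zone to carry any simulated fluence.
    """
    half_x = grid.extent_x_mm / 2
    entry_x = tip_x_mm - depth_mm / np.tan(np.radians(angle_deg))
    if entry_x >= -half_x:
        return True  # the entry point itself is inside the grid: depth 0
    # depth at which the shaft crosses the left grid edge
    z_edge = depth_mm * (-half_x - entry_x) / (tip_x_mm - entry_x)
    return z_edge <= illum_depth_mm


def split_sizes(n: int, fractions) -> tuple:
    """Largest-remainder allocation of n entries over split fractions."""
    raw = [n * f for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    leftovers = n - sum(sizes)
    order = np.argsort([s - r for s, r in zip(sizes, raw)])  # largest remainder
    for i in range(leftovers):
        sizes[order[i]] += 1
    return tuple(sizes)


def build_dataset(cfg: SemisynthConfig,
                  probe: ProbeGeometry,
                  grid: Grid2D,
                  out_dir,
                  seed: int = 0,
                  acfg: AcousticConfig | None = None,
                  rcfg: ReconConfig | None = None,
                  medium_mu_a=(0.10, 0.15, 0.20),
                  depths_mm=(5.0, 10.0, 15.0, 20.0, 25.0),
                  angles_deg=(20.0, 25.0, 30.0, 35.0, 40.0,
                              45.0, 50.0, 55.0, 60.0, 65.0),
                  tip_x_mm: float = 5.0,
                  beam: BeamSpec | None = None,
                  background_spec: BackgroundSpec | None = None,
                  n_photons: int = 100_000,
                  materialise: bool = True) -> DatasetManifest:
    """Assemble the semi-synthetic dataset and write its manifest.

    With ``materialise=False`` only the manifest (poses, background pairings,
    split assignment) is produced; image files are skipped.  Pose sampling and
    the split permutation are identical either way for a given seed.
    """
    acfg = acfg or AcousticConfig(output_fs_mhz=probe.fs_mhz)
    rcfg = rcfg or ReconConfig()
    beam = beam or BeamSpec()
    background_spec = background_spec or BackgroundSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)

    # nodal sweep: depth x angle x absorption level
    nodes = [(float(d), float(a), mi)
             for mi in range(len(medium_mu_a))
             for d in depths_mm for a in angles_deg]
    if not nodes:
        raise ConfigError("needle sweep is empty")
    if cfg.n_backgrounds < 1:
        raise ConfigError("at least one background is required")

    # draw poses and pairings (cheap; always done).  A pose is only usable if
    # the in-grid shaft rises into the illuminated zone near the surface —
    # light barely penetrates beyond a few mm at these absorption levels, so
    # a shaft confined to large depths carries no photoacoustic source.
    records = []
    for i in range(cfg.size):
        depth0, angle0, mi = nodes[i % len(nodes)]
        for attempt in range(30):
            depth = depth0 + rng.uniform(-cfg.jitter_depth_mm, cfg.jitter_depth_mm)
            angle = angle0 + rng.uniform(-cfg.jitter_angle_deg, cfg.jitter_angle_deg)
            depth = float(np.clip(depth, 3.0, grid.extent_z_mm - 3.0))
            angle = float(np.clip(angle, 15.0, 70.0))
            if shaft_reaches_light(depth, angle, tip_x_mm, grid):
                break
        while not shaft_reaches_light(depth, angle, tip_x_mm, grid):
            depth -= 1.0  # geometric fallback: pull the tip up until lit
        bg_id = int(rng.integers(cfg.n_backgrounds))
        records.append({"angle_deg": angle, "tip_depth_mm": depth,
                        "tip_x_mm": tip_x_mm, "background_id": bg_id,
                        "medium_id": mi})

    # seeded split permutation
    sizes = split_sizes(cfg.size, cfg.split)
    order = rng.permutation(cfg.size)
    split_of = np.empty(cfg.size, dtype=object)
    split_of[order[:sizes[0]]] = "train"
    split_of[order[sizes[0]:sizes[0] + sizes[1]]] = "val"
    split_of[order[sizes[0] + sizes[1]:]] = "test"

    fluences: dict = {}
    backgrounds: dict = {}
    if materialise:
        for mi, mu_a in enumerate(medium_mu_a):
            medium = OpticalMedium(mu_a=float(mu_a))
            fluences[mi] = simulate_fluence(medium, beam, grid,
                                            n_photons=n_photons,
                                            seed=seed * 1000 + mi)
        for b in range(cfg.n_backgrounds):
            bg_seed = seed * 1000 + 100 + b
            p0_bg = generate_background_p0(background_spec, grid, seed=bg_seed)
            backgrounds[b] = averaged_background_rf(
                p0_bg, grid, probe, acfg, background_spec, seed=bg_seed)

    entries = []
    for i, rec in enumerate(records):
        input_path = f"pair_{i:05d}_input.h5"
        target_path = f"pair_{i:05d}_target.h5"
        if materialise:
            needle = NeedleSpec(angle_deg=rec["angle_deg"],
                                tip_depth_mm=rec["tip_depth_mm"],
                                tip_x_mm=rec["tip_x_mm"])
            p0_needle = needle_initial_pressure(fluences[rec["medium_id"]], needle)
            rf_needle = simulate_sensor_rf(p0_needle, grid, probe, acfg)
            rf_bg = backgrounds[rec["background_id"]]
            rf_needle = normalize_needle_rf(rf_needle, rf_bg, cfg.kappa)
            combined = combine_rf(rf_needle, rf_bg, cfg.zero_n)
            img = reconstruct(combined, probe, envelope=rcfg.envelope)
            img = resample_and_crop(img, probe, rcfg)
            img = resize_for_model(img, rcfg.model_size)
            if img.pixels.max() > 0:      # per-image max normalisation
                img.pixels = img.pixels / img.pixels.max()
            target = project_map_to_image(p0_needle, grid, probe, rcfg)
            target = resize_for_model(target, rcfg.model_size)
            # resize can nudge values past the bounds; ground truth stays [0, 1]
            target.pixels = np.clip(target.pixels, 0.0, 1.0)
            write_image(out_dir / input_path, img)
            write_image(out_dir / target_path, target)
        entries.append(ManifestEntry(
            input_path=input_path, target_path=target_path,
            needle_pose={"angle_deg": rec["angle_deg"],
                         "tip_depth_mm": rec["tip_depth_mm"],
                         "tip_x_mm": rec["tip_x_mm"]},
            background_id=rec["background_id"],
            medium_id=rec["medium_id"],
            split=str(split_of[i])))

    manifest = DatasetManifest(entries=entries, meta={
        "seed": seed, "size": cfg.size, "kappa": cfg.kappa,
        "zero_n": cfg.zero_n, "split": list(cfg.split),
        "mu_a_levels": list(medium_mu_a),
        "n_backgrounds": cfg.n_backgrounds,
        "materialised": bool(materialise),
        "model_size": rcfg.model_size,
    })
    manifest.save(out_dir / "manifest.json")
    return manifest


def check_no_leakage(manifest: DatasetManifest) -> bool:
    """No (needle pose, background) pairing may appear in both train and test."""
    def key(e):
        pose = e.needle_pose
        return (round(pose["angle_deg"], 6), round(pose["tip_depth_mm"], 6),
                round(pose["tip_x_mm"], 6), e.background_id, e.medium_id)

    train = {key(e) for e in manifest.subset("train")}
    test = {key(e) for e in manifest.subset("test")}
    return not (train & test)


def load_split_arrays(manifest: DatasetManifest, data_dir) -> dict:
    """Load the materialised pairs as float32 arrays keyed by split."""
    from .core import read_image

    data_dir = Path(data_dir)
    out = {}
    for split in ("train", "val", "test"):
        xs, ys = [], []
        for e in manifest.subset(split):
            xs.append(read_image(data_dir / e.input_path).pixels)
            ys.append(read_image(data_dir / e.target_path).pixels)
        if xs:
            out[split] = (np.asarray(xs, dtype=np.float32),
                          np.asarray(ys, dtype=np.float32))
        else:
            out[split] = (np.empty((0,)), np.empty((0,)))
    return out
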