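"""2D Monte Carlo photon transport and needle initial-pressure maps.

The light source is a wide, uniform beam entering the tissue surface (z = 0).
Photon packets carry a statistical weight; scattering free paths are sampled
from the scattering coefficient, direction changes from a 2D Henyey-Greenstein
phase function, and absorption is deposited continuously along each free path
(Beer-Lambert weight decay scored per grid cell).  Fluence is recovered with
the absorption estimator: deposited weight / (mu_a * cell area), per launched
photon.  Packets leaving the grid are terminated and their weight logged as
escaped; low-weight packets play Russian roulette.  An energy ledger keeps the
audit ``launched = deposited + escaped + roulette_net`` exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import ConfigError, Grid2D

ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1


@dataclass(frozen=True)
class OpticalMedium:
    """Homogeneous optical properties of the background tissue."""

    refractive_index: float = 1.4
    mu_s: float = 10.0       # scattering coefficient, mm^-1
    anisotropy: float = 0.9  # Henyey-Greenstein g
    mu_a: float = 1.0        # absorption coefficient, mm^-1

    def __post_init__(self) -> None:
        if self.mu_s < 0:
            raise ConfigError("mu_s must be non-negative")
        if self.mu_a <= 0:
            raise ConfigError("mu_a must be positive")
        if not -1 < self.anisotropy < 1:
            raise ConfigError("anisotropy must lie in (-1, 1)")
        if self.refractive_index < 1:
            raise ConfigError("refractive_index must be >= 1")


@dataclass(frozen=True)
class BeamSpec:
    """Uniform illumination stripe entering at z = 0, centred laterally."""

    width_mm: float = 38.4

    def validate(self, grid: Grid2D) -> None:
        if not 0 < self.width_mm <= grid.extent_x_mm:
            raise ConfigError("beam width must be positive and fit inside the grid")


@dataclass
class EnergyLedger:
    """Photon-weight bookkeeping for conservation audits."""

    launched: float = 0.0
    deposited: float = 0.0
    escaped: float = 0.0
    roulette_net: float = 0.0  # weight destroyed minus weight created by roulette

    @property
    def imbalance(self) -> float:
        return self.launched - (self.deposited + self.escaped + self.roulette_net)


@dataclass
class FluenceMap:
    """Per-launched-photon fluence on a Grid2D (arbitrary units)."""

    values: np.ndarray
    grid: Grid2D
    ledger: EnergyLedger = field(default_factory=EnergyLedger)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.grid.nz, self.grid.nx):
            raise ConfigError("fluence map shape must match the grid")


@dataclass(frozen=True)
class NeedleSpec:
    """In-plane needle pose.

    The needle enters from the left at ``angle_deg`` above the horizontal
    surface and its tip sits at depth ``tip_depth_mm``, lateral position
    ``tip_x_mm``.  Anchoring the tip (rather than the surface entry point)
    keeps the visible shaft inside the field of view across the whole
    depth/angle sweep; the implied surface entry point is a derived property.
    """

    angle_deg: float
    tip_depth_mm: float
    tip_x_mm: float = 5.0
    half_thickness_cells: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.angle_deg < 90:
            raise ConfigError("angle_deg must lie in (0, 90)")
        if self.tip_depth_mm <= 0:
            raise ConfigError("tip_depth_mm must be positive")
        if self.half_thickness_cells < 0:
            raise ConfigError("half_thickness_cells must be >= 0")

    @property
    def entry_x_mm(self) -> float:
        """Lateral position where the shaft line crosses the surface z = 0."""
        return self.tip_x_mm - self.tip_depth_mm / np.tan(np.radians(self.angle_deg))

    def shaft_mask(self, grid: Grid2D) -> np.ndarray:
        """Rasterise the in-grid portion of the shaft as a boolean mask.

        Raises ConfigError if the tip lies outside the grid or no shaft cell
        falls inside it.
        """
        half_x = grid.extent_x_mm / 2
        if not (0 < self.tip_depth_mm < grid.extent_z_mm
                and -half_x < self.tip_x_mm < half_x):
            raise ConfigError("needle tip lies outside the grid")
        # march from the surface entry point to the tip in half-cell steps
        x0, z0 = self.entry_x_mm, 0.0
        x1, z1 = self.tip_x_mm, self.tip_depth_mm
        length = float(np.hypot(x1 - x0, z1 - z0))
        n_steps = max(int(np.ceil(length / (grid.dx_mm / 2))), 1)
        t = np.linspace(0.0, 1.0, n_steps + 1)
        xs = x0 + t * (x1 - x0)
        zs = z0 + t * (z1 - z0)
        ix = np.floor((xs + half_x) / grid.dx_mm).astype(int)
        iz = np.floor(zs / grid.dx_mm).astype(int)
        inside = (ix >= 0) & (ix < grid.nx) & (iz >= 0) & (iz < grid.nz)
        if not inside.any():
            raise ConfigError("rasterised shaft lies entirely outside the grid")
        mask = np.zeros((grid.nz, grid.nx), dtype=bool)
        mask[iz[inside], ix[inside]] = True
        if self.half_thickness_cells > 0:
            size = 2 * self.half_thickness_cells + 1
            mask = ndimage.binary_dilation(mask, structure=np.ones((size, size), bool))
        return mask


def _sample_hg_2d(rng: np.random.Generator, g: float, n: int) -> np.ndarray:
    """Sample deflection angles from the 2D Henyey-Greenstein phase function."""
    if abs(g) < 1e-8:
        return rng.uniform(-np.pi, np.pi, n)
    u = rng.uniform(0.0, 1.0, n)
    # analytic inverse CDF of p(theta) = (1 - g^2) / (2*pi*(1 + g^2 - 2 g cos(theta)))
    return 2.0 * np.arctan((1 - g) / (1 + g) * np.tan(np.pi * (u - 0.5)))


def simulate_fluence(medium: OpticalMedium, beam: BeamSpec, grid: Grid2D,
                     n_photons: int = 100_000, seed: int = 0,
                     substep_mm: float | None = None) -> FluenceMap:
    """Run the 2D photon-packet simulation and return the fluence map.

    Deterministic for a fixed ``seed``.  ``substep_mm`` controls the spatial
    resolution of the continuous absorption deposition (default: half a cell).
    """
    if n_photons < 1:
        raise ConfigError("n_photons must be >= 1")
    beam.validate(grid)
    rng = np.random.default_rng(seed)
    ds = substep_mm if substep_mm is not None else grid.dx_mm / 2
    half_x = grid.extent_x_mm / 2

    # specular reflection at the surface from the index mismatch (applied once)
    n1, n2 = 1.0, medium.refractive_index
    r_spec = ((n1 - n2) / (n1 + n2)) ** 2

    ledger = EnergyLedger(launched=float(n_photons))
    ledger.escaped += n_photons * r_spec

    x = rng.uniform(-beam.width_mm / 2, beam.width_mm / 2, n_photons)
    z = np.zeros(n_photons)
    theta = np.full(n_photons, np.pi / 2)        # straight down (+z)
    w = np.full(n_photons, 1.0 - r_spec)

    deposit = np.zeros(grid.nz * grid.nx)
    attn = np.exp(-medium.mu_a * ds)

    # remaining distance to the next scattering event
    if medium.mu_s > 0:
        remaining = rng.exponential(1.0 / medium.mu_s, n_photons)
    else:
        remaining = np.full(n_photons, np.inf)

    while x.size:
        step = np.minimum(remaining, ds)
        x = x + step * np.cos(theta)
        z = z + step * np.sin(theta)

        inside = (x > -half_x) & (x < half_x) & (z > 0) & (z < grid.extent_z_mm)
        ledger.escaped += float(w[~inside].sum())
        x, z, theta, w, remaining, step = (a[inside] for a in
                                           (x, z, theta, w, remaining, step))
        if not x.size:
            break

        # continuous Beer-Lambert deposition over this sub-step, scored at the
        # sub-step midpoint to avoid aliasing against the cell boundaries
        frac = 1.0 - np.exp(-medium.mu_a * step)
        dw = w * frac
        xm = x - 0.5 * step * np.cos(theta)
        zm = z - 0.5 * step * np.sin(theta)
        ix = np.clip(np.floor((xm + half_x) / grid.dx_mm).astype(np.int64),
                     0, grid.nx - 1)
        iz = np.clip(np.floor(zm / grid.dx_mm).astype(np.int64), 0, grid.nz - 1)
        np.add.at(deposit, iz * grid.nx + ix, dw)
        ledger.deposited += float(dw.sum())
        w = w - dw
        remaining = remaining - step

        # scatter packets that completed their free path
        done = remaining <= 1e-12
        if done.any() and medium.mu_s > 0:
            theta[done] = theta[done] + _sample_hg_2d(rng, medium.anisotropy,
                                                      int(done.sum()))
            remaining[done] = rng.exponential(1.0 / medium.mu_s, int(done.sum()))

        # Russian roulette on low-weight packets
        low = w < ROULETTE_THRESHOLD
        if low.any():
            survive = rng.uniform(size=int(low.sum())) < ROULETTE_SURVIVAL
            idx = np.flatnonzero(low)
            killed = idx[~survive]
            boosted = idx[survive]
            ledger.roulette_net += float(w[killed].sum())
            ledger.roulette_net -= float(w[boosted].sum()) * (1 / ROULETTE_SURVIVAL - 1)
            w[boosted] = w[boosted] / ROULETTE_SURVIVAL
            keep = np.ones(x.size, dtype=bool)
            keep[killed] = False
            x, z, theta, w, remaining = (a[keep] for a in (x, z, theta, w, remaining))

    cell_area = grid.dx_mm ** 2
    fluence = deposit.reshape(grid.nz, grid.nx) / (medium.mu_a * cell_area * n_photons)
    return FluenceMap(values=fluence, grid=grid, ledger=ledger)


def needle_initial_pressure(fluence: FluenceMap, needle: NeedleSpec) -> np.ndarray:
    """Initial pressure on the needle shaft: local fluence, max-normalised to 1.

    Zero everywhere off the rasterised shaft mask.  An all-zero fluence map
    yields an all-zero pressure map.
    """
    mask = needle.shaft_mask(fluence.grid)
    p0 = np.where(mask, fluence.values, 0.0)
    peak = p0.max()
    if peak > 0:
        p0 = p0 / peak
    return p0


def sweep_specs(depths_mm, angles_deg, mu_a_levels, tip_x_mm: float = 5.0):
    """Enumerate the (needle pose, absorption) nodes of the simulation sweep."""
    nodes = []
    for mu_idx, _ in enumerate(mu_a_levels):
        for depth in depths_mm:
            for angle in angles_deg:
                nodes.append((NeedleSpec(angle_deg=float(angle),
                                         tip_depth_mm=float(depth),
                                         tip_x_mm=float(tip_x_mm)), mu_idx))
    return nodes
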