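"""Synthetic inputs for the full pipeline: scaffold phantoms, shear-driven
weekly mineralization series, and micro-CT-like acquisitions.

The phantom emulates a salt-leached silk-fibroin disc: spherical pores with
diameters drawn uniformly from the granule sieve range (315-400 um by
default, overlap allowed, as packed salt granules touch) are carved out of
a solid cylinder until the measured pore fraction reaches the target
porosity (55% by default, matching the porous-flow model of the real
scaffold; the material itself is far more porous, ~90%, at scales the
averaged model does not represent — see docs/methods.md).

Mineralization is a per-week hazard model: an unmineralized pore voxel
mineralizes with probability rate*link(tau) + bonus*(mineralized neighbor
fraction).  With the band link (1 inside [0.55, 24] mPa, else 0) tissue
grows where the simulated stimulus lies in the osteogenic window, which on
perfused fields produces the edge-to-center growth seen under flow; the
uniform link reproduces spatially uniform static-culture growth.  Masks
are nested across weeks (no demineralization).

The acquisition model assigns a mineral density to formed tissue (the
scaffold material stays below the segmentation threshold, as silk is
indistinguishable from culture medium in the scans), blurs with a Gaussian
PSF and adds Gaussian noise.  Every generator is a pure function of its
seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .stress_field import VoxelFieldSample
from .uct_pipeline import BinaryMask, VoxelVolume, cylinder_mask

__all__ = [
    "PhantomParams",
    "MineralizationLink",
    "ScanParams",
    "PhantomError",
    "gen_scaffold_phantom",
    "gen_mineralization",
    "simulate_uct_scan",
]


class PhantomError(RuntimeError):
    """Target porosity unreachable with the given pore-size range/geometry."""


@dataclass(frozen=True)
class PhantomParams:
    """Salt-leached scaffold phantom parameters."""

    scaffold_radius: float = 4.0e-3  # m
    scaffold_height: float = 3.0e-3  # m
    porosity: float = 0.55  # target pore fraction
    pore_diameter_range: tuple[float, float] = (315e-6, 400e-6)  # m
    voxel_size: float = 36e-6  # m
    scaffold_density: float = 30.0  # mg HA/cm^3, sub-threshold
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity < 1.0:
            raise ValueError("porosity must be in (0, 1)")
        lo, hi = self.pore_diameter_range
        if not (0 < lo <= hi):
            raise ValueError("pore diameter range must be positive and ordered")
        if self.voxel_size <= 0 or self.scaffold_radius <= 0 or self.scaffold_height <= 0:
            raise ValueError("lengths must be positive")


@dataclass(frozen=True)
class MineralizationLink:
    """Stress-to-mineralization link and weekly kinetics.

    ``kind``: "band" (1 inside [lo, hi], 0 outside), "logistic" (smooth
    rise across lo with width ``logistic_width``), or "uniform" (link == 1,
    the static-culture control).
    """

    kind: str = "band"
    lo: float = 0.55e-3  # Pa
    hi: float = 24e-3  # Pa
    rate: float = 0.6  # per-week mineralization probability at link == 1
    bonus: float = 0.35  # neighborhood-growth bonus weight
    noise: float = 0.0  # probability jitter SD
    logistic_width: float = 0.1e-3  # Pa
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("band", "logistic", "uniform"):
            raise ValueError(f"unknown link kind {self.kind!r}")
        if not self.lo < self.hi:
            raise ValueError("band edges must satisfy lo < hi")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must be in [0, 1]")
        if self.bonus < 0 or self.noise < 0:
            raise ValueError("bonus and noise must be non-negative")

    def __call__(self, tau: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        if self.kind == "uniform":
            return np.ones_like(tau)
        if self.kind == "band":
            return ((tau >= self.lo) & (tau <= self.hi)).astype(float)
        up = 1.0 / (1.0 + np.exp(-(tau - self.lo) / self.logistic_width))
        down = 1.0 / (1.0 + np.exp((tau - self.hi) / self.logistic_width))
        return up * down


@dataclass(frozen=True)
class ScanParams:
    """Micro-CT acquisition forward model."""

    psf_sigma: float = 0.5  # voxels
    noise_sd: float = 15.0  # mg HA/cm^3
    mineral_density: float = 200.0  # mg HA/cm^3 assigned to formed ECM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma < 0:
            raise ValueError("PSF width must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.mineral_density <= 0:
            raise ValueError("mineral density must be positive")


def gen_scaffold_phantom(params: PhantomParams,
                         max_attempts: int = 200_000) -> tuple[VoxelVolume, BinaryMask]:
    """Generate a porous scaffold phantom.

    Returns the scaffold density volume (scaffold material at its
    sub-threshold density, pores and exterior at 0) and the pore-space
    mask.  Spheres are added one at a time until the measured pore
    fraction inside the cylinder envelope is within +-2% (absolute) of the
    target porosity; unreachable targets raise :class:`PhantomError`.
    """
    rng = np.random.default_rng(params.seed)
    vs = params.voxel_size
    n_xy = int(np.ceil(2 * params.scaffold_radius / vs))
    n_z = int(np.ceil(params.scaffold_height / vs))
    shape = (n_xy, n_xy, n_z)
    envelope = cylinder_mask(shape, vs, params.scaffold_radius, params.scaffold_height).data
    n_env = int(envelope.sum())
    if n_env == 0:
        raise PhantomError("scaffold envelope contains no voxels; voxel size too large")

    pores = np.zeros(shape, dtype=bool)
    cx = cy = 0.5 * n_xy * vs
    lo_d, hi_d = params.pore_diameter_range
    # re-measure after every batch that can add at most ~0.5% pore fraction
    mean_sphere_vol = np.pi / 6.0 * (0.5 * (lo_d + hi_d)) ** 3
    batch = max(1, int(0.005 * n_env * vs**3 / mean_sphere_vol))
    pore_count = 0
    frac = 0.0
    for _ in range(max_attempts):
        if abs(frac - params.porosity) <= 0.02:
            break
        if frac > params.porosity + 0.02:
            raise PhantomError("pore fraction overshot the target band")
        d = rng.uniform(lo_d, hi_d)
        # centers inside the cylinder (pores open to the boundary are fine)
        r_pos = params.scaffold_radius * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        x0 = cx + r_pos * np.cos(phi)
        y0 = cy + r_pos * np.sin(phi)
        z0 = rng.uniform(0, params.scaffold_height)
        rad = 0.5 * d
        i0 = max(int((x0 - rad) / vs), 0)
        i1 = min(int((x0 + rad) / vs) + 2, n_xy)
        j0 = max(int((y0 - rad) / vs), 0)
        j1 = min(int((y0 + rad) / vs) + 2, n_xy)
        k0 = max(int((z0 - rad) / vs), 0)
        k1 = min(int((z0 + rad) / vs) + 2, n_z)
        xs = (np.arange(i0, i1) + 0.5) * vs - x0
        ys = (np.arange(j0, j1) + 0.5) * vs - y0
        zs = (np.arange(k0, k1) + 0.5) * vs - z0
        ball = (
            xs[:, None, None] ** 2 + ys[None, :, None] ** 2 + zs[None, None, :] ** 2
            <= rad**2
        )
        pores[i0:i1, j0:j1, k0:k1] |= ball
        pore_count += 1
        if pore_count % batch == 0:
            frac = (pores & envelope).sum() / n_env
    else:
        raise PhantomError(
            f"target porosity {params.porosity} not reached after {max_attempts} spheres"
        )
    pores &= envelope
    density = np.where(envelope & ~pores, params.scaffold_density, 0.0)
    vol = VoxelVolume(density, vs)
    return vol, BinaryMask(pores, vs)


def _neighbor_fraction(mask: np.ndarray) -> np.ndarray:
    """Fraction of mineralized voxels among the 26 neighbors."""
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    counts = ndimage.convolve(mask.astype(float), kernel, mode="constant")
    return counts / 26.0


def gen_mineralization(
    ss: VoxelFieldSample,
    pores: BinaryMask,
    link: MineralizationLink,
    weeks: Sequence[int],
    seed: int | None = None,
) -> dict[int, BinaryMask]:
    """Per-week nested mineralization masks driven by the stress field.

    Each listed week applies one hazard round: every still-unmineralized
    pore voxel mineralizes with probability
    ``rate * link(tau) + bonus * neighbor_fraction`` (clipped to [0, 1],
    with optional Gaussian jitter of SD ``noise``).  Pore voxels without a
    valid tau never mineralize under a stress-dependent link.
    """
    weeks = list(weeks)
    if len(weeks) == 0:
        raise ValueError("weeks must be non-empty")
    if any(b <= a for a, b in zip(weeks, weeks[1:])):
        raise ValueError("weeks must be strictly increasing")
    if ss.tau.shape != pores.data.shape:
        raise ValueError("stress sample and pore mask must share one lattice")
    rng = np.random.default_rng(link.seed if seed is None else seed)

    tau = np.where(ss.valid, np.nan_to_num(ss.tau), 0.0)
    link_val = link(tau)
    if link.kind != "uniform":
        link_val = np.where(ss.valid, link_val, 0.0)
    base_p = link.rate * link_val

    current = np.zeros_like(pores.data)
    out: dict[int, BinaryMask] = {}
    for week in weeks:
        p = base_p + (link.bonus * _neighbor_fraction(current) if link.bonus > 0 else 0.0)
        if link.noise > 0:
            p = p + rng.normal(0.0, link.noise, size=p.shape)
        p = np.clip(p, 0.0, 1.0)
        draw = rng.uniform(size=p.shape) < p
        current = current | (draw & pores.data & ~current)
        out[week] = BinaryMask(current.copy(), pores.voxel_size, pores.origin)
    return out


def simulate_uct_scan(
    mineral: BinaryMask,
    scan: ScanParams,
    background: VoxelVolume | None = None,
    week: int | None = None,
) -> VoxelVolume:
    """Forward-model a density-calibrated micro-CT acquisition.

    Mineralized voxels take ``mineral_density``; the optional background
    (e.g. the sub-threshold scaffold density volume) is added underneath;
    the volume is blurred by a Gaussian PSF and Gaussian noise is added.
    """
    density = np.where(mineral.data, scan.mineral_density, 0.0)
    if background is not None:
        if background.data.shape != mineral.data.shape:
            raise ValueError("background volume must share the mineral mask lattice")
        density = np.maximum(density, background.data)
    if scan.psf_sigma > 0:
        density = ndimage.gaussian_filter(density, scan.psf_sigma, mode="mirror")
    if scan.noise_sd > 0:
        rng = np.random.default_rng(scan.seed)
        density = density + rng.normal(0.0, scan.noise_sd, size=density.shape)
    return VoxelVolume(density, mineral.voxel_size, mineral.origin, week=week)
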