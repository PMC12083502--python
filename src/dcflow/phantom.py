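"""Voxelized breast-slab phantoms, probe geometry, and synthetic lesion cohorts.

The slab emulates a handheld-probe measurement volume: an 8 x 8 x 3 cm
tissue block discretized into 0.5 cm voxels (16 x 16 x 6), with sources and
detectors on the top (z = 0) face.  Blood flow is described per voxel by the
blood flow index alpha*Db (``BFI``, cm^2/s); lesions are spherical inclusions
with elevated and heterogeneous flow.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

__all__ = [
    "VoxelGrid",
    "OpticalProperties",
    "ProbeLayout",
    "BFIMap",
    "LesionSpec",
    "make_probe",
    "make_phantom",
    "make_cohort",
    "save_bfi_map",
    "load_bfi_map",
    "save_cohort_labels",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid covering the tissue slab.

    Linear voxel index is ``i = iz*nx*ny + iy*nx + ix`` with ``iz`` increasing
    with depth below the probe face.
    """

    nx: int = 16
    ny: int = 16
    nz: int = 6
    voxel_edge: float = 0.5  # cm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("voxel counts must be >= 1")
        if self.voxel_edge <= 0:
            raise ValueError("voxel_edge must be positive")

    @property
    def n_voxels(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (cm) along x, y, z."""
        return (
            self.nx * self.voxel_edge,
            self.ny * self.voxel_edge,
            self.nz * self.voxel_edge,
        )

    def linear_index(self, ix, iy, iz):
        return iz * self.nx * self.ny + iy * self.nx + ix

    def voxel_centers(self) -> np.ndarray:
        """(n_voxels, 3) array of voxel center coordinates in cm."""
        e = self.voxel_edge
        ox, oy, oz = self.origin
        xs = ox + (np.arange(self.nx) + 0.5) * e
        ys = oy + (np.arange(self.ny) + 0.5) * e
        zs = oz + (np.arange(self.nz) + 0.5) * e
        zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous tissue optics (breast defaults).

    ``k0`` is derived from refractive index and wavelength, never stored.
    """

    mus_prime: float = 8.0  # reduced scattering, cm^-1
    mua: float = 0.05  # absorption, cm^-1
    refractive_index: float = 1.37
    anisotropy_g: float = 0.9
    wavelength: float = 785e-7  # cm

    def __post_init__(self) -> None:
        if self.mus_prime <= 0 or self.mua <= 0:
            raise ValueError("scattering/absorption coefficients must be > 0")
        if not (0 <= self.anisotropy_g < 1):
            raise ValueError("anisotropy g must lie in [0, 1)")
        if self.refractive_index <= 0 or self.wavelength <= 0:
            raise ValueError("refractive index and wavelength must be > 0")

    @property
    def k0(self) -> float:
        """Optical wave-vector magnitude in tissue, 2*pi*n/lambda (cm^-1)."""
        return 2.0 * np.pi * self.refractive_index / self.wavelength


@dataclass(frozen=True)
class ProbeLayout:
    """Source/detector positions on the top probe face (cm)."""

    source_positions: tuple[tuple[float, float], ...]
    detector_positions: tuple[tuple[float, float], ...]
    acceptance_radius: float = 0.25  # cm

    def __post_init__(self) -> None:
        if len(self.source_positions) < 1 or len(self.detector_positions) < 1:
            raise ValueError("need at least one source and one detector")
        if self.acceptance_radius <= 0:
            raise ValueError("acceptance_radius must be positive")

    @property
    def n_sources(self) -> int:
        return len(self.source_positions)

    @property
    def n_detectors(self) -> int:
        return len(self.detector_positions)

    def separations(self) -> np.ndarray:
        """(M, J) matrix of source-detector separations in cm."""
        s = np.asarray(self.source_positions)
        d = np.asarray(self.detector_positions)
        return np.linalg.norm(s[:, None, :] - d[None, :, :], axis=-1)


@dataclass
class BFIMap:
    """Voxelwise blood flow index alpha*Db (cm^2/s)."""

    values: np.ndarray
    grid: VoxelGrid = field(default_factory=VoxelGrid)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.grid.n_voxels:
            raise ValueError(
                f"expected {self.grid.n_voxels} voxel values, got {self.values.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BFI values must be finite")
        if np.any(self.values < 0):
            raise ValueError("BFI values must be nonnegative")

    def as_volume(self) -> np.ndarray:
        """Reshape to (nz, ny, nx)."""
        return self.values.reshape(self.grid.nz, self.grid.ny, self.grid.nx)


@dataclass(frozen=True)
class LesionSpec:
    """Spherical flow inclusion: center (cm), diameter (cm), flow contrast
    over background, and relative within-lesion heterogeneity."""

    center: tuple[float, float, float]
    diameter: float
    contrast: float
    texture_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")
        if self.texture_sigma < 0:
            raise ValueError("texture_sigma must be nonnegative")


def make_probe(
    n_sources: int = 8,
    n_detectors: int = 6,
    source_radius: float = 3.0,
    detector_radius: float = 1.0,
    center: tuple[float, float] = (4.0, 4.0),
    face_extent: tuple[float, float] = (8.0, 8.0),
    acceptance_radius: float = 0.25,
    phase_deg: float = 0.0,
) -> ProbeLayout:
    """Concentric-circle source-detector array on the probe face.

    Sources sit evenly spaced on an outer circle, detectors on an inner one,
    both centered on the face.  Defaults (8 sources at r=3 cm, 6 detectors at
    r=1 cm) give 48 S-D pairs with separations between 2 and 4 cm, probing
    roughly 5-10 mm below the surface.
    """
    if n_sources < 1 or n_detectors < 1:
        raise ValueError("counts must be >= 1")
    if source_radius < 0 or detector_radius < 0:
        raise ValueError("radii must be nonnegative")
    cx, cy = center
    for r in (source_radius, detector_radius):
        if (cx - r < 0 or cx + r > face_extent[0]
                or cy - r < 0 or cy + r > face_extent[1]):
            raise ValueError(
                f"circle of radius {r} cm centered at {center} exceeds the "
                f"{face_extent[0]} x {face_extent[1]} cm probe face"
            )

    def ring(n: int, r: float) -> tuple[tuple[float, float], ...]:
        ang = np.deg2rad(phase_deg) + 2 * np.pi * np.arange(n) / n
        return tuple((cx + r * float(np.cos(a)), cy + r * float(np.sin(a))) for a in ang)

    layout = ProbeLayout(
        source_positions=ring(n_sources, source_radius),
        detector_positions=ring(n_detectors, detector_radius),
        acceptance_radius=acceptance_radius,
    )
    if np.any(layout.separations() < 1e-12):
        raise ValueError("degenerate layout: a source coincides with a detector")
    return layout


def make_phantom(
    grid: VoxelGrid,
    background_bfi: float = 4.5e-8,
    lesions: Sequence[LesionSpec] = (),
    seed: int = 0,
) -> BFIMap:
    """Background flow plus spherical lesion inclusions.

    Voxels inside a lesion get ``background * contrast`` modulated by
    lognormal multiplicative texture (sigma = ``texture_sigma`` in log space),
    which keeps values positive while creating within-lesion heterogeneity.
    Overlapping lesions resolve by maximum contrast.  Deterministic per seed.
    """
    if background_bfi <= 0:
        raise ValueError("background_bfi must be positive")
    rng = np.random.default_rng(seed)
    values = np.full(grid.n_voxels, background_bfi, dtype=float)
    centers = grid.voxel_centers()
    # max-contrast-wins on overlap
    contrast_map = np.ones(grid.n_voxels)
    sigma_map = np.zeros(grid.n_voxels)
    ext = grid.extent
    for les in lesions:
        c = np.asarray(les.center)
        r = les.diameter / 2.0
        if np.any(c - r < np.asarray(grid.origin)) or np.any(
            c + r > np.asarray(grid.origin) + np.asarray(ext)
        ):
            raise ValueError(f"lesion at {les.center} (d={les.diameter}) exceeds the slab")
        inside = np.linalg.norm(centers - c, axis=1) <= r
        take = inside & (les.contrast > contrast_map)
        contrast_map[take] = les.contrast
        sigma_map[take] = les.texture_sigma
    values *= contrast_map
    textured = sigma_map > 0
    if np.any(textured):
        # mean-preserving lognormal: E[exp(N(-s^2/2, s^2))] = 1
        s = sigma_map[textured]
        values[textured] *= rng.lognormal(mean=-0.5 * s**2, sigma=s)
    return BFIMap(values=values, grid=grid)


def _truncnorm_diameter_cm(rng: np.random.Generator, mean_mm: float, sd_mm: float,
                           lo_mm: float = 3.0, *, hi_mm: float = 40.0) -> float:
    """Rejection-sampled truncated normal lesion diameter, returned in cm."""
    while True:
        d = rng.normal(mean_mm, sd_mm)
        if lo_mm <= d <= hi_mm:
            return d / 10.0


# Lesion-size priors (mm): clinical cohort statistics for benign and
# malignant maximal tumor size.
BENIGN_SIZE_MM = (11.4, 8.4)
MALIGNANT_SIZE_MM = (20.4, 9.7)
# Flow-contrast priors: malignant lesions show higher flow magnitude and
# heterogeneity than benign ones; malignant contrast reaches >10x background.
BENIGN_CONTRAST = (2.0, 5.0)
MALIGNANT_CONTRAST = (5.0, 15.0)
BENIGN_TEXTURE_SIGMA = 0.1
MALIGNANT_TEXTURE_SIGMA = 0.4


def make_cohort(
    n_benign: int,
    n_malignant: int,
    seed: int = 0,
    grid: VoxelGrid | None = None,
    background_bfi: float = 4.5e-8,
) -> list[tuple[str, BFIMap]]:
    """Labeled cohort of single-lesion phantoms.

    Benign-like phantoms draw lesion diameter from N(11.4, 8.4) mm truncated
    to [3, 40] mm, contrast from U(2, 5), and low texture; malignant-like draw
    diameter from N(20.4, 9.7) mm truncated, contrast from U(5, 15), and high
    texture.  Lesion centers fall in the shallow half of the slab under the
    probe.  Returns ``[(label, BFIMap), ...]`` with labels in
    {"benign", "malignant"}; bitwise-reproducible per seed.
    """
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("cohort counts must be nonnegative")
    grid = grid or VoxelGrid()
    rng = np.random.default_rng(seed)
    ext = grid.extent
    cohort: list[tuple[str, BFIMap]] = []
    specs = [("benign", BENIGN_SIZE_MM, BENIGN_CONTRAST, BENIGN_TEXTURE_SIGMA)] * n_benign
    specs += [("malignant", MALIGNANT_SIZE_MM, MALIGNANT_CONTRAST,
               MALIGNANT_TEXTURE_SIGMA)] * n_malignant
    # a lesion sphere must fit the slab: cap the size prior at the slab depth
    hi_mm = min(40.0, min(ext) * 10.0 - 1.0)
    for label, size_mm, contrast_rng, tex in specs:
        d = _truncnorm_diameter_cm(rng, *size_mm, hi_mm=hi_mm)
        r = d / 2.0
        # lateral: keep the sphere at least 1 cm (when possible) off the edge
        margin = min(1.0, (min(ext[0], ext[1]) / 2.0 - r) * 0.5)
        cx = rng.uniform(grid.origin[0] + r + margin, grid.origin[0] + ext[0] - r - margin)
        cy = rng.uniform(grid.origin[1] + r + margin, grid.origin[1] + ext[1] - r - margin)
        # depth: prefer the imaged 0.5-1.5 cm band, intersected with feasibility
        z_min, z_max = grid.origin[2] + r, grid.origin[2] + ext[2] - r
        zlo = min(max(z_min, grid.origin[2] + 0.5), z_max)
        zhi = max(min(z_max, grid.origin[2] + 1.5), zlo)
        cz = rng.uniform(zlo, zhi) if zhi > zlo else zlo
        lesion = LesionSpec(
            center=(float(cx), float(cy), float(cz)),
            diameter=d,
            contrast=float(rng.uniform(*contrast_rng)),
            texture_sigma=tex,
        )
        phantom_seed = int(rng.integers(0, 2**31 - 1))
        cohort.append(
            (label, make_phantom(grid, background_bfi, [lesion], seed=phantom_seed))
        )
    return cohort


def save_bfi_map(path: str | Path, bfi: BFIMap) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("/bfi", data=bfi.values)
        ds.attrs["nx"] = bfi.grid.nx
        ds.attrs["ny"] = bfi.grid.ny
        ds.attrs["nz"] = bfi.grid.nz
        ds.attrs["voxel_edge"] = bfi.grid.voxel_edge
        ds.attrs["origin"] = bfi.grid.origin


def load_bfi_map(path: str | Path) -> BFIMap:
    with h5py.File(path, "r") as f:
        ds = f["/bfi"]
        grid = VoxelGrid(
            nx=int(ds.attrs["nx"]),
            ny=int(ds.attrs["ny"]),
            nz=int(ds.attrs["nz"]),
            voxel_edge=float(ds.attrs["voxel_edge"]),
            origin=tuple(float(v) for v in ds.attrs["origin"]),
        )
        return BFIMap(values=ds[()], grid=grid)


def save_cohort_labels(path: str | Path, labels: Sequence[str]) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["id", "label"])
        for i, lab in enumerate(labels):
            w.writerow([i, lab])
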