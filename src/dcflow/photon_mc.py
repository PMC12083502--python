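"""Monte Carlo photon transport in the voxelized slab.

Photons are launched downward at each source position and random-walked with
exponentially distributed scattering steps.  Two transport modes are
supported: ``reduced_isotropic`` (isotropic scattering at mu_s = mu_s',
the similarity relation appropriate for the diffuse regime, and the default)
and ``henyey_greenstein`` (anisotropic phase function with
mu_s = mu_s'/(1-g)).  Absorption is applied analytically as
exp(-mu_a * path) so path-length statistics are unbiased (microscopic
Beer-Lambert; no roulette).  A photon exiting the top face within the
acceptance radius of a detector is recorded for that source-detector pair,
together with its per-voxel path lengths — the raw material of the
correlation forward model and the reconstruction sensitivity matrix.

Randomness uses an explicit xorshift64* generator so runs are
bitwise-reproducible for a given seed regardless of library versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import scipy.sparse as sp
from numba import njit

from .phantom import OpticalProperties, ProbeLayout, VoxelGrid

__all__ = [
    "MonteCarloConfig",
    "PairSensitivity",
    "SensitivityTensor",
    "run_monte_carlo",
    "diffusion_reflectance",
    "save_sensitivity",
    "load_sensitivity",
]


@dataclass(frozen=True)
class MonteCarloConfig:
    n_photons: int = 100_000
    seed: int = 0
    scattering_mode: str = "reduced_isotropic"  # or "henyey_greenstein"
    max_path: float = 100.0  # cm

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if self.max_path <= 0:
            raise ValueError("max_path must be positive")
        if self.scattering_mode not in ("reduced_isotropic", "henyey_greenstein"):
            raise ValueError(f"unknown scattering_mode {self.scattering_mode!r}")


@dataclass
class PairSensitivity:
    """Detected-photon record for one source-detector pair.

    ``weights`` are normalized to sum to 1 within the pair; ``total_weight``
    keeps the unnormalized detected-weight sum (for absolute reflectance).
    ``pathlengths`` is a CSR matrix of shape (n_detected, n_voxels), cm.
    """

    weights: np.ndarray
    pathlengths: sp.csr_matrix
    total_weight: float
    n_detected: int

    @property
    def empty(self) -> bool:
        return self.n_detected == 0


@dataclass
class SensitivityTensor:
    pairs: dict[tuple[int, int], PairSensitivity]
    grid: VoxelGrid
    optics: OpticalProperties
    probe: ProbeLayout
    n_photons: int
    seed: int

    def pair(self, m: int, j: int) -> PairSensitivity:
        return self.pairs[(m, j)]

    def nonempty_pairs(self) -> list[tuple[int, int]]:
        return [k for k, v in sorted(self.pairs.items()) if not v.empty]

    def reflectance(self, m: int, j: int) -> float:
        """Detected diffuse reflectance for pair (m, j), per cm^2 per photon."""
        area = np.pi * self.probe.acceptance_radius**2
        return self.pairs[(m, j)].total_weight / self.n_photons / area


@njit(cache=True, inline="always")
def _rng_next(state):
    # xorshift64*; state must stay nonzero uint64
    x = state
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x &= np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(27)
    return x


@njit(cache=True, inline="always")
def _rng_uniform(state):
    s = _rng_next(state)
    val = ((s * np.uint64(0x2545F4914F6CDD1D)) & np.uint64(0xFFFFFFFFFFFFFFFF)) >> np.uint64(11)
    return s, (np.float64(val) + 0.5) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _seed_state(seed, stream):
    # splitmix64 over (seed, stream) to decorrelate per-source streams
    z = (np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15) + np.uint64(stream + 1)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = z ^ (z >> np.uint64(31))
    if z == np.uint64(0):
        z = np.uint64(0x1234567887654321)
    return z


@njit(cache=True)
def _simulate_source(
    sx,
    sy,
    nx,
    ny,
    nz,
    edge,
    mus_t,
    mua,
    g,
    use_hg,
    det_xy,
    acc_r2,
    n_photons,
    max_path,
    state0,
    det_cap,
    len_cap,
):
    """Transport n_photons from one source; returns detected-photon records.

    Output arrays: per detected photon the detector index, unnormalized
    weight, and CSR-style per-voxel path lengths.  Returns -1 in the count
    slot on capacity overflow (caller retries with larger buffers).
    """
    n_vox = nx * ny * nz
    pl = np.zeros(n_vox, dtype=np.float64)
    touched = np.empty(n_vox, dtype=np.int64)

    det_j = np.empty(det_cap, dtype=np.int64)
    det_w = np.empty(det_cap, dtype=np.float64)
    indptr = np.empty(det_cap + 1, dtype=np.int64)
    vox_idx = np.empty(len_cap, dtype=np.int64)
    vox_len = np.empty(len_cap, dtype=np.float64)
    indptr[0] = 0

    n_det = 0
    nnz = 0
    state = state0
    n_detectors = det_xy.shape[0]

    xmax = nx * edge
    ymax = ny * edge
    zmax = nz * edge

    for _ in range(n_photons):
        # launch straight down into the tissue at the source position
        x = sx
        y = sy
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        ix = min(max(int(x / edge), 0), nx - 1)
        iy = min(max(int(y / edge), 0), ny - 1)
        iz = 0
        total_path = 0.0
        ntouched = 0
        alive = True
        exit_top = False

        while alive:
            state, u = _rng_uniform(state)
            step = -np.log(u) / mus_t
            # voxel-by-voxel traversal of this step
            remaining = step
            while remaining > 0.0:
                # distance to the next voxel boundary along each axis
                if ux > 0.0:
                    tx = ((ix + 1) * edge - x) / ux
                elif ux < 0.0:
                    tx = (ix * edge - x) / ux
                else:
                    tx = 1e30
                if uy > 0.0:
                    ty = ((iy + 1) * edge - y) / uy
                elif uy < 0.0:
                    ty = (iy * edge - y) / uy
                else:
                    ty = 1e30
                if uz > 0.0:
                    tz = ((iz + 1) * edge - z) / uz
                elif uz < 0.0:
                    tz = (iz * edge - z) / uz
                else:
                    tz = 1e30
                tmin = min(tx, ty, tz)
                if tmin < 0.0:
                    tmin = 0.0
                lin = iz * nx * ny + iy * nx + ix
                if tmin >= remaining:
                    # scatter inside the current voxel
                    if pl[lin] == 0.0 and remaining > 0.0:
                        touched[ntouched] = lin
                        ntouched += 1
                    pl[lin] += remaining
                    total_path += remaining
                    x += remaining * ux
                    y += remaining * uy
                    z += remaining * uz
                    remaining = 0.0
                else:
                    if pl[lin] == 0.0 and tmin > 0.0:
                        touched[ntouched] = lin
                        ntouched += 1
                    pl[lin] += tmin
                    total_path += tmin
                    x += tmin * ux
                    y += tmin * uy
                    z += tmin * uz
                    remaining -= tmin
                    # advance the voxel index across the crossed face
                    if tmin == tx:
                        ix += 1 if ux > 0.0 else -1
                        if ix < 0 or ix >= nx:
                            alive = False
                            break
                    elif tmin == ty:
                        iy += 1 if uy > 0.0 else -1
                        if iy < 0 or iy >= ny:
                            alive = False
                            break
                    else:
                        iz += 1 if uz > 0.0 else -1
                        if iz < 0:
                            alive = False
                            exit_top = True
                            break
                        if iz >= nz:
                            alive = False
                            break
            if total_path > max_path:
                alive = False
                exit_top = False
            if not alive:
                break
            # scatter: new direction
            if use_hg:
                state, u1 = _rng_uniform(state)
                if g != 0.0:
                    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
                    cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                else:
                    cost = 2.0 * u1 - 1.0
                if cost > 1.0:
                    cost = 1.0
                elif cost < -1.0:
                    cost = -1.0
                sint = np.sqrt(1.0 - cost * cost)
                state, u2 = _rng_uniform(state)
                phi = 2.0 * np.pi * u2
                cosp = np.cos(phi)
                sinp = np.sin(phi)
                if abs(uz) > 0.99999:
                    nux = sint * cosp
                    nuy = sint * sinp
                    nuz = cost * (1.0 if uz >= 0.0 else -1.0)
                else:
                    den = np.sqrt(1.0 - uz * uz)
                    nux = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                    nuy = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                    nuz = -sint * cosp * den + uz * cost
                ux, uy, uz = nux, nuy, nuz
            else:
                state, u1 = _rng_uniform(state)
                uz = 2.0 * u1 - 1.0
                sint = np.sqrt(max(0.0, 1.0 - uz * uz))
                state, u2 = _rng_uniform(state)
                phi = 2.0 * np.pi * u2
                ux = sint * np.cos(phi)
                uy = sint * np.sin(phi)

        if exit_top:
            # which detector disc (non-overlapping under default layouts)?
            hit = -1
            for j in range(n_detectors):
                dx = x - det_xy[j, 0]
                dy = y - det_xy[j, 1]
                if dx * dx + dy * dy <= acc_r2:
                    hit = j
                    break
            if hit >= 0:
                if n_det >= det_cap or nnz + ntouched > len_cap:
                    return det_j, det_w, indptr, vox_idx, vox_len, -1, 0
                det_j[n_det] = hit
                det_w[n_det] = np.exp(-mua * total_path)
                for t in range(ntouched):
                    lin = touched[t]
                    if pl[lin] > 0.0:
                        vox_idx[nnz] = lin
                        vox_len[nnz] = pl[lin]
                        nnz += 1
                n_det += 1
                indptr[n_det] = nnz
        # reset the per-photon accumulator
        for t in range(ntouched):
            pl[touched[t]] = 0.0

    return det_j, det_w, indptr, vox_idx, vox_len, n_det, nnz


def run_monte_carlo(
    grid: VoxelGrid,
    optics: OpticalProperties,
    probe: ProbeLayout,
    mc: MonteCarloConfig,
) -> SensitivityTensor:
    """Run the voxel Monte Carlo for every source and assemble the
    per-pair photon weights and path-length records."""
    if optics.anisotropy_g >= 1.0:
        raise ValueError("anisotropy must be < 1")
    if mc.scattering_mode == "henyey_greenstein":
        mus_t = optics.mus_prime / (1.0 - optics.anisotropy_g)
        g = optics.anisotropy_g
        use_hg = True
    else:
        mus_t = optics.mus_prime
        g = 0.0
        use_hg = False

    det_xy = np.asarray(probe.detector_positions, dtype=float)
    acc_r2 = probe.acceptance_radius**2
    pairs: dict[tuple[int, int], PairSensitivity] = {}

    for m, (sx, sy) in enumerate(probe.source_positions):
        state0 = np.uint64(_seed_state(np.int64(mc.seed), np.int64(m)))
        det_cap = max(1024, mc.n_photons // 20)
        len_cap = det_cap * 256
        while True:
            out = _simulate_source(
                float(sx),
                float(sy),
                grid.nx,
                grid.ny,
                grid.nz,
                grid.voxel_edge,
                mus_t,
                optics.mua,
                g,
                use_hg,
                det_xy,
                acc_r2,
                mc.n_photons,
                mc.max_path,
                state0,
                det_cap,
                len_cap,
            )
            det_j, det_w, indptr, vox_idx, vox_len, n_det, nnz = out
            if n_det >= 0:
                break
            det_cap *= 2
            len_cap *= 2

        det_j = det_j[:n_det]
        det_w = det_w[:n_det]
        indptr = indptr[: n_det + 1]
        csr_all = sp.csr_matrix(
            (vox_len[:nnz], vox_idx[:nnz], indptr),
            shape=(n_det, grid.n_voxels),
        )
        for j in range(probe.n_detectors):
            sel = np.flatnonzero(det_j == j)
            w = det_w[sel]
            total = float(w.sum())
            pairs[(m, j)] = PairSensitivity(
                weights=w / total if total > 0 else w,
                pathlengths=csr_all[sel],
                total_weight=total,
                n_detected=int(sel.size),
            )

    return SensitivityTensor(
        pairs=pairs,
        grid=grid,
        optics=optics,
        probe=probe,
        n_photons=mc.n_photons,
        seed=mc.seed,
    )


def diffusion_reflectance(rho: np.ndarray | float, optics: OpticalProperties) -> np.ndarray:
    """Steady-state diffuse reflectance R(rho) (cm^-2) of a semi-infinite
    medium with an index-matched extrapolated boundary.

    Standard dipole solution: an isotropic source at depth z0 = 1/(mua+mus')
    and its negative image mirrored about the extrapolated boundary at
    z = -2*zb with zb = 2*A*D, A = 1 (index matched).  Serves as the
    independent closed-form check of the Monte Carlo at separations where
    diffusion theory is valid (rho >= 2 cm here).
    """
    rho = np.asarray(rho, dtype=float)
    mutr = optics.mua + optics.mus_prime
    z0 = 1.0 / mutr
    D = 1.0 / (3.0 * mutr)
    mueff = np.sqrt(3.0 * optics.mua * mutr)
    zb = 2.0 * D  # A = 1
    r1 = np.sqrt(z0**2 + rho**2)
    r2 = np.sqrt((z0 + 2 * zb) ** 2 + rho**2)
    term1 = z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1**2
    term2 = (z0 + 2 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2**2
    return (term1 + term2) / (4.0 * np.pi)


def diffusion_reflectance_disc(
    rho: float, disc_radius: float, optics: OpticalProperties, n_quad: int = 64
) -> float:
    """Diffusion-theory reflectance averaged over a detector disc of radius
    ``disc_radius`` centered at separation ``rho`` (polar quadrature).

    The Monte Carlo observable is the mean reflectance over the acceptance
    aperture, so the closed form is averaged over the same disc before
    comparison.
    """
    r = (np.arange(n_quad) + 0.5) / n_quad * disc_radius
    th = (np.arange(n_quad) + 0.5) / n_quad * 2 * np.pi
    rr, tt = np.meshgrid(r, th, indexing="ij")
    dist = np.sqrt((rho + rr * np.cos(tt)) ** 2 + (rr * np.sin(tt)) ** 2)
    vals = diffusion_reflectance(dist, optics)
    # area-weighted mean: weight each radial shell by r
    return float((vals * rr).sum() / rr.sum())


def reflectance_validation(
    optics: OpticalProperties,
    separations: np.ndarray | list[float] = (2.0, 2.5, 3.0, 3.5, 4.0),
    n_photons: int = 1_000_000,
    seed: int = 0,
    scattering_mode: str = "reduced_isotropic",
    disc_radius: float = 0.25,
    detectors_per_ring: int = 16,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte Carlo vs diffusion-theory reflectance at given separations.

    Emulates a semi-infinite half-space with a large deep slab (22 x 22 x 12
    cm), one source at the center, and rings of detector discs at each
    separation.  Returns ``(R_mc, R_theory)`` per separation, both in cm^-2
    per launched photon; ``R_theory`` is the dipole solution averaged over
    the detector aperture.
    """
    separations = np.asarray(separations, dtype=float)
    if separations.size > 1 and np.min(np.diff(np.sort(separations))) < 2 * disc_radius:
        raise ValueError("rings closer than a disc diameter would overlap")
    grid = VoxelGrid(nx=44, ny=44, nz=24, voxel_edge=0.5)
    cx = cy = 11.0
    det: list[tuple[float, float]] = []
    ring_of: list[int] = []
    for k, rho in enumerate(separations):
        for a in 2 * np.pi * np.arange(detectors_per_ring) / detectors_per_ring:
            det.append((cx + rho * float(np.cos(a)), cy + rho * float(np.sin(a))))
            ring_of.append(k)
    probe = ProbeLayout(
        source_positions=((cx, cy),),
        detector_positions=tuple(det),
        acceptance_radius=disc_radius,
    )
    mc = MonteCarloConfig(
        n_photons=n_photons, seed=seed, scattering_mode=scattering_mode, max_path=500.0
    )
    sens = run_monte_carlo(grid, optics, probe, mc)
    area = np.pi * disc_radius**2
    r_mc = np.zeros(len(separations))
    for j, k in enumerate(ring_of):
        r_mc[k] += sens.pairs[(0, j)].total_weight
    r_mc /= n_photons * area * detectors_per_ring
    r_th = np.array([diffusion_reflectance_disc(rho, disc_radius, optics) for rho in separations])
    return r_mc, r_th


def save_sensitivity(path: str | Path, sens: SensitivityTensor) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["nx"], f.attrs["ny"], f.attrs["nz"] = sens.grid.nx, sens.grid.ny, sens.grid.nz
        f.attrs["voxel_edge"] = sens.grid.voxel_edge
        f.attrs["origin"] = sens.grid.origin
        f.attrs["mus_prime"] = sens.optics.mus_prime
        f.attrs["mua"] = sens.optics.mua
        f.attrs["refractive_index"] = sens.optics.refractive_index
        f.attrs["anisotropy_g"] = sens.optics.anisotropy_g
        f.attrs["wavelength"] = sens.optics.wavelength
        f.attrs["sources"] = np.asarray(sens.probe.source_positions)
        f.attrs["detectors"] = np.asarray(sens.probe.detector_positions)
        f.attrs["acceptance_radius"] = sens.probe.acceptance_radius
        f.attrs["n_photons"] = sens.n_photons
        f.attrs["seed"] = sens.seed
        grp = f.create_group("pairs")
        for (m, j), p in sens.pairs.items():
            g = grp.create_group(f"m{m}_j{j}")
            g.create_dataset("weights", data=p.weights)
            g.create_dataset("indptr", data=p.pathlengths.indptr)
            g.create_dataset("indices", data=p.pathlengths.indices)
            g.create_dataset("pathlengths", data=p.pathlengths.data)
            g.attrs["total_weight"] = p.total_weight
            g.attrs["n_detected"] = p.n_detected


def load_sensitivity(path: str | Path) -> SensitivityTensor:
    with h5py.File(path, "r") as f:
        grid = VoxelGrid(
            nx=int(f.attrs["nx"]),
            ny=int(f.attrs["ny"]),
            nz=int(f.attrs["nz"]),
            voxel_edge=float(f.attrs["voxel_edge"]),
            origin=tuple(float(v) for v in f.attrs["origin"]),
        )
        optics = OpticalProperties(
            mus_prime=float(f.attrs["mus_prime"]),
            mua=float(f.attrs["mua"]),
            refractive_index=float(f.attrs["refractive_index"]),
            anisotropy_g=float(f.attrs["anisotropy_g"]),
            wavelength=float(f.attrs["wavelength"]),
        )
        probe = ProbeLayout(
            source_positions=tuple(map(tuple, f.attrs["sources"])),
            detector_positions=tuple(map(tuple, f.attrs["detectors"])),
            acceptance_radius=float(f.attrs["acceptance_radius"]),
        )
        pairs = {}
        for name, g in f["pairs"].items():
            m, j = name[1:].split("_j")
            n_det = int(g.attrs["n_detected"])
            csr = sp.csr_matrix(
                (g["pathlengths"][()], g["indices"][()], g["indptr"][()]),
                shape=(n_det, grid.n_voxels),
            )
            pairs[(int(m), int(j))] = PairSensitivity(
                weights=g["weights"][()],
                pathlengths=csr,
                total_weight=float(g.attrs["total_weight"]),
                n_detected=n_det,
            )
        return SensitivityTensor(
            pairs=pairs,
            grid=grid,
            optics=optics,
            probe=probe,
            n_photons=int(f.attrs["n_photons"]),
            seed=int(f.attrs["seed"]),
        )
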