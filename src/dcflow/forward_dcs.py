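"""Forward synthesis of g1/g2 autocorrelation curves and the acquisition schedule.

The exact Monte Carlo forward model for the normalized field autocorrelation
of source-detector pair (m, j) is

    g1(m, j, tau) = sum_q w(q,m,j) * exp(-2 tau sum_i k0^2 alphaDb(i) s(i,q,m,j) mus'(i))

i.e. each detected photon decorrelates at a rate set by the flow-weighted
path it took through the tissue.  The intensity autocorrelation follows from
the Siegert relation g2 = 1 + beta*g1^2.  The acquisition simulator emulates
the instrument schedule: an optical switch steps through the sources, each
dwell records the parallel detectors at 1 Hz for 15 s, and the 15 curves per
pair are averaged (after Siegert inversion) into one g1 curve per pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .phantom import BFIMap, OpticalProperties
from .photon_mc import SensitivityTensor

__all__ = [
    "DelayGrid",
    "CorrelationCurve",
    "AcquisitionFrame",
    "NoiseConfig",
    "synth_g1",
    "decay_rates",
    "siegert_g2",
    "invert_siegert",
    "add_noise",
    "simulate_acquisition",
    "save_curves",
    "load_curves",
    "curves_to_csv",
]


@dataclass(frozen=True)
class DelayGrid:
    """Geometric ladder of correlator delay times (s)."""

    taus: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e-7, 1e-1, 64)
    )

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        if taus.ndim != 1 or taus.size < 2:
            raise ValueError("need a 1-D grid of at least 2 delays")
        if np.any(taus <= 0) or np.any(np.diff(taus) <= 0):
            raise ValueError("delays must be positive and strictly increasing")
        object.__setattr__(self, "taus", taus)


@dataclass
class CorrelationCurve:
    kind: str  # "g1" or "g2"
    taus: np.ndarray
    values: np.ndarray
    pair: tuple[int, int]
    beta: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("g1", "g2"):
            raise ValueError("kind must be 'g1' or 'g2'")
        self.taus = np.asarray(self.taus, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.taus.shape != self.values.shape:
            raise ValueError("taus and values must align")


@dataclass
class AcquisitionFrame:
    """One complete acquisition: an averaged g1 curve per S-D pair."""

    curves: dict[tuple[int, int], CorrelationCurve]
    raw_count: int  # raw 1-Hz curves averaged per pair
    duration: float  # s


@dataclass(frozen=True)
class NoiseConfig:
    sigma: float = 5e-3  # additive Gaussian std per tau bin on g2

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def decay_rates(
    sens: SensitivityTensor, bfi: BFIMap, optics: OpticalProperties,
    pair: tuple[int, int],
) -> np.ndarray:
    """Per detected photon, the decorrelation rate
    B_q = sum_i k0^2 alphaDb(i) s(i,q) mus'(i)   (s^-1)."""
    p = sens.pair(*pair)
    if p.empty:
        raise ValueError(f"pair {pair} recorded no photons")
    return optics.k0**2 * optics.mus_prime * (p.pathlengths @ bfi.values)


def synth_g1(
    sens: SensitivityTensor,
    bfi: BFIMap,
    optics: OpticalProperties,
    grid: DelayGrid,
    beta: float = 0.5,
) -> dict[tuple[int, int], CorrelationCurve]:
    """Noiseless g1 curves for every nonempty pair via the exact forward model."""
    if bfi.grid.n_voxels != sens.grid.n_voxels:
        raise ValueError("BFI map and sensitivity tensor use different grids")
    curves = {}
    for pair in sorted(sens.pairs):
        p = sens.pair(*pair)
        if p.empty:
            warnings.warn(f"pair {pair} is empty; skipped")
            continue
        B = decay_rates(sens, bfi, optics, pair)
        vals = np.exp(-2.0 * np.outer(grid.taus, B)) @ p.weights
        curves[pair] = CorrelationCurve("g1", grid.taus, vals, pair, beta)
    return curves


def siegert_g2(curve: CorrelationCurve, beta: float | None = None) -> CorrelationCurve:
    """g2 = 1 + beta * g1^2."""
    if curve.kind != "g1":
        raise ValueError("siegert_g2 expects a g1 curve")
    b = curve.beta if beta is None else beta
    if not (0 < b <= 1):
        raise ValueError("beta must lie in (0, 1]")
    return CorrelationCurve("g2", curve.taus, 1.0 + b * curve.values**2, curve.pair, b)


def invert_siegert(curve: CorrelationCurve, beta: float | None = None) -> CorrelationCurve:
    """g1 = sqrt((g2 - 1)/beta), taking the nonnegative root; g2 values that
    noise pushed below 1 are clipped to 1 first."""
    if curve.kind != "g2":
        raise ValueError("invert_siegert expects a g2 curve")
    b = curve.beta if beta is None else beta
    if not (0 < b <= 1):
        raise ValueError("beta must lie in (0, 1]")
    vals = np.maximum(curve.values, 1.0)
    return CorrelationCurve("g1", curve.taus, np.sqrt((vals - 1.0) / b), curve.pair, b)


def add_noise(curve: CorrelationCurve, sigma: float, seed: int) -> CorrelationCurve:
    """Additive Gaussian noise per tau bin on a g2 curve, clipped to >= 1."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if curve.kind != "g2":
        raise ValueError("noise is applied to measured g2 curves")
    if sigma == 0:
        return CorrelationCurve("g2", curve.taus, curve.values.copy(), curve.pair, curve.beta)
    rng = np.random.default_rng(seed)
    vals = np.maximum(curve.values + rng.normal(0.0, sigma, curve.values.shape), 1.0)
    return CorrelationCurve("g2", curve.taus, vals, curve.pair, curve.beta)


def simulate_acquisition(
    sens: SensitivityTensor,
    bfi: BFIMap,
    optics: OpticalProperties,
    grid: DelayGrid | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    beta: float = 0.5,
    curves_per_dwell: int = 15,
) -> AcquisitionFrame:
    """Emulate one full acquisition sweep.

    For each switch position (source) the parallel detectors record
    ``curves_per_dwell`` one-second g2 curves with independent noise; under
    the defaults (8 sources x 6 detectors x 15 s) that is 720 raw curves in
    a 120-s schedule.  Each pair's raw curves are Siegert-inverted and
    averaged into a single g1 curve.
    """
    grid = grid or DelayGrid()
    noise = noise or NoiseConfig()
    clean = synth_g1(sens, bfi, optics, grid, beta)
    rng = np.random.default_rng(seed)
    curves: dict[tuple[int, int], CorrelationCurve] = {}
    for pair in sorted(clean):
        g2 = siegert_g2(clean[pair])
        acc = np.zeros_like(g2.values)
        for _ in range(curves_per_dwell):
            noisy = add_noise(g2, noise.sigma, int(rng.integers(0, 2**31 - 1)))
            acc += invert_siegert(noisy).values
        curves[pair] = CorrelationCurve(
            "g1", grid.taus, acc / curves_per_dwell, pair, beta
        )
    return AcquisitionFrame(
        curves=curves,
        raw_count=curves_per_dwell,
        duration=float(sens.probe.n_sources * curves_per_dwell),
    )


def save_curves(path, frame: AcquisitionFrame) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["raw_count"] = frame.raw_count
        f.attrs["duration"] = frame.duration
        grp = f.create_group("curves")
        for (m, j), c in frame.curves.items():
            g = grp.create_group(f"m{m}_j{j}")
            g.create_dataset("tau", data=c.taus)
            g.create_dataset("g1", data=c.values)
            g.attrs["beta"] = c.beta


def curves_to_csv(path, frame: AcquisitionFrame) -> None:
    """Flat CSV export of the averaged curves (columns m, j, tau, value)."""
    import csv

    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["m", "j", "tau", "value"])
        for (m, j), c in sorted(frame.curves.items()):
            for tau, val in zip(c.taus, c.values):
                w.writerow([m, j, repr(float(tau)), repr(float(val))])


def load_curves(path) -> AcquisitionFrame:
    with h5py.File(path, "r") as f:
        curves = {}
        for name, g in f["curves"].items():
            m, j = name[1:].split("_j")
            pair = (int(m), int(j))
            curves[pair] = CorrelationCurve(
                "g1", g["tau"][()], g["g1"][()], pair, float(g.attrs["beta"])
            )
        return AcquisitionFrame(
            curves=curves,
            raw_count=int(f.attrs["raw_count"]),
            duration=float(f.attrs["duration"]),
        )
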