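"""End-to-end orchestration and YAML configuration.

Glue for the full chain: cohort generation -> acquisition simulation ->
NL-DCT reconstruction -> imaging -> feature table -> classification.
The YAML config mirrors the object model with sections ``grid``, ``optics``,
``probe``, ``cohort``, ``acquisition`` and ``recon``; omitted keys fall back
to the package defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import FEATURE_NAMES, compute_features, features_to_frame
from .forward_dcs import NoiseConfig, simulate_acquisition
from .imaging import take_slice
from .nldct import ReconConfig, reconstruct
from .phantom import (
    BFIMap,
    OpticalProperties,
    ProbeLayout,
    VoxelGrid,
    make_cohort,
    make_probe,
)
from .photon_mc import MonteCarloConfig, SensitivityTensor, run_monte_carlo

__all__ = ["PipelineConfig", "load_config", "cohort_feature_table",
           "default_sensitivity"]


@dataclass
class PipelineConfig:
    grid: VoxelGrid = field(default_factory=VoxelGrid)
    optics: OpticalProperties = field(default_factory=OpticalProperties)
    probe: ProbeLayout = field(default_factory=make_probe)
    mc: MonteCarloConfig = field(default_factory=MonteCarloConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    n_benign: int = 38
    n_malignant: int = 21
    background_bfi: float = 4.5e-8


def load_config(path: str | Path | None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (None -> all defaults)."""
    if path is None:
        return PipelineConfig()
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    cfg = PipelineConfig()
    if "grid" in raw:
        cfg.grid = VoxelGrid(**raw["grid"])
    if "optics" in raw:
        cfg.optics = OpticalProperties(**raw["optics"])
    if "probe" in raw:
        cfg.probe = make_probe(**raw["probe"])
    if "mc" in raw:
        cfg.mc = MonteCarloConfig(**raw["mc"])
    if "recon" in raw:
        cfg.recon = ReconConfig(**raw["recon"])
    if "acquisition" in raw:
        cfg.noise = NoiseConfig(**raw["acquisition"])
    cohort = raw.get("cohort", {})
    cfg.n_benign = int(cohort.get("n_benign", cfg.n_benign))
    cfg.n_malignant = int(cohort.get("n_malignant", cfg.n_malignant))
    cfg.background_bfi = float(cohort.get("background_bfi", cfg.background_bfi))
    return cfg


def default_sensitivity(
    n_photons: int = 100_000, seed: int = 0, config: PipelineConfig | None = None
) -> SensitivityTensor:
    """Monte Carlo sensitivity tensor for the default slab and probe."""
    cfg = config or PipelineConfig()
    mc = MonteCarloConfig(
        n_photons=n_photons,
        seed=seed,
        scattering_mode=cfg.mc.scattering_mode,
        max_path=cfg.mc.max_path,
    )
    return run_monte_carlo(cfg.grid, cfg.optics, cfg.probe, mc)


def cohort_feature_table(
    sens: SensitivityTensor,
    cohort: list[tuple[str, BFIMap]],
    optics: OpticalProperties | None = None,
    recon: ReconConfig | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate, reconstruct and featurize every phantom in a cohort.

    Returns a table with ``id``, the 12 feature columns, and ``label``.
    Per-phantom acquisition noise seeds derive from ``seed``.
    """
    optics = optics or OpticalProperties()
    recon = recon or ReconConfig()
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)
    vectors, labels = [], []
    for label, bfi in cohort:
        frame = simulate_acquisition(
            sens, bfi, optics, noise=noise, seed=int(rng.integers(0, 2**31 - 1))
        )
        rbfi, _ = reconstruct(frame, sens, optics, recon)
        vectors.append(compute_features(take_slice(rbfi, layer=2)))
        labels.append(label)
    return features_to_frame(vectors, labels=labels, ids=range(len(labels)))
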