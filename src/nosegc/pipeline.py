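"""Config-driven pipeline: geometry -> flow -> absorption -> chromatography.

The pipeline is fully deterministic under fixed seeds; every output bundle
carries a manifest recording the package version, the resolved config and
its hash, so any row in any CSV is traceable to the configuration that
produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .geometry import (
    AnteriorSpec,
    PosteriorSpec,
    NasalNetwork,
    build_parallel_coil_network,
    build_straight_tube_network,
    cat_default_network,
    mean_path_length,
    surface_area_profile,
)
from .airflow import BreathingCondition, dm_fraction, regime_report, solve_network_flow
from .absorption import anterior_depletion_experiment, solubility_sweep, solve_network_absorption
from .chromatography import (
    SpeciesCalibration,
    builtin_calibration,
    load_calibration,
    species_comparison,
)
from .odorants import Odorant, builtin_odorant_table, read_odorant_table

__all__ = [
    "GeometryConfig",
    "BreathingConfig",
    "AbsorptionConfig",
    "ChromatographyConfig",
    "PipelineConfig",
    "load_config",
    "run_pipeline",
]


class GeometryConfig(BaseModel):
    generator: Literal["cat_parallel_coil", "parallel_coil", "straight_tube"] = "cat_parallel_coil"
    seed: int = 0
    parameters: dict = Field(default_factory=dict)

    def build(self) -> NasalNetwork:
        if self.generator == "cat_parallel_coil":
            return cat_default_network(seed=self.seed)
        if self.generator == "parallel_coil":
            params = dict(self.parameters)
            params["anterior_spec"] = AnteriorSpec(**params["anterior_spec"])
            params["posterior_spec"] = PosteriorSpec(**params["posterior_spec"])
            return build_parallel_coil_network(seed=self.seed, **params)
        return build_straight_tube_network(**self.parameters)


class BreathingConfig(BaseModel):
    total_flow: float = 22e-6
    frequency: float = 1.0
    kinematic_viscosity: float = 1.5e-5

    def condition(self) -> BreathingCondition:
        return BreathingCondition(
            total_flow=self.total_flow,
            frequency=self.frequency,
            kinematic_viscosity=self.kinematic_viscosity,
        )


class AbsorptionConfig(BaseModel):
    odorant_table: str | None = None  # path to CSV; None -> builtin fixture table
    odorants: list[str] = Field(default_factory=list)  # subset by name; empty -> all
    beta_decades: tuple[float, float] = (-5.0, 2.0)
    beta_points: int = 29
    run_sweep: bool = True
    run_depletion: bool = True

    def load_odorants(self) -> list[Odorant]:
        table = (
            read_odorant_table(self.odorant_table)
            if self.odorant_table
            else builtin_odorant_table()
        )
        if self.odorants:
            table = [o for o in table if o.name in self.odorants]
            if not table:
                raise ValueError("no odorant in the table matches the requested names")
        return table

    def beta_grid(self) -> np.ndarray:
        lo, hi = self.beta_decades
        return np.logspace(lo, hi, self.beta_points)


class ChromatographyConfig(BaseModel):
    calibrations: list[str] = Field(
        default_factory=lambda: ["cat", "rat", "human", "straight_tube"]
    )

    def load(self) -> list[SpeciesCalibration]:
        out = []
        for item in self.calibrations:
            if item.endswith((".yaml", ".yml")):
                out.append(load_calibration(item))
            else:
                out.append(builtin_calibration(item))
        return out


class PipelineConfig(BaseModel):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    breathing: BreathingConfig = Field(default_factory=BreathingConfig)
    absorption: AbsorptionConfig = Field(default_factory=AbsorptionConfig)
    chromatography: ChromatographyConfig = Field(default_factory=ChromatographyConfig)
    n_paths: int = 10
    area_profile_bin_width: float = 0.005

    @field_validator("n_paths")
    @classmethod
    def _positive_paths(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_paths must be >= 1")
        return v


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(payload)


def _config_hash(config: PipelineConfig) -> str:
    canon = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run the full pipeline and write a report bundle to ``out_dir``.

    Returns the manifest dict.  ``seed`` overrides the geometry seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = config.model_copy(deep=True)
        config.geometry.seed = seed

    net = config.geometry.build()
    net.write_json(out / "network.json")

    condition = config.breathing.condition()
    flow = solve_network_flow(net, condition)
    flow.write_csv(net, out / "flow.csv")
    regime = regime_report(net, flow, condition)
    regime.table.to_csv(out / "regime.csv", index=False)

    profile = surface_area_profile(net, config.area_profile_bin_width)
    profile_frame = profile.fractions.copy()
    profile_frame.insert(0, "bin_center", profile.bin_centers)
    profile_frame.insert(1, "total_area", profile.total_area)
    profile_frame.to_csv(out / "area_profile.csv", index=False)

    summary: dict = {
        "mean_olfactory_path_length": mean_path_length(net, config.n_paths, config.geometry.seed),
        "quasi_steady": regime.quasi_steady,
        "laminar": regime.laminar,
    }
    try:
        summary["dm_fraction"] = dm_fraction(flow, net)
    except Exception:
        summary["dm_fraction"] = None  # e.g. straight tube has no DM segment

    odorants = config.absorption.load_odorants()
    for odorant in odorants:
        result = solve_network_absorption(net, flow, odorant)
        result.write_csv(out / f"absorption_{odorant.name}.csv")
    if config.absorption.run_depletion:
        exp = anterior_depletion_experiment(net, flow, odorants[0])
        exp.region_table().to_csv(out / "depletion.csv", index=False)
    if config.absorption.run_sweep:
        sweep = solubility_sweep(net, flow, odorants[0], config.absorption.beta_grid())
        sweep.write_csv(out / "solubility_sweep.csv")
        summary["sweep_peak_beta"] = sweep.peak_beta

    calibrations = config.chromatography.load()
    for cal in calibrations:
        cal.plate_curve().write_csv(out / f"plate_curve_{cal.name}.csv")
    if len(calibrations) >= 2 and sum(c.reference for c in calibrations) == 1:
        species_comparison(calibrations).to_csv(out / "comparison.csv", index=False)

    manifest = {
        "package": "nosegc",
        "version": __version__,
        "config": config.model_dump(mode="json"),
        "config_hash": _config_hash(config),
        "summary": summary,
        "outputs": sorted(
            p.name for p in out.iterdir() if p.suffix in {".csv", ".json"} and p.name != "manifest.json"
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
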