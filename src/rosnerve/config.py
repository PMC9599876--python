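"""Configuration schema, validation and model construction.

Simulations are described by a single YAML document with three blocks —
``geometry``, ``biochem`` and ``run`` — validated strictly (unknown keys are
rejected) so that a config file is a complete, reproducible record of a run.
The resolved configuration, with every default filled in, is echoed to a
lockfile next to the outputs.

Randomness is controlled by one master seed split into named independent
streams (axon placement, mitochondria, dynamics, permutation tests), so a
sweep can vary one stream without perturbing the others.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import geometry as geo
from .dynamics import BiochemParams

__all__ = [
    "SimulationConfig", "GeometryConfig", "BiochemConfig", "RunConfig",
    "load_config", "seed_streams", "build_model", "to_biochem_params",
    "write_lockfile", "config_to_yaml",
]

_STREAMS = ("placement", "mito", "dynamics", "permutation")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OctantLawConfig(_Strict):
    median_um: float = Field(gt=0)
    sigma_log: float = Field(ge=0)
    density_per_um2: float = Field(ge=0)


class DiametersConfig(_Strict):
    """Per-octant diameter laws; omitted octants fall back to the default
    temporally-skewed distribution set."""

    per_octant: dict[str, OctantLawConfig] | None = None
    min_diameter_um: float = 0.5
    max_diameter_um: float = 2.5
    density_scale: float = 1.0

    def build(self) -> geo.DiameterDistribution:
        base = geo.DiameterDistribution.default(self.density_scale)
        laws = dict(base.laws)
        if self.per_octant:
            for name, law in self.per_octant.items():
                if name not in geo.OCTANTS:
                    raise ValueError(f"unknown octant {name!r}")
                laws[name] = geo.OctantLaw(law.median_um, law.sigma_log,
                                           law.density_per_um2)
        return geo.DiameterDistribution(
            laws=laws, min_diameter_um=self.min_diameter_um,
            max_diameter_um=self.max_diameter_um)


class SlabConfig(_Strict):
    zone: str
    thickness_um: float = Field(gt=0)


class GeometryConfig(_Strict):
    nerve_radius_um: float | None = Field(default=15.0, gt=0)
    model_percent: float | None = Field(default=None, gt=0)
    res_xy: float = Field(default=7.0, gt=0)
    res_z: float = Field(default=1.0, gt=0)
    layout: list[SlabConfig] | None = None
    layout_preset: str | None = None       # "abridged" | "node_slice"
    segment_um: float = Field(default=5.0, gt=0)
    paranodal_extent_um: float = Field(default=2.0, ge=0)
    diameters: DiametersConfig = Field(default_factory=DiametersConfig)
    mito_axon_pct: float = Field(default=4.0, ge=0, le=100)
    mito_glia_pct: float = Field(default=0.0, ge=0, le=100)
    max_attempts: int = Field(default=2000, gt=0)

    @model_validator(mode="after")
    def _check(self):
        if self.layout is not None and self.layout_preset is not None:
            raise ValueError("give either layout or layout_preset, not both")
        if self.nerve_radius_um is None and self.model_percent is None:
            raise ValueError("need nerve_radius_um or model_percent")
        return self

    def radius_um(self) -> float:
        if self.model_percent is not None:
            return geo.reduced_model_radius(self.model_percent)
        return float(self.nerve_radius_um)

    def slabs(self) -> list[geo.Slab] | None:
        if self.layout_preset == "abridged":
            return geo.abridged_layout()
        if self.layout_preset == "node_slice":
            return geo.node_slice_layout()
        if self.layout_preset is not None:
            raise ValueError(f"unknown layout preset {self.layout_preset!r}")
        if self.layout is None:
            return None
        return [geo.Slab(s.zone, s.thickness_um) for s in self.layout]


class BiochemConfig(_Strict):
    d_free_um2_s: float = 2000.0
    p_m_um_s: float | None = None          # default by species: h2o2 20, o2- 0
    p_m_node_um_s: float | None = None
    myelin_attenuation: float = 20.0
    rs_intra: float = 10.0
    rs_extra: float = 10.0
    rs_mito_factor: float = 5.0
    zone_rs: dict[str, float] = Field(default_factory=dict)
    rp_h: float = 10.0
    production_model: str = "RP_SAME"
    alpha: float = 1.0
    firing_rate_hz: float = 1.0
    stress_mode: str = "NF_RP"
    stress_factor: float | None = None
    glia_rp_h: float | None = None
    glia_stress_mode: str | None = None
    glia_stress_factor: float | None = None
    stress_threshold_nM: float = 100.0
    death_threshold_nM: float = 1000.0
    stress_dwell_s: float = 60.0
    allow_recovery: bool = True
    paranodal_fraction: float = 0.75
    internodal_fraction: float = 0.05
    c0_nM: float = 0.0
    segment_aggregate: str = "mean"


class RunConfig(_Strict):
    species: str = "h2o2"                  # "h2o2" | "o2minus"
    t_max_s: float = Field(default=10.0, gt=0)
    tol: float = Field(default=1e-4, gt=0)
    cadence: int = Field(default=10, gt=0)
    seed: int = 0
    fast_forward_timers: bool = True
    out: str | None = None

    @model_validator(mode="after")
    def _check(self):
        if self.species not in ("h2o2", "o2minus"):
            raise ValueError("species must be 'h2o2' or 'o2minus'")
        return self


class SimulationConfig(_Strict):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    biochem: BiochemConfig = Field(default_factory=BiochemConfig)
    run: RunConfig = Field(default_factory=RunConfig)

    @model_validator(mode="after")
    def _validate_biochem(self):
        # constructing BiochemParams applies the domain invariants
        # (threshold ordering, the ±30 % stress-factor bound, ...)
        to_biochem_params(self)
        return self


def to_biochem_params(config: SimulationConfig) -> BiochemParams:
    """Resolve the biochem block (plus species defaults) into BiochemParams.

    The membrane permeability default is species-dependent: ~20 µm/s for
    hydrogen peroxide, 0 for superoxide (charged, membrane-impermeant).
    """
    b = config.biochem
    p_m = b.p_m_um_s
    if p_m is None:
        p_m = 0.0 if config.run.species == "o2minus" else 20.0
    kwargs = b.model_dump()
    kwargs["p_m_um_s"] = p_m
    kwargs["mito_axon_pct"] = config.geometry.mito_axon_pct
    return BiochemParams(**kwargs)


def seed_streams(seed: int) -> dict[str, np.random.Generator]:
    """Named independent random streams derived from one master seed."""
    root = np.random.SeedSequence(int(seed))
    children = root.spawn(len(_STREAMS))
    return {name: np.random.default_rng(child)
            for name, child in zip(_STREAMS, children)}


def build_model(config: SimulationConfig,
                streams: dict[str, np.random.Generator] | None = None
                ) -> geo.NerveModel:
    """Construct the nerve model a config describes (placement, raster, mito)."""
    g = config.geometry
    if streams is None:
        streams = seed_streams(config.run.seed)
    radius = g.radius_um()
    axons = geo.place_axons(radius, g.diameters.build(),
                            rng_seed=streams["placement"],
                            max_attempts=g.max_attempts)
    slabs = g.slabs()
    if slabs is None:
        model = geo.rasterize_model(axons, res_xy=g.res_xy, res_z=g.res_z,
                                    nz=1, nerve_radius_um=radius,
                                    segment_um=g.segment_um,
                                    paranodal_extent_um=g.paranodal_extent_um)
    else:
        model = geo.build_longitudinal_model(
            slabs, axons, res_xy=g.res_xy, res_z=g.res_z,
            nerve_radius_um=radius, segment_um=g.segment_um,
            paranodal_extent_um=g.paranodal_extent_um)
    return geo.place_mitochondria(model, g.mito_axon_pct, g.mito_glia_pct,
                                  rng_seed=streams["mito"])


def config_to_yaml(config: SimulationConfig) -> str:
    return yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML configuration file.

    Schema violations raise with field-level messages; unknown keys are
    rejected rather than silently ignored.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    # underscore-prefixed top-level keys are lockfile metadata, not schema
    data = {k: v for k, v in data.items() if not str(k).startswith("_")}
    return SimulationConfig.model_validate(data)


def write_lockfile(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Echo the fully resolved config (and tool version) next to the outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "config.lock.yaml"
    payload = config.model_dump(mode="json")
    payload["_tool"] = {"name": "rosnerve", "version": __version__}
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path
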