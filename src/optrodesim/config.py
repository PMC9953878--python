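"""Validated run configuration for the end-to-end pipeline.

A :class:`RunConfig` collects the grid, medium, electrode, fiber, Monte
Carlo and analysis settings needed to chain field -> VTA -> photon
transport -> dose-response summary.  Validation is strict: unknown keys
are rejected, and every run writes its resolved configuration beside its
outputs so results are reproducible from the manifest alone.

Defaults follow the reference optrode setup: 2 mm tissue cube, K =
4.120 S/m, 450-um bipolar pair on the z-axis through the cube centre,
200-um NA-0.48 fiber aimed at the electrodes, 465/525 nm white-matter
optics, and the 50/100/200/300 uA, 0.4 ms, 3 Hz stimulation protocol.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .field import ElectrodePair
from .grid import EMISSION_525, EXCITATION_465, OpticalProperties, VoxelGrid, make_grid
from .mc import FiberSpec


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    extent_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    voxel_edge_um: float = Field(10.0, gt=0)
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def build(self) -> VoxelGrid:
        return make_grid(self.extent_mm, self.voxel_edge_um, self.origin_um)


class OpticsConfig(_Strict):
    mu_a_per_cm: float = Field(ge=0)
    mu_s_per_cm: float = Field(ge=0)
    g: float = 0.9
    n: float = 1.37

    def build(self, tag: str) -> OpticalProperties:
        return OpticalProperties(self.mu_a_per_cm, self.mu_s_per_cm, self.g,
                                 self.n, wavelength_tag=tag)


class MediumConfig(_Strict):
    conductivity_s_per_m: float = Field(4.120, gt=0)
    relative_permittivity: float = 80.0
    excitation: OpticsConfig = OpticsConfig(
        mu_a_per_cm=EXCITATION_465.mu_a_per_cm, mu_s_per_cm=EXCITATION_465.mu_s_per_cm)
    emission: OpticsConfig = OpticsConfig(
        mu_a_per_cm=EMISSION_525.mu_a_per_cm, mu_s_per_cm=EMISSION_525.mu_s_per_cm)


class ElectrodeConfig(_Strict):
    source_um: tuple[float, float, float] = (1000.0, 1000.0, 775.0)
    sink_um: tuple[float, float, float] = (1000.0, 1000.0, 1225.0)

    def build(self, current_a: float) -> ElectrodePair:
        return ElectrodePair(self.source_um, self.sink_um, current_a)


class FiberConfig(_Strict):
    tip_position_um: tuple[float, float, float] = (1000.0, 1000.0, 500.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    core_diameter_um: float = Field(200.0, gt=0)
    numerical_aperture: float = Field(0.48, gt=0)
    half_angle_deg: float = Field(20.5, ge=0, lt=90)

    def build(self) -> FiberSpec:
        return FiberSpec(tip_position_um=self.tip_position_um, axis=self.axis,
                         core_diameter_um=self.core_diameter_um,
                         numerical_aperture=self.numerical_aperture,
                         half_angle_deg=self.half_angle_deg)


class MCConfig(_Strict):
    n_photons: int = Field(10_000_000, ge=1)
    seed: int = Field(12345, ge=0)
    roulette_threshold: float = Field(1e-4, gt=0)
    roulette_survival: float = Field(0.1, gt=0, le=1)


class AnalysisConfig(_Strict):
    af_axis: str = "x"
    vta_threshold_v_per_m2: float = Field(1e5, ge=0)
    qy_inside_vta: float = Field(1.0, ge=0, le=1)


class RunConfig(_Strict):
    grid: GridConfig = GridConfig()
    medium: MediumConfig = MediumConfig()
    electrodes: ElectrodeConfig = ElectrodeConfig()
    fiber: FiberConfig = FiberConfig()
    mc: MCConfig = MCConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    currents_ua: list[float] = Field(default=[50.0, 100.0, 200.0, 300.0], min_length=1)
    write_volumes: bool = True

    @model_validator(mode="after")
    def _geometry_inside_grid(self) -> "RunConfig":
        grid = self.grid.build()
        for name, pos in (("source", self.electrodes.source_um),
                          ("sink", self.electrodes.sink_um),
                          ("fiber tip", self.fiber.tip_position_um)):
            if not grid.contains(pos):
                raise ValueError(f"{name} position {pos} lies outside the grid")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        from .io import load_yaml
        return cls.model_validate(load_yaml(path))

    def to_yaml(self, path):
        from .io import dump_yaml
        return dump_yaml(path, self.model_dump(mode="json"))
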