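"""Declarative scenario configuration, device presets and run orchestration.

A :class:`Scenario` captures everything needed to reproduce a run: device
geometry, fluid, angular velocity (single rpm or a sweep list), particle
populations or inlet concentrations, solver settings and the seed.  The
on-disk dialect is YAML (schema version 1); loading validates every field
and fills defaults, and load -> dump -> load is idempotent.

``presets()`` returns the study scenarios: the separator at its six sweep
speeds, the three-population separator run, and the obstacle /
no-obstacle / rpm-sweep mixer runs, all on the default geometries at
radial offsets 3 cm (separator) and 4.3 cm (mixer).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from . import geometry as geo
from . import io as cio
from . import mixing as mx
from . import tracking as trk
from .flow import ConvergenceError, Fluid, RotatingFrame, solve_flow
from .forces import LiftModel, Particle

__all__ = [
    "Scenario",
    "load_scenario",
    "dump_scenario",
    "presets",
    "paper_presets",
    "build_geometry",
    "run_scenario",
]

UM = 1e-6

SWEEP_RPMS = (500.0, 1000.0, 1500.0, 2000.0, 2500.0, 3000.0)
MIXER_SWEEP_RPMS = (1000.0, 1500.0, 2000.0, 2500.0)


class FluidConfig(BaseModel):
    density: float = Field(1000.0, gt=0, description="kg/m^3")
    viscosity: float = Field(1e-3, gt=0, description="Pa s")
    diffusivity: float = Field(1.67e-9, gt=0, description="m^2/s")

    def to_fluid(self) -> Fluid:
        return Fluid(self.density, self.viscosity, self.diffusivity)


class PopulationConfig(BaseModel):
    label: str
    diameter: float = Field(gt=0, description="m")
    density: float = Field(1050.0, gt=0, description="kg/m^3")
    count: int = Field(ge=0)

    def to_particle(self) -> Particle:
        return Particle(self.diameter, self.density, self.label)


class SeparatorGeometryConfig(BaseModel):
    contraction_width: float = Field(50 * UM, gt=0)
    contraction_length: float = Field(200 * UM, gt=0)
    expansion_width: float = Field(250 * UM, gt=0)
    expansion_length: float = Field(400 * UM, gt=0)
    height: float = Field(50 * UM, gt=0)
    n_units: int = Field(8, ge=1)
    radial_offset: float = Field(0.03, gt=0)
    split_y: Optional[float] = None

    def to_spec(self) -> geo.ContractionExpansionSpec:
        return geo.ContractionExpansionSpec(
            contraction=geo.ChannelSection(
                self.contraction_width, self.height, self.contraction_length
            ),
            expansion=geo.ChannelSection(
                self.expansion_width, self.height, self.expansion_length
            ),
            n_units=self.n_units,
            inlet=geo.ChannelSection(
                self.contraction_width, self.height, 200 * UM
            ),
            split_y=self.split_y,
            radial_offset=self.radial_offset,
        )


class MixerGeometryConfig(BaseModel):
    width: float = Field(100 * UM, gt=0)
    height: float = Field(50 * UM, gt=0)
    total_length: float = Field(2500 * UM, gt=0)
    n_turns: int = Field(6, ge=0)
    obstacle_edge: float = Field(40 * UM, gt=0)
    obstacles: bool = True
    leg_pitch: float = Field(300 * UM, gt=0)
    merge_length: float = Field(300 * UM, gt=0)
    radial_offset: float = Field(0.043, gt=0)

    def to_spec(self) -> geo.SerpentineMixerSpec:
        return geo.SerpentineMixerSpec(
            cross_section=geo.ChannelSection(
                self.width, self.height, self.total_length
            ),
            n_turns=self.n_turns,
            obstacle_edge=self.obstacle_edge,
            obstacles_enabled=self.obstacles,
            leg_pitch=self.leg_pitch,
            merge_length=self.merge_length,
            radial_offset=self.radial_offset,
        )


class SolverConfig(BaseModel):
    target_edge: float = Field(5 * UM, gt=0, description="mesh spacing, m")
    dt: float = Field(5e-5, gt=0, description="particle reporting step, s")
    tol_rate: float = Field(0.05, gt=0, description="steady tolerance, 1/s")
    max_steps: int = Field(8000, ge=1)
    t_max: Optional[float] = Field(None, description="tracking cutoff, s")
    displacement_cap: Optional[float] = Field(
        None, description="per-substep displacement bound, m (default dx/2)"
    )
    include_secondary: bool = Field(
        True, description="apply the Coriolis secondary-flow closure"
    )


class MixingConfig(BaseModel):
    peclet: Optional[float] = Field(
        mx.DEFAULT_PECLET,
        description="target channel Peclet (None: molecular diffusivity)",
    )
    n_stations: int = Field(12, ge=2)
    n_samples: int = Field(mx.DEFAULT_STATION_SAMPLES, ge=2)
    inlet_concentrations: dict[str, float] = Field(
        default_factory=lambda: {"inlet_sample": 0.0, "inlet_buffer": 1.0}
    )


class Scenario(BaseModel):
    schema_version: Literal[1] = 1
    name: str = "unnamed"
    kind: Literal["separator", "mixer"]
    rpm: Optional[float] = Field(None, gt=0)
    rpm_list: Optional[list[float]] = None
    rotation_sense: Literal["clockwise", "counterclockwise"] = "clockwise"
    fluid: FluidConfig = Field(default_factory=FluidConfig)
    separator: Optional[SeparatorGeometryConfig] = None
    mixer: Optional[MixerGeometryConfig] = None
    populations: list[PopulationConfig] = Field(default_factory=list)
    target_outlet: str = "outlet_lower"
    target_labels: list[str] = Field(default_factory=lambda: ["CTC"])
    solver: SolverConfig = Field(default_factory=SolverConfig)
    mixing: MixingConfig = Field(default_factory=MixingConfig)
    seed: int = 1

    @model_validator(mode="after")
    def _check(self) -> "Scenario":
        if (self.rpm is None) == (self.rpm_list is None):
            raise ValueError("exactly one of 'rpm' or 'rpm_list' must be set")
        if self.rpm_list is not None and not self.rpm_list:
            raise ValueError("'rpm_list' must be nonempty")
        if self.kind == "separator":
            if self.separator is None:
                object.__setattr__(self, "separator", SeparatorGeometryConfig())
            if not self.populations:
                raise ValueError(
                    "'populations' is required for a separator scenario"
                )
        else:
            if self.mixer is None:
                object.__setattr__(self, "mixer", MixerGeometryConfig())
        return self

    @property
    def rpms(self) -> list[float]:
        return list(self.rpm_list) if self.rpm_list else [self.rpm]


def load_scenario(path) -> Scenario:
    """Load and validate a YAML scenario file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return Scenario.model_validate(data)


def dump_scenario(scenario: Scenario, path=None) -> str:
    """Serialize a scenario to YAML (round-trip stable)."""
    text = yaml.safe_dump(
        scenario.model_dump(mode="json"), sort_keys=True, default_flow_style=False
    )
    if path is not None:
        Path(path).write_text(text)
    return text


def build_geometry(scenario: Scenario) -> geo.ChannelGeometry:
    if scenario.kind == "separator":
        return geo.build_contraction_expansion_channel(scenario.separator.to_spec())
    return geo.build_serpentine_mixer(scenario.mixer.to_spec())


# -- presets ---------------------------------------------------------------


def _default_populations() -> list[PopulationConfig]:
    return [
        PopulationConfig(label="WBC", diameter=10 * UM, count=20),
        PopulationConfig(label="CTC", diameter=20 * UM, count=20),
    ]


def presets() -> dict[str, Scenario]:
    """Named study scenarios (sweeps kept as single scenarios)."""
    out: dict[str, Scenario] = {}
    out["separator-2000"] = Scenario(
        name="separator-2000", kind="separator", rpm=2000.0,
        populations=_default_populations(),
    )
    out["separator-sweep"] = Scenario(
        name="separator-sweep", kind="separator", rpm_list=list(SWEEP_RPMS),
        populations=_default_populations(),
    )
    out["separator-three-population"] = Scenario(
        name="separator-three-population", kind="separator", rpm=2000.0,
        populations=[
            PopulationConfig(label="WBC", diameter=10 * UM, count=20),
            PopulationConfig(label="CTC15", diameter=15 * UM, count=10),
            PopulationConfig(label="CTC20", diameter=20 * UM, count=10),
        ],
        target_labels=["CTC15", "CTC20"],
    )
    out["mixer-obstacles-2000"] = Scenario(
        name="mixer-obstacles-2000", kind="mixer", rpm=2000.0,
        mixer=MixerGeometryConfig(obstacles=True),
    )
    out["mixer-no-obstacles-2000"] = Scenario(
        name="mixer-no-obstacles-2000", kind="mixer", rpm=2000.0,
        mixer=MixerGeometryConfig(obstacles=False),
    )
    out["mixer-rpm-sweep"] = Scenario(
        name="mixer-rpm-sweep", kind="mixer",
        rpm_list=list(MIXER_SWEEP_RPMS),
        mixer=MixerGeometryConfig(obstacles=True),
    )
    return out


def paper_presets() -> list[Scenario]:
    """The study scenario inventory with sweeps expanded one-per-rpm."""
    out: list[Scenario] = []
    for name, scn in presets().items():
        if scn.rpm_list is None:
            out.append(scn)
            continue
        for rpm in scn.rpm_list:
            single = scn.model_copy(
                update={"rpm": rpm, "rpm_list": None,
                        "name": f"{name}-{int(rpm)}rpm"}
            )
            out.append(single)
    return out


# -- orchestration ---------------------------------------------------------


def run_scenario(
    scenario: Scenario,
    outdir=None,
    lift_model: LiftModel | None = None,
    quiet: bool = True,
):
    """Execute a scenario end to end and optionally write all outputs.

    Separator scenarios return ``{"reports": [EfficiencyReport, ...]}``;
    mixer scenarios return ``{"reports": [MixingReport, ...]}``.  Per-rpm
    failures inside sweeps are recorded in the report objects.  With
    ``outdir`` set, VTK/CSV/JSON outputs and a checksummed manifest are
    written there.
    """
    manifest = cio.RunManifest(
        config=scenario.model_dump(mode="json"), seed=scenario.seed
    )
    geometry = build_geometry(scenario)
    mesh = geo.generate_mesh(geometry, scenario.solver.target_edge)
    manifest.record_stage("mesh", "ok", cells=mesh.n_cells, dx=mesh.dx)
    fluid = scenario.fluid.to_fluid()
    model = lift_model or LiftModel.default()
    solver_opts = dict(
        tol_rate=scenario.solver.tol_rate, max_steps=scenario.solver.max_steps
    )
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    reports = []
    flow_fields = []
    extra = {}
    for rpm in scenario.rpms:
        frame = RotatingFrame.from_rpm(rpm, scenario.rotation_sense)
        tag = f"{int(rpm)}rpm"
        try:
            fld = solve_flow(mesh, fluid, frame, **solver_opts)
            flow_fields.append(fld)
            manifest.record_stage(
                f"flow-{tag}", "ok", **{
                    k: v for k, v in fld.summary().items()
                    if k not in ("port_fluxes_m3_per_s",)
                }
            )
            if scenario.kind == "separator":
                states = trk.seed_inlet_ensemble(
                    geometry,
                    [(p.to_particle(), p.count) for p in scenario.populations],
                    scenario.seed,
                    flow_field=fld,
                )
                result = trk.simulate_ensemble(
                    states, fld, model, frame, fluid,
                    dt=scenario.solver.dt,
                    t_max=scenario.solver.t_max,
                    displacement_cap=scenario.solver.displacement_cap,
                    include_secondary=scenario.solver.include_secondary,
                )
                report = trk.make_report(
                    result, rpm, scenario.target_outlet,
                    tuple(scenario.target_labels),
                )
                reports.append(report)
                manifest.warnings.extend(result.warnings)
                if outdir is not None:
                    manifest.record_file(cio.write_trajectories_csv(
                        outdir / f"trajectories-{tag}.csv", result
                    ))
                    manifest.record_file(cio.write_vtk_trajectories(
                        outdir / f"trajectories-{tag}.vtk", result.history
                    ))
                    manifest.record_file(cio.write_json(
                        outdir / f"efficiency-{tag}.json", report.to_dict()
                    ))
                extra.setdefault("trajectories", []).append(result)
            else:
                conc = mx.solve_concentration(
                    fld,
                    inlet_values=scenario.mixing.inlet_concentrations,
                    peclet=scenario.mixing.peclet,
                )
                report = mx.mixing_profile(
                    conc, scenario.mixing.n_stations,
                    scenario.mixing.n_samples, rpm=rpm,
                )
                reports.append(report)
                if outdir is not None:
                    manifest.record_file(cio.write_concentration_vtk(
                        outdir / f"concentration-{tag}.vtk", conc
                    ))
                    manifest.record_file(cio.write_json(
                        outdir / f"mixing-{tag}.json", report.to_dict()
                    ))
                extra.setdefault("concentrations", []).append(conc)
            if outdir is not None:
                manifest.record_file(
                    cio.write_flow_vtk(outdir / f"flow-{tag}.vtk", fld)
                )
                manifest.record_file(cio.write_json(
                    outdir / f"flow-{tag}.json", fld.summary()
                ))
        except (ConvergenceError, geo.GeometryError, ValueError) as exc:
            manifest.record_stage(f"flow-{tag}", "failed", error=str(exc))
            if scenario.kind == "separator":
                reports.append(trk.EfficiencyReport(
                    rpm=rpm, counts={}, efficiency={},
                    target_outlet=scenario.target_outlet, ensemble_size=0,
                    error=str(exc),
                ))
            else:
                import math as _m

                import numpy as _np
                reports.append(mx.MixingReport(
                    rpm=rpm, stations=_np.array([]), cov=_np.array([]),
                    mq=_np.array([]), outlet_mq=_m.nan,
                    outlet_mq_flow_weighted=_m.nan,
                    n_samples=scenario.mixing.n_samples,
                    peclet=scenario.mixing.peclet, diffusivity=_m.nan,
                    error=str(exc),
                ))
    if outdir is not None:
        manifest.finalize(outdir)
    return {
        "scenario": scenario,
        "mesh": mesh,
        "flow_fields": flow_fields,
        "reports": reports,
        "manifest": manifest,
        **extra,
    }
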