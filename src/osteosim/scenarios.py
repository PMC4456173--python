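"""Scenario construction and the coupled daily healing loop.

The geometry is an idealized longitudinal half-section of a rat femur
diaphysis (symmetry axis at y = 0): medullary canal, endosteum strip,
cortical wall, periosteum strip, and, for small-gap fractures, a fixed
outer callus band. A central segment of length ``gap_mm`` is removed from
the cortex; critical-defect scenarios may fill the defect with alginate
hydrogel carrying a BMP-2 dose, small-gap scenarios start from a
debris-filled fracture hematoma.

Each macro step (one day) runs, in order: tissue-fraction homogenization
and the plane-strain FE solve for the stimulus psi; MSC transport;
proliferation, strain-selected differentiation and matrix production /
maturation; the BMP-2 balance with this step's differentiation-event
sink; and hydrogel degradation. The model is fully deterministic for a
given configuration; the seed only drives the optional mesh jitter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bmp2 import BMPParams, BMPState, step_bmp2
from .grid import Grid, segmented_faces
from .hydrogel import AlginateParams, alginate_step
from .materials import TissueComposition, TissueProperties, homogenize_properties
from .mechanics import LoadCase, MechanicalState, compute_strains, \
    compute_stimulus, solve_displacements
from .modulation import ModulationSet
from .rules import RuleThresholds, differentiate, mature_and_produce, proliferate
from .transport import CellFields, MotilityParams, transport_step
from .vtkio import write_vtk_rectilinear

SUMMARY_COLUMNS = ("day", "bone_pct", "alginate_pct", "mean_g_defect",
                   "max_g", "min_g_tissue", "gel_bmp2_total_ng", "total_msc",
                   "total_bone_cells", "psi_median_defect", "min_cs", "min_a")

__all__ = ["Geometry", "Scenario", "SimState", "RunSummary", "SUMMARY_COLUMNS",
           "build_scenario", "run", "report",
           "small_gap_scenario", "critical_defect_scenario"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Geometry:
    """Section dimensions in mm (reconstructed idealized geometry).

    Radial build-up from the symmetry axis: medullary canal to
    ``r_medullary``, endosteum strip, cortical wall, periosteum strip,
    and an outer callus band used only by small-gap scenarios.
    """

    length: float = 20.0
    r_medullary: float = 1.1
    t_endosteum: float = 0.2
    t_cortex: float = 0.7
    t_periosteum: float = 0.2
    t_callus: float = 1.0
    callus_halflength: float = 6.0

    @property
    def y_endosteum(self) -> tuple[float, float]:
        return (self.r_medullary, self.r_medullary + self.t_endosteum)

    @property
    def y_cortex(self) -> tuple[float, float]:
        lo = self.r_medullary + self.t_endosteum
        return (lo, lo + self.t_cortex)

    @property
    def y_periosteum(self) -> tuple[float, float]:
        lo = self.y_cortex[1]
        return (lo, lo + self.t_periosteum)

    @property
    def y_callus(self) -> tuple[float, float]:
        lo = self.y_periosteum[1]
        return (lo, lo + self.t_callus)


@dataclass(frozen=True)
class Scenario:
    """Complete, self-contained run configuration."""

    gap_mm: float = 8.0
    gel_present: bool = True
    bmp2_dose_ug: float = 5.0
    horizon_days: int = 84
    mesh_h: float = 0.4
    seed: int = 0
    mesh_jitter: float = 0.0       # fraction of local spacing; 0 = regular
    source_density: float = 1e5    # periosteal/endosteal MSC density
    stimulus_kind: str = "sqrt_j2"
    dt_react: float = 0.05
    bone_marker: str = "osterix"   # saturation anchoring of the curve
    modulation_anchors: dict = field(default_factory=dict)
    geometry: Geometry = field(default_factory=Geometry)
    bmp: BMPParams = field(default_factory=BMPParams)
    alginate: AlginateParams = field(default_factory=AlginateParams)
    motility: MotilityParams = field(default_factory=MotilityParams)
    rules: RuleThresholds = field(default_factory=RuleThresholds)
    load: LoadCase | None = None
    props: TissueProperties = field(default_factory=TissueProperties)

    def __post_init__(self):
        if self.horizon_days <= 0:
            raise ValueError("horizon must be positive")
        if self.bmp2_dose_ug < 0:
            raise ValueError("dose must be non-negative")
        if self.bmp2_dose_ug > 0 and not self.gel_present:
            raise ValueError("a BMP-2 dose requires the hydrogel carrier")
        if not 0 < self.gap_mm < self.geometry.length:
            raise ValueError("gap must fit inside the modeled length")

    @property
    def has_callus_band(self) -> bool:
        """Small-gap fractures grow an outer callus; large defects do not."""
        return self.gap_mm <= 4.0

    @property
    def gap_x(self) -> tuple[float, float]:
        c = self.geometry.length / 2
        return (c - self.gap_mm / 2, c + self.gap_mm / 2)


def small_gap_scenario(**overrides) -> Scenario:
    """The 2 mm fracture validation case (42 days, no gel, no dose)."""
    base = dict(gap_mm=2.0, gel_present=False, bmp2_dose_ug=0.0,
                horizon_days=42)
    base.update(overrides)
    return Scenario(**base)


def critical_defect_scenario(dose_ug: float = 5.0, gel: bool = True,
                             **overrides) -> Scenario:
    """The 8 mm critical defect (84 days); empty, gel-only, or gel + dose."""
    base = dict(gap_mm=8.0, gel_present=gel, bmp2_dose_ug=dose_ug,
                horizon_days=84)
    base.update(overrides)
    return Scenario(**base)


@dataclass
class SimState:
    """Mutable fields of a running simulation."""

    scenario: Scenario
    grid: Grid
    comp: TissueComposition
    cells: CellFields
    bmp: BMPState
    a: np.ndarray                 # normalized alginate
    gel_mask: np.ndarray          # cells initially filled with hydrogel
    defect_mask: np.ndarray       # original cortical window in the gap
    defect_region: np.ndarray     # full defect cross-section (endo..peri)
    source_mask: np.ndarray       # periosteal/endosteal MSC sources
    host_mask: np.ndarray         # vascularized host tissue at day 0
    load: LoadCase
    mech: MechanicalState | None = None


def _build_grid(sc: Scenario) -> Grid:
    geo = sc.geometry
    x0, x1 = sc.gap_x
    xb = [0.0, x0, x1, geo.length]
    yb = [0.0, geo.r_medullary, geo.y_endosteum[1], geo.y_cortex[1],
          geo.y_periosteum[1]]
    if sc.has_callus_band:
        yb.append(geo.y_callus[1])
    xf = segmented_faces(xb, sc.mesh_h)
    yf = segmented_faces(yb, sc.mesh_h)
    if sc.mesh_jitter > 0:
        rng = np.random.default_rng(sc.seed)
        for f, bounds in ((xf, xb), (yf, yb)):
            interior = ~np.isin(np.round(f, 12), np.round(bounds, 12))
            h = np.minimum(np.diff(f).min(), sc.mesh_h)
            f[interior] += rng.uniform(-1, 1, interior.sum()) \
                * sc.mesh_jitter * h
    return Grid(xf, yf)


def build_scenario(sc: Scenario) -> SimState:
    """Mesh the geometry and set every initial field of the scenario."""
    geo = sc.geometry
    grid = _build_grid(sc)
    x0, x1 = sc.gap_x
    in_gap = grid.region_mask(x_range=(x0, x1))
    medullary = grid.region_mask(y_range=(0.0, geo.r_medullary))
    endosteum = grid.region_mask(y_range=geo.y_endosteum)
    cortex = grid.region_mask(y_range=geo.y_cortex)
    periosteum = grid.region_mask(y_range=geo.y_periosteum)

    comp = TissueComposition(grid.shape)
    comp["cortical_bone"][cortex & ~in_gap] = 1.0
    comp["granulation"][(endosteum | periosteum) & ~in_gap] = 1.0
    comp["debris"][medullary & ~in_gap] = 1.0

    defect_mask = cortex & in_gap
    defect_region = (endosteum | cortex | periosteum) & in_gap
    gel_mask = defect_region & sc.gel_present

    if sc.has_callus_band:
        callus = grid.region_mask(
            y_range=geo.y_callus,
            x_range=(geo.length / 2 - geo.callus_halflength,
                     geo.length / 2 + geo.callus_halflength))
        comp["debris"][callus] = 1.0
        # a fresh fracture hematoma fills the small gap with debris tissue
        comp["debris"][in_gap & (medullary | endosteum | cortex | periosteum)] = 1.0

    a = grid.zeros()
    g_gel = grid.zeros()
    if sc.gel_present:
        a[gel_mask] = 1.0
        comp["alginate"][gel_mask] = 1.0
        if sc.bmp2_dose_ug > 0:
            vol_cm3 = grid.integrate(np.ones(grid.shape), gel_mask) / 1000.0
            g_gel[gel_mask] = sc.bmp2_dose_ug * 1000.0 / vol_cm3

    # free BMP-2 sits at the physiological floor wherever host tissue
    # exists; the implant and empty space start without free BMP-2
    tissue = (comp.total() - comp["alginate"]) > 0
    g = np.where(tissue, sc.bmp.g_min, 0.0)

    source_mask = (endosteum | periosteum) & ~in_gap
    cells = CellFields.zeros(grid.shape)
    cells.cs[source_mask] = sc.source_density

    load = sc.load or LoadCase(cortex_band=geo.y_cortex)
    return SimState(scenario=sc, grid=grid, comp=comp, cells=cells,
                    bmp=BMPState(g, g_gel), a=a, gel_mask=gel_mask,
                    defect_mask=defect_mask, defect_region=defect_region,
                    source_mask=source_mask, host_mask=tissue.copy(),
                    load=load)


@dataclass
class RunSummary:
    """Daily time series plus derived outcome scalars."""

    scenario: Scenario
    table: pd.DataFrame

    @property
    def final_bone_pct(self) -> float | None:
        if self.table.empty:
            return None
        return float(self.table["bone_pct"].iloc[-1])

    @property
    def final_alginate_pct(self) -> float | None:
        if self.table.empty:
            return None
        return float(self.table["alginate_pct"].iloc[-1])

    @property
    def week_cross_10pct(self) -> float | None:
        """Week at which defect bone content first crosses 10%."""
        if self.table.empty:
            return None
        hit = self.table[self.table["bone_pct"] >= 10.0]
        if hit.empty:
            return None
        return float(hit["day"].iloc[0]) / 7.0

    def outcome(self) -> dict:
        return {
            "gap_mm": self.scenario.gap_mm,
            "gel_present": self.scenario.gel_present,
            "bmp2_dose_ug": self.scenario.bmp2_dose_ug,
            "days": 0 if self.table.empty else int(self.table["day"].iloc[-1]),
            "final_bone_pct": self.final_bone_pct,
            "final_alginate_pct": self.final_alginate_pct,
            "week_cross_10pct": self.week_cross_10pct,
            "n_cells_mesh": int(self.table.attrs.get("n_cells", 0)),
        }


def _record(state: SimState, day: int) -> dict:
    grid, comp = state.grid, state.comp
    bone = comp.bone()
    psi = state.mech.psi if state.mech is not None else np.zeros(grid.shape)
    in_defect = state.defect_region
    w = grid.cell_area
    return {
        "day": day,
        "bone_pct": 100.0 * grid.mean(bone, state.defect_mask),
        "alginate_pct": 100.0 * grid.mean(state.a, state.defect_region),
        "mean_g_defect": grid.mean(state.bmp.g, state.defect_region),
        "max_g": float(state.bmp.g.max()),
        "min_g_tissue": float(state.bmp.g[comp.total() > 0].min()),
        "gel_bmp2_total_ng": float(np.sum(state.bmp.g_gel * w) / 1000.0),
        "total_msc": float(np.sum(state.cells.cs * w) / 1000.0),
        "total_bone_cells": float(np.sum(state.cells.cb * w) / 1000.0),
        "psi_median_defect": float(np.median(psi[in_defect]))
        if in_defect.any() else 0.0,
        "min_cs": float(state.cells.cs.min()),
        "min_a": float(state.a.min()),
    }


def run(sc: Scenario, out_dir=None, snapshots_every: int = 0) -> RunSummary:
    """Execute the daily macro loop over the scenario horizon."""
    state = build_scenario(sc)
    anchors = dict(sc.modulation_anchors)
    if sc.bone_marker == "osteocalcin" and "bone_production" not in anchors:
        from .modulation import DEFAULT_ANCHORS
        anchors["bone_production"] = \
            DEFAULT_ANCHORS["bone_production_osteocalcin"]
    modulation = ModulationSet(anchors=anchors)
    grid = state.grid
    rows = [_record(state, 0)]
    if out_dir is not None:
        out_dir = _prepare_out(out_dir)
    dt = 1.0

    for day in range(1, sc.horizon_days + 1):
        # 1. mechanics: homogenize, solve, stimulus
        E, nu, _k = homogenize_properties(state.comp, sc.props)
        u = solve_displacements(grid, E, nu, state.load)
        strain = compute_strains(grid, u)
        psi = compute_stimulus(strain, sc.stimulus_kind)
        state.mech = MechanicalState(strain, psi)

        # 2. MSC migration
        state.cells.cs = transport_step(
            state.cells.cs, state.a, state.bmp.g, state.comp, dt, grid,
            sc.motility, modulation)

        # 3. cellular rules
        state.cells.cs = proliferate(state.cells.cs, state.bmp.g, dt,
                                     sc.rules, modulation,
                                     adhesion=1.0 - state.a)
        state.cells, events = differentiate(
            state.cells, psi, state.bmp.g, dt, sc.rules, state.comp,
            modulation)
        state.cells, state.comp = mature_and_produce(
            state.cells, state.comp, psi, state.bmp.g, dt, sc.rules,
            modulation)

        # 4. BMP-2 balance with this step's event sink
        state.bmp = step_bmp2(state.bmp, state.a, state.cells.cs,
                              state.cells.cb, events.event_mask, dt, grid,
                              sc.bmp, sc.alginate, sc.dt_react,
                              conductive=state.comp.total() > 1e-6)

        # vascularized tissue exchanges with the systemic circulation,
        # which maintains at least the physiological BMP-2 floor there;
        # newly formed matrix (revascularized callus) joins the host mask
        host = state.host_mask | \
            ((state.comp.total() - state.comp["alginate"]) > 0.35)
        state.bmp.g = np.where(host, np.maximum(state.bmp.g, sc.bmp.g_min),
                               state.bmp.g)

        # 5. hydrogel degradation: the cell term models active cellular
        # invasion (ion exchange and water uptake around motile and
        # matrix-producing cells), and shuts down once mineralized matrix
        # seals the volume off
        invasion_open = np.clip(
            1.0 - state.comp.mineralized()
            / sc.motility.erosion_freeze_frac, 0.0, 1.0)
        state.a = alginate_step(state.a, state.cells.total() * invasion_open,
                                dt, sc.alginate)
        state.comp["alginate"] = state.a * state.gel_mask

        # 6. replenish the progenitor sources and record
        state.cells.cs[state.source_mask] = sc.source_density
        state.cells.validate()
        rows.append(_record(state, day))

        if out_dir is not None and snapshots_every and \
                day % snapshots_every == 0:
            _snapshot(state, out_dir, day)
        if day % 28 == 0:
            log.info("day %d: bone %.1f%%, alginate %.1f%%", day,
                     rows[-1]["bone_pct"], rows[-1]["alginate_pct"])

    table = pd.DataFrame(rows)
    table.attrs["n_cells"] = grid.n_cells
    summary = RunSummary(sc, table)
    if out_dir is not None:
        report(summary, out_dir)
        if snapshots_every:
            _snapshot(state, out_dir, sc.horizon_days)
    return summary


def _prepare_out(out_dir):
    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return out_dir


def _snapshot(state: SimState, out_dir, day: int) -> None:
    fields = {
        "bmp2_free": state.bmp.g,
        "bmp2_gel": state.bmp.g_gel,
        "alginate": state.a,
        "msc": state.cells.cs,
        "bone_cells": state.cells.cb,
        "bone_fraction": state.comp.bone(),
        "cartilage_fraction": state.comp["cartilage"]
        + state.comp["calcified_cartilage"],
    }
    if state.mech is not None:
        fields["psi"] = state.mech.psi
    write_vtk_rectilinear(out_dir / f"snapshot_{day:03d}.vtk", state.grid,
                          fields, title=f"day {day}")


def report(summary: RunSummary, out_dir) -> dict:
    """Write the CSV time series and the JSON outcome summary."""
    out_dir = _prepare_out(out_dir)
    csv_path = out_dir / "timeseries.csv"
    summary.table.to_csv(csv_path, index=False, float_format="%.10g")
    out = summary.outcome()
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(out, fh, indent=2)
    log.info("wrote %s", csv_path)
    return out
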