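"""MSC migration: diffusion-chemotaxis with hydrogel and matrix gating.

Only mesenchymal progenitors migrate; differentiated cells stay where
they were born and act as matrix producers. The flux is a Keller-Segel
form, random motility D(a) down the cell gradient plus chemotactic drift
chi_eff * grad(g) up the BMP-2 gradient. The chemical stimulus enters
multiplicatively: chi_eff = chi0 * (1 - a) * chemotaxis_fold(g), the
product of the mechanical/structural sensitivity and the dose-dependent
bell curve.

Gating rules close cell faces where either neighbor is impassable:
mineralized matrix dominating the volume (fraction above a threshold),
or no adhesion substrate at all (an empty defect offers nothing to crawl
on). Inside intact gel only the weak random floor of D(a) remains.

Discretization: cell-centered finite volumes, harmonic-mean face
diffusivities, first-order upwinding of the drift term, explicit
sub-steps limited by a positivity/CFL bound. The update is exactly
conservative under the zero-flux outer boundaries and keeps cs >= 0 by
construction of the scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fv import face_harmonic
from .hydrogel import cell_mobility
from .materials import TissueComposition
from .modulation import ModulationSet

__all__ = ["MotilityParams", "CellFields", "migration_mask", "transport_step"]


@dataclass(frozen=True)
class MotilityParams:
    """Free-tissue motility constants; calibration knobs, not literature.

    D0   : random motility in gel-free tissue, mm^2/day
    chi0 : chemotactic sensitivity, mm^2/day per (ng/cm^3)
    floor_frac : residual random motility inside intact gel, fraction of D0
    mineral_block_threshold : mineralized fraction above which a volume is
        impassable to MSCs
    substrate_min : minimum total solid fraction required for migration
        (an empty defect provides no adhesion substrate)
    packing_density : cell density at which chemotactic influx saturates
    erosion_freeze_frac : mineralized fraction at which cell-driven
        hydrogel erosion is fully shut off (mineral seals water exchange)
    """

    D0: float = 0.24
    chi0: float = 0.05
    floor_frac: float = 3e-5
    mineral_block_threshold: float = 0.5
    substrate_min: float = 0.05
    packing_density: float = 3e5
    erosion_freeze_frac: float = 0.22

    def __post_init__(self):
        if self.D0 <= 0 or self.chi0 <= 0:
            raise ValueError("D0 and chi0 must be positive")
        if not 0 < self.mineral_block_threshold <= 1:
            raise ValueError("mineral_block_threshold must be in (0, 1]")


@dataclass
class CellFields:
    """Cell concentrations (cells/cm^3): cs migrates, the rest are static."""

    cs: np.ndarray   # mesenchymal progenitors
    cb: np.ndarray   # bone cells (osteoblasts)
    cc: np.ndarray   # chondrocytes
    ch: np.ndarray   # hypertrophic / calcifying chondrocytes
    cf: np.ndarray   # fibroblasts

    @classmethod
    def zeros(cls, shape) -> "CellFields":
        return cls(*(np.zeros(shape) for _ in range(5)))

    def total(self) -> np.ndarray:
        return self.cs + self.cb + self.cc + self.ch + self.cf

    def copy(self) -> "CellFields":
        return CellFields(self.cs.copy(), self.cb.copy(), self.cc.copy(),
                          self.ch.copy(), self.cf.copy())

    def validate(self) -> None:
        for name in ("cs", "cb", "cc", "ch", "cf"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"negative cell concentration in {name}")


def migration_mask(comp: TissueComposition,
                   params: MotilityParams | None = None) -> np.ndarray:
    """True where MSC migration is blocked by mineralized matrix.

    A volume is impassable when calcified cartilage + woven + cortical
    bone together dominate it (fraction above the threshold).
    """
    params = params or MotilityParams()
    return comp.mineralized() > params.mineral_block_threshold


def transport_step(cs, a, g, comp: TissueComposition, dt: float, grid,
                   params: MotilityParams | None = None,
                   modulation: ModulationSet | None = None,
                   cfl: float = 0.45) -> np.ndarray:
    """Advance the MSC field by dt days; conservative and non-negative.

    Face coefficients are frozen over the macro step (a, g and the
    composition evolve on the slower daily scale); the explicit update is
    sub-cycled so that every cell's total outflow coefficient satisfies
    the positivity bound.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    params = params or MotilityParams()
    modulation = modulation or ModulationSet()
    cs = np.asarray(cs, dtype=float).copy()
    if np.any(cs < 0):
        raise ValueError("negative cell concentration on entry")

    D, chi = cell_mobility(np.asarray(a, float), params.D0, params.chi0,
                           params.floor_frac)
    chi = chi * modulation.chemotaxis_fold(np.asarray(g, float), "MSC")
    open_cell = (~migration_mask(comp, params)) \
        & (comp.total() >= params.substrate_min)
    D = D * open_cell
    chi = chi * open_cell

    # face coefficients; harmonic means propagate closed cells to faces
    Dx = face_harmonic(D[:, :-1], D[:, 1:])
    Dy = face_harmonic(D[:-1, :], D[1:, :])
    chix = face_harmonic(chi[:, :-1], chi[:, 1:])
    chiy = face_harmonic(chi[:-1, :], chi[1:, :])
    ddx = 0.5 * (grid.dx[:-1] + grid.dx[1:])
    ddy = 0.5 * (grid.dy[:-1] + grid.dy[1:])
    Ax = grid.dy[:, None] * np.ones_like(Dx)          # face areas
    Ay = grid.dx[None, :] * np.ones_like(Dy)
    Tx = Dx * Ax / ddx[None, :]
    Ty = Dy * Ay / ddy[:, None]
    g = np.asarray(g, dtype=float)
    vx = chix * (g[:, 1:] - g[:, :-1]) / ddx[None, :]  # drift, mm/day (+x)
    vy = chiy * (g[1:, :] - g[:-1, :]) / ddy[:, None]

    # positivity bound: dt * (sum of outflow coefficients) <= cfl * V
    vol = grid.cell_area
    out_coef = np.zeros_like(cs)
    out_coef[:, :-1] += Tx + np.maximum(vx, 0.0) * Ax
    out_coef[:, 1:] += Tx + np.maximum(-vx, 0.0) * Ax
    out_coef[:-1, :] += Ty + np.maximum(vy, 0.0) * Ay
    out_coef[1:, :] += Ty + np.maximum(-vy, 0.0) * Ay
    w = out_coef / vol
    wmax = float(w.max())
    n_sub = max(1, int(np.ceil(dt * wmax / cfl))) if wmax > 0 else 1
    h = dt / n_sub

    pack = params.packing_density
    for _ in range(n_sub):
        # upwinded advective face rates (+x / +y direction positive), with
        # a volume-filling factor that switches the drift off as the
        # receiving cell approaches the packing density
        fill_xp = np.clip(1.0 - cs[:, 1:] / pack, 0.0, 1.0)
        fill_xm = np.clip(1.0 - cs[:, :-1] / pack, 0.0, 1.0)
        fill_yp = np.clip(1.0 - cs[1:, :] / pack, 0.0, 1.0)
        fill_ym = np.clip(1.0 - cs[:-1, :] / pack, 0.0, 1.0)
        adv_x = (np.maximum(vx, 0.0) * cs[:, :-1] * fill_xp
                 + np.minimum(vx, 0.0) * cs[:, 1:] * fill_xm) * Ax
        adv_y = (np.maximum(vy, 0.0) * cs[:-1, :] * fill_yp
                 + np.minimum(vy, 0.0) * cs[1:, :] * fill_ym) * Ay
        dif_x = Tx * (cs[:, 1:] - cs[:, :-1])
        dif_y = Ty * (cs[1:, :] - cs[:-1, :])
        div = np.zeros_like(cs)
        div[:, :-1] += dif_x - adv_x
        div[:, 1:] += adv_x - dif_x
        div[:-1, :] += dif_y - adv_y
        div[1:, :] += adv_y - dif_y
        cs = cs + h * div / vol

    if np.any(cs < -1e-9 * max(1.0, float(np.abs(cs).max()))):
        raise RuntimeError("cell transport produced negative concentrations")
    np.maximum(cs, 0.0, out=cs)   # scrub roundoff-level negatives only
    return cs
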