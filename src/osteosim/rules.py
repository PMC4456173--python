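"""Mechanoregulated, BMP-2-modulated cell fate and matrix dynamics.

The classical strain-regulated differentiation rules are kept as the
mechanical baseline and every chemically sensitive rate is multiplied by
the corresponding BMP-2 fold curve (a product of mechanical and chemical
stimulus terms):

* proliferation: logistic MSC growth at r_prolif * proliferation_fold(g);
* differentiation: where g >= g_min, MSCs convert at rate r_diff into
  bone cells (psi <= psi_bone_max), chondrocytes (psi <= psi_cartilage_max)
  or fibroblasts (larger distortion). Chondro/osteogenic conversions set
  the BMP-2 event mask (the differentiation sink); fibroblastic ones do
  not, since BMP-2 does not act on that pathway;
* maturation: chondrocytes become hypertrophic and their cartilage matrix
  calcifies at r_mature * hypertrophy_fold(g); calcified cartilage is
  then replaced by woven bone (endochondral ossification) at r_endo;
* matrix production: bone cells deposit woven bone linearly in their
  concentration and in bone_production_fold(g); chondrocytes and
  fibroblasts deposit their matrices at unmodulated base rates.

Produced matrix displaces granulation and debris first, then occupies
free (fluid) space; fractions are kept valid with priority given to the
mineralized phases if a cell would overflow. Cells dominated by cortical
bone are inert (the original cortex neither differentiates nor remodels
on the healing time scale).

The stimulus thresholds and base rates are calibration constants of the
underlying mechanistic healing model; they are exposed in full in the
run configuration and documented in the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .materials import TissueComposition
from .modulation import ModulationSet
from .transport import CellFields

__all__ = ["RuleThresholds", "EventRecord", "proliferate", "differentiate",
           "mature_and_produce"]

log = logging.getLogger(__name__)
_warned_overflow = False


@dataclass(frozen=True)
class RuleThresholds:
    """Differentiation bands and base rates (calibrated defaults).

    psi bands: distortional stimulus below ``psi_bone_max`` drives the
    osteogenic fate, up to ``psi_cartilage_max`` the chondrogenic fate,
    above it the fibrous fate; below ``psi_resorb_min`` no tissue forms
    (0 disables). Rates are per day; matrix rates are volume-fraction per
    day per (cell/cm^3).
    """

    psi_resorb_min: float = 0.0
    psi_bone_max: float = 6e-3
    psi_cartilage_max: float = 3e-2
    r_prolif: float = 0.5
    r_diff: float = 0.2
    r_mature: float = 0.15
    r_endo: float = 0.2
    r_bone_matrix: float = 8e-7
    r_cart_matrix: float = 4e-7
    r_fib_matrix: float = 2e-7
    cell_capacity: float = 2.5e5      # logistic carrying density, cells/cm^3
    event_min_cells: float = 1e3    # MSC density below which no event fires
    cortex_inert_frac: float = 0.5  # cortical fraction marking original bone

    def __post_init__(self):
        if not 0 <= self.psi_resorb_min < self.psi_bone_max < self.psi_cartilage_max:
            raise ValueError("require 0 <= psi_resorb_min < psi_bone_max "
                             "< psi_cartilage_max")
        for name in ("r_prolif", "r_diff", "r_mature", "r_endo",
                     "r_bone_matrix", "r_cart_matrix", "r_fib_matrix"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class EventRecord:
    """Per-cell differentiation bookkeeping for one macro step."""

    event_mask: np.ndarray      # chondro/osteogenic events (BMP-2 sink)
    fate: np.ndarray            # 0 none, 1 bone, 2 cartilage, 3 fibrous
    converted: np.ndarray       # MSC concentration converted this step


def proliferate(cs, g, dt: float, thr: RuleThresholds,
                modulation: ModulationSet | None = None,
                adhesion=None) -> np.ndarray:
    """Logistic MSC growth toward the carrying density.

    The instantaneous rate is r_prolif * proliferation_fold(g) *
    (1 - cs / capacity); growth stops at the carrying density.
    ``adhesion`` (in [0, 1], default 1) scales the rate by the available
    adhesion substrate: cells embedded in intact alginate, which offers no
    integrin binding sites, cannot spread and divide until the gel around
    them has degraded (pass 1 - a).
    """
    modulation = modulation or ModulationSet()
    cs = np.asarray(cs, dtype=float)
    rate = thr.r_prolif * np.asarray(modulation.proliferation_fold(g))
    if adhesion is not None:
        rate = rate * np.clip(np.asarray(adhesion, dtype=float), 0.0, 1.0)
    # exponential form of the logistic step: positive for any dt, decays
    # toward the carrying density from above
    return cs * np.exp(dt * rate * (1.0 - cs / thr.cell_capacity))


def _fate_bands(psi, thr: RuleThresholds) -> np.ndarray:
    psi = np.asarray(psi, dtype=float)
    fate = np.full(psi.shape, 3, dtype=int)               # fibrous default
    fate[psi <= thr.psi_cartilage_max] = 2
    fate[psi <= thr.psi_bone_max] = 1
    fate[psi < thr.psi_resorb_min] = 0
    return fate


def differentiate(cells: CellFields, psi, g, dt: float, thr: RuleThresholds,
                  comp: TissueComposition,
                  modulation: ModulationSet | None = None
                  ) -> tuple[CellFields, EventRecord]:
    """Convert MSCs to their strain-selected fate where BMP-2 allows it.

    Returns the updated cell fields and the event record whose mask feeds
    the BMP-2 differentiation sink (fibroblastic events excluded).
    """
    modulation = modulation or ModulationSet()
    allowed = np.asarray(modulation.differentiation_allowed(g))
    inert = comp["cortical_bone"] > thr.cortex_inert_frac
    active = allowed & (cells.cs > thr.event_min_cells) & ~inert
    fate = _fate_bands(psi, thr)
    fate = np.where(active, fate, 0)

    frac = 1.0 - np.exp(-thr.r_diff * dt)
    # differentiated cells accumulate in place; cap their density at the
    # carrying capacity so conversions stop in saturated volumes
    room = np.clip(1.0 - (cells.cb + cells.cc + cells.ch + cells.cf)
                   / thr.cell_capacity, 0.0, 1.0)
    conv = np.where(fate > 0, cells.cs * frac * room, 0.0)

    out = cells.copy()
    out.cs = cells.cs - conv
    out.cb = cells.cb + np.where(fate == 1, conv, 0.0)
    out.cc = cells.cc + np.where(fate == 2, conv, 0.0)
    out.cf = cells.cf + np.where(fate == 3, conv, 0.0)

    event_mask = (fate == 1) | (fate == 2)
    return out, EventRecord(event_mask & (conv > 0), fate, conv)


def mature_and_produce(cells: CellFields, comp: TissueComposition, psi, g,
                       dt: float, thr: RuleThresholds,
                       modulation: ModulationSet | None = None
                       ) -> tuple[CellFields, TissueComposition]:
    """Chondrocyte maturation, endochondral replacement, matrix deposition."""
    modulation = modulation or ModulationSet()
    comp = comp.copy()
    cells = cells.copy()
    inert = comp["cortical_bone"] > thr.cortex_inert_frac
    live = ~inert

    hyp = np.asarray(modulation.hypertrophy_fold(g), dtype=float)
    # chondrocytes mature to the hypertrophic phenotype; their cartilage
    # matrix calcifies at the same BMP-2-modulated rate
    m = (1.0 - np.exp(-thr.r_mature * hyp * dt)) * live
    moved = cells.cc * m
    cells.cc = cells.cc - moved
    cells.ch = cells.ch + moved
    calcified = comp["cartilage"] * m
    comp["cartilage"] = comp["cartilage"] - calcified
    comp["calcified_cartilage"] = comp["calcified_cartilage"] + calcified

    # endochondral replacement of calcified cartilage by woven bone
    e = (1.0 - np.exp(-thr.r_endo * dt)) * live
    replaced = comp["calcified_cartilage"] * e
    comp["calcified_cartilage"] = comp["calcified_cartilage"] - replaced
    comp["woven_bone"] = comp["woven_bone"] + replaced

    # matrix deposition, bone first (priority to mineralized tissue)
    bone_fold = np.asarray(modulation.bone_production_fold(g), dtype=float)
    wanted = [
        ("woven_bone", thr.r_bone_matrix * bone_fold * cells.cb * dt * live),
        ("cartilage", thr.r_cart_matrix * cells.cc * dt * live),
        ("fibrous", thr.r_fib_matrix * cells.cf * dt * live),
    ]
    overflow = False
    for target, want in wanted:
        want = np.minimum(want, 1.0)
        for source in ("granulation", "debris", None):
            room = comp[source] if source else 1.0 - comp.total()
            take = np.minimum(want, np.maximum(room, 0.0))
            if source:
                comp[source] = comp[source] - take
            comp[target] = comp[target] + take
            want = want - take
        overflow = overflow or bool(np.any(want > 1e-12))
    if overflow:
        # saturation is the normal end state of a healed volume; warn once
        global _warned_overflow
        if not _warned_overflow:
            log.warning("matrix production clipped in saturated volumes "
                        "(further occurrences logged at DEBUG)")
            _warned_overflow = True
        else:
            log.debug("matrix production clipped: composition saturated")

    comp.validate()
    return cells, comp
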