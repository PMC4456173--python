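"""Dose-dependent modulation of cell behavior by BMP-2.

Each curve maps a local BMP-2 concentration g (ng/cm^3) to a fold change
relative to untreated cells, built by monotone shape-preserving (PCHIP)
interpolation of literature anchor points on a log10 concentration axis
and clamped to the terminal anchor values outside the anchored range.
Anchors at the physiological ceiling (0.5 ng/cm^3) pin every curve to
1-fold across the physiological band 0.008-0.5 ng/cm^3, reflecting that
endogenous BMP-2 levels leave baseline cell behavior unchanged.

The five modeled effects: proliferation, chemotaxis (MSC and bone cells,
a bell peaking at 1 ng/cm^3), chondrocyte hypertrophy, bone-matrix
production, and an on/off differentiation gate at the minimum
physiological concentration g_min.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "PhysiologicalRange",
    "ModulationCurve",
    "ModulationSet",
    "DEFAULT_ANCHORS",
    "load_anchor_csv",
    "save_anchor_csv",
]


@dataclass(frozen=True)
class PhysiologicalRange:
    """Endogenous BMP-2 concentration band (ng/cm^3)."""

    g_min: float = 0.008
    g_phys_high: float = 0.5

    def __post_init__(self):
        if not 0 < self.g_min < self.g_phys_high:
            raise ValueError("require 0 < g_min < g_phys_high")


#: Anchor tables (concentration ng/cm^3, fold). The printed literature
#: anchors are kept exactly; each rising curve also carries a
#: physiological-ceiling anchor (0.5, 1) so folds are neutral across the
#: endogenous band. The 500/2000 proliferation folds are qualitative
#: defaults ("significantly reduced"), overridable via configuration.
DEFAULT_ANCHORS: dict[str, tuple[tuple[float, float], ...]] = {
    "proliferation": ((0.008, 1.0), (0.5, 1.0), (10.0, 2.0), (50.0, 2.0),
                      (200.0, 2.0), (500.0, 1.5), (2000.0, 0.8)),
    "chemotaxis_msc": ((0.008, 1.0), (0.5, 1.0), (1.0, 3.5), (100.0, 1.0)),
    "chemotaxis_bone": ((0.008, 1.0), (0.5, 1.0), (1.0, 2.2), (100.0, 1.0)),
    "hypertrophy": ((0.3, 1.0), (0.5, 1.0), (3.0, 2.0), (30.0, 3.8)),
    "bone_production": ((0.5, 1.0), (10.0, 2.3), (200.0, 5.5)),
    # alternative saturation based on the weaker marker (osteocalcin)
    "bone_production_osteocalcin": ((0.5, 1.0), (10.0, 2.3), (200.0, 3.1)),
}


class ModulationCurve:
    """Positive, continuous fold-change curve g -> fold.

    Interpolates anchors with a PCHIP scheme on log10(g), which preserves
    monotone runs between anchors (hence the bell shape of the chemotaxis
    data and the plateaus of the production data) and reproduces every
    anchor exactly. Below the first / above the last anchor the curve is
    clamped to the terminal folds.
    """

    def __init__(self, anchors: Iterable[tuple[float, float]]):
        pts = sorted((float(g), float(f)) for g, f in anchors)
        if len(pts) < 2:
            raise ValueError("need at least two anchors")
        g = np.array([p[0] for p in pts])
        f = np.array([p[1] for p in pts])
        if np.any(g <= 0):
            raise ValueError("anchor concentrations must be positive")
        if np.any(np.diff(g) == 0):
            raise ValueError("anchor concentrations must be distinct")
        if np.any(f <= 0):
            raise ValueError("anchor folds must be positive")
        self.anchors = tuple(pts)
        self._logg = np.log10(g)
        self._interp = PchipInterpolator(self._logg, f, extrapolate=False)
        self.clamp_low = f[0]
        self.clamp_high = f[-1]

    def __call__(self, g):
        g_arr = np.asarray(g, dtype=float)
        if np.any(g_arr < 0):
            raise ValueError("BMP-2 concentration must be non-negative")
        out = np.empty_like(g_arr)
        # g == 0 sits below the lowest anchor: clamp (log10 undefined)
        low = g_arr <= 10.0 ** self._logg[0]
        high = g_arr >= 10.0 ** self._logg[-1]
        mid = ~(low | high)
        out[low] = self.clamp_low
        out[high] = self.clamp_high
        if np.any(mid):
            out[mid] = self._interp(np.log10(g_arr[mid]))
        return out if out.ndim else float(out)


@dataclass
class ModulationSet:
    """The five BMP-2 effect curves plus the differentiation gate."""

    phys: PhysiologicalRange = field(default_factory=PhysiologicalRange)
    anchors: dict[str, Sequence[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self):
        tables = dict(DEFAULT_ANCHORS)
        tables.update(self.anchors)
        self._curves = {
            name: ModulationCurve(tab)
            for name, tab in tables.items()
        }

    def curve(self, name: str) -> ModulationCurve:
        return self._curves[name]

    def proliferation_fold(self, g):
        """Fold change of MSC proliferation (doubles near 10 ng/cm^3)."""
        return self._curves["proliferation"](g)

    def chemotaxis_fold(self, g, cell_kind: str = "MSC"):
        """Bell-shaped chemotactic sensitivity fold, peaking at 1 ng/cm^3.

        ``cell_kind`` is ``"MSC"`` (peak 3.5) or ``"bone"`` (peak 2.2).
        """
        kind = cell_kind.lower()
        if kind == "msc":
            return self._curves["chemotaxis_msc"](g)
        if kind == "bone":
            return self._curves["chemotaxis_bone"](g)
        raise ValueError(f"unknown cell kind: {cell_kind!r}")

    def hypertrophy_fold(self, g):
        """Chondrocyte maturation fold; saturates at 3.8 above 30 ng/cm^3."""
        return self._curves["hypertrophy"](g)

    def bone_production_fold(self, g, marker: str = "osterix"):
        """Bone matrix production fold; osterix anchoring saturates at 5.5."""
        if marker == "osterix":
            return self._curves["bone_production"](g)
        if marker == "osteocalcin":
            return self._curves["bone_production_osteocalcin"](g)
        raise ValueError(f"unknown marker: {marker!r}")

    def differentiation_allowed(self, g):
        """True where g >= g_min: differentiation needs at least the
        minimum physiological BMP-2 concentration (boundary inclusive,
        since the differentiation sink itself drives g down to g_min)."""
        g_arr = np.asarray(g, dtype=float)
        out = g_arr >= self.phys.g_min
        return out if out.ndim else bool(out)


def load_anchor_csv(path) -> tuple[tuple[float, float], ...]:
    """Read an anchor table (columns concentration_ng_per_cm3, fold)."""
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return tuple((float(g), float(f)) for g, f in data)


def save_anchor_csv(path, anchors) -> None:
    with open(path, "w") as fh:
        fh.write("concentration_ng_per_cm3,fold\n")
        for g, f in anchors:
            fh.write(f"{g},{f}\n")
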