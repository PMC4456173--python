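"""Tissue materials, per-element composition, and rule-of-mixtures averaging.

Eight solid constituents are tracked per cell as volume fractions:
debris, granulation tissue, cartilage, calcified cartilage, fibrous
tissue, woven bone, cortical bone and alginate hydrogel. Whatever is left
(1 - sum of fractions) is interstitial fluid / free space. Drained
elastic constants and permeabilities are the standard poroelastic tissue
table used by callus mechanoregulation models; element properties are the
fraction-weighted (Voigt) average over the constituents present,
renormalized over the solid content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MATERIALS", "MINERALIZED", "TissueProperties", "TissueComposition",
           "homogenize_properties"]

MATERIALS = (
    "debris",
    "granulation",
    "cartilage",
    "calcified_cartilage",
    "fibrous",
    "woven_bone",
    "cortical_bone",
    "alginate",
)

#: constituents counting as mineralized matrix for migration blocking
MINERALIZED = ("calcified_cartilage", "woven_bone", "cortical_bone")

_DEFAULT_TABLE = {
    #                       E (MPa)   nu      k (mm^2)
    "debris":              (1.85,     0.048,  7e-12),
    "granulation":         (7.79,     0.048,  1e-14),
    "cartilage":           (27.05,    0.103,  5e-15),
    "calcified_cartilage": (57.05,    0.108,  5e-15),
    "fibrous":             (80.07,    0.127,  1e-14),
    "woven_bone":          (982.48,   0.295,  1e-17),
    "cortical_bone":       (20e3,     0.3,    1e-17),
    "alginate":            (0.05,     0.048,  7e-12),
}


@dataclass(frozen=True)
class TissueProperties:
    """Drained E (MPa), Poisson ratio and permeability k (mm^2) per material.

    ``void`` properties are the floor assigned to (near-)empty cells so the
    stiffness matrix stays positive definite; they are orders of magnitude
    below any tissue and carry no physical meaning.
    """

    table: dict = field(default_factory=lambda: dict(_DEFAULT_TABLE))
    void: tuple = (0.01, 0.3, 7e-12)

    def __post_init__(self):
        for name, (E, nu, k) in self.table.items():
            if E <= 0 or k <= 0 or not 0 <= nu < 0.5:
                raise ValueError(f"invalid properties for {name}")

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        E = np.array([self.table[m][0] for m in MATERIALS])
        nu = np.array([self.table[m][1] for m in MATERIALS])
        k = np.array([self.table[m][2] for m in MATERIALS])
        return E, nu, k


class TissueComposition:
    """Per-cell volume fractions of the solid constituents.

    Stored as a ``(n_materials, ny, nx)`` array; the fluid/void remainder
    is implicit. Fractions are validated to [0, 1] with sum <= 1.
    """

    def __init__(self, shape: tuple[int, int]):
        self.shape = shape
        self.frac = np.zeros((len(MATERIALS),) + tuple(shape))

    def __getitem__(self, material: str) -> np.ndarray:
        return self.frac[MATERIALS.index(material)]

    def __setitem__(self, material: str, value) -> None:
        self.frac[MATERIALS.index(material)] = value

    def copy(self) -> "TissueComposition":
        out = TissueComposition(self.shape)
        out.frac = self.frac.copy()
        return out

    def total(self) -> np.ndarray:
        """Total solid fraction per cell."""
        return self.frac.sum(axis=0)

    def mineralized(self) -> np.ndarray:
        """Mineralized-matrix fraction (calcified cartilage + bone)."""
        return sum(self[m] for m in MINERALIZED)

    def bone(self) -> np.ndarray:
        """Bone-tissue fraction (woven + cortical)."""
        return self["woven_bone"] + self["cortical_bone"]

    def validate(self, tol: float = 1e-9) -> None:
        if np.any(self.frac < -tol) or np.any(self.frac > 1 + tol):
            raise ValueError("tissue fractions out of [0, 1]")
        if np.any(self.total() > 1 + 1e-6):
            raise ValueError("tissue fractions sum above 1")


def homogenize_properties(comp: TissueComposition,
                          props: TissueProperties | None = None,
                          solid_eps: float = 1e-6):
    """Per-cell (E, nu, k) by fraction-weighted arithmetic averaging.

    Fractions are renormalized over the solid content, so a half-full cell
    of pure granulation still behaves as granulation; cells with
    (numerically) no solid content get the void floor properties. The
    averaged E is therefore always bounded by the min/max constituent E.
    """
    props = props or TissueProperties()
    if comp.frac.size == 0:
        raise ValueError("empty composition")
    Em, num, km = props.arrays()
    solid = comp.total()
    w = comp.frac
    E = np.einsum("m,myx->yx", Em, w)
    nu = np.einsum("m,myx->yx", num, w)
    k = np.einsum("m,myx->yx", km, w)
    filled = solid > solid_eps
    E = np.where(filled, E / np.where(filled, solid, 1.0), props.void[0])
    nu = np.where(filled, nu / np.where(filled, solid, 1.0), props.void[1])
    k = np.where(filled, k / np.where(filled, solid, 1.0), props.void[2])
    return E, nu, k
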