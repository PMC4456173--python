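"""Alginate hydrogel: degradation, BMP-2 release rate, and mobility gating.

The carrier is tracked as a normalized amount a(x, t) in [0, 1]. It decays
pointwise at rate lambda_bulk + c * lambda_cell: slow hydrolytic "aging"
of the acellular gel plus a contribution proportional to the local cell
concentration (invading cells destabilize the ionic cross-links). The
update is the exact exponential, so a stays in [0, 1] and is monotone
non-increasing for any step size.

The gel gates both transport processes: the BMP-2 release rate grows as
the gel degrades, lambda_rel = lambda_rel0 * (1 - a) (more contact
surface on a degraded gel), and cell motility scales with (1 - a) since
cells cannot adhere to intact alginate. A small residual random-motility
floor keeps a weak migration channel open through intact gel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AlginateParams", "alginate_step", "release_rate", "cell_mobility"]


@dataclass(frozen=True)
class AlginateParams:
    """Hydrogel kinetic and mechanical constants.

    lambda_deg_bulk : 1/day, acellular hydrolysis rate
    lambda_deg_cell : 1/day per (cell/cm^3), cell-enhanced degradation
    lambda_rel0     : 1/day, BMP-2 release-rate scale (fully degraded gel)
    E_hg, nu_hg, k_hg : drained stiffness (MPa), Poisson ratio,
                        permeability (mm^2) of the gel
    """

    lambda_deg_bulk: float = 5e-4
    lambda_deg_cell: float = 6.5e-6
    lambda_rel0: float = 0.027
    E_hg: float = 0.05
    nu_hg: float = 0.048
    k_hg: float = 7e-12

    def __post_init__(self):
        for name in ("lambda_deg_bulk", "lambda_deg_cell", "lambda_rel0",
                     "E_hg", "nu_hg", "k_hg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _check_a(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("normalized alginate amount must lie in [0, 1]")
    return a


def alginate_step(a, c_total, dt: float, params: AlginateParams | None = None):
    """Advance the alginate field by dt days (exact pointwise exponential)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    params = params or AlginateParams()
    a = _check_a(a)
    c = np.asarray(c_total, dtype=float)
    if np.any(c < 0):
        raise ValueError("cell concentration must be non-negative")
    rate = params.lambda_deg_bulk + c * params.lambda_deg_cell
    return a * np.exp(-rate * dt)


def release_rate(a, params: AlginateParams | None = None):
    """BMP-2 release rate lambda_rel(a) = lambda_rel0 * (1 - a), 1/day."""
    params = params or AlginateParams()
    return params.lambda_rel0 * (1.0 - _check_a(a))


def cell_mobility(a, D0: float, chi0: float, floor_frac: float = 0.01):
    """Hydrogel-gated motility coefficients (D, chi).

    D = D0 * (1 - a) + eps_D * a with eps_D = floor_frac * D0: the random
    component keeps a weak floor inside intact gel. The chemotactic
    sensitivity chi = chi0 * (1 - a) vanishes entirely at a = 1 (dense gel
    blocks directed migration even in the presence of a chemical cue).
    """
    a = _check_a(a)
    eps_D = floor_frac * D0
    D = D0 * (1.0 - a) + eps_D * a
    chi = chi0 * (1.0 - a)
    return D, chi
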