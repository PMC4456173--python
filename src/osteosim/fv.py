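"""Finite-volume building blocks shared by the diffusion and transport solvers.

All operators act on cell-centered fields of shape ``(ny, nx)`` and use
zero-flux (no-leak) outer boundaries, which makes pure diffusion exactly
conservative. Face diffusivities are harmonic means, so a zero diffusivity
on either side closes the face — this is how impermeable (mineralized or
substrate-free) cells block fluxes without any special casing.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "face_harmonic",
    "transmissibilities",
    "divergence",
    "ImplicitDiffusion",
]


def face_harmonic(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Harmonic mean of two cell arrays, zero where either side is zero."""
    s = left + right
    out = np.zeros_like(s)
    pos = s > 0
    out[pos] = 2.0 * left[pos] * right[pos] / s[pos]
    return out


def transmissibilities(grid, D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Face transmissibilities T = D_face * A_face / d_centers.

    Returns ``(Tx, Ty)`` with shapes ``(ny, nx-1)`` and ``(ny-1, nx)``;
    ``Tx[j, i]`` couples cells (j, i) and (j, i+1). Units: mm^3/day per
    unit concentration for a diffusivity in mm^2/day (unit thickness).
    """
    Dx = face_harmonic(D[:, :-1], D[:, 1:])
    Dy = face_harmonic(D[:-1, :], D[1:, :])
    ddx = 0.5 * (grid.dx[:-1] + grid.dx[1:])          # center distances, x
    ddy = 0.5 * (grid.dy[:-1] + grid.dy[1:])
    Tx = Dx * grid.dy[:, None] / ddx[None, :]
    Ty = Dy * grid.dx[None, :] / ddy[:, None]
    return Tx, Ty


def divergence(grid, Tx: np.ndarray, Ty: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Net diffusive inflow per unit volume, i.e. (1/V) * sum_f T (c_nb - c)."""
    Fx = Tx * (c[:, 1:] - c[:, :-1])     # flux from (j,i) into (j,i+1) is -Fx
    Fy = Ty * (c[1:, :] - c[:-1, :])
    out = np.zeros_like(c)
    out[:, :-1] += Fx
    out[:, 1:] -= Fx
    out[:-1, :] += Fy
    out[1:, :] -= Fy
    return out / grid.cell_area


class ImplicitDiffusion:
    """Backward-Euler diffusion step (V/dt + L) c_new = (V/dt) c_old + V*src.

    The operator is refactorized whenever the diffusivity field changes
    (it does daily, as the hydrogel degrades); a single LU factorization is
    then reused for any number of right-hand sides.
    """

    def __init__(self, grid, D: np.ndarray, dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.grid = grid
        self.dt = float(dt)
        ny, nx = grid.shape
        n = ny * nx
        Tx, Ty = transmissibilities(grid, D)
        idx = np.arange(n).reshape(ny, nx)
        rows, cols, vals = [], [], []

        def couple(i, j, t):
            rows.extend([i, j, i, j])
            cols.extend([i, j, j, i])
            vals.extend([t, t, -t, -t])

        couple(idx[:, :-1].ravel(), idx[:, 1:].ravel(), Tx.ravel())
        couple(idx[:-1, :].ravel(), idx[1:, :].ravel(), Ty.ravel())
        rows = np.concatenate([np.asarray(r).ravel() for r in rows])
        cols = np.concatenate([np.asarray(c).ravel() for c in cols])
        vals = np.concatenate([np.asarray(v).ravel() for v in vals])
        L = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
        self._vol = grid.cell_area.ravel()
        A = sp.diags(self._vol / self.dt) + L
        self._lu = spla.splu(A.tocsc())

    def step(self, c: np.ndarray, source: np.ndarray | None = None) -> np.ndarray:
        """Advance one implicit step; ``source`` is a rate per unit volume."""
        rhs = self._vol / self.dt * c.ravel()
        if source is not None:
            rhs = rhs + self._vol * source.ravel()
        return self._lu.solve(rhs).reshape(self.grid.shape)
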