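"""Plane-strain finite-element mechanics and the distortional stimulus.

The loaded construct (bone fragments + interfragmentary tissue + external
fixator) is solved quasi-statically once per macro step with bilinear
quadrilateral elements, one per grid cell, using the homogenized drained
elastic constants. Boundary conditions follow the experimental setup: the
distal end plate is fixed, the axial gait load is applied as a traction
on the proximal cortical cross-section, the lower edge is the symmetry
axis, and the fixator enters as a linear spring between the end plates
(modeled as a rank-one stiffness on the mean axial displacement of the
loaded plate, the distal plate being grounded).

From the element-centroid small-strain tensor (eps_zz = 0 in plane
strain) the mechanical stimulus is computed as psi = sqrt(J2), the square
root of the second invariant of the strain deviator, so purely
volumetric deformation yields zero stimulus; raw J2 is available as a
configuration switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["LoadCase", "MechanicalState", "assemble_stiffness",
           "solve_displacements", "compute_strains", "compute_stimulus"]

_GP = 1.0 / np.sqrt(3.0)
_GAUSS = [(-_GP, -_GP), (_GP, -_GP), (_GP, _GP), (-_GP, _GP)]


@dataclass(frozen=True)
class LoadCase:
    """Axial load case for the fixated construct.

    ``axial_load`` (N) and ``fixator_stiffness`` (N/mm) refer to the full
    construct; with ``half_model=True`` (symmetric half-section) both are
    halved internally. ``cortex_band`` is the (y_lo, y_hi) range of the
    cortical wall where the end traction acts.
    """

    axial_load: float = 14.4
    fixator_stiffness: float = 277.0
    cortex_band: tuple[float, float] = (1.3, 2.0)
    half_model: bool = True

    def __post_init__(self):
        if self.axial_load < 0 or self.fixator_stiffness < 0:
            raise ValueError("load and fixator stiffness must be >= 0")

    @property
    def model_load(self) -> float:
        return self.axial_load * (0.5 if self.half_model else 1.0)

    @property
    def model_fixator(self) -> float:
        return self.fixator_stiffness * (0.5 if self.half_model else 1.0)


@dataclass
class MechanicalState:
    """Element strain tensors and the scalar stimulus field."""

    strain: np.ndarray   # (ny, nx, 3): eps_xx, eps_yy, gamma_xy
    psi: np.ndarray      # (ny, nx)


def _element_B(dx, dy, xi, eta):
    """Strain-displacement matrices, shape (ne, 3, 8), for rectangles."""
    # bilinear shape-function derivatives in natural coordinates
    dN_dxi = 0.25 * np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)])
    dN_deta = 0.25 * np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)])
    ne = dx.size
    dN_dx = np.outer(2.0 / dx, dN_dxi)       # (ne, 4)
    dN_dy = np.outer(2.0 / dy, dN_deta)
    B = np.zeros((ne, 3, 8))
    B[:, 0, 0::2] = dN_dx
    B[:, 1, 1::2] = dN_dy
    B[:, 2, 0::2] = dN_dy
    B[:, 2, 1::2] = dN_dx
    return B


def _elastic_C(E, nu):
    """Plane-strain constitutive matrices, shape (ne, 3, 3)."""
    E = np.asarray(E, dtype=float).ravel()
    nu = np.asarray(nu, dtype=float).ravel()
    f = E / ((1 + nu) * (1 - 2 * nu))
    C = np.zeros((E.size, 3, 3))
    C[:, 0, 0] = C[:, 1, 1] = f * (1 - nu)
    C[:, 0, 1] = C[:, 1, 0] = f * nu
    C[:, 2, 2] = f * (1 - 2 * nu) / 2
    return C


def _element_dofs(grid):
    """Global dof indices per element, shape (ne, 8)."""
    ny, nx = grid.shape
    node = np.arange((ny + 1) * (nx + 1)).reshape(ny + 1, nx + 1)
    n1 = node[:-1, :-1].ravel()
    n2 = node[:-1, 1:].ravel()
    n3 = node[1:, 1:].ravel()
    n4 = node[1:, :-1].ravel()
    nodes = np.stack([n1, n2, n3, n4], axis=1)        # (ne, 4) CCW
    dofs = np.empty((nodes.shape[0], 8), dtype=int)
    dofs[:, 0::2] = 2 * nodes
    dofs[:, 1::2] = 2 * nodes + 1
    return dofs


def assemble_stiffness(grid, E, nu) -> sp.csr_matrix:
    """Global stiffness matrix from per-cell elastic constants."""
    ny, nx = grid.shape
    DX = np.broadcast_to(grid.dx[None, :], (ny, nx)).ravel()
    DY = np.broadcast_to(grid.dy[:, None], (ny, nx)).ravel()
    C = _elastic_C(E, nu)
    Ke = np.zeros((DX.size, 8, 8))
    detJ = DX * DY / 4.0
    for xi, eta in _GAUSS:
        B = _element_B(DX, DY, xi, eta)
        Ke += np.einsum("eji,ejk,ekl,e->eil", B, C, B, detJ)
    dofs = _element_dofs(grid)
    rows = np.repeat(dofs, 8, axis=1).ravel()
    cols = np.tile(dofs, (1, 8)).ravel()
    ndof = 2 * grid.n_nodes
    return sp.coo_matrix((Ke.ravel(), (rows, cols)),
                         shape=(ndof, ndof)).tocsr()


def _face_nodes(grid, load: LoadCase):
    """Proximal-face node indices in the cortical band and their weights."""
    ny, nx = grid.shape
    yl, yh = load.cortex_band
    tol = 1e-9
    # nodes of the x = L face whose tributary segment overlaps the band
    ynodes = grid.yf
    trib = np.zeros(ny + 1)
    for j in range(ny):
        lo, hi = ynodes[j], ynodes[j + 1]
        ov = max(0.0, min(hi, yh) - max(lo, yl))
        trib[j] += 0.5 * ov
        trib[j + 1] += 0.5 * ov
    sel = np.nonzero(trib > tol)[0]
    if sel.size == 0:
        raise ValueError("cortex band does not intersect the loaded face")
    node_ids = sel * (nx + 1) + nx
    return node_ids, trib[sel] / trib[sel].sum()


def solve_displacements(grid, E, nu, load: LoadCase) -> np.ndarray:
    """Quasi-static displacement field, shape (n_nodes, 2) in mm.

    Raises a descriptive error if the constrained system is singular.
    """
    ny, nx = grid.shape
    K = assemble_stiffness(grid, E, nu).tolil()
    ndof = 2 * grid.n_nodes

    node_ids, w = _face_nodes(grid, load)
    F = np.zeros(ndof)
    F[2 * node_ids] = load.model_load * w

    # fixator: spring on the weighted mean axial displacement of the plate
    kf = load.model_fixator
    if kf > 0:
        ux = 2 * node_ids
        K[np.ix_(ux, ux)] = K[np.ix_(ux, ux)].toarray() + kf * np.outer(w, w)
    K = K.tocsr()

    fixed = np.zeros(ndof, dtype=bool)
    left_nodes = np.arange(0, grid.n_nodes, nx + 1)     # x = 0 plate
    fixed[2 * left_nodes] = True
    fixed[2 * left_nodes + 1] = True
    bottom_nodes = np.arange(nx + 1)                    # y = 0 symmetry axis
    fixed[2 * bottom_nodes + 1] = True

    free = ~fixed
    Kff = K[free][:, free]
    try:
        u_free = spla.spsolve(Kff.tocsc(), F[free])
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"singular mechanical system: {exc}") from exc
    if np.any(~np.isfinite(u_free)):
        raise RuntimeError("singular mechanical system: unconstrained modes "
                           "(non-finite displacements)")
    u = np.zeros(ndof)
    u[free] = u_free
    return u.reshape(-1, 2)


def compute_strains(grid, u: np.ndarray) -> np.ndarray:
    """Element-centroid small strains (eps_xx, eps_yy, gamma_xy), (ny,nx,3)."""
    ny, nx = grid.shape
    DX = np.broadcast_to(grid.dx[None, :], (ny, nx)).ravel()
    DY = np.broadcast_to(grid.dy[:, None], (ny, nx)).ravel()
    B = _element_B(DX, DY, 0.0, 0.0)
    dofs = _element_dofs(grid)
    ue = u.ravel()[dofs]                      # (ne, 8)
    eps = np.einsum("eij,ej->ei", B, ue)
    return eps.reshape(ny, nx, 3)


def compute_stimulus(strain: np.ndarray, kind: str = "sqrt_j2") -> np.ndarray:
    """Distortional stimulus from the (plane-strain) strain tensor.

    Builds the full 3x3 tensor with eps_zz = 0, removes the volumetric
    part and returns sqrt(J2) (default) or J2 of the deviator, with
    J2 = 0.5 * e_dev : e_dev. Zero for any purely volumetric state.
    """
    exx = strain[..., 0]
    eyy = strain[..., 1]
    exy = 0.5 * strain[..., 2]               # tensorial shear
    tr = exx + eyy                           # eps_zz = 0
    dxx = exx - tr / 3.0
    dyy = eyy - tr / 3.0
    dzz = -tr / 3.0
    J2 = 0.5 * (dxx**2 + dyy**2 + dzz**2 + 2.0 * exy**2)
    if kind == "sqrt_j2":
        return np.sqrt(J2)
    if kind == "j2":
        return J2
    raise ValueError(f"unknown stimulus kind: {kind!r}")
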