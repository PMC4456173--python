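"""Boundary-snapped tensor-product grid for the 2D longitudinal section.

The idealized femur section is a union of axis-aligned rectangles
(medullary canal, endosteum, cortex, periosteum, optional callus band;
bone fragments separated by the gap), so a rectilinear grid whose face
lines coincide with every region boundary resolves the geometry exactly.
Scalar fields (concentrations, alginate, stimulus, tissue fractions) are
cell-centered; the mechanics solver uses the same grid's nodes with
bilinear quadrilateral elements, one element per cell.

Lengths are in mm; the section carries unit (1 mm) out-of-plane thickness,
so a cell "volume" is dx*dy mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["segmented_faces", "Grid"]


def segmented_faces(bounds, target: float) -> np.ndarray:
    """Face coordinates subdividing each interval of ``bounds`` uniformly.

    Every entry of ``bounds`` (strictly increasing) becomes a grid face,
    which is what snaps region boundaries onto the mesh; each interval is
    split into ``ceil(width / target)`` equal pieces so no cell exceeds the
    target size.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 1 or bounds.size < 2:
        raise ValueError("bounds must contain at least two coordinates")
    if np.any(np.diff(bounds) <= 0):
        raise ValueError("bounds must be strictly increasing")
    if target <= 0:
        raise ValueError("target cell size must be positive")
    faces = [bounds[0]]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        n = max(1, int(np.ceil((hi - lo) / target - 1e-9)))
        faces.extend(np.linspace(lo, hi, n + 1)[1:])
    return np.asarray(faces)


@dataclass
class Grid:
    """Rectilinear grid defined by its x and y face coordinates.

    Cell arrays are indexed ``[iy, ix]`` with shape ``(ny, nx)``; node
    arrays have shape ``(ny + 1, nx + 1)``.
    """

    xf: np.ndarray
    yf: np.ndarray
    xc: np.ndarray = field(init=False, repr=False)
    yc: np.ndarray = field(init=False, repr=False)
    dx: np.ndarray = field(init=False, repr=False)
    dy: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.xf = np.asarray(self.xf, dtype=float)
        self.yf = np.asarray(self.yf, dtype=float)
        if np.any(np.diff(self.xf) <= 0) or np.any(np.diff(self.yf) <= 0):
            raise ValueError("face coordinates must be strictly increasing")
        self.dx = np.diff(self.xf)
        self.dy = np.diff(self.yf)
        self.xc = 0.5 * (self.xf[:-1] + self.xf[1:])
        self.yc = 0.5 * (self.yf[:-1] + self.yf[1:])

    @property
    def nx(self) -> int:
        return self.dx.size

    @property
    def ny(self) -> int:
        return self.dy.size

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def n_nodes(self) -> int:
        return (self.nx + 1) * (self.ny + 1)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def cell_area(self) -> np.ndarray:
        """Cell areas (== volumes for unit thickness), shape (ny, nx)."""
        return np.outer(self.dy, self.dx)

    def zeros(self) -> np.ndarray:
        return np.zeros(self.shape)

    def full(self, value: float) -> np.ndarray:
        return np.full(self.shape, float(value))

    # -- cell-center meshes -------------------------------------------------

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Broadcast cell-center coordinates (X, Y), each (ny, nx)."""
        return np.meshgrid(self.xc, self.yc)

    def region_mask(self, x_range=None, y_range=None) -> np.ndarray:
        """Boolean cell mask selecting centers inside the given ranges."""
        X, Y = self.centers()
        mask = np.ones(self.shape, dtype=bool)
        if x_range is not None:
            mask &= (X > x_range[0]) & (X < x_range[1])
        if y_range is not None:
            mask &= (Y > y_range[0]) & (Y < y_range[1])
        return mask

    def integrate(self, f: np.ndarray, mask: np.ndarray | None = None) -> float:
        """Area integral of a cell field, optionally over a cell mask."""
        w = self.cell_area
        if mask is not None:
            return float(np.sum(f * w * mask))
        return float(np.sum(f * w))

    def mean(self, f: np.ndarray, mask: np.ndarray) -> float:
        """Area-weighted mean of a cell field over a cell mask."""
        w = self.cell_area * mask
        total = np.sum(w)
        if total <= 0:
            raise ValueError("region mask selects no area")
        return float(np.sum(f * w) / total)
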