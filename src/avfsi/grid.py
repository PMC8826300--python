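"""Uniform Cartesian grid shared by the flow solver and the level sets.

The adaptive quadtree lives in :mod:`avfsi.amr`; field storage for the
Navier--Stokes solve uses this uniform (base-resolution) grid with a
staggered MAC arrangement:

* ``u`` on vertical faces, shape ``(nx+1, ny)``
* ``v`` on horizontal faces, shape ``(nx, ny+1)``
* ``p`` and level-set samples at cell centres, shape ``(nx, ny)``

All coordinates are in centimetres; spacing is isotropic (``dx == dy == h``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class UniformGrid:
    """Axis-aligned uniform grid over ``[x0, x0+nx*h] x [y0, y0+ny*h]``."""

    nx: int
    ny: int
    h: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell per direction")
        if not self.h > 0:
            raise ValueError("grid spacing h must be positive")

    @property
    def lx(self) -> float:
        return self.nx * self.h

    @property
    def ly(self) -> float:
        return self.ny * self.h

    @property
    def xc(self) -> np.ndarray:
        """Cell-centre x coordinates, shape (nx,)."""
        return self.x0 + (np.arange(self.nx) + 0.5) * self.h

    @property
    def yc(self) -> np.ndarray:
        """Cell-centre y coordinates, shape (ny,)."""
        return self.y0 + (np.arange(self.ny) + 0.5) * self.h

    @property
    def xf(self) -> np.ndarray:
        """Face (node) x coordinates, shape (nx+1,)."""
        return self.x0 + np.arange(self.nx + 1) * self.h

    @property
    def yf(self) -> np.ndarray:
        """Face (node) y coordinates, shape (ny+1,)."""
        return self.y0 + np.arange(self.ny + 1) * self.h

    def cell_centres(self) -> np.ndarray:
        """All cell-centre points, shape (nx*ny, 2), x fastest along axis 0."""
        X, Y = np.meshgrid(self.xc, self.yc, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel()])

    def u_face_points(self) -> np.ndarray:
        X, Y = np.meshgrid(self.xf, self.yc, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel()])

    def v_face_points(self) -> np.ndarray:
        X, Y = np.meshgrid(self.xc, self.yf, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel()])

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return (
            (pts[:, 0] >= self.x0)
            & (pts[:, 0] <= self.x0 + self.lx)
            & (pts[:, 1] >= self.y0)
            & (pts[:, 1] <= self.y0 + self.ly)
        )


def interp_cc(grid: UniformGrid, field: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a cell-centred field at arbitrary points.

    Points outside the cell-centre lattice are clamped to the boundary value
    (constant extrapolation), which is the behaviour the narrow-band level-set
    code relies on.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    gx = (pts[:, 0] - grid.x0) / grid.h - 0.5
    gy = (pts[:, 1] - grid.y0) / grid.h - 0.5
    gx = np.clip(gx, 0.0, grid.nx - 1.0)
    gy = np.clip(gy, 0.0, grid.ny - 1.0)
    i0 = np.clip(np.floor(gx).astype(int), 0, grid.nx - 2) if grid.nx > 1 else np.zeros(len(pts), int)
    j0 = np.clip(np.floor(gy).astype(int), 0, grid.ny - 2) if grid.ny > 1 else np.zeros(len(pts), int)
    tx = gx - i0
    ty = gy - j0
    f00 = field[i0, j0]
    f10 = field[np.minimum(i0 + 1, grid.nx - 1), j0]
    f01 = field[i0, np.minimum(j0 + 1, grid.ny - 1)]
    f11 = field[np.minimum(i0 + 1, grid.nx - 1), np.minimum(j0 + 1, grid.ny - 1)]
    return (
        f00 * (1 - tx) * (1 - ty)
        + f10 * tx * (1 - ty)
        + f01 * (1 - tx) * ty
        + f11 * tx * ty
    )
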