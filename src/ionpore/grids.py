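"""Regular 3D grids with validity masks.

A single container serves voxel-averaged free-energy grids (origin = center
of the first voxel) and node-based potential/dielectric grids (origin =
first node); which convention applies is the producing operation's contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError


@dataclass
class Grid3D:
    """Scalar values on a uniform cubic-spacing grid.

    Attributes
    ----------
    origin : (3,) array
        Coordinate of values[0, 0, 0] in angstrom.
    spacing : float
        Grid spacing in angstrom (same along x, y, z).
    values : (nx, ny, nz) array
        Stored quantity (kcal/mol for energies, kcal/(mol.e) for potentials).
    mask : (nx, ny, nz) bool array
        True where the value is valid.
    meta : dict
        Free-form provenance (units, species, temperature, ...).
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise InvalidParameterError("grid spacing must be > 0")
        if self.values.ndim != 3:
            raise InvalidParameterError("grid values must be a 3D array")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise InvalidParameterError("mask shape must match values shape")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise InvalidParameterError("grid values must be finite where valid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_coords(self, axis: int) -> np.ndarray:
        """Coordinates of the grid points along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing * np.arange(n)

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid (ij indexing) of point coordinates."""
        return np.meshgrid(
            self.axis_coords(0), self.axis_coords(1), self.axis_coords(2),
            indexing="ij",
        )

    def points(self) -> np.ndarray:
        """All grid-point coordinates as an (n, 3) array."""
        x, y, z = self.coords()
        return np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)


def write_opendx(grid: Grid3D, path, name: str = "potential") -> None:
    """Write a Grid3D as an OpenDX scalar field (readable by PyMOL/VMD).

    Masked points are written as 0.0; the mask itself is not representable
    in the format.
    """
    nx, ny, nz = grid.shape
    vals = np.where(grid.mask, grid.values, 0.0).ravel(order="C")
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin %.6f %.6f %.6f\n" % tuple(grid.origin))
        fh.write("delta %.6f 0.0 0.0\n" % grid.spacing)
        fh.write("delta 0.0 %.6f 0.0\n" % grid.spacing)
        fh.write("delta 0.0 0.0 %.6f\n" % grid.spacing)
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {vals.size} data follows\n"
        )
        for i in range(0, vals.size, 3):
            fh.write(" ".join("%.6e" % v for v in vals[i:i + 3]) + "\n")
        fh.write(f'object "{name}" class field\n')
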