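"""Volumetric scalar/vector fields on uniform grids, Gaussian-cube I/O,
analytic Gaussian-orbital field evaluation, and grid integration.

Every density-based descriptor in this package (ELF basin populations,
Hirshfeld-condensed Fukui functions, the IGM pair index) is evaluated on a
:class:`UniformGrid`.  Fields either come from the analytic
:class:`OrbitalModel` fixtures or are read from Gaussian cube files exported
by a quantum-chemistry code.  Positions and grid vectors are in bohr
throughout; densities in e/bohr^3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "UniformGrid",
    "ScalarField",
    "VectorField",
    "AtomSite",
    "MoleculeSpec",
    "GaussianPrimitive",
    "Orbital",
    "OrbitalModel",
    "CubeFormatError",
    "read_cube",
    "write_cube",
    "evaluate_model_fields",
    "integrate_field",
    "default_grid",
    "ELEMENTS",
]

# element symbol <-> atomic number for the organic subset this package meets
ELEMENTS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Si": 14, "P": 15, "S": 16,
    "Cl": 17,
}
_SYMBOL_BY_Z = {z: s for s, z in ELEMENTS.items()}

ANGSTROM_TO_BOHR = 1.0 / 0.52917721067


class CubeFormatError(ValueError):
    """Raised for a malformed or inconsistent Gaussian cube file."""


@dataclass(frozen=True)
class UniformGrid:
    """Regular 3-D grid: ``point(i,j,k) = origin + i*a0 + j*a1 + k*a2``.

    Attributes
    ----------
    origin : (3,) array, bohr
    axes : (3, 3) array, bohr — row ``m`` is the step vector for index ``m``
    shape : (3,) ints — number of points along each index
    """

    origin: np.ndarray
    axes: np.ndarray
    shape: tuple[int, int, int]

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        shape = tuple(int(n) for n in self.shape)
        if any(n < 2 for n in shape):
            raise ValueError(f"grid needs >= 2 points per axis, got {shape}")
        if abs(np.linalg.det(axes)) <= 0.0:
            raise ValueError("grid axes are singular (zero cell volume)")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "shape", shape)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.axes)))

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    @property
    def is_orthogonal(self) -> bool:
        off = self.axes @ self.axes.T - np.diag(np.sum(self.axes**2, axis=1))
        return bool(np.allclose(off, 0.0, atol=1e-12))

    def points(self) -> np.ndarray:
        """All grid points as an ``(nx, ny, nz, 3)`` array (bohr)."""
        idx = np.indices(self.shape).astype(float)  # (3, nx, ny, nz)
        pts = np.tensordot(idx, self.axes, axes=(0, 0))
        return pts + self.origin

    def __eq__(self, other):
        if not isinstance(other, UniformGrid):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.axes, other.axes)
        )


@dataclass
class ScalarField:
    """One scalar value per grid point (C-order: last index fastest)."""

    grid: UniformGrid
    values: np.ndarray
    quantity: str = ""
    units: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).reshape(self.grid.shape)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in field {self.quantity!r}")


@dataclass
class VectorField:
    """Three scalar components per grid point (e.g. a density gradient)."""

    grid: UniformGrid
    components: np.ndarray  # (3, nx, ny, nz)
    quantity: str = ""

    def __post_init__(self):
        comp = np.asarray(self.components, dtype=float)
        self.components = comp.reshape((3, *self.grid.shape))
        if not np.all(np.isfinite(self.components)):
            raise ValueError(f"non-finite components in field {self.quantity!r}")

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.components**2, axis=0))


@dataclass(frozen=True)
class AtomSite:
    """A nucleus: element symbol, atomic number and position (bohr)."""

    element: str
    Z: int
    position: np.ndarray

    def __post_init__(self):
        if self.Z < 1:
            raise ValueError(f"atomic number must be >= 1, got {self.Z}")
        expected = ELEMENTS.get(self.element)
        if expected is not None and expected != self.Z:
            raise ValueError(f"element {self.element} inconsistent with Z={self.Z}")
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )


@dataclass(frozen=True)
class MoleculeSpec:
    """Atom list plus net charge; electron count N0 = sum(Z) - charge."""

    atoms: tuple[AtomSite, ...]
    charge: int = 0

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        if self.n_electrons < 1:
            raise ValueError("molecule must have at least one electron")

    @property
    def n_electrons(self) -> int:
        return sum(a.Z for a in self.atoms) - self.charge

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


@dataclass(frozen=True)
class GaussianPrimitive:
    """Atom-centered s or p Cartesian Gaussian.

    ``kind`` is "s", "px", "py" or "pz"; normalized so <g|g> = 1.
    """

    center: np.ndarray
    alpha: float
    kind: str = "s"

    def __post_init__(self):
        if self.kind not in ("s", "px", "py", "pz"):
            raise ValueError(f"unsupported primitive kind {self.kind!r}")
        if self.alpha <= 0:
            raise ValueError("Gaussian exponent must be positive")
        object.__setattr__(
            self, "center", np.asarray(self.center, dtype=float).reshape(3)
        )

    @property
    def norm(self) -> float:
        a = self.alpha
        if self.kind == "s":
            return (2.0 * a / np.pi) ** 0.75
        return (128.0 * a**5 / np.pi**3) ** 0.25

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        d = pts - self.center
        r2 = np.sum(d * d, axis=-1)
        g = self.norm * np.exp(-self.alpha * r2)
        if self.kind == "s":
            return g
        axis = {"px": 0, "py": 1, "pz": 2}[self.kind]
        return d[..., axis] * g

    def gradient(self, pts: np.ndarray) -> np.ndarray:
        """Closed-form Cartesian gradient, shape ``pts.shape``."""
        d = pts - self.center
        r2 = np.sum(d * d, axis=-1)
        e = self.norm * np.exp(-self.alpha * r2)
        if self.kind == "s":
            return -2.0 * self.alpha * d * e[..., None]
        axis = {"px": 0, "py": 1, "pz": 2}[self.kind]
        grad = -2.0 * self.alpha * d * (d[..., axis] * e)[..., None]
        grad[..., axis] += e
        return grad


@dataclass(frozen=True)
class Orbital:
    """Contraction of primitives: psi = sum_k c_k g_k."""

    primitives: tuple[GaussianPrimitive, ...]
    coefficients: tuple[float, ...]

    def __post_init__(self):
        if len(self.primitives) != len(self.coefficients):
            raise ValueError("one coefficient per primitive required")
        object.__setattr__(self, "primitives", tuple(self.primitives))
        object.__setattr__(
            self, "coefficients", tuple(float(c) for c in self.coefficients)
        )

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        out = np.zeros(pts.shape[:-1])
        for c, g in zip(self.coefficients, self.primitives):
            out += c * g(pts)
        return out

    def gradient(self, pts: np.ndarray) -> np.ndarray:
        out = np.zeros(pts.shape)
        for c, g in zip(self.coefficients, self.primitives):
            out += c * g.gradient(pts)
        return out


@dataclass(frozen=True)
class OrbitalModel:
    """Occupied-orbital set standing in for a wavefunction.

    Occupations are per spatial orbital, 0 < occ <= 2; their sum must equal
    the electron count of the owning molecule.
    """

    orbitals: tuple[Orbital, ...]
    occupations: tuple[float, ...]

    def __post_init__(self):
        if len(self.orbitals) != len(self.occupations):
            raise ValueError("one occupation per orbital required")
        if len(self.orbitals) == 0:
            raise ValueError("orbital set is empty")
        for occ in self.occupations:
            if not (0.0 < occ <= 2.0):
                raise ValueError(f"occupation {occ} outside (0, 2]")
        object.__setattr__(self, "orbitals", tuple(self.orbitals))
        object.__setattr__(
            self, "occupations", tuple(float(o) for o in self.occupations)
        )

    @property
    def n_electrons(self) -> float:
        return float(sum(self.occupations))


def default_grid(
    mol: MoleculeSpec, spacing: float = 0.2, margin: float = 5.0
) -> UniformGrid:
    """Orthogonal grid covering the molecule's bounding box plus a margin.

    Defaults (0.2 bohr spacing, 5 bohr margin) give grid-converged descriptor
    plateaus for the fixture models at desk-scale cost.
    """
    pos = mol.positions
    lo = pos.min(axis=0) - margin
    hi = pos.max(axis=0) + margin
    shape = tuple(int(np.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    axes = np.eye(3) * spacing
    return UniformGrid(origin=lo, axes=axes, shape=shape)


def evaluate_model_fields(
    mol: MoleculeSpec, orbitals: OrbitalModel, grid: UniformGrid
) -> tuple[ScalarField, VectorField, ScalarField]:
    """Evaluate density, density gradient and orbital-gradient-square sum.

    Returns
    -------
    density : ScalarField
        rho = sum_i occ_i psi_i^2  (e/bohr^3)
    density_gradient : VectorField
        grad rho = sum_i occ_i 2 psi_i grad psi_i, analytic
    orbital_gradient_sum : ScalarField
        sum_i occ_i |grad psi_i|^2, the ingredient of the Pauli kinetic
        energy density
    """
    pts = grid.points()
    rho = np.zeros(grid.shape)
    grad = np.zeros((*grid.shape, 3))
    grad2sum = np.zeros(grid.shape)
    for occ, orb in zip(orbitals.occupations, orbitals.orbitals):
        psi = orb(pts)
        dpsi = orb.gradient(pts)
        rho += occ * psi**2
        grad += occ * 2.0 * psi[..., None] * dpsi
        grad2sum += occ * np.sum(dpsi**2, axis=-1)
    density = ScalarField(grid, rho, quantity="density", units="e/bohr^3")
    gradient = VectorField(grid, np.moveaxis(grad, -1, 0), quantity="density_gradient")
    gradsum = ScalarField(grid, grad2sum, quantity="orbital_gradient_sum",
                          units="e/bohr^5")
    return density, gradient, gradsum


def integrate_field(field: ScalarField, mask: np.ndarray | None = None) -> float:
    """Midpoint Riemann sum: sum(values) * |det(axes)|.

    An optional boolean ``mask`` restricts the sum to a voxel subset (used
    for basin populations and Hirshfeld weights).
    """
    vals = field.values
    if mask is not None:
        mask = np.asarray(mask, dtype=bool).reshape(field.grid.shape)
        vals = vals[mask]
    return float(vals.sum() * field.grid.voxel_volume)


# ---------------------------------------------------------------------------
# Gaussian cube dialect
# ---------------------------------------------------------------------------

def write_cube(
    mol: MoleculeSpec,
    fld: ScalarField,
    path: str | Path,
    comment: str = "pyroepl volumetric field",
) -> None:
    """Write a field in the Gaussian cube dialect (positions in bohr).

    Header: two comment lines; natoms + origin; three axis records
    (npts + step vector); atom records (Z, charge, x, y, z); then values with
    the third (z) index varying fastest, six per line.
    """
    if len(mol.atoms) == 0:
        raise ValueError("cube format requires at least one atom")
    if fld.values.shape != fld.grid.shape:
        raise ValueError("field values inconsistent with its grid shape")
    path = Path(path)
    g = fld.grid
    lines = [comment, f"field: {fld.quantity or 'scalar'} [{fld.units or '-'}]"]
    lines.append(
        f"{len(mol.atoms):5d} {g.origin[0]:12.6f} {g.origin[1]:12.6f} {g.origin[2]:12.6f}"
    )
    for m in range(3):
        a = g.axes[m]
        lines.append(f"{g.shape[m]:5d} {a[0]:12.6f} {a[1]:12.6f} {a[2]:12.6f}")
    for atom in mol.atoms:
        x, y, z = atom.position
        lines.append(f"{atom.Z:5d} {float(atom.Z):12.6f} {x:12.6f} {y:12.6f} {z:12.6f}")
    flat = fld.values.reshape(-1)  # C order: z fastest
    for start in range(0, flat.size, 6):
        chunk = flat[start : start + 6]
        lines.append(" ".join(f"{v:13.5E}" for v in chunk))
    path.write_text("\n".join(lines) + "\n")


def read_cube(path: str | Path) -> tuple[MoleculeSpec, ScalarField]:
    """Read a Gaussian cube file; returns the molecule and the scalar field.

    Positive voxel counts mean bohr (the only dialect written here; negative
    counts, the Angstrom convention, are converted).  Non-orthogonal axes are
    accepted and flagged in ``field.metadata['orthogonal'] = False``.
    """
    path = Path(path)
    text = path.read_text().split("\n")
    if len(text) < 7:
        raise CubeFormatError(f"{path}: truncated cube header")
    try:
        hdr = text[2].split()
        natoms = int(hdr[0])
        origin = np.array([float(x) for x in hdr[1:4]])
        axes = np.zeros((3, 3))
        shape = [0, 0, 0]
        scale = [1.0, 1.0, 1.0]
        for m in range(3):
            rec = text[3 + m].split()
            n = int(rec[0])
            if n < 0:  # negative count flags Angstrom units
                n = -n
                scale[m] = ANGSTROM_TO_BOHR
            shape[m] = n
            axes[m] = np.array([float(x) for x in rec[1:4]]) * scale[m]
    except (IndexError, ValueError) as exc:
        raise CubeFormatError(f"{path}: malformed cube header") from exc
    if natoms <= 0:
        raise CubeFormatError(f"{path}: cube declares {natoms} atoms")
    atoms = []
    try:
        for k in range(natoms):
            rec = text[6 + k].split()
            z = int(rec[0])
            pos = np.array([float(x) for x in rec[2:5]])
            atoms.append(AtomSite(_SYMBOL_BY_Z.get(z, f"Z{z}"), z, pos))
    except (IndexError, ValueError) as exc:
        raise CubeFormatError(f"{path}: malformed atom record") from exc
    values = []
    for line in text[6 + natoms :]:
        values.extend(float(x) for x in line.split())
    n_expected = int(np.prod(shape))
    if len(values) != n_expected:
        raise CubeFormatError(
            f"{path}: {len(values)} values for a {shape[0]}x{shape[1]}x{shape[2]} "
            f"grid ({n_expected} expected)"
        )
    grid = UniformGrid(origin=origin, axes=axes, shape=tuple(shape))
    fld = ScalarField(grid, np.array(values).reshape(grid.shape))
    fld.metadata["orthogonal"] = grid.is_orthogonal
    fld.metadata["source"] = str(path)
    mol = MoleculeSpec(atoms=tuple(atoms))
    return mol, fld


def write_field_metadata(fld: ScalarField, path: str | Path) -> None:
    """Write a JSON sidecar with the field's label, units and metadata."""
    payload = {"quantity": fld.quantity, "units": fld.units, **fld.metadata}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def cartesian_gradient(fld: ScalarField) -> VectorField:
    """Numerical (central-difference) Cartesian gradient of a scalar field.

    Differentiates along grid indices, then maps index derivatives to
    Cartesian components through the inverse axes matrix, so sheared grids
    are handled correctly.
    """
    g = fld.grid
    d_idx = np.stack(np.gradient(fld.values), axis=0)  # d/di, d/dj, d/dk
    inv = np.linalg.inv(g.axes)  # d(index_m)/d(r_c) = inv[c, m]
    cart = np.einsum("cm,m...->c...", inv, d_idx)
    return VectorField(g, cart, quantity=f"grad({fld.quantity})")
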