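"""Electron localization function (ELF), basin partitioning and populations.

The ELF

    eta(r) = 1 / (1 + (tau_P / tau_H)^2),   0 <= eta <= 1

compares the local Pauli kinetic energy density

    tau_P(r) = 1/2 sum_i occ_i |grad psi_i|^2 - 1/8 |grad rho|^2 / rho

with the Thomas-Fermi reference tau_H(r) = 3/5 (6 pi^2)^(2/3) rho^(5/3).
Maxima of eta mark cores, lone pairs and two-center bonds; the gradient
field of eta partitions space into basins, one per attractor, and the
electron population of a basin is the density integral over it.  The
populations of all basins close to the molecular electron count.

Basin assignment here is an on-grid steepest-ascent (watershed-by-flooding
in reverse): each voxel follows its highest-eta neighbor under
26-connectivity until a local maximum; grid maxima closer than a merge
radius are fused into a single attractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid_fields import (
    MoleculeSpec,
    ScalarField,
    VectorField,
    integrate_field,
)
from .hirshfeld_fukui import FreeAtomDensity, free_atom_density

__all__ = [
    "ElfField",
    "BasinPartition",
    "BasinReport",
    "compute_elf",
    "partition_basins",
    "basin_populations",
    "disynaptic_bond_populations",
    "basin_report_table",
    "RHO_MIN",
]

#: density floor (e/bohr^3) below which ELF is numerically meaningless
#: (the tau_P/tau_H ratio degenerates to 0/0 as rho -> 0)
RHO_MIN = 1e-6

_TF_CONST = 0.6 * (6.0 * np.pi**2) ** (2.0 / 3.0)  # 3/5 (6 pi^2)^(2/3)


@dataclass
class ElfField:
    """ELF values on a grid plus references to the fields they came from.

    The ingredient references are None when the ELF arrived precomputed
    (e.g. from a cube file) rather than from :func:`compute_elf`.
    """

    field: ScalarField
    density: ScalarField | None = None
    tau_pauli: ScalarField | None = None
    tau_thomas_fermi: ScalarField | None = None

    def __post_init__(self):
        vals = self.field.values
        if vals.min() < -1e-12 or vals.max() > 1.0 + 1e-12:
            raise ValueError("ELF values outside [0, 1]")


@dataclass
class BasinPartition:
    """Voxel labels (>= 0; -1 below the density floor) and attractors."""

    labels: np.ndarray  # int array, grid shape
    attractors: list[dict]  # per label: {"position", "eta", "flat_index"}

    @property
    def n_basins(self) -> int:
        return len(self.attractors)


@dataclass
class BasinReport:
    """Population and synaptic classification of one basin."""

    label: int
    population: float
    synaptic_class: str  # "core" | "monosynaptic" | "disynaptic" | "polysynaptic"
    atoms: tuple[int, ...]  # connected atom indices
    attractor_position: np.ndarray = field(default=None)
    attractor_eta: float = 0.0


def compute_elf(
    density: ScalarField,
    density_gradient: VectorField,
    orbital_gradient_sum: ScalarField,
    rho_min: float = RHO_MIN,
) -> ElfField:
    """ELF from density, its gradient and the orbital-gradient-square sum.

    tau_P is clamped at zero from below (it is positive-definite in exact
    arithmetic; small negatives are finite-precision noise).  Voxels with
    rho < rho_min get eta = 0.
    """
    grid = density.grid
    if density_gradient.grid != grid or orbital_gradient_sum.grid != grid:
        raise ValueError("ELF ingredient fields live on different grids")
    rho = density.values
    if rho.min() < -1e-10:
        raise ValueError("negative density")
    live = rho >= rho_min
    grad2 = np.sum(density_gradient.components**2, axis=0)

    tau_p = np.zeros_like(rho)
    np.divide(grad2, rho, out=tau_p, where=live)
    tau_p = 0.5 * orbital_gradient_sum.values - 0.125 * tau_p
    tau_p = np.where(live, np.maximum(tau_p, 0.0), 0.0)

    tau_h = _TF_CONST * np.maximum(rho, 0.0) ** (5.0 / 3.0)

    chi = np.zeros_like(rho)  # tau_P / tau_H
    np.divide(tau_p, tau_h, out=chi, where=live & (tau_h > 0.0))
    eta = np.where(live, 1.0 / (1.0 + chi**2), 0.0)

    return ElfField(
        field=ScalarField(grid, eta, quantity="elf", units=""),
        density=density,
        tau_pauli=ScalarField(grid, tau_p, quantity="tau_pauli"),
        tau_thomas_fermi=ScalarField(grid, tau_h, quantity="tau_thomas_fermi"),
    )


def _neighbor_offsets(shape) -> list[int]:
    """Flat-index offsets of the 26 neighbors, ascending (deterministic)."""
    _, ny, nz = shape
    offs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) != (0, 0, 0):
                    offs.append(di * ny * nz + dj * nz + dk)
    return sorted(offs)


def _shifted(padded: np.ndarray, di: int, dj: int, dk: int, shape) -> np.ndarray:
    nx, ny, nz = shape
    return padded[1 + di : nx + 1 + di, 1 + dj : ny + 1 + dj, 1 + dk : nz + 1 + dk]


def _steepest_ascent_parents(work: np.ndarray) -> np.ndarray:
    """Flat parent index per voxel under plateau-aware steepest ascent.

    Each live voxel points to its strictly highest 26-connected neighbor
    (ties broken by the lowest flat-index offset).  Voxels with no strictly
    higher neighbor lie on a plateau: they are resolved by geodesic
    propagation from any equal-valued neighbor that already has an uphill
    path; connected plateaus with no higher rim are true maximal regions and
    collapse onto one root (their lowest flat-index voxel).  Values must be
    pre-quantized by the caller so float noise does not split plateaus;
    excluded voxels hold -inf and point to themselves.
    """
    shape = work.shape
    nx, ny, nz = shape
    padded = np.full((nx + 2, ny + 2, nz + 2), -np.inf)
    padded[1:-1, 1:-1, 1:-1] = work

    shifts = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                off = di * ny * nz + dj * nz + dk
                shifts.append((off, di, dj, dk))
    shifts.sort()  # ascending flat offset = deterministic tie order

    best_val = np.full(shape, -np.inf)
    best_off = np.zeros(shape, dtype=np.int64)
    for off, di, dj, dk in shifts:
        cand = _shifted(padded, di, dj, dk, shape)
        better = cand > best_val
        best_val[better] = cand[better]
        best_off[better] = off

    flat = np.arange(work.size, dtype=np.int64)
    live = np.isfinite(work).reshape(-1)
    uphill = (best_val > work).reshape(-1) & live
    parents = flat.copy()
    parents[uphill] = flat[uphill] + best_off.reshape(-1)[uphill]

    # plateau resolution: a flat voxel adopts the lowest-offset equal-valued
    # neighbor that already has an uphill path
    resolved = uphill | ~live
    flat_mask3 = (~resolved.reshape(shape)) & np.isfinite(work)
    while True:
        res3 = resolved.reshape(shape)
        res_pad = np.zeros((nx + 2, ny + 2, nz + 2), dtype=bool)
        res_pad[1:-1, 1:-1, 1:-1] = res3 & np.isfinite(work)
        adopted = np.zeros(shape, dtype=bool)
        new_parent_off = np.zeros(shape, dtype=np.int64)
        for off, di, dj, dk in shifts:
            cand_val = _shifted(padded, di, dj, dk, shape)
            cand_res = _shifted(res_pad, di, dj, dk, shape)
            ok = flat_mask3 & ~adopted & cand_res & (cand_val == work)
            new_parent_off[ok] = off
            adopted |= ok
        if not adopted.any():
            break
        af = adopted.reshape(-1)
        parents[af] = flat[af] + new_parent_off.reshape(-1)[af]
        resolved |= af
        flat_mask3 &= ~adopted

    # remaining flat voxels form maximal plateaus; each connected component
    # is one attractor rooted at its lowest flat index
    if flat_mask3.any():
        from scipy import ndimage

        comp, ncomp = ndimage.label(flat_mask3, structure=np.ones((3, 3, 3)))
        comp_flat = comp.reshape(-1)
        for c in range(1, ncomp + 1):
            members = np.flatnonzero(comp_flat == c)
            parents[members] = members.min()
    return parents


def partition_basins(
    elf: ElfField,
    density: ScalarField | None = None,
    rho_min: float = RHO_MIN,
    merge_radius: float = 0.3,
) -> BasinPartition:
    """Assign every voxel with rho >= rho_min to an ELF attractor basin.

    Grid-resolution maxima of one physical attractor are merged when their
    positions lie within ``merge_radius`` (bohr) of each other.
    """
    if density is None:
        density = elf.density
    grid = elf.field.grid
    if density.grid != grid:
        raise ValueError("density grid differs from ELF grid")
    mask = density.values >= rho_min
    if not mask.any():
        raise ValueError("no voxel reaches the density floor")
    eta = elf.field.values
    if np.ptp(eta[mask]) == 0.0 and mask.all():
        # a constant field with no density-floor boundary carries no
        # topological information at all; a constant field on a *bounded*
        # live region (single-orbital systems, where eta = 1 identically)
        # is legitimate and yields the live region as one basin
        raise ValueError("ELF field is constant on the whole grid: no maxima")

    # quantize so float-level noise cannot split a physical plateau
    work = np.where(mask, np.round(eta, 9), -np.inf)
    parents = _steepest_ascent_parents(work)
    # pointer doubling until every chain terminates at a root
    while True:
        nxt = parents[parents]
        if np.array_equal(nxt, parents):
            break
        parents = nxt

    flat_mask = mask.reshape(-1)
    roots = np.unique(parents[flat_mask])
    root_pos = np.array(
        [_flat_to_position(grid, r) for r in roots]
    )
    # merge roots closer than merge_radius (transitive closure over the
    # small attractor set)
    groups = _merge_close(root_pos, merge_radius)
    root_to_group = {}
    attractors = []
    eta_flat = eta.reshape(-1)
    for gi, members in enumerate(groups):
        member_roots = [roots[m] for m in members]
        # representative: highest eta, then lowest flat index
        rep = min(member_roots, key=lambda r: (-eta_flat[r], r))
        for r in member_roots:
            root_to_group[r] = gi
        attractors.append(
            {
                "position": _flat_to_position(grid, rep),
                "eta": float(eta_flat[rep]),
                "flat_index": int(rep),
            }
        )
    labels = np.full(grid.n_points, -1, dtype=np.int64)
    lut = np.zeros(grid.n_points, dtype=np.int64)
    for r, gi in root_to_group.items():
        lut[r] = gi
    labels[flat_mask] = lut[parents[flat_mask]]
    return BasinPartition(labels=labels.reshape(grid.shape), attractors=attractors)


def _flat_to_position(grid, flat_index: int) -> np.ndarray:
    idx = np.unravel_index(int(flat_index), grid.shape)
    return grid.origin + np.array(idx, dtype=float) @ grid.axes


def _merge_close(positions: np.ndarray, radius: float) -> list[list[int]]:
    """Connected components of the within-radius graph (union-find)."""
    n = len(positions)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(positions[i] - positions[j]) <= radius:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    # deterministic ordering: by lowest member index
    return sorted(comps.values(), key=lambda m: min(m))


#: attractor-to-nucleus distance (bohr) under which a basin is a core basin
CORE_RADIUS = 0.35
#: free-atom density share of the promolecule above which an atom counts as
#: connected to a valence basin
CONNECT_FRACTION = 0.05


def basin_populations(
    partition: BasinPartition,
    density: ScalarField,
    mol: MoleculeSpec,
    free_atoms: list[FreeAtomDensity] | None = None,
) -> tuple[list[BasinReport], dict]:
    """Integrate the density over every basin and classify each basin.

    Classification: an attractor within ``CORE_RADIUS`` of a nucleus with
    Z > 2 makes a core basin; otherwise the basin is valence and is
    connected to each atom whose free-atom density at the attractor exceeds
    ``CONNECT_FRACTION`` of the promolecule density there — exactly two such
    atoms make a disynaptic basin V(A,B).

    Returns the reports plus a closure summary: the basin populations and
    the below-floor residue add up to the total density integral exactly,
    because the basin masks partition the grid.
    """
    if partition.labels.shape != density.grid.shape:
        raise ValueError("partition and density grids differ")
    if free_atoms is None:
        free_atoms = [free_atom_density(a.Z) for a in mol.atoms]
    total = integrate_field(density)
    reports = []
    assigned = 0.0
    for lab, att in enumerate(partition.attractors):
        mask = partition.labels == lab
        pop = integrate_field(density, mask=mask)
        assigned += pop
        pos = att["position"]
        dists = np.linalg.norm(mol.positions - pos, axis=1)
        zs = np.array([a.Z for a in mol.atoms])
        near_heavy = (dists <= CORE_RADIUS) & (zs > 2)
        if near_heavy.any():
            cls = "core"
            atoms = (int(np.argmin(np.where(near_heavy, dists, np.inf))),)
        else:
            free_here = np.array(
                [fa(np.linalg.norm(pos - a.position))
                 for a, fa in zip(mol.atoms, free_atoms)]
            )
            promol = free_here.sum()
            connected = np.where(free_here >= CONNECT_FRACTION * promol)[0]
            atoms = tuple(int(i) for i in connected)
            cls = {1: "monosynaptic", 2: "disynaptic"}.get(
                len(atoms), "polysynaptic"
            )
        reports.append(
            BasinReport(
                label=lab,
                population=pop,
                synaptic_class=cls,
                atoms=atoms,
                attractor_position=np.asarray(pos),
                attractor_eta=att["eta"],
            )
        )
    closure = {
        "total_integral": total,
        "assigned": assigned,
        "residue_below_floor": total - assigned,
    }
    return reports, closure


def disynaptic_bond_populations(
    reports: list[BasinReport],
    mol: MoleculeSpec,
    element_pairs: frozenset = frozenset({frozenset({"C", "O"}), frozenset({"C", "C"})}),
) -> dict[tuple[int, int], float]:
    """Electron populations of disynaptic basins on selected element pairs.

    By default only C-O and C-C bonds are exported (those are the bonds the
    barrier models consume).  Basins sharing one atom pair are summed.
    """
    out: dict[tuple[int, int], float] = {}
    for rep in reports:
        if rep.synaptic_class != "disynaptic":
            continue
        a, b = sorted(rep.atoms)
        pair_elems = frozenset({mol.atoms[a].element, mol.atoms[b].element})
        if pair_elems in element_pairs:
            out[(a, b)] = out.get((a, b), 0.0) + rep.population
    return out


def basin_report_table(reports: list[BasinReport]) -> pd.DataFrame:
    """Reports as a tidy table (label, class, atoms, population)."""
    return pd.DataFrame(
        {
            "label": [r.label for r in reports],
            "synaptic_class": [r.synaptic_class for r in reports],
            "atoms": ["-".join(str(i) for i in r.atoms) for r in reports],
            "population": [r.population for r in reports],
        }
    )
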