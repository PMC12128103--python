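"""ELF closed forms, basin partitioning and population closure."""

import numpy as np
import pytest

from pyroepl.elf_topology import (
    RHO_MIN,
    ElfField,
    basin_populations,
    compute_elf,
    disynaptic_bond_populations,
    partition_basins,
)
from pyroepl.grid_fields import (
    AtomSite,
    MoleculeSpec,
    ScalarField,
    UniformGrid,
    VectorField,
    integrate_field,
)


def _uniform_fields(shape=(4, 4, 4), rho_val=0.1, gradsum_val=1.0,
                    grad_val=0.0):
    grid = UniformGrid(origin=(0, 0, 0), axes=np.eye(3) * 0.5, shape=shape)
    rho = ScalarField(grid, np.full(shape, rho_val), quantity="density")
    grad = VectorField(grid, np.full((3, *shape), grad_val))
    gsum = ScalarField(grid, np.full(shape, gradsum_val))
    return rho, grad, gsum


class TestComputeElf:
    def test_equal_kinetic_densities_give_half(self):
        # choose rho so tau_H matches the constructed tau_P exactly
        rho_val = 0.1
        tau_h = 0.6 * (6 * np.pi**2) ** (2 / 3) * rho_val ** (5 / 3)
        rho, grad, gsum = _uniform_fields(rho_val=rho_val,
                                          gradsum_val=2.0 * tau_h)
        elf = compute_elf(rho, grad, gsum)
        assert np.allclose(elf.field.values, 0.5)

    def test_triple_reference_ratio(self):
        # tau_P = 3 tau_H  ->  eta = 1/(1 + 9) = 0.1
        rho_val = 0.1
        tau_h = 0.6 * (6 * np.pi**2) ** (2 / 3) * rho_val ** (5 / 3)
        rho, grad, gsum = _uniform_fields(rho_val=rho_val,
                                          gradsum_val=6.0 * tau_h)
        elf = compute_elf(rho, grad, gsum)
        assert np.allclose(elf.field.values, 0.1)

    def test_single_orbital_model_is_fully_localized(self, evaluated):
        # one doubly occupied orbital: the Pauli excess vanishes identically,
        # so eta = 1 wherever the density is meaningful
        data = evaluated["homonuclear_2e"]
        rho = data["density"]
        grad2 = np.sum(data["gradient"].components ** 2, axis=0)
        live = rho.values >= RHO_MIN
        ratio = np.zeros_like(grad2)
        np.divide(grad2, rho.values, out=ratio, where=live)
        tau_p = 0.5 * data["gradient_sum"].values - 0.125 * ratio
        assert np.abs(tau_p[live]).max() < 1e-8
        elf = compute_elf(rho, data["gradient"], data["gradient_sum"])
        assert np.all(elf.field.values[live] == 1.0)

    def test_eta_bounded_on_every_toy_model(self, evaluated):
        for data in evaluated.values():
            elf = compute_elf(data["density"], data["gradient"],
                              data["gradient_sum"])
            assert elf.field.values.min() >= 0.0
            assert elf.field.values.max() <= 1.0

    def test_grid_mismatch_rejected(self):
        rho, grad, gsum = _uniform_fields()
        other = UniformGrid(origin=(1, 0, 0), axes=np.eye(3) * 0.5,
                            shape=(4, 4, 4))
        gsum_other = ScalarField(other, gsum.values)
        with pytest.raises(ValueError, match="different grids"):
            compute_elf(rho, grad, gsum_other)


def _surrogate_elf(grid, eta_values, rho_values):
    """Package a hand-made eta field (and density) as an ElfField."""
    eta = ScalarField(grid, eta_values, quantity="elf")
    rho = ScalarField(grid, rho_values, quantity="density")
    return ElfField(field=eta, density=rho), rho


class TestPartitionBasins:
    def test_single_maximum_gives_one_basin(self):
        grid = UniformGrid(origin=(-3, -3, -3), axes=np.eye(3) * 0.25,
                           shape=(25, 25, 25))
        r2 = np.sum(grid.points() ** 2, axis=-1)
        eta = np.exp(-r2)
        elf, rho = _surrogate_elf(grid, eta, np.full(grid.shape, 1.0))
        part = partition_basins(elf, rho)
        assert part.n_basins == 1
        assert np.all(part.labels >= 0)

    def test_two_symmetric_maxima_split_at_midplane(self):
        grid = UniformGrid(origin=(-6, -2, -2), axes=np.eye(3) * 0.2,
                           shape=(61, 21, 21))
        pts = grid.points()
        eta = (np.exp(-np.sum((pts - [-2.5, 0, 0]) ** 2, axis=-1))
               + np.exp(-np.sum((pts - [2.5, 0, 0]) ** 2, axis=-1)))
        rho = np.maximum(eta, 1e-5)
        elf, rho_f = _surrogate_elf(grid, eta / eta.max(), rho)
        part = partition_basins(elf, rho_f)
        assert part.n_basins == 2
        pops = [integrate_field(rho_f, mask=part.labels == lab)
                for lab in range(2)]
        assert abs(pops[0] - pops[1]) / max(pops) < 0.01

    def test_monotone_ramp_has_single_boundary_attractor(self):
        grid = UniformGrid(origin=(0, 0, 0), axes=np.eye(3) * 0.5,
                           shape=(8, 6, 6))
        eta = np.broadcast_to(
            np.linspace(0.0, 0.9, 8)[:, None, None], grid.shape
        ).copy()
        elf, rho = _surrogate_elf(grid, eta, np.full(grid.shape, 1.0))
        part = partition_basins(elf, rho)
        assert part.n_basins == 1
        # the attractor sits on the maximal (last-index) boundary plane
        att_idx = np.unravel_index(part.attractors[0]["flat_index"], grid.shape)
        assert att_idx[0] == grid.shape[0] - 1

    def test_all_constant_field_rejected(self):
        grid = UniformGrid(origin=(0, 0, 0), axes=np.eye(3) * 0.5,
                           shape=(5, 5, 5))
        elf, rho = _surrogate_elf(grid, np.full(grid.shape, 0.7),
                                  np.full(grid.shape, 1.0))
        with pytest.raises(ValueError, match="no maxima"):
            partition_basins(elf, rho)

    def test_partition_is_deterministic(self):
        grid = UniformGrid(origin=(-3, -3, -3), axes=np.eye(3) * 0.3,
                           shape=(21, 21, 21))
        rng = np.random.default_rng(5)
        eta = rng.uniform(0, 1, size=grid.shape)
        elf, rho = _surrogate_elf(grid, eta, np.full(grid.shape, 1.0))
        p1 = partition_basins(elf, rho)
        p2 = partition_basins(elf, rho)
        assert np.array_equal(p1.labels, p2.labels)


class TestBasinPopulations:
    def test_closure_assigned_plus_residue_equals_total(self, evaluated):
        data = evaluated["polar_4e"]
        elf = compute_elf(data["density"], data["gradient"],
                          data["gradient_sum"])
        part = partition_basins(elf, data["density"])
        reports, closure = basin_populations(part, data["density"],
                                             data["molecule"])
        total = integrate_field(data["density"])
        assigned = sum(r.population for r in reports)
        assert assigned + closure["residue_below_floor"] == pytest.approx(
            total, rel=1e-12
        )
        assert total == pytest.approx(data["molecule"].n_electrons, abs=1e-2)

    def test_two_center_two_electron_valence_basin(self, evaluated):
        # H2-like: eta = 1 on the whole live region -> one valence basin
        # holding (almost exactly) both electrons
        data = evaluated["homonuclear_2e"]
        elf = compute_elf(data["density"], data["gradient"],
                          data["gradient_sum"])
        part = partition_basins(elf, data["density"])
        reports, _ = basin_populations(part, data["density"], data["molecule"])
        valence = [r for r in reports if r.synaptic_class != "core"]
        assert len(valence) == 1
        assert valence[0].population == pytest.approx(2.0, abs=1e-2)

    def test_symmetric_basins_have_equal_populations(self):
        mol = MoleculeSpec(
            atoms=(AtomSite("H", 1, (-2.5, 0, 0)), AtomSite("H", 1, (2.5, 0, 0)))
        )
        grid = UniformGrid(origin=(-6, -2, -2), axes=np.eye(3) * 0.2,
                           shape=(61, 21, 21))
        pts = grid.points()
        eta = (np.exp(-np.sum((pts - [-2.5, 0, 0]) ** 2, axis=-1))
               + np.exp(-np.sum((pts - [2.5, 0, 0]) ** 2, axis=-1)))
        rho = ScalarField(grid, np.maximum(eta, 1e-5))
        elf = ElfField(field=ScalarField(grid, eta / eta.max()), density=rho)
        part = partition_basins(elf, rho)
        reports, _ = basin_populations(part, rho, mol)
        pops = sorted(r.population for r in reports)
        assert len(pops) == 2
        assert abs(pops[1] - pops[0]) / pops[1] < 0.01

    def test_homonuclear_valence_basin_centered_on_midpoint(self, evaluated):
        data = evaluated["homonuclear_2e"]
        elf = compute_elf(data["density"], data["gradient"],
                          data["gradient_sum"])
        part = partition_basins(elf, data["density"])
        # population-weighted centroid of the single basin = bond midpoint
        mask = part.labels == 0
        pts = data["grid"].points()
        w = data["density"].values[mask]
        centroid = (pts[mask] * w[:, None]).sum(axis=0) / w.sum()
        assert np.allclose(centroid, (0, 0, 0), atol=0.05)

    def test_disynaptic_export_filters_element_pairs(self):
        from pyroepl.elf_topology import BasinReport

        mol = MoleculeSpec(
            atoms=(
                AtomSite("C", 6, (0, 0, 0)),
                AtomSite("O", 8, (0, 0, 2.2)),
                AtomSite("H", 1, (0, 0, -2.0)),
            )
        )
        reports = [
            BasinReport(0, 1.8, "disynaptic", (0, 1)),
            BasinReport(1, 1.9, "disynaptic", (0, 2)),  # C-H: not exported
            BasinReport(2, 2.1, "monosynaptic", (1,)),
        ]
        out = disynaptic_bond_populations(reports, mol)
        assert out == {(0, 1): pytest.approx(1.8)}
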