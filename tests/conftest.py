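"""Shared fixtures: toy density models and their evaluated fields.

Field evaluation at the default 0.2 bohr spacing is the expensive step, so
it happens once per session and is shared across test modules.
"""

from __future__ import annotations

import pytest

from pyroepl.fixtures import toy_density_suite
from pyroepl.grid_fields import default_grid, evaluate_model_fields


@pytest.fixture(scope="session")
def suite():
    return toy_density_suite()


@pytest.fixture(scope="session")
def evaluated(suite):
    """name -> dict with molecule, grid and the three neutral-state fields."""
    out = {}
    for name, tm in suite.items():
        grid = default_grid(tm.molecule)
        rho, grad, gsum = evaluate_model_fields(tm.molecule, tm.neutral, grid)
        out[name] = {
            "model": tm,
            "molecule": tm.molecule,
            "grid": grid,
            "density": rho,
            "gradient": grad,
            "gradient_sum": gsum,
        }
    return out


@pytest.fixture(scope="session")
def state_fields(suite):
    """name -> state -> density field for the three vertical charge states."""
    out = {}
    for name, tm in suite.items():
        grid = default_grid(tm.molecule)
        per_state = {}
        for state, om in (
            ("N0", tm.neutral), ("N0-1", tm.cation), ("N0+1", tm.anion)
        ):
            rho, _, _ = evaluate_model_fields(tm.molecule, om, grid)
            per_state[state] = rho
        out[name] = {"molecule": tm.molecule, "grid": grid, "states": per_state}
    return out
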