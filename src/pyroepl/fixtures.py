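"""Packaged datasets and synthetic inputs.

Four input families live here:

* the packaged barrier table — 30 pyrolysis reactions of three
  functionalized xylopyranoses, five levels of theory, two temperatures;
* a composition-level species builder for functionalized xylopyranoses and
  their 1,4-condensed dimers (bookkeeping and electron counting only — the
  descriptor engine takes volumetric fields, not conformers);
* analytic toy electron-density models (s-Gaussian orbital sets) with
  vertical N0-1/N0/N0+1 occupation variants, the stand-ins for quantum
  chemistry wavefunctions in every grid-level test;
* a synthetic regression-row generator for parameter-recovery studies of
  the barrier-model fit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .epl_models import AggregateDescriptors, EPLModel
from .grid_fields import AtomSite, MoleculeSpec, GaussianPrimitive, Orbital, OrbitalModel

__all__ = [
    "Table1Record",
    "SubstitutionPattern",
    "SpeciesSpec",
    "load_table1",
    "table1_frame",
    "table1_sha256",
    "lookup_barrier",
    "build_species",
    "species_catalog",
    "toy_density_suite",
    "synthetic_regression_dataset",
    "LEVEL_COLUMNS",
]

LEVEL_COLUMNS = {
    ("DFT", 0): "dft_0", ("CBS", 0): "cbs_0", ("G4", 0): "g4_0",
    ("DLPNO", 0): "dlpno_0", ("DLPNO/CBS", 0): "dlpnocbs_0",
    ("DFT", 298): "dft_298", ("CBS", 298): "cbs_298", ("G4", 298): "g4_298",
    ("DLPNO", 298): "dlpno_298", ("DLPNO/CBS", 298): "dlpnocbs_298",
}


@dataclass(frozen=True)
class Table1Record:
    """One (reaction, level, temperature) cell of the packaged barrier table."""

    reactant: str
    product: str
    leaving: str  # "H2O" | "CH3COOH" | "CH3OH" | "none"
    level: str  # "DFT" | "CBS" | "G4" | "DLPNO" | "DLPNO/CBS"
    temperature: int  # 0 or 298 (K)
    barrier: float | None  # kcal/mol; None where no TS was ever located
    relaxed_convergence: bool = False


def _table1_text() -> str:
    return (
        resources.files("pyroepl.data")
        .joinpath("activation_enthalpies.tsv")
        .read_text()
    )


def table1_sha256() -> str:
    """Digest of the packaged table resource (locks it against edits)."""
    return hashlib.sha256(_table1_text().encode()).hexdigest()


def table1_frame() -> pd.DataFrame:
    """The packaged table as shipped (cells are strings; 'a' flags kept)."""
    from io import StringIO

    return pd.read_csv(StringIO(_table1_text()), sep="\t", dtype=str)


def load_table1() -> list[Table1Record]:
    """All 300 (reaction x level x temperature) records, flags decoded."""
    frame = table1_frame()
    records = []
    for row in frame.itertuples(index=False):
        for (level, temp), col in LEVEL_COLUMNS.items():
            cell = getattr(row, col)
            relaxed = False
            if cell == "-":
                value = None
            else:
                if cell.endswith("a"):
                    relaxed = True
                    cell = cell[:-1]
                value = float(cell)
            records.append(
                Table1Record(
                    reactant=row.reactant,
                    product=row.product,
                    leaving=row.leaving,
                    level=level,
                    temperature=temp,
                    barrier=value,
                    relaxed_convergence=relaxed,
                )
            )
    return records


def lookup_barrier(
    reactant: str, product: str, level: str, temperature: int
) -> Table1Record:
    """Single-cell lookup; raises KeyError if the cell does not exist."""
    for rec in load_table1():
        if (rec.reactant, rec.product, rec.level, rec.temperature) == (
            reactant, product, level, temperature,
        ):
            return rec
    raise KeyError(f"no record ({reactant}, {product}, {level}, {temperature})")


# ---------------------------------------------------------------------------
# species bookkeeping
# ---------------------------------------------------------------------------

#: legal (position, group) combinations on the xylopyranose ring
LEGAL_SUBSTITUTIONS = {
    "acetyl": (2, 3),  # O-linked C2H3O on the 2- and/or 3-hydroxyl
    "methoxy": (4,),  # 4-hydroxyl H replaced by CH3
    "carboxyl": (5,),  # one C5 H replaced by COOH
}

#: composition deltas (element -> count) of each substitution
_GROUP_DELTAS = {
    "acetyl": {"C": 2, "H": 2, "O": 1},
    "methoxy": {"C": 1, "H": 2},
    "carboxyl": {"C": 1, "O": 2},
}

_BASE_COMPOSITIONS = {
    "xylose": {"C": 5, "H": 10, "O": 5},  # beta-D-xylopyranose
    "glucose": {"C": 6, "H": 12, "O": 6},  # beta-D-glucopyranose
}

_Z = {"H": 1, "C": 6, "O": 8}


@dataclass(frozen=True)
class SubstitutionPattern:
    """Ring position -> functional group map, validated against legality."""

    groups: tuple[tuple[int, str], ...]

    def __post_init__(self):
        seen = set()
        for pos, grp in self.groups:
            if grp not in LEGAL_SUBSTITUTIONS:
                raise ValueError(f"unknown group {grp!r}")
            if pos not in LEGAL_SUBSTITUTIONS[grp]:
                raise ValueError(f"{grp} not legal at ring position {pos}")
            if pos in seen:
                raise ValueError(f"two groups at position {pos}")
            seen.add(pos)

    @classmethod
    def from_dict(cls, mapping: dict[int, str]) -> "SubstitutionPattern":
        return cls(groups=tuple(sorted(mapping.items())))


@dataclass(frozen=True)
class SpeciesSpec:
    """Composition-level description of one (possibly dimeric) species."""

    name: str
    composition: tuple[tuple[str, int], ...]  # sorted (element, count)
    substitutions: SubstitutionPattern
    charge: int = 0
    monomers: int = 1

    @property
    def n_electrons(self) -> int:
        return sum(_Z[el] * n for el, n in self.composition) - self.charge

    def composition_dict(self) -> dict[str, int]:
        return dict(self.composition)


def _merge(comp: dict[str, int], delta: dict[str, int], sign: int = 1) -> None:
    for el, n in delta.items():
        comp[el] = comp.get(el, 0) + sign * n


def build_species(
    base: str = "xylose",
    substitutions: dict[int, str] | SubstitutionPattern | None = None,
    dimer_partner: "SpeciesSpec | str | None" = None,
    name: str | None = None,
) -> SpeciesSpec:
    """Species from a base sugar, substituent pattern and optional partner.

    Substituent arithmetic is purely compositional (group deltas on the
    element counts), so it commutes across positions.  A dimer partner is
    condensed through a 1,4 linkage with loss of one H2O.
    """
    if base not in _BASE_COMPOSITIONS:
        raise ValueError(f"unknown base sugar {base!r}")
    if substitutions is None:
        pattern = SubstitutionPattern(groups=())
    elif isinstance(substitutions, SubstitutionPattern):
        pattern = substitutions
    else:
        pattern = SubstitutionPattern.from_dict(substitutions)

    comp = dict(_BASE_COMPOSITIONS[base])
    for _, grp in pattern.groups:
        _merge(comp, _GROUP_DELTAS[grp])

    monomers = 1
    if dimer_partner is not None:
        if isinstance(dimer_partner, str):
            dimer_partner = build_species(base=dimer_partner)
        _merge(comp, dimer_partner.composition_dict())
        _merge(comp, {"H": 2, "O": 1}, sign=-1)  # condensation water
        monomers = 1 + dimer_partner.monomers

    if name is None:
        prefix = "-".join(
            f"{pos}-{grp}" for pos, grp in pattern.groups
        )
        name = f"{prefix}-{base}" if prefix else base
        if dimer_partner is not None:
            name = f"{name},1,4-{dimer_partner.name}"
    return SpeciesSpec(
        name=name,
        composition=tuple(sorted(comp.items())),
        substitutions=pattern,
        monomers=monomers,
    )


def species_catalog() -> dict[str, SpeciesSpec]:
    """The named species this package's datasets refer to."""
    xylose = build_species("xylose")
    glucuronic = build_species(
        "xylose", {4: "methoxy", 5: "carboxyl"},
        name="4-O-methyl-D-glucuronicacid",
    )
    catalog = {
        "xylose": xylose,
        "2-O-acetyl-xylose": build_species(
            "xylose", {2: "acetyl"}, name="2-O-acetyl-xylose"
        ),
        "3-O-acetyl-xylose": build_species(
            "xylose", {3: "acetyl"}, name="3-O-acetyl-xylose"
        ),
        "4-O-methyl-D-glucuronicacid": glucuronic,
        "5-carboxy-xylose": build_species(
            "xylose", {5: "carboxyl"}, name="5-carboxy-xylose"
        ),
        "glucose": build_species("glucose"),
        "xylobiose": build_species(
            "xylose", dimer_partner="xylose", name="xylobiose"
        ),
        "xyloglucan": build_species(
            "xylose", dimer_partner="glucose", name="xyloglucan"
        ),
        "glucuronoxylan": build_species(
            "xylose", {4: "methoxy", 5: "carboxyl"},
            dimer_partner="xylose", name="glucuronoxylan",
        ),
    }
    return catalog


def species_catalog_json() -> str:
    """Catalog as JSON (name, composition, electron count, monomer count)."""
    payload = {
        name: {
            "composition": sp.composition_dict(),
            "n_electrons": sp.n_electrons,
            "monomers": sp.monomers,
        }
        for name, sp in species_catalog().items()
    }
    return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# analytic toy density models
# ---------------------------------------------------------------------------

def _s(center, alpha) -> GaussianPrimitive:
    return GaussianPrimitive(center=np.asarray(center, float), alpha=alpha, kind="s")


def _s_overlap(g1: GaussianPrimitive, g2: GaussianPrimitive) -> float:
    """Analytic overlap of two normalized s primitives."""
    a, b = g1.alpha, g2.alpha
    r2 = float(np.sum((g1.center - g2.center) ** 2))
    return (2.0 * np.sqrt(a * b) / (a + b)) ** 1.5 * np.exp(-a * b / (a + b) * r2)


def _normalized_s_contraction(prims: list[GaussianPrimitive],
                              raw_coeffs: list[float]) -> Orbital:
    """s-contraction rescaled so the orbital is unit-normalized."""
    c = np.asarray(raw_coeffs, float)
    S = np.array([[_s_overlap(p, q) for q in prims] for p in prims])
    norm2 = float(c @ S @ c)
    return Orbital(primitives=tuple(prims), coefficients=tuple(c / np.sqrt(norm2)))


@dataclass(frozen=True)
class ToyModel:
    """A molecule with neutral/cation/anion analytic orbital models."""

    name: str
    molecule: MoleculeSpec
    neutral: OrbitalModel
    cation: OrbitalModel
    anion: OrbitalModel

    def __post_init__(self):
        n0 = self.molecule.n_electrons
        for model, expect in ((self.neutral, n0), (self.cation, n0 - 1),
                              (self.anion, n0 + 1)):
            if abs(model.n_electrons - expect) > 1e-12:
                raise ValueError(
                    f"{self.name}: occupations sum to {model.n_electrons}, "
                    f"expected {expect}"
                )


def toy_density_suite() -> dict[str, ToyModel]:
    """Four analytic density models with vertical charge-state variants.

    one_center_2e   He-like single center, one doubly occupied s orbital
    homonuclear_2e  H2-like symmetric two-center sigma bond
    polar_4e        LiH-like polar bond with a tight core on the heavy atom
    bent_3c_2e      H3+-like bent three-center two-electron system

    Anion variants add a diffuse orbital holding the extra electron; cation
    variants remove one electron from the highest-occupied orbital.  All
    orbitals are unit-normalized s-contractions, so each model's density
    integrates to its electron count analytically.
    """
    suite = {}

    # one-center, 2 electrons
    he = MoleculeSpec(atoms=(AtomSite("He", 2, (0.0, 0.0, 0.0)),))
    s_he = _normalized_s_contraction([_s((0, 0, 0), 1.0)], [1.0])
    s_he_diff = _normalized_s_contraction([_s((0, 0, 0), 0.30)], [1.0])
    suite["one_center_2e"] = ToyModel(
        name="one_center_2e",
        molecule=he,
        neutral=OrbitalModel((s_he,), (2.0,)),
        cation=OrbitalModel((s_he,), (1.0,)),
        anion=OrbitalModel((s_he, s_he_diff), (2.0, 1.0)),
    )

    # homonuclear two-center sigma, 2 electrons
    h2 = MoleculeSpec(
        atoms=(
            AtomSite("H", 1, (0.0, 0.0, -0.7)),
            AtomSite("H", 1, (0.0, 0.0, 0.7)),
        )
    )
    sigma = _normalized_s_contraction(
        [_s((0, 0, -0.7), 1.3), _s((0, 0, 0.7), 1.3)], [1.0, 1.0]
    )
    sigma_diff = _normalized_s_contraction(
        [_s((0, 0, -0.7), 0.30), _s((0, 0, 0.7), 0.30)], [1.0, 1.0]
    )
    suite["homonuclear_2e"] = ToyModel(
        name="homonuclear_2e",
        molecule=h2,
        neutral=OrbitalModel((sigma,), (2.0,)),
        cation=OrbitalModel((sigma,), (1.0,)),
        anion=OrbitalModel((sigma, sigma_diff), (2.0, 1.0)),
    )

    # polar two-center, 4 electrons (tight core + polarized bond)
    lih = MoleculeSpec(
        atoms=(
            AtomSite("Li", 3, (0.0, 0.0, 0.0)),
            AtomSite("H", 1, (0.0, 0.0, 3.0)),
        )
    )
    core = _normalized_s_contraction([_s((0, 0, 0), 4.0)], [1.0])
    bond = _normalized_s_contraction(
        [_s((0, 0, 0), 0.55), _s((0, 0, 3.0), 0.85)], [0.4, 1.0]
    )
    bond_diff = _normalized_s_contraction(
        [_s((0, 0, 1.5), 0.30)], [1.0]
    )
    suite["polar_4e"] = ToyModel(
        name="polar_4e",
        molecule=lih,
        neutral=OrbitalModel((core, bond), (2.0, 2.0)),
        cation=OrbitalModel((core, bond), (2.0, 1.0)),
        anion=OrbitalModel((core, bond, bond_diff), (2.0, 2.0, 1.0)),
    )

    # bent three-center, 2 electrons
    h3 = MoleculeSpec(
        atoms=(
            AtomSite("H", 1, (0.0, 0.0, 0.0)),
            AtomSite("H", 1, (1.65, 0.0, 0.0)),
            AtomSite("H", 1, (0.55, 1.55, 0.0)),
        ),
        charge=1,
    )
    centers = [(0.0, 0.0, 0.0), (1.65, 0.0, 0.0), (0.55, 1.55, 0.0)]
    tri = _normalized_s_contraction(
        [_s(c, 1.1) for c in centers], [1.0, 1.0, 1.0]
    )
    tri_diff = _normalized_s_contraction(
        [_s(c, 0.30) for c in centers], [1.0, 1.0, 1.0]
    )
    suite["bent_3c_2e"] = ToyModel(
        name="bent_3c_2e",
        molecule=h3,
        neutral=OrbitalModel((tri,), (2.0,)),
        cation=OrbitalModel((tri,), (1.0,)),
        anion=OrbitalModel((tri, tri_diff), (2.0, 1.0)),
    )
    return suite


# ---------------------------------------------------------------------------
# synthetic regression rows
# ---------------------------------------------------------------------------

#: descriptor sampling windows bracketing the magnitudes the real reactions
#: produce: mean Fukui values a few hundredths, bond populations around one
#: to two electrons, gross pair indices a few tenths to one
DEFAULT_DESCRIPTOR_RANGES = {
    "f_bar": (0.02, 0.12),
    "n_bar": (0.8, 1.8),
    "dg_bar": (0.2, 1.2),
}


def synthetic_regression_dataset(
    true_model: EPLModel,
    n: int,
    noise_sigma: float = 0.0,
    seed: int = 0,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> list[tuple[AggregateDescriptors, float]]:
    """Rows (descriptors, barrier) from a known affine truth plus noise.

    Descriptors are uniform over their windows; the barrier is the affine
    model value plus Gaussian noise of standard deviation ``noise_sigma``
    (kcal/mol).  Deterministic for a seed.
    """
    if noise_sigma < 0:
        raise ValueError("noise sigma must be nonnegative")
    ranges = ranges or DEFAULT_DESCRIPTOR_RANGES
    for key, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"range for {key} is reversed")
    rng = np.random.default_rng(seed)
    f = rng.uniform(*ranges["f_bar"], size=n)
    nb = rng.uniform(*ranges["n_bar"], size=n)
    g = rng.uniform(*ranges["dg_bar"], size=n)
    noise = rng.normal(0.0, noise_sigma, size=n) if noise_sigma > 0 else np.zeros(n)
    rows = []
    for k in range(n):
        agg = AggregateDescriptors(f_bar=float(f[k]), n_bar=float(nb[k]),
                                   dg_bar=float(g[k]))
        dh = (true_model.c_f * f[k] + true_model.c_N * nb[k]
              + true_model.c_g * g[k] + true_model.c_0 + noise[k])
        rows.append((agg, float(dh)))
    return rows
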