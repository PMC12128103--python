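"""Evans-Polanyi-like (EPL) activation-enthalpy models.

A classical Evans-Polanyi relation maps a reaction enthalpy linearly onto an
activation energy.  The models here replace the reaction enthalpy with three
reactant-only electron-density descriptors — a mean condensed Fukui value
f_bar over the reacting sites, a mean disynaptic-basin electron population
N_bar over the breaking C-O/C-C bonds, and a mean gross IGM pair index
dg_bar over the reacting atom pairs — so that

    dH_act = c_f * f_bar + c_N * N_bar + c_g * dg_bar + c_0   [kcal/mol, 298 K]

Which sites, bonds and pairs enter the three means is fixed per reaction
class (ring opening, the two ring-contraction channels toward furanics, and
seven elimination channels toward anhydro sugars) by a :class:`ReactionRecipe`.

Four published coefficient sets are packaged (one per reference level of
theory); :func:`fit_epl` refits the same affine form on user data and never
overwrites the packaged constants.

Ring-site labeling convention: ring carbons C1..C5 (C1 anomeric), ring
oxygen O, hydroxyl oxygens O1..O4 numbered by their carbon, hydroxyl
protons H_O1.., carbon protons H1..; pair labels join two site labels with
"-" (e.g. "C1-O", "O1-H_O1"); disynaptic bond labels read "V(C1,O)".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorTable",
    "ReactionRecipe",
    "AggregateDescriptors",
    "EPLModel",
    "FitReport",
    "PUBLISHED_EPL",
    "RecipeWarning",
    "build_recipe",
    "aggregate_descriptors",
    "predict_barrier",
    "fit_epl",
    "evaluate_metrics",
    "split_dataset",
    "REACTION_CLASSES",
]

REACTION_CLASSES = (
    "ring_opening",
    "ring_contraction_FF1",
    "ring_contraction_FF2",
    "elimination",
)


class RecipeWarning(UserWarning):
    """Raised (as a warning) when a substitution makes a recipe ambiguous."""


@dataclass
class DescriptorTable:
    """Per-species descriptor store keyed by (species id, label).

    Three label families: atom sites carry Fukui triples (f+, f-, f0);
    disynaptic bond labels ``V(A,B)`` carry ELF electron populations; pair
    labels ``A-B`` carry gross IGM indices.  Duplicate keys are rejected.
    """

    fukui: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=dict
    )
    bond_population: dict[tuple[str, str], float] = field(default_factory=dict)
    pair_index: dict[tuple[str, str], float] = field(default_factory=dict)

    def add_fukui(self, species: str, site: str,
                  f_plus: float, f_minus: float, f_zero: float) -> None:
        key = (species, site)
        if key in self.fukui:
            raise ValueError(f"duplicate Fukui key {key}")
        self.fukui[key] = (float(f_plus), float(f_minus), float(f_zero))

    def add_bond(self, species: str, bond_label: str, population: float) -> None:
        key = (species, bond_label)
        if key in self.bond_population:
            raise ValueError(f"duplicate bond key {key}")
        self.bond_population[key] = float(population)

    def add_pair(self, species: str, pair_label: str, value: float) -> None:
        key = (species, pair_label)
        if key in self.pair_index:
            raise ValueError(f"duplicate pair key {key}")
        self.pair_index[key] = float(value)

    # --- delimited-text round trip ------------------------------------
    _COLUMNS = ["species", "kind", "label", "f_plus", "f_minus", "f_zero", "value"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sp, site), (fp, fm, f0) in self.fukui.items():
            rows.append((sp, "fukui", site, fp, fm, f0, np.nan))
        for (sp, lab), v in self.bond_population.items():
            rows.append((sp, "bond", lab, np.nan, np.nan, np.nan, v))
        for (sp, lab), v in self.pair_index.items():
            rows.append((sp, "pair", lab, np.nan, np.nan, np.nan, v))
        return pd.DataFrame(rows, columns=self._COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DescriptorTable":
        table = cls()
        for row in frame.itertuples(index=False):
            if row.kind == "fukui":
                table.add_fukui(row.species, row.label,
                                row.f_plus, row.f_minus, row.f_zero)
            elif row.kind == "bond":
                table.add_bond(row.species, row.label, row.value)
            elif row.kind == "pair":
                table.add_pair(row.species, row.label, row.value)
            else:
                raise ValueError(f"unknown descriptor kind {row.kind!r}")
        return table

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class ReactionRecipe:
    """Site/bond/pair lists defining the three descriptor means of a class."""

    reaction_class: str
    fukui_sites: tuple[tuple[str, str], ...]  # (site label, "f0" | "f-")
    bonds: tuple[str, ...]  # V(A,B) labels
    pairs: tuple[str, ...]  # A-B pair labels
    index: int | None = None  # elimination channel 1..7
    notes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.reaction_class == "ring_opening":
            _require(len(self.fukui_sites) == 3 and len(self.bonds) == 1
                     and len(self.pairs) == 2, "ring_opening shape")
        elif self.reaction_class == "ring_contraction_FF1":
            _require(len(self.fukui_sites) == 5 and len(self.bonds) == 1
                     and len(self.pairs) == 3, "FF1 shape")
        elif self.reaction_class == "ring_contraction_FF2":
            _require(len(self.fukui_sites) == 5 and len(self.bonds) == 2
                     and len(self.pairs) == 3, "FF2 shape")
        elif self.reaction_class == "elimination":
            _require(len(self.fukui_sites) == 3 and len(self.bonds) == 1
                     and len(self.pairs) == 2, "elimination shape")
        else:
            raise ValueError(f"unknown reaction class {self.reaction_class!r}")


def _require(cond: bool, what: str) -> None:
    if not cond:
        raise ValueError(f"recipe violates the {what} site-count rule")


# elimination channels i = 1..7: index arithmetic for
# (two f0 carbons, one f- hydroxyl oxygen, the broken C-O bond, and the
# proton-transfer C-H pair)
_ELIM_RULES = {
    1: {"fc": (0, +1), "fo": 0, "co": 0, "ch": +1},
    2: {"fc": (0, -1), "fo": 0, "co": 0, "ch": -1},
    3: {"fc": (0, -1), "fo": -1, "co": -1, "ch": 0},
    4: {"fc": (-1, -2), "fo": -1, "co": -1, "ch": -2},
    5: {"fc": (-1, -2), "fo": -2, "co": -2, "ch": -1},
    6: {"fc": (-2, -3), "fo": -2, "co": -2, "ch": -2},
    7: {"fc": (-2, -3), "fo": -3, "co": -3, "ch": -2},
}


def build_recipe(
    reaction_class: str,
    index: int | None = None,
    substitution: dict[int, str] | None = None,
) -> ReactionRecipe:
    """Recipe for one reaction class (and elimination channel).

    ``substitution`` maps ring positions to functional groups ("acetyl",
    "methoxy", "carboxyl").  When the recipe's leaving hydroxyl is
    substituted, its proton no longer exists: the O_i-H_Oi pair is replaced
    by the oxygen-to-substituent-carbon linkage pair and a
    :class:`RecipeWarning` is emitted (acetyl/methoxy positions eliminate
    CH3COOH/CH3OH instead of water).
    """
    substitution = substitution or {}
    notes: list[str] = []

    if reaction_class == "ring_opening":
        sites = (("C1", "f0"), ("O", "f-"), ("O1", "f-"))
        bonds = ("V(C1,O)",)
        pairs = ("C1-O", "O1-H_O1")
        hydroxyl = 1
    elif reaction_class == "ring_contraction_FF1":
        sites = (("C1", "f0"), ("C2", "f0"), ("C3", "f0"),
                 ("O1", "f-"), ("O2", "f-"))
        bonds = ("V(C1,O1)",)
        pairs = ("C2-C3", "C1-O1", "O2-H_O2")
        hydroxyl = 2
    elif reaction_class == "ring_contraction_FF2":
        sites = (("C1", "f0"), ("C2", "f0"), ("O", "f-"),
                 ("O1", "f-"), ("O2", "f-"))
        bonds = ("V(C1,O)", "V(C2,O2)")
        pairs = ("C1-O", "C2-O2", "O1-H_O1")
        hydroxyl = 1
    elif reaction_class == "elimination":
        if index is None or index not in _ELIM_RULES:
            raise ValueError(
                f"elimination channel must be 1..7, got {index!r}"
            )
        rule = _ELIM_RULES[index]
        c_a, c_b = (index + d for d in rule["fc"])
        o = index + rule["fo"]
        co = index + rule["co"]
        ch = index + rule["ch"]
        sites = ((f"C{c_a}", "f0"), (f"C{c_b}", "f0"), (f"O{o}", "f-"))
        bonds = (f"V(C{co},O{co})",)
        pairs = (f"C{co}-O{co}", f"C{ch}-H{ch}")
        hydroxyl = o
    else:
        raise ValueError(f"unknown reaction class {reaction_class!r}")

    # leaving-group-aware relabeling: an acetylated/methylated hydroxyl has
    # no proton, so an O_i-H_Oi pair points at the linkage carbon instead;
    # elimination recipes carry no hydroxyl proton, but the substituted
    # position changes what leaves (acid/alcohol instead of water)
    group = substitution.get(hydroxyl)
    if group in ("acetyl", "methoxy"):
        leaving = {"acetyl": "CH3COOH", "methoxy": "CH3OH"}[group]
        old = f"O{hydroxyl}-H_O{hydroxyl}"
        if old in pairs:
            new = f"O{hydroxyl}-C{group}{hydroxyl}"
            pairs = tuple(new if p == old else p for p in pairs)
            msg = (
                f"position {hydroxyl} bears {group}: pair {old} relabeled to "
                f"{new}; leaving molecule is {leaving}"
            )
        else:
            msg = (
                f"position {hydroxyl} bears {group}: O{hydroxyl} is the "
                f"linkage oxygen and the leaving molecule is {leaving}"
            )
        notes.append(msg)
        warnings.warn(msg, RecipeWarning, stacklevel=2)

    return ReactionRecipe(
        reaction_class=reaction_class,
        fukui_sites=sites,
        bonds=bonds,
        pairs=pairs,
        index=index,
        notes=tuple(notes),
    )


@dataclass(frozen=True)
class AggregateDescriptors:
    """The three per-reaction scalars: f_bar, N_bar, dg_bar."""

    f_bar: float
    n_bar: float
    dg_bar: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f_bar, self.n_bar, self.dg_bar])


def aggregate_descriptors(
    recipe: ReactionRecipe, table: DescriptorTable, species: str
) -> AggregateDescriptors:
    """Arithmetic means over the recipe's site, bond and pair lists."""
    f_vals = []
    for site, kind in recipe.fukui_sites:
        key = (species, site)
        if key not in table.fukui:
            raise KeyError(f"Fukui label {site!r} missing for species {species!r}")
        fp, fm, f0 = table.fukui[key]
        f_vals.append(f0 if kind == "f0" else fm)
    n_vals = []
    for bond in recipe.bonds:
        key = (species, bond)
        if key not in table.bond_population:
            raise KeyError(f"bond label {bond!r} missing for species {species!r}")
        n_vals.append(table.bond_population[key])
    g_vals = []
    for pair in recipe.pairs:
        key = (species, pair)
        if key not in table.pair_index:
            raise KeyError(f"pair label {pair!r} missing for species {species!r}")
        g_vals.append(table.pair_index[key])
    return AggregateDescriptors(
        f_bar=float(np.mean(f_vals)),
        n_bar=float(np.mean(n_vals)),
        dg_bar=float(np.mean(g_vals)),
    )


@dataclass(frozen=True)
class EPLModel:
    """Affine barrier model: dH = c_f f_bar + c_N N_bar + c_g dg_bar + c_0."""

    level: str
    c_f: float
    c_N: float
    c_g: float
    c_0: float

    def coefficients(self) -> np.ndarray:
        return np.array([self.c_f, self.c_N, self.c_g, self.c_0])


#: published coefficient sets (kcal/mol at 298 K), one per reference level
PUBLISHED_EPL: dict[str, EPLModel] = {
    "DFT": EPLModel("DFT", c_f=-168.82, c_N=-66.28, c_g=328.10, c_0=-18.80),
    "CBS": EPLModel("CBS", c_f=-189.01, c_N=-65.11, c_g=266.44, c_0=13.96),
    "G4": EPLModel("G4", c_f=-184.99, c_N=-64.85, c_g=275.10, c_0=8.52),
    "DLPNO": EPLModel("DLPNO", c_f=-187.82, c_N=-72.45, c_g=296.14, c_0=7.72),
}


def predict_barrier(model: EPLModel, agg: AggregateDescriptors) -> float:
    """Standard activation enthalpy (kcal/mol, 298 K) from the affine form."""
    return float(
        model.c_f * agg.f_bar
        + model.c_N * agg.n_bar
        + model.c_g * agg.dg_bar
        + model.c_0
    )


@dataclass
class FitReport:
    """Outcome of a multilinear EPL fit."""

    model: EPLModel
    n: int
    r2_adj: float
    mae: float
    rmse: float
    std_errors: tuple[float, float, float, float]
    split_seed: int | None = None
    train_ids: tuple[int, ...] = ()
    validation_ids: tuple[int, ...] = ()
    validation_mae: float | None = None
    validation_rmse: float | None = None

    def __post_init__(self):
        if self.mae > self.rmse + 1e-12:
            raise ValueError("MAE cannot exceed RMSE")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "level": self.model.level,
            "coefficients": {
                "c_f": self.model.c_f,
                "c_N": self.model.c_N,
                "c_g": self.model.c_g,
                "c_0": self.model.c_0,
            },
            "n": self.n,
            "r2_adj": self.r2_adj,
            "mae": self.mae,
            "rmse": self.rmse,
            "std_errors": list(self.std_errors),
            "split_seed": self.split_seed,
            "train_ids": list(self.train_ids),
            "validation_ids": list(self.validation_ids),
            "validation_mae": self.validation_mae,
            "validation_rmse": self.validation_rmse,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def evaluate_metrics(
    predictions, references, p: int = 3
) -> tuple[float, float, float]:
    """MAE, RMSE and adjusted R-squared of predictions against references.

    R2_adj = 1 - (1 - R2)(n - 1)/(n - p - 1), with p the number of
    predictors; requires n > p + 1.
    """
    pred = np.asarray(predictions, dtype=float)
    ref = np.asarray(references, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("prediction/reference length mismatch")
    n = pred.size
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 = {p + 1} points for adjusted R2")
    resid = pred - ref
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0.0:
        # degenerate reference with no variance: R2 is defined only for a
        # perfect fit
        r2 = 1.0 if ss_res == 0.0 else float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return mae, rmse, float(r2_adj)


def fit_epl(
    rows: list[tuple[AggregateDescriptors, float]],
    validation: list[tuple[AggregateDescriptors, float]] | None = None,
    level: str = "fitted",
) -> FitReport:
    """Ordinary least squares on the three descriptors plus an intercept.

    Needs at least 5 rows (more rows than the 4 parameters) and full column
    rank (collinear descriptors raise).  Training metrics are always
    reported; validation metrics when held-out rows are supplied.
    """
    n = len(rows)
    if n < 5:
        raise ValueError(f"underdetermined fit: need >= 5 rows, got {n}")
    X = np.array([[a.f_bar, a.n_bar, a.dg_bar, 1.0] for a, _ in rows])
    y = np.array([dh for _, dh in rows], dtype=float)
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("rank-deficient design: descriptors are collinear")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ beta
    mae, rmse, r2_adj = evaluate_metrics(pred, y, p=3)
    dof = n - 4
    s2 = float(np.sum((y - pred) ** 2)) / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)
    se = tuple(float(v) for v in np.sqrt(np.diag(cov)))
    model = EPLModel(level=level, c_f=float(beta[0]), c_N=float(beta[1]),
                     c_g=float(beta[2]), c_0=float(beta[3]))
    report = FitReport(model=model, n=n, r2_adj=r2_adj, mae=mae, rmse=rmse,
                       std_errors=se)
    if validation:
        vX = np.array([[a.f_bar, a.n_bar, a.dg_bar, 1.0] for a, _ in validation])
        vy = np.array([dh for _, dh in validation], dtype=float)
        vres = vX @ beta - vy
        report.validation_mae = float(np.mean(np.abs(vres)))
        report.validation_rmse = float(np.sqrt(np.mean(vres**2)))
    return report


def split_dataset(
    n_rows: int,
    fraction: float = 0.8,
    seed: int = 0,
    labels=None,
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Deterministic train/validation split of row indices.

    With ``labels`` (one class label per row) the split is stratified:
    each class contributes its own ``fraction`` share (rounded), keeping
    class proportions within one row of the target.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if labels is None:
        perm = rng.permutation(n_rows)
        k = int(round(fraction * n_rows))
        return (tuple(sorted(int(i) for i in perm[:k])),
                tuple(sorted(int(i) for i in perm[k:])))
    labels = list(labels)
    if len(labels) != n_rows:
        raise ValueError("one label per row required")
    train: list[int] = []
    val: list[int] = []
    for cls in sorted(set(labels), key=str):
        idx = np.array([i for i, c in enumerate(labels) if c == cls])
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 rows")
        perm = rng.permutation(idx)
        k = int(round(fraction * idx.size))
        k = min(max(k, 1), idx.size - 1)  # both sides non-empty per class
        train.extend(int(i) for i in perm[:k])
        val.extend(int(i) for i in perm[k:])
    return tuple(sorted(train)), tuple(sorted(val))
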