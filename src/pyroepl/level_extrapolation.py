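"""Level-of-theory barrier maps and two-point complete-basis-set extrapolation.

Activation enthalpies computed at a cheap level of theory track those of
expensive composite/coupled-cluster levels almost perfectly linearly, so a
slope/intercept map moves a barrier between levels.  Six maps are packaged
(kcal/mol, slopes near +1); :func:`fit_level_map` derives new ones.

Basis-set truncation error is removed with the standard two-point scheme on
cardinal numbers Y < X:

    E_SCF(X)  = E_SCF(inf) + A exp(-alpha X)          (SCF channel)
    E_corr(inf) = (X^beta E_corr(X) - Y^beta E_corr(Y)) / (X^beta - Y^beta)

with alpha = 4.42 and beta = 2.46 for the (Y, X) = (2, 3) pair.  Energies
pass through unit-agnostic (hartree in practice); the barrier maps, by
contrast, are fixed to kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LevelMap",
    "CBSParams",
    "PUBLISHED_LEVEL_MAPS",
    "DEFAULT_CBS_PARAMS",
    "apply_level_map",
    "invert_level_map",
    "fit_level_map",
    "cbs_extrapolate",
]

LEVELS = ("DFT", "CBS", "G4", "DLPNO")


@dataclass(frozen=True)
class LevelMap:
    """Affine barrier map between two levels of theory (kcal/mol)."""

    source: str
    target: str
    slope: float
    intercept: float
    r2: float | None = None
    mae: float | None = None

    def __post_init__(self):
        if self.slope == 0.0:
            raise ValueError("level map slope must be nonzero")


#: the six packaged lower-to-higher-level maps (slope, intercept in kcal/mol)
PUBLISHED_LEVEL_MAPS: dict[tuple[str, str], LevelMap] = {
    ("DFT", "CBS"): LevelMap("DFT", "CBS", 0.96, 1.67),
    ("DFT", "G4"): LevelMap("DFT", "G4", 0.96, 1.72),
    ("DFT", "DLPNO"): LevelMap("DFT", "DLPNO", 1.02, -1.57),
    ("CBS", "G4"): LevelMap("CBS", "G4", 0.96, 2.86),
    ("CBS", "DLPNO"): LevelMap("CBS", "DLPNO", 1.01, -0.14),
    ("G4", "DLPNO"): LevelMap("G4", "DLPNO", 1.05, -2.77),
}


def get_level_map(source: str, target: str) -> LevelMap:
    """Packaged map for a level pair; raises for an unknown pair."""
    try:
        return PUBLISHED_LEVEL_MAPS[(source, target)]
    except KeyError:
        known = ", ".join(f"{s}->{t}" for s, t in PUBLISHED_LEVEL_MAPS)
        raise KeyError(
            f"no packaged map {source}->{target}; available: {known}"
        ) from None


def apply_level_map(level_map: LevelMap, barrier: float) -> float:
    """slope * barrier + intercept (kcal/mol)."""
    return float(level_map.slope * barrier + level_map.intercept)


def invert_level_map(level_map: LevelMap) -> LevelMap:
    """The exact inverse affine map (target back to source)."""
    return LevelMap(
        source=level_map.target,
        target=level_map.source,
        slope=1.0 / level_map.slope,
        intercept=-level_map.intercept / level_map.slope,
    )


def fit_level_map(
    pairs: list[tuple[float, float]], source: str = "user", target: str = "user"
) -> LevelMap:
    """Least-squares line through (source, target) barrier pairs.

    Needs at least 3 pairs and nonzero variance in the source column;
    attaches R^2 and MAE of the fitted line.
    """
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 barrier pairs, got {len(pairs)}")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in source barriers")
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 and ss_res == 0.0 else 1.0 - ss_res / ss_tot
    mae = float(np.mean(np.abs(y - pred)))
    return LevelMap(source=source, target=target, slope=float(slope),
                    intercept=float(intercept), r2=r2, mae=mae)


@dataclass(frozen=True)
class CBSParams:
    """Exponents and cardinal numbers of the two-point extrapolation.

    alpha governs the exponential SCF channel, beta the power-law
    correlation channel; X > Y >= 2 are the basis-set cardinal numbers.
    The SCF amplitude A is solved from the data, never supplied.
    """

    alpha: float = 4.42
    beta: float = 2.46
    Y: int = 2
    X: int = 3

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not (self.X > self.Y >= 2):
            raise ValueError(f"need X > Y >= 2, got X={self.X}, Y={self.Y}")


#: the study parameters for the (2, 3) cardinal pair
DEFAULT_CBS_PARAMS = CBSParams()


def cbs_extrapolate(
    e_scf_y: float,
    e_scf_x: float,
    e_corr_y: float,
    e_corr_x: float,
    params: CBSParams = DEFAULT_CBS_PARAMS,
) -> tuple[float, float, float]:
    """Extrapolate SCF and correlation energies to the basis-set limit.

    SCF: the amplitude A = (E_Y - E_X) / (exp(-alpha Y) - exp(-alpha X))
    is eliminated, giving E_inf = E_Y - A exp(-alpha Y).  Correlation uses
    the closed two-point power-law form.  Returns
    (E_SCF_inf, E_corr_inf, E_total_inf) in the input units.
    """
    a, b, Y, X = params.alpha, params.beta, params.Y, params.X
    wy, wx = np.exp(-a * Y), np.exp(-a * X)
    amp = (e_scf_y - e_scf_x) / (wy - wx)
    e_scf_inf = e_scf_y - amp * wy
    e_corr_inf = (X**b * e_corr_x - Y**b * e_corr_y) / (X**b - Y**b)
    return float(e_scf_inf), float(e_corr_inf), float(e_scf_inf + e_corr_inf)
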