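"""Enzyme kinetics for the coupled GDH deamidase assay.

Covers the quantitative enzymology of the family: Michaelis-Menten and Hill
initial-rate laws, nonlinear least-squares fitting with double-reciprocal
initialization, conversion of A360 slopes from the NADPH-coupled glutamate
dehydrogenase assay into activity units, and ligand-efficiency arithmetic on
docking scores.

Unit conventions: substrate concentrations in mM (MM) or µM (Hill), kcat in
s^-1, enzyme concentration E0 in µM, so mm_rate returns µM/s.  The coupled
assay consumes one NADPH per NMN deamidated, so one unit = 1 µmol NADPH/min.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

#: Extinction coefficient of NADPH at 360 nm, M^-1 cm^-1.
EPSILON_NADPH_360 = 4320.0

#: Subunit molecular weight of the O. iheyensis enzyme (mass spectrometry), kDa.
OIPNCC_MW_KDA = 47.32

#: Molecular formulas used for heavy-atom counts (no cheminformatics
#: dependency needed for two ligands).
LIGAND_FORMULAS = {
    "NMN": "C11H15N2O8P",
    "ADP-ribose": "C15H23N5O14P2",
}

#: MolDock binding scores (kcal/mol) reported for the two binding sites;
#: inputs to the ligand-efficiency arithmetic, never recomputed here.
DOCKING_SCORES_KCAL = {
    "NMN": -122.053,
    "ADP-ribose": -117.923,
    "Moco": -87.612,
}


class FitError(RuntimeError):
    """Nonlinear fit failed; carries the last parameter iterate."""

    def __init__(self, message: str, last_params: Optional[dict] = None):
        super().__init__(message)
        self.last_params = last_params or {}


@dataclass(frozen=True)
class MMParams:
    """Michaelis-Menten parameters: Km (mM), kcat (s^-1), E0 (µM)."""

    Km: float
    kcat: float
    E0: float = 1.0

    def __post_init__(self) -> None:
        if self.Km <= 0 or self.kcat <= 0 or self.E0 <= 0:
            raise ValueError("Km, kcat and E0 must be strictly positive")

    @property
    def Vmax(self) -> float:
        return self.kcat * self.E0


@dataclass(frozen=True)
class HillParams:
    """Hill parameters: S0.5 (µM), nH (dimensionless), Vmax (rate units)."""

    S05: float
    nH: float
    Vmax: float

    def __post_init__(self) -> None:
        if self.S05 <= 0 or self.nH <= 0 or self.Vmax <= 0:
            raise ValueError("S0.5, nH and Vmax must be strictly positive")


def mm_rate(params: MMParams, S: float) -> float:
    """v = kcat * E0 * S / (Km + S); S in the same units as Km."""
    if S < 0:
        raise ValueError("substrate concentration must be >= 0")
    return params.kcat * params.E0 * S / (params.Km + S)


def hill_rate(params: HillParams, S: float) -> float:
    """v = Vmax * S^n / (S0.5^n + S^n)."""
    if S < 0:
        raise ValueError("substrate concentration must be >= 0")
    if S == 0:
        return 0.0
    Sn = S**params.nH
    return params.Vmax * Sn / (params.S05**params.nH + Sn)


def absorbance_to_rate(
    dA360_per_min: float,
    epsilon: float = EPSILON_NADPH_360,
    path_cm: float = 1.0,
    volume_L: float = 200e-6,
    enzyme_mg: Optional[float] = None,
) -> dict:
    """Convert an A360 slope from the coupled assay into µmol NADPH/min.

    rate [µmol/min] = (dA/dt) / (epsilon * l) * V * 1e6.  With ``enzyme_mg``
    given, also reports specific activity in U/mg (1 U = 1 µmol/min).
    """
    if epsilon <= 0:
        raise ValueError("extinction coefficient must be positive")
    if path_cm <= 0 or volume_L <= 0:
        raise ValueError("path length and volume must be positive")
    umol_per_min = abs(dA360_per_min) / (epsilon * path_cm) * volume_L * 1e6
    out = {"umol_per_min": umol_per_min, "units": umol_per_min}
    if enzyme_mg is not None:
        out["U_per_mg"] = umol_per_min / enzyme_mg
    return out


def _check_table(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if not {"concentration", "rate"} <= set(table.columns):
        raise ValueError("rate table needs 'concentration' and 'rate' columns")
    S = table["concentration"].to_numpy(dtype=float)
    v = table["rate"].to_numpy(dtype=float)
    if (S < 0).any():
        raise ValueError("negative substrate concentrations")
    if len(np.unique(S[S > 0])) < 4:
        raise ValueError("need at least 4 distinct concentrations to fit")
    return S, v


def fit_mm(table: pd.DataFrame, E0: float = 1.0) -> dict:
    """Nonlinear least-squares Michaelis-Menten fit of an initial-rate table.

    Initialization comes from the double-reciprocal (Lineweaver-Burk)
    linearization; reported are Km, kcat (= Vmax/E0), asymptotic standard
    errors and kcat/Km.
    """
    S, v = _check_table(table)
    mask = (S > 0) & (v > 0)
    slope, intercept, *_ = linregress(1.0 / S[mask], 1.0 / v[mask])
    Vmax0 = 1.0 / intercept if intercept > 0 else float(np.max(v)) * 1.2
    Km0 = slope * Vmax0 if slope * Vmax0 > 0 else float(np.median(S))

    def law(S, Vmax, Km):
        return Vmax * S / (Km + S)

    try:
        popt, pcov = curve_fit(law, S, v, p0=[Vmax0, Km0], maxfev=10000)
    except RuntimeError as exc:
        raise FitError(
            f"Michaelis-Menten fit did not converge: {exc}",
            last_params={"Vmax": Vmax0, "Km": Km0},
        ) from exc
    Vmax, Km = popt
    se_Vmax, se_Km = np.sqrt(np.diag(pcov))
    kcat = Vmax / E0
    return {
        "model": "mm",
        "Km": float(Km),
        "Km_se": float(se_Km),
        "Vmax": float(Vmax),
        "Vmax_se": float(se_Vmax),
        "kcat": float(kcat),
        "kcat_se": float(se_Vmax / E0),
        "kcat_over_Km": float(kcat / Km),
        "E0": float(E0),
        "n_points": int(len(S)),
    }


def fit_hill(table: pd.DataFrame, E0: Optional[float] = None) -> dict:
    """Nonlinear least-squares Hill fit (Vmax, S0.5, nH) with linearized
    initialization from the Hill plot."""
    S, v = _check_table(table)
    Vmax0 = float(np.max(v)) * 1.05
    mask = (S > 0) & (v > 0) & (v < Vmax0)
    y = np.log(v[mask] / (Vmax0 - v[mask]))
    x = np.log(S[mask])
    slope, intercept, *_ = linregress(x, y)
    n0 = slope if slope > 0 else 1.0
    S05_0 = float(np.exp(-intercept / n0)) if n0 > 0 else float(np.median(S))

    def law(S, Vmax, S05, n):
        return Vmax * S**n / (S05**n + S**n)

    try:
        popt, pcov = curve_fit(law, S, v, p0=[Vmax0, S05_0, n0], maxfev=20000)
    except RuntimeError as exc:
        raise FitError(
            f"Hill fit did not converge: {exc}",
            last_params={"Vmax": Vmax0, "S05": S05_0, "nH": n0},
        ) from exc
    Vmax, S05, nH = popt
    se = np.sqrt(np.diag(pcov))
    out = {
        "model": "hill",
        "Vmax": float(Vmax),
        "Vmax_se": float(se[0]),
        "S05": float(S05),
        "S05_se": float(se[1]),
        "nH": float(nH),
        "nH_se": float(se[2]),
        "n_points": int(len(S)),
    }
    if E0 is not None:
        out["kcat"] = float(Vmax / E0)
    return out


def heavy_atom_count(formula: str) -> int:
    """Heavy (non-hydrogen) atoms in a molecular formula like C11H15N2O8P."""
    total = 0
    for element, count in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if not element:
            continue
        if element == "H":
            continue
        total += int(count) if count else 1
    return total


def ligand_efficiency(score_kcal: float, heavy_atoms: int) -> float:
    """LE1 = docking score / heavy-atom count, to 3 decimals (round-half-even)."""
    if heavy_atoms < 1:
        raise ValueError("heavy_atoms must be >= 1")
    return round(score_kcal / heavy_atoms, 3)


def e0_micromolar(mass_ug: float, volume_L: float, mw_kda: float = OIPNCC_MW_KDA) -> float:
    """Enzyme concentration (µM) from a mass load and assay volume."""
    if mass_ug <= 0 or volume_L <= 0 or mw_kda <= 0:
        raise ValueError("mass, volume and MW must be positive")
    mol = mass_ug * 1e-6 / (mw_kda * 1e3)
    return mol / volume_L * 1e6
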