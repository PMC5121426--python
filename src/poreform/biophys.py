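"""Experimental-side calculators.

Bench-top companions to the trajectory analysis: average peptide masses
from sequence, two-state CD titration analysis (mole-fraction partition
coefficient and binding free energy), fluorescence leakage normalisation,
cuvette thermometer calibration, and the geometric dye-size -> minimum
pore oligomer estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import R_KCAL

#: average (not monoisotopic) residue masses, g/mol
RESIDUE_AVG_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153
#: OH -> NH2 substitution at an amidated C terminus
AMIDE_DELTA = -0.9847

#: molar concentration of water, used in the mole-fraction partition isotherm
WATER_MOLARITY = 55.3

AVOGADRO = 6.02214076e23


@dataclass
class PeptideSequence:
    """One-letter sequence with its C-terminal chemistry."""

    sequence: str
    c_terminus: str = "amide"    # "amide" or "acid"

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - set(RESIDUE_AVG_MASS)
        if bad:
            raise ValueError(f"unknown residue letters: {sorted(bad)}")
        if self.c_terminus not in ("amide", "acid"):
            raise ValueError("c_terminus must be 'amide' or 'acid'")


def peptide_average_mass(seq: str | PeptideSequence, c_terminus: str = "amide") -> float:
    """Average molecular mass (g/mol) of a peptide from its sequence.

    Residue masses are summed, one water is added for the free termini, and
    an amidated C terminus substitutes NH2 for OH (-0.98 Da).
    """
    if isinstance(seq, PeptideSequence):
        sequence, c_terminus = seq.sequence, seq.c_terminus
    else:
        sequence = seq
        PeptideSequence(sequence, c_terminus)   # validates
    mass = sum(RESIDUE_AVG_MASS[c] for c in sequence.upper()) + WATER_MASS
    if c_terminus == "amide":
        mass += AMIDE_DELTA
    return round(mass, 2)


def apply_mutations(sequence: str, *mutations: str) -> str:
    """Apply point mutations written as e.g. 'P15A' (1-based positions)."""
    seq = list(sequence)
    for mut in mutations:
        old, pos, new = mut[0], int(mut[1:-1]), mut[-1]
        if seq[pos - 1] != old:
            raise ValueError(
                f"mutation {mut}: position {pos} is {seq[pos - 1]}, not {old}"
            )
        seq[pos - 1] = new
    return "".join(seq)


def fraction_folded(theta: float, theta_folded: float, theta_unfolded: float) -> float:
    """Folded fraction from an ellipticity reading between the two-state
    reference signals; clamped to [0, 1] with a warning outside."""
    if theta_folded == theta_unfolded:
        raise ValueError("reference ellipticities must differ")
    f = (theta - theta_unfolded) / (theta_folded - theta_unfolded)
    if not 0.0 <= f <= 1.0:
        warnings.warn(f"fraction folded {f:.3f} outside [0, 1]; clamped", stacklevel=2)
    return float(np.clip(f, 0.0, 1.0))


@dataclass
class TitrationCurve:
    """A lipid titration monitored by mean residue ellipticity at 222 nm."""

    lipid_conc: np.ndarray       # M, strictly increasing
    theta: np.ndarray            # deg cm^2 dmol^-1
    theta_folded: float
    theta_unfolded: float
    temperature: float = 298.15  # K
    water_conc: float = WATER_MOLARITY

    def __post_init__(self) -> None:
        self.lipid_conc = np.asarray(self.lipid_conc, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if len(self.lipid_conc) != len(self.theta):
            raise ValueError("lipid and ellipticity arrays must align")
        if np.any(np.diff(self.lipid_conc) <= 0):
            raise ValueError("lipid concentrations must be strictly increasing")
        if self.theta_folded == self.theta_unfolded:
            raise ValueError("reference ellipticities must differ")


def partition_isotherm(lipid_conc, k_x, water_conc=WATER_MOLARITY):
    """Mole-fraction partitioning: bound fraction f = Kx[L]/([W] + Kx[L])."""
    lipid_conc = np.asarray(lipid_conc, dtype=float)
    return k_x * lipid_conc / (water_conc + k_x * lipid_conc)


def partition_dG(curve: TitrationCurve) -> tuple[float, float]:
    """Fit the mole-fraction partition coefficient Kx and return (Kx, dG).

    The folded fraction at each lipid concentration is fitted to
    f = Kx[L]/([W]+Kx[L]) by least squares ([W] = 55.3 M); the binding free
    energy is dG = -RT ln Kx in kcal/mol.
    """
    if len(curve.lipid_conc) < 2:
        raise ValueError("need at least 2 titration points")
    f = np.array(
        [
            fraction_folded(t, curve.theta_folded, curve.theta_unfolded)
            for t in curve.theta
        ]
    )
    if np.all(f <= 0) or np.all(f >= 1):
        raise ValueError("titration shows no two-state transition to fit")
    # linearised initial guess: f/(1-f) = Kx [L]/[W]
    interior = (f > 0) & (f < 1)
    ratio = f[interior] / (1 - f[interior])
    k0 = float(np.median(ratio * curve.water_conc / curve.lipid_conc[interior]))
    try:
        popt, _ = curve_fit(
            lambda l, k: partition_isotherm(l, k, curve.water_conc),
            curve.lipid_conc, f, p0=[max(k0, 1e-6)], maxfev=10000,
        )
    except RuntimeError as exc:
        raise ValueError(f"partition fit did not converge: {exc}") from exc
    k_x = float(popt[0])
    dg = float(-R_KCAL * curve.temperature * np.log(k_x))
    return k_x, dg


def leakage_percent(f: float, f0: float, f100: float) -> float:
    """Leakage as percent of full permeabilisation.

    ``f0`` is the no-peptide baseline, ``f100`` the detergent (full-lysis)
    signal; output is clamped to [0, 100] with a warning outside.
    """
    if f100 == f0:
        raise ValueError("0% and 100% reference signals must differ")
    pct = 100.0 * (f - f0) / (f100 - f0)
    if not 0.0 <= pct <= 100.0:
        warnings.warn(f"leakage {pct:.1f}% outside [0, 100]; clamped", stacklevel=2)
    return float(np.clip(pct, 0.0, 100.0))


@dataclass
class PoreGeometryModel:
    """Order-of-magnitude pore sizing from the largest leaking dye.

    The dye is treated as a sphere of its molecular volume (partial
    specific volume 0.73 cm^3/g); the pore as a ring of n helices of
    effective diameter d with centres on the ring circumference, so the
    lumen radius is n*d/(2*pi) - d/2.
    """

    dye_mw: float                     # g/mol
    specific_volume: float = 0.73     # cm^3/g
    helix_diameter: float = 10.0      # Å

    def __post_init__(self) -> None:
        if min(self.dye_mw, self.specific_volume, self.helix_diameter) <= 0:
            raise ValueError("all geometry-model fields must be positive")


def dye_radius(model: PoreGeometryModel) -> float:
    """Spherical-molecule radius (Å) from molecular weight and specific volume."""
    vol_cm3 = model.dye_mw * model.specific_volume / AVOGADRO
    vol_a3 = vol_cm3 * 1e24
    return float((3.0 * vol_a3 / (4.0 * np.pi)) ** (1.0 / 3.0))


def min_oligomer_for_dye(model: PoreGeometryModel) -> int:
    """Smallest helix ring whose lumen passes the dye.

    n helices of diameter d on a ring give ring radius R = n*d/(2*pi) and
    lumen radius R - d/2; the smallest n with a positive lumen at least the
    dye radius is returned (n >= 4 even for a vanishing dye).
    """
    r = dye_radius(model)
    d = model.helix_diameter
    n = 2
    while True:
        lumen = n * d / (2.0 * np.pi) - d / 2.0
        if lumen > 0 and lumen >= r:
            return n
        n += 1


def cuvette_temperature(t_setting: float) -> float:
    """Actual sample temperature (°C) from the instrument setting.

    Linear thermometer calibration T_actual = 0.766*T_setting + 4.715.
    """
    return 0.766 * t_setting + 4.715


def cuvette_setting(t_actual: float) -> float:
    """Inverse of :func:`cuvette_temperature`."""
    return (t_actual - 4.715) / 0.766
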