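"""Embedded X-ray physics constants for mineralized-tissue work.

Mass attenuation coefficients (cm^2/g) are shipped as a small frozen table
over 3-20 keV, log-log interpolated between grid points, rather than pulled
from a live atomic-data dependency, so that every quantification run is
bit-reproducible.  Values for O, P and Ca are photoabsorption coefficients
derived from Cromer-Liberman f'' cross sections; at these energies the
photoelectric effect dominates total attenuation for Z >= 8.  The Ca grid is
split across the K edge at 4.038 keV.  Hydrogen attenuates almost purely by
scattering and contributes ~0.2% of hydroxyapatite by mass, so its
(scattering-dominated) total coefficients are used.
"""

from __future__ import annotations

import numpy as np

# Atomic masses (g/mol) as conventionally rounded in the dental literature.
ATOMIC_MASS = {
    "H": 1.008,
    "O": 15.999,
    "P": 30.974,
    "Ca": 40.08,
    "Mg": 24.305,
    "Ti": 47.867,
    "Fe": 55.845,
    "Cu": 63.546,
    "Zn": 65.38,
    "Sr": 87.62,
}

# Weighted K-alpha fluorescence line energies, keV.
KALPHA_KEV = {
    "Ca": 3.6917,
    "Ti": 4.5109,
    "Cr": 5.4147,
    "Mn": 5.8988,
    "Fe": 6.4039,
    "Cu": 8.0478,
    "Zn": 8.6389,
    "Rb": 13.3953,
    "Sr": 14.1650,
}

# Energy grid (keV).  4.036/4.040 bracket the Ca K edge.
_E_GRID = np.array(
    [3.0, 3.5, 4.0, 4.036, 4.040, 4.5, 5.0, 6.0, 7.0, 8.0,
     9.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0]
)

_MU_RHO = {
    "H": np.array(
        [0.5612, 0.4970, 0.4546, 0.4536, 0.4535, 0.4353, 0.4193, 0.4042,
         0.3969, 0.3914, 0.3880, 0.3854, 0.3810, 0.3780, 0.3750, 0.3730,
         0.3695]),
    "O": np.array(
        [206.7768, 131.2679, 88.2738, 85.9455, 85.6918, 62.0534, 45.1853,
         25.9839, 16.2057, 10.7317, 7.4421, 5.3536, 3.0087, 1.8445, 1.2054,
         0.8273, 0.5903]),
    "P": np.array(
        [1116.0031, 742.7908, 519.1694, 506.7496, 505.3942, 376.6056,
         281.4481, 169.0241, 109.1841, 74.4481, 52.9262, 38.8453, 22.6381,
         14.2901, 9.5677, 6.7026, 4.8671]),
    "Ca": np.array(
        [253.4055, 165.4313, 114.1253, 111.3103, 1053.4487, 789.1055,
         600.6169, 371.4103, 245.4544, 170.4798, 123.0437, 91.5251, 54.5733,
         35.0716, 23.8233, 16.8840, 12.3742]),
}

# Hydroxyapatite Ca10(PO4)6(OH)2 mass fractions.
_M_HAP = 10 * ATOMIC_MASS["Ca"] + 6 * (ATOMIC_MASS["P"] + 4 * ATOMIC_MASS["O"]) \
    + 2 * (ATOMIC_MASS["O"] + ATOMIC_MASS["H"])
HYDROXYAPATITE_MASS_FRACTIONS = {
    "Ca": 10 * ATOMIC_MASS["Ca"] / _M_HAP,
    "P": 6 * ATOMIC_MASS["P"] / _M_HAP,
    "O": 26 * ATOMIC_MASS["O"] / _M_HAP,
    "H": 2 * ATOMIC_MASS["H"] / _M_HAP,
}


def mass_attenuation(element: str, energy_kev: float | np.ndarray) -> np.ndarray:
    """µ/ρ of a pure element in cm²/g, log-log interpolated on the 3-20 keV grid.

    Raises ``KeyError`` for elements outside the embedded matrix set and
    ``ValueError`` for energies outside table coverage.
    """
    if element not in _MU_RHO:
        raise KeyError(
            f"no embedded attenuation data for element {element!r}; "
            f"available: {sorted(_MU_RHO)}"
        )
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e < _E_GRID[0]) or np.any(e > _E_GRID[-1]):
        raise ValueError(
            f"energy {energy_kev} keV outside embedded table coverage "
            f"[{_E_GRID[0]}, {_E_GRID[-1]}] keV"
        )
    out = np.exp(np.interp(np.log(e), np.log(_E_GRID), np.log(_MU_RHO[element])))
    return out if out.shape else float(out)


def matrix_mass_attenuation(energy_kev: float,
                            mass_fractions: dict[str, float] | None = None) -> float:
    """µ/ρ of a compound by the mass-weighted mixture rule (default hydroxyapatite)."""
    fr = HYDROXYAPATITE_MASS_FRACTIONS if mass_fractions is None else mass_fractions
    return float(sum(w * mass_attenuation(el, energy_kev) for el, w in fr.items()))
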