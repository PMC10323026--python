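"""Physical constants and element data used throughout the package.

Energies are kcal/mol, lengths Å, temperatures K — the conventional units
of biomolecular force fields.
"""

from __future__ import annotations

import numpy as np
from scipy import constants as _sc

#: Boltzmann constant in kcal·mol⁻¹·K⁻¹.
KB_KCAL = _sc.k * _sc.N_A / (_sc.calorie * 1000.0)

#: Coulomb constant e²/(4πε₀) in kcal·Å·mol⁻¹·e⁻², the value used by the
#: major MD engines.
COULOMB_KCAL_ANG = 332.0637

#: Default relative permittivity of water at 298 K.
EPSILON_R_WATER = 78.4

#: Default analysis temperature (K).
T_DEFAULT = 298.0


def kbt(temperature: float = T_DEFAULT) -> float:
    """Thermal energy k_B·T in kcal/mol."""
    return KB_KCAL * temperature


def debye_kappa(ionic_strength: float, epsilon_r: float = EPSILON_R_WATER,
                temperature: float = T_DEFAULT) -> float:
    """Inverse Debye screening length κ in Å⁻¹.

    Parameters
    ----------
    ionic_strength : float
        Ionic strength in mol·dm⁻³ (I = ½ Σ cᵢ zᵢ²; for a 1:1 salt this is
        simply the salt concentration).
    epsilon_r : float
        Relative permittivity of the solvent.
    temperature : float
        Temperature in K.

    Notes
    -----
    κ² = 2 e² N_A (1000·I) / (ε₀ ε_r k_B T) in SI units, converted to Å⁻¹.
    At I = 2 mol·dm⁻³, 298 K, ε_r = 78.4 this gives κ⁻¹ ≈ 2.15 Å.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength == 0.0:
        return 0.0
    number_density = 1000.0 * ionic_strength * _sc.N_A  # ions per m^3 per species
    kappa_sq = (2.0 * _sc.e ** 2 * number_density /
                (_sc.epsilon_0 * epsilon_r * _sc.k * temperature))
    return float(np.sqrt(kappa_sq) * 1e-10)  # 1/m -> 1/Å


#: Bondi van der Waals radii (Å) for the elements that occur in protein /
#: water / salt systems.  Overridable per call in the SASA routine.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "K": 2.75,
    "NA": 2.27,
    "BR": 1.85,
    "I": 1.98,
}
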