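"""Distance-resolved synergy from potentials of mean force.

Three two-body PMFs — between two charged aspartate-like side chains
(D-D), two neutral asparagine-like ones (N-N), and the mixed pair (D-N) —
are combined into

    ΔΔG(ξ) = g_DD(ξ) + g_NN(ξ) − 2·g_DN(ξ),

the distance-resolved analog of the alchemical synergy statistic: negative
values would signal a synergistic attraction between the two carboxylates.
Each WHAM curve is only defined up to a constant, so the three curves are
anchored first: the D-N and N-N curves are shifted to zero at a reference
separation (15 Å by default) where their interaction is negligible, and
the D-D curve is shifted so that its offset from N-N at the reference
equals the analytic Coulomb interaction of two point charges — screened by
the electrolyte at the stated ionic strength (Debye–Hückel), or unscreened
on request.  The alignment uses the bin containing the reference, not an
interpolated value.

The PMFs deliberately exclude the ideal-gas (Jacobian) term −2·k_BT·ln ξ
of a 3D distance coordinate; :func:`jacobian_term` adds or removes it
explicitly when needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .constants import COULOMB_KCAL_ANG, EPSILON_R_WATER, T_DEFAULT, debye_kappa, kbt
from .wham import PMFCurve

__all__ = [
    "ScreenedCoulombParams",
    "PairPMFSet",
    "XI_REF_DEFAULT",
    "ionic_strength_from_molality",
    "screened_coulomb",
    "align_pair_set",
    "ddg_xi",
    "jacobian_term",
    "mean_field_screening_profile",
]

XI_REF_DEFAULT = 15.0  # Å


def ionic_strength_from_molality(b_salt: float, density: float = 1.0) -> float:
    """Ionic strength (mol/dm³) of a 1:1 salt from molality (mol/kg).

    Assumes a solution density of 1 kg/dm³ — an approximation adequate for
    anchoring curves at separations where the interaction is already tiny.
    """
    if b_salt < 0:
        raise ValueError("molality must be >= 0")
    return b_salt * density


@dataclass(frozen=True)
class ScreenedCoulombParams:
    """Point-charge electrostatics with optional Debye–Hückel screening."""

    z1: float
    z2: float
    epsilon_r: float = EPSILON_R_WATER
    ionic_strength: float = 0.0  # mol/dm³
    temperature: float = T_DEFAULT
    coulomb_constant: float = COULOMB_KCAL_ANG
    screened: bool = True

    def __post_init__(self):
        if self.epsilon_r <= 0:
            raise ValueError("epsilon_r must be > 0")
        if self.ionic_strength < 0:
            raise ValueError("ionic_strength must be >= 0")

    @property
    def kappa(self) -> float:
        """Inverse Debye length (Å⁻¹); zero when unscreened or I = 0."""
        if not self.screened:
            return 0.0
        return debye_kappa(self.ionic_strength, self.epsilon_r, self.temperature)

    @classmethod
    def for_salt_molality(cls, b_salt: float, z1: float = -1.0, z2: float = -1.0,
                          **kwargs) -> "ScreenedCoulombParams":
        return cls(z1=z1, z2=z2,
                   ionic_strength=ionic_strength_from_molality(b_salt), **kwargs)


def screened_coulomb(params: ScreenedCoulombParams, r) -> np.ndarray | float:
    """U(r) = C·z₁·z₂/(ε_r·r)·exp(−κr) in kcal/mol, r in Å."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("r must be > 0")
    u = (params.coulomb_constant * params.z1 * params.z2 /
         (params.epsilon_r * r_arr) * np.exp(-params.kappa * r_arr))
    return float(u) if np.ndim(r) == 0 else u


@dataclass(frozen=True)
class PairPMFSet:
    """The D-D / N-N / D-N PMF triple on a common grid."""

    dd: PMFCurve
    nn: PMFCurve
    dn: PMFCurve
    salt_molality: float = 0.0
    orientation: tuple[float, float, float] = (90.0, 90.0, 0.0)  # θ1, θ2, φ deg
    aligned: bool = False

    def __post_init__(self):
        e0 = self.dd.edges
        for curve in (self.nn, self.dn):
            if len(curve.edges) != len(e0) or any(
                    a.shape != b.shape or not np.allclose(a, b)
                    for a, b in zip(curve.edges, e0)):
                raise ValueError("the three PMFs must share a common bin grid")

    @property
    def curves(self) -> dict[str, PMFCurve]:
        return {"dd": self.dd, "nn": self.nn, "dn": self.dn}


def align_pair_set(pair_set: PairPMFSet, xi_ref: float = XI_REF_DEFAULT,
                   params: ScreenedCoulombParams | None = None) -> PairPMFSet:
    """Anchor the PMF triple at the reference separation.

    After alignment g_dn(ξ_ref) = g_nn(ξ_ref) = 0 and
    g_dd(ξ_ref) − g_nn(ξ_ref) equals the analytic (screened) Coulomb
    interaction of the two charged side chains at ξ_ref.  Aligning an
    already aligned set is a no-op.  Raises if the reference bin is
    unvisited in any curve.
    """
    if params is None:
        params = ScreenedCoulombParams.for_salt_molality(pair_set.salt_molality)
    ref_values = {}
    for name, curve in pair_set.curves.items():
        v = curve.value_at(xi_ref)
        if not np.isfinite(v):
            raise ValueError(f"reference bin at xi={xi_ref} Å is undefined "
                             f"in the {name.upper()} curve")
        ref_values[name] = v
    u_ref = screened_coulomb(params, xi_ref)
    nn = pair_set.nn.shifted(-ref_values["nn"])
    dn = pair_set.dn.shifted(-ref_values["dn"])
    dd = pair_set.dd.shifted(-ref_values["dd"] + u_ref)
    return replace(pair_set, dd=dd, nn=nn, dn=dn, aligned=True)


def ddg_xi(pair_set: PairPMFSet) -> pd.DataFrame:
    """Pointwise ΔΔG(ξ) = g_DD + g_NN − 2·g_DN on the common grid.

    Requires an aligned set (the raw WHAM curves carry arbitrary offsets
    that would shift ΔΔG(ξ) by an arbitrary constant).  Bins undefined in
    any input are NaN in the output.
    """
    if not pair_set.aligned:
        raise ValueError("pair set is not aligned; call align_pair_set() first "
                         "so the three curves share a physical zero")
    g = pair_set.dd.g + pair_set.nn.g - 2.0 * pair_set.dn.g
    xi = pair_set.dd.centers[0]
    return pd.DataFrame({"xi": xi, "ddg": g})


def jacobian_term(curve: PMFCurve, direction: Literal["add", "remove"],
                  temperature: float | None = None) -> PMFCurve:
    """Add or remove the ideal-gas entropic term 2·k_BT·ln ξ of a radial
    coordinate.

    ``add`` returns g + 2k_BT ln ξ, ``remove`` subtracts it; the state is
    recorded under ``meta['jacobian_included']``.
    """
    if curve.ndim != 1:
        raise ValueError("jacobian term applies to a 1D radial PMF")
    if direction not in ("add", "remove"):
        raise ValueError("direction must be 'add' or 'remove'")
    xi = curve.centers[0]
    if np.any(xi <= 0):
        raise ValueError("all grid points must be positive to take ln(xi)")
    temp = curve.temperature if temperature is None else temperature
    term = 2.0 * kbt(temp) * np.log(xi)
    sign = 1.0 if direction == "add" else -1.0
    meta = dict(curve.meta)
    meta["jacobian_included"] = direction == "add"
    return replace(curve, g=curve.g + sign * term, meta=meta)


def mean_field_screening_profile(params: ScreenedCoulombParams, r_grid,
                                 cutoff: float | None = None
                                 ) -> tuple[pd.DataFrame, float | None]:
    """Screened-Coulomb profile U(r) plus the shielding crossing distance.

    Returns the table of U on ``r_grid`` and the smallest grid r at which
    |U| drops below ``cutoff`` (default k_BT at the stated temperature), or
    None if it never does on the grid.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(r_grid <= 0):
        raise ValueError("r_grid must be positive")
    if cutoff is None:
        cutoff = kbt(params.temperature)
    u = screened_coulomb(params, r_grid)
    table = pd.DataFrame({"r": r_grid, "u": u})
    below = np.abs(u) < cutoff
    r_cross = float(r_grid[below][0]) if below.any() else None
    return table, r_cross
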