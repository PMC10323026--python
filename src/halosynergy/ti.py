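"""Thermodynamic integration of alchemical mutation free energies.

A residue mutation X→Y is carried out in three alchemical legs — removing
the atomic charges of X (``decharge``), morphing the Lennard-Jones/bonded
terms of the uncharged residue (``vdw``), and reinstating the charges of Y
(``charge``).  Each leg samples ∂V/∂λ at a ladder of coupling values
λ ∈ [0, 1]; the leg free energy is ΔG = ∫₀¹ ⟨∂V/∂λ⟩ dλ, evaluated here with
either a natural cubic spline (the default, "TI-3" in the alchemical
literature) or the composite trapezoid rule.  The mutation free energy is
the sum of the three leg integrals.

The user-facing entry point is the :class:`ThermodynamicIntegration` model,
built from a collection of :class:`LambdaWindow` time series; ``fit()``
returns a :class:`TIResults` carrying per-leg estimates, the total, and
propagated standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "LEG_LABELS",
    "LambdaWindow",
    "LegEstimate",
    "MutationFreeEnergy",
    "EmptyWindowError",
    "discard_equilibration",
    "block_statistics",
    "replicate_statistics",
    "window_statistics",
    "integration_weights",
    "integrate_leg",
    "mutation_free_energy",
    "ThermodynamicIntegration",
    "TIResults",
]

LEG_LABELS = ("decharge", "vdw", "charge")

#: Default equilibration discard: the first 1 ns of each production window.
T_EQ_DEFAULT = 1000.0  # ps

#: Default number of blocks for block averaging, mirroring the five
#: independent calculations used to gauge reproducibility.
N_BLOCKS_DEFAULT = 5


class EmptyWindowError(ValueError):
    """Raised when an operation would leave a λ-window without samples."""


@dataclass(frozen=True)
class LambdaWindow:
    """One alchemical window: a ∂V/∂λ time series at fixed λ.

    Parameters
    ----------
    lambda_value : float
        Coupling parameter in [0, 1].
    times : ndarray
        Sample times in ps, strictly increasing.
    dvdl : ndarray
        ∂V/∂λ samples in kcal/mol, same length as ``times``.
    leg : str
        One of ``decharge``, ``vdw``, ``charge``.
    """

    lambda_value: float
    times: np.ndarray
    dvdl: np.ndarray
    leg: str

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "dvdl", np.asarray(self.dvdl, dtype=float))
        if not 0.0 <= self.lambda_value <= 1.0:
            raise ValueError(f"lambda_value {self.lambda_value} outside [0, 1]")
        if self.leg not in LEG_LABELS:
            raise ValueError(f"unknown leg label {self.leg!r}; expected one of {LEG_LABELS}")
        if self.times.size == 0:
            raise EmptyWindowError(
                f"window (leg={self.leg}, lambda={self.lambda_value}) has no samples")
        if self.times.size != self.dvdl.size:
            raise ValueError("times and dvdl must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def discard_equilibration(window: LambdaWindow, t_eq: float = T_EQ_DEFAULT) -> LambdaWindow:
    """Drop all samples with time ≤ ``t_eq`` (ps) from a window.

    Raises :class:`EmptyWindowError` (naming the window) if nothing remains.
    """
    if t_eq < 0:
        raise ValueError("t_eq must be >= 0")
    keep = window.times > t_eq
    if not keep.any():
        raise EmptyWindowError(
            f"discarding t <= {t_eq} ps leaves window "
            f"(leg={window.leg}, lambda={window.lambda_value}) empty")
    return replace(window, times=window.times[keep], dvdl=window.dvdl[keep])


def block_statistics(window: LambdaWindow, n_blocks: int = N_BLOCKS_DEFAULT
                     ) -> tuple[float, float]:
    """Mean and block-averaged SEM of one window's ∂V/∂λ series.

    The series is split into ``n_blocks`` contiguous blocks of equal length
    (a remainder shorter than a block is folded into the last block); the
    SEM is the sample standard deviation of the block means over
    √n_blocks.  With a single block the SEM is undefined and returned as
    NaN with a warning — never silently zero.
    """
    mean = float(np.mean(window.dvdl))
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if n_blocks == 1 or len(window) < 2 * n_blocks:
        warnings.warn(
            f"SEM undefined for window (leg={window.leg}, "
            f"lambda={window.lambda_value}): need >= 2 samples per block",
            stacklevel=2)
        return mean, float("nan")
    edges = np.linspace(0, len(window), n_blocks + 1).astype(int)
    block_means = np.array([window.dvdl[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    sem = float(np.std(block_means, ddof=1) / np.sqrt(n_blocks))
    return mean, sem


def replicate_statistics(windows: Sequence[LambdaWindow]) -> tuple[float, float]:
    """Mean and SEM over independent replicate windows at the same λ.

    The replicate spread is the authoritative uncertainty when replicates
    exist: mean of the replicate means, SEM their sample standard deviation
    over √n.  A single replicate yields SEM = NaN with a warning.
    """
    if len(windows) == 0:
        raise ValueError("need at least one replicate window")
    lam = windows[0].lambda_value
    leg = windows[0].leg
    for w in windows[1:]:
        if w.leg != leg or not np.isclose(w.lambda_value, lam):
            raise ValueError("replicates must share leg and lambda")
    means = np.array([np.mean(w.dvdl) for w in windows])
    mean = float(means.mean())
    if len(windows) < 2:
        warnings.warn(
            f"SEM undefined from a single replicate (leg={leg}, lambda={lam})",
            stacklevel=2)
        return mean, float("nan")
    sem = float(np.std(means, ddof=1) / np.sqrt(len(means)))
    return mean, sem


def window_statistics(window: LambdaWindow | None = None, *,
                      n_blocks: int | None = None,
                      replicates: Sequence[LambdaWindow] | None = None
                      ) -> tuple[float, float]:
    """Dispatch to block averaging or replicate statistics.

    Exactly one of ``n_blocks`` (with ``window``) or ``replicates`` must be
    given.
    """
    if replicates is not None:
        if window is not None or n_blocks is not None:
            raise ValueError("pass either (window, n_blocks) or replicates, not both")
        return replicate_statistics(replicates)
    if window is None:
        raise ValueError("window required in block mode")
    return block_statistics(window, N_BLOCKS_DEFAULT if n_blocks is None else n_blocks)


@dataclass(frozen=True)
class LegEstimate:
    """Per-λ means/SEMs and the integrated ΔG of one alchemical leg."""

    leg: str
    lambdas: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    delta_g: float
    delta_g_sem: float
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda": self.lambdas, "mean": self.means,
                             "sem": self.sems})


def _validate_grid(lambdas: np.ndarray) -> None:
    if lambdas.size < 2:
        raise ValueError("need at least two lambda points")
    if np.any(np.diff(lambdas) <= 0):
        raise ValueError("lambda grid must be strictly ascending (no duplicates)")
    if lambdas[0] < 0 or lambdas[-1] > 1:
        raise ValueError("lambda grid must lie within [0, 1]")
    if not (np.isclose(lambdas[0], 0.0) and np.isclose(lambdas[-1], 1.0)):
        raise ValueError(
            "lambda grid must include both endpoints 0 and 1; "
            "extrapolating alchemical endpoints silently biases the integral")


def integration_weights(lambdas: np.ndarray,
                        method: Literal["spline", "trapezoid"] = "spline"
                        ) -> np.ndarray:
    """Quadrature weights w such that ∫₀¹ f dλ ≈ Σ wᵢ f(λᵢ).

    For the trapezoid rule these are the classical composite weights.  For
    the natural cubic spline the interpolant is linear in the ordinates, so
    exact weights follow from integrating the cardinal splines (one unit
    basis vector per node).
    """
    lambdas = np.asarray(lambdas, dtype=float)
    _validate_grid(lambdas)
    if method == "trapezoid":
        w = np.zeros_like(lambdas)
        d = np.diff(lambdas)
        w[:-1] += d / 2.0
        w[1:] += d / 2.0
        return w
    if method == "spline":
        n = lambdas.size
        w = np.empty(n)
        eye = np.eye(n)
        for i in range(n):
            cs = CubicSpline(lambdas, eye[i], bc_type="natural")
            w[i] = cs.integrate(lambdas[0], lambdas[-1])
        return w
    raise ValueError(f"unknown method {method!r}")


def integrate_leg(lambdas: Sequence[float], means: Sequence[float],
                  sems: Sequence[float] | None = None,
                  method: Literal["spline", "trapezoid"] = "spline",
                  leg: str = "decharge") -> LegEstimate:
    """Integrate ⟨∂V/∂λ⟩ over λ ∈ [0, 1] into a leg free energy.

    ``delta_g_sem`` propagates the per-λ SEMs through the (linear)
    quadrature weights in quadrature, assuming independence across windows.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    means = np.asarray(means, dtype=float)
    if sems is None:
        sems = np.zeros_like(means)
    sems = np.asarray(sems, dtype=float)
    if not (lambdas.shape == means.shape == sems.shape):
        raise ValueError("lambdas, means, sems must have identical shape")
    if not np.all(np.isfinite(means)):
        raise ValueError("non-finite mean values")
    if np.any(sems[np.isfinite(sems)] < 0):
        raise ValueError("SEMs must be >= 0")
    w = integration_weights(lambdas, method)
    delta_g = float(w @ means)
    delta_g_sem = float(np.sqrt(np.sum((w * sems) ** 2)))
    return LegEstimate(leg=leg, lambdas=lambdas, means=means, sems=sems,
                       delta_g=delta_g, delta_g_sem=delta_g_sem, method=method)


@dataclass(frozen=True)
class MutationFreeEnergy:
    """Total free energy of one X→Y mutation in one neighbor context."""

    site: str
    from_aa: str
    to_aa: str
    neighbor_state: str  # "charged" (−) or "neutral" (0)
    legs: dict[str, LegEstimate]
    total: float
    total_sem: float

    def __post_init__(self):
        if set(self.legs) != set(LEG_LABELS):
            raise ValueError(f"expected exactly one leg per label {LEG_LABELS}, "
                             f"got {sorted(self.legs)}")
        s = sum(est.delta_g for est in self.legs.values())
        if abs(s - self.total) > 1e-9:
            raise ValueError("total does not equal the sum of the legs")


def mutation_free_energy(decharge: LegEstimate, vdw: LegEstimate,
                         charge: LegEstimate, site: str = "",
                         from_aa: str = "D", to_aa: str = "N",
                         neighbor_state: str = "charged") -> MutationFreeEnergy:
    """Combine the three leg estimates into the mutation free energy.

    total = ΔG_decharge + ΔG_vdW + ΔG_charge; the SEM is the quadrature sum
    of the leg SEMs.
    """
    legs = {}
    for expected, est in zip(LEG_LABELS, (decharge, vdw, charge)):
        if est.leg != expected:
            raise ValueError(f"leg in position {expected!r} carries label {est.leg!r}")
        legs[expected] = est
    total = sum(est.delta_g for est in legs.values())
    total_sem = float(np.sqrt(sum(est.delta_g_sem ** 2 for est in legs.values())))
    return MutationFreeEnergy(site=site, from_aa=from_aa, to_aa=to_aa,
                              neighbor_state=neighbor_state, legs=legs,
                              total=total, total_sem=total_sem)


class ThermodynamicIntegration:
    """TI model over a collection of per-λ ∂V/∂λ windows.

    Windows may span several legs; multiple windows at the same (leg, λ)
    are treated as independent replicates and their spread is used for the
    SEM (replicate mode).  Otherwise the SEM comes from block averaging
    within each window.

    Parameters
    ----------
    windows : iterable of LambdaWindow
    t_eq : float
        Equilibration time discarded from the start of every window (ps).
    n_blocks : int
        Number of blocks for block averaging.

    Examples
    --------
    >>> model = ThermodynamicIntegration(windows, t_eq=1000.0)
    >>> res = model.fit(method="spline")
    >>> res.legs["decharge"].delta_g  # doctest: +SKIP
    """

    def __init__(self, windows: Iterable[LambdaWindow],
                 t_eq: float = T_EQ_DEFAULT,
                 n_blocks: int = N_BLOCKS_DEFAULT):
        self.windows = [discard_equilibration(w, t_eq) if t_eq > 0 else w
                        for w in windows]
        if not self.windows:
            raise ValueError("no windows supplied")
        self.t_eq = t_eq
        self.n_blocks = n_blocks

    def fit(self, method: Literal["spline", "trapezoid"] = "spline") -> "TIResults":
        grouped: dict[str, dict[float, list[LambdaWindow]]] = {}
        for w in self.windows:
            grouped.setdefault(w.leg, {}).setdefault(round(w.lambda_value, 12), []).append(w)
        legs = {}
        for leg, by_lambda in grouped.items():
            lambdas = np.array(sorted(by_lambda))
            means = np.empty_like(lambdas)
            sems = np.empty_like(lambdas)
            for i, lam in enumerate(lambdas):
                reps = by_lambda[lam]
                if len(reps) > 1:
                    means[i], sems[i] = replicate_statistics(reps)
                else:
                    means[i], sems[i] = block_statistics(reps[0], self.n_blocks)
            legs[leg] = integrate_leg(lambdas, means, sems, method=method, leg=leg)
        return TIResults(model=self, legs=legs, method=method)


@dataclass
class TIResults:
    """Results of a thermodynamic-integration fit."""

    model: ThermodynamicIntegration
    legs: dict[str, LegEstimate]
    method: str

    def mutation_free_energy(self, site: str = "", from_aa: str = "D",
                             to_aa: str = "N",
                             neighbor_state: str = "charged") -> MutationFreeEnergy:
        """Assemble the three-leg total; requires all three legs fitted."""
        missing = set(LEG_LABELS) - set(self.legs)
        if missing:
            raise ValueError(f"legs missing from fit: {sorted(missing)}")
        return mutation_free_energy(self.legs["decharge"], self.legs["vdw"],
                                    self.legs["charge"], site=site,
                                    from_aa=from_aa, to_aa=to_aa,
                                    neighbor_state=neighbor_state)

    def summary(self) -> str:
        rows = []
        for leg in LEG_LABELS:
            if leg in self.legs:
                est = self.legs[leg]
                rows.append({"leg": leg, "n_lambda": est.lambdas.size,
                             "delta_g": est.delta_g, "sem": est.delta_g_sem})
        df = pd.DataFrame(rows)
        lines = ["Thermodynamic integration results",
                 f"  method: {self.method} (natural cubic spline)" if self.method == "spline"
                 else f"  method: {self.method}",
                 f"  t_eq discarded: {self.model.t_eq} ps",
                 df.to_string(index=False, float_format=lambda v: f"{v:10.4f}")]
        if set(self.legs) == set(LEG_LABELS):
            total = sum(e.delta_g for e in self.legs.values())
            sem = np.sqrt(sum(e.delta_g_sem ** 2 for e in self.legs.values()))
            lines.append(f"  total ΔG = {total:.4f} ± {sem:.4f} kcal/mol")
        return "\n".join(lines)
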