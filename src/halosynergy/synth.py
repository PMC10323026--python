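"""Synthetic inputs with known ground truth for every pipeline stage.

Cluster-scale MD is out of reach at desk scale, so each input class the
estimators consume is emulated by a generator that records machine-
readable truth alongside the data:

* ``gen_dvdl`` — noisy, AR(1)-autocorrelated ∂V/∂λ time series around a
  polynomial mean whose integral is known in closed form;
* ``gen_umbrella`` — Metropolis-sampled umbrella windows on a mimic pair
  potential (screened Coulomb between the side-chain charge centers plus
  a 12-6 short-range well), with the exact potential as truth.  Sampling
  is plain 1D in ξ, i.e. the ideal-gas ξ² Jacobian of a radial coordinate
  is deliberately absent, matching the convention of the PMF analysis;
* ``gen_toy_structures`` and friends — minimal aspartate-like residues
  (stub backbone + CG/OD1/OD2) and water molecules placed at controlled
  hydrogen-bond geometries.

Every generator is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import T_DEFAULT, kbt
from .pmf import ScreenedCoulombParams, screened_coulomb
from .structure import Structure, Trajectory
from .ti import LambdaWindow
from .wham import UmbrellaWindow

__all__ = [
    "DvdlProfile",
    "MimicPotential",
    "RestraintSpec",
    "gen_dvdl",
    "gen_umbrella",
    "gen_toy_structures",
    "gen_gaussian_pair_trajectory",
    "gen_hbond_frames",
    "default_mimic_triple",
]

#: Default umbrella schedule: centers every 0.5 Å from 3 to 16 Å with
#: k = 10 kcal·mol⁻¹·Å⁻², chosen for adjacent-window histogram overlap at
#: 298 K (window width ≈ √(k_BT/k) ≈ 0.24 Å).
UMBRELLA_CENTERS_DEFAULT = np.arange(3.0, 16.0 + 1e-9, 0.5)
UMBRELLA_K_DEFAULT = 10.0

OH_BOND = 0.9572          # Å, rigid water geometry
HOH_ANGLE = np.deg2rad(104.52)


@dataclass(frozen=True)
class DvdlProfile:
    """Specification of one leg's synthetic ∂V/∂λ data.

    ``coefficients`` are polynomial coefficients in λ, lowest order first;
    the exact leg integral is Σ cₖ/(k+1).  Noise is stationary AR(1)
    Gaussian with standard deviation ``noise_sd`` and lag-1 correlation
    ``ar1_coefficient``.
    """

    leg: str = "decharge"
    coefficients: tuple[float, ...] = (2.0, 3.0)
    noise_sd: float = 0.5
    ar1_coefficient: float = 0.8
    n_samples: int = 2000
    lambda_grid: tuple[float, ...] = tuple(np.linspace(0.0, 1.0, 11))
    seed: int = 0
    dt: float = 1.0  # ps between samples

    def __post_init__(self):
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def exact_integral(self) -> float:
        return sum(c / (k + 1) for k, c in enumerate(self.coefficients))

    def mean(self, lam) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(lam), self.coefficients)


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd, size=n)
    if phi == 0.0:
        return innov
    x = np.empty(n)
    x[0] = innov[0]
    scale = np.sqrt(1.0 - phi ** 2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + scale * innov[t]
    return x


def gen_dvdl(profile: DvdlProfile, out_dir: str | Path | None = None
             ) -> tuple[list[LambdaWindow], dict]:
    """Generate one leg's λ-windows plus a truth record.

    Returns the windows and a dict with the exact integral; when
    ``out_dir`` is given, one two-column text file per window, a manifest
    and a JSON truth record are written in the dialect the readers accept.
    """
    rng = np.random.default_rng(profile.seed)
    times = profile.dt * np.arange(1, profile.n_samples + 1)
    windows = []
    for lam in profile.lambda_grid:
        noise = _ar1(rng, profile.n_samples, profile.noise_sd,
                     profile.ar1_coefficient)
        dvdl = profile.mean(lam) + noise
        windows.append(LambdaWindow(lambda_value=float(lam), times=times,
                                    dvdl=dvdl, leg=profile.leg))
    truth = {"leg": profile.leg, "exact_integral": profile.exact_integral,
             "coefficients": list(profile.coefficients), "seed": profile.seed}
    if out_dir is not None:
        from .io_ import write_timeseries, write_manifest
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        entries = []
        for w in windows:
            fname = f"dvdl_{profile.leg}_{w.lambda_value:.4f}.dat"
            write_timeseries(out / fname, np.column_stack([w.times, w.dvdl]),
                             header=f"leg={profile.leg} lambda={w.lambda_value}")
            entries.append({"file": fname, "lambda": w.lambda_value,
                            "leg": profile.leg})
        write_manifest(out / f"manifest_{profile.leg}.yaml",
                       kind="ti", entries=entries)
        (out / f"truth_{profile.leg}.json").write_text(json.dumps(truth, indent=1))
    return windows, truth


@dataclass(frozen=True)
class MimicPotential:
    """Side-chain mimic pair potential: screened Coulomb + 12-6 well.

    The short-range term ε·[(r_m/r)¹² − 2(r_m/r)⁶] has its minimum −ε at
    the contact distance r_m, standing in for the attractive LJ contact
    the real mimics show below ≈4.5 Å.
    """

    electrostatic: ScreenedCoulombParams
    well_depth: float = 0.5        # kcal/mol
    contact_distance: float = 4.5  # Å
    label: str = "DD"

    def short_range(self, r) -> np.ndarray | float:
        x = self.contact_distance / np.asarray(r, dtype=float)
        u = self.well_depth * (x ** 12 - 2.0 * x ** 6)
        return float(u) if np.ndim(r) == 0 else u

    def energy(self, r) -> np.ndarray | float:
        return screened_coulomb(self.electrostatic, r) + self.short_range(r)


def default_mimic_triple(salt_molality: float = 2.0,
                         well_depth: float = 0.5,
                         contact_distance: float = 4.5,
                         temperature: float = T_DEFAULT
                         ) -> dict[str, MimicPotential]:
    """DD / NN / DN mimic potentials at the given salt molality.

    Charges are −1/−1, 0/0 and −1/0; the short-range well is identical for
    the three pairs, so the analytic ΔΔG(ξ) of the triple reduces to the
    DD screened-Coulomb repulsion (nonnegative everywhere).
    """
    def params(z1, z2):
        return ScreenedCoulombParams.for_salt_molality(
            salt_molality, z1=z1, z2=z2, temperature=temperature)
    return {
        "dd": MimicPotential(params(-1.0, -1.0), well_depth, contact_distance, "DD"),
        "nn": MimicPotential(params(0.0, 0.0), well_depth, contact_distance, "NN"),
        "dn": MimicPotential(params(-1.0, 0.0), well_depth, contact_distance, "DN"),
    }


def analytic_ddg_xi(triple: dict[str, MimicPotential], xi) -> np.ndarray:
    """Exact ΔΔG(ξ) = U_DD + U_NN − 2·U_DN of a mimic triple."""
    xi = np.asarray(xi, dtype=float)
    return (triple["dd"].energy(xi) + triple["nn"].energy(xi)
            - 2.0 * triple["dn"].energy(xi))


@dataclass(frozen=True)
class RestraintSpec:
    """Orientation restraints of the mimic systems, recorded as metadata.

    θ₁, θ₂ are the Cβ–Cα–Cα angles, φ the Cβ–Cα–Cα–Cβ dihedral; the
    backbone positional restraint constant (35 kcal·mol⁻¹·Å⁻²) is carried
    for the record only — restraint energy never enters ∂V/∂λ.
    """

    theta1: float = 90.0
    theta2: float = 90.0
    phi: float = 0.0
    angle_force_constant: float = 10.0
    backbone_force_constant: float = 35.0

    def __post_init__(self):
        if not (0.0 <= self.theta1 <= 180.0 and 0.0 <= self.theta2 <= 180.0):
            raise ValueError("angles must be in [0, 180] degrees")
        if not -180.0 < self.phi <= 180.0:
            raise ValueError("dihedral must be in (-180, 180] degrees")


def gen_umbrella(potential: MimicPotential,
                 centers: Sequence[float] = UMBRELLA_CENTERS_DEFAULT,
                 force_constant: float = UMBRELLA_K_DEFAULT,
                 n_steps: int = 50_000, step_size: float = 0.3,
                 seed: int = 0, temperature: float = T_DEFAULT,
                 xi_min: float = 0.5,
                 out_dir: str | Path | None = None
                 ) -> tuple[list[UmbrellaWindow], dict]:
    """Metropolis-sample umbrella windows on a mimic potential.

    All windows are advanced as one vectorized Markov chain (independent
    components, shared RNG stream), each under U(ξ) + ½k(ξ−c)²; proposals
    are Gaussian with width ``step_size`` and chains start at their
    centers.  Returns the windows plus a truth record holding the exact
    potential on a fine grid and the per-window acceptance rates; raises
    if any window accepts (almost) nothing.
    """
    centers = np.asarray(centers, dtype=float)
    if np.any(np.diff(centers) <= 0):
        raise ValueError("centers must be ascending")
    if n_steps < 1000:
        raise ValueError("n_steps must be >= 1000")
    rng = np.random.default_rng(seed)
    kt = kbt(temperature)

    def total_u(x):
        u = np.where(x > xi_min, potential.energy(np.maximum(x, xi_min)), np.inf)
        return u + 0.5 * force_constant * (x - centers) ** 2

    x = centers.copy()
    u = total_u(x)
    n_win = centers.size
    samples = np.empty((n_steps, n_win))
    accepted = np.zeros(n_win)
    for step in range(n_steps):
        prop = x + rng.normal(0.0, step_size, size=n_win)
        u_prop = total_u(prop)
        accept = np.log(rng.uniform(size=n_win)) < (u - u_prop) / kt
        x = np.where(accept, prop, x)
        u = np.where(accept, u_prop, u)
        accepted += accept
        samples[step] = x
    rates = accepted / n_steps
    if np.any(rates < 1e-3):
        bad = centers[rates < 1e-3]
        raise RuntimeError(f"Metropolis acceptance ~0 for windows at {bad}; "
                           "reduce step_size")
    windows = [UmbrellaWindow(centers=(float(c),),
                              force_constants=(force_constant,),
                              samples=samples[:, i], temperature=temperature)
               for i, c in enumerate(centers)]
    fine = np.linspace(max(xi_min, centers[0] - 1.0), centers[-1] + 1.0, 1001)
    truth = {"label": potential.label, "xi": fine.tolist(),
             "u": np.asarray(potential.energy(fine)).tolist(),
             "acceptance_rates": rates.tolist(), "seed": seed,
             "centers": centers.tolist(), "force_constant": force_constant,
             "temperature": temperature}
    if out_dir is not None:
        from .io_ import write_timeseries, write_manifest
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        entries = []
        times = np.arange(1, n_steps + 1, dtype=float)
        for i, w in enumerate(windows):
            fname = f"umbrella_{potential.label}_{w.centers[0]:.2f}.dat"
            write_timeseries(out / fname,
                             np.column_stack([times, w.samples[:, 0]]),
                             header=f"center={w.centers[0]} k={force_constant}")
            entries.append({"file": fname, "center": w.centers[0],
                            "force_constant": force_constant,
                            "temperature": temperature})
        write_manifest(out / f"manifest_{potential.label}.yaml",
                       kind="umbrella", entries=entries)
        (out / f"truth_{potential.label}.json").write_text(json.dumps(truth))
    return windows, truth


def _water_atoms(o_pos: np.ndarray, h1_pos: np.ndarray,
                 away_from: np.ndarray) -> np.ndarray:
    """Coordinates (O, H1, H2) completing a rigid water from O and H1.

    The second hydrogen is oriented with its in-plane component pointing
    away from ``away_from`` (the acceptor), so only H1 can register as the
    donating hydrogen.
    """
    b1 = h1_pos - o_pos
    b1 /= np.linalg.norm(b1)
    v = o_pos - away_from
    v_perp = v - (v @ b1) * b1
    norm = np.linalg.norm(v_perp)
    if norm < 1e-8:
        ref = np.array([1.0, 0.0, 0.0])
        if abs(b1 @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        v_perp = np.cross(b1, ref)
        norm = np.linalg.norm(v_perp)
    perp = v_perp / norm
    b2 = np.cos(HOH_ANGLE) * b1 + np.sin(HOH_ANGLE) * perp
    h2 = o_pos + OH_BOND * b2
    return np.stack([o_pos, h1_pos, h2])


def _asp_residue(cg: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Atom coordinates (N, CA, CB, CG, OD1, OD2) of a minimal Asp-like
    residue with its carboxylate carbon at ``cg``, side chain along
    ``direction``."""
    d = direction / np.linalg.norm(direction)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    perp = np.cross(d, ref)
    perp /= np.linalg.norm(perp)
    cb = cg - 1.52 * d
    ca = cb - 1.53 * (0.5 * d + np.sqrt(0.75) * perp) / 1.0
    n = ca - 1.46 * d
    od1 = cg + 1.25 * (0.766 * d + 0.643 * perp)
    od2 = cg + 1.25 * (0.766 * d - 0.643 * perp)
    return np.stack([n, ca, cb, cg, od1, od2])


ASP_ATOM_NAMES = ("N", "CA", "CB", "CG", "OD1", "OD2")


def gen_toy_structures(cg_positions: Sequence[Sequence[float]],
                       directions: Sequence[Sequence[float]] | None = None,
                       waters: Sequence[tuple[int, float, float]] = (),
                       seed: int = 0, box: Sequence[float] | None = None,
                       min_separation: float = 0.8
                       ) -> tuple[Structure, dict]:
    """Build a toy structure of Asp-like residues plus placed waters.

    Parameters
    ----------
    cg_positions : (n, 3)
        Carboxylate-carbon positions; one minimal aspartate per entry.
    directions : (n, 3), optional
        Side-chain directions (default: random unit vectors, seeded).
    waters : sequence of (acid_index, d, cos_theta)
        Each entry places one water hydrogen-bonded to OD1 of the given
        acid with heavy-atom distance ``d`` (Å) and hydrogen-angle cosine
        ``cos_theta`` exactly.
    box : length-3, optional
        Orthorhombic box edges.

    Returns the structure and a truth record with the CG–CG distance
    matrix and the requested (d, cos θ) per water.  Raises if any two
    atoms end up closer than ``min_separation``.
    """
    rng = np.random.default_rng(seed)
    cg_positions = np.asarray(cg_positions, dtype=float)
    n_acid = cg_positions.shape[0]
    if directions is None:
        v = rng.normal(size=(n_acid, 3))
        directions = v / np.linalg.norm(v, axis=1, keepdims=True)
    directions = np.asarray(directions, dtype=float)

    names, resnames, resids, chains, coords = [], [], [], [], []
    od1_pos = []
    for i in range(n_acid):
        atoms = _asp_residue(cg_positions[i], directions[i])
        od1_pos.append(atoms[4])
        coords.append(atoms)
        names += list(ASP_ATOM_NAMES)
        resnames += ["ASP"] * 6
        resids += [i + 1] * 6
        chains += ["A"] * 6

    truth_waters = []
    for w, (acid_idx, d, cos_theta) in enumerate(waters):
        oc = od1_pos[acid_idx]
        cg = cg_positions[acid_idx]
        out_dir_vec = oc - cg
        out_dir_vec /= np.linalg.norm(out_dir_vec)
        # place H on the outward direction at distance r_h solving the
        # triangle |Ow - Oc| = d with |H - Ow| = OH_BOND and angle θ at H
        disc = OH_BOND ** 2 * cos_theta ** 2 - OH_BOND ** 2 + d ** 2
        if disc < 0:
            raise ValueError(f"no geometry with d={d}, cos_theta={cos_theta}")
        r_h = OH_BOND * cos_theta + np.sqrt(disc)
        if r_h <= 0:
            raise ValueError(f"no positive H distance for d={d}, cos={cos_theta}")
        h = oc + r_h * out_dir_vec
        # O_water in the plane spanned by out_dir and a perpendicular, at
        # angle (π − θ) from H→Oc
        ref = np.array([0.0, 0.0, 1.0])
        if abs(out_dir_vec @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        perp = np.cross(out_dir_vec, ref)
        perp /= np.linalg.norm(perp)
        to_oc = -out_dir_vec  # unit vector H -> Oc
        sin_theta = np.sqrt(max(0.0, 1.0 - cos_theta ** 2))
        dir_ow = cos_theta * to_oc + sin_theta * perp
        ow = h + OH_BOND * dir_ow
        wat = _water_atoms(ow, h, away_from=oc)
        coords.append(wat)
        names += ["O", "H1", "H2"]
        resnames += ["HOH"] * 3
        resids += [n_acid + w + 1] * 3
        chains += ["W"] * 3
        truth_waters.append({"acid": acid_idx, "d": float(d),
                             "cos_theta": float(cos_theta)})

    xyz = np.concatenate(coords)
    from scipy.spatial.distance import pdist
    if xyz.shape[0] > 1 and pdist(xyz).min() < min_separation:
        raise ValueError("generated atoms overlap beyond tolerance; "
                         "adjust placements")
    structure = Structure(names=names, resnames=resnames, resids=resids,
                          chains=chains, xyz=xyz,
                          box=None if box is None else np.asarray(box, float))
    dmat = np.linalg.norm(cg_positions[:, None] - cg_positions[None, :], axis=-1)
    truth = {"cg_distances": dmat.tolist(), "waters": truth_waters,
             "seed": seed}
    return structure, truth


def gen_gaussian_pair_trajectory(mu: float = 6.0, sigma: float = 0.5,
                                 n_frames: int = 10_000, seed: int = 0,
                                 box: Sequence[float] | None = None
                                 ) -> tuple[Trajectory, dict]:
    """Two Asp residues whose CG–CG distance is Gaussian over frames."""
    rng = np.random.default_rng(seed)
    distances = rng.normal(mu, sigma, size=n_frames)
    distances = np.abs(distances)
    frames = []
    base, _ = gen_toy_structures([[0.0, 0.0, 0.0], [mu, 0.0, 0.0]],
                                 directions=[[0, 0, 1], [0, 0, 1]], seed=seed)
    shift_atoms = np.flatnonzero(base.resids == 2)
    for dist in distances:
        xyz = base.xyz.copy()
        xyz[shift_atoms, 0] += dist - mu
        frames.append(xyz)
    traj = Trajectory(names=base.names, resnames=base.resnames,
                      resids=base.resids, chains=base.chains,
                      coords=np.stack(frames),
                      box=None if box is None else np.asarray(box, float))
    return traj, {"mu": mu, "sigma": sigma, "n_frames": n_frames, "seed": seed,
                  "distances": distances}


def gen_hbond_frames(n_waters: int = 500, d_mean: float = 2.8,
                     d_sd: float = 0.15, cos_mean: float = -0.9,
                     cos_sd: float = 0.08, d_bounds: tuple = (2.4, 3.4),
                     cos_bounds: tuple = (-1.0, -0.6),
                     seed: int = 0) -> tuple[Trajectory, dict]:
    """One acid plus many waters at truncated-Gaussian (d, cos θ).

    d is drawn from N(d_mean, d_sd) truncated to ``d_bounds``; cos θ from
    N(cos_mean, cos_sd) truncated to ``cos_bounds``.  The default bounds
    keep every placed water an unambiguous near-linear donor, so the
    recorded (d, cos θ) truth matches the events the histogram routine
    counts one-to-one.
    """
    rng = np.random.default_rng(seed)

    def truncated(mean, sd, lo, hi, n):
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(mean, sd, size=2 * (n - filled))
            draw = draw[(draw >= lo) & (draw <= hi)]
            take = min(draw.size, n - filled)
            out[filled:filled + take] = draw[:take]
            filled += take
        return out

    d = truncated(d_mean, d_sd, *d_bounds, n_waters)
    cos_theta = truncated(cos_mean, cos_sd, *cos_bounds, n_waters)
    # one acid far from everything plus single-water structures merged
    # frame-by-frame would allow waters to clash; instead spread waters on
    # separate structures (frames), one water per frame
    frames = []
    for i in range(n_waters):
        s, _ = gen_toy_structures([[0.0, 0.0, 0.0]], directions=[[0, 0, 1]],
                                  waters=[(0, float(d[i]), float(cos_theta[i]))],
                                  seed=seed + i)
        frames.append(s)
    traj = Trajectory.from_structures(frames)
    return traj, {"d": d, "cos_theta": cos_theta,
                  "d_mean": float(d.mean()), "cos_mean": float(cos_theta.mean()),
                  "seed": seed}
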