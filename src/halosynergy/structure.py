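"""Structural observables on structures and trajectories.

Three analyses support the interpretation of the synergy statistic:

* solvent-exposure-based selection of candidate acidic residue pairs
  (Shrake–Rupley SASA ≥ 50 Å² per residue and carboxylate-carbon distance
  < 7 Å in the starting frame);
* histograms of carboxylate-carbon distances per residue pair over a
  trajectory;
* 2D histograms of water→carboxylate hydrogen-bond geometry, binned in
  the water-oxygen–carboxylate-oxygen distance d and the cosine of the
  angle θ at the *hydrogen* between the H→O_water and H→O_carboxylate
  vectors — a perfectly linear bond therefore accumulates at cos θ = −1.
  (The angle convention is a documented package choice; it is the standard
  donor-H-acceptor angle complemented through the hydrogen.)

Coordinates are treated with the orthorhombic minimum-image convention
when a box is present, open-boundary otherwise.  SASA itself is computed
without periodic images (intended for solutes centered in the box).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import VDW_RADII

__all__ = [
    "Structure",
    "Trajectory",
    "ResiduePair",
    "GeomHistogram",
    "DifferenceMap",
    "guess_element",
    "minimum_image",
    "sphere_points",
    "shrake_rupley_sasa",
    "select_acidic_pairs",
    "pair_distance_histogram",
    "hbond_geometry_histogram",
    "histogram_difference",
]

#: Carboxylate carbon / oxygen atom names per acidic residue type.
CARBOXYLATE_CARBON = {"ASP": "CG", "GLU": "CD"}
CARBOXYLATE_OXYGENS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}

WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3"}
WATER_OXYGEN_NAMES = {"O", "OW"}

SASA_MIN_DEFAULT = 50.0   # Å²
DMAX_DEFAULT = 7.0        # Å
HBOND_D_CUTOFF = 3.5      # Å heavy-atom cutoff
DIST_BIN_WIDTH = 0.25     # Å, 1D distance histograms
HBOND_BIN_WIDTH = 0.05    # Å and cosθ units, 2D maps

# PDB atom-name prefixes that denote two-letter elements.  "CA"/"CB" are
# deliberately absent: in protein records they are carbons.
_TWO_LETTER = {"CL", "NA", "BR", "FE", "MG", "ZN", "MN", "CU"}


def guess_element(name: str) -> str:
    """Element symbol from a PDB atom name (e.g. OD1 → O, HW2 → H)."""
    stripped = "".join(c for c in name if c.isalpha()).upper()
    if stripped[:2] in _TWO_LETTER and len(stripped) <= 2:
        return stripped[:2]
    return stripped[:1]


def minimum_image(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the orthorhombic minimum-image convention to displacement(s)."""
    if box is None:
        return d
    return d - box * np.round(d / box)


@dataclass(frozen=True)
class Structure:
    """A single frame: per-atom metadata plus coordinates in Å."""

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    xyz: np.ndarray
    box: np.ndarray | None = None
    elements: np.ndarray | None = None

    def __post_init__(self):
        xyz = np.asarray(self.xyz, dtype=float)
        object.__setattr__(self, "xyz", xyz)
        object.__setattr__(self, "names", np.asarray(self.names, dtype=object))
        object.__setattr__(self, "resnames", np.asarray(self.resnames, dtype=object))
        object.__setattr__(self, "resids", np.asarray(self.resids, dtype=int))
        object.__setattr__(self, "chains", np.asarray(self.chains, dtype=object))
        if not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be finite")
        if self.elements is None:
            object.__setattr__(self, "elements",
                               np.array([guess_element(n) for n in self.names],
                                        dtype=object))
        if self.box is not None:
            object.__setattr__(self, "box", np.asarray(self.box, dtype=float))

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[0]

    def residues(self) -> list[tuple[tuple, np.ndarray]]:
        """[(key, atom_indices)] with key = (chain, resid, resname), in
        order of first appearance."""
        keys = list(zip(self.chains, self.resids, self.resnames))
        seen: dict[tuple, list[int]] = {}
        for i, k in enumerate(keys):
            seen.setdefault(k, []).append(i)
        return [(k, np.asarray(v)) for k, v in seen.items()]

    def atom_index(self, chain, resid, name) -> int:
        mask = (self.chains == chain) & (self.resids == resid) & (self.names == name)
        idx = np.flatnonzero(mask)
        if idx.size != 1:
            raise KeyError(f"atom {name} of residue {chain}/{resid}: "
                           f"{idx.size} matches")
        return int(idx[0])


@dataclass(frozen=True)
class Trajectory:
    """Shared topology plus stacked frame coordinates (n_frames, n_atoms, 3)."""

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    coords: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        object.__setattr__(self, "coords", coords)
        for attr in ("names", "resnames", "chains"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=object))
        object.__setattr__(self, "resids", np.asarray(self.resids, dtype=int))
        if coords.shape[1] != self.names.size:
            raise ValueError("coordinate array does not match atom count")
        if self.box is not None:
            object.__setattr__(self, "box", np.asarray(self.box, dtype=float))

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Structure:
        return Structure(names=self.names, resnames=self.resnames,
                         resids=self.resids, chains=self.chains,
                         xyz=self.coords[i], box=self.box)

    def __iter__(self):
        return (self.frame(i) for i in range(self.n_frames))

    @classmethod
    def from_structures(cls, frames: Sequence[Structure]) -> "Trajectory":
        first = frames[0]
        for f in frames[1:]:
            if f.n_atoms != first.n_atoms or np.any(f.names != first.names):
                raise ValueError("frames must share an identical atom list")
        return cls(names=first.names, resnames=first.resnames,
                   resids=first.resids, chains=first.chains,
                   coords=np.stack([f.xyz for f in frames]), box=first.box)


@dataclass(frozen=True)
class ResiduePair:
    """A candidate acidic pair with its selection observables."""

    residue_a: tuple
    residue_b: tuple
    cc_distance_t0: float
    sasa_a: float
    sasa_b: float

    def __post_init__(self):
        if self.cc_distance_t0 <= 0:
            raise ValueError("carboxylate-carbon distance must be > 0")

    @property
    def key(self) -> tuple:
        return (self.residue_a, self.residue_b)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def shrake_rupley_sasa(structure: Structure, probe: float = 1.4,
                       n_sphere_points: int = 960,
                       radii: dict[str, float] | None = None) -> pd.Series:
    """Per-residue solvent-accessible surface area (Å²), Shrake–Rupley.

    Each atom is inflated by the probe radius and covered with a
    deterministic quasi-uniform point set; points falling inside any
    neighboring inflated sphere are buried.  Atom areas are summed per
    residue.  Unknown elements raise unless a radius override is supplied.
    """
    radius_table = dict(VDW_RADII)
    if radii:
        radius_table.update({k.upper(): v for k, v in radii.items()})
    try:
        r_atom = np.array([radius_table[el.upper()] for el in structure.elements])
    except KeyError as exc:
        raise KeyError(f"no van der Waals radius for element {exc.args[0]!r}; "
                       "pass a radii override") from None
    r_ext = r_atom + probe
    pts = sphere_points(n_sphere_points)
    xyz = structure.xyz
    tree = cKDTree(xyz)
    max_r = r_ext.max()
    atom_area = np.empty(structure.n_atoms)
    for i in range(structure.n_atoms):
        neighbors = [j for j in tree.query_ball_point(xyz[i], r_ext[i] + max_r)
                     if j != i and np.linalg.norm(xyz[j] - xyz[i]) < r_ext[i] + r_ext[j]]
        surf = xyz[i] + r_ext[i] * pts
        if neighbors:
            d2 = np.sum((surf[:, None, :] - xyz[neighbors][None, :, :]) ** 2, axis=-1)
            buried = np.any(d2 < (r_ext[neighbors] ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        atom_area[i] = 4.0 * np.pi * r_ext[i] ** 2 * frac
    keys, areas = [], []
    for key, idx in structure.residues():
        keys.append(key)
        areas.append(atom_area[idx].sum())
    return pd.Series(areas, index=pd.MultiIndex.from_tuples(
        keys, names=["chain", "resid", "resname"]), name="sasa")


def _carboxylate_carbons(structure: Structure) -> list[tuple[tuple, int]]:
    out = []
    for key, idx in structure.residues():
        chain, resid, resname = key
        if resname not in CARBOXYLATE_CARBON:
            continue
        cname = CARBOXYLATE_CARBON[resname]
        sub = idx[structure.names[idx] == cname]
        if sub.size != 1:
            raise KeyError(f"residue {chain}/{resid} ({resname}) lacks its "
                           f"carboxylate carbon {cname}")
        out.append((key, int(sub[0])))
    return out


def select_acidic_pairs(structure: Structure,
                        sasa_min: float = SASA_MIN_DEFAULT,
                        dmax: float = DMAX_DEFAULT,
                        sasa: pd.Series | None = None,
                        probe: float = 1.4,
                        n_sphere_points: int = 960) -> list[ResiduePair]:
    """Unordered acidic residue pairs passing exposure + proximity filters.

    Both residues must have SASA ≥ ``sasa_min`` and the distance between
    their carboxylate carbons (minimum image if a box is present) must be
    < ``dmax`` in this frame.  Precomputed per-residue SASA can be passed
    to skip the internal Shrake–Rupley call.
    """
    carbons = _carboxylate_carbons(structure)
    if sasa is None:
        sasa = shrake_rupley_sasa(structure, probe=probe,
                                  n_sphere_points=n_sphere_points)
    pairs = []
    for a in range(len(carbons)):
        key_a, ia = carbons[a]
        if sasa.loc[key_a] < sasa_min:
            continue
        for b in range(a + 1, len(carbons)):
            key_b, ib = carbons[b]
            if sasa.loc[key_b] < sasa_min:
                continue
            d = minimum_image(structure.xyz[ib] - structure.xyz[ia], structure.box)
            dist = float(np.linalg.norm(d))
            if dist < dmax:
                pairs.append(ResiduePair(residue_a=key_a, residue_b=key_b,
                                         cc_distance_t0=dist,
                                         sasa_a=float(sasa.loc[key_a]),
                                         sasa_b=float(sasa.loc[key_b])))
    return pairs


@dataclass(frozen=True)
class GeomHistogram:
    """Normalized 1D/2D histogram of structural observables."""

    axes: tuple[str, ...]
    edges: list[np.ndarray]
    p: np.ndarray
    n_samples: int

    def __post_init__(self):
        object.__setattr__(self, "edges",
                           [np.asarray(e, dtype=float) for e in self.edges])
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if np.any(p < 0):
            raise ValueError("probabilities must be >= 0")
        if self.n_samples > 0 and abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("histogram must be normalized to 1")

    @classmethod
    def from_samples(cls, samples: np.ndarray, edges: list[np.ndarray],
                     axes: tuple[str, ...]) -> "GeomHistogram":
        samples = np.atleast_2d(np.asarray(samples, dtype=float))
        if samples.shape[0] and samples.shape[1] != len(edges):
            samples = samples.T
        counts, _ = np.histogramdd(samples, bins=edges)
        n = int(counts.sum())
        p = counts / n if n > 0 else counts
        return cls(axes=tuple(axes), edges=edges, p=np.squeeze(p)
                   if len(edges) == 1 else p, n_samples=n)

    @property
    def centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]

    def mean(self, axis: int = 0) -> float:
        """Probability-weighted mean of the bin centers along one axis."""
        marg = self.p if self.p.ndim == 1 else self.p.sum(axis=1 - axis)
        return float(np.sum(self.centers[axis] * marg))

    def to_frame(self) -> pd.DataFrame:
        if len(self.edges) == 1:
            return pd.DataFrame({self.axes[0]: self.centers[0], "p": self.p})
        c1, c2 = np.meshgrid(*self.centers, indexing="ij")
        return pd.DataFrame({self.axes[0]: c1.ravel(), self.axes[1]: c2.ravel(),
                             "p": self.p.ravel()})


@dataclass(frozen=True)
class DifferenceMap:
    """Signed difference of two normalized histograms (sums to ~0)."""

    axes: tuple[str, ...]
    edges: list[np.ndarray]
    dp: np.ndarray


def _snap_edges(lo: float, hi: float, width: float) -> np.ndarray:
    lo = np.floor(lo / width) * width
    hi = np.ceil(hi / width) * width
    n = max(int(round((hi - lo) / width)), 1)
    return lo + width * np.arange(n + 1)


def pair_distance_histogram(traj: Trajectory, pairs: Sequence[ResiduePair],
                            bin_width: float = DIST_BIN_WIDTH,
                            range: tuple[float, float] | None = None,
                            stride: int = 1) -> dict[tuple, GeomHistogram]:
    """Per-pair histograms of carboxylate-carbon distance over all frames."""
    top = traj.frame(0)
    out = {}
    for pair in pairs:
        chain_a, resid_a, resname_a = pair.residue_a
        chain_b, resid_b, resname_b = pair.residue_b
        ia = top.atom_index(chain_a, resid_a, CARBOXYLATE_CARBON[resname_a])
        ib = top.atom_index(chain_b, resid_b, CARBOXYLATE_CARBON[resname_b])
        d = minimum_image(traj.coords[::stride, ib] - traj.coords[::stride, ia],
                          traj.box)
        dist = np.linalg.norm(d, axis=-1)
        lo, hi = range if range is not None else (dist.min(), dist.max() + 1e-9)
        edges = _snap_edges(lo, hi, bin_width)
        out[pair.key] = GeomHistogram.from_samples(dist[:, None], [edges], ("d",))
    return out


def _water_groups(structure: Structure) -> list[tuple[int, np.ndarray]]:
    """[(oxygen_index, hydrogen_indices)] for every water residue."""
    groups = []
    for key, idx in structure.residues():
        if key[2] not in WATER_RESNAMES:
            continue
        names = structure.names[idx]
        o_idx = idx[np.isin(names, list(WATER_OXYGEN_NAMES))]
        h_idx = idx[np.array([str(n).startswith("H") for n in names])]
        if o_idx.size != 1 or h_idx.size != 2:
            raise ValueError(f"malformed water residue {key}: expected one "
                             f"oxygen and two hydrogens, got {names.tolist()}")
        groups.append((int(o_idx[0]), h_idx))
    return groups


def hbond_geometry_histogram(traj: Trajectory,
                             acceptor_residues: Sequence[tuple] | None = None,
                             d_cutoff: float = HBOND_D_CUTOFF,
                             bins: list[np.ndarray] | None = None,
                             stride: int = 1) -> GeomHistogram:
    """2D (d, cos θ) histogram of water→carboxylate hydrogen bonds.

    For every water hydrogen, the nearest carboxylate oxygen (both oxygens
    of each group are eligible) is found; the event is recorded if the
    *heavy-atom* distance d = |O_water − O_carboxylate| is within
    ``d_cutoff`` and the hydrogen points toward the acceptor (it is closer
    to the acceptor than its own oxygen is).  θ is the angle at the
    hydrogen between the H→O_water and H→O_carboxylate vectors, so linear
    bonds give cos θ = −1.

    ``acceptor_residues`` restricts the carboxylate groups to the given
    (chain, resid) or (chain, resid, resname) keys; default: all acidic
    residues.
    """
    top = traj.frame(0)
    acc_keys = None
    if acceptor_residues is not None:
        acc_keys = {tuple(k[:2]) for k in acceptor_residues}
    oc_idx = []
    for key, idx in top.residues():
        chain, resid, resname = key
        if resname not in CARBOXYLATE_OXYGENS:
            continue
        if acc_keys is not None and (chain, resid) not in acc_keys:
            continue
        for name in CARBOXYLATE_OXYGENS[resname]:
            sub = idx[top.names[idx] == name]
            if sub.size != 1:
                raise KeyError(f"residue {chain}/{resid} ({resname}) lacks "
                               f"carboxylate oxygen {name}")
            oc_idx.append(int(sub[0]))
    if not oc_idx:
        raise ValueError("no carboxylate oxygens selected")
    oc_idx = np.asarray(oc_idx)
    waters = _water_groups(top)
    if not waters:
        raise ValueError("no water residues found")
    ow_of_h = []
    h_idx = []
    for o, hs in waters:
        for h in hs:
            h_idx.append(int(h))
            ow_of_h.append(o)
    h_idx = np.asarray(h_idx)
    ow_of_h = np.asarray(ow_of_h)

    events = []
    for f in range(0, traj.n_frames, stride):
        xyz = traj.coords[f]
        # nearest carboxylate O for each hydrogen
        dh = minimum_image(xyz[oc_idx][None, :, :] - xyz[h_idx][:, None, :], traj.box)
        dist_h = np.linalg.norm(dh, axis=-1)
        nearest = np.argmin(dist_h, axis=1)
        oc_near = oc_idx[nearest]
        d_h = dist_h[np.arange(h_idx.size), nearest]
        d_heavy = np.linalg.norm(
            minimum_image(xyz[oc_near] - xyz[ow_of_h], traj.box), axis=-1)
        # the hydrogen must point toward the acceptor (closer to it than
        # its own oxygen is) — excludes the non-donating hydrogen of a
        # water whose oxygen happens to sit within the heavy-atom cutoff
        within = (d_heavy <= d_cutoff) & (d_h < d_heavy)
        if not within.any():
            continue
        v_ow = minimum_image(xyz[ow_of_h[within]] - xyz[h_idx[within]], traj.box)
        v_oc = minimum_image(xyz[oc_near[within]] - xyz[h_idx[within]], traj.box)
        cos_theta = np.sum(v_ow * v_oc, axis=-1) / (
            np.linalg.norm(v_ow, axis=-1) * np.linalg.norm(v_oc, axis=-1))
        events.append(np.column_stack([d_heavy[within],
                                       np.clip(cos_theta, -1.0, 1.0)]))
    samples = (np.concatenate(events) if events else np.empty((0, 2)))
    if bins is None:
        d_edges = _snap_edges(0.0, d_cutoff, HBOND_BIN_WIDTH)
        cos_edges = _snap_edges(-1.0, 1.0, HBOND_BIN_WIDTH)
        cos_edges[-1] = 1.0 + 1e-12  # include cosθ = 1 in the last bin
        bins = [d_edges, cos_edges]
    return GeomHistogram.from_samples(samples, bins, ("d", "cos_theta"))


def histogram_difference(p_a: GeomHistogram, p_b: GeomHistogram) -> DifferenceMap:
    """Elementwise p_a − p_b; requires identical axes and bin edges."""
    if p_a.axes != p_b.axes:
        raise ValueError("histograms have different axes")
    if len(p_a.edges) != len(p_b.edges) or any(
            a.shape != b.shape or not np.allclose(a, b)
            for a, b in zip(p_a.edges, p_b.edges)):
        raise ValueError("histograms have mismatched bin edges")
    return DifferenceMap(axes=p_a.axes, edges=list(p_a.edges), dp=p_a.p - p_b.p)
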