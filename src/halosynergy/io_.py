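"""File formats, manifests and the two end-to-end pipelines.

Readers accept the plain-text dialects the upstream MD tooling emits:
two-column (time, value) or three-column (time, ξ₁, ξ₂) tables with
``#``/``@`` comment lines, whitespace- or comma-delimited.  Structures
travel as multi-frame PDB (via biotite) or a minimal XYZ dialect.  All
tabular outputs are comma-delimited text at full precision.

Manifests are small YAML documents binding data files to their roles
(λ/leg for alchemical windows, center/force constant for umbrella
windows, the two context summaries for residue pairs).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .structure import Structure, Trajectory, guess_element
from .ti import (LEG_LABELS, LambdaWindow, LegEstimate, MutationFreeEnergy,
                 ThermodynamicIntegration)
from .wham import WHAM, PMFCurve, UmbrellaWindow

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_manifest",
    "write_manifest",
    "windows_from_ti_manifest",
    "windows_from_umbrella_manifest",
    "read_multiframe_structure",
    "write_multiframe_pdb",
    "read_xyz",
    "write_xyz",
    "write_leg_table",
    "write_run_summary",
    "read_run_summary",
    "write_pmf_table",
    "read_pmf_table",
    "RunReport",
    "run_pipeline",
]


# ---------------------------------------------------------------- time series

def read_timeseries(path: str | Path) -> np.ndarray:
    """Parse a delimited numeric table, skipping ``#``/``@`` comment lines.

    Returns an (n_rows, n_cols) float array.  Ragged or non-numeric rows
    raise with the offending line number; an empty payload is an explicit
    error, never an empty array.
    """
    path = Path(path)
    rows: list[list[float]] = []
    n_cols = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped[0] in "#@":
                continue
            fields = stripped.replace(",", " ").split()
            try:
                values = [float(v) for v in fields]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric payload "
                                 f"{stripped!r}") from None
            if n_cols is None:
                n_cols = len(values)
            elif len(values) != n_cols:
                raise ValueError(f"{path}:{lineno}: expected {n_cols} columns, "
                                 f"got {len(values)}")
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no data rows found")
    return np.asarray(rows, dtype=float)


def write_timeseries(path: str | Path, data: np.ndarray, header: str = "") -> None:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    with Path(path).open("w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for row in data:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


# ------------------------------------------------------------------ manifests

def _plain(obj):
    """Coerce numpy scalars/arrays to plain Python for YAML emission."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_manifest(path: str | Path, kind: str, entries: list[dict],
                   **extra) -> None:
    doc = {"schema": 1, "kind": kind, "entries": _plain(entries),
           **_plain(extra)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_manifest(path: str | Path, expected_kind: str | None = None) -> dict:
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or "entries" not in doc:
        raise ValueError(f"{path}: not a manifest (missing 'entries')")
    if expected_kind is not None and doc.get("kind") != expected_kind:
        raise ValueError(f"{path}: manifest kind {doc.get('kind')!r}, "
                         f"expected {expected_kind!r}")
    for entry in doc["entries"]:
        if "file" in entry:
            p = path.parent / entry["file"]
            if not p.exists():
                raise FileNotFoundError(f"{path}: referenced file missing: {p}")
            entry["file"] = str(p)
    return doc


def windows_from_ti_manifest(path: str | Path) -> list[LambdaWindow]:
    """Load λ-windows listed in a TI manifest (file, lambda, leg per entry).

    Duplicate (leg, λ) entries are legitimate independent replicates.
    """
    doc = read_manifest(path, expected_kind="ti")
    windows = []
    for entry in doc["entries"]:
        data = read_timeseries(entry["file"])
        if data.shape[1] < 2:
            raise ValueError(f"{entry['file']}: need (time, dvdl) columns")
        windows.append(LambdaWindow(lambda_value=float(entry["lambda"]),
                                    times=data[:, 0], dvdl=data[:, 1],
                                    leg=str(entry["leg"])))
    return windows


def windows_from_umbrella_manifest(path: str | Path) -> list[UmbrellaWindow]:
    """Load umbrella windows (file, center(s), force_constant(s), T)."""
    doc = read_manifest(path, expected_kind="umbrella")
    windows = []
    for entry in doc["entries"]:
        data = read_timeseries(entry["file"])
        samples = data[:, 1:]  # drop the time column
        centers = np.atleast_1d(entry["center"]).astype(float)
        ks = np.atleast_1d(entry["force_constant"]).astype(float)
        windows.append(UmbrellaWindow(
            centers=tuple(centers), force_constants=tuple(ks),
            samples=samples if samples.shape[1] > 1 else samples[:, 0],
            temperature=float(entry.get("temperature", 298.0))))
    return windows


# ----------------------------------------------------------------- structures

def _structure_to_atom_array(frame_xyz: np.ndarray, traj: Trajectory):
    import biotite.structure as struc
    n = traj.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(frame_xyz, dtype=np.float32)
    arr.atom_name = np.array([str(s) for s in traj.names])
    arr.res_name = np.array([str(s) for s in traj.resnames])
    arr.res_id = np.asarray(traj.resids)
    arr.chain_id = np.array([str(s) for s in traj.chains])
    arr.element = np.array([guess_element(str(s)) for s in traj.names])
    arr.hetero = np.isin(arr.res_name, ["HOH", "WAT", "SOL", "TIP3"])
    if traj.box is not None:
        arr.box = np.diag(traj.box).astype(np.float32)
    return arr


def write_multiframe_pdb(traj: Trajectory | Structure, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (CRYST1 when a box exists)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio
    if isinstance(traj, Structure):
        traj = Trajectory.from_structures([traj])
    arrays = [_structure_to_atom_array(traj.coords[i], traj)
              for i in range(traj.n_frames)]
    stack = struc.stack(arrays)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def _read_pdb(path: Path) -> Trajectory:
    import biotite.structure.io.pdb as pdbio
    pdb_file = pdbio.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)
    box = None
    if stack.box is not None:
        box = np.diagonal(np.asarray(stack.box[0]))
    return Trajectory(names=stack.atom_name.astype(object),
                      resnames=stack.res_name.astype(object),
                      resids=stack.res_id,
                      chains=stack.chain_id.astype(object),
                      coords=np.asarray(stack.coord, dtype=float),
                      box=None if box is None or not np.any(box) else box)


def read_xyz(path: str | Path) -> Trajectory:
    """Minimal multi-frame XYZ reader (n_atoms / comment / name x y z)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    frames, names = [], None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"{path}:{i + 1}: expected atom count") from None
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: truncated frame starting at line {i + 1}")
        frame_names, xyz = [], []
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{i + 3 + j}: expected 'name x y z'")
            frame_names.append(parts[0])
            xyz.append([float(v) for v in parts[1:4]])
        if names is None:
            names = frame_names
        elif frame_names != names:
            raise ValueError(f"{path}: inconsistent atom lists across frames")
        frames.append(np.asarray(xyz))
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    n_atoms = len(names)
    return Trajectory(names=np.array(names, dtype=object),
                      resnames=np.array(["UNK"] * n_atoms, dtype=object),
                      resids=np.arange(1, n_atoms + 1),
                      chains=np.array(["A"] * n_atoms, dtype=object),
                      coords=np.stack(frames))


def write_xyz(traj: Trajectory | Structure, path: str | Path,
              comment: str = "") -> None:
    if isinstance(traj, Structure):
        traj = Trajectory.from_structures([traj])
    with Path(path).open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n{comment or f'frame {f}'}\n")
            for name, (x, y, z) in zip(traj.names, traj.coords[f]):
                fh.write(f"{name} {x:.17g} {y:.17g} {z:.17g}\n")


def read_multiframe_structure(path: str | Path,
                              format: str | None = None) -> Trajectory:
    """Read a multi-frame PDB or XYZ file; format inferred from the suffix."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "pdb":
        return _read_pdb(path)
    if format == "xyz":
        return read_xyz(path)
    raise ValueError(f"unknown structure format {format!r} (expected pdb or xyz)")


# -------------------------------------------------- tabular results round-trip

def write_leg_table(est: LegEstimate, path: str | Path) -> None:
    est.to_frame().to_csv(path, index=False, float_format="%.17g")


def write_run_summary(mfe: MutationFreeEnergy, path: str | Path) -> None:
    """One-row CSV with the leg ΔGs, SEMs, total and metadata."""
    row = {"site": mfe.site, "from_aa": mfe.from_aa, "to_aa": mfe.to_aa,
           "neighbor_state": mfe.neighbor_state}
    for leg in LEG_LABELS:
        row[leg] = mfe.legs[leg].delta_g
        row[f"{leg}_sem"] = mfe.legs[leg].delta_g_sem
    row["total"] = mfe.total
    row["total_sem"] = mfe.total_sem
    pd.DataFrame([row]).to_csv(path, index=False, float_format="%.17g")


def read_run_summary(path: str | Path) -> MutationFreeEnergy:
    row = pd.read_csv(path).iloc[0]
    legs = {}
    for leg in LEG_LABELS:
        legs[leg] = LegEstimate(
            leg=leg, lambdas=np.array([0.0, 1.0]),
            means=np.array([np.nan, np.nan]), sems=np.array([0.0, 0.0]),
            delta_g=float(row[leg]), delta_g_sem=float(row[f"{leg}_sem"]),
            method="loaded")
    return MutationFreeEnergy(site=str(row["site"]), from_aa=str(row["from_aa"]),
                              to_aa=str(row["to_aa"]),
                              neighbor_state=str(row["neighbor_state"]),
                              legs=legs, total=float(row["total"]),
                              total_sem=float(row["total_sem"]))


def write_pmf_table(curve: PMFCurve, path: str | Path,
                    sem: np.ndarray | None = None) -> None:
    df = curve.to_frame()
    if sem is not None:
        df["sem"] = np.asarray(sem).ravel()
    df.to_csv(path, index=False, float_format="%.17g")


def read_pmf_table(path: str | Path, temperature: float = 298.0) -> PMFCurve:
    """Rebuild a 1D PMFCurve from its table (uniform grid assumed)."""
    df = pd.read_csv(path)
    xi = df["xi"].to_numpy()
    if xi.size < 2:
        raise ValueError(f"{path}: PMF table needs >= 2 bins")
    w = np.diff(xi)
    if not np.allclose(w, w[0]):
        raise ValueError(f"{path}: non-uniform grid cannot be rebuilt")
    edges = np.concatenate([xi - w[0] / 2, [xi[-1] + w[0] / 2]])
    counts = df["counts"].to_numpy() if "counts" in df else np.ones_like(xi)
    return PMFCurve(edges=[edges], g=df["g"].to_numpy(), counts=counts,
                    offsets=np.zeros(1), n_iterations=0, converged=True,
                    temperature=temperature)


# ------------------------------------------------------------------ pipelines

@dataclass
class RunReport:
    """Provenance record of one pipeline run."""

    pipeline: str
    parameters: dict
    inputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    outputs: dict[str, str] = field(default_factory=dict)  # stage -> path
    warnings: list[str] = field(default_factory=list)
    failures: list[str] = field(default_factory=list)
    seeds: dict[str, int] = field(default_factory=dict)
    version: str = __version__

    def digest_input(self, path: str | Path) -> None:
        p = Path(path)
        self.inputs[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload


_ALCHEMICAL_KEYS = {"pairs"}
_PMF_KEYS = {"dd", "nn", "dn"}


def _validate_config(config: dict) -> list[str]:
    errors = []
    pipeline = config.get("pipeline")
    if pipeline not in ("alchemical", "pmf"):
        errors.append("config.pipeline must be 'alchemical' or 'pmf'")
        return errors
    required = _ALCHEMICAL_KEYS if pipeline == "alchemical" else _PMF_KEYS
    for key in required:
        if key not in config:
            errors.append(f"config.{key} is required for the {pipeline} pipeline")
    if pipeline == "alchemical":
        for i, pair in enumerate(config.get("pairs", [])):
            for key in ("protein", "site_a", "site_b", "salt_molality",
                        "charged_manifest", "neutral_manifest"):
                if key not in pair:
                    errors.append(f"config.pairs[{i}].{key} is required")
    if "out_dir" not in config:
        errors.append("config.out_dir is required")
    return errors


def run_pipeline(config: dict | str | Path) -> RunReport:
    """Execute a configured pipeline; partial failure keeps what finished.

    ``config`` is a dict or path to a YAML file.  The ``alchemical``
    pipeline turns per-window manifests into a per-pair synergy table; the
    ``pmf`` pipeline turns three umbrella manifests into aligned PMFs and
    a ΔΔG(ξ) table.  Schema violations are reported exhaustively.
    """
    from .synergy import MutationPair, delta_delta_g
    from .pmf import PairPMFSet, ScreenedCoulombParams, align_pair_set, ddg_xi

    config_path = None
    if not isinstance(config, dict):
        config_path = Path(config)
        config = yaml.safe_load(config_path.read_text())
    errors = _validate_config(config)
    if errors:
        raise ValueError("invalid pipeline config:\n  " + "\n  ".join(errors))

    base = config_path.parent if config_path is not None else Path(".")
    out_dir = Path(config["out_dir"])
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(pipeline=config["pipeline"],
                       parameters={k: v for k, v in config.items()
                                   if k not in ("pairs",)})
    if "seed" in config:
        report.seeds["config"] = int(config["seed"])

    if config["pipeline"] == "alchemical":
        _run_alchemical(config, base, out_dir, report)
    else:
        _run_pmf(config, base, out_dir, report)
    report.to_json(out_dir / "run_report.json")
    report.outputs["report"] = str(out_dir / "run_report.json")
    return report


def _resolve(base: Path, p: str | Path) -> Path:
    p = Path(p)
    return p if p.is_absolute() else base / p


def _run_alchemical(config, base, out_dir, report):
    from .synergy import MutationPair, delta_delta_g
    import warnings as _w

    t_eq = float(config.get("t_eq", 1000.0))
    method = config.get("method", "spline")
    threshold = float(config.get("threshold", 0.5))
    rows = []
    for pair_cfg in config["pairs"]:
        name = f"{pair_cfg['protein']}:{pair_cfg['site_a']}~{pair_cfg['site_b']}"
        try:
            mfes = {}
            for state, key in (("charged", "charged_manifest"),
                               ("neutral", "neutral_manifest")):
                manifest = _resolve(base, pair_cfg[key])
                report.digest_input(manifest)
                windows = windows_from_ti_manifest(manifest)
                with _w.catch_warnings(record=True) as caught:
                    _w.simplefilter("always")
                    res = ThermodynamicIntegration(windows, t_eq=t_eq).fit(method)
                    mfes[state] = res.mutation_free_energy(
                        site=str(pair_cfg["site_a"]), neighbor_state=state)
                report.warnings += [f"{name}/{state}: {w.message}" for w in caught]
            mp = MutationPair(site_a=str(pair_cfg["site_a"]),
                              site_b=str(pair_cfg["site_b"]),
                              protein=str(pair_cfg["protein"]),
                              salt_molality=float(pair_cfg["salt_molality"]),
                              g_charged_neighbor=mfes["charged"],
                              g_neutral_neighbor=mfes["neutral"])
            result = delta_delta_g(mp, threshold=threshold)
            row = {"protein": mp.protein, "site_a": mp.site_a,
                   "site_b": mp.site_b, "salt_molality": mp.salt_molality,
                   "ddg": result.ddg, "ddg_sem": result.ddg_sem,
                   "label": result.label}
            row.update({f"ddg_{leg}": v for leg, v in result.components.items()})
            rows.append(row)
            if abs(abs(result.ddg) - threshold) < 1e-12:
                report.warnings.append(f"{name}: ddg exactly at the "
                                       f"classification boundary")
        except Exception as exc:  # partial failure keeps completed pairs
            report.failures.append(f"{name}: {exc}")
    if rows:
        table = out_dir / "synergy_table.csv"
        pd.DataFrame(rows).to_csv(table, index=False, float_format="%.17g")
        report.outputs["synergy_table"] = str(table)


def _run_pmf(config, base, out_dir, report):
    from .pmf import PairPMFSet, ScreenedCoulombParams, align_pair_set, ddg_xi
    import warnings as _w

    bin_width = config.get("bin_width", 0.1)
    tol = float(config.get("tol", 1e-7))
    xi_ref = float(config.get("xi_ref", 15.0))
    salt = float(config.get("salt_molality", 0.0))
    curves = {}
    window_sets = {}
    for label in ("dd", "nn", "dn"):
        manifest = _resolve(base, config[label])
        report.digest_input(manifest)
        window_sets[label] = windows_from_umbrella_manifest(manifest)
    common_range = config.get("range")
    if common_range is None:
        # the three curves must share one bin grid for alignment
        lo = min(w.samples.min() for ws in window_sets.values() for w in ws)
        hi = max(w.samples.max() for ws in window_sets.values() for w in ws)
        common_range = [(float(lo), float(hi))]
    for label in ("dd", "nn", "dn"):
        windows = window_sets[label]
        with _w.catch_warnings(record=True) as caught:
            _w.simplefilter("always")
            curve = WHAM(windows, bin_width=bin_width,
                         range=common_range).fit(tol=tol)
        report.warnings += [f"{label}: {w.message}" for w in caught]
        if not curve.converged:
            report.warnings.append(f"{label}: WHAM did not converge")
        curves[label] = curve
        path = out_dir / f"pmf_{label}.csv"
        write_pmf_table(curve, path)
        report.outputs[f"pmf_{label}"] = str(path)
    try:
        pair_set = PairPMFSet(dd=curves["dd"], nn=curves["nn"],
                              dn=curves["dn"], salt_molality=salt)
        aligned = align_pair_set(pair_set, xi_ref=xi_ref)
        for label, curve in aligned.curves.items():
            path = out_dir / f"pmf_{label}_aligned.csv"
            write_pmf_table(curve, path)
            report.outputs[f"pmf_{label}_aligned"] = str(path)
        table = ddg_xi(aligned)
        path = out_dir / "ddg_xi.csv"
        table.to_csv(path, index=False, float_format="%.17g")
        report.outputs["ddg_xi"] = str(path)
    except Exception as exc:
        report.failures.append(f"alignment/ddg_xi: {exc}")
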