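"""Weighted histogram analysis of umbrella-sampling data.

Umbrella sampling restrains a reaction coordinate ξ (here: the distance
between side-chain Cα atoms, in Å) with harmonic biases at a ladder of
centers; WHAM combines the biased window histograms into the unbiased
potential of mean force g(ξ) = −k_BT ln ρ(ξ) by iterating the standard
self-consistency equations

    ρ_j = Σ_i n_ij / Σ_i N_i exp(f_i − u_ij)
    exp(−f_i) = Σ_j ρ_j exp(−u_ij)

(u_ij = bias of window i at bin j in units of k_BT) to a fixed point.
Accumulation is done in log space to avoid underflow for strongly biased
windows.  1D and 2D coordinates are supported; unvisited bins carry NaN,
never an imputed value.

No autocorrelation correction is applied inside WHAM — samples are assumed
decorrelated; subsample with a stride beforehand if they are not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import T_DEFAULT, kbt

__all__ = [
    "UmbrellaWindow",
    "PMFCurve",
    "bias_energy",
    "WHAM",
    "wham",
    "pmf_uncertainty",
]

#: Default bin widths (Å) for 1D and 2D coordinates.
BIN_WIDTH_1D = 0.1
BIN_WIDTH_2D = 0.2

TOL_DEFAULT = 1e-7  # in units of k_BT
MAX_ITER_DEFAULT = 100_000


@dataclass(frozen=True)
class UmbrellaWindow:
    """One biased window: samples of ξ under a harmonic restraint.

    ``centers`` and ``force_constants`` are scalars for a 1D coordinate or
    length-2 tuples for a 2D (ξ₁, ξ₂) coordinate; force constants are in
    kcal·mol⁻¹·Å⁻².  ``bias_offset`` adds a constant to the bias (it must
    not change the recovered PMF; exposed for exactly that invariance).
    """

    centers: tuple[float, ...]
    force_constants: tuple[float, ...]
    samples: np.ndarray  # (n,) or (n, d)
    temperature: float = T_DEFAULT
    bias_offset: float = 0.0

    def __post_init__(self):
        centers = np.atleast_1d(np.asarray(self.centers, dtype=float))
        ks = np.atleast_1d(np.asarray(self.force_constants, dtype=float))
        object.__setattr__(self, "centers", tuple(centers))
        object.__setattr__(self, "force_constants", tuple(ks))
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim == 1:
            samples = samples[:, None]
        object.__setattr__(self, "samples", samples)
        if samples.size == 0:
            raise ValueError("window has no samples")
        if samples.shape[1] != len(self.centers):
            raise ValueError("sample dimensionality does not match centers")
        if len(ks) != len(self.centers):
            raise ValueError("one force constant per coordinate required")
        if np.any(ks < 0):
            raise ValueError("force constants must be >= 0")

    @property
    def ndim(self) -> int:
        return len(self.centers)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


def bias_energy(window: UmbrellaWindow, x) -> np.ndarray | float:
    """Harmonic bias ½·k·(x−center)² summed over coordinates, kcal/mol."""
    x = np.asarray(x, dtype=float)
    scalar_in = x.ndim == 0 or (x.ndim == 1 and window.ndim > 1)
    pts = np.atleast_2d(x) if x.ndim <= 1 else x
    if window.ndim == 1 and pts.shape[-1] != 1:
        pts = pts.reshape(-1, 1)
    c = np.asarray(window.centers)
    k = np.asarray(window.force_constants)
    u = 0.5 * np.sum(k * (pts - c) ** 2, axis=-1) + window.bias_offset
    return float(u[0]) if scalar_in and u.size == 1 else u


@dataclass
class PMFCurve:
    """A potential of mean force on a bin grid, with WHAM diagnostics.

    ``g`` is in kcal/mol with its minimum at zero; bins never visited by
    any window are NaN.  Only differences of ``g`` are physically
    meaningful — adding a constant changes nothing downstream.
    """

    edges: list[np.ndarray]          # bin edges per axis
    g: np.ndarray                    # (n_bins,) or (n1, n2); NaN where unvisited
    counts: np.ndarray               # pooled histogram counts, same shape
    offsets: np.ndarray              # per-window free energy constants, kcal/mol
    n_iterations: int
    converged: bool
    temperature: float = T_DEFAULT
    warnings_: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]

    @property
    def grid(self) -> np.ndarray:
        """Bin centers: (n,) for 1D, else the list of axis centers."""
        return self.centers[0] if self.ndim == 1 else self.centers

    def bin_index(self, x) -> tuple[int, ...]:
        """Index of the bin containing point ``x`` (error if outside)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        idx = []
        for xi, e in zip(x, self.edges):
            i = int(np.searchsorted(e, xi, side="right")) - 1
            if i < 0 or i >= e.size - 1:
                raise ValueError(f"coordinate {xi} outside the PMF grid")
            idx.append(i)
        return tuple(idx)

    def value_at(self, x) -> float:
        """g in the bin containing ``x`` (no interpolation)."""
        return float(self.g[self.bin_index(x)])

    def shifted(self, delta: float) -> "PMFCurve":
        return replace(self, g=self.g + delta)

    def marginalize(self, axis: int) -> "PMFCurve":
        """Integrate out one coordinate of a 2D PMF (Boltzmann weights)."""
        if self.ndim != 2:
            raise ValueError("marginalize requires a 2D PMF")
        kt = kbt(self.temperature)
        w = np.exp(-np.nan_to_num(self.g, nan=np.inf) / kt)
        p = w.sum(axis=axis)
        g = np.where(p > 0, -kt * np.log(np.where(p > 0, p, 1.0)), np.nan)
        g = g - np.nanmin(g)
        keep = 1 - axis
        return PMFCurve(edges=[self.edges[keep]], g=g,
                        counts=self.counts.sum(axis=axis),
                        offsets=self.offsets, n_iterations=self.n_iterations,
                        converged=self.converged, temperature=self.temperature,
                        warnings_=list(self.warnings_), meta=dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        if self.ndim == 1:
            return pd.DataFrame({"xi": self.centers[0], "g": self.g,
                                 "counts": self.counts})
        c1, c2 = np.meshgrid(*self.centers, indexing="ij")
        return pd.DataFrame({"xi1": c1.ravel(), "xi2": c2.ravel(),
                             "g": self.g.ravel(), "counts": self.counts.ravel()})

    def summary(self) -> str:
        n_def = int(np.isfinite(self.g).sum())
        lines = [
            "WHAM potential of mean force",
            f"  dimensions: {self.ndim}, bins: {self.g.shape}, defined: {n_def}",
            f"  windows: {self.offsets.size}, iterations: {self.n_iterations}, "
            f"converged: {self.converged}",
            f"  temperature: {self.temperature} K",
        ]
        lines += [f"  warning: {w}" for w in self.warnings_]
        return "\n".join(lines)


def _make_edges(samples: np.ndarray, bin_width, bins, range_) -> list[np.ndarray]:
    ndim = samples.shape[1]
    if bins is not None:
        if isinstance(bins, (int, np.integer)):
            bins = [bins] * ndim
        edges = []
        for d, b in enumerate(bins):
            if np.ndim(b) > 0:
                edges.append(np.asarray(b, dtype=float))
            else:
                lo, hi = (range_[d] if range_ is not None
                          else (samples[:, d].min(), samples[:, d].max()))
                edges.append(np.linspace(lo, hi, int(b) + 1))
        return edges
    if bin_width is None:
        bin_width = BIN_WIDTH_1D if ndim == 1 else BIN_WIDTH_2D
    widths = np.broadcast_to(np.atleast_1d(bin_width), (ndim,))
    edges = []
    for d, w in enumerate(widths):
        lo, hi = (range_[d] if range_ is not None
                  else (samples[:, d].min(), samples[:, d].max()))
        lo = np.floor(lo / w) * w
        hi = np.ceil(hi / w) * w + 0.5 * w
        edges.append(np.arange(lo, hi + 0.5 * w, w))
    return edges


class WHAM:
    """WHAM model over a set of umbrella windows.

    Parameters
    ----------
    windows : sequence of UmbrellaWindow
        All windows must share the temperature and coordinate dimension.
    bin_width : float or sequence, optional
        Bin width per axis (default 0.1 Å in 1D, 0.2 Å in 2D).
    bins : int or sequence of edges, optional
        Explicit bin count or edges (overrides ``bin_width``).
    range : sequence of (lo, hi), optional
        Histogram range per axis; defaults to the sampled range.

    ``fit()`` returns a :class:`PMFCurve`.
    """

    def __init__(self, windows: Sequence[UmbrellaWindow], bin_width=None,
                 bins=None, range=None):
        if len(windows) < 1:
            raise ValueError("need at least one window")
        ndim = windows[0].ndim
        temp = windows[0].temperature
        for w in windows:
            if w.ndim != ndim:
                raise ValueError("windows mix coordinate dimensions")
            if not np.isclose(w.temperature, temp):
                raise ValueError("all windows must share the temperature")
        self.windows = list(windows)
        self.ndim = ndim
        self.temperature = temp
        all_samples = np.concatenate([w.samples for w in windows], axis=0)
        self.edges = _make_edges(all_samples, bin_width, bins, range)

    def fit(self, tol: float = TOL_DEFAULT, max_iter: int = MAX_ITER_DEFAULT
            ) -> PMFCurve:
        kt = kbt(self.temperature)
        shape = tuple(e.size - 1 for e in self.edges)
        n_win = len(self.windows)

        counts = np.empty((n_win,) + shape)
        for i, w in enumerate(self.windows):
            h, _ = np.histogramdd(w.samples, bins=self.edges)
            counts[i] = h
        counts_flat = counts.reshape(n_win, -1)
        m_j = counts_flat.sum(axis=0)
        visited = m_j > 0
        n_i = counts_flat.sum(axis=1)

        warn_msgs = self._overlap_warnings(counts_flat)
        for msg in warn_msgs:
            warnings.warn(msg, stacklevel=2)

        centers = self.centers_mesh().reshape(-1, self.ndim)[visited]
        u = np.stack([bias_energy(w, centers) for w in self.windows]) / kt

        log_m = np.log(m_j[visited])
        log_n = np.log(n_i)[:, None]
        f = np.zeros(n_win)
        n_iter = 0
        converged = False
        for n_iter in range(1, max_iter + 1):
            # log rho_j (unnormalized)
            log_rho = log_m - logsumexp(log_n + f[:, None] - u, axis=0)
            f_new = -logsumexp(log_rho[None, :] - u, axis=1)
            f_new -= f_new[0]
            delta = np.max(np.abs(f_new - f))
            f = f_new
            if delta < tol:
                converged = True
                break

        log_rho = log_m - logsumexp(log_n + f[:, None] - u, axis=0)
        g_flat = np.full(m_j.shape, np.nan)
        g_flat[visited] = -kt * log_rho
        g_flat -= np.nanmin(g_flat)
        offsets = kt * f
        if warn_msgs:
            converged = False
        return PMFCurve(edges=list(self.edges), g=g_flat.reshape(shape),
                        counts=counts_flat.sum(axis=0).reshape(shape),
                        offsets=offsets, n_iterations=n_iter,
                        converged=converged, temperature=self.temperature,
                        warnings_=warn_msgs)

    def centers_mesh(self) -> np.ndarray:
        cs = [0.5 * (e[1:] + e[:-1]) for e in self.edges]
        mesh = np.meshgrid(*cs, indexing="ij")
        return np.stack(mesh, axis=-1)

    def _overlap_warnings(self, counts_flat: np.ndarray) -> list[str]:
        """Flag adjacent windows whose occupied bins share nothing."""
        msgs = []
        occupied = counts_flat > 0
        if self.ndim == 1:
            order = np.argsort([w.centers[0] for w in self.windows])
            for a, b in zip(order[:-1], order[1:]):
                if not np.any(occupied[a] & occupied[b]):
                    ca = self.windows[a].centers[0]
                    cb = self.windows[b].centers[0]
                    msgs.append(f"no histogram overlap between windows centered "
                                f"at {ca:g} and {cb:g} Å")
        else:
            for i in range(len(self.windows)):
                others = [j for j in range(len(self.windows)) if j != i]
                if others and not any(np.any(occupied[i] & occupied[j]) for j in others):
                    msgs.append(f"window {i} (centers {self.windows[i].centers}) "
                                f"shares no occupied bin with any other window")
        return msgs


def wham(windows: Sequence[UmbrellaWindow], bin_width=None, bins=None,
         range=None, tol: float = TOL_DEFAULT,
         max_iter: int = MAX_ITER_DEFAULT) -> PMFCurve:
    """Functional wrapper: ``WHAM(windows, ...).fit(tol, max_iter)``."""
    return WHAM(windows, bin_width=bin_width, bins=bins, range=range).fit(
        tol=tol, max_iter=max_iter)


def pmf_uncertainty(windows: Sequence[UmbrellaWindow], n_boot: int = 20,
                    seed: int | None = None, bin_width=None, bins=None,
                    range=None, tol: float = TOL_DEFAULT,
                    max_iter: int = MAX_ITER_DEFAULT
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap-over-windows per-bin SEM of the PMF.

    Windows are resampled with replacement ``n_boot`` times; each resample
    is solved on the *same* bin grid as the full set and aligned at the
    best-sampled bin before the per-bin standard deviation is taken.
    Returns ``(centers, sem)`` where bins not defined in every resample are
    NaN.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    model = WHAM(windows, bin_width=bin_width, bins=bins, range=range)
    full = model.fit(tol=tol, max_iter=max_iter)
    ref = np.unravel_index(np.argmax(full.counts), full.counts.shape)
    boots = np.full((n_boot,) + full.g.shape, np.nan)
    edges_as_bins = [e for e in model.edges]
    for b in np.arange(n_boot):  # note: `range` is shadowed by the kwarg
        idx = rng.integers(0, len(windows), size=len(windows))
        sub = [windows[i] for i in idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = WHAM(sub, bins=edges_as_bins).fit(tol=tol, max_iter=max_iter)
        boots[b] = curve.g - curve.g[ref]
    sem = np.std(boots, axis=0, ddof=1)
    sem[np.any(~np.isfinite(boots), axis=0)] = np.nan
    centers = full.centers[0] if full.ndim == 1 else full.centers
    return centers, sem
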