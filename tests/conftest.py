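"""Shared fixtures: tiny potentials and reusable synthetic inputs."""

import numpy as np
import pytest

from halosynergy.synth import default_mimic_triple, gen_umbrella


class HarmonicPotential:
    """U(ξ) = ½·k·(ξ−ξ₀)², the analytically solvable WHAM test system."""

    label = "HARM"

    def __init__(self, k=1.0, x0=4.0):
        self.k = k
        self.x0 = x0

    def energy(self, x):
        return 0.5 * self.k * (np.asarray(x, dtype=float) - self.x0) ** 2


class FlatPotential:
    """U ≡ 0: windows sample their bias distribution exactly."""

    label = "FLAT"

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return np.zeros_like(x) if x.ndim else 0.0


@pytest.fixture(scope="session")
def harmonic_windows():
    """Five-window Metropolis sample of the harmonic oracle system."""
    windows, truth = gen_umbrella(HarmonicPotential(k=1.0, x0=4.0),
                                  centers=np.arange(2.0, 6.01, 1.0),
                                  force_constant=10.0, n_steps=50_000,
                                  step_size=0.3, seed=7)
    return windows, truth


@pytest.fixture(scope="session")
def mimic_curves():
    """End-to-end WHAM curves for the DD/NN/DN mimic triple at 2 mol/kg."""
    from halosynergy.wham import WHAM

    triple = default_mimic_triple(2.0)
    window_sets = {}
    for i, (label, pot) in enumerate(triple.items()):
        windows, _ = gen_umbrella(pot, n_steps=50_000, seed=11 + i)
        window_sets[label] = windows
    lo = min(w.samples.min() for ws in window_sets.values() for w in ws)
    hi = max(w.samples.max() for ws in window_sets.values() for w in ws)
    curves = {label: WHAM(ws, bin_width=0.1, range=[(lo, hi)]).fit()
              for label, ws in window_sets.items()}
    return triple, curves
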