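"""The ΔΔG synergy statistic for pairs of acidic residues.

For a solvent-exposed acidic residue at site *a* next to an acidic
neighbor at site *b*, the statistic compares the free energy of the
charge-neutralizing mutation X→Y (D→N or E→Q) in two contexts:

    ΔΔG = ΔG(0)_XaY − ΔG(−)_XaY

where (−) means the neighbor carries its native negative charge and (0)
means it was replaced by its neutral analog beforehand.  ΔΔG < 0 signals a
synergistic (mutually stabilizing) interaction — it is *harder* to
neutralize the acid when its acidic neighbor is present; ΔΔG > 0 signals
ordinary electrostatic interference.  A significance threshold of
0.5 kcal/mol absorbs the statistical uncertainty of the underlying
alchemical estimates.  The statistic decomposes leg-wise into decharge,
vdW and charge contributions that sum exactly to ΔΔG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ti import LEG_LABELS, MutationFreeEnergy

__all__ = [
    "MutationPair",
    "SynergyResult",
    "DEFAULT_THRESHOLD",
    "propagate_error",
    "classify",
    "delta_delta_g",
    "summarize_dataset",
    "classify_table",
]

DEFAULT_THRESHOLD = 0.5  # kcal/mol

LABELS = ("synergistic", "negligible", "interfering")


@dataclass(frozen=True)
class MutationPair:
    """The two neighbor-context mutation free energies for one residue pair."""

    site_a: str
    site_b: str
    protein: str
    salt_molality: float
    g_charged_neighbor: MutationFreeEnergy
    g_neutral_neighbor: MutationFreeEnergy

    def __post_init__(self):
        gc, gn = self.g_charged_neighbor, self.g_neutral_neighbor
        if (gc.site, gc.from_aa, gc.to_aa) != (gn.site, gn.from_aa, gn.to_aa):
            raise ValueError(
                "the two records must describe the same mutation at the same site; "
                f"got {(gc.site, gc.from_aa, gc.to_aa)} vs {(gn.site, gn.from_aa, gn.to_aa)}")
        if gc.neighbor_state == gn.neighbor_state:
            raise ValueError("neighbor states must differ between the two records")


@dataclass(frozen=True)
class SynergyResult:
    """ΔΔG, its leg-wise components, propagated error and class label."""

    ddg: float
    components: dict[str, float]
    ddg_sem: float
    label: str
    threshold: float
    pair: MutationPair | None = None

    def __post_init__(self):
        if abs(sum(self.components.values()) - self.ddg) > 1e-9:
            raise ValueError("components do not sum to ddg")


def propagate_error(sems: Iterable[float]) -> float:
    """Quadrature error propagation: sqrt of the sum of squares."""
    total = 0.0
    for s in sems:
        if s < 0:
            raise ValueError("SEMs must be >= 0")
        total += s * s
    return math.sqrt(total)


def classify(ddg: float, threshold: float = DEFAULT_THRESHOLD,
             sem: float | None = None, significance_aware: bool = False) -> str:
    """Classify a ΔΔG value as synergistic / negligible / interfering.

    The boundary |ΔΔG| = threshold belongs to the significant class.  With
    ``significance_aware=True`` a value is significant only if |ΔΔG| also
    exceeds 1×``sem`` (opt-in variant; the plain threshold rule is the
    default).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if not math.isfinite(ddg):
        raise ValueError("ddg must be finite")
    significant = abs(ddg) >= threshold
    if significance_aware:
        if sem is None:
            raise ValueError("significance_aware classification needs sem")
        significant = significant and abs(ddg) > sem
    if not significant:
        return "negligible"
    return "synergistic" if ddg < 0 else "interfering"


def delta_delta_g(pair: MutationPair, threshold: float = DEFAULT_THRESHOLD,
                  significance_aware: bool = False) -> SynergyResult:
    """Compute the synergy statistic for one residue pair.

    ΔΔG = total(neutral neighbor) − total(charged neighbor); components are
    the same difference taken leg-wise, so they sum exactly to ΔΔG; the SEM
    is the quadrature of the two totals' SEMs (the two alchemical campaigns
    are independent simulations).
    """
    gn = pair.g_neutral_neighbor
    gc = pair.g_charged_neighbor
    ddg = gn.total - gc.total
    components = {leg: gn.legs[leg].delta_g - gc.legs[leg].delta_g
                  for leg in LEG_LABELS}
    sem = propagate_error([gn.total_sem, gc.total_sem])
    label = classify(ddg, threshold, sem=sem, significance_aware=significance_aware)
    return SynergyResult(ddg=ddg, components=components, ddg_sem=sem,
                         label=label, threshold=threshold, pair=pair)


def summarize_dataset(results: Sequence[SynergyResult]) -> pd.DataFrame:
    """Count labels per (protein, salt molality) condition.

    Results whose pair metadata is missing fall into a single unlabeled
    group.  Every group reports all three labels, zero-filled, and the
    counts sum to the number of results.
    """
    if len(results) == 0:
        raise ValueError("results must be nonempty")
    rows = []
    for r in results:
        protein = r.pair.protein if r.pair is not None else ""
        salt = r.pair.salt_molality if r.pair is not None else float("nan")
        rows.append({"protein": protein, "salt_molality": salt, "label": r.label})
    df = pd.DataFrame(rows)
    counts = (df.groupby(["protein", "salt_molality"], dropna=False)["label"]
                .value_counts().unstack(fill_value=0))
    for lab in LABELS:
        if lab not in counts.columns:
            counts[lab] = 0
    counts = counts[list(LABELS)]
    counts["n_pairs"] = counts.sum(axis=1)
    return counts.reset_index()


def classify_table(df: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD,
                   ddg_column: str = "ddg") -> pd.DataFrame:
    """Apply the threshold rule to a plain table of ΔΔG values.

    Convenience for compiled datasets (one row per pair, columns at least
    ``ddg``); returns a copy with a ``label`` column appended.
    """
    out = df.copy()
    out["label"] = [classify(v, threshold) for v in out[ddg_column]]
    return out
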