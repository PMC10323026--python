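"""Bundled example datasets.

The package ships one small table: a *synthetic* reconstruction of the
per-pair ΔΔG compilation for the three halophilic proteins studied with
the alchemical synergy statistic.  The individual values are constructed,
not simulated; they satisfy every published summary constraint (the
per-condition synergistic / fully-shielded / interfering counts and the
value ranges) and exist so the classification and summary machinery can be
exercised end to end without microsecond MD.  See the file header of
``data/ddg_compilation_synthetic.csv`` for the exact constraints encoded.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["ddg_compilation"]


def ddg_compilation() -> pd.DataFrame:
    """Load the synthetic per-pair ΔΔG compilation.

    Returns a DataFrame with columns ``protein``, ``pdb_id``, ``state``
    (folded/unfolded), ``salt_molality`` (mol/kg), ``pair`` (condensed
    mutation notation) and ``ddg`` (kcal/mol).
    """
    ref = resources.files("halosynergy").joinpath("data/ddg_compilation_synthetic.csv")
    with ref.open() as fh:
        return pd.read_csv(fh, comment="#")
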