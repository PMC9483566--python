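"""Published delta-Ea reference tables for murine adenosine deaminase.

Two tables of peptide-level apparent-activation-energy differences
(kcal/mol, with propagated uncertainties in parentheses in the original
report) ship with the package as CSV data:

* **WT ligand comparison** — 11 peptides, three pairwise columns over a
  shared apo baseline: ES-apo (substrate-analog binding), ETS-apo
  (inhibitor binding) and ETS-ES.
* **F61A vs WT comparison** — 12 peptides, apo and inhibitor-bound
  states, with the peptides reported as indeterminate flagged.

The control-elimination set lists the peptides whose mutant response
also appeared in the F61I control variant (which slows turnover
without shifting the catalytic activation energy) and that were
therefore removed from the refined thermal network.

These tables are inputs for consistency and classification checks;
they are never used to parameterize the pipeline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .compare import DeltaEaRecord

#: Peptides removed from the refined thermal network by the F61I control.
ADA_CONTROL_ELIMINATED = frozenset({"167-179", "201-229", "301-320"})


def _load(name: str) -> pd.DataFrame:
    with resources.files("tdhdx.data").joinpath(name).open("rb") as fh:
        df = pd.read_csv(fh, dtype={"peptide_id": str, "pair": str})
    df["indeterminate"] = df["indeterminate"].astype(bool)
    return df


def load_wt_ligand_table() -> pd.DataFrame:
    """WT mADA delta-Ea table: pairs ES-apo, ETS-apo, ETS-ES (11 peptides)."""
    return _load("ada_wt_ligand_delta_ea.csv")


def load_f61a_table() -> pd.DataFrame:
    """F61A-vs-WT delta-Ea table: apo and inhibitor-bound pairs (12 peptides)."""
    return _load("ada_f61a_delta_ea.csv")


def records_for_pair(table: pd.DataFrame, pair: str) -> list[DeltaEaRecord]:
    """Materialize one pair label of a reference table as DeltaEaRecords."""
    sub = table[table["pair"] == pair]
    if sub.empty:
        raise ValueError(f"pair {pair!r} not present in table")
    return [
        DeltaEaRecord(
            peptide_id=row.peptide_id,
            pair=pair,
            delta=float(row.delta),
            sigma=float(row.sigma),
            indeterminate=bool(row.indeterminate),
        )
        for row in sub.itertuples()
    ]
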