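"""State comparisons: uptake differences, delta-Ea, network classification.

Two complementary comparisons of protein states are supported. At a
single temperature, per-time-point uptake differences identify
protection or deprotection (a binding-footprint readout that mixes
enthalpic and entropic contributions). Across temperatures, the
difference in apparent activation energy

    delta_Ea = Ea(state B) - Ea(state A),
    sigma    = sqrt(se_A^2 + se_B^2)

isolates the enthalpic barrier change and defines the thermal network.
A peptide's delta-Ea is *significant* when |delta| > sigma,
*indeterminate* when either input fit is indeterminate, and
*control-eliminated* when it belongs to an explicit elimination set —
peptides whose response also appears in a control mutant that perturbs
turnover without changing the activation energy, and which therefore
cannot be attributed to the thermal network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arrhenius import ArrheniusFit
from .io import UptakeCurve

CLASSIFICATIONS = ("significant", "not_significant", "indeterminate", "control_eliminated")

#: Start of the uptake plateau used for single-temperature comparison, seconds.
PLATEAU_START_S = 600.0


@dataclass
class DeltaEaRecord:
    """Difference in apparent activation energy between two states."""

    peptide_id: str
    pair: str                     # e.g. "ETS-ES" meaning Ea(ETS) - Ea(ES)
    delta: float                  # kcal/mol
    sigma: float                  # kcal/mol, quadrature-propagated
    indeterminate: bool = False
    classification: str | None = None


@dataclass
class UptakeDifferenceRecord:
    """Per-time-point uptake difference between two states at one temperature."""

    peptide_id: str
    pair: str
    times_s: np.ndarray
    differences: np.ndarray       # mean over replicates, state B minus state A
    plateau_sum: float
    direction: str                # protected | deprotected | unchanged


def single_temperature_difference(
    curves_a: list[UptakeCurve],
    curves_b: list[UptakeCurve],
    threshold: float = 1.0,
    pair: str = "B-A",
    plateau_start_s: float = PLATEAU_START_S,
) -> UptakeDifferenceRecord:
    """Compare two states of one peptide at one temperature.

    Replicate curves are averaged per state, and the per-time-point
    difference (B minus A) is summed over the plateau region
    (t >= ``plateau_start_s``): below ``-threshold`` the peptide is
    *protected* in state B, above ``+threshold`` *deprotected*, else
    *unchanged*. All curves must share peptide, temperature and time
    grid.
    """
    if not curves_a or not curves_b:
        raise ValueError("need at least one curve per state")
    ref = curves_a[0]
    for c in curves_a + curves_b:
        if c.peptide_id != ref.peptide_id or c.temperature_c != ref.temperature_c:
            raise ValueError("curves must share peptide and temperature")
        if not np.array_equal(c.times_s, ref.times_s):
            raise ValueError(f"{c.peptide_id}: mismatched time grids between states")
    mean_a = np.mean([c.deuterons for c in curves_a], axis=0)
    mean_b = np.mean([c.deuterons for c in curves_b], axis=0)
    diff = mean_b - mean_a
    plateau = ref.times_s >= plateau_start_s
    total = float(np.sum(diff[plateau]))
    if total < -threshold:
        direction = "protected"
    elif total > threshold:
        direction = "deprotected"
    else:
        direction = "unchanged"
    return UptakeDifferenceRecord(
        peptide_id=ref.peptide_id, pair=pair, times_s=ref.times_s.copy(),
        differences=diff, plateau_sum=total, direction=direction,
    )


def delta_ea(fit_a: ArrheniusFit, fit_b: ArrheniusFit, pair: str | None = None) -> DeltaEaRecord:
    """Difference Ea(b) - Ea(a) with quadrature-propagated uncertainty.

    Indeterminacy in either input propagates to the record (delta and
    sigma are still reported when both Ea values exist).
    """
    if fit_a.peptide_id != fit_b.peptide_id:
        raise ValueError(f"peptide mismatch: {fit_a.peptide_id} vs {fit_b.peptide_id}")
    if pair is None:
        pair = f"{fit_b.state}-{fit_a.state}"
    return DeltaEaRecord(
        peptide_id=fit_a.peptide_id,
        pair=pair,
        delta=fit_b.ea - fit_a.ea,
        sigma=float(np.hypot(fit_a.se_ea, fit_b.se_ea)),
        indeterminate=bool(fit_a.indeterminate or fit_b.indeterminate),
    )


def classify(record: DeltaEaRecord, eliminated: set[str] | frozenset[str] = frozenset()) -> str:
    """Classify one delta-Ea record.

    Precedence: control elimination, then indeterminacy, then the
    |delta| > sigma significance rule. The classification is stored on
    the record and returned.
    """
    if record.peptide_id in eliminated:
        cls = "control_eliminated"
    elif record.indeterminate or not np.isfinite(record.delta):
        cls = "indeterminate"
    elif abs(record.delta) > record.sigma:
        cls = "significant"
    else:
        cls = "not_significant"
    record.classification = cls
    return cls


def count_significant(
    records: list[DeltaEaRecord], eliminated: set[str] | frozenset[str] = frozenset()
) -> int:
    """Number of records classified significant for one pair label."""
    return sum(1 for r in records if classify(r, eliminated) == "significant")


def check_pair_consistency(table: pd.DataFrame, pair_ba: str, pair_ca: str, pair_cb: str) -> pd.Series:
    """Residual of the three-pair closure over a shared baseline.

    For states a, b, c with pairwise differences (b-a), (c-a), (c-b),
    each peptide's residual is ``delta(c-b) - [delta(c-a) - delta(b-a)]``
    — identically zero whenever all three derive from one Ea per state.

    ``table`` needs columns peptide_id, pair, delta; returns the
    residual indexed by peptide_id, requiring all three pairs per
    peptide.
    """
    wide = table.pivot(index="peptide_id", columns="pair", values="delta")
    for p in (pair_ba, pair_ca, pair_cb):
        if p not in wide.columns or wide[p].isna().any():
            missing = [] if p not in wide.columns else wide.index[wide[p].isna()].tolist()
            raise ValueError(f"pair {p!r} missing{' for ' + str(missing) if missing else ''}")
    return wide[pair_cb] - (wide[pair_ca] - wide[pair_ba])


def delta_table(records: list[DeltaEaRecord]) -> pd.DataFrame:
    """Flatten records into the delta-Ea CSV layout."""
    return pd.DataFrame(
        [
            {
                "peptide_id": r.peptide_id,
                "pair": r.pair,
                "delta_Ea": r.delta,
                "sigma": r.sigma,
                "indeterminate": r.indeterminate,
                "classification": r.classification,
            }
            for r in records
        ],
        columns=["peptide_id", "pair", "delta_Ea", "sigma", "indeterminate", "classification"],
    )
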