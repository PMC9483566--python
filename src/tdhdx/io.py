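"""Tabular I/O for temperature-dependent HDX-MS data.

This module defines the two on-disk formats the pipeline consumes and
produces, plus the small pieces of domain arithmetic that belong with
them: counting exchangeable backbone amides and correcting deuteron
counts for back-exchange.

Formats
-------
Peptide map (CSV)
    ``peptide_id,start_res,end_res,sequence,f_BE[,N_T]`` — one row per
    pepsin peptide. ``N_T`` (exchangeable amides) is computed from the
    sequence unless the optional column overrides it.

Uptake table (CSV)
    ``peptide_id,state,temperature_C,replicate,time_s,deuterons[,raw]``
    — one row per observation. Rows flagged ``raw=1`` carry uncorrected
    deuteron counts and are divided by ``1 - f_BE`` on read.

Conventions
-----------
Residue numbers are 1-based inclusive. Times are stored in seconds;
rate fitting happens in minutes elsewhere. Deuteron counts are floats
(centroid mass shifts, not integers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Standard one-letter amino-acid codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Amide-counting conventions, see :func:`count_exchangeable_amides`.
AMIDE_CONVENTIONS = ("exclude_nterm", "literal")

#: Default slack (deuterons) for clipping corrected uptake above N_T.
DEFAULT_CLIP_TOLERANCE = 0.1


def count_exchangeable_amides(sequence: str, convention: str = "exclude_nterm") -> int:
    """Count exchangeable backbone amide hydrogens in a peptide.

    Proline has no backbone amide hydrogen and is never counted.

    Parameters
    ----------
    sequence
        Peptide sequence in one-letter code.
    convention
        ``"exclude_nterm"`` (default): the N-terminal residue's amide is
        also excluded, as its hydrogen back-exchanges too fast to retain
        label — the count is ``(len - 1) - #prolines at positions 2..end``.
        ``"literal"``: every non-proline residue counts, i.e.
        ``len - #prolines``.

    Returns
    -------
    int
        Number of exchangeable amides (N_T), possibly zero.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValueError(f"unknown residue letters {sorted(bad)!r} in {sequence!r}")
    if convention == "exclude_nterm":
        return (len(sequence) - 1) - sequence[1:].count("P")
    if convention == "literal":
        return len(sequence) - sequence.count("P")
    raise ValueError(f"unknown amide convention {convention!r}; choose from {AMIDE_CONVENTIONS}")


def correct_uptake(raw_deuterons, f_be: float):
    """Correct an observed deuteron count for back-exchange.

    During quench, digestion and chromatography a peptide loses a fixed
    fraction ``f_BE`` of its incorporated deuterium back to protiated
    solvent; the standard fractional-recovery model inverts that loss
    multiplicatively::

        D_corrected = D_raw / (1 - f_BE)

    Accepts scalars or arrays; raw counts must be nonnegative and
    ``0 <= f_BE < 1``.
    """
    raw = np.asarray(raw_deuterons, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw deuteron count must be nonnegative")
    if not 0.0 <= f_be < 1.0:
        raise ValueError(f"back-exchange fraction must be in [0, 1), got {f_be}")
    out = raw / (1.0 - f_be)
    return float(out) if np.isscalar(raw_deuterons) else out


@dataclass(frozen=True)
class PeptideRecord:
    """One pepsin peptide of the intact protein.

    Attributes
    ----------
    peptide_id : str
        Label, conventionally ``"<start>-<end>"`` (e.g. ``"46-62"``).
    start_res, end_res : int
        1-based inclusive residue numbers in the intact protein.
    sequence : str
        One-letter amino-acid sequence, length ``end_res - start_res + 1``.
    n_t : int
        Number of exchangeable backbone amides.
    f_be : float
        Back-exchange fraction in [0, 1).
    """

    peptide_id: str
    start_res: int
    end_res: int
    sequence: str
    n_t: int
    f_be: float

    def __post_init__(self) -> None:
        if self.start_res < 1 or self.end_res < self.start_res:
            raise ValueError(f"{self.peptide_id}: bad residue span {self.start_res}-{self.end_res}")
        if len(self.sequence) != self.end_res - self.start_res + 1:
            raise ValueError(
                f"{self.peptide_id}: sequence length {len(self.sequence)} does not match span "
                f"{self.start_res}-{self.end_res}"
            )
        if not 1 <= self.n_t <= len(self.sequence):
            raise ValueError(f"{self.peptide_id}: N_T={self.n_t} outside [1, {len(self.sequence)}]")
        if not 0.0 <= self.f_be < 1.0:
            raise ValueError(f"{self.peptide_id}: f_BE={self.f_be} outside [0, 1)")

    @classmethod
    def from_sequence(
        cls,
        peptide_id: str,
        start_res: int,
        end_res: int,
        sequence: str,
        f_be: float,
        convention: str = "exclude_nterm",
    ) -> "PeptideRecord":
        """Build a record with N_T computed from the sequence."""
        n_t = count_exchangeable_amides(sequence, convention)
        return cls(peptide_id, start_res, end_res, sequence, n_t, f_be)


@dataclass
class UptakeCurve:
    """Deuteron uptake versus time for one (peptide, state, T, replicate).

    ``deuterons`` are back-exchange-corrected counts unless ``raw`` is
    True. Times are seconds, strictly increasing from 0.
    """

    peptide_id: str
    state: str
    temperature_c: float
    replicate: int
    times_s: np.ndarray
    deuterons: np.ndarray
    raw: bool = False

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.deuterons = np.asarray(self.deuterons, dtype=float)
        if self.times_s.shape != self.deuterons.shape:
            raise ValueError("times and deuterons must have equal length")
        if self.times_s.size == 0 or self.times_s[0] != 0.0:
            raise ValueError(f"{self.peptide_id}: time grid must start at 0 s")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError(f"{self.peptide_id}: times must be strictly increasing")

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + 273.15

    def key(self) -> tuple:
        return (self.peptide_id, self.state, self.temperature_c, self.replicate)

    def __eq__(self, other) -> bool:  # value equality for round-trip tests
        if not isinstance(other, UptakeCurve):
            return NotImplemented
        return (
            self.key() == other.key()
            and self.raw == other.raw
            and np.array_equal(self.times_s, other.times_s)
            and np.array_equal(self.deuterons, other.deuterons)
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

PEPTIDE_MAP_COLUMNS = ["peptide_id", "start_res", "end_res", "sequence", "f_BE"]
UPTAKE_COLUMNS = ["peptide_id", "state", "temperature_C", "replicate", "time_s", "deuterons"]


def read_peptide_map(path, convention: str = "exclude_nterm") -> list[PeptideRecord]:
    """Read a peptide map CSV into validated :class:`PeptideRecord` objects.

    An optional ``N_T`` column overrides the sequence-derived count.
    Peptide ids must be unique.
    """
    df = pd.read_csv(path, dtype={"peptide_id": str, "sequence": str}, float_precision="round_trip")
    missing = [c for c in PEPTIDE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peptide map {path}: missing columns {missing}")
    if df["peptide_id"].duplicated().any():
        dups = df.loc[df["peptide_id"].duplicated(), "peptide_id"].tolist()
        raise ValueError(f"peptide map {path}: duplicate peptide_ids {dups}")
    records = []
    for _, row in df.iterrows():
        if "N_T" in df.columns and pd.notna(row.get("N_T")):
            rec = PeptideRecord(
                row["peptide_id"], int(row["start_res"]), int(row["end_res"]),
                row["sequence"], int(row["N_T"]), float(row["f_BE"]),
            )
        else:
            rec = PeptideRecord.from_sequence(
                row["peptide_id"], int(row["start_res"]), int(row["end_res"]),
                row["sequence"], float(row["f_BE"]), convention,
            )
        records.append(rec)
    if not records:
        logger.warning("peptide map %s is empty", path)
    return records


def write_peptide_map(path, peptides: list[PeptideRecord]) -> None:
    pd.DataFrame(
        [
            {
                "peptide_id": p.peptide_id,
                "start_res": p.start_res,
                "end_res": p.end_res,
                "sequence": p.sequence,
                "f_BE": p.f_be,
                "N_T": p.n_t,
            }
            for p in peptides
        ],
        columns=PEPTIDE_MAP_COLUMNS + ["N_T"],
    ).to_csv(path, index=False)


def read_uptake_table(
    path,
    peptide_map: list[PeptideRecord],
    clip_tolerance: float = DEFAULT_CLIP_TOLERANCE,
) -> list[UptakeCurve]:
    """Read an uptake table CSV into :class:`UptakeCurve` objects.

    Rows flagged ``raw=1`` are back-exchange corrected using the
    peptide's ``f_BE``. Corrected values in ``(N_T, N_T + clip_tolerance]``
    are clipped to ``N_T`` with a log entry; larger excesses are an
    error reported with row numbers, as are duplicate
    (peptide, state, T, replicate, time) rows and unknown peptide ids.
    """
    df = pd.read_csv(path, dtype={"peptide_id": str, "state": str}, float_precision="round_trip")
    missing = [c for c in UPTAKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"uptake table {path}: missing columns {missing}")
    if df.empty:
        logger.warning("uptake table %s has an empty data section", path)
        return []
    by_id = {p.peptide_id: p for p in peptide_map}
    unknown = sorted(set(df["peptide_id"]) - set(by_id))
    if unknown:
        raise ValueError(f"uptake table {path}: unknown peptide ids {unknown}")

    keycols = ["peptide_id", "state", "temperature_C", "replicate", "time_s"]
    dup_mask = df.duplicated(subset=keycols, keep=False) & df.duplicated(subset=keycols)
    if dup_mask.any():
        rows = (df.index[dup_mask] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"uptake table {path}: duplicate observation rows at lines {rows}")

    raw_col = df["raw"].astype(bool) if "raw" in df.columns else pd.Series(False, index=df.index)
    corrected = df["deuterons"].to_numpy(dtype=float).copy()
    for pid, pep in by_id.items():
        sel = (df["peptide_id"] == pid) & raw_col
        if sel.any():
            corrected[sel.to_numpy()] = correct_uptake(corrected[sel.to_numpy()], pep.f_be)

    n_t = df["peptide_id"].map(lambda pid: by_id[pid].n_t).to_numpy(dtype=float)
    excess = corrected - n_t
    too_high = excess > clip_tolerance
    if too_high.any():
        rows = (df.index[too_high] + 2).tolist()
        raise ValueError(
            f"uptake table {path}: corrected deuterons exceed N_T by more than "
            f"{clip_tolerance} at lines {rows}"
        )
    clip_mask = (excess > 0) & ~too_high
    if clip_mask.any():
        logger.info(
            "uptake table %s: clipped %d values within tolerance %.3g of N_T",
            path, int(clip_mask.sum()), clip_tolerance,
        )
        corrected[clip_mask] = n_t[clip_mask]
    corrected = np.clip(corrected, 0.0, None)
    df = df.assign(_corrected=corrected)

    curves = []
    for (pid, state, temp, rep), grp in df.groupby(
        ["peptide_id", "state", "temperature_C", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_s")
        curves.append(
            UptakeCurve(
                peptide_id=pid,
                state=state,
                temperature_c=float(temp),
                replicate=int(rep),
                times_s=grp["time_s"].to_numpy(dtype=float),
                deuterons=grp["_corrected"].to_numpy(dtype=float),
            )
        )
    return curves


def write_uptake_table(path, curves: list[UptakeCurve]) -> None:
    """Write curves to the uptake CSV format (lossless round-trip)."""
    rows = []
    for c in curves:
        for t, d in zip(c.times_s, c.deuterons):
            rows.append(
                {
                    "peptide_id": c.peptide_id,
                    "state": c.state,
                    "temperature_C": c.temperature_c,
                    "replicate": c.replicate,
                    "time_s": t,
                    "deuterons": repr(float(d)),
                    "raw": int(c.raw),
                }
            )
    pd.DataFrame(rows, columns=UPTAKE_COLUMNS + ["raw"]).to_csv(path, index=False)
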