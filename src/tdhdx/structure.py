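"""Peptide-to-residue expansion and PDB B-factor painting.

Peptide-level quantities (Ea, delta-Ea, classification codes) are
expanded to per-residue values and written into the temperature-factor
column of a PDB file, the conventional vehicle for structure heat maps.
Only the B-factor columns (61-66) of ATOM/HETATM records are touched;
every other byte of the file is preserved. Residues not covered by any
peptide get 0.00 in the column (it has no missing-value encoding) and
are listed in a sidecar file.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .io import PeptideRecord

logger = logging.getLogger(__name__)

ResidueMap = dict[int, float]  # residue number -> value; absence is the sentinel


def expand_peptides(values: dict[str, float], peptides: list[PeptideRecord]) -> ResidueMap:
    """Spread per-peptide values over their residue spans.

    A residue covered by several peptides receives the mean of their
    values; uncovered residues are simply absent from the map.
    """
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    by_id = {p.peptide_id: p for p in peptides}
    for pid, value in values.items():
        pep = by_id.get(pid)
        if pep is None:
            logger.warning("expand_peptides: unknown peptide id %r ignored", pid)
            continue
        for res in range(pep.start_res, pep.end_res + 1):
            sums[res] = sums.get(res, 0.0) + float(value)
            counts[res] = counts.get(res, 0) + 1
    return {res: sums[res] / counts[res] for res in sums}


def _parse_resseq(line: str) -> int | None:
    try:
        return int(line[22:26])
    except ValueError:
        return None


def paint_pdb(
    in_path,
    out_path,
    residue_map: ResidueMap,
    chain: str | None = None,
    max_mismatch_fraction: float = 0.5,
) -> dict:
    """Write mapped values into the B-factor column of a PDB file.

    ATOM/HETATM records (optionally restricted to ``chain``) get their
    temperature factor replaced by the residue's mapped value at the
    column's fixed %6.2f precision; unmapped residues get 0.00 and are
    listed in ``<out_path>.uncovered.txt``. Aborts when the fraction of
    map residues absent from the structure exceeds
    ``max_mismatch_fraction`` (numbering mismatch). All non-B-factor
    bytes are preserved, so painting is idempotent.

    Returns a summary dict (residues painted/uncovered/missing).
    """
    in_path, out_path = Path(in_path), Path(out_path)
    lines = in_path.read_text().splitlines(keepends=True)

    structure_residues: set[int] = set()
    for line in lines:
        if line.startswith(("ATOM  ", "HETATM")) and (chain is None or line[21] == chain):
            res = _parse_resseq(line)
            if res is not None:
                structure_residues.add(res)
    if residue_map:
        missing = sorted(set(residue_map) - structure_residues)
        frac = len(missing) / len(residue_map)
        if frac > max_mismatch_fraction:
            raise ValueError(
                f"{frac:.0%} of mapped residues absent from structure "
                f"(first missing: {missing[:5]}); residue numbering mismatch?"
            )
        if missing:
            logger.warning("paint_pdb: %d mapped residues not in structure: %s", len(missing), missing)
    else:
        missing = []

    uncovered = sorted(structure_residues - set(residue_map))
    out_lines = []
    for line in lines:
        if line.startswith(("ATOM  ", "HETATM")) and (chain is None or line[21] == chain):
            res = _parse_resseq(line)
            value = residue_map.get(res, 0.0) if res is not None else 0.0
            body = line.rstrip("\n")
            if len(body) < 66:
                body = body.ljust(66)
            line = body[:60] + f"{value:6.2f}" + body[66:] + ("\n" if line.endswith("\n") else "")
        out_lines.append(line)
    out_path.write_text("".join(out_lines))

    sidecar = out_path.with_name(out_path.name + ".uncovered.txt")
    sidecar.write_text("".join(f"{res}\n" for res in uncovered))
    return {
        "painted": len(structure_residues) - len(uncovered),
        "uncovered": uncovered,
        "missing_from_structure": missing,
    }


def write_attribute_file(path, residue_map: ResidueMap) -> None:
    """Per-residue ``residue<TAB>value`` text file for external viewers."""
    with open(path, "w") as fh:
        for res in sorted(residue_map):
            fh.write(f"{res}\t{residue_map[res]:.6g}\n")
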