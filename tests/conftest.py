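import numpy as np
import pytest

from tdhdx.io import PeptideRecord, UptakeCurve

#: The study's sampling grid, seconds.
TIMES_S = np.array(
    [0, 10, 30, 45, 60, 180, 600, 1200, 1800, 2700, 3600, 7200, 10800, 14400], dtype=float
)


@pytest.fixture
def times_s():
    return TIMES_S.copy()


def make_triexp_curve(
    times_s,
    a=1.0,
    b=3.0,
    c=4.0,
    k1=2.5,
    k2=0.4,
    k3=0.02,
    peptide_id="46-62",
    state="apo",
    temperature_c=30.0,
    replicate=1,
    noise_sd=0.0,
    rng=None,
):
    """Exact saturating-triexponential curve, optionally with noise."""
    t_min = np.asarray(times_s) / 60.0
    y = (
        a * (1 - np.exp(-k1 * t_min))
        + b * (1 - np.exp(-k2 * t_min))
        + c * (1 - np.exp(-k3 * t_min))
    )
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        y = y + rng.normal(0, noise_sd, y.size)
        y[0] = 0.0
        y = np.clip(y, 0.0, None)
    return UptakeCurve(peptide_id, state, temperature_c, replicate, np.asarray(times_s, float), y)


@pytest.fixture
def toy_peptides():
    return [
        PeptideRecord.from_sequence("5-10", 5, 10, "GASTAL", f_be=0.2),
        PeptideRecord.from_sequence("8-12", 8, 12, "TALKS", f_be=0.1),
    ]


TOY_PDB = """\
HEADER    TOY STRUCTURE
ATOM      1  N   ALA A   5      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   5      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   5      12.773   7.058  -4.937  1.00 10.00           C
ATOM      4  N   GLY A   6      13.441   6.993  -3.797  1.00 12.00           N
ATOM      5  CA  GLY A   6      14.541   7.910  -3.513  1.00 12.00           C
ATOM      6  N   SER A   7      15.370   7.447  -2.361  1.00 14.00           N
ATOM      7  CA  SER A   7      16.470   8.364  -2.077  1.00 14.00           C
TER       8      SER A   7
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


def make_ca_pdb(path, n_residues=352, chain="A"):
    """Write a synthetic CA-trace PDB spanning residues 1..n_residues."""
    lines = ["HEADER    SYNTHETIC CA TRACE\n"]
    for i in range(1, n_residues + 1):
        lines.append(
            f"ATOM  {i:5d}  CA  ALA {chain}{i:4d}    "
            f"{float(i % 60):8.3f}{float(i // 60):8.3f}{0.0:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"           C\n"
        )
    lines.append("END\n")
    path.write_text("".join(lines))
    return path
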