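"""Synthetic temperature-dependent HDX datasets with known ground truth.

The generator runs the analysis model forwards: each peptide owns a
four-way amplitude split (burst A, intermediate B, slow C,
non-exchanging N_NE summing to N_T), per-minute reference rates for the
intermediate and slow phases at a reference temperature, and phase
activation energies that propagate the rates across temperature via
the Arrhenius law. Protein states (ligand-bound, mutant) shift both
phase barriers by a per-peptide offset, so the true between-state
difference in apparent Ea equals the offset difference exactly. On the
way out each value is attenuated by the peptide's back-exchange
fraction — the exact inverse of the pipeline's correction — and
perturbed by additive Gaussian replicate noise (t > 0 only; the t = 0
point is the undeuterated reference).

The default scenario (:func:`default_scenario`) mirrors the adenosine
deaminase study design: 23 non-overlapping peptides, five temperatures
(10–40 °C), 14 time points (0–14400 s), two replicates, noise sd 0.15
deuterons, and a state layout in which ligand binding stiffens most of
the protein (positive Ea offsets), loosens one peptide, and a
function-altering mutant softens a designated network subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arrhenius import R_KCAL, _ols_ea
from .io import PeptideRecord, UptakeCurve
from .kinetics import weighted_rate

#: Study-design temperature series, Celsius.
DEFAULT_TEMPERATURES_C = (10.0, 20.0, 25.0, 30.0, 40.0)

#: Study-design sampling times, seconds.
DEFAULT_TIMES_S = (0, 10, 30, 45, 60, 180, 600, 1200, 1800, 2700, 3600, 7200, 10800, 14400)

#: Residue spans of the 23 non-overlapping pepsin peptides used throughout.
DEFAULT_PEPTIDE_SPANS = (
    (1, 14), (15, 28), (29, 45), (46, 62), (63, 74), (76, 85), (86, 97),
    (98, 108), (109, 131), (132, 144), (145, 152), (155, 163), (167, 179),
    (180, 200), (201, 229), (230, 248), (253, 259), (260, 267), (268, 290),
    (291, 300), (301, 320), (321, 344), (348, 352),
)


def arrhenius_rate(k_ref: float, ea: float, t_k: float, t_ref_k: float):
    """Propagate a rate constant from T_ref to T with barrier ``ea``.

    k(T) = k_ref * exp(-(Ea/R) * (1/T - 1/T_ref)), rates per minute,
    Ea in kcal/mol, temperatures in kelvin.
    """
    if np.any(np.asarray(k_ref) <= 0):
        raise ValueError("rate constant must be positive")
    if np.any(np.asarray(t_k) <= 0) or np.any(np.asarray(t_ref_k) <= 0):
        raise ValueError("absolute temperature must be positive")
    return k_ref * np.exp(-(ea / R_KCAL) * (1.0 / np.asarray(t_k) - 1.0 / t_ref_k))


@dataclass
class PeptideKinetics:
    """Ground-truth kinetic parameters for one peptide (baseline state)."""

    a: float                 # burst amplitude, amides
    b: float                 # intermediate amplitude
    c: float                 # slow amplitude
    n_ne: float              # non-exchanging amides
    k1: float                # burst rate, min^-1 (temperature-insensitive)
    k2_ref: float            # intermediate rate at T_ref, min^-1
    k3_ref: float            # slow rate at T_ref, min^-1
    ea2: float               # intermediate-phase barrier, kcal/mol
    ea3: float               # slow-phase barrier, kcal/mol


@dataclass
class SyntheticModel:
    """Full generative model: peptides, kinetics, state offsets, noise."""

    peptides: list[PeptideRecord]
    kinetics: dict[str, PeptideKinetics]          # peptide_id -> parameters
    state_offsets: dict[str, dict[str, float]]    # state -> {peptide_id: Ea offset}
    noise_sd: float = 0.15                        # deuterons, additive Gaussian
    t_ref_k: float = 298.15
    seed: int = 0

    def __post_init__(self):
        for p in self.peptides:
            kin = self.kinetics.get(p.peptide_id)
            if kin is None:
                raise ValueError(f"no kinetics for peptide {p.peptide_id}")
            total = kin.a + kin.b + kin.c + kin.n_ne
            if not np.isclose(total, p.n_t, atol=1e-9):
                raise ValueError(
                    f"{p.peptide_id}: amplitudes sum to {total}, expected N_T={p.n_t}"
                )
            for name in ("k1", "k2_ref", "k3_ref"):
                if getattr(kin, name) <= 0:
                    raise ValueError(f"{p.peptide_id}: {name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")


@dataclass
class SimConfig:
    """Experimental design: states, temperatures, times, replicates."""

    states: tuple = ("WT-apo",)
    temperatures_c: tuple = DEFAULT_TEMPERATURES_C
    times_s: tuple = DEFAULT_TIMES_S
    n_replicates: int = 2

    def __post_init__(self):
        self.states = tuple(self.states)
        self.temperatures_c = tuple(float(t) for t in self.temperatures_c)
        self.times_s = tuple(float(t) for t in self.times_s)
        if self.times_s[0] != 0:
            raise ValueError("time series must start at 0 s")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def _state_rates(kin: PeptideKinetics, offset: float, t_k: float, t_ref_k: float):
    k2 = arrhenius_rate(kin.k2_ref, kin.ea2 + offset, t_k, t_ref_k)
    k3 = arrhenius_rate(kin.k3_ref, kin.ea3 + offset, t_k, t_ref_k)
    return k2, k3


def true_uptake(kin: PeptideKinetics, offset: float, t_k: float, t_ref_k: float, times_s):
    """Noise-free, back-exchange-free uptake curve (deuterons vs seconds)."""
    t_min = np.asarray(times_s, dtype=float) / 60.0
    k2, k3 = _state_rates(kin, offset, t_k, t_ref_k)
    return (
        kin.a * (1.0 - np.exp(-kin.k1 * t_min))
        + kin.b * (1.0 - np.exp(-k2 * t_min))
        + kin.c * (1.0 - np.exp(-k3 * t_min))
    )


def true_weighted_ea(
    kin: PeptideKinetics, offset: float, temperatures_c, t_ref_k: float, n_t: float
) -> float:
    """Ground-truth apparent Ea of the weighted-average rate constant.

    With two Arrhenius phases, ln k_WA is mildly convex in 1/T, so the
    estimand of the downstream regression is the OLS slope of the
    noise-free ln k_WA over the design temperatures — computed here by
    running that regression on exact rates.
    """
    temps_k = np.asarray(temperatures_c, dtype=float) + 273.15
    if temps_k.size < 3:
        return float("nan")  # projection undefined on a degenerate design
    kwa = []
    for t in temps_k:
        k2, k3 = _state_rates(kin, offset, t, t_ref_k)
        kwa.append(weighted_rate(kin.b, k2, kin.c, k3, n_t))
    return _ols_ea(temps_k, np.asarray(kwa))[0]


def generate_uptake(
    model: SyntheticModel, config: SimConfig
) -> tuple[list[UptakeCurve], pd.DataFrame]:
    """Generate observed uptake curves plus the ground-truth Ea table.

    Every state in the config must have an offset entry in the model.
    Observed counts are ``(1 - f_BE) * y(t) + eps`` clipped to
    [0, N_T], with ``eps ~ N(0, noise_sd)`` at t > 0 and the t = 0
    reference identically zero. Curves are marked ``raw`` so the
    reading stage applies the back-exchange correction. Identical
    (model, config) including seed reproduce byte-identical output.
    """
    missing = [s for s in config.states if s not in model.state_offsets]
    if missing:
        raise ValueError(f"states without Ea-offset entries: {missing}")
    rng = np.random.default_rng(model.seed)
    times = np.asarray(config.times_s, dtype=float)
    curves: list[UptakeCurve] = []
    truth_rows = []
    for pep in model.peptides:
        kin = model.kinetics[pep.peptide_id]
        for state in config.states:
            offset = model.state_offsets[state].get(pep.peptide_id, 0.0)
            truth_rows.append(
                {
                    "peptide_id": pep.peptide_id,
                    "state": state,
                    "ea_true": true_weighted_ea(kin, offset, config.temperatures_c, model.t_ref_k, pep.n_t),
                    "ea_offset": offset,
                }
            )
            for temp_c in config.temperatures_c:
                y = true_uptake(kin, offset, temp_c + 273.15, model.t_ref_k, times)
                observed_clean = (1.0 - pep.f_be) * y
                for rep in range(1, config.n_replicates + 1):
                    eps = rng.normal(0.0, model.noise_sd, times.size) if model.noise_sd > 0 else 0.0
                    obs = observed_clean + eps
                    obs = np.asarray(obs, dtype=float)
                    obs[0] = 0.0  # undeuterated reference
                    obs = np.clip(obs, 0.0, pep.n_t)
                    curves.append(
                        UptakeCurve(
                            peptide_id=pep.peptide_id,
                            state=state,
                            temperature_c=temp_c,
                            replicate=rep,
                            times_s=times.copy(),
                            deuterons=obs,
                            raw=True,
                        )
                    )
    truth = pd.DataFrame(truth_rows, columns=["peptide_id", "state", "ea_true", "ea_offset"])
    return curves, truth


# ---------------------------------------------------------------------------
# default adenosine-deaminase-like scenario
# ---------------------------------------------------------------------------

#: Peptides whose barriers the ligand raises in the default scenario.
LIGAND_STIFFENED = ("46-62", "63-74", "86-97", "109-131", "132-144", "180-200", "301-320", "348-352")
#: The one peptide the ligand loosens (the active-site flap analogue).
LIGAND_LOOSENED = "201-229"
#: Network subset the mutant softens in the apo state: every peptide
#: with N_T >= 14 — the size at which the weighted rate, and hence Ea,
#: is determinable to ~10% at the simulated noise level — except the
#: ligand-loosened flap analogue. Exactly seven peptides.
MUTANT_NETWORK = ("46-62", "109-131", "180-200", "230-248", "268-290", "301-320", "321-344")
#: Subset the mutant softens in the inhibitor-bound state.
MUTANT_NETWORK_ETS = ("46-62", "109-131", "230-248", "268-290", "301-320")

DEFAULT_STATES = ("WT-apo", "WT-ES", "WT-ETS", "F61A-apo", "F61A-ETS")

_RESIDUES = "ACDEFGHIKLMNQRSTVWY"  # proline inserted separately


def _make_sequence(rng: np.random.Generator, length: int) -> str:
    seq = list(rng.choice(list(_RESIDUES), size=length))
    # sprinkle an occasional proline after position 2
    if length >= 8 and rng.random() < 0.6:
        seq[int(rng.integers(2, length))] = "P"
    return "".join(seq)


def default_scenario(
    seed: int = 0,
    noise_sd: float = 0.15,
    states: tuple = DEFAULT_STATES,
    n_replicates: int = 2,
) -> tuple[SyntheticModel, SimConfig]:
    """Build the shipped study-design scenario.

    The peptide map, kinetic parameters and state offsets are fixed
    (drawn from an internal constant seed so they define *the*
    scenario); ``seed`` controls only the replicate noise stream.

    State layout:

    * ``WT-apo`` — baseline, all offsets zero;
    * ``WT-ES`` / ``WT-ETS`` — substrate-analog / inhibitor-bound:
      +5 (resp. +5.5) kcal/mol on most peptides, -5 (resp. -6) on the
      201-229 flap analogue;
    * ``F61A-apo`` — mutant: -7 kcal/mol on the seven network peptides;
    * ``F61A-ETS`` — mutant bound to inhibitor: the WT-ETS offsets plus
      -7 on the bound-state network subset.
    """
    struct_rng = np.random.default_rng(20240212)  # scenario identity, not noise
    peptides = []
    kinetics = {}
    for start, end in DEFAULT_PEPTIDE_SPANS:
        length = end - start + 1
        seq = _make_sequence(struct_rng, length)
        pid = f"{start}-{end}"
        pep = PeptideRecord.from_sequence(pid, start, end, seq, f_be=float(struct_rng.uniform(0.10, 0.30)))
        peptides.append(pep)
        fracs = np.array([0.20, 0.32, 0.28, 0.20]) + struct_rng.uniform(-0.04, 0.04, 4)
        fracs /= fracs.sum()
        a, b, c, n_ne = fracs * pep.n_t
        # Baseline barriers sit in the upper part of the observed 5-15
        # kcal/mol window so every state's barrier stays physically
        # positive and measurable after a negative offset; peptides that
        # lose 7 kcal/mol in the mutant must have started high enough
        # that the softened barrier still clears the indeterminacy rule.
        if pid in MUTANT_NETWORK:
            ea2 = float(struct_rng.uniform(10.5, 12.0))
        else:
            ea2 = float(struct_rng.uniform(8.0, 12.0))
        # Rates chosen so both measurable phases stay resolvable over the
        # whole 10-40 C range on the 0-14400 s grid: the intermediate
        # phase well inside the densely sampled window and clear of the
        # burst at 40 C, the slow phase clear of the non-exchanging
        # baseline (k3 * t_max >= ~3 at 10 C), and a >4x separation
        # between the two throughout.
        k2_ref = float(np.exp(struct_rng.uniform(np.log(0.10), np.log(0.25))))
        k3_ref = k2_ref / 7.0 * float(struct_rng.uniform(0.8, 1.25))
        kinetics[pid] = PeptideKinetics(
            a=float(a), b=float(b), c=float(c), n_ne=float(n_ne),
            k1=20.0,
            k2_ref=k2_ref,
            k3_ref=k3_ref,
            ea2=ea2,
            ea3=ea2 + 4.0,
        )

    all_ids = [p.peptide_id for p in peptides]
    offsets: dict[str, dict[str, float]] = {"WT-apo": {pid: 0.0 for pid in all_ids}}
    es = {pid: 0.0 for pid in all_ids}
    es.update({pid: 5.0 for pid in LIGAND_STIFFENED})
    es[LIGAND_LOOSENED] = -5.0
    offsets["WT-ES"] = es
    ets = {pid: 0.0 for pid in all_ids}
    ets.update({pid: 5.5 for pid in LIGAND_STIFFENED})
    ets[LIGAND_LOOSENED] = -6.0
    offsets["WT-ETS"] = ets
    f61a = {pid: 0.0 for pid in all_ids}
    f61a.update({pid: -7.0 for pid in MUTANT_NETWORK})
    offsets["F61A-apo"] = f61a
    f61a_ets = dict(ets)
    for pid in MUTANT_NETWORK_ETS:
        f61a_ets[pid] = f61a_ets.get(pid, 0.0) - 7.0
    offsets["F61A-ETS"] = f61a_ets

    model = SyntheticModel(
        peptides=peptides, kinetics=kinetics, state_offsets=offsets,
        noise_sd=noise_sd, seed=seed,
    )
    config = SimConfig(states=tuple(states), n_replicates=n_replicates)
    return model, config
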