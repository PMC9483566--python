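"""End-to-end orchestration of the TDHDX analysis stages.

Each ``run_*`` function consumes a :class:`RunConfig`, reads the
upstream CSV artifacts from the output directory (or writes them, for
the simulation stage), and emits its own tables plus a JSON run
manifest. ``run_all`` chains simulate → fit → ea → compare → map.

One seed governs every stochastic stage; per-stage sub-seeds are
derived deterministically from it so stages can be re-run in
isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arrhenius import DEFAULT_ANOMALY_THRESHOLD, fit_arrhenius_with_anomaly_check
from .compare import classify, delta_ea, delta_table, single_temperature_difference
from .io import (
    DEFAULT_CLIP_TOLERANCE,
    read_peptide_map,
    read_uptake_table,
    write_peptide_map,
    write_uptake_table,
)
from .kinetics import average_replicates, average_uptake_curves, fit_triexponential
from .structure import expand_peptides, paint_pdb, write_attribute_file
from .synthetic import DEFAULT_STATES, default_scenario, generate_uptake

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a pipeline run (YAML-loadable).

    Unknown keys are rejected so typos fail loudly. ``peptide_map`` and
    ``uptake_table`` default to the artifacts the simulate stage writes
    into ``outdir``; point them at real data to skip simulation.
    """

    outdir: str = "tdhdx-run"
    seed: int = 0
    peptide_map: str | None = None
    uptake_table: str | None = None
    structure: str | None = None
    chain: str | None = None
    states: tuple = DEFAULT_STATES
    n_replicates: int = 2
    noise_sd: float = 0.15
    pairs: tuple = (("WT-apo", "WT-ES"), ("WT-apo", "WT-ETS"), ("WT-ES", "WT-ETS"), ("WT-apo", "F61A-apo"))
    eliminated: tuple = ()
    map_pair: str | None = None          # pair label to paint; default: first pair
    fit_mode: str = "per_replicate"      # or "average_uptake"
    anomaly_threshold: float = DEFAULT_ANOMALY_THRESHOLD
    clip_tolerance: float = DEFAULT_CLIP_TOLERANCE
    uptake_difference_threshold: float = 1.0
    comparison_temperature_c: float = 30.0

    def __post_init__(self):
        self.states = tuple(self.states)
        self.pairs = tuple(tuple(p) for p in self.pairs)
        self.eliminated = tuple(self.eliminated)
        if self.fit_mode not in ("per_replicate", "average_uptake"):
            raise ValueError(f"unknown fit_mode {self.fit_mode!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seed(cfg: RunConfig, stage: str) -> int:
    payload = f"{cfg.seed}:{stage}".encode()
    return int.from_bytes(hashlib.sha256(payload).digest()[:4], "big") % (2**31)


def _outdir(cfg: RunConfig) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_manifest(cfg: RunConfig, stage: str, outputs: list[str]) -> None:
    out = _outdir(cfg)
    resolved = cfg.resolved()
    blob = json.dumps(resolved, sort_keys=True, default=str)
    manifest = {
        "stage": stage,
        "seed": cfg.seed,
        "config": resolved,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "version": __version__,
        "outputs": outputs,
    }
    with open(out / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"{path} not found — run the '{producer}' stage first")
    return path


def run_simulate(cfg: RunConfig):
    """Generate the synthetic scenario into the output directory."""
    out = _outdir(cfg)
    model, sim = default_scenario(
        seed=_stage_seed(cfg, "simulate"),
        noise_sd=cfg.noise_sd,
        states=cfg.states,
        n_replicates=cfg.n_replicates,
    )
    curves, truth = generate_uptake(model, sim)
    write_peptide_map(out / "peptide_map.csv", model.peptides)
    write_uptake_table(out / "uptake.csv", curves)
    truth.to_csv(out / "ground_truth_ea.csv", index=False)
    _write_manifest(cfg, "simulate", ["peptide_map.csv", "uptake.csv", "ground_truth_ea.csv"])
    return curves, truth


def _load_inputs(cfg: RunConfig):
    out = _outdir(cfg)
    pep_path = Path(cfg.peptide_map) if cfg.peptide_map else _require(out / "peptide_map.csv", "simulate")
    upt_path = Path(cfg.uptake_table) if cfg.uptake_table else _require(out / "uptake.csv", "simulate")
    peptides = read_peptide_map(pep_path)
    curves = read_uptake_table(upt_path, peptides, clip_tolerance=cfg.clip_tolerance)
    return peptides, curves


def run_fit(cfg: RunConfig) -> pd.DataFrame:
    """Fit the three-exponential model to every curve; write fits.csv."""
    out = _outdir(cfg)
    peptides, curves = _load_inputs(cfg)
    n_t = {p.peptide_id: p.n_t for p in peptides}
    if cfg.fit_mode == "average_uptake":
        curves = average_uptake_curves(curves)
    seed0 = _stage_seed(cfg, "fit")
    fits = [
        fit_triexponential(c, n_t[c.peptide_id], seed=(seed0 + i) % (2**31))
        for i, c in enumerate(curves)
    ]
    df = pd.DataFrame(
        [
            {
                "peptide_id": f.peptide_id, "state": f.state,
                "temperature_C": f.temperature_c, "replicate": f.replicate,
                "A": f.a, "B": f.b, "C": f.c, "N_NE": f.n_ne,
                "k1": f.k1, "k2": f.k2, "k3": f.k3, "k_wa": f.k_wa,
                "sse": f.sse, "converged": f.converged, "reduced": f.reduced,
                "warnings": "; ".join(f.warnings),
            }
            for f in fits
        ]
    )
    df.to_csv(out / "fits.csv", index=False)
    _write_manifest(cfg, "fit", ["fits.csv"])
    return df


def run_ea(cfg: RunConfig) -> pd.DataFrame:
    """Arrhenius-regress fitted rate constants; write ea.csv."""
    out = _outdir(cfg)
    fits_path = _require(out / "fits.csv", "fit")
    df = pd.read_csv(fits_path, dtype={"peptide_id": str, "state": str})
    df = df[df["converged"]]
    rows = []
    for (pid, state), grp in df.groupby(["peptide_id", "state"], sort=True):
        piv = grp.pivot_table(index="temperature_C", columns="replicate", values="k_wa")
        temps_k = piv.index.to_numpy(dtype=float) + 273.15
        k_mean = piv.mean(axis=1).to_numpy()
        rep_kwa = {int(r): piv[r].to_numpy() for r in piv.columns} if piv.shape[1] > 1 else None
        primary, full = fit_arrhenius_with_anomaly_check(
            temps_k, k_mean, pid, state, rep_kwa, cfg.anomaly_threshold
        )
        rows.append(
            {
                "peptide_id": pid, "state": state,
                "Ea_kcal_mol": primary.ea, "se_Ea": primary.se_ea,
                "intercept": primary.intercept, "r_squared": primary.r_squared,
                "n_temps": primary.n_temps,
                "temps_excluded": "; ".join(f"{t:.2f}K ({why})" for t, why in primary.temps_excluded),
                "indeterminate": primary.indeterminate,
                "Ea_full_series": full.ea if full is not None else primary.ea,
            }
        )
    ea = pd.DataFrame(rows)
    ea.to_csv(out / "ea.csv", index=False)
    _write_manifest(cfg, "ea", ["ea.csv"])
    return ea


def _arr_from_row(sub: pd.DataFrame, pid: str, state: str):
    from .arrhenius import ArrheniusFit

    row = sub.loc[pid]
    return ArrheniusFit(
        peptide_id=pid, state=state, ea=float(row["Ea_kcal_mol"]),
        se_ea=float(row["se_Ea"]), indeterminate=bool(row["indeterminate"]),
        n_temps=int(row["n_temps"]),
    )


def run_compare(cfg: RunConfig) -> pd.DataFrame:
    """Delta-Ea for each configured state pair; write delta_ea.csv and network.csv."""
    out = _outdir(cfg)
    ea = pd.read_csv(_require(out / "ea.csv", "ea"), dtype={"peptide_id": str, "state": str})
    known = set(ea["peptide_id"])
    eliminated = set()
    for pid in cfg.eliminated:
        if pid in known:
            eliminated.add(pid)
        else:
            logger.warning("eliminated set entry %r matches no peptide; ignored", pid)

    records = []
    for state_a, state_b in cfg.pairs:
        sub_a = ea[ea["state"] == state_a].set_index("peptide_id")
        sub_b = ea[ea["state"] == state_b].set_index("peptide_id")
        for pid in sorted(set(sub_a.index) & set(sub_b.index)):
            rec = delta_ea(
                _arr_from_row(sub_a, pid, state_a),
                _arr_from_row(sub_b, pid, state_b),
                pair=f"{state_b}-{state_a}",
            )
            classify(rec, eliminated)
            records.append(rec)
    table = delta_table(records)
    table.to_csv(out / "delta_ea.csv", index=False)
    network = (
        table[table["classification"] == "significant"]
        .groupby("pair")["peptide_id"]
        .agg(list)
        .reset_index()
        .rename(columns={"peptide_id": "significant_peptides"})
    )
    network["n_significant"] = network["significant_peptides"].str.len()
    network["significant_peptides"] = network["significant_peptides"].map(lambda v: "; ".join(v))
    network.to_csv(out / "network.csv", index=False)

    # single-temperature uptake differences at the comparison temperature
    _write_uptake_differences(cfg, out)

    _write_manifest(cfg, "compare", ["delta_ea.csv", "network.csv", "uptake_differences.csv"])
    return table


def _write_uptake_differences(cfg: RunConfig, out: Path) -> None:
    try:
        peptides, curves = _load_inputs(cfg)
    except FileNotFoundError:
        logger.info("uptake inputs unavailable; skipping single-temperature differences")
        return
    rows = []
    for state_a, state_b in cfg.pairs:
        for pep in peptides:
            sel_a = [
                c for c in curves
                if c.peptide_id == pep.peptide_id and c.state == state_a
                and c.temperature_c == cfg.comparison_temperature_c
            ]
            sel_b = [
                c for c in curves
                if c.peptide_id == pep.peptide_id and c.state == state_b
                and c.temperature_c == cfg.comparison_temperature_c
            ]
            if not sel_a or not sel_b:
                continue
            rec = single_temperature_difference(
                sel_a, sel_b, threshold=cfg.uptake_difference_threshold,
                pair=f"{state_b}-{state_a}",
            )
            rows.append(
                {
                    "peptide_id": rec.peptide_id, "pair": rec.pair,
                    "temperature_C": cfg.comparison_temperature_c,
                    "plateau_sum": rec.plateau_sum, "direction": rec.direction,
                }
            )
    pd.DataFrame(rows).to_csv(out / "uptake_differences.csv", index=False)


def run_map(cfg: RunConfig) -> dict | None:
    """Paint delta-Ea (or Ea) values onto the structure, if one is given."""
    out = _outdir(cfg)
    delta = pd.read_csv(_require(out / "delta_ea.csv", "compare"), dtype={"peptide_id": str})
    pair = cfg.map_pair or delta["pair"].iloc[0]
    sub = delta[delta["pair"] == pair]
    values = {
        row.peptide_id: float(row.delta_Ea)
        for row in sub.itertuples()
        if row.classification == "significant"
    }
    peptides = read_peptide_map(
        Path(cfg.peptide_map) if cfg.peptide_map else _require(out / "peptide_map.csv", "simulate")
    )
    rmap = expand_peptides(values, peptides)
    write_attribute_file(out / "residue_values.tsv", rmap)
    outputs = ["residue_values.tsv"]
    summary = None
    if cfg.structure:
        summary = paint_pdb(cfg.structure, out / "painted.pdb", rmap, chain=cfg.chain)
        outputs.append("painted.pdb")
    _write_manifest(cfg, "map", outputs)
    return summary


def analyze_curves(
    curves,
    peptides,
    seed: int = 0,
    anomaly_threshold: float = DEFAULT_ANOMALY_THRESHOLD,
) -> dict:
    """In-memory pipeline core: corrected curves -> ArrheniusFit per (peptide, state).

    Fits every replicate curve, averages replicate k_WA values, applies
    the anomalous-top-temperature rule and returns the primary fits
    keyed by ``(peptide_id, state)``. The file-based stages wrap the
    same sequence with CSV artifacts in between.
    """
    n_t = {p.peptide_id: p.n_t for p in peptides}
    fits = [
        fit_triexponential(c, n_t[c.peptide_id], seed=(seed + i) % (2**31))
        for i, c in enumerate(curves)
    ]
    kwa = average_replicates(fits)
    out = {}
    for (pid, state), grp in kwa.groupby(["peptide_id", "state"], sort=True):
        grp = grp.sort_values("temperature_C")
        temps_k = grp["temperature_C"].to_numpy(dtype=float) + 273.15
        k_mean = grp["k_wa"].to_numpy(dtype=float)
        reps: dict[int, list] = {}
        for d in grp["replicate_k_wa"]:
            for r in d:
                reps.setdefault(r, [])
        rep_kwa = None
        if len(reps) > 1:
            rep_kwa = {
                r: np.array([d.get(r, np.nan) for d in grp["replicate_k_wa"]], dtype=float)
                for r in reps
            }
        primary, _ = fit_arrhenius_with_anomaly_check(
            temps_k, k_mean, pid, state, rep_kwa, anomaly_threshold
        )
        out[(pid, state)] = primary
    return out


def run_all(cfg: RunConfig) -> dict:
    """Chain every stage; returns the key output tables."""
    run_simulate(cfg)
    fits = run_fit(cfg)
    ea = run_ea(cfg)
    delta = run_compare(cfg)
    map_summary = run_map(cfg)
    return {"fits": fits, "ea": ea, "delta": delta, "map": map_summary}
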