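"""Arrhenius regression of weighted-average exchange rates.

Plotting ln k_WA against 1/T (kelvin) and taking the slope gives the
apparent activation energy of the exchange-competent opening motions,

    Ea = -slope * R,      R = 1.9872e-3 kcal mol^-1 K^-1,

reported per peptide and state with the slope's standard error. Two
data-quality rules from the experimental protocol are made explicit
here:

* an *anomalously low* top temperature — at the highest temperature a
  peptide's intermediate phase can speed past the sampled time window,
  depressing k_WA below the Arrhenius trend — is detected by comparing
  the top point against a regression on the remaining points, and the
  reduced fit is then reported as primary;
* a result is *indeterminate* when fewer than three usable temperatures
  remain or the standard error reaches the estimate itself; such
  peptides are excluded from network classification downstream.

When per-replicate rate constants are available the reported error is
the root sum of squares of the regression standard error and the
between-replicate spread of per-replicate Ea estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3

#: Default anomaly threshold: multiples of the reduced-fit residual sd.
DEFAULT_ANOMALY_THRESHOLD = 2.0

#: Minimum ln-rate deficit for a top-temperature exclusion. The reduced
#: fit keeps only ~2 residual degrees of freedom, so its residual sd is
#: itself noisy; without an absolute floor the rule trips on ordinary
#: scatter instead of the genuine regime change it is meant to catch.
DEFAULT_MIN_DEFICIT = 0.2


@dataclass
class ArrheniusFit:
    """Activation energy for one (peptide, state)."""

    peptide_id: str
    state: str
    ea: float = np.nan              # kcal/mol
    se_ea: float = np.nan           # kcal/mol
    intercept: float = np.nan       # ln A0 (k in min^-1)
    r_squared: float = np.nan
    temps_used_k: tuple = ()
    temps_excluded: tuple = ()      # of (T_kelvin, reason)
    n_temps: int = 0
    indeterminate: bool = True

    def __post_init__(self):
        self.temps_used_k = tuple(self.temps_used_k)
        self.temps_excluded = tuple(self.temps_excluded)


def _ols_ea(temps_k: np.ndarray, k_wa: np.ndarray):
    """OLS of ln k on 1/T; returns (ea, se_ea, intercept, r2)."""
    x = 1.0 / temps_k
    yv = np.log(k_wa)
    res = stats.linregress(x, yv)
    ea = -res.slope * R_KCAL
    se = res.stderr * R_KCAL
    return ea, se, res.intercept, res.rvalue**2


def fit_arrhenius(
    temps_k,
    k_wa,
    peptide_id: str = "",
    state: str = "",
    replicate_k_wa: dict[int, "np.ndarray"] | None = None,
) -> ArrheniusFit:
    """Regress ln k_WA on 1/T and report Ea with its standard error.

    Parameters
    ----------
    temps_k, k_wa
        Matched arrays of absolute temperature and (replicate-averaged)
        weighted-average rate constants. Nonpositive rates are dropped
        with a log entry; fewer than three surviving points yield an
        indeterminate result with no Ea.
    replicate_k_wa
        Optional per-replicate rate arrays aligned with ``temps_k``;
        when at least two replicates each support a 3-point fit, the
        spread of per-replicate Ea estimates (sd of the replicate Ea
        values divided by sqrt(n)) is folded into ``se_ea`` in
        quadrature.

    The result is flagged indeterminate when ``se_ea >= |Ea|``.
    """
    temps_k = np.asarray(temps_k, dtype=float)
    k_wa = np.asarray(k_wa, dtype=float)
    fit = ArrheniusFit(peptide_id=peptide_id, state=state)

    good = np.isfinite(k_wa) & (k_wa > 0)
    dropped = [(float(t), "nonpositive or missing k_WA") for t in temps_k[~good]]
    if dropped:
        logger.info("%s/%s: dropped %d temperature(s) with unusable k_WA", peptide_id, state, len(dropped))
    t_use, k_use = temps_k[good], k_wa[good]
    fit.temps_excluded = tuple(dropped)
    fit.n_temps = int(t_use.size)
    fit.temps_used_k = tuple(float(t) for t in t_use)
    if t_use.size < 3:
        logger.info("%s/%s: indeterminate (only %d usable temperatures)", peptide_id, state, t_use.size)
        return fit

    ea, se, intercept, r2 = _ols_ea(t_use, k_use)

    se_rep = _replicate_spread(temps_k, good, replicate_k_wa)
    if se_rep is not None:
        se = float(np.hypot(se, se_rep))

    fit.ea, fit.se_ea, fit.intercept, fit.r_squared = ea, se, intercept, r2
    fit.indeterminate = bool(se >= abs(ea)) or not np.isfinite(ea)
    return fit


def _replicate_spread(temps_k, good, replicate_k_wa):
    if not replicate_k_wa or len(replicate_k_wa) < 2:
        return None
    eas = []
    for rep, vals in sorted(replicate_k_wa.items()):
        vals = np.asarray(vals, dtype=float)
        ok = good & np.isfinite(vals) & (vals > 0)
        if ok.sum() >= 3:
            eas.append(_ols_ea(temps_k[ok], vals[ok])[0])
    if len(eas) < 2:
        return None
    # the spread itself, not the standard error of the mean: with two
    # replicates the 1-dof sd already underestimates tail risk, so the
    # conservative convention is kept
    return float(np.std(eas, ddof=1))


def detect_anomalous_top_temperature(
    temps_k,
    k_wa,
    threshold: float = DEFAULT_ANOMALY_THRESHOLD,
    min_deficit: float = DEFAULT_MIN_DEFICIT,
) -> dict:
    """Decide whether the highest temperature falls below the Arrhenius trend.

    The remaining points are regressed alone; the top temperature is
    flagged when its observed ln k_WA lies below the reduced fit's
    prediction by more than ``threshold`` times the reduced fit's
    residual standard deviation and by at least ``min_deficit``
    ln-units. Requires at least four points so the reduced fit keeps
    three.

    Returns a dict with ``excluded`` (bool), ``deficit`` (predicted
    minus observed ln k_WA at the top temperature) and
    ``residual_sd`` of the reduced fit.
    """
    temps_k = np.asarray(temps_k, dtype=float)
    k_wa = np.asarray(k_wa, dtype=float)
    if temps_k.size < 4 or np.any(k_wa <= 0):
        return {"excluded": False, "deficit": np.nan, "residual_sd": np.nan}
    top = int(np.argmax(temps_k))
    rest = np.ones(temps_k.size, dtype=bool)
    rest[top] = False
    x, yv = 1.0 / temps_k, np.log(k_wa)
    res = stats.linregress(x[rest], yv[rest])
    pred = res.slope * x[top] + res.intercept
    resid = yv[rest] - (res.slope * x[rest] + res.intercept)
    dof = max(int(rest.sum()) - 2, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    deficit = float(pred - yv[top])
    excluded = deficit > max(threshold * residual_sd, min_deficit, 1e-8)
    return {"excluded": bool(excluded), "deficit": deficit, "residual_sd": residual_sd}


def fit_arrhenius_with_anomaly_check(
    temps_k,
    k_wa,
    peptide_id: str = "",
    state: str = "",
    replicate_k_wa: dict | None = None,
    anomaly_threshold: float = DEFAULT_ANOMALY_THRESHOLD,
) -> tuple[ArrheniusFit, ArrheniusFit | None]:
    """Fit Ea, excluding an anomalously low top temperature when detected.

    Returns ``(primary, full)``: when the top temperature is flagged the
    primary fit omits it (the full-series fit is returned alongside for
    reporting); otherwise ``full`` is None and the primary fit uses all
    usable temperatures.
    """
    temps_k = np.asarray(temps_k, dtype=float)
    k_wa = np.asarray(k_wa, dtype=float)
    good = np.isfinite(k_wa) & (k_wa > 0)
    decision = detect_anomalous_top_temperature(temps_k[good], k_wa[good], anomaly_threshold)
    if not decision["excluded"]:
        return fit_arrhenius(temps_k, k_wa, peptide_id, state, replicate_k_wa), None

    top_t = float(np.max(temps_k[good]))
    keep = temps_k != top_t
    sub_rep = (
        {r: np.asarray(v, dtype=float)[keep] for r, v in replicate_k_wa.items()}
        if replicate_k_wa
        else None
    )
    primary = fit_arrhenius(temps_k[keep], k_wa[keep], peptide_id, state, sub_rep)
    primary.temps_excluded = primary.temps_excluded + (
        (top_t, f"anomalously low (deficit {decision['deficit']:.3g} ln-units)"),
    )
    full = fit_arrhenius(temps_k, k_wa, peptide_id, state, replicate_k_wa)
    logger.info("%s/%s: top temperature %.2f K excluded as anomalously low", peptide_id, state, top_t)
    return primary, full
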