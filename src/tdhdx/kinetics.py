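"""Multi-exponential fitting of deuteron-uptake time courses.

Under EX-2 exchange the observed per-amide rate is the product of a
local opening equilibrium and the intrinsic chemical exchange rate, and
a peptide's uptake curve is well described by three kinetic classes of
amides — fast (burst), intermediate and slow — plus a non-exchanging
tail::

    y(t) = N_T - A e^(-k1 t) - B e^(-k2 t) - C e^(-k3 t) - N_NE

with A + B + C + N_NE = N_T, so y(0) = 0 and y(inf) = N_T - N_NE. The
constraint is imposed exactly by eliminating N_NE, which reduces the
model to a sum of saturating exponentials::

    y(t) = A (1 - e^(-k1 t)) + B (1 - e^(-k2 t)) + C (1 - e^(-k3 t))

Fits are unbounded nonlinear least squares (Levenberg–Marquardt) from
the standard protocol start — rates (2.5, 0.5, 0.01) per minute and all
four amplitudes at 0.25 N_T — followed by validation: phases are
relabelled so k1 >= k2 >= k3, slightly negative amplitudes are zeroed,
and a strongly negative amplitude triggers a reduced (two-exponential)
refit. The summary statistic passed downstream is the weighted-average
rate constant

    k_WA = (B k2 + C k3) / N_T

which deliberately excludes the burst phase: A exchanges before the
first sampled time point and carries no usable temperature dependence.

Times enter in seconds and are converted to minutes internally, so all
rate constants are per-minute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io import UptakeCurve

logger = logging.getLogger(__name__)

#: Standard-protocol initial rate constants, per minute (fast, intermediate, slow).
INITIAL_RATES = (2.5, 0.5, 0.01)

#: Negative-amplitude tolerance as a fraction of N_T: amplitudes above
#: -NEG_AMP_FRACTION*N_T are zeroed, below it trigger model reduction.
NEG_AMP_FRACTION = 0.05

#: k2/k3 ratio below which the two slow phases are flagged as collinear.
COLLINEARITY_RATIO = 3.0


def default_initial_guess(n_t: float) -> dict[str, float]:
    """Initial parameter values of the standard fitting protocol.

    Rates start at (2.5, 0.5, 0.01) per minute for the fast,
    intermediate and slow phases; every amplitude (A, B, C, N_NE)
    starts at 0.25 N_T.
    """
    if n_t < 1:
        raise ValueError(f"N_T must be >= 1, got {n_t}")
    a = 0.25 * float(n_t)
    k1, k2, k3 = INITIAL_RATES
    return {"A": a, "B": a, "C": a, "N_NE": a, "k1": k1, "k2": k2, "k3": k3}


def triexp_uptake(t_min, amplitudes, rates):
    """Evaluate the saturating-exponential uptake model at times in minutes."""
    t = np.asarray(t_min, dtype=float)[..., None]
    amp = np.asarray(amplitudes, dtype=float)
    k = np.asarray(rates, dtype=float)
    # exponent clipped so LM excursions to negative rates stay finite
    return np.sum(amp * (1.0 - np.exp(np.clip(-k * t, -700.0, 700.0))), axis=-1)


@dataclass
class TriexpFit:
    """Result of fitting one uptake curve.

    Amplitudes are amide counts; rates are per-minute and ordered
    k1 >= k2 >= k3 (for a reduced two-phase fit the dropped phase has
    zero amplitude and a NaN rate). ``k_wa`` is (B k2 + C k3)/N_T.
    """

    peptide_id: str
    state: str
    temperature_c: float
    replicate: int
    n_t: float
    a: float = np.nan
    b: float = np.nan
    c: float = np.nan
    n_ne: float = np.nan
    k1: float = np.nan
    k2: float = np.nan
    k3: float = np.nan
    sse: float = np.nan
    converged: bool = False
    reduced: bool = False
    k_wa: float = np.nan
    warnings: list[str] = field(default_factory=list)

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + 273.15


def weighted_rate(b: float, k2: float, c: float, k3: float, n_t: float) -> float:
    """Weighted-average rate constant (B k2 + C k3)/N_T, per minute.

    The amplitude-weighted mean of the intermediate and slow phase
    rates; the burst phase is excluded by construction.
    """
    return (b * k2 + c * k3) / n_t


def _residuals(params, t_min, y, n_phases):
    amp = params[:n_phases]
    k = params[n_phases:]
    return triexp_uptake(t_min, amp, k) - y


def _jacobian(params, t_min, y, n_phases):
    amp = params[:n_phases]
    k = params[n_phases:]
    t = t_min[:, None]
    decay = np.exp(np.clip(-k * t, -700.0, 700.0))     # (T, P)
    jac = np.empty((t_min.size, 2 * n_phases))
    jac[:, :n_phases] = 1.0 - decay
    jac[:, n_phases:] = amp * t * decay
    return jac


def _lm_fit(t_min, y, amp0, k0):
    x0 = np.concatenate([amp0, k0])
    n_phases = len(amp0)
    try:
        res = least_squares(
            _residuals, x0, jac=_jacobian, args=(t_min, y, n_phases), method="lm",
            max_nfev=150 * x0.size,
        )
    except Exception:  # LM can raise on wild parameter excursions
        return None
    if not res.success or not np.all(np.isfinite(res.x)):
        return None
    if np.any(res.x[n_phases:] <= 0):
        return None  # nonphysical rate; caller restarts
    return res


#: Phase-class boundaries: geometric means of adjacent protocol start rates.
_PHASE_BOUNDARIES = (
    float(np.sqrt(INITIAL_RATES[0] * INITIAL_RATES[1])),  # burst / intermediate
    float(np.sqrt(INITIAL_RATES[1] * INITIAL_RATES[2])),  # intermediate / slow
)


def _slot_two_phases(amp2, k2_):
    """Assign a reduced two-phase fit to the (fast, intermediate, slow) slots.

    Each surviving rate is classified against the protocol-derived
    boundaries so a rate that is really a burst is never mistaken for
    the intermediate phase (which would corrupt k_WA); a collision
    pushes the slower rate one slot down (or the faster one up).
    """
    b12, b23 = _PHASE_BOUNDARIES

    def slot_of(rate):
        return 0 if rate >= b12 else 1 if rate >= b23 else 2

    s_fast, s_slow = slot_of(k2_[0]), slot_of(k2_[1])
    if s_fast == s_slow:
        if s_fast == 0:
            s_slow = 1
        elif s_slow == 2:
            s_fast = 1
        else:
            s_fast, s_slow = 1, 2
    amp = np.zeros(3)
    k = np.full(3, np.nan)
    amp[[s_fast, s_slow]] = amp2
    k[[s_fast, s_slow]] = k2_
    return amp, k


def fit_triexponential(
    curve: UptakeCurve,
    n_t: float,
    seed: int = 0,
    max_restarts: int = 5,
    min_attempts: int = 2,
    neg_amp_fraction: float = NEG_AMP_FRACTION,
) -> TriexpFit:
    """Fit the three-exponential uptake model to one curve.

    Unbounded Levenberg–Marquardt least squares from the standard
    initial guess; the rate starts are jittered by seeded factors in
    [1/3, 3] for up to ``max_restarts`` additional attempts, at least
    ``min_attempts`` starts are always tried (multi-start damps the
    occasional poor local minimum near the protocol start), and the
    best physically admissible solution by SSE wins. Post-fit the phases are
    relabelled in decreasing-rate order; an amplitude below
    ``-neg_amp_fraction * N_T`` triggers a reduced two-exponential
    refit, smaller negative amplitudes are zeroed. Curves with no
    signal, too few points, or exhausted restarts come back with
    ``converged=False`` and are excluded downstream.
    """
    fit = TriexpFit(
        peptide_id=curve.peptide_id, state=curve.state,
        temperature_c=curve.temperature_c, replicate=curve.replicate, n_t=float(n_t),
    )
    t_min = curve.times_s / 60.0
    y = curve.deuterons
    if t_min.size < 8:
        fit.warnings.append("fewer than 8 time points")
        return fit
    if np.allclose(y, 0.0):
        fit.warnings.append("no exchange signal (all deuterons zero)")
        return fit

    guess = default_initial_guess(n_t)
    amp0 = np.array([guess["A"], guess["B"], guess["C"]])
    k_base = np.array(INITIAL_RATES)
    neg_floor = -neg_amp_fraction * n_t

    def physical(amp_vec):
        return np.all(amp_vec >= neg_floor) and (n_t - amp_vec.sum()) >= neg_floor

    # Protocol start first; restarts explore when it fails or lands in an
    # unphysical local minimum (negative amplitude / strongly negative N_NE).
    rng = np.random.default_rng(seed)
    best = None           # lowest SSE overall
    best_physical = None  # lowest SSE among physically admissible solutions
    for attempt in range(max_restarts + 1):
        k0 = k_base if attempt == 0 else k_base * np.exp(rng.uniform(-np.log(3), np.log(3), 3))
        res = _lm_fit(t_min, y, amp0, k0)
        if res is None:
            continue
        sse = float(2 * res.cost)
        if best is None or sse < best[0]:
            best = (sse, res.x)
        if physical(res.x[:3]) and (best_physical is None or sse < best_physical[0]):
            best_physical = (sse, res.x)
        if attempt + 1 >= min_attempts and best_physical is not None:
            break  # admissible solution in hand after the required attempts
    if best is None:
        fit.warnings.append(f"no convergence after {max_restarts} restarts")
        return fit
    if best_physical is not None:
        if best_physical is not best:
            fit.warnings.append("restart chosen over lower-SSE unphysical solution")
        sse, x = best_physical
    else:
        sse, x = best

    amp, k = x[:3], x[3:]
    order = np.argsort(-k)  # relabel so k1 >= k2 >= k3
    amp, k = amp[order], k[order]

    # Validate amplitudes: zero the slightly negative, reduce on the strongly
    # negative (including the baseline N_NE degenerating via k3 -> 0).
    n_ne_raw = n_t - amp.sum()
    if np.any(amp < neg_floor) or n_ne_raw < neg_floor:
        if np.min(amp) < n_ne_raw:
            drop = int(np.argmin(amp))
            fit.warnings.append(
                f"amplitude {amp[drop]:.3g} < {neg_floor:.3g}: refit without phase {drop + 1}"
            )
        else:
            drop = 2  # N_NE collinear with a vanishing slow phase: drop it
            fit.warnings.append(
                f"N_NE {n_ne_raw:.3g} < {neg_floor:.3g}: refit without the slow phase"
            )
        keep = [i for i in range(3) if i != drop]
        fit.reduced = True
        res = _lm_fit(t_min, y, np.maximum(amp[keep], 0.0), k[keep])
        if res is None:
            fit.warnings.append("reduced refit failed")
            return fit
        sse = float(2 * res.cost)
        amp2, k2_ = res.x[:2], res.x[2:]
        order = np.argsort(-k2_)
        amp2, k2_ = amp2[order], k2_[order]
        amp, k = _slot_two_phases(amp2, k2_)
    small_neg = (amp < 0) & (amp >= neg_floor)
    if np.any(small_neg):
        fit.warnings.append("zeroed slightly negative amplitude(s)")
        amp = np.where(small_neg, 0.0, amp)

    n_ne = n_t - float(np.sum(amp))
    if n_ne < neg_floor:
        fit.warnings.append(f"N_NE={n_ne:.3g} strongly negative")
    n_ne = max(n_ne, 0.0)

    with np.errstate(invalid="ignore"):
        if np.isfinite(k[1]) and np.isfinite(k[2]) and k[2] > 0 and k[1] / k[2] < COLLINEARITY_RATIO:
            fit.warnings.append(f"intermediate/slow rates nearly collinear (k2/k3={k[1] / k[2]:.2f})")

    fit.a, fit.b, fit.c = (float(v) for v in amp)
    fit.k1, fit.k2, fit.k3 = (float(v) for v in k)
    fit.n_ne = float(n_ne)
    fit.sse = float(sse)
    fit.converged = True
    b = fit.b if np.isfinite(fit.k2) else 0.0
    c = fit.c if np.isfinite(fit.k3) else 0.0
    fit.k_wa = weighted_rate(b, np.nan_to_num(fit.k2), c, np.nan_to_num(fit.k3), n_t)
    return fit


def average_replicates(fits: list[TriexpFit]) -> pd.DataFrame:
    """Average replicate k_WA values per (peptide, state, temperature).

    Only converged fits contribute. Returns one row per group with the
    mean, the between-replicate standard deviation (NaN for a single
    replicate), the replicate count, and the individual replicate
    values (dict replicate -> k_WA) for error propagation downstream.
    """
    rows = []
    keyfn = lambda f: (f.peptide_id, f.state, f.temperature_c)
    groups: dict[tuple, list[TriexpFit]] = {}
    for f in fits:
        groups.setdefault(keyfn(f), []).append(f)
    for (pid, state, temp), grp in sorted(groups.items()):
        ok = [f for f in grp if f.converged]
        if len(ok) < len(grp):
            logger.info(
                "%s/%s/%g C: %d of %d replicate fits unusable",
                pid, state, temp, len(grp) - len(ok), len(grp),
            )
        if not ok:
            continue
        vals = np.array([f.k_wa for f in ok])
        rows.append(
            {
                "peptide_id": pid,
                "state": state,
                "temperature_C": temp,
                "k_wa": float(vals.mean()),
                "k_wa_sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "n_replicates": len(vals),
                "replicate_k_wa": {f.replicate: f.k_wa for f in ok},
                "any_flagged": len(ok) < len(grp),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peptide_id", "state", "temperature_C", "k_wa", "k_wa_sd",
            "n_replicates", "replicate_k_wa", "any_flagged",
        ],
    )


def average_uptake_curves(curves: list[UptakeCurve]) -> list[UptakeCurve]:
    """Average replicate curves point-wise (alternative to per-replicate fits).

    All replicates of a (peptide, state, temperature) group must share
    the same time grid. The returned curves carry replicate id -1.
    """
    groups: dict[tuple, list[UptakeCurve]] = {}
    for c in curves:
        groups.setdefault((c.peptide_id, c.state, c.temperature_c), []).append(c)
    out = []
    for (pid, state, temp), grp in sorted(groups.items()):
        t0 = grp[0].times_s
        for c in grp[1:]:
            if not np.array_equal(c.times_s, t0):
                raise ValueError(f"{pid}/{state}/{temp} C: replicate time grids differ")
        mean = np.mean([c.deuterons for c in grp], axis=0)
        out.append(UptakeCurve(pid, state, temp, -1, t0.copy(), mean))
    return out
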