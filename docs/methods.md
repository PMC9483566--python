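# Methods

## The measurement and the model

Backbone amide hydrogens exchange with solvent deuterium only from
transiently open (exchange-competent) conformations. In the EX-2 limit
— reclosing much faster than intrinsic chemistry — the observed rate
for an amide is K_op · k_int, so exchange kinetics report on the local
opening equilibrium. Measured at several temperatures, the apparent
activation energy of exchange (Ea_HDX) reports on the enthalpic barrier
of the underlying opening motions, peptide by peptide.

A pepsin peptide's deuteron-uptake time course is modelled with three
kinetic classes of amides plus a non-exchanging tail:

    y(t) = N_T − A e^(−k1 t) − B e^(−k2 t) − C e^(−k3 t) − N_NE

with A + B + C + N_NE = N_T. `tdhdx` imposes the sum constraint exactly
by eliminating N_NE, fitting

    y(t) = A(1 − e^(−k1 t)) + B(1 − e^(−k2 t)) + C(1 − e^(−k3 t)),

so y(0) = 0 holds by construction. Fits are unbounded
Levenberg–Marquardt least squares (plain, unweighted loss) from the
standard protocol start — rates (2.5, 0.5, 0.01) min⁻¹, all amplitudes
0.25 N_T — with times converted to minutes. The downstream statistic is
the weighted-average rate constant

    k_WA = (B k2 + C k3) / N_T,

which excludes the burst phase A·k1: the burst completes before the
first sampled time point and carries no usable temperature dependence.

Per (peptide, state), k_WA values at the design temperatures
{10, 20, 25, 30, 40} °C are regressed as ln k_WA against 1/T (OLS), and
Ea = −slope·R with R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹.

## Post-fit validation and numerical choices

* **Restarts.** If the protocol start fails or lands in a physically
  inadmissible minimum (an amplitude, or the implied N_NE, below
  −0.05 N_T), up to five seeded restarts jitter the rate starts by
  factors in [1/3, 3]; the best admissible solution by SSE wins, the
  best overall is used only when no admissible one exists.
* **Phase labels.** Phases are relabelled so k1 ≥ k2 ≥ k3. Amplitudes
  slightly below zero (≥ −0.05 N_T) are zeroed; a strongly negative
  amplitude — or a strongly negative N_NE, the signature of the slow
  phase degenerating into a linear drift (k3 → 0 with huge C) —
  triggers a reduced two-exponential refit. Reduced-fit phases are
  slotted as burst/intermediate/slow against boundaries at the
  geometric means of adjacent protocol start rates (≈1.12 and
  ≈0.071 min⁻¹), so a surviving burst is never mistaken for the
  intermediate phase (which would corrupt k_WA).
* **Collinearity.** A warning is emitted when fitted k2/k3 < 3.
* **Replicates.** Replicates are fitted separately and their k_WA
  values averaged (an option to average uptake curves before fitting
  exists). The reported se(Ea) is the OLS slope standard error combined
  in quadrature with the standard deviation of per-replicate Ea
  estimates — the spread itself, not the standard error of its mean:
  with two replicates the 1-degree-of-freedom estimate is noisy and the
  conservative convention is deliberate.
* **Anomalous top temperature.** At the highest temperature a peptide's
  intermediate phase can outrun the sampled window, depressing k_WA
  below the Arrhenius trend. The rule: regress the remaining points,
  and exclude the top temperature when its ln k_WA falls below the
  prediction by more than 2× the reduced fit's residual sd *and* by at
  least 0.2 ln-units. The absolute floor matters because the reduced
  fit keeps only ~2 residual degrees of freedom, so its residual sd
  estimate collapses randomly and the relative threshold alone trips on
  ordinary scatter; a genuine regime change (e.g. a halved rate,
  deficit ln 2 ≈ 0.69) clears both gates. Both fits are reported; the
  reduced one is primary.
* **Indeterminacy.** A result is indeterminate when fewer than three
  usable temperatures remain or se(Ea) ≥ |Ea|; indeterminate peptides
  are excluded from network classification.
* **Back-exchange.** Corrected multiplicatively, D/(1 − f_BE), the
  standard fractional-recovery model; the correction exactly inverts
  the generator's attenuation in the noise-free limit.
* **Amide counting.** Default convention: the N-terminal residue and
  all prolines after position 1 carry no countable amide, N_T =
  (len − 1) − #Pro(2..end). A `literal` option counts every non-proline
  residue. The convention is recorded in output metadata.

## State comparison and the thermal network

For states a, b of one peptide, ΔEa = Ea(b) − Ea(a) with σ =
√(se_a² + se_b²). Classification precedence: *control-eliminated*
(peptide in an explicit elimination list — responses shared with a
control mutant that slows turnover without changing the catalytic
barrier, hence not attributable to the thermal network), then
*indeterminate* (either input flagged), then *significant* iff
|ΔEa| > σ. The |ΔEa| > σ rule reproduces every significance call in the
published adenosine-deaminase tables shipped under `tdhdx/data/`
(3 inhibitor-vs-substrate-analog peptides; 7 apo-network and 5
inhibitor-bound-network peptides after eliminating 167-179, 201-229 and
301-320). Because all pairwise differences derive from one Ea per
state, the three-pair closure ΔEa(c−b) − [ΔEa(c−a) − ΔEa(b−a)] is
identically zero, and holds exactly in the published table as well.

Single-temperature comparisons average replicates per state, difference
the curves point-wise and sum the differences over the plateau
(t ≥ 600 s); beyond a threshold (default 1 deuteron) the peptide is
called protected or deprotected. This readout mixes binding-free-energy
and flexibility contributions and is reported separately from ΔEa.

## The synthetic scenario: what it emulates, and how it was designed

The generator runs the model forwards: per-peptide amplitude splits,
per-minute reference rates at 298.15 K, phase barriers Ea2 and
Ea3 = Ea2 + 4 kcal/mol (slow-exchanging amides sit behind somewhat
larger opening barriers; the gap also gives the Arrhenius plots the
mild convexity real weighted-rate data show), a temperature-insensitive
burst (k1 = 20 min⁻¹, complete before the first sampled point), state
offsets added equally to both phase barriers, multiplicative
back-exchange attenuation, and additive Gaussian replicate noise
(sd 0.15 deuterons) at every t > 0 — the t = 0 point is the
undeuterated reference and stays exactly zero. Because offsets shift
both barriers equally, the true between-state ΔEa equals the offset
difference exactly. The emitted "true" Ea is the OLS projection of the
noise-free ln k_WA over the design temperatures — precisely the
estimand of the downstream regression (with two Arrhenius phases,
ln k_WA is not exactly linear in 1/T, so no single closed-form Ea
exists).

The default scenario mirrors the adenosine-deaminase study design: 23
non-overlapping peptides at the study's residue spans (one span, 29-45,
fills the gap the published list leaves between 28 and 46), synthetic
sequences, peptide-specific back-exchange fractions in [0.10, 0.30],
14 time points (0–14400 s), five temperatures, two replicates, and five
states — apo and two ligand-bound forms of the wild type, plus a
function-altering mutant apo and inhibitor-bound. Ligand binding
stiffens most peptides (+5 to +5.5 kcal/mol), loosens one active-site
flap analogue (201-229, −5 to −6), and the mutant softens a designated
seven-peptide network by −7 kcal/mol, the upper range of mutant effects
the field reports.

Scenario parameters were chosen for *identifiability under the stated
noise*, checked a priori against the Cramér–Rao bound for k_WA on this
time grid: with iid noise of 0.15 deuterons, one curve determines k_WA
to no better than ~10–20% (relative) for peptides with N_T ≥ 14, and
30–80% for N_T ≤ 10 — a floor set by the amplitude/rate trade-offs of
the four-phase model, not by the optimizer (the LM fitter measures
within ~20–30% of the bound). Per-state Ea is therefore determined to
~1 kcal/mol at best. Consequently: baseline barriers are drawn in
[8, 12] kcal/mol — and in [10.5, 12] for the network peptides, since a
peptide that loses 7 kcal/mol must have started high enough that the
softened barrier still clears the indeterminacy rule; rates are drawn
(k2 at 298 K in [0.10, 0.25] min⁻¹, k3 ≈ k2/7) so both measurable
phases stay resolvable across 10–40 °C on the fixed grid (in
particular k3·t_max ≳ 3 at 10 °C, keeping the slow phase clear of the
non-exchanging baseline); and the designated network comprises every
peptide with N_T ≥ 14 — the size at which the bound allows ~10% rate
precision and hence ~1 kcal/mol Ea precision — except the flap
analogue, which yields exactly seven peptides. Small peptides (down to
N_T = 4) remain in the map as realistic hard cases — their Ea errors
honestly reach several kcal/mol.

What the generator does **not** emulate: isotope envelopes or
spectral-level effects, EX-1 behaviour, correlated (curve-level)
replicate error, temperature-dependent back-exchange, or drift in the
burst phase. Passing tests therefore demonstrate correct inference
under the model's own assumptions, not robustness to every systematic
error of a real LC-MS workflow.

## Structure painting

Peptide values expand to residues (overlaps averaged — moot for the
non-overlapping default map); values land in the B-factor column
(%6.2f) of ATOM/HETATM records, all other bytes preserved, so painting
is idempotent. The column has no missing-value encoding: uncovered
residues are written as 0.00 and listed in a sidecar file. A
residue-number/value TSV is emitted for viewers that prefer attributes.

## Problem sizes

The shipped studies use the full study geometry: 23 peptides × 5
temperatures × 2 replicates per state. The recovery study runs 100
regressions; the classification power study repeats the two-state
end-to-end pipeline 50 times (~460 curve fits per repeat). A single
end-to-end run completes in seconds; the power study in minutes.

## Known limitations

* Absolute Ea values of the original study are not reproducible — its
  raw uptake tables are not machine-readable here; published-table
  arithmetic and synthetic recovery carry the validation instead.
* The |ΔEa| > σ rule with n = 2 replicates and five temperatures has
  limited power: per-state Ea errors near 1 kcal/mol put ~4 kcal/mol
  effects on small peptides below reliable detection, matching the
  indeterminate entries the original tables report.
* The same rule also has a high false-positive floor on duplicate
  designs: the replicate-spread term of σ carries a single degree of
  freedom, so when duplicates agree by chance σ collapses and truly
  unchanged peptides are flagged in roughly 15% of repeated synthetic
  runs — even though σ's *expected* value would imply ~8%. Significance
  calls from a single n = 2 experiment are a screening readout, not
  calibrated inference; three or more replicates, or a pooled variance
  model, would be needed for a ≤10% false-positive rate.
* The printed parenthetical errors of the published tables have
  unstated provenance; this package's σ is a declared convention
  (quadrature of OLS and replicate spread) and is never tuned to
  reproduce those printed values.
* No EX-1/EX-2 discrimination, no global multi-temperature fitting, no
  Eyring reparameterization.
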