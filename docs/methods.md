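# Methods

## The model

One divalent metal (Zn(II)) equilibrates among three kinds of pools:

* a **multi-site receptor** — a protein with `n` independent binding sites,
  each described by a conditional step dissociation constant; constants are
  stored weakest-first, so `site_kds[0]` (K_d1) belongs to the first metal
  ion to leave the fully loaded protein.  Sites are independent with fixed
  microscopic constants: no statistical factors and no cooperativity terms.
  The packaged `mt2_ref32` model carries the solution constants for human
  MT2 (one site at 2e-8 M, one at 1.1e-10 M, one at 3.6e-11 M, four at
  1.6e-12 M); `mt2_esi` and `mt1_esi` carry the all-picomolar
  ESI-MS-derived alternatives for model comparison.
* **competitor ligands** — chelators, probes, zinc-finger peptides or
  enzyme sites forming 1:1 or 1:2 metal:ligand complexes with a single
  conditional constant (M or M², e.g. K_d12 = [M][L]²/[ML₂] = 7.1e-13 M²
  for the chromogenic chelator PAR).  PAR is modelled as the 1:2 complex
  only; the 1:1 species is negligible at pH 7.4.  Ligand depletion counts
  `stoich` ligands per bound metal.
* a **free-ion pool**.

All constants are conditional (apparent) values at the stated pH (7.4
unless noted).  Protonation equilibria are never computed; for
low-molecular-weight ligands with mixed Zn_iH_jL_k speciation the
competitivity index CI (the -log10 of the apparent dissociation constant
of a hypothetical aggregate 1:1 complex ZnZ at stated total ligand) absorbs
them.  CI values are inputs, computed externally from literature
protonation constants; where a published CI range spans two ligand
concentrations, the higher concentration is assigned the higher CI (an
assumption — the pairing is not stated in the source data).

## Speciation solving

For trial free metal `m` every species is a closed form (Langmuir site
occupancies; free 1:1 ligand `L_tot/(1+m/Kd)`; free 1:2 ligand the stable
positive root of `2(m/Kd)L² + L = L_tot`).  The metal mass balance is
strictly increasing in `m`, so the equilibrium is unique; the root is
bracketed on log10(m) in [-20, log10(total metal)] and solved with Brent's
method (free Zn(II) in these systems spans ~1e-13..1e-7 M, and log-scale
bracketing is unconditionally convergent).  Default mass-balance tolerance
is 1e-9 relative; exceeding it raises a solver failure carrying the last
residual.  1:2 complex concentrations are evaluated from mass action
(`m L²/Kd`), not from the ligand-balance difference, which cancels
catastrophically when depletion is trace-level.  Degenerate inputs (zero
total metal, zero ligand) return exact zeros rather than errors.

The **pairwise exchange** model deliberately omits the free-metal pool:
it solves `x²/((D-x)(A-x)) = K_ex = Kd_donor/Kd_acceptor` for the
transferred concentration `x`, taking the unique root in (0, min(D, A)).
This is the formalism that relates only the loaded and once-depleted donor
species, and it reproduces the enzyme-inhibition arithmetic exactly
(61% residual activity for an equimolar 0.1 uM pairing of a -logKd 8.2
donor with a Kd 1.6e-8 M enzyme site).  The two routes agree whenever free
metal is below ~0.1% of total metal; tests assert this.  With an explicit
free pool the same 61% would map to a slightly weaker donor (~8.0), which
is why the two formalisms are kept separate and never mixed.

## Estimators

* **Step-wise**: with transferred metal `x`, the once-depleted protein is
  `x`, the loaded protein `R - x`, the free ligand `L_tot - stoich*x`
  (depletion-corrected; competitions run to ~235-fold excess where the
  correction is small but nonzero).  `K_d1 = Kd_comp * K_ex` with
  `K_ex = x² / ((R-x) L^stoich)`.  Valid in the single-event regime
  `0 < x < R`; outside it the estimator refuses rather than extrapolates.
* **Cooperative** (the simplified model under critique): all `n` sites
  identical, apo protein `x/n`, bulk constant
  `K_d(1..n)av = Kd_comp**n * K_ex_coop` in units M^n.  The per-ion
  reduction is the n-th root (equivalently -log divided by n): only the
  root form maps the M⁷-scale range 1e-78..1e-54 onto per-ion constants of
  1e-11..1e-8 M.  The literal "divide by n" arithmetic is exposed as a
  documented non-default option for comparison.  Computation is done in
  log10 space to avoid under/overflow on hypothetical-competitor grids.
* **CI-based**: Kd1 = 10^-CI * [depleted][ZnZ] / ([loaded][Z]); for a true
  1:1 competitor with CI = -log10(kd) it reduces exactly to the step-wise
  form.  Note the published per-ligand weakest-site values were obtained
  with full speciation software from replicate-level inputs that are not
  recoverable; the aggregate arithmetic here gives, e.g., ~8.2 for the ATP
  scenario where the full-speciation analysis reported 7.9 +/- 0.2.  Both
  numbers are documented; they are not reconciled.
* **Probe readout**: for a turn-on 1:1 probe calibrated by EDTA (Fmin) and
  excess metal (Fmax), `[M]free = Kd_probe (F - Fmin)/(Fmax - F)`.
  Published statements of this relation sometimes print the ratio
  inverted; only this orientation is consistent with the calibration
  procedure (see the saturation/underflow semantics: F <= Fmin reports
  zero free metal, F >= Fmax is indeterminate).
* **Isotherm fitting**: transferred equivalents vs -log10 free metal are
  fitted with a logistic `plateau / (1 + 10^(n(mid - x)))` (lmfit;
  midpoint initialised at the abscissa median, Hill slope bounded to
  [0.3, 5], plateau initialised at the maximum and optionally pinned).
  The inflection abscissa is the -logKd of the transferring site; a Hill
  slope above 1 signals overlapping transfer from more than one site.
* **Grid matching**: a scenario function predicts the observable for each
  member of a -logKd grid (default 7..12, step 0.1, mirroring the +/-0.1
  resolution such overlays support; the enzyme scenario uses 5.5..10);
  the SSE-minimising member is returned, ties break toward the weaker
  affinity, and best fits at a grid edge are flagged as boundary hits
  (affinity outside the resolvable window).

Every estimate carries a mandatory model tag (stepwise / cooperative /
ci_based / grid_matched), an inputs digest and replicate-SD uncertainty;
averaging across model tags is refused unless explicitly requested — the
step-wise and cooperative numbers answer different questions, and
conflating them is precisely the historical error the package quantifies.

## Synthetic data

Generators are pure functions of (ground truth, parameters, seed), with
defaults set to the experimental conditions of the corresponding assays:
1.7 uM protein with 5-400 uM chromogenic chelator (1 h traces, first-order
approach with tau = 300 s, consistent with plateaus complete within
30-60 min); 0.5 uM protein with 0.05-5 uM fluorescent probe; equimolar
0.1 uM enzyme incubations with four replicates; 5 uM zinc finger titrated
at 0.1-2.0 donor/acceptor ratios; 38 uM protein with 20-40 mM
low-molecular-weight ligand.  Noise is multiplicative Gaussian (default
sigma 2%, since spectroscopic readouts scale with concentration) plus an
additive floor of 0.1% of full scale; each dataset consumes a single
`numpy.random.default_rng(seed)` stream, so identical seeds give
byte-identical output.

Phenomenological layers and their limits:

* Kinetics are a single saturating exponential toward the speciation
  equilibrium; without a reducing agent a linear drift (default 15% of the
  equilibrium absorbance per hour) emulates oxidative signal rise.  Real
  oxidation chemistry, instrument drift and inner-filter effects are not
  modelled, so passing tests show correct equilibrium bookkeeping, not
  kinetic realism.
* Fluorescence intensities scale linearly with probe concentration with a
  60-fold turn-on between Fmin and Fmax (a typical aminofluorescein
  enhancement); F, Fmin and Fmax carry independent noise as in a real
  calibration.  Ternary protein-probe complexes are not modelled.
* The CD titration relaxes ellipticity from an apo baseline (-4 mdeg) to a
  holo level (-20 mdeg) with one time constant; the number of mobilisable
  donor sites is a parameter (1 reproduces the weakened-finger behaviour;
  2 lets a tight finger saturate at a donor/acceptor ratio of ~0.5).
* The SEC partition represents the ligand by its CI aggregate and the
  exchange model, so it inherits the no-free-pool assumption.

## Plateau detection

The plateau is the mean over the final window (default 300 s); a trace
counts as equilibrated when the least-squares slope over that window is
below a tolerance that adapts to the trace: three times the standard error
a slope estimate would have under the trace's own point-to-point noise
(estimated from the median absolute successive difference), plus a drift
allowance of 0.1% of full scale per window.  Consequence: a sustained
oxidative drift is detected reliably on clean traces, but a drift smaller
than the slope uncertainty of a noisy window cannot be distinguished from
equilibrium — the recovery pipelines therefore skip unreached traces
rather than trusting them.

## Parameter-recovery pipelines

The chromogenic route feeds plateau absorbances at the lowest competitor
concentrations (5-20 uM, the initial competition points least affected by
the second dissociation event) through Beer-Lambert inversion into the
step-wise estimator.  The fluorescent route converts each titration point
into free metal (probe readout) and *released* equivalents — probe-bound
plus free metal per protein, because at sub-micromolar probe a sizeable
share of the mobilised metal stays in the free pool and counting only the
probe complex biases the isotherm — then fits the logistic restricted to
the single-event window (released <= 0.95 eq) with the plateau pinned at
one equivalent.  On noiseless data both routes recover the generating
weakest-site constant within 0.05 log units; at 2% noise the median over
25 seeds stays within 0.1.

## Bias surface

For every cell of a competitor grid (affinity 1e-14..1e-6 M; totals from
5 uM — the experimental floor of the chromogenic competition — up to
10 mM) the *true* differentiated-site model is solved to equilibrium and
the transferred metal is analysed with the cooperative estimator, exactly
as a single-competition experiment would be.  The resulting naive
-logKd_av spans more than three log units and is monotone along both grid
axes while the generating model is fixed; in the weak-competitor limit at
the lowest concentration it approaches the weakest-site constant (within
0.4 log units).  The published table of averages mobilising 1-7 ions is
reproduced qualitatively (ordering and order of magnitude); exact cells
depend on competitor concentrations that are not stated and are not
asserted.

## Numerical choices and edge cases

* Root bracketing [-20, 0] log10 M; Brent tolerance near machine epsilon;
  residual verified against the requested tolerance after solving.
* If even 1e-20 M free metal overshoots the balance (vanishing totals),
  the free metal is taken as the total: binding is negligible there.
* Exchange quadratic solved via the numerically stable root `c/q`,
  continuous through K_ex = 1 (where the root is DA/(D+A)).
* Estimators work in log10 space; zero transfer and out-of-regime
  observations raise typed signals instead of returning values.
* Grid-match ties break toward weaker affinity; boundary hits warn.
* Clipping (activity to [0, 100], CD saturation to [0, 1]) always carries
  an out-of-range flag.

## Problem sizes

The test suite runs the solver-vs-oracle comparison on 1000 randomised
systems (up to 8 sites, up to 3 ligands), Monte-Carlo recovery on 25 seeds
per assay route, and a 17 x 12 bias grid; the whole suite completes in a
few seconds on one core.

## Known limitations

* Single metal only; no Cd/Cu competition, no ternary complexes, no
  kinetic (rate-constant) modelling of exchange.
* Independent-site receptor: no statistical factors, no site-site
  coupling; the ESI-MS constant sets are included for comparison but the
  gas-phase effects that produced them are outside the solution model.
* CI values are consumed, not derived; full Zn/H/ligand speciation of
  ATP/GSH/His is out of scope.
* The no-free-pool exchange model and the full speciation model disagree
  when free metal is non-negligible; both are exposed and the choice is
  explicit, never silent.
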