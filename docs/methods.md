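# Methods

This note documents the generative models, the statistical procedures, the
default parameters (with units and rationale), and the limits of what the
synthetic-data tests can show.

## Task and schedule generation

A session is `n_blocks = 10` blocks of 8 forced trials (4 per lever in a
shuffled order) followed by 4 free-choice trials: 120 trials. Surprise
outcomes are assigned with *exact* per-session counts,
`round(rate × trial count)` — 8 forced SWITCH (10%), 4 forced MORE (5%),
2 choice SWITCH (5%) — with positions drawn without replacement under the
seed. Exact counts make design quantities deterministic and testable;
per-trial Bernoulli draws would only add nuisance variance. Configurations
whose rates round to zero surprise trials are rejected as degenerate.

Event timing defaults: cue onset → lever extension 5 s, lever extension →
reward delivery 2 s (matching the registered 5-s cue and 2-s lever analysis
windows), reward → next cue 8 s. The inter-trial interval is not dictated
by the task structure; 8 s keeps adjacent-trial dopamine transients
(clearance time constant 1 s) from bleeding into the next trial's baseline
window.

## Value model

Each animal carries two value pairs per reinforcer:

* **learned predictions** `v_food, v_sucrose` — drive cue-evoked dopamine
  and softmax choice, and update only through experience by the
  Rescorla–Wagner rule `v ← v + α (m·u − v)` where `m` is the delivered
  magnitude (1 standard, 4 MORE) and `u` the current unit value;
* **intrinsic unit values** `u_food, u_sucrose` — the worth of consuming
  one standard reward in the current physiological state.

Selective satiation multiplies the sated reinforcer's `u` by
`devaluation_factor = 0.3`, reduces a multiplicative anticipatory gain
(`general_gain`, ×0.7), and by default boosts the *valued sucrose* unit
value ×1.4 after food satiation (the asymmetric contrast effect on the
sweet liquid; no analogous boost for food). Predictions `v` are left
untouched at session start. This split is the load-bearing design choice:
it is the only arrangement in which (i) the first devaluation-session trial
shows a *general*, not reinforcer-specific, reduction of cue dopamine,
(ii) the lever-period signal is already reinforcer-specific on that first
trial (it reads out `u`), (iii) cue dopamine separates by valuation within
the first session bin as `v` catches up, and (iv) receipt of the valued
reward carries a positive prediction error that shrinks linearly over the
session. A single value variable cannot produce (i) and (ii) together.

**Learning rate α = 0.1.** The within-session decline of the
valued-reward excess is approximately linear across five session bins only
if the prediction-error decay timescale spans the session (~50 experiences
of each reinforcer); α ≈ 0.3 collapses the effect into the first bin.

**Choice temperature β = 0.5** (softmax on `v_food − v_sucrose`). At
β = 0.25 a devalued-state value gap of ~1 unit saturates the softmax and
every simulated animal chooses the valued lever on every trial — zero
between-animal variance, which neither resembles the graded preference
shifts of real cohorts nor admits a t test. β = 0.5 yields devalued-state
food-choice fractions around 0.2 with realistic spread.

Forced-trial errors: base miss and wrong-lever probabilities of 0.02 each,
multiplied by 4 on devalued-option trials; lognormal response latencies
(median 0.5 s, log-sd 0.4, ×1.5 on devalued trials), clipped to precede
reward delivery.

## Dopamine forward model

Each event injects an impulse (nM), convolved with first-order clearance
(`τ = 1 s`, 10 Hz scan rate):

* cue: `amp_cue (50 nM/unit) × general_gain × v(available option)`;
* lever: `amp_lever (30) × general_gain × u(available option)`;
* reward: `amp_reward (50) × [max(δ,0) + 0.25·min(δ,0)]` with
  `δ = m·u(delivered) − v(expected)`. The 0.25 factor encodes the
  empirical asymmetry of voltammetric sensitivity to pauses/dips; it is
  configurable.

Gaussian trace noise (sd 2 nM) and a slow pH wander (sd 0.02 units)
complete the trace. Currents are an exact linear mixture of synthetic
Gaussian-peak voltammogram templates (dopamine 0.01 nA/nM oxidation peak at
+0.6 V on a 1000-sample −0.4 → +1.3 → −0.4 V triangular grid; pH 5 nA/unit;
optional drift shape) plus i.i.d. Gaussian current noise (default
0.02 nA). The templates are stand-ins that play only the linear-algebraic
role of measured electrochemistry — no adsorption kinetics, no
unsubtracted background, no electrode-to-electrode transfer.

## Chemometric extraction

`PrincipalComponentRegression` takes a calibration set (≥ 2 standards per
analyte, factorial dopamine × pH mixtures by default, generated *with*
measurement noise so the residual eigenvalue spectrum is informative).
Scans are not mean-centered by default, so exact mixtures of calibration
components are recovered exactly. Components are retained to a cumulative
variance floor of 99.5% (never fewer than the number of analytes); scores
map to concentrations by least squares. The per-scan Q statistic (residual
sum of squares outside the retained subspace) is thresholded by the
Jackson–Mudholkar approximation at α = 0.05; when the discarded spectrum
is numerically empty the threshold falls back to twice the worst
calibration residual. Flagged scans are reported and, by default, linearly
interpolated (keeping aligned-trace grids rectangular); `keep` and `nan`
policies are available. Component-count selection by Malinowski's F-test is
out of scope.

## Peri-event statistics

Alignment cuts a [−2 s, +5 s] window per event and subtracts each trial's
[−2, 0] s pre-event mean (the baseline window is a convention fixed here;
no published value dictates it). Missed, wrong-lever, and unrewarded trials
are excluded from dopamine analyses, with counts logged. Note that the
pre-reward baseline window overlaps the lever-period transient; window
means therefore carry an identity-dependent offset, which cancels in
within-identity contrasts (the binned dynamics use them) but adds variance
to cross-identity ones.

The time-point GLM fits, per animal, OLS of the trial × time matrix on a
constant plus {0,1}-coded regressors (reward design: MORE indicator,
reward-type food = 1, their product; cue design: reward-type indicator),
sweeping all timepoints through one normal-equation solve. Rank-deficient
animal designs (e.g. no MORE trials in a subset) are reported and skipped,
never silently dropped.

Group inference sign-flips the per-animal coefficient traces; with ≤ 12
animals all 2ⁿ flips are enumerated, so p-values are exact with resolution
2/2ⁿ (0.0078 at n = 8 — the corrected pointwise alpha of 0.001 used for
multi-comparison display is then unreachable at the group level, and
results report the resolution floor rather than pretending otherwise).
Within-animal tests shuffle trial labels; the default statistic is the
group mean difference (vectorised over permutations), with a rank-based
auROC statistic available whose p-values are invariant to monotone
transformations. Monte-Carlo p-values use the add-one convention
`p = (1 + b)/(1 + n_perm)`. The default guard requires
`n_perm ≥ 10/corrected_alpha`; an explicit `guard="resolve"` relaxes this
to the resolution bound for reduced-permutation runs, in which case
`n_perm` is chosen so that `alpha·(n_perm + 1)` is an integer (e.g. 2000),
making the realised pointwise rate exactly nominal. The multiple-comparison
correction is a fixed corrected pointwise alpha (0.001), not cluster-based.

auROC is computed from rank sums (ties count one half) and equals the
exhaustive pairwise comparison by construction; the scalar discrimination
index is the auROC of 5-s post-reward window means. Groups with fewer than
2 trials are computed but flagged low-n.

## Behavioral statistics

All t tests are two-tailed at alpha 0.05; zero-variance inputs return a
flagged degenerate result rather than an error. Repeated-measures ANOVA
delegates to statsmodels' `AnovaRM` (pure within designs) or pingouin's
`mixed_anova` (one within × one between); identical-valued tables
short-circuit to F = 0. Sphericity correction is unnecessary for the
two-level factors used here. The linear trend across ordered bins is a
polynomial contrast: per-subject bin means projected onto centered linear
weights and tested against zero (reported as F = t² with (1, n−1) df).
Latency summaries use arithmetic per-animal means of raw latencies.

## Problem sizes and determinism

Every stochastic step takes an explicit seed; a fixed configuration
reproduces byte-identical event logs. The verification suite uses: 1000
random instances for the auROC oracle; 100 seeds for SNR-20 PCR recovery
(RMSE < 5% of peak; measured ≈ 0.7%); 500 null simulations × 2000 label
shuffles for permutation calibration; 100 simulations for GLM coverage;
200 session pairs for the within-session dynamics; 8-animal cohorts for the
interaction sign flip and behavioral statistics. These sizes give
Monte-Carlo standard errors comfortably inside the asserted bands while
keeping a full run to a few minutes.

## What the synthetic tests do and do not show

The generator reproduces the *structure* of the experiment — trial
arithmetic, value dynamics, surprise contingencies, state-dependent
re-ordering of dopamine responses, realistic measurement noise — so
passing tests demonstrate that the analysis chain recovers known ground
truth under those conditions. They do not certify behavior on real
electrochemistry: measured voltammograms drift, electrodes differ in
sensitivity, background subtraction is imperfect, and dopamine kinetics
are not a clean exponential. No attempt is made to reproduce the original
subjects' specific test statistics, which depend on unavailable raw data.
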