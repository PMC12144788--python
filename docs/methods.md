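# Methods

This note records the models, estimators, numerical conventions and design
choices behind `lungturnover`, and what the synthetic-data tests do and do
not demonstrate about real cohorts.

## Data contract

A patient series couples a taxa × samples abundance matrix with strictly
increasing calendar dates, per-sample %FEV1 (percent of predicted; NaN for
missing), a BETR disease-state label per sample (B0 baseline pre-PEx, E
exacerbation ≤30 d before treatment, T treatment, R recovery ≤30 d after
treatment, B1 baseline post-PEx), and optional treatment start/end dates.
Columns are normalized to relative abundance at assembly; all-zero sample
columns are rejected at load. Presence means relative abundance strictly
greater than `presence_threshold` (default 0 — processed tables are assumed
denoised upstream, so any nonzero entry is a detection). Elapsed time is
computed from dates, with day 0 anchored at each patient's first sample.
Samples labelled T must fall inside the recorded treatment window; this is
validated, not repaired.

Missing %FEV1 values are kept for microbiota analyses and skipped — never
imputed — in lung-function computations, with differences bridged across the
gap. The two data streams are fitted separately throughout, so this
asymmetry is safe.

## Turnover estimation

The species–time relationship is built by moving-window accumulation: for
each window length L in 1..N, the number of distinct taxa present at least
once inside a window is averaged over all N−L+1 contiguous windows. The
power model S = c·T^w is fitted by OLS on natural logs; the slope is
base-invariant and c is recovered by back-transforming the intercept.
Diagnostics (R², F with (1, n−2) df, two-sided p) come from the standard
regression F-test.

Time axis: the default T is the ordinal window length. An elapsed-days mode
maps each L to the mean duration spanned by windows of that length plus one
mean inter-sample interval (so L = 1 carries a positive T, and a perfectly
even schedule reproduces the ordinal axis up to a constant factor, leaving w
unchanged). The ordinal default makes w insensitive to sampling jitter; one
fit is produced per patient despite uneven schedules, and w is
dimensionless either way.

Degenerate inputs: a curve with all richness values equal means "no
turnover" and is reported as w = 0, c = S, R² = 1 by convention with p = NaN
rather than raised as an error. Subsets with no detected members (e.g. a
patient with no chronic taxa) yield an explicit empty result, not a crash.

Two structural facts about this estimator are worth recording. First, mean
moving-window richness is non-decreasing in window length, so the fitted
w is never negative — local quadrat values included. Second, the statistic
is bounded above: because mean window richness can exceed proportionality
to window length only through interior-weighting effects, the log–log slope
over a 5-point quadrat cannot materially exceed 1 (numerical suprema over
adversarial richness profiles reach ≈1.07). Fine-scale w values far above 1
are therefore not producible by this construction; see "Onset detection"
for the consequence.

## Colonization classes and PAR

Persistence is computed over the whole series (n detected / n samples);
chronic means strictly greater than the 50% cutoff, so a taxon present in
exactly half the samples is intermittent. Labels are fixed per patient and
reused unchanged by every subset analysis — fine-scale windows never
relabel. The PAR is OLS of log10 mean relative abundance (over detected
samples only) on the untransformed persistence fraction; abundance spans
orders of magnitude while persistence is bounded in (0, 1], which motivates
logging only the former. A `par_log_persistence` switch fits log10
persistence instead for sensitivity analyses. PAR fitting requires at least
3 profiled taxa and non-constant persistence.

## Lung function

Cumulative absolute Δ%FEV1 is accumulated over consecutive non-missing
values and fitted as a·T^b with T in days from the first usable timepoint.
Points with zero elapsed time or zero cumulative change are excluded from
the log–log fit (log undefined); a completely flat curve short-circuits to
the degenerate b = 0 convention, and fewer than 3 usable points yields an
explicit "insufficient" result. b is a pure shape statistic — rescaling the
curve leaves it unchanged — which matters when interpreting it: its
log–log OLS estimate at ~20 visits carries irreducible sampling noise
(standard deviation ≈ 0.4 in simulation) dominated by the leverage of the
earliest positive points and by event-timing jitter.

## Fine scale and onset detection

A quadrat of `quadrat_size` consecutive timepoints (default 5, minimum 3)
slides one timepoint at a time; inside each quadrat the same moving-window
accumulation runs on the whole-microbiota presence matrix restricted to
those samples, and the 5 sub-length points are fitted on the ordinal axis.
w_local is plotted at the quadrat's middle timepoint (third of five) with
that sample's date and disease state. b_local is computed from the
quadrat's %FEV1 values only when at least 3 strictly positive
cumulative-change points exist, else recorded absent. The whole-series w is
not the mean of w_local values; the two are related only qualitatively.

Onset is the first quadrat midpoint, scanned in date order up to treatment
start (the whole series for untreated patients), with w_local strictly
above the threshold. Lead time = treatment start − crossing date, in whole
days; crossings without a recorded treatment are flagged censored, and a
first crossing after treatment start is reported as a late-crossing
diagnostic but never yields a lead. A configurable sustained-run variant
(`sustained_windows` = k) requires k consecutive exceedances and dates the
crossing at the first of the run; the default k = 1 matches the
single-departure reading. Lead time is monotone non-increasing in the
threshold by construction.

Default thresholds are 0.5 (the cross-ecosystem norm that turnover
exponents rarely exceed) and 1.0 (a conservative variant discounting small
departures). Under the ordinal quadrat fit the 1.0 threshold is effectively
unreachable — the estimator's ≈1.07 ceiling sits just above it, and
simulated exacerbation bursts peak near 0.7 — so conservative detection
must rely on the 0.5 threshold plus the sustained-run option. The
alternative that makes w_local ≫ 1 attainable (fitting against absolute
days since the series start) was evaluated and rejected: it is
non-stationary, inflating w for any late-series window regardless of
dynamics, which destroys specificity on stable patients. The thresholds
remain configurable for users who supply their own fine-scale statistic.

## Cohort statistics

Turnover exponents are compared across subsets with the tie-corrected
Kruskal–Wallis test (chi-square reference, k−1 df; identical pooled values
short-circuit to H = 0, p = 1) followed by Dunn's pairwise z tests on
pooled ranks with the tie correction Σ(t³−t)/(12(N−1)). The multiplicity
adjustment defaults to Bonferroni (configurable: none, bonferroni, holm) —
conservative, since the upstream literature reports only pairwise P values
without naming an adjustment. The lung-function rate b is regressed on w by
OLS with standard F diagnostics. All p-values are two-sided.

## Synthetic cohorts

The generator reproduces the cohort regime the analysis expects, with every
parameter overridable:

- **Cohort shape.** 12 patients, 2 of which never exacerbate. PEx patients:
  samples ~ N(22.2, 5.1) clipped to [16, 35] over N(315.9, 42.7) days
  clipped to [221, 368]. Non-PEx comparators are sparse — 6–9 samples over
  300–313 days — matching their role as stable controls. Visit days are a
  jittered near-regular grid (gamma-shape-8 intervals); an optional
  time-warp densifies visits inside E∪T (off by default).
- **Community.** A 12-taxon chronic core present i.i.d. with probability
  0.9 per sample (the dominant pathogen never absent), lognormal abundances
  with the dominant taxon ~17× the other core taxa; a 90-taxon satellite
  pool of which each patient can access a random 60–90 subset, with
  per-sample intermittent detection counts Poisson(λ), λ = 2.0 ± 30%
  per patient, recurrence allowed. These rates were fixed once, by
  closed-form expectation against the target regime (≈50 intermittent taxa
  per patient, chronic persistence above the Leeds cutoff, baseline
  whole-series w below 0.5) before the test suite existed.
- **Exacerbation.** Treatment starts at 45–65% of the series and lasts
  10–18 days; the exacerbation window opens 30 days before treatment and
  recovery closes 30 days after it. The immigration rate is multiplied by
  κ = 8 (±80% per patient) from the true onset — 21 days before treatment
  by default — until treatment end. Onset after treatment start is rejected
  as infeasible.
- **Lung function.** %FEV1 = patient baseline (N(50, 17) clipped to
  [22, 85]) + disease trend + observation noise (sd 0.3), recorded at 0.25
  resolution, 8% of visits missing. With coupling on, the trend declines
  0.5 %/day from onset and recovers 0.7 %/day under treatment, and each
  visit whose realized new-taxon count exceeds the patient's baseline rate
  by more than 3 is depressed by 1.2% per excess taxon — small colonization
  fluctuations leave lung function unmoved, large waves move it. With
  coupling off the trajectory is stationary noise, a true null for
  turnover/lung-function association tests.

Ground truth (onset day, per-patient rates, chronic set) is written to a
separate file the analysis path never reads. All randomness flows from one
cohort seed through spawned per-patient seeds, so output is byte-stable and
independent of patient ordering.

**What the synthetic tests show — and don't.** They demonstrate estimator
correctness (exact agreement with brute-force window enumeration,
closed-form limits, hand-computed rank statistics), ground-truth recovery
(injected 21-day onsets recovered within two mean sampling intervals at the
0.5 threshold; strict dose–response of w in κ), and the qualitative
orderings expected of exacerbating cohorts. They do not reproduce real
data's features beyond this: taxon abundances are compositionally
normalized but carry no sequencing noise, immigration is memoryless rather
than episodic, and %FEV1 noise is idealized. One consequence is calibrated
honesty about the b–w association: with iid spirometry noise the
across-patient correlation between two fitted exponents plateaus near 0.5,
so simulation can show the association's direction and its power advantage
over null cohorts, but not the near-deterministic R² ≈ 0.8 that real
cohorts can display — structure in real lung-function trajectories, not
reproducible from independent noise, carries that extra signal.

## Numerical conventions

- OLS fits via `scipy.stats.linregress`; F = t² on (1, n−2) df; p-values
  two-sided. Normal-equation oracles in the tests pin these to 1e-10.
- Power fits require strictly positive x and y and at least 3 points.
- Sample statistics use the n−1 denominator; SD of a single value is NaN.
- TSV outputs are written with `%.10g` floats; integer count tables
  round-trip bit-exactly. Run manifests record SHA-256 digests of all
  inputs and outputs, and fixed-seed reruns are digest-identical.
- Problem sizes in the test suite (patient counts, seed counts per
  property) are chosen to estimate each property's frequency with fixed
  seed sets, keeping results deterministic.

## Known limitations

- The ordinal quadrat fit bounds local w near 1; studies wanting the
  conservative w > 1 onset rule need a different local statistic.
- Detection at the 0.5 threshold dates onset at quadrat midpoints, so lead
  times are quantized by the sampling interval and biased upward by about
  one interval (a window's midpoint precedes its trailing burst samples).
- No mixed-effects or repeated-measures modelling; cohort-level inference
  treats per-patient exponents as independent observations.
- Readers accept the documented TSV/CSV/BIOM-JSON layouts only; externally
  deposited cohorts with other layouts need a one-off column mapping.
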