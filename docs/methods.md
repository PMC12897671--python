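# Methods

This note documents the statistical model behind `mirprobe`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions used where the procedure leaves room
for interpretation.

## Measurement model and quantification

qPCR reports a quantification cycle Cp per assay and sample; abundance is
proportional to 2^(−Cp), so every analysis step works on the Cp (log2)
scale. Relative quantification is the comparative-Cp method against the
control group:

    ΔCp[f, s] = Cp[f, s] − mean(Cp[f, HC samples])
    LR[f, s]  = −ΔCp[f, s]            # base-2 log ratio
    FC        = 2^LR                  # fold change

The sign convention LR = −ΔCp is forced by the chemistry: a later-amplifying
(higher-Cp) target is less abundant, so downregulated targets carry negative
log ratios and FC < 1. Regulation calls use strict thresholds (up iff
LR > 1, down iff LR < −1). Group logFC is the difference of group mean LRs,
i.e. the log of the geometric-mean fold change — the standard choice for
log-scale data; the log of the arithmetic-mean FC would be dominated by
single high-expressing samples.

Censored values (targets that hit the detection limit of 37 cycles) are by
default used *at* the limit rather than dropped (`censored_policy=
"use-at-limit"`). Near-threshold targets are exactly the ones that produce
the very large negative logFCs this kind of panel reports; dropping them
would silently delete the phenomenon. The alternative (`"drop"`) is
available for sensitivity analysis. A consequence worth knowing: group
effects larger than the headroom between a target's baseline and the limit
are attenuated by censoring, so recovered logFCs are a lower bound on the
planted magnitude.

Report tables round FC to 6 decimals, logFC to 2 and p to 3, matching the
conventional presentation of such panels.

## Sample quality control

Two rules, applied before any statistics, both strict (boundary values
pass):

* spike-in Cp > 37 for any of UniSp2/UniSp4 (RNA extraction) or UniSp6
  (cDNA synthesis) — poor yield;
* hemolysis delta Cp(miR-23a) − Cp(miR-451) > 7 — red-cell contamination
  (miR-451 is erythrocyte-enriched, so hemolysis lowers its Cp).

Failing samples are excluded outright. Missing control values count as
failures (a sample whose controls cannot be read cannot be vouched for).
The Cp > 37 rule is applied to the spike-in controls only, not to target
assays — target values at the limit are handled by the censoring policy
above, not discarded as samples.

## Wilcoxon testing

`wilcoxon_p` uses exact enumeration when the pooled sample is tie-free with
at most 12 values, otherwise the normal approximation with mid-rank tie
correction and continuity correction. All tests are two-sided. If every
pooled value is identical the test is uninformative and p = 1.

Inside the probe-selection loop, where hundreds of columns are ranked per
repeat, a vectorized asymptotic version ranks all columns in one pass. For
tie-free columns at a fixed fold size the asymptotic and exact p induce the
same ordering (both are monotone in |U − n1·n2/2|), so the ranking — the
only thing the selection consumes — is unaffected by the approximation.

Because the group sizes are small, the attainable significance level of the
α = 0.05 test is below 5% (the null distribution is discrete): about 4.6%
at 6 vs 13, 3.5% at 7 vs 6. The calibration tests compare the empirical
rejection rate against the exactly enumerated level rather than against a
nominal 5%.

The DE table reports the raw p as the primary quantity (tested at
α = 0.05), with a Benjamini–Hochberg column included as a clearly
supplementary adjustment — the table mirrors exploratory panels that do not
correct, and the BH column is there for honesty.

## Permutation-probe stability selection

Per repeat: 50 probe variables are built by drawing a source feature
uniformly **with replacement** and permuting its sample values (destroying
any association with the outcome while preserving the marginal
distribution). Originals and probes are jointly ranked by two-sided
Wilcoxon p ascending, ties broken by name for determinism. The selection
keeps the **largest** prefix length k whose probe:original ratio is ≤ 0.1
with at least one original — even when smaller prefixes transiently violate
the bound; the ratio bounds the expected fraction of null features among the
kept originals. Repeating over 100 seeds (counter-derived from the base
seed, so repeat r of run s is always identical) yields per-feature selection
frequencies; features at frequency ≥ 0.45 are retained, and ≥ 0.70 marks
the high-stability tier.

An important property, visible in both simulation and the motivating
application: on a *fixed* dataset the repeats re-randomize only the probes,
so the by-chance best-ranked originals of a null dataset beat all 50 fresh
probes in most repeats and acquire high "stability". Stability here
measures robustness of the ranking to probe randomness, not evidence of
signal — which is precisely why the nested cross-validated AUC, not the
retained set, is the pipeline's measure of predictive value (null data
yields a handful of confidently retained features *and* chance-level AUC).
An optional `bootstrap_subjects` mode additionally resamples subjects per
repeat, giving a stability notion that also reflects sampling variability.

The near-zero-variance prefilter removes constant features and those with
(top count / runner-up count) ≥ 19 and unique-value fraction ≤ 10% — the
dominant convention of the established preprocessing frameworks (19 ≈
95/5). On continuous Cp data it mainly removes all-censored rows, which
become constant at the limit.

When stability retains nothing inside a training fold, the evaluation falls
back to the single top-ranked original (silently empty folds would bias the
AUC); the fallback is logged and flagged in the fold record.

## Nested LOOCV evaluation

The outer loop is leave-one-out. Within each training fold, independently:
NZV filter → probe stability selection → centering/scaling with train-fold
statistics (sd with ddof = 1; constant columns map to 0 and are flagged) →
inner-LOOCV hyperparameter tuning → final fit; the held-out sample is then
scored. The held-out sample influences nothing — this is asserted by a
mutation test (perturbing the held-out sample leaves the fold's selections,
scaling statistics and chosen hyperparameters bit-identical).

Model families and grids (config-overridable):

| family | grid | score |
|---|---|---|
| elastic-net logistic (saga) | l1_ratio 0.1–1.0 step 0.1 × C log-grid | P(class 1) |
| linear SVM | cost 2⁻⁵ … 2⁵ | signed decision value |
| random forest, 500 trees | variables/split ∈ {1, √p, p/3} | P(class 1) |

The SVM uses the decision value because Platt probability calibration is
unstable at ~18 training samples. Inner tuning computes leave-one-out
predictions per grid point over the training fold and maximizes the AUC of
the *aggregated* inner predictions (a per-fold AUC is undefined with one
held-out sample). Ties resolve to the most regularized point (smallest C /
smallest cost / fewest variables per split; for the elastic net, larger
l1_ratio breaks remaining ties toward sparser models). Grid points that
resolve to identical fitted models — e.g. every variables-per-split choice
collapses to 1 when only one or two features survive selection — are
deduplicated before tuning, and a single-point grid skips the inner loop
entirely.

The outer AUC is the Mann–Whitney form, P(score⁺ > score⁻) + ½P(equal).
Uncertainty is a percentile bootstrap over subjects (default 2000
replicates, 95% level; replicate count and level are conventions, not given
by the motivating study); one-class replicates are skipped, with a warning
if they exceed half.

All stochastic stages derive seeds from (global seed, fold index) via
counter-based seed sequences; the run manifest records every fold seed, and
fixed seeds reproduce every output byte-for-byte.

## Synthetic data generator

The generator emulates the structure the analysis assumes:

* 179 target assays over groups HC = 6 / LC = 7 / LC_BM = 6 (configurable);
* additive Cp model: baseline(feature) ~ U(20, 33) + per-sample technical
  shift N(0, 0.5²) + well noise N(0, 0.8²) + planted group effects in
  cycles; noise magnitudes are plausible for serum panels (sub-cycle
  technical noise, half-cycle sample-to-sample yield variation) — the
  motivating study publishes no measurement model, so these are the
  package's own defaults, overridable in config;
* right-censoring of target rows at the detection limit (37 cycles),
  recorded in a censoring mask, never dropped;
* control rows at fixed baselines (spike-ins tight; hemolysis pair set to a
  clean-serum delta of 3), reported *uncensored* so that the Cp > 37
  spike-in failure rule remains observable — censoring models the analytic
  floor of target quantification, not of the controls;
* fault injection: hemolysis (lower miR-451 by a chosen delta for one
  sample) and spike-in failure (controls pushed above the limit).

Random streams are derived per (seed, purpose), so adding an injection does
not perturb unrelated draws, and a fixed config+seed is bit-reproducible.

What it does **not** emulate: amplification-efficiency differences between
assays, plate/batch layouts and inter-plate calibrators, correlated miRNA
co-regulation modules, missingness mechanisms other than censoring, and
storage/preanalytic drift. Consequently, passing tests demonstrate that the
*procedures* behave as specified under a clean additive model — they say
nothing about assay chemistry, and calibration results (e.g. null AUC bands)
should be read as properties of the method at this sample geometry, not of
any real cohort.

## Evaluation sizes

The calibration and recovery suites run at deliberately chosen sizes: null
calibration uses 10 generator seeds at the cohort geometry with 25 selection
repeats per fold, a reduced hyperparameter grid density (3×3 elastic-net
points, 5 SVM costs) and 40-tree forests; signal recovery plants two
4-cycle effects at 20 samples per class with the full 100 selection
repeats. These sizes give stable averages while keeping the suites
desk-runnable; the acceptance script uses the same 10-seed prescription.
Reduced grids and tree counts affect per-fold score noise, not the location
of the null AUC distribution, which is what those checks measure.

## Known limitations

* LOOCV AUC at n = 19 is extremely variable (single-seed null AUCs range
  roughly 0.1–0.8); only seed-averaged values are meaningful, and the
  evaluation exists to demonstrate honesty of the protocol rather than
  statistical power.
* The comparative-Cp method assumes equal amplification efficiency across
  assays; no Pfaffl-style efficiency correction is implemented.
* With `use-at-limit` censoring, heavily censored features carry attenuated
  effect sizes; the censoring mask is propagated so downstream users can
  filter, but no Tobit-style censored model is fitted.
* The stability-selection retention threshold (0.45) sits below the 0.6–0.9
  range usually recommended for stability selection; it is kept as the
  motivating procedure's exploratory tier, with 0.70 marking the
  conventionally defensible tier.
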