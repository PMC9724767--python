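# Methods

This note documents the statistical model behind `episig`, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical conventions that make runs reproducible.

## The analysis model

The pipeline treats an episignature study as a two-group comparison on a
probes × samples matrix of methylation beta values, with three layers:

1. **Differential probes.** Statistics run on M-values,
   `M = log2(β/(1−β))` with β clamped into `[ε, 1−ε]` (default
   `ε = 0.01`), because beta-value variance collapses near 0 and 1 while
   M-values are approximately homoskedastic.  Effect sizes are always
   reported on the beta scale (`Δβ`), the scale on which biological and
   diagnostic relevance is judged.

   The per-probe test is an empirical-Bayes moderated t.  The prior
   `(d₀, s₀²)` is estimated by matching the first two moments of the log
   pooled variances to a scaled inverse-χ² model: under that model
   `s_g²/s₀² ~ F(d_g, d₀)`, so the mean and the excess variance of
   `log s_g²` (beyond the trigamma term explained by χ² sampling alone)
   identify `s₀²` and `d₀` through digamma/trigamma equations, solved by
   Newton iteration on the trigamma inverse.  When the observed
   log-variance dispersion does not exceed the sampling term, `d₀ = ∞`
   and the test reference becomes the standard normal.  Two degenerate
   conventions: exactly identical variances return `d₀ = ∞` with `s₀²`
   equal to the common value (there is no sampling dispersion to correct
   for), and a zero posterior variance with a nonzero mean difference
   yields `p = 0` with a warning rather than an exception.

2. **Selection and pruning.** BH-adjusted `p < α` (default 0.01) AND
   `|Δβ| ≥ 0.10`, ranked by `|t|·|Δβ|` (significance alone over-rewards
   low-variance probes with negligible effects; effect size alone ignores
   precision), ties broken lexicographically by probe id, capped at 1000.
   The ranked list is then greedily pruned so that every retained probe
   has `|r| < 0.90` (Pearson, beta scale, training samples) with all
   higher-ranked retained probes.

   Inside `derive_signature` the pruning correlation is computed after
   centering each probe **within** the case and control groups.  This is
   deliberate: across a mixed case/control set, any two genuinely
   differential probes correlate strongly through the group indicator
   itself — with a small, low-noise case group that correlation routinely
   exceeds 0.9, and raw-correlation pruning would discard roughly half of
   a true signature as "redundant".  Redundancy worth pruning is
   co-variation *beyond* the group effect (duplicated or co-regulated
   probes, which still correlate near 1 within groups).  The standalone
   `prune_correlated` function defaults to plain correlation and accepts
   the group labels explicitly.

3. **Embedding and classification.** Classical (Torgerson) MDS on
   pairwise Euclidean distances: deterministic, exactly recovers
   Euclidean-realizable configurations, and reduces to principal
   coordinates — there is no stress-optimization randomness to seed.
   Sign convention: the largest-magnitude entry of each coordinate column
   is positive.  Separation is summarized by silhouette coefficients on
   the embedding plus a centroid-distance/within-spread ratio.

   The classifier is a linear nu-SVM over the signature probes (beta
   scale).  A stratified 25% test split is held out; ν is chosen from
   {0.05, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50} by mean accuracy in
   stratified 5-fold cross-validation on the training portion, ties going
   to the smallest ν (the least aggressive margin-error budget).  Values
   of ν infeasible for the class balance (ν > 2·min(n₊,n₋)/n within a
   fold) are skipped with a warning.  Out-of-fold decision margins feed a
   Platt sigmoid `P = 1/(1+exp(A·f+B))` fit with Platt's smoothed
   targets, A constrained nonpositive so the score is monotone in the
   margin; perfectly separated training data therefore still yield
   finite, monotone calibration.  Scores are called in three bands —
   `< 0.25` control, `0.25–0.5` inconclusive (both boundaries
   inconclusive), `> 0.5` pathogenic.

Control selection is greedy per-case nearest-age matching without
replacement, exact on sex by default, at a configurable ratio (default 3
controls per case); ties are broken by a seeded shuffle and the match
table (case, control, age gap) is part of the output, so the matching is
auditable.  Greedy matching is transparent and reproducible; optimal
assignment would change the selected set only in pathological pools.

## Synthetic cohorts

`simulate_cohort` generates the study geometry the pipeline targets:
a small case group (default 8), a healthy-control pool for matching
(default 200), a background cohort of unaffected and other-disorder
samples (default 270), and optionally a second case group carrying a
*disjoint* planted signature for two-signature experiments.

Per probe, a baseline mean is drawn from a three-component mixture of
mostly-unmethylated (~0.1), intermediate (~0.5) and mostly-methylated
(~0.9) betas with weights (0.35, 0.30, 0.35) and Gaussian jitter
(sd 0.04), resembling the bimodal-with-shoulder distribution of array
data.  Sample values are the logistic transform of
`mean + effects + N(0, noise_sd)` on the log2-logit scale
(default noise 0.4), which keeps betas in range and reproduces the
heteroskedastic beta-value variance near the boundaries.

The planted case effect is specified as a target beta-scale mean
difference (default 0.2 over 175 of 20,000 probes) and solved on the
logit scale per probe; the shift direction is randomized per probe and
flipped when the shifted mean would leave the representable range, so
planted probes are a mixture of hyper- and hypomethylated, as in real
episignatures, and the achievable |Δβ| is preserved (shortfalls beyond a
0.02 tolerance are recorded as warnings in the ground truth).

Nuisance structure, applied to all samples on designated probe subsets:
linear age drift (default 1000 probes at 0.02 logit units/year, centered
at mid-range of the 10–80y age span), a sex effect (500 probes,
+2.0 logit units in females — the scale of X-inactivation-linked probes),
and a two-batch shift (500 probes, 0.25 logit units).  Nuisance counts
cap at the probe count so scaled-down cohorts remain valid.  All values
are artifact choices: the source data's distributional facts beyond the
cohort counts are not public.

What the generator does **not** emulate: probe cross-reactivity,
SNP-under-probe artifacts, cell-type composition differences, spatial/
chip effects, or a real EPIC manifest.  Passing recovery tests therefore
demonstrate that the pipeline's inference machinery is correct under its
own statistical assumptions, not that those assumptions capture every
failure mode of real arrays.

## Numerical and reproducibility conventions

* One `SeedSequence` per simulation, spawning child streams in a fixed
  order (probes, samples, planted effects, noise): identical configs and
  seeds give bit-identical cohorts regardless of call order.
* All pipeline outputs (TSV/JSON) avoid timestamps and use sorted JSON
  keys and fixed float formatting, so identical config + seed reruns are
  byte-identical; every report embeds the seed and a config hash.
* Median imputation of missing betas uses control samples only, so case
  signal never leaks into imputed values.
* QC (missing-fraction > 5%, zero-variance, optional X/Y removal) is
  idempotent and never drops samples.
* Empty signatures are a reported outcome, not an error: a null cohort
  should produce one.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale, chosen so
the full suite completes in a few minutes on one CPU while preserving the
statistical geometry: signature recovery at 20,000 probes / 175 planted /
8 cases vs 24 matched controls; null-safety over 100 cohorts at 5,000
probes; classification with 40 training carriers, 20 disjoint-signature
carriers and 200 controls at 10,000 probes.  Unit fixtures use 1,200–3,000
probes with nuisance probe counts scaled proportionally.

## Known limitations

* The two-group contrast has no covariate design matrix; age and sex are
  handled by matching, and unmatched confounding would surface as false
  probes (the null-safety check covers only the matched design).
* Greedy matching and greedy pruning are order-dependent heuristics;
  both are deterministic and auditable but not globally optimal.
* Platt calibration is fit on out-of-fold margins of the selected ν
  only; scores are calibrated relative to the training cohort's class
  balance and are not population probabilities.
* The prior fit assumes the scaled inverse-χ² variance model; heavy
  contamination of the variance distribution (not simulated here) would
  call for a robustified fit.
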