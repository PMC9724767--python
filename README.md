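# episig

Derivation and classification of DNA-methylation **episignatures** — the
reproducible sets of differentially methylated CpG probes that
characterise carriers of variants in a given disease gene and can be used
as a diagnostic classifier.

The package is aimed at the common diagnostic situation in rare-disease
epigenomics: a handful of cases carrying variants of uncertain
significance, an in-house database of healthy controls and other-disorder
samples profiled on an Infinium-style methylation array, and an
established reference episignature for the early-onset form of the
disease.  Two questions follow:

* **Stage A** — do the new cases match the *established* episignature?
  (scored by a trained classifier and by where the cases fall in an MDS
  embedding of the reference cohorts)
* **Stage B** — do the new cases share a *distinct* methylation pattern
  of their own?  (differential probes vs age/sex-matched controls,
  validated by MDS against the background cohort)

Because real patient methylation data of this kind are access-restricted,
the package ships a first-class synthetic-cohort generator that plants
known probe signatures plus age, sex and batch nuisance structure, so the
whole pipeline is testable end to end against a known ground truth.

## Methods at a glance

* Beta values `β ∈ [0,1]` are converted to M-values
  `M = log2(β / (1−β))` for testing; effect sizes are reported as
  `Δβ = mean(β_case) − mean(β_control)`.
* Per-probe **moderated t**: the pooled variance `s_g²` (df
  `d_g = n₁+n₂−2`) is shrunk toward an empirical-Bayes prior
  `(d₀, s₀²)` fit by moment-matching log variances to a scaled
  inverse-χ² distribution:
  `s̃² = (d₀s₀² + d_g s_g²)/(d₀ + d_g)`,
  `t = Δx̄ / (s̃ √(1/n₁ + 1/n₂))`, p from t on `d₀+d_g` df.
* Benjamini–Hochberg FDR control, then selection at `p_adj < 0.01` and
  `|Δβ| ≥ 0.10`, ranking by `|t|·|Δβ|`, and greedy correlation pruning
  (`|r| < 0.90`, within-group centered) to an *independent* probe set.
* **Classical MDS** (Torgerson principal coordinates) on pairwise
  Euclidean distances between samples over the signature probes, with
  silhouette-based separation metrics.
* **nu-SVM** (linear kernel) over signature probes: 75/25 stratified
  split, 5-fold cross-validated choice of ν, Platt-calibrated [0,1]
  scores, and the three-band call rule
  `score < 0.25 → control`, `0.25–0.5 → inconclusive`,
  `> 0.5 → pathogenic`.

Everything is exposed both as scikit-learn-style estimators
(`EpiSignatureSelector`, `ClassicalMDS`, `EpisignatureClassifier`) and as
plain functions, plus an `episig` command-line tool
(`simulate | derive | embed | classify | stage-a | stage-b`).

## Worked example

```python
import episig as es

# a cohort of 8 cases, a 200-control pool and a 270-sample background,
# 20k probes with a planted 175-probe signature at delta-beta 0.2
cfg = es.SimulationConfig(seed=1)
beta, sheet, truth = es.simulate_cohort(cfg)

report = es.run_stage_b(beta, sheet, match_cfg=es.MatchConfig(ratio=3, seed=1),
                        seed=1)
signature = report["_signature"]
print(len(signature), report["stage_counts"])
print(round(report["separation"]["silhouette_by_group"]["case"], 3))

planted = set(truth.signature_probe_ids)
got = set(signature.probe_ids)
print(round(len(got & planted) / len(planted), 3),
      round(len(got & planted) / len(got), 3))
```

prints

```
173 {'probes_in': 20000, 'probes_after_qc': 20000, 'probes_significant': 175, 'probes_selected': 174, 'probes_pruned': 173}
0.858
0.989 1.0
```

i.e. from 20,000 probes the pipeline selects a 173-probe signature
(8 cases vs the 24 age/sex-matched controls drawn from the pool), the
cases form a cleanly separated cluster in the MDS embedding against the
full 302-sample cohort (mean case silhouette 0.858), and the signature
recovers 98.9% of the planted probes with no false probes.

The same analysis from the shell:

```bash
episig simulate --config cohort.yaml --out-dir sim/
episig stage-b --beta sim/beta.tsv --sheet sim/samples.csv --out stageb/
```

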