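# regulonsurv

Transcription-regulator activity scoring and survival risk modeling for
gene-expression cohorts.

Multigene prognostic signatures built directly on gene expression values are
fragile across platforms: RNA-seq counts and the various microarray chips
measure the same transcriptome on different, incompatible scales.
`regulonsurv` instead summarizes each patient's expression profile as the
*activity* of transcription regulators (transcription factors, cofactors,
chromatin remodelers), estimated only from the **ranks** of each regulator's
target genes within that patient's own profile.  Because any strictly
increasing per-sample distortion of expression values leaves within-sample
ranks unchanged, a risk model trained on one platform transfers to another
without renormalization.

The package is aimed at computational biologists building or validating
regulator-level prognostic models on bulk expression cohorts with
overall-survival follow-up.

## Method

1. **Regulon construction.**  For each regulator *r* with ChIP-derived
   candidate targets *C(r)*, every gene *g* is regressed on all regulator
   expressions with stochastic gradient-boosted trees; the total split gain
   of *r* in the model for *g* scores the pair (*r*, *g*).  The top 5% of all
   pairs is intersected with *C(r)*, giving the cohort-specific regulon
   *R(r) ⊆ C(r)*.

2. **Activity scoring.**  For sample *s*, genes are ranked by expression
   (highest first).  With *N* genes, rank cutoff *x*<sub>max</sub> =
   ⌈0.2 · *N*⌉ and recovery curve *y*(*x*) = #{g ∈ R(r) : rank(g) ≤ x}, the
   activity is the normalized area under the recovery curve

   A(r, s) = Σ<sub>x=1..x_max</sub> y(x) / Σ<sub>x=1..x_max</sub> min(x, m) ∈ [0, 1],

   where *m* = |R(r)| genes present.  A(r, s) = 1 iff the regulon occupies
   the top *m* ranks.

3. **Risk model.**  Each regulator's activity (z-scored) is screened with a
   univariate Cox proportional-hazards fit; regulators with Wald p < 0.05
   enter one multivariate Cox model, and

   risk score(s) = Σ<sub>i</sub> β<sub>i</sub> · z(A(r<sub>i</sub>, s)).

   Cohorts are split at their own median risk score into high/low groups and
   compared by Kaplan–Meier curves and the log-rank test.  The training
   means/SDs are frozen inside the model so validation cohorts are scored on
   the training scale.

A synthetic-cohort generator plants known regulons, latent activities and
proportional-hazards effects so every stage can be tested against ground
truth; see `docs/methods.md`.

## Worked example

```python
import regulonsurv as rs

cfg = rs.CohortConfig(n_samples=300, n_genes=300, n_regulators=6, regulon_size=20,
                      prognostic_regulators=((0, 0.7), (1, -0.7)), seed=1)
expr, clinical, chip, truth = rs.generate_cohort(cfg)

imp = rs.infer_importances(expr, list(chip.entries), seed=1)
regulons = rs.build_regulons(rs.select_top_pairs(imp, 0.05), chip, min_size=5)
act = rs.score_activity_matrix(expr, regulons, cutoff_fraction=0.2)

hits = rs.univariate_screen(act, clinical, alpha=0.05)
for h in hits:
    print(f"{h.regulator}: HR {h.hazard_ratio:.2f} ({h.ci_low:.2f}-{h.ci_high:.2f}), "
          f"Wald p {h.wald_p:.2e}")

model = rs.fit_risk_model(act, clinical, [h.regulator for h in hits])
groups = rs.assign_risk_groups(rs.compute_risk_scores(model, act))
chi2, p = rs.logrank_test(groups.groups_series().to_numpy(),
                          clinical.align(groups.sample_ids))
print(f"high vs low risk: log-rank chi-square {chi2:.1f}, p = {p:.2e}")
```

prints

```
TF001: HR 1.41 (1.24-1.61), Wald p 3.66e-07
TF002: HR 0.64 (0.51-0.80), Wald p 7.34e-05
high vs low risk: log-rank chi-square 23.6, p = 1.18e-06
```

The generator planted a hazard-increasing effect on TF001 (log HR +0.7 per
SD of latent activity) and a protective effect on TF002 (−0.7); the screen
recovers both with the correct directions (HR above/below 1), and the
median-split risk groups separate clearly in survival.

The same flow is available from the shell:

```bash
regulonsurv run-all --config cfg.yaml --seed 17 --out results/
```

which writes the importance table, regulon GMT, activity matrices, screening
table, risk model, risk assignments, Kaplan–Meier tables/plots and a hashed
artifact manifest.

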