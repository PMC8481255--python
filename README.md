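# metadrift

Hierarchical Bayesian drift–diffusion analysis of two-choice behavior in a
2×2 within-subject design, built for metaphor-comprehension experiments:
participants read a supporting (SC) or opposing (OC) context sentence, then
a familiar (FM) or novel (NM) metaphor, and judge as fast as possible
whether the pair makes sense. The package is for researchers who want to go
beyond mean RTs and accuracies and ask *which stage* of the decision the
experimental factors and individual differences act on.

## The model

Each trial is a Wiener diffusion: evidence accumulates with drift *v*
between boundaries 0 and *a* from start *z·a*, plus non-decision time *t₀*
(diffusion coefficient 1, accuracy coding: upper boundary = correct,
*z* = 0.5). Trial-to-trial variability enters through *s_v* (Normal drift
variability, integrated in closed form) and *s_t* (uniform non-decision
variability, Gauss–Legendre). For participant *i* in condition *j*:

    v_ij = v_i + bF_i·F_j + bC_i·C_j + β_v·score_i
    a_i  = a_i + β_a·score_i          (condition-constant)
    t0_i = t0_i + β_t·score_i         (condition-constant)

with effect coding F = ±0.5 (FM/NM), C = ±0.5 (OC/SC), so the group means
of bF and bC are directly the familiar−novel and opposing−supporting drift
differences. Subject parameters are hierarchical Normal draws; `score` is a
z-scored neuropsychological test score with population-level slopes. Three
model families — **Null** (no condition/covariate terms), **FC** (condition
effects on drift), **Full** (FC + one covariate on *v*, *a*, *t₀*) — are
fitted by Metropolis-within-Gibbs MCMC and compared by DIC; effects are
judged by whether the 95% highest-density interval (HDI) of the population
posterior excludes zero.

The classical side of the pipeline (3-SD participant and trial screens with
an exclusion ledger, condition descriptives, 2×2 repeated-measures ANOVA,
Bonferroni pairwise tests, z-scored Pearson correlation table, Welch t from
summary statistics) is included, as is a synthetic-cohort generator that
simulates the full design from known ground truth so every stage is
testable end to end. See `docs/methods.md` for the complete specification.

## Worked example

Simulate a study-scale cohort (38 participants × 124 trials) and run the
behavioral pipeline and a Full-model fit:

```sh
metadrift simulate --out cohort --seed 7
metadrift behav --trials cohort/trials.csv --covariates cohort/covariates.csv --out behav
metadrift fit --trials cohort/trials.csv --covariates cohort/covariates.csv \
    --model full --covariate COWAT_Semantic \
    --samples 5000 --burn 1500 --seed 7 --out fit
```

`behav/descriptives.csv` begins (RT in ms, correct trials only; accuracy in
percent; SEMs across participants):

```
condition,mean_rt_ms,sem_rt_ms,accuracy_pct,sem_accuracy_pct,n_participants
SC-FM,918.4318128489931,28.327043700755155,94.56042776574361,0.8408434296651538,38.0
OC-FM,914.9111809747752,27.303645901038525,94.34312979333764,0.728347649069694,38.0
SC-NM,1029.8840569012166,36.41090565392061,81.76937755958305,1.4089931087263967,38.0
OC-NM,1023.0858163076509,34.01858448798093,83.3907279321775,1.534871526358835,38.0
```

Familiar metaphors are answered ~110 ms faster and ~12 points more
accurately than novel ones — the planted familiarity effect.
`fit/effects.csv` then separates the decision stages:

```
effect,mean,hdi_low,hdi_high,prob_positive,credible
mu_bF,0.6740652350501267,0.5835028257513956,0.7676588561069118,1.0,True
mu_bC,0.03237616959742164,-0.05863166630227333,0.12107369143475111,0.7942857142857143,False
beta_v,0.12102316918599958,0.042993808502273044,0.22176468502390365,0.9905714285714285,True
beta_a,-0.08701393677696394,-0.16690010919725526,-0.011429144571882145,0.008,True
beta_t,-0.034629130250217334,-0.04900682962289856,-0.020049406827810062,0.0,True
```

Reading: the familiarity drift effect is ≈0.67 with a 95% HDI excluding
zero (every posterior draw positive) — familiar metaphors drive faster
evidence accumulation — while the context effect is small and not
credible. The semantic-fluency covariate raises drift (β_v > 0), narrows
the boundary (β_a < 0) and shortens non-decision time (β_t < 0). The
cohort's generating truth is (bF, bC, β_v, β_a, β_t) =
(0.76, 0.06, 0.16, −0.11, −0.03); each estimate's HDI covers its truth for
this realization. The numbers above are exactly what these commands print
for seed 7 (the fit takes ~3 minutes on one CPU); any other seed gives
statistically equivalent output.

`metadrift compare` fits Null, FC, and one Full model per covariate and
writes the DIC table (base models first, Full models alphabetical);
`metadrift recover` runs a replicate recovery study and scores HDI
coverage against the generating truth; `metadrift ppc` produces posterior
predictive checks (accuracy and RT deciles per condition) from a saved fit.

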