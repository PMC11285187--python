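# gmnet — longitudinal network-based grey-matter volume analysis

`gmnet` is a pipeline for analysing longitudinal regional grey-matter (GM)
volumes from multi-site clinical studies — built with multiple-sclerosis
trials in mind, where whole-brain atrophy measures can dilute regionally
concentrated disease and treatment effects.

Instead of a single whole-brain number, `gmnet` works with *networks of
co-varying GM regional volumes*:

1. **Discover** networks by spatial ICA on the observation × region volume
   matrix (FastICA, logcosh contrast, PCA whitening to K ≤ 20 components).
   Each network is a spatial map over regions; each subject-visit gets one
   loading per network. Signs are oriented so a lower loading always means
   lower GM volume.
2. **Score prospectively** with a Lasso surrogate: ICA can only be estimated
   on a whole cohort at once, so a sparse linear model per network
   (regional volumes → ICA loading) is trained on a 70% subject split,
   validated on the held-out 30% by intra-class correlation ICC(2,1), and
   frozen for application to unseen participants and visits.
3. **Harmonize** network measures and whole-brain GM across sites/scanners
   with parametric (empirical-Bayes) ComBat.
4. **Analyse** with REML random-intercept linear mixed models:
   phenotype × time trajectories (RR/SP/PP), EDSS disability associations
   (z-scored loading × time), stepwise predictor selection, and
   treatment × time effects with first-to-last-visit Cohen's d and per-arm
   sample sizes from exact noncentral-t power (α = 0.05, power = 0.80).
   All families are corrected by Benjamini–Hochberg FDR.

A synthetic-cohort generator with planted ground truth (sparse network
maps, phenotype-specific atrophy slopes, treatment deltas, site gains,
EDSS coupling) is part of the package, so every stage can be validated
end to end against known truth.

## Model sketch

With regional volumes `x ∈ R^R` per subject-visit, ICA factorizes the
centered data as `x − μ ≈ Aᵀ s`, where the rows of `A` (K × R) are spatial
maps and `s` the per-visit network loadings. The surrogate replaces the
group-level estimate of `s_k` with the affine rule
`ŝ_k = β₀ₖ + βₖ · standardize(x)`, `βₖ` sparse via
`min (1/2n)‖s_k − Xβ − β₀‖² + λ‖β‖₁`, λ chosen by subject-grouped CV.
Longitudinal models are of the form

```
measure ~ phenotype * time + age + sex + duration + TIV + treatment + (1 | subject)
EDSS    ~ loading_z * time + covariates + (1 | subject)
measure ~ arm * time + age + sex + TIV + (1 | subject)
```

fitted by profiled REML (Brent search over the variance ratio
σ²_subject/σ²_resid) with Wald z inference and CIs `β ± 1.96·se`.

## Worked example

```bash
gmnet simulate cohort.csv gt.json --n-subjects 100 --seed 7   # 600 subjects, 4 visits
gmnet discover cohort.csv ica.json --k 8 --seed 7
gmnet train-surrogate cohort.csv surrogate.json --k 8 --seed 7
gmnet apply surrogate.json cohort.csv measures.csv
gmnet harmonize measures.csv cohort.csv measures_h.csv
gmnet analyze treatment measures_h.csv cohort.csv treatment.csv
gmnet sample-size --d 0.4
```

The training step prints the held-out fidelity of the surrogate:

```
held-out ICC per network: 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000
```

and the treatment report (on this synthetic cohort, three networks carry a
planted treatment effect) reads:

```
  measure     beta      p      q  significant  cohens_d  n_per_arm
loading_1  -0.0057 0.0238 0.0429         True   -0.2050        375
loading_2   0.0017 0.4917 0.6353        False    0.0800       2452
loading_3   0.0102 0.0000 0.0000         True    0.3465        132
loading_4  -0.0011 0.6353 0.6353        False   -0.0346      13147
loading_5  -0.0014 0.5585 0.6353        False   -0.0597       4400
loading_6   0.0012 0.5772 0.6353        False   -0.0157      63898
loading_7   0.0195 0.0000 0.0000         True    0.6444         39
loading_8   0.0133 0.0000 0.0000         True    0.4799         70
 gm_total 136.3141 0.0000 0.0000         True    0.4662         74
```

`beta` is the time × arm interaction (loading units per year; positive =
slower loss in the treated arm), `q` the BH-adjusted p-value, `cohens_d`
the first-to-last-visit change effect size, and `n_per_arm` the subjects
per arm a two-arm trial would need to detect that effect at α = 0.05 with
80% power. The three strongly flagged networks (`loading_3`, `loading_7`,
`loading_8`) are the three with planted treatment deltas; whole-brain GM
responds too, but with a weaker effect size than the best network —
the motivation for network-level endpoints. `gmnet sample-size --d 0.4`
prints `100`.

`gmnet run --seed 0 --out-dir run/` executes the whole workflow
(simulate → discover → stability check → train → apply → harmonize →
analyses) and writes every artifact with provenance.

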