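# nmrstrat

Serum ¹H-NMR metabolomics of the response to induction chemotherapy in
locally advanced head-and-neck squamous-cell carcinoma (LA-HNSCC):
a tested, reproducible reimplementation of the full analysis pipeline —
spectral preprocessing, two-class OPLS-DA with complete validation,
panel-metabolite quantification, score-trajectory stratification of weak
responders, and correlation of metabolic change with clinical response.

Because no raw spectra from such studies are publicly deposited, the
package ships a first-class **synthetic cohort generator** that emulates
the statistical structure the analysis assumes (paired pre/post samples,
a lipid-up / alanine-glucose-NAG-down treatment effect, sex-dependent
baselines, three response subgroups), so every downstream stage is
testable end-to-end without any download.

## Who this is for

Metabolomics researchers and statisticians who want a transparent,
scriptable alternative to point-and-click chemometrics suites for paired
pre/post treatment designs: the whole chain from `(ppm, intensity)` traces
to validated OPLS-DA diagnostics and responder strata is a few library
calls or one CLI invocation.

## The model

Spectra are referenced to the alanine methyl doublet, bucketed over
9.0–0.5 ppm at 0.002 ppm (4250 buckets), the water window 5.15–4.38 ppm is
removed (385 buckets), **no normalization is applied**, and the matrix is
Pareto scaled (center, divide by √SD). Two-class OPLS-DA then splits the
predictor variation into one predictive component (scores t[1]) and
orthogonal components:

    X = t p' + Σ_o t_o p_o' + E,      ŷ = t c + ȳ

with diagnostics R²X (predictive X-variation), R²X(o) per orthogonal
component, R²Y (class variation modelled), Q² = 1 − PRESS/SS from 7-fold
interleaved cross-validation, per-variable p(corr) = corr(x, t[1]), label
permutation tests of R²Y and Q², and CV-ANOVA (F-test of PRESS against the
total corrected variation).

Patients whose post-treatment sample stays on the negative (pre) side of
t[1] form the **Red** stratum; patients whose pre-treatment sample already
sits on the positive (post) side form the **Green** stratum (Red takes
precedence); all others are **Grey** (full responders). Univariate
statistics use Wilcoxon signed-rank, Mann–Whitney U, Kruskal–Wallis and
Spearman correlations, with the between-group effect size reported as the
median ratio `100 − (lower median)/(higher median) × 100` and a
`|R| > 0.3, p < 0.05` retention filter for response correlations.

## Worked example

```python
from nmrstrat.pipeline import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(outdir="demo_run", seed=7,
                                  n_patients=20, n_perm=199))
print(manifest["results"])
```

prints (abridged):

```
r2x                0.355      # X-variation correlated with class
r2x_orth           [0.246, 0.129]
r2y                0.662      # class variation modelled
q2                 0.368      # cross-validated predictive ability
cv_anova_F         6.99
cv_anova_p         0.0008     # model significant by CV-ANOVA
perm_p_r2y         0.005      # minimum attainable with 199 permutations
perm_p_q2          0.005
external_pct_correct  95.8    # 24-sample external test set
strata_counts      {'Grey': 16, 'Green': 2, 'Red': 2}
```

The 20-patient synthetic cohort carries a planted treatment effect
(lipids up; alanine, glucose, NAG down), so the model separates pre from
post samples well above chance (permutation p at its floor), classifies a
held-out external cohort, and the trajectory stratification recovers the
planted weak-responder subgroups (2 Red-like, 2 Green-like here). The run
directory contains every stage output (bucket table, metabolite integrals,
model JSON, trajectories, univariate statistics, retained correlations)
plus a manifest with checksums; rerunning with the same seed is
bit-identical.

The same pipeline is available from the shell:

```bash
nmrstrat simulate --n-patients 20 --seed 7 --outdir demo
nmrstrat all --seed 7 --outdir demo_run
```

## Layout

- `src/nmrstrat/synth.py` — synthetic paired-cohort generator
- `src/nmrstrat/preprocess.py` — referencing, bucketing, water exclusion, Pareto scaling
- `src/nmrstrat/quantify.py` — "sum all points in region" panel integrals
- `src/nmrstrat/oplsda.py` — OPLS-DA, Q², permutation tests, CV-ANOVA, p(corr)
- `src/nmrstrat/stratify.py` — trajectory strata, WSR/MWU/KWA battery, Spearman filter
- `src/nmrstrat/clinical.py` — TNM staging, regression formulas, cohort summaries
- `src/nmrstrat/pipeline.py`, `cli.py` — orchestration and the `nmrstrat` CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
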