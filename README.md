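# cogclust

Dual clustering of normatively banded cognitive test batteries.

Psychiatric inpatients are cognitively heterogeneous: within and across
diagnoses (schizophrenia spectrum, bipolar, depressive and personality
disorders), neuropsychological performance ranges from severe deficit to
superior ability, and that heterogeneity carries prognostic information.
`cogclust` implements, as a tested and reusable pipeline, the analysis
strategy of classifying such cohorts from *nominal* cognitive measures: each
test score is standardized against published norms, banded into three
performance levels, and the resulting subjects × items categorical profiles
are clustered with two independent families of methods whose agreement
vouches for the stability of the solution. It is aimed at researchers in
biostatistics and clinical neuropsychology who want the full procedure —
banding, dual clustering, model selection, and validation — reproducible
from a single seed, either on their own score tables or on synthetic cohorts
with known structure.

## The methods

**Normative banding.** Raw scores become z = (x − μ)/σ with μ, σ from the
normative reference for each test (time/error scales are sign-flipped so
larger z is always better), then trichotomized at the 10th and 90th
normative percentiles: z < −1.3 → *below* (deficit), −1.3 ≤ z < 1.3 →
*within*, z ≥ 1.3 → *above*.

**Latent class analysis.** A finite mixture for polytomous items: subject i
belongs to class r with prevalence p_r and, under local independence,

    P(x_i) = Σ_r p_r Π_j π_{j r x_ij},

with π_{jrk} the class-conditional probability of level k on item j.
Estimation is EM from multiple random starts (missing items contribute
through observed cells only); `predict_proba` gives the posterior membership
τ_ir by Bayes' rule.

**Two-step clustering.** Complete-case profiles are first compressed into
dense pre-clusters (at the default threshold 0, the distinct response
patterns), then merged stepwise under the log-likelihood distance
d(s,t) = ξ_{s∪t} − ξ_s − ξ_t, where ξ_v = N_v Σ_j H_vj is the
size-weighted within-cluster entropy cost; an optional continuous mode adds
Gaussian variance terms so the same machinery runs on z-scores directly.

**Model selection.** For k = 1..4 both methods report AIC, BIC
(−2·loglik + penalty) and relative entropy
E = 1 − Σ_ir (−τ_ir ln τ_ir)/(N ln R). Adjacent solutions are compared by
the *consecutive change* (2vs1, 3vs2, 4vs3); each index votes for the k with
its strongest improvement, ties and full disagreements resolve to the
smaller k (parsimony).

**Validation.** Per-item cluster × level contingency tables with Pearson χ²,
Low/High Cognitive Profile labelling (the cluster with the larger share of
*below* scores is Low), optimal label alignment between partitions, Cohen's
κ = (p_o − p_e)/(1 − p_e), and internal validity by refitting the whole
pipeline inside each diagnostic stratum.

The package is organised as scikit-learn-style estimators
(`LatentClassAnalysis`, `TwoStepClusterer`, `NormativeBander`) with thin
functional wrappers (`lca_fit`, `twostep_fit`, `standardize`, `categorize`,
…) and a `cogclust` command-line interface. A synthetic-data module
generates cohorts from the two-class, 10-item structure reported for a
published cross-diagnostic inpatient cohort (N = 387), whose printed count
tables also ship as exact fixtures.

## Worked example

```bash
cogclust simulate --n 387 --seed 11 --with-strata --out demo
# merge the diagnosis column into the level table, then:
cogclust run --input demo/with_strata.csv --strata-col diagnosis \
             --method both --seed 11 --n-starts 10 --out demo/out
```

prints

```
lca: chosen k = 2
twostep: chosen k = 2
cross-method kappa: 0.657
reports written to demo/out
```

Both methods recover the two-cluster (Low/High) structure the cohort was
generated with, and after label alignment they classify the same subjects
identically often enough for κ ≈ 0.66 — substantial cross-method agreement.
`demo/out/index_changes.tsv` holds the consecutive index changes behind the
choice (e.g. the latent-class BIC improves by ≈ 397 from k = 1 to 2, then
*worsens* by ≈ 69 from 2 to 3), and `stratum_validation_lca.json` shows each
diagnosis subsample re-selecting k = 2 with κ between 0.86 and 0.96 against
the whole-sample labels. Because every stage is seeded, rerunning the same
commands reproduces these files byte for byte.

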