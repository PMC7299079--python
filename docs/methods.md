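# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `cogclust`, together with what the synthetic-data
generator does and does not emulate.

## Normative banding

Raw test scores are standardized as z = (x − μ)/σ against a user-supplied
normative reference (the package bundles none: norms are instrument- and
population-specific). Each reference entry carries a `direction` flag;
`lower_is_better` scales (times, error counts) have their z negated before
banding so that *below* uniformly means deficit. The cutpoints are fixed at
z = −1.3 and z = +1.3 — the conventional 10th/90th normative percentiles —
with half-open bands: z = −1.3 itself is *within* and z = +1.3 is *above*.
Whether original norm tables for time/error subscales are published
pre-oriented or not varies by instrument; the per-test flag makes the
orientation explicit instead of guessing, which is the package's own
resolution of an ambiguity the banding convention leaves open. Missing raw
scores stay missing; each downstream module decides its own policy (below).

## Latent class analysis

The mixture has R classes with prevalences p and class-conditional level
probabilities π[j, r, k]; items are conditionally independent given class.
Free parameters: q = (R − 1) + R·Σ_j (K_j − 1), here K_j = 3.

Estimation choices:

* **Starts.** EM from `n_starts = 20` random responsibility matrices by
  default; the start with the highest maximized log-likelihood wins.
  Twenty starts is comparable with common practice for polytomous mixtures
  at this scale; the well-separated two-class structure typically converges
  to the same optimum from most starts.
* **Convergence.** Relative log-likelihood improvement below `tol = 1e-8`,
  cap `max_iter = 5000`; hitting the cap flags the solution but returns the
  best iterate.
* **Missing data.** The likelihood multiplies over observed cells only; no
  imputation. Subjects with no observed items contribute nothing (and fall
  back to the prevalences in the posterior).
* **Numerical safety.** π is clipped to [1e-10, 1 − 1e-10] each M-step so
  log π stays finite on separable data; all posterior arithmetic runs in
  log space with log-sum-exp normalization. The clip can in principle break
  exact EM monotonicity at the 1e-10 boundary, so the monotonicity tests
  allow a 1e-7 slack.
* **Degeneracy.** Requesting more classes than distinct observed response
  patterns raises an error; items observed at a single level are rejected
  as carrying no grouping information.

Relative entropy is E = 1 − [Σ_i Σ_r −τ_ir ln τ_ir]/(N ln R), defined as 1
for R = 1 (a one-class model classifies with certainty). This is the
standard normalized form with 1 = perfect separation; the selection stage
only uses differences of E, so any affine variant would vote identically.

## Two-step clustering

The classical two-step procedure compresses cases into pre-clusters with a
CF-tree and then merges them hierarchically. At desk scale (N ≈ 400) the
tree is unnecessary: the package uses a single-pass leader algorithm in a
seeded random order, and with the default `threshold = 0` (exact mode) the
pre-clusters are exactly the distinct complete response patterns, making
the pass order-invariant. Listwise deletion is applied first — the
count-table distance is undefined under missing cells — and logged.

The within-cluster cost is ξ_v = N_v Σ_j H_vj (size-weighted summed entropy
of the item margins); the merge distance is the cost increase
d(s, t) = ξ_{s∪t} − ξ_s − ξ_t ≥ 0, the categorical case of the
log-likelihood distance. Continuous variables, when enabled, contribute
N_v · ½ ln(σ̂_j² + σ̂_vj²) per variable, with the overall variance σ̂_j²
regularising single-member clusters; this is the standard mixed-type form
and lets the same pipeline cluster z-scores directly (off by default).

Merging is greedy: the pair with the smallest d merges; ties (within 1e-12)
break on the smallest combined cost ξ_s + ξ_t, then on the lexicographically
smallest member ids — determinism over cleverness. Greedy agglomeration is
not globally optimal on arbitrary data; on separated-block structures (the
regime where a cluster analysis is meaningful) it attains the exhaustive
set-partition optimum, and the test suite checks exactly that.

Per-k indices treat the total cost as a deviance: AIC_k = 2Σξ + 2m_k,
BIC_k = 2Σξ + m_k ln N with m_k = k·(Σ_j (K_j − 1) + 2·n_continuous). The
"entropy" reported for a hard partition is an assignment-certainty analog:
each cluster's average member is softly reassigned to all clusters with
weight exp(−d), and the relative entropy of those weights is reported. For
well-separated solutions it sits at ≈ 1 and its consecutive changes are
near zero, so selection is effectively driven by BIC/AIC — which mirrors
how the procedure is used in practice.

## Model selection

Solutions k = 1..k_max (default 4, the plausible range for cognitive
profiles in this literature) are compared by consecutive improvement:
Δ_k(AIC) = AIC_{k−1} − AIC_k, Δ_k(BIC) likewise, and
Δ_k(entropy) = E_k − E_{k−1}, labelled 2vs1, 3vs2, 4vs3. Signs are chosen
so that *larger change = greater improvement* for every index. Each index
votes for arg max_k Δ_k with ties to the smaller k; the overall k is the
majority vote, a full three-way disagreement resolving to the smallest
winner, and if no index improves anywhere the one-cluster solution stands.
The vote is invariant to strictly increasing transforms applied uniformly
to one index — only the ordering of changes matters.

## Validation

* χ² tests are Pearson, no continuity correction (required to reproduce
  published 2 × 3 statistics), via `scipy.stats.chi2_contingency`; an
  independent expected-count oracle in the tests guards the call.
* Cohen's κ is computed from the confusion matrix after explicit label
  alignment (exhaustive over k! permutations, k ≤ 4, maximising the
  diagonal); `sklearn.metrics.cohen_kappa_score` serves as a test oracle
  only. Degenerate margins (p_e = 1) yield κ = NaN with a flag.
* Low/High labelling: with k = 2 the cluster holding the larger overall
  share of *below* performances is Low; exact ties are flagged and resolved
  by label order.
* Within-stratum validation refits the full path per stratum (default
  minimum 20 subjects, smaller strata are skipped with a warning) and
  reports the chosen k plus κ and percent agreement against the
  whole-sample labels restricted to the stratum; one-class strata or k
  mismatches are flagged instead of forced.
* Group-difference models on external measures (GLMs with covariates,
  rank tests) are out of scope by design: the pipeline exports assignment
  tables joinable to any such analysis.

## Synthetic data

The generator is the package's study-condition stand-in for a real cohort:
class → (optional stratum) → independent item levels, missingness MCAR,
everything driven by one seed (same seed ⇒ byte-identical sample). The
bundled preset encodes a published cross-diagnostic inpatient cohort
(N = 387): prevalences 184/387 (Low) and 203/387 (High), and per-item
class-conditional level probabilities taken from the published within-cluster
percentage composition of the latent-class solution, renormalised per
item/class because the printed percentages are rounded. Those percentages
are empirical within-cluster frequencies, not the fitted conditional
probabilities (which were only published graphically); they are the only
numerically printed source and are close enough to generate cohorts whose
two-cluster structure both methods recover. The stratified variant converts
the published per-diagnosis cluster counts (BD 73/61, DD 26/67, PD 19/31,
SZ 66/44) into P(class | diagnosis) with diagnoses at their cohort
proportions; its Low-class mass (184/387) is consistent with the marginal
prevalences.

What the generator does **not** emulate: inter-item correlation beyond the
latent class (real batteries violate local independence), informative
missingness, measurement error in the norms, or the continuous raw-score
distributions (the raw layer is uniform within each z band — sufficient to
exercise banding round-trips, not a model of real score distributions).
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the assumed model, not robustness to violations of it.

## Problem sizes used by the tests and the acceptance script

Chosen as the package's own verification scale: selection-rule recovery
uses 10 replicate cohorts at the study size N = 387 (LCA with 10 starts per
k); parameter recovery uses 10 replicates at N = 5000 with 5 starts
(well-separated two-class fits converge identically from few starts);
optimizer-oracle comparisons use 20 restarts on 20 × 3 toys; exhaustive
partition search is limited to ≤ 8 pre-clusters. The acceptance script
derives every sub-seed from its `--seed` argument.

## Known limitations

* The two-step stage makes no claim of bit-compatibility with commercial
  implementations (noise handling, auto-clustering ratios, CF-tree
  truncation differ); it reproduces the procedure's statistical behaviour.
* Greedy merging can be suboptimal on unstructured data (documented above).
* No bootstrap likelihood-ratio test, covariate-on-class regression, or
  ordinal-constrained latent-class variants.
* κ between a stratum refit and the whole-sample solution is only defined
  when both partitions share k; the package flags rather than forces the
  comparison.
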