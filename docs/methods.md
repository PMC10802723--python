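# Methods

## Presence model

Population presence of a missense variant is modelled as a Bernoulli
observation of a latent Gaussian process over the (standardised) base
score:

    f ~ GP(0, k),   y_i | f(x_i) ~ Bernoulli(sigmoid(f(x_i))),
    k(x, x') = sigma_f^2 exp(-(x - x')^2 / (2 l^2)).

Presence is boolean by design: discarding allele-frequency magnitude, and
letting the latent function depend on the score only (never on variant
identity), are the two properties that make the calibration insensitive to
population structure. The prior mean is exactly zero, not a fitted
constant, so in regions without data the posterior latent mean returns to
0 ("no evidence against neutrality") instead of extrapolating
pathogenicity; the calibrated score of a variant is the posterior latent
mean, i.e. the log-odds of presence, with more negative meaning more
constrained.

### Inference

Sparse variational inference with M inducing inputs placed at empirical
quantiles of the training scores (a quantile grid per dimension for the
joint multi-score variant). The variational Gaussian q(u) is parameterised
in whitened coordinates u = L_K v (L_K the Cholesky factor of K_uu), which
removes the severe ill-conditioning that direct (m, S) optimisation
inherits from K_uu⁻¹ — in direct coordinates L-BFGS stalls within ~50
iterations on these problems. The ELBO's Bernoulli expectations use
20-point Gauss–Hermite quadrature; gradients are analytic; optimisation is
full-batch L-BFGS, which is deterministic and monotone in the objective,
so fits are bit-reproducible and the ELBO trace is non-decreasing by
construction. The Cholesky diagonal is optimised in log space to keep S
positive definite.

### Defaults and units

| parameter | default | unit / scale | rationale |
|---|---|---|---|
| M (inducing points) | 100 | — | resolves a smooth 1-D link with head-room; fits are O(M²n) |
| lengthscale l | 1.0 | standardised score sd | links vary on the scale of the score distribution itself |
| signal variance σ_f² | 25 | latent logit² | prior sd 5 admits presence log-odds of ±10 without prior resistance |
| quadrature points | 20 | — | exact to machine precision for these smooth integrands |
| max L-BFGS iterations | 500 | — | converged well before this at n ≤ 2·10⁴ |
| jitter | 1e-8·σ_f² | — | Cholesky stability |

Kernel hyperparameters are fixed, config-exposed quantities rather than
optimised: on standardised inputs the defaults are appropriate across the
simulated regimes, and fixing them keeps fits deterministic and fast.
Monotonicity of the calibrated map is *not* structurally enforced; it is
an emergent property verified by test on monotone-link data.

Per-base-model calibrators are fitted independently and ensembled by
averaging latent means (sds combine as root mean square); a joint GP
conditioning on all score columns at once is available via `gp_joint`.
The independent-then-average default is the simpler identifiable choice
and is the one whose variance-reduction behaviour is tested.

Models persist to a single JSON file; Python float repr round-trips IEEE
doubles exactly, so a reloaded model predicts bit-identically.

## Mixture thresholds

A two-component Gaussian mixture is fitted by EM (best of 10
k-means-seeded restarts, relative log-likelihood tolerance 1e-8, at most
1000 iterations, variance floor 1e-6) to the calibrated scores of cohort
DNMs, cases and controls pooled without labels. Components are ordered so
index 0 has the lower mean. "Likelihood of being in the low-fitness
distribution" is interpreted as posterior component membership
w₀φ₀/(w₀φ₀ + w₁φ₁), computed in log space so the deep tail saturates to 1
without underflow; a CDF-tail reading would also be defensible but the
membership form is the standard mixture-model semantics. The severe
(default level 0.9999) and moderate (0.99) cutoffs are the largest scores
t ≤ μ₁ with posterior ≥ level on the whole prefix (−∞, t], located by a
1000-point grid and refined by bisection to 1e-6. The prefix rule keeps
the threshold well defined when unequal variances make the posterior
non-monotone. By default the mixture is fitted on unique variant scores;
`per_observation: true` weights by patient observations instead, which is
the right choice when planted variants recur across patients (as in small
synthetic cohorts).

## Cohort statistics

* **Expectation**: over N probands the expected DNM count is 2·N·Σμ
  (diploid factor times per-haploid rates), optionally restricted to a
  severity band by classifying every rate-table variant.
* **Enrichment**: fold = observed/expected with an exact Poisson
  upper-tail p and the exact (Garwood, chi-square) 95% interval for the
  Poisson mean divided by the expectation, so the CI always brackets the
  point estimate.
* **Gene collapsing**: statistic T = Σ(−score) over a gene's observed
  DNMs; null DNM counts are Poisson(2·N·Σμ_gene) with variant identities
  drawn ∝ μ; p = (1 + #{T_null ≥ T_obs})/(n_sims + 1). The add-one
  correction bounds p away from 0, so permutation results are reported as
  p ≤ 1/(n+1) rather than "p = 0". A posterior-membership-weighted
  statistic is available as an alternative weight function.
* **BH adjustment**: hand-rolled five-line step-up with monotonicity
  enforcement (cross-checked against statsmodels in the tests);
  significance at q < 0.05 over all genes with ≥ 1 case DNM.
* **Patient ranking**: within each patient, variants sort ascending by
  calibrated score with lexicographic (gene, position, alt) tie-breaks;
  the summary fraction is computed over patients with ≥ 1 DNM at or below
  the severe cutoff.
* **Network test**: observed statistic is the mean node degree of the
  subgraph induced by base ∪ added gene sets; the null draws equal-size
  added sets uniformly from non-base graph nodes; add-one permutation p.
  "Interaction" means any edge in the supplied graph — confidence
  filtering belongs upstream.

## Synthetic data generator

The generator emulates the *structure* of the real problem, not its
scale or biology:

* **Scores**: each gene draws a severity offset (N(0, gene_sd²)); a 5%
  "constrained class" of genes is shifted a further 5 units down,
  emulating haploinsufficient-like genes and giving cohort score
  distributions their bimodal shape. Two base-score columns are drawn
  around the offset from a bivariate normal whose within-gene correlation
  is solved so the *total* column correlation equals the requested value
  (default 0.5 — evolutionary predictors of different families correlate
  imperfectly in practice).
* **Presence**: Bernoulli through a monotone link on the score, default
  g(x) = 1.2x + 3 on the standardised scale, so strongly negative scores
  have near-zero presence probability (purifying selection) while the
  bulk is common.
* **Rates**: log-normal per-variant weights normalised to Σμ = 0.35, so
  the expected background missense DNM load is 0.7 per proband — the
  order observed in exome trio studies.
* **Cohorts**: every patient receives Poisson(2Σμ) background DNMs drawn
  ∝ μ; a causal fraction of cases additionally receives one planted severe
  DNM — the minimum-score variant of a random gene whose minimum lies at
  least `severe_shift` sd below the overall mean, so planted variants are
  real table entries, keeping collapsing-power tests honest. An
  `inherited_mean` option adds inherited-labelled rare variants per
  patient so that mixed DNM/inherited ranking can be exercised.

What the generator does **not** model — and hence what passing tests do
not demonstrate about real data: trinucleotide-context mutation rates,
sex chromosomes, realistic allele-frequency spectra, relatedness or
ancestry structure, genes with heavy-tailed non-Gaussian score
distributions, and any annotation error in upstream consequence calling.

## Test-scale choices

Recovery experiments run at n = 20,000 observations (M = 100) for link
and mixture recovery, 20 replicates at n = 10,000 (M = 50) for the
ensembling comparison, 1000 null genes / 50 power replicates at 2000
probands for collapsing calibration, and 100 replicates for CI coverage
and network-null uniformity — sizes at which the checked tolerances are
comfortably resolved on a single CPU. The collapsing null-calibration
fixture uses per-gene rate totals high enough (λ ≈ 8 expected DNMs per
gene) that the Monte-Carlo statistic is effectively continuous; at
realistically sparse rates most genes observe zero DNMs and the p-value
mass at 1 makes a uniformity check meaningless, though the test remains
valid (conservative) there.

## Known limitations

* Loss-of-function variants are out of scope; the calibration applies to
  missense substitutions only.
* Base-model scores are inputs; nothing here trains or approximates the
  underlying evolutionary models.
* The GP assumes a single global score-to-presence link per base model;
  gene-family-specific deviations would be absorbed, not modelled.
* Kernel hyperparameters are fixed rather than learned; severely
  non-stationary links would need a lengthscale rethink.
* The collapsing-test null ignores inter-gene pleiotropy and assumes
  rates are known exactly.
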