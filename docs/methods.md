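# Methods

## Problem and model

`mirmix` analyzes paired expression profiles — an mRNA view `E_m` (genes ×
samples, RPKM) and a miRNA view `E_mi` (mature strands × samples, RPM)
measured on the same tumor samples. The working model is a linear latent
decomposition

    E = C M

with `C` (G × I) the component matrix holding gene weights of I latent
transcriptional programs and `M` (I × S) the mixing matrix holding each
program's activity per sample. Components are identified by maximizing the
non-Gaussianity (negentropy) of the gene-weight columns, i.e. independent
component analysis with genes as observations and samples as variables.
The two views share `M`'s sample-level structure, so a single orthonormal
un-mixing matrix `W` is estimated such that

    C_m  = centered(E_m)  K_m  W
    C_mi = centered(E_mi) K_mi W

are simultaneously maximally independent. Downstream, components are linked
to right-censored survival, miRNA→target repression is detected as negative
Spearman correlation supported by 7mer seed sites, and gene lists are scored
by exact hypergeometric overlap.

## Preprocessing

Transcript-level tables are summed to gene level. Features whose maximum
abundance is strictly below 10 RPKM/RPM are removed; the boundary value 10
is retained. Outlier features with coefficient of variation sd/mean > 5
(raw scale, (n−1)-denominator sd) are removed; zero-mean features have an
undefined CV and no signal, and are removed too. Values are then
log2-transformed with a pseudo-value (default 0.01 — three orders below the
abundance floor) substituted for smaller values. Filtering happens on the
raw scale before the log transform; both filters are row predicates and
commute. When expression and clinical tables disagree on samples, the
analysis silently restricts to the intersection and logs the counts.

## Joint ICA

**Centering.** Each view is double-centered: per-feature means (baseline
abundance, constant across samples) are removed first, then per-sample
means. Left in place, feature baselines form a dominant rank-one direction
that consumes a component while carrying no sample-level structure.

**Shared whitening.** Both centered views are rescaled to unit per-entry
variance and row-stacked; the stack is projected onto its first I principal
directions in sample space and whitened there. The projection `K` is shared
between the views (`K_v` differs only by the view's scale factor). This is
deliberate: whitening each view by its own PCA hands each view an
arbitrary, noise-determined rotation of the shared latent coordinates
(exactly arbitrary when source variances are comparable), after which no
single `W` can unmix both views — measured on the default synthetic cohort,
per-view whitening capped matched recovery correlations at ~0.7–0.8 while
the shared projection reaches ≥0.99. The per-entry rescaling matters for
the same reason: balancing views by total Frobenius weight inflates the
smaller view's entries severalfold, and the resulting two-scale mixture is
*more* non-Gaussian under the log-cosh contrast than the true sources,
pulling the optimum away from them.

**View balance.** With `balanced=True` (default) every expectation in the
whitening and in the contrast weights rows by N/(2·G_v), giving each view
half the total vote regardless of feature count; `balanced=False` weights
every feature row equally, letting the larger view dominate. Both modes
are exposed because the right choice depends on whether the smaller view is
trusted as much as the larger one.

**Estimation.** Fixed-point fastICA on the whitened stack: log-cosh
contrast with a = 1, symmetric decorrelation via the eigendecomposition of
`W Wᵀ`, convergence when every direction's dot product with its update is
within `tol` (default 1e−6) of ±1, at most `max_iter` (1000) iterations.
Non-convergence returns the model flagged `converged=False` with a warning.
Each component is oriented so its stacked gene-weight distribution has
positive skewness (tie → largest-|weight| entry positive), and stacked
columns are standardized to mean 0, variance 1 — the per-view slices `C_m`,
`C_mi` are plain row slices of the standardized stack, so the stacked
convention (not a per-view one) holds exactly.

**Number of components.** Features are standardized, the eigenvalues of the
S × S correlation-like matrix are compared with the Marchenko–Pastur upper
edge (1 + √(ratio))² with the smaller matrix dimension as the sample count,
and the count above the edge (capped at S − 1) is the view's dimension; the
joint dimension is the maximum over views.

**Mixing matrices.** `M_v` is the least-squares solve of
`C_v M_v ≈ centered(E_v)`; since `C_v` spans the view's projection of the
joint rank-I subspace, `C_v M_v` reproduces the centered view's best
approximation within that shared subspace. This is within ~1e−5 relative of
(but not identical to) the view's own rank-I PCA truncation, which a
per-view whitening would give; exact reconstruction holds for noiseless
low-rank input.

**Stability.** The fit is repeated over `runs` (default 30) seeded
restarts. For each component of the reference run the highest |Spearman|
against every other run's components is recorded and averaged; components
are reported sorted by descending stability. The per-run maximum is taken
without enforcing a bijection between runs, so a duplicated component can
match the same partner twice — scores are a coherence measure, not a
clustering.

**Significant features.** Within a component, features with
|weight| ≥ α · SD(|weights|) are selected (α = 3 by default; 1 and 6 are
used for miRNA and mRNA emphasis respectively in the pipeline). If all
absolute weights are equal the SD is zero; every feature is selected and a
warning is logged.

## Target inference

A binding site is an exact 7mer seed match: the UTR contains the reverse
complement of miRNA nucleotides 2–8 (7mer-m8; the 7mer-A1 variant —
complement of nucleotides 2–7 followed by an A — is available). U and T are
equivalent; N in the seed is an error, N in the UTR simply never matches.
When a gene has several UTR records only the longest is scanned (first
record wins ties). Spearman correlations are computed between every
miRNA/gene pair over shared samples (rank-based, hence insensitive to any
monotone transform such as log); two-sided p-values use the exact
permutation distribution for tie-free vectors with n ≤ 10 and the
t-approximation otherwise. Benjamini–Hochberg correction is applied
separately within each miRNA's family of tests, and pairs are kept at
q < 0.05, rho < −0.3 (configurable), optionally requiring a seed site.

## Survival linkage

Kaplan–Meier estimation and the two-group log-rank test are delegated to
lifelines. The optimal-cutoff scan evaluates every midpoint between
consecutive sorted unique values whose split leaves both groups at least
`min_group_frac` (default 10%) of samples, and returns the split minimizing
the log-rank p (ties broken toward the more balanced split); constant
variables return an explicit no-cutoff result. The scan uses an internal
vectorized O−E/V log-rank for speed; its agreement with lifelines is
enforced by tests. Because the minimum over a scan is anti-conservative,
the result also carries `p_adj`, the Lausen–Schumacher approximation for
the null distribution of a maximally selected rank statistic over the
scanned quantile range; FDR adjustment across scanned variables operates on
`p_adj`. (BH on the uncorrected minima does not control the null
q < 0.05 fraction — measured 4–19% across simulated null cohorts — while on
`p_adj` it stays ≤1%.)

Differential abundance across outcome groups uses the Kruskal–Wallis test
per feature with BH across features; a group with fewer than 2 samples
yields p = 1 with a warning. The subset search enumerates every non-empty
subset of a miRNA universe (capped at 12 strands = 4095 subsets unless
raised explicitly), double-normalizes abundances — each sample divided by
its total over the universe, then each strand rescaled to [0, 1] across
samples so no strand's range dominates — clusters samples with seeded
k-means (k = 2, 25 restarts, cluster labels ordered by mean abundance),
tests the two groups by log-rank, BH-corrects across subsets, and ranks by
q then by the size of the smaller group, descending.

## Overlap and enrichment

`overlap_pvalue(n_pop, d, n, x)` is the exact upper tail P(X ≥ x) of the
hypergeometric overlap, summed in log space (gammaln + logsumexp), exact
down to ~1e−300 (the double-precision floor). The ≥ convention is used
throughout: it reproduces the published worked example (6.3E-10 for
n_pop = 21929, d = 1368, n = 200, x = 38) where a strict > tail would not.
Set enrichment intersects each set with the population (all features
surviving preprocessing by default), computes the same tail for the overlap
with the significant list, and BH-corrects across sets. Gene identifiers
are matched exactly after uppercasing.

## Synthetic cohorts

The generator emulates a paired bulk-sequencing tumor cohort on the log2
scale: shared mixing `M` (rows standardized), per-view gene weights drawn
i.i.d. from non-Gaussian families (Laplace / uniform / bimodal, unit
variance), expression = 2^(baseline + C·M + noise) so the standard log2
preprocessing inverts the construction exactly and filter semantics stay
meaningful. Defaults: 2000 genes, 200 strands, 100 samples, 3 components,
noise sd 0.5. Ten planted miRNAs load positively on component 1 and their
mapped targets (5% of genes, split disjointly) load negatively, producing
negative miRNA–target Spearman correlations whose strength follows
`repression_strength`. Survival times are exponential with rate
0.02·exp(β·M₁ₛ) (β = 1 by default; baseline mean survival 50 months, an
ovarian-cohort-like scale) under independent uniform censoring whose range
is solved analytically so the expected censored fraction equals
`censor_rate` (30%). UTRs (300 nt) carry at least one planted 7mer-m8 site
per mapped miRNA and are rejection-sampled to carry none elsewhere; the
gene-set collection holds the planted target set among 200 uniform decoys.

What the generator does **not** emulate: library-size and GC biases, batch
effects, copy-number confounding, count noise at low abundance, correlated
censoring, or realistic miRNA family structure. A green recovery test
establishes that the estimator separates well-posed non-Gaussian structure
at realistic dimensions and noise — not that it would on any real cohort.

## Numerical choices and edge cases

- All randomness flows from explicit integer seeds; the pipeline derives
  per-stage seeds by hashing the stage name with the base seed (below 2³¹),
  so stages can be rerun in isolation.
- Whitening rejects rank-deficient requests (singular values below
  1e−12 of the largest).
- BH is statsmodels' `multipletests(method="fdr_bh")` throughout.
- Log-rank variance terms with a single subject at risk contribute zero and
  are skipped, matching the standard hypergeometric-variance form.
- k-means cluster labels are fixed by mean abundance so results do not
  depend on sklearn's internal label order.

## Known limitations

- The shared-subspace mixing solve makes per-view reconstructions optimal
  within the joint subspace, not per view (difference ~1e−5 relative on
  realistic data).
- The exact Spearman permutation path requires tie-free vectors; ties at
  n ≤ 10 silently fall back to the t-approximation.
- The Lausen–Schumacher correction is asymptotic; for very small cohorts
  (n < ~30) it can be conservative.
- Stability scoring compares against a single reference run rather than
  clustering all runs' components (Icasso-style); with highly unstable
  solutions the reference choice matters.
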