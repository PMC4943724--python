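# Methods

## Statistical model

Each trait's deregressed EBVs are treated as pseudo-phenotypes under the
polygenic (GBLUP) model with heteroscedastic residuals

    y = 1μ + g + e,  g ~ N(0, K σ²g),  e ~ N(0, diag(w) σ²e),

so the phenotypic covariance is V = K σ²g + diag(w) σ²e. The assumptions
are the usual ones for dEBV-based association in livestock: records behave
as independent pseudo-phenotypes up to the additive relationships captured
by K, and the heterogeneity of dEBV precision is fully described by the
reliability-derived weight w. K is the VanRaden (method 1) estimator,
K = ZZ'/(2 Σ p̂(1−p̂)), computed from mean-imputed dosages centred by 2p̂;
a standardized-marker variant is not provided because the downstream tests
depend on K only through V and the choice is immaterial at the tested
scales.

### Residual weights and the accuracy filter

w = λ⁻¹(d + c) with λ = (1−h²)/h², d = (1−r²)/r². Parameters:

| parameter | meaning | default | notes |
|---|---|---|---|
| h² | trait heritability before deregression | per trait (0.25–0.37 for the nine bundled trait labels) | enters only through λ |
| c | reliability-balance constant | 0.5 | in [0, 1]; c = 0 reduces w to d/λ |
| min accuracy | record filter | 0.50 on r = √r² | inclusive; `mode="reliability"` filters on r² instead |

w is increasing in h² (w ∝ h²/(1−h²)) and decreasing in r². The accuracy
filter is applied per trait independently, so trait record counts differ.
The filter threshold is interpreted on the accuracy scale (r ≥ 0.50, i.e.
r² ≥ 0.25); the reliability-scale alternative is kept behind a flag because
the convention differs between evaluation systems.

### REML

After transforming by diag(w)^(−1/2), V becomes K̃ σ²g + I σ²e with
K̃ = W^(−1/2) K W^(−1/2). One eigendecomposition of K̃ per (trait, fold)
makes each restricted-likelihood evaluation O(n): with rotated data, μ and
σ²g profile out in closed form and only the variance ratio δ = σ²e/σ²g
remains. δ is found by bounded scalar minimisation on log δ ∈ [−12, 12]
(tolerance 1e-8, at most 200 iterations); eigenvalues of K̃ are clipped at
zero. The optimiser trace records the best restricted log-likelihood so
far, which is non-decreasing by construction. Degenerate cases behave
sensibly: with K = I and w = 1 only σ²g + σ²e is identified, and a null
trait drives δ to the upper bound (σ²g ≈ 0).

### LOCO score test

Markers on chromosome j are tested against the null fit whose K excludes
all chromosome-j markers, so the tested signal is never absorbed by the
random term (proximal contamination). LOCO matrices are built by
subtracting per-chromosome cross-products from the genome-wide
cross-product — algebraically identical to rebuilding K per fold.
Variance components are re-estimated per fold by default
(`per_loco_reml=False` re-uses the genome-wide ratio for speed). The test
is the mmscore-type statistic on the mean-centred, mean-imputed dosage:
b = (x'V⁻¹x)⁻¹x'V⁻¹y*, VAR(b) = (x'V⁻¹x)⁻¹, with y* = y − 1μ̂ and a
two-sided normal p-value (large-sample score test, not a t reference).
Constant markers are reported flagged with b = 0, p = 1 rather than
dropped, so tables stay aligned across traits.

GRMs are computed once on all QC-passing samples and sub-setted to each
trait's filtered records; allele frequencies therefore come from the full
QC'd sample. This keeps one GRM set for nine traits and makes per-trait
results comparable.

Conditional scans include [1, fixed-marker dosages] as GLS covariates:
y and x are projected onto the V⁻¹-orthogonal complement of the covariate
span. Fixed markers and markers collinear with them are flagged with p = 1
and a reason code; collinear covariate columns are dropped with a warning.

## Multi-trait meta-analysis

Per marker, the q signed t-values are combined as t'C⁻¹t against χ²_q.
C starts from the Pearson correlations of t across all genome-wide markers
that are unflagged in every trait (complete case). Because traits with
high average correlation can produce large composite statistics from
collectively weak evidence, each diagonal element is inflated to
1 + (signed mean of that row's off-diagonal entries) before inversion; an
absolute-value mode is available behind `diag_mode="absolute"`. The signed
mean is the default because it is the literal reading of "average
correlation of each trait", and with all-positive trait correlations the
two coincide. The correction makes the statistic stochastically smaller
than χ²_q (verified empirically over 10⁵ draws), i.e. conservative.

The FDR threshold follows the empirical rule: sort the m p-values, let s be
the largest rank i with p(i) ≤ f·i/m (f = 0.05), set α = f·s/m, and declare
p < α significant (strict). Up to ties exactly at α — excluded by the
strict inequality and of measure zero for continuous statistics — this
rejection set equals the Benjamini–Hochberg step-up set, which the tests
verify against both a brute-force oracle and statsmodels.

## Gene-based (VEGAS-style) test

Per trait and gene: markers with 1-based positions inside
[max(1, start − 100000), end + 100000] on the gene's chromosome are
members (boundaries inclusive; BED-dialect inputs are converted on read).
Monomorphic and flagged markers are removed, then the member set is thinned
to the maximum subset with all pairwise squared dosage correlations ≤ 0.5,
which keeps the local LD matrix D (signed Pearson correlations of
mean-imputed dosages) well conditioned. Finding that subset is a
maximum-clique-type problem: for ≤ 15 members an exact search returns the
lexicographically first maximum feasible subset; above that a greedy pass
ordered by ascending conflict count with lower-index tie-breaking is used —
deterministic, always feasible, and in practice optimal on local LD
structure (the tests compare it against brute force on small instances).

The gene statistic is Σt² over the pruned set. Its null is approximated by
draws x² = Σz² with z ~ MVN(0, D) via Cholesky of D (repaired, if needed,
by clipping eigenvalues at 1e-8). Simulation size escalates adaptively —
10³, 10⁴, 10⁵, 10⁶ — whenever the current p estimate falls below 1/k,
re-using all previous draws; p is the fraction of draws ≥ the observed
statistic (ties inclusive, no add-one correction), and a zero count at the
final stage is reported as the floor 1/k_final (10⁻⁶ by default) with an
explicit censored flag. Genes with no usable markers get p = 1. Each
(gene, trait) pair draws from its own substream seeded by
(global seed, CRC32(gene id), CRC32(trait id)), so scans are reproducible
independent of evaluation order.

A gene is a pleiotropic candidate when it appears at p < 0.01 (strict) in
at least 4 of the 9 trait lists and no exclusion applies. Exclusions are
user-supplied — gene-id lists, or whole chromosomes with named exceptions
(the pattern needed when one large LD block dominates a chromosome and
only its lead gene should be retained); nothing is hard-coded.

## Synthetic data generator

The generator emulates the structure of a cattle genomic-selection
reference population at desk scale. Defaults (the study conditions for all
statistical tests):

| knob | default | emulates |
|---|---|---|
| n_individuals | 1,000 | ~1,000 genotyped bulls |
| n_markers / n_chromosomes | 20,000 / 29 | HD panel on 29 autosomes, ~5 kb spacing |
| block_size, within_block_r | 10, 0.7 | LD blocks with adjacent-marker correlation |
| maf_range | (0.05, 0.5) | post-QC allele-frequency spectrum |
| trait_h2 | 0.37, 0.26, 0.25, 0.25, 0.26, 0.33, 0.31, 0.31, 0.30 | nine weight/CPM trait heritabilities |
| n_qtl / qtl_var_frac | 3 / 0.07 | a few shared QTLs, each a PLAG1-like major locus explaining ~7% of genetic variance per affected trait |
| bg_corr | 0.45 | moderate cross-trait genetic correlations (~0.44 mean) |
| reliability_range | (0.15, 0.95) | heterogeneous dEBV reliabilities, some failing the 0.50 accuracy filter |
| missing_rate | 0.01 | ~0.99 genotyping rate |

Genotypes use a haplotype-copy LD scheme: within a block all markers share
an allele frequency drawn from `maf_range`, and each haplotype copies the
previous marker's allele with probability `within_block_r`, else draws
fresh. This makes the expected adjacent dosage correlation equal the knob
exactly, which a thresholded Gaussian autoregression does not (tetrachoric
attenuation pushes the realized dosage correlation well below the latent
one). Blocks are independent; dosages are oriented to the realized minor
allele. QTL effect signs follow a growth-locus pattern — positive on
weight/conformation traits, negative on precocity/muscling — and true
breeding values add a genome-wide polygenic background whose per-marker
effects are drawn with a common cross-trait correlation, normalised to
unit genetic variance. dEBVs are TBV plus noise of variance
var(TBV)·(1−r²)/r², so corr²(dEBV, TBV) = r² by construction.

What the generator does **not** emulate: maternal effects and contemporary
groups (dEBVs are drawn directly, not deregressed from an evaluation),
allele-frequency–dependent effect sizes, long-range LD and population
substructure beyond what the GRM induces, selection, and genotyping error.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under the assumed model, not robustness to
real-data violations of it.

## Problem sizes used by the test suite

Simulation-based checks are sized to run comfortably on a single core:
null calibration uses n = 500 with 20,000 LD-free markers on 29
chromosomes (LD-free so the 20,000 t-values are effectively independent
and the KS test's assumptions hold); REML recovery uses 50 replicates at
n = 1,000 with 2,000 markers; the pleiotropic-recovery experiment uses 20
replicates at n = 1,000 with 4,000 markers on 5 chromosomes and 80 genes,
with Monte Carlo stages capped at 10⁴ (ample for calls at the 0.01 list
threshold); generator convergence checks use n = 5,000 with 10,000
independent markers (the implied-vs-empirical correlation comparison is
limited by the number of effectively independent background markers, not
by n alone).

## Known limitations

* The weighted REML is a 1-D profile search; models with more than one
  random effect (e.g. maternal genetic) are out of scope.
* p-values below the Monte Carlo floor are censored, not extrapolated;
  ranking among censored genes must use the statistic, not p.
* The greedy LD-pruning path above 15 members is near-optimal, not
  guaranteed optimal; the exact path covers typical ±100 kb windows after
  monomorphic removal only when marker density is low.
* The meta-analysis diagonal correction is justified empirically
  (conservative under the null); no closed-form null distribution is
  claimed for the corrected statistic.
* dEBV cross-trait correlations in the correlation report are computed
  pairwise-complete over each pair's common filtered animals; with very
  disjoint record sets the matrix need not be positive definite.
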