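# Methods

`rarestrat` is a simulation framework for one question: when a rare-variant
burden test is run on a case/control cohort whose cases and controls have
different ancestry composition, which correction keeps the gene-level
type-I error honest, and at what cost in power?  It implements the tests
and corrections as a library and reproduces the comparison on synthetic
structured exome-like cohorts.

## Association model

For `n` samples with binary phenotypes `Y` and an `n x p` genotype matrix
`X` of minor-allele counts, a gene `g` is collapsed into a score `Z_g`:

* **CAST**: `z_gi = 1` if sample `i` carries at least one rare allele of
  the gene, else 0 (no dose effect).
* **WSS** (Madsen-Browning): `z_gi = sum_k w_k x_ik` with
  `w_k = 1 / sqrt(MAF_k (1 - MAF_k))`, MAFs taken from the analyzed
  sample.

Rare variants enter the gene test when their folded MAF in the analyzed
sample is at most 5% — private (single-carrier) variants included.  Genes
with fewer than 10 rare-variant carriers are excluded.  The association
test is the likelihood-ratio test of `beta_g` in

    logit P(Y = 1) = alpha + beta_g Z_g + gamma_1 PC_1 + ... + gamma_m PC_m

against the null model that drops only `beta_g` (the PC covariates stay in
the null), with the statistic referred to chi-square(1).  `m = 0` is the
unadjusted test; the default adjustment is the first 3 PCs computed on
common variants ("PC3_CV").  Logistic fits use IRLS (at most 100
iterations, convergence when the log-likelihood moves < 1e-8); complete or
quasi-complete separation is flagged (|beta| > 30) and the gene reported
with a missing p-value rather than a fabricated one.  For a binary score
with no covariates the maximized likelihood is the saturated two-binomial
fit, so the scan paths (and the permutation statistics below) use that
closed form; it is algebraically the same LRT, and a test asserts equality
with the IRLS path to 1e-6.

## Genetic similarity, PCA, distances

Genotypes are normalized per column as `(x - mu_j) / sqrt(f_j (1 - f_j))`
where `f_j` is the *unfolded* observed frequency of the counted allele
(folding would flip centering signs; folded MAF is used only to classify
variants).  For a variant set `H`, the similarity matrix is
`S^H = X~ X~'`.  Variant classes on the total sample, private variants
excluded from all of them: RV (0 < MAF < 1%), LFV (1% <= MAF < 5%),
CV (MAF >= 5%), ALLV (their union).  Each set is LD-pruned at pairwise
r^2 > 0.2 before matrix building (greedy, windowed 50 variants / step 5 by
default, dropping the lower-MAF member of an offending pair; global
pruning available — with independent simulated sites the choice is almost
immaterial).

PCA is the eigendecomposition of `S^H`; scores are eigenvectors scaled so
component `k` has squared norm `lambda_k`, signs fixed by making each
component's largest-magnitude loading positive.  The genetic distance is
the eigenvalue-weighted squared Euclidean distance over the top 10
components, `d_ij^2 = sum_k lambda_k (PC_ki - PC_kj)^2`; it drives the
neighbor graph, and reference-based cohort selection
(`select_by_reference_distance`) thresholds it directly.

## Linear mixed model

`Y = alpha + beta_g Z_g + u + e`, `u ~ MVN(0, tau S^H)`,
`e ~ MVN(0, sigma^2 I)`, with the 0/1 phenotype treated as quantitative —
the standard linearization used by fast LMM association tools, kept here
deliberately and documented as an approximation.  One eigendecomposition
of `S^H` rotates the model to independent residuals; `beta` and `tau` are
profiled in closed form and the ML fit is a 1-D search over
`log delta = log(sigma^2 / tau)` on [-10, 10]: a 50-point grid, then
bounded Brent refinement inside the best bracket.  Both null and
alternative re-optimize `delta`, so the LRT is a true likelihood ratio
(chi-square 1 df); ML rather than REML for the same reason.  A boundary
optimum (delta at either end) is a valid estimate and flagged, not an
error.  `S = I` collapses the fit to OLS; `S = 0` is exact OLS; scaling
`S` by `c` rescales `tau` by `1/c` and leaves the LRT unchanged when the
optimum is interior.

## Local permutations (LocPerm)

Under structure, phenotypes are not freely exchangeable.  LocPerm
constrains permutations so each sample receives the phenotype of itself or
of one of its `N = 30` nearest neighbors under the distance above
(neighbor lists exclude self; the feasibility rule adds self back so the
identity starts the chain).  The constraint is enforced in the receiving
direction and is isolated in one predicate so a mutual variant can be
swapped in.

Sampling is Metropolis over feasible permutations: propose the
transposition of a uniformly chosen sample with one of its neighbors (a
lazy no-op with probability 1/(N+1) keeps the chain aperiodic), accept iff
both reassigned samples remain feasible.  The proposal distribution over
transpositions is state-independent, so the acceptance rule satisfies
detailed balance with respect to the *uniform* distribution over feasible
permutations — verified by full enumeration at n = 5.  Uniform-pair
proposals would also be correct but accept only ~(N/n)^2 of proposals; at
n = 500, N = 30 that left draw-to-draw autocorrelation near 0.94,
underestimating the null spread and inflating the semi-empirical type-I
error to ~0.033 at alpha = 0.01.  With neighbor proposals, a burn-in of
`50 * sweeps * n` proposals (an order of magnitude more than needed to
forget the identity start) and thinning of `sweeps = 10` sweeps between
retained draws, measured calibration is ~0.011-0.012; both knobs are
arguments.

The statistic is `T = sign(effect) * sqrt(LRT)` from the unadjusted
logistic CAST test.  Semi-empirical mode (default, B = 500) fits
`N(m, sigma^2)` to the permuted statistics by sample moments and returns
the two-sided `p = 2(1 - Phi(|T0 - m| / sigma))`; one-sided is a flag (the
sidedness is a genuine modeling choice — two-sided because `T` is signed).
Full-empirical mode returns `#{T_i >= T_0} / B` (uncorrected estimator;
B = 5000 default).  A degenerate null (`sigma = 0`) raises, naming the
gene.

## Synthetic cohorts

The generator is a Balding-Nichols stand-in for the real exome cohorts the
comparison was designed around.  Ancestral frequencies follow Beta(0.2, 2)
truncated to (0, 0.5] (a heavily rare-skewed spectrum); each
subpopulation's frequency is Beta-distributed around the ancestral one
with divergence `F`; genotypes are Binomial(2, p_s).  Defaults:
"European-like" = 3 subpopulations at F = 0.005 (fine structure),
"Worldwide-like" = 4 at F = 0.1 (coarse structure).  Genes receive
Poisson(18.7) variants (the biallelic-SNP-per-gene ratio of a ~329k-SNP /
~17.6k-gene exome cohort), and private variants are injected post hoc as
singleton heterozygotes — guaranteeing the single-carrier property — at a
rate targeting a private:non-private ratio of 1:3, matching the
~102k : 329k ratio such cohorts show.  Private variants are treated as
additional to the per-gene counts and are configurable.  One seed drives
four separate sub-streams (gene sizes, frequencies, genotypes, private
injection), so toggling the private rate does not perturb the genotype
draw and seeded runs are bit-reproducible.

What the generator does *not* emulate: linkage disequilibrium (sites are
independent), haplotype or demographic history, sequencing error and
missingness (genotypes are complete; the VCF reader tolerates missing
calls in external data), admixture gradients (labels are discrete).
Passing benchmarks here therefore demonstrates the statistical machinery
under clean, separable structure; on real exomes the corrections face
LD-correlated similarity matrices and continuous ancestry clines, and the
relative ranking of PC vs LMM corrections can differ.

## Scenario engine

Null phenotypes: a fixed 15% case fraction allocated across
subpopulations by scenario weights — proportional (NoPS), 70/20/10 or
70/15/10/5 (ModeratePS; the original study's exact moderate proportions
are not published, so these are declared defaults), or all cases from one
subpopulation (HighPS) — then uniform sampling without replacement within
subpopulation.  Small-sample designs draw e.g. 50 cases from one
subpopulation plus 100 matched or 1000-2000 cohort-wide controls, disjoint
within a replicate.

Alternative phenotypes: carrier status is the indicator of at least one
*causal* variant (about half of each power gene's rare variants, chosen at
random, same effect direction, rounding half up).  Per subgroup `s`, the
disease frequency `K_s` is the scenario's case allocation divided by the
subgroup size, and the penetrances solve `f_n = K_s / (p_s RR + 1 - p_s)`,
`f_c = RR f_n` — the mixture identity `p f_c + (1-p) f_n = K` holds
exactly by construction, and infeasible combinations (`f_c > 1`) raise.
Power genes are chosen with cumulative rare-variant frequency nearest 10%
(~20% carriers) and at least 10 carriers; for few-cases designs whose
implied `K` is large (50 cases of 150 analyzed means K = 1/3) the
selection additionally requires the causal-carrier frequency in the case
subpopulation to clear the solvability bound `(RR K - 1)/(RR - 1)`.

Evaluation: `fp = #{p <= alpha}/G` with the adjusted prediction interval
`alpha +/- Z_{0.975/#methods} sqrt(alpha(1-alpha)/G)`.  The interval is
centered at the nominal level by default — that is how the printed
per-table interval is used to flag methods — with an observed-centered
variant available.  Power is the rejection fraction pooled over genes and
replicates.  Pretreatment (similarity matrix, PCA, distances, neighbor
graph, permutation set, gene filter, carrier matrix) is computed once per
dataset and reused across replicates.  Replicate seeds derive
deterministically from the master seed.  For per-replicate small-sample
subsets, LocPerm neighborhoods come from the full-cohort PC coordinates
restricted to the subset rows (a per-replicate re-PCA of each 1050-sample
subset would dominate runtime and changes distances only marginally); the
permutation set is resampled per replicate because the subset changes.

## Problem sizes and numerical choices

The shipped benchmarks use desk-scale versions of the study designs,
chosen to keep every suite re-runnable while leaving the qualitative
contrasts unambiguous: null calibration on 1 subpopulation x 500 samples,
2000 genes, 5 replicates (~10,000 gene-tests per method); the
stratification contrast on 4 x 200 samples, 2000 genes, 5 replicates;
power on 1500 samples, 10 genes x 100 replicates per RR in {1,2,3,4}; the
few-cases comparison on a 4 x 600 cohort with 10 genes x 20 replicates.
Monomorphic variants are excluded from gene selections (no carriers,
undefined WSS weight) and from every similarity class; all-missing
variants get an undefined MAF and are likewise excluded.  Eigenvalues are
clipped at zero within PSD tolerance; eigenvalue ties keep original order;
neighbor-distance ties break toward the lower sample index.  MAFs are
folded on integer allele counts so boundary values (exactly 0.05) are not
perturbed by floating-point subtraction.

## Known limitations

* The LMM treats the binary trait linearly; with very unbalanced designs
  its type-I error drifts upward (visible in the benchmarks as values near
  the top of the interval), consistent with how such linearizations
  behave.
* The semi-empirical p-value rests on a normal fit to a discrete
  statistic; for genes with few carriers the tail approximation is rough,
  which is why calibration is always judged against the prediction
  interval rather than pointwise.
* Irreducibility of the constrained-permutation chain over the entire
  feasible set is not guaranteed for arbitrary neighbor graphs (a known
  subtlety of constrained-permutation samplers); diagnostics (acceptance
  rate, burn-in, thinning) are exposed on the returned object.
* SKAT-style variance-component tests, read-level QC, kinship-based
  relatedness pruning and tool benchmarking are out of scope.
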