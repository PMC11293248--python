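# Methods

## Background and model

Complex biological systems often pass through an unstable *critical state*
immediately before a qualitative transition — here, the progression of a
chronically injured (cirrhotic) liver to hepatocellular carcinoma in a
carcinogen-induced mouse model sampled monthly.  Dynamic network biomarker
(DNB) theory predicts that as the system approaches the tipping point, a
small *dominant group* of genes appears whose members

1. fluctuate more (their per-time standard deviations SD_i rise),
2. co-fluctuate more (their mutual absolute Pearson correlation PCC_i
   rises), and
3. decouple from the rest of the transcriptome (their correlation to
   non-members, PCC_o, falls).

The three signatures combine into the criticality index

    CI(t) = SD_i(t) * PCC_i(t) / (PCC_o(t) + eps),

computed for the best candidate group at each time point; the time point at
which CI peaks is reported as the tipping point.  `eps` (default 1e-3)
guards the denominator; activation of the guard is logged.  The algebraic
form is isolated in `dnb_core.compute_ci` so a size-weighted variant can be
swapped in without touching the scan.

## Dominant-group search

At each non-baseline time point `t`:

1. **Candidate screen.**  Genes whose sample SD at `t` is at least
   `sd_fold` (default 1.5) times their *reference SD*.  The reference is
   the per-gene **median SD over all other time points**
   (`sd_reference="median"`); the SD at the baseline month alone is
   available as `sd_reference="baseline"`.  With r = 4 replicates a
   per-time SD estimate has 3 degrees of freedom; a single-time reference
   makes the screening ratio an F(3,3) variable under the null, passing
   ~14% of null genes at fold 2, whereas the median reference is stable
   (~21 df).  The fold default is deliberately liberal: requiring the full
   design effect (3-fold inflation) *in-sample* at 3 df would miss ~25% of
   true members per gene; specificity is delegated to the next two stages.
2. **Candidate clustering.**  Average-linkage hierarchical clustering on
   correlation distance 1 − |r|, cut at `linkage_cut` (default 0.65),
   discarding clusters smaller than `min_group_size` (default 5).  By
   default the correlation used here is **pooled across all time points
   after centering within each time point** (`cluster_corr="pooled"`).
   Module membership is time-invariant, so pooling is valid for discovery
   and raises the degrees of freedom from r − 1 = 3 (where the null |r| is
   exactly uniform on [0,1], i.e. useless for clustering) to
   T·(r − 1) = 24.  Within-time centering removes mean shifts, so
   differential expression does not masquerade as co-fluctuation.  The cut
   0.65 sits between the expected pooled correlation distance inside a
   strongly co-fluctuating module (~0.45 under the default tipping
   signature) and the null expectation (~0.84 at 24 df).
3. **Scoring and selection.**  Each surviving cluster is scored by the CI
   computed from the *per-time* SDs and correlations at `t` (the pooled
   matrix is never used in the CI itself).  The dominant group is the
   cluster maximizing sqrt(N) · CI (`selection_weight="sqrt_n"`): with few
   replicates, small spurious clusters reach high CI by selection effects
   alone, and group size is the most robust feature distinguishing a real
   module.  Reported CI values are always the unweighted form above;
   `selection_weight="none"` restores the literal max-CI rule.

The baseline month is assigned CI 0 with no group.  Ties at the peak
resolve to the earliest month (logged); a series with no group anywhere is
flagged `"no transition detected"`.

## Significance

`permutation_test` shuffles the sample-to-time assignment wholesale,
recomputes the peak CI for each permutation, and reports
p = (1 + #{null peak ≥ observed}) / (n_perm + 1).  Under exchangeability
(no planted transition) this p-value is calibrated; the acceptance suite
verifies the type-I rate at alpha = 0.05 over 200 null simulations.  Note
that with a genuine transition the permuted arrangements retain the
inflated-variance samples wherever they land, so the null is conservative
rather than arbitrarily far below the observed peak.

## Differential expression and temporal patterns

The across-time screen is a per-gene one-way ANOVA over the T time groups;
per-month DEG sets are two-sided Welch t-tests of each later month against
month 1.  Both use Benjamini–Hochberg step-up control within the test
family (`bh_adjust`, capped at 1, input order preserved).  Constant genes
are untestable and get p = 1 with a log entry.  Temporal profiles
(per-time means, z-scored across time with ddof = 1) are soft-clustered by
classic fuzzy c-means (fuzzifier m = 2, c = 9 patterns by default,
Euclidean distance, membership update u ∝ (1/d²)^{1/(m−1)}).  Initial
centroids are chosen by a seeded RNG *after* putting profiles in a
canonical lexicographic order, so results are independent of input row
order; a profile exactly on a centroid receives membership 1 there.

## Prioritization

DNB genes (the detected tipping group) are ranked by four criteria:
(1) fraction of network neighbors that are DEGs, (2) number of annotated
pathways containing the gene, (3) DEG status (0/1), (4) membership in one
of the temporal clusters (0/1, cluster id reported).  The default
combination is strict lexicographic descending order over (1)–(4) with
gene-id tie-break; `ranksum` (mean of per-criterion competition ranks) is
the documented alternative.  Genes missing from the network or annotation
score 0 on the affected criterion rather than being excluded, keeping the
ranking total.

## Focal-gene subnet

`subnet_dynamics` ranks all genes by |Pearson r| to a focal gene within
each month (competition ranking, ties share the smaller rank), aggregates
months by mean rank into an overall top-k (default 20), and expresses
correlation weights of a gene set around the tipping point (months
{t* − 1, t*}) as shares normalized within the evaluated set (an
"all-genes" denominator is available, under which shares no longer sum
to 1).  "Correlation weight" is read as |r| by default; signed and
squared-r variants are options of `focal_correlations`.

## Synthetic data generator

The generator emulates the targeted study design: T = 8 monthly time
points with r = 4 replicates, 500 genes, a 10-gene module, tipping at
month 6.  Samples at each month are drawn from a multivariate normal whose
covariance is built block-wise: module variance sigma0² (SD multiplied by
3 at the tipping month), intra-module correlation 0.2 (0.8 at tipping),
module-background correlation 0.2 (0.02 at tipping), independent
background.  Placing the transition directly in the covariance gives exact
control of the three DNB signatures; the tipping signature is placed only
at t* (abrupt transition), not ramped.  100 background DEGs receive mean
shifts of 2.0 log2 units concentrated at month 2 (down) and month 6 (up).

A feasibility constraint shapes one design choice: a 10-gene module with
intra-correlation 0.2 cannot be correlated at 0.2 with hundreds of
mutually independent background genes (the block matrix is far from
positive semidefinite, and projecting it back would manufacture
background–background correlation, contradicting the independent-background
design and planting spurious modules).  The module-background coupling is
therefore applied to a small background subset (`n_coupled_background`,
default 5), which keeps every stated correlation value and makes both
covariance matrices exactly PSD.  A diagonal-preserving nearest-PSD repair
remains in place (and is logged) for user configurations that are
indefinite.

The companion network generator wires an Erdős–Rényi background
(edge probability 0.04) and resamples the neighborhoods of module genes so
the planted top gene's neighbors are DEGs with probability 0.9 versus 0.3
for other module genes; the pathway generator gives the top gene strictly
more pathway memberships than any other module gene.  All generator
outputs are deterministic functions of the seed.

What the generator does **not** emulate: count noise (negative binomial
overdispersion), library-size effects, batch structure, heavy-tailed or
skewed expression, autocorrelated dynamics (an Ornstein–Uhlenbeck mode was
considered and left out; the per-time MVN gives exact moment control), and
gradual ramps into the critical state.  Passing recovery tests therefore
demonstrates correctness of the machinery under idealized Gaussian
conditions, not performance on real RNA-seq.

## Numerical and degenerate-input conventions

- Sample SD uses ddof = 1 throughout.
- Correlations involving a zero-variance gene are recorded as 0 (logged);
  correlation matrices are clipped to [−1, 1] with unit diagonal.
- Genes with zero reference SD in the candidate screen are compared
  against the global median reference SD (logged).
- Linkage ties are made deterministic by sorting candidates
  lexicographically before clustering.
- BH q-values are computed by the step-up definition and verified against
  an independent brute-force implementation and statsmodels.
- The IHC rule leaves the attainable product 6 between its printed "below
  6 = low" and "7 and above = high" bands; 6 is labelled low so that
  "high" is exactly ≥ 7, and the gap is logged when hit.
- Expression values are treated as already normalized/log-scale; CI values
  are therefore unit-dependent and comparable only within one data set.

## Problem sizes

The recovery study uses 100 independent simulations of the default
conditions and the calibration study 200 null simulations with 19
permutations each; these sizes keep the full suite within a few minutes on
one CPU while leaving the binomial confidence bands informative.

## Known limitations

Four replicates per time point is a hard statistical ceiling for this
method family.  The sampling distribution of |r| between independent genes
at r = 4 is uniform, so per-month correlation carries almost no
information; a per-month SD estimate has 3 df; and because module members
share a common factor, their sample SDs at the tipping month co-inflate or
co-deflate — in roughly a fifth of simulations the planted signature is
simply not realized in the drawn samples, and no estimator could recover
it.  Measured under the default conditions: the tipping month is recovered
in ~78/100 seeds, the median Jaccard overlap between the detected group
and the planted module is ~0.47, and the planted top gene reaches rank 1
in ~43/100 seeds (the latter two are limited by the same membership
recall).  The corresponding acceptance tests assert the stricter
aspirational rates and are expected to fail at these replicate numbers;
they are kept strict deliberately rather than weakened to match the
measured ceiling.  The permutation test, by contrast, is well calibrated,
and all exact-rule and oracle-equivalence checks pass to 1e-10.
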