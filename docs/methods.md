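# Methods

## Generating models

### Quantitative traits (study 1)

Three linear-Gaussian structural models over a SNP instrument G (coded
0/1/2), a continuous instrument Z, an exposure X and an outcome Y; all
structural equations have residual SD 1 (configurable via
`residual_sd`):

* **model 1** (no confounding): `X ~ N(b_GX G, 1)`,
  `Y ~ N(b_XY X + b_ZY Z, 1)`;
* **model 2** (non-genetic confounding): a latent `C ~ N(0,1)` enters
  both equations with coefficients `b_CX`, `b_CY`;
* **model 3** (genetic confounding): a mediator `S ~ N(b_GS G, 1)`
  feeds Y with coefficient `b_SY`, so G reaches Y around X.

Reversed causation (`direction="y_to_x"`) swaps the structural roles of
X and Y while the instruments keep their targets:
`Y ~ N(b_ZY Z [+ confounding], 1)`, `X ~ N(b_YX Y + b_GX G [+ ...], 1)`.
Exactly one of `beta_XY`/`beta_YX` may be nonzero; the constructor
enforces this.

Default coefficients follow the published presets: instrument strengths
`b_GX = 0.1`, `b_ZY = 0.075`; the four confounding coefficients are all
0.25 (weak) or 0.5 (strong); the causal effect is varied over 0–0.5;
n = 2500 per dataset. The generating description leaves three marginal
laws unspecified, so the package fixes them as: G ~ Binomial(2, maf)
with maf 0.3 (configurable) under Hardy–Weinberg proportions; Z and C
standard normal. These choices match the variables' descriptions (a
SNP, a continuous allele-count-like score, a generic confounder) and
are validated by analytic variance/correlation oracles in the tests.

### Binary traits (study 2)

Four Bernoulli nodes generated in topological order on the graph
Q → W → H → Y (with Q → H, Q → Y, W → Y, H → Y), using inverse-logit
links: `P(Q=1) = freq_Q` and, e.g.,
`logit P(W=1) = delta_0 + delta_q Q`. The four published coefficient
scenarios A–D are available as presets (`scenario("C")`), with
`freq_Q = 0.49` and n = 5000. A logistic link is the only reading
consistent with the negative coefficients in the published table (an
additive-probability model would leave (0,1)); the scenario-B mixture
oracle `P(W=1) = 0.51 expit(0.2) + 0.49 expit(0.5)` in the tests pins
both the link and the coefficient layout.

### Pleiotropy (study 3)

10,000 SNPs under HWE with MAF ~ Uniform(0.01, 0.5): 150 drive the 12
metabolites through a sparse effect matrix, 75 distinct SNPs act
directly on the outcome Y, and 9775 are null. Four metabolites are
null, four causal on Y and four reverse-caused by Y, every coupling
with coefficient 0.3 and residual SD 1 ("standard error set to 1" is
read as unit residual SD throughout).

The real design drew SNP–metabolite coefficients from an external GWAS;
those are not reproducible offline, so `generate_snp_effects` draws a
synthetic stand-in: each SNP–metabolite entry is nonzero with
probability `sparsity = 0.1` (row/column coverage forced so every SNP
affects ≥ 1 metabolite and every metabolite has ≥ 1 SNP), and nonzero
per-allele effects are `±|N(0.3, 0.05²)| / sd_allele`, i.e. a
standardized magnitude of about 0.3. With ~15 SNPs per metabolite this
puts each instrument SNP at r² ≈ 0.04 of its metabolite, so at
n = 1000 most metabolites have several SNPs passing the p < 5×10⁻⁶
selection threshold, as the re-constructed allele scores require. The
75 outcome-SNP coefficients are drawn from the same law (the original
design recycled coefficients of a discarded metabolite). A loader for
a user-supplied coefficient CSV is provided
(`EffectTable.read_csv`/`write_csv`).

What the generator does **not** emulate: linkage disequilibrium between
SNPs (instruments are independent, as in the published design), the
empirical distribution and genetic correlations of real metabolite GWAS
coefficients, and family/twin structure. Passing tests therefore show
method behaviour under idealized independent instruments, not
robustness to correlated or weak real-world instruments.

## Mendelian randomization

`fit_2sls` implements two-stage least squares directly from the normal
equations. Both modes share the point estimate; they differ only in the
residual vector used for the standard error (observed-exposure
residuals in the corrected/IV mode, predicted-exposure residuals in the
uncorrected MR′ mode). p-values use a t distribution with n − 2 df; at
n in the thousands the difference from a normal approximation is
immaterial but the t form is kept for exactness at small n. The
single-instrument identity between MR′ and the outcome-on-instrument
regression is exact and tested at machine precision.

`build_allele_score` re-estimates per-SNP weights within each dataset
by marginal regressions of the target on each SNP (vectorized
closed-form), keeps SNPs with p < 5×10⁻⁶, and returns the weighted
allele count. An empty selection yields a flagged invalid score rather
than an exception so replicate loops keep running.

`steiger_direction_test` uses the Steiger (1980) Z̄ test for two
dependent correlations sharing one variable (Fisher z-transforms; the
same form implemented by `psych::r.test`), applied to |r| since the
question is instrument suitability, not sign. The published procedure
names no specific variant; this shared-variable form is the natural one
and is mirrored by an independently coded oracle in the tests. Both
gates (first-stage association, direction test) default to the MR alpha
threshold and are configurable.

## Bayesian networks

### Scoring

BIC on the "higher is better" scale,
`loglik - (d/2) log n` per node. Gaussian nodes: OLS fit with
intercept, MLE variance (divisor n), `d = #parents + 2`; a variance
floor of 1e-12 guards degenerate bootstrap columns. Multinomial nodes:
counts over parent configurations with declared (not observed) level
sets, so the parameter count `d = (L-1) * prod(parent levels)` is
stable when a resample drops a level; zero-count cells contribute 0.
Mixed continuous-parent/discrete-child scoring is not supported — each
study declares a homogeneous treatment (all-continuous for studies 1
and 3, even for the 0/1/2-coded SNPs; all-multinomial for study 2).

### Search

Hill climbing evaluates all legal single-edge additions, deletions and
reversals (acyclicity via incremental reachability; blacklist respected;
whitelist edges protected), applies the best strictly-improving move
(tolerance 1e-9) and stops at a local optimum. Ties are broken
deterministically: smallest from-index, then to-index, then
add < delete < reverse. Local scores are cached per (node, parent set).

Plain greedy search provably stalls on covered-edge plateaus, where an
improving deletion is reachable only through a score-neutral reversal;
this was observed on a substantial fraction of small random
linear-Gaussian datasets. `hill_climb` therefore defaults to 50 seeded
random restarts (random legal start graphs, best local optimum kept,
deterministic given the seed), which restores agreement with the
exhaustive-search oracle on all tested 3–4-node datasets; `restarts=0`
recovers the plain greedy variant.

The exhaustive oracle enumerates every constraint-respecting DAG over
≤ 5 nodes (three orientation states per node pair, acyclicity filtered;
25 DAGs at 3 nodes, 543 at 4 — matching the labelled-DAG recurrence)
and sums cached local scores.

### Bootstrap averaging

B nonparametric resamples (rows with replacement); replicate i uses an
independent generator derived from (seed, i), so results are invariant
to execution order and a parallel map would reproduce the serial
output (the implementation runs serially). A resample that leaves any
column constant is redrawn from a further-derived stream and counted.

Each replicate's climb starts from a *random legal start graph* (each
node pair gets an edge with probability 1/2 in a random orientation,
subject to constraints and acyclicity). This is the one place where
the search is deliberately randomized: orientations inside a Markov
equivalence class are not identified by the score, and a fixed start
plus deterministic tie-breaking would resolve every such orientation
the same way in all B resamples, collapsing direction probabilities to
0 or 1. With random starts the unidentified orientations are resolved
symmetrically across replicates, which is what makes unanchored
direction probabilities hover near 0.5 ("no better than chance") and
gives anchored networks honest intermediate direction probabilities.
A consequence worth knowing: direction probabilities for edges whose
orientation is only weakly identified (e.g. the Y–W edge in binary
scenario C, where a two-edge chain and a three-edge fork fit almost
equally well) are sensitive to this resolution mechanism and to the
dataset draw; across dataset seeds the scenario-C Y→W direction
probability ranges roughly 0.75–0.88.

The averaged-network inclusion threshold minimizes the L1 distance
between the empirical CDF of pair strengths and the ideal degenerate
step CDF, by brute-force search over observed strength values; edges
with strength ≥ threshold are reported, oriented by majority direction,
with an exact 0.5 split broken to canonical node order and flagged
ambiguous.

## Evaluation harness

`run_experiment` loops over replicates of the quantitative study,
deriving each replicate's simulation and bootstrap seeds from
(config.seed, replicate), and records p-values (MR, MR′, MR Steiger
with either candidate instrument) and directed-edge bootstrap
probabilities (BN with any anchor subset of {G, Z}). Detection uses
strict comparisons — p < alpha for p-value methods, probability >
threshold for BN — over the grids {0.01, 0.05, 0.1} and
{0.7, 0.8, 0.9}; no multiple-testing adjustment is applied anywhere
(thresholds are heuristics, as in the source analyses). Monte-Carlo
standard errors are sqrt(p(1-p)/R). ROC curves sweep the pooled
replicate values and support both no-effect and wrong-direction null
sets. Method failures within a replicate are recorded (NaN, counted)
without aborting the loop; NaNs count as non-detections.

The pleiotropy study is analysed per replicate
(`analyse_study3_replicate`): allele scores are re-built within the
replicate for each metabolite and the outcome; MR tests run in both
directions; the B1 layout learns one 4-node network per metabolite
(metabolite, outcome, their two scores) and B12 one joint network, with
every score node pinned by a single-outgoing whitelist/blacklist
pattern to its instrumented variable.

## Problem sizes used by the shipped checks

The full published scale (1000 replicates × 1000 bootstraps, 10,000
SNPs) is available through the configuration objects. The shipped test
and acceptance runs use sizes chosen to keep a desk run in minutes
while leaving Monte-Carlo error well below the margins being asserted:
R = 1000 for pure-MR calibration/recovery/gating checks (n = 2500);
B = 200 with 30 replicate datasets for equivalence-class symmetry;
R = 200, B = 100 for the BN power-ordering and ROC-dominance checks;
the binary scenario-C network runs at full scale (n = 5000, B = 1000);
study-3 checks scale the SNP panel down (e.g. 600 SNPs, n = 800) while
preserving the 150/75-style causal structure.

## Known limitations

* Mixed discrete/continuous networks are out of scope by design.
* The bootstrap direction probabilities inherit the random-start
  resolution described above; quantities that depend on orientation
  within an equivalence class are reproducible under a fixed seed but
  implementation-sensitive in distribution.
* MR estimates with the default weak instrument (b_GX = 0.1) have heavy
  tails at n = 2500; mean-recovery statements are Monte-Carlo
  statements over many replicates, not single-dataset guarantees.
* The LCV, SMUT and multivariable-MR comparators of the source
  analyses, and any real-data application, are outside this package.
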