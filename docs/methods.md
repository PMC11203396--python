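# Methods

## The two-compartment deconvolution model

A bulk tumor sample is modeled as a mixture of two cell populations — cancer
(malignant) cells and stroma (all nonmalignant cells, including immune
infiltrate) — with the tumor purity `p_i` as the mixing weight. For a single
gene and a group of samples,

    e_i = p_i * c + (1 - p_i) * s + eps_i ,     c >= 0, s >= 0,

where `c` and `s` are group-level compartment means on the scale of the
supplied expression values. The design columns `p` and `1 - p` sum to one, so
the model has no separate intercept; the two compartment means jointly play
that role. The assumptions worth keeping in mind:

- **Group-level means, not per-sample expression.** The fit recovers the
  average compartment expression of a sample group; per-sample compartment
  values are not identified.
- **Scale.** The pipeline convention is normalized log2 expression, matching
  how the differential-expression thresholds are defined. On the log scale
  the linear mixing identity holds only approximately (the log of a mixture
  is not the mixture of logs), so compartment estimates are biased toward the
  bulk value and strong effects in one compartment partially *leak* into the
  fitted mean of the other. Inference is unaffected in the null sense — the
  permutation test is exact regardless of scale — but compartment assignment
  of very strong signals is sharper the closer the data is to the linear
  mixing scale. Ground-truth recovery oracles therefore run on the linear
  pre-rescaling mixture, where recovery is exact at zero noise.
- **Purity spread.** With all purities equal the two means are confounded
  with the sample mean; such fits raise `UnidentifiableGeneError` (or are
  carried as NaN marker rows in group tables, never silently dropped).

NNLS is solved per gene (scipy) and, for transcriptome-wide permutation
loops, by a closed-form vectorized solver: the unconstrained 2x2
normal-equation solution, falling back to the better of the two
single-compartment clamped candidates by residual sum of squares — the exact
NNLS solution for two coefficients. The batch solver is cross-checked against
scipy and a dense grid-search oracle in the test suite.

### Standard errors

The SE of a fitted compartment mean is the predicted-mean SE of the
regression line at purity `p_h` (1 for cancer, 0 for stroma):

    SE_h = sqrt( MSE * ( 1/n + (p_h - p_bar)^2 / Sxx ) ),   Sxx = sum (p_i - p_bar)^2

with `MSE = RSS / (n - 2)` by default (two fitted parameters; a divisor of
`n` is available via `mse_divisor`). This formula assumes an unconstrained
fit; when a compartment is clamped at zero the value is still reported and
the `clamped` flag set — downstream inference is carried by the permutation
test, for which the SE only standardizes the statistic. Monte-Carlo
calibration (n = 200, Beta(5,3) purity, Gaussian residuals, 2,000 replicates)
puts the empirical-SD-to-analytic-SE ratio within a few percent of 1 for
interior solutions.

## Permutation differential expression

For each gene and compartment the statistic is the standardized group
difference `T = (m_A - m_B) / sqrt(SE_A^2 + SE_B^2)`; a raw-difference
variant (`stat="raw"`) is provided, since the permutation null guarantees
calibration either way. Conventions, chosen where the procedure leaves room:

- **Add-one p-value** `p = (1 + #{|T*| >= |T_obs|}) / (1 + n_perm)`: p is
  never zero (required by Fisher combination downstream) and ties count
  toward the numerator (conservative).
- **Two-sided by |T|**; |T| is invariant to exchanging the group labels, so
  swapped labels give identical p-values.
- **Zero-SE conventions**: delta = 0 with zero SE gives T = 0; nonzero delta
  with zero SE gives a signed infinity that outranks every finite null value.
- **One shared permutation stream per cohort** (permutation-once design): all
  genes see the same label shufflings, which makes runs deterministic given a
  seed, keeps gene-level nulls exchangeable across genes, and lets the whole
  transcriptome be processed with two matrix products per permutation. The
  stream is a cohort-level choice, so p-values across genes are positively
  dependent in small designs where `n_perm` exceeds the number of distinct
  assignments; per-gene validity is unaffected (verified against exhaustive
  enumeration on 4-vs-4 designs).
- **Discreteness**: a design with `C(n, n_A)` distinct assignments cannot
  produce p-values below the reciprocal of that count (35 effective levels
  for 4-vs-4 after complement symmetry); at nominal levels below the grid the
  test is conservative by construction.

## Cross-cohort consensus

Per-cohort p-values are combined with Fisher's method
(`X = -2 sum ln p_k ~ chi2(2K)`); cohorts missing a gene reduce K, and genes
observed in fewer than two cohorts are dropped. Multiple testing uses
Bonferroni with the family defined per compartment (m = genes tested in that
compartment; `family="joint"` doubles it) and alpha = 0.01. Two filters
operationalize "differentially expressed" as nominal p < 0.1 — the only
nominal threshold the procedure fixes:

- **Direction conflict**: a gene supported at p < 0.1 in opposite directions
  by at least one cohort each is removed. The consensus direction is the sign
  of the (-log10 p)-weighted majority of per-cohort fold-change signs; a tied
  weight counts as a conflict.
- **ICB support**: at least one clinically annotated ICB cohort must reach
  p < 0.1 *in the consensus direction*. Direction concordance is required
  here as a design choice — without it an opposing signal could satisfy the
  filter.

The ligand-receptor survey reports, per gene and compartment, the median over
ICB cohorts of `sign(log2FC) * (-log10 p)`, shown only for genes reaching
p < 0.1 in at least 3 ICB cohorts; a pair is *coordinated* when ligand and
receptor both qualify in the same compartment with the same sign. The bundled
checkpoint and cytokine pair tables are curated starter lists and are
deliberately user-editable fixtures, not a fixed reference. (The survey
threshold is implemented as p *below* 0.1; the alternative reading of the
threshold direction would survey only non-significant genes, which is
inconsistent with the rest of the procedure.)

## Response classifiers

- **IOSelect score**: mean normalized log2 expression of the 10-gene up set
  divided by that of the 8-gene down set. Log2-normalized input is the
  default (the scale on which the DEGs are defined); samples with a
  nonpositive down-set mean get NaN with a warning. Genes absent from a
  matrix are tolerated up to 25% per set.
- **Cytolytic score** on linear TPM; **VIGex** as the mean of within-cohort
  z-scored expression of its fixed 12-gene panel. Standardization is
  deliberately asymmetric: TMB and model features use training-set z-score
  parameters on test cohorts, while VIGex is within-cohort by its published
  definition.
- **Logistic models** are unpenalized maximum-likelihood fits; perfect
  separation is flagged (provenance `separation_flag`) rather than raised,
  since ranking metrics remain well defined.
- **Stability selection**: 100 resamples of `ceil(0.9 n)` samples drawn
  *without* replacement by default ("90% of the data"; bootstrap resampling
  available), an L1-penalized logistic path per resample on a glmnet-style
  grid (lambda_max = max |X'(y - y_bar)|/n, 15 points over three decades,
  sklearn-liblinear backend with C = 1/(n lambda)), the penalty chosen by
  stratified 10-fold CV as the largest lambda whose mean deviance is within
  one **SD** of the minimum, and features kept at selection frequency >= 0.75.
  The one-SD band (rather than the one-SE band common in CV folklore) is the
  procedure's stated rule and is the more conservative choice; with the SE
  band, chance-correlated noise features survive in roughly half of simulated
  datasets at the default study size, while the SD band recovers exactly the
  planted features. `rule="se"` restores the SE convention.
- **AUC** is the Mann-Whitney probability that a random positive outranks a
  random negative, ties at 1/2; model comparisons use a paired t-test on
  per-cohort AUCs, with zero-variance difference vectors flagged as
  degenerate instead of fabricating a t statistic.

## The synthetic study generator

The generator inverts the mixing model: per gene and sample, linear-scale
bulk expression is `p * 2^c + (1-p) * 2^s` times `2^N(0, noise_sd)` noise,
then rescaled per sample to TPM (columns sum to 1e6). It emulates the
structure the pipeline is designed to detect, with all distributional choices
being stand-ins — the upstream study design does not specify a generative
model:

- **Layout**: 4 ICB cohorts (n = 45, 298, 118, 73, mirroring typical
  published checkpoint-blockade series) and 3 proxy cohorts (n = 300);
  responder fractions 0.25/0.20/0.30/0.45 (ICB) and enriched fractions
  0.15/0.20/0.30 (proxy).
- **Purity** ~ Beta(5, 3) (median ≈ 0.64, a TCGA-like consensus-purity
  spread), configurable.
- **Effects in log2 units**: a stroma-shared responder effect (±1 log2FC by
  default) applied identically in every cohort, and cancer effects of equal
  size each confined to a single cohort. Planted sets are disjoint.
- **Proxy label fidelity**: the "responder-enriched" group contains true
  responders at rate 0.4 (clinically, roughly 30–50% of MSI tumors respond),
  with a 5% background responder rate among the remaining samples (MSS
  response rates are below 10%). Expression and TMB follow the *true*
  response, labels the enriched grouping — so proxy cohorts carry diluted
  signal, exactly the situation the ICB-support filter addresses.
- **Baselines**: cancer log2 means uniform in [2, 10]; the compartment
  divergence log2(stroma/cancer) is N(0, 1.5) for null genes, while planted
  stromal DEGs are drawn stroma-dominant (divergence N(+2, 0.5)) and planted
  cancer DEGs cancer-dominant — immune and checkpoint genes are
  predominantly expressed by stromal cells, and the MSI-biology genes the
  cancer compartment picks up are cancer-intrinsic. Without this, a stromal
  effect on a gene whose expression is dominated by cancer cells is close to
  undetectable in bulk at realistic depth, which is a statement about bulk
  deconvolution, not about the planted biology.
- **Noise** is multiplicative `2^N(0, 0.3)` by default — the SD is in the
  same log2 units as the effects.
- **TMB** is log-normal, medians ~10 (responders) vs ~4 mutations/Mb.

What the generator does *not* emulate: count-level sampling noise and
library-size effects, gene-gene correlation, batch effects between cohorts,
purity estimation error (purities are passed to the pipeline as known), and
cohort heterogeneity in effect size. Passing tests therefore demonstrate the
pipeline's statistical behavior under its own model assumptions — exactness,
calibration, and recovery where signal is identifiable — not robustness to
every failure mode of real cohort data.

One coupling is worth knowing about: TPM rescaling ties each sample's scale
factor to the planted signal (responder samples have slightly different
totals). At realistic noise this is negligible, but at exactly zero noise it
dominates every gene; zero-noise recovery oracles therefore run on the
pre-rescaling mixture, which the generator exposes as a diagnostic
(`CohortData.premix`, alongside `true_response`).

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` exercise the pipeline at 400 genes
(20 stroma-up, 20 stroma-down, 14 cohort-private cancer genes), 2,000
permutations, 2,000 null genes for calibration, 20,000 genes for the
global-null consensus count, and 100-resample stability selection — sizes
chosen so the full battery runs in minutes on one core while keeping every
statistical check at a scale where its expected behavior is unambiguous.
Transcriptome-scale inputs run through exactly the same code paths; the
permutation engine processes all genes simultaneously, so cost grows linearly
in genes x samples x permutations.
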