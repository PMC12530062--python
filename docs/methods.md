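# Methods

## Model

`emixed` estimates the cell-type composition of bulk tissue samples from two
molecular modalities, separately or jointly, using allocation mixture models
with closed-form EM updates.

**RNA.** Each sequenced read of sample *n* is assigned a cell type
*k* ~ Multinomial(1, θ<sub>n</sub>) and then a gene
*i* ~ Multinomial(1, A<sub>·k</sub>), where A is the reference profile
(genes × cell types, columns normalized to sum 1). Marginally the gene
counts are X<sub>·n</sub> ~ Multinomial(R<sub>n</sub>, A θ<sub>n</sub>), a
mixture of multinomials — the same structure as a topic model with genes as
words, cell types as topics and samples as documents. The EM steps are

- E: ψ<sub>ik</sub> = X<sub>i</sub> A<sub>ik</sub> θ<sub>k</sub> / Σ<sub>k′</sub> A<sub>ik′</sub> θ<sub>k′</sub>
- M: θ<sub>k</sub> = Σ<sub>i</sub> ψ<sub>ik</sub> / Σ<sub>ik′</sub> ψ<sub>ik′</sub>

The observed-data log-likelihood Σ<sub>i</sub> X<sub>i</sub> log(Aθ)<sub>i</sub>
is concave in θ, so the EM optimum does not depend on the starting point;
we initialize uniformly.

θ is a *transcript*-level fraction. Cell types differ in transcripts per
cell, so cell fractions are obtained by dividing by the cell-size vector S
and renormalizing: θ<sup>cell</sup><sub>k</sub> ∝ θ<sub>k</sub>/S<sub>k</sub>.
S can be supplied or derived from per-type average library sizes (rescaled
to mean 1; the formula is scale-invariant). Because this adjustment is a
deterministic bijection of θ that does not enter the E/M updates, it is
applied once after convergence; applying it every iteration would produce
the identical result.

**DNAm.** Each DNA molecule covering CpG locus *g* is assigned a cell type
from θ<sub>n</sub> and is methylated with the known signature probability
π<sub>gk</sub>. Marginally the methylated count is
Binomial(D<sub>gn</sub>, π<sub>g</sub>·θ<sub>n</sub>). The E-step computes,
for methylated and unmethylated molecules separately, the posterior
cell-type responsibilities per locus; the M-step weights them by the
methylated and unmethylated counts. For array data only beta values are
observed; under a large constant per-sample coverage, the count weights
reduce to β and 1 − β — so the array update is the sequencing update with
unit coverage, and with constant coverage both code paths produce identical
iterates (verified to 1e-10 in the tests). DNA copy number per cell is
treated as constant across cell types, so no cell-size correction applies
to this modality. π is fixed and known throughout; re-estimating the
reference from bulk data is out of scope.

**Integration.** Matched RNA and DNAm samples share one true composition.
The integrated estimate is the unweighted mean of the cell-size-adjusted RNA
fractions and the DNAm fractions over the shared cell types, renormalized to
the simplex (a `--weight` flag exists, default 0.5). We average the
cell-size-adjusted RNA fractions, not the raw transcript fractions, because
only those are on the same "fraction of cells" scale as the DNAm estimate;
this is switchable by passing a different table to `emixed multi`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `tol` | 1e-6 | stop when max |Δθ| per iteration falls below this |
| `max_iter` | 1000 | iteration cap; exceeding it flags non-convergence |
| `epsilon` | 1e-6 | π clipped to [ε, 1−ε] so E-step denominators stay positive |
| `quantile_norm` | on | joint quantile normalization in array mode |
| integration weight | 0.5 | RNA weight in the modality average |

The convergence tolerance is on the parameter, not the likelihood, because
the fractions are the quantity of interest and the likelihood can flatten
long before the fractions stabilize in ill-conditioned references.

## Numerical choices

- Genes with zero counts contribute nothing to either EM step and are
  skipped; loci with zero coverage are likewise skipped per sample, not
  imputed.
- A gene with observed reads but zero reference mass under the current θ is
  an error, not silently clipped: it signals a reference/bulk mismatch the
  user must see.
- A reference whose columns are all identical is degenerate (every θ fits
  equally well); it is detected and warned about, and the fit returns the
  uniform fixed point.
- Feature matching between reference and bulk is by exact string identifier,
  taking the intersection in reference order; rows with missing values are
  dropped with a logged count. Non-integer RNA values are accepted with a
  warning (the model is designed for raw counts, but normalized inputs
  should degrade gracefully rather than crash).
- Quantile normalization pools the reference and bulk columns, replaces each
  column by rank-wise means of the pooled order statistics, and gives ties
  the mean of their spanned quantiles; outputs are re-clipped to [0, 1].

## Quantile normalization caveat

Joint quantile normalization exists to remove platform- and batch-level
distributional shifts between an array reference and array bulk data, and is
on by default in array mode. On *clean* simulated beta values it is actively
harmful: a bulk mixture's beta distribution legitimately differs from the
reference columns' distributions, and forcing them to agree distorts the
mixture (MAE ~0.1 vs ~0.001 without). The noise-free identifiability tests
therefore disable it (`quantile_norm = off`), and users fitting data that
share a platform with their reference may wish to do the same.

## Synthetic data

The simulators draw from exactly the generative models above, so estimator
tests are parameter-recovery tests under the model's own assumptions.

- True fractions: symmetric Dirichlet(α), default α = 1 (flat on the
  simplex), emulating a cohort with widely varying compositions.
- RNA reference: a shared per-gene baseline (uniform on [0.5, 1.5]) with an
  equal block of marker genes per type elevated by `marker_strength`
  (default 20, a strong sorted-cell-like signature; the stress tests use 5),
  columns normalized. Library sizes scale with the configured cell sizes.
- DNAm signature: marker loci per type draw Beta(8, 2) in their own type and
  Beta(2, 8) elsewhere, giving the near-0/near-1 bimodality of real
  sorted-cell methylation signatures.
- Bulk RNA: Multinomial(depth, A θ̃) with transcript fractions
  θ̃ ∝ θ·S, so end-to-end tests exercise the cell-size adjustment. Default
  depth 1e5.
- Bulk DNAm: Binomial(D, π θ) per locus — the exact marginal of the
  molecule-level process, which is kept as a slow reference implementation
  and checked against the shortcut by a chi-square goodness-of-fit test.
  Coverage is constant by default (matching the array-mode assumption) or
  per-locus Poisson.
- Reference-noise stress options: multiplicative log-normal noise on A and
  additive truncated Gaussian noise on π, emulating a reference built from a
  different cohort or platform. The integration benchmark uses sd 0.8 on A
  and sd 0.3 on π with marker strength 5, depth 5000 and coverage 30 —
  calibrated so both single modalities are comparably, moderately degraded
  (mean CCC ≈ 0.92-0.93), the regime where averaging is expected to help.

What the simulations do *not* contain: technical over-dispersion beyond
sampling noise, batch effects, probe-level artifacts, correlated errors
across features, or mismatch between the reference's cell-type set and the
tissue's true composition. Passing recovery tests therefore demonstrates
correctness of the estimator under its own model, not performance on real
tissue, where reference quality dominates.

## Evaluation metrics

Lin's concordance correlation coefficient
CCC = 2·cov(x,y) / (var(x) + var(y) + (mean x − mean y)²), with population
(1/n) moments as in Lin's original definition — sample-moment
implementations differ by (n−1)/n factors. CCC penalizes location and scale
shifts that Pearson correlation ignores, and |CCC| ≤ |Pearson| always. MAE
and Spearman correlation (average ranks on ties) complete the report;
`evaluate` computes each per cell type across samples plus the unweighted
mean over cell types. Undefined cases (constant inputs) return NaN by
default or raise on request.

## Problem sizes

The shipped tests and the acceptance script run on deliberately small
instances — tens of samples, hundreds of features, 10-20 replicates —
chosen so the full suite completes in seconds while leaving the measured
errors an order of magnitude clear of their thresholds. All sizes are
arguments, so larger studies are a config change.

## Known limitations

- Modality weights are fixed (default equal); data-driven weighting is not
  implemented.
- The DNAm signature π is never updated from the bulk data.
- No missing-data mechanism: features with missing values are dropped.
- EM converges linearly; for near-degenerate references the iteration cap
  may be reached before `tol` (flagged per sample in the result, and in the
  convergence report the CLI writes).
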