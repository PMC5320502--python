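# Methods

## Data model

A dropout screen is represented by three layers:

- **Library manifest** — one row per hairpin: opaque shRNA id, target gene
  symbol (opaque, case-sensitive; no identifier mapping), barcode, optional
  19-nt hairpin sequence and duplex ΔG (kcal/mol). Barcodes must be unique
  and of a common length; `validate_distances` reports pairs below a
  Hamming threshold. ΔG outside the design window [−32, −28] kcal/mol
  raises a warning, never an error — it is a library-design rule, not a
  property of data being analyzed. Because published per-gene hairpin
  counts and printed library totals can disagree, the manifest validates
  against a *user-declared* expected total rather than a hard-coded one.
- **Count matrix** — integer reads per shRNA per sample, where a sample is
  (cell line, passage, replicate) tagged with its 8-bp sequencing index.
  Unmatched and ambiguous reads are carried per sample so read totals are
  conserved end to end.
- **Gene observations** — for one gene and one (cancer, normal) line pair:
  the transformed reads Y₁ (length n₁), Y₂ (length n₂) with passage
  covariates X₁, X₂.

## Quantification

Index matching is exact: indexes are only 8 bp and carry no declared
error-correction guarantee, so a single tolerated mismatch could collide
two samples. Barcode matching tolerates one mismatch, exact hits taking
precedence; ties at the minimal distance are counted as ambiguous and
discarded. On a barcode set with pairwise Hamming distance ≥ 3 a read with
at most one substitution in its barcode window can never be misassigned
(distance to the true barcode ≤ 1, to any other ≥ 2); the test suite
checks this exhaustively on small manifests. For the default one-mismatch
tolerance the matcher tabulates all 3·L Hamming-1 neighbours of each
barcode once, making per-read matching O(1). Offsets (index start, barcode
start) are 0-based half-open user configuration — amplicon layouts differ
between vector systems, so no default is asserted as universally correct.
Reads are never quality-filtered.

## Normalization

Upper-quantile normalization divides each sample by the 75th percentile of
its *nonzero* counts (sparse count matrices make the all-counts quantile
unstable) and rescales by the geometric mean of those quantiles so values
stay on a count-like scale. The rescale is cosmetic: it shifts all samples
by a common constant and cannot change the sign or ordering of downstream
slopes; consequently, scaling one raw sample by c leaves the normalized
matrix unchanged *up to* a common factor c^(1/K) (K samples), which is the
practical reading of scale-equivariance here.

The Box-Cox transform y → ((y + c)^λ − 1)/λ (ln(y + c) at λ = 0, evaluated
through `scipy.special.boxcox` for numerical stability near λ = 0) uses a
pseudocount c = 1 by default, since barcode counts contain zeros and the
transform needs positivity. λ can be fixed (0.5 reproduces the near-
square-root transform appropriate for overdispersed counts) or estimated
by maximizing the Box-Cox profile log-likelihood on a grid ([−2, 2], step
0.01), pooling all matrix entries as one sample — a single global λ, since
per-sample exponents would put samples on different scales. Degenerate
input (a single distinct value) returns the user default 0.5 with a
warning. Shapiro–Wilk statistics, skewness and kurtosis of pooled per-gene
residuals are reported as diagnostics only and never gate the analysis.

## The cone-restricted bootstrap LRT

Model: per gene and cancer line, Y₁ = β₁₀ + β₁₁X₁ + ε, Y₂ = β₂₀ + β₂₁X₂ + ε,
ε ~ N(0, σ²) iid with a **common variance** across the two lines. The
alternative region is the open cone C = {β₁₁ < 0, β₁₁ < β₂₁ < −β₁₁};
boundary points belong to the null.

- **Unrestricted fit**: per-group OLS; σ̂² = (RSS₁ + RSS₂)/N, N = n₁ + n₂
  (the MLE, not the unbiased estimator — only the RSS ratio matters).
- **Restricted fit**: if the unrestricted slopes are outside C the fit is
  already null-feasible. Otherwise the null projection lies on the cone
  boundary, the two half-lines β₂₁ = ±β₁₁ with β₁₁ ≤ 0. With intercepts
  profiled out, the pooled RSS on each line is quadratic in the common
  slope c with minimizer c = (S₁ₓᵧ ± S₂ₓᵧ)/(S₁ₓₓ + S₂ₓₓ); c > 0 is clamped
  to 0 (the half-line corner, valid by convexity). Both candidates are
  evaluated and the smaller pooled RSS wins — fitting both lines and
  taking the minimum is the restricted MLE by definition, and avoids
  having to pre-select a boundary from the unrestricted estimates.
- **Statistic**: T₀ = N·ln(RSS_r/RSS_u) ≥ 0, clipped at 0 against
  floating-point underflow; RSS_u = 0 with RSS_r > 0 reports +inf with a
  flag.
- **Bootstrap**: residuals of both unrestricted fits are pooled (justified
  by the equal-variance assumption), resampled with replacement into
  groups of n₁ and n₂, and added to the *restricted* fitted values; T\* is
  recomputed by the full chain, M times (default 10,000). Ties T\* = T₀
  count toward the tail. The default p-value is (1 + #{T\* ≥ T₀})/(M + 1),
  bounded away from 0; the raw #/M is also reported. The inner loop is
  vectorized over the M resamples using the closed forms above; a test
  asserts elementwise equality with the explicit scalar chain.

**Observation unit.** n₁ and n₂ default to hairpins × passages ×
replicates per line (every normalized value is one observation; replicates
are stacked, not averaged), with a `replicate-mean` aggregation available.
The passage covariate is the integer passage number (1..5); slopes' signs
do not depend on this coding.

**Determinism.** One root seed; each gene draws its bootstrap stream from
`SeedSequence([seed, sha256(gene)[:4]])`, so results are independent of
gene order and parallelization.

**Calibration.** The bootstrap is consistent at null points away from the
cone vertex: simulations at boundary slopes (−0.3, ±0.3) give empirical
type-I rates of 0.045–0.07 at nominal 0.05. At the vertex itself (both
slopes 0) the test is *conservative* (empirical rate ~0.005): the
restricted MLE that centers the resamples sits on the boundary at |c| > 0,
where the statistic is stochastically larger than at the vertex — the
classic non-regularity of the bootstrap at a cone vertex. The test
therefore never exceeds its nominal level (asserted in the suite as
rate ≤ α + 3 Monte-Carlo SEs) but sacrifices some power for genes whose
true slopes are near zero. Power is nevertheless high at realistic effect
sizes: a cancer-only depletion of 0.5 σ/passage with n₁ = n₂ = 60 is
detected at p ≤ 0.05 in ~97% of simulations.

## Stratification and filters

With k = number of cancer lines where T₀ > 0: group 1 (k = 4), 2 (k = 3),
3 (k = 2), 4 (k = 1 and that line's T₀ > 0.1 — read as a threshold on
−2 ln LRT, consistent with the surrounding statistics); otherwise none.
The threshold comparison is strict (> 0.1). Genes missing a line's
statistic are flagged and never grouped. Multiple-testing adjustment
defaults to Benjamini–Hochberg within each cell line (no procedure is
canonical here; Holm is available). The GSE filter normalizes per-gene
counts to library size (column totals by default), computes tumor/normal
enrichment (+inf over a zero normal count), and passes a gene on
enrichment > 1.5 in ≥ 2 tumor lines *or* ≥ 2 distinct GSEs.

## Simulator

`simulate_manifest` rejection-samples barcodes to a minimum pairwise
Hamming distance (default 3), erroring out on infeasible requests after a
bounded run of rejections. `simulate_screen_counts` draws negative-binomial
counts — counts from pooled PCR + sequencing are overdispersed, and NB
followed by Box-Cox lands close to the Gaussian linear model the test
assumes — with expectation baseline · exp(slope · passage); baselines are
log-normal around a mean depth of 3·10⁶/1,273 ≈ 2,357 reads/hairpin/sample,
matching the screen's design the defaults mirror (6 hairpins/gene, 5
passages, duplicates, four cancer lines + BJ-hTERT). Replicate variability
that grows late in a screen is modelled as log-normal jitter on the NB
mean for passages > 3, with σ = ln(inflation); the default inflation of 1
turns it off so calibration experiments run on clean data.
`simulate_fastq` renders counts to reads (index + barcode at the
configured offsets, random padding to 50 bp, uniform per-base substitution
errors), giving an exact round-trip at error rate 0.

What the simulator does *not* emulate: PCR chimeras and duplicates, index
hopping, infection (MOI) dynamics, guide-specific off-target toxicity, and
any correlation between hairpins beyond their shared gene effect. Passing
recovery tests on simulated data therefore validates the statistical
machinery, not robustness to those artifacts.

## Numerical choices and limitations

- Restricted-fit candidates are compared by pooled RSS; at exact ties the
  antisymmetric boundary (β₂₁ = −β₁₁) is returned — the statistic is
  identical either way.
- RSS ratios are computed directly from sums of squares; T₀ is clipped at
  0; σ̂²_r ≥ σ̂²_u is guaranteed by construction.
- Degenerate inputs fail loudly: constant passage covariate, all-zero
  samples, nonpositive shifted values for Box-Cox, duplicate barcodes or
  indexes.
- The acceptance/experiment scripts use n₁ = n₂ = 60 (6 hairpins × 5
  passages × 2 replicates), M = 499–999 bootstrap replicates and a few
  hundred simulated genes — sizes chosen so the full battery reruns in
  about half a minute while keeping Monte-Carlo error well inside the
  margins being checked; the library default of M = 10,000 is what an
  actual screen analysis should use.
- Asymptotic (chi-bar-squared) p-values, unequal group variances, and
  mixed-effects extensions are out of scope.
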