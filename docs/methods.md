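# Methods

## The model and the test

For each unordered pair of SNPs the scanner fits a logistic regression of
disease status Y (1 = case, 0 = control) on the two additive genotype scores
g1, g2 ∈ {0, 1, 2} and their product:

    logit P(Y = 1) = β0 + β1·g1 + β2·g2 + β12·g1·g2

Epistasis is assessed by a likelihood-ratio test of H0: β12 = 0: the null
model drops the product term, both models are maximized on the same
complete-case rows, and Λ = 2·(ℓ_full − ℓ_null) is referred to the
chi-squared distribution with one degree of freedom. This is the standard
case/control pairwise interaction test (the same 1-df test PLINK's
`--epistasis` implements); the additive coding means β12 is a log-odds
ratio per unit of the allele-count product.

Assumptions worth keeping in mind: the test is asymptotic (the χ²₁ reference
is an approximation that degrades for sparse genotype cells, which is one
reason the MAF filter exists); there is no covariate adjustment; genotype
scores are taken at face value as minor-allele counts, and the direction of
coding does not change the test (only the sign of coefficients).

## Newton solver

Both models are maximized by Newton–Raphson (equivalently IRLS) in double
precision, starting from β = 0. The zero start makes iteration counts and
results exactly reproducible. Convergence is declared when the
log-likelihood change between successive iterations falls below `tol`
(default 1e-8) or the largest coefficient update does; the iteration cap is
25. These mirror common association-toolkit defaults.

Three pathologies are detected rather than silently mis-reported:

* **separated** — a fitted probability hits the clamp bounds
  [1e-10, 1 − 1e-10], a coefficient magnitude exceeds 30, or the response is
  constant (the intercept MLE diverges; this degenerate case is detected up
  front because the likelihood flattens fast enough that the ℓ-change
  criterion would otherwise fire while the intercept is still drifting).
* **singular** — the weighted normal-equations matrix is numerically
  rank-deficient (smallest singular value below 1e-12 of the largest), e.g.
  for a monomorphic SNP among the complete cases; pairs with fewer than two
  distinct observed genotypes at either SNP are flagged singular without
  fitting.
* **max_iter** — the cap was reached without convergence.

A pair's status is the worse of its two fits (converged < max_iter <
separated < singular); only converged pairs carry a statistic and p-value,
and Λ is clamped at zero before the tail call because finite tolerance can
leave a tiny negative difference. Non-converged pairs are excluded from
thresholded output but counted in the run summary. No Firth correction is
attempted for separated pairs; they are simply reported as such.

## Missing data and the MAF filter

Missing genotypes (token `NA` on disk, a reserved sentinel internally) are
handled by complete-case exclusion per pair: an individual missing either
genotype is dropped from that pair's fit, so different pairs may use
different n (reported per pair as N_USED). Missingness is assumed
uninformative.

MAF is computed per SNP over all individuals, cases and controls pooled,
excluding missing entries, and folded to min(p, 1−p). The filter keeps SNPs
with MAF **strictly greater** than the threshold (default 0.15), matching
the convention of keeping "greater than" the cutoff. All-missing columns
have no defined MAF and are dropped by the filter.

## Fragment-tiled enumeration

The SNP axis is partitioned into ⌈M/S⌉ contiguous fragments of S SNPs; the
last fragment is conceptually padded up to S. Padding is pure index
bookkeeping — padded slots cannot appear in any pair. Every unordered pair
is visited exactly once: k(k−1)/2 pairs within each fragment and k_i·k_j
pairs across each fragment pair i < j. Each block is an independent batch, a
pure function of the data and its pair list, so blocks can be distributed
over any number of joblib workers; results are merged and sorted into
canonical order (first SNP index, then second), making the output file
byte-identical across worker counts and fragment sizes.

S defaults to 256. The constraint that S be a nonzero multiple of 32 no
larger than 512 is a GPU-hardware-era recommendation, not a correctness
requirement; off-recommendation sizes warn and proceed, and a dedicated
invariance check (`scan_invariance_check`, also run by `episcan check`)
verifies that results do not depend on S. The historical cap on the number
of individuals (a device-memory limit in the original setting) survives only
as an optional `max_individuals` guard, off by default.

Output rows with p ≤ `p_threshold` (default 0.001; inclusive, so boundary
results are kept) are written as tab-delimited text with columns GENE1,
GENE2, SNP1, SNP2, N_USED, MAF1, MAF2, CHISQ, P, with P in 6-significant-
digit scientific notation. Long scans checkpoint raw passing rows to
`<output>.partial` every `flush_interval` tested pairs (default 100,000);
the final output is written sorted and atomically, and the partial file is
then removed.

## Synthetic data generator

The generator emulates a retrospective case/control association study:
independent SNPs in Hardy–Weinberg proportions (each column Binomial(2,
maf)), disease status from the logistic model above with configurable
baseline log-odds, planted main effects and planted pairwise interactions,
and completely-at-random missingness applied afterward. Case/control quotas
are filled by rejection sampling — simulate a population, keep individuals
until both quotas are met — which is exact and cheap at the scales used
here; a pilot estimate of the marginal case probability rejects
configurations whose rarer class would yield fewer than ~1 individual per
10⁷ draws. The default MAF of 0.3 sits in the middle of the post-filter
(>0.15) range a scan actually sees.

What the generator deliberately omits: linkage disequilibrium, population
structure, genotyping error, informative missingness, and covariates. Tests
passing on this generator therefore certify the statistical machinery
(calibration of the 1-df test under the null, unbiased recovery of a planted
β12, enumeration and determinism contracts) — not robustness to the
confounding structure of real cohorts, where LD will smear an interaction
signal across nearby pairs.

## Problem sizes used in the checks

The self-contained checks run at desk scale, chosen to keep each property
statistically sharp: null calibration uses 2,000 replicates of 200 cases +
200 controls at MAF 0.3 (the α = 0.05 rejection rate is required within 3
binomial standard errors, ±0.0146); parameter recovery uses 20 seeds of
1,000 + 1,000 individuals with planted β12 ∈ {0.5, 1.0}; the ranking check
scans 50-SNP datasets (1,225 pairs) with one planted pair at β12 = 1.0 —
the weaker 0.5 effect is checked for unbiased estimation only, since
ranking first among 1,224 null pairs is not a reliable event at that effect
size and n. Enumeration completeness is verified exhaustively against
brute-force all-pairs sets for M ≤ 200, and at genome scale (M = 500,000,
~1.25 × 10¹¹ pairs) by block arithmetic alone.

## Design choices that were genuinely open

* **Threshold strictness**: the output filter is inclusive (p ≤ threshold);
  the MAF filter is strict (>). Both are documented contracts here, not
  claims about the original tool's behavior.
* **Canonical file dialect**: no layout is standard for this kind of tool,
  so the package defines one (header `PHENO` + SNP ids; one row per
  individual; `NA` for missing) plus a transposed variant with a separate
  phenotype file and an optional 1/2 phenotype recode, giving converters a
  concrete target. Genotype values are trusted as minor-allele counts; the
  converter never re-folds columns.
* **Deterministic merge instead of split-and-concatenate**: the original
  multi-worker scheme split input files and concatenated outputs; here
  batches are pure functions merged in canonical order, which upgrades
  parallel runs from "same set of results" to "byte-identical file".
* **Retrospective sampling by rejection** rather than deriving
  case-conditional genotype distributions: exact, simple, and fast at desk
  scale; the feasibility guard bounds the cost for pathological effect
  configurations.

## Known limitations

Pairs are fitted one at a time in Python/NumPy; the package targets
correctness, determinism and desk-scale studies (10³–10⁴ SNPs), not
genome-wide throughput. No covariates, no dominance/recessive codings, no
Wald or score alternatives, no Firth correction under separation, no LD
pruning, and no binary container formats (text layouts only).
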