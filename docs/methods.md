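# Methods

## The shadow model

A sample is a multiset of equal-length reads. For a sequence *t*, the
observed count splits as r_t = n_t + e_t into error-free and erroneous
copies; neither term is observable directly. The working assumptions are
(i) the top-N most frequent sequences of a sample (N = 1000 by default)
are error free, and (ii) a read within two substitutions of an error-free
sequence is a *shadow* — an error-bearing copy of it. Shadow counts s_t
then proxy e_t, and the (n_t, s_t) pairs drive all estimation. Reads that
differ by more than two bases (extensive polymorphism, isoforms, unrelated
transcripts) are deliberately not counted as shadows, which is what makes
the approach reference free.

Shadow attribution is ambiguous when a read is within distance two of
several anchors. The package assigns each distinct read to exactly one
error-free sequence — nearest, then highest count, then lexicographic —
so no multiplicity is counted twice and Σs is never inflated; counting a
read toward every nearby anchor is available behind
`assign_shadows(..., unique_assignment=False)`. Positions holding `N`
count as mismatches everywhere, and sequences containing `N` can be
shadows but never anchors (an uncalled base cannot anchor mismatch
counting). Only substitutions are modeled; an indel shifts every
downstream base and simply fails the distance filter.

The implementation compares every distinct read against all N anchors in
vectorized byte arithmetic, O(D·N·L) for D distinct reads of length L; a
brute-force all-pairs scan is kept in the test suite as the oracle and the
two agree exactly on randomized instances.

## Estimators

**SRER.** s = α + βn + ε fitted by Huber M-estimation (tuning constant
1.345, MAD scale, iterated to relative coefficient change < 1e-8 or 100
iterations; statsmodels RLM underneath). The rate is β/(1+β), with β
clamped at 0 since a rate cannot be negative. Noiseless collinear input
short-circuits to the exact least-squares line, which is a fixed point of
the reweighting that IRLS itself cannot reach when the scale estimate
collapses to zero.

**Smoothing spline.** The curve Ŝ minimizes
Σ (s_i − Ŝ(n_i))² + λ ∫ Ŝ″(n)² dn over twice continuously differentiable
functions; the minimizer is a natural cubic spline with knots at the
distinct n_i. The solver is the classic Reinsch banded algorithm for the
weighted problem: with Q the second-difference matrix and R the penalty
Gram matrix, solve (R + λ QᵀW⁻¹Q) γ = Qᵀy (pentadiagonal, SPD) and set
f = y − λW⁻¹Qγ. This formulation is exact in both limits — λ → 0
interpolates, λ → ∞ yields the weighted least-squares line to machine
precision — which generic smoothing-spline routines do not guarantee
numerically; an LU fallback covers penalty/spacing ratios extreme enough
to defeat the Cholesky factorization. Ties in n are collapsed to their
(weighted) mean with summed weights, which leaves the criterion unchanged.
Off-knot evaluation and derivatives come from the natural cubic
interpolant of the fitted values, which is the minimizer itself.

λ = "auto" (the default) minimizes the generalized cross-validation score
GCV(λ) = (RSS_w/m) / (1 − tr(H)/m)², with the hat-matrix trace computed
exactly as tr(H) = 2 + tr(A⁻¹R) via the Takahashi band-inverse recursion
(O(m) per λ), over a log grid spanning 1e-8–1e2 times ptp(n)³ with a
bounded local refinement. λ has units shadows²·reads³ and is reported in
every fit summary.

**Robust spline.** Iteratively reweighted: w_i = 1/max(|s_i − Ŝ(n_i)|, δ)
with floor δ = 1e-6 × (max s − min s) (or 1e-6 for constant s), iterated
until the fitted values move by less than 1e-6 relative or 50 iterations.
When λ is "auto" it is selected by GCV on the initial equal-weight fit and
held fixed through the reweighting; re-selecting per iteration would
couple the penalty to the weights and triples the cost for no observed
benefit. The 1/|residual| weights make small oscillations between nearby
fits common on noisy data; non-convergence within 50 iterations is
reported as a flag and the last iterate returned, which in practice is
already stable to ~1e-4.

**Per-read and sample-level error rates.** ER(x) is the cumulative ratio
of fitted shadows (clamped at 0 — a fitted count cannot be negative) to
fitted shadows plus error-free counts over observations with n_j ≤ x; as a
ratio of non-negative cumulative sums with n_j ≥ 1 it always lies in
[0, 1). Evaluation at a sampled x uses the cumulative sums over observed
points, not spline evaluation at unobserved abscissae, because the
defining sums index observed sequences. The sample EER is the median
(midpoint convention) of ER at 1000 counts drawn uniformly from the
integers in [n₁, n_m]; drawing from the observed counts instead is
available via `scheme="observed"`. Ties in n stay separate cumulative
terms. The cubic and robust EERs reuse the same draws so their comparison
is paired.

## Frequency-based simulator

Given a sample's pairs, read counts are binned at empirical quantiles (20
bins by default — unequal widths keep sparse high-count bins populated)
and shadow counts within each read bin into 30 equal-width bins. The exact
bin counts and edge placements behind published applications of this
design are not available, so results carry binning sensitivity; both knobs
are exposed (`read_edges`, `shadow_bins`). Bins are half-open [lo, hi)
with the final bin closed. Sampling draws U, V ~ uniform(0,1): U selects
the read bin through the p_j CDF and n uniformly within it, V the shadow
bin through q_kj and s within it. Draws are continuous by default (the
downstream fits are indifferent); `integer=True` rounds for count realism.
When every shadow count in a read bin is identical, the equal-width bins
would have zero width; the bin is made effectively atomic (width 1e-9) so
draws reproduce the constant. The model's analytic expected error rate —
cell-midpoint E[s]/(E[s]+E[n]) — is the infinite-sample limit of
Σs/(Σs+Σn) over draws and serves as the fidelity oracle.

## Calibration simulator

`inject_errors` flips each base of each read copy independently with its
positional probability, replacing it uniformly by one of the three
alternatives (no confusion matrix is assumed); total read count is
conserved. `estimate_base_profile` inverts this against a small reference
(PhiX-scale, ≤ ~1e6 bases): each distinct read anchors at its unique
mismatch-minimal placement (exact matches via a window dictionary, the
rest by a blocked all-offsets scan); reads without a unique minimal
placement are skipped and counted. Alignment to large genomes is out of
scope — pre-tallied per-position mismatch counts can be supplied as a TSV
profile instead.

Polymorphism and duplication perturbations probe robustness to
sample–reference divergence. The densities (1 substitution per 1000 bp, 2
tandem base duplications per 1000 bp) are applied over the pooled bases of
the input: k = round(total_bases × rate) sites drawn without replacement,
so a single 1000-base sequence receives exactly 1 (resp. 2) sites and read
sets shorter than 1000 bp per read are still perturbed at the stated
density. Duplication is tandem and in place, truncating back to the
original length to preserve fixed read length; the mechanics beyond the
density are this package's choice.

## Replicated studies

`run_simulation_study` draws `pairs_per_rep` pairs per replicate from a
frequency model, estimates expected ER, SRER, EER_CS and EER_RS, and
reports medians and absolute biases |median estimate − median expected
ER|. Replicate seeds are spawned from the master seed (`SeedSequence`), so
the study is bit-reproducible and any replicate can be re-run alone.
Replicates whose estimator fails (e.g. spline degeneracy when the draws
collapse onto fewer than 4 distinct counts) are excluded and counted in
the summary. Interquartile ranges are reported alongside the medians as a
labeled extra for diagnostics. The reference protocol is 1000 replicates
of 1000 pairs; the bundled tests run 200 replicates, which already pins
the medians to ±0.01.

## Synthetic fixtures

`generate_sample` emulates the structure the estimators face: source
sequences are windows of a random reference, multiplicities follow a
power-law abundance (exponent 0.5 over 1200 sources at 100k reads in the
full-scale fixture — skewed enough that the top-1000 counts sit well above
any error mutant's), and substitution errors are injected per position.
Every fixture carries machine-readable truth (parent and error flag per
read), so the pipeline's Σs/(Σs+Σn) is validated against the true error
fraction among top-anchored reads. What the fixtures do **not** emulate:
quality-score structure, platform-specific error spectra, indels,
GC-coverage bias, and reads sharing k-mers through real transcript
homology. Passing tests therefore demonstrate correctness of the
machinery and of parameter recovery under the stated generative model,
not calibration on any particular instrument's data.

`generate_linear_pairs` and `generate_nonlinear_pairs` produce pair sets
with known truth for the estimator tests; the nonlinear shape library
covers monotone-saturating, linear and locally-decreasing (shadows falling
with rising counts at low n, as mRNA-seq samples show) forms, each
returned together with its generating function.

## Numerical choices and degenerate inputs

- Ranking ties (equal counts) break lexicographically, so error-free
  selection is deterministic across platforms.
- The linear fit requires ≥ 3 observations and a non-degenerate design;
  the splines require ≥ 4 distinct n (fewer raises with a pointer to the
  linear model).
- Negative fitted shadow counts are clamped to zero inside ER; a negative
  regression slope clamps SRER to zero.
- GCV scores that fail to factorize at extreme λ are treated as +∞ rather
  than aborting the search.
- An all-zero shadow vector yields zero for every estimator (the
  error-free sample case).

## Known limitations

- The error-free assumption fails for samples whose true abundance
  distribution is flat: if the top-N counts are not well separated from
  error multiplicities, anchors are contaminated.
- Distance-2 shadows under-count reads with ≥ 3 substitution errors; at
  per-base rates ≲ 0.01 and L = 36 this is negligible, at higher rates it
  biases estimates downward.
- Outlier pre-screening of the pairs (boxplot rule and similar) is left to
  the caller; the robust spline mitigates but does not replace it.
- Estimates are point estimates; no confidence intervals are provided.
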