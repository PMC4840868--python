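# shadowspline

Reference-free estimation of substitution error rates in short-read
next-generation sequencing data, from the relationship between read counts
and *shadow* counts.

## The problem and the approach

High-throughput short-read sequencing has per-read error rates high enough
to matter for downstream analysis, yet estimating them usually requires
alignment to a trusted reference genome. The shadow approach needs none:
in a sample of equal-length reads, the most frequent distinct sequences
are presumed error free, and a **shadow** of such a sequence *t* is any
other read within two substitutions of it. Writing *n<sub>t</sub>* for the
count of the error-free sequence and *s<sub>t</sub>* for its shadow count,
sequencing errors make shadows accumulate as reads accumulate, so the
pairs (*n<sub>t</sub>*, *s<sub>t</sub>*) carry the error signal.

Two estimators are implemented on these pairs:

* **SRER** (shadow-regression error rate). Robust (Huber) linear
  regression of *s* on *n*, *s = α + βn + ε*, gives the per-read error
  rate **ER = β / (1 + β)**. This presumes the read–shadow relationship is
  linear, which holds for clean DNA samples (e.g. PhiX) but fails for many
  mRNA-seq and resequencing samples.
* **EER** (empirical error rate). A natural cubic smoothing spline
  *Ŝ(n)* minimizing

  Σᵢ (sᵢ − Ŝ(nᵢ))² + λ ∫ Ŝ″(n)² dn

  replaces the line (EER_CS), optionally with iterative reweighting by
  1/|residual| for robustness (EER_RS). The per-read error rate at count
  *x* is the cumulative ratio

  ER(x) = Σ_{nⱼ ≤ x} Ŝⱼ / ( Σ_{nⱼ ≤ x} Ŝⱼ + Σ_{nⱼ ≤ x} nⱼ ),

  and the sample-level EER is the median of ER over 1000 counts drawn
  uniformly from [n₁, n_m]. This drops the linearity assumption and lets
  the error rate vary with read count.

Two simulators support method evaluation: a **frequency-based simulator**
that bins a sample's (n, s) pairs into a joint distribution (unequal-width
read bins, equal-width shadow bins per read bin) and resamples pairs by a
two-uniform inverse-CDF scheme, reproducing non-linear read–shadow
structure; and a **calibration simulator** that injects per-position
substitution errors into presumed error-free reads (with optional
polymorphism and tandem-duplication perturbations of the truth), with the
per-position profile estimable from reads anchored on a small reference.

## Worked example

```python
import shadowspline as ss

# synthetic pairs with a linear read-shadow relationship, slope 0.25
pairs = ss.generate_linear_pairs(slope=0.25, intercept=2.0, noise=5.0, m=1000, seed=1)
results = ss.ShadowErrorModel(pairs).fit(seed=1)
print(results.summary())
```

```
Shadow error-rate estimates
===========================
observations (m):           1000
count range [n_1, n_m]:     [120, 9991]

SRER   (robust linear):     0.2000
EER_CS (cubic spline):      0.2004
EER_RS (robust spline):     0.2005
expected ER (sum s/(s+n)):  0.2002

linear fit: intercept=1.957 slope=0.25 converged=True
cubic spline:  lambda=9.603e+13 (GCV)
robust spline: lambda=9.603e+13 (GCV), 28 reweighting iterations, converged=True

absolute biases vs expected ER: srer=0.0002, eer_cs=0.0002, eer_rs=0.0002
```

With a true slope of 0.25 the true error rate is 0.25/1.25 = 0.2; all
three estimators recover it, and in this linear regime the spline-based
EERs agree with SRER — the regimes where they diverge are non-linear
read–shadow relationships, where the splines track the data and the line
cannot.

Starting from a FASTQ file instead:

```python
results = ss.ShadowErrorModel.from_fastq("sample.fastq").fit(seed=1)
```

or from the shell:

```sh
shadowspline count   --fastq sample.fastq --out counts.tsv
shadowspline shadows --counts counts.tsv --top-n 1000 --max-mismatch 2 --out pairs.tsv
shadowspline estimate --pairs pairs.tsv --seed 17 --out estimate.json
shadowspline study   --counts counts.tsv --replicates 1000 --pairs-per-rep 1000 \
                     --seed 17 --out summary.json
```

`study` runs the replicated evaluation protocol: fit the frequency model
to the sample's pairs, then per replicate draw 1000 pairs, estimate SRER /
EER_CS / EER_RS, and report medians with absolute biases against the
median expected error rate Σs/(Σs+Σn).

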