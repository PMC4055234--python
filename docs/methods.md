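# Methods

## The estimation problem

A bi-allelic structural variant is observed in each of N individuals as a
pair of counts: `l` observations of the reference allele and `k − l` of the
alternative allele (split reads or paired ends mapping specifically to one
allele; possibly fractional "effective" counts after per-observation quality
weighting). Genotypes are latent. Three nuisance parameters describe the
observation process:

* **λ** — the odds of drawing the reference allele in a single observation
  from a diploid heterozygote. λ = 1 is unbiased; structural variants
  observed through read mapping commonly have λ between ~0.002 and ~10⁴,
  or effectively infinite, because the two alleles are not equally
  detectable.
* **ε_r, ε_a** — the frequencies of erroneous counts among reference- and
  alternative-labelled counts. They are conditional error frequencies, not
  flip probabilities; both must be < 0.5 (errors are a minority) for the
  model to be identifiable.

Genotype likelihoods are the products over counts given in the README. They
are implemented exactly in that printed form. One consequence worth noting:
for λ ≠ 1 and ε_r ≠ ε_a, the per-count label law implied by the heterozygote
expression is not normalized — the expressions treat ε_r and ε_a as
conditional error frequencies attached to each label. We keep the printed
form; the asymmetric-error heterozygote has no stated generative law, and at
realistic error magnitudes (≤ 0.01) the discrepancy is far below sampling
noise.

All likelihood work is done in log space with the 0·log 0 = 0 convention
(empty products are 1; a zero base with a positive exponent is −∞). ε = 0
exactly is allowed, matching the common practice of near-zero error rates.
λ must be finite; effectively infinite bias should be passed as a large
number such as 1e6 — at low coverage all sufficiently extreme odds produce
the same data (the disfavoured allele is simply never seen), so the choice
of the large value is immaterial.

## EM algorithm

Genotypes are treated as missing data. The E step converts current
parameters into per-individual genotype posteriors and accumulates the
expected genotype memberships (D_g for diploids, H_g for hemizygotes) and
the expected count masses per genotype class (R0/R2 and A0/A2 for
reference/alternative counts in the homozygous-or-hemizygous classes, C1r
and C1a in diploid heterozygotes). The M step is closed-form for the
frequencies:

* HWE: ψ' = (2D₀ + D₁ + H₀) / (2(D₀+D₁+D₂) + H₀ + H₁)
* free: ψ_g' = D_g / D and φ_g' = H_g / H

For the error rates, the ε-dependent part of the expected complete-data
log-likelihood separates into two concave one-dimensional objectives,

    Q_r(x) = R0·log x + C1r·log(x + λ(1−x)) + R2·log(1−x)
    Q_a(x) = A2·log x + C1a·log((1−x) + λx) + A0·log(1−x),

each a sum of logs of affine functions, hence concave and unimodal on
[0, 0.5). Setting the derivative to zero gives a quadratic, solved
analytically; at λ = 1 the middle term is constant and the update reduces to
the closed forms R0/(R0+R2) and A2/(A0+A2). The derivative at the upper
bound detects maximizers at or beyond 0.5: estimation then stops with a
`halted_eps` flag, and the last valid estimates are reported (flagged
unreliable) rather than discarded — the model cannot distinguish "mostly
errors" from a label swap, so no better answer exists. The analytic solver
is contract-tested against a dense (1e-7 step) grid search of Q to 1e-6.

### Numerical choices and defaults

* Initialization: ψ⁽⁰⁾ = 0.5; free mode starts at (¼, ½, ¼) and (½, ½).
  Interior starts avoid the absorbing boundary; on realistic data the fixed
  point is unique, verified by grid-search oracle tests on small tables.
* Convergence: |Δℓ| < 1e-8 on the observed-data log-likelihood, max 10 000
  iterations. If ψ̂ reaches exactly 0 or 1 iteration stops (the boundary is
  absorbing under the updates).
* Samples with k = 0 are retained: they contribute only prior information,
  and the free-mode denominators D and H are defined over all individuals.
* EM ascent is asserted to 1e-9 per iteration across the test conditions.
* Co-estimating ε with mean coverage < 4 or fewer than 100 individuals
  triggers a warning: with so little information the errors and the
  frequency are weakly separable, and a-priori error values are preferable.

## Outputs

Posteriors are P(g|data) ∝ L(g)·prior(g) with the HWE prior (ψ̂², 2ψ̂(1−ψ̂),
(1−ψ̂)²) over g = (0, 1, 2) reference alleles — ψ is the *alternative*
allele frequency — or the free ψ̂_g/φ̂_g. Maximum-posterior genotype calls
break ties toward the heterozygote, then toward lower g; the heterozygote
preference minimizes the expected allele-count error of the call.

Derived statistics: heterozygosity is read directly off ψ̂₁ from a free fit
(a contract error under HWE, where it is 2ψ̂(1−ψ̂) by construction);
F̂ = 1 − ψ̂₁/(2ψ̂(1−ψ̂)), undefined at fixation. For F_ST we use the
Hudson-type two-population single-locus estimator

    F̂ST = [(p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)] / [p₁(1−p₂) + p₂(1−p₁)]

with n₁, n₂ chromosomes sampled; several variants circulate under this name
and the choice among them is ours, documented here and oracle-tested by
direct arithmetic.

Likelihood-ratio tests compare 2(ℓ₁ − ℓ₀) with a χ² distribution. The HWE
test fits both modes with identical λ/ε handling; df = 1 for all-diploid
tables, 2 when hemizygous frequencies are also estimated. An all-hemizygous
table gives df = 0 (the free model has the same dimension as the null), so
the test is refused as undefined. The two-population test runs three HWE
fits (each sample, then pooled); λ and ε are fixed and shared — co-estimating
them per population would change the df, so it is rejected rather than
silently miscounted. Tiny negative statistics (within 1e-6) from the finite
EM tolerance on nested fits are clamped to zero.

## Obtaining λ

λ is a property of the detection pipeline, best measured by remapping reads
from both alleles. When that is not available:

* `lambda_from_known_hets`: the pooled reference/alternative count ratio
  over individuals known heterozygous by external evidence (PCR, high
  coverage). A pooled alternative count of zero signals effectively
  infinite bias.
* `lambda_from_size`: log-log regressions of λ on variant length fitted on
  a large panel of real deletions (log λ = −4.22 + 0.94·log size) and
  insertions (log λ = 3.84 − 0.87·log size) detected with 100 bp single-end
  reads; for inversions λ = 1 is a fair default. The natural-log convention
  is assumed (the source regressions state only "logarithmic scales"); since
  values within a factor of ~2 of the truth yield small biases, the base
  ambiguity is tolerable for a first approximation, and the function warns
  that the value is rough.

## Synthetic data

The generator draws, per individual: a genotype from HWE at frequency ψ (or
from explicit genotype frequencies), a total count k ~ Poisson(mean
coverage), true alleles per count (reference with probability 1, 0, or
λ/(1+λ) for a diploid heterozygote), and an independent symmetric label
flip with probability `flip_error` (default 0.005). Under symmetric flips
the likelihood model with ε_r = ε_a = flip rate is exactly the per-count
sampling law, so estimator calibration can be checked against a correctly
specified model. Asymmetric error generation is deliberately not offered:
the likelihood's ε parameters are conditional frequencies, and no generative
law for the asymmetric case is defined.

What the generator does **not** emulate: read-level artifacts (mapping
quality, duplicated reads), coverage heterogeneity beyond Poisson,
between-site linkage, population structure within a sample, and
count-producing pipelines themselves. Passing tests therefore validate the
estimator under its own sampling assumptions, not any particular upstream
caller.

## Validation results and problem sizes

The statistical suite (tests/test_acceptance.py) regenerates everything it
checks; sizes were chosen to keep the full suite around a minute while
leaving Monte-Carlo error well below each tolerance:

* Genotyping-error ceiling: 5000 diploids at ψ = 0.5, coverage 1,
  true-parameter posteriors → mismatch ≈ 42%, below the 50% ceiling that
  holds even with perfect parameter knowledge in this regime.
* Unbiasedness: ψ ∈ {0.01, 0.05, 0.2, 0.5} × coverage {0.2, 1, 2, 4},
  100 replicates of n = 100 each; mean ψ̂ within 2 SE of truth everywhere
  except the known failure zone (ψ ≤ 0.01 with coverage < 0.5, where the
  boundary at 0 biases the estimate).
* λ misspecification: with λ̂ = λ the estimates are unbiased at
  λ ∈ {0.01, 1, 100}. With λ̂ off by a factor of two the bias depends
  strongly on λ: negligible (< 0.01) at extreme λ, but up to ≈ 0.05 in
  allele frequency at λ = 1 and intermediate ψ — confirmed by an
  implementation-independent computation of the argmax of the expected
  model log-likelihood under the generating law. "Minor" bias under
  twofold misspecification should be read as a few hundredths, not as
  arbitrarily small; the corresponding acceptance check encodes a tighter
  bound (0.02) and is expected to fail for the λ = 1 twofold cases.
* Oracle equivalence: EM ψ̂ matches a 1e-5-step grid search of the observed
  likelihood to 1e-4 on 50 random small tables (run at tol = 1e-12).
* Calibration: 1000 null replicates each (n = 100, coverage 4) put the
  empirical type-I error of both tests within 3 binomial SE of α = 0.05.

Stochastic tests use fixed `SeedSequence` derivations, so results are
reproducible run to run.

## Known limitations

* One variant, one fit: no joint multi-site model, no linkage
  disequilibrium, no multi-allelic variants, no per-observation qualities
  beyond the two average error frequencies.
* λ is not estimated within the fit (deliberately, to save degrees of
  freedom); a badly wrong λ near 1 biases both frequencies and genotype
  calls, and the direction of the error matters more than its magnitude.
* Free-mode estimates need mean coverage above ~2 to be stable; the HWE
  test inherits that requirement through its alternative fit.
* When error co-estimation halts at ε ≥ 0.5 the reported estimates are the
  last valid iterates and should not be trusted; extreme allele frequencies
  with substantial error rates are genuinely unidentifiable in this model.
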