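# countem

Population-genetic analysis of **bi-allelic structural variants** (deletions,
insertions, inversions, translocations) from low-coverage sequencing data,
**without calling genotypes first**.

Structural variants detected from split reads or paired ends are genotyped by
counting, per individual, how many sequencing observations support the
reference allele (`l`) and how many support the alternative allele (`k − l`).
At low coverage these counts rarely determine a genotype — and unlike SNPs,
the two alleles of a heterozygote are usually **not** sampled with equal
probability: conservative read mapping and asymmetric allele detectability
make the reference allele over- or under-represented by orders of magnitude.
`countem` models that allele-sampling bias explicitly with one parameter, λ
(the odds of drawing the reference allele from a diploid heterozygote), and
estimates population quantities by maximum likelihood directly from the
counts.

## Model

For an individual of ploidy *m* ∈ {1, 2}, genotype *g* = number of reference
alleles, with error frequencies ε<sub>r</sub> (among reference counts) and
ε<sub>a</sub> (among alternative counts), the genotype likelihoods are

    L(0) = ε_r^l (1 − ε_a)^(k−l)
    L(1) = (1/(1+λ))^k (ε_r + λ(1 − ε_r))^l ((1 − ε_a) + λ ε_a)^(k−l)    (diploid het)
    L(2) = (1 − ε_r)^l ε_a^(k−l)

(hemizygous genotypes reuse the homozygous forms). Treating genotypes as
missing data, an **expectation-maximization** algorithm estimates either the
alternative-allele frequency ψ under Hardy-Weinberg equilibrium (HWE), or
free genotype frequencies ψ<sub>g</sub> (diploids) and φ<sub>g</sub>
(hemizygotes), optionally co-estimating ε<sub>r</sub> and ε<sub>a</sub>.
From the fits you get genotype posterior probabilities
P(g|data) ∝ L(g)·P(g|ψ̂), direct heterozygosity ψ̂₁, the inbreeding
coefficient F̂ = 1 − ψ̂₁/(2ψ̂(1−ψ̂)), Hudson's F<sub>ST</sub>, and two
likelihood-ratio tests: HWE (χ², 1 df for diploid tables, 2 df with
hemizygotes) and equality of allele frequencies between two samples (1 df).

## Worked example

Input is a plain text table — sample id, reference count, alternative count,
optional ploidy (default 2); counts may be fractional "effective" counts:

```sh
countem simulate --n 100 --psi 0.3 --mean-coverage 4 --seed 1 --out demo.txt
countem fit demo.txt --lam 1 --eps-ref 0.005 --eps-alt 0.005
cut -f1-2,10 demo.txt.estimates.tsv
```

prints

```
#mode	psi	loglik
HWE	0.327479522	-198.8444535
```

i.e. the maximum-likelihood alternative-allele frequency is ψ̂ ≈ 0.327 for
data simulated at ψ = 0.3 (the truth is well inside the sampling error of
200 chromosomes), with the observed-data log-likelihood at the optimum.
`demo.txt.samples.tsv` lists, per individual, the genotype log-likelihoods,
posterior probabilities, and the maximum-posterior genotype call. The same
workflow is available in Python:

```python
from countem import EMConfig, ErrorRates, SimConfig, run_em, simulate_counts

truth = simulate_counts(SimConfig(n=100, psi=0.3, mean_coverage=4.0, seed=1))
fit = run_em(truth.table, EMConfig(err=ErrorRates(0.005, 0.005)))
print(fit.psi)            # 0.32747952201750813
```

Other subcommands: `countem test-hwe`, `countem test-diff`,
`countem bias` (λ from size regressions or from known heterozygotes).

λ must be supplied, not estimated from the fit; rough values are usable — a
value within a factor of two of the truth shifts frequency estimates by at
most a few hundredths — and extreme bias just needs any similarly extreme
value.

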