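# Methods

## Model

A cohort of `n` cancer patients is sampled from a population in which a
chromosomal segment containing a biallelic locus (alleles A/a) has been
duplicated, so every subject is triploid at that locus.  The observable
genotype classes are indexed `k = 1..4` for AAA, AAa, Aaa, aaa.

### Genotype frequencies

Genotype frequencies are parameterised by the A-allele frequency `p`
(`q = 1 - p`) and two Hardy-Weinberg disequilibrium (HWD) coefficients
attached to the homozygous classes:

```
P1 = p^3 + D1                 P2 = 3 p^2 q - 2 D1 + D2
P3 = 3 p q^2 + D1 - 2 D2      P4 = q^3 + D2
```

The `P2`/`P3` terms are the unique closure that preserves both
`sum(P) = 1` and allele-counting consistency `(3 P1 + 2 P2 + P3)/3 = p`.
With three free parameters against three multinomial degrees of freedom
the model is saturated; the maximum-likelihood estimates have closed form
(`p` by allele counting, `D1 = P1_hat - p_hat^3`, `D2 = P4_hat - q_hat^3`)
and the EM iteration shares that fixed point exactly — the package
provides both and tests their agreement.  Estimates are clipped to the
valid frequency region, with clipping flagged in the result.

The forward duplication model (`duplicate_population`) makes the origin of
the disequilibrium concrete: duplicating proportions `g` of A alleles and
`h` of a alleles in an equilibrium diploid pool and conditioning on the
triploid fraction yields genotype frequencies that generically carry
`D1, D2 != 0`.  For `g + h > 1` the two rates are interpreted as relative
duplication propensities; the conditional triploid distribution remains
well defined (and reproduces the balanced-duplication benchmark
`(1/6, 1/3, 1/3, 1/6)` at `p = 0.5, g = h = 1`).

### Configurations and genetic effects

Each genotype hides two parent-of-origin configurations (`j = 1` maternal
duplication, `j = 2` paternal) with mixture weights `(u, 1-u)` for the
A-duplication genotypes (AAA, AAa) and `(v, 1-v)` for the a-duplication
genotypes (Aaa, aaa).  The eight cell means `mu_kj` decompose through an
invertible 8x8 linear design into the overall mean `mu`, additive effect
`a`, dominance effects `d` (AA over a) and `d'` (A over aa), imprinting
effect `lambda`, and interactions `I_a`, `I_d`, `I_d'`:

```
mu_11 = mu + a  + lambda + I_a      mu_12 = mu + a  - lambda - I_a
mu_21 = mu + d  + lambda + I_d      mu_22 = mu + d  - lambda - I_d
mu_31 = mu + d' + lambda + I_d'     mu_32 = mu + d' - lambda - I_d'
mu_41 = mu - a  + lambda            mu_42 = mu - a  - lambda
```

Pair sums identify `mu`, `a`, `d`, `d'`; parent-of-origin half-differences
carry `lambda` plus one interaction each, and the aaa half-difference
identifies `lambda` alone.  `means_to_effects` is the exact inverse and
round-trips to machine precision.

### Phenotype likelihood and EM

The phenotype within genotype `k` is a two-component normal mixture with
means `mu_k1, mu_k2`, shared variance `sigma^2`, and weights tied across
genotypes through `(u, v)`.  The EM algorithm alternates posterior
configuration probabilities (E) with posterior-weighted updates of
`(u, v)`, the cell means, and `sigma^2` (M).  Null fits for
likelihood-ratio tests pin chosen effect coordinates (or a duplication
rate) to fixed values; the constrained mean update is the exact
posterior-weighted least-squares solution in effect space.

Numerical choices:

* initialisation: `u = v = 0.5`, cell means at stratum mean +/- 0.5
  stratum SD (maternal component above — see *Identifiability*),
  `sigma^2` = pooled within-stratum variance;
* five starts, the later four with seeded Gaussian jitter on the starting
  means; each start runs at most 200 burn-in sweeps and only the best is
  polished to convergence (relative log-likelihood change < 1e-8, cap
  2000 sweeps);
* E-step computed in log space, so component underflow cannot produce
  0/0 posteriors; `sigma^2` floored at `1e-12 * var(y)`;
* empty genotype strata keep their initial means (zero posterior weight
  never updates them) and are reported in the fit;
* null fits for LRTs additionally start from the alternative fit projected
  onto the constraint set, and a negative statistic triggers an
  alternative refit from the null solution before clipping at zero.

### Hypothesis tests

* joint HWD (`D1 = D2 = 0`): chi-square, 2 df, closed-form nulls;
* single HWD (`D1 = 0` via `P1 = p^3`, or `D2 = 0` via `P4 = q^3`):
  remaining parameters profiled by Nelder-Mead over the valid frequency
  region, 1 df;
* overall association (all eight means equal): chi-square with 7 df by
  default; a permutation calibration is provided because `(u, v)` are
  unidentified under this null (see *Calibration limits*);
* genetic effects (any nonempty subset of `a, d, d', lambda, I_a, I_d,
  I_d'` fixed to zero): chi-square with df = subset size;
* duplication rates: `u` (or `v`) fixed at 0.5 (no parental bias;
  interior null, chi-square 1 df) or at 1.0 (boundary null; 50:50 mixture
  of a point mass at zero and chi-square-1).  The choice of null value is
  explicit in the API and CLI.

### Simulator and heritability

`simulate_sample` draws genotypes from the multinomial frequencies,
configurations as Bernoulli with maternal probability `u` or `v`, and
phenotypes as the cell mean plus Gaussian noise.  Heritability is
broad-sense: with `Vg` the variance of the cell means over the eight
(genotype, configuration) cells (weights `P_k * pi_kj`), the residual
variance is `sigma^2 = Vg * (1 - H2) / H2`.  Null generators flatten all
means (`no_effect`) or zero the imprinting terms (`no_imprinting`) while
keeping `sigma^2` anchored at the alternative's value so power and
false-positive runs are comparable.

The benchmark scenario used throughout is `p = 0.6, D1 = 0.08, D2 = 0.06,
u = 0.3, v = 0.4`, effects `(a, d, d', lambda, I_a, I_d, I_d') =
(0.8, 0.5, 0.4, 0.5, 0.4, 0.5, 0.3)`, `mu = 0` (the overall mean is a pure
translation and does not affect recovery of the other effects), with
heritabilities 0.05/0.1/0.2 and sample sizes 400/800/2000.  Under it
`Vg = 0.8254`, so `sigma = 1.82` at `H2 = 0.2`.

The study harness replicates each (n, H2) cell with seeds derived from a
master seed via `SeedSequence([master, cell, replicate])`, excludes and
counts failed fits, reports per-cell means, SDs and standard errors of
every parameter (both dispersion measures, since either may be wanted),
and caches per-cell tables as CSV when a cache directory is given.  Default
replicate counts: 200 for studies, with acceptance-level checks sized at
200 (power, recovery) and 500 (null calibration) replicates to balance
Monte-Carlo error against runtime on a single CPU.

## Identifiability and calibration limits

Two structural properties of this model matter for interpretation; both
are measured by the test suite rather than hidden.

**Label flip.**  The likelihood is invariant under
`(u, v, mu_k1, mu_k2) -> (1-u, 1-v, mu_k2, mu_k1)`, which flips the sign
of `lambda` and the interactions but leaves `mu, a, d, d'` and every
likelihood ratio unchanged.  The initialisation places the maternal
component above the stratum mean, selecting the `lambda >= 0` basin when
the data prefer one; at `u ~ v ~ 0.5` a warning flags the residual sign
ambiguity.

**Weak separation of the configuration mixture.**  Under the benchmark
scenario the two configurations of a genotype differ by 0.55-1.1 residual
SDs.  Mixtures this overlapped carry very little Fisher information about
the within-stratum contrast, with three consequences, all quantified on
this package's own simulations:

* the imprinting-side estimates (`lambda`, interactions, and `u`, `v`)
  are noisy and biased at realistic sizes (e.g. mean `lambda`-hat ~ 0.63
  against a generating 0.5 at n = 2000, H2 = 0.2), while `p`, `a`, `d`,
  `d'` are recovered essentially unbiased; under the imprinting null the
  fitted `lambda` drifts well away from zero even though the identified
  mixture-weighted stratum means are recovered;
* the power of the `lambda = 0` likelihood-ratio test at n = 400,
  H2 = 0.2 is ~0.11-0.17 (the asymptotic noncentrality per 400 subjects
  is ~0.05); detecting imprinting at such sizes requires either observed
  parental origins or far larger cohorts;
* the chi-square references for the mixture-based tests are
  anticonservative (the within-stratum split is unidentified under the
  null — a Davies-type nonregularity): measured type-I error at nominal
  0.05 is ~0.15-0.24 for the effect tests and the df = 7 association
  test.  The permutation calibration of the association test is exact by
  construction and is the recommended choice when calibration matters
  more than runtime.  The multinomial HWD tests are regular and calibrate
  at the nominal level.

What passing tests show — and what they do not: the simulator draws from
the model itself, so the suite demonstrates internal consistency
(estimator correctness, EM monotonicity, calibration of the regular
tests, honest measurement of the irregular ones), not robustness to
non-Gaussian phenotypes, genotyping error, covariates, or multi-locus
structure, none of which the generator emulates.

## Known limitations

* Single locus, single duplication event, triploid only; tetraploid and
  higher-order aneuploidy, multi-locus association/epistasis and
  non-genetic covariates are out of scope.
* No standard errors from the information matrix; uncertainty is
  Monte-Carlo based via the study harness.
* `g` and `h` of the forward duplication model are not estimable from
  triploid-only genotype counts (the four counts carry three degrees of
  freedom, already spent on `p, D1, D2`); the package does not attempt it.
* File formats are deliberately minimal (header-checked TSV in, flat
  key-value text out); no VCF/PLINK ingestion.
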